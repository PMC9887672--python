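"""Experiment manifests: which recordings belong to which compound/tissue/dose.

A manifest is a YAML document::

    dose_unit: uM            # uM | nM | M, mandatory
    analysis: {...}          # optional AnalysisConfig overrides
    compounds:
      - name: dofetilide
        vehicle: false
        c_max_uM: 0.002
        f_etpc_uM: 0.002
        tissues:
          - id: T1
            baseline: dofetilide_T1_baseline.csv
            doses: {0.001: dofetilide_T1_d0.001.csv, ...}

Paths are resolved relative to the manifest file; doses are converted to
micromolar internally.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import yaml

from .config import AnalysisConfig
from .errors import InputError

UNIT_TO_UM = {"uM": 1.0, "nM": 1e-3, "M": 1e6, "mM": 1e3}


@dataclass
class TissueEntry:
    tissue_id: str
    baseline_path: str
    dose_paths: dict[float, str]  # dose in uM -> path


@dataclass
class CompoundEntry:
    name: str
    vehicle: bool
    tissues: list[TissueEntry]
    c_max_uM: float | None = None
    f_etpc_uM: float | None = None

    @property
    def doses(self) -> list[float]:
        all_doses = sorted({d for t in self.tissues for d in t.dose_paths})
        return all_doses


@dataclass
class RunManifest:
    compounds: list[CompoundEntry]
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    root: str = "."


def _require(mapping: dict, key: str, context: str):
    if key not in mapping:
        raise InputError(f"manifest: missing field {key!r} in {context}")
    return mapping[key]


def load_manifest(path: str | os.PathLike) -> RunManifest:
    try:
        with open(path) as f:
            doc = yaml.safe_load(f)
    except (OSError, yaml.YAMLError) as exc:
        raise InputError(f"cannot read manifest {path}: {exc}") from exc
    if not isinstance(doc, dict):
        raise InputError(f"manifest {path}: top level must be a mapping")
    root = os.path.dirname(os.path.abspath(path))

    unit = _require(doc, "dose_unit", "manifest root")
    if unit not in UNIT_TO_UM:
        raise InputError(
            f"manifest: dose_unit must be one of {sorted(UNIT_TO_UM)}, got {unit!r}"
        )
    factor = UNIT_TO_UM[unit]

    try:
        analysis = AnalysisConfig(**(doc.get("analysis") or {}))
    except TypeError as exc:
        raise InputError(f"manifest: bad analysis config: {exc}") from exc

    compounds = []
    for c in _require(doc, "compounds", "manifest root"):
        name = _require(c, "name", "compound entry")
        tissues = []
        for t in _require(c, "tissues", f"compound {name!r}"):
            tid = _require(t, "id", f"compound {name!r} tissue entry")
            base = _require(t, "baseline", f"tissue {tid!r}")
            base_path = os.path.join(root, base)
            if not os.path.exists(base_path):
                raise InputError(f"manifest: baseline file {base!r} of tissue "
                                 f"{tid!r} does not exist")
            dose_paths = {}
            for dose, rel in (t.get("doses") or {}).items():
                try:
                    dose_um = float(dose) * factor
                except (TypeError, ValueError):
                    raise InputError(
                        f"manifest: unparseable dose {dose!r} for tissue {tid!r}"
                    ) from None
                p = os.path.join(root, rel)
                if not os.path.exists(p):
                    raise InputError(f"manifest: recording {rel!r} for tissue "
                                     f"{tid!r} does not exist")
                dose_paths[dose_um] = p
            tissues.append(TissueEntry(tissue_id=tid, baseline_path=base_path,
                                       dose_paths=dose_paths))
        compounds.append(CompoundEntry(
            name=name, vehicle=bool(c.get("vehicle", False)), tissues=tissues,
            c_max_uM=(None if c.get("c_max_uM") is None else float(c["c_max_uM"])),
            f_etpc_uM=(None if c.get("f_etpc_uM") is None else float(c["f_etpc_uM"])),
        ))
    if not compounds:
        raise InputError("manifest: no compounds listed")
    return RunManifest(compounds=compounds, analysis=analysis, root=root)
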