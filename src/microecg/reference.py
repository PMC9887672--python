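"""The packaged reference panel: published screen calls + FDA-label classes.

The fixture lets the concordance and risk-scoring stages run table-level,
reproducing the published classification metrics without re-recording the
underlying signals.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .dose import CompoundCall, ThresholdCall, DIR_NONE


def load_reference_panel() -> pd.DataFrame:
    with resources.files("microecg.data").joinpath("reference_panel.csv").open() as f:
        df = pd.read_csv(f, comment="#")
    for col in ("vehicle", "qt_label", "tdp_label", "arrhythmia", "cessation"):
        df[col] = df[col].astype(bool)
    return df


def label_table(panel: pd.DataFrame) -> pd.DataFrame:
    """FDA-label ground truth per compound (QT prolongation, TdP, CiPA class)."""
    return panel.set_index("compound")[["qt_label", "tdp_label", "cipa_risk"]]


def calls_from_panel(panel: pd.DataFrame) -> dict[str, CompoundCall]:
    """Build per-compound :class:`CompoundCall` objects from the fixture rows."""
    out: dict[str, CompoundCall] = {}
    for _, row in panel.iterrows():
        calls = {}
        for name in ("LOW", "MID", "HIGH"):
            direction = row[f"{name.lower()}_direction"]
            conc = row[f"{name.lower()}_conc_uM"]
            conc = None if pd.isna(conc) else float(conc)
            c_max = row["c_max_uM"]
            margin = None
            if conc is not None and not pd.isna(c_max) and c_max > 0:
                margin = conc / float(c_max)
            calls[name] = ThresholdCall(
                direction=direction if isinstance(direction, str) else DIR_NONE,
                concentration=conc, margin=margin)

        def _opt(v):
            return None if pd.isna(v) else float(v)

        out[row["compound"]] = CompoundCall(
            compound=row["compound"],
            calls=calls,
            arrhythmia=bool(row["arrhythmia"]),
            arrhythmia_lowest_dose=_opt(row["arrhythmia_lowest_uM"]),
            arrhythmia_tissue_pct=_opt(row["arrhythmia_tissue_pct"]),
            cessation=bool(row["cessation"]),
            cessation_tissue_pct=_opt(row["cessation_tissue_pct"]),
            c_max=_opt(row["c_max_uM"]),
            f_etpc=_opt(row["f_etpc_uM"]),
            max_tested=_opt(row["max_tested_uM"]),
        )
    return out
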