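"""Readers and writers for recordings and analysis artifacts.

Two recording formats are supported:

* delimited text — one header row, a ``time_s`` column and one column per
  channel in microvolts;
* HDF5 — one dataset per channel under ``/signals/<channel>``, with
  ``sampling_rate`` and ``units`` attributes on the ``/signals`` group.

Units must be declared explicitly; a text file whose header does not state
microvolts (``_uV`` suffix) is rejected rather than guessed at.
"""

from __future__ import annotations

import os

import h5py
import numpy as np
import pandas as pd

from .errors import InputError
from .recording import FPRecording

TIME_COLUMN = "time_s"
VOLT_SUFFIX = "_uV"


def write_recording_csv(recording: FPRecording, path: str | os.PathLike) -> None:
    data = {TIME_COLUMN: recording.time}
    for cid, row in zip(recording.channel_ids, recording.samples):
        data[f"{cid}{VOLT_SUFFIX}"] = row
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.6g")


def read_recording_csv(path: str | os.PathLike) -> FPRecording:
    try:
        df = pd.read_csv(path)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise InputError(f"cannot read recording {path}: {exc}") from exc
    if TIME_COLUMN not in df.columns:
        raise InputError(f"{path}: missing required column {TIME_COLUMN!r}")
    volt_cols = [c for c in df.columns if c.endswith(VOLT_SUFFIX)]
    if not volt_cols:
        raise InputError(
            f"{path}: no channel columns with declared microvolt units "
            f"('{VOLT_SUFFIX}' suffix)"
        )
    t = df[TIME_COLUMN].to_numpy(dtype=float)
    if len(t) < 2:
        raise InputError(f"{path}: recording too short")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-3, atol=1e-9) or dt[0] <= 0:
        raise InputError(f"{path}: time column is not uniformly sampled")
    fs = 1.0 / dt[0]
    samples = np.vstack([df[c].to_numpy(dtype=float) for c in volt_cols])
    if np.isnan(samples).any():
        raise InputError(f"{path}: recording contains NaN samples")
    ids = [c[: -len(VOLT_SUFFIX)] for c in volt_cols]
    return FPRecording(samples, sampling_rate=round(fs, 6), channel_ids=ids,
                       metadata={"source": str(path)})


def write_recording_hdf5(recording: FPRecording, path: str | os.PathLike) -> None:
    with h5py.File(path, "w") as f:
        grp = f.create_group("signals")
        grp.attrs["sampling_rate"] = recording.sampling_rate
        grp.attrs["units"] = "uV"
        for cid, row in zip(recording.channel_ids, recording.samples):
            grp.create_dataset(cid, data=row)
        for key, val in recording.metadata.items():
            if isinstance(val, (str, int, float, bool)):
                grp.attrs[f"meta_{key}"] = val


def read_recording_hdf5(path: str | os.PathLike) -> FPRecording:
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise InputError(f"cannot read recording {path}: {exc}") from exc
    with f:
        if "signals" not in f:
            raise InputError(f"{path}: missing /signals group")
        grp = f["signals"]
        if "sampling_rate" not in grp.attrs:
            raise InputError(f"{path}: /signals lacks a sampling_rate attribute")
        if grp.attrs.get("units") != "uV":
            raise InputError(f"{path}: units attribute must declare 'uV'")
        ids = sorted(grp.keys())
        if not ids:
            raise InputError(f"{path}: no channel datasets under /signals")
        samples = np.vstack([grp[c][()] for c in ids])
        meta = {k[5:]: grp.attrs[k] for k in grp.attrs if k.startswith("meta_")}
        return FPRecording(samples, sampling_rate=float(grp.attrs["sampling_rate"]),
                           channel_ids=ids, metadata=meta)


def read_recording(path: str | os.PathLike) -> FPRecording:
    """Dispatch on file extension (.h5/.hdf5 -> HDF5, otherwise delimited text)."""
    if str(path).lower().endswith((".h5", ".hdf5")):
        return read_recording_hdf5(path)
    return read_recording_csv(path)


# ---------------------------------------------------------------------------
# analysis artifacts

BEAT_COLUMNS = ["beat_index", "peak_index", "peak_time_s", "align_offset_depol",
                "align_offset_repol", "bp_s", "fpd_s", "fpd_cf_s", "amp_uV", "flag"]


def write_beat_table(beats: pd.DataFrame, path: str | os.PathLike) -> None:
    cols = [c for c in BEAT_COLUMNS if c in beats.columns]
    beats[cols].to_csv(path, index=False)


def read_beat_table(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"beat_index", "peak_time_s"} - set(df.columns)
    if missing:
        raise InputError(f"{path}: beat table missing columns {sorted(missing)}")
    return df


def write_events(events: list[tuple[float, float]], path: str | os.PathLike,
                 kind: str = "irregular_peak") -> None:
    """Irregular-event file: time_s, amplitude_uV, kind."""
    df = pd.DataFrame(events, columns=["time_s", "amplitude_uV"])
    df["kind"] = kind
    df.to_csv(path, index=False)


def read_manual_annotations(path: str | os.PathLike) -> np.ndarray:
    """Depolarization peak times (s) from a manual-annotation sidecar file.

    The sidecar carries one ``peak_time_s`` column and overrides the
    automatic beat detection for recordings the software could not analyze.
    """
    df = pd.read_csv(path)
    if "peak_time_s" not in df.columns:
        raise InputError(f"{path}: annotation file needs a peak_time_s column")
    times = np.sort(df["peak_time_s"].to_numpy(dtype=float))
    if np.isnan(times).any():
        raise InputError(f"{path}: annotation times contain NaN")
    return times
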