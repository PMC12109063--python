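"""Reading and writing traces, SMFDR models, and trajectory tables.

Delimited-text traces carry two columns (time_s, value_V) with a header
line and '.' decimal separator; lines starting with '#' hold provenance and
are skipped on read. EDF recordings are read through MNE.
"""

from __future__ import annotations

import json
from importlib import metadata
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError
from .fatigue import SMFDR, FatigueEstimate, LinearFit
from .trace import SignalTrace

#: maximum relative jitter tolerated in a CSV time column
_MAX_JITTER = 1e-6


def package_version() -> str:
    try:
        return metadata.version("emgfatigue")
    except metadata.PackageNotFoundError:  # pragma: no cover - editable quirk
        return "unknown"


def _provenance_lines(config: dict | None) -> list[str]:
    lines = [f"# emgfatigue version: {package_version()}"]
    for key, val in sorted((config or {}).items()):
        lines.append(f"# {key}: {val}")
    return lines


def read_trace(
    path: str | Path,
    format: str = "auto",
    column: str = "value_V",
    sampling_rate: float | None = None,
    channel: int = 0,
) -> SignalTrace:
    """Read a single-channel trace from CSV or EDF.

    For CSV the sampling rate is taken from `sampling_rate` or derived from
    the ``time_s`` column, which must be uniform to within 1 ppm. NaN rows
    are rejected with the offending row named.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    fmt = format
    if fmt == "auto":
        fmt = "edf" if path.suffix.lower() == ".edf" else "csv"
    if fmt == "edf":
        return _read_edf(path, channel)
    return _read_csv(path, column, sampling_rate)


def _read_csv(path: Path, column: str, sampling_rate: float | None) -> SignalTrace:
    df = pd.read_csv(path, comment="#")
    if column not in df.columns:
        raise InputError(f"{path}: missing column {column!r} (have {list(df.columns)})")
    values = df[column].to_numpy(dtype=float)
    bad = np.flatnonzero(~np.isfinite(values))
    if bad.size:
        raise InputError(f"{path}: non-finite value in column {column!r} at data row {bad[0]}")

    t0 = 0.0
    if "time_s" in df.columns:
        t = df["time_s"].to_numpy(dtype=float)
        if np.any(~np.isfinite(t)):
            row = int(np.flatnonzero(~np.isfinite(t))[0])
            raise InputError(f"{path}: non-finite time at data row {row}")
        dt = np.diff(t)
        if dt.size == 0 or np.any(dt <= 0):
            raise InputError(f"{path}: time column must be strictly increasing")
        mean_dt = float(np.mean(dt))
        if np.max(np.abs(dt - mean_dt)) > _MAX_JITTER * mean_dt + 1e-12:
            raise InputError(f"{path}: non-uniform time steps (> 1 ppm jitter)")
        derived_fs = 1.0 / mean_dt
        t0 = float(t[0])
        if sampling_rate is None:
            sampling_rate = derived_fs
    elif sampling_rate is None:
        raise InputError(f"{path}: no time_s column; pass sampling_rate explicitly")
    return SignalTrace(values, sampling_rate, t0)


def _read_edf(path: Path, channel: int) -> SignalTrace:
    import mne  # heavy import; only needed for EDF

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data()
    if channel >= data.shape[0]:
        raise InputError(f"{path}: channel {channel} out of range ({data.shape[0]} channels)")
    return SignalTrace(data[channel], float(raw.info["sfreq"]))


def write_trace(trace: SignalTrace, path: str | Path, config: dict | None = None) -> None:
    """Write a trace as two-column delimited text with a provenance block."""
    path = Path(path)
    header = _provenance_lines(config) + ["time_s,value_V"]
    t = trace.times
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        for ti, vi in zip(t, trace.samples):
            fh.write(f"{ti:.17g},{vi:.17g}\n")


def write_imfs(imfs, path: str | Path, fs: float, config: dict | None = None) -> None:
    """Dump an IMFSet as delimited text, one column per IMF plus residue."""
    path = Path(path)
    cols = {f"imf{j + 1}": imfs.imfs[j] for j in range(imfs.n_imfs)}
    cols["residue"] = imfs.residue
    n = imfs.residue.size
    df = pd.DataFrame({"time_s": np.arange(n) / fs, **cols})
    with open(path, "w") as fh:
        fh.write("\n".join(_provenance_lines(config)) + "\n")
        df.to_csv(fh, index=False)


def write_smfdr(
    smfdr: SMFDR, path: str | Path, fits: list[LinearFit] | None = None,
    config: dict | None = None,
) -> None:
    """Serialize an SMFDR model (plus pipeline parameters) to JSON."""
    payload = {
        "subject_id": smfdr.subject_id,
        "load_label": smfdr.load_label,
        "mf0_bar": smfdr.mf0_bar,
        "mfs_bar": smfdr.mfs_bar,
        "n_train": smfdr.n_train,
        "usable": smfdr.usable,
        "training_fits": [
            {
                "slope_A": f.slope_A,
                "intercept_b": f.intercept_b,
                "mf_S": f.mf_S,
                "R": f.R,
                "t_end": f.t_end,
                "n_windows": f.n_windows,
            }
            for f in (fits or [])
        ],
        "provenance": {"emgfatigue_version": package_version(), **(config or {})},
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_smfdr(path: str | Path) -> SMFDR:
    d = json.loads(Path(path).read_text())
    try:
        return SMFDR(
            mf0_bar=float(d["mf0_bar"]),
            mfs_bar=float(d["mfs_bar"]),
            n_train=int(d["n_train"]),
            subject_id=str(d.get("subject_id", "")),
            load_label=str(d.get("load_label", "")),
        )
    except KeyError as exc:
        raise InputError(f"{path}: SMFDR file missing key {exc}") from exc


def write_trajectory(
    estimates: list[FatigueEstimate],
    times: np.ndarray,
    path: str | Path,
    config: dict | None = None,
) -> None:
    """Export a fatigue trajectory as time_s, y_i_Hz, k, LF."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\n".join(_provenance_lines(config)) + "\n")
        fh.write("time_s,y_i_Hz,k,LF\n")
        for t, e in zip(np.asarray(times, dtype=float), estimates):
            fh.write(f"{t:.6f},{e.y_i:.6f},{e.level_index_k},{e.LF:.6f}\n")


def write_mf_series(series, path: str | Path, config: dict | None = None) -> None:
    """Export an MF series as time_s, mf_Hz."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\n".join(_provenance_lines(config)) + "\n")
        fh.write("time_s,mf_Hz\n")
        for t, m in zip(series.times, series.mf):
            fh.write(f"{t:.6f},{m:.6f}\n")
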