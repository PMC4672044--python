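"""Delimited-text readers/writers for telemetry data and ground truth.

Formats are deliberately plain: CSV with stable column order for epoch
and beat series, a two-column sampled trace with a small ``# key=value``
header for waveforms, and a key-value sidecar for simulation ground
truth.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .pwv import DualPressureWaveform
from .telemetry import DEFAULT_START, BeatSeries, TelemetryEpochSeries

EPOCH_COLUMNS = ["timestamp", "sbp_mmHg", "dbp_mmHg", "hr_bpm", "rat_id", "group"]


def write_epochs(series: list[TelemetryEpochSeries], path: str | Path) -> None:
    """Concatenate epoch series (any rats/weeks) into one CSV."""
    df = pd.concat([s.to_frame() for s in series], ignore_index=True)
    df.to_csv(path, index=False, columns=EPOCH_COLUMNS)


def read_epochs(path: str | Path,
                column_map: Mapping[str, str] | None = None
                ) -> list[TelemetryEpochSeries]:
    """Read an epoch CSV back into per-rat, per-window series.

    ``column_map`` renames user columns onto the canonical names
    (``timestamp, sbp_mmHg, dbp_mmHg, hr_bpm, rat_id, group``); missing
    ``hr_bpm``/``rat_id``/``group`` columns get neutral defaults.
    Windows are split wherever consecutive timestamps jump by more than
    one epoch interval times four (the weekly gap).
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if column_map:
        df = df.rename(columns=dict(column_map))
    for col, default in (("hr_bpm", np.nan), ("rat_id", 0), ("group", "")):
        if col not in df.columns:
            df[col] = default
    df["timestamp"] = pd.to_datetime(df["timestamp"])

    out: list[TelemetryEpochSeries] = []
    for (rat, group), sub in df.groupby(["rat_id", "group"], sort=True):
        sub = sub.sort_values("timestamp")
        dt_h = sub["timestamp"].diff().dt.total_seconds().to_numpy() / 3600.0
        step = np.nanmedian(dt_h) if len(sub) > 1 else 0.25
        brk = np.zeros(len(sub), dtype=bool)
        brk[1:] = dt_h[1:] > 4.0 * step
        for wk, chunk in sub.groupby(np.cumsum(brk)):
            t0 = chunk["timestamp"].iloc[0]
            hours = (chunk["timestamp"] - t0).dt.total_seconds().to_numpy() / 3600.0
            out.append(TelemetryEpochSeries(
                epoch_times_h=hours,
                sbp=chunk["sbp_mmHg"].to_numpy(),
                dbp=chunk["dbp_mmHg"].to_numpy(),
                hr=chunk["hr_bpm"].to_numpy(),
                start_time=t0, rat_id=int(rat), group=str(group),
                week_index=int(wk) + 1))
    return out


def write_beats(beats: BeatSeries, path: str | Path) -> None:
    beats.to_frame().to_csv(path, index=False)


def read_beats(path: str | Path) -> BeatSeries:
    return BeatSeries.from_frame(
        pd.read_csv(path, float_precision="round_trip"))


def write_waveform(wave: DualPressureWaveform, path: str | Path) -> None:
    """Two-column sampled trace with a ``# key=value`` header."""
    header = (f"# fs_hz={wave.fs!r}\n"
              f"# distance_cm={wave.distance_cm!r}\n"
              "proximal_mmHg,distal_mmHg\n")
    body = "\n".join(f"{float(p)!r},{float(d)!r}"
                     for p, d in zip(wave.proximal, wave.distal))
    Path(path).write_text(header + body + "\n")


def read_waveform(path: str | Path) -> DualPressureWaveform:
    meta = {}
    lines = Path(path).read_text().splitlines()
    n_head = 0
    for line in lines:
        if not line.startswith("#"):
            break
        key, val = line.lstrip("# ").split("=", 1)
        meta[key.strip()] = float(val)
        n_head += 1
    df = pd.read_csv(path, skiprows=n_head, float_precision="round_trip")
    return DualPressureWaveform(
        proximal=df["proximal_mmHg"].to_numpy(),
        distal=df["distal_mmHg"].to_numpy(),
        fs=meta["fs_hz"], distance_cm=meta["distance_cm"])


def write_sidecar(truth: Mapping[str, object], path: str | Path) -> None:
    """Ground-truth key-value sidecar (one ``key = value`` per line)."""
    with open(path, "w") as fh:
        for key, val in truth.items():
            if isinstance(val, (list, tuple, np.ndarray)):
                val = ",".join(repr(float(x)) for x in np.asarray(val).ravel())
            fh.write(f"{key} = {val}\n")


def read_sidecar(path: str | Path) -> dict[str, object]:
    out: dict[str, object] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        key, val = line.split("=", 1)
        key, val = key.strip(), val.strip()
        try:
            out[key] = float(val) if "," not in val else \
                np.array([float(x) for x in val.split(",")])
        except ValueError:
            out[key] = val
    return out
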