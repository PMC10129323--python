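"""Reading, validation and merging of gaze AOI sample streams.

Two acquisition sources feed the looking-based measures: a 500 Hz
eye-tracker export and hand-coded webcam video at 30 fps.  Both arrive as
long-form CSV (one row per sample) and are merged into canonical per-trial
AOI time series.  Streams are kept at native cadence; every downstream
measure is computed on time-weighted AOI intervals, so the two cadences
never need resampling.

AOI labels are closed over ``{left, right, away, missing}``.  Time is
milliseconds from trial onset, 0-based, and a sample's label holds over the
half-open interval ``[t_i, t_{i+1})`` (the last sample extends to the end
of the trial).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

AOI_LABELS = ("left", "right", "away", "missing")
ONSCREEN = ("left", "right")
SOURCES = ("eyetracker", "video")

GAZE_COLUMNS = ["participant_id", "year", "trial_index", "t_ms", "aoi", "source"]
TRIAL_COLUMNS = ["participant_id", "year", "trial_index", "load", "change_side"]

#: experimental design: memory loads shown in each study year, ascending
LOADS_BY_YEAR = {1: (1, 2, 3), 2: (2, 4, 6)}
LOAD_LEVELS = ("low", "medium", "high")


class GazeValidationError(ValueError):
    """Raised when a gaze file or trial table violates its schema."""


@dataclass(frozen=True)
class TaskConfig:
    """Timing constants of the preferential-looking change-detection task.

    The two displays blink on for ``on_ms`` and off for ``off_ms``
    throughout a 10 s trial; the first colour change is anchored at
    ``first_change_onset_ms``.  Windows are half-open ``[start, end)`` in
    milliseconds from trial onset.
    """

    trial_duration_ms: int = 10_000
    on_ms: int = 500
    off_ms: int = 250
    first_change_onset_ms: int = 1_000
    firstlook_fallback_end_ms: int = 2_500
    cp_window: tuple[int, int] = (1_750, 6_750)
    lw1_window: tuple[int, int] = (0, 750)  # the first 750 ms, pre-change
    away_exclusion_fraction: float = 0.75
    #: if True, the away-time exclusion is evaluated inside cp_window only
    away_fraction_window_restricted: bool = False

    def __post_init__(self) -> None:
        for lo, hi in (self.cp_window, self.lw1_window):
            if not (0 <= lo < hi <= self.trial_duration_ms):
                raise ValueError("analysis windows must lie inside the trial")


@dataclass
class GazeTrial:
    """One trial's AOI-labelled time series plus its design metadata."""

    participant_id: str
    year: int
    trial_index: int
    t_ms: np.ndarray
    aoi: np.ndarray  # array of strings drawn from AOI_LABELS
    source_used: str
    load: int | None = None
    load_level: str | None = None
    change_side: str | None = None

    def intervals(self, duration_ms: int = 10_000) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (start, end, label) arrays of half-open AOI intervals.

        Any gap before the first sample is treated as missing.
        """
        t = np.asarray(self.t_ms, dtype=float)
        labels = np.asarray(self.aoi, dtype=object)
        if t.size == 0:
            return (np.array([0.0]), np.array([float(duration_ms)]),
                    np.array(["missing"], dtype=object))
        starts = t
        ends = np.append(t[1:], float(duration_ms))
        if t[0] > 0:
            starts = np.insert(starts, 0, 0.0)
            ends = np.insert(ends, 0, t[0])
            labels = np.insert(labels, 0, "missing")
        keep = ends > starts
        return starts[keep], ends[keep], labels[keep]


def _require_columns(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise GazeValidationError(f"{what} is missing columns {missing}")


def validate_gaze_samples(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a long-form gaze sample table and return it canonically sorted."""
    _require_columns(df, GAZE_COLUMNS, "gaze sample table")
    bad_aoi = ~df["aoi"].isin(AOI_LABELS)
    if bad_aoi.any():
        rows = df.index[bad_aoi][:5].tolist()
        raise GazeValidationError(
            f"unknown aoi labels {sorted(df.loc[bad_aoi, 'aoi'].unique())} at rows {rows}"
        )
    bad_src = ~df["source"].isin(SOURCES)
    if bad_src.any():
        raise GazeValidationError(
            f"unknown sources {sorted(df.loc[bad_src, 'source'].unique())}"
        )
    if (df["t_ms"] < 0).any() or (df["t_ms"] > 10_000).any():
        raise GazeValidationError("t_ms outside [0, 10000]")
    key = ["participant_id", "year", "trial_index", "source", "t_ms"]
    dup = df.duplicated(subset=key)
    if dup.any():
        first = df.loc[dup, key].iloc[0].to_dict()
        raise GazeValidationError(f"duplicate sample timestamp within trial: {first}")
    return df.sort_values(key, kind="mergesort").reset_index(drop=True)


def read_gaze_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate a gaze sample CSV.

    Malformed rows raise with the offending line number; unknown AOI labels
    and duplicate within-trial timestamps raise :class:`GazeValidationError`.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path,
            dtype={"participant_id": str, "aoi": str, "source": str},
            keep_default_na=False,
        )
        df["year"] = df["year"].astype(int)
        df["trial_index"] = df["trial_index"].astype(int)
        df["t_ms"] = df["t_ms"].astype(int)
    except (ValueError, TypeError) as exc:
        raise GazeValidationError(f"malformed gaze CSV {path}: {exc}") from exc
    return validate_gaze_samples(df)


def write_gaze_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, columns=GAZE_COLUMNS)


def read_trials_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"participant_id": str, "change_side": str})
    _require_columns(df, TRIAL_COLUMNS, "trial metadata table")
    return df


def load_level_of(year: int, load: int) -> str:
    """Within-year rank of an absolute memory load (low/medium/high)."""
    design = LOADS_BY_YEAR.get(int(year))
    if design is None or int(load) not in design:
        raise GazeValidationError(f"load {load} not in the year-{year} design {design}")
    return LOAD_LEVELS[design.index(int(load))]


def merge_sources(
    eyetracker: pd.DataFrame | None,
    video: pd.DataFrame | None,
    expected_trials: pd.DataFrame | None = None,
) -> list[GazeTrial]:
    """Merge the two acquisition streams into per-trial AOI series.

    Per trial the eye-tracker stream is used when it exists; otherwise the
    hand-coded video stream.  Substitution is whole-trial, never
    sample-interleaved.  Trials listed in ``expected_trials`` but present in
    neither stream are omitted with a logged warning.
    """
    frames = []
    if eyetracker is not None and len(eyetracker):
        frames.append(eyetracker)
    if video is not None and len(video):
        frames.append(video)
    key = ["participant_id", "year", "trial_index"]
    trials: dict[tuple, GazeTrial] = {}
    if frames:
        allsamp = pd.concat(frames, ignore_index=True)
        for (pid, year, idx, source), g in allsamp.groupby(
            key + ["source"], sort=True
        ):
            k = (pid, year, idx)
            if k in trials and trials[k].source_used == "eyetracker":
                continue
            if k in trials and source == "video":
                continue
            trials[k] = GazeTrial(
                participant_id=str(pid),
                year=int(year),
                trial_index=int(idx),
                t_ms=g["t_ms"].to_numpy(),
                aoi=g["aoi"].to_numpy(dtype=object),
                source_used=str(source),
            )
    if expected_trials is not None:
        expected = {
            (str(r.participant_id), int(r.year), int(r.trial_index))
            for r in expected_trials.itertuples()
        }
        absent = sorted(expected - set(trials))
        for k in absent:
            logger.warning("trial %s present in neither source; omitted", k)
    return [trials[k] for k in sorted(trials)]


def attach_metadata(trials: Iterable[GazeTrial], trial_table: pd.DataFrame) -> list[GazeTrial]:
    """Attach load / change-side metadata and derive the within-year load level.

    Every trial must have a metadata row; year/load combinations outside the
    design are rejected.
    """
    _require_columns(trial_table, TRIAL_COLUMNS, "trial metadata table")
    meta = {
        (str(r.participant_id), int(r.year), int(r.trial_index)): r
        for r in trial_table.itertuples()
    }
    out, orphans = [], []
    for tr in trials:
        k = (tr.participant_id, tr.year, tr.trial_index)
        row = meta.get(k)
        if row is None:
            orphans.append(k)
            continue
        if row.change_side not in ONSCREEN:
            raise GazeValidationError(f"change_side {row.change_side!r} for trial {k}")
        tr.load = int(row.load)
        tr.change_side = str(row.change_side)
        tr.load_level = load_level_of(tr.year, tr.load)
        out.append(tr)
    if orphans:
        raise GazeValidationError(f"trials without metadata rows: {orphans[:10]}")
    return out
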