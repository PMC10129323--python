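"""Shared fixtures: trial builders, random synthetic trials, and an
independent per-millisecond brute-force scorer used as the oracle for the
interval-based looking measures."""

from __future__ import annotations

import numpy as np
import pytest

from gazecog.gaze_io import GazeTrial, TaskConfig
from gazecog import synth


@pytest.fixture
def task_cfg() -> TaskConfig:
    return TaskConfig()


def make_trial(segments, change_side="left", participant="p0", year=1,
               trial_index=0, load=2, load_level="medium"):
    """Build a GazeTrial from (start_ms, label) segments."""
    t = np.array([s[0] for s in segments], dtype=float)
    aoi = np.array([s[1] for s in segments], dtype=object)
    return GazeTrial(
        participant_id=participant, year=year, trial_index=trial_index,
        t_ms=t, aoi=aoi, source_used="eyetracker",
        load=load, load_level=load_level, change_side=change_side,
    )


def random_trials(n: int, seed: int, video_fraction: float = 0.5,
                  missingness: float = 0.1) -> list[GazeTrial]:
    """Random synthetic trials from the generator's look model, mixing
    native 500 Hz and 30 fps cadences."""
    rng = np.random.default_rng(seed)
    et_grid = np.arange(0, 10_000, 2).astype(float)
    vid_grid = (np.arange(300) * (1000.0 / 30.0)).astype(int).astype(float)
    out = []
    for i in range(n):
        change_side = "left" if rng.random() < 0.5 else "right"
        load = int(rng.choice([1, 2, 3]))
        segs = synth.simulate_trial_segments(
            rng, change_side, load, capacity=float(rng.uniform(0.5, 3.5)),
            look_mean_ms=float(rng.uniform(600, 2500)),
        )
        grid = vid_grid if rng.random() < video_fraction else et_grid
        aoi = np.empty(len(grid), dtype=object)
        starts = np.array([s[0] for s in segs])
        labels = np.array([s[1] for s in segs], dtype=object)
        idx = np.clip(np.searchsorted(starts, grid, side="right") - 1, 0, len(segs) - 1)
        aoi[:] = labels[idx]
        miss = rng.random(len(grid)) < missingness
        aoi[miss] = "missing"
        out.append(GazeTrial(
            participant_id=f"p{i:03d}", year=1, trial_index=i,
            t_ms=grid.copy(), aoi=aoi, source_used="eyetracker",
            load=load, load_level=["low", "medium", "high"][load - 1],
            change_side=change_side,
        ))
    return out


# ---------------------------------------------------------------------------
# Brute-force per-millisecond oracle (independent straight-loop scorer)
# ---------------------------------------------------------------------------

def ms_labels(trial: GazeTrial, duration: int = 10_000) -> list[str]:
    """Label for every millisecond, by direct scan over the samples."""
    labels = ["missing"] * duration
    t = list(trial.t_ms)
    a = list(trial.aoi)
    for j in range(len(t)):
        start = int(t[j])
        end = int(t[j + 1]) if j + 1 < len(t) else duration
        for ms in range(start, min(end, duration)):
            labels[ms] = str(a[j])
    return labels


def oracle_first_look(trial: GazeTrial, cfg: TaskConfig) -> str:
    lab = ms_labels(trial, cfg.trial_duration_ms)
    at = lab[cfg.first_change_onset_ms]
    if at in ("left", "right"):
        return "change" if at == trial.change_side else "no_change"
    for ms in range(cfg.first_change_onset_ms, cfg.firstlook_fallback_end_ms + 1):
        if ms < len(lab) and lab[ms] in ("left", "right"):
            return "change" if lab[ms] == trial.change_side else "no_change"
    return "unclassified"


def oracle_away_fraction(trial: GazeTrial, cfg: TaskConfig) -> float:
    lab = ms_labels(trial, cfg.trial_duration_ms)
    off = sum(1 for x in lab if x in ("away", "missing"))
    return off / len(lab)


def oracle_cp(trial: GazeTrial, cfg: TaskConfig):
    if oracle_away_fraction(trial, cfg) > cfg.away_exclusion_fraction:
        return None
    lab = ms_labels(trial, cfg.trial_duration_ms)
    lo, hi = cfg.cp_window
    change = other = 0
    for ms in range(lo, hi):
        if lab[ms] == trial.change_side:
            change += 1
        elif lab[ms] in ("left", "right"):
            other += 1
    if change + other == 0:
        return None
    return change / (change + other)


def oracle_shift_rate(trial: GazeTrial, cfg: TaskConfig):
    lab = ms_labels(trial, cfg.trial_duration_ms)
    looking_ms = 0
    switches = 0
    last_side = None
    for x in lab:
        if x in ("left", "right"):
            looking_ms += 1
            if last_side is not None and x != last_side:
                switches += 1
            last_side = x
    if looking_ms == 0:
        return None
    return switches / (looking_ms / 1000.0)


def oracle_lw1(trial: GazeTrial, cfg: TaskConfig):
    lab = ms_labels(trial, cfg.trial_duration_ms)
    lo, hi = cfg.lw1_window
    first = None
    onscreen = {"left": 0, "right": 0}
    for ms in range(lo, hi):
        if lab[ms] in ("left", "right"):
            onscreen[lab[ms]] += 1
            if first is None:
                first = lab[ms]
    denom = onscreen["left"] + onscreen["right"]
    if denom == 0:
        return None
    return onscreen[first] / denom
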