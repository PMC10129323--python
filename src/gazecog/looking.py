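"""Per-trial looking-based visual-cognition measures.

Four measures are computed from each trial's AOI interval sequence:

* **first-look class** — which display (change / no-change) the infant
  fixates at the onset of the first colour change, with a bounded forward
  scan when that sample is missing or away;
* **change preference** — time-weighted proportion of on-display looking
  directed at the changing display inside the analysis window;
* **shift rate** — gaze switches between the two displays per second of
  on-display looking, over the full trial;
* **LookingWindow1** — proportion of early-window on-display looking spent
  on the first-fixated display, before any change has occurred.

All measures are time-weighted over half-open intervals, which makes the
500 Hz eye-tracker and 30 fps video streams directly commensurable.
Coder reliability is summarized with Cohen's kappa.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import cohen_kappa_score

from .gaze_io import GazeTrial, ONSCREEN, TaskConfig

__all__ = [
    "TrialScore",
    "classify_first_look",
    "change_preference",
    "shift_rate",
    "looking_window1",
    "away_fraction",
    "cohens_kappa",
    "score_trial",
    "score_dataset",
]


@dataclass
class TrialScore:
    """Derived per-trial quantities plus validity flags."""

    participant_id: str
    year: int
    trial_index: int
    load: int | None
    load_level: str | None
    first_look: str  # change | no_change | unclassified
    change_preference: float | None
    cp_valid: bool
    shift_rate: float | None
    looking_window1: float | None
    away_fraction: float


def _label_at(trial: GazeTrial, t: float) -> tuple[str, int]:
    """AOI label holding at time t, and the index of the governing sample.

    Returns ("missing", -1) when the stream has no sample at or before t.
    """
    idx = int(np.searchsorted(trial.t_ms, t, side="right")) - 1
    if idx < 0:
        return "missing", -1
    return str(trial.aoi[idx]), idx


def classify_first_look(trial: GazeTrial, cfg: TaskConfig = TaskConfig()) -> str:
    """Classify a trial by where gaze rests at the first change onset.

    The AOI at ``first_change_onset_ms`` decides directly when it is
    on-screen.  When it is missing — or away, which equally fails to answer
    where on the display the infant is looking — the first on-screen sample
    up to ``firstlook_fallback_end_ms`` (inclusive) decides instead.
    Returns "unclassified" when no on-screen sample exists in that span.
    """
    if trial.change_side is None:
        raise ValueError("trial has no change_side metadata")
    label, idx = _label_at(trial, cfg.first_change_onset_ms)
    if label in ONSCREEN:
        return "change" if label == trial.change_side else "no_change"
    t = np.asarray(trial.t_ms)
    for j in range(idx + 1, len(t)):
        if t[j] > cfg.firstlook_fallback_end_ms:
            break
        if str(trial.aoi[j]) in ONSCREEN:
            side = str(trial.aoi[j])
            return "change" if side == trial.change_side else "no_change"
    return "unclassified"


def _clipped_durations(trial: GazeTrial, window: tuple[float, float],
                       duration_ms: int) -> dict[str, float]:
    """Total duration (ms) per AOI label within a half-open window."""
    starts, ends, labels = trial.intervals(duration_ms)
    lo = np.maximum(starts, window[0])
    hi = np.minimum(ends, window[1])
    dur = np.maximum(hi - lo, 0.0)
    out = {"left": 0.0, "right": 0.0, "away": 0.0, "missing": 0.0}
    for lab in out:
        out[lab] = float(dur[labels == lab].sum())
    return out


def away_fraction(trial: GazeTrial, cfg: TaskConfig = TaskConfig()) -> float:
    """Fraction of the trial (or of cp_window, by config) not spent on-screen.

    'Not looking at the screen' covers both coded-away and untracked time.
    """
    if cfg.away_fraction_window_restricted:
        window = cfg.cp_window
    else:
        window = (0.0, float(cfg.trial_duration_ms))
    d = _clipped_durations(trial, window, cfg.trial_duration_ms)
    total = sum(d.values())
    return (d["away"] + d["missing"]) / total if total > 0 else 1.0


def change_preference(trial: GazeTrial, cfg: TaskConfig = TaskConfig()) -> float | None:
    """Time-weighted preference for the changing display inside cp_window.

    Undefined (None) when more than ``away_exclusion_fraction`` of the trial
    is off-screen (strict inequality: exactly 75% away is retained) or when
    there is no on-display looking inside the window.
    """
    if trial.change_side is None:
        raise ValueError("trial has no change_side metadata")
    if away_fraction(trial, cfg) > cfg.away_exclusion_fraction:
        return None
    d = _clipped_durations(trial, cfg.cp_window, cfg.trial_duration_ms)
    change = d[trial.change_side]
    other = d["left" if trial.change_side == "right" else "right"]
    denom = change + other
    if denom <= 0:
        return None
    return change / denom


def shift_rate(trial: GazeTrial, cfg: TaskConfig = TaskConfig()) -> float | None:
    """Gaze switches per second of on-display looking, over the full trial.

    The AOI stream collapses to its sequence of on-screen looks (left/right
    runs); intervening away/missing time neither breaks a run nor counts as
    looking.  Undefined when total looking time is zero.
    """
    starts, ends, labels = trial.intervals(cfg.trial_duration_ms)
    onscreen = np.isin(labels.astype(str), ONSCREEN)
    sides = labels[onscreen].astype(str)
    looking_ms = float((ends - starts)[onscreen].sum())
    if looking_ms <= 0:
        return None
    switches = int(np.sum(sides[1:] != sides[:-1]))
    return switches / (looking_ms / 1000.0)


def looking_window1(trial: GazeTrial, cfg: TaskConfig = TaskConfig()) -> float | None:
    """Proportion of early-window on-display time on the first-fixated side.

    The window precedes any visual change, so the measure indexes baseline
    visual dynamics rather than memory.  Undefined when the window contains
    no on-display looking.
    """
    starts, ends, labels = trial.intervals(cfg.trial_duration_ms)
    lo, hi = cfg.lw1_window
    s = np.maximum(starts, lo)
    e = np.minimum(ends, hi)
    dur = np.maximum(e - s, 0.0)
    onscreen = np.isin(labels.astype(str), ONSCREEN) & (dur > 0)
    if not onscreen.any():
        return None
    first_side = str(labels[onscreen][0])
    denom = float(dur[onscreen].sum())
    num = float(dur[onscreen & (labels == first_side)].sum())
    return num / denom


def cohens_kappa(coding_a, coding_b) -> float:
    """Chance-corrected agreement between two frame-aligned codings.

    kappa = (p_o - p_e) / (1 - p_e) with expected agreement from the
    marginal label frequencies.  Two identical constant codings have
    p_e = 1; that degenerate case is reported as perfect agreement (1.0).
    """
    a = np.asarray(coding_a)
    b = np.asarray(coding_b)
    if a.shape != b.shape:
        raise ValueError("codings must have equal length")
    if a.size == 0:
        raise ValueError("codings are empty")
    labels = np.unique(np.concatenate([a, b]))
    if labels.size == 1:
        return 1.0  # both coders constant and equal: p_e = 1
    return float(cohen_kappa_score(a, b))


def score_trial(trial: GazeTrial, cfg: TaskConfig = TaskConfig()) -> TrialScore:
    fl = classify_first_look(trial, cfg)
    af = away_fraction(trial, cfg)
    cp = change_preference(trial, cfg)
    cp_valid = cp is not None and fl != "unclassified"
    return TrialScore(
        participant_id=trial.participant_id,
        year=trial.year,
        trial_index=trial.trial_index,
        load=trial.load,
        load_level=trial.load_level,
        first_look=fl,
        change_preference=cp,
        cp_valid=cp_valid,
        shift_rate=shift_rate(trial, cfg),
        looking_window1=looking_window1(trial, cfg),
        away_fraction=af,
    )


def score_dataset(
    trials, cfg: TaskConfig = TaskConfig()
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, int]]:
    """Score every trial and aggregate to analysis cells.

    Returns ``(scores, aggregates, exclusions)``: one row per trial; cell
    means of change preference and shift rate per participant x year x
    load level x first-look class; and counts of trials removed by each
    filter.
    """
    rows = [score_trial(t, cfg) for t in trials]
    scores = pd.DataFrame([vars(s) for s in rows])
    exclusions = {
        "n_trials": len(scores),
        "firstlook_unclassified": int((scores["first_look"] == "unclassified").sum()) if len(scores) else 0,
        "away_excluded": 0,
        "cp_invalid_total": 0,
    }
    if len(scores):
        exclusions["away_excluded"] = int(
            (scores["away_fraction"] > cfg.away_exclusion_fraction).sum()
        )
        exclusions["cp_invalid_total"] = int((~scores["cp_valid"]).sum())
        valid_cp = scores[scores["cp_valid"]]
        agg_cp = (
            valid_cp.groupby(["participant_id", "year", "load_level", "first_look"], dropna=False)
            ["change_preference"].mean().rename("cp_mean")
        )
        agg_sr = (
            scores.dropna(subset=["shift_rate"])
            .groupby(["participant_id", "year", "load_level", "first_look"], dropna=False)
            ["shift_rate"].mean().rename("shift_rate_mean")
        )
        agg = pd.concat([agg_cp, agg_sr], axis=1).reset_index()
    else:
        agg = pd.DataFrame(
            columns=["participant_id", "year", "load_level", "first_look",
                     "cp_mean", "shift_rate_mean"]
        )
    return scores, agg, exclusions
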