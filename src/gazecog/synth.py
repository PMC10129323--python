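"""Synthetic study generator: households, AQI logs, gaze trials, assessments.

Every downstream stage of the pipeline is exercisable against data from
this module, and every generated dataset ships with a ground-truth ledger
(:class:`SynthTruth`) so that parameter recovery is measurable.  The
generator emulates the study design: two age cohorts (6 and 9 months at
enrolment) each seen in two annual waves; in-home air-quality logging at a
10 s cadence over 3-day rounds repeated up to six times per household;
a 36-trial preferential-looking change-detection session per visit; and
standardized assessment scores (Mullen in year 1, ASQ in year 2).

The embedded effect structure mirrors the reported findings: indoor air
quality is worse in solid-fuel and low-SES households; household exposure
depresses gaze shift rate in both years and change preference in year 1
only; assessment scores track SES but not exposure.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Household",
    "GenConfig",
    "SynthTruth",
    "generate_households",
    "make_truth",
    "generate_aqi_logs",
    "generate_gaze_trials",
    "generate_assessments",
    "generate_shift_cells",
    "generate_cp_cells",
    "write_dataset",
    "load_truth",
    "FUEL_PROBS",
]

FUELS = ("cow_dung", "wood", "lpg")

#: P(fuel | SES half), column sums of the study's demographic table
FUEL_PROBS = {
    "high": {"cow_dung": 0.12, "wood": 0.55, "lpg": 0.33},
    "low": {"cow_dung": 0.12, "wood": 0.84, "lpg": 0.04},
}
_ELECTRICITY_P = {"high": 0.88, "low": 0.40}

TZ = "Asia/Kolkata"  # fixed +05:30, no DST


@dataclass
class Household:
    household_id: str
    ses_score: float
    cooking_fuel: str
    electricity: bool
    income_tertile: str
    cohort: str  # "6mo" | "9mo"


@dataclass
class GenConfig:
    """Generator parameters; defaults are the study's own conditions."""

    n_households: int = 215
    n_rounds: int = 4          # mean rounds per household in the study (max 6)
    round_days: int = 3
    sample_interval_s: int = 10
    baseline_aqi: float = 160.0
    seasonal_amplitude: float = 40.0
    seasonal_peak_doy: float = 15.0       # winter peak (mid January)
    diurnal_peak_hours: tuple[float, ...] = (7.0, 18.0)   # meal preparation
    diurnal_amplitude: float = 45.0
    diurnal_width_h: float = 1.5
    noise_sd: float = 20.0
    ar1_coefficient: float = 0.9          # at the 10 s cadence
    household_offset_sd: float = 25.0
    fuel_offsets: dict = field(
        default_factory=lambda: {"cow_dung": 25.0, "wood": 10.0, "lpg": -20.0}
    )
    ses_offset_slope: float = -1.15       # AQI units per centered SES point
    trial_count: int = 36
    blocks: int = 6
    missingness_rate: float = 0.13
    video_fraction: float = 0.30          # share of trials hand-coded at 30 fps
    start_date: str = "2018-06-01"

    def __post_init__(self) -> None:
        if not (1 <= self.n_rounds <= 6):
            raise ValueError("n_rounds must be in 1..6")
        for r in (self.missingness_rate, self.video_fraction):
            if not (0.0 <= r <= 1.0):
                raise ValueError("rates must lie in [0, 1]")
        if self.trial_count % self.blocks:
            raise ValueError("trial_count must divide into blocks")


@dataclass
class SynthTruth:
    """Ground-truth ledger written alongside every generated dataset."""

    household_offsets: dict[str, float]
    beta_aqi_shift: float = -7e-4    # shifts/s per AQI unit
    beta_aqi_cp_y1: float = -8e-4    # CP units per AQI unit, year 1
    beta_aqi_cp_y2: float = 0.0      # attenuated to null in year 2
    beta_ses_assessment: float = 0.8
    capacity_by_age: dict[str, float] = field(
        default_factory=lambda: {"6mo:1": 1.3, "9mo:1": 2.1, "6mo:2": 3.2, "9mo:2": 3.7}
    )
    shift_base: float = 0.63         # shifts/s grand mean
    shift_participant_sd: float = 0.12
    seed: int = 0

    def capacity(self, cohort: str, year: int) -> float:
        return self.capacity_by_age[f"{cohort}:{year}"]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)


def load_truth(path: str | Path) -> SynthTruth:
    with open(path) as fh:
        return SynthTruth(**json.load(fh))


def _rng(seed: int, stream: str) -> np.random.Generator:
    # crc32 keyed sub-streams: stable across processes, unlike builtin hash()
    ss = np.random.SeedSequence([seed, zlib.crc32(stream.encode())])
    return np.random.default_rng(ss)


def generate_households(n: int, seed: int) -> list[Household]:
    """Draw households with SES-dependent cooking fuel and amenities.

    SES scores follow a Kuppuswamy-like continuous scale; fuel is assigned
    from :data:`FUEL_PROBS` conditional on a median split, so LPG
    concentrates in high-SES homes and solid fuels in low-SES homes.
    """
    if n < 1:
        raise ValueError("need at least one household")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    ses = np.clip(rng.normal(15.0, 5.0, n), 3.0, 29.0)
    half = np.where(ses >= np.median(ses), "high", "low")
    income_latent = ses + rng.normal(0.0, 4.0, n)
    tert = np.quantile(income_latent, [1 / 3, 2 / 3])
    income = np.where(income_latent < tert[0], "low",
                      np.where(income_latent < tert[1], "medium", "high"))
    out = []
    for i in range(n):
        probs = FUEL_PROBS[half[i]]
        fuel = rng.choice(FUELS, p=[probs[f] / sum(probs.values()) for f in FUELS])
        out.append(
            Household(
                household_id=f"hh{i:04d}",
                ses_score=float(ses[i]),
                cooking_fuel=str(fuel),
                electricity=bool(rng.random() < _ELECTRICITY_P[half[i]]),
                income_tertile=str(income[i]),
                cohort="6mo" if rng.random() < 0.5 else "9mo",
            )
        )
    return out


def make_truth(households: list[Household], cfg: GenConfig, seed: int, **overrides) -> SynthTruth:
    """Realize household AQI offsets and assemble the ground-truth ledger.

    offset = fuel effect + SES slope x centered SES + household noise.
    """
    rng = _rng(seed, "offsets")
    ses = np.array([h.ses_score for h in households])
    ses_c = ses - ses.mean()
    offsets = {}
    for i, h in enumerate(households):
        offsets[h.household_id] = float(
            cfg.fuel_offsets[h.cooking_fuel]
            + cfg.ses_offset_slope * ses_c[i]
            + rng.normal(0.0, cfg.household_offset_sd)
        )
    return SynthTruth(household_offsets=offsets, seed=seed, **overrides)


def _diurnal(hour: np.ndarray, cfg: GenConfig) -> np.ndarray:
    out = np.zeros_like(hour, dtype=float)
    for peak in cfg.diurnal_peak_hours:
        d = np.abs(hour - peak)
        d = np.minimum(d, 24.0 - d)  # circular distance
        out += cfg.diurnal_amplitude * np.exp(-0.5 * (d / cfg.diurnal_width_h) ** 2)
    return out


def _seasonal(doy: np.ndarray, cfg: GenConfig) -> np.ndarray:
    return cfg.seasonal_amplitude * np.cos(
        2.0 * np.pi * (doy - cfg.seasonal_peak_doy) / 365.25
    )


def generate_aqi_logs(
    households: list[Household], cfg: GenConfig, truth: SynthTruth, seed: int
) -> pd.DataFrame:
    """Simulate device logs: smooth seasonal + meal-time diurnal structure,
    household offsets, and AR(1) noise at the device cadence.

    Rounds are 3-day windows spaced three months apart, with per-household
    enrolment jitter.  Values are clipped at zero (the index is nonnegative).
    """
    if not households:
        raise ValueError("households must be nonempty")
    rng = _rng(seed, "aqi")
    start = pd.Timestamp(cfg.start_date, tz=TZ)
    n_per_round = cfg.round_days * 86400 // cfg.sample_interval_s
    phi = cfg.ar1_coefficient
    innov_sd = cfg.noise_sd * np.sqrt(max(1.0 - phi**2, 1e-12))
    cols: dict[str, list] = {k: [] for k in
                             ("device_id", "household_id", "timestamp", "aqi", "round_index")}
    for i, h in enumerate(households):
        jitter_days = int(rng.integers(0, 90))
        offset = truth.household_offsets[h.household_id]
        for r in range(1, cfg.n_rounds + 1):
            t0 = start + pd.Timedelta(days=jitter_days + (r - 1) * 91)
            ts = t0.value // 10**9 + np.arange(n_per_round, dtype=np.int64) * cfg.sample_interval_s
            t_idx = pd.to_datetime(ts, unit="s", utc=True).tz_convert(TZ)
            hour = t_idx.hour.to_numpy() + t_idx.minute.to_numpy() / 60.0
            doy = t_idx.dayofyear.to_numpy().astype(float)
            noise = rng.normal(0.0, innov_sd, n_per_round)
            noise[0] = rng.normal(0.0, cfg.noise_sd)
            if phi > 0:
                from scipy.signal import lfilter
                noise = lfilter([1.0], [1.0, -phi], noise)
            aqi = (cfg.baseline_aqi + _seasonal(doy, cfg) + _diurnal(hour, cfg)
                   + offset + noise)
            cols["device_id"].append(np.repeat(f"dev{i % 20:02d}", n_per_round))
            cols["household_id"].append(np.repeat(h.household_id, n_per_round))
            cols["timestamp"].append(ts)
            cols["aqi"].append(np.maximum(aqi, 0.0))
            cols["round_index"].append(np.repeat(r, n_per_round))
    ts_all = np.concatenate(cols["timestamp"])
    return pd.DataFrame(
        {
            "device_id": pd.Categorical(np.concatenate(cols["device_id"])),
            "household_id": pd.Categorical(np.concatenate(cols["household_id"])),
            "timestamp": pd.to_datetime(ts_all, unit="s", utc=True).tz_convert(TZ),
            "aqi": np.concatenate(cols["aqi"]),
            "round_index": np.concatenate(cols["round_index"]).astype(np.int16),
        }
    )


# ---------------------------------------------------------------------------
# Gaze-trial simulation: two-state semi-Markov look process
# ---------------------------------------------------------------------------

_LOADS = {1: (1, 2, 3), 2: (2, 4, 6)}


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def simulate_trial_segments(
    rng: np.random.Generator,
    change_side: str,
    load: int,
    capacity: float,
    look_mean_ms: float,
    cp_adjust: float = 0.0,
    first_change_ms: float = 1000.0,
    duration_ms: float = 10_000.0,
    p_away: float = 0.25,
    away_mean_ms: float = 400.0,
) -> list[tuple[float, str]]:
    """One trial as (start_ms, state) segments of a semi-Markov look process.

    Looks alternate between the two displays with occasional away periods.
    After the first change, discriminability g = sigmoid(capacity - load +
    cp_adjust) shortens looks on the no-change display (sameness detected,
    fixation released) and lengthens looks on the change display (novelty
    sustained), which raises the change preference when load is within
    capacity and lowers it as load exceeds capacity.
    """
    g = _sigmoid(capacity - load + cp_adjust)
    other = {"left": "right", "right": "left"}
    segs: list[tuple[float, str]] = []
    t = 0.0
    side = "left" if rng.random() < 0.5 else "right"
    if rng.random() < 0.10:
        segs.append((t, "away"))
        t += rng.exponential(away_mean_ms)
    while t < duration_ms:
        if t < first_change_ms:
            mean = look_mean_ms
        elif side == change_side:
            mean = look_mean_ms * (0.8 + g)
        else:
            mean = look_mean_ms * (1.5 - g)
        segs.append((t, side))
        t += rng.exponential(mean)
        if t >= duration_ms:
            break
        if rng.random() < p_away:
            segs.append((t, "away"))
            t += rng.exponential(away_mean_ms)
        side = other[side]
    return segs


def _sample_segments(segs, t_grid: np.ndarray) -> np.ndarray:
    starts = np.array([s[0] for s in segs])
    labels = np.array([s[1] for s in segs], dtype=object)
    idx = np.searchsorted(starts, t_grid, side="right") - 1
    idx = np.clip(idx, 0, len(segs) - 1)
    return labels[idx]


def generate_gaze_trials(
    households: list[Household],
    truth: SynthTruth,
    cfg: GenConfig,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate gaze sample streams and trial metadata for both study years.

    One participant per household (sharing its id).  Latent processing
    speed and effective capacity depend linearly on the household exposure
    offset through the truth ledger; trial counts per session follow the
    study's completion rates.  Returns (samples, trials) long-form tables.
    """
    rng = _rng(seed, "gaze")
    et_grid = np.arange(0, 10_000, 2)                      # 500 Hz
    vid_grid = (np.arange(300) * (1000.0 / 30.0)).astype(int)  # 30 fps
    samp_cols: dict[str, list] = {k: [] for k in
                                  ("participant_id", "year", "trial_index", "t_ms", "aoi", "source")}
    trial_rows = []
    per_block = cfg.trial_count // cfg.blocks
    for h in households:
        offset = truth.household_offsets[h.household_id]
        for year in (1, 2):
            speed = max(
                truth.shift_base + truth.beta_aqi_shift * offset
                + rng.normal(0.0, truth.shift_participant_sd),
                0.15,
            )
            look_mean_ms = 1000.0 / speed
            beta_cp = truth.beta_aqi_cp_y1 if year == 1 else truth.beta_aqi_cp_y2
            cp_adjust = beta_cp * offset / 0.25  # CP units -> logit slope at 0
            capacity = truth.capacity(h.cohort, year)
            n_done = int(np.clip(round(rng.normal(21 if year == 1 else 26, 9.7)),
                                 per_block, cfg.trial_count))
            design = []
            for _ in range(cfg.blocks):
                block = [(ld, sd) for ld in _LOADS[year] for sd in ("left", "right")]
                rng.shuffle(block)
                design.extend(block)
            for trial_index in range(n_done):
                load, change_side = design[trial_index]
                segs = simulate_trial_segments(
                    rng, change_side, load, capacity, look_mean_ms, cp_adjust
                )
                source = "video" if rng.random() < cfg.video_fraction else "eyetracker"
                grid = vid_grid if source == "video" else et_grid
                aoi = _sample_segments(segs, grid.astype(float))
                if cfg.missingness_rate > 0:
                    miss = rng.random(len(grid)) < cfg.missingness_rate
                    aoi = aoi.copy()
                    aoi[miss] = "missing"
                samp_cols["participant_id"].append(np.repeat(h.household_id, len(grid)))
                samp_cols["year"].append(np.repeat(year, len(grid)))
                samp_cols["trial_index"].append(np.repeat(trial_index, len(grid)))
                samp_cols["t_ms"].append(grid)
                samp_cols["aoi"].append(aoi)
                samp_cols["source"].append(np.repeat(source, len(grid)))
                trial_rows.append((h.household_id, year, trial_index, load, change_side))
    samples = pd.DataFrame(
        {
            "participant_id": np.concatenate(samp_cols["participant_id"]),
            "year": np.concatenate(samp_cols["year"]).astype(int),
            "trial_index": np.concatenate(samp_cols["trial_index"]).astype(int),
            "t_ms": np.concatenate(samp_cols["t_ms"]).astype(int),
            "aoi": np.concatenate(samp_cols["aoi"]),
            "source": np.concatenate(samp_cols["source"]),
        }
    )
    trials = pd.DataFrame(
        trial_rows,
        columns=["participant_id", "year", "trial_index", "load", "change_side"],
    )
    return samples, trials


def generate_assessments(
    households: list[Household], truth: SynthTruth, seed: int, noise_sd: float = 10.0
) -> pd.DataFrame:
    """Standardized assessment scores: SES effect positive, exposure null.

    Year 1 yields a Mullen-composite-like score; year 2 three ASQ subscale
    scores.  Age-cohort effects follow the study's direction (older cohort
    slightly lower raw ASQ scores).
    """
    rng = _rng(seed, "assess")
    ses = np.array([h.ses_score for h in households])
    ses_c = ses - ses.mean()
    specs = {  # measure -> (year, intercept, age effect, noise scale)
        "mullen_composite": (1, 101.3, -0.3, noise_sd),
        "asq_problem_solving": (2, 30.6, -5.5, noise_sd),
        "asq_fine_motor": (2, 34.2, -5.7, noise_sd),
        "asq_gross_motor": (2, 36.8, -8.2, noise_sd),
    }
    rows = []
    for i, h in enumerate(households):
        age_coded = -0.5 if h.cohort == "6mo" else 0.5
        for measure, (year, icpt, b_age, sd) in specs.items():
            score = (icpt + b_age * age_coded
                     + truth.beta_ses_assessment * ses_c[i]
                     + 0.0 * truth.household_offsets[h.household_id]
                     + rng.normal(0.0, sd))
            rows.append((h.household_id, year, measure, float(score)))
    return pd.DataFrame(rows, columns=["participant_id", "year", "measure", "score"])


# ---------------------------------------------------------------------------
# Reduced-form cell generators for replicate-heavy simulations
# ---------------------------------------------------------------------------

def generate_shift_cells(
    n_participants: int,
    truth: SynthTruth,
    seed: int,
    offset_sd: float = 30.0,
    cell_sd: float = 0.15,
) -> pd.DataFrame:
    """Participant x year x load-level mean shift rates, direct from truth.

    Draws the same linear structure the full gaze generator induces —
    participant intercepts, a small load gradient, and the exposure effect
    ``beta_aqi_shift`` — without simulating sample streams, so thousands of
    replicates stay cheap.  Column ``exposure`` carries the (centered)
    household offset.
    """
    rng = np.random.default_rng(seed)
    offs = rng.normal(0.0, offset_sd, n_participants)
    ses = rng.normal(0.0, 1.0, n_participants)
    b = rng.normal(0.0, truth.shift_participant_sd, n_participants)
    load_eff = {"low": 0.03, "medium": 0.0, "high": -0.03}
    rows = []
    for i in range(n_participants):
        for year in (1, 2):
            for lev in ("low", "medium", "high"):
                mu = (truth.shift_base + load_eff[lev] + b[i]
                      + truth.beta_aqi_shift * offs[i])
                rows.append((f"p{i:04d}", year, lev, ses[i],
                             "6mo" if i % 2 == 0 else "9mo", offs[i],
                             mu + rng.normal(0.0, cell_sd)))
    return pd.DataFrame(
        rows,
        columns=["participant_id", "year", "load_level", "ses_score",
                 "cohort", "exposure", "shift_rate"],
    )


def generate_cp_cells(
    n_participants: int,
    truth: SynthTruth,
    seed: int,
    offset_sd: float = 30.0,
    cell_sd: float = 0.18,
    participant_sd: float = 0.08,
    beta_year_ses: float = 0.0,
) -> pd.DataFrame:
    """Participant x year x load-level mean change preference (first-look
    no-change cells), with year-specific exposure effects from the truth
    ledger and an optional Year x SES interaction for selection studies."""
    rng = np.random.default_rng(seed)
    offs = rng.normal(0.0, offset_sd, n_participants)
    ses = rng.normal(0.0, 1.0, n_participants)
    b = rng.normal(0.0, participant_sd, n_participants)
    lw1 = np.clip(rng.normal(0.8, 0.1, n_participants), 0.0, 1.0)
    load_eff = {"low": 0.03, "medium": 0.0, "high": -0.03}
    rows = []
    for i in range(n_participants):
        for year in (1, 2):
            beta_aqi = truth.beta_aqi_cp_y1 if year == 1 else truth.beta_aqi_cp_y2
            yr_coded = -0.5 if year == 1 else 0.5
            for lev in ("low", "medium", "high"):
                mu = (0.55 + load_eff[lev] + b[i] + beta_aqi * offs[i]
                      + beta_year_ses * yr_coded * ses[i])
                rows.append((f"p{i:04d}", year, lev, ses[i],
                             "6mo" if i % 2 == 0 else "9mo", offs[i], lw1[i],
                             float(np.clip(mu + rng.normal(0.0, cell_sd), 0.0, 1.0))))
    return pd.DataFrame(
        rows,
        columns=["participant_id", "year", "load_level", "ses_score",
                 "cohort", "exposure", "looking_window1", "cp"],
    )


def write_dataset(
    outdir: str | Path,
    households: list[Household],
    truth: SynthTruth,
    aqi: pd.DataFrame | None = None,
    gaze: tuple[pd.DataFrame, pd.DataFrame] | None = None,
    assessments: pd.DataFrame | None = None,
) -> dict[str, Path]:
    """Write the generated tables and the truth ledger to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    hh = pd.DataFrame([asdict(h) for h in households])
    paths["households"] = outdir / "households.csv"
    hh.to_csv(paths["households"], index=False)
    paths["truth"] = outdir / "truth.json"
    paths["truth"].write_text(truth.to_json())
    if aqi is not None:
        paths["aqi_log"] = outdir / "aqi_log.csv"
        tmp = aqi.copy()
        tmp["timestamp"] = tmp["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S%z")
        tmp.to_csv(paths["aqi_log"], index=False)
    if gaze is not None:
        samples, trials = gaze
        paths["gaze_samples"] = outdir / "gaze_samples.csv"
        samples.to_csv(paths["gaze_samples"], index=False)
        paths["trials"] = outdir / "trials.csv"
        trials.to_csv(paths["trials"], index=False)
    if assessments is not None:
        paths["assessments"] = outdir / "assessments.csv"
        assessments.to_csv(paths["assessments"], index=False)
    return paths
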