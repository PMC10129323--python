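"""In-home air-quality processing and the household exposure model.

The raw input is a 10 s-cadence device log of US AQI readings per
household, collected in 3-day rounds.  Processing steps:

1. round-level QC — a household-round is kept only with >= 5 h coverage;
2. device plausibility filtering against configurable AQI bounds;
3. hourly downsampling (arithmetic mean per household-hour), which damps
   the strong 10 s autocorrelation;
4. an additive exposure model of hourly AQI on a tensor-product smooth of
   hour-of-day (cyclic) and date, plus shrunken household intercepts, fit
   by penalized least squares with AR(1) whitening (rho = 0.6) of
   consecutive within-round hours and smoothing weights chosen by GCV.

The centered household intercept is the single exposure score per home:
positive means poorer air than the sample grand mean, in AQI units.  The
module also carries the US EPA PM2.5 <-> AQI piecewise-linear conversion
and the health-band categorization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.interpolate import BSpline

__all__ = [
    "qc_rounds",
    "device_plausibility_filter",
    "downsample_hourly",
    "ExposureSpec",
    "ExposureModel",
    "fit_exposure_model",
    "extract_exposure",
    "pm25_to_aqi",
    "aqi_to_pm25",
    "aqi_category",
    "AQI_BREAKPOINTS",
]

# US EPA PM2.5 breakpoints (24 h, 2012 standard): (C_lo, C_hi, AQI_lo, AQI_hi)
AQI_BREAKPOINTS = [
    (0.0, 12.0, 0, 50),
    (12.1, 35.4, 51, 100),
    (35.5, 55.4, 101, 150),
    (55.5, 150.4, 151, 200),
    (150.5, 250.4, 201, 300),
    (250.5, 350.4, 301, 400),
    (350.5, 500.4, 401, 500),
]

_CATEGORIES = [
    (50, "good"),
    (100, "moderate"),
    (150, "unhealthy_sensitive"),
    (200, "unhealthy"),
    (300, "very_unhealthy"),
]


def pm25_to_aqi(conc: float) -> float:
    """US AQI value for a PM2.5 concentration (ug/m^3), piecewise linear."""
    c = float(conc)
    if c < 0:
        raise ValueError("concentration must be nonnegative")
    if c > AQI_BREAKPOINTS[-1][1]:
        warnings.warn("PM2.5 above breakpoint table; clamping", stacklevel=2)
        c = AQI_BREAKPOINTS[-1][1]
    for c_lo, c_hi, a_lo, a_hi in AQI_BREAKPOINTS:
        if c <= c_hi:
            c_eff = max(c, c_lo)
            return a_lo + (a_hi - a_lo) * (c_eff - c_lo) / (c_hi - c_lo)
    raise AssertionError("unreachable")


def aqi_to_pm25(aqi: float) -> float:
    """Inverse of :func:`pm25_to_aqi` (exact at every breakpoint)."""
    a = float(aqi)
    if a < 0:
        raise ValueError("AQI must be nonnegative")
    if a > AQI_BREAKPOINTS[-1][3]:
        warnings.warn("AQI above breakpoint table; clamping", stacklevel=2)
        a = AQI_BREAKPOINTS[-1][3]
    for c_lo, c_hi, a_lo, a_hi in AQI_BREAKPOINTS:
        if a <= a_hi:
            a_eff = max(a, a_lo)
            return c_lo + (c_hi - c_lo) * (a_eff - a_lo) / (a_hi - a_lo)
    raise AssertionError("unreachable")


def aqi_category(aqi: float) -> str:
    """Health band of an AQI value (good ... hazardous)."""
    if aqi < 0:
        raise ValueError("AQI must be nonnegative")
    for upper, label in _CATEGORIES:
        if aqi <= upper:
            return label
    return "hazardous"


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------

def qc_rounds(records: pd.DataFrame, min_hours: float = 5.0
              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop household-rounds with less than ``min_hours`` of recorded data.

    Coverage is the number of samples times the round's typical sampling
    interval (median timestamp difference).  The boundary is inclusive:
    exactly ``min_hours`` is retained.  Returns (retained records, report).
    """
    report_rows = []
    keep_keys = []
    for (hh, rnd), g in records.groupby(["household_id", "round_index"],
                                        observed=True, sort=True):
        if len(g) > 1:
            dt = g["timestamp"].sort_values().diff().dropna().dt.total_seconds()
            interval = float(np.median(dt))
        else:
            interval = 10.0
        coverage_h = len(g) * interval / 3600.0
        retained = coverage_h >= min_hours
        report_rows.append((hh, rnd, coverage_h, retained))
        if retained:
            keep_keys.append((hh, rnd))
    report = pd.DataFrame(
        report_rows, columns=["household_id", "round_index", "coverage_hours", "retained"]
    )
    idx = pd.MultiIndex.from_frame(records[["household_id", "round_index"]])
    retained_records = records[idx.isin(keep_keys)].reset_index(drop=True)
    return retained_records, report


def device_plausibility_filter(
    records: pd.DataFrame,
    bounds: tuple[float, float] = (1.0, 750.0),
    max_flag_fraction: float = 0.10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flag implausible readings and retire misbehaving devices.

    A reading outside ``bounds`` is flagged.  A device whose flagged
    fraction within a round exceeds ``max_flag_fraction`` is excluded from
    that round onward (retirement is forward-only: earlier rounds stand).
    Flagged readings from retained devices are dropped individually.
    Returns (retained records, per-device-round report).
    """
    lo, hi = bounds
    flagged = (records["aqi"] < lo) | (records["aqi"] > hi)
    report_rows = []
    retired_from: dict[str, int] = {}
    for (dev, rnd), g in records.groupby(["device_id", "round_index"],
                                         observed=True, sort=True):
        frac = float(flagged.loc[g.index].mean())
        excluded = frac > max_flag_fraction
        report_rows.append((dev, rnd, frac, excluded))
        if excluded and (dev not in retired_from or rnd < retired_from[dev]):
            retired_from[dev] = rnd
    report = pd.DataFrame(
        report_rows,
        columns=["device_id", "round_index", "flag_fraction", "excluded"],
    )
    drop = flagged.copy()
    for dev, rnd0 in retired_from.items():
        drop |= (records["device_id"] == dev) & (records["round_index"] >= rnd0)
    return records[~drop].reset_index(drop=True), report


def downsample_hourly(records: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean AQI per household-hour; empty hours are absent."""
    df = records.copy()
    ts = df["timestamp"]
    df["date"] = ts.dt.date.astype(str)
    df["hour"] = ts.dt.hour.astype(int)
    out = (
        df.groupby(["household_id", "round_index", "date", "hour"],
                   observed=True, sort=True)
        .agg(aqi_mean=("aqi", "mean"), n_samples=("aqi", "size"))
        .reset_index()
    )
    out["household_id"] = out["household_id"].astype(str)
    return out


# ---------------------------------------------------------------------------
# Exposure model: tensor-product P-spline + shrunken household intercepts
# ---------------------------------------------------------------------------

@dataclass
class ExposureSpec:
    k_hour: int = 11
    k_date: int = 11
    rho: float = 0.6
    spline_degree: int = 3


def _cyclic_basis(x: np.ndarray, k: int, period: float, degree: int = 3):
    """Cyclic B-spline design matrix with ``k`` coefficients over a period."""
    step = period / k
    knots = (np.arange(-degree, k + degree + 1) - 0.0) * step
    B = BSpline.design_matrix(np.mod(x, period), knots, degree).toarray()
    # fold wrapped columns back onto the first ones
    out = B[:, :k].copy()
    for j in range(k, B.shape[1]):
        out[:, j - k] += B[:, j]
    return out


def _open_basis(x: np.ndarray, k: int, degree: int = 3):
    """Clamped B-spline design matrix with ``k`` coefficients."""
    x0, x1 = float(np.min(x)), float(np.max(x))
    if x1 <= x0:
        x1 = x0 + 1.0
    inner = np.linspace(x0, x1, k - degree + 1)
    knots = np.r_[[x0] * degree, inner, [x1] * degree]
    xc = np.clip(x, x0, x1 - 1e-9 * (x1 - x0))
    return BSpline.design_matrix(xc, knots, degree).toarray()


def _diff_penalty(k: int, cyclic: bool) -> np.ndarray:
    if cyclic:
        D = np.zeros((k, k))
        for i in range(k):
            D[i, i] = 1.0
            D[i, (i + 1) % k] = -2.0
            D[i, (i + 2) % k] = 1.0
    else:
        D = np.diff(np.eye(k), n=2, axis=0)
    return D.T @ D


@dataclass
class ExposureModel:
    """Fitted exposure model: smooth surface + centered household scores."""

    spec: ExposureSpec
    coef: np.ndarray
    lambdas: np.ndarray  # (hour, date, household) penalty weights
    household_ids: list[str]
    household_intercepts: pd.Series  # centered, AQI units
    household_se: pd.Series          # approximate SEs of the intercepts
    grand_mean: float
    tensor_col_means: np.ndarray
    date_origin: float
    date_range: tuple[float, float]
    gcv: float
    n_obs: int
    edf: float

    def _tensor(self, hours: np.ndarray, dates: np.ndarray) -> np.ndarray:
        Bh = _cyclic_basis(hours, self.spec.k_hour, 24.0, self.spec.spline_degree)
        x0, x1 = self.date_range
        inner = np.linspace(x0, x1, self.spec.k_date - self.spec.spline_degree + 1)
        knots = np.r_[[x0] * self.spec.spline_degree, inner, [x1] * self.spec.spline_degree]
        dc = np.clip(dates, x0, x1 - 1e-9 * max(x1 - x0, 1.0))
        Bd = BSpline.design_matrix(dc, knots, self.spec.spline_degree).toarray()
        T = np.einsum("ij,ik->ijk", Bh, Bd).reshape(len(hours), -1)
        return T - self.tensor_col_means

    def predict_surface(self, hours, dates) -> np.ndarray:
        """Smooth surface value (grand-mean scale) at (hour, date) pairs."""
        hours = np.asarray(hours, dtype=float)
        dates = np.asarray(dates, dtype=float)
        T = self._tensor(hours, dates)
        p_t = self.spec.k_hour * self.spec.k_date
        return self.coef[0] + T @ self.coef[1 : 1 + p_t] + (
            self.grand_mean - self.coef[0]
        )

    def diurnal_profile(self, hours=None, n_dates: int = 25) -> pd.Series:
        """Fitted hour-of-day profile, averaged over the observed date span."""
        if hours is None:
            hours = np.arange(0, 24, 0.25)
        hours = np.asarray(hours, dtype=float)
        dates = np.linspace(self.date_range[0], self.date_range[1], n_dates)
        H, D = np.meshgrid(hours, dates)
        vals = self.predict_surface(H.ravel(), D.ravel()).reshape(n_dates, len(hours))
        return pd.Series(vals.mean(axis=0), index=hours, name="aqi")


def _whiten(X: np.ndarray, y: np.ndarray, hourly: pd.DataFrame, rho: float):
    """AR(1) whitening of consecutive within-round hourly rows.

    A row whose predecessor (same household-round) is exactly one hour
    earlier becomes row - rho * prev; chain breaks at gaps > 1 h.
    """
    t = (pd.to_datetime(hourly["date"]).astype("int64") // 10**9 // 3600
         + hourly["hour"]).to_numpy()
    hh = hourly["household_id"].to_numpy()
    rnd = hourly["round_index"].to_numpy()
    prev_ok = np.zeros(len(hourly), dtype=bool)
    prev_ok[1:] = (hh[1:] == hh[:-1]) & (rnd[1:] == rnd[:-1]) & (t[1:] - t[:-1] == 1)
    Xw = X.copy()
    yw = y.copy()
    Xw[prev_ok] -= rho * X[np.flatnonzero(prev_ok) - 1]
    yw[prev_ok] -= rho * y[np.flatnonzero(prev_ok) - 1]
    return Xw, yw


def fit_exposure_model(hourly: pd.DataFrame, spec: ExposureSpec = ExposureSpec()
                       ) -> ExposureModel:
    """Fit hourly AQI on hour x date tensor smooth + household intercepts.

    Penalized least squares: second-difference penalties on each tensor
    margin (cyclic on the hour margin), a ridge penalty shrinking the
    household intercepts, AR(1) whitening at the fixed rho, and smoothing
    weights chosen by generalized cross-validation.
    """
    req = {"household_id", "round_index", "date", "hour", "aqi_mean"}
    if not req.issubset(hourly.columns):
        raise ValueError(f"hourly table needs columns {sorted(req)}")
    hourly = hourly.sort_values(
        ["household_id", "round_index", "date", "hour"]
    ).reset_index(drop=True)
    hh_ids = sorted(hourly["household_id"].unique())
    if len(hh_ids) < 2:
        raise ValueError("need at least two households to identify an exposure model")
    hours = hourly["hour"].to_numpy(dtype=float) + 0.5  # bin midpoints
    date_num = (pd.to_datetime(hourly["date"]).astype("int64") // 10**9 / 86400.0
                ).to_numpy()
    date_num = date_num - date_num.min()
    n = len(hourly)
    if len(np.unique(np.floor(date_num))) < 4 or len(np.unique(hours)) < 4:
        raise ValueError(
            "too few distinct dates/hours for the tensor basis; "
            "collect more data or use a smaller basis dimension"
        )
    y = hourly["aqi_mean"].to_numpy(dtype=float)

    Bh = _cyclic_basis(hours, spec.k_hour, 24.0, spec.spline_degree)
    Bd = _open_basis(date_num, spec.k_date, spec.spline_degree)
    T = np.einsum("ij,ik->ijk", Bh, Bd).reshape(n, -1)
    col_means = T.mean(axis=0)
    T = T - col_means
    hh_index = pd.Categorical(hourly["household_id"], categories=hh_ids).codes
    Z = np.zeros((n, len(hh_ids)))
    Z[np.arange(n), hh_index] = 1.0
    X = np.hstack([np.ones((n, 1)), T, Z])

    Xw, yw = _whiten(X, y, hourly, spec.rho)
    B = Xw.T @ Xw
    v = Xw.T @ yw
    yy = float(yw @ yw)

    p_t = spec.k_hour * spec.k_date
    S_h = np.kron(_diff_penalty(spec.k_hour, cyclic=True), np.eye(spec.k_date))
    S_d = np.kron(np.eye(spec.k_hour), _diff_penalty(spec.k_date, cyclic=False))
    p = X.shape[1]

    def penalty(loglams: np.ndarray) -> np.ndarray:
        lh, ld, lr = np.exp(loglams)
        S = np.zeros((p, p))
        S[1 : 1 + p_t, 1 : 1 + p_t] = lh * S_h + ld * S_d
        idx = np.arange(1 + p_t, p)
        S[idx, idx] = lr
        return S

    def gcv_of(loglams: np.ndarray) -> float:
        S = penalty(loglams)
        try:
            M = np.linalg.solve(B + S, np.column_stack([v[:, None], B]))
        except np.linalg.LinAlgError:
            return np.inf
        beta = M[:, 0]
        edf = float(np.trace(M[:, 1:]))
        rss = yy - 2 * float(v @ beta) + float(beta @ B @ beta)
        denom = max(n - edf, 1.0)
        return n * rss / denom**2

    res = optimize.minimize(
        gcv_of, x0=np.log([1.0, 1.0, 1.0]), method="Nelder-Mead",
        options={"xatol": 0.1, "fatol": 1e-3 * np.var(y) if np.var(y) > 0 else 1e-6,
                 "maxiter": 200},
    )
    S = penalty(res.x)
    try:
        M = np.linalg.solve(B + S, np.column_stack([v[:, None], B]))
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "penalized system is singular; try a smaller basis dimension"
        ) from exc
    beta = M[:, 0]
    if not np.all(np.isfinite(beta)):
        raise ValueError("exposure model failed to converge to finite coefficients")
    edf = float(np.trace(M[:, 1:]))
    hh_eff = beta[1 + p_t :]
    grand = float(beta[0] + hh_eff.mean())
    centered = pd.Series(hh_eff - hh_eff.mean(), index=hh_ids, name="exposure_score")
    # sandwich variance of the penalized estimator under iid whitened errors
    rss = yy - 2 * float(v @ beta) + float(beta @ B @ beta)
    sigma2 = rss / max(n - edf, 1.0)
    Ainv_B = M[:, 1:]
    var_diag = sigma2 * np.einsum(
        "ij,ji->i", Ainv_B, np.linalg.solve(B + S, np.eye(p))
    )
    hh_se = pd.Series(np.sqrt(np.maximum(var_diag[1 + p_t :], 0.0)),
                      index=hh_ids, name="se")
    return ExposureModel(
        spec=spec,
        coef=beta,
        lambdas=np.exp(res.x),
        household_ids=hh_ids,
        household_intercepts=centered,
        household_se=hh_se,
        grand_mean=grand,
        tensor_col_means=col_means,
        date_origin=0.0,
        date_range=(float(date_num.min()), float(date_num.max())),
        gcv=float(res.fun),
        n_obs=n,
        edf=edf,
    )


def extract_exposure(model: ExposureModel) -> pd.DataFrame:
    """One centered exposure score per household, plus the grand mean.

    Adding ``grand_mean`` to a score recovers the visualization scale
    (an average household sits at the grand mean).
    """
    return pd.DataFrame(
        {
            "household_id": model.household_ids,
            "exposure_score": model.household_intercepts.to_numpy(),
            "grand_mean": model.grand_mean,
        }
    )
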