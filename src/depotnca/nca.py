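"""Per-profile noncompartmental analysis (NCA) for extravascular dosing.

Implements the standard parameter set reported for single-dose PK studies:
Cmax/Tmax/Tlast/Clast by direct observation, AUC by the linear-up/log-down
trapezoidal rule, the terminal elimination rate constant (lambda_z) by a
best-adjusted-R² log-linear suffix search, t1/2 = ln 2 / lambda_z,
extrapolation to infinity via Clast/lambda_z, apparent clearance CL/F =
dose / AUC0–∞, mean residence times from the first-moment curve, and
time-above-threshold with log-linear extrapolation past the last sample.

Units are fixed: hours, ng/mL (≡ µg/L), mg/kg, L/h/kg.  lambda_z is reported
in 1/h (report tables sometimes mislabel this unit; the half-life relation
t1/2 = ln 2 / lambda_z requires 1/h).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "Profile",
    "NCAOptions",
    "LambdaZFit",
    "ThresholdResult",
    "NCAResult",
    "NoQuantifiableDataError",
    "observed_extrema",
    "auc_segment",
    "aumc_segment",
    "auc_last",
    "aumc_last",
    "fit_lambda_z",
    "half_life",
    "auc_inf",
    "clearance_over_F",
    "mean_residence_time",
    "time_above_threshold",
    "run_nca",
]


class NoQuantifiableDataError(ValueError):
    """The profile contains no quantifiable (non-BLQ) observations."""


@dataclass(frozen=True)
class Profile:
    """One subject × analyte concentration–time series with its dose.

    ``times`` strictly increasing (hours); ``concs`` in ng/mL with NaN at
    censored points; ``blq`` flags below-quantitation observations.
    """

    subject_id: str
    analyte: str
    dose: float
    times: tuple[float, ...]
    concs: tuple[float, ...]
    blq: tuple[bool, ...]

    def __post_init__(self) -> None:
        t = tuple(float(x) for x in self.times)
        c = tuple(float(x) for x in self.concs)
        b = tuple(bool(x) for x in self.blq)
        if not (len(t) == len(c) == len(b)):
            raise ValueError("times, concs and blq must have equal length")
        if any(t2 <= t1 for t1, t2 in zip(t, t[1:])):
            raise ValueError("times must be strictly increasing")
        if any(x < 0 for x in t):
            raise ValueError("times must be non-negative")
        if any((not flag) and (math.isnan(x) or x < 0) for x, flag in zip(c, b)):
            raise ValueError("quantifiable concentrations must be non-negative numbers")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concs", c)
        object.__setattr__(self, "blq", b)

    @classmethod
    def from_points(
        cls,
        times: Sequence[float],
        concs: Sequence[float],
        *,
        dose: float = 1.0,
        blq: Sequence[bool] | None = None,
        subject_id: str = "subject",
        analyte: str = "parent",
    ) -> "Profile":
        """Convenience constructor; points are sorted by time."""
        order = np.argsort(np.asarray(times, dtype=float), kind="stable")
        t = [float(times[i]) for i in order]
        c = [float(concs[i]) for i in order]
        b = [bool(blq[i]) for i in order] if blq is not None else [False] * len(t)
        return cls(subject_id, analyte, dose, tuple(t), tuple(c), tuple(b))

    def quantifiable(self) -> tuple[np.ndarray, np.ndarray]:
        """(times, concs) of the non-BLQ points."""
        mask = ~np.asarray(self.blq)
        return np.asarray(self.times)[mask], np.asarray(self.concs)[mask]


@dataclass(frozen=True)
class NCAOptions:
    """Analysis switches.

    lambda_z selection searches suffixes of the post-Cmax quantifiable points
    (the Cmax point itself excluded), at least ``lambda_z_min_points`` each,
    keeping the best adjusted R²; fits within ``lambda_z_r2_tol`` of the best
    prefer more points.  ``clast_mode`` chooses the observed or the
    regression-predicted last concentration for the AUC tail.
    ``extrapolation_warn_pct`` flags profiles whose extrapolated AUC fraction
    exceeds the usual acceptance heuristic (a warning, never a failure).
    """

    lambda_z_min_points: int = 3
    lambda_z_r2_tol: float = 1e-4
    clast_mode: str = "observed"  # or "predicted"
    threshold: float | None = None
    extrapolation_warn_pct: float = 20.0

    def __post_init__(self) -> None:
        if self.lambda_z_min_points < 3:
            raise ValueError("lambda_z needs at least 3 points")
        if self.clast_mode not in ("observed", "predicted"):
            raise ValueError("clast_mode must be 'observed' or 'predicted'")


@dataclass(frozen=True)
class LambdaZFit:
    """Terminal log-linear regression: ln C = intercept − lambda_z · t."""

    lambda_z: float
    intercept: float
    n_points: int
    adj_r2: float
    window: tuple[float, float]

    def predict(self, t: float) -> float:
        return math.exp(self.intercept - self.lambda_z * t)


@dataclass(frozen=True)
class ThresholdResult:
    """Time-above-threshold summary.

    ``duration`` is crossing − onset; when no terminal fit exists and the
    curve is still above threshold at the last sample, the duration is a
    censored lower bound (``censored=True``) equal to tlast − onset.
    """

    onset: float | None
    duration: float
    censored: bool
    extrapolated: bool
    crossing: float | None


@dataclass(frozen=True)
class NCAResult:
    subject_id: str
    analyte: str
    dose: float
    cmax: float
    tmax: float
    tlast: float
    clast: float
    lambda_z_fit: LambdaZFit | None
    t_half: float | None
    auc_last: float
    auc_inf: float | None
    pct_extrapolated: float | None
    clearance_over_F: float | None
    mrt_last: float
    mrt_inf: float | None
    threshold: ThresholdResult | None
    flags: tuple[str, ...] = field(default_factory=tuple)


# ---------------------------------------------------------------------------
# observed quantities


def observed_extrema(profile: Profile) -> tuple[float, float, float, float]:
    """(cmax, tmax, tlast, clast) over the quantifiable points.

    Tmax takes the earliest time attaining the maximum (plateau tie-break).
    """
    t, c = profile.quantifiable()
    if len(t) == 0:
        raise NoQuantifiableDataError(
            f"profile {profile.subject_id}/{profile.analyte} has no quantifiable points"
        )
    imax = int(np.argmax(c))  # argmax returns the first maximal index
    return float(c[imax]), float(t[imax]), float(t[-1]), float(c[-1])


# ---------------------------------------------------------------------------
# trapezoidal segments


def auc_segment(t1: float, c1: float, t2: float, c2: float) -> float:
    """Area of one segment under the linear-up/log-down rule (ng·h/mL).

    Rising or flat segments, or segments touching zero, use the arithmetic
    trapezoid; strictly declining positive segments use the exact area under
    the exponential interpolant, (c1−c2)·Δt/ln(c1/c2).
    """
    if t2 <= t1:
        raise ValueError("segment times must be strictly increasing")
    if c1 < 0 or c2 < 0:
        raise ValueError("concentrations must be non-negative")
    dt = t2 - t1
    if c2 < c1 and c2 > 0.0:
        return (c1 - c2) * dt / math.log(c1 / c2)
    return 0.5 * (c1 + c2) * dt


def aumc_segment(t1: float, c1: float, t2: float, c2: float) -> float:
    """First-moment area ∫ t·C(t) dt of one segment (ng·h²/mL), under the
    same interpolant as :func:`auc_segment`."""
    if t2 <= t1:
        raise ValueError("segment times must be strictly increasing")
    if c1 < 0 or c2 < 0:
        raise ValueError("concentrations must be non-negative")
    dt = t2 - t1
    if c2 < c1 and c2 > 0.0:
        k = math.log(c1 / c2) / dt
        return (t1 * c1 - t2 * c2) / k + (c1 - c2) / (k * k)
    return 0.5 * (t1 * c1 + t2 * c2) * dt


def _working_series(profile: Profile) -> tuple[np.ndarray, np.ndarray]:
    """The point series AUC/AUMC integrate over.

    BLQ policy: leading BLQ samples (before the first quantifiable one) enter
    as zeros; embedded and trailing BLQ samples are excluded.  A (0, 0)
    anchor is prepended when the series starts after dose time, reflecting
    extravascular dosing with no drug on board at t = 0.
    """
    times = np.asarray(profile.times)
    concs = np.asarray(profile.concs)
    blq = np.asarray(profile.blq)
    quant_idx = np.flatnonzero(~blq)
    if len(quant_idx) == 0:
        raise NoQuantifiableDataError(
            f"profile {profile.subject_id}/{profile.analyte} has no quantifiable points"
        )
    first, last = quant_idx[0], quant_idx[-1]
    t_list = [times[i] for i in range(first)]  # leading BLQ as zeros
    c_list = [0.0] * first
    for i in range(first, last + 1):
        if blq[i]:
            continue  # embedded BLQ excluded
        t_list.append(times[i])
        c_list.append(concs[i])
    if t_list[0] > 0.0:
        t_list.insert(0, 0.0)
        c_list.insert(0, 0.0)
    return np.asarray(t_list), np.asarray(c_list)


def auc_last(profile: Profile) -> float:
    """AUC from dose time to the last quantifiable sample (ng·h/mL)."""
    t, c = _working_series(profile)
    return float(
        sum(auc_segment(t[i], c[i], t[i + 1], c[i + 1]) for i in range(len(t) - 1))
    )


def aumc_last(profile: Profile) -> float:
    """First-moment area to the last quantifiable sample (ng·h²/mL)."""
    t, c = _working_series(profile)
    return float(
        sum(aumc_segment(t[i], c[i], t[i + 1], c[i + 1]) for i in range(len(t) - 1))
    )


# ---------------------------------------------------------------------------
# terminal phase


def fit_lambda_z(profile: Profile, options: NCAOptions = NCAOptions()) -> LambdaZFit | None:
    """Select the terminal window and regress ln C on t.

    Candidates are the suffixes of the strictly-post-Tmax quantifiable points
    (Cmax excluded) with at least ``options.lambda_z_min_points`` points and
    all-positive concentrations.  The fit maximising adjusted R² wins; among
    fits within ``lambda_z_r2_tol`` of the best, the one using more points.
    Returns None when no candidate yields a declining terminal phase.
    """
    t, c = profile.quantifiable()
    _, tmax, _, _ = observed_extrema(profile)
    mask = (t > tmax) & (c > 0.0)
    tt, cc = t[mask], c[mask]
    n_total = len(tt)
    if n_total < options.lambda_z_min_points:
        return None
    best: LambdaZFit | None = None
    candidates: list[LambdaZFit] = []
    for start in range(0, n_total - options.lambda_z_min_points + 1):
        x, y = tt[start:], np.log(cc[start:])
        n = len(x)
        res = stats.linregress(x, y)
        if res.slope >= 0:
            continue
        r2 = res.rvalue**2
        adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
        candidates.append(
            LambdaZFit(
                lambda_z=-float(res.slope),
                intercept=float(res.intercept),
                n_points=n,
                adj_r2=float(adj_r2),
                window=(float(x[0]), float(x[-1])),
            )
        )
    if not candidates:
        return None
    best_r2 = max(f.adj_r2 for f in candidates)
    near_best = [f for f in candidates if f.adj_r2 >= best_r2 - options.lambda_z_r2_tol]
    best = max(near_best, key=lambda f: f.n_points)
    return best


def half_life(fit: LambdaZFit) -> float:
    """Terminal half-life ln 2 / lambda_z (hours)."""
    return math.log(2.0) / fit.lambda_z


def auc_inf(auc_last_value: float, clast: float, fit: LambdaZFit) -> tuple[float, float]:
    """(AUC0–∞, percent extrapolated): AUC0–∞ = AUC0–Tlast + Clast/lambda_z."""
    total = auc_last_value + clast / fit.lambda_z
    pct = 100.0 * (total - auc_last_value) / total if total > 0 else 0.0
    return total, pct


def clearance_over_F(dose: float, auc_inf_value: float) -> float:
    """Apparent clearance CL/F = dose / AUC0–∞ in L/h/kg.

    dose mg/kg → µg/kg over ng·h/mL ≡ µg·h/L gives L/h/kg exactly.
    """
    if auc_inf_value <= 0:
        raise ValueError("auc_inf must be strictly positive")
    return dose * 1e3 / auc_inf_value


def mean_residence_time(
    profile: Profile, fit: LambdaZFit | None, *, clast: float | None = None
) -> tuple[float, float | None]:
    """(MRT to Tlast, MRT to infinity) in hours.

    MRT = AUMC/AUC; the infinite-time moments add the exponential-tail terms
    Clast·Tlast/lambda_z + Clast/lambda_z² (AUMC) and Clast/lambda_z (AUC).
    The infinity variant is None when no terminal fit exists.
    """
    a_last = auc_last(profile)
    m_last = aumc_last(profile)
    mrt_l = m_last / a_last
    if fit is None:
        return mrt_l, None
    _, _, tlast, clast_obs = observed_extrema(profile)
    cl = clast if clast is not None else clast_obs
    lz = fit.lambda_z
    a_inf = a_last + cl / lz
    m_inf = m_last + cl * tlast / lz + cl / (lz * lz)
    return mrt_l, m_inf / a_inf


# ---------------------------------------------------------------------------
# therapeutic threshold


def time_above_threshold(
    times: Sequence[float],
    concs: Sequence[float],
    threshold: float,
    fit: LambdaZFit | None = None,
) -> ThresholdResult:
    """Onset and duration of the period the curve spends above ``threshold``.

    Works on any sampled curve (an individual profile's quantifiable points
    or a group mean curve).  Onset is the first *sampled* time at or above
    threshold — never interpolated before the first sample.  The downward
    crossing is log-linearly interpolated between samples, or extrapolated
    past the last sample as tlast + ln(clast/threshold)/lambda_z when a
    terminal fit is supplied; with no fit the duration is reported as a
    censored lower bound.
    """
    if threshold <= 0:
        raise ValueError("threshold must be strictly positive")
    t = np.asarray(times, dtype=float)
    c = np.asarray(concs, dtype=float)
    above = c >= threshold
    if not above.any():
        return ThresholdResult(None, 0.0, False, False, None)
    onset = float(t[int(np.argmax(above))])
    last_above = int(np.flatnonzero(above)[-1])
    if last_above == len(t) - 1:
        # still above threshold at the last sample
        tlast, clast = float(t[-1]), float(c[-1])
        if fit is not None:
            crossing = tlast + math.log(clast / threshold) / fit.lambda_z
            return ThresholdResult(onset, crossing - onset, False, True, crossing)
        return ThresholdResult(onset, tlast - onset, True, False, None)
    # interpolate the downward crossing on the declining segment
    t1, c1 = float(t[last_above]), float(c[last_above])
    t2, c2 = float(t[last_above + 1]), float(c[last_above + 1])
    if c1 > 0 and c2 > 0 and c2 < c1:
        crossing = t1 + (t2 - t1) * math.log(c1 / threshold) / math.log(c1 / c2)
    else:  # linear fallback for a segment touching zero
        crossing = t1 + (t2 - t1) * (c1 - threshold) / (c1 - c2)
    return ThresholdResult(onset, crossing - onset, False, False, crossing)


# ---------------------------------------------------------------------------
# orchestration


def run_nca(profile: Profile, options: NCAOptions = NCAOptions()) -> NCAResult:
    """Full per-profile NCA: every reported parameter or an explicit absence flag."""
    cmax, tmax, tlast, clast_obs = observed_extrema(profile)
    a_last = auc_last(profile)
    fit = fit_lambda_z(profile, options)
    flags: list[str] = []
    if fit is None:
        flags.append("lambda_z_not_estimable")
        t_half = a_inf = pct = cl_f = mrt_inf = None
        mrt_l, _ = mean_residence_time(profile, None)
    else:
        clast_used = fit.predict(tlast) if options.clast_mode == "predicted" else clast_obs
        t_half = half_life(fit)
        a_inf, pct = auc_inf(a_last, clast_used, fit)
        cl_f = clearance_over_F(profile.dose, a_inf)
        mrt_l, mrt_inf = mean_residence_time(profile, fit, clast=clast_used)
        if pct > options.extrapolation_warn_pct:
            flags.append(f"extrapolated_auc_above_{options.extrapolation_warn_pct:g}pct")
    thr = None
    if options.threshold is not None:
        t_q, c_q = profile.quantifiable()
        thr = time_above_threshold(t_q, c_q, options.threshold, fit)
    return NCAResult(
        subject_id=profile.subject_id,
        analyte=profile.analyte,
        dose=profile.dose,
        cmax=cmax,
        tmax=tmax,
        tlast=tlast,
        clast=clast_obs,
        lambda_z_fit=fit,
        t_half=t_half,
        auc_last=a_last,
        auc_inf=a_inf,
        pct_extrapolated=pct if fit is not None else None,
        clearance_over_F=cl_f,
        mrt_last=mrt_l,
        mrt_inf=mrt_inf,
        threshold=thr,
        flags=tuple(flags),
    )
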