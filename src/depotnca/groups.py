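"""Group-level reporting: mean ± SD curves, parameter summary tables,
exact nonparametric comparisons and dose-trend description.

The comparison of PK parameters between small treatment arms (n = 3–8) uses
the two-sided Mann–Whitney U test.  At these sizes the exact permutation
null is enumerable, so the exact p-value (conditional on the observed tie
pattern, U computed with mid-ranks) is the default; larger samples fall back
to the tie-corrected normal approximation, and every result records which
branch produced it.  Bonferroni adjustment takes an explicit family size —
the family is a study-design fact, never inferred from the data.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .nca import NCAResult
from .simulate import StudyDesign

__all__ = [
    "MeanCurve",
    "ComparisonResult",
    "TABLE_PARAMETERS",
    "mean_sd_curve",
    "results_frame",
    "summarize_parameters",
    "format_summary",
    "mann_whitney_exact",
    "mann_whitney",
    "bonferroni",
    "compare_groups",
    "dose_trend",
    "EXACT_LIMIT",
]

#: the ten parameters of the standard single-dose report table, in report order
TABLE_PARAMETERS = (
    "cmax",
    "tmax",
    "tlast",
    "t_half",
    "auc_last",
    "auc_inf",
    "clearance_over_F",
    "lambda_z",
    "mrt_last",
    "mrt_inf",
)

PARAMETER_LABELS = {
    "cmax": "Cmax (ng/mL)",
    "tmax": "Tmax (h)",
    "tlast": "Tlast (h)",
    "t_half": "t1/2 (h)",
    "auc_last": "AUC0-Tlast (ng*h/mL)",
    "auc_inf": "AUC0-inf (ng*h/mL)",
    "clearance_over_F": "Clearance (L/h/kg)",
    "lambda_z": "lambda_z (1/h)",
    "mrt_last": "MRT (h)",
    "mrt_inf": "MRT0-inf (h)",
}

#: largest combined sample size for which the exact permutation null is enumerated
EXACT_LIMIT = 20


@dataclass(frozen=True)
class MeanCurve:
    """Per-time-point arithmetic mean ± sample SD over quantifiable values."""

    group_label: str
    analyte: str
    times: tuple[float, ...]
    mean: tuple[float, ...]
    sd: tuple[float, ...]  # NaN where n < 2
    n: tuple[int, ...]


@dataclass(frozen=True)
class ComparisonResult:
    parameter: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    u_statistic: float
    p_exact: float
    p_adjusted: float
    method: str  # "exact" or "normal-approx"


# ---------------------------------------------------------------------------
# curves and summaries


def mean_sd_curve(table: pd.DataFrame, group_label: str, analyte: str) -> MeanCurve:
    """Mean ± SD concentration curve for one group × analyte.

    Only quantifiable (non-BLQ) values enter the mean; per-point n is
    reported so readers can see where censoring bit.  SD is the n−1 sample
    standard deviation, NaN when n < 2.
    """
    sub = table[(table["group_label"] == group_label) & (table["analyte"] == analyte)]
    sub = sub[~sub["blq"].astype(bool)]
    if sub.empty:
        return MeanCurve(group_label, analyte, (), (), (), ())
    g = sub.groupby("time_h")["conc_ng_per_ml"]
    agg = g.agg(["mean", "std", "count"]).sort_index()
    return MeanCurve(
        group_label,
        analyte,
        tuple(float(t) for t in agg.index),
        tuple(float(x) for x in agg["mean"]),
        tuple(float(x) for x in agg["std"]),
        tuple(int(x) for x in agg["count"]),
    )


def results_frame(results: list[NCAResult]) -> pd.DataFrame:
    """Flatten NCA results into a tidy frame, one row per subject × analyte."""
    rows = []
    for r in results:
        rows.append(
            {
                "subject_id": r.subject_id,
                "analyte": r.analyte,
                "dose_mg_per_kg": r.dose,
                "cmax": r.cmax,
                "tmax": r.tmax,
                "tlast": r.tlast,
                "clast": r.clast,
                "lambda_z": r.lambda_z_fit.lambda_z if r.lambda_z_fit else np.nan,
                "lambda_z_n_points": r.lambda_z_fit.n_points if r.lambda_z_fit else 0,
                "lambda_z_adj_r2": r.lambda_z_fit.adj_r2 if r.lambda_z_fit else np.nan,
                "t_half": r.t_half if r.t_half is not None else np.nan,
                "auc_last": r.auc_last,
                "auc_inf": r.auc_inf if r.auc_inf is not None else np.nan,
                "pct_extrapolated": (
                    r.pct_extrapolated if r.pct_extrapolated is not None else np.nan
                ),
                "clearance_over_F": (
                    r.clearance_over_F if r.clearance_over_F is not None else np.nan
                ),
                "mrt_last": r.mrt_last,
                "mrt_inf": r.mrt_inf if r.mrt_inf is not None else np.nan,
                "threshold_onset": (
                    r.threshold.onset if r.threshold and r.threshold.onset is not None else np.nan
                ),
                "threshold_duration": r.threshold.duration if r.threshold else np.nan,
                "threshold_censored": bool(r.threshold.censored) if r.threshold else False,
                "flags": ";".join(r.flags),
            }
        )
    return pd.DataFrame(rows)


def summarize_parameters(
    results: list[NCAResult],
    design: StudyDesign,
    group_of_subject: dict[str, str],
    analyte: str = "parent",
) -> pd.DataFrame:
    """Report-table summary: per parameter × group, mean, SD and the number
    of subjects for which the parameter was estimable.

    Returns a tidy frame (parameter, group_label, mean, sd, n); SD is NaN
    when n < 2, rows with n = 0 keep NaN mean.
    """
    df = results_frame([r for r in results if r.analyte == analyte])
    df["group_label"] = df["subject_id"].map(group_of_subject)
    rows = []
    for param in TABLE_PARAMETERS:
        for group in design.groups:
            vals = df.loc[df["group_label"] == group.label, param].dropna()
            rows.append(
                {
                    "parameter": param,
                    "label": PARAMETER_LABELS[param],
                    "group_label": group.label,
                    "mean": float(vals.mean()) if len(vals) else np.nan,
                    "sd": float(vals.std(ddof=1)) if len(vals) >= 2 else np.nan,
                    "n": int(len(vals)),
                }
            )
    return pd.DataFrame(rows)


def format_summary(summary: pd.DataFrame) -> str:
    """Human-readable 'mean ± sd' table, parameters as rows, groups as columns."""
    groups = list(dict.fromkeys(summary["group_label"]))
    width = max(len(g) for g in groups) + 2
    lwidth = max(len(l) for l in summary["label"]) + 2
    lines = ["".ljust(lwidth) + "".join(g.ljust(width) for g in groups)]
    for param in dict.fromkeys(summary["parameter"]):
        block = summary[summary["parameter"] == param]
        label = block["label"].iloc[0]
        cells = []
        for g in groups:
            row = block[block["group_label"] == g].iloc[0]
            if row["n"] == 0 or math.isnan(row["mean"]):
                cells.append("-".ljust(width))
            elif math.isnan(row["sd"]):
                cells.append(f"{row['mean']:.2f} (n={row['n']})".ljust(width))
            else:
                cells.append(f"{row['mean']:.2f} ± {row['sd']:.2f}".ljust(width))
        lines.append(label.ljust(lwidth) + "".join(cells))
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# Mann–Whitney


def _u_statistic(ranks: np.ndarray, nx: int, ny: int) -> float:
    """U for the first sample from mid-ranks of the combined sample
    (first nx entries belong to x)."""
    rank_sum_x = float(ranks[:nx].sum())
    return rank_sum_x - nx * (nx + 1) / 2.0


def mann_whitney_exact(x, y) -> tuple[float, float]:
    """Exact two-sided Mann–Whitney U test by full enumeration.

    U uses mid-ranks, so ties are handled; the null distribution is built by
    enumerating all C(nx+ny, nx) assignments of the observed values to the
    two groups (conditional on the tie pattern).  The two-sided p-value is
    the null probability of a U at least as far from its mean nx·ny/2 as the
    observed one.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx == 0 or ny == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    u_obs = _u_statistic(ranks, nx, ny)
    mu = nx * ny / 2.0
    dev_obs = abs(u_obs - mu)
    n = nx + ny
    # all assignments: which positions of the combined sample go to group x
    idx = np.fromiter(
        itertools.chain.from_iterable(itertools.combinations(range(n), nx)),
        dtype=np.intp,
    ).reshape(-1, nx)
    rank_sums = ranks[idx].sum(axis=1)
    u_all = rank_sums - nx * (nx + 1) / 2.0
    p = float(np.mean(np.abs(u_all - mu) >= dev_obs - 1e-12))
    return u_obs, p


def mann_whitney(x, y) -> tuple[float, float, str]:
    """(U, two-sided p, method tag); exact by enumeration for combined
    n ≤ EXACT_LIMIT, tie-corrected normal approximation above."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    if len(x) + len(y) <= EXACT_LIMIT:
        u, p = mann_whitney_exact(x, y)
        return u, p, "exact"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue), "normal-approx"


def bonferroni(p_values, family_size: int) -> list[float]:
    """Bonferroni adjustment: p → min(1, m·p) with explicit family size m."""
    if family_size < 1:
        raise ValueError("family size must be at least 1")
    return [min(1.0, family_size * float(p)) for p in p_values]


def compare_groups(
    results: list[NCAResult],
    group_of_subject: dict[str, str],
    pairs: list[tuple[str, str]],
    parameters=TABLE_PARAMETERS,
    *,
    analyte: str = "parent",
    family_size: int | None = None,
) -> list[ComparisonResult]:
    """Pairwise Mann–Whitney comparisons of NCA parameters between groups.

    ``family_size`` defaults to the number of tests performed (pairs ×
    parameters with data); pass 1 for unadjusted p-values.
    """
    df = results_frame([r for r in results if r.analyte == analyte])
    df["group_label"] = df["subject_id"].map(group_of_subject)
    raw: list[tuple[str, str, str, int, int, float, float, str]] = []
    for a, b in pairs:
        for param in parameters:
            xa = df.loc[df["group_label"] == a, param].dropna().to_numpy()
            xb = df.loc[df["group_label"] == b, param].dropna().to_numpy()
            if len(xa) == 0 or len(xb) == 0:
                continue
            u, p, method = mann_whitney(xa, xb)
            raw.append((param, a, b, len(xa), len(xb), u, p, method))
    m = family_size if family_size is not None else max(len(raw), 1)
    adjusted = bonferroni([r[6] for r in raw], m)
    return [
        ComparisonResult(param, a, b, na, nb, u, p, p_adj, method)
        for (param, a, b, na, nb, u, p, method), p_adj in zip(raw, adjusted)
    ]


def dose_trend(summary: pd.DataFrame, design: StudyDesign, formulation: str = "EXR") -> dict:
    """Descriptive dose trend across the arms of one formulation.

    Reports whether group-mean Cmax and AUC0–Tlast strictly increase with
    dose, and the log-log slope of each against dose (1.0 under exact dose
    proportionality).  Purely descriptive — no inferential claim.
    """
    arms = sorted(
        (g for g in design.groups if g.formulation == formulation), key=lambda g: g.dose
    )
    if len(arms) < 2:
        raise ValueError("dose trend needs at least two arms of the formulation")
    doses = np.array([g.dose for g in arms])
    out: dict = {"formulation": formulation, "doses": [float(d) for d in doses]}
    for param in ("cmax", "auc_last"):
        means = np.array(
            [
                float(
                    summary.loc[
                        (summary["parameter"] == param)
                        & (summary["group_label"] == g.label),
                        "mean",
                    ].iloc[0]
                )
                for g in arms
            ]
        )
        increasing = bool(np.all(np.diff(means) > 0))
        slope = float(
            stats.linregress(np.log(doses), np.log(means)).slope
        ) if np.all(means > 0) else float("nan")
        out[param] = {
            "means": [float(x) for x in means],
            "strictly_increasing": increasing,
            "loglog_slope": slope,
        }
    return out
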