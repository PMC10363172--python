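"""Synthetic concentration–time data for extended-release depot formulations.

The generator is a two-depot, one-compartment model: a subcutaneous dose is
split between a fast and a slow first-order absorption depot, both feeding a
single disposition compartment with first-order elimination.  Superposing two
Bateman functions is the minimal mechanism that produces both the rapid onset
(quantifiable drug within the first sampling time) and the multi-day
persistence characteristic of extended-release buprenorphine depots; a single
depot is the ``frac_fast = 1`` special case.

Units are fixed throughout: time in hours, dose in mg/kg, volumes in L/kg,
concentrations in ng/mL (≡ µg/L).  Microsome time courses use minutes and µM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PKParameters",
    "MetaboliteParams",
    "PopulationParams",
    "StudyDesign",
    "GroupSpec",
    "MicrosomePreset",
    "MICROSOME_PRESETS",
    "DEFAULT_POPULATION",
    "paper_design",
    "default_population",
    "dual_bateman_concentration",
    "metabolite_concentration",
    "simulate_subject",
    "censor_lloq",
    "simulate_study",
    "simulate_microsome_timecourse",
]

#: relative tolerance below which two first-order rates are treated as equal
#: (the superposed-Bateman closed form is singular at ka == ke)
RATE_EPSILON = 1e-9


class DegenerateRateError(ValueError):
    """Raised when an absorption rate coincides with elimination and nudging is disabled."""


@dataclass(frozen=True)
class PKParameters:
    """Subject-level disposition and absorption parameters.

    ``clearance_over_F`` (L/h/kg) and ``volume_over_F`` (L/kg) are apparent
    (bioavailability-scaled) values; ``ke = CL/F / V/F`` is derived.
    """

    clearance_over_F: float
    volume_over_F: float
    ka_fast: float
    ka_slow: float
    frac_fast: float

    def __post_init__(self) -> None:
        for name in ("clearance_over_F", "volume_over_F", "ka_fast", "ka_slow"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0.0 <= self.frac_fast <= 1.0:
            raise ValueError("frac_fast must lie in [0, 1]")

    @property
    def ke(self) -> float:
        return self.clearance_over_F / self.volume_over_F

    def nudged(self) -> "PKParameters":
        """Return parameters with absorption rates nudged off the ke singularity.

        A relative nudge of ``RATE_EPSILON`` is applied whenever
        ``|ka - ke|/ke < RATE_EPSILON``; the Bateman closed form is singular
        at equality and the perturbation is far below any observable effect.
        """
        ke = self.ke
        ka_f, ka_s = self.ka_fast, self.ka_slow
        if abs(ka_f - ke) / ke < RATE_EPSILON:
            ka_f = ke * (1.0 + RATE_EPSILON)
        if abs(ka_s - ke) / ke < RATE_EPSILON:
            ka_s = ke * (1.0 + RATE_EPSILON)
        if ka_f == self.ka_fast and ka_s == self.ka_slow:
            return self
        return replace(self, ka_fast=ka_f, ka_slow=ka_s)


@dataclass(frozen=True)
class MetaboliteParams:
    """First-order formation of a single metabolite from parent elimination.

    ``fm`` is the fraction of parent elimination converted to metabolite;
    ``ke_m`` (1/h) its elimination rate; ``volume_m_over_F`` (L/kg) its
    apparent distribution volume.
    """

    fm: float
    volume_m_over_F: float
    ke_m: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.fm <= 1.0:
            raise ValueError("fm must lie in [0, 1]")
        if not self.volume_m_over_F > 0 or not self.ke_m > 0:
            raise ValueError("metabolite volume and rate must be strictly positive")


@dataclass(frozen=True)
class PopulationParams:
    """Typical values plus between-subject and residual variability.

    ``bsv_cv`` maps parameter names (fields of :class:`PKParameters`) to
    log-normal between-subject coefficients of variation; parameters not
    listed are fixed at their typical value.  ``residual_cv`` is the
    proportional (log-normal) assay/residual error CV.
    """

    typical: PKParameters
    bsv_cv: dict[str, float] = field(default_factory=dict)
    residual_cv: float = 0.0
    metabolite: MetaboliteParams | None = None

    def __post_init__(self) -> None:
        if any(cv < 0 for cv in self.bsv_cv.values()) or self.residual_cv < 0:
            raise ValueError("coefficients of variation must be non-negative")

    def draw_subject(self, rng: np.random.Generator) -> PKParameters:
        """Draw one subject's parameters log-normally around the typical values.

        The log-normal is parameterised so the *median* equals the typical
        value, preserving positivity for every parameter.  ``frac_fast`` is
        perturbed on the logit scale to stay inside [0, 1].
        """
        values = {}
        for name in ("clearance_over_F", "volume_over_F", "ka_fast", "ka_slow"):
            typ = getattr(self.typical, name)
            cv = self.bsv_cv.get(name, 0.0)
            if cv > 0:
                sigma = math.sqrt(math.log(1.0 + cv * cv))
                values[name] = typ * math.exp(rng.normal(0.0, sigma))
            else:
                values[name] = typ
        f = self.typical.frac_fast
        cv_f = self.bsv_cv.get("frac_fast", 0.0)
        if cv_f > 0 and 0.0 < f < 1.0:
            logit = math.log(f / (1.0 - f)) + rng.normal(0.0, cv_f)
            f = 1.0 / (1.0 + math.exp(-logit))
        values["frac_fast"] = f
        return PKParameters(**values)


@dataclass(frozen=True)
class GroupSpec:
    """One treatment arm: label, formulation tag, dose (mg/kg), group size."""

    label: str
    formulation: str
    dose: float
    n: int

    def __post_init__(self) -> None:
        if not self.dose > 0:
            raise ValueError("dose must be strictly positive")
        if self.n < 1:
            raise ValueError("group size must be at least 1")


@dataclass(frozen=True)
class StudyDesign:
    """Trial structure: arms, sampling schedule (h), assay LLOQ and the
    therapeutic threshold (both ng/mL)."""

    groups: tuple[GroupSpec, ...]
    schedule: tuple[float, ...]
    lloq: float
    threshold: float

    def __post_init__(self) -> None:
        sched = tuple(self.schedule)
        if any(t <= 0 for t in sched) or any(b <= a for a, b in zip(sched, sched[1:])):
            raise ValueError("schedule must be strictly increasing with all times > 0")
        if not self.lloq > 0:
            raise ValueError("lloq must be strictly positive")
        if not self.threshold > 0:
            raise ValueError("threshold must be strictly positive")
        object.__setattr__(self, "groups", tuple(self.groups))
        object.__setattr__(self, "schedule", sched)

    @property
    def n_subjects(self) -> int:
        return sum(g.n for g in self.groups)


def paper_design() -> StudyDesign:
    """The marmoset extended-release buprenorphine crossover-free design:
    four arms (one compounded sustained-release, three doses of the
    pharmaceutical product), seven samples over 72 h, 0.1 ng/mL LLOQ and
    therapeutic threshold."""
    return StudyDesign(
        groups=(
            GroupSpec("BSR 0.15 mg/kg", "BSR", 0.15, 8),
            GroupSpec("EXR 0.1 mg/kg", "EXR", 0.10, 6),
            GroupSpec("EXR 0.15 mg/kg", "EXR", 0.15, 3),
            GroupSpec("EXR 0.2 mg/kg", "EXR", 0.20, 8),
        ),
        schedule=(0.25, 0.5, 1.0, 8.0, 24.0, 48.0, 72.0),
        lloq=0.1,
        threshold=0.1,
    )


#: typical marmoset-scale values: CL/F and t1/2 in the band reported for
#: extended-release buprenorphine (CL/F ~ 1.7-2.3 L/h/kg, t1/2 ~ 20-37 h),
#: with the fast depot dominating so peak concentrations at 0.1-0.2 mg/kg
#: land in the observed 1.4-2.5 ng/mL window around 5-8 h post-dose.
DEFAULT_TYPICAL = PKParameters(
    clearance_over_F=1.9,
    volume_over_F=57.5,
    ka_fast=0.6,
    ka_slow=0.08,
    frac_fast=0.8,
)

#: metabolite defaults place its typical curve just above a 0.1 ng/mL LLOQ
#: from ~8 h through 72 h, lagging the parent peak by ~20 h
DEFAULT_METABOLITE = MetaboliteParams(fm=0.5, volume_m_over_F=80.0, ke_m=0.06)

DEFAULT_POPULATION = PopulationParams(
    typical=DEFAULT_TYPICAL,
    bsv_cv={
        "clearance_over_F": 0.3,
        "volume_over_F": 0.3,
        "ka_fast": 0.5,
        "ka_slow": 0.5,
    },
    residual_cv=0.15,
    metabolite=DEFAULT_METABOLITE,
)


def default_population(residual_cv: float | None = None) -> PopulationParams:
    """The shipped population model, optionally overriding the residual CV."""
    if residual_cv is None:
        return DEFAULT_POPULATION
    return replace(DEFAULT_POPULATION, residual_cv=residual_cv)


# ---------------------------------------------------------------------------
# mechanistic curves


def _bateman(t, dose_ug_per_kg: float, v: float, ka: float, ke: float):
    # one-depot Bateman: first-order absorption into first-order elimination
    return (
        dose_ug_per_kg
        / v
        * ka
        / (ka - ke)
        * (np.exp(-ke * np.asarray(t, dtype=float)) - np.exp(-ka * np.asarray(t, dtype=float)))
    )


def dual_bateman_concentration(t, dose: float, p: PKParameters, *, nudge: bool = True):
    """Parent concentration (ng/mL) at time(s) ``t`` hours after a
    subcutaneous ``dose`` in mg/kg.

    Superposition of two Bateman functions sharing one disposition
    compartment.  The mg/kg → µg/kg dose conversion makes the output
    µg/L ≡ ng/mL.  Scalar in, scalar out; array in, array out.
    """
    if dose <= 0:
        raise ValueError("dose must be strictly positive")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be non-negative")
    if nudge:
        p = p.nudged()
    ke = p.ke
    for ka in (p.ka_fast, p.ka_slow):
        if abs(ka - ke) / ke < RATE_EPSILON:
            raise DegenerateRateError(
                f"absorption rate {ka} coincides with elimination rate {ke}"
            )
    dose_ug = dose * 1e3
    c = p.frac_fast * _bateman(t_arr, dose_ug, p.volume_over_F, p.ka_fast, ke) + (
        1.0 - p.frac_fast
    ) * _bateman(t_arr, dose_ug, p.volume_over_F, p.ka_slow, ke)
    c = np.maximum(c, 0.0)  # clip roundoff at t=0
    return float(c) if np.isscalar(t) or t_arr.ndim == 0 else c


def _chain_amount(t, a0: float, k1: float, k2: float, k3: float):
    """Amount in the third compartment of a linear cascade a0 --k1--> --k2--> --k3-->.

    Three-exponential closed form; requires the three rates pairwise distinct.
    """
    t = np.asarray(t, dtype=float)
    denom = lambda a, b, c: (b - a) * (c - a)
    return (
        a0
        * k1
        * k2
        * (
            np.exp(-k1 * t) / denom(k1, k2, k3)
            + np.exp(-k2 * t) / denom(k2, k1, k3)
            + np.exp(-k3 * t) / denom(k3, k1, k2)
        )
    )


def metabolite_concentration(
    t, dose: float, p: PKParameters, m: MetaboliteParams, *, nudge: bool = True
):
    """Metabolite concentration (ng/mL) from the depot → parent → metabolite
    first-order cascade, superposed over the two depots.

    A fraction ``m.fm`` of parent elimination forms metabolite, which is
    cleared at ``m.ke_m``.  Closed three-exponential form per depot; the
    cascade rates are nudged apart when numerically coincident.
    """
    if dose <= 0:
        raise ValueError("dose must be strictly positive")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be non-negative")
    if m.fm == 0.0:
        z = np.zeros_like(t_arr)
        return float(z) if np.isscalar(t) or t_arr.ndim == 0 else z
    if nudge:
        p = p.nudged()
    ke = p.ke
    ke_m = m.ke_m

    def one_depot(ka: float) -> np.ndarray:
        k1, k2, k3 = ka, ke, ke_m
        # nudge pairwise-coincident cascade rates off the singular manifold
        if abs(k3 - k1) / k1 < RATE_EPSILON:
            k3 = k1 * (1.0 + RATE_EPSILON)
        if abs(k3 - k2) / k2 < RATE_EPSILON:
            k3 = k2 * (1.0 + RATE_EPSILON)
        if abs(k1 - k2) / k2 < RATE_EPSILON:
            raise DegenerateRateError("absorption rate coincides with elimination rate")
        return _chain_amount(t_arr, dose * 1e3, k1, k2, k3)

    amount = m.fm * (
        p.frac_fast * one_depot(p.ka_fast)
        + (1.0 - p.frac_fast) * one_depot(p.ka_slow)
    )
    c = np.maximum(amount / m.volume_m_over_F, 0.0)
    return float(c) if np.isscalar(t) or t_arr.ndim == 0 else c


# ---------------------------------------------------------------------------
# study simulation


def simulate_subject(
    p: PKParameters,
    dose: float,
    schedule: Sequence[float],
    residual_cv: float,
    rng: np.random.Generator,
    *,
    metabolite: MetaboliteParams | None = None,
) -> pd.DataFrame:
    """Simulate one subject's sampled concentrations.

    Returns a tidy frame with columns ``analyte`` (parent, and metabolite if
    given), ``time_h`` and ``conc_ng_per_ml``.  Residual error is proportional
    log-normal with CV ``residual_cv`` (median-preserving); ``residual_cv = 0``
    reproduces the noise-free model values exactly.
    """
    if residual_cv < 0:
        raise ValueError("residual_cv must be non-negative")
    times = np.asarray(schedule, dtype=float)
    rows = []
    curves = {"parent": dual_bateman_concentration(times, dose, p)}
    if metabolite is not None:
        curves["metabolite"] = metabolite_concentration(times, dose, p, metabolite)
    for analyte, clean in curves.items():
        if residual_cv > 0:
            sigma = math.sqrt(math.log(1.0 + residual_cv**2))
            noisy = clean * np.exp(rng.normal(0.0, sigma, size=len(times)))
        else:
            noisy = np.asarray(clean, dtype=float)
        for t, c in zip(times, noisy):
            rows.append({"analyte": analyte, "time_h": t, "conc_ng_per_ml": c})
    return pd.DataFrame(rows)


def censor_lloq(table: pd.DataFrame, lloq: float) -> pd.DataFrame:
    """Flag concentrations below the quantitation limit.

    Adds/overwrites a ``blq`` column (True where ``conc < lloq``; the boundary
    value ``conc == lloq`` is quantifiable) and blanks the numeric value of
    censored rows: the analysis layer, not the file, owns any imputation.
    Row count and non-censored values are unchanged.
    """
    out = table.copy()
    below = out["conc_ng_per_ml"] < lloq
    out["blq"] = below
    out.loc[below, "conc_ng_per_ml"] = np.nan
    return out


def simulate_study(
    design: StudyDesign,
    pop: PopulationParams,
    seed: int,
) -> tuple[pd.DataFrame, dict[str, dict]]:
    """Simulate a full study: one profile per subject per analyte.

    Returns ``(table, truth)`` where ``table`` is the canonical concentration
    table (columns ``subject_id, group_label, formulation, dose_mg_per_kg,
    analyte, time_h, conc_ng_per_ml, blq``) and ``truth`` maps subject id to
    the simulated individual parameters, for parameter-recovery checks.

    Reproducibility: each subject draws from its own child generator spawned
    deterministically from the root seed, so changing one group's size never
    perturbs another subject's data.
    """
    root = np.random.SeedSequence(seed)
    frames = []
    truth: dict[str, dict] = {}
    subj_idx = 0
    children = root.spawn(design.n_subjects)
    for group in design.groups:
        for i in range(group.n):
            child = children[subj_idx]
            subj_idx += 1
            rng = np.random.default_rng(child)
            subject_id = f"{group.formulation}{group.dose:g}-{i + 1:02d}"
            p = pop.draw_subject(rng)
            prof = simulate_subject(
                p, group.dose, design.schedule, pop.residual_cv, rng,
                metabolite=pop.metabolite,
            )
            prof.insert(0, "subject_id", subject_id)
            prof.insert(1, "group_label", group.label)
            prof.insert(2, "formulation", group.formulation)
            prof.insert(3, "dose_mg_per_kg", group.dose)
            frames.append(prof)
            truth[subject_id] = {
                "group_label": group.label,
                "dose_mg_per_kg": group.dose,
                "clearance_over_F": p.clearance_over_F,
                "volume_over_F": p.volume_over_F,
                "ka_fast": p.ka_fast,
                "ka_slow": p.ka_slow,
                "frac_fast": p.frac_fast,
                "ke": p.ke,
                "t_half": math.log(2.0) / min(p.ke, p.ka_slow),
            }
    table = censor_lloq(pd.concat(frames, ignore_index=True), design.lloq)
    return table, truth


# ---------------------------------------------------------------------------
# in-vitro microsome time courses


@dataclass(frozen=True)
class MicrosomePreset:
    """A -> B -> (cleared) first-order kinetics for a liver-microsome
    depletion assay: parent depleted at ``k_dep`` (1/min), of which ``k_form``
    forms the metabolite, itself cleared onward at ``k_out``; ``c0`` is the
    starting substrate concentration in µM."""

    species: str
    k_dep: float
    k_form: float
    k_out: float
    c0: float

    def __post_init__(self) -> None:
        if min(self.k_dep, self.k_form, self.k_out) < 0:
            raise ValueError("rates must be non-negative")
        if self.k_form > self.k_dep:
            raise ValueError("k_form cannot exceed k_dep (formation is a branch of depletion)")
        if not self.c0 > 0:
            raise ValueError("c0 must be strictly positive")


#: species presets reproducing the qualitative in-vitro pattern: marmoset and
#: macaque microsomes deplete the parent within 15 min while human microsomes
#: do not; macaque metabolite is cleared by 45-60 min; marmoset (and human)
#: metabolite plateaus and persists through 60 min.
MICROSOME_PRESETS: dict[str, MicrosomePreset] = {
    "marmoset": MicrosomePreset("marmoset", k_dep=0.5, k_form=0.35, k_out=0.002, c0=10.0),
    "macaque": MicrosomePreset("macaque", k_dep=0.5, k_form=0.40, k_out=0.15, c0=10.0),
    "human": MicrosomePreset("human", k_dep=0.05, k_form=0.04, k_out=0.003, c0=10.0),
}

#: assay sampling grid in minutes
MICROSOME_GRID = (0.0, 5.0, 10.0, 15.0, 30.0, 45.0, 60.0)


def simulate_microsome_timecourse(
    preset: MicrosomePreset, t_grid: Sequence[float] = MICROSOME_GRID
) -> pd.DataFrame:
    """Closed-form parent and metabolite time courses (µM) on ``t_grid`` minutes.

    parent(t)    = c0·exp(−k_dep·t)
    metabolite(t)= c0·k_form/(k_out−k_dep)·(exp(−k_dep·t) − exp(−k_out·t)),
    degenerating to c0·k_form·t·exp(−k_dep·t) when k_out = k_dep.
    """
    t = np.asarray(t_grid, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    parent = preset.c0 * np.exp(-preset.k_dep * t)
    if preset.k_form == 0.0:
        metab = np.zeros_like(t)
    elif abs(preset.k_out - preset.k_dep) < 1e-12 * max(preset.k_dep, 1.0):
        metab = preset.c0 * preset.k_form * t * np.exp(-preset.k_dep * t)
    else:
        metab = (
            preset.c0
            * preset.k_form
            / (preset.k_out - preset.k_dep)
            * (np.exp(-preset.k_dep * t) - np.exp(-preset.k_out * t))
        )
    return pd.DataFrame(
        {
            "species": preset.species,
            "time_min": t,
            "parent_uM": parent,
            "metabolite_uM": np.maximum(metab, 0.0),
        }
    )
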