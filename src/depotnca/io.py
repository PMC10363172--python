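"""File formats and run configuration.

The interchange format is a plain CSV, one row per subject × time × analyte:

    subject_id, group_label, formulation, dose_mg_per_kg, analyte,
    time_h, conc_ng_per_ml, blq

``blq`` is 0/1; a missing concentration is permitted (and expected) only on
censored rows.  Reading validates the invariants, sorts canonically, and
round-trips byte-stably with :func:`write_concentration_table`.  Run
configuration is a JSON document validated by pydantic; every run writes the
fully resolved configuration next to its outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from . import groups as grp
from .nca import NCAOptions, NCAResult, Profile
from .simulate import (
    DEFAULT_POPULATION,
    GroupSpec,
    MetaboliteParams,
    PKParameters,
    PopulationParams,
    StudyDesign,
    paper_design,
)

__all__ = [
    "COLUMNS",
    "read_concentration_table",
    "write_concentration_table",
    "profiles_from_table",
    "RunConfig",
    "write_results",
]

log = logging.getLogger("depotnca")

COLUMNS = [
    "subject_id",
    "group_label",
    "formulation",
    "dose_mg_per_kg",
    "analyte",
    "time_h",
    "conc_ng_per_ml",
    "blq",
]


class TableFormatError(ValueError):
    """The concentration table violates the format contract."""


def read_concentration_table(path) -> pd.DataFrame:
    """Read and validate a concentration-table CSV.

    Unknown columns are preserved but ignored.  Hard errors: missing
    required columns, duplicate (subject, analyte, time) rows, negative
    times or concentrations, and BLQ inconsistencies (a numeric value on a
    censored row, or a missing value on a quantifiable one).
    """
    df = pd.read_csv(path)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"missing required columns: {missing}")
    if df.empty:
        log.warning("concentration table %s is empty (header only)", path)
        df["blq"] = df["blq"].astype(bool)
        return df
    df["blq"] = df["blq"].astype(int).astype(bool)
    dup = df.duplicated(subset=["subject_id", "analyte", "time_h"], keep=False)
    if dup.any():
        offenders = df.loc[dup, ["subject_id", "analyte", "time_h"]].drop_duplicates()
        raise TableFormatError(
            "duplicate (subject, analyte, time) rows: "
            + "; ".join(
                f"{r.subject_id}/{r.analyte}@{r.time_h}h" for r in offenders.itertuples()
            )
        )
    if (df["time_h"] < 0).any():
        raise TableFormatError("negative sampling times present")
    quant = ~df["blq"]
    if df.loc[quant, "conc_ng_per_ml"].isna().any():
        raise TableFormatError("quantifiable rows with missing concentration")
    if (df.loc[quant, "conc_ng_per_ml"] < 0).any():
        raise TableFormatError("negative concentrations present")
    if df.loc[df["blq"], "conc_ng_per_ml"].notna().any():
        raise TableFormatError("censored (blq=1) rows must not carry a concentration")
    df = df.sort_values(["subject_id", "analyte", "time_h"], kind="stable").reset_index(
        drop=True
    )
    log.info(
        "read %d rows, %d subjects from %s",
        len(df),
        df["subject_id"].nunique(),
        path,
    )
    return df


def write_concentration_table(table: pd.DataFrame, path) -> None:
    """Write the canonical CSV dialect (blq as 0/1, blank conc on censored rows)."""
    out = table.copy()
    out["blq"] = out["blq"].astype(bool).astype(int)
    out = out[COLUMNS + [c for c in out.columns if c not in COLUMNS]]
    out.to_csv(path, index=False, float_format="%.10g")


def profiles_from_table(table: pd.DataFrame) -> list[Profile]:
    """Split a concentration table into per-subject × analyte profiles."""
    profiles = []
    for (subject, analyte), g in table.groupby(["subject_id", "analyte"], sort=True):
        g = g.sort_values("time_h")
        profiles.append(
            Profile(
                subject_id=str(subject),
                analyte=str(analyte),
                dose=float(g["dose_mg_per_kg"].iloc[0]),
                times=tuple(g["time_h"]),
                concs=tuple(
                    float(c) if not blq else float("nan")
                    for c, blq in zip(g["conc_ng_per_ml"], g["blq"])
                ),
                blq=tuple(bool(b) for b in g["blq"]),
            )
        )
    return profiles


# ---------------------------------------------------------------------------
# run configuration


class GroupConfig(BaseModel):
    label: str
    formulation: str
    dose_mg_per_kg: float = Field(gt=0)
    n: int = Field(ge=1)


class DesignConfig(BaseModel):
    groups: list[GroupConfig]
    schedule_h: list[float]
    lloq_ng_per_ml: float = Field(default=0.1, gt=0)
    threshold_ng_per_ml: float = Field(default=0.1, gt=0)

    @field_validator("schedule_h")
    @classmethod
    def _increasing(cls, v: list[float]) -> list[float]:
        if any(t <= 0 for t in v) or any(b <= a for a, b in zip(v, v[1:])):
            raise ValueError("schedule must be strictly increasing with positive times")
        return v

    def to_design(self) -> StudyDesign:
        return StudyDesign(
            groups=tuple(
                GroupSpec(g.label, g.formulation, g.dose_mg_per_kg, g.n)
                for g in self.groups
            ),
            schedule=tuple(self.schedule_h),
            lloq=self.lloq_ng_per_ml,
            threshold=self.threshold_ng_per_ml,
        )


class TypicalConfig(BaseModel):
    clearance_over_F: float = Field(gt=0)
    volume_over_F: float = Field(gt=0)
    ka_fast: float = Field(gt=0)
    ka_slow: float = Field(gt=0)
    frac_fast: float = Field(ge=0, le=1)


class MetaboliteConfig(BaseModel):
    fm: float = Field(ge=0, le=1)
    volume_m_over_F: float = Field(gt=0)
    ke_m: float = Field(gt=0)


class PopulationConfig(BaseModel):
    typical: TypicalConfig
    bsv_cv: dict[str, float] = Field(default_factory=dict)
    residual_cv: float = Field(default=0.0, ge=0)
    metabolite: MetaboliteConfig | None = None

    def to_population(self) -> PopulationParams:
        met = (
            MetaboliteParams(**self.metabolite.model_dump())
            if self.metabolite is not None
            else None
        )
        return PopulationParams(
            typical=PKParameters(**self.typical.model_dump()),
            bsv_cv=dict(self.bsv_cv),
            residual_cv=self.residual_cv,
            metabolite=met,
        )


class NCAConfig(BaseModel):
    lambda_z_min_points: int = Field(default=3, ge=3)
    lambda_z_r2_tol: float = Field(default=1e-4, ge=0)
    clast_mode: str = "observed"
    extrapolation_warn_pct: float = Field(default=20.0, gt=0)

    def to_options(self, threshold: float | None) -> NCAOptions:
        return NCAOptions(
            lambda_z_min_points=self.lambda_z_min_points,
            lambda_z_r2_tol=self.lambda_z_r2_tol,
            clast_mode=self.clast_mode,
            threshold=threshold,
            extrapolation_warn_pct=self.extrapolation_warn_pct,
        )


class RunConfig(BaseModel):
    """One self-contained run: design, population truth, NCA options,
    comparison plan, seed."""

    design: DesignConfig
    population: PopulationConfig
    nca: NCAConfig = NCAConfig()
    comparison_pairs: list[tuple[str, str]] = Field(default_factory=list)
    bonferroni_family: int | None = None
    seed: int = 0

    @classmethod
    def default(cls, seed: int = 0) -> "RunConfig":
        """The shipped study configuration (four arms, seven samples over 72 h)."""
        d = paper_design()
        pop = DEFAULT_POPULATION
        return cls(
            design=DesignConfig(
                groups=[
                    GroupConfig(
                        label=g.label, formulation=g.formulation,
                        dose_mg_per_kg=g.dose, n=g.n,
                    )
                    for g in d.groups
                ],
                schedule_h=list(d.schedule),
                lloq_ng_per_ml=d.lloq,
                threshold_ng_per_ml=d.threshold,
            ),
            population=PopulationConfig(
                typical=TypicalConfig(**asdict(pop.typical)),
                bsv_cv=dict(pop.bsv_cv),
                residual_cv=pop.residual_cv,
                metabolite=MetaboliteConfig(**asdict(pop.metabolite)),
            ),
            comparison_pairs=[
                (d.groups[0].label, g.label) for g in d.groups[1:]
            ],
            seed=seed,
        )

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls.model_validate_json(Path(path).read_text())

    def to_json(self, path) -> None:
        Path(path).write_text(self.model_dump_json(indent=2) + "\n")


# ---------------------------------------------------------------------------
# result writing


def write_results(
    results: list[NCAResult],
    summary: pd.DataFrame,
    comparisons: list[grp.ComparisonResult],
    mean_curves: list[grp.MeanCurve],
    config: RunConfig,
    outdir,
) -> dict[str, Path]:
    """Write the full output set; byte-stable for identical inputs and config.

    Files: nca_results.csv / .json (per-subject parameters; absent values as
    empty cells plus the flag column), summary.csv, summary.txt (report-table
    layout), comparisons.csv, mean_curves.csv, resolved config JSON.
    Timestamps are confined to the logger, never to these files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    df = grp.results_frame(results)
    paths["nca_csv"] = outdir / "nca_results.csv"
    df.to_csv(paths["nca_csv"], index=False, float_format="%.10g")
    paths["nca_json"] = outdir / "nca_results.json"
    records = json.loads(df.to_json(orient="records"))
    paths["nca_json"].write_text(json.dumps(records, indent=1) + "\n")

    paths["summary_csv"] = outdir / "summary.csv"
    summary.to_csv(paths["summary_csv"], index=False, float_format="%.10g")
    paths["summary_txt"] = outdir / "summary.txt"
    paths["summary_txt"].write_text(grp.format_summary(summary) + "\n")

    paths["comparisons_csv"] = outdir / "comparisons.csv"
    pd.DataFrame([asdict(c) for c in comparisons]).to_csv(
        paths["comparisons_csv"], index=False, float_format="%.10g"
    )

    curve_rows = []
    for mc in mean_curves:
        for t, m, s, n in zip(mc.times, mc.mean, mc.sd, mc.n):
            curve_rows.append(
                {
                    "group_label": mc.group_label,
                    "analyte": mc.analyte,
                    "time_h": t,
                    "mean_ng_per_ml": m,
                    "sd_ng_per_ml": s,
                    "n": n,
                }
            )
    paths["mean_curves_csv"] = outdir / "mean_curves.csv"
    pd.DataFrame(curve_rows).to_csv(
        paths["mean_curves_csv"], index=False, float_format="%.10g"
    )

    paths["config_json"] = outdir / "resolved_config.json"
    config.to_json(paths["config_json"])
    log.info("wrote %d result files to %s", len(paths), outdir)
    return paths
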