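"""End-to-end pipeline: simulate -> prepare -> score -> PRS -> Cox -> life table.

Every stage is a library call; this module only sequences them, fans the
root seed out to per-stage streams, writes publication-shaped delimited
tables, and records a manifest (config, seed, package version, output
hashes). Rerunning with the same config is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from . import __version__
from .lifetable import run_life_expectancy
from .prep import alcohol_category, apply_exclusions, average_assessments
from .prs import compute_prs, prs_tertiles
from .scoring import score_all
from .simulate import (
    SimulationParams,
    generate_cohort,
    generate_population_life_table,
)
from .specs import INDEX_NAMES
from .survival import HazardRatioSet, ModelSpec, fit_cox, interaction_analysis, joint_groups

__all__ = ["PipelineConfig", "run_pipeline", "summarize_baseline",
           "build_analysis_cohort", "prevalence_from_cohort"]


class PipelineConfig(BaseModel):
    """Configuration of one pipeline run."""

    n_participants: int = Field(default=5000, ge=100)
    seed: int = 0
    indices: List[str] = Field(default_factory=lambda: list(INDEX_NAMES))
    covariate_set: str = "model2"
    start_ages: List[int] = Field(default_factory=lambda: [45])
    n_draws: int = 500
    with_genetics: bool = True
    with_life_table: bool = True
    sex_specific_hrs: bool = False
    out_dir: str = "dietspan_run"
    simulation: Optional[dict] = None  # overrides for SimulationParams

    @field_validator("indices")
    @classmethod
    def _known_indices(cls, v):
        unknown = [i for i in v if i not in INDEX_NAMES]
        if unknown:
            raise ValueError(
                f"unknown dietary index name(s): {unknown}; "
                f"known: {', '.join(INDEX_NAMES)}"
            )
        return v

    @field_validator("covariate_set")
    @classmethod
    def _known_covset(cls, v):
        if v not in ("model1", "model2"):
            raise ValueError("covariate_set must be 'model1' or 'model2'")
        return v


def build_analysis_cohort(
    participants: pd.DataFrame,
    profiles: pd.DataFrame,
    scores: pd.DataFrame,
    prs: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Merge covariates, averaged exposures, scores and PRS into the
    model-ready analysis table (one row per retained participant)."""
    cohort = participants.merge(profiles, on="pid", suffixes=("", "_diet"))
    cohort = cohort.merge(scores, on="pid")
    if "alcohol_g" in cohort.columns:
        cohort["alcohol_cat"] = cohort["alcohol_g"].map(alcohol_category)
    if prs is not None:
        cohort = cohort.merge(prs.rename("prs"), left_on="pid", right_index=True)
        cohort["prs_tertile"] = prs_tertiles(cohort["prs"]).to_numpy()
    return cohort


def prevalence_from_cohort(
    cohort: pd.DataFrame, group_col: str, band_width: int = 10
) -> pd.DataFrame:
    """Sex- and 10-year-age-band prevalence of each exposure group."""
    band = (cohort["age"] // band_width * band_width).astype(int)
    tab = (
        cohort.assign(age_band=band)
        .groupby(["sex", "age_band", group_col])
        .size()
        .rename("n")
        .reset_index()
    )
    tab["prevalence"] = tab.groupby(["sex", "age_band"])["n"].transform(
        lambda x: x / x.sum()
    )
    tab = tab.rename(columns={group_col: "group"})
    # every group present in every band (possibly 0)
    full = (
        tab.set_index(["sex", "age_band", "group"])["prevalence"]
        .unstack(fill_value=0.0)
        .stack()
        .rename("prevalence")
        .reset_index()
    )
    return full


def summarize_baseline(
    cohort: pd.DataFrame,
    scores: pd.DataFrame,
    variables: Optional[Dict[str, str]] = None,
    indices: Sequence[str] = INDEX_NAMES,
) -> pd.DataFrame:
    """Baseline characteristics overall and by extreme score quintiles.

    ``variables`` maps a cohort column to a summary kind: "mean_sd",
    "median_iqr", or "count_pct:<level>". Defaults cover age, sex, energy,
    alcohol and smoking.
    """
    if variables is None:
        variables = {
            "age": "mean_sd",
            "sex": "count_pct:male",
            "energy_kcal": "mean_sd",
            "alcohol_g": "median_iqr",
            "smoking": "count_pct:current",
        }

    def cell(sub: pd.DataFrame, var: str, kind: str) -> str:
        v = sub[var]
        if kind == "mean_sd":
            return f"{v.mean():.1f} ({v.std(ddof=1):.1f})"
        if kind == "median_iqr":
            return (
                f"{v.median():.1f} ({v.quantile(0.25):.1f}, {v.quantile(0.75):.1f})"
            )
        if kind.startswith("count_pct:"):
            level = kind.split(":", 1)[1]
            n = int((v.astype(str) == level).sum())
            return f"{n} ({100 * n / len(sub):.1f}%)"
        raise ValueError(f"unknown summary kind {kind!r}")

    merged = cohort.merge(
        scores[["pid"] + [f"{i}_q" for i in indices if f"{i}_q" in scores.columns]],
        on="pid",
    )
    rows = []
    for var, kind in variables.items():
        if var not in merged.columns:
            continue
        row = {"characteristic": f"{var} [{kind}]", "overall": cell(merged, var, kind)}
        for idx in indices:
            qcol = f"{idx}_q"
            if qcol not in merged.columns:
                continue
            for q in (1, 5):
                row[f"{idx}_Q{q}"] = cell(merged[merged[qcol] == q], var, kind)
        rows.append(row)
    return pd.DataFrame(rows)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _hr_frame(hr_sets: Dict[str, HazardRatioSet]) -> pd.DataFrame:
    frames = []
    for name, hrs in hr_sets.items():
        t = hrs.hr_table()
        t["p_trend"] = hrs.p_trend
        t["per_sd_hr"] = hrs.per_sd_hr
        if hrs.per_sd_ci:
            t["per_sd_ci_low"], t["per_sd_ci_high"] = hrs.per_sd_ci
        frames.append(t)
    return pd.concat(frames, ignore_index=True)


def run_pipeline(config: PipelineConfig, out_dir: Optional[str] = None) -> Dict:
    """Run the configured pipeline; returns the manifest dictionary.

    Outputs under ``out_dir``: the analysis cohort, exclusion report,
    baseline characteristics, per-index HR tables, interaction and joint
    tables (when genetics is on), life-expectancy estimates, and a manifest.
    A stage failure leaves a manifest recording the failure point and moves
    partial outputs to ``quarantine/``.
    """
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig(**config)
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: Dict = {
        "config": config.model_dump(),
        "seed": config.seed,
        "version": __version__,
        "stages": [],
        "outputs": {},
    }
    stage = "init"
    try:
        # --- simulate ----------------------------------------------------
        stage = "simulate"
        sim_kwargs = dict(config.simulation or {})
        sim_kwargs.setdefault("n_participants", config.n_participants)
        sim_kwargs["seed"] = config.seed
        params = SimulationParams(**sim_kwargs)
        cohort = generate_cohort(params)
        manifest["stages"].append(stage)

        # --- prepare -----------------------------------------------------
        stage = "prepare"
        retained, report = apply_exclusions(
            cohort.participants, cohort.assessments
        )
        kept_assessments = cohort.assessments[
            cohort.assessments["pid"].isin(retained["pid"])
        ]
        profiles = average_assessments(kept_assessments)
        manifest["stages"].append(stage)

        # --- score + PRS ---------------------------------------------------
        stage = "score"
        profile_tbl = profiles.merge(retained[["pid", "sex"]], on="pid")
        scores = score_all(profile_tbl)
        prs = None
        if config.with_genetics:
            weights = pd.DataFrame(
                {
                    "snp": [f"snp_{j+1}" for j in range(params.n_snps)],
                    "effect_allele": "A",
                    "weight": params.snp_weights,
                }
            )
            geno = cohort.genotypes[cohort.genotypes["pid"].isin(retained["pid"])]
            prs = compute_prs(geno, weights)
        analysis = build_analysis_cohort(retained, profiles, scores, prs)
        manifest["stages"].append(stage)

        # --- survival models ----------------------------------------------
        stage = "fit"
        hr_sets: Dict[str, HazardRatioSet] = {}
        inter_rows = []
        joint_frames = []
        for idx in config.indices:
            spec = ModelSpec(index=idx, covariates=config.covariate_set)
            hr_sets[idx] = fit_cox(analysis, idx, spec)
            if config.with_genetics:
                res = interaction_analysis(analysis, idx, spec=spec)
                inter_rows.append(
                    {
                        "index": idx,
                        "p_multiplicative": res.p_multiplicative,
                        "reri": res.reri,
                        "reri_ci_low": res.reri_ci[0],
                        "reri_ci_high": res.reri_ci[1],
                    }
                )
                jt = joint_groups(analysis, idx, spec=spec).levels
                jt.insert(0, "index", idx)
                joint_frames.append(jt)
        manifest["stages"].append(stage)

        # --- life table ----------------------------------------------------
        stage = "lifetable"
        le_table = None
        if config.with_life_table:
            life_tbl = generate_population_life_table(
                gompertz_params=params.gompertz
            )
            idx0 = config.indices[0]
            prev = prevalence_from_cohort(analysis, f"{idx0}_q")
            lv = hr_sets[idx0].levels
            hr_in = pd.DataFrame(
                {"group": lv["level"], "hr": lv["hr"],
                 "ci_low": lv["ci_low"], "ci_high": lv["ci_high"]}
            )
            hr_in.loc[hr_in["group"] == 1, ["ci_low", "ci_high"]] = 1.0
            res = run_life_expectancy(
                life_tbl, prev, hr_in, reference=1,
                start_ages=config.start_ages, n_draws=config.n_draws,
                seed=config.seed,
            )
            le_table = res.table
            le_table.insert(0, "index", idx0)
        manifest["stages"].append(stage)

        # --- write outputs ---------------------------------------------------
        stage = "write"
        analysis.to_csv(out / "analysis_cohort.csv", index=False)
        (out / "exclusion_report.json").write_text(
            json.dumps(report.to_dict(), indent=2)
        )
        summarize_baseline(analysis, scores, indices=config.indices).to_csv(
            out / "baseline_characteristics.csv", index=False
        )
        _hr_frame(hr_sets).to_csv(out / "hazard_ratios.csv", index=False)
        if inter_rows:
            pd.DataFrame(inter_rows).to_csv(out / "interaction.csv", index=False)
        if joint_frames:
            pd.concat(joint_frames, ignore_index=True).to_csv(
                out / "joint_groups.csv", index=False
            )
        if le_table is not None:
            le_table.to_csv(out / "life_expectancy.csv", index=False)
        manifest["stages"].append(stage)

        for p in sorted(out.glob("*.csv")) + sorted(out.glob("*.json")):
            if p.name != "manifest.json":
                manifest["outputs"][p.name] = _sha256(p)
        manifest["status"] = "ok"
    except Exception as e:
        manifest["status"] = "failed"
        manifest["failed_stage"] = stage
        manifest["error"] = str(e)
        q = out / "quarantine"
        q.mkdir(exist_ok=True)
        for p in list(out.glob("*.csv")) + list(out.glob("*.json")):
            if p.name != "manifest.json":
                p.rename(q / p.name)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
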