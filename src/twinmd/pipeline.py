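"""Pipeline orchestration: simulate/ingest -> classify -> correlate -> fit -> report.

A run is driven by a :class:`PipelineConfig` (constructible from a YAML
file) and writes all intermediate and final artifacts into a run directory
together with a manifest echoing the full configuration, master seed, and
package version.  Re-running with the same configuration reproduces every
output byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ace import (
    aic_select,
    bivariate_fits_frame,
    build_joint_tables,
    fit_bivariate,
    fit_univariate,
    univariate_fits_frame,
)
from .classify import censor_four_symptom_clusters, classify_sample, profiles_to_frame
from .definitions import CRITERIA
from .io import read_interviews, read_profiles, write_interviews, write_profiles
from .simulate import (
    EpisodeModelConfig,
    GenerativeConfig,
    simulate_interview_sample,
    simulate_liability_sample,
)
from .summary import assemble_reports, paired_fisher_test
from .tetrachoric import build_pair_tables, correlations_frame, tetrachoric_mle

log = logging.getLogger("twinmd")

__all__ = ["PipelineConfig", "run_pipeline"]

_MEASURE_PAIRS = ("in-in", "out-out", "in-out")


@dataclass
class PipelineConfig:
    """Declarative configuration of a full pipeline run.

    ``generator`` selects the synthetic input level ("liability" or
    "interview"); alternatively ``input_path`` names an interview CSV to
    ingest.  The master ``seed`` deterministically seeds every stochastic
    stage.
    """

    out_dir: str = "twinmd_run"
    seed: int = 0
    generator: str | None = "liability"
    input_path: str | None = None
    liability: dict = field(default_factory=dict)
    episode: dict = field(default_factory=dict)
    sizes: dict = field(default_factory=dict)
    pool_os: bool = True
    censoring: bool = False
    univariate_models: list = field(default_factory=lambda: ["ACE"])
    bivariate_models: list = field(default_factory=lambda: ["AE"])
    compute_ci: bool = True
    fit_bivariate: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _correlate(profiles: pd.DataFrame, pool_os: bool, compute_ci: bool,
               measure_pairs=_MEASURE_PAIRS) -> pd.DataFrame:
    estimates = {}
    for mp in measure_pairs:
        for zyg in ("MZ", "DZ"):
            tables = build_pair_tables(profiles, mp, zyg, pool_os=pool_os)
            for crit, tab in tables.items():
                estimates[(crit, mp, zyg)] = tetrachoric_mle(tab, compute_ci=compute_ci)
    return correlations_frame(estimates)


def _fit_univariate_stage(
    profiles: pd.DataFrame, models: list, pool_os: bool, compute_ci: bool
) -> pd.DataFrame:
    fits = {}
    selected = {}
    for measure in ("in", "out"):
        mp = f"{measure}-{measure}"
        mz = build_pair_tables(profiles, mp, "MZ", pool_os=pool_os)
        dz = build_pair_tables(profiles, mp, "DZ", pool_os=pool_os)
        for crit in CRITERIA:
            per_model = []
            for model in models:
                f = fit_univariate(
                    {"MZ": mz[crit], "DZ": dz[crit]}, model, compute_ci=compute_ci
                )
                fits[(crit, measure, model)] = f
                per_model.append(f)
            selected[(crit, measure)] = aic_select(per_model).model
    df = univariate_fits_frame(fits)
    df["selected"] = [
        selected[(r.criterion, r.measure)] == r.model for r in df.itertuples()
    ]
    return df


def _fit_bivariate_stage(
    profiles: pd.DataFrame, models: list, pool_os: bool, compute_ci: bool
) -> pd.DataFrame:
    mz = build_joint_tables(profiles, "MZ", pool_os=pool_os)
    dz = build_joint_tables(profiles, "DZ", pool_os=pool_os)
    fits = {}
    selected = {}
    for crit in CRITERIA:
        per_model = []
        for model in models:
            f = fit_bivariate(
                {"MZ": mz[crit], "DZ": dz[crit]}, model, compute_ci=compute_ci
            )
            fits[(crit, model)] = f
            per_model.append(f)
        selected[crit] = aic_select(per_model).model
    df = bivariate_fits_frame(fits)
    df["selected"] = [selected[r.criterion] == r.model for r in df.itertuples()]
    return df


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages and return the run directory.

    Artifacts: ``interviews.csv`` (interview mode), ``profiles.csv`` (and
    ``profiles_censored.csv`` with the censoring switch), ``correlations.csv``
    (+ ``correlations_censored.csv``), ``univariate_fits.csv``,
    ``bivariate_fits.csv``, ``descriptives.csv``, ``key_estimates.csv``,
    ``paired_tests.csv``, and ``manifest.json``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    # --- stage 1: simulate or ingest -------------------------------------
    records = None
    censored_profiles = None
    if config.input_path is not None:
        log.info("ingesting interview records from %s", config.input_path)
        records = read_interviews(config.input_path)
    elif config.generator == "interview":
        ep = EpisodeModelConfig(**{**config.episode, "seed": config.seed})
        records = simulate_interview_sample(ep, **config.sizes)
        write_interviews(records, out / "interviews.csv")
        (out / "episode_config.json").write_text(ep.to_json())
    elif config.generator == "liability":
        gc = GenerativeConfig(**{**config.liability, **config.sizes, "seed": config.seed})
        profiles = simulate_liability_sample(gc)
        (out / "liability_config.json").write_text(gc.to_json())
    else:
        raise ValueError("config must name an input_path or a generator")

    # --- stage 2: classification -----------------------------------------
    if records is not None:
        counts["twins_read"] = len(records)
        log.info("classifying %d interview records", len(records))
        prof_objs = classify_sample(records)
        profiles = profiles_to_frame(prof_objs)
        if config.censoring:
            cens = censor_four_symptom_clusters(prof_objs, records)
            censored_profiles = profiles_to_frame(cens)
    elif config.censoring:
        log.warning("censoring requested but no interview-level data; skipped")

    counts["twins"] = len(profiles)
    counts["pairs"] = int(profiles["pair_id"].nunique())
    write_profiles(profiles, out / "profiles.csv")
    if censored_profiles is not None:
        write_profiles(censored_profiles, out / "profiles_censored.csv")

    # --- stage 3: cross-twin tables and tetrachoric correlations ---------
    log.info("estimating tetrachoric correlations")
    corr = _correlate(profiles, config.pool_os, config.compute_ci)
    corr.to_csv(out / "correlations.csv", index=False)
    counts["correlations"] = len(corr)
    if censored_profiles is not None:
        corr_c = _correlate(
            censored_profiles, config.pool_os, config.compute_ci,
            measure_pairs=("out-out", "in-out"),
        )
        corr_c.to_csv(out / "correlations_censored.csv", index=False)

    # --- stage 4: variance-component fits ---------------------------------
    log.info("fitting univariate models: %s", config.univariate_models)
    uni = _fit_univariate_stage(
        profiles, config.univariate_models, config.pool_os, config.compute_ci
    )
    uni.to_csv(out / "univariate_fits.csv", index=False)
    counts["univariate_fits"] = len(uni)
    counts["fits_converged"] = int(uni["converged"].sum())

    biv = None
    if config.fit_bivariate:
        log.info("fitting bivariate models: %s", config.bivariate_models)
        biv = _fit_bivariate_stage(
            profiles, config.bivariate_models, config.pool_os, config.compute_ci
        )
        biv.to_csv(out / "bivariate_fits.csv", index=False)
        counts["bivariate_fits"] = len(biv)

    # --- stage 5: summaries ------------------------------------------------
    log.info("assembling reports")
    uni_sel = uni[uni["selected"]] if "selected" in uni else uni
    biv_sel = None
    if biv is not None:
        biv_sel = biv[biv["selected"]] if "selected" in biv else biv
    reports = assemble_reports(profiles, corr, uni_sel, biv_sel)
    reports["descriptives"].to_csv(out / "descriptives.csv", index=False)
    reports["key_estimates"].to_csv(out / "key_estimates.csv", index=False)

    # paired Fisher-z comparison of the in-in vs out-out correlation sets
    paired_rows = []
    for zyg in ("MZ", "DZ"):
        sets = {}
        for mp in ("in-in", "out-out"):
            grp = corr[(corr["measure_pair"] == mp) & (corr["zygosity"] == zyg)]
            rs = grp.set_index("criterion").loc[list(CRITERIA), "rho"].to_numpy()
            # boundary estimates would make arctanh infinite
            sets[mp] = np.clip(rs, -0.9999, 0.9999)
        res = paired_fisher_test(sets["in-in"], sets["out-out"])
        paired_rows.append(
            {
                "comparison": f"{zyg} in-in vs out-out",
                "t": res.statistic,
                "p": res.p_value,
                "df": res.df,
                "mean_z_difference": res.mean_z_difference,
            }
        )
    pd.DataFrame(paired_rows).to_csv(out / "paired_tests.csv", index=False)

    manifest = {
        "package": "twinmd",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "counts": counts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    log.info("run complete: %s", out)
    return out
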