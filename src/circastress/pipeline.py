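"""End-to-end orchestration: simulate -> periods -> classify -> stress models
-> cosinor -> bootstrap group comparison, with a manifest for reproducibility.
"""

from __future__ import annotations

import hashlib
import json
import logging
import pathlib

import numpy as np
import pandas as pd

from . import __version__
from .cosinor import CosinorMixedModel, bootstrap_compare, group_marginal_params
from .occupation import classify_participants_table, classify_periods_table
from .periods import assign_periods_table, build_period_table
from .simulate import SimulationConfig, simulate_all, write_tables
from .stress import fit_multivariate, stratified_effects, tertialize, univariate_screen

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "PipelineError", "DEFAULT_SCREEN_CANDIDATES"]

DEFAULT_SCREEN_CANDIDATES = [
    "age",
    "gender",
    "bmi",
    "emotional_support",
    "cd_risc2",
    "qol_baseline",
    "optimism",
    "anxiety_depression",
    "mean_case_count",
    "mean_symptom_severity",
    "mean_left_home",
    "post_pcr_4wk",
    "post_pcr_any",
]


class PipelineError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage, original):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {original}")


def _config_hash(config_dict):
    payload = json.dumps(config_dict, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def run_pipeline(config=None, out_dir="run", seed=None, n_boot=1000,
                 screen_candidates=None, stratify_trait="emotional_support",
                 cosinor_covariates=("age", "bmi", "gender"),
                 skip_cosinor=False):
    """Run every stage on a simulated (or pre-loaded) cohort.

    Parameters
    ----------
    config : SimulationConfig, dict, or None
        Simulation settings; a dict is coerced.  None uses the defaults.
    out_dir : path
        Run directory receiving tables, JSON results, and the manifest.
    seed : int or None
        Overrides ``config.seed`` when given.
    n_boot : int
        Bootstrap iterations for the circadian group comparison.

    Returns a dict of in-memory results (also written to ``out_dir``).
    """
    if config is None:
        config = SimulationConfig()
    elif isinstance(config, dict):
        config = SimulationConfig.from_dict(config)
    if seed is not None:
        config.seed = int(seed)
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages_done = []
    results = {}

    def _stage(name, fn):
        try:
            val = fn()
        except Exception as err:
            raise PipelineError(name, err) from err
        stages_done.append(name)
        return val

    # 1. simulate -------------------------------------------------------
    tables = _stage("simulate", lambda: simulate_all(config))
    write_tables(tables, out / "tables")
    baseline, weekly, daily, hrv, cases = (
        tables["baseline"], tables["weekly"], tables["daily"],
        tables["hrv"], tables["cases"],
    )

    # 2. periods --------------------------------------------------------
    def _periods():
        tab = build_period_table(weekly, daily, cases, baseline)
        return tab

    period_table = _stage("periods", _periods)

    # 3. classify -------------------------------------------------------
    def _classify():
        enrollment = dict(zip(baseline.participant_id,
                              pd.to_datetime(baseline.enrollment_date).dt.date))
        periods_df = assign_periods_table(weekly, enrollment=enrollment)
        per_class = classify_periods_table(daily, periods_df)
        part_class = classify_participants_table(per_class, baseline)
        return per_class, part_class

    per_class, part_class = _stage("classify", _classify)
    period_table = period_table.merge(per_class, on=["participant_id", "period"],
                                      how="left")
    period_table = period_table.merge(part_class, on="participant_id", how="left")
    period_table.to_csv(out / "period_table.csv", index=False)

    # 4. stress models --------------------------------------------------
    def _stress():
        data = period_table.copy()
        # tertials of the stratifying trait for stage 4c
        data[f"{stratify_trait}_tertial"] = tertialize(data[stratify_trait])
        candidates = [
            c for c in (screen_candidates or DEFAULT_SCREEN_CANDIDATES)
            if c in data.columns and data[c].notna().any()
        ]
        screen_tab, selected = univariate_screen(data, candidates)
        multi = None
        if selected:
            multi = fit_multivariate(data, selected)
        strat_fit, strat = (None, [])
        if "post_pcr_4wk" in data.columns and data["post_pcr_4wk"].any():
            strat_fit, strat = stratified_effects(
                data, f"{stratify_trait}_tertial", "post_pcr_4wk",
                covariates=[c for c in selected if c not in
                            ("post_pcr_4wk", "post_pcr_any", stratify_trait)],
            )
        return data, screen_tab, selected, multi, strat

    data, screen_tab, selected, multi, strat = _stage("fit-stress", _stress)
    screen_tab.to_csv(out / "stress_screen.tsv", sep="\t")
    stress_json = {
        "selected": selected,
        "screen": {
            v: {"estimate": screen_tab.loc[v, "estimate"],
                "p": screen_tab.loc[v, "p"]}
            for v in screen_tab.index
        },
    }
    if multi is not None:
        fit = multi["fit"]
        stress_json["multivariate"] = {
            "coefficients": fit.coef_.to_dict(),
            "se": dict(zip(fit.coef_.index,
                           np.sqrt(np.diag(fit.coef_cov_.to_numpy())))),
            "variance_components": fit.variance_components_,
            "car1_phi": fit.phi_,
            "restricted_loglik": fit.loglik_,
            "slope_lrt_stat": multi["slope_lrt_stat"],
            "slope_lrt_p": multi["slope_lrt_p"],
            "n_obs": fit.n_obs_,
            "n_subjects": fit.n_subjects_,
        }
    stress_json["stratified_post_pcr_4wk"] = [
        {"label": r.label, "estimate": r.estimate, "se": r.se, "p": r.p}
        for r in strat
    ]
    (out / "stress_results.json").write_text(
        json.dumps(_jsonable(stress_json), indent=2)
    )
    results["stress"] = stress_json

    # 5 & 6. cosinor + bootstrap ---------------------------------------
    if skip_cosinor or not len(hrv):
        logger.info("HRV inputs absent; cosinor stages skipped")
        cos_json = None
    else:
        def _cosinor():
            grp_col = f"{config.hrv_group_trait}_tertial"
            base = baseline.copy()
            base[grp_col] = tertialize(base[config.hrv_group_trait])
            merged = hrv.merge(
                base[["participant_id", grp_col, *[
                    c for c in cosinor_covariates if c in base.columns]]],
                on="participant_id", how="left",
            )
            covs = [c for c in cosinor_covariates if c in merged.columns]
            covs = [f"C({c})" if merged[c].dtype == object else c for c in covs]
            model = CosinorMixedModel(group=grp_col, covariates=tuple(covs))
            model.fit(merged)
            return model

        model = _stage("fit-cosinor", _cosinor)
        params_tab = group_marginal_params(model)
        params_tab.to_csv(out / "cosinor_params.tsv", sep="\t")

        comps = _stage(
            "compare-groups",
            lambda: bootstrap_compare(model, n_boot=n_boot, seed=config.seed),
        )
        cos_json = {
            "group_params": {
                str(lev): {
                    "mesor": model.params_[lev].mesor,
                    "amplitude": model.params_[lev].amplitude,
                    "acrophase": model.params_[lev].acrophase,
                    "acrophase_hours": model.params_[lev].acrophase_hours,
                }
                for lev in model.levels_
            },
            "comparisons": [
                {
                    "parameter": c.parameter,
                    "groups": [str(c.group_a), str(c.group_b)],
                    "observed": c.observed,
                    "p": c.p,
                    "n_boot": c.n_boot,
                }
                for c in comps
            ],
            "n_obs": model.n_obs_,
            "n_subjects": model.n_subjects_,
        }
        (out / "cosinor_results.json").write_text(
            json.dumps(_jsonable(cos_json), indent=2)
        )
        results["cosinor"] = cos_json

    # manifest ----------------------------------------------------------
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": _config_hash(config.to_dict()),
        "stages": stages_done,
        "outputs": sorted(str(p.relative_to(out)) for p in out.rglob("*")
                          if p.is_file() and p.name != "manifest.json"),
    }
    (out / "manifest.json").write_text(json.dumps(_jsonable(manifest), indent=2))
    results["manifest"] = manifest
    return results
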