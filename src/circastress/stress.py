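"""Longitudinal perceived-stress modelling.

Builds on :mod:`circastress.lmm`: univariate screening of candidate
covariates (marginal Type-III Wald test at P < .10), the multivariate model
with a per-subject random slope on the community case burden (tested by a
boundary-corrected likelihood-ratio test), marginal-mean contrasts, and
effects of a focal exposure stratified by baseline-trait tertials.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lmm import (
    CAR1MixedModel,
    ContrastResult,
    _counterfactual_row,
    contrast,
    likelihood_ratio_test,
    wald_table,
)

__all__ = [
    "ModelSpec",
    "tertialize",
    "univariate_screen",
    "fit_multivariate",
    "stratified_effects",
    "estimate_contrasts",
]

SCREEN_ALPHA = 0.10


@dataclass
class ModelSpec:
    """Declarative description of one stress mixed model."""

    response: str = "pss4"
    fixed_effects: list = field(default_factory=list)
    random_slopes: tuple = ()
    correlation: str = "car1"
    reml: bool = True
    groups: str = "participant_id"
    time: str = "period"

    @property
    def formula(self) -> str:
        rhs = " + ".join(self.fixed_effects) if self.fixed_effects else "1"
        return f"{self.response} ~ {rhs}"

    def build(self) -> CAR1MixedModel:
        return CAR1MixedModel(
            self.formula,
            groups=self.groups,
            time=None if self.correlation == "none" else self.time,
            correlation=self.correlation,
            random_slopes=self.random_slopes,
            reml=self.reml,
        )


def tertialize(scores):
    """Split baseline scores into low/medium/high tertials.

    Cutpoints are the 1/3 and 2/3 sample quantiles (lower interpolation),
    with ties going to the lower tertial, so the labels are exhaustive and
    reproducible on integer-scored instruments.
    """
    arr = np.asarray(scores, dtype=float)
    if np.unique(arr[~np.isnan(arr)]).size < 2:
        raise ValueError("tertials undefined: all scores identical")
    q1, q2 = np.quantile(arr[~np.isnan(arr)], [1 / 3, 2 / 3], method="lower")
    labels = np.where(arr <= q1, "low", np.where(arr <= q2, "medium", "high"))
    labels = pd.Categorical(labels, categories=["low", "medium", "high"], ordered=True)
    if isinstance(scores, pd.Series):
        return pd.Series(labels, index=scores.index, name=f"{scores.name}_tertial")
    return labels


def _standardized(data, cols):
    """Copy of ``data`` with the named continuous columns z-scored."""
    out = data.copy()
    for c in cols:
        if c in out.columns and pd.api.types.is_numeric_dtype(out[c]) and not pd.api.types.is_bool_dtype(out[c]):
            v = out[c].astype(float)
            sd = v.std(ddof=0)
            if sd > 0:
                out[c] = (v - v.mean()) / sd
    return out


def univariate_screen(data, candidates, response="pss4", groups="participant_id",
                      time="period", alpha=SCREEN_ALPHA, standardize=True):
    """One random-intercept CAR(1) model per candidate covariate.

    Each candidate enters alone; its marginal (Type-III) Wald chi-square
    p-value decides selection at ``alpha`` (default .10).  Continuous
    candidates are standardized by default so the effect estimates are per
    covariate SD.  Per-variable fit failures are recorded and skipped.

    Returns (table, selected) where ``table`` has one row per candidate with
    the single-df effect estimate (NaN for multi-df factors), the marginal
    p-value, and the selection flag.
    """
    work = _standardized(data, candidates) if standardize else data
    rows = []
    for var in candidates:
        spec = ModelSpec(response=response, fixed_effects=[var],
                         groups=groups, time=time)
        try:
            fit = spec.build().fit(work)
            wt = wald_table(fit)
            term = wt.index[0]
            rows.append(
                {
                    "variable": var,
                    "estimate": float(wt.loc[term, "estimate"]),
                    "p": float(wt.loc[term, "p"]),
                    "error": "",
                }
            )
        except Exception as err:  # noqa: BLE001 - per-variable isolation
            warnings.warn(f"univariate fit failed for {var!r}: {err}")
            rows.append({"variable": var, "estimate": np.nan, "p": np.nan,
                         "error": str(err)})
    tab = pd.DataFrame(rows).set_index("variable")
    tab["selected"] = tab["p"] < alpha
    selected = list(tab.index[tab["selected"]])
    return tab, selected


def fit_multivariate(data, selected, response="pss4", groups="participant_id",
                     time="period", slope_var="mean_case_count",
                     standardize=True, boundary=True):
    """Joint model over the screened covariates with a random case-count slope.

    Fits the multivariate model twice — random intercept only, and random
    intercept plus an independent per-subject slope on the (standardized)
    community case burden — and reports the likelihood-ratio test of zero
    slope variance against the boundary-corrected 50:50 chi-square mixture.

    Returns a dict with the slope-model fit, the intercept-only fit, and the
    LRT statistic and p-value.
    """
    if not selected:
        raise ValueError("no covariates selected for the multivariate model")
    work = _standardized(data, selected + [slope_var]) if standardize else data
    spec0 = ModelSpec(response=response, fixed_effects=list(selected),
                      groups=groups, time=time)
    fit0 = spec0.build().fit(work)
    if slope_var in work.columns:
        spec1 = ModelSpec(response=response, fixed_effects=list(selected),
                          random_slopes=(slope_var,), groups=groups, time=time)
        fit1 = spec1.build().fit(work)
        stat, p = likelihood_ratio_test(fit1, fit0, boundary=boundary)
    else:
        fit1, stat, p = None, np.nan, np.nan
    return {
        "fit": fit1 if fit1 is not None else fit0,
        "fit_intercept_only": fit0,
        "slope_lrt_stat": stat,
        "slope_lrt_p": p,
    }


def stratified_effects(data, stratifier, focal, covariates=(), response="pss4",
                       groups="participant_id", time="period", standardize=True):
    """Per-tertial effect of a focal exposure on longitudinal stress.

    Fits the model with tertial-by-focal interaction and reports the focal
    effect (per unit of the focal variable) within each tertial, via
    counterfactual marginal means.  A focal variable that never varies
    yields a warning and no contrasts.

    Returns (fit, list of ContrastResult).
    """
    cont = [focal] + [c for c in covariates]
    work = _standardized(data, cont) if standardize else data.copy()
    if work[focal].nunique(dropna=True) < 2:
        warnings.warn(f"focal term {focal!r} is constant; no stratified contrasts")
        return None, []
    # one focal column per tertial (focal * indicator), so that a tertial
    # whose focal term never varies (empty tertial-by-event cell) can simply
    # be left out instead of aliasing the interaction design
    focal_vals = work[focal].astype(float)
    active = []
    for lev in ["low", "medium", "high"]:
        mask = work[stratifier] == lev
        if not mask.any():
            warnings.warn(f"empty tertial {lev!r}; contrast absent")
            continue
        if focal_vals[mask].nunique(dropna=True) < 2:
            warnings.warn(
                f"focal term {focal!r} constant within tertial {lev!r}; "
                "contrast absent"
            )
            continue
        col = f"_focal_{lev}"
        work[col] = focal_vals.where(mask, 0.0).fillna(0.0)
        active.append((lev, col))
    if not active:
        warnings.warn("no tertial has focal variation; nothing to estimate")
        return None, []
    terms = (
        [f"C({stratifier})"] + [col for _, col in active] + list(covariates)
    )
    spec = ModelSpec(response=response, fixed_effects=terms, groups=groups,
                     time=time)
    fit = spec.build().fit(work)
    results = []
    for lev, col in active:
        L = np.zeros(len(fit.coef_))
        L[fit.coef_.index.get_loc(col)] = 1.0
        results.append(contrast(fit, L, label=f"{focal} | {stratifier}={lev}"))
    return fit, results


def estimate_contrasts(fit, contrasts):
    """Evaluate a set of named coefficient contrasts on a fitted model.

    ``contrasts`` maps label -> coefficient-space vector.
    """
    return [contrast(fit, L, label=lab) for lab, L in contrasts.items()]
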