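"""Mixed-effect cosinor model for sparse, nonuniformly sampled SDNN.

The 24-hour cosinor writes heart-rate variability at clock time ``t`` as

.. math:: Y(t) = M + A\\,\\cos(2\\pi t/\\tau + \\phi) + e(t), \\qquad \\tau = 24,

with MESOR :math:`M` (rhythm-adjusted mean, ms), amplitude :math:`A \\ge 0`
(half the within-day swing, ms) and acrophase :math:`\\phi` (phase angle of
the daily peak, radians).  Substituting
``x = cos(2*pi*t/24)``, ``z = sin(2*pi*t/24)`` linearises the model to
``Y = M + beta*x + gamma*z`` with ``beta = A cos(phi)``,
``gamma = -A sin(phi)``, so a linear mixed model with a per-subject random
intercept absorbs the longitudinal correlation while group-by-(x, z)
interactions let each tertial of a baseline trait carry its own rhythm.
Group differences in (M, A, phi) are tested by a subject-weighted
(Bayesian) bootstrap that refits the linear model by weighted least squares
with the variance components frozen at their full-data REML estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from patsy import build_design_matrices
from scipy import linalg, stats
from sklearn.base import BaseEstimator

from .lmm import CAR1MixedModel, _counterfactual_row

__all__ = [
    "CosinorParams",
    "CosinorMixedModel",
    "BootstrapComparison",
    "linearize_time",
    "invert_to_circadian",
    "predict_daily_curve",
    "fit_cosinor_mixed",
    "group_marginal_params",
    "bootstrap_compare",
]

PERIOD_HOURS = 24.0
_OMEGA = 2.0 * np.pi / PERIOD_HOURS


@dataclass(frozen=True)
class CosinorParams:
    """(MESOR, amplitude, acrophase) description of one 24-h rhythm.

    The acrophase is reported in radians wrapped into ``(-2*pi, 0]`` (the
    standard rhythmometry convention); ``acrophase_hours`` renders it as the
    clock time of the daily peak.  ``acrophase_defined`` is False for a flat
    rhythm (amplitude exactly zero), where the phase is meaningless.
    """

    mesor: float
    amplitude: float
    acrophase: float
    period_hours: float = PERIOD_HOURS
    acrophase_defined: bool = True

    def __post_init__(self):
        if self.amplitude < 0:
            raise ValueError("amplitude must be nonnegative")
        if self.acrophase_defined and not (-2 * np.pi < self.acrophase <= 0):
            raise ValueError("acrophase must lie in (-2*pi, 0]")

    @property
    def acrophase_hours(self):
        if not self.acrophase_defined:
            return float("nan")
        return -self.acrophase * self.period_hours / (2 * np.pi)

    def predict(self, t_hours):
        """Fitted curve Y(t) = M + A cos(2*pi*t/24 + phi)."""
        t = np.asarray(t_hours, dtype=float)
        phi = self.acrophase if self.acrophase_defined else 0.0
        return self.mesor + self.amplitude * np.cos(_OMEGA * t + phi)


@dataclass
class BootstrapComparison:
    """Bootstrap test of one circadian parameter between two groups."""

    parameter: str
    group_a: str
    group_b: str
    observed: float
    replicates: np.ndarray
    p: float
    n_boot: int
    seed: int
    n_failures: int = 0


def linearize_time(timestamps):
    """Hours since local midnight and the cosinor regressors (x, z).

    Returns (t_hours, x, z) with ``x = cos(2*pi*t/24)`` and
    ``z = sin(2*pi*t/24)``.
    """
    ts = pd.to_datetime(pd.Series(timestamps))
    t = (
        ts.dt.hour
        + ts.dt.minute / 60.0
        + ts.dt.second / 3600.0
        + ts.dt.microsecond / 3.6e9
    ).to_numpy()
    return t, np.cos(_OMEGA * t), np.sin(_OMEGA * t)


def _wrap_acrophase(phi):
    """Wrap an angle into (-2*pi, 0]."""
    w = phi % (2 * np.pi)  # [0, 2*pi)
    return w - 2 * np.pi if w > 0 else 0.0


def wrap_phase_difference(d):
    """Wrap an acrophase difference into (-pi, pi]."""
    return float(-((-d + np.pi) % (2 * np.pi) - np.pi))


def invert_to_circadian(beta, gamma, mesor):
    """Recover (M, A, phi) from the linear coefficients.

    ``A = sqrt(beta^2 + gamma^2)`` and ``phi = atan2(-gamma, beta)`` wrapped
    into ``(-2*pi, 0]``; the round trip ``beta = A cos(phi)``,
    ``gamma = -A sin(phi)`` holds to machine precision.  A zero (beta, gamma)
    pair gives amplitude 0 with the acrophase flagged undefined.
    """
    amp = float(np.hypot(beta, gamma))
    if amp == 0.0:
        return CosinorParams(mesor=float(mesor), amplitude=0.0,
                             acrophase=float("nan"), acrophase_defined=False)
    phi = _wrap_acrophase(float(np.arctan2(-gamma, beta)))
    return CosinorParams(mesor=float(mesor), amplitude=amp, acrophase=phi)


def predict_daily_curve(params, t_hours=None):
    """Fitted SDNN over 24 h; max - min equals twice the amplitude."""
    if t_hours is None:
        t_hours = np.linspace(0.0, PERIOD_HOURS, 241)
    return np.asarray(t_hours, dtype=float), params.predict(t_hours)


class CosinorMixedModel(BaseEstimator):
    """Mixed-effect cosinor regression of SDNN with optional group rhythms.

    Parameters
    ----------
    group : str or None
        Categorical column (e.g. a trait tertial) whose levels carry their
        own MESOR/amplitude/acrophase via interactions with (x, z).
    covariates : tuple of str
        Adjustment covariates entering as fixed main effects.
    min_obs : int
        Minimum HRV observations per subject for inclusion.
    response, groups, timestamp : str
        Column names of the SDNN value, the subject id, and the timestamp.

    Attributes
    ----------
    fit_ : CAR1MixedModel
        The underlying linear mixed-model fit (random intercept, REML).
    params_ : dict
        Per-group :class:`CosinorParams` (key ``"all"`` when ungrouped).
    params_se_ : dict
        Delta-method standard errors ``{level: {"mesor": .., "amplitude": ..,
        "acrophase": ..}}``.
    """

    def __init__(self, group=None, covariates=(), min_obs=10, reml=True,
                 response="sdnn_ms", groups="participant_id",
                 timestamp="timestamp"):
        self.group = group
        self.covariates = covariates
        self.min_obs = min_obs
        self.reml = reml
        self.response = response
        self.groups = groups
        self.timestamp = timestamp

    def _formula(self):
        rhythm = "cos_t + sin_t"
        terms = [f"C({self.group}) * ({rhythm})" if self.group else rhythm]
        terms += list(self.covariates)
        return f"{self.response} ~ " + " + ".join(terms)

    def fit(self, data):
        """Fit to an HRV table (one row per SDNN recording) already joined
        with any subject-level covariates."""
        work = data.copy()
        counts = work.groupby(self.groups)[self.response].transform("size")
        n_excl = int((counts < self.min_obs).sum())
        if n_excl:
            warnings.warn(
                f"excluding {work.loc[counts < self.min_obs, self.groups].nunique()}"
                f" subjects with fewer than {self.min_obs} observations"
            )
        work = work[counts >= self.min_obs]
        if not len(work):
            raise ValueError("no subjects meet the minimum-observation threshold")
        if self.timestamp in work.columns:
            t, x, z = linearize_time(work[self.timestamp])
        elif "t_hours" in work.columns:
            t = work["t_hours"].to_numpy(dtype=float)
            x, z = np.cos(_OMEGA * t), np.sin(_OMEGA * t)
        else:
            raise ValueError(
                f"need a {self.timestamp!r} or 't_hours' column"
            )
        work = work.assign(t_hours=t, cos_t=x, sin_t=z)
        inner = CAR1MixedModel(
            self._formula(),
            groups=self.groups,
            correlation="none",
            random_intercept=True,
            reml=self.reml,
        )
        self.fit_ = inner.fit(work)
        self.levels_ = (
            list(pd.unique(work[self.group])) if self.group else ["all"]
        )
        self._compute_group_params()
        self.n_obs_ = self.fit_.n_obs_
        self.n_subjects_ = self.fit_.n_subjects_
        return self

    # ------------------------------------------------------------------

    def _group_rows(self, level):
        """Counterfactual design rows (L_M, L_beta, L_gamma) for one group.

        L_M pins (cos_t, sin_t) = (0, 0); L_beta and L_gamma are the
        derivative rows with respect to the cosine and sine regressors.
        """
        pin = {} if self.group is None else {self.group: level}
        L_m = _counterfactual_row(self.fit_, {**pin, "cos_t": 0.0, "sin_t": 0.0})
        L_b = (
            _counterfactual_row(self.fit_, {**pin, "cos_t": 1.0, "sin_t": 0.0})
            - L_m
        )
        L_g = (
            _counterfactual_row(self.fit_, {**pin, "cos_t": 0.0, "sin_t": 1.0})
            - L_m
        )
        return L_m, L_b, L_g

    def _params_from_coef(self, beta_vec, level):
        L_m, L_b, L_g = self._group_rows(level)
        return invert_to_circadian(
            float(L_b @ beta_vec), float(L_g @ beta_vec), float(L_m @ beta_vec)
        )

    def _compute_group_params(self):
        coef = self.fit_.coef_.to_numpy()
        C = self.fit_.coef_cov_.to_numpy()
        self.params_ = {}
        self.params_se_ = {}
        for lev in self.levels_:
            L_m, L_b, L_g = self._group_rows(lev)
            m = float(L_m @ coef)
            b = float(L_b @ coef)
            g = float(L_g @ coef)
            par = invert_to_circadian(b, g, m)
            self.params_[lev] = par
            # delta-method SEs from the coefficient covariance
            se_m = float(np.sqrt(L_m @ C @ L_m))
            B = np.vstack([L_b, L_g])
            C2 = B @ C @ B.T
            if par.amplitude > 0:
                ga = np.array([b, g]) / par.amplitude
                se_a = float(np.sqrt(max(ga @ C2 @ ga, 0.0)))
                gp = np.array([g, -b]) / par.amplitude**2
                se_p = float(np.sqrt(max(gp @ C2 @ gp, 0.0)))
            else:
                se_a = float(np.sqrt(max(C2[0, 0], C2[1, 1])))
                se_p = float("nan")
            self.params_se_[lev] = {
                "mesor": se_m,
                "amplitude": se_a,
                "acrophase": se_p,
            }


def fit_cosinor_mixed(data, group=None, covariates=(), **kwargs):
    """Thin functional wrapper over :class:`CosinorMixedModel`."""
    return CosinorMixedModel(group=group, covariates=covariates, **kwargs).fit(data)


def group_marginal_params(model, levels=None):
    """Per-group circadian parameters of a fitted model as a DataFrame."""
    levels = levels if levels is not None else model.levels_
    rows = []
    for lev in levels:
        if lev not in model.params_:
            raise ValueError(f"unknown group level {lev!r}")
        p = model.params_[lev]
        se = model.params_se_[lev]
        rows.append(
            {
                "group": lev,
                "mesor": p.mesor,
                "amplitude": p.amplitude,
                "acrophase": p.acrophase,
                "acrophase_hours": p.acrophase_hours,
                "se_mesor": se["mesor"],
                "se_amplitude": se["amplitude"],
                "se_acrophase": se["acrophase"],
            }
        )
    return pd.DataFrame(rows).set_index("group")


# ----------------------------------------------------------------------
# bootstrap comparison


def _subject_stats(model):
    """Per-subject GLS sufficient statistics with frozen variance components.

    For subject i with n_i rows, W_i^-1 = I - c_i 1 1' where
    c_i = g / (1 + g n_i) and g is the intercept-to-residual variance ratio;
    returns stacked A_i = X_i' W_i^-1 X_i and d_i = X_i' W_i^-1 y_i.
    """
    fit = model.fit_
    frame = fit.model_frame_
    (Xd,) = build_design_matrices([fit.design_info_], frame)
    X = np.asarray(Xd)
    y = frame[model.response].to_numpy(dtype=float)
    sub = pd.Categorical(frame[model.groups]).codes
    g = fit.variance_components_.get("intercept", 0.0) / fit.sigma2_
    A_list, d_list = [], []
    for code in np.unique(sub):
        J = np.flatnonzero(sub == code)
        Xi, yi = X[J], y[J]
        ni = len(J)
        c = g / (1.0 + g * ni)
        s = Xi.sum(axis=0)
        A = Xi.T @ Xi - c * np.outer(s, s)
        d = Xi.T @ yi - c * s * yi.sum()
        A_list.append(A)
        d_list.append(d)
    return np.stack(A_list), np.stack(d_list)


def bootstrap_compare(model, n_boot=1000, seed=0, mode="bayesian",
                      max_failure_frac=0.05):
    """Pairwise bootstrap comparison of (M, A, phi) between group levels.

    Each iteration draws independent unit-mean weights per subject
    (exponential for the Bayesian bootstrap, multinomial resampling counts
    for ``mode="resample"``), solves the weighted least-squares problem with
    the variance components frozen at their full-data REML values, rebuilds
    each group's marginal circadian parameters, and records every pairwise
    difference.  Acrophase differences are wrapped into ``(-pi, pi]``.
    The two-sided p-value is ``2 * min(frac <= 0, frac >= 0)`` with the
    ``(r + 1) / (n_boot + 1)`` continuity correction.
    """
    if model.group is None or len(model.levels_) < 2:
        raise ValueError("bootstrap comparison requires >= 2 group levels")
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    if mode not in ("bayesian", "resample"):
        raise ValueError(f"unknown bootstrap mode {mode!r}")
    rng = np.random.default_rng(seed)
    A, d = _subject_stats(model)
    S = A.shape[0]
    levels = list(model.levels_)
    rows = {lev: model._group_rows(lev) for lev in levels}
    pairs = [(a, b) for i, a in enumerate(levels) for b in levels[i + 1:]]

    reps = {
        (pm, a, b): np.empty(n_boot)
        for pm in ("mesor", "amplitude", "acrophase")
        for a, b in pairs
    }
    n_failures = 0
    it = 0
    while it < n_boot:
        if mode == "bayesian":
            w = rng.exponential(1.0, size=S)
        else:
            w = rng.multinomial(S, np.full(S, 1.0 / S)).astype(float)
        try:
            beta = linalg.solve(
                np.einsum("s,spq->pq", w, A),
                np.einsum("s,sp->p", w, d),
                assume_a="pos",
            )
        except linalg.LinAlgError:
            n_failures += 1
            if n_failures > max_failure_frac * n_boot:
                raise RuntimeError(
                    f"more than {max_failure_frac:.0%} of bootstrap iterations failed"
                )
            continue
        par = {}
        for lev in levels:
            L_m, L_b, L_g = rows[lev]
            par[lev] = invert_to_circadian(
                float(L_b @ beta), float(L_g @ beta), float(L_m @ beta)
            )
        for a, b in pairs:
            reps[("mesor", a, b)][it] = par[a].mesor - par[b].mesor
            reps[("amplitude", a, b)][it] = par[a].amplitude - par[b].amplitude
            reps[("acrophase", a, b)][it] = wrap_phase_difference(
                par[a].acrophase - par[b].acrophase
            )
        it += 1

    out = []
    for (pm, a, b), r in reps.items():
        pa, pb = model.params_[a], model.params_[b]
        if pm == "acrophase":
            obs = wrap_phase_difference(pa.acrophase - pb.acrophase)
        else:
            obs = getattr(pa, pm) - getattr(pb, pm)
        lo = (np.sum(r <= 0) + 1) / (n_boot + 1)
        hi = (np.sum(r >= 0) + 1) / (n_boot + 1)
        p = min(1.0, 2.0 * min(lo, hi))
        out.append(
            BootstrapComparison(
                parameter=pm, group_a=a, group_b=b, observed=float(obs),
                replicates=r, p=float(p), n_boot=n_boot, seed=seed,
                n_failures=n_failures,
            )
        )
    return out
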