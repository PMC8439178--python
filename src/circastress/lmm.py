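"""Gaussian linear mixed models with continuous AR(1) within-subject correlation.

The model for subject :math:`i` with :math:`n_i` longitudinal observations is

.. math::

    y_i = X_i \\beta + Z_i b_i + \\varepsilon_i,\\qquad
    b_i \\sim N(0, \\Psi),\\qquad
    \\varepsilon_i \\sim N(0, \\sigma^2 \\Phi_i(\\varphi)),

where :math:`\\Phi_i` is the continuous first-order autoregressive (CAR(1))
correlation matrix over the subject's ordering variable (the survey *period*
index): :math:`[\\Phi_i]_{jk} = \\varphi^{|t_{ij} - t_{ik}|}` with
:math:`\\varphi \\in [0, 1)`.  Random effects are a subject intercept and
optionally independent subject slopes (diagonal :math:`\\Psi`).

Estimation profiles :math:`\\beta` and :math:`\\sigma^2` out of the restricted
likelihood and optimises the remaining variance ratios and :math:`\\varphi`
on transformed (log / logistic) scales with multiple starts.  No installed
library fits this residual-correlation structure, so the likelihood is
implemented here from first principles; the test-suite checks it against a
brute-force dense multivariate-normal evaluation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from patsy import build_design_matrices, dmatrices
from scipy import linalg, optimize, stats
from scipy.special import expit
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

__all__ = [
    "CAR1MixedModel",
    "ContrastResult",
    "ConvergenceError",
    "SingularDesignError",
    "contrast",
    "factor_contrast",
    "fit_lmm",
    "likelihood_ratio_test",
    "marginal_means",
    "wald_table",
]

# bounds for the transformed covariance parameters:
# variance ratios g = exp(a), CAR(1) phi = expit(u)
_A_LO, _A_HI = -12.0, 8.0
_U_LO, _U_HI = -12.0, 5.0

_LOG2PI = np.log(2.0 * np.pi)


class ConvergenceError(RuntimeError):
    """Optimiser failed to converge; ``trace`` holds the per-start results."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace or []


class SingularDesignError(ValueError):
    """Design matrix is rank deficient; ``aliased`` names the dependent columns."""

    def __init__(self, aliased):
        self.aliased = list(aliased)
        super().__init__(
            "singular fixed-effect design; aliased columns: " + ", ".join(self.aliased)
        )


@dataclass
class ContrastResult:
    """A linear combination of fixed-effect coefficients with its Wald test."""

    label: str
    estimate: float
    se: float
    z: float
    p: float


def _check_full_rank(X, names):
    q, r, piv = linalg.qr(X, mode="economic", pivoting=True)
    d = np.abs(np.diag(r))
    tol = d[0] * max(X.shape) * np.finfo(float).eps if d.size else 0.0
    rank = int(np.sum(d > tol))
    if rank < X.shape[1]:
        raise SingularDesignError([names[j] for j in piv[rank:]])


class _SubjectBlocks:
    """Per-subject design blocks grouped by shared (time-pattern, Z-pattern).

    Subjects that share an identical ordering vector and random-effect design
    share the same within-subject covariance ``W``; their contributions are
    accumulated with one Cholesky factorisation per pattern, which makes
    balanced simulated designs essentially free.
    """

    def __init__(self, y, X, Z, t, subject):
        order = np.argsort(subject, kind="stable")
        y, X, subject = y[order], X[order], subject[order]
        Z = Z[order] if Z is not None else None
        t = t[order] if t is not None else None

        self.n, self.p = X.shape
        self.q = 0 if Z is None else Z.shape[1]
        self.car1 = t is not None

        starts = np.flatnonzero(np.r_[True, subject[1:] != subject[:-1]])
        bounds = np.r_[starts, self.n]
        self.n_subjects = len(starts)

        groups: dict[bytes, list[int]] = {}
        blocks = []
        for s, e in zip(bounds[:-1], bounds[1:]):
            ti = t[s:e] if self.car1 else None
            Zi = Z[s:e] if Z is not None else None
            key = (ti.tobytes() if ti is not None else b"") + b"|" + (
                Zi.tobytes() if Zi is not None else b""
            )
            groups.setdefault(key, []).append(len(blocks))
            blocks.append((s, e, ti, Zi))

        # one entry per pattern: (t, Z, stacked X (m, ni, p), stacked y (m, ni))
        self.patterns = []
        for idx in groups.values():
            s0, e0, t0, Z0 = blocks[idx[0]]
            Xs = np.stack([X[blocks[j][0]: blocks[j][1]] for j in idx])
            ys = np.stack([y[blocks[j][0]: blocks[j][1]] for j in idx])
            self.patterns.append((t0, Z0, Xs, ys))

    # -- likelihood building blocks -------------------------------------

    def _pattern_W(self, t, Z, g, phi):
        ni = t.shape[0] if t is not None else Z.shape[0] if Z is not None else None
        if ni is None:
            raise AssertionError("pattern with neither time nor Z")
        W = np.eye(ni)
        if t is not None and phi is not None and phi > 0:
            W = phi ** np.abs(t[:, None] - t[None, :])
        if Z is not None and len(g):
            W = W + (Z * g) @ Z.T
        return W

    def accumulate(self, g, phi):
        """Return (logdet_W_total, X'W^-1 X, X'W^-1 y, y'W^-1 y)."""
        p = self.p
        XtWX = np.zeros((p, p))
        XtWy = np.zeros(p)
        yty = 0.0
        logdet = 0.0
        g = np.asarray(g, dtype=float)
        for t, Zfull, Xs, ys in self.patterns:
            m, ni, _ = Xs.shape
            no_corr = t is None or phi is None or phi <= 0
            Z, gz = Zfull, g
            if Zfull is not None and len(g) and not np.all(g > 0):
                keep = g > 0
                Z = Zfull[:, keep] if np.any(keep) else None
                gz = g[keep]
            if (Z is None or not len(gz)) and no_corr:
                # W = I: plain cross-products
                C = np.einsum("mnk,mnl->kl", Xs, Xs)
                XtWX += C
                XtWy += np.einsum("mnk,mn->k", Xs, ys)
                yty += float(np.einsum("mn,mn->", ys, ys))
                continue
            if no_corr:
                # W = I + Z G Z': Woodbury with a q x q capacitance matrix,
                # avoiding any n_i x n_i factorisation (sparse-HRV fast path)
                ZtZ = Z.T @ Z  # (q, q)
                cap = np.diag(1.0 / gz) + ZtZ
                Mcap = linalg.inv(cap)
                sign, ld = np.linalg.slogdet(np.eye(len(gz)) + gz[:, None] * ZtZ)
                logdet += m * float(ld)
                XZ = np.einsum("mnk,nq->mkq", Xs, Z)  # per-subject X'Z
                yZ = ys @ Z  # (m, q)
                XtWX += np.einsum("mnk,mnl->kl", Xs, Xs) - np.einsum(
                    "mkq,qr,mlr->kl", XZ, Mcap, XZ
                )
                XtWy += np.einsum("mnk,mn->k", Xs, ys) - np.einsum(
                    "mkq,qr,mr->k", XZ, Mcap, yZ
                )
                yty += float(np.einsum("mn,mn->", ys, ys)) - float(
                    np.einsum("mq,qr,mr->", yZ, Mcap, yZ)
                )
                continue
            W = self._pattern_W(t, Z, gz, phi)
            L = linalg.cholesky(W, lower=True)
            logdet += 2.0 * m * float(np.sum(np.log(np.diag(L))))
            B = np.concatenate([Xs, ys[:, :, None]], axis=2)  # (m, ni, p+1)
            B2 = np.moveaxis(B, 1, 0).reshape(ni, -1)  # (ni, m*(p+1))
            U = linalg.solve_triangular(L, B2, lower=True)
            U = U.reshape(ni, m, p + 1)
            C = np.einsum("nmk,nml->mkl", U, U)  # per-subject crossprods
            XtWX += C[:, :p, :p].sum(axis=0)
            XtWy += C[:, :p, p].sum(axis=0)
            yty += float(C[:, p, p].sum())
        return logdet, XtWX, XtWy, yty


def _gls(XtWX, XtWy, yty):
    try:
        cf = linalg.cho_factor(XtWX)
    except linalg.LinAlgError as err:  # pragma: no cover - guarded by rank check
        raise SingularDesignError(["<numerically singular>"]) from err
    beta = linalg.cho_solve(cf, XtWy)
    rss = max(float(yty - XtWy @ beta), 1e-300)
    logdet_XtWX = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    return beta, rss, logdet_XtWX, cf


class CAR1MixedModel(BaseEstimator):
    """Mixed-effect regression with subject random effects and CAR(1) residuals.

    Parameters
    ----------
    formula : str
        patsy formula for the response and fixed effects, e.g.
        ``"pss4 ~ mean_case_count + emotional_support"``.
    groups : str
        Column identifying the subject.
    time : str or None
        Ordering column (period index) for the CAR(1) structure.  Required
        when ``correlation="car1"``.
    correlation : {"car1", "none"}
        Within-subject residual correlation structure.
    random_intercept : bool
        Include a per-subject random intercept.
    random_slopes : tuple of str
        Columns receiving independent per-subject random slopes.
    reml : bool
        Restricted (True) or ordinary (False) maximum likelihood.
    n_starts : int
        Number of optimiser starting points.
    tol : float
        Convergence tolerance on the objective.

    Attributes
    ----------
    coef_ : pandas.Series
        Fixed-effect estimates.
    coef_cov_ : pandas.DataFrame
        Covariance of the fixed-effect estimates.
    sigma2_ : float
        Residual variance.
    variance_components_ : dict
        ``{"residual": .., "intercept": .., "slope_<col>": ..}`` variances.
    phi_ : float or None
        CAR(1) correlation parameter estimate.
    loglik_ : float
        Restricted (or full) log-likelihood at the optimum.
    """

    def __init__(
        self,
        formula,
        groups="participant_id",
        time=None,
        correlation="car1",
        random_intercept=True,
        random_slopes=(),
        reml=True,
        n_starts=3,
        tol=1e-8,
    ):
        self.formula = formula
        self.groups = groups
        self.time = time
        self.correlation = correlation
        self.random_intercept = random_intercept
        self.random_slopes = random_slopes
        self.reml = reml
        self.n_starts = n_starts
        self.tol = tol

    # ------------------------------------------------------------------

    def _prepare(self, data):
        if self.correlation not in ("car1", "none"):
            raise ValueError(f"unknown correlation structure {self.correlation!r}")
        if self.correlation == "car1" and self.time is None:
            raise ValueError("correlation='car1' requires a `time` ordering column")
        ydf, Xdf = dmatrices(self.formula, data, return_type="dataframe")
        idx = Xdf.index
        n_dropped = len(data) - len(idx)
        if n_dropped:
            logger.info("dropped %d rows with missing model variables", n_dropped)
        y = np.asarray(ydf).ravel()
        X = np.asarray(Xdf)
        names = list(Xdf.columns)
        _check_full_rank(X, names)

        sub = pd.Categorical(data.loc[idx, self.groups]).codes.astype(np.int64)
        t = None
        if self.correlation == "car1":
            t = np.asarray(data.loc[idx, self.time], dtype=float)

        zcols = []
        znames = []
        if self.random_intercept:
            zcols.append(np.ones(len(idx)))
            znames.append("intercept")
        for c in self.random_slopes:
            zcols.append(np.asarray(data.loc[idx, c], dtype=float))
            znames.append(f"slope_{c}")
        Z = np.column_stack(zcols) if zcols else None
        return y, X, Z, t, sub, names, znames, data.loc[idx], Xdf.design_info

    def _unpack(self, theta, q):
        g = np.exp(theta[:q]) if q else np.empty(0)
        phi = float(expit(theta[q])) if self.correlation == "car1" else None
        return g, phi

    def _neg2(self, theta, blocks):
        g, phi = self._unpack(theta, blocks.q)
        logdet, XtWX, XtWy, yty = blocks.accumulate(g, phi)
        beta, rss, logdet_XtWX, _ = _gls(XtWX, XtWy, yty)
        n, p = blocks.n, blocks.p
        if self.reml:
            dof = n - p
            sig2 = rss / dof
            return dof * (_LOG2PI + np.log(sig2) + 1.0) + logdet + logdet_XtWX
        sig2 = rss / n
        return n * (_LOG2PI + np.log(sig2) + 1.0) + logdet

    # ------------------------------------------------------------------

    def fit(self, data):
        """Fit the model to a long-format DataFrame."""
        y, X, Z, t, sub, names, znames, frame, dinfo = self._prepare(data)
        if len(np.unique(sub)) < 1 or len(y) <= X.shape[1]:
            raise ValueError("too few observations for the requested design")
        blocks = _SubjectBlocks(y, X, Z, t, sub)
        q = blocks.q
        ndim = q + (1 if self.correlation == "car1" else 0)

        trace = []
        if ndim == 0:
            theta = np.empty(0)
            converged = True
        else:
            starts = [np.zeros(ndim)]
            alt1 = np.full(ndim, -2.3)
            alt2 = np.full(ndim, 1.6)
            if self.correlation == "car1":
                starts[0][q] = stats.logistic.ppf(0.3)
                alt1[q] = stats.logistic.ppf(0.7)
                alt2[q] = stats.logistic.ppf(0.05)
            starts += [alt1, alt2]
            starts = starts[: max(1, self.n_starts)]
            bounds = [(_A_LO, _A_HI)] * q
            if self.correlation == "car1":
                bounds.append((_U_LO, _U_HI))
            best = None
            for x0 in starts:
                res = optimize.minimize(
                    self._neg2,
                    x0,
                    args=(blocks,),
                    method="L-BFGS-B",
                    bounds=bounds,
                    options={"ftol": self.tol * 1e-4, "gtol": 1e-7, "maxiter": 500},
                )
                trace.append(res)
                if best is None or res.fun < best.fun - 0.0:
                    best = res
            if best is None or not np.isfinite(best.fun):
                raise ConvergenceError("all optimiser starts failed", trace)
            converged = any(r.success for r in trace)
            if not converged:
                raise ConvergenceError("optimiser did not converge", trace)
            theta = best.x

        g, phi = self._unpack(theta, q)
        logdet, XtWX, XtWy, yty = blocks.accumulate(g, phi)
        beta, rss, logdet_XtWX, cf = _gls(XtWX, XtWy, yty)
        n, p = blocks.n, blocks.p
        dof = n - p if self.reml else n
        sig2 = rss / dof
        neg2 = self._neg2(theta, blocks)

        self.coef_ = pd.Series(beta, index=names)
        cov = sig2 * linalg.cho_solve(cf, np.eye(p))
        cov = (cov + cov.T) / 2.0
        self.coef_cov_ = pd.DataFrame(cov, index=names, columns=names)
        self.sigma2_ = float(sig2)
        vc = {"residual": float(sig2)}
        for k, nm in enumerate(znames):
            vc[nm] = float(g[k] * sig2)
        self.variance_components_ = vc
        self.phi_ = phi
        self.loglik_ = -0.5 * float(neg2)
        self.theta_ = theta
        self.n_obs_ = int(n)
        self.n_subjects_ = int(blocks.n_subjects)
        self.converged_ = converged
        self.design_info_ = dinfo
        self.model_frame_ = frame
        self._blocks = blocks
        self._znames = znames
        self._compute_theta_se(blocks, theta)
        return self

    def _compute_theta_se(self, blocks, theta):
        """Approximate SEs for the covariance parameters from the profiled
        objective's numerical Hessian (central differences)."""
        ndim = len(theta)
        self.theta_se_ = np.full(ndim, np.nan)
        self.phi_se_ = None
        self.variance_se_log_ = {}
        if ndim == 0:
            return
        h = 1e-4
        H = np.empty((ndim, ndim))
        f0 = self._neg2(theta, blocks)
        for i in range(ndim):
            for j in range(i, ndim):
                ei = np.zeros(ndim); ei[i] = h
                ej = np.zeros(ndim); ej[j] = h
                if i == j:
                    fpp = self._neg2(theta + ei, blocks)
                    fmm = self._neg2(theta - ei, blocks)
                    H[i, i] = (fpp - 2 * f0 + fmm) / h**2
                else:
                    fpp = self._neg2(theta + ei + ej, blocks)
                    fpm = self._neg2(theta + ei - ej, blocks)
                    fmp = self._neg2(theta - ei + ej, blocks)
                    fmm = self._neg2(theta - ei - ej, blocks)
                    H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h**2)
        try:
            cov = 2.0 * linalg.inv(H)
            d = np.diag(cov)
            if np.all(d > 0):
                self.theta_se_ = np.sqrt(d)
        except linalg.LinAlgError:
            return
        q = blocks.q
        for k, nm in enumerate(self._znames):
            self.variance_se_log_[nm] = float(self.theta_se_[k])
        if self.correlation == "car1" and np.isfinite(self.theta_se_[q]):
            phi = self.phi_
            self.phi_se_ = float(self.theta_se_[q] * phi * (1.0 - phi))

    # ------------------------------------------------------------------

    def loglik_at(self, sigma2, variance_components=None, phi=None):
        """Evaluate the (restricted) log-likelihood at explicit covariance
        parameters, without profiling.  Used for oracle comparisons.

        Parameters
        ----------
        sigma2 : float
            Residual variance.
        variance_components : dict or None
            Random-effect variances keyed like ``variance_components_``
            (``"intercept"``, ``"slope_<col>"``); missing keys mean zero.
        phi : float or None
            CAR(1) parameter; ignored unless ``correlation="car1"``.
        """
        blocks = self._blocks
        vc = variance_components or {}
        g = np.array([vc.get(nm, 0.0) / sigma2 for nm in self._znames])
        use_phi = phi if self.correlation == "car1" else None
        logdet, XtWX, XtWy, yty = blocks.accumulate(g, use_phi)
        beta, rss, logdet_XtWX, _ = _gls(XtWX, XtWy, yty)
        n, p = blocks.n, blocks.p
        if self.reml:
            neg2 = (
                (n - p) * (_LOG2PI + np.log(sigma2))
                + logdet
                + logdet_XtWX
                + rss / sigma2
            )
        else:
            neg2 = n * (_LOG2PI + np.log(sigma2)) + logdet + rss / sigma2
        return -0.5 * float(neg2)

    def predict(self, data):
        """Population-level (fixed-effect) predictions for new rows."""
        (X,) = build_design_matrices([self.design_info_], data)
        return np.asarray(X) @ self.coef_.to_numpy()


# ----------------------------------------------------------------------
# inference helpers


def fit_lmm(data, formula, **kwargs):
    """Thin functional wrapper: ``CAR1MixedModel(formula, **kwargs).fit(data)``."""
    return CAR1MixedModel(formula, **kwargs).fit(data)


def contrast(fit, L, label=""):
    """Wald test of the linear combination ``L @ coef``."""
    L = np.asarray(L, dtype=float)
    k = len(fit.coef_)
    if L.shape != (k,):
        raise ValueError(f"contrast vector must have length {k}")
    est = float(L @ fit.coef_.to_numpy())
    var = float(L @ fit.coef_cov_.to_numpy() @ L)
    se = np.sqrt(max(var, 0.0))
    if se == 0.0:
        z = 0.0 if est == 0.0 else np.inf * np.sign(est)
    else:
        z = est / se
    p = 1.0 if se == 0.0 and est == 0.0 else 2.0 * stats.norm.sf(abs(z))
    return ContrastResult(label=label, estimate=est, se=se, z=float(z), p=float(p))


def _counterfactual_row(fit, assignments):
    """Average design-matrix row with some columns pinned to given values.

    Continuous covariates stay at their observed values and factors keep
    their observed distribution, so the average is an observed-weights
    marginal (the ``emmeans`` "proportional" grid).
    """
    frame = fit.model_frame_.copy()
    for col, val in assignments.items():
        if col not in frame.columns:
            raise ValueError(f"unknown model variable {col!r}")
        frame[col] = val
    (X,) = build_design_matrices([fit.design_info_], frame)
    return np.asarray(X).mean(axis=0)


def marginal_means(fit, factor, levels=None):
    """Model-based marginal means for each level of ``factor``."""
    if levels is None:
        levels = list(pd.unique(fit.model_frame_[factor]))
    rows = []
    for lev in levels:
        L = _counterfactual_row(fit, {factor: lev})
        res = contrast(fit, L, label=f"{factor}={lev}")
        rows.append({"level": lev, "mean": res.estimate, "se": res.se})
    return pd.DataFrame(rows).set_index("level")


def factor_contrast(fit, factor, level_a, level_b, extra=None):
    """Marginal-mean difference ``level_a - level_b`` of a model factor.

    ``extra`` optionally pins additional columns (e.g. a stratifying
    tertial) in both counterfactual frames.
    """
    base = dict(extra or {})
    La = _counterfactual_row(fit, {**base, factor: level_a})
    Lb = _counterfactual_row(fit, {**base, factor: level_b})
    return contrast(fit, La - Lb, label=f"{factor}: {level_a} - {level_b}")


def wald_table(fit):
    """Type-III (marginal) Wald chi-square test for every non-intercept term."""
    rows = []
    C = fit.coef_cov_.to_numpy()
    b = fit.coef_.to_numpy()
    for term, sl in fit.design_info_.term_name_slices.items():
        if term == "Intercept":
            continue
        J = np.arange(len(b))[sl]
        bj = b[J]
        Cj = C[np.ix_(J, J)]
        try:
            stat = float(bj @ linalg.solve(Cj, bj, assume_a="pos"))
        except linalg.LinAlgError:
            stat = np.nan
        df = len(J)
        p = float(stats.chi2.sf(stat, df)) if np.isfinite(stat) else np.nan
        est = float(bj[0]) if df == 1 else np.nan
        rows.append({"term": term, "estimate": est, "chi2": stat, "df": df, "p": p})
    return pd.DataFrame(rows).set_index("term")


def likelihood_ratio_test(fit_full, fit_reduced, boundary=True):
    """LRT of nested covariance structures.

    When testing a variance component (``boundary=True``) the reference
    distribution is the 50:50 mixture of a point mass at zero and a
    chi-square with 1 df; otherwise plain chi-square with 1 df.
    """
    stat = max(0.0, 2.0 * (fit_full.loglik_ - fit_reduced.loglik_))
    if stat <= 0.0:
        return 0.0, 1.0
    p = stats.chi2.sf(stat, 1)
    if boundary:
        p = 0.5 * p
    return float(stat), float(p)
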