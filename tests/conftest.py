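"""Shared fixtures and independent data generators for the test-suite.

The generators here build longitudinal data *directly* from the model
equations (not through the cohort simulator), so parameter-recovery tests
exercise the estimators against a known truth that is independent of the
package's own simulation code.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest


def make_car1_panel(n_subjects, n_periods, beta=(2.0, 0.5, -0.3), phi=0.6,
                    subject_sd=1.2, resid_sd=1.5, slope_sd=0.0, seed=0):
    """Balanced longitudinal panel with known truth.

    y = b0 + b1*x1 + b2*x2 + u_i (+ s_i * x2 when slope_sd > 0) + e,
    x1 between-subject, x2 within-subject, e an AR(1) sequence over the
    period index with parameter phi and marginal SD resid_sd.
    """
    rng = np.random.default_rng(seed)
    b0, b1, b2 = beta
    n, K = n_subjects, n_periods
    u = rng.normal(0.0, subject_sd, size=n)
    s = rng.normal(0.0, slope_sd, size=n) if slope_sd > 0 else np.zeros(n)
    x1 = rng.normal(size=n)
    e = np.empty((n, K))
    e[:, 0] = rng.normal(0.0, resid_sd, size=n)
    innov_sd = np.sqrt(1 - phi**2) * resid_sd
    for k in range(1, K):
        e[:, k] = phi * e[:, k - 1] + rng.normal(0.0, innov_sd, size=n)
    x2 = rng.normal(size=(n, K))
    y = b0 + b1 * x1[:, None] + (b2 + s)[:, None] * x2 + u[:, None] + e
    ids = np.repeat([f"S{i:04d}" for i in range(n)], K)
    return pd.DataFrame(
        {"participant_id": ids, "period": np.tile(np.arange(1, K + 1), n),
         "x1": np.repeat(x1, K), "x2": x2.ravel(), "y": y.ravel()}
    )


def make_cosinor_sample(n_subjects, n_days, obs_per_day_mean=4.0, mesor=40.0,
                        amplitudes=(10.0,), acrophases=(-2.0,),
                        subject_sd=8.0, noise_sd=10.0, seed=0,
                        group_labels=None):
    """Sparse within-day SDNN observations from a 24-h cosinor.

    Subjects are spread evenly over the supplied groups (one rhythm per
    group); returns a long table with participant_id, timestamp columns
    replaced by hours (t_hours) plus precomputed cos_t/sin_t regressors.
    """
    rng = np.random.default_rng(seed)
    omega = 2 * np.pi / 24.0
    n_groups = len(amplitudes)
    labels = group_labels or [f"g{j}" for j in range(n_groups)]
    gi = np.arange(n_subjects) % n_groups
    b = rng.normal(0.0, subject_sd, size=n_subjects)
    counts = rng.poisson(obs_per_day_mean, size=(n_subjects, n_days)).sum(axis=1)
    total = int(counts.sum())
    sub = np.repeat(np.arange(n_subjects), counts)
    t = rng.uniform(0.0, 24.0, size=total)
    amps = np.asarray(amplitudes)[gi[sub]]
    phis = np.asarray(acrophases)[gi[sub]]
    y = mesor + b[sub] + amps * np.cos(omega * t + phis)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=total)
    ids = np.array([f"S{i:04d}" for i in range(n_subjects)])
    lab = np.array(labels)
    return pd.DataFrame(
        {"participant_id": ids[sub], "group": lab[gi[sub]], "t_hours": t,
         "cos_t": np.cos(omega * t), "sin_t": np.sin(omega * t), "sdnn_ms": y}
    )


def dense_reml_loglik(data, formula_cols, response, sigma2, subject_var, phi,
                      groups="participant_id", time="period"):
    """Brute-force restricted log-likelihood with an explicit dense covariance.

    Builds each subject's full marginal covariance
    sigma2 * CAR1(phi) + subject_var, stacks the block-diagonal V, and
    evaluates -0.5 * [(n-p) log 2pi + log|V| + log|X'V^-1 X| + r'V^-1 r]
    with r the GLS residual.  Deliberately independent of the package's
    profiled implementation.
    """
    X = np.column_stack([np.ones(len(data))] + [data[c].to_numpy(dtype=float)
                                                for c in formula_cols])
    y = data[response].to_numpy(dtype=float)
    n, p = X.shape
    V = np.zeros((n, n))
    ids = data[groups].to_numpy()
    for pid in pd.unique(ids):
        J = np.flatnonzero(ids == pid)
        t = data[time].to_numpy(dtype=float)[J]
        Phi = (
            phi ** np.abs(t[:, None] - t[None, :]) if phi > 0 else np.eye(len(J))
        )
        V[np.ix_(J, J)] = sigma2 * Phi + subject_var
    Vi = np.linalg.inv(V)
    XtVX = X.T @ Vi @ X
    beta = np.linalg.solve(XtVX, X.T @ Vi @ y)
    r = y - X @ beta
    _, ldV = np.linalg.slogdet(V)
    _, ldX = np.linalg.slogdet(XtVX)
    return -0.5 * ((n - p) * np.log(2 * np.pi) + ldV + ldX + r @ Vi @ r)


@pytest.fixture(scope="session")
def tiny_panel():
    """5 subjects x 4 periods, the oracle-equivalence instance size."""
    return make_car1_panel(5, 4, seed=42)


@pytest.fixture(scope="session")
def small_config():
    """A fast, small simulation configuration for structural tests."""
    from circastress import SimulationConfig

    return SimulationConfig(n_subjects=40, study_days=30, seed=11)
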