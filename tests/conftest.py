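"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from woundtriage.synth import SyntheticConfig, generate_cohort


# ---------------------------------------------------------------------------
# independent oracles (deliberately implemented apart from the package code)
# ---------------------------------------------------------------------------

def brute_force_auc(scores, labels) -> float:
    """Mean pairwise concordance over all case-control pairs, ties = 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                total += 1.0
            elif a == b:
                total += 0.5
    return total / (len(pos) * len(neg))


def irls_logistic(X, y, tol=1e-12, max_iter=200):
    """Iteratively reweighted least squares for logistic regression.

    Textbook Newton-Raphson on the binomial log-likelihood with an
    intercept column prepended; returns (intercept, coefficients).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    Z = np.column_stack([np.ones(len(y)), X])
    beta = np.zeros(Z.shape[1])
    for _ in range(max_iter):
        eta = Z @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        # weighted least squares step
        WZ = Z * w[:, None]
        step = np.linalg.solve(Z.T @ WZ, Z.T @ (y - mu))
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta[0], beta[1:]


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def small_cohort():
    """~400-patient cohort at default (study-calibrated) conditions."""
    return generate_cohort(SyntheticConfig(n_patients=400, seed=1))


@pytest.fixture(scope="session")
def tiny_imaged_cohort():
    """Small cohort with 64-px images for image-model tests."""
    cfg = SyntheticConfig(
        n_patients=120,
        seed=3,
        image_size=64,
        mean_responses_per_patient=2.0,
        p_ssi48=0.10,
        images_per_response=(0.3, 0.7, 0.0, 0.0),
    )
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
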