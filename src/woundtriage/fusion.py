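"""Late fusion of the tabular and image risk models.

A fusion head combines the two unimodal output probabilities into one
multimodal risk. The study's missing-data rules are honoured exactly:

* a response with no image keeps the PROMs-model probability unchanged
  (provenance ``proms_only``);
* a response with several images fuses each image with the PROMs
  probability and takes the highest fused risk.

Heads: ``average`` (parameter-free mean), ``logistic_stack`` (default; a
2-input logistic model on the unimodal probabilities, slope coefficients
constrained non-negative so fused risk is monotone in each input) and
``shallow_net`` (a small trained network on the probability pair).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

from . import _engine as eng
from .tabular import _validate_binary


def _check_probs(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.size and ((p < 0) | (p > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    return p


class AverageFusion:
    """Parameter-free head: the mean of the two unimodal probabilities."""

    kind = "average"

    def fit(self, p_proms, p_image, y):  # noqa: ARG002 - nothing to learn
        return self

    def fuse_pair(self, p_proms, p_image) -> np.ndarray:
        return (_check_probs(p_proms) + _check_probs(p_image)) / 2.0


class LogisticStackFusion:
    """2-input logistic stacker on the unimodal probabilities.

    Slopes are constrained to be non-negative, so the fused risk is
    monotone non-decreasing in each unimodal input by construction; a
    modality carrying no signal is simply assigned weight ~0.
    """

    kind = "logistic_stack"

    def __init__(self):
        self.coef_ = None
        self.intercept_ = None

    def fit(self, p_proms, p_image, y):
        X = np.column_stack([_check_probs(p_proms), _check_probs(p_image)])
        y = _validate_binary(y)

        def nll(theta):
            z = theta[0] + X @ theta[1:]
            return float(np.sum(np.logaddexp(0.0, z) - y * z))

        def grad(theta):
            z = theta[0] + X @ theta[1:]
            r = expit(z) - y
            return np.concatenate([[r.sum()], X.T @ r])

        res = minimize(
            nll,
            x0=np.array([0.0, 1.0, 1.0]),
            jac=grad,
            method="L-BFGS-B",
            bounds=[(None, None), (0.0, None), (0.0, None)],
        )
        self.intercept_ = float(res.x[0])
        self.coef_ = res.x[1:].copy()
        return self

    def fuse_pair(self, p_proms, p_image) -> np.ndarray:
        if self.coef_ is None:
            raise RuntimeError("logistic_stack head must be fitted before use")
        X = np.column_stack([_check_probs(p_proms), _check_probs(p_image)])
        return expit(self.intercept_ + X @ self.coef_)


class ShallowNetFusion:
    """Small trained network (2 -> 8 -> 1) on the probability pair."""

    kind = "shallow_net"

    def __init__(self, seed: int = 0):
        self.seed = seed
        self._net = None

    def fit(self, p_proms, p_image, y):
        X = np.column_stack([_check_probs(p_proms), _check_probs(p_image)])
        y = _validate_binary(y)
        rng = np.random.default_rng(np.random.SeedSequence([int(self.seed), 0xF5]))
        self._net = eng.Sequential(
            [eng.Dense(2, 8, rng), eng.ReLU(), eng.Dense(8, 1, rng)]
        )
        eng.train_network(
            self._net,
            X,
            y,
            optimizer=eng.Adam(lr=0.02),
            epochs=200,
            batch_size=32,
            rng=rng,
            eval_every=max(1, int(np.ceil(len(y) / 32))),
            patience=10,
        )
        return self

    def fuse_pair(self, p_proms, p_image) -> np.ndarray:
        if self._net is None:
            raise RuntimeError("shallow_net head must be fitted before use")
        X = np.column_stack([_check_probs(p_proms), _check_probs(p_image)])
        return eng.sigmoid(self._net.forward(X).ravel())


_HEADS = {
    "average": AverageFusion,
    "logistic_stack": LogisticStackFusion,
    "shallow_net": ShallowNetFusion,
}


def fit_fusion_head(p_proms, p_image, y, kind: str = "logistic_stack", seed: int = 0):
    """Fit a fusion head on training unimodal probability pairs and labels.

    ``p_proms``/``p_image`` are aligned per-image records (each image
    inherits its response's outcome label). The ``average`` head has no
    parameters and ignores the data.
    """
    if kind not in _HEADS:
        raise ValueError(f"unknown fusion head kind: {kind!r}")
    head = _HEADS[kind](seed=seed) if kind == "shallow_net" else _HEADS[kind]()
    return head.fit(p_proms, p_image, y)


def fuse(p_proms: float, p_image_list, head) -> tuple[float, str]:
    """Fuse one response's unimodal probabilities into a multimodal risk.

    Returns ``(p_fused, provenance)``: with no image the PROMs probability
    is passed through untouched (``proms_only``); with k >= 1 images each
    image is fused with the PROMs probability and the highest fused risk
    is kept (``fused``).
    """
    p_proms = float(_check_probs(np.array([p_proms]))[0])
    p_images = _check_probs(np.asarray(list(p_image_list), dtype=float))
    if p_images.size == 0:
        return p_proms, "proms_only"
    fused = head.fuse_pair(np.full(p_images.size, p_proms), p_images)
    return float(np.max(fused)), "fused"


@dataclass
class RiskPrediction:
    """Per-response risk record (unimodal, per-image, fused)."""

    response_id: str
    p_proms: float
    p_image_list: list[float]
    p_fused: float
    provenance: str


def fuse_responses(
    response_ids,
    p_proms: np.ndarray,
    p_images_by_response: dict[str, list[float]],
    head,
) -> pd.DataFrame:
    """Fuse a whole cohort; returns the exportable prediction table.

    Columns: ``response_id, p_proms, p_image_max, p_fused, provenance``
    (``p_image_max`` empty for image-free responses).
    """
    rows = []
    for rid, pt in zip(response_ids, np.asarray(p_proms, dtype=float)):
        imgs = p_images_by_response.get(rid, [])
        p_fused, provenance = fuse(pt, imgs, head)
        rows.append(
            {
                "response_id": rid,
                "p_proms": pt,
                "p_image_max": max(imgs) if imgs else np.nan,
                "p_fused": p_fused,
                "provenance": provenance,
            }
        )
    return pd.DataFrame(rows, columns=["response_id", "p_proms", "p_image_max", "p_fused", "provenance"])
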