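"""Encoding of patient-reported outcome measures (PROMs) into model features.

The eight symptom items are categorical. By default each item is collapsed
to presence/absence — one column per item, keeping the canonical 8-wide
input — and missing answers are imputed as *absent* before encoding, the
assumption a clinician would make for a partially completed form. Columns
are then centred and scaled with statistics learned on the training data
only.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .synth.config import SYMPTOM_ITEMS, TREND_LEVELS

_PRESENT_VALUES = frozenset({"present", *TREND_LEVELS})
_MISSING_VALUES = frozenset({"", "nan", "none", "missing"})


def _symptom_frame(responses: pd.DataFrame) -> pd.DataFrame:
    cols = [f"sym_{item}" for item in SYMPTOM_ITEMS]
    missing = [c for c in cols if c not in responses.columns]
    if missing:
        raise ValueError(f"responses table lacks symptom columns: {missing}")
    return responses[cols]


class PromEncoder(BaseEstimator, TransformerMixin):
    """One-hot encode the 8 PROM items, then centre and scale.

    Parameters
    ----------
    collapse_trends:
        If True (default) a trend answer ("new", "worse", "same",
        "better") counts simply as the symptom being present, producing
        one column per item. If False, each trend level gets its own
        indicator column (absence is the implicit baseline).

    Attributes
    ----------
    feature_names_ : list of str
        Column names of the encoded matrix, in fixed order.
    mean_, scale_ : ndarray
        Per-column centring/scaling statistics learned by :meth:`fit`;
        :meth:`transform` always reuses them and never re-learns.
    """

    def __init__(self, collapse_trends: bool = True):
        self.collapse_trends = collapse_trends

    def _encode_raw(self, responses: pd.DataFrame) -> np.ndarray:
        sym = _symptom_frame(responses)
        n = len(sym)
        cols = []
        names = []
        for item in SYMPTOM_ITEMS:
            raw = sym[f"sym_{item}"].astype(object).to_numpy()
            values = np.array(
                ["absent" if (v is None or (isinstance(v, float) and np.isnan(v)) or str(v).strip().lower() in _MISSING_VALUES) else str(v).strip().lower() for v in raw],
                dtype=object,
            )
            bad = ~np.isin(values, list(_PRESENT_VALUES) + ["absent"])
            if bad.any():
                i = int(np.flatnonzero(bad)[0])
                raise ValueError(
                    f"unknown category {values[i]!r} for symptom item {item!r} (row {i})"
                )
            if self.collapse_trends:
                cols.append(np.isin(values, list(_PRESENT_VALUES)).astype(float))
                names.append(item)
            else:
                for level in ("present", *TREND_LEVELS):
                    cols.append((values == level).astype(float))
                    names.append(f"{item}_{level}")
        self._last_names = names
        return np.column_stack(cols) if n else np.empty((0, len(names)))

    def fit(self, responses: pd.DataFrame, y=None):
        X = self._encode_raw(responses)
        self.feature_names_ = list(self._last_names)
        self.mean_ = X.mean(axis=0) if len(X) else np.zeros(X.shape[1])
        sd = X.std(axis=0, ddof=0) if len(X) else np.ones(X.shape[1])
        # constant columns carry no information; avoid dividing by zero
        self.scale_ = np.where(sd > 0, sd, 1.0)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, responses: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "mean_")
        X = self._encode_raw(responses)
        if self._last_names != self.feature_names_:
            raise ValueError("encoded columns do not match the fitted encoder")
        return (X - self.mean_) / self.scale_


def encode_proms(responses: pd.DataFrame, encoder: PromEncoder | None = None):
    """Encode a response table into the standardized feature matrix.

    With no ``encoder`` a new one is fitted on ``responses`` (training
    use); passing a fitted encoder reuses its stored centring/scaling
    (evaluation use). Returns ``(X, encoder)``.
    """
    if encoder is None:
        encoder = PromEncoder().fit(responses)
    return encoder.transform(responses), encoder
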