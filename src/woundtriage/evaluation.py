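"""Grouped stratified splitting and discrimination metrics.

Responses from the same patient must never straddle the train/test
boundary (repeat submissions are strongly correlated), so splitting is by
patient. Stratification uses the patient-level outcome (did *any* of the
patient's responses have confirmed SSI) with greedy allocation of
patients until each stratum's test share of responses reaches the target
fraction.

AUC is the rank-statistic (concordance) definition with ties counted
half, with an asymptotic DeLong confidence interval (bootstrap fallback
for degenerate inputs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata


@dataclass
class SplitPlan:
    """Patient-grouped train/test assignment of responses."""

    train_ids: list[str]  # response ids
    test_ids: list[str]
    train_patients: set[str]
    test_patients: set[str]
    test_fraction: float

    def assignment(self) -> dict[str, str]:
        out = {rid: "train" for rid in self.train_ids}
        out.update({rid: "test" for rid in self.test_ids})
        return out


def grouped_stratified_split(
    responses: pd.DataFrame,
    test_fraction: float = 0.2,
    seed: int = 0,
    outcome_col: str = "ssi48",
) -> SplitPlan:
    """Split responses 4:1 (default) by patient, stratified by outcome.

    Patients are stratified by their patient-level outcome (any response
    with the outcome), shuffled within stratum, and greedily assigned to
    the test partition until that stratum's test share of *responses*
    reaches ``test_fraction``. No patient appears in both partitions.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    patients = responses.groupby("patient_id").agg(
        n=("response_id", "size"), label=(outcome_col, "max")
    )
    if len(patients) < 2:
        raise ValueError("need at least 2 patients to form a grouped split")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5117]))

    test_patients: set[str] = set()
    for label in sorted(patients["label"].unique()):
        stratum = patients[patients["label"] == label]
        order = stratum.index.to_numpy()[rng.permutation(len(stratum))]
        target = test_fraction * stratum["n"].sum()
        taken = 0
        for pid in order:
            if taken >= target:
                break
            test_patients.add(pid)
            taken += int(stratum.loc[pid, "n"])

    is_test = responses["patient_id"].isin(test_patients).to_numpy()
    plan = SplitPlan(
        train_ids=list(responses.loc[~is_test, "response_id"]),
        test_ids=list(responses.loc[is_test, "response_id"]),
        train_patients=set(responses.loc[~is_test, "patient_id"]),
        test_patients=set(test_patients),
        test_fraction=float(is_test.mean()),
    )
    assert not (plan.train_patients & plan.test_patients)
    return plan


def _delong_variance(scores: np.ndarray, labels: np.ndarray, auc_value: float) -> float:
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    # structural components via midranks
    all_ranks = rankdata(np.concatenate([pos, neg]))
    pos_ranks = rankdata(pos)
    neg_ranks = rankdata(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n  # per-case placement values
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m  # per-control
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def auc(scores, labels, ci: bool = True, n_boot: int = 1000, seed: int = 0):
    """Concordance AUC with an asymptotic (DeLong) 95% CI.

    Ties count one half. Raises on single-class labels. If either class
    has fewer than 2 members the variance is undefined and a seeded
    bootstrap CI is used instead.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).astype(int).ravel()
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must be aligned")
    m = int((labels == 1).sum())
    n = int((labels == 0).sum())
    if m == 0 or n == 0:
        raise ValueError("AUC undefined: labels contain a single class")
    ranks = rankdata(scores)
    value = (ranks[labels == 1].sum() - m * (m + 1) / 2) / (m * n)
    if not ci:
        return float(value)
    if m >= 2 and n >= 2:
        se = np.sqrt(_delong_variance(scores, labels, value))
        lo, hi = value - 1.959963984540054 * se, value + 1.959963984540054 * se
    else:
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xB007]))
        stats = []
        idx1, idx0 = np.flatnonzero(labels == 1), np.flatnonzero(labels == 0)
        for _ in range(n_boot):
            take = np.concatenate(
                [rng.choice(idx1, size=m, replace=True), rng.choice(idx0, size=n, replace=True)]
            )
            stats.append(auc(scores[take], labels[take], ci=False))
        lo, hi = np.percentile(stats, [2.5, 97.5])
    return float(value), float(max(lo, 0.0)), float(min(hi, 1.0))


def discrimination_band(auc_value: float) -> str:
    """Qualitative discrimination label for an AUC.

    Bands are lower-inclusive: [0.5, 0.6) poor, [0.6, 0.7) moderate,
    [0.7, 0.8) good, >= 0.8 excellent; values below 0.5 are below-chance.
    """
    if not 0.0 <= auc_value <= 1.0:
        raise ValueError("AUC must be in [0, 1]")
    if auc_value < 0.5:
        return "below-chance"
    if auc_value < 0.6:
        return "poor"
    if auc_value < 0.7:
        return "moderate"
    if auc_value < 0.8:
        return "good"
    return "excellent"


def benchmark_report(records: list[dict]) -> pd.DataFrame:
    """Benchmark table: model x dataset x outcome -> AUC (95% CI), band.

    Each record needs keys ``model``, ``dataset``, ``outcome``,
    ``scores``, ``labels``.
    """
    rows = []
    for rec in records:
        value, lo, hi = auc(rec["scores"], rec["labels"])
        rows.append(
            {
                "model": rec["model"],
                "dataset": rec["dataset"],
                "outcome": rec["outcome"],
                "auc": value,
                "ci_low": lo,
                "ci_high": hi,
                "band": discrimination_band(value),
            }
        )
    return pd.DataFrame(rows)
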