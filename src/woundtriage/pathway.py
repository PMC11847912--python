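"""Simulation of triage implementation strategies and their workload impact.

Three pathways for handling remote wound-monitoring responses are
compared against the confirmed-SSI-within-48h outcome:

* ``full_clinical`` — every response is reviewed by a clinician; the
  recommendation for in-person review is the clinician triage label
  (moderate/high risk -> review).
* ``hybrid`` — responses with model risk at or below the threshold are
  ruled out automatically (never seen by a clinician); the remainder are
  clinician-reviewed and decided by the triage label.
* ``full_auto`` — no clinician involvement; responses above the
  threshold are recommended for in-person review.

"Positive" throughout means *routed to in-person review*. The failure
rate is the proportion of low-risk-classified responses with confirmed
SSI within 48 h, identically 1 - NPV. Clinical review of one response is
costed at 2 minutes, automated assessment at 0; one full-time equivalent
(FTE) is 1950 h/year (37.5 h/week over 52 weeks).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

LOW_RISK = "low_risk"
IN_PERSON_REVIEW = "in_person_review"
_REVIEW_LABELS = frozenset({"moderate", "high"})
_STRATEGY_KINDS = ("full_clinical", "hybrid", "full_auto")


@dataclass(frozen=True)
class Strategy:
    """An implementation strategy; hybrid/full_auto need a rule-out threshold.

    A response is "low risk" to the model when its predicted probability is
    less than or equal to ``threshold``.
    """

    kind: str
    threshold: float | None = None

    def __post_init__(self):
        if self.kind not in _STRATEGY_KINDS:
            raise ValueError(f"unknown strategy kind: {self.kind!r}")
        if self.kind != "full_clinical":
            if self.threshold is None or not 0.0 <= self.threshold <= 1.0:
                raise ValueError(f"{self.kind} requires a threshold in [0, 1]")


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 tally of routing decisions against confirmed SSI within 48 h."""

    tp: int  # reviewed, SSI
    fp: int  # reviewed, no SSI
    tn: int  # low risk, no SSI
    fn: int  # low risk, SSI

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class StaffingModel:
    """Time and staffing assumptions for the workload arithmetic.

    ``annualization`` scales the observed response volume to a yearly
    volume, and ``caseload_scale``/``study_patients`` rescale from the
    study cohort to a reference caseload. The printed study FTE is not
    derivable from its stated inputs, so every scaling factor here is
    explicit and configurable.
    """

    minutes_per_clinical_review: float = 2.0
    minutes_per_automated: float = 0.0
    weekly_fte_hours: float = 37.5
    annual_fte_hours: float = 1950.0
    caseload_scale: int = 1000
    study_patients: int = 423
    annualization: float = 1.0

    def __post_init__(self):
        if not math.isclose(self.annual_fte_hours, self.weekly_fte_hours * 52):
            raise ValueError("annual_fte_hours must equal weekly_fte_hours * 52")


def route(
    responses: pd.DataFrame,
    predictions: np.ndarray | None,
    strategy: Strategy,
) -> pd.DataFrame:
    """Per-response routing decisions under a strategy.

    ``responses`` needs a ``triage_label`` column for clinician-dependent
    strategies; ``predictions`` (fused model probabilities, aligned to the
    rows) is required for hybrid/full_auto. Returns a frame with columns
    ``decision`` ({low_risk, in_person_review}) and ``clinician_reviewed``.
    """
    n = len(responses)
    if strategy.kind != "full_clinical":
        if predictions is None:
            raise ValueError(f"{strategy.kind} strategy requires model predictions")
        predictions = np.asarray(predictions, dtype=float)
        if predictions.shape[0] != n:
            raise ValueError("one prediction per response is required")
        if np.isnan(predictions).any():
            raise ValueError("missing prediction for at least one response")

    def _triage() -> np.ndarray:
        if "triage_label" not in responses.columns:
            raise ValueError("clinician triage labels required for this strategy")
        lab = responses["triage_label"].astype(str).to_numpy()
        bad = ~np.isin(lab, ["low", "moderate", "high"])
        if bad.any():
            raise ValueError(f"missing/invalid triage label at row {int(np.flatnonzero(bad)[0])}")
        return lab

    if strategy.kind == "full_clinical":
        lab = _triage()
        decision = np.where(np.isin(lab, list(_REVIEW_LABELS)), IN_PERSON_REVIEW, LOW_RISK)
        reviewed = np.ones(n, dtype=bool)
    elif strategy.kind == "hybrid":
        ruled_out = predictions <= strategy.threshold
        lab = _triage()
        decision = np.where(
            ruled_out,
            LOW_RISK,
            np.where(np.isin(lab, list(_REVIEW_LABELS)), IN_PERSON_REVIEW, LOW_RISK),
        )
        reviewed = ~ruled_out
    else:  # full_auto
        decision = np.where(predictions > strategy.threshold, IN_PERSON_REVIEW, LOW_RISK)
        reviewed = np.zeros(n, dtype=bool)

    return pd.DataFrame(
        {"decision": decision, "clinician_reviewed": reviewed}, index=responses.index
    )


def confusion(decisions, ssi48) -> ConfusionCounts:
    """Tally routing decisions against the confirmed-SSI outcome."""
    d = np.asarray(decisions)
    y = np.asarray(ssi48).astype(int)
    if d.shape[0] != y.shape[0]:
        raise ValueError("decisions and outcomes must have equal length")
    pos = d == IN_PERSON_REVIEW
    return ConfusionCounts(
        tp=int(np.sum(pos & (y == 1))),
        fp=int(np.sum(pos & (y == 0))),
        tn=int(np.sum(~pos & (y == 0))),
        fn=int(np.sum(~pos & (y == 1))),
    )


def _metric(num: int, den: int, ci_method: str) -> dict:
    if den == 0:
        return {"value": None, "ci": (None, None), "defined": False}
    lo, hi = proportion_confint(num, den, alpha=0.05, method=ci_method)
    # guard float slop at the boundaries
    lo, hi = min(max(float(lo), 0.0), 1.0), min(max(float(hi), 0.0), 1.0)
    return {"value": num / den, "ci": (lo, hi), "defined": True}


def diagnostics(counts: ConfusionCounts, ci_method: str = "wilson") -> dict:
    """Sensitivity, specificity, PPV, NPV and failure rate with CIs.

    Failure rate is 1 - NPV exactly: the share of low-risk-classified
    responses that have confirmed SSI within 48 h. Zero-denominator
    metrics are flagged ``defined: False`` rather than silently 0.
    """
    out = {
        "sensitivity": _metric(counts.tp, counts.tp + counts.fn, ci_method),
        "specificity": _metric(counts.tn, counts.tn + counts.fp, ci_method),
        "ppv": _metric(counts.tp, counts.tp + counts.fp, ci_method),
        "npv": _metric(counts.tn, counts.tn + counts.fn, ci_method),
    }
    fail = _metric(counts.fn, counts.tn + counts.fn, ci_method)
    if fail["defined"]:
        # identity with NPV holds to machine precision
        fail["value"] = 1.0 - out["npv"]["value"]
    out["failure_rate"] = fail
    return out


def staffing(
    n_clinician_reviewed: int,
    model: StaffingModel = StaffingModel(),
    baseline_reviewed: int | None = None,
) -> dict:
    """Staff-hours, percent reduction vs the baseline pathway, and FTE.

    ``baseline_reviewed`` is the clinician-review count of the comparator
    (full clinical) pathway; reduction is relative to it. The annual FTE
    per ``caseload_scale`` patients applies the model's explicit scaling
    factors.
    """
    if n_clinician_reviewed < 0:
        raise ValueError("review count must be >= 0")
    hours = n_clinician_reviewed * model.minutes_per_clinical_review / 60.0
    out = {"staff_hours": hours}
    if baseline_reviewed is not None:
        if baseline_reviewed == 0:
            if n_clinician_reviewed > 0:
                raise ValueError("baseline review count is 0 but pathway reviews responses")
            out["staff_hours_reduction_pct"] = 0.0
        else:
            out["staff_hours_reduction_pct"] = 100.0 * (1.0 - n_clinician_reviewed / baseline_reviewed)
    annual_hours = hours * model.annualization * (model.caseload_scale / model.study_patients)
    out["fte_per_caseload"] = annual_hours / model.annual_fte_hours
    return out


@dataclass
class PathwayOutcome:
    """Everything the Table-3-style report needs for one strategy."""

    strategy: Strategy
    n_responses: int
    n_clinician_reviewed: int
    counts: ConfusionCounts
    metrics: dict
    staff_hours: float
    staff_hours_reduction_pct: float | None
    fte_per_caseload: float
    extras: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        row = {
            "strategy": self.strategy.kind,
            "threshold": self.strategy.threshold,
            "n_responses": self.n_responses,
            "n_clinician_reviewed": self.n_clinician_reviewed,
            "n_in_person_review": self.counts.tp + self.counts.fp,
            "n_low_risk": self.counts.tn + self.counts.fn,
            "tp": self.counts.tp,
            "fp": self.counts.fp,
            "tn": self.counts.tn,
            "fn": self.counts.fn,
            "staff_hours": self.staff_hours,
            "staff_hours_reduction_pct": self.staff_hours_reduction_pct,
            "fte_per_caseload": self.fte_per_caseload,
        }
        for name, m in self.metrics.items():
            row[name] = m["value"]
            row[f"{name}_ci_low"], row[f"{name}_ci_high"] = m["ci"]
        return row


def evaluate_pathway(
    responses: pd.DataFrame,
    predictions: np.ndarray | None,
    strategy: Strategy,
    staffing_model: StaffingModel = StaffingModel(),
    baseline_reviewed: int | None = None,
    ci_method: str = "wilson",
) -> PathwayOutcome:
    """Route, tally, and cost one strategy end to end."""
    routed = route(responses, predictions, strategy)
    counts = confusion(routed["decision"].to_numpy(), responses["ssi48"].to_numpy())
    n_reviewed = int(routed["clinician_reviewed"].sum())
    staff = staffing(n_reviewed, staffing_model, baseline_reviewed)
    return PathwayOutcome(
        strategy=strategy,
        n_responses=len(responses),
        n_clinician_reviewed=n_reviewed,
        counts=counts,
        metrics=diagnostics(counts, ci_method),
        staff_hours=staff["staff_hours"],
        staff_hours_reduction_pct=staff.get("staff_hours_reduction_pct"),
        fte_per_caseload=staff["fte_per_caseload"],
    )


def threshold_sweep(
    responses: pd.DataFrame,
    predictions: np.ndarray,
    strategy_kind: str,
    grid,
    staffing_model: StaffingModel = StaffingModel(),
    baseline_reviewed: int | None = None,
) -> pd.DataFrame:
    """Sensitivity analysis of the rule-out threshold.

    One :class:`PathwayOutcome` row per threshold in ``grid`` (must be a
    non-empty, sorted subset of [0, 1]).
    """
    grid = np.asarray(list(grid), dtype=float)
    if grid.size == 0:
        raise ValueError("threshold grid is empty")
    if (grid < 0).any() or (grid > 1).any() or not np.all(np.diff(grid) >= 0):
        raise ValueError("grid must be sorted and within [0, 1]")
    if baseline_reviewed is None:
        baseline_reviewed = len(responses)  # full clinical reviews everything
    rows = []
    for t in grid:
        outcome = evaluate_pathway(
            responses,
            predictions,
            Strategy(strategy_kind, float(t)),
            staffing_model,
            baseline_reviewed,
        )
        rows.append(outcome.to_row())
    return pd.DataFrame(rows)


def pathway_report(outcomes: list[PathwayOutcome]) -> pd.DataFrame:
    """Table-3-style summary: one formatted column block per strategy.

    Proportions are printed to 3 dp, percentages and hours to 1 dp.
    """

    def fmt_metric(m):
        if not m["defined"]:
            return "undefined"
        return f"{m['value']:.3f} ({m['ci'][0]:.3f}-{m['ci'][1]:.3f})"

    rows = []
    for o in outcomes:
        met = o.metrics
        fail = met["failure_rate"]
        rows.append(
            {
                "strategy": o.strategy.kind,
                "cutoff": "-" if o.strategy.threshold is None else f"{o.strategy.threshold:g}",
                "sensitivity": fmt_metric(met["sensitivity"]),
                "specificity": fmt_metric(met["specificity"]),
                "ppv": fmt_metric(met["ppv"]),
                "npv": fmt_metric(met["npv"]),
                "failure_rate": (
                    "undefined"
                    if not fail["defined"]
                    else f"{100 * fail['value']:.1f}% ({100 * fail['ci'][0]:.1f}-{100 * fail['ci'][1]:.1f})"
                ),
                "responses_requiring_triage": o.n_clinician_reviewed,
                "staff_hours": f"{o.staff_hours:.1f}"
                + (
                    ""
                    if o.staff_hours_reduction_pct is None
                    else f" ({-o.staff_hours_reduction_pct:.1f}%)"
                ),
                "fte_per_caseload": f"{o.fte_per_caseload:.3f}",
                "n_low_risk": o.counts.tn + o.counts.fn,
                "n_in_person": o.counts.tp + o.counts.fp,
            }
        )
    return pd.DataFrame(rows)
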