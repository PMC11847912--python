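"""Pathway routing, diagnostic accuracy, workload arithmetic, sweeps."""

import numpy as np
import pandas as pd
import pytest

from woundtriage.pathway import (
    IN_PERSON_REVIEW,
    LOW_RISK,
    ConfusionCounts,
    StaffingModel,
    Strategy,
    confusion,
    diagnostics,
    evaluate_pathway,
    pathway_report,
    route,
    staffing,
    threshold_sweep,
)

# Published routing-by-outcome counts for the three implementation
# strategies (full clinical / hybrid rule-out at 0.2 / full automation):
# (tp, fp, tn, fn) with positive = routed to in-person review.
FULL_CLINICAL = ConfusionCounts(tp=39, fp=158, tn=1330, fn=18)
HYBRID = ConfusionCounts(tp=31, fp=84, tn=1404, fn=26)
FULL_AUTO = ConfusionCounts(tp=40, fp=232, tn=1256, fn=17)


def _responses(triage, ssi, p=None):
    df = pd.DataFrame(
        {
            "response_id": [f"r{i}" for i in range(len(triage))],
            "triage_label": triage,
            "ssi48": ssi,
        }
    )
    return df, (None if p is None else np.asarray(p, dtype=float))


# -- confusion --------------------------------------------------------------

def test_confusion_from_published_full_clinical_counts():
    """197 reviewed (39 SSI) and 1348 low-risk (18 SSI) tally correctly."""
    decisions = np.array([IN_PERSON_REVIEW] * 197 + [LOW_RISK] * 1348)
    ssi = np.array([1] * 39 + [0] * 158 + [1] * 18 + [0] * 1330)
    counts = confusion(decisions, ssi)
    assert counts == FULL_CLINICAL
    assert counts.total == 1545


def test_confusion_all_low_risk_no_ssi():
    counts = confusion(np.array([LOW_RISK] * 7), np.zeros(7, dtype=int))
    assert (counts.tp, counts.fp, counts.tn, counts.fn) == (0, 0, 7, 0)


def test_confusion_matches_brute_force_tally(rng):
    decisions = rng.choice([LOW_RISK, IN_PERSON_REVIEW], size=20)
    ssi = rng.integers(0, 2, size=20)
    counts = confusion(decisions, ssi)
    tally = {"tp": 0, "fp": 0, "tn": 0, "fn": 0}
    for d, s in zip(decisions, ssi):
        if d == IN_PERSON_REVIEW:
            tally["tp" if s else "fp"] += 1
        else:
            tally["fn" if s else "tn"] += 1
    assert (counts.tp, counts.fp, counts.tn, counts.fn) == (
        tally["tp"], tally["fp"], tally["tn"], tally["fn"],
    )


def test_confusion_length_mismatch():
    with pytest.raises(ValueError, match="equal length"):
        confusion(np.array([LOW_RISK]), np.array([0, 1]))


# -- diagnostics ------------------------------------------------------------

def test_published_full_clinical_metrics_to_3dp():
    m = diagnostics(FULL_CLINICAL)
    assert m["sensitivity"]["value"] == pytest.approx(0.684, abs=5e-4)
    assert m["specificity"]["value"] == pytest.approx(0.894, abs=5e-4)
    assert m["ppv"]["value"] == pytest.approx(0.198, abs=5e-4)
    assert m["npv"]["value"] == pytest.approx(0.987, abs=5e-4)
    assert m["failure_rate"]["value"] == pytest.approx(0.013, abs=5e-4)


def test_published_hybrid_metrics_to_3dp():
    m = diagnostics(HYBRID)
    assert m["sensitivity"]["value"] == pytest.approx(0.544, abs=5e-4)
    assert m["specificity"]["value"] == pytest.approx(0.944, abs=5e-4)
    assert m["ppv"]["value"] == pytest.approx(0.270, abs=5e-4)
    assert m["failure_rate"]["value"] == pytest.approx(0.018, abs=5e-4)


def test_published_full_auto_metrics_to_3dp():
    m = diagnostics(FULL_AUTO)
    assert m["sensitivity"]["value"] == pytest.approx(0.702, abs=5e-4)
    assert m["specificity"]["value"] == pytest.approx(0.844, abs=5e-4)
    assert m["ppv"]["value"] == pytest.approx(0.147, abs=5e-4)
    assert m["npv"]["value"] == pytest.approx(0.987, abs=5e-4)


def test_perfect_classifier_metrics():
    m = diagnostics(ConfusionCounts(tp=10, fp=0, tn=90, fn=0))
    for name in ("sensitivity", "specificity", "ppv", "npv"):
        assert m[name]["value"] == 1.0
    assert m["failure_rate"]["value"] == 0.0


def test_zero_denominator_flagged_undefined():
    m = diagnostics(ConfusionCounts(tp=0, fp=0, tn=5, fn=0))
    assert m["ppv"]["defined"] is False
    assert m["ppv"]["value"] is None
    assert m["npv"]["defined"] is True


def test_failure_rate_identity_machine_precision(rng):
    for _ in range(20):
        tp, fp, tn, fn = rng.integers(1, 100, size=4)
        m = diagnostics(ConfusionCounts(int(tp), int(fp), int(tn), int(fn)))
        assert m["failure_rate"]["value"] == 1.0 - m["npv"]["value"]


def test_counts_must_be_nonnegative():
    with pytest.raises(ValueError):
        ConfusionCounts(tp=-1, fp=0, tn=0, fn=0)


# -- staffing ---------------------------------------------------------------

def test_staff_hours_full_clinical_review():
    out = staffing(1545)
    assert out["staff_hours"] == pytest.approx(51.5, abs=0.05)


def test_staff_hours_hybrid_and_reduction():
    out = staffing(272, baseline_reviewed=1545)
    assert out["staff_hours"] == pytest.approx(9.1, abs=0.05)
    assert out["staff_hours_reduction_pct"] == pytest.approx(82.4, abs=0.05)


def test_staff_hours_full_automation():
    out = staffing(0, baseline_reviewed=1545)
    assert out["staff_hours"] == 0.0
    assert out["staff_hours_reduction_pct"] == pytest.approx(100.0)


def test_staffing_baseline_zero_guard():
    with pytest.raises(ValueError, match="baseline"):
        staffing(5, baseline_reviewed=0)
    assert staffing(0, baseline_reviewed=0)["staff_hours_reduction_pct"] == 0.0


def test_staffing_model_invariant():
    with pytest.raises(ValueError, match="52"):
        StaffingModel(weekly_fte_hours=40.0, annual_fte_hours=1950.0)


def test_fte_scaling_explicit():
    sm = StaffingModel(study_patients=423, caseload_scale=1000, annualization=2.0)
    out = staffing(1545, sm)
    expected = (1545 * 2 / 60) * 2.0 * (1000 / 423) / 1950
    assert out["fte_per_caseload"] == pytest.approx(expected)


# -- routing ----------------------------------------------------------------

def test_hybrid_rules_out_below_threshold():
    df, p = _responses(["high", "low"], [1, 0], [0.10, 0.90])
    out = route(df, p, Strategy("hybrid", 0.2))
    # p=0.10 <= 0.2 -> ruled out despite the high triage label
    assert out.loc[0, "decision"] == LOW_RISK
    assert not out.loc[0, "clinician_reviewed"]
    # p=0.90 survives rule-out, then decided by the (low) triage label
    assert out.loc[1, "decision"] == LOW_RISK
    assert out.loc[1, "clinician_reviewed"]


def test_hybrid_threshold_one_reviews_nothing():
    df, p = _responses(["high"] * 5, [0] * 5, [0.1, 0.5, 0.9, 1.0, 0.3])
    out = route(df, p, Strategy("hybrid", 1.0))
    assert (out["decision"] == LOW_RISK).all()
    assert not out["clinician_reviewed"].any()


def test_full_auto_threshold_zero_reviews_all_positive():
    df, p = _responses(["low"] * 4, [0] * 4, [0.0, 0.01, 0.5, 1.0])
    out = route(df, p, Strategy("full_auto", 0.0))
    assert list(out["decision"]) == [LOW_RISK] + [IN_PERSON_REVIEW] * 3
    assert not out["clinician_reviewed"].any()


def test_full_clinical_follows_triage_label():
    df, _ = _responses(["low", "moderate", "high"], [0, 0, 1])
    out = route(df, None, Strategy("full_clinical"))
    assert list(out["decision"]) == [LOW_RISK, IN_PERSON_REVIEW, IN_PERSON_REVIEW]
    assert out["clinician_reviewed"].all()


def test_route_missing_prediction_errors():
    df, _ = _responses(["low", "high"], [0, 1])
    with pytest.raises(ValueError, match="predictions"):
        route(df, None, Strategy("hybrid", 0.2))
    with pytest.raises(ValueError, match="missing prediction"):
        route(df, np.array([0.2, np.nan]), Strategy("hybrid", 0.2))


def test_route_missing_triage_errors():
    df = pd.DataFrame({"response_id": ["a"], "ssi48": [0]})
    with pytest.raises(ValueError, match="triage"):
        route(df, np.array([0.5]), Strategy("hybrid", 0.2))


def test_strategy_validation():
    with pytest.raises(ValueError, match="threshold"):
        Strategy("hybrid")
    with pytest.raises(ValueError, match="unknown strategy"):
        Strategy("oracle", 0.2)


# -- end-to-end pathway properties ------------------------------------------

@pytest.fixture()
def simulated(rng):
    n = 400
    ssi = (rng.random(n) < 0.1).astype(int)
    p = np.clip(0.55 * ssi + rng.random(n) * 0.45, 0, 1)
    triage = np.where(p > 0.5, "high", np.where(p > 0.25, "moderate", "low"))
    df, p = _responses(triage, ssi, p)
    return df, p


def test_conservation_across_strategies(simulated):
    df, p = simulated
    for strat in (Strategy("full_clinical"), Strategy("hybrid", 0.3), Strategy("full_auto", 0.3)):
        out = evaluate_pathway(df, p, strat)
        assert out.counts.total == len(df)


def test_full_auto_zero_staff_hours(simulated):
    df, p = simulated
    out = evaluate_pathway(df, p, Strategy("full_auto", 0.2), baseline_reviewed=len(df))
    assert out.n_clinician_reviewed == 0
    assert out.staff_hours == 0.0
    assert out.staff_hours_reduction_pct == pytest.approx(100.0)


def test_hybrid_reviews_no_more_than_full_clinical(simulated):
    df, p = simulated
    full = evaluate_pathway(df, p, Strategy("full_clinical"))
    hybrid = evaluate_pathway(df, p, Strategy("hybrid", 0.2))
    assert hybrid.n_clinician_reviewed <= full.n_responses


def test_sweep_monotone_review_counts(simulated):
    df, p = simulated
    grid = np.linspace(0, 1, 11)
    table = threshold_sweep(df, p, "hybrid", grid)
    assert len(table) == 11
    assert np.all(np.diff(table["n_clinician_reviewed"]) <= 0)


def test_sweep_full_auto_sensitivity_monotone(simulated):
    df, p = simulated
    table = threshold_sweep(df, p, "full_auto", np.linspace(0, 1, 11))
    sens = table["sensitivity"].astype(float).to_numpy()
    assert np.all(np.diff(sens[~np.isnan(sens)]) <= 1e-12)


def test_sweep_endpoints_match_boundary_routing(simulated):
    df, p = simulated
    table = threshold_sweep(df, p, "hybrid", [0.0, 1.0])
    assert table.loc[1, "n_clinician_reviewed"] == 0
    direct = route(df, p, Strategy("hybrid", 0.0))
    assert table.loc[0, "n_clinician_reviewed"] == direct["clinician_reviewed"].sum()


def test_perfect_prediction_hybrid_zero_failure(simulated):
    df, _ = simulated
    p_perfect = df["ssi48"].to_numpy().astype(float)
    for t in (0.2, 0.5, 0.8):
        out = evaluate_pathway(df, p_perfect, Strategy("hybrid", t))
        assert out.metrics["failure_rate"]["value"] == 0.0


def test_sweep_empty_grid_refused(simulated):
    df, p = simulated
    with pytest.raises(ValueError, match="empty"):
        threshold_sweep(df, p, "hybrid", [])


def test_pathway_report_formatting(simulated):
    df, p = simulated
    outs = [
        evaluate_pathway(df, p, Strategy("full_clinical"), baseline_reviewed=len(df)),
        evaluate_pathway(df, p, Strategy("hybrid", 0.2), baseline_reviewed=len(df)),
    ]
    report = pathway_report(outs)
    assert list(report["strategy"]) == ["full_clinical", "hybrid"]
    assert report.loc[0, "cutoff"] == "-"
    # proportions formatted to 3 dp with CI
    assert report.loc[0, "sensitivity"].count(".") == 3


# -- property tests ---------------------------------------------------------

from hypothesis import given, settings
from hypothesis import strategies as st


@given(
    tp=st.integers(0, 300), fp=st.integers(0, 300),
    tn=st.integers(0, 300), fn=st.integers(0, 300),
)
@settings(deadline=None, derandomize=True, max_examples=150)
def test_diagnostics_identities_hold_for_any_counts(tp, fp, tn, fn):
    """1 - NPV = failure rate exactly; every defined metric lies in [0, 1]."""
    counts = ConfusionCounts(tp, fp, tn, fn)
    m = diagnostics(counts)
    if m["npv"]["defined"]:
        assert m["failure_rate"]["value"] == 1.0 - m["npv"]["value"]
    for name in ("sensitivity", "specificity", "ppv", "npv", "failure_rate"):
        if m[name]["defined"]:
            assert 0.0 <= m[name]["value"] <= 1.0
            lo, hi = m[name]["ci"]
            assert 0.0 <= lo <= hi <= 1.0
    assert counts.total == tp + fp + tn + fn
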