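"""Late fusion: missing-image and multiple-image rules, head behaviour."""

import numpy as np
import pytest
from scipy.special import expit

from woundtriage.evaluation import auc
from woundtriage.fusion import (
    AverageFusion,
    LogisticStackFusion,
    ShallowNetFusion,
    fit_fusion_head,
    fuse,
    fuse_responses,
)


def _two_signal_data(n=2000, seed=0):
    """Outcome driven by two independent latent signals, one per modality."""
    rng = np.random.default_rng(seed)
    a = rng.normal(size=n)
    b = rng.normal(size=n)
    y = (rng.random(n) < expit(1.5 * a + 1.5 * b - 1.0)).astype(int)
    p1 = expit(1.5 * a - 0.5 + rng.normal(0, 0.3, n))
    p2 = expit(1.5 * b - 0.5 + rng.normal(0, 0.3, n))
    return p1, p2, y


def test_no_image_passes_proms_probability_through():
    p, provenance = fuse(0.30, [], AverageFusion())
    assert p == 0.30
    assert provenance == "proms_only"


def test_average_head_equal_inputs():
    p, provenance = fuse(0.2, [0.2], AverageFusion())
    assert p == pytest.approx(0.2)
    assert provenance == "fused"


def test_average_head_mean_then_max():
    p, _ = fuse(0.1, [0.2, 0.8], AverageFusion())
    assert p == pytest.approx(max((0.1 + 0.2) / 2, (0.1 + 0.8) / 2))  # = 0.45


def test_image_order_never_changes_result(rng):
    head = AverageFusion()
    imgs = list(rng.random(5))
    p_ref, _ = fuse(0.4, imgs, head)
    for _ in range(5):
        rng.shuffle(imgs)
        assert fuse(0.4, imgs, head)[0] == pytest.approx(p_ref)


def test_out_of_range_probability_rejected():
    with pytest.raises(ValueError, match=r"\[0, 1\]"):
        fuse(1.2, [], AverageFusion())
    with pytest.raises(ValueError, match=r"\[0, 1\]"):
        fuse(0.5, [-0.1], AverageFusion())


def test_average_head_needs_no_fitting():
    head = AverageFusion().fit(None, None, None)
    assert head.fuse_pair(np.array([0.2]), np.array([0.6]))[0] == pytest.approx(0.4)


def test_logistic_stack_beats_or_matches_unimodal():
    p1, p2, y = _two_signal_data()
    half = len(y) // 2
    head = fit_fusion_head(p1[:half], p2[:half], y[:half], kind="logistic_stack")
    fused = head.fuse_pair(p1[half:], p2[half:])
    auc_fused = auc(fused, y[half:], ci=False)
    auc_1 = auc(p1[half:], y[half:], ci=False)
    auc_2 = auc(p2[half:], y[half:], ci=False)
    assert auc_fused >= max(auc_1, auc_2) - 0.02


def test_logistic_stack_zeroes_noise_modality(rng):
    p1, _, y = _two_signal_data(seed=3)
    noise = rng.random(len(y))
    head = fit_fusion_head(p1, noise, y, kind="logistic_stack")
    assert head.coef_[1] < 0.1  # non-negativity bound pins pure noise near 0


@pytest.mark.parametrize("kind", ["average", "logistic_stack"])
def test_fusion_monotone_in_each_input(kind):
    p1, p2, y = _two_signal_data(n=500, seed=1)
    head = fit_fusion_head(p1, p2, y, kind=kind)
    grid = np.linspace(0, 1, 21)
    for fixed in (0.1, 0.5, 0.9):
        out1 = head.fuse_pair(grid, np.full_like(grid, fixed))
        out2 = head.fuse_pair(np.full_like(grid, fixed), grid)
        assert np.all(np.diff(out1) >= -1e-12)
        assert np.all(np.diff(out2) >= -1e-12)


def test_shallow_net_head_deterministic():
    p1, p2, y = _two_signal_data(n=300, seed=2)
    f1 = ShallowNetFusion(seed=5).fit(p1, p2, y).fuse_pair(p1[:10], p2[:10])
    f2 = ShallowNetFusion(seed=5).fit(p1, p2, y).fuse_pair(p1[:10], p2[:10])
    assert np.array_equal(f1, f2)


def test_single_class_refused():
    with pytest.raises(ValueError, match="single class"):
        fit_fusion_head([0.1, 0.2], [0.3, 0.4], [1, 1], kind="logistic_stack")


def test_unknown_head_kind_refused():
    with pytest.raises(ValueError, match="unknown fusion head"):
        fit_fusion_head([0.1], [0.2], [0, 1], kind="mystery")


def test_fuse_responses_table():
    table = fuse_responses(
        ["r1", "r2", "r3"],
        np.array([0.3, 0.6, 0.2]),
        {"r2": [0.4, 0.9], "r3": [0.1]},
        AverageFusion(),
    )
    assert list(table["provenance"]) == ["proms_only", "fused", "fused"]
    assert table.loc[0, "p_fused"] == 0.3
    assert np.isnan(table.loc[0, "p_image_max"])
    assert table.loc[1, "p_fused"] == pytest.approx(0.75)
    assert table.loc[1, "p_image_max"] == pytest.approx(0.9)


def test_provenance_iff_images():
    table = fuse_responses(["a"], np.array([0.5]), {}, AverageFusion())
    assert (table["provenance"] == "proms_only").all()
    table2 = fuse_responses(["a"], np.array([0.5]), {"a": [0.5]}, AverageFusion())
    assert (table2["provenance"] == "fused").all()


# -- property tests ---------------------------------------------------------

from hypothesis import given, settings
from hypothesis import strategies as st

probs = st.floats(0.0, 1.0, allow_nan=False)


@given(p_proms=probs, imgs=st.lists(probs, max_size=6), perm_seed=st.integers(0, 99))
@settings(deadline=None, derandomize=True, max_examples=150)
def test_fuse_bounds_provenance_and_permutation_invariance(p_proms, imgs, perm_seed):
    """Fused risk stays in [0, 1], provenance tracks image presence, and
    the max-over-images rule is order-independent."""
    head = AverageFusion()
    p, provenance = fuse(p_proms, imgs, head)
    assert 0.0 <= p <= 1.0
    assert provenance == ("proms_only" if not imgs else "fused")
    if not imgs:
        assert p == p_proms
    shuffled = list(imgs)
    np.random.default_rng(perm_seed).shuffle(shuffled)
    assert fuse(p_proms, shuffled, head)[0] == p
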