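"""Stimulus generator: pair invariants, rendering determinism, sampling laws."""

import numpy as np
import pytest
from scipy import stats

from relapath.stimuli import (FeatureVector, TaskConfig, make_phase,
                              predictive_value, render_image, sample_pair)


def pair_rng(seed=0):
    return np.random.default_rng(seed)


@pytest.mark.parametrize("feature,alpha", [
    ("size", 0.5), ("size", -0.7), ("size", 1.0), ("size", 0.0),
    ("color", 0.3), ("color", -1.0), ("number", 0.25), ("number", -0.5),
])
def test_pair_invariants(feature, alpha):
    """Predictive difference equals alpha; everything else is shared."""
    cfg = TaskConfig(predictive_feature=feature, alpha=alpha, image_side=56)
    rng = pair_rng(3)
    for _ in range(20):
        p = sample_pair(cfg, rng)
        diff = predictive_value(p.right_features, feature) - \
            predictive_value(p.left_features, feature)
        if feature == "number":
            assert diff == pytest.approx(alpha, abs=0)  # exact on the 1/8 grid
        else:
            assert diff == pytest.approx(alpha, abs=1e-9)
        for other in ("color", "size", "number", "shape_type"):
            if other == feature:
                continue
            assert getattr(p.left_features, other) == \
                getattr(p.right_features, other)
        for f in (p.left_features, p.right_features):
            assert 0.0 <= predictive_value(f, feature) <= 1.0
            assert len(f.arrangement) == f.number


def test_alpha_zero_pixel_identical():
    cfg = TaskConfig(alpha=0.0, image_side=56)
    p = sample_pair(cfg, pair_rng(1))
    assert p.left_features == p.right_features
    np.testing.assert_array_equal(p.left_image, p.right_image)


def test_alpha_one_size_forced_extremes():
    """alpha = 1 on size admits only the (0, 1) pair."""
    cfg = TaskConfig(predictive_feature="size", alpha=1.0)
    p = sample_pair(cfg, pair_rng(2))
    assert p.left_features.size == 0.0
    assert p.right_features.size == 1.0


def test_invalid_rules_rejected():
    with pytest.raises(ValueError):
        TaskConfig(alpha=1.2)
    with pytest.raises(ValueError):
        TaskConfig(predictive_feature="number", alpha=0.3)  # not k/8
    with pytest.raises(ValueError):
        TaskConfig(predictive_feature="shape_type")


def test_render_deterministic_and_grid():
    fv = FeatureVector(color=0.4, number=9, size=0.6,
                       arrangement=tuple(range(9)), shape_type="star")
    img1 = render_image(fv, 224)
    img2 = render_image(fv, 224)
    np.testing.assert_array_equal(img1, img2)
    # full grid: every one of the 9 cells contains non-background pixels
    cell = 224 / 3
    for r in range(3):
        for c in range(3):
            block = img1[int(r * cell):int((r + 1) * cell),
                         int(c * cell):int((c + 1) * cell)]
            assert (block < 1.0).any()
    # empty cells stay background when fewer shapes are drawn
    fv1 = FeatureVector(color=0.4, number=1, size=0.6,
                        arrangement=(4,), shape_type="circle")
    img = render_image(fv1, 224)
    assert (img[:74, :74] == 1.0).all()      # corner cell untouched
    assert (img[75:149, 75:149] < 1.0).any()  # center cell drawn


def test_size_to_pixel_map():
    """size=1 renders a circle whose diameter hits the 70 px maximum."""
    fv = FeatureVector(color=0.0, number=1, size=1.0, arrangement=(4,),
                       shape_type="circle")
    img = render_image(fv, 224)
    rows = np.where((img < 1.0).any(axis=1))[0]
    cols = np.where((img < 1.0).any(axis=0))[0]
    assert rows.max() - rows.min() + 1 == pytest.approx(70, abs=1)
    assert cols.max() - cols.min() + 1 == pytest.approx(70, abs=1)
    # and size=0 gives the 12 px minimum
    fv0 = FeatureVector(color=0.0, number=1, size=0.0, arrangement=(4,),
                        shape_type="circle")
    img0 = render_image(fv0, 224)
    rows0 = np.where((img0 < 1.0).any(axis=1))[0]
    assert rows0.max() - rows0.min() + 1 == pytest.approx(12, abs=1)


def test_make_phase_counts_and_reproducibility():
    cfg = TaskConfig(alpha=0.5, image_side=56, seed=7)
    train, test = make_phase(cfg)
    assert len(train) == 160 and len(test) == 32
    train2, test2 = make_phase(cfg)
    np.testing.assert_array_equal(train[0].left_image, train2[0].left_image)
    np.testing.assert_array_equal(test[-1].right_image, test2[-1].right_image)
    assert train[3].left_features == train2[3].left_features


def test_left_value_uniform_over_feasible_interval():
    """Marginal of the left predictive value is uniform on [0, 1 - alpha]."""
    cfg = TaskConfig(predictive_feature="size", alpha=0.3, image_side=56)
    rng = pair_rng(11)
    # sample feature draws through the public path but skip most rendering
    # cost by using many pairs at a small side
    vals = np.array([sample_pair(cfg, rng).left_features.size
                     for _ in range(400)])
    assert vals.min() >= 0.0 and vals.max() <= 0.7 + 1e-12
    p = stats.kstest(vals / 0.7, "uniform").pvalue
    assert p > 1e-3
    # the draw itself at n = 10^4 (no rendering): both signs of alpha
    from relapath.stimuli import _feasible_uniform
    for alpha, lo, span in ((0.3, 0.0, 0.7), (-0.4, 0.4, 0.6)):
        draws = np.array([_feasible_uniform(alpha, rng) for _ in range(10_000)])
        assert stats.kstest((draws - lo) / span, "uniform").pvalue > 1e-3


def test_nonpredictive_features_independent_across_pairs():
    cfg = TaskConfig(predictive_feature="size", alpha=0.5, image_side=56)
    rng = pair_rng(13)
    pairs = [sample_pair(cfg, rng) for _ in range(300)]
    color = np.array([p.left_features.color for p in pairs])
    number = np.array([p.left_features.number for p in pairs])
    size = np.array([p.left_features.size for p in pairs])
    assert abs(np.corrcoef(color, number)[0, 1]) < 0.15
    assert abs(np.corrcoef(color, size)[0, 1]) < 0.15
    assert abs(np.corrcoef(size, number)[0, 1]) < 0.15
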