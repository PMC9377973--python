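"""Loss values, reductions to cross-entropy, gradients and batch vectorization."""

import numpy as np
import pytest
import scipy.special
from hypothesis import given, settings
from hypothesis import strategies as st

from dbloss.balance import BalanceParams, ClassCounts, build_weight_table
from dbloss.losses import (
    LossConfig,
    batch_grad_logits,
    batch_loss,
    class_balanced_ce,
    cross_entropy,
    db_loss,
    default_wce_weights,
    difficulty_weight,
    focal_loss,
    grad_wrt_logits,
    softmax,
    weight_curve,
    weighted_cross_entropy,
)

ALL_CONFIGS = [
    LossConfig(kind="ce"),
    LossConfig(kind="wce"),
    LossConfig(kind="focal", gamma=2.0),
    LossConfig(kind="focal", gamma=0.7),
    LossConfig(kind="cb"),
    LossConfig(kind="db", variant="printed"),
    LossConfig(kind="db", variant="derived"),
]


class TestSoftmax:
    def test_uniform(self):
        np.testing.assert_allclose(softmax([0.0, 0.0, 0.0]), 1 / 3)

    def test_closed_form(self):
        np.testing.assert_allclose(softmax([np.log(2), 0.0]), [2 / 3, 1 / 3])

    def test_overflow_safe(self):
        p = softmax([1000.0, 0.0, 0.0])
        assert np.isfinite(p).all()
        np.testing.assert_allclose(p, [1, 0, 0], atol=1e-12)

    def test_shift_invariance(self, rng):
        z = rng.normal(size=7)
        np.testing.assert_allclose(softmax(z), softmax(z + 123.4), atol=1e-12)

    def test_matches_scipy(self, rng):
        z = rng.normal(0, 5, size=(20, 4))
        np.testing.assert_allclose(softmax(z), scipy.special.softmax(z, axis=-1))

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            softmax([np.inf, 0.0])


class TestPerSampleLosses:
    def test_cross_entropy_values(self):
        assert cross_entropy([1.0, 0.0], 0) == pytest.approx(0.0, abs=1e-10)
        p = np.array([np.e**-1, 1 - np.e**-1])
        assert cross_entropy(p, 0) == pytest.approx(1.0)

    def test_only_true_class_matters(self):
        a = np.array([0.5, 0.3, 0.2])
        b = np.array([0.5, 0.2, 0.3])
        assert cross_entropy(a, 0) == cross_entropy(b, 0)

    def test_wce_scaling(self):
        p = np.array([np.e**-1, 1 - np.e**-1])
        assert weighted_cross_entropy(p, 0, [2.0, 1.0]) == pytest.approx(2.0)
        assert weighted_cross_entropy(p, 0, [1.0, 1.0]) == pytest.approx(
            cross_entropy(p, 0)
        )

    def test_default_wce_weights_inverse_frequency_mean_one(self):
        t = build_weight_table(ClassCounts(("a", "b", "c"), (2, 1, 1)))
        w = default_wce_weights(t)
        np.testing.assert_allclose(w, np.array([0.2, 0.4, 0.4]) * 3)  # mean 1
        assert w.mean() == pytest.approx(1.0)

    def test_focal_closed_form(self):
        p = np.array([0.5, 0.5])
        assert focal_loss(p, 0, gamma=2.0) == pytest.approx(0.25 * np.log(2))
        assert focal_loss(p, 0, gamma=0.0) == pytest.approx(cross_entropy(p, 0))

    def test_class_balanced_weight_monotone(self, lesion_counts):
        p = np.array([0.5, 0.25, 0.25])
        # cancer (fewest effective samples) weighted above adenoma
        l_cancer = class_balanced_ce(np.array([0.25, 0.5, 0.25]), 1, lesion_counts, 0.99)
        l_adenoma = class_balanced_ce(p, 0, lesion_counts, 0.99)
        assert l_cancer > l_adenoma
        # beta=0 collapses to plain CE
        assert class_balanced_ce(p, 0, lesion_counts, 0.0) == pytest.approx(
            cross_entropy(p, 0)
        )

    def test_difficulty_weight(self):
        assert difficulty_weight(1.0, 1.0) == pytest.approx(0.0, abs=1e-10)
        assert difficulty_weight(1.0, np.e**-1) == pytest.approx(1.0)
        assert difficulty_weight(0.4, 0.5) == pytest.approx(0.4 * np.log(2))


class TestDBLoss:
    def test_zero_at_certainty(self, lesion_table):
        p = np.array([1.0, 0.0, 0.0])
        for variant in ("printed", "derived"):
            assert db_loss(p, 0, lesion_table, variant) == pytest.approx(0.0, abs=1e-10)

    def test_uniform_counts_closed_form(self, uniform_table):
        # alpha = pp = 1/3: printed variant gives (1 + 1/9) * (log p)^2
        p = np.array([np.e**-1, 0.5 * (1 - np.e**-1), 0.5 * (1 - np.e**-1)])
        assert db_loss(p, 0, uniform_table, "printed") == pytest.approx(10 / 9)

    def test_rarer_class_weighted_higher(self, lesion_table):
        pt = 0.4
        rest = (1 - pt) / 2
        loss_adenoma = db_loss(np.array([pt, rest, rest]), 0, lesion_table)
        loss_cancer = db_loss(np.array([rest, pt, rest]), 1, lesion_table)
        assert loss_cancer > loss_adenoma

    def test_decreasing_in_p_true(self, lesion_table):
        vals = []
        for pt in (0.2, 0.4, 0.6, 0.8, 0.99):
            rest = (1 - pt) / 2
            vals.append(db_loss(np.array([pt, rest, rest]), 0, lesion_table))
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_k_mismatch_rejected(self, lesion_table):
        with pytest.raises(ValueError):
            db_loss(np.array([0.5, 0.5]), 0, lesion_table)

    def test_unknown_variant_rejected(self, lesion_table):
        with pytest.raises(ValueError):
            db_loss(np.array([0.5, 0.3, 0.2]), 0, lesion_table, variant="other")


class TestWeightCurve:
    def test_equal_counts_identical_curves(self, uniform_table):
        p = np.linspace(0.05, 0.95, 10)
        c0 = weight_curve(uniform_table, 0, p)
        for i in (1, 2):
            np.testing.assert_allclose(weight_curve(uniform_table, i, p), c0)

    def test_ordered_opposite_to_counts_and_decreasing(self, lesion_table):
        p = np.linspace(0.01, 0.99, 50)
        adenoma, cancer, polyp = (weight_curve(lesion_table, i, p) for i in range(3))
        assert np.all(adenoma < polyp) and np.all(polyp < cancer)
        for curve in (adenoma, cancer, polyp):
            assert np.all(np.diff(curve) < 0)
        assert weight_curve(lesion_table, 0, np.array([1 - 1e-9]))[0] < 1e-6

    def test_rho_widens_gap(self, lesion_counts):
        gaps = []
        for rho in (0.25, 0.5, 0.75):
            t = build_weight_table(lesion_counts, BalanceParams(0.99, rho))
            at_half = [weight_curve(t, i, np.array([0.5]))[0] for i in range(3)]
            gaps.append(max(at_half) - min(at_half))
        assert gaps[0] < gaps[1] < gaps[2]

    def test_grid_outside_unit_interval_rejected(self, lesion_table):
        with pytest.raises(ValueError):
            weight_curve(lesion_table, 0, np.array([0.0, 0.5]))


def _loop_oracle(cfg, P, y, table):
    """Brute-force per-sample loop against which batch_loss is checked."""
    out = []
    for i in range(P.shape[0]):
        if cfg.kind == "ce":
            out.append(cross_entropy(P[i], y[i], cfg.eps))
        elif cfg.kind == "wce":
            out.append(weighted_cross_entropy(P[i], y[i], default_wce_weights(table), cfg.eps))
        elif cfg.kind == "focal":
            out.append(focal_loss(P[i], y[i], cfg.gamma, cfg.eps))
        elif cfg.kind == "cb":
            out.append(class_balanced_ce(P[i], y[i], table.counts, table.params.beta, cfg.eps))
        else:
            out.append(db_loss(P[i], y[i], table, cfg.variant, cfg.eps))
    return np.array(out)


class TestBatchLoss:
    @pytest.mark.parametrize("cfg", ALL_CONFIGS, ids=lambda c: f"{c.kind}-{c.variant}-{c.gamma}")
    def test_matches_loop_oracle(self, cfg, lesion_table, rng):
        P = softmax(rng.normal(0, 3, size=(64, 3)))
        y = rng.integers(0, 3, size=64)
        vec = batch_loss(
            LossConfig(cfg.kind, cfg.gamma, cfg.variant, cfg.eps, "none"),
            P, y, lesion_table,
        )
        oracle = _loop_oracle(cfg, P, y, lesion_table)
        np.testing.assert_allclose(vec, oracle, atol=1e-12)
        mean = batch_loss(cfg, P, y, lesion_table)
        assert mean == pytest.approx(oracle.mean(), abs=1e-12)

    def test_reductions(self, lesion_table, rng):
        P = softmax(rng.normal(size=(8, 3)))
        y = rng.integers(0, 3, size=8)
        none = batch_loss(LossConfig("db", reduction="none"), P, y, lesion_table)
        assert batch_loss(LossConfig("db", reduction="sum"), P, y, lesion_table) == pytest.approx(none.sum())
        # duplicating every row leaves the mean unchanged
        mean1 = batch_loss(LossConfig("db"), P, y, lesion_table)
        mean2 = batch_loss(LossConfig("db"), np.vstack([P, P]), np.hstack([y, y]), lesion_table)
        assert mean1 == pytest.approx(mean2, abs=1e-12)

    def test_shape_mismatch_rejected(self, lesion_table):
        with pytest.raises(ValueError):
            batch_loss(LossConfig("ce"), np.full((3, 3), 1 / 3), [0, 1], lesion_table)

    def test_non_probability_rows_rejected(self, lesion_table):
        with pytest.raises(ValueError):
            batch_loss(LossConfig("ce"), np.array([[0.9, 0.5, 0.1]]), [0], lesion_table)


class TestGradients:
    def test_ce_gradient_closed_form(self):
        g = grad_wrt_logits(LossConfig("ce"), np.zeros(3), 0)
        np.testing.assert_allclose(g, [-2 / 3, 1 / 3, 1 / 3])

    @pytest.mark.parametrize("cfg", ALL_CONFIGS, ids=lambda c: f"{c.kind}-{c.variant}-{c.gamma}")
    def test_vanishes_at_certainty(self, cfg, lesion_table):
        g = grad_wrt_logits(cfg, np.array([60.0, 0.0, 0.0]), 0, lesion_table)
        np.testing.assert_allclose(g, 0.0, atol=1e-8)

    @pytest.mark.parametrize("cfg", ALL_CONFIGS, ids=lambda c: f"{c.kind}-{c.variant}-{c.gamma}")
    def test_matches_finite_differences(self, cfg, lesion_table, rng):
        cfg_none = LossConfig(cfg.kind, cfg.gamma, cfg.variant, cfg.eps, "none")
        h = 1e-5
        for _ in range(100):
            z = rng.normal(0, 2, size=3)
            y = int(rng.integers(0, 3))
            g = grad_wrt_logits(cfg, z, y, lesion_table)
            for j in range(3):
                e = np.zeros(3)
                e[j] = h
                num = (
                    batch_loss(cfg_none, softmax(z + e)[None], [y], lesion_table)[0]
                    - batch_loss(cfg_none, softmax(z - e)[None], [y], lesion_table)[0]
                ) / (2 * h)
                assert g[j] == pytest.approx(num, rel=1e-5, abs=1e-8)

    def test_batch_gradient_matches_per_sample(self, lesion_table, rng):
        Z = rng.normal(size=(16, 3))
        y = rng.integers(0, 3, size=16)
        cfg = LossConfig("db")
        G = batch_grad_logits(cfg, Z, y, lesion_table)
        for i in range(16):
            np.testing.assert_allclose(
                G[i], grad_wrt_logits(cfg, Z[i], int(y[i]), lesion_table), atol=1e-12
            )


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    z=st.lists(st.floats(-15, 15), min_size=2, max_size=5),
    y=st.integers(0, 4),
    kind=st.sampled_from(["ce", "wce", "focal", "cb", "db"]),
)
def test_losses_nonnegative(z, y, kind):
    """Every loss is >= 0 for any valid prediction/label pair."""
    z = np.asarray(z)
    y = y % z.size
    counts = ClassCounts(tuple(map(str, range(z.size))), tuple([7] * z.size))
    table = build_weight_table(counts)
    val = batch_loss(LossConfig(kind), softmax(z)[None], [y], table)
    assert val >= -1e-12
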