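"""Set-operator contracts: permutation invariance, cardinality flexibility,
duplication behaviour, weight sharing, linear attention cost, and the
K-means limit of the simplified attention update."""

from __future__ import annotations

import numpy as np
import pytest

from picaso import (AGGREGATOR_NAMES, PicasoConfig, init_hive,
                    kmeans_limit_iterate, kmeans_limit_update, make_aggregator)
from picaso.autodiff import Tensor
from picaso.operators import MultiheadCrossAttention, PicasoAggregator

RNG = np.random.default_rng(1234)


def rand_set(m: int, d: int = 64) -> np.ndarray:
    return RNG.standard_normal((m, d)).astype(np.float32)


# ----------------------------------------------------------------- init_hive
class TestInitHive:
    def test_shape_and_learnable(self):
        h = init_hive(1, 512, seed=0)
        assert h.mu.shape == (1, 512)
        assert h.learnable and h.step_index == 0

    def test_deterministic_under_seed(self):
        a = init_hive(2, 64, seed=7)
        b = init_hive(2, 64, seed=7)
        assert np.array_equal(a.mu, b.mu)

    def test_kaiming_variance(self):
        # >= 10^4 entries so the empirical variance is tight
        h = init_hive(40, 256, seed=1)
        var = h.mu.var()
        assert 2 / 256 * 0.7 < var < 2 / 256 * 1.3

    @pytest.mark.parametrize("n,d", [(0, 8), (2, 0), (-1, 4)])
    def test_nonpositive_dims_rejected(self, n, d):
        with pytest.raises(ValueError):
            init_hive(n, d, seed=0)


# ----------------------------------------------------------------- attention
class TestCrossAttention:
    def test_single_instance_weight_is_one(self):
        attn = MultiheadCrossAttention(np.random.default_rng(0), 32, 4)
        _, w = attn(Tensor(rand_set(1, 32)), Tensor(rand_set(1, 32)))
        assert w.shape == (1, 1)
        assert w[0, 0] == pytest.approx(1.0, abs=1e-7)

    def test_identical_rows_give_uniform_weights_and_m1_output(self):
        attn = MultiheadCrossAttention(np.random.default_rng(0), 32, 4)
        q = Tensor(rand_set(1, 32))
        row = rand_set(1, 32)
        out_m1, _ = attn(q, Tensor(row))
        out_m8, w = attn(q, Tensor(np.repeat(row, 8, axis=0)))
        np.testing.assert_allclose(w, 1 / 8, atol=1e-6)
        np.testing.assert_allclose(out_m8.data, out_m1.data, atol=1e-5)

    def test_indivisible_heads_rejected(self):
        with pytest.raises(ValueError):
            MultiheadCrossAttention(np.random.default_rng(0), 30, 4)

    def test_rows_on_probability_simplex(self):
        attn = MultiheadCrossAttention(np.random.default_rng(3), 64, 8)
        for m in (1, 3, 17):
            out = attn(Tensor(rand_set(2, 64)), Tensor(rand_set(m, 64)))
            _, w = out
            assert np.all(w >= 0)
            np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-6)


# ----------------------------------------------------- common operator laws
@pytest.mark.parametrize("name", AGGREGATOR_NAMES)
class TestOperatorContract:
    def test_permutation_invariance(self, name):
        agg = make_aggregator(name, dim=64, seed=5)
        rng = np.random.default_rng(99)
        for _ in range(20):
            m = int(rng.integers(1, 33))
            e = rand_set(m)
            base = agg(Tensor(e)).data
            perm = rng.permutation(m)
            out = agg(Tensor(e[perm])).data
            assert np.max(np.abs(base - out)) < 1e-5

    def test_cardinality_flexibility(self, name):
        agg = make_aggregator(name, dim=64, seed=5)
        shapes = {agg(Tensor(rand_set(m))).data.shape for m in (1, 2, 8, 64)}
        assert len(shapes) == 1

    def test_output_finite(self, name):
        agg = make_aggregator(name, dim=64, seed=5)
        assert np.all(np.isfinite(agg(Tensor(rand_set(7))).data))


def test_duplication_invariance_holds_for_attention_and_mean_not_sum():
    e = rand_set(3)
    dup = np.vstack([e, e])
    for name in ("picaso", "deepset_mean", "set_transformer"):
        agg = make_aggregator(name, dim=64, seed=6)
        a, b = agg(Tensor(e)).data, agg(Tensor(dup)).data
        assert np.max(np.abs(a - b)) < 1e-5, name
    agg = make_aggregator("deepset_sum", dim=64, seed=6)
    a, b = agg(Tensor(e)).data, agg(Tensor(dup)).data
    assert np.max(np.abs(a - b)) > 1e-3


# ---------------------------------------------------------------- cascade
class TestPicasoCascade:
    def test_weight_sharing_parameter_count_independent_of_j(self):
        counts = {j: make_aggregator("picaso", dim=64, n_steps=j,
                                     share_weights=True, seed=0).n_parameters()
                  for j in (1, 2, 4)}
        assert len(set(counts.values())) == 1

    def test_unshared_parameter_count_grows_affinely_in_j(self):
        counts = [make_aggregator("picaso", dim=64, n_steps=j,
                                  share_weights=False, seed=0).n_parameters()
                  for j in (1, 2, 3)]
        assert counts[1] - counts[0] == counts[2] - counts[1] > 0

    def test_invalid_steps_rejected(self):
        with pytest.raises(ValueError):
            PicasoConfig(dim=64, n_steps=0)

    def test_dimension_mismatch_rejected(self):
        agg = make_aggregator("picaso", dim=64, seed=0)
        with pytest.raises(ValueError):
            agg(Tensor(rand_set(4, 32)))

    def test_attention_trace_shapes_and_simplex(self):
        agg = make_aggregator("picaso", dim=64, n_steps=3, n_hive=2, seed=1)
        agg(Tensor(rand_set(9)))
        assert len(agg.attention_trace) == 3
        for w in agg.attention_trace:
            assert w.shape == (2, 9)
            np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-6)

    @pytest.mark.parametrize("m", [8, 64, 512])
    def test_linear_attention_cost(self, m):
        """Score storage per step is exactly n_heads * n_hive * M entries."""
        agg = make_aggregator("picaso", dim=64, n_heads=8, n_hive=1,
                              n_steps=3, seed=2)
        agg(Tensor(rand_set(m)))
        assert agg.score_elements_trace == [8 * 1 * m] * 3
        assert sum(agg.score_elements_trace) == 3 * 8 * m  # no M^2 term

    def test_set_transformer_without_sab_equals_cross_attention(self):
        """PMA with zero self-attention blocks is cross-attention with the
        seeds as query."""
        from picaso.operators import SetTransformerAggregator

        st = SetTransformerAggregator(np.random.default_rng(3), dim=32,
                                      n_heads=4, n_seeds=1, n_sab=0)
        e = Tensor(rand_set(6, 32))
        direct, _ = st.pma(st.seeds, e)
        np.testing.assert_allclose(st(e).data, direct.data, atol=1e-6)


# ------------------------------------------------------------- k-means limit
def lloyd_step(mu: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Brute-force oracle: hard nearest-centroid assignment, then means."""
    d2 = ((x[:, None, :] - mu[None, :, :]) ** 2).sum(-1)
    assign = d2.argmin(axis=1)
    out = mu.copy().astype(float)
    for k in range(mu.shape[0]):
        if np.any(assign == k):
            out[k] = x[assign == k].mean(axis=0)
    return out


class TestKmeansLimit:
    def test_matches_lloyd_oracle_on_random_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            m = int(rng.integers(5, 51))
            k = int(rng.integers(2, 6))
            d = int(rng.integers(1, 5))
            x = rng.standard_normal((m, d)) * 3
            mu = x[rng.choice(m, size=k, replace=False)] + 0.01 * rng.standard_normal((k, d))
            ours = kmeans_limit_update(mu, x, temperature=1e-6)
            np.testing.assert_allclose(ours, lloyd_step(mu, x), atol=1e-4)

    def test_identical_points_collapse_to_that_point(self):
        p = np.array([2.0, -1.0])
        x = np.tile(p, (10, 1))
        mu = np.random.default_rng(0).standard_normal((3, 2))
        out = kmeans_limit_update(mu, x, temperature=1.0)
        np.testing.assert_allclose(out, np.tile(p, (3, 1)), atol=1e-10)

    def test_infinite_temperature_gives_global_mean(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((30, 3))
        mu = rng.standard_normal((4, 3))
        out = kmeans_limit_update(mu, x, temperature=1e12)
        np.testing.assert_allclose(out, np.tile(x.mean(0), (4, 1)), atol=1e-6)

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError):
            kmeans_limit_update(np.zeros((2, 2)), np.zeros((3, 2)), 0.0)

    def test_dot_product_variant_runs(self):
        rng = np.random.default_rng(2)
        out = kmeans_limit_update(rng.standard_normal((2, 3)),
                                  rng.standard_normal((10, 3)),
                                  temperature=1.0, score="dot")
        assert out.shape == (2, 3) and np.all(np.isfinite(out))

    def test_iterated_update_recovers_separated_clusters(self):
        from sklearn.metrics import adjusted_rand_score

        from picaso import MixtureSetSpec, gen_mixture_sets

        spec = MixtureSetSpec(k=2, dims=2, separation=10.0, n_sets=5, seed=3)
        for x, labels in gen_mixture_sets(spec):
            # farthest-point initialisation keeps the two starts apart
            far = ((x - x[0]) ** 2).sum(1).argmax()
            mu0 = np.vstack([x[0], x[far]]).astype(float)
            mu = kmeans_limit_iterate(mu0, x, temperature=1e-6)
            d2 = ((x[:, None, :] - mu[None, :, :]) ** 2).sum(-1)
            ari = adjusted_rand_score(labels, d2.argmin(1))
            assert ari > 0.95
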