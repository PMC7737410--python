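"""Scalar-product similarity, UPGMA modules, cosine tuning, preferred
direction statistics and module typing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from synergyemg import synergy_analysis as sa
from synergyemg.emg_synth import build_montage


def brute_force_upgma(sp: np.ndarray, threshold: float) -> np.ndarray:
    """Independent oracle: average linkage computed from scratch (mean of
    the ORIGINAL pairwise dissimilarities between cluster members),
    merging the smallest-dissimilarity pair while it stays below
    1 - threshold."""
    D = 1.0 - sp
    clusters = [[i] for i in range(sp.shape[0])]
    while len(clusters) > 1:
        best, pair = np.inf, None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = np.mean([D[i, j] for i in clusters[a]
                             for j in clusters[b]])
                if d < best - 1e-15:
                    best, pair = d, (a, b)
        if best >= 1.0 - threshold:
            break
        a, b = pair
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    out = np.empty(sp.shape[0], dtype=int)
    order = {}
    for members in clusters:
        for i in members:
            out[i] = min(members)
    for idx in range(len(out)):
        if out[idx] not in order:
            order[out[idx]] = len(order)
        out[idx] = order[out[idx]]
    return out


def random_similarity(rng, k):
    sp = rng.uniform(0, 1, (k, k))
    sp = (sp + sp.T) / 2
    np.fill_diagonal(sp, 1.0)
    return sp


class TestScalarProduct:
    def test_identical_vectors_give_one(self):
        v = np.array([0.2, 0.5, 1.0])
        assert sa.scalar_product(v, v) == pytest.approx(1.0)

    def test_disjoint_supports_give_zero(self):
        assert sa.scalar_product(np.array([1.0, 0.0]),
                                 np.array([0.0, 2.0])) == 0.0

    def test_known_angle(self):
        assert sa.scalar_product(np.array([1.0, 1.0]),
                                 np.array([1.0, 0.0])) == \
            pytest.approx(1 / np.sqrt(2), abs=1e-4)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            sa.scalar_product(np.zeros(3), np.ones(3))

    @settings(max_examples=25, deadline=None)
    @given(scale=st.floats(0.01, 100.0), seed=st.integers(0, 10**6))
    def test_symmetric_and_scale_invariant(self, scale, seed):
        rng = np.random.default_rng(seed)
        e = rng.uniform(0.01, 1, 6)
        f = rng.uniform(0.01, 1, 6)
        assert sa.scalar_product(e, f) == pytest.approx(
            sa.scalar_product(f, e))
        assert sa.scalar_product(scale * e, f) == pytest.approx(
            sa.scalar_product(e, f), rel=1e-9)


class TestUPGMA:
    def test_all_similar_items_form_one_module(self):
        sp = np.full((4, 4), 0.9)
        np.fill_diagonal(sp, 1.0)
        assert len(set(sa.upgma_cluster(sp))) == 1

    def test_identity_similarity_gives_singletons(self):
        sp = np.eye(5)
        assert len(set(sa.upgma_cluster(sp))) == 5

    def test_two_clear_pairs(self):
        sp = np.eye(4)
        sp[0, 1] = sp[1, 0] = 0.9
        sp[2, 3] = sp[3, 2] = 0.8
        sp[0, 2] = sp[2, 0] = sp[0, 3] = sp[3, 0] = 0.3
        sp[1, 2] = sp[2, 1] = sp[1, 3] = sp[3, 1] = 0.3
        labels = sa.upgma_cluster(sp)
        assert labels[0] == labels[1]
        assert labels[2] == labels[3]
        assert labels[0] != labels[2]
        assert np.array_equal(labels, brute_force_upgma(sp, 0.75))

    def test_non_symmetric_rejected(self):
        sp = np.eye(3)
        sp[0, 1] = 0.5
        with pytest.raises(ValueError):
            sa.upgma_cluster(sp)

    def test_matches_brute_force_and_scipy_on_random_matrices(self):
        rng = np.random.default_rng(42)
        for _ in range(40):
            k = int(rng.integers(2, 7))
            sp = random_similarity(rng, k)
            ours = sa.upgma_cluster(sp)
            oracle = brute_force_upgma(sp, 0.75)
            assert _same_partition(ours, oracle)
            Z = linkage(squareform(1.0 - sp, checks=False),
                        method="average")
            scipy_labels = fcluster(Z, t=0.25 * (1 - 1e-12),
                                    criterion="distance")
            assert _same_partition(ours, scipy_labels)


def _same_partition(a, b):
    a = np.asarray(a)
    b = np.asarray(b)
    pairs_a = {(i, j) for i in range(a.size) for j in range(i + 1, a.size)
               if a[i] == a[j]}
    pairs_b = {(i, j) for i in range(b.size) for j in range(i + 1, b.size)
               if b[i] == b[j]}
    return pairs_a == pairs_b


class TestDirectionMeans:
    def test_constant_trials_give_equal_means(self):
        vals = np.ones(16)
        direction = np.tile(np.arange(1, 9), 2)
        assert np.allclose(sa.direction_means(vals, direction), 1.0)

    def test_permutation_invariant(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0, 1, 24)
        direction = np.tile(np.arange(1, 9), 3)
        m1 = sa.direction_means(vals, direction)
        perm = rng.permutation(24)
        m2 = sa.direction_means(vals[perm], direction[perm])
        assert np.allclose(m1, m2)

    def test_missing_direction_rejected(self):
        with pytest.raises(ValueError):
            sa.direction_means(np.ones(7), np.arange(1, 8))


class TestCosineTune:
    def test_exact_recovery_on_orthogonal_design(self):
        theta = sa.DIRECTION_ANGLES_DEG
        m = 0.5 + 0.3 * np.cos(np.deg2rad(theta - 60.0))
        fit = sa.cosine_tune(m, normalize=None)
        assert fit.a0 == pytest.approx(0.5, abs=1e-10)
        assert fit.w == pytest.approx(0.3, abs=1e-10)
        assert fit.pd_deg == pytest.approx(60.0, abs=1e-8)

    def test_constant_tuning_has_undefined_pd(self):
        fit = sa.cosine_tune(np.full(8, 0.4))
        assert fit.w == pytest.approx(0.0, abs=1e-12)
        assert not fit.defined
        assert np.isnan(fit.pd_deg)

    def test_pd_near_wraparound(self):
        theta = sa.DIRECTION_ANGLES_DEG
        m = 0.6 + 0.2 * np.cos(np.deg2rad(theta - 350.0))
        fit = sa.cosine_tune(m, normalize=None)
        assert fit.pd_deg == pytest.approx(350.0, abs=1e-8)

    def test_max_normalization_rescales_w(self):
        theta = sa.DIRECTION_ANGLES_DEG
        m = 0.5 + 0.25 * np.cos(np.deg2rad(theta))
        fit = sa.cosine_tune(m, normalize="max")
        assert fit.w == pytest.approx(0.25 / 0.75, abs=1e-10)

    def test_too_few_angles_rejected(self):
        with pytest.raises(ValueError):
            sa.cosine_tune(np.ones(2), theta_deg=np.array([0.0, 90.0]))

    @settings(max_examples=30, deadline=None)
    @given(a0=st.floats(0.3, 2.0), w=st.floats(0.01, 0.29),
           pd=st.floats(0.0, 359.9))
    def test_fourier_closed_form_property(self, a0, w, pd):
        """On 8 equally spaced angles the OLS coefficients equal the
        discrete Fourier terms a1 = (2/8) sum m cos, a2 = (2/8) sum m sin."""
        theta = np.deg2rad(sa.DIRECTION_ANGLES_DEG)
        m = a0 + w * np.cos(theta - np.deg2rad(pd))
        fit = sa.cosine_tune(m, normalize=None)
        a1 = 2 / 8 * np.sum(m * np.cos(theta))
        a2 = 2 / 8 * np.sum(m * np.sin(theta))
        assert fit.a1 == pytest.approx(a1, abs=1e-10)
        assert fit.a2 == pytest.approx(a2, abs=1e-10)
        assert fit.w == pytest.approx(np.hypot(a1, a2), abs=1e-10)


class TestPdError:
    def test_same_posture_pair(self):
        assert sa.pd_error([10.0, 30.0], [0.0, 0.0]) == pytest.approx(10.0)

    def test_wraparound_pair(self):
        assert sa.pd_error([359.0, 1.0], [0.0, 0.0]) == pytest.approx(1.0)

    def test_identical_pds_zero_error(self):
        assert sa.pd_error([45.0, 45.0, 45.0], [0.0, 0.0, 0.0]) == \
            pytest.approx(0.0)

    def test_elbow90_compensation(self):
        # PD measured 135 deg at Elbow 90 equals 45 deg after the 90 deg
        # clockwise shift, matching the Elbow-0 PD exactly
        assert sa.pd_error([45.0, 135.0], [0.0, 90.0]) == pytest.approx(0.0)

    def test_undefined_pds_excluded(self):
        assert np.isnan(sa.pd_error([np.nan, 10.0], [0.0, 0.0]))


class TestModuleType:
    def test_axial_column_is_parallel(self):
        m = build_montage()
        grid = m.grid_mask()
        w = np.zeros(int(grid.sum()))
        col = m.circ_deg[grid] == 0.0
        w[col] = 1.0
        assert sa.classify_module_type(w, m) == "parallel"

    def test_single_ring_is_local(self):
        m = build_montage()
        grid = m.grid_mask()
        w = np.zeros(int(grid.sum()))
        ring = m.axial_mm[grid] == 100.0
        w[ring] = 1.0
        assert sa.classify_module_type(w, m) == "local"

    def test_all_zero_weights_rejected(self):
        m = build_montage()
        with pytest.raises(ValueError):
            sa.classify_module_type(np.zeros(95), m)


class TestCompareTuningWeights:
    def test_identical_groups_null(self):
        g = np.array([0.1, 0.2, 0.3])
        out = sa.compare_tuning_weights(g, g)
        assert out["t"] == pytest.approx(0.0, abs=1e-12)
        assert out["p"] == pytest.approx(1.0)

    def test_separated_groups_significant(self):
        rng = np.random.default_rng(0)
        a = 1.0 + 1e-6 * rng.standard_normal(5)
        b = 0.0 + 1e-6 * rng.standard_normal(5)
        out = sa.compare_tuning_weights(a, b)
        assert out["p"] < 0.01

    def test_swapping_groups_flips_t(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(0, 1, 6)
        b = rng.uniform(0.5, 1.5, 6)
        o1 = sa.compare_tuning_weights(a, b)
        o2 = sa.compare_tuning_weights(b, a)
        assert o1["t"] == pytest.approx(-o2["t"])
        assert o1["p"] == pytest.approx(o2["p"])

    def test_degenerate_variance_reported_infinite(self):
        out = sa.compare_tuning_weights([1.0, 1.0], [0.0, 0.0])
        assert np.isinf(out["t"]) and out["p"] == 0.0
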