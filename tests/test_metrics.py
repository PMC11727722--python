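import itertools

import numpy as np
import pytest
from sklearn.metrics import (adjusted_rand_score, calinski_harabasz_score,
                             davies_bouldin_score)

import spotdomains as sd


def ari_pair_counting_oracle(a, b):
    """Brute force over all element pairs (independent of the
    contingency-table implementation)."""
    a, b = np.asarray(a), np.asarray(b)
    n = len(a)
    ss = sd_ = ds = dd = 0
    for i, j in itertools.combinations(range(n), 2):
        same_a, same_b = a[i] == a[j], b[i] == b[j]
        if same_a and same_b:
            ss += 1
        elif same_a and not same_b:
            sd_ += 1
        elif not same_a and same_b:
            ds += 1
        else:
            dd += 1
    total = n * (n - 1) / 2
    ri = (ss + dd) / total
    # expectation under random labeling with fixed marginals
    exp_index = ((ss + sd_) * (ss + ds)) / total
    max_index = 0.5 * ((ss + sd_) + (ss + ds))
    if max_index == exp_index:
        return 1.0
    return (ss - exp_index) / (max_index - exp_index)


FOUR_POINT_Z = np.array([[0.0, 0], [0, 1], [10, 0], [10, 1]])
FOUR_POINT_LABELS = np.array([0, 0, 1, 1])


def db_cdist_oracle(Z, labels):
    """Independent Davies-Bouldin implementation built on scipy cdist."""
    from scipy.spatial.distance import cdist

    uniq = np.unique(labels)
    cents = np.array([Z[labels == u].mean(axis=0) for u in uniq])
    s = np.array([cdist(Z[labels == u], c[None, :]).mean()
                  for u, c in zip(uniq, cents)])
    D = cdist(cents, cents)
    k = len(uniq)
    R = (s[:, None] + s[None, :]) / np.where(D > 0, D, np.inf)
    np.fill_diagonal(R, -np.inf)
    return R.max(axis=1).mean()


class TestARI:
    def test_identical_labelings(self):
        assert sd.adjusted_rand_index([0, 0, 1, 1], [0, 0, 1, 1]) == 1.0

    def test_relabel_invariance(self):
        assert sd.adjusted_rand_index([0, 0, 1, 1], [1, 1, 0, 0]) == 1.0

    def test_hand_case_minus_half(self):
        assert sd.adjusted_rand_index([0, 0, 1, 1], [0, 1, 0, 1]) == \
            pytest.approx(-0.5)

    def test_matches_pair_counting_oracle_on_500_random_pairs(self):
        rng = np.random.default_rng(0)
        for _ in range(500):
            n = int(rng.integers(2, 13))
            a = rng.integers(0, 4, size=n)
            b = rng.integers(0, 4, size=n)
            ours = sd.adjusted_rand_index(a, b)
            assert ours == pytest.approx(ari_pair_counting_oracle(a, b),
                                         abs=1e-12)

    def test_symmetry_and_sklearn_agreement(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            a = rng.integers(0, 5, size=30)
            b = rng.integers(0, 5, size=30)
            assert sd.adjusted_rand_index(a, b) == pytest.approx(
                sd.adjusted_rand_index(b, a), abs=1e-12)
            assert sd.adjusted_rand_index(a, b) == pytest.approx(
                adjusted_rand_score(a, b), abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            sd.adjusted_rand_index([0, 1], [0, 1, 1])


class TestDaviesBouldin:
    def test_hand_fixture(self):
        assert sd.davies_bouldin(FOUR_POINT_Z, FOUR_POINT_LABELS) == \
            pytest.approx(0.1)

    def test_duplicate_points_zero(self):
        Z = np.array([[0.0, 0], [0, 0], [5, 5], [5, 5]])
        assert sd.davies_bouldin(Z, [0, 0, 1, 1]) == 0.0

    def test_matches_reference_on_100_random_datasets(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            n, d, k = int(rng.integers(10, 40)), int(rng.integers(2, 5)), \
                int(rng.integers(2, 5))
            Z = rng.normal(size=(n, d))
            labels = rng.integers(0, k, size=n)
            if len(np.unique(labels)) < 2:
                continue
            assert sd.davies_bouldin(Z, labels) == pytest.approx(
                db_cdist_oracle(Z, labels), abs=1e-9)
            # sklearn cross-check, looser: its distance shortcut costs
            # a few digits of precision
            assert sd.davies_bouldin(Z, labels) == pytest.approx(
                davies_bouldin_score(Z, labels), rel=1e-6)

    def test_coincident_centroids_named(self):
        Z = np.array([[0.0, 0], [2, 0], [0, 0.0], [2, 0]])
        with pytest.raises(ValueError, match="coincident"):
            sd.davies_bouldin(Z, [0, 0, 1, 1])


class TestCalinskiHarabasz:
    def test_hand_fixture(self):
        assert sd.calinski_harabasz(FOUR_POINT_Z, FOUR_POINT_LABELS) == \
            pytest.approx(200.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        Z = rng.normal(size=(20, 3))
        labels = rng.integers(0, 3, size=20)
        a = sd.calinski_harabasz(Z, labels)
        b = sd.calinski_harabasz(2.0 * Z, labels)
        assert a == pytest.approx(b)

    def test_matches_reference_on_100_random_datasets(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            n, d, k = int(rng.integers(10, 40)), int(rng.integers(2, 5)), \
                int(rng.integers(2, 5))
            Z = rng.normal(size=(n, d))
            labels = rng.integers(0, k, size=n)
            if len(np.unique(labels)) < 2:
                continue
            assert sd.calinski_harabasz(Z, labels) == pytest.approx(
                calinski_harabasz_score(Z, labels), abs=1e-9, rel=1e-9)

    def test_degenerate_scatter_rejected(self):
        Z = np.array([[0.0, 0], [0, 0], [1, 1], [1, 1]])
        with pytest.raises(ValueError, match="degenerate"):
            sd.calinski_harabasz(Z, [0, 0, 1, 1])


def s_dbw_component_oracle(Z, labels):
    """Independent recomputation of Scat and Dens_bw from the definitions,
    written with explicit loops."""
    Z = np.asarray(Z, float)
    uniq = np.unique(labels)
    k = len(uniq)
    sigma_all = np.linalg.norm(Z.var(axis=0))
    scat_terms, cents, sig_norms, members = [], [], [], []
    for u in uniq:
        pts = Z[labels == u]
        members.append(np.flatnonzero(labels == u))
        cents.append(pts.mean(axis=0))
        nrm = np.linalg.norm(pts.var(axis=0))
        sig_norms.append(nrm)
        scat_terms.append(nrm / sigma_all)
    scat = np.mean(scat_terms)
    stdev = np.sqrt(np.sum(sig_norms)) / k

    def dens(u, pts):
        return np.sum(np.linalg.norm(pts - u, axis=1) <= stdev)

    total = 0.0
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            pts = Z[np.concatenate([members[i], members[j]])]
            mid = (cents[i] + cents[j]) / 2
            denom = max(dens(cents[i], pts), dens(cents[j], pts))
            if denom > 0:
                total += dens(mid, pts) / denom
    return scat, total / (k * (k - 1))


class TestSDbw:
    def test_good_labels_beat_shuffled(self):
        rng = np.random.default_rng(5)
        Z = np.vstack([rng.normal((0, 0), 0.2, (20, 2)),
                       rng.normal((10, 10), 0.2, (20, 2))])
        truth = np.repeat([0, 1], 20)
        shuffled = rng.permutation(truth)
        assert sd.s_dbw(Z, truth) < sd.s_dbw(Z, shuffled)

    def test_matches_component_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            Z = rng.normal(size=(30, 3))
            labels = rng.integers(0, 3, size=30)
            if len(np.unique(labels)) < 2:
                continue
            scat, dens = s_dbw_component_oracle(Z, labels)
            assert sd.s_dbw(Z, labels) == pytest.approx(scat + dens,
                                                        abs=1e-10)

    def test_separation_reduces_density_term(self):
        rng = np.random.default_rng(7)
        blob = rng.normal(0, 1.0, size=(25, 2))
        for gap_small, gap_big in [(3.0, 30.0)]:
            Z_near = np.vstack([blob, blob + gap_small])
            Z_far = np.vstack([blob, blob + gap_big])
            labels = np.repeat([0, 1], 25)
            scat_near, dens_near = s_dbw_component_oracle(Z_near, labels)
            scat_far, dens_far = s_dbw_component_oracle(Z_far, labels)
            assert sd.s_dbw(Z_far, labels) < sd.s_dbw(Z_near, labels)
            assert dens_far <= dens_near

    def test_single_point_clusters_zero_scat(self):
        Z = np.array([[0.0, 0], [5, 5], [9, 1]])
        val = sd.s_dbw(Z, [0, 1, 2])
        assert val == 0.0  # zero variance per cluster, empty densities


class TestOrderingOnPlantedBlobs:
    def test_better_labels_score_better_on_all_indices(self):
        rng = np.random.default_rng(8)
        Z = np.vstack([rng.normal(c, 0.4, size=(25, 3)) for c in
                       [(0, 0, 0), (8, 0, 0), (0, 8, 0), (0, 0, 8)]])
        truth = np.repeat(np.arange(4), 25)
        shuffled = rng.permutation(truth)
        good = sd.evaluate(Z, truth, truth)
        bad = sd.evaluate(Z, shuffled, truth)
        assert good.db < bad.db
        assert good.s_dbw < bad.s_dbw
        assert good.ch > bad.ch
        assert good.ari == 1.0 and bad.ari < 0.2
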