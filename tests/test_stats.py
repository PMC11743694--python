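"""Permutation, cluster-permutation and cosine-similarity tests."""

import numpy as np
import pytest

from attnerp import (
    AdjacencyGraph,
    EpochSet,
    UndefinedSimilarityError,
    ValidationError,
    bonferroni_alpha,
    cosine_similarity_test,
    permutation_test,
    spatial_cluster_test,
    temporal_cluster_test,
)
from attnerp.montage import SCALP_32


# ---------------------------------------------------------------------------
# Bonferroni
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("base,n,expected", [
    (0.05, 4, 0.0125),
    (0.05, 2, 0.025),
    (0.05, 1, 0.05),
])
def test_bonferroni_correction(base, n, expected):
    assert bonferroni_alpha(base, n) == expected


def test_bonferroni_zero_comparisons_errors():
    with pytest.raises(ValueError):
        bonferroni_alpha(0.05, 0)


# ---------------------------------------------------------------------------
# plain permutation test
# ---------------------------------------------------------------------------

def test_identical_sets_give_p_one(rng):
    a = rng.standard_normal((10, 1))
    p = permutation_test(a, a.copy(), n_perm=200, seed=0)
    assert p == 1.0


def test_strong_effect_reaches_minimum_p(rng):
    a = rng.standard_normal((20, 1)) + 50.0
    b = rng.standard_normal((20, 1))
    p = permutation_test(a, b, n_perm=500, sided="two", seed=0)
    assert p == pytest.approx(1.0 / 501.0)


def test_permutation_p_reproducible_under_seed(rng):
    a = rng.standard_normal((15, 1)) + 0.4
    b = rng.standard_normal((15, 1))
    p1 = permutation_test(a, b, n_perm=300, seed=11)
    p2 = permutation_test(a, b, n_perm=300, seed=11)
    assert p1 == p2


def test_permutation_invalid_inputs(rng):
    a = rng.standard_normal((5, 1))
    with pytest.raises(ValueError):
        permutation_test(a, a, n_perm=0)
    with pytest.raises(ValidationError):
        permutation_test(a[:0], a)


def test_null_rejection_rate_is_calibrated(rng):
    """Two same-distribution sets: rejection rate at alpha=.05 stays inside
    the 95% binomial band (quick version of the full calibration check)."""
    n_runs, rej = 200, 0
    for _ in range(n_runs):
        a = rng.standard_normal((12, 1))
        b = rng.standard_normal((12, 1))
        rej += permutation_test(a, b, n_perm=200, seed=rng) <= 0.05
    assert 0.05 * n_runs - 3 * np.sqrt(n_runs * 0.05 * 0.95) <= rej
    assert rej <= 0.05 * n_runs + 3 * np.sqrt(n_runs * 0.05 * 0.95)


# ---------------------------------------------------------------------------
# temporal cluster test
# ---------------------------------------------------------------------------

def test_subthreshold_difference_yields_no_clusters(rng):
    a = np.zeros((6, 50))
    b = np.zeros((6, 50)) + 0.2
    res = temporal_cluster_test(a, b, threshold=1.0, n_perm=100, seed=0)
    assert res.n_clusters == 0
    assert not res.any_significant()


def test_single_contiguous_segment_forms_one_cluster():
    a = np.zeros((8, 60))
    a[:, 20:35] = 2.0
    b = np.zeros((8, 60))
    res = temporal_cluster_test(a, b, threshold=1.0, n_perm=100, seed=0)
    assert res.clusters == [(20, 35)]
    assert res.cluster_stats[0] == pytest.approx(2.0 * 15)


def test_two_sided_finds_negative_clusters_separately():
    a = np.zeros((8, 60))
    a[:, 10:15] = 2.0
    a[:, 40:44] = -2.0
    b = np.zeros((8, 60))
    res = temporal_cluster_test(a, b, threshold=1.0, n_perm=50, seed=0)
    assert res.clusters == [(10, 15), (40, 44)]
    one = temporal_cluster_test(a, b, threshold=1.0, n_perm=50, sided="one", seed=0)
    assert one.clusters == [(10, 15)]


def test_cluster_p_values_monotone_in_cluster_stat(rng):
    a = rng.standard_normal((30, 80))
    a[:, 10:30] += 1.2
    a[:, 50:55] += 1.1
    b = rng.standard_normal((30, 80))
    res = temporal_cluster_test(a, b, threshold=0.5, n_perm=300, seed=3)
    order = np.argsort(-np.abs(res.cluster_stats))
    ps = res.p_values[order]
    assert (np.diff(ps) >= 0).all()


def test_label_exchange_symmetry_two_sided(rng):
    a = rng.standard_normal((12, 40)) + 0.3
    b = rng.standard_normal((15, 40))
    r1 = temporal_cluster_test(a, b, threshold=0.4, n_perm=1000, seed=8)
    r2 = temporal_cluster_test(b, a, threshold=0.4, n_perm=1000, seed=9)
    assert r1.clusters == r2.clusters
    np.testing.assert_allclose(r1.cluster_stats, -r2.cluster_stats)
    # permutation nulls are resampled, so p's agree to Monte-Carlo accuracy
    np.testing.assert_allclose(r1.p_values, r2.p_values, atol=0.06)


def test_invalid_threshold_errors(rng):
    a = rng.standard_normal((5, 20))
    with pytest.raises(ValueError):
        temporal_cluster_test(a, a, threshold=0.0)


def test_cluster_identification_matches_mne(rng):
    """Dual route: observed clusters and their summed statistics agree with
    MNE's cluster machinery driven by the same mean-difference statistic."""
    mne_stats = pytest.importorskip("mne.stats")
    a = rng.standard_normal((40, 120))
    a[:, 40:70] += 1.2
    b = rng.standard_normal((60, 120))

    def stat_fun(x, y):
        return x.mean(axis=0) - y.mean(axis=0)

    T_obs, clusters, _, _ = mne_stats.permutation_cluster_test(
        [a, b], threshold=0.8, n_permutations=50, stat_fun=stat_fun,
        tail=1, out_type="indices", verbose=False,
    )
    mne_cl = sorted((int(c[0][0]), int(c[0][-1]) + 1) for c in clusters)
    mne_sums = sorted(float(T_obs[c[0]].sum()) for c in clusters)
    ours = temporal_cluster_test(a, b, threshold=0.8, n_perm=50,
                                 sided="one", seed=0)
    assert sorted(ours.clusters) == mne_cl
    np.testing.assert_allclose(sorted(ours.cluster_stats), mne_sums)


# ---------------------------------------------------------------------------
# adjacency + spatial cluster test
# ---------------------------------------------------------------------------

def test_adjacency_from_montage_is_symmetric_without_self_edges():
    adj = AdjacencyGraph.from_montage(SCALP_32)
    assert all(len(e) == 2 for e in adj.edges)
    assert "Pz" in adj.neighbors("CP1") or "CP1" in adj.neighbors("Pz")
    # neighbourhood relation is symmetric by construction
    for e in adj.edges:
        u, v = tuple(e)
        assert u in adj.neighbors(v) and v in adj.neighbors(u)


def _scalp_epochs(data, conds):
    labels = list(SCALP_32)
    times = (np.arange(data.shape[2]) - 5) * 8.0
    return EpochSet(data, times, 125.0, labels,
                    {c: "scalp" for c in labels}, np.asarray(conds, object),
                    dict(SCALP_32))


def test_all_channels_below_threshold_gives_no_spatial_clusters(rng):
    data = 0.05 * rng.standard_normal((10, 32, 60))
    a = _scalp_epochs(data[:5], ["AT"] * 5)
    b = _scalp_epochs(data[5:], ["AN"] * 5)
    res = spatial_cluster_test(a, b, window=(0.0, 400.0), threshold=1.0,
                               n_perm=50, seed=0)
    assert res.n_clusters == 0


def test_nonadjacent_channels_form_separate_singleton_clusters():
    labels = list(SCALP_32)
    data = np.zeros((8, 32, 60))
    for ch in ("Fp1", "O2"):  # far apart: not adjacent
        data[:4, labels.index(ch), :] = 2.0
    a = _scalp_epochs(data[:4], ["AT"] * 4)
    b = _scalp_epochs(data[4:], ["AN"] * 4)
    res = spatial_cluster_test(a, b, window=(0.0, 400.0), threshold=1.0,
                               n_perm=50, seed=0)
    assert sorted(res.clusters) == [("Fp1",), ("O2",)]


def test_parietal_effect_yields_parietal_and_opposite_frontal_clusters(rng):
    """A dipolar scalp pattern produces a positive parietal cluster plus an
    opposite-sign frontal cluster under two-sided testing."""
    from attnerp.montage import cognitive_leadfield

    lead = cognitive_leadfield()
    labels = list(SCALP_32)
    w = np.array([lead[c] for c in labels])
    data = 0.3 * rng.standard_normal((40, 32, 60))
    data[:20] += 2.0 * w[None, :, None]
    a = _scalp_epochs(data[:20], ["AT"] * 20)
    b = _scalp_epochs(data[20:], ["AN"] * 20)
    res = spatial_cluster_test(a, b, window=(0.0, 400.0), threshold=1.0,
                               n_perm=100, seed=1)
    assert res.n_clusters >= 2
    best = res.clusters[int(np.argmin(res.p_values))]
    assert "Pz" in best
    signs = {tuple(sorted(c)): s for c, s in zip(res.clusters, res.cluster_stats)}
    frontal = [c for c in res.clusters if "Fp1" in c or "Fp2" in c]
    assert frontal and res.cluster_stats[res.clusters.index(frontal[0])] < 0


def test_channel_missing_from_adjacency_errors(rng):
    data = rng.standard_normal((4, 32, 60))
    a = _scalp_epochs(data[:2], ["AT"] * 2)
    b = _scalp_epochs(data[2:], ["AN"] * 2)
    adj = AdjacencyGraph.from_montage({k: v for k, v in SCALP_32.items()
                                       if k != "Pz"})
    with pytest.raises(ValidationError):
        spatial_cluster_test(a, b, window=(0.0, 400.0), adjacency=adj,
                             threshold=1.0, n_perm=10, seed=0)


# ---------------------------------------------------------------------------
# cosine similarity test
# ---------------------------------------------------------------------------

def test_proportional_waveforms_score_one(rng):
    v = np.sin(np.linspace(0, 4, 100))
    T = np.tile(3.0 * v, (10, 1))
    N = np.zeros((20, 100))
    score, p = cosine_similarity_test(T, N, v, n_perm=100, seed=0)
    assert score == pytest.approx(1.0)


def test_orthogonal_waveforms_score_zero():
    t = np.linspace(0, 2 * np.pi, 128, endpoint=False)
    T = np.tile(np.sin(t), (8, 1))
    N = np.zeros((8, 128))
    score, _ = cosine_similarity_test(T, N, np.cos(t), n_perm=50, seed=0)
    assert score == pytest.approx(0.0, abs=1e-10)


def test_zero_norm_waveform_is_undefined():
    T = np.zeros((5, 64))
    N = np.zeros((5, 64))
    with pytest.raises(UndefinedSimilarityError):
        cosine_similarity_test(T, N, np.ones(64), n_perm=10, seed=0)


def test_similarity_p_small_for_matched_component(rng):
    v = np.sin(np.linspace(0, 3, 100))
    T = v[None, :] + 0.3 * rng.standard_normal((30, 100))
    N = 0.3 * rng.standard_normal((60, 100))
    score, p = cosine_similarity_test(T, N, v, n_perm=500, seed=2)
    assert score > 0.8
    assert p == pytest.approx(1.0 / 501.0)
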