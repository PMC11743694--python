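"""Max-SNR spatial filter: covariances, GEVD solution, cross-task scheme."""

import numpy as np
import pytest

from attnerp import (
    EpochSet,
    MaxSNRFilter,
    ValidationError,
    apply_filter,
    compute_covariances,
    cross_task_validate,
    solve_filter,
)


def _ear_epochs(data, conds, fs=125.0):
    data = np.asarray(data, float)
    labels = [f"E{i}" for i in range(data.shape[1])]
    times = (np.arange(data.shape[2]) - 25) / fs * 1000.0
    return EpochSet(data, times, fs, labels,
                    {c: "ear_left" for c in labels},
                    np.asarray(conds, object))


# ---------------------------------------------------------------------------
# covariances
# ---------------------------------------------------------------------------

def test_single_epoch_single_channel_covariance():
    R_T, R_N = compute_covariances(np.array([[[1.0, 2.0]]]),
                                   np.array([[[1.0, 2.0]]]))
    np.testing.assert_allclose(R_T, [[5.0]])
    np.testing.assert_allclose(R_N, [[5.0]])


def test_nontarget_concatenation_equals_sum_of_outer_products(rng):
    X = rng.standard_normal((3, 4, 10))
    _, R_N = compute_covariances(X[:1], X)
    expected = sum(x @ x.T for x in X)
    np.testing.assert_allclose(R_N, expected, atol=1e-10)


def test_target_covariance_uses_average_epoch(rng):
    X = rng.standard_normal((5, 4, 10))
    R_T, _ = compute_covariances(X, X)
    XT = X.mean(axis=0)
    np.testing.assert_allclose(R_T, XT @ XT.T, atol=1e-10)


def test_covariances_are_symmetric_psd(rng):
    X = rng.standard_normal((6, 5, 30))
    Y = rng.standard_normal((8, 5, 30))
    for R in compute_covariances(X, Y):
        np.testing.assert_allclose(R, R.T, atol=1e-12)
        assert np.linalg.eigvalsh(R).min() >= -1e-9


def test_empty_or_mismatched_sets_error(rng):
    X = rng.standard_normal((2, 3, 10))
    with pytest.raises(ValidationError):
        compute_covariances(X[:0], X)
    with pytest.raises(ValidationError):
        compute_covariances(X, rng.standard_normal((2, 4, 10)))


# ---------------------------------------------------------------------------
# GEVD solution
# ---------------------------------------------------------------------------

def test_identity_pair_gives_unit_norm_and_unit_eigenvalue():
    res = solve_filter(np.eye(3), np.eye(3), shrinkage=0.0)
    assert res.eigenvalue == pytest.approx(1.0)
    assert res.w @ res.w == pytest.approx(1.0)
    assert res.constraint_residual() < 1e-10


def test_diagonal_pair_selects_strongest_direction():
    res = solve_filter(np.diag([4.0, 1.0]), np.eye(2), shrinkage=0.0)
    np.testing.assert_allclose(np.abs(res.w), [1.0, 0.0], atol=1e-10)
    assert res.eigenvalue == pytest.approx(4.0)


def test_gevd_matches_brute_force_rayleigh_search(rng):
    """On random SPD pairs the GEVD objective dominates a dense random
    search of the Rayleigh quotient (small instance of the full oracle)."""
    for _ in range(5):
        A = rng.standard_normal((4, 7))
        B = rng.standard_normal((4, 9))
        R_T, R_N = A @ A.T, B @ B.T
        res = solve_filter(R_T, R_N, shrinkage=0.0)
        W = rng.standard_normal((20000, 4))
        ratios = (np.einsum("ij,jk,ik->i", W, R_T, W)
                  / np.einsum("ij,jk,ik->i", W, R_N, W))
        assert res.eigenvalue >= ratios.max() - 1e-9
        # 20k directions in 4-D land close to, never above, the optimum
        assert ratios.max() >= 0.95 * res.eigenvalue


def test_stationarity_and_constraint_residuals(rng):
    A = rng.standard_normal((5, 8))
    B = rng.standard_normal((5, 40))
    res = solve_filter(A @ A.T, B @ B.T, shrinkage=0.0)
    assert res.constraint_residual() < 1e-8
    assert res.stationarity_residual() < 1e-6


def test_solution_direction_is_scale_invariant(rng):
    X_t = rng.standard_normal((4, 6, 20))
    X_n = rng.standard_normal((10, 6, 20))
    r1 = MaxSNRFilter(X_t, X_n).fit()
    r2 = MaxSNRFilter(5.0 * X_t, 5.0 * X_n).fit()
    cos = abs(r1.w @ r2.w / (np.linalg.norm(r1.w) * np.linalg.norm(r2.w)))
    assert cos == pytest.approx(1.0, abs=1e-8)


def test_objective_never_worse_than_any_single_channel(rng):
    A = rng.standard_normal((6, 9))
    B = rng.standard_normal((6, 50))
    R_T, R_N = A @ A.T, B @ B.T
    res = solve_filter(R_T, R_N, shrinkage=0.0)
    for i in range(6):
        e = np.zeros(6)
        e[i] = 1.0
        assert res.eigenvalue >= (e @ R_T @ e) / (e @ R_N @ e) - 1e-9


def test_degenerate_target_falls_back_with_warning(rng):
    B = rng.standard_normal((4, 30))
    with pytest.warns(RuntimeWarning):
        res = solve_filter(np.zeros((4, 4)), B @ B.T)
    assert res.degenerate_target


def test_singular_nontarget_covariance_without_shrinkage_errors():
    R_N = np.zeros((3, 3))
    R_N[0, 0] = 1.0  # rank 1
    with pytest.raises(np.linalg.LinAlgError, match="shrinkage"):
        solve_filter(np.eye(3), R_N, shrinkage=0.0)


# ---------------------------------------------------------------------------
# application
# ---------------------------------------------------------------------------

def test_basis_vector_filter_extracts_one_channel(rng):
    data = rng.standard_normal((3, 4, 15))
    eps = _ear_epochs(data, ["TARGET"] * 3)
    res = solve_filter(np.diag([1.0, 0, 0, 0]) + 0, np.eye(4), shrinkage=0.0)
    out = apply_filter(eps, res)
    assert out.n_channels == 1
    np.testing.assert_allclose(np.abs(out.data[:, 0, :]),
                               np.abs(data[:, 0, :]), atol=1e-10)
    assert (out.conditions == eps.conditions).all()


def test_apply_is_linear(rng):
    data = rng.standard_normal((3, 4, 15))
    res = solve_filter(np.eye(4), np.eye(4), shrinkage=0.0)
    out1 = apply_filter(_ear_epochs(data, ["AT"] * 3), res)
    out2 = apply_filter(_ear_epochs(2.5 * data, ["AT"] * 3), res)
    np.testing.assert_allclose(out2.data, 2.5 * out1.data)


def test_channel_mismatch_errors(rng):
    eps = _ear_epochs(rng.standard_normal((2, 5, 10)), ["AT", "AT"])
    res = solve_filter(np.eye(4), np.eye(4))
    with pytest.raises(ValidationError):
        res.apply(eps)


def test_sign_convention_makes_filtered_target_positive(rng):
    """The filtered average target is positive-going over 400-800 ms."""
    tpl = np.zeros(150)
    tpl[70:110] = 1.0  # crude positive bump in the late window
    pattern = np.array([1.0, 0.5, -0.5, -1.0])
    tgt = pattern[None, :, None] * tpl[None, None, :] + 0.1 * rng.standard_normal((20, 4, 150))
    ntg = 0.1 * rng.standard_normal((40, 4, 150))
    eps_t = _ear_epochs(tgt, ["TARGET"] * 20)
    eps_n = _ear_epochs(ntg, ["NONTARGET"] * 40)
    res = MaxSNRFilter(eps_t, eps_n).fit()
    filt = res.apply(eps_t)
    late = (filt.times_ms >= 400) & (filt.times_ms <= 800)
    assert filt.data.mean(axis=0)[0, late].mean() > 0


# ---------------------------------------------------------------------------
# cross-task validation
# ---------------------------------------------------------------------------

def _paradigm_data(rng, scale=1.0):
    tgt = scale * rng.standard_normal((6, 4, 30))
    ntg = scale * rng.standard_normal((12, 4, 30))
    return (_ear_epochs(tgt, ["AT"] * 6), _ear_epochs(ntg, ["AN"] * 12))


def test_three_paradigms_give_three_heldout_filters(rng):
    data = {p: _paradigm_data(rng) for p in ("P1", "P2", "P3")}
    out = cross_task_validate(data, ear="left")
    assert set(out) == {"P1", "P2", "P3"}
    for p, res in out.items():
        assert p not in res.filter.trained_on
        assert set(res.filter.trained_on) == {"P1", "P2", "P3"} - {p}
        assert res.filtered_target.n_channels == 1


def test_single_paradigm_errors(rng):
    with pytest.raises(ValidationError):
        cross_task_validate({"P1": _paradigm_data(rng)})


def test_identical_paradigm_data_gives_identical_filters(rng):
    base = _paradigm_data(rng)
    data = {p: base for p in ("P1", "P2", "P3")}
    out = cross_task_validate(data)
    w0 = out["P1"].filter.w
    for p in ("P2", "P3"):
        w = out[p].filter.w
        np.testing.assert_allclose(np.abs(w), np.abs(w0), atol=1e-8)


def test_summary_mentions_provenance(rng):
    data = {p: _paradigm_data(rng) for p in ("P1", "P2")}
    out = cross_task_validate(data, ear="right")
    text = out["P1"].filter.summary()
    assert "P2" in text and "right" in text
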