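"""Reconstruction operators: closed forms, greedy oracles, optimality bounds."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bspmaf.errors import ConfigError, DimensionError, UndefinedResultError
from bspmaf.reconstruct import (
    _sequential_select_naive,
    abse,
    nrmse,
    pca_error,
    pca_reconstruct,
    pinv_fit,
    sequential_select,
    subset_error_profile,
    subset_reconstruct,
)
from bspmaf.synthetic import SynthConfig, generate_aa_segment
from bspmaf.types import ElectrodeSubset


def brute_force_best(x, k):
    """Exhaustive column-subset search: minimal residual over all C(n, k) sets."""
    n = x.shape[1]
    best_err, best_set = np.inf, None
    for combo in itertools.combinations(range(n), k):
        s = x[:, list(combo)]
        resid = x - s @ (np.linalg.pinv(s) @ x)
        err = np.linalg.norm(resid)
        if err < best_err:
            best_err, best_set = err, combo
    return best_err, best_set


class TestNrmse:
    def test_perfect_reconstruction_is_zero(self, rng):
        x = rng.standard_normal((10, 4))
        assert nrmse(x, x) == 0.0

    def test_zero_reconstruction_is_one(self, rng):
        x = rng.standard_normal((10, 4))
        assert nrmse(x, np.zeros_like(x)) == pytest.approx(1.0)

    def test_identity_with_single_column_reconstruction(self):
        # X = I2, X_hat keeps only the first coordinate: error 1/sqrt(2)
        x = np.eye(2)
        x_hat = np.array([[1.0, 0.0], [0.0, 0.0]])
        assert nrmse(x, x_hat) == pytest.approx(1 / np.sqrt(2))

    def test_zero_norm_matrix_undefined(self):
        with pytest.raises(UndefinedResultError):
            nrmse(np.zeros((3, 3)), np.zeros((3, 3)))

    def test_shape_mismatch(self):
        with pytest.raises(DimensionError):
            nrmse(np.zeros((3, 3)), np.zeros((3, 2)))


class TestPinvFit:
    def test_identity_single_column_closed_form(self):
        # S = first column of I2 -> A = [1, 0], X_hat = diag(1, 0)
        x = np.eye(2)
        a = pinv_fit(x, [0])
        np.testing.assert_allclose(a, [[1.0, 0.0]], atol=1e-12)
        x_hat = x[:, [0]] @ a
        np.testing.assert_allclose(x_hat, [[1, 0], [0, 0]], atol=1e-12)
        assert nrmse(x, x_hat) == pytest.approx(1 / np.sqrt(2))

    def test_residual_orthogonal_to_subset_columns(self, rng):
        x = rng.standard_normal((30, 8))
        idx = [0, 3, 5]
        a = pinv_fit(x, idx)
        resid = x - x[:, idx] @ a
        scale = np.abs(x[:, idx]).max() * np.abs(resid).max() + 1e-30
        assert np.abs(x[:, idx].T @ resid).max() / scale < 1e-8

    def test_exact_representability(self, rng):
        b = rng.standard_normal((3, 8))
        s = rng.standard_normal((30, 3))
        x = np.zeros((30, 9))
        x[:, :8] = s @ b
        x[:, 8] = s[:, 0]
        idx = [8, 0, 1]  # columns spanning the same 3-D space
        x[:, idx[1]] = s[:, 1]
        x[:, idx[2]] = s[:, 2]
        a = pinv_fit(x, idx)
        assert np.linalg.norm(x - x[:, idx] @ a) < 1e-9

    def test_orthonormal_subset_gives_transpose_fit(self, rng):
        q, _ = np.linalg.qr(rng.standard_normal((20, 3)))
        x = np.zeros((20, 5))
        x[:, :3] = q
        x[:, 3:] = rng.standard_normal((20, 2))
        a = pinv_fit(x, [0, 1, 2])
        np.testing.assert_allclose(a, q.T @ x, atol=1e-9)

    def test_rank_deficient_subset_warns(self, rng):
        x = rng.standard_normal((20, 5))
        x[:, 1] = x[:, 0]
        with pytest.warns(RuntimeWarning, match="rank-deficient"):
            pinv_fit(x, [0, 1])


class TestPcaReconstruct:
    def test_diagonal_closed_form(self):
        x = np.diag([3.0, 2.0, 1.0])
        res = pca_reconstruct(x, 2)
        assert np.linalg.norm(x - res.x_hat) == pytest.approx(1.0)
        assert res.nrmse == pytest.approx(1 / np.sqrt(14))

    def test_full_rank_reconstruction_exact(self, rng):
        x = rng.standard_normal((10, 4))
        assert pca_reconstruct(x, 4).nrmse < 1e-9

    def test_rank_one_matrix_recovered_at_k1(self, rng):
        x = np.outer(rng.standard_normal(10), rng.standard_normal(4))
        assert pca_reconstruct(x, 1).nrmse < 1e-9

    def test_error_equals_discarded_singular_values(self, rng):
        x = rng.standard_normal((40, 12))
        s = np.linalg.svd(x, compute_uv=False)  # independent routine
        for k in (1, 5, 11):
            expected = np.sqrt(np.sum(s[k:] ** 2)) / np.linalg.norm(x)
            assert pca_reconstruct(x, k).nrmse == pytest.approx(expected, rel=1e-9)
            assert pca_error(x, k) == pytest.approx(
                np.sqrt(np.sum(s[k:] ** 2)), rel=1e-9, abs=1e-9
            )

    def test_k_out_of_range(self, rng):
        with pytest.raises(ConfigError):
            pca_reconstruct(rng.standard_normal((5, 3)), 4)


class TestSequentialSelect:
    def test_step1_matches_exhaustive_best_column(self, rng):
        for _ in range(100):
            x = rng.standard_normal((20, 6))
            _, best = brute_force_best(x, 1)
            sub = sequential_select(x, 1)
            assert sub.lead_indices == best

    def test_greedy_pair_never_beats_exhaustive_optimum(self, rng):
        for _ in range(50):
            x = rng.standard_normal((20, 6))
            best_err, _ = brute_force_best(x, 2)
            sub = sequential_select(x, 2)
            greedy_err = np.linalg.norm(
                x - x[:, list(sub.lead_indices)] @ sub.mixing
            )
            assert greedy_err >= best_err - 1e-9 * max(best_err, 1.0)

    def test_fast_path_equals_naive_refit(self, rng):
        for _ in range(20):
            x = rng.standard_normal((30, 10))
            fast = list(sequential_select(x, 5).lead_indices)
            assert fast == _sequential_select_naive(x, 5)

    def test_duplicated_column_never_selected_after_twin(self, rng):
        x = rng.standard_normal((20, 6))
        x[:, 4] = x[:, 1]
        sub = sequential_select(x, 4)
        chosen = sub.lead_indices
        assert not (1 in chosen and 4 in chosen)

    def test_selection_is_deterministic(self, rng):
        x = rng.standard_normal((50, 12))
        assert sequential_select(x, 6).lead_indices == sequential_select(x, 6).lead_indices

    def test_k_must_be_below_n(self, rng):
        with pytest.raises(ConfigError):
            sequential_select(rng.standard_normal((10, 4)), 4)


class TestSubsetReconstruct:
    def test_anchor_window_fit_and_apply_is_least_squares(self, rng):
        x = rng.standard_normal((40, 8))
        sub = sequential_select(x, 3)
        res = subset_reconstruct(x, sub)
        # residual must match the direct least-squares residual on the anchor
        direct = x - x[:, list(sub.lead_indices)] @ pinv_fit(x, sub.lead_indices)
        assert res.nrmse == pytest.approx(np.linalg.norm(direct) / np.linalg.norm(x))

    def test_lead_permutation_invariance(self, rng):
        x = rng.standard_normal((40, 8))
        idx = [1, 6, 3]
        sub = ElectrodeSubset(lead_indices=tuple(idx), kind="SEQ",
                              mixing=pinv_fit(x, idx))
        perm = rng.permutation(8)
        xp = x[:, perm]
        # map subset indices and the mixing's columns through the permutation
        inv = np.argsort(perm)
        idx_p = [int(inv[i]) for i in idx]
        sub_p = ElectrodeSubset(lead_indices=tuple(idx_p), kind="SEQ",
                                mixing=pinv_fit(xp, idx_p))
        assert subset_reconstruct(x, sub).nrmse == pytest.approx(
            subset_reconstruct(xp, sub_p).nrmse, rel=1e-9
        )

    def test_eckart_young_lower_bound(self, rng):
        for _ in range(20):
            x = rng.standard_normal((30, 10))
            k = int(rng.integers(1, 6))
            sub = sequential_select(x, k)
            sub_err = subset_reconstruct(x, sub).nrmse
            assert sub_err >= pca_reconstruct(x, k).nrmse - 1e-9


class TestAbse:
    FS = 1000.0

    def _tones(self, freqs, dur=5.0):
        t = np.arange(int(dur * self.FS)) / self.FS
        return np.column_stack([np.sin(2 * np.pi * f * t) for f in freqs])

    def test_identical_matrices_give_zero(self):
        x = self._tones([5.0, 7.0])
        assert abse(x, x, self.FS) == 0.0

    def test_two_lead_df_arithmetic(self):
        # on-grid DFs so the half-Hz lead difference is exact: bin = fs/4096
        b = self.FS / 4096
        x = self._tones([20 * b, 29 * b])
        x_hat = self._tones([20 * b, 33 * b])  # lead DFs differ by 0, 4 bins
        assert abse(x, x_hat, self.FS) == pytest.approx(2 * b)

    def test_amplitude_rescaling_invariance(self):
        x = self._tones([5.0, 7.0])
        assert abse(x, 3 * x, self.FS) == 0.0

    def test_undefined_leads_excluded_and_counted(self):
        x = np.column_stack([self._tones([6.0]), np.zeros(5000)])
        x_hat = np.column_stack([self._tones([6.5]), np.zeros(5000)])
        value, n_excl = abse(x, x_hat, self.FS, return_excluded=True)
        assert n_excl == 1
        assert value > 0

    def test_all_leads_undefined_raises(self):
        z = np.zeros((5000, 2))
        with pytest.raises(UndefinedResultError):
            abse(z, z, self.FS)


@pytest.fixture(scope="module")
def segment():
    return generate_aa_segment(SynthConfig(n_leads=56, duration_s=15.0, seed=7))


class TestErrorProfile:

    def test_pca_nrmse_nonincreasing_in_k(self, segment):
        table = subset_error_profile(segment, kinds=("PCA",), k_range=(2, 8),
                                     compute_abse=False)
        errs = table.sort_values("k")["nrmse"].to_numpy()
        assert np.all(np.diff(errs) <= 1e-12)

    def test_seq_at_least_pca_for_every_k(self, segment):
        table = subset_error_profile(segment, kinds=("SEQ", "PCA"), k_range=(2, 8),
                                     compute_abse=False)
        piv = table.pivot_table(index="k", columns="kind", values="nrmse")
        assert np.all(piv["SEQ"] >= piv["PCA"] - 1e-12)

    def test_anchored_seq_nonincreasing_on_fitting_window(self, segment):
        x = segment.window(0)
        errs = [subset_reconstruct(x, sequential_select(x, k)).nrmse
                for k in range(2, 9)]
        assert np.all(np.diff(errs) <= 1e-12)

    def test_ecg_profile_requires_leads(self, segment):
        with pytest.raises(ConfigError):
            subset_error_profile(segment, kinds=("ECG8",), compute_abse=False)


def test_subset_quality_ordering_over_seeded_segments():
    """Fixed ECG analogues < greedy selection < rank-k optimum, on average."""
    from bspmaf.geometry import grid_geometry
    from bspmaf.reconstruct import pinv_fit

    geo = grid_geometry(4, 7)
    ecg_err, seq_err, pca_err = [], [], []
    for seed in range(20):
        seg = generate_aa_segment(
            SynthConfig(n_leads=56, duration_s=10.0, seed=800 + seed)
        )
        for xw in seg.windows():
            leads = list(geo.ecg8_leads)
            ecg_err.append(
                np.linalg.norm(xw - xw[:, leads] @ pinv_fit(xw, leads))
                / np.linalg.norm(xw)
            )
            seq_err.append(subset_reconstruct(xw, sequential_select(xw, 8)).nrmse)
            pca_err.append(pca_reconstruct(xw, 8).nrmse)
    assert np.mean(ecg_err) > np.mean(seq_err) > np.mean(pca_err)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000), st.integers(min_value=1, max_value=5))
def test_subset_error_dominates_pca_error_property(seed, k):
    """Eckart–Young: no k-lead subset beats the rank-k SVD truncation."""
    x = np.random.default_rng(seed).standard_normal((25, 8))
    sub = sequential_select(x, k)
    assert subset_reconstruct(x, sub).nrmse >= pca_reconstruct(x, k).nrmse - 1e-9
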