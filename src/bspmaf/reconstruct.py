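"""Subset- and PCA-based reconstruction of the full lead set.

Given an atrial-activity window ``X`` (m samples x n leads) and a subset
``S = X[:, idx]`` of k lead signals, the least-squares reconstruction of all
leads from the subset is ``X_hat = S A`` with ``A = S^+ X`` (Moore–Penrose
pseudoinverse).  The optimal rank-k reconstruction — the lower bound on any
k-lead subset's error, by the Eckart–Young theorem — is the truncated SVD
``X_k = U_k S_k V_k^T``.  Errors are measured as NRMSE (Frobenius-relative)
and ABSE (mean absolute per-lead dominant-frequency difference, in Hz).

Subset selection is greedy: electrodes are added one at a time, each step
picking the column that most reduces the Frobenius reconstruction error given
the columns already chosen (exact column-subset selection is NP-hard).  The
inner loop runs on the Gram matrix with incremental orthogonalization, which
is algebraically identical to refitting the pseudoinverse from scratch at
each step (the equivalence is asserted in the test suite).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DimensionError, UndefinedResultError
from .spectral import SpectralConfig, df_map
from .types import AASegment, ElectrodeSubset

__all__ = [
    "ReconResult",
    "pinv_fit",
    "subset_reconstruct",
    "pca_reconstruct",
    "sequential_select",
    "nrmse",
    "abse",
    "subset_error_profile",
]

# singular values below this fraction of the largest are treated as zero
RANK_RTOL = 1e-10


@dataclass
class ReconResult:
    """A reconstructed matrix with its error measures."""

    x_hat: np.ndarray
    basis: str  # e.g. "subset(k=8)" or "pca(k=8)"
    nrmse: float
    abse: Optional[float] = None

    def __post_init__(self) -> None:
        if self.nrmse < 0:
            raise ConfigError("nrmse must be nonnegative")


def nrmse(x: np.ndarray, x_hat: np.ndarray) -> float:
    """Normalized root-mean-square reconstruction error ||X - X^||_F / ||X||_F."""
    x = np.asarray(x, dtype=float)
    x_hat = np.asarray(x_hat, dtype=float)
    if x.shape != x_hat.shape:
        raise DimensionError(f"shape mismatch {x.shape} vs {x_hat.shape}")
    denom = np.linalg.norm(x)
    if denom == 0:
        raise UndefinedResultError("NRMSE is undefined for a zero-norm matrix")
    return float(np.linalg.norm(x - x_hat) / denom)


def abse(
    x: np.ndarray,
    x_hat: np.ndarray,
    fs: float,
    cfg: Optional[SpectralConfig] = None,
    return_excluded: bool = False,
):
    """Mean absolute per-lead DF difference between X and its reconstruction (Hz).

    Leads whose DF is undefined on either matrix are excluded from the mean
    and counted; if all leads are undefined the measure itself is undefined.
    """
    x = np.asarray(x, dtype=float)
    x_hat = np.asarray(x_hat, dtype=float)
    if x.shape != x_hat.shape:
        raise DimensionError(f"shape mismatch {x.shape} vs {x_hat.shape}")
    d1 = df_map(x, fs, cfg)
    d2 = df_map(x_hat, fs, cfg)
    valid = ~(np.isnan(d1) | np.isnan(d2))
    n_excluded = int((~valid).sum())
    if not valid.any():
        raise UndefinedResultError("ABSE undefined: DF undefined on every lead")
    value = float(np.mean(np.abs(d1[valid] - d2[valid])))
    return (value, n_excluded) if return_excluded else value


def pinv_fit(x: np.ndarray, subset_indices: Sequence[int]) -> np.ndarray:
    """Least-squares mixing ``A = S^+ X`` (k x n) for ``S = X[:, idx]``.

    The residual ``X - S A`` is orthogonal to the column space of ``S``.  A
    rank-deficient subset yields the minimum-norm solution with a warning.
    """
    x = np.asarray(x, dtype=float)
    idx = np.asarray(subset_indices, dtype=int)
    m, n = x.shape
    k = idx.size
    if k >= n:
        raise ConfigError(f"subset size k={k} must be smaller than n={n} leads")
    if m < k:
        raise ConfigError(f"need at least k={k} samples, got m={m}")
    s = x[:, idx]
    rank = np.linalg.matrix_rank(s, tol=None)
    if rank < k:
        warnings.warn(
            f"subset matrix is rank-deficient (rank {rank} < k={k}); "
            "returning the minimum-norm least-squares solution",
            RuntimeWarning,
            stacklevel=2,
        )
    return np.linalg.pinv(s, rcond=RANK_RTOL) @ x


def subset_reconstruct(
    x_i: np.ndarray,
    subset: ElectrodeSubset,
    fs: Optional[float] = None,
    spectral_cfg: Optional[SpectralConfig] = None,
) -> ReconResult:
    """Reconstruct a window from its own subset samples and the anchored mixing.

    ``X_hat = X_i[:, idx] @ A`` where ``A`` was fitted on the subset's anchor
    window.  ABSE is computed only when ``fs`` is provided.
    """
    x_i = np.asarray(x_i, dtype=float)
    if subset.mixing is None:
        raise ConfigError("subset.mixing has not been fitted (call pinv_fit first)")
    if x_i.ndim != 2 or x_i.shape[1] != subset.mixing.shape[1]:
        raise DimensionError(
            f"window has shape {x_i.shape}; expected (m, {subset.mixing.shape[1]})"
        )
    x_hat = x_i[:, list(subset.lead_indices)] @ subset.mixing
    err = nrmse(x_i, x_hat)
    ab = abse(x_i, x_hat, fs, spectral_cfg) if fs is not None else None
    return ReconResult(x_hat=x_hat, basis=f"subset(k={subset.k})", nrmse=err, abse=ab)


def pca_reconstruct(
    x: np.ndarray,
    k: int,
    fs: Optional[float] = None,
    spectral_cfg: Optional[SpectralConfig] = None,
) -> ReconResult:
    """Best rank-k approximation ``X_k = U_k S_k V_k^T`` (uncentered SVD).

    The Frobenius error equals the root-sum-square of the discarded singular
    values.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise DimensionError("pca_reconstruct expects a 2-D matrix")
    if not 1 <= k <= min(x.shape):
        raise ConfigError(f"rank k={k} out of range [1, {min(x.shape)}]")
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    x_k = (u[:, :k] * s[:k]) @ vt[:k]
    denom = np.linalg.norm(x)
    if denom == 0:
        raise UndefinedResultError("NRMSE is undefined for a zero-norm matrix")
    err = float(np.sqrt(np.sum(s[k:] ** 2)) / denom)
    ab = abse(x, x_k, fs, spectral_cfg) if fs is not None else None
    return ReconResult(x_hat=x_k, basis=f"pca(k={k})", nrmse=err, abse=ab)


def pca_error(x: np.ndarray, k: int) -> float:
    """Frobenius norm ||X - X_k||_F without forming X_k.

    Computed from the eigenvalues of the (n x n) Gram matrix — the squared
    singular values — which is cheaper than a full SVD for tall windows.
    """
    x = np.asarray(x, dtype=float)
    evals = np.linalg.eigvalsh(x.T @ x)[::-1]
    evals = np.clip(evals, 0.0, None)
    return float(np.sqrt(evals[k:].sum()))


def sequential_select(
    x: np.ndarray,
    k: int,
    kind: str = "SEQ",
    anchor_window: int = 0,
) -> ElectrodeSubset:
    """Greedy sequential electrode selection on a window matrix.

    At each step the column minimizing the residual Frobenius error given the
    already-selected columns is added; ties break toward the lowest lead
    index.  The returned subset carries the mixing ``A = S^+ X`` fitted on
    ``x`` itself.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise DimensionError("sequential_select expects a 2-D matrix")
    m, n = x.shape
    if not 1 <= k < n:
        raise ConfigError(f"subset size k={k} must satisfy 1 <= k < n={n}")

    g = x.T @ x  # Gram matrix; all scoring happens in lead space
    diag = np.diag(g).copy()
    gmax = diag.max()
    if gmax == 0:
        raise UndefinedResultError("cannot select electrodes from an all-zero matrix")

    selected: list[int] = []
    w = np.zeros((n, 0))  # W = X^T Q for the orthonormal basis Q of selected columns
    for _ in range(k):
        resid_diag = diag - np.einsum("ij,ij->i", w, w)  # ||c_perp||^2 per candidate
        proj = g - w @ w.T  # column j = X^T c_perp_j
        gains = np.einsum("ij,ij->j", proj, proj)
        denom = resid_diag.copy()
        dead = (denom <= RANK_RTOL * gmax)
        scores = np.where(dead, -np.inf, gains / np.where(dead, 1.0, denom))
        scores[selected] = -np.inf
        j = int(np.argmax(scores))
        if not np.isfinite(scores[j]):
            # remaining candidates add no span (duplicates / rank exhausted):
            # fall back to the lowest-index unselected lead, deterministically
            warnings.warn(
                "greedy selection exhausted the column space before reaching k; "
                "padding with lowest-index unselected leads",
                RuntimeWarning,
                stacklevel=2,
            )
            j = int(next(i for i in range(n) if i not in selected))
            selected.append(j)
            continue
        selected.append(j)
        w_new = proj[:, j] / np.sqrt(denom[j])
        w = np.column_stack([w, w_new])

    mixing = pinv_fit(x, selected)
    return ElectrodeSubset(
        lead_indices=tuple(selected),
        kind=kind,
        mixing=mixing,
        anchor_window=anchor_window,
        n_leads=n,
    )


def _sequential_select_naive(x: np.ndarray, k: int) -> list[int]:
    """Reference greedy selector that refits the pseudoinverse at every step.

    O(k * n * pinv); used in tests as the oracle for the fast implementation.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[1]
    selected: list[int] = []
    for _ in range(k):
        best_j, best_err = None, np.inf
        for j in range(n):
            if j in selected:
                continue
            idx = selected + [j]
            s = x[:, idx]
            resid = x - s @ (np.linalg.pinv(s, rcond=RANK_RTOL) @ x)
            err = np.linalg.norm(resid)
            if best_j is None or err < best_err - 1e-12 * max(best_err, 1.0):
                best_j, best_err = j, err
        selected.append(best_j)
    return selected


def subset_error_profile(
    segment: AASegment,
    kinds: Sequence[str] = ("SEQ", "ECG8", "ECG11", "PCA"),
    k_range: tuple[int, int] = (8, 30),
    ecg8_leads: Optional[Sequence[int]] = None,
    ecg11_leads: Optional[Sequence[int]] = None,
    mode: str = "per_window",
    compute_abse: bool = True,
    spectral_cfg: Optional[SpectralConfig] = None,
) -> pd.DataFrame:
    """Window-averaged NRMSE/ABSE per subset kind and size.

    For SEQ/ECG kinds the subset is fitted and applied within each window
    (``mode="per_window"``, the survey protocol) or selected/fitted on the
    first window and applied to the rest (``mode="anchored"``, the index
    protocol); PCA rows always use the window's own rank-k truncation.
    """
    if mode not in ("per_window", "anchored"):
        raise ConfigError("mode must be 'per_window' or 'anchored'")
    segment.require_windows(2)
    lo, hi = k_range
    if not 1 <= lo <= hi < segment.n_leads:
        raise ConfigError(f"k_range {k_range} out of range for {segment.n_leads} leads")
    fs = segment.fs if compute_abse else None

    tasks: list[tuple[str, int, Optional[list[int]]]] = []
    for kind in kinds:
        if kind == "SEQ":
            tasks += [("SEQ", kk, None) for kk in range(lo, hi + 1)]
        elif kind == "PCA":
            tasks += [("PCA", kk, None) for kk in range(lo, hi + 1)]
        elif kind == "ECG8":
            if ecg8_leads is None:
                raise ConfigError("ECG8 profile requires ecg8_leads")
            tasks.append(("ECG8", 8, list(ecg8_leads)))
        elif kind == "ECG11":
            if ecg11_leads is None:
                raise ConfigError("ECG11 profile requires ecg11_leads")
            tasks.append(("ECG11", 11, list(ecg11_leads)))
        else:
            raise ConfigError(f"unknown subset kind {kind!r}")

    windows = list(segment.windows())
    rows = []
    for kind, kk, leads in tasks:
        errs, abses = [], []
        anchored_subset: Optional[ElectrodeSubset] = None
        if mode == "anchored":
            if kind == "SEQ":
                anchored_subset = sequential_select(windows[0], kk)
            elif kind in ("ECG8", "ECG11"):
                anchored_subset = ElectrodeSubset(
                    lead_indices=tuple(leads), kind=kind,
                    mixing=pinv_fit(windows[0], leads), anchor_window=0,
                )
        for wi, xw in enumerate(windows):
            if kind == "PCA":
                res = pca_reconstruct(xw, kk, fs=fs, spectral_cfg=spectral_cfg)
            elif mode == "anchored":
                if wi == 0:
                    continue
                res = subset_reconstruct(xw, anchored_subset, fs=fs,
                                         spectral_cfg=spectral_cfg)
            else:
                if kind == "SEQ":
                    sub = sequential_select(xw, kk)
                else:
                    sub = ElectrodeSubset(
                        lead_indices=tuple(leads), kind=kind,
                        mixing=pinv_fit(xw, leads),
                    )
                res = subset_reconstruct(xw, sub, fs=fs, spectral_cfg=spectral_cfg)
            errs.append(res.nrmse)
            if res.abse is not None:
                abses.append(res.abse)
        rows.append(
            {
                "kind": kind,
                "k": kk,
                "nrmse": float(np.mean(errs)),
                "abse": float(np.mean(abses)) if abses else np.nan,
                "n_windows": len(errs),
            }
        )
    return pd.DataFrame(rows, columns=["kind", "k", "nrmse", "abse", "n_windows"])
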