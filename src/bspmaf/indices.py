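"""Segment-level spatiotemporal indices: ER_NRMSE, ER_ABSE and NDI.

A 1-min atrial-activity segment is divided into contiguous non-overlapping
5-s windows.  The electrode subset (greedy SEQ, or the fixed ECG analogues)
and its mixing matrix A^1 are fitted on the *first* window only; every later
window i is reconstructed from its own subset samples through that anchored
A^1 and compared with the window's own optimal rank-k PCA truncation:

    ER_NRMSE^i = ||X^i - X_hat^i||_F / ||X^i - X_k^i||_F
    ER_ABSE^i  = sum_l |DF(X^i_l) - DF(X_hat^i_l)| / sum_l |DF(X^i_l) - DF(X_k^i_l)|

averaged over windows 2..W for one value per segment.  Because the rank-k
truncation is Frobenius-optimal (Eckart–Young) and the anchored subset
reconstruction has rank <= k, ER_NRMSE >= 1 always; values close to 1 mean
the anchor-window subset representation stays near-optimal over time, i.e.
spatiotemporally stable (organized) fibrillation.

NDI (non-dipolar component index) is the per-window fraction of variance not
captured by the first three principal components of the column-centered
window, averaged over all windows; it is subset-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import ConfigError, UndefinedResultError
from .geometry import VestGeometry
from .reconstruct import pca_error, pinv_fit, sequential_select
from .spectral import SpectralConfig, df_map
from .types import AASegment, ElectrodeSubset, SegmentIndices

__all__ = [
    "IndexConfig",
    "er_nrmse_segment",
    "er_abse_segment",
    "er_abse_window",
    "ndi_segment",
    "compute_all",
]

_KIND_TABLE = {
    "SEQ8": ("SEQ", 8),
    "SEQ11": ("SEQ", 11),
    "ECG8": ("ECG8", 8),
    "ECG11": ("ECG11", 11),
}


@dataclass
class IndexConfig:
    """Settings for segment-index computation."""

    window_len_s: float = 5.0
    subset_kinds: tuple[str, ...] = ("SEQ8", "SEQ11", "ECG8", "ECG11")
    ndi_components: int = 3
    seq_k_range: tuple[int, int] = (8, 30)
    compute_abse: bool = True
    spectral: SpectralConfig = field(default_factory=SpectralConfig)

    def __post_init__(self) -> None:
        if self.window_len_s <= 0:
            raise ConfigError("window_len_s must be positive")
        if self.ndi_components < 1:
            raise ConfigError("ndi_components must be >= 1")
        for kind in self.subset_kinds:
            self.parse_kind(kind)

    @staticmethod
    def parse_kind(kind: str) -> tuple[str, int]:
        """``"SEQ8" -> ("SEQ", 8)``; also accepts ``"SEQ<k>"`` for any k."""
        if kind in _KIND_TABLE:
            return _KIND_TABLE[kind]
        if kind.startswith("SEQ") and kind[3:].isdigit():
            return ("SEQ", int(kind[3:]))
        raise ConfigError(f"unknown subset kind {kind!r}")


def _resolve_subset(
    anchor: np.ndarray,
    kind: str,
    k: int,
    geometry: Optional[VestGeometry],
) -> ElectrodeSubset:
    """Select/fit the anchored subset on the first window."""
    if kind == "SEQ":
        return sequential_select(anchor, k)
    if geometry is None:
        raise ConfigError(f"{kind} subsets require a VestGeometry")
    leads = geometry.ecg8_leads if kind == "ECG8" else geometry.ecg11_leads
    return ElectrodeSubset(
        lead_indices=leads, kind=kind, mixing=pinv_fit(anchor, leads), anchor_window=0
    )


def er_nrmse_segment(
    segment: AASegment,
    subset_kind: str = "SEQ8",
    geometry: Optional[VestGeometry] = None,
    cfg: Optional[IndexConfig] = None,
    _subset: Optional[ElectrodeSubset] = None,
) -> SegmentIndices:
    """Anchored-subset vs same-window-PCA Frobenius error ratio, window-averaged."""
    cfg = cfg or IndexConfig()
    kind, k = IndexConfig.parse_kind(subset_kind)
    segment.require_windows(2)
    windows = list(segment.windows())
    subset = _subset or _resolve_subset(windows[0], kind, k, geometry)
    sel = list(subset.lead_indices)

    ratios = []
    for xw in windows[1:]:
        num = np.linalg.norm(xw - xw[:, sel] @ subset.mixing)
        den = pca_error(xw, k)
        if den < 1e-12:
            continue  # exactly low-rank window: ratio undefined, excluded
        ratios.append(num / den)
    if not ratios:
        raise UndefinedResultError(
            "ER_NRMSE undefined: every window had a vanishing PCA denominator"
        )
    return SegmentIndices(subset_kind=subset_kind, k=k, er_nrmse=float(np.mean(ratios)))


def er_abse_window(
    x: np.ndarray,
    x_hat: np.ndarray,
    x_k: np.ndarray,
    fs: float,
    spectral_cfg: Optional[SpectralConfig] = None,
) -> float:
    """Single-window DF error ratio with the zero-denominator policy.

    Leads with an undefined DF on any of the three matrices are dropped from
    both sums.  A zero denominator with zero numerator yields 1 (both
    reconstructions DF-perfect); a zero denominator with nonzero numerator is
    undefined (NaN), and window-level aggregation excludes it.
    """
    d0 = df_map(x, fs, spectral_cfg)
    dh = df_map(x_hat, fs, spectral_cfg)
    dk = df_map(x_k, fs, spectral_cfg)
    valid = ~(np.isnan(d0) | np.isnan(dh) | np.isnan(dk))
    if not valid.any():
        return float("nan")
    num = float(np.sum(np.abs(d0[valid] - dh[valid])))
    den = float(np.sum(np.abs(d0[valid] - dk[valid])))
    if den == 0:
        return 1.0 if num == 0 else float("nan")
    return num / den


def er_abse_segment(
    segment: AASegment,
    subset_kind: str = "SEQ8",
    geometry: Optional[VestGeometry] = None,
    cfg: Optional[IndexConfig] = None,
    _subset: Optional[ElectrodeSubset] = None,
) -> SegmentIndices:
    """Anchored-subset vs same-window-PCA DF error ratio, window-averaged.

    Windows with an undefined ratio are excluded; if every window is
    excluded the segment index is reported as absent (None).
    """
    cfg = cfg or IndexConfig()
    kind, k = IndexConfig.parse_kind(subset_kind)
    segment.require_windows(2)
    windows = list(segment.windows())
    subset = _subset or _resolve_subset(windows[0], kind, k, geometry)
    sel = list(subset.lead_indices)

    ratios = []
    for xw in windows[1:]:
        x_hat = xw[:, sel] @ subset.mixing
        u, s, vt = np.linalg.svd(xw, full_matrices=False)
        x_k = (u[:, :k] * s[:k]) @ vt[:k]
        r = er_abse_window(xw, x_hat, x_k, segment.fs, cfg.spectral)
        if np.isfinite(r):
            ratios.append(r)
    value = float(np.mean(ratios)) if ratios else None
    return SegmentIndices(subset_kind=subset_kind, k=k, er_abse=value)


def ndi_segment(segment: AASegment, cfg: Optional[IndexConfig] = None) -> float:
    """Mean over windows of the residual variance beyond the first 3 PCs.

    Windows are column-centered before the SVD (variance semantics);
    zero-energy windows are excluded.
    """
    cfg = cfg or IndexConfig()
    p = cfg.ndi_components
    segment.require_windows(1)
    vals = []
    for xw in segment.windows():
        xc = xw - xw.mean(axis=0)
        evals = np.clip(np.linalg.eigvalsh(xc.T @ xc)[::-1], 0.0, None)
        total = evals.sum()
        if total < 1e-24:
            continue
        vals.append(1.0 - evals[:p].sum() / total)
    if not vals:
        raise UndefinedResultError("NDI undefined: every window has zero energy")
    return float(np.clip(np.mean(vals), 0.0, 1.0))


def compute_all(
    segment: AASegment,
    geometry: Optional[VestGeometry] = None,
    cfg: Optional[IndexConfig] = None,
    patient_id: str = "",
    segment_id: str = "",
    outcome: str = "UNKNOWN",
) -> list[SegmentIndices]:
    """All requested subset indices plus the shared, subset-independent NDI.

    Returns one row per subset kind; every row carries the same NDI value.
    """
    cfg = cfg or IndexConfig()
    segment.require_windows(2)
    ndi = ndi_segment(segment, cfg)
    rows = []
    for kind_name in cfg.subset_kinds:
        kind, k = IndexConfig.parse_kind(kind_name)
        subset = _resolve_subset(segment.window(0), kind, k, geometry)
        row_nrmse = er_nrmse_segment(segment, kind_name, geometry, cfg, _subset=subset)
        er_ab = None
        if cfg.compute_abse:
            er_ab = er_abse_segment(segment, kind_name, geometry, cfg, _subset=subset).er_abse
        rows.append(
            SegmentIndices(
                subset_kind=kind_name,
                k=k,
                er_nrmse=row_nrmse.er_nrmse,
                er_abse=er_ab,
                ndi=ndi,
                patient_id=patient_id,
                segment_id=segment_id,
                outcome=outcome,
            )
        )
    return rows
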