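"""Domain containers for multichannel body-surface signals and results.

Conventions
-----------
* Signal matrices are ``(m samples, n leads)`` float arrays; column ``l`` is
  vest lead ``l`` (0-based internally, 1-based in files and reports).
* ``fs`` is the sampling rate in Hz.
* Outcome labels are ``"SR"`` (sinus rhythm maintained), ``"AR"`` (arrhythmia
  recurrence) or ``"UNKNOWN"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import ConfigError, DimensionError, InsufficientDataError
from .geometry import VestGeometry

__all__ = [
    "BspmRecording",
    "AASegment",
    "BeatSet",
    "ElectrodeSubset",
    "WindowMetrics",
    "SegmentIndices",
    "CvReport",
    "OUTCOMES",
    "SUBSET_KINDS",
]

OUTCOMES = ("SR", "AR", "UNKNOWN")
SUBSET_KINDS = ("SEQ", "ECG8", "ECG11")


def _as_matrix(samples) -> np.ndarray:
    x = np.asarray(samples, dtype=float)
    if x.ndim != 2:
        raise DimensionError(f"signal matrix must be 2-D (samples x leads), got {x.ndim}-D")
    return x


@dataclass
class BspmRecording:
    """A raw multichannel recording plus metadata.

    Parameters
    ----------
    samples
        ``(m, n)`` matrix of lead voltages.
    fs
        Sampling rate in Hz (1000 for the canonical vest).
    geometry
        Vest layout; ``n`` must equal ``geometry.n_leads``.
    lead_quality
        Per-lead boolean flags, True = good. Defaults to all-good.
    annotations
        Optional dict; recognised keys are ``"r_peaks"`` (sample indices) and
        ``"qrst_windows"`` (per-beat ``(onset, offset)`` pairs).
    """

    samples: np.ndarray
    fs: float
    geometry: VestGeometry
    lead_quality: Optional[np.ndarray] = None
    annotations: Optional[dict] = None

    def __post_init__(self) -> None:
        self.samples = _as_matrix(self.samples)
        m, n = self.samples.shape
        if m < 1:
            raise DimensionError("recording must contain at least one sample")
        if n != self.geometry.n_leads:
            raise DimensionError(
                f"recording has {n} leads but geometry declares {self.geometry.n_leads}"
            )
        if self.fs <= 0:
            raise ConfigError("sampling rate must be positive")
        if self.lead_quality is None:
            self.lead_quality = np.ones(n, dtype=bool)
        else:
            self.lead_quality = np.asarray(self.lead_quality, dtype=bool)
            if self.lead_quality.shape != (n,):
                raise DimensionError("lead_quality must have one flag per lead")
        if self.annotations:
            for key in ("r_peaks",):
                idx = np.asarray(self.annotations.get(key, []), dtype=int)
                if idx.size and (idx.min() < 0 or idx.max() >= m):
                    raise DimensionError(f"annotation '{key}' has indices outside [0, {m})")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_leads(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, samples: np.ndarray) -> "BspmRecording":
        """New recording sharing metadata, with replaced sample matrix."""
        return BspmRecording(
            samples=samples,
            fs=self.fs,
            geometry=self.geometry,
            lead_quality=self.lead_quality.copy(),
            annotations=dict(self.annotations) if self.annotations else None,
        )


@dataclass
class AASegment:
    """Atrial-activity matrix after ventricular cancellation.

    Canonical segments are 1 min long and are analysed in contiguous
    non-overlapping 5-s windows; any duration of at least two windows is
    accepted. ``normalized`` marks per-lead zero-mean/unit-variance scaling.
    """

    samples: np.ndarray
    fs: float
    window_len_s: float = 5.0
    normalized: bool = False
    meta: Optional[dict] = None

    def __post_init__(self) -> None:
        self.samples = _as_matrix(self.samples)
        if self.fs <= 0:
            raise ConfigError("sampling rate must be positive")
        if self.window_len_s <= 0:
            raise ConfigError("window_len_s must be positive")
        if self.normalized:
            live = self.samples.std(axis=0) > 1e-12
            mu = self.samples[:, live].mean(axis=0)
            sd = self.samples[:, live].std(axis=0)
            if mu.size and (np.abs(mu).max() > 1e-6 or np.abs(sd - 1).max() > 1e-2):
                raise ConfigError(
                    "normalized=True but per-lead mean/std are not ~0/~1 "
                    f"(max|mean|={np.abs(mu).max():.2e}, max|std-1|={np.abs(sd - 1).max():.2e})"
                )

    @property
    def n_leads(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.samples.shape[0] / self.fs

    @property
    def window_samples(self) -> int:
        return int(round(self.window_len_s * self.fs))

    @property
    def n_windows(self) -> int:
        """Number of whole windows; a shorter tail is dropped."""
        return self.samples.shape[0] // self.window_samples

    def window(self, i: int) -> np.ndarray:
        """Sample matrix of window ``i`` (0-based)."""
        w = self.window_samples
        if not 0 <= i < self.n_windows:
            raise IndexError(f"window {i} out of range [0, {self.n_windows})")
        return self.samples[i * w : (i + 1) * w]

    def windows(self):
        """Iterate over whole windows in temporal order."""
        for i in range(self.n_windows):
            yield self.window(i)

    def require_windows(self, k: int) -> None:
        if self.n_windows < k:
            raise InsufficientDataError(
                f"segment provides {self.n_windows} whole {self.window_len_s}-s windows; "
                f"{k} required"
            )


@dataclass
class BeatSet:
    """Detected beats: locations, per-beat QRST windows, cluster structure.

    ``templates`` maps cluster label -> per-lead ensemble-average QRST matrix
    of shape ``(window_samples, n_leads)``; ``template_start_offset`` is the
    sample offset of the template's first row relative to the R-peak
    (negative: template starts before the R-peak).
    """

    r_peaks: np.ndarray
    qrst_windows: np.ndarray  # (n_beats, 2) onset/offset sample pairs
    cluster_labels: np.ndarray
    templates: dict
    template_start_offset: int

    def __post_init__(self) -> None:
        self.r_peaks = np.asarray(self.r_peaks, dtype=int)
        self.qrst_windows = np.asarray(self.qrst_windows, dtype=int)
        self.cluster_labels = np.asarray(self.cluster_labels, dtype=int)
        nb = self.r_peaks.size
        if self.qrst_windows.shape != (nb, 2):
            raise DimensionError("qrst_windows must be (n_beats, 2)")
        if self.cluster_labels.shape != (nb,):
            raise DimensionError("every beat must carry a cluster label")
        if nb and np.any(np.diff(self.r_peaks) <= 0):
            raise DimensionError("r_peaks must be strictly increasing")
        if nb and np.any(self.qrst_windows[1:, 0] < self.qrst_windows[:-1, 1]):
            raise DimensionError("qrst_windows must be non-overlapping after trimming")
        missing = set(self.cluster_labels) - set(self.templates)
        if missing:
            raise DimensionError(f"no template for cluster labels {sorted(missing)}")

    @property
    def n_beats(self) -> int:
        return self.r_peaks.size


@dataclass
class ElectrodeSubset:
    """An ordered electrode subset and its anchor-window mixing matrix.

    ``mixing`` is the least-squares transform ``A`` (k x n) mapping subset
    signals to all leads, fitted on ``anchor_window``; reconstruction of a
    later window uses that window's subset samples with this anchored ``A``.
    """

    lead_indices: tuple[int, ...]
    kind: str
    mixing: Optional[np.ndarray] = None
    anchor_window: int = 0
    n_leads: Optional[int] = None

    def __post_init__(self) -> None:
        self.lead_indices = tuple(int(i) for i in self.lead_indices)
        k = len(self.lead_indices)
        if k < 1:
            raise ConfigError("electrode subset must contain at least one lead")
        if len(set(self.lead_indices)) != k:
            raise ConfigError("electrode subset contains duplicate leads")
        if self.kind not in SUBSET_KINDS:
            raise ConfigError(f"kind must be one of {SUBSET_KINDS}, got {self.kind!r}")
        if self.kind == "ECG8" and k != 8:
            raise ConfigError("ECG8 subsets contain exactly 8 leads")
        if self.kind == "ECG11" and k != 11:
            raise ConfigError("ECG11 subsets contain exactly 11 leads")
        if self.mixing is not None:
            self.mixing = np.asarray(self.mixing, dtype=float)
            if self.mixing.ndim != 2 or self.mixing.shape[0] != k:
                raise DimensionError(
                    f"mixing must be (k={k}, n_leads), got {self.mixing.shape}"
                )
            if self.n_leads is None:
                self.n_leads = self.mixing.shape[1]
            elif self.mixing.shape[1] != self.n_leads:
                raise DimensionError("mixing column count disagrees with n_leads")
        if self.n_leads is not None and any(i >= self.n_leads for i in self.lead_indices):
            raise ConfigError("subset lead indices must be < n_leads")

    @property
    def k(self) -> int:
        return len(self.lead_indices)


@dataclass
class WindowMetrics:
    """Per-window reconstruction and spectral error measures."""

    window_index: int
    nrmse: float
    abse: Optional[float] = None
    er_nrmse: Optional[float] = None
    er_abse: Optional[float] = None
    per_lead_df: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.nrmse < 0:
            raise ConfigError("nrmse must be nonnegative")
        if self.abse is not None and self.abse < 0:
            raise ConfigError("abse must be nonnegative")
        if self.er_nrmse is not None and self.er_nrmse < 1 - 1e-9:
            raise ConfigError("er_nrmse below 1 violates the optimality of the PCA denominator")


@dataclass
class SegmentIndices:
    """Segment-level indices: window-averaged ER_NRMSE, ER_ABSE and NDI."""

    subset_kind: str
    k: int
    er_nrmse: Optional[float] = None
    er_abse: Optional[float] = None
    ndi: Optional[float] = None
    patient_id: str = ""
    segment_id: str = ""
    outcome: str = "UNKNOWN"

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ConfigError(f"outcome must be one of {OUTCOMES}, got {self.outcome!r}")
        if self.er_nrmse is not None and self.er_nrmse < 1 - 1e-9:
            raise ConfigError("er_nrmse must be >= 1 (PCA denominator is optimal)")
        if self.ndi is not None and not (-1e-12 <= self.ndi <= 1 + 1e-12):
            raise ConfigError("ndi must lie in [0, 1]")


@dataclass
class CvReport:
    """Cross-validated ROC summary for one index/outcome comparison."""

    fold_aucs: list
    auc_mean: float
    auc_std: float
    sensitivity: float
    specificity: float
    fold_pvalues: list
    roc_points: list  # (fpr, tpr) pairs, pooled over folds

    def __post_init__(self) -> None:
        if any(not 0 <= a <= 1 for a in self.fold_aucs):
            raise ConfigError("fold AUCs must lie in [0, 1]")
        for name, v in (("sensitivity", self.sensitivity), ("specificity", self.specificity)):
            if not 0 <= v <= 100:
                raise ConfigError(f"{name} must be a percentage in [0, 100]")
        pts = np.asarray(self.roc_points, dtype=float)
        if pts.size and (np.any(np.diff(pts[:, 0]) < -1e-12) or np.any(np.diff(pts[:, 1]) < -1e-12)):
            raise ConfigError("ROC points must be monotone nondecreasing in both coordinates")

    def to_dict(self) -> dict:
        return {
            "fold_aucs": [float(a) for a in self.fold_aucs],
            "auc_mean": float(self.auc_mean),
            "auc_std": float(self.auc_std),
            "sensitivity": float(self.sensitivity),
            "specificity": float(self.specificity),
            "fold_pvalues": [float(p) for p in self.fold_pvalues],
            "roc_points": [[float(a), float(b)] for a, b in self.roc_points],
        }
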