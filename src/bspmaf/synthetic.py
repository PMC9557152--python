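"""Synthetic body-surface AF recordings.

No public data accompany the clinical vest recordings this package targets, so
every downstream stage is exercised on generated signals that emulate their
salient structure:

* quasi-periodic atrial f-waves: a small number of harmonic sources
  (fundamental f with harmonics 2f, 3f at amplitudes 1, 1/2, 1/4 and slow
  sinusoidal phase modulation) mixed onto the leads through a low-rank,
  spatially smooth mixing, plus a weak per-lead oscillation at the lead's
  target dominant frequency ("DF-field detail");
* superimposed QRST complexes (sum-of-Gaussians template, ~400 ms) at
  log-normally distributed RR intervals, scaled well above the atrial
  amplitude;
* baseline wander and broadband noise.

Two regimes control spatiotemporal organization.  In the *organized* regime
the source-to-lead mixing and the source fundamentals are constant over the
whole segment.  In the *disorganized* regime the mixing takes an independent
random step at every analysis-window boundary and the fundamentals are
jittered per window — the temporal instability the error-ratio indices are
designed to detect.

Source fundamentals are the distinct values of the per-lead DF target field
(quantized to ``n_sources`` levels for smoothly varying fields), and each
lead predominantly mixes the source nearest its target, so the realized
per-lead dominant frequency tracks the field up to that quantization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import ConfigError
from .geometry import VestGeometry
from .types import AASegment, BspmRecording

__all__ = ["SynthConfig", "generate_f_waves", "generate_recording", "generate_aa_segment"]

REGIMES = ("organized", "disorganized")


@dataclass
class SynthConfig:
    """Generator settings; defaults are the canonical study conditions."""

    n_leads: int = 252
    fs: float = 1000.0
    duration_s: float = 60.0
    regime: str = "organized"
    df_field: Optional[np.ndarray] = None  # default: smooth gradient 5 -> 7 Hz
    n_sources: int = 4
    mixing_drift: Optional[float] = None  # default 0.0 organized / 0.3 disorganized
    df_jitter_hz: Optional[float] = None  # default 0.0 organized / 0.5 disorganized
    mean_rr_s: float = 0.7
    rr_cv: float = 0.25
    qrst_amp: float = 8.0
    noise_std: float = 0.1
    baseline_amp: float = 0.2
    baseline_freq_hz: float = 0.3
    detail_amp: float = 0.08
    phase_diffusion_rad2_s: float = 0.6
    window_len_s: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ConfigError(f"regime must be one of {REGIMES}, got {self.regime!r}")
        if self.n_leads < 2 or self.fs <= 0 or self.duration_s <= 0:
            raise ConfigError("n_leads >= 2, fs > 0 and duration_s > 0 required")
        if self.n_sources < 1:
            raise ConfigError("n_sources must be >= 1")
        if self.df_field is None:
            self.df_field = np.linspace(5.0, 7.0, self.n_leads)
        else:
            self.df_field = np.asarray(self.df_field, dtype=float)
            if self.df_field.shape != (self.n_leads,):
                raise ConfigError("df_field must have one target DF per lead")
        if np.any(self.df_field <= 3.0) or np.any(self.df_field >= 12.0):
            raise ConfigError("df_field values must lie strictly within (3, 12) Hz")
        if self.mixing_drift is None:
            self.mixing_drift = 0.0 if self.regime == "organized" else 0.3
        if self.df_jitter_hz is None:
            self.df_jitter_hz = 0.0 if self.regime == "organized" else 0.5
        for name in ("mixing_drift", "df_jitter_hz", "qrst_amp", "noise_std",
                     "baseline_amp", "detail_amp", "phase_diffusion_rad2_s"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be nonnegative")
        if self.rr_cv < 0 or self.mean_rr_s <= 0:
            raise ConfigError("mean_rr_s > 0 and rr_cv >= 0 required")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))


def _source_fundamentals(cfg: SynthConfig) -> np.ndarray:
    """One fundamental per source: distinct field values, or quantized levels."""
    uniq = np.unique(cfg.df_field)
    if uniq.size <= cfg.n_sources:
        reps = int(np.ceil(cfg.n_sources / uniq.size))
        return np.tile(uniq, reps)[: cfg.n_sources]
    return np.linspace(uniq.min(), uniq.max(), cfg.n_sources)


def _base_mixing(cfg: SynthConfig, fund: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Spatially structured (n_leads, n_sources) mixing, unit row norms.

    Each lead's weight on a source falls off with the distance between the
    lead's DF target and the source fundamental, so the nearest source
    dominates that lead's spectrum.
    """
    spread = max(np.ptp(fund) / max(cfg.n_sources - 1, 1), 0.2)
    bw = 0.35 * spread
    w = np.exp(-((cfg.df_field[:, None] - fund[None, :]) / bw) ** 2)
    w *= np.exp(0.25 * rng.standard_normal(w.shape))  # spatial gain variety
    w += 0.03 * rng.standard_normal(w.shape)
    norms = np.linalg.norm(w, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return w / norms


def _normalize_rows(m: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(m, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return m / norms


def generate_f_waves(cfg: SynthConfig) -> np.ndarray:
    """Ground-truth atrial-activity matrix ``(m, n_leads)``, global RMS 1.

    Deterministic for a fixed config (the config seed drives all draws).
    """
    rng = np.random.default_rng(cfg.seed)
    m, n, fs = cfg.n_samples, cfg.n_leads, cfg.fs
    t = np.arange(m) / fs
    win = int(round(cfg.window_len_s * fs))
    n_win = max(1, int(np.ceil(m / win)))
    fund = _source_fundamentals(cfg)

    # per-window per-source fundamentals (jittered in the disorganized regime)
    f_sw = np.tile(fund[:, None], (1, n_win))
    if cfg.df_jitter_hz > 0:
        f_sw = f_sw + rng.uniform(-cfg.df_jitter_hz, cfg.df_jitter_hz, size=f_sw.shape)
        f_sw = np.clip(f_sw, 3.05, 11.95)

    # sources: harmonic series on a phase track that is continuous across
    # window boundaries, with slow sinusoidal phase modulation plus Brownian
    # phase diffusion (f-waves are quasi-periodic, not phase-stable tones:
    # diffusion sets a finite coherence time ~1/phase_diffusion_rad2_s)
    mod_amp = rng.uniform(0.2, 0.5, size=cfg.n_sources)
    mod_freq = rng.uniform(0.08, 0.25, size=cfg.n_sources)
    mod_phase = rng.uniform(0, 2 * np.pi, size=cfg.n_sources)
    win_idx = np.minimum(np.arange(m) // win, n_win - 1)
    sources = np.empty((m, cfg.n_sources))
    for s in range(cfg.n_sources):
        inst_f = f_sw[s, win_idx]
        phi = 2 * np.pi * np.cumsum(inst_f) / fs
        phi = phi + mod_amp[s] * np.sin(2 * np.pi * mod_freq[s] * t + mod_phase[s])
        if cfg.phase_diffusion_rad2_s > 0:
            step = np.sqrt(cfg.phase_diffusion_rad2_s / fs)
            phi = phi + np.cumsum(step * rng.standard_normal(m))
        src = np.sin(phi) + 0.5 * np.sin(2 * phi) + 0.25 * np.sin(3 * phi)
        sd = src.std()
        sources[:, s] = src / (sd if sd > 0 else 1.0)

    # mixing: constant (organized) or random-stepped per window (disorganized)
    mix0 = _base_mixing(cfg, fund, rng)
    x = np.empty((m, n))
    mix = mix0
    for w in range(n_win):
        if w > 0 and cfg.mixing_drift > 0:
            step = cfg.mixing_drift * rng.standard_normal(mix.shape) / np.sqrt(cfg.n_sources)
            mix = _normalize_rows(mix + step)
        sl = slice(w * win, min((w + 1) * win, m))
        x[sl] = sources[sl] @ mix.T

    # weak per-lead oscillation pinning each lead's own DF target
    if cfg.detail_amp > 0:
        phases = rng.uniform(0, 2 * np.pi, size=n)
        x += cfg.detail_amp * np.sin(2 * np.pi * cfg.df_field[None, :] * t[:, None]
                                     + phases[None, :])

    rms = np.sqrt(np.mean(x**2))
    if rms > 0:
        x /= rms
    return x


def _qrst_template(fs: float, pre_s: float = 0.08, post_s: float = 0.40) -> tuple[np.ndarray, int]:
    """Analytic single-lead QRST shape: Q/R/S Gaussians plus a wide T wave.

    The T wave is placed so the whole complex decays to negligible amplitude
    within the template span (~480 ms).  Returns the shape (unit R amplitude)
    and the offset of its first sample relative to the R peak (negative).
    """
    t = np.arange(-int(round(pre_s * fs)), int(round(post_s * fs))) / fs

    def g(center, width):
        return np.exp(-((t - center) ** 2) / (2 * width**2))

    shape = (-0.15 * g(-0.040, 0.012) + 1.0 * g(0.0, 0.014)
             - 0.25 * g(0.045, 0.016) + 0.35 * g(0.220, 0.050))
    return shape, -int(round(pre_s * fs))


def _smooth_lead_pattern(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Spatially smooth per-lead QRST amplitude with anterior/posterior polarity."""
    n = cfg.n_leads
    raw = rng.standard_normal(n)
    width = max(n // 20, 2)
    kernel = np.exp(-0.5 * (np.arange(-3 * width, 3 * width + 1) / width) ** 2)
    kernel /= kernel.sum()
    smooth = np.convolve(raw, kernel, mode="same")
    sd = smooth.std()
    smooth = smooth / (sd if sd > 0 else 1.0)
    pattern = 1.0 + 0.35 * smooth
    pattern[n // 2 :] *= -0.8  # posterior panel: reduced amplitude, flipped polarity
    return pattern


def generate_recording(
    cfg: SynthConfig, geometry: Optional[VestGeometry] = None
) -> tuple[BspmRecording, dict]:
    """Full synthetic recording and its ground truth.

    Returns ``(recording, truth)`` where ``truth`` holds ``aa_matrix`` (the
    clean atrial activity), ``r_peaks`` (sample indices) and ``df_field``.
    """
    aa = generate_f_waves(cfg)
    m, n, fs = cfg.n_samples, cfg.n_leads, cfg.fs
    rng = np.random.default_rng([cfg.seed, 1])
    t = np.arange(m) / fs

    x = aa.copy()
    shape, start_off = _qrst_template(fs)
    pattern = _smooth_lead_pattern(cfg, rng)

    # RR intervals: log-normal with the requested mean and coefficient of variation
    sigma2 = np.log1p(cfg.rr_cv**2)
    mu = np.log(cfg.mean_rr_s) - sigma2 / 2
    r_times = []
    tcur = 0.35  # leave room for the first complex's Q onset
    min_rr = 0.25
    while True:
        if tcur * fs < m - 1:
            r_times.append(tcur)
        else:
            break
        rr = max(float(rng.lognormal(mu, np.sqrt(sigma2))), min_rr)
        tcur += rr
    r_peaks = np.asarray([int(round(rt * fs)) for rt in r_times], dtype=int)
    if cfg.qrst_amp > 0 and r_peaks.size == 0:
        raise ConfigError("duration too short to place a single QRST complex")

    if cfg.qrst_amp > 0:
        for r in r_peaks:
            amp = cfg.qrst_amp * (1.0 + 0.05 * rng.standard_normal())
            lo = r + start_off
            hi = lo + shape.size
            s0, s1 = max(lo, 0), min(hi, m)
            x[s0:s1] += amp * np.outer(shape[s0 - lo : s1 - lo], pattern)
    else:
        r_peaks = r_peaks if r_peaks.size else np.asarray([], dtype=int)

    if cfg.baseline_amp > 0:
        ph = rng.uniform(0, 2 * np.pi, size=n)
        fb = cfg.baseline_freq_hz * (1.0 + 0.1 * rng.uniform(-1, 1, size=n))
        x += cfg.baseline_amp * np.sin(2 * np.pi * fb[None, :] * t[:, None] + ph[None, :])

    if cfg.noise_std > 0:
        x += cfg.noise_std * rng.standard_normal(x.shape)

    geo = geometry or VestGeometry.for_n_leads(n)
    rec = BspmRecording(
        samples=x,
        fs=fs,
        geometry=geo,
        annotations={"r_peaks": r_peaks},
    )
    truth = {"aa_matrix": aa, "r_peaks": r_peaks, "df_field": cfg.df_field.copy()}
    return rec, truth


def generate_aa_segment(cfg: SynthConfig) -> AASegment:
    """Convenience: clean atrial activity plus broadband noise as an AASegment.

    This is the ventricular-free analogue of a preprocessed segment and is the
    canonical input for index-level simulation studies (QRST cancellation is
    validated separately against :func:`generate_recording` ground truth).
    """
    x = generate_f_waves(cfg)
    if cfg.noise_std > 0:
        rng = np.random.default_rng([cfg.seed, 2])
        x = x + cfg.noise_std * rng.standard_normal(x.shape)
    return AASegment(samples=x, fs=cfg.fs, window_len_s=cfg.window_len_s, normalized=False)
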