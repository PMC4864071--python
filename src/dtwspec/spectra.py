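"""Template-based DTW spectrum and the matched direct DFT spectrum.

The DTW spectrum of a short signal segment is computed by sweeping a bank of
unit-variance sinusoids over a frequency grid and recording, per frequency,
the banded-DTW dissimilarity between the standardized segment and the
template.  Low values mean the segment closely resembles an oscillation at
that frequency, so the DTW spectrum is an *inverted* analogue of a power
spectrum: where the DFT peaks, the DTW dissimilarity dips.

Both the segment and templates are z-standardized by default so that the
dissimilarity is driven by waveform shape (frequency content) rather than
amplitude; DTW's time warping absorbs phase offsets, which is why a single
zero-phase template per frequency suffices.

Per trial the spectrum is condensed to a scalar — its standard deviation
across the frequency band (default 8-13 Hz, the alpha band) — which is what
enters the cross-prediction GLMs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy import stats

from .dtw import DTWConfig, dtw_distance

__all__ = [
    "TemplateBank",
    "SpectrumResult",
    "make_templates",
    "dtw_spectrum",
    "dft_spectrum",
    "spectra_correlation",
]

TEMPLATE_SHAPES = ("sine", "sawtooth")


@dataclass
class TemplateBank:
    """Standardized waveform templates on an increasing frequency grid."""

    shape: str
    frequencies: np.ndarray
    templates: np.ndarray  # n_freq x n_samples, zero mean / unit variance rows
    rate: float

    def __len__(self) -> int:
        return len(self.frequencies)


@dataclass
class SpectrumResult:
    """Per-frequency values of one spectrum plus its SD reduction.

    ``kind`` is ``"dtw"`` (dissimilarity, lower = more similar) or ``"dft"``
    (power).  ``sd`` is the sample standard deviation of ``values`` — the
    trial-wise scalar used downstream.
    """

    kind: str
    frequencies: np.ndarray
    values: np.ndarray

    @property
    def sd(self) -> float:
        return float(np.std(self.values, ddof=1)) if len(self.values) > 1 else 0.0


def _standardize(v: np.ndarray) -> np.ndarray:
    s = v.std()
    if s == 0:
        raise ValueError("zero-variance segment cannot be standardized")
    return (v - v.mean()) / s


def make_templates(
    f_lo: float,
    f_hi: float,
    step: float,
    n_samples: int,
    rate: float,
    shape: str = "sine",
) -> TemplateBank:
    """Build the bank of progressively higher-frequency templates.

    Frequencies run ``f_lo, f_lo + step, ...`` up to and including ``f_hi``
    when the grid lands on it.  Templates have phase 0 at the first sample and
    are standardized to zero mean, unit variance.
    """
    if shape not in TEMPLATE_SHAPES:
        raise ValueError(f"shape must be one of {TEMPLATE_SHAPES}")
    if step <= 0:
        raise ValueError("step must be positive")
    if not (0 < f_lo <= f_hi):
        raise ValueError("need 0 < f_lo <= f_hi")
    if f_hi >= rate / 2:
        raise ValueError(f"f_hi = {f_hi} at or above Nyquist ({rate / 2})")
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    n_freq = int(np.floor((f_hi - f_lo) / step + 1e-9)) + 1
    freqs = f_lo + step * np.arange(n_freq)
    t = np.arange(n_samples) / rate
    rows = []
    for f in freqs:
        if shape == "sine":
            w = np.sin(2 * np.pi * f * t)
        else:
            w = sps.sawtooth(2 * np.pi * f * t)
        rows.append(_standardize(w))
    return TemplateBank(shape=shape, frequencies=freqs, templates=np.array(rows), rate=rate)


def dtw_spectrum(
    segment,
    bank: TemplateBank,
    cfg: DTWConfig | None = None,
    standardize: bool = True,
) -> SpectrumResult:
    """DTW dissimilarity of one segment against every template in the bank."""
    cfg = cfg or DTWConfig()
    seg = np.asarray(segment, dtype=float).ravel()
    if seg.size != bank.templates.shape[1]:
        raise ValueError(
            f"segment length {seg.size} != template length {bank.templates.shape[1]}"
        )
    if seg.std() == 0:
        raise ValueError("degenerate input: zero-variance segment")
    if standardize:
        seg = _standardize(seg)
    values = np.array([dtw_distance(seg, tpl, cfg) for tpl in bank.templates])
    return SpectrumResult(kind="dtw", frequencies=bank.frequencies, values=values)


def dft_spectrum(segment, rate: float, frequencies) -> SpectrumResult:
    """Direct per-frequency DFT power of the mean-removed segment.

    Evaluates the squared magnitude of the Fourier projection on exactly the
    supplied grid (the same grid as the template bank), rather than an FFT on
    padded data, so the two spectra are bin-aligned.
    """
    seg = np.asarray(segment, dtype=float).ravel()
    freqs = np.asarray(frequencies, dtype=float)
    if seg.size < 2:
        raise ValueError("segment too short")
    if np.any(freqs >= rate / 2):
        raise ValueError("frequency at or above Nyquist")
    seg = seg - seg.mean()
    t = np.arange(seg.size) / rate
    # n_freq x n_samples complex projection basis
    basis = np.exp(-2j * np.pi * freqs[:, None] * t[None, :])
    values = np.abs(basis @ seg) ** 2
    return SpectrumResult(kind="dft", frequencies=freqs, values=values)


def spectra_correlation(a: SpectrumResult, b: SpectrumResult) -> float:
    """Spearman rank correlation between two spectra on the same grid."""
    if len(a.frequencies) != len(b.frequencies) or not np.allclose(
        a.frequencies, b.frequencies
    ):
        raise ValueError("frequency grids differ")
    if np.ptp(a.values) == 0 or np.ptp(b.values) == 0:
        raise ValueError("correlation undefined for constant spectrum values")
    rho = stats.spearmanr(a.values, b.values).statistic
    return float(rho)
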