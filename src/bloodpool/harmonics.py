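"""Per-pixel first-harmonic Fourier analysis of a gated cine.

Each pixel's count-time curve is modelled as

    c(t) = A0 + A1 * cos(2*pi*t/T - phi),

the clinical phase-analysis convention: ``A0`` is the mean count (DC),
``A1 >= 0`` the contraction amplitude and ``phi`` (degrees, [0, 360)) the
timing of the count maximum within the cycle — a positive lag. Delaying
the cine by k frames therefore adds 360k/T degrees to every phase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import GatedCine

__all__ = ["HarmonicMaps", "PhaseHistogram", "first_harmonic", "phase_histogram"]


@dataclass
class HarmonicMaps:
    """DC, amplitude and phase images from the first Fourier harmonic.

    ``low_amplitude`` flags pixels whose amplitude is numerically zero;
    their phase is undefined and set to 0.
    """

    dc: np.ndarray
    amplitude: np.ndarray
    phase: np.ndarray
    low_amplitude: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.dc.shape


@dataclass
class PhaseHistogram:
    """Amplitude-weighted phase distribution over a region."""

    bin_edges: np.ndarray  # degrees, [0, 360] in n_bins equal bins
    probabilities: np.ndarray  # per-bin mass, sums to 1

    @property
    def n_bins(self) -> int:
        return len(self.probabilities)


def first_harmonic(cine: GatedCine, eps_fraction: float = 1e-9) -> HarmonicMaps:
    """Fit the cosine model per pixel via the first DFT coefficient.

    Pixels with ``A1 < eps_fraction * max(A1)`` are flagged low-amplitude
    and given phase 0.
    """
    frames = np.asarray(cine.frames, dtype=float)
    t = frames.shape[0]
    if t < 3:
        raise ValueError("first-harmonic analysis needs at least 3 frames")
    spectrum = np.fft.fft(frames, axis=0)
    dc = spectrum[0].real / t
    x1 = spectrum[1]
    amplitude = 2.0 * np.abs(x1) / t
    # c(t) = A1 cos(2 pi t / T - phi) contributes (A1 T / 2) e^{-i phi}
    # to the first DFT coefficient, so phi = -angle(X1).
    phase = np.degrees(-np.angle(x1)) % 360.0
    amax = amplitude.max()
    low = amplitude < (eps_fraction * amax if amax > 0 else np.inf)
    phase = np.where(low, 0.0, phase)
    return HarmonicMaps(dc=dc, amplitude=amplitude, phase=phase, low_amplitude=low)


def phase_histogram(
    maps: HarmonicMaps,
    mask: np.ndarray,
    n_bins: int = 64,
    amplitude_weighted: bool = True,
) -> PhaseHistogram:
    """Histogram of phases inside ``mask``, weighted by amplitude.

    Bins are half-open [a, b) over [0, 360], the last bin closed. Set
    ``amplitude_weighted=False`` for a plain pixel-count histogram.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    phases = maps.phase[mask]
    weights = maps.amplitude[mask] if amplitude_weighted else np.ones(phases.size)
    total = weights.sum()
    if total <= 0:
        raise ValueError("zero total amplitude in mask")
    edges = np.linspace(0.0, 360.0, n_bins + 1)
    hist, _ = np.histogram(phases, bins=edges, weights=weights)
    return PhaseHistogram(bin_edges=edges, probabilities=hist / total)
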