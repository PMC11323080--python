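"""Hybrid region-growing / active-contour (ACRG) LV segmentation.

Gated blood-pool frames are noisy, so the ventricle is delineated in four
stages that combine the count image with the first-harmonic maps, which
offer better contrast:

1. seeded region growing on each (filtered, background-corrected) frame
   gives an initial, typically over-large contour per frame;
2. a shrink-only two-phase active contour evolves each initial contour on
   the phase image, gated to pixels whose phase lies within +/-90 degrees
   of the seed's phase (atria and great vessels move in phase opposition
   and are excluded by the gate);
3. region growing on the amplitude image, bounded by the stage-2 mask,
   re-grows the ventricle from the same seed;
4. the stage-3 masks are applied back to the count frames; end-diastole
   and end-systole are the extrema of the resulting time-activity curve.

Every stage is deterministic: identical inputs give identical masks.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .harmonics import HarmonicMaps
from .io import GatedCine

__all__ = [
    "SeedPoint",
    "LVSegmentation",
    "region_grow",
    "active_contour_refine",
    "acrg_segment",
    "detect_ed_es",
]

_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class SeedPoint:
    """A pixel inside the LV chosen by the operator."""

    row: int
    col: int

    def as_tuple(self) -> tuple[int, int]:
        return (self.row, self.col)


@dataclass
class LVSegmentation:
    """Per-frame LV masks with the seed and ED/ES frame indices."""

    masks: list[np.ndarray]
    seed: SeedPoint
    ed_frame: int
    es_frame: int

    def __post_init__(self) -> None:
        t = len(self.masks)
        if not (0 <= self.ed_frame < t and 0 <= self.es_frame < t):
            raise ValueError("ED/ES indices out of range")
        if self.ed_frame == self.es_frame:
            raise ValueError("ED and ES frames must differ")
        for i, m in enumerate(self.masks):
            if not m.any():
                raise ValueError(f"empty LV mask at frame {i}")
            if not m[self.seed.row, self.seed.col]:
                raise ValueError(f"mask at frame {i} does not contain the seed")
            if ndimage.label(m, structure=_STRUCT8)[1] != 1:
                raise ValueError(f"mask at frame {i} is not connected")


def region_grow(
    image: np.ndarray,
    seed: SeedPoint,
    threshold_fraction: float = 0.25,
    bounds: np.ndarray | None = None,
) -> np.ndarray:
    """Seeded region growing with a running-maximum threshold.

    Starting from the seed, 8-connected neighbours are visited in
    decreasing order of intensity and accepted while their value is at
    least ``threshold_fraction`` times the maximum value absorbed into the
    region so far — the count-based analogue of the fractional-of-peak LV
    edge criterion. ``bounds``, when given, restricts growth to a mask.
    """
    img = np.asarray(image, dtype=float)
    if not 0 < threshold_fraction <= 1:
        raise ValueError("threshold_fraction must lie in (0, 1]")
    h, w = img.shape
    r0, c0 = seed.row, seed.col
    if not (0 <= r0 < h and 0 <= c0 < w):
        raise ValueError("seed outside image")
    if bounds is not None:
        bounds = np.asarray(bounds, dtype=bool)
        if not bounds[r0, c0]:
            raise ValueError("seed outside bounds mask")
    if img[r0, c0] <= 0:
        raise ValueError("seed value must be > 0")

    mask = np.zeros(img.shape, dtype=bool)
    visited = np.zeros(img.shape, dtype=bool)
    visited[r0, c0] = True
    heap = [(-img[r0, c0], r0, c0)]
    region_max = 0.0
    while heap:
        negv, r, c = heapq.heappop(heap)
        v = -negv
        if v <= 0 or v < threshold_fraction * region_max:
            continue
        mask[r, c] = True
        region_max = max(region_max, v)
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w and not visited[rr, cc]:
                    if bounds is None or bounds[rr, cc]:
                        visited[rr, cc] = True
                        heapq.heappush(heap, (-img[rr, cc], rr, cc))
    return mask


def active_contour_refine(
    phase_img: np.ndarray,
    init_mask: np.ndarray,
    seed: SeedPoint,
    max_iter: int = 200,
    smoothing: int = 1,
    tol: float = 0.001,
) -> np.ndarray:
    """Shrink-only two-phase (piecewise-constant) contour evolution.

    Boundary pixels whose intensity is closer to the outside mean than to
    the inside mean are peeled off; ``smoothing`` rounds of morphological
    opening regularise the contour. The mask never grows beyond
    ``init_mask``, stays 8-connected and always contains the seed.
    Stops after ``max_iter`` iterations or when the per-iteration change
    drops below ``tol`` of the image pixels.
    """
    img = np.asarray(phase_img, dtype=float)
    mask = np.asarray(init_mask, dtype=bool).copy()
    sr, sc = seed.row, seed.col
    if not mask[sr, sc]:
        raise ValueError("init_mask must contain the seed")
    npix = mask.size
    for _ in range(max_iter):
        c_in = img[mask].mean()
        outside = ~mask
        c_out = img[outside].mean() if outside.any() else c_in
        interior = ndimage.binary_erosion(mask, structure=_STRUCT8)
        boundary = mask & ~interior
        drop = boundary & ((img - c_in) ** 2 > (img - c_out) ** 2)
        new = mask & ~drop
        for _ in range(max(0, smoothing)):
            opened = ndimage.binary_opening(new, structure=_STRUCT8)
            if opened.any():
                new = opened
        new[sr, sc] = True
        labels, _ = ndimage.label(new, structure=_STRUCT8)
        new = labels == labels[sr, sc]
        changed = int(np.count_nonzero(mask ^ new))
        mask = new
        if changed < tol * npix:
            break
    if not mask.any():
        raise RuntimeError("active contour collapsed to an empty mask")
    return mask


def _circular_distance_deg(phase: np.ndarray, reference: float) -> np.ndarray:
    """Angular distance in degrees, in [0, 180]."""
    d = np.abs((phase - reference + 180.0) % 360.0 - 180.0)
    return d


def acrg_segment(
    cine: GatedCine,
    maps: HarmonicMaps,
    seed: SeedPoint,
    threshold_fraction: float = 0.25,
    max_iter: int = 200,
    smoothing: int = 1,
    phase_gate: float = 90.0,
) -> LVSegmentation:
    """Run the full four-stage ACRG segmentation.

    ``cine`` should already be filtered and background-corrected.
    ``threshold_fraction`` is shared by the stage-1 (frame) and stage-3
    (amplitude) region growing. Raises if the seed sits in zero-amplitude
    background or any stage yields an empty frame mask.
    """
    sr, sc = seed.row, seed.col
    if maps.low_amplitude[sr, sc] or maps.amplitude[sr, sc] <= 0:
        raise ValueError("seed lies in zero-amplitude background")

    # Stage 1: per-frame region growing from the seed on the count frames.
    inits = [
        region_grow(cine.frames[t], seed, threshold_fraction)
        for t in range(cine.n_frames)
    ]

    # Ventricular reference phase: the amplitude-weighted phasor mean over
    # the union of the initial contours. A single pixel's phase is fragile
    # under counting noise (the chamber centre has low contraction
    # amplitude), so the gate is anchored to the region's phase instead.
    union = np.logical_or.reduce(inits)
    amp = maps.amplitude[union]
    z = (amp * np.exp(1j * np.radians(maps.phase[union]))).sum()
    if np.abs(z) <= 0:
        raise ValueError("zero net amplitude in the initial contours")
    seed_phase = float(np.degrees(np.angle(z)) % 360.0)
    phase_dist = _circular_distance_deg(maps.phase, seed_phase)
    # A pixel with no contraction has no meaningful timing: treat it as
    # maximally distant so the contour never confuses static background
    # (whose flagged phase is 0) with ventricle.
    phase_dist[maps.low_amplitude] = 180.0
    gate = (phase_dist <= phase_gate) & ~maps.low_amplitude
    gate[sr, sc] = True

    final_masks: list[np.ndarray] = []
    for t in range(cine.n_frames):
        init = inits[t] & gate
        init[sr, sc] = True
        refined = active_contour_refine(
            phase_dist, init, seed, max_iter=max_iter, smoothing=smoothing
        )
        # Guard against contrast failure: when the phase image offers no
        # usable two-phase structure on a frame (low-count, strongly
        # dyssynchronous scans), the shrink-only evolution can implode to
        # the protected seed. The initial contour is the better estimate
        # then, so keep it rather than poisoning the time-activity curve.
        if refined.sum() < max(0.25 * init.sum(), 5):
            refined = init
        grown = region_grow(maps.amplitude, seed, threshold_fraction, bounds=refined)
        if not grown.any():
            raise RuntimeError(f"empty LV mask at frame {t}")
        final_masks.append(grown)

    tac = np.array(
        [float(cine.frames[t][final_masks[t]].sum()) for t in range(cine.n_frames)]
    )
    ed, es = detect_ed_es(tac)
    return LVSegmentation(masks=final_masks, seed=seed, ed_frame=ed, es_frame=es)


def detect_ed_es(tac: np.ndarray) -> tuple[int, int]:
    """ED = argmax, ES = argmin of a time-activity curve (earliest on ties)."""
    tac = np.asarray(tac, dtype=float)
    if tac.size < 3:
        raise ValueError("time-activity curve too short")
    if np.any(tac < 0):
        raise ValueError("negative counts in time-activity curve")
    ed = int(np.argmax(tac))
    es = int(np.argmin(tac))
    if tac[ed] == tac[es]:
        raise ValueError("constant time-activity curve: ED/ES undefined")
    return ed, es
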