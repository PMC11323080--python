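"""Extraction of the full biomarker vector from a segmented cine.

Count-based indices (LVEF, phase LVEF, ejection rate, approximate
entropy), phase-domain dyssynchrony indices (entropy, synchrony, phase
standard deviation), shape indices (circularity, elongation, fractional
shortening, chamber sizes) and time-based gating statistics are all
computed here, and :func:`compute_all` orchestrates the whole pipeline —
filtering, background correction, harmonic analysis, ACRG segmentation
and parameter extraction — in a single deterministic pass.

Approximate entropy follows Pincus: with embedding dimension m and
tolerance r, ApEn = Phi_m(r) - Phi_{m+1}(r) where

    Phi_m(r) = (N-m+1)^-1 * sum_i ln C_i^m(r),
    C_i^m(r) = #{j : max_k |x[i+k] - x[j+k]| <= r} / (N-m+1),

Chebyshev distance, self-matches included, natural logarithm. The
"bounded" variant fixes r as a fraction of the signal range, which makes
the statistic invariant to affine rescaling of the signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields

import numpy as np
from skimage import measure as skmeasure

from .harmonics import HarmonicMaps, first_harmonic, phase_histogram
from .io import AcquisitionMeta, GatedCine
from .preprocess import (
    BackgroundSpec,
    FilterSpec,
    build_background_rois,
    correct_background,
    filter_cine,
    measure_background,
    time_averaged_frame,
)
from .segmentation import LVSegmentation, SeedPoint, acrg_segment, region_grow

__all__ = [
    "ParameterSet",
    "AnalysisConfig",
    "time_activity_curve",
    "compute_lvef",
    "phase_lvef",
    "ejection_rate",
    "approx_entropy",
    "bounded_apen",
    "phase_statistics",
    "apen_spatial",
    "shape_metrics",
    "fractional_shortening",
    "lung_heart_ratio",
    "beat_statistics",
    "compute_all",
]


@dataclass
class ParameterSet:
    """The full biomarker vector for one scan; absent values are ``None``."""

    lvef: float | None = None  # %
    phase_lvef: float | None = None  # %
    ejection_rate: float | None = None  # EDC-fractions/s, peak systolic
    e_raw: float | None = None  # bits
    e_norm: float | None = None  # [0, 1], range-bounded entropy
    apen: float | None = None
    b_apen: float | None = None
    apen_d: float | None = None
    apen_s: float | None = None
    apen_ds: float | None = None
    synchrony: float | None = None  # [0, 1]
    phase_sd: float | None = None  # degrees
    mean_phase: float | None = None  # degrees, [0, 360)
    lhr: float | None = None
    circ_ed: float | None = None
    circ_es: float | None = None
    elong_ed: float | None = None
    elong_es: float | None = None
    fs_long: float | None = None  # %
    fs_short: float | None = None  # %
    lv_size_ed: float | None = None  # pixels
    lv_size_es: float | None = None  # pixels
    lv_size_ed_mm2: float | None = None
    lv_size_es_mm2: float | None = None
    counts_ed: float | None = None
    counts_es: float | None = None
    heart_rate: float | None = None  # bpm
    mean_beat_duration: float | None = None  # ms
    rejected_fraction: float | None = None  # [0, 1]
    frame_time: float | None = None  # ms
    provenance: dict = field(default_factory=dict, repr=False, compare=False)

    @classmethod
    def csv_columns(cls) -> list[str]:
        """Fixed, documented CSV column order (provenance excluded)."""
        return [f.name for f in fields(cls) if f.name != "provenance"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Pipeline settings for :func:`compute_all` (package defaults)."""

    filter_spec: FilterSpec = field(default_factory=FilterSpec)  # MMWF 5x5
    background: BackgroundSpec = field(default_factory=BackgroundSpec)  # loc 1, w 4
    n_bins: int = 64
    apen_m: int = 2
    apen_r_frac: float = 0.2
    rg_fraction: float = 0.25
    ac_iter: int = 200
    ac_smoothing: int = 1
    phase_gate: float = 90.0
    lung_offset_bbox_widths: float = 1.5


def time_activity_curve(cine: GatedCine, seg: LVSegmentation) -> np.ndarray:
    """Summed counts of frame t inside mask t, for every frame."""
    if len(seg.masks) != cine.n_frames:
        raise ValueError("segmentation/cine frame count mismatch")
    if seg.masks[0].shape != cine.shape:
        raise ValueError("segmentation/cine shape mismatch")
    return np.array(
        [float(cine.frames[t][seg.masks[t]].sum()) for t in range(cine.n_frames)]
    )


def compute_lvef(tac: np.ndarray, ed: int, es: int) -> float:
    """Count-based ejection fraction in percent: 100*(EDC-ESC)/EDC.

    The curve must already be background-corrected — residual background
    inside the LV region dilutes the fraction.
    """
    tac = np.asarray(tac, dtype=float)
    if tac[ed] <= 0:
        raise ValueError("end-diastolic counts must be > 0")
    return 100.0 * (tac[ed] - tac[es]) / tac[ed]


def phase_lvef(maps: HarmonicMaps, ed_mask: np.ndarray) -> float:
    """First-harmonic ejection-fraction estimate in percent.

    Over the ED mask, EDC ~ sum(A0 + A1) and ESC ~ sum(A0 - A1), giving
    EF = 2*sum(A1) / (sum(A0) + sum(A1)).
    """
    ed_mask = np.asarray(ed_mask, dtype=bool)
    a0 = float(maps.dc[ed_mask].sum())
    a1 = float(maps.amplitude[ed_mask].sum())
    denom = a0 + a1
    if denom <= 0:
        raise ValueError("non-positive total counts in ED mask")
    return 100.0 * 2.0 * a1 / denom


def ejection_rate(tac: np.ndarray, ed: int, frame_time: float) -> float:
    """Peak systolic emptying rate in end-diastolic-count fractions per second.

    The maximum frame-to-frame count drop after ED, normalised by EDC and
    the frame duration.
    """
    tac = np.asarray(tac, dtype=float)
    if frame_time <= 0:
        raise ValueError("frame_time must be > 0")
    if tac[ed] <= 0:
        raise ValueError("end-diastolic counts must be > 0")
    t_len = len(tac)
    drops = [tac[(ed + i) % t_len] - tac[(ed + i + 1) % t_len] for i in range(t_len - 1)]
    peak = max(max(drops), 0.0)
    return float(peak / (tac[ed] * (frame_time / 1000.0)))


def _phi(x: np.ndarray, m: int, r: float) -> float:
    n = len(x)
    n_vec = n - m + 1
    emb = np.lib.stride_tricks.sliding_window_view(x, m)
    # Chebyshev distances between all embedded vectors, self-matches kept.
    dist = np.abs(emb[:, None, :] - emb[None, :, :]).max(axis=2)
    c = (dist <= r).sum(axis=1) / n_vec
    return float(np.log(c).mean())


def _phi_slow(x: np.ndarray, m: int, r: float) -> float:
    n = len(x)
    n_vec = n - m + 1
    total = 0.0
    for i in range(n_vec):
        count = 0
        for j in range(n_vec):
            d = 0.0
            for k in range(m):
                d = max(d, abs(x[i + k] - x[j + k]))
            if d <= r:
                count += 1
        total += np.log(count / n_vec)
    return total / n_vec


def approx_entropy(x: np.ndarray, m: int = 2, r: float | None = None, mode: str = "fast") -> float:
    """Pincus approximate entropy of a 1-d signal.

    ``r`` defaults to 0.2 times the signal's standard deviation. The
    ``slow`` mode is a literal brute-force transcription of the
    definition and serves as the oracle for the vectorised ``fast`` mode;
    the two agree to 1e-9.
    """
    x = np.asarray(x, dtype=float).ravel()
    n = len(x)
    if m < 1:
        raise ValueError("embedding dimension m must be >= 1")
    if n < m + 2:
        raise ValueError(f"signal too short: N={n} < m+2={m + 2}")
    if r is None:
        r = 0.2 * float(np.std(x))
    if r < 0:
        raise ValueError("tolerance r must be >= 0")
    phi = _phi_slow if mode == "slow" else _phi
    if mode not in ("fast", "slow"):
        raise ValueError("mode must be 'fast' or 'slow'")
    return phi(x, m, r) - phi(x, m + 1, r)


def bounded_apen(x: np.ndarray, m: int = 2, r_frac: float = 0.2, mode: str = "fast") -> float:
    """Approximate entropy with tolerance fixed to a fraction of the range.

    r = r_frac * (max(x) - min(x)); invariant to affine rescaling of x.
    """
    x = np.asarray(x, dtype=float).ravel()
    if not 0 < r_frac <= 1:
        raise ValueError("r_frac must lie in (0, 1]")
    rng = float(x.max() - x.min()) if x.size else 0.0
    if rng <= 0:
        raise ValueError("zero signal range: bounded tolerance undefined")
    return approx_entropy(x, m=m, r=r_frac * rng, mode=mode)


def phase_statistics(
    maps: HarmonicMaps, mask: np.ndarray, n_bins: int = 64
) -> tuple[float, float, float, float, float]:
    """Entropy, synchrony and circular phase moments over a region.

    Returns ``(e_raw, e_norm, synchrony, mean_phase, phase_sd)``:

    * ``e_raw``: Shannon entropy (bits) of the amplitude-weighted phase
      histogram; ``e_norm = e_raw / log2(n_bins)`` in [0, 1];
    * ``synchrony``: |sum A*exp(i*phi)| / sum A over the mask, 1 when all
      pixels contract in unison;
    * ``mean_phase``: argument of that phasor sum, degrees in [0, 360);
    * ``phase_sd``: amplitude-weighted standard deviation (degrees) of
      phases unwrapped to (mean_phase - 180, mean_phase + 180].
    """
    mask = np.asarray(mask, dtype=bool)
    hist = phase_histogram(maps, mask, n_bins=n_bins)
    p = hist.probabilities
    nz = p[p > 0]
    e_raw = max(0.0, float(-(nz * np.log2(nz)).sum()))
    e_norm = e_raw / np.log2(n_bins)

    amp = maps.amplitude[mask]
    phi = np.radians(maps.phase[mask])
    total = amp.sum()
    z = (amp * np.exp(1j * phi)).sum()
    synchrony = float(np.abs(z) / total)
    mean_phase = float(np.degrees(np.angle(z)) % 360.0) if np.abs(z) > 0 else 0.0
    dev = (maps.phase[mask] - mean_phase + 180.0) % 360.0 - 180.0
    phase_sd = float(np.sqrt((amp * dev**2).sum() / total))
    return e_raw, e_norm, synchrony, mean_phase, phase_sd


def apen_spatial(
    maps: HarmonicMaps,
    ed_mask: np.ndarray,
    es_mask: np.ndarray,
    m: int = 2,
    r_frac: float = 0.2,
) -> tuple[float, float, float]:
    """Bounded ApEn of the spatial phase sequences inside the ED/ES masks.

    The phase values are read out in row-major order; ``apen_ds`` is the
    mean of the diastolic and systolic values. A region whose phase is
    perfectly uniform has zero range and no defined bounded tolerance; by
    convention it scores 0 (with a warning) so that perfectly synchronous
    scans still yield a complete parameter set.
    """

    def one(mask: np.ndarray) -> float:
        mask = np.asarray(mask, dtype=bool)
        sig = maps.phase[mask]
        if sig.size < m + 2:
            raise ValueError("mask smaller than m+2 pixels")
        if sig.max() - sig.min() <= 0:
            warnings.warn(
                "uniform phase in mask: bounded ApEn undefined, returning 0",
                stacklevel=3,
            )
            return 0.0
        return bounded_apen(sig, m=m, r_frac=r_frac)

    apen_d = one(ed_mask)
    apen_s = one(es_mask)
    return apen_d, apen_s, (apen_d + apen_s) / 2.0


def shape_metrics(mask: np.ndarray, pixel_spacing=None):
    """Area, circularity and equivalent-ellipse axes of a region.

    Returns ``(area_px, area_mm2, circularity, elongation, long_axis,
    short_axis)``. Circularity is 4*pi*area/perimeter^2 with the
    perimeter measured by the 4-direction Crofton estimator (the least
    biased of skimage's boundary-length estimators on rasterised discs);
    elongation = long/short axis of the second-central-moment equivalent
    ellipse, always >= 1. ``area_mm2`` is ``None`` unless pixel spacing
    is known.
    """
    mask = np.asarray(mask, dtype=bool)
    area = int(mask.sum())
    if area < 5:
        raise ValueError("degenerate mask: fewer than 5 pixels")
    props = skmeasure.regionprops(mask.astype(np.uint8))[0]
    perimeter = skmeasure.perimeter_crofton(mask, directions=4)
    long_axis = props.axis_major_length
    short_axis = props.axis_minor_length
    if perimeter <= 0 or short_axis <= 0:
        raise ValueError("degenerate mask: zero perimeter or 1-pixel-wide line")
    circularity = 4.0 * np.pi * area / perimeter**2
    elongation = long_axis / short_axis
    area_mm2 = None
    if pixel_spacing is not None:
        sy, sx = pixel_spacing
        area_mm2 = float(area * sy * sx)
    return area, area_mm2, float(circularity), float(elongation), float(long_axis), float(short_axis)


def fractional_shortening(ed_axes, es_axes) -> tuple[float, float]:
    """Percent ED->ES shortening of the long and short axes.

    A negative value (ES axis longer than ED) is returned as-is; callers
    may flag it but it is not an error.
    """
    l_ed, s_ed = ed_axes
    l_es, s_es = es_axes
    if l_ed <= 0 or s_ed <= 0:
        raise ValueError("non-positive ED axis")
    return (
        100.0 * (l_ed - l_es) / l_ed,
        100.0 * (s_ed - s_es) / s_ed,
    )


def lung_heart_ratio(frame: np.ndarray, lung_roi: np.ndarray, lv_mask: np.ndarray) -> float:
    """Mean counts/pixel in the lung ROI over that in the LV.

    Measured on the time-averaged, background-uncorrected frame; the
    ratio is invariant to global count scaling.
    """
    frame = np.asarray(frame, dtype=float)
    lung_roi = np.asarray(lung_roi, dtype=bool)
    lv_mask = np.asarray(lv_mask, dtype=bool)
    if not lung_roi.any() or not lv_mask.any():
        raise ValueError("lung and LV masks must be non-empty")
    if (lung_roi & lv_mask).any():
        raise ValueError("lung and LV masks overlap")
    lv_mean = frame[lv_mask].mean()
    if lv_mean <= 0:
        raise ValueError("zero mean counts in LV mask")
    return float(frame[lung_roi].mean() / lv_mean)


def beat_statistics(meta: AcquisitionMeta):
    """Heart rate, beat duration, rejected-beat fraction and frame time.

    Heart rate and mean beat duration are interconvertible via
    HR = 60000 / beat_ms; whichever is absent is derived from the other.
    """
    hr, beat = meta.heart_rate, meta.mean_beat_duration
    if hr is None and beat is None:
        raise ValueError("both heart_rate and mean_beat_duration absent")
    if hr is None:
        hr = 60000.0 / beat
    if beat is None:
        beat = 60000.0 / hr
    rejected_fraction = None
    if meta.accepted_beats is not None and meta.rejected_beats is not None:
        total = meta.accepted_beats + meta.rejected_beats
        if total > 0:
            rejected_fraction = meta.rejected_beats / total
    return float(hr), float(beat), rejected_fraction, meta.frame_time


def _bbox_of(mask: np.ndarray) -> tuple[int, int, int, int]:
    rows = np.any(mask, axis=1).nonzero()[0]
    cols = np.any(mask, axis=0).nonzero()[0]
    return int(rows[0]), int(cols[0]), int(rows[-1]) + 1, int(cols[-1]) + 1


def _lung_roi_from_bbox(shape, bbox, offset_widths: float) -> np.ndarray | None:
    """Default lung ROI: a rectangle of bbox height placed laterally."""
    h, w = shape
    r0, c0, r1, c1 = bbox
    bw = c1 - c0
    centre = (c0 + c1) // 2
    half = max(2, bw // 4)
    for direction in (+1, -1):  # prefer the patient-lateral (image right) side
        lc = int(round(centre + direction * offset_widths * bw))
        lo, hi = lc - half, lc + half + 1
        if 0 <= lo and hi <= w:
            roi = np.zeros(shape, dtype=bool)
            roi[r0:r1, lo:hi] = True
            return roi
    return None


def compute_all(cine: GatedCine, seed: SeedPoint, config: AnalysisConfig | None = None) -> ParameterSet:
    """Run the full pipeline on a raw scan and return every biomarker.

    Stages: filter (default MMWF 5x5) -> background band measurement on
    the time-averaged frame and subtraction (location 1, width 4) ->
    first-harmonic maps -> ACRG segmentation -> parameter extraction.
    Provenance (filter, background value, seed, tool version) is recorded
    on the returned :class:`ParameterSet`. The pipeline is deterministic:
    the same scan, seed and config always give the same result.
    """
    from . import __version__

    cfg = config or AnalysisConfig()
    raw_avg = time_averaged_frame(cine)

    filtered = filter_cine(cine, cfg.filter_spec)
    avg = time_averaged_frame(filtered)

    rough = region_grow(avg, seed, cfg.rg_fraction)
    bbox = _bbox_of(rough)
    rois = build_background_rois(
        avg, bbox, width=cfg.background.width, margin=cfg.background.margin
    )
    bkg = measure_background(avg, rois[cfg.background.location - 1])
    corrected = correct_background(filtered, bkg)

    maps = first_harmonic(corrected)
    seg = acrg_segment(
        corrected,
        maps,
        seed,
        threshold_fraction=cfg.rg_fraction,
        max_iter=cfg.ac_iter,
        smoothing=cfg.ac_smoothing,
        phase_gate=cfg.phase_gate,
    )
    ed, es = seg.ed_frame, seg.es_frame
    ed_mask, es_mask = seg.masks[ed], seg.masks[es]

    tac = time_activity_curve(corrected, seg)
    lvef = compute_lvef(tac, ed, es)
    p_lvef = phase_lvef(maps, ed_mask)
    frame_time = cine.meta.frame_time
    ej_rate = ejection_rate(tac, ed, frame_time) if frame_time else None

    # Dyssynchrony statistics are measured over the LV "core" — pixels that
    # stay inside the blood pool on every frame. Pixels near the moving edge
    # spend part of the cycle outside the chamber, which clips their
    # count-time curves and shifts their first-harmonic phase (a
    # partial-volume artifact, not mechanics); the core excludes them.
    core_mask = np.logical_and.reduce(seg.masks)
    if not core_mask.any():
        core_mask = es_mask
    e_raw, e_norm, synchrony, mean_phase, phase_sd = phase_statistics(
        maps, core_mask, n_bins=cfg.n_bins
    )
    apen = approx_entropy(tac, m=cfg.apen_m)
    tac_range = tac.max() - tac.min()
    b_apen = bounded_apen(tac, m=cfg.apen_m, r_frac=cfg.apen_r_frac) if tac_range > 0 else 0.0
    apen_d, apen_s, apen_ds = apen_spatial(
        maps, ed_mask, es_mask, m=cfg.apen_m, r_frac=cfg.apen_r_frac
    )

    spacing = cine.meta.pixel_spacing
    ed_area, ed_mm2, circ_ed, elong_ed, ed_long, ed_short = shape_metrics(ed_mask, spacing)
    es_area, es_mm2, circ_es, elong_es, es_long, es_short = shape_metrics(es_mask, spacing)
    fs_long, fs_short = fractional_shortening((ed_long, ed_short), (es_long, es_short))

    lhr = None
    lung_roi = _lung_roi_from_bbox(cine.shape, bbox, cfg.lung_offset_bbox_widths)
    if lung_roi is not None and not (lung_roi & ed_mask).any():
        lhr = lung_heart_ratio(raw_avg, lung_roi, ed_mask)

    hr, beat, rejected_fraction, _ = beat_statistics(cine.meta)

    return ParameterSet(
        lvef=lvef,
        phase_lvef=p_lvef,
        ejection_rate=ej_rate,
        e_raw=e_raw,
        e_norm=e_norm,
        apen=apen,
        b_apen=b_apen,
        apen_d=apen_d,
        apen_s=apen_s,
        apen_ds=apen_ds,
        synchrony=synchrony,
        phase_sd=phase_sd,
        mean_phase=mean_phase,
        lhr=lhr,
        circ_ed=circ_ed,
        circ_es=circ_es,
        elong_ed=elong_ed,
        elong_es=elong_es,
        fs_long=fs_long,
        fs_short=fs_short,
        lv_size_ed=float(ed_area),
        lv_size_es=float(es_area),
        lv_size_ed_mm2=ed_mm2,
        lv_size_es_mm2=es_mm2,
        counts_ed=float(tac[ed]),
        counts_es=float(tac[es]),
        heart_rate=hr,
        mean_beat_duration=beat,
        rejected_fraction=rejected_fraction,
        frame_time=frame_time,
        provenance={
            "tool_version": __version__,
            "filter": cfg.filter_spec.kind,
            "kernel": cfg.filter_spec.kernel,
            "background_location": cfg.background.location,
            "background_width": cfg.background.width,
            "background_value": bkg,
            "seed": seed.as_tuple(),
            "rg_fraction": cfg.rg_fraction,
            "ed_frame": ed,
            "es_frame": es,
        },
    )
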