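"""Synthetic beating-LV phantom with analytic ground truth.

The left ventricle is modelled as a blood-filled ellipsoid whose volume
follows a raised-cosine systolic pulse,

    V(t) = EDV * (1 - EF * s(t)),

with s = 0 at end-diastole (frame 0) and s = 1 at end-systole. The three
semi-axes shrink isotropically, so a(t) = a0 * (1 - EF*s(t))^(1/3) and
likewise for b and c. Pixel intensity is activity times the projected
chamber thickness

    2 c(t) * sqrt(1 - (x/a(t))^2 - (y/b(t))^2),

which makes total LV counts exactly proportional to V(t): the count-based
ejection fraction of the phantom equals the volumetric EF by
construction, so EF recovery is a sharp end-to-end test. A uniform
background plateau and a lateral lung rectangle are added on top, and
Poisson counting noise is optional.

Mechanical dyssynchrony is emulated by splitting the LV into six angular
sectors and delaying the pulse of the first ``dyssync_sectors`` of them
by ``dyssync_delay`` degrees of cycle phase. An optional opposite-phase
"atrial" blob exercises the segmentation's ventricular phase gate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import AcquisitionMeta, GatedCine

__all__ = ["PhantomConfig", "PhantomTruth", "generate_phantom", "systolic_pulse"]


@dataclass(frozen=True)
class PhantomConfig:
    """Study conditions for one synthetic scan.

    Defaults emulate a typical resting acquisition: 16 frames, 64x64
    matrix, EF 0.60, about 1e4 LV counts at end-diastole, a background
    plateau of 3 counts/pixel and a dimmer lung field. ``ed_semi_axes``
    are (row, column, thickness) semi-axes in pixels at end-diastole.
    """

    image_size: int = 64
    n_frames: int = 16
    true_ef: float = 0.60
    ed_semi_axes: tuple[float, float, float] = (14.0, 11.0, 10.0)
    activity: float = 1.55
    background_level: float = 3.0
    lung_level: float = 1.5
    systolic_fraction: float = 0.375
    dyssync_sectors: int = 0
    dyssync_delay: float = 0.0
    poisson: bool = False
    rng_seed: int = 0
    pixel_spacing: float = 3.0
    heart_rate: float = 70.0
    atrial_blob: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.true_ef < 1:
            raise ValueError("true_ef must lie in (0, 1)")
        if not 0 <= self.dyssync_sectors <= 6:
            raise ValueError("dyssync_sectors must be in 0..6")
        if not 0 <= self.dyssync_delay < 360:
            raise ValueError("dyssync_delay must be in [0, 360)")
        if not 0 < self.systolic_fraction < 1:
            raise ValueError("systolic_fraction must lie in (0, 1)")
        if self.n_frames < 8:
            raise ValueError("n_frames must be >= 8")


@dataclass
class PhantomTruth:
    """Ground truth paired with a generated cine."""

    ef: float
    masks: list[np.ndarray]
    ed_frame: int
    es_frame: int
    sector_phase_offsets: np.ndarray  # degrees, one per sector
    volume_curve: np.ndarray  # analytic V(t), pixel^3
    lv_center: tuple[int, int]
    lung_mask: np.ndarray | None = None


def systolic_pulse(u: np.ndarray, systolic_fraction: float) -> np.ndarray:
    """Raised-cosine contraction pulse over cycle fraction ``u`` in [0, 1).

    0 at end-diastole, rising to 1 at ``u = systolic_fraction``
    (end-systole) and returning smoothly to 0 over diastole.
    """
    u = np.asarray(u, dtype=float) % 1.0
    ts = systolic_fraction
    rising = 0.5 * (1.0 - np.cos(np.pi * u / ts))
    falling = 0.5 * (1.0 + np.cos(np.pi * (u - ts) / (1.0 - ts)))
    return np.where(u <= ts, rising, falling)


def generate_phantom(config: PhantomConfig) -> tuple[GatedCine, PhantomTruth]:
    """Generate a gated cine and its ground truth from ``config``."""
    n = config.image_size
    t_frames = config.n_frames
    a0, b0, c0 = config.ed_semi_axes
    # LV centred vertically, shifted left to leave room for the lung field.
    crow, ccol = n // 2, int(round(0.35 * n))
    margin = 8
    if (
        crow - a0 < margin
        or n - 1 - crow - a0 < margin
        or ccol - b0 < margin
        or n - 1 - ccol - b0 < margin
    ):
        raise ValueError("LV overlaps the image border (margin < 8 px)")

    rr, cc = np.mgrid[0:n, 0:n].astype(float)
    drow, dcol = rr - crow, cc - ccol
    sector = (np.degrees(np.arctan2(drow, dcol)) % 360.0 // 60.0).astype(int)
    offsets = np.zeros(6)
    offsets[: config.dyssync_sectors] = config.dyssync_delay

    u = np.arange(t_frames) / t_frames
    ef = config.true_ef
    lv_stack = np.zeros((t_frames, n, n))
    for k in range(6):
        s_k = systolic_pulse(u - offsets[k] / 360.0, config.systolic_fraction)
        lam = (1.0 - ef * s_k) ** (1.0 / 3.0)
        in_sector = sector == k
        for t in range(t_frames):
            r2 = (drow / (a0 * lam[t])) ** 2 + (dcol / (b0 * lam[t])) ** 2
            thickness = 2.0 * c0 * lam[t] * np.sqrt(np.clip(1.0 - r2, 0.0, None))
            lv_stack[t][in_sector] += (config.activity * thickness)[in_sector]

    truth_masks = [lv_stack[t] > 1e-9 for t in range(t_frames)]

    # Extra-cardiac structures: uniform plateau plus a lateral lung field.
    noise_free = lv_stack + config.background_level
    lung = np.zeros((n, n), dtype=bool)
    lung_c0 = int(round(ccol + 3.0 * b0))
    lung_half = max(2, int(round(b0 / 2.0)))
    r_lo, r_hi = int(crow - a0), int(crow + a0) + 1
    c_lo, c_hi = lung_c0 - lung_half, lung_c0 + lung_half + 1
    if 0 <= c_lo and c_hi <= n:
        lung[r_lo:r_hi, c_lo:c_hi] = True
        noise_free[:, lung] += config.lung_level
    else:
        lung = None  # no room for a lung field at this geometry

    if config.atrial_blob:
        # Opposite-phase blob above the LV to exercise the phase gate.
        blob_c = (max(margin, int(crow - a0 - 6)), ccol)
        br2 = ((rr - blob_c[0]) / 4.0) ** 2 + ((cc - blob_c[1]) / 5.0) ** 2
        blob_shape = np.clip(1.0 - br2, 0.0, None)
        s_blob = systolic_pulse(u - 0.5, config.systolic_fraction)
        for t in range(t_frames):
            noise_free[t] += (
                config.activity * c0 * blob_shape * (1.0 - ef * s_blob[t])
            )

    if config.poisson:
        rng = np.random.default_rng(config.rng_seed)
        frames = rng.poisson(noise_free).astype(np.int64)
    else:
        frames = noise_free

    # Analytic volume curve: per-sector raised-cosine volumes with weights
    # taken from the rasterised end-diastolic sector shares.
    edv = 4.0 / 3.0 * np.pi * a0 * b0 * c0
    ed_thickness = lv_stack[0] / config.activity
    total0 = ed_thickness.sum()
    volume = np.zeros(t_frames)
    for k in range(6):
        w_k = ed_thickness[sector == k].sum() / total0
        s_k = systolic_pulse(u - offsets[k] / 360.0, config.systolic_fraction)
        volume += edv * w_k * (1.0 - ef * s_k)
    ed_frame = int(np.argmax(volume))
    es_frame = int(np.argmin(volume))

    beat_ms = 60000.0 / config.heart_rate
    meta = AcquisitionMeta(
        n_frames=t_frames,
        frame_time=beat_ms / t_frames,
        heart_rate=config.heart_rate,
        accepted_beats=200,
        rejected_beats=10,
        mean_beat_duration=beat_ms,
        pixel_spacing=(config.pixel_spacing, config.pixel_spacing),
    )
    cine = GatedCine(frames=frames, meta=meta)
    truth = PhantomTruth(
        ef=ef,
        masks=truth_masks,
        ed_frame=ed_frame,
        es_frame=es_frame,
        sector_phase_offsets=offsets,
        volume_curve=volume,
        lv_center=(crow, ccol),
        lung_mask=lung,
    )
    return cine, truth
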