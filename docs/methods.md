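# Methods

## Conventions

Frames are row-major with pixel (0, 0) top-left; frame 0 is the first
gated frame after the R-wave. Phases follow the cosine-with-positive-lag
convention `c(t) = A0 + A1·cos(2πt/T − φ)` in degrees on [0, 360): φ is
the within-cycle timing of a pixel's count maximum, and delaying the cine
by k frames adds 360k/T degrees to every phase. All times are
milliseconds, pixel spacing millimetres.

## Pipeline model and assumptions

The analysis assumes a planar gated acquisition in which pixel counts are
proportional to superimposed blood volume, background activity is an
approximately uniform additive plateau near the heart, and the LV is the
connected high-count structure around the operator's seed pixel whose
counts pulse once per cycle. Everything downstream of the raw counts is
deterministic: the same scan, seed and configuration always produce the
same parameter vector, and provenance (filter, background value, seed,
ED/ES indices, tool version) is recorded with each result.

### Filters

The bank offers mean and median smoothers plus two locally adaptive
estimators. The adaptive Wiener filter computes, over the k×k window,
the local mean μ and variance σ², estimates the noise power ν² as the
image-wide mean of σ², and returns
`out = μ + max(σ²−ν², 0)/max(σ², ν²)·(x − μ)`; the median-modified Wiener
filter (MMWF) substitutes the local median for μ in both occurrences,
which preserves edges better on low-count images. All filters use reflect
padding to avoid dark-border bias; on a constant image every member is the
identity, and on a linear ramp MMWF equals Wiener wherever the window sees
a pure ramp (the padded border breaks the ramp, so the identity holds on
the interior only). MMWF 5×5 is the pipeline default: on noisy phantoms
the change in downstream phase entropy when switching kernels 3↔5 is an
order of magnitude smaller for MMWF (~0.01) than for the mean or median
(~0.1), so the choice of kernel stops being a tuning liability.

### Background

Six candidate arc-band ROIs of configurable width (default 4 px) sit on a
ring `margin` (default 2) pixels outside the LV bounding box at 60°
spacing; location 1 is centred on the inferolateral border, the usual
clinical reference, and is the default source of the background value.
The exact geometry of the band is a package choice (the ring is the
natural parameterisation that keeps all six locations equidistant from
the chamber); the band is measured on the time-averaged frame by default
since averaging suppresses gating noise, and the measured mean is
subtracted from every frame with clipping at zero.

### Segmentation (ACRG)

Stage 1 grows a region from the seed on each filtered, background-
corrected frame. The growth rule visits 8-connected neighbours in
decreasing intensity order and accepts a pixel while its value is at
least `threshold_fraction` of the brightest value absorbed so far. The
default fraction is 0.25: for a projected-ellipsoid intensity profile
(∝ √(1−ρ²)) the p-of-peak contour sits at relative radius √(1−p²), so
the classic half-max rule would truncate the chamber at 87% of its
radius, while quarter-max recovers 97% of it and still sits far above
residual background after subtraction.

Stage 2 refines each initial contour with a shrink-only two-phase
(piecewise-constant) evolution on the phase-distance image — the angular
distance of every pixel's phase from the ventricular reference phase.
The reference is the amplitude-weighted phasor mean over the union of
stage-1 contours rather than the seed pixel's own phase: the chamber
centre has low contraction amplitude, so a single pixel's phase can
jitter by tens of degrees under counting noise. Pixels flagged as
low-amplitude are assigned the maximal distance (180°), since "no
contraction" carries no timing information and must not imitate the
ventricular phase. Pixels with phase more than 90° from the reference are
gated out before the evolution; atria and great vessels fill in phase
opposition and fall outside this gate. The evolution peels boundary
pixels whose value is closer to the outside mean than the inside mean,
applies `smoothing` (default 1) rounds of morphological opening, keeps
the seed's connected component, and stops at `max_iter` (default 200) or
when fewer than 0.1% of image pixels change. If a frame's contour
implodes below 25% of its initialisation the phase contrast was
insufficient on that frame and the stage-1 contour is kept instead.

Stage 3 re-grows the region from the same seed on the amplitude image,
bounded by the stage-2 contour (so stage-3 ⊆ stage-2 by construction),
and stage 4 applies the final masks to the count frames. ED and ES are
the argmax/argmin of the resulting time-activity curve, earliest frame on
ties.

### Parameters

* LVEF: `100·(EDC − ESC)/EDC` on the background-corrected TAC. Phase
  LVEF uses the first-harmonic identity EDC ≈ Σ(A0+A1), ESC ≈ Σ(A0−A1)
  over the ED mask. Ejection rate is the peak frame-to-frame count drop
  after ED, normalised by EDC and the frame duration (s⁻¹).
* Approximate entropy follows Pincus (Chebyshev distance, self-matches
  included, natural log), defaults m = 2 and r = 0.2·SD; the bounded
  variant sets r = r_frac·range(x) (default 0.2), making it invariant to
  affine rescaling. A literal brute-force implementation is kept as the
  oracle for the vectorised one (agreement to 1e-9). The diastolic and
  systolic spatial variants apply the bounded statistic to the row-major
  phase sequences inside the ED and ES masks; a perfectly uniform phase
  region has zero range, which is reported as 0 with a warning so that
  ideal synchronous scans still yield complete parameter sets.
* Dyssynchrony indices are computed over the LV *core* — the intersection
  of all per-frame masks. Pixels near the moving edge spend part of the
  cycle outside the chamber; the clipping distorts their first-harmonic
  phase by several degrees (a partial-volume artifact), and the core
  excludes exactly those pixels. Entropy uses the amplitude-weighted
  64-bin phase histogram (E in bits; bounded E = E/log2(64) ∈ [0, 1]; an
  unweighted switch is provided since conventions differ); synchrony is
  the normalised phasor magnitude; phase SD is the amplitude-weighted
  standard deviation of phases unwrapped around the circular mean.
  Histogram entropy separates dyssynchrony from synchrony sharply but
  saturates once a delayed cluster sits more than one bin from the main
  cluster — entropy sees bin masses, not distances — so at large delays
  phase SD and synchrony are the discriminating indices.
* Shape: area (pixels, and mm² when spacing is known), circularity
  `4π·area/perimeter²` with the 4-direction Crofton perimeter (the
  least-biased skimage estimator on rasterised discs: 0.97 for a radius-20
  disc, where the weighted-step estimator gives 0.91), and elongation from
  the second-central-moment equivalent ellipse. Fractional shortening is
  the relative ED→ES shortening per axis; a negative value (ES longer
  than ED) is reported, not raised. The lung ROI defaults to a rectangle
  of bounding-box height placed 1.5 box-widths lateral to the LV,
  measured on the raw time-averaged frame.

## The phantom

The LV is an ellipsoid with end-diastolic semi-axes (14, 11, 10) pixels
on a 64×64 matrix (3 mm pixels) whose volume follows
`V(t) = EDV·(1 − EF·s(t))` with a raised-cosine pulse `s` (0 at ED,
1 at end-systole, systolic fraction 0.375 of the cycle — a typical
resting value). The axes shrink isotropically and pixel intensity is
activity × projected chamber thickness, so total LV counts are exactly
proportional to V(t) and count-based EF equals volumetric EF by
construction. Defaults give ≈10⁴ LV counts at ED over a background
plateau of 3 counts/pixel with a dimmer lateral lung field; Poisson
sampling is optional and fully seeded. Dyssynchrony is emulated by
delaying the pulse of 0–6 angular sectors by a fixed cycle-phase offset;
an optional opposite-phase blob above the base exercises the ±90° gate.

What the phantom does *not* emulate: attenuation, scatter, overlapping
right-ventricular or atrial activity (beyond the optional blob), motion
or gating artifacts, and smooth intramural activation gradients (the
sector delay is piecewise-constant). Passing phantom tests therefore
demonstrates correct mechanics and noise robustness of the pipeline, not
clinical accuracy on patient scans. Two phantom-specific artifacts are
worth knowing: the projected geometry gives rim pixels clipped time
curves (the reason dyssynchrony statistics use the core mask), and a
filter kernel straddling a sector boundary mixes the two pulses, placing
a small number of pixels at intermediate phases.

## Statistics

The univariate screen fits each predictor separately by least squares and
keeps p < 0.2 (two-sided t). Stepwise selection is forward-by-smallest-p
(enter at p < 0.05) with backward elimination (remove at p > 0.10),
equivalent to partial F-tests; VIFs come from auxiliary regressions
(1/(1−R²ⱼ)), flagged above 10; exactly collinear candidates are rejected
up front with both offending names. With strong signal (SNR 5, n = 500)
the true predictors are always retained; note that any pure-noise
candidate still enters in ≈5% of replicates — that is the stated
p-to-enter operating, not a defect. ROC analysis labels LVEF < 54% as
abnormal, orients the score so that lower predicted LVEF is more
abnormal, and computes AUC by the tie-corrected rank (Mann-Whitney)
formula. Agreement between two methods reports Bland-Altman mean
difference and 1.96·SD limits with t-based CIs (SE of a limit taken as
SD·√(3/n)), Pearson r, Lin's concordance
`2·s_xy/(s_x² + s_y² + (x̄−ȳ)²)` with its bias-correction factor
C_b = CCC/r, and the two-way random-effects absolute-agreement
single-measure ICC; the ICC matches an independent implementation
(pingouin's ICC(A,1)) to 1e-9 in the test suite.

## Problem sizes in tests and the acceptance script

Phantom experiments use the default 64×64×16 geometry; EF recovery
averages 20 Poisson replicates, segmentation quality 5 (plus the
noise-free scan per frame), filter sensitivity 3, and the synthetic
cohort 60 scans — sizes at which every quantity is stable to well within
the asserted margins while the full suite runs in seconds.

## Known limitations

* The seed is operator-supplied; there is no automatic seed finder.
* Planar only: no SPECT reconstruction, no attenuation or scatter model.
* The ±90° phase gate cannot distinguish a ventricular segment delayed by
  ≥90° from non-ventricular structures; such extreme dyssynchrony relies
  on the reference phase rotating toward the delayed mass.
* Circularity inherits the raggedness of noisy masks (the perimeter grows
  with boundary noise), so it is best compared within a filter setting.
* DICOM support covers multi-frame nuclear-medicine images with standard
  gating tags; DICOM writing is out of scope (the HDF5 fixture container
  is the interchange format).
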