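# bloodpool

Quantitative analysis of ECG-gated planar blood-pool scans (MUGA /
radionuclide angiography), aimed at serial cardiac monitoring of patients
receiving cardiotoxic chemotherapy. From a single T-frame cine the package
extracts the left-ventricular ejection fraction together with a broad
vector of count-, phase-, shape- and time-based biomarkers, and provides
the downstream statistics (univariate screen, stepwise regression,
variance-inflation check, ROC at the abnormal-LVEF cutoff, Bland-Altman /
Lin's CCC / ICC agreement) used to relate those biomarkers to ventricular
function.

## The method

A gated acquisition averages many cardiac cycles into T frames (typically
16) of counts proportional to regional blood volume. The pipeline is:

1. **Denoising** — mean, median, adaptive Wiener or median-modified Wiener
   (MMWF) filter at 3×3 or 5×5; the MMWF 5×5 is the default because its
   output is nearly insensitive to kernel size.
2. **Background correction** — a 4-pixel band just outside the LV
   (six candidate locations at 60° spacing; location 1, on the
   inferolateral border, is the default) is averaged on the time-averaged
   frame and subtracted from every frame, clipping at zero.
3. **First-harmonic analysis** — per pixel, the count-time curve is fit as
   `c(t) = A0 + A1·cos(2πt/T − φ)`, giving DC (A0), amplitude (A1) and
   phase (φ, degrees) images.
4. **ACRG segmentation** — a hybrid of region growing (RG) and a
   shrink-only active contour (AC): seeded RG on each frame gives initial
   contours; the AC refines them on the phase image, gated to ±90° of the
   ventricular phase so structures in phase opposition (atria, great
   vessels) are excluded; RG on the amplitude image, bounded by the
   refined contour, yields the final per-frame masks. End-diastole (ED)
   and end-systole (ES) are the extrema of the time-activity curve (TAC).
5. **Parameters** — `LVEF = 100·(EDC − ESC)/EDC` on the
   background-corrected TAC; first-harmonic ("phase") LVEF; peak ejection
   rate; Shannon entropy E of the LV phase histogram (raw and normalised
   to [0, 1]); synchrony `S = |Σ A·e^{iφ}| / Σ A`; phase SD; Pincus
   approximate entropy of the TAC and of the spatial phase sequences in
   the ED/ES masks (plain and range-bounded); lung-to-heart ratio;
   circularity, elongation, long/short-axis fractional shortening,
   chamber sizes; heart rate, beat duration and rejected-beat fraction.

A synthetic beating-LV phantom (shrinking ellipsoid, projected-thickness
intensity, optional Poisson noise, per-sector phase delays, background
plateau and lung field) provides exact ground truth for every stage; see
`docs/methods.md`.

## Worked example

Generate a noisy phantom with true EF 60% and analyse it:

```sh
bloodpool phantom --ef 0.6 --poisson --seed 11 --out demo.h5
bloodpool analyze --input demo.h5 --seed 32,22 --out demo_params.csv
```

The analysis log prints `LVEF 58.5%, synchrony 0.961`, and the CSV holds
the full parameter vector, including:

| parameter | value | meaning |
| --- | --- | --- |
| `lvef` | 58.49 | count-based ejection fraction, % (true value 60) |
| `phase_lvef` | 57.53 | first-harmonic EF estimate, % |
| `ejection_rate` | 2.96 | peak systolic emptying, EDC fractions/s |
| `synchrony` | 0.961 | phasor coherence of LV pixel timing (1 = uniform) |
| `phase_sd` | 16.3 | spread of contraction timing, degrees |
| `lv_size_ed` / `lv_size_es` | 370 / 204 | chamber area, pixels |
| `fs_long` / `fs_short` | 25.9 / 28.7 | axis fractional shortening, % |
| `lhr` | 0.218 | lung-to-heart count ratio |

The residual 1.5-point EF error and the 16° phase spread reflect the
Poisson counting noise; on the noise-free phantom the pipeline returns
LVEF 60.4% with phase SD 0.4°.

DICOM scans are read the same way (`--dialect dicom`); gating metadata
(frame time, heart rate, accepted/rejected beats, pixel spacing) is taken
from the standard tags and never defaulted when absent.

For cohort tables, `bloodpool model --table params.csv --outcome lvef_post`
runs the univariate screen (p < 0.2), stepwise regression
(p-enter 0.05 / p-remove 0.10, VIF > 10 flagged) and the ROC at the
LVEF < 54% abnormality cutoff; `bloodpool agree` reports Bland-Altman
limits, Lin's concordance and ICC(2,1) between two measurement columns.

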