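# Methods

This note documents the models, parameter choices and numerical conventions
behind `zfcardio`, and what the synthetic-data experiments do and do not
demonstrate about real microscopy data.

## Conventions

Image arrays are ordered `(time_or_z, row, column)` with row 0 at the top
and x increasing with the column index. Lengths are µm, areas µm², volumes
µm³ internally; reports additionally express volumes in nL (1 nL = 10⁶ µm³)
and cardiac output in nL/min, the natural magnitudes for an embryonic heart
(EDV ≈ 0.2–0.6 nL, CO ≈ 20–80 nL/min). Frame *i* is timestamped *i*/fps
seconds. Calibration (fps, µm/px, z-step) is always user-supplied and never
inferred from pixel data; a missing calibration field is an error, never a
silent default of 1.

## Cardiac quantification

**Segmentation.** Per frame: global Otsu threshold on the gray-value
histogram (polarity-aware; a fixed threshold can be forced), hole filling,
largest connected component. `area_series` applies exactly this per-frame
chain but vectorised across the movie (stacked per-frame histograms, hole
filling and labelling with an in-plane-only structuring element so frames
never interact); a test asserts bit-equality with the per-frame route.

**Ellipse fit.** The "fit-to-ellipse" step is the moments-equivalence
ellipse: centroid plus second central moments of the region, axis lengths
4√λ of the covariance eigenvalues. Treating each pixel as a unit square adds
1/12 per-axis variance, which removes the small-region bias (a rasterised
disc of radius r recovers axis 2r). Collinearity is tested on the raw
pixel-centre moments, so a one-pixel-wide line is still rejected as
degenerate. For circular regions the orientation is reported as 0 by
tie-break.

**Beat detection.** The area trace is smoothed with a centred moving
average of round(fps/10) frames (~0.1 s — suppresses rasterisation jitter,
preserves 2–4 Hz cardiac dynamics). The dominant period comes from the
first major autocorrelation peak; end-diastoles are maxima and end-systoles
minima with a minimum separation of 0.4× that period, forced to alternate
strictly (the more extreme event of a same-type run wins). A boundary
maximum at frame 0 counts as a diastole, because acquisitions start at
end-diastole by protocol. Peak times are refined to sub-frame resolution by
parabolic interpolation; heart rate is 3·60/Δt with Δt the refined time
from diastole *i* to *i*+3 (the first available three-beat window — the
deterministic reading of "interval between three heartbeats").

**Report.** All parameters are computed in triplicate over the first three
complete diastole→systole→diastole beats and averaged. EF uses the averaged
SV over the averaged EDV (the formula's already-averaged quantities), not a
mean of per-beat ratios. A perfectly flat area series (a non-contracting
ventricle) cannot yield a beat interval; the report then carries zero
contraction indices, hr_bpm = 0 and a `flat_series` flag rather than an
error, so that CO = HR·SV = 0 holds degenerately.

**Edema and morphometrics.** Pericardial area is the rasterised polygon of
user-supplied landmarks minus the ventricle mask (automated landmark
detection is out of scope); interorbital distance and body length are
calibrated Euclidean distances between landmark pairs.

## Velocimetry

Particles are detected by thresholding halfway between the median intensity
(a robust background estimate — cells cover well under 1% of the field) and
the extreme intensity; Otsu's criterion is deliberately *not* used here
because with so small a foreground fraction it splits the background noise
instead. Blobs touching the frame border are discarded (their clipped
centroids bias velocity), and centroids are intensity-weighted for
sub-pixel accuracy. Linking is greedy mutual-nearest-neighbour in order of
increasing displacement, which resolves crossings toward the smallest total
displacement and is deterministic; it is adequate for the sparse, few-cell
fields this pipeline targets and would not be for dense scenes.

A track's velocity is the mean frame-to-frame displacement magnitude ×
pixel size × fps. Vein mode scores the three longest tracks over ten
consecutive frames from track start (venous flow is non-pulsatile); aorta
mode scores the three longest tracks over their entire length so the fast
and slow phases of pulsatile flow cancel — the whole-sequence reading of
averaging "over the whole imaged area". A regression test demonstrates the
motivation: a ten-frame window at the pulse peak overestimates the mean by
>20%.

## Vessel volumetry

Otsu threshold over the full stack, 26-connected 3D labelling, then either
the component containing a seed voxel or the largest component is kept —
the transparent counterpart of eliminating interfering vessels in an
interactive surface tool. Volume is foreground voxel count × the full
anisotropic voxel volume (z-step × pixel² for confocal stacks). Because
surface-smoothing parameters of commercial reconstructions are not
reproducible, absolute volumes are comparable only within this pipeline.

## Statistics

The comparison layer follows the mean ± s.d. (n−1) convention and a
normality-gated two-test policy: D'Agostino–Pearson omnibus K² per group
(requires n ≥ 8; smaller groups count as "too small to test" and default to
the t-branch), then a pooled-variance two-tailed unpaired Student's t-test
when both groups pass at α = 0.05, else a two-tailed Mann–Whitney U. Either
test can be forced. The Mann–Whitney null distribution is enumerated
exactly (dynamic programme over rank sums) when n₁·n₂ ≤ 400 and the data
carry no ties; otherwise a normal approximation with continuity correction
and tie-corrected variance is used. All statistics are computed from their
defining formulas; SciPy supplies only special functions (regularised
incomplete beta for the t tail). Degenerate inputs — zero variance in both
groups — are flagged and yield p = 1 (equal means) or p = 0 (unequal).
Screening efficiencies are rounded half-up to one decimal. No
multiple-testing correction is applied anywhere, matching the source
workflow; the cohort runner therefore reports raw per-metric p-values (see
the caveat below).

## Synthetic data

The generators render what the measurement side assumes, plus controllable
corruption:

- **Heart**: a filled ellipse whose axes follow a raised cosine between
  systolic and diastolic extremes, a(t) = a_s + (a_d − a_s)(1 + cos 2πft)/2,
  so frame 0 is exactly end-diastole and the extremes are attained exactly.
  The waveform is a modelling choice — only the two extremes are
  physiologically prescribed. Defaults (120×80 µm diastole, 100×60 µm
  systole, 180 bpm, 150 fps, 10 s, 2 µm/px) give ~30 cycles per clip at
  healthy-larva magnitudes.
- **Flow**: dark discs advected along +x, constant (vein) or
  v(t) = v(1 + m sin 2πf_p t) (aorta, closed-form positions, m < 1 so flow
  never reverses); cells re-enter at x = 0. No vessel walls are drawn —
  velocimetry needs only moving cells.
- **Vessels**: a torus (ring radius R, tube radius r, axis along z; volume
  2π²Rr²) with an optional disconnected straight tube through the ring's
  hole as the interfering vessel. Defaults emulate a 250-slice stack at
  1 µm slice interval.

Rasterisation is pixel-centre-inside; noise is additive Gaussian clipped to
the dtype range; identical parameters and seed give bit-identical output.
What these generators deliberately omit: motion blur, illumination
gradients, out-of-focus light, neighbouring organs (atrium, yolk), cell
deformation and photobleaching. Passing the recovery experiments therefore
shows the *computational* chain is correct and calibrated — not that
segmentation will survive arbitrary real-world image quality.

## Cohorts and the validation experiments

`run_cohort` simulates each individual with seed = base_seed + running
index and optional per-individual biological jitter (default cv 5%,
truncated at ±3 cv) along three natural axes: overall heart size, heart
rate, and contractility (the systolic/diastolic axis ratio), plus velocity
and vessel radii for the other modalities. Group comparisons use the auto
policy per metric.

Problem sizes in the tests and the reproduction script are chosen for desk
scale: recovery experiments use 96-px frames at 2 µm/px and 2.4-s clips
(enough for four diastoles at 120 bpm); the cohort experiments use 64-px
frames at 3 µm/px and 1.8-s clips so that hundreds of 30-animal cohorts are
cheap. Generator defaults keep the full acquisition geometry.

The null-cohort experiment follows the identical-groups design: both groups
share one parameter set and differ only in per-individual seeds. At the
default noise (s.d. 6 on a 150-unit object/background contrast, ~12σ per
pixel from the threshold) segmentation is exactly reproducible, so
identical groups measure identically, the comparison layer flags the
zero-variance ties and returns p = 1, and no replicate can fabricate a
group difference. The power experiment scales the mutant's axes by
1.5^(1/3) (+50% EDV, SV and CO) and is detected in every replicate.

The jittered variants of the same experiments are also implemented
(``param_cv > 0``) and reported alongside. They expose an inherent caveat
of the screen design rather than of the pipeline: eight metrics are
compared per cohort without multiplicity correction (matching the source
workflow), so once every metric genuinely varies between animals, the
family-wise chance that *some* metric dips below α = 0.01 is
1 − 0.99⁸ ≈ 7.7% discounted by the correlation between metrics — measured
at 3–7 replicates per 100 across jitter and noise settings. A real screen
should correct for multiplicity or confirm hits on an independent cohort.

## Known limitations

- Single dominant ventricle assumed per frame; no atrium/ventricle
  disambiguation (real movies need a crop or a polarity/threshold choice).
- The prolate-spheroid volume model inherits its usual bias for
  non-ellipsoidal chambers; values are comparable within, not across,
  methodologies.
- Greedy linking can swap identities in dense or fast-crossing scenes.
- Mann–Whitney p-values with heavy ties rely on the normal approximation.
- Vessel volumes depend on the threshold; only threshold-consistent
  comparisons are meaningful.
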