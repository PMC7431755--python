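# Methods

This note documents the generative model behind `hccapa.synthgen`, the
segmentation and selection procedures, the statistical layer, and the
numerical and design choices a maintainer should know about.

## Generative model of the assay

One simulated cell carries a latent state: log-normal HaloTag–GFP
expression `E` (median 1.0, CV 0.35 by default), a damage flag
(Bernoulli, default p = 0.15, optionally ramping with transporter
concentration via `p_damaged_slope`), and — in transient mode — an
expression class drawn from `transient_mix` (default 20% non-expressers at
~0 expression, 20% normal, 60% over-expressers at ≥10× the median).  The
chloroalkane mechanism enters as the blocked HaloTag fraction

    θ(c) = c^h / (c^h + CP50^h),  defaults CP50 = 7.3 µM, h = 1,

applied uniformly to all cells of a well.  The functional form and the
slope are modelling choices — the assay only *defines* CP50 as the
half-maximal penetration point — and both are exposed in the
configuration.

Channels are rendered at 512×512 px (0.65 µm/px, ~60 cells/field placed on
a jittered grid whose margin keeps segmented bodies clear of the border):

* **nuclear stain** — Gaussian blobs (σ = 5 px); damaged cells are
  condensed and brighter (0.55σ, 1.8× amplitude), the standard
  early-apoptosis proxy;
* **GFP** — the organelle texture at amplitude `gfp_gain·E`:
  random-walk filaments for mitochondria, a peri-nuclear punctate cluster
  for Golgi, scattered specks for damaged (fragmented) networks, and a
  soft-edged whole-body fill for over-expressers (a sharp-edged fill would
  leave a physically meaningless dark rim between the rendered edge and
  the segmented boundary);
* **reporter** — amplitude `reporter_gain·E·(1−θ)·η` on the same texture,
  where η is a per-cell labeling-efficiency factor (log-normal, CV 0.05);
  this biological noise is what keeps the per-cell GFP–reporter r² near
  0.98 rather than exactly 1.

**Off-target dye.**  The reporter is added at a fixed dose; when HaloTags
are blocked, the unreacted excess accumulates at saturable non-specific
sites.  The integrated off-target signal per cell is

    offtarget_amplitude · (reporter_gain·E·A_organelle) · θ/(θ + K),

split over `offtarget_puncta_per_cell` Gaussian puncta placed inside the
body but strictly outside every organelle texture (defaults: amplitude
0.15 of the maximal integrated specific signal, K = 0.4, 4 puncta).  Two
properties follow.  First, because the off-target term is a *saturating*
(not affine) function of θ, the whole-cell dose–response is right-shifted:
its apparent midpoint exceeds the true CP50 (≈ +1 µM at the defaults),
while the organelle-restricted readout is unbiased — any off-target model
affine in θ would be absorbed by the free asymptotes of a 4PL fit and
could not reproduce a mask-dependent CP50.  Monotonicity of the whole-cell
response is guaranteed for amplitude ≤ K.  Second, the off-target
amplitude fluctuates between wells (log-normal, CV 0.5; staining/wash
batch effects), so the whole-cell readout carries extra well-level noise
that the organelle mask never sees — this is why the organelle CP50 comes
with the smaller replicate SEM.

**Camera.**  counts = offset + g·Poisson(signal/g) + N(0, σ_read), clipped
to 16 bit, with g = 0.5 counts/e⁻, σ_read = 3, offset = 100 (a standard
sCMOS approximation).  `noise=False` reduces this to adding the offset and
also disables the labeling noise, giving exact-signal oracle images.

**Determinism.**  Every field draws from an RNG stream seeded by
(master seed, CRC32(well id), field index); off-target placement uses a
derived substream so rendered textures are bit-identical across off-target
settings.  Plates rebuilt with the same seed are byte-identical.

## Segmentation

* *Nuclei*: Otsu threshold on a σ=2 smoothed nuclear channel,
  distance-transform watershed to split touching nuclei, area filter
  (30–2500 px).  A guard requires the Otsu threshold to clear the robust
  background by 5 SDs, so blank fields yield zero nuclei.
* *Cell bodies*: seeded watershed from the nuclei over the sum of the two
  smoothed channels (each scaled by its background SD), constrained to a
  foreground where either channel exceeds background by 4 SDs and to a
  42 px radius around the nucleus; bodies are disjoint, contain their
  nucleus, share its label, and border-touching cells are discarded.
* *Organelle mask*: per cell, white-top-hat GFP (square structuring
  element of half-width 4 px — separable, ~10× faster than a disk and
  equivalent here) above the cell's median + 3·MAD; components below 4 px
  are removed as single-pixel noise excursions, which would otherwise
  dominate the fragmentation index.
* *Dark region*: body pixels with raw GFP ≤ background + 3 SD.
* *Background*: the level is a shortest-interval mode (centre of the
  narrowest window holding 5% of pixels, tie runs centred — quantised
  intensities produce long tie runs), and the SD comes from the lower
  half-distribution only.  This estimator survives the transient
  scenario, where bright over-expressers can cover most of a field and
  both the median and the symmetric MAD fail.

Coordinates are 0-based (row, col); labelling is 4-connected, watershed
basins 8-connected.  These choices are ordinary HCS practice and are not
claimed to match any particular commercial software.

## Cell selection

*Damaged-cell filter.*  A cell is flagged when its nuclear area falls
below, nuclear intensity rises above, or organelle fragmentation index
(components per unit mask area) rises above control-calibrated bounds:
median ± 4·(1.4826·MAD) of the untreated control wells, in the damage
direction.  Robust location/scale is essential — the controls themselves
contain the ~15% damaged cells, so percentile-based bounds would sit
inside the damaged subpopulation and flag almost nothing.

*Transfection gate* (transient mode only).  A cell is removed when its
dark-region fraction is below 0.25 (GFP throughout the body: an
over-expresser) or its organelle GFP mean is below 15 background SDs (a
non/under-expresser; an empty organelle mask counts as such).  The 15 SD
floor is deliberately far above the ~3.5 SD upper-tail selection bias that
any threshold-derived mask exhibits on a non-expressing cell, and far
below genuine expression (~300 SD at the defaults).

## Statistics

* *Mask-accuracy r²*: OLS of reporter on GFP across selected cells
  (pooled, computed on untreated controls in the pipeline); undefined for
  n < 3 or zero predictor variance.
* *Dose–response*: per well, the median over selected cells of the
  per-cell reporter/GFP ratio under the chosen mask.  The ratio is the
  natural CAPA response — reporter and GFP are both proportional to the
  HaloTag count, so it tracks the free-HaloTag fraction and cancels the
  broad expression distribution, which at desk scale (~60–120 cells/well
  rather than thousands) would otherwise dominate the CP50 error.  The
  4PL is fitted by Levenberg–Marquardt least squares with CP50 and slope
  in log space (tolerances 1e-8; start: top = max, bottom = min, CP50 =
  geometric mid of the tested concentrations, slope 1); c = 0 wells enter
  as exact top-asymptote observations.  The headline parameters come from
  a pooled fit; `se_cp50` is the SEM of per-replicate CP50s (the
  single-fit covariance SE is kept as a diagnostic — whether replicate
  SEM or fit covariance is the better error model is genuinely open, so
  both are reported).  A response span below 3× the residual noise is
  flagged non-convergent with no CP50.
* *Toxicity*: percent of selected cells relative to the untreated-control
  mean, SEM over replicate wells.
* *Mask comparison*: one-tailed paired Student's t-test across replicate
  CP50s with the alternative fixed a priori as whole-cell > organelle
  (the direction the off-target mechanism implies); no multiple-testing
  correction (single planned comparison).  Zero-variance differences with
  zero mean resolve to t = 0, p = 0.5 by convention; with non-zero mean
  the p-value is reported at the machine floor with a warning.

## Problem sizes

Validation workloads are desk-scale by design: ~10⁴ cells (167 fields)
for the filter/gate recovery rates, 9-concentration × 3-replicate plates
(~27 fields) for CP50 recovery, and n = 5000 pairs for the analytic r²
recovery, where the sampling SD of r̂² at ρ = 0.626 is ≈ 0.008 — sharp
recovery statements at that ρ therefore average several independent
draws.

## What the generator does and does not emulate

It reproduces the assay's structure — expression heterogeneity, Hill-type
blocking, mask-dependent off-target bias, damage morphology, transfection
mixtures, camera noise — so passing tests show the *analysis chain* is
correct and unbiased under known ground truth.  It does not model optics
(PSF, defocus), cell shape diversity, touching/overlapping cells beyond
mild crowding, endosomal uptake dynamics, time dependence, or the true
(unknown) off-target statistics of any real dye; recovery results
therefore do not certify segmentation accuracy on real images, only the
correctness of the measurement and inference machinery downstream of
masks of comparable quality.

## Known limitations

* The damage morphology is a nuclear-condensation + fragmentation proxy;
  real early apoptosis is richer.
* The dose–response aggregation assumes the reporter/GFP ratio is
  expression-independent; strong saturation or quench effects would break
  this.
* With only 3 replicates the SEM of a CP50 is itself noisy (χ², 2 df);
  mask-comparison p-values at desk scale sit near the significance
  boundary by construction.
* Whole-cell and organelle r² differ little on untreated controls because
  dye-excess off-target vanishes without transporter; the r² gap grows
  with occupancy.
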