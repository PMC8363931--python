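# Methods

`mesozone` reproduces, as tested and seedable code, a pixel-based analysis
chain for multiplexed-fluorescence immunohistochemistry (mfIHC) of tissue
microarray (TMA) cores, together with the survival statistics used to screen
marker variables: compartment segmentation, concentric stromal distance
zones, per-patient "average mean intensity" variables, positive-area
fractions, and scaled Cox proportional-hazards screens.  Because no public
patient images exist for this kind of study, the package ships a phantom and
cohort simulator whose ground truth acts as the oracle for every stage.

## Image model and phantoms

A core is a square raster containing one circular 1.0 mm tissue core.
Pixel centres sit at (i + 0.5, j + 0.5)·`pixel_size_um` (0-based, row-major)
and a pixel belongs to a geometric shape iff its centre lies inside.  This
convention makes every area statement an exact point-in-disc count, so
rasterized areas agree with πr²/pixel_area to the boundary-rasterization
level (≈2% for a 100 px-radius disc).

Discs placed inside the core define tumor nests, blood vessels and
autofluorescent debris, with precedence debris → vessel → tumor; the rest of
the core is stroma, and pixels outside the core disc are background.  The
four masks (autofluorescence, vessel, background, tissue) partition the
frame exactly; tumor and stroma partition tissue exactly.

Each channel is rendered as

    I(p) = baseline + offset[compartment(p)]
           (+ slope · d_tumor(p) on stroma, optionally)
           + ε,  ε ~ N(0, noise_sd), clamped to [0, 1]

where `d_tumor` is the Euclidean distance (μm) from the tumor compartment.
Intensities are unitless floats in [0, 1]; the original scanners' bit depth
is not modelled.  Ground truth stores the analytic expectation of every
channel over every compartment.  With noise on, the expectation uses the
closed-form mean of the clamped Gaussian, so compartments rendered near an
intensity bound (e.g. background at 0.02 with SD 0.05) remain exactly
predictable; without noise the expectation equals the clean compartment
value, and the rendered means match it to machine precision.

The default panel mirrors a two-round staining design: a nuclear
counterstain per round, tumor-cell markers (CK5 in round 1; a combined
CK5/CK5-6/calretinin channel in round 2) and seven fibroblast markers
(PDGFRA, PDGFRB, aSMA, FAP; SPARC, POSTN, collagen I).  Simulated "round 2"
acquisitions are translated by a random integer stage offset of up to ±3 px
so the registration stage has something to recover.

What the phantoms deliberately do **not** emulate: cell-level texture,
nuclei, point-spread blur, spectral bleed-through, and non-rigid section
deformation.  Tests passing on phantoms therefore demonstrate the
correctness of the measurement chain (masking → compartments → zones →
means → Cox), not robustness to optical artefacts of real scanners.

## Registration and QC

Staining rounds of the same physical section differ mainly by a stage
offset, so registration is a rigid integer-pixel translation chosen by
exhaustively maximizing the normalized cross-correlation of the shared
nuclear channel over shifts up to `max_shift_um` (default 50–60 μm).  A
constant reference channel, or a maximum on the search boundary, raises a
registration error.  Fusion never alters round-1 pixels; round-2 channels
are shifted back and pixels that leave the frame are flagged invalid and
excluded from every downstream mask and mean.  Spot QC computes the tissue
fraction of the nominal core disc; the threshold (default 0.1) is inclusive,
and failed spots are dropped whole.

## Segmentation

Masking uses a random-forest pixel classifier (the model family of
scribble-trained histology maskers) over per-channel intensity plus
Gaussian-smoothed intensity at σ ∈ {1, 2} px — 3 features per channel.  The
four classes are predicted jointly; argmax of the per-class posteriors gives
the masks, and the posteriors are retained, the tissue posterior doubling as
the per-pixel confidence used by the positive-area filter (default ≥ 0.85).
In simulation the forest is trained on ground-truth-labelled pixels drawn
from phantoms that span the per-patient marker-offset distribution; training
on a single fixed-intensity phantom demonstrably fails to generalize, which
is why the default training pool is 4 phantoms × 1500 px/class.  Training is
deterministic given the seed.

Tissue is split into the mesothelioma (tumor-cell) compartment and stroma by
thresholding the pixelwise maximum of the Gaussian-smoothed (σ = 2 px)
tumor-marker channels; the default threshold is Otsu over tissue pixels,
overridable.  Closing-then-opening with a radius-2 disc removes interface
speckle; the cleanup is skipped when the threshold puts all tissue on one
side (there is no interface to clean), which keeps tumor area monotone
non-increasing in the threshold — both morphological operators are
inclusion-monotone.  Vessels are never part of tumor or stroma.

## Distance zones

Stroma is decomposed into rings of width w = 12 μm (four by default) around
a source compartment — the tumor-cell mask ("meso" zones) or the vessel mask
("vessel" zones).  Distance is centre-to-centre Euclidean distance in μm to
the nearest source pixel; ring k is the half-open shell ((k−1)w, kw] with
ceil labelling, so a stroma pixel adjacent to the source (d = pixel size)
is ring 1 and d = w exactly is still ring 1.  Stroma beyond ring n keeps
label 0 but still counts toward "total stroma" variables.  Meso and vessel
rings are computed independently; a pixel may carry both.

Implementation detail that matters for exactness: the distance transform's
feature indices are used to recompute d = √(Δi² + Δj²)·px with the same
float expression the brute-force nearest-source oracle uses, so the two
routes agree bit-for-bit, not merely within tolerance.

Known bias, quantified: because distance is measured to the nearest source
pixel *centre* (which lies inside the rasterized disc boundary), the
innermost ring's outer edge sits ≈0.4 μm short of the ideal circle.  At
2 μm pixels around a 120 μm disc this depresses the ring-1 pixel count by
3.3% relative to the ideal annulus π[(r+w)² − r²]; rings 2–4 are within
1.3–2.8% because the offset cancels between their boundaries.  Any
implementation using the centre-to-centre convention shares this bias; it
shrinks linearly with pixel size.

## Quantification

The analysis variable is the *average mean intensity*: the arithmetic mean
of a marker over a compartment's (valid) pixels in one core, averaged over
the patient's QC-passed cores.  Variables are named `<MARKER>_<comp>` with
10 compartments per marker (meso, stroma, meso_Z1..Z4, vessel_Z1..Z4) — 70
variables for the 7 fibroblast markers.  Empty masks yield missing values
(never 0) and missingness propagates into complete-case survival models.
Before Cox modelling every intensity is multiplied by 1,000 (once; double
scaling errors out) so hazard ratios per unit are readable.

The positive-area fraction takes tumor pixels with classifier confidence
≥ 0.85, calls those at or above an intensity threshold (default Otsu over
tumor pixels) positive, and reports 100·positive/eligible.  Per-patient
pooling aggregates areas across cores before forming the ratio
(area-weighted), the natural estimator of the pooled fraction.

## Survival statistics

The Cox partial likelihood with Efron tie handling is maximized by Newton
iterations (analytic gradient and Hessian, step halving, convergence at
gradient ∞-norm < 1e−8, ≤100 iterations) on internally standardized
covariates; coefficients are reported on the original scale, which makes the
linear-predictor invariances exact — adding a constant leaves β unchanged
and scaling by c divides β by c (exactly the ×1000 convention).  Monotone
likelihoods (perfect separation) and singular information matrices raise
errors rather than returning garbage.  Tie-free data takes a fully
vectorized path (Efron reduces to Breslow), which is what makes the
500-replicate calibration simulations cheap.  Confidence intervals and
p-values are Wald (exp(β ± 1.96·SE)); tests cross-check β and SE against an
independent implementation to 1e−5 and against direct scalar maximization
of a hand-coded partial likelihood to 1e−6 on tiny datasets.

The proportional-hazards diagnostic computes Efron-averaged Schoenfeld
residuals per event and applies the Grambsch–Therneau score test of the
scaled residuals against event time (identity transform): per covariate
χ²₁ = d(Σ(g−ḡ)·cov·r)ⱼ² / (covⱼⱼ·Σ(g−ḡ)²), plus a global χ²ₚ.  Under
proportional hazards the 0.05 rejection rate is 2–9% in simulation; a
sign-flipping effect is detected in the majority of replicates.

Bonferroni correction is min(1, m·p) with the family size m explicit
(default: number of screened variables; m = 70 reproduces the worked
examples 0.03 → 1.00 and 0.0006 → 0.04).  The log-rank test delegates to a
standard survival library; Mann–Whitney uses exact enumeration for
n_x·n_y ≤ 400 without ties and the tie-corrected normal approximation
otherwise; Spearman uses exact permutation enumeration for n ≤ 8 and the
t approximation above.

`run_screen` joins the scaled table to the cohort, fits one univariate Cox
per variable (Bonferroni over m), then any requested multivariable models
with the clinical adjusters age, sex, side, stage (dichotomized I–II vs
III–IV) and histology, dropping adjuster dummies that are constant in the
complete cases with a warning.  Reports carry n_used per model.

## Cohort simulator

Death times are exponential with hazard h₀·exp(β·x_scaled); any
proportional-hazards generator would do and the exponential has closed-form
sampling.  Censoring is administrative: C ~ Uniform(0, H) with H calibrated
by bisection on the realized death times to hit the requested expected
censoring fraction (default 3/74 ≈ 4%).  Clinical covariates follow a
mesothelioma surgical-series profile (median age 65, 84% male, 93%
epithelioid, ~even stage split).  The default marker distribution
Beta(2, 50) puts the ×1000-scaled variable at SD ≈ 26, so β = ln 1.02 per
scaled unit is a strong but realistic effect; the imaging pipeline's
end-to-end simulations use Uniform(0.05, 0.45) for the injected tumor-cell
offset so the marker spans the renderable intensity range.

## Pipeline and reproducibility

`run_pipeline` executes simulate → register/QC → segment → zones → quantify
→ screen, writing stable filenames plus a manifest with the config hash.
The single global seed is fanned out per stage by CRC-32 hashing of the
stage name, so identical configs reproduce every numeric output
bit-for-bit (asserted in tests by comparing output bytes).

Simulation sizes used by the test suite and the acceptance script, chosen
once: end-to-end effect recovery runs 20 seeds × 300 patients × 2 cores at
96×96 px (10.4 μm pixels — the coarsest raster at which ring 1 is
non-empty); the family-wise-error simulation runs 500 all-null replicates
at the cohort-profile size n = 74; CI coverage runs 200 replicates at
n = 1000; HR recovery averages 20 seeds at n = 2000.

## Known limitations

- The observed family-wise error of the all-null screen at n = 74 is ≈6%
  rather than the asymptotic 4.9%: small-sample Wald p-values with skewed
  covariates are slightly anti-conservative in the far tail that Bonferroni
  probes.  A likelihood-ratio screen would be better calibrated there.
- Zones are straight-line Euclidean, not geodesic within tissue; the ring-1
  rasterization bias above applies.
- Registration is integer-pixel rigid translation only; no rotation,
  scaling, or illumination correction.
- The positivity operation thresholds intensity; membrane-specific
  morphology is not modelled.
- Phantom realism limits are listed under "Image model and phantoms".
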