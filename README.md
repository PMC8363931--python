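# mesozone

Compartment-aware quantification of multiplexed-fluorescence
immunohistochemistry (mfIHC) on tissue-microarray cores, with survival
screening of the resulting marker variables.

Malignant pleural mesothelioma and similar stroma-rich tumors are studied by
staining ~1 mm TMA cores for a nuclear counterstain, tumor-cell markers
(CK5 / CK5-6 / calretinin) and a panel of fibroblast markers (PDGFRA,
PDGFRB, aSMA, FAP, SPARC, POSTN, collagen I) over two staining rounds.
`mesozone` turns those per-core channel stacks into per-patient analysis
variables and asks which markers, in which tissue compartment, are
associated with overall survival:

1. **Overlay** the two staining rounds (rigid integer-pixel registration on
   the nuclear channel) and apply spot-level QC.
2. **Mask** autofluorescence, vessels, background and tissue with a
   random-forest pixel classifier, then split tissue into the mesothelioma
   (tumor-cell) compartment and stroma by tumor-marker thresholding.
3. **Zone** the stroma into concentric 12 μm rings at increasing Euclidean
   distance from the tumor cells (meso Z1–Z4) and from vessels
   (vessel Z1–Z4).
4. **Quantify** the mean intensity of every marker in every compartment
   (10 compartments × 7 markers = 70 variables), averaged over each
   patient's QC-passed cores, plus the marker-positive fraction of the
   tumor area (classifier confidence ≥ 0.85).
5. **Screen** the ×1000-scaled variables with univariate Cox
   proportional-hazards models (Efron ties, Newton–Raphson, Wald CIs),
   Bonferroni correction over the m screened variables, multivariable
   models adjusted for age, sex, side, stage and histology, and
   Schoenfeld-residual proportional-hazards diagnostics.  Log-rank,
   Mann–Whitney and Spearman utilities round out the stack.

Because studies of this kind deposit no raw images, the package includes a
first-class synthetic-data module: TMA-core phantoms with exact geometric
and intensity ground truth (tumor nests, vessels, autofluorescent debris,
radial intensity gradients, clamped Gaussian noise) and survival cohorts
with a known log-linear hazard in a chosen marker variable.  Every pipeline
stage is validated against these oracles. See `docs/methods.md` for the
model details and known limitations.

## Worked example

Simulate a cohort in which only tumor-cell PDGFRB carries a hazard
(HR = 1.02 per ×1000-scaled intensity unit), run the full imaging +
statistics pipeline, and look at the screen:

```python
import numpy as np
import pandas as pd
from mesozone import RunConfig, run_pipeline

cfg = RunConfig(seed=1, n_patients=50, frame_px=96,
                beta=np.log(1.02),          # injected effect on PDGFRB_meso
                compute_ph=False)
run_pipeline(cfg, "run1")

report = pd.read_csv("run1/screen.csv")
print(report[report.model_id == "univariate"]
      .head(3)[["variable", "hr", "p", "p_corrected"]])
```

```
        variable        hr             p   p_corrected
0    PDGFRB_meso  1.025979  1.114122e-11  7.798854e-10
1     SPARC_meso  1.002382  5.199697e-02  1.000000e+00
2  FAP_vessel_Z1  1.003303  8.487612e-02  1.000000e+00
```

The injected variable (`PDGFRB_meso`, tumor-cell PDGFRB mean intensity) is
recovered with a fitted HR of ≈1.026 per scaled unit against a true 1.02,
and it is the only variable surviving Bonferroni correction over the 70
screened marker×compartment variables; the other 69 behave as nulls.  The
run directory also contains the per-core QC table, the raw and ×1000-scaled
patient variable tables, per-patient PDGFRB positive-area fractions, and a
manifest with the config hash — re-running the same config reproduces every
output bit-for-bit.

The same stages are scriptable from the shell:

```bash
mesozone run --config run.yaml --out rundir
mesozone simulate --config run.yaml --out bundle/   # phantom TIFFs + truth
mesozone survive --table table.csv --cohort cohort.csv --m 70 --out screen.csv
mesozone register --round1 a.tif --round2 b.tif --out fused.tif
```

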