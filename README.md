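# synovol

Synovitis — inflammation of the synovial lining — is common in painful knee
osteoarthritis and is a candidate treatment target: if anti-inflammatory
therapy shrinks the synovium and pain tracks that change, synovial tissue
volume (STV) becomes a usable structural outcome for trials. `synovol`
implements the full analysis chain for that question, for imaging analysts
and trial statisticians:

1. **Quantify STV** from contrast-enhanced MRI. Inside a manually segmented
   synovium mask, cartilage is first excluded by thresholding the
   co-registered precontrast channel (Otsu by default). Every remaining
   voxel is treated as a two-compartment fluid/tissue mixture and its
   tissue fraction is

   P = (I − m_f) / (m_s − m_f), truncated to [0, 1],

   where I is the postcontrast voxel intensity and m_f, m_s are the mean
   intensities of synovial fluid and enhancing synovial tissue. STV is the
   sum of fractions times the physical voxel volume; fluid volume is the
   complement, so tissue + fluid + cartilage = segmented volume exactly.

2. **Classify treatment response** from KOOS pain scores (0–100, 100 = no
   pain) with the OARSI-OMERACT rule: a responder improves ≥ 50 %
   relative to baseline, or ≥ 20 % with reported global improvement, with
   an absolute-change requirement of ≥ 3 points when the baseline score is
   ≤ 15. A responder whose score later falls back to within 20 % of
   baseline has relapsed; no relapse through 6 months (183 days) means a
   persistent response.

3. **Relate pain to volume** with a within-subject fixed-effects panel
   model

   y_it = β·(STV_it / 1000) + γ′·visit_it + α_i + u_it,

   absorbing each subject's level α_i by demeaning, so β is the
   within-person change in pain per 1000 mm³ change in STV. The toolkit
   also provides intraclass correlation (segmentation repeatability),
   Spearman correlation with a Fisher-z CI, paired change scores, χ²
   independence tests and change-by-group interaction tests.

Because no patient data ship with the package, two synthetic generators
make everything testable end to end: a geometric **phantom** (ellipsoidal
synovial shell, fluid pool, cartilage plate) with exact ground-truth
volumes, and a longitudinal **cohort simulator** with a three-visit trial
structure whose pain/volume coupling is the fixed-effects model itself.

## Worked example

```bash
synovol full --seed 17 --out demo/
```

simulates a 120-subject cohort, classifies response and writes
`table1.csv` … `table4.csv`, `status.csv`, `visits.csv` and `report.md`.
With seed 17 the run prints a cohort of 83/120 classified responders, a
baseline-to-follow-up KOOS pain improvement of +23.2 points (95 % CI 19.3
to 27.1) with an STV reduction of −898 mm³ (−1504 to −292), and the
fixed-effects fits in `table4.csv`:

```
        outcome  b_per_1000mm3  ci_low  ci_high      p  beta_std  delta_r2
koos_pain_0_100        -1.2290  -2.097  -0.3609 0.0058   -0.3433    0.0154
    vas_na_0_10         0.1882   0.110   0.2664 0.0000    0.4543    0.0269
```

Read: within a subject, each additional 1000 mm³ of synovial tissue costs
about 1.2 KOOS points (more pain) and 0.19 cm on the activity VAS; adding
STV to a visit-only model raises overall R² by 0.015 and 0.027. Single-run
estimates scatter around the simulator's generating slopes (−1.13 and
+0.17 per 1000 mm³) with CI half-widths near ±0.9 and ±0.08.

Image-side, `synovol phantom --out ph/ --seed 1` writes a ground-truth
phantom and

```bash
synovol quantify --post ph/postcontrast.nii.gz --pre ph/precontrast.nii.gz \
    --mask ph/segmentation.nii.gz --out report.csv
```

prints `stv_mm3=9024.00 fluid_mm3=8400.00`, matching `ph/truth.json`
exactly in the noise-free case.

## Layout

```
src/synovol/imaging.py    voxel-fraction model, cartilage masking, NIfTI I/O
src/synovol/phantom.py    ground-truth phantom generator
src/synovol/outcomes.py   KOOS scoring, eligibility, response/relapse rules
src/synovol/panel.py      within estimator, ICC, paired changes, chi-square
src/synovol/simulate.py   longitudinal cohort simulator
src/synovol/reporting.py  tables 1-4 and the full-run orchestration
src/synovol/cli.py        synovol {quantify,phantom,simulate,classify,analyze,full}
```

See `docs/methods.md` for the models, parameter choices and limitations.
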