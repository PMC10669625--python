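# Methods

## The measurement model

The quantity modelled throughout is the amount of limonene (ng) in one
standardized 400 mL breath sample. Blood and breath are not modelled
separately: breath levels of a volatile are proportional to venous blood
levels, and since no blood is drawn in this design the blood→breath
proportionality, the dose-to-amount conversion and the sampled fraction are
folded into a single dimensionless constant `breath_scale`. Subjects ingest
`dose_ng` = 1e8 ng (100 mg) at t = 0 and provide samples at
0/20/40/60/90/120 min.

### Washout curve

Post-dose signal follows the one-compartment first-order
absorption/elimination (Bateman) solution

    A(t) = breath_scale · F_sys · dose · ka/(ka−ke) · (e^(−ke·t) − e^(−ka·t)),

with the L'Hôpital limit `breath_scale·F_sys·dose·ka·t·e^(−ka·t)` taken when
|ka−ke| ≤ 1e−8·max(ka, ke). After the absorption phase dies out this is a
single-phase exponential decay, so the generated data are log-linear from
shortly after the peak — which is exactly the working assumption of the
terminal-fit stage.

### Hepatic first pass

Systemic availability uses the well-stirred liver model with a
portosystemic shunt:

    E = Cl_int/(Q + Cl_int)        (parameterized as cl_int_rel = Cl_int/Q)
    F_sys = F_abs · (shunt + (1−shunt)·(1−E)).

`F_sys` is monotone increasing in the shunt fraction and decreasing in
intrinsic clearance. For a high-extraction compound (E ≈ 0.9–0.95 in
controls) modest shunting multiplies availability several-fold while leaving
the systemic elimination rate `ke` untouched — the mechanism by which the
simulated groups differ in level but not slope.

### Baseline and censoring

Each subject carries a dietary baseline amount that rides additively on the
post-dose signal (it is ~100-fold smaller and is not subtracted). The
baseline is coupled to the subject's own `F_sys` — dietary limonene passes
the same liver — which is both mechanistically sensible and what makes the
>100-fold post-dose spike hold across essentially the whole cohort: a
subject with poor availability has proportionally less dose signal *and*
less baseline. Amounts below the limit of quantification (1.18 ng) are
imputed at the limit and flagged; LOQ-imputed values participate in AUC at
their imputed value.

Measurement noise is multiplicative log-normal with coefficient of variation
`noise_cv` applied to post-dose samples (the baseline draw already carries
its own variability). Scheduled samples are missing completely at random
with probability `missing_rate`; the design gives no mechanism for
missingness, so none is modelled.

## Default calibration

Defaults were set once, analytically, to the study conditions the analysis
stages expect, and define the package's reference scenario:

| parameter | default | rationale |
|---|---|---|
| group sizes | 29 / 29 | study scale |
| `ka_per_min` | LogNormal(0.16, 0.35) | free choice; puts the continuous peak at ~13–18 min so the sampled Tmax falls at 20–40 min, and absorption has decayed enough by Tmax that the terminal fit is clean |
| `ke_per_min` | LogNormal(0.026, 0.15) | identical in both groups; slope medians ≈ −0.025 to −0.027/min, half-life ~27 min |
| `cl_int_rel` | control LogNormal(19, 0.55); cirrhosis LogNormal(8, 0.50) | control E ≈ 0.95 (flow-limited); cirrhosis E ≈ 0.89 |
| `shunt_fraction` | control 0; cirrhosis Beta(2, 12) | median ≈ 0.12, right-skewed; controls have no portosystemic shunt |
| `breath_scale` | 2e−4 | fixes control median Cmax near 600 ng/sample and AUC(0–90) near 3e4 ng·min/sample given the above |
| `baseline_ng` | control LogNormal(2.0, 0.5); cirrhosis LogNormal(4.5, 0.5) | ~20% of control baselines fall below the 1.18 ng LOQ; baseline-only classification lands near AUROC 0.8 |
| `noise_cv` | 0.25 | keeps ~95–98% of terminal fits above the R² = 0.8 screen while producing realistic scatter |
| `score_coupling` | MELD (4.0, 1.1), FIB4 (1.0, 0.8), APRI (0.15, 0.22) | slopes/noise per ln-AUC unit chosen so the canonical loadings order MELD > FIB4 > APRI with a first canonical correlation ~0.8 |
| `missing_rate` | 0.02 | occasional lost samples |

The cirrhosis/control ratios implied by these choices are ≈ 4× for Cmax and
≈ 4–5× for AUC, with identical slope distributions. Control severity scores
are drawn independently of the kinetics so the control-group canonical
correlation is null by construction. The portal-hypertension flag is the
indicator `shunt > 0.12`; platelets fall and spleen length grows with the
shunt, and the thrombocytopenia (<150×10⁹/L) and splenomegaly (>12 cm) flags
are deterministic in those covariates.

### What the generator does not emulate

Real assay drift and batch effects; enterohepatic or multi-compartment
distribution (notably adipose uptake on repeated exposure); correlation
between absorption rate and disease; non-random missingness; measured blood
levels. Scores are generated through the coupling, not computed from the
simulated labs, so lab/score consistency is approximate. Passing tests
therefore demonstrate that the analysis chain recovers the structure this
generator encodes — not that the generator is a complete model of clinical
breath data.

## Analysis stages

**NCA.** Cmax/Tmax use post-dose samples only, ties broken to the earliest
time. The terminal fit is OLS of ln(amount) on time over all samples from
the observed Tmax (inclusive) onward, needing ≥3 points; the intercept is
reported at t = 0 on the natural-log scale (a decadic option exists but the
natural log is the package's reporting scale, since typical intercepts near
e^7 ≈ 1100 ng are only coherent on that scale). Fits with R² ≤ 0.8 are
retained but excluded from slope/intercept group comparisons; level
parameters (Cmax, AUC) keep every subject. AUC(0–90) is the linear
trapezoid over observed points; when 90 min falls between two samples the
endpoint value is linearly interpolated from its flanking observations, and
subjects whose samples cannot cover the window get a missing AUC rather
than an extrapolated one.

**Classification.** The published description of the evaluation scheme
("5-fold cross validation on an 80/20% training/test split") is read as five
repeated stratified 80/20 hold-outs with test-set averaging, which matches
the reported "test set … then averaged" language; stratified k-fold is
available behind the `scheme` flag. AUROC/sens/spec are reported as mean ± sd
across splits (sd, labelled as such). Predictive values and likelihood
ratios are instead computed from the whole-cohort confusion matrix at the
full-fit Youden threshold: published values of this kind are exactly
consistent with integer matrices at the full group sizes, so the two
conventions are kept side by side and labelled. Logistic fitting is Newton
iteration to gradient norm < 1e−8; complete separation is detected from the
data ordering (and from divergence) and handled by refitting with ridge
1e−4 on the coefficient, flagged. Youden ties break toward higher
specificity, and candidate thresholds are midpoints between adjacent unique
scores so separated classes report the gap midpoint.

**CCA.** Complete cases only (rows with any missing score or AUC are
dropped and counted). Columns are standardized; canonical correlations are
singular values of QxᵀQy from QR decompositions — numerically equal to the
eigenvalue formulation but stable for near-collinear blocks, with collinear
columns named in the error. The first-dimension test is Bartlett's
χ² = −(n−1−(p+q+1)/2)·ln Λ with Λ = Π(1−rᵢ²) on p·q df; Rao's F
approximation is computed alongside (`p_value_rao`). Sign convention: each
dimension is flipped so the y variable with the largest |loading| loads
positively, making loadings reproducible.

**Mann–Whitney U.** Mid-rank U; exact enumeration p-value when
n₁+n₂ ≤ 16 and no ties (the cutoff is a desk-scale enumeration choice,
configurable), otherwise the normal approximation with tie and continuity
corrections. U/(n₁·n₂) equals the ROC area of the same data; the test suite
asserts the identity across modules.

**Linear mixed model.** The age-confounder check fits
ln(amount) ~ group + age + timepoint(categorical) with a random intercept
per subject, by maximum likelihood (ML rather than REML so Wald tests are
coherent with the likelihood; the choice is exposed). The variance ratio
ψ = σ²_b/σ²_e is profiled: β and σ²_e have closed forms at fixed ψ, and ψ is
maximized by golden-section search on log ψ to 1e−8, with the ψ = 0 (OLS)
boundary checked explicitly. Fixed-effect p-values are Wald z tests.

## Numerical choices and degenerate inputs

- ka = ke degeneracy: explicit limit branch at relative tolerance 1e−8.
- Terminal fit with constant amounts: R² defined as 1 (perfect fit of a
  flat line) rather than 0/0.
- Confusion metrics with empty denominators return signalled `inf`
  (positive/zero) or `nan` (0/0), never silently.
- LMM singular designs and CCA rank-deficient blocks raise errors naming
  the offending column.
- All cohort randomness flows from a single integer seed through
  `numpy.random.default_rng` / `SeedSequence.spawn`; the pipeline manifest
  contains no timestamps, so determinism is checkable by byte comparison.

## Problem sizes used by the test suite and acceptance script

Group contrasts and classification run at the study scale (29/group);
parameter recovery at 200/group with 5% assay CV; the replicate-level
pattern checks use 50 seeded cohorts; the CCA null calibration uses 500
replicates at n = 500; loading-order recovery uses one 1000-subject
cirrhosis cohort. These sizes give Monte-Carlo error comfortably below the
asserted margins while keeping the default runs quick on a laptop.

## Known limitations

The generator's score coupling is linear in ln AUC with Gaussian noise —
adequate for rank-based and correlation analyses, but not a model of the
clinical scores' true discreteness or skew. The classification stage is
univariable by design (one feature per timepoint); multivariable
combinations are out of scope. AUC is never extrapolated beyond the last
sample, and no compartmental model is fitted.
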