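# methalc

Blood DNA-methylation analysis of self-reported alcohol consumption, as a
tested, reusable Python pipeline. The package is aimed at epigenetics
researchers who want to (a) train and evaluate a methylation-based predictor
of weekly alcohol intake (an *EpiScore*), (b) run a Bayesian mixture-prior
epigenome-wide association study (EWAS) with methylome variance
partitioning, and (c) screen a battery of phenome associations — all
exercised end-to-end on seeded synthetic cohorts with known ground truth, so
no access-restricted cohort data is required.

## The models

**Phenotype.** Weekly alcohol units (1 NHS unit = 8 g ethanol), analysed as
log(units + 1). Drinkers are categorized with sex-specific moderate/heavy
thresholds (≥14 units/week for females, ≥21 for males). Each record carries
a "normal week" flag: whether last week's intake matched habit.

**EpiScore.** A sparse weighted sum of standardized CpG beta values fitted
by elastic net (mixing α = 0.5), with the shrinkage λ chosen by seeded
10-fold cross-validation at minimum mean CV error. Features may be
pre-filtered to a prior-evidence CpG list or an array intersection.
Performance is summarized by Pearson r with log units and the incremental
R² over a linear model with age and sex.

**Mixture-prior EWAS.** With M-values X (columns residualized on age, sex,
smoking score and batch, then standardized) and the residualized, unit
variance phenotype y:

    y = Xβ + ε,  β_j ~ π₀δ₀ + Σ_k π_k N(0, γ_k),  γ = (10⁻⁴, 10⁻³, 10⁻²)

so the three slabs correspond to CpGs explaining 0.01%, 0.1% and 1% of
phenotypic variance. A single-site Gibbs sampler (O(n) per CpG update,
numba-compiled) yields per-CpG posterior inclusion probabilities (PIP; CpGs
with PIP > 0.95 are lead associations), mixture occupancies, and per-draw
variance explained Σ_j β_j², whose posterior mean and 95% credible interval
estimate the methylome variance component. Geweke z-scores and
autocorrelation tables diagnose convergence.

**Associations.** Standardized β (linear), OR per SD (logistic) and HR per
SD (Cox) with Wald CIs, under Benjamini–Hochberg FDR across the battery.

**Synthetic cohorts.** One seed generates a bimodal beta-value matrix with
batch shifts and cell-composition-like latent factors, plants a sparse
three-tier CpG architecture on the M-value scale, and emits reported units
in which the methylome tracks *habitual* intake while "more"/"less"
reporters deviate from it — with full ground truth recorded. See
`docs/methods.md` for every default and the reasoning behind it.

## Worked example

```python
import methalc as m

methyl = m.simulate_methylome(n_samples=2000, n_cpgs=1500, n_batches=4, seed=7)
arch = m.EffectArchitecture(n_cpgs_small=100, n_cpgs_medium=90, n_cpgs_large=10,
                            total_methylome_variance=0.2)
cohort = m.simulate_phenotype(methyl, arch=arch, seed=7)
train, test = m.split_cohort(cohort, fractions=(0.52, 0.48), seed=7)

model = m.train_elastic_net(
    m.preselect_features(train.methyl, cohort.truth.causal_cpgs),
    m.log_units(train.cohort["units_last_week"].to_numpy()),
    seed=7,
)
score = m.project(model, test.methyl)
rep = m.evaluate(score, test.cohort["units_last_week"],
                 test.cohort["age"], test.cohort["sex"])
print(f"r = {rep.pearson_r:.2f}, incremental R2 = {rep.incremental_r2:.1f}%")
```

This prints (selected features: 48):

```
r = 0.25, incremental R2 = 6.3%
```

i.e. on a held-out set of 960 samples the 48-CpG score correlates 0.25 with
self-reported log units and adds 6.3 percentage points of R² over age and
sex — a reasonable recovery at this small scale, since the generator planted
a methylome that explains 20% of the habitual phenotype and the
questionnaire adds reporting noise on top.

The same pipeline is available from the shell:

```bash
methalc simulate -n 400 -p 300 --n-small 40 --n-medium 20 --n-large 5 \
    --total-variance 0.45 --seed 42 --out-dir demo_sim
methalc ewas --matrix demo_sim/methyl.tsv --cohort demo_sim/cohort.tsv \
    --burn-in 500 --draws 1000 --thin 1 --used 1000 --seed 42 --out demo_ewas.tsv
```

```
variance explained: 43.8% (95% CrI 31.2%, 57.2%); 6 lead CpG(s) at PIP > 0.95
  cg00000089    PIP=1.000
  cg00000158    PIP=1.000
  cg00000185    PIP=1.000
  cg00000258    PIP=0.999
  cg00000100    PIP=0.992
  cg00000144    PIP=0.973
```

The lead CpGs are planted effects and the variance component's interval
covers the planted 45% even at n = 400.
`methalc pipeline --seed 1 --out-dir run1` runs the full driver
(simulate → split → design grid → final model → EWAS → associations) and
writes a machine-readable `summary.json`.

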