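# methylaging

Aging-methylome analysis and epigenetic clocks for reduced-representation
bisulfite sequencing (RRBS) count data, built around a cross-sectional aging
study in a short-lived fish (Japanese medaka) with a companion chronic
ionizing-radiation (IR) exposure experiment.

## Who this is for

Researchers analysing per-cytosine methylated/unmethylated count tables
(Bismark-coverage-style files) across an age series who want to:

- screen every CpG site for association with age and control the FDR,
- build and compare epigenetic clocks (a top-k linear model, an elastic-net
  model of log10 age, and a PC1-based predictor),
- annotate sites by CpG-island context (island / shore / shelf / open sea)
  and genic context, with exact binomial enrichment against a background set,
- scan a genome for hormone-response elements with exact PSSM score p-values,
- quantify read-level methylation discordance (PDR) as a drift proxy, and
- test how an environmental exposure (here, IR at 0/5/50/500 mGy/day)
  interacts with the aging continuum of the methylome.

Every stage also runs at desk scale on a seeded synthetic study with known
ground truth (the `simulate` module), so the complete analysis is testable
without any sequencing data.

## The models at the core

**Age association.** For site $i$ with percent methylation $m_{ij}$ in sample
$j$ of age $t_j$ (days), Spearman's $\rho_i$ (midranks) is computed per site;
a site is *age-associated* when $|\rho_i| > 0.5$. Raw p-values are adjusted by
Benjamini–Hochberg. Sites are placed in seven bins along the correlation
continuum ($[-1,-0.5]$, $(-0.5,-0.25]$, $(-0.25,0)$, $\{0\}$, $(0,0.25)$,
$[0.25,0.5)$, $[0.5,1]$; boundary values go to the bin farther from zero).

**Differentially methylated cytosines (DMCs).** Counts are pooled per group;
the two-proportion likelihood-ratio (G) test gives $p$, BH gives $q$, and a
DMC requires $|\Delta m| \ge 25$ percentage points and $q \le 0.01$.

**Clocks.** Three families sharing one prediction interface
$\hat t = g^{-1}(b_0 + \sum_i w_i m_i)$, where a site missing from a new
dataset contributes zero:

- *linear top-k*: OLS of age on the $k=10$ sites with largest training-set
  Pearson $|r|$, greedily skipping sites within 100 bp of a chosen site;
- *elastic net* ($\alpha=0.5$, gaussian) of $\log_{10}$(age) on standardized
  predictors, $\lambda$ chosen by leave-one-out cross-validation over a
  100-point grid spanning four decades below $\lambda_{\max}$;
- *PCA*: PC1 of the training-set age-associated sites (centred/scaled,
  oriented to correlate positively with age), then OLS of age on PC1.

**PDR.** A read with $\ge 2$ CpGs is discordant when its within-read
methylation lies in $[10\%, 90\%]$; PDR is the percent of discordant reads
among eligible reads, and its trend is fitted as
$\mathrm{PDR} \sim \beta \ln(\text{age}) + (1\mid\text{batch})$ by REML.

**IR × aging.** Per-dose DMC tables against the control arm are unioned;
shared sites are tested bin-by-bin for enrichment along the aging continuum
with exact two-sided binomial tests, and each shared DMC is classified as
moving in the *same* or *opposite* direction as its age trend (or
*dose-dependent* when significant doses disagree).

## Worked example

```python
import methylaging as ma
from methylaging.preprocess import preprocess_chain

cfg = ma.SimulationConfig(seed=7, n_sites=20_000)
ds, truth = ma.simulate_aging_cohort(cfg)   # 47 fish, 7 age groups, 2 batches
pre = preprocess_chain(ds)                  # filter 5-100x, normalize, unite,
                                            # KNN-impute, drop invariant sites
train, test = ma.split_train_test(pre, 10, seed=7)
fit = ma.fit_clock(pre.subset_samples(train), "linear")
print(fit.summary())
ev = fit.evaluate(pre.subset_samples(test), "test")
print(f"test MAE {ev.mae:.1f} days, R2 {ev.r2:.3f}")
```

prints

```
Epigenetic clock (linear_topk)
  sites          : 10 (10 nonzero weights)
  age transform  : identity
  intercept      : -211.245
  n_train        : 37
  k              : 10
  min_spacing_bp : 100
  top sites      :
    chr7:811885:+            +2.53526
    chr15:2632203:+          -1.96004
    ...
test MAE 33.3 days, R2 0.874
```

The summary lists the ten selected CpG sites and their weights (percent
methylation → days); the held-out mean absolute error of 33 days on a 61–426
day cohort corresponds to ~9% of the sampled age range. The full pipeline
(simulation → preprocessing → age association → clocks → genomic context →
motif scan → PDR → IR interaction) runs from one config:

```bash
methylaging run --seed 7 --out run_out/      # writes report.json + manifest
```

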