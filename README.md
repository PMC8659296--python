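# pupamp

At the onset of *Drosophila melanogaster* metamorphosis, the moulting
hormone ecdysone drives a sharp peak of antimicrobial-peptide (AMP)
expression — dominated by *drosomycin* (*drs*), *drsl2* and *drsl5* — that
controls the bacteria left behind by an imperfect larval gut purge.
`pupamp` packages the quantitative workflow needed to study that process:
qPCR relative quantification with factorial contrasts, per-pupa bacterial
load (CFU) quantification and binning, a resampled zero-inflated negative
binomial (ZINB) inference on stage-dependent bacterial load, and
position-weight-matrix scanning of promoter sequences. It is aimed at
researchers who want to rerun, audit, or adapt this style of analysis; every
stage is exercisable on synthetic data with known ground truth.

## The models at the core

**Expression.** Fold-change by the ddCT method,
FC = 2^−[(CT_gene − CT_rpl32)_sample − (CT_gene − CT_rpl32)_calibrator],
analysed as log FC ~ Genotype × Stage × Gene by OLS with Tukey-adjusted
pairwise contrasts of cell means and compact-letter groups.

**Bacterial load.** Per-individual counts y at stage s ∈ {P0 = 0,
pharate adult = 1} follow a zero-inflated negative binomial:

    logit π = γ₀ + γ₁ s          (structural zeros: cleared individuals)
    log  μ  = β₀ + β₁ s,  Var(y) = μ + μ²/θ      (NB2 counts)

The dataset is subsampled without replacement (60 individuals per cycle,
4000 cycles), the ZINB refitted per cycle, and the β₁/γ₁ sampling
distributions summarised by median, IQR, 0.05/0.95 quantiles and a
one-sided one-sample Wilcoxon test with effect size r = |z|/√n. Negative
β₁ medians mean bacteria decline through metamorphosis; positive medians
mean they persist and grow.

**Motifs.** A JASPAR position frequency matrix becomes a log-odds PWM
(bits) against a background with pseudocount; window p-values come from the
exact dynamic-programming null score distribution, filtered at p < 1e-4 on
both strands.

## Worked example

```python
import numpy as np
from pupamp import RunConfig, resample_coefficients
from pupamp.cfu import summarize_coefficients
from pupamp.synthetic import control_like_spec, simulate_zinb_counts

data = simulate_zinb_counts(control_like_spec(), seed=11)  # 100/stage
res = resample_coefficients(data, RunConfig(seed=11, n_iterations=4000))
print(summarize_coefficients(res.to_frame()).round(3).to_string(index=False))
```

prints

```
component  median    q25    q75    q05    q95   mean  wilcoxon_statistic  z_value  p_value  effect_size_r alternative  n_used
    count  -1.595 -2.367 -1.063 -4.164 -0.002 -1.788            159513.0  -52.592      0.0          0.832        less    4000
     zero   1.083  0.588  1.492 -0.116  1.944  1.011           7842274.0   52.589      0.0          0.832     greater    4000
```

The count-component median of −1.60 (IQR −2.37; −1.06) says bacterial
loads drop sharply between pupariation and the pharate adult stage in this
control-like condition — the generator's true stage effect is
log(80/800) ≈ −2.3, and a single 200-individual dataset estimates it with
this much sampling spread — while the one-sided Wilcoxon effect size
r = 0.83 (ceiling ≈ 0.866) reflects that almost every resampling cycle
agrees on the sign. The zero-component median (+1.08 on the logit scale)
says cleared individuals become more common at the later stage.

The numbered scripts under `analysis/` run the full narrative — simulate
datasets, fold-changes and contrasts, load categories, resampled ZINB
inference, AMP peak decomposition, motif scan — writing tables under
`results/`:

```bash
python analysis/01_simulate_datasets.py --seed 1
python analysis/02_expression_contrasts.py
python analysis/03_cfu_categories.py
python analysis/04_zinb_resampling.py --seed 1
python analysis/05_amp_peak_share.py
python analysis/06_motif_scan.py --seed 1
```

A thin CLI over the same library is installed as `pupamp`
(`simulate`, `foldchange`, `contrasts`, `zinb-fit`, `resample`,
`summarize-cfu`, `motif-scan`).

## Layout

- `src/pupamp/` — the library: `io`/`cli`/`config` (formats, commands,
  run manifests), `synthetic` (generators), `qpcr` (ddCT + contrasts),
  `zinb` (the regression), `resample` (the subsampling engine), `cfu`
  (scaling, binning, summaries), `motif` (PWM scanning), `datasets`
  (packaged synthetic fixtures).
- `analysis/` — numbered narrative drivers.
- `tests/` — unit, property and end-to-end acceptance tests.
- `docs/methods.md` — models, assumptions, numerical choices, limitations.
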