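# repeatratio

Repeat-to-gene expression ratio (R/G ratio) analysis for bulk RNA-seq cohorts.

Transposable elements and other repeats make up roughly half of the human
genome and are transcriptionally derepressed in many cancers, including acute
myeloid leukemia (AML). When repeat and gene expression are quantified jointly
(a TETranscripts-style count table whose repeat rows are named
`subfamily:family:class`), each patient sample can be summarized by a single
statistic, the **R/G ratio**:

```
R/G = median( normalized log2 expression over all repeat features )
      ---------------------------------------------------------------
      median( normalized log2 expression over all gene features )
```

Cohorts are stratified by z-scoring the per-sample ratios and splitting the
z-score *range* into three equal-width intervals (`low` / `mid` / `high`
repeat expression — equal range, not equal counts, so a single extreme sample
can occupy a stratum alone). The strata act as a prognostic biomarker:
low-repeat patients carry the higher hazard. Around this statistic the package
provides the full analysis chain:

* **io_tables** — readers/writers for the joint count-table dialect and
  clinical metadata (gender, age, cytogenetic risk, survival, mutation flags).
* **normalize** — median-of-ratios size factors and a
  `log2(count/sf + pseudocount)` variance-stabilizing transform.
* **rg_stratify** — R/G ratios, z-scores, equal-interval stratification,
  repeat-class read fractions, inter-patient variation tables.
* **diffexpr** — between-stratum negative-binomial Wald tests with
  Benjamini–Hochberg FDR and the strict significance filter
  (baseMean > 100, |log2FC| > 1, adjusted p < 0.05).
* **survival_stats** — Kaplan–Meier curves, log-rank tests, multivariate Cox
  proportional hazards (Efron ties) with forest-table export.
* **factor_corr** — Pearson correlation of chromatin enzyme/factor expression
  with R/G ratios (BH across the panel) and Wilcoxon rank-sum association of
  ratios with binary mutation status (exact for small groups).
* **sim_data** — a synthetic cohort generator with planted low/mid/high
  groups, realistic repeat-class composition, group-dependent survival and
  tiered factor correlations, used to validate every stage end to end.
* **pipeline / CLI** — one command from counts (or simulation) to all tables
  plus a reproducibility manifest.

## Worked example

```python
import numpy as np
from repeatratio import (
    SimConfig, simulate_cohort, size_factors, normalize_log,
    rg_profiles, stratify_cohort, profiles_to_frame, correlate_panel,
)

cfg = SimConfig(seed=7)                      # 3 x 20 samples, planted groups
table, meta, truth, factors = simulate_cohort(cfg)
norm = normalize_log(table, size_factors(table))
profiles = stratify_cohort(rg_profiles(norm))
df = profiles_to_frame(profiles)
print(df.head(4).round(4))
```

```
         median_repeat_expr  median_gene_expr  rg_ratio  zscore stratum
sample
LOW_001              5.4297            8.1743    0.6642 -1.2959     low
LOW_002              5.4513            8.1091    0.6722 -1.1693     low
LOW_003              5.4696            8.1050    0.6748 -1.1282     low
LOW_004              5.5065            8.1106    0.6789 -1.0636     low
```

Each row is one sample: the two medians (log2 units), their ratio, the
cohort z-score and the assigned stratum. At this seed the strata split
20/20/20 and match the planted groups for all 60 samples. Correlating the
chromatin-factor panel with the ratios recovers the planted tiers:

```python
print(correlate_panel(df["rg_ratio"].to_numpy(), factors[df.index.tolist()]))
```

```
            pcc       p    padj   n
factor
POU5F2   0.7929  0.0000  0.0000  60
ASH1L    0.8243  0.0000  0.0000  60
BAZ2B    0.8007  0.0000  0.0000  60
ATRX     0.8240  0.0000  0.0000  60
SUV39H1  0.5016  0.0000  0.0001  60
EHMT2    0.3399  0.0079  0.0135  60
...
```

High-tier factors (planted population correlation 0.8) report Pearson
coefficients near 0.8 with vanishing BH-adjusted p-values; mid-tier factors
land near 0.4; null-tier factors are indistinguishable from zero.

The same analysis runs from the shell:

```sh
repeatratio run --simulate --seed 7 --outdir results/demo
```

writing the normalized matrix, R/G profiles, class fractions, DE tables for
high-vs-mid and low-vs-mid, KM/log-rank/Cox tables, the factor-correlation
panel, mutation associations and a `manifest.json` recording the seed, config
hash and every analysis decision in effect. Re-running with the same seed
reproduces every file byte-identically.

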