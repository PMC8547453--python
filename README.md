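# replomics

Bacterial replication-rate estimation from metagenome coverage, and a
dual-regression framework that separates baseline-BMI associations from
weight-loss associations across multi-omic feature types.

The package is aimed at microbiome researchers analysing weight-loss
intervention cohorts with stool metagenomes and blood multi-omics.  It
implements two bespoke computations end to end, with a synthetic-data
generator that emulates the statistical structure of such cohorts for
validation and testing.

## The two methods

**Contig-level replication rates (iRep-style).**  Actively replicating
bacterial populations are sequenced mid-replication, so read coverage is
highest near the origin of replication and decays toward the terminus.  For
each assembled contig, per-base depth is averaged into 100-bp bins, smoothed
with a 50-bin sliding-window mean, sorted ascending, symmetrically trimmed
(5% per tail), and log2-transformed; ordinary least squares of log2 coverage
against sorted rank rescaled to [0, 1] gives a slope *m*, and the
replication rate is

    rate = 2^m

— a dimensionless index equal to 1 for a non-replicating population and to
the local peak-to-trough coverage ratio for a contig spanning a full
replichore.  Only contigs ≥ 11,000 bp with mean coverage ≥ 2× are used.
Rates are aggregated per sample and phylum (unclassified contigs pool under
"NA") and group differences are tested with the linear model
`mean_rate ~ group + age + baseline_bmi`.

**Dual regression for multi-omic associations.**  Subjects with high
baseline BMI lose more weight on follow-up (regression to the mean), so any
feature correlated with BMI looks weight-loss-associated.  For every feature
two models are fitted:

    weight-loss model:  y ~ group + baseline_BMI + age + sex
    BMI model:          y ~ baseline_BMI + age + sex

with t = coef / se for the target term of each.  Log-scale analytes
(metabolites, proteins, SRM log ratios) and ordinal diet scores use OLS;
sequencing counts use per-feature negative-binomial log-link regression
with median-of-ratios ("poscounts") size factors as offsets and a Wald
pseudo-t.  P values are Benjamini–Hochberg adjusted within each data type
and features are classified `bmi_only` / `wl_only` / `both` / `neither`
from the two FDR values.  Supporting operations cover cohort selection
(> 1% body weight lost per month vs stable weight), metabolite batch/QC
normalization, protein missingness filtering, SRM log ratios, KO-term gene
cluster aggregation, and rarefied gene richness at 100,000 assigned reads.

## Worked example

```python
import numpy as np
import replomics as rp

# simulate one replicating genome (true peak-to-trough ratio 2.0, 20x depth)
cfg = rp.CoverageSimConfig(
    genome_length=100_000, origin_index=0, true_ptr=2.0, mean_depth=20.0,
    noise="poisson", contig_lengths=[50_000], seed=1,
)
tables, truth = rp.simulate_coverage(cfg)
binned = rp.bin_coverage(tables["contig_0"], 50_000, 100)
est = rp.estimate_rate(rp.smooth(binned.values, 50))
print(f"rate={est.rate:.3f}  r2={est.r_squared:.3f}  n_bins={est.n_bins}")
```

prints

```
rate=2.004  r2=1.000  n_bins=450
```

i.e. the fitted local coverage gradient recovers the simulated
peak-to-trough ratio of 2.0 to well within 1% at 20× Poisson coverage, with
a near-perfect rank-regression fit over the 450 bins that survive trimming.

The association half works the same way from simulated cohorts:

```python
import pandas as pd

specs = pd.DataFrame({
    "feature_id": ["hit"] + [f"null{i}" for i in range(49)],
    "kind": "count",
    "beta_wl": [np.log(2)] + [0.0] * 49,   # 2-fold group effect on one gene
    "intercept": 3.0, "dispersion": 0.1,
})
sim = rp.simulate_cohort(rp.CohortSimConfig(
    n_subjects=25, group_fraction=15 / 25, feature_specs=specs, seed=1))
dual = rp.DualAssociation(kind="count").fit(sim["count"], sim["metadata"])
print(dual.results_.loc["hit", ["coef_wl", "t_wl", "fdr_wl", "class"]])
```

```
coef_wl    0.670202
t_wl       5.579867
fdr_wl     0.000001
class       wl_only
```

The marked gene cluster is recovered as weight-loss-associated (its
natural-log coefficient 0.67 vs the simulated ln 2 ≈ 0.69) while all 49
null features are classified `neither`.

A command-line chain mirrors the library (`simulate-coverage`,
`simulate-cohort`, `cohort-select`, `coverage`, `irep`, `rates-test`,
`prep`, `sizefactors`, `richness`, `associate`); every stage reads and
writes plain CSV/TSV.

## Layout

- `src/replomics/cohort.py` — weight-change rates, exclusions, group labels
- `src/replomics/coverage.py` — per-base depth, binning, contig filters
- `src/replomics/replication.py` — rate estimator, taxon summaries, group test
- `src/replomics/feature_prep.py` — per-data-type normalization, size factors, richness
- `src/replomics/associations.py` — dual-regression framework, FDR, classification
- `src/replomics/simulate.py` — synthetic coverage / taxa / cohort generators
- `src/replomics/cli.py` — click commands
- `docs/methods.md` — models, assumptions, parameter choices, limitations
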