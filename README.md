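# mipmeter

Pooled selection-and-sequencing analysis with molecular inversion probes
(MIP-seq): panel design, SNV allele counting, strain-frequency estimation,
and starvation-resistance trait extraction for *C. elegans* wild isolates.

## What problem this solves

Measuring fitness differences among ~100 genotypes competing in one culture
requires counting each genotype deep enough to see small frequency shifts.
MIP-seq does this by capturing, for every strain in the pool, a handful of
genomic loci carrying SNVs unique to that strain. Each molecular inversion
probe (MIP) is an 80-nt oligo whose two 20-nt arms hybridize around a 100-nt
window containing the diagnostic SNV; gap fill and ligation circularize the
probe, and sequencing the captured window yields, per probe, reads carrying
the reference allele, the alternative allele, or one of the two other
nucleotides. The alternative-read fraction

    f = n_alt / (n_alt + n_ref)

estimates the frequency of the strain that uniquely carries the alternative
allele. Applied to a pool starved during L1 arrest and sampled at days
1, 9, 13, and 17 (each sample recovering and reproducing before sequencing),
the time course of `f` measures starvation resistance as a fitness-proximal
trait integrating survival, growth, and early fecundity.

Two per-strain trait values summarize the time course of
y = log2(f(day) / f(baseline)):

* **Slope** — the zero-intercept least-squares slope of the
  replicate-averaged y over days 1, 9, 13: `slope = Σ t·ȳ(t) / Σ t²`.
  Positive slope = starvation-resistant.
* **PC1** — the strain's score on the first principal component of the
  strain × day matrix of y (columns mean-centered), sign-oriented to
  correlate positively with Slope.

The package also implements the supporting statistics used around the assay:
probe QC against an equimolar pilot (3.5-fold band around 1/S, OTHER-read
and total-read thresholds), log-log standard-curve evaluation, hypergeometric
category enrichment with Bonferroni correction, hyper-divergent-region
overlap calls, logistic survival fitting with half-life t-tests, a
detectable-effect power inversion, and the ΔΔ (difference-in-differences)
interaction effect size — plus a pooled-competition simulator with recorded
ground truth that drives the entire test suite. See `docs/methods.md` for
the model details and design choices.

## Worked example

Simulate a competition of 8 strains (5 replicates, half-lives graded from
6 to 16 days), quantify it, and extract traits:

```python
import numpy as np
from scipy import stats
from mipmeter import (SimConfig, simulate_trajectories, simulate_counts,
                      strain_frequencies, normalize_to_baseline, trait_table)
from mipmeter.readquant import frame_to_records

cfg = SimConfig.default(n_strains=8, replicates=5, seed=42)
truth = simulate_trajectories(cfg)
counts, sample_map = simulate_counts(truth)
freq, _ = strain_frequencies(frame_to_records(counts), None, truth.probe_strain)
traits = trait_table(normalize_to_baseline(freq, sample_map))
print(traits.round(4).to_string(index=False))
rho = stats.spearmanr(cfg.strain_half_life,
                      traits.set_index("strain_id")
                            .loc[truth.strain_ids, "slope"]).statistic
print(f"Spearman(true half-life, Slope) = {rho:.3f}")
```

prints

```
strain_id   slope     pc1  n_replicates_used
     S000 -0.1582 -3.1631                  5
     S001 -0.1107 -2.1531                  5
     S002 -0.0625 -1.0855                  5
     S003 -0.0217 -0.1937                  5
     S004  0.0114  0.6330                  5
     S005  0.0389  1.3842                  5
     S006  0.0603  2.0370                  5
     S007  0.0736  2.5412                  5
Spearman(true half-life, Slope) = 1.000
```

Strains were programmed with half-lives increasing from S000 (6 days) to
S007 (16 days); Slope (log2 units/day) and PC1 recover that ordering
exactly, with the hardiest strain gaining ~0.07 log2 units of relative
frequency per starvation day.

The same pipeline is available from the shell, stage by stage
(`mipmeter design | count | qc | freq | traits | enrich | divergence |
survival | power | ddelta | simulate`) or as a configured run with a
reproducibility manifest:

```sh
mipmeter run --config pipeline.yaml --out outdir/ --seed 42
```

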