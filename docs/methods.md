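# Methods

## Background and scope

`mipmeter` implements the computational side of a pooled
selection-and-sequencing assay for *C. elegans* starvation resistance built on
molecular inversion probes (MIP-seq). A pool of genetically diverse wild
strains is starved during L1 arrest; aliquots sampled at days 1, 9, 13, and 17
recover on food and reproduce before sequencing, so the readout integrates
survival, growth, and early fecundity. Each strain's relative frequency in a
sample is measured from targeted sequencing of SNVs unique to that strain.
The package covers probe-panel design, allele counting from reads, probe QC
and frequency estimation, trait extraction for association mapping, the
surrounding validation statistics, and a simulator that generates complete
synthetic experiments with recorded ground truth. Genome-wide association
itself, fine mapping, and external annotation scanners are out of scope; the
package exports trait tables and consumes their outputs as plain tables.

## Probe model

A MIP is an 80-nt oligo: a 20-nt extension arm, a 30-nt backbone carrying the
two amplification landing sites, a 10-nt UMI, and a 20-nt ligation arm. The
arms hybridize to reference sequence flanking a 100-nt capture window (the
"scan" sequence) containing the target SNV. Targets are biallelic SNVs at
which exactly one panel strain is homozygous-alternative and every other panel
strain is homozygous-reference; sites with any missing or heterozygous panel
genotype are excluded so that the alternative-read fraction is exactly the
target strain's frequency. Four probes per strain are designed by default for
redundancy.

Design choices that the underlying protocol leaves open:

* **Capture window placement.** The window slides left-to-right over every
  position that keeps the SNV within `read_length − umi_length` = 40 nt of the
  UMI in a 50-nt single-end read; the first placement whose arms fit the
  contig without ambiguous bases wins. Deterministic, so panels are
  reproducible and order-invariant.
* **`snv_offset`** is a 1-based distance from the UMI end; the ligation arm
  occupies offsets 1–20 and the SNV therefore sits at offsets 21–40.
* **Candidate ranking.** The original pipeline delegated probe scoring to an
  external thermodynamic model; here candidates are ranked by combined arm GC
  content closest to 50%, ties broken by genomic coordinate. This is a
  deterministic stand-in, not a reimplementation of that model.
* **Backbone and oligo order.** The backbone sequence and component order
  (extension arm + backbone + UMI + ligation arm, 5′→3′) are configurable
  with documented defaults; the default backbone is the canonical 30-nt MIP
  linker.

## Read model and allele counting

Reads are laid out as `UMI (10) + ligation arm (20) + scan prefix`, matching
the published two-tier accounting ("matched the ligation probe" vs "matched
the ligation probe and scan sequence"). Assignment requires an exact match of
the 20-nt ligation arm at the post-UMI position (a Hamming-distance ≤ 1 mode
exists but is off by default); the allele is the single base at the SNV slot.
The two non-REF/non-ALT nucleotides map to OTHER_A/OTHER_B in lexicographic
order. Base qualities are ignored and reads are used untrimmed. UMI
deduplication (collapse of identical probe × UMI × allele triples) is
implemented but off by default, since it did not improve the published
analysis at the DNA masses used.

## QC and frequency estimation

Per-probe frequency is `n_alt / (n_alt + n_ref)`; OTHER reads are excluded
from the denominator. Against an equimolar pilot of S strains a probe passes
if (1) its frequency is within 3.5-fold of 1/S — a closed band, checked by
cross-multiplication so the exact boundary passes without float rounding —
(2) OTHER reads total < 20,000, and (3) the alt+ref total lies in
[20,000, 2,000,000]. The count thresholds are tied to the original pilot's
depth (≈600k reads/probe, from 246,986,236 mapped reads over 412 probes) and
rescale proportionally via `QcThresholds.scaled` for shallower runs. Probes of
designated strains (e.g. a reference-derived strain with almost no unique
SNVs) can be exempted: they bypass filtering but remain flagged. Strain
frequency per sample is the unweighted mean over usable probes — weighting by
depth is deliberately not applied because the published procedure averages
frequencies; strains with no usable probe are omitted and reported, never
imputed.

Standard curves are evaluated by least squares of log10(observed) on
log10(expected), since the mixing design spans three orders of magnitude;
zero observations are floored at half the smallest nonzero observed frequency
(with a warning) before logging.

## Traits

Time-course frequencies are divided by the same replicate's baseline (day-1
aliquot) frequency and log2-transformed. Entries with zero or missing
baseline, or zero frequency, are masked with recorded reasons.

* **Slope** = Σ t·ȳ(t) / Σ t² over days {1, 9, 13}, where ȳ is the
  replicate-averaged log2 ratio — a zero-intercept least-squares fit. The
  zero intercept treats y(0) = 0 as implied by baseline normalization; this
  is an approximation because day 1 already reflects one day of arrest.
  Replicates are averaged before fitting; a fit-per-replicate-then-average
  mode exists for sensitivity analysis.
* **PC1**: the strain × day matrix (replicates averaged, all four days,
  complete cases) is column mean-centered — not variance-scaled, the minimal
  convention; both toggles are exposed — and decomposed by SVD. The first
  left-singular scores are the trait; the component's sign is arbitrary, so
  it is oriented to correlate non-negatively with Slope. A replicate-level
  decomposition (rows = individual libraries, columns = strains) is returned
  as a diagnostic; its first component should track starvation day.

Strains missing any fitted day are dropped from PC1 but keep a Slope when at
least two days exist.

## Annotation and validation statistics

Category enrichment uses the upper-tail hypergeometric law, counting each
gene at most once per category (the alternative — counting domain instances —
would inflate multi-domain genes). The Bonferroni divisor is the number of
categories observed in the hit set, and categories with fewer than five hit
occurrences are excluded from significance calls. Hyper-divergence at a locus
is a ≥1-base overlap between the locus and any of the strain's hyper-divergent
regions (0-based half-open intervals). Group comparisons use Welch's t-test.

Survival series are fit with p(t) = A / (1 + exp(rate·(t − t50))), A fixed at
1 by default (a free-asymptote mode handles degraded day-1 viability; the
original parameterization is not printed). t50 always comes from the fitted
curve, and series that never cross 0.5 yield a flagged, extrapolated t50
rather than a censored one so replicate t-tests stay balanced. The detectable
effect size inverts the two-sided two-sample noncentral-t power relation for
Cohen's d by bisection and multiplies by the control-group standard
deviation; with n = 5, α = 0.05, power = 0.5 this gives d ≈ 1.41. The ΔΔ
statistic is (A_late − A_early) − (B_late − B_early) on cell means of worm
length, so a positive value means the first-listed strain is less affected by
starvation; p-values for the corresponding mixed-model interaction are left
to external statistics tooling.

## Simulator

The simulator is first-class, tested code and the source of every synthetic
dataset in the test suite.

* **Dynamics.** Per-replicate baselines are Dirichlet around equal
  composition (concentration 100 per strain ⇒ ≈10% CV, emulating the
  intended ~5000 larvae per strain with realistic representation drift).
  Strain weight at day t is baseline × [survival(t; half-life) ×
  exp(gain × survival)]^γ(t): the same logistic survival form as the
  validation module (default steepness 0.35/day), an optional
  recovery/fecundity multiplier increasing with survival advantage (so
  survival and reproduction effects can be decoupled in tests), and an
  optional late-day attenuation exponent γ (default 1) reproducing the
  observed compression of strain differences at day 17, when late recovery
  cultures yield few progeny. Frequencies are renormalized weights and sum
  to 1 to machine precision.
* **Reads.** Per-probe depth is Poisson (default mean 10⁴ reads/probe, chosen
  so full experiments simulate in seconds; a paper-scale depth is one config
  knob away). Capture bias is log-normal per probe with unit mean (sd 0.3 on
  the log scale — moderate, enough to make the 3.5-fold QC band meaningful).
  Substitution error (default 0.002/base) reallocates reads to the two OTHER
  classes at e/2 each; ref↔alt cross-error is neglected as second-order, so
  the expected alt fraction of assigned reads is the true frequency times
  (1 − e). All randomness flows from one seed; FASTQ emission realizes the
  exact drawn counts, so counts mode and FASTQ mode piped through the
  counter agree bit-for-bit.
* **Defaults for experiments.** `SimConfig.default(n_strains=30,
  replicates=5)` grades half-lives evenly from 6 to 16 days, spanning the
  plausible range of wild-strain L1 survival.

What the simulator does **not** emulate: PCR duplicate structure beyond UMI
multiplicity, within-culture spatial or density effects, strain-by-strain
capture chemistry (bias is i.i.d. log-normal), index hopping, and alignment
artifacts. Passing recovery tests therefore demonstrates that the estimator
stack is calibrated and ranks programmed fitness correctly under this noise
model — not that real libraries are free of systematic capture bias.

## Numerical choices and degenerate inputs

Problem sizes in the test suite are scaled for interactive runs: panels of
103 strains × 4 probes, pools of ≤30 strains × 5 replicates at 10⁴
reads/probe, 200-replicate calibration studies. Zero-read probes return an
undefined frequency and are skipped with a warning; empty trajectories,
single-strain PCA, sub-replicate t-tests, and malformed intervals raise
typed errors or warnings rather than propagating NaN. VCF positions are
1-based, internal interval arithmetic is 0-based half-open, and converters
live at the I/O boundary.
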