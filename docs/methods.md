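# Methods

## The weighted enrichment model

The unit of observation is an assembled contig with a read count `R` and a
length `L` (bp). Read counts proxy transcript abundance, but long contigs
accumulate reads for purely geometric reasons, so all depth comparisons use
the length-normalised weight

    W_t,g = scale · R_t,g / L_t,g

for term `t` in group `g` — reads per `scale` bases, with `scale = 1000`
(reads per kilobase) by default. `R_t,g`/`L_t,g` sum over the contigs of
group `g` whose annotation set contains `t`; an unannotated term has
weight 0. The whole-group weight `T_g = scale · (group reads)/(group
length)` is the same quantity over all contigs and serves as the reference
scale: under uniform coverage every term's weight concentrates near `T_g`
(≈ 130 reads/kb at the default generator scale).

Annotations follow the true-path rule by default: a contig annotated to a
term is counted for all of the term's `is_a` ancestors. Only `is_a` edges
are traversed (the conservative core of the GO graph); propagation can be
disabled (`--no-propagate`) for pipelines whose annotation tool already
emitted ancestor-closed term lists — annotation-era tooling is ambiguous on
this point, so both behaviours are supported and the default is documented
here.

### Contingency construction

Fisher's exact test needs integer cells. For each term we build

    [[ round(W_t,treated),  round(W_¬t,treated) ],
     [ round(W_t,control),  round(W_¬t,control) ]]

where `¬t` is the complement — the contigs *not* annotated to the term.
Rounding is round-half-even. An alternative construction, in which the
second column is `round(T_g) − round(W_t,g)` with negative values clamped
to zero, is implemented behind `complement="dataset_total"`
(`build_contingency`). It is not the default because weights are
intensities, not partitions of a total: whenever coverage is near-uniform,
`W_t,g ≈ T_g` for every term, the subtraction collapses the second column
to ~0, and the table degenerates — a spiked term then clamps to
`[[a, 0], [c, 0]]` and becomes untestable. The complement construction
keeps both columns on the reads-per-kilobase scale and remains informative
in exactly those situations.

The two-sided p-value sums the hypergeometric probabilities of all tables
with the observed margins that are no more probable than the observed
table (computed by `scipy.stats.fisher_exact`; the test suite checks it
exhaustively against exact rational enumeration for every table with grand
total ≤ 40). Degenerate tables (a zero margin) are assigned p = 1. The
family for Benjamini–Hochberg correction is the set of terms annotated to
at least one contig in either group.

### Filter cascade

A term is *reported* when q ≤ α (default 0.05) and none of these flags is
set:

* `fold_filtered` — the fold, the ratio of within-group weight proportions
  `(W_t,treated/T_treated) / (W_t,control/T_control)`, equals exactly 1, or
  is undefined (both weights zero). A zero control proportion with nonzero
  treated proportion yields the +∞ sentinel (direction `enriched`), the
  mirror case 0 (`repressed`); both pass the filter. Direction is assigned
  post hoc from the fold, which is why the test is two-sided.
* `min_contig_filtered` — fewer than 2 annotated contigs across both
  groups.
* `child_pruned` — a significant `is_a` *descendant* exists (not just a
  direct child: the transitive reading is stricter and order-independent).
  After pruning, the reported set is an antichain — only the most specific
  significant terms survive.
* `score_filtered` — score = max(W_t,control, W_t,treated) is not > 100.
  The score threshold is a "strongest signals" restriction on the absolute
  depth scale; 100 reads/kb sits just below the typical dataset-wide weight
  (~130 reads/kb), so it removes terms whose stronger group is still below
  average coverage. It is configurable, and off by default in qualitative
  mode (whose cells are contig counts, where no comparable unit exists).

The qualitative mode replaces the weight cells by annotated /
not-annotated contig counts per group and by default applies only the
min-contig, FDR and pruning filters.

## Microarray stage

Columns (samples) are scaled so every column mean equals the grand mean of
column means, then log2-transformed. Zeros are replaced by half the
smallest positive intensity first. Mean-scaling per sample column is one
of several readings of "normalised by relative intensity of the means" in
legacy array software; it is the documented choice here.

Per time point, treated vs control replicates are compared with the
pooled-variance two-sample t-test (df = n1 + n2 − 2); Welch's correction is
available behind a flag. Dye-swapped arrays are treated as independent
samples. The ANOVA pools all control columns into one level against the
treated columns of each exposure time; with two levels its p equals the
pairwise t-test's (checked to 1e−10). Fold changes are signed:
`2^Δ` when Δ ≥ 0 and `−2^−Δ` otherwise, so a halving prints as −2.0.

Zero-variance probes: identical replicate values in both groups give
p = 1, fold ±1; zero variance with a genuine mean difference yields the
smallest positive float and a `zero_variance` flag. A mean difference at
floating-point rounding level (≤ 1e−9 relative to the mean magnitude) with
zero variance is treated as no-signal, not as infinite evidence — without
this rule, 1e−16-scale normalisation residue would dominate the noise-free
limit.

PCA treats samples as observations (probes as variables), mean-centred,
via SVD; explained variances sum to the total sample variance and the full
reconstruction is exact to machine precision. Sample clustering is
average-linkage agglomeration on Manhattan distances of the log2 columns,
exported as Newick. Both are provided because legacy figure captions
attach distance/linkage language to "PCA", which is contradictory; either
reading is reproducible.

## qPCR stage

ΔCt = Ct_target − Ct_reference per condition; ΔΔCt = ΔCt_treated −
ΔCt_control; fold = 2^−ΔΔCt, reported with the signed convention.
Amplification efficiency is fixed at 100% (base 2) — no standard-curve
estimation is attempted. Technical replicates are averaged within each
biological replicate first, then biological replicates are averaged, so
unbalanced technical replication cannot bias a condition mean; the
aggregation order is this package's choice since protocols of this design
(2 biological × 2–3 technical) rarely state one. Reference-gene
normalisation cancels any global Ct shift exactly.

## Synthetic-data generators

The generators emit data with the statistical structure the analyses
assume, plus ground-truth tables.

**Contig experiment.** Defaults mirror the full-scale study conditions:
1,318 control / 1,140 treated contigs carrying 134,090 / 124,287 reads,
contig lengths log-normal (σ_log = 0.6) with mean ≈ 780 bp, a 300-term
random `is_a` DAG (each non-root term has 1–2 parents), and Poisson(3)
direct annotations per contig drawn uniformly over terms — after
propagation, per-contig annotation totals land in the 15–20 range typical
of annotation pipelines at this scale. Reads are allocated multinomially
with probability ∝ contig length, so the weight `W` is flat across terms
under the null and a spiked term's fold is the estimand of the enrichment
statistic. Spiked terms multiply the allocation probability of their
(propagated) member contigs by the fold — or its reciprocal for repressed
spikes — with the fixed group total renormalised; spike directions
alternate so up- and down-spikes roughly balance the reallocation. Spiked
terms are drawn from the DAG's leaves (hence pairwise non-ancestral), and
contigs that draw a spiked term carry only that term: reads are a
per-contig resource shared by all of a contig's labels, so multi-label
spiked contigs would genuinely perturb every co-annotated term and the
truth table would no longer delimit the changed set.

Two scaled-down profiles, `tiny` (100 contigs, 5,000 reads, 40 terms) and
`benchmark` (1,000 contigs, 50,000 reads, 200 terms), keep the per-contig
read depth of the full profile by shrinking mean contig length to
≈ 370 bp. This preserves the reads-per-kilobase scale on which the score
threshold operates (`T_g` ≈ 130 in all profiles), so the filter cascade
behaves identically across scales.

**Microarray.** Probes have log2 baselines N(10, 1); differential probes
are shifted by ±2 log2 units in the treated cells of their affected times;
replicate noise is N(0, 0.2²); intensities are exponentiated. The design
mirrors the real chip: 23,671 probes (500 in the tiny profile), two
conditions × {6, 12, 24} h × two biological replicates with the dye label
swapped between them (the dye carries no simulated bias; it exists so the
metadata round-trips). Differential probes are drawn in induced/repressed
pairs whose baselines differ by exactly the effect size and that share
affected times, which makes the differential content exactly mean-neutral
per column: mean-scaling normalisation stays neutral and the noise-free
(σ = 0) limit recovers exactly the truth set at any threshold. With an odd
number of differential probes the last one is unpaired and neutrality is
approximate.

**qPCR.** The reference gene has a condition-independent Ct (18.0); each
target's treated Ct is offset by −log2(fold) from its control Ct
(≈ 22 ± 1), with N(0, 0.2²) cycle noise and 2 biological × 3 technical
replicates. Default true folds (+37.9 / −7.2) mirror the two
chitin-binding-domain transcripts the study assayed.

All generators are pure functions of their config (seed included): equal
configs give byte-identical outputs.

### What the generators do not model

Real 454 contig sets have expression-driven, heavily overdispersed
coverage; annotation is biased toward well-studied functions and
correlated within a contig; arrays carry dye bias, spatial artefacts and
intensity-dependent variance; qPCR efficiency is rarely exactly 2.
Passing the recovery and calibration tests therefore shows that the
statistics behave correctly *under their own assumptions* — it does not
certify performance on real data, where the weighted test inherits the
usual composition-effect caveats of relative abundance measures (a large
enriched fraction depresses every other term's share; mixed-direction
spikes in the generator keep this effect small, real data may not).

## Numerical choices

* Weight rounding: round-half-even; negative cells in the dataset-total
  construction clamp to 0 with a logged warning.
* Fisher degenerate tables: p = 1.
* BH: statsmodels step-up, clipped at 1; ties need no extra handling.
* Zero-variance t/F cells: see above; ANOVA uses the analogous rule via an
  absolute 1e−8 tolerance on the between-group sum of squares.
* PCA centring subtracts the per-probe mean over samples; components come
  from SVD, so signs are arbitrary but deterministic.
* All randomness flows through `numpy.random.default_rng(seed)` objects
  created from explicit config seeds; nothing touches global RNG state.

## Problem sizes used in the checks

The calibration and recovery checks run at the `benchmark` profile
(1,000 contigs and 50,000 reads per group, 200 terms; 50 null seeds, 20
spiked seeds), the array checks at 2,000 probes × 10 seeds (type-I) and
500 probes (noise-free limit), the Fisher sweep over all 135,750 tables
with grand total ≤ 40, and the end-to-end determinism check at the tiny
profile. These sizes make the whole suite run in a couple of minutes while
leaving every rate estimate with a standard error well below the margins
asserted.

## Known limitations

* Two groups only; no multi-factor or >2-group contig designs.
* The weighted test treats rounded intensities as hypergeometric counts;
  its variance model is approximate (conservative for large terms, mildly
  anti-conservative for very small ones — the ≥2-contig filter trims the
  worst cases).
* OBO support is the minimal subset (id, name, namespace, is_a,
  is_obsolete); no `part_of`, no GO-slim mapping.
* The ANOVA is fixed-effects and unpaired; no dye-swap-aware ratio model.
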