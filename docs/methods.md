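# Methods notes

This note records the model assumptions, parameter choices, numerical
conventions and known limitations of `cazyarray`, at the level of detail a
maintainer or reviewer needs to judge what a passing test suite does and
does not demonstrate.

## Catalog model

A target is a CAZyme coding sequence with a catalytic-domain interval
(0-based half-open internally; the annotation TSV declares its convention
per row and 1-based-inclusive input is converted at the boundary). Only
the eight targeted families (GH5, GH9, GH10, GH11, GH43, GH48, CE1, CE6)
and three taxon groups (bacteria, protozoa, fungi) are admitted;
validation is strict — non-ACGT characters, out-of-bounds domains and
unknown families are reported per record and never silently masked.

**Identity and grouping.** Sequences with global identity strictly above
0.96 cannot be told apart by 25-mer probes and are grouped by
single-linkage on the >0.96 relation — the simplest deterministic
partition consistent with "indistinguishable". Identity is defined as
matched columns / alignment length with gap columns counted as
mismatches, computed from an edit-distance-optimal global alignment
(edlib). Edit-optimal alignments are not unique: a tie can trade two
mismatches for an insertion–deletion pair and shift identity by a few
tenths of a percent. At the 96 % threshold on near-identical sequences
this slop is immaterial, and the tests assert it stays within 0.6 % of
the substitution-only (Hamming) truth on equal-length pairs.

**Consensus.** Groups are summarized against their longest member as the
coordinate frame: each other member is globally aligned to it, and a
column is conserved iff every member carries the seed's base there;
member insertions mark the flanking seed column non-conserved.
Non-conserved columns carry `N` and are excluded from probe windows. This
seed-projection is exact for substitution-only divergence (the regime
>96 %-identical sequences are overwhelmingly in) and conservative under
indels; a full progressive MSA was deliberately avoided to keep consensus
construction dependency-free, fast and bit-stable.

## Probe design

* **Windows.** One candidate per admissible offset: fully inside the
  catalytic domain and, for groups, covering only conserved columns.
* **Tm.** Unified nearest-neighbor model (biopython `Tm_NN`), fixed at
  50 mM monovalent salt, 250 nM probe strand, no formamide correction, so
  results are bit-stable across runs. Acceptance window 46–64 °C. The
  duplex model is symmetric under reverse complement, which the tests
  exploit as a free invariant.
* **Complexity.** Count of distinct overlapping trinucleotides in the
  25-mer (range 1–23), threshold 10. This is a deterministic
  low-complexity proxy whose scale is consistent with a threshold of 10
  on 25-mers; the metric sits behind a single function and is pluggable.
* **Cross-hybridization.** Best *ungapped* alignment of the probe at all
  offsets on both strands of every background sequence. Rejection
  requires identity > 0.85 (i.e. ≥ 22/25) **and** an exact match stretch
  > 15 nt (≥ 16) — the conjunctive reading of the published criterion;
  a disjunctive mode is available since these two criteria are often
  applied either/or in probe-design practice. Gapped similarity is
  covered implicitly by the stretch criterion; probes are too short for
  gapped identity to diverge meaningfully from ungapped.
* **rDNA screen.** With precomputed 12-column tabular hits, any hit with
  e-value < 1e-5 rejects. With raw rDNA FASTA, the built-in ungapped
  local aligner (+1 match / −2 mismatch, Kadane per diagonal, both
  strands) scores the best hit and a Karlin–Altschul e-value
  `K·m·n·exp(−λS)` is computed with λ solved for uniform base composition
  and K fixed at 0.46. The screen needs decisions, not calibrated
  e-values; a perfect 25-base hit on any realistic rDNA set is many
  orders of magnitude below the cap, and random probes are far above it.
* **Selection.** Among screen-clean candidates, k = min(20, available)
  probes are chosen to maximize the minimum pairwise start distance —
  binary search on the gap with a greedy feasibility check anchored at
  the leftmost candidate, which is exact for this objective. Sources with
  fewer than 2 probes are kept and flagged under-covered rather than
  dropped, so coverage loss is visible instead of silent.
* **Composites.** Default pairing is "chained" (rank i with i+1, n−1
  composites per source) so composite counts scale linearly with probe
  counts, matching the observed ratio of roughly 9 composites to 5 short
  probes per gene; "all-pairs" is available. The 4-nt spacer is drawn
  from the run seed and redrawn (up to 20 times) if the 54-mer fails the
  specificity screen. Published descriptions fix neither the pairing rule
  nor the spacer sequence; both are configuration here.
* **Layout.** Triplicate spots at seed-permuted positions within a 15 000
  slot subarray (grid 100×150), controls interspersed. Placement is a
  permutation (injective), so replicate conservation and reproducibility
  are structural invariants.

## Signal analysis

Probe signal = median of replicate intensities (even counts average the
central pair); SNR = signal / median local background. Probes whose
background is ≤ 0 are excluded and reduce the 65 %-rule denominator — a
dead spot is evidence of nothing. The 65 % rule uses the weak inequality
(≥ 0.65), which keeps 2-of-3 detectable; the gene SNR averages **all**
probes of the type, not only positive ones. Both readings follow the
method's literal definition; the boundary convention and the averaging
set are configurable. No between-channel normalization is applied by
default (none is part of the method); an optional global median scaling
(`median_scale_channels`) is available for two-color runs with a visible
dye imbalance, and complex-mode reporting can restrict to composite
results via a flag rather than dropping short-probe data.

## Differential expression and profiling

Log2 ratios are computed per co-hybridized replicate pair
(paired-by-index) on gene SNRs and averaged; the SEM is over the
per-replicate log2 ratios (n = replicate hybridizations) — the error
bar's denominator is a design choice here, as the published figure does
not define it. Up-regulation is strict (> 2); a symmetric down threshold
(< −2) is added. Genes undetected in both conditions are excluded; genes
detected in one condition but with a missing or non-positive SNR in a
replicate are flagged `condition-exclusive` rather than given a ratio.
Composition profiles count each detected target once (presence-based) and
report percentages per family and per taxon; the two-method comparison
reports per-family shares `pct_X / (pct_X + pct_Y) × 100`, where 50 %
means both methods agree on the family's contribution.

## Simulator

The simulator reproduces qualitative regimes, not hybridization physics:

* 25-mers are all-or-nothing (`mismatch_tolerance = 0` by default, per
  the observed behavior of short probes against a 95 %-identity variant);
* composites follow full > half > none; `half_match_factor = 0.4` is an
  arbitrary mid-range constant — only the ordering is meaningful, and the
  tests assert the ordering, never the constant;
* spot intensity = lognormal background (mean 100, CV 0.15) + gain
  (1000 fluorescence units per abundance unit) × abundance × match factor
  × lognormal replicate noise (CV 0.1). At these defaults a transcript at
  abundance 1 yields SNR ≈ 11, and the detection floor
  (`abundance_floor = 0.2`) corresponds to SNR ≈ 3.

Scenario conditions: `two_condition` uses 50 genes, 3 replicate two-color
hybridizations, base abundance 2 in the reference channel, and embedded
fold changes 8× (up), one exact 4× boundary case, 1/8× (down) and 1×
(null); `complex_community` uses 60 genes across the three taxa with 30 %
absent; `pure_culture` includes one 98 %-identity pair so consensus
groups are exercised end to end; `variant_probe` expresses one gene as a
92 %-identity variant. Fixture designs cap selection at 6 probes per
source, matching the realized average of about five short probes per gene
on real catalogs rather than the hard maximum of 20; together with the
catalog sizes above this keeps a full 20-seed recovery study of both
stochastic scenarios to about a minute on one CPU while keeping ≥ 45
informative genes per seed.

**The boundary case.** An exact 4-fold gene sits *at* the strict >2
threshold; moreover its analytically expected log2 SNR ratio,
`log2((1 + g·aA/b)/(1 + g·aB/b))`, is slightly **below** 2 because the
additive background compresses observed ratios. Under replicate noise its
call is therefore a coin flip by construction. The truth table labels any
gene whose expected value lies within 0.3 of a ±2 threshold
`status = "boundary"`; exact-set recovery is asserted over the firm
(up/down/ns) genes, and the boundary gene's ns call (strict inequality)
is asserted separately in a noiseless run. The same expected-value
formula, not `log2(fold)`, is the reference for the ±0.3 recovery check,
since the background offset is a property of the signal model, not an
estimation error.

What passing simulations do **not** show: the simulator omits dye bias
and channel crosstalk (an optional linear dye-bias factor exists for
testing the normalization flag), scanner saturation / extended-dynamic-
range merging (assumed done upstream by feature extraction), spatial
artifacts, and any calibrated mismatch thermodynamics. Its attenuation
constants are stand-ins and must never be read as estimates of a real
array's physics.

## Numerical conventions and degenerate inputs

Coordinates are 0-based half-open internally. All randomness flows
through `numpy.random.default_rng(seed)`; identical seeds give
byte-identical fixture bundles (output tables carry a provenance comment
with version, seed and config digest, never timestamps). Empty background
→ screen passes with a logged warning; zero surviving candidates → source
reported undesignable, not a crash; empty call sets → header-only tables;
clustering an empty catalog, inverted Tm windows, capacity overflow and
orphan probe ids all raise with the offending name or count.

## Known limitations

* The original probe counts of the published array (1631 short, 2618
  composite over 392 targets) depend on background databases that are not
  redistributable; the design arithmetic is reproduced from the printed
  totals, while the design pipeline itself is validated on synthetic
  catalogs and oracle equivalence.
* Consensus construction assumes near-identity; it is not a general MSA.
* The rDNA e-value is screening-grade (fixed K, uniform composition).
* Wet-lab quantities (absolute SNR magnitudes, rumen detection counts,
  eukaryote share percentages) are laboratory outcomes the toolkit
  consumes or simulates qualitatively; it does not claim to predict them.
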