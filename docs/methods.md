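# Methods

## Statistical model

**Inputs.** A gene-level table of log fold changes FC_g (treated vs.
untreated), a prediction map assigning each miRNA family f a target-gene set
P_f and a member-miRNA set M_f, and an EV cargo profile assigning each
miRNA an abundance, hence a 1-based rank (descending abundance, ties broken
lexicographically so ranks are deterministic).

**Universe.** The tested universe is U = (∪_f P_f) ∩ {measured genes}:
only genes that are a predicted target of *some* family act as background,
so every comparison is competitive — a family's targets against the targets
of other families, not against the whole transcriptome. Measured genes with
no prediction are excluded and counted in the log.

**Per-family test.** For each family, T_f = P_f ∩ U and B_f = U \ T_f. The
Mann–Whitney U statistic for T_f is computed from mid-ranks of the pooled
log fold changes. The p-value uses

* the **exact null distribution** of U — built by convolving the rank
  generating function, equivalent to complete enumeration of all
  C(|T|+|B|, |T|) group assignments — when |T|+|B| ≤ `exact_limit`
  (default 16) and the pooled sample is tie-free;
* otherwise a **normal approximation** with tie-corrected variance
  n1·n2/12·[(N+1) − Σ(t³−t)/(N(N−1))] and a 0.5 continuity correction.

Two-sided p-values are twice the smaller tail, clamped to (0, 1]. The
default is two-sided: planted repression shifts targets down, but observed
target medians can sit above the background, so no direction is presumed;
`alternative="less"` is available when a one-sided down-regulation
hypothesis is intended. Families with fewer than `min_targets` (default 5)
usable targets, or with an empty background, are skipped with a logged
reason. Results are ordered by (p, family_id) and are invariant to the
row order of the input table.

**Selection.** Families with p strictly below α (default 0.05, no
multiple-testing correction — *nominal* significance; Benjamini–Hochberg
step-up available via `correction="bh"`) are cross-matched against the
cargo: a family is selected iff at least one member miRNA has rank ≤ top_k
(default 50); its `ev_rank` is the best member rank and the best-ranked
member is the reported representative (the map is many-member; all in-cargo
members are retained). Forced includes append individual miRNAs with
`provenance="forced"`; they never alter and never duplicate scan+cargo
selections, and are excluded from recovery metrics.

**Optional pre-filter.** `prefilter="down"` restricts the fold-change table
to log FC < 0 before building the universe, for the reading of the method in
which only down-regulated genes are compared. The default is no pre-filter:
a positive background median is perfectly compatible with the competitive
test, and pre-filtering conditions the universe on the outcome.

## Synthetic data generator

The generator emulates the three inputs with a known planted signal:

* gene log fold changes ~ Normal(`baseline_mu`, `noise_sigma`²), i.i.d.;
* each of `n_families` families receives `targets_per_family` genes sampled
  uniformly (independently across families when `overlap` is true, disjoint
  blocks of a permutation otherwise); `n_active` families are drawn at
  random as *active* and the **union** of their target sets is shifted by
  −`effect_delta` (a gene targeted by two active families shifts once —
  repeated subtraction would make the planted effect size depend on map
  collisions);
* each family has exactly one member miRNA (the many-member mapping is
  exercised through IO fixtures, not the generator); the cargo carries all
  family members plus decoys: active members at distinct random ranks within
  1..`active_member_max_rank`, inactive members strictly below that block,
  decoys filling the rest, with strictly positive random abundances assigned
  in rank order so the reader reconstructs exactly the planted ranks.

A single seeded generator is consumed in fixed stream order (genes →
families → cargo), so datasets are bit-reproducible and new config fields
appended to later streams cannot silently reshuffle earlier draws.

Defaults — the package's reference study conditions — are 2000 genes, 50
families × 40 targets, 5 active, `baseline_mu` = 0.03 (a typical background
median log FC in this setting), `noise_sigma` = 0.2, `effect_delta` = 0.6
(= 3σ, a strong, clearly recoverable repression), cargo of 150 miRNAs with
active members inside the top 50. Units of `baseline_mu`, `noise_sigma` and
`effect_delta` are log-fold-change units (dimensionless).

The planted-rank separation (inactive members strictly below the top block)
is a deliberate design choice: it makes end-to-end recovery a test of the
scan + selection logic rather than of whether a false-positive family's
member happened to collide with the top-k cargo. Real cargo profiles do have
such incidental overlaps; the cost of the choice is that the cargo
cross-match in simulation never has to veto a significant-by-chance family,
so simulated precision reflects the planted geometry, not cargo noise.

## Calibration and recovery

`run_calibration` generates replicate datasets (seeds spawned
deterministically from the config seed), scans each, and pools family-level
p-values: the type-I rate is the rejection fraction among inactive families,
power among active ones. Families within one replicate share their
competitive background, so their p-values are positively correlated; the
package's calibration checks therefore pool **many small replicates**
(200 × 10 families = 2000 tests) rather than few large ones, keeping the
pooled tests close to the independence a binomial reference interval
assumes. Under the global null the empirical type-I rate at α = 0.05 falls
inside the exact binomial 99% interval and the pooled p-values pass a KS
uniformity test (verified in the test suite and recomputed by
`scripts/acceptance.py`); at the default 3σ effect the measured power is
≈ 1, consistent with the closed-form large-sample approximation
(P(X<Y) = Φ(δ/σ√2), normal approximation of U).

`evaluate_recovery` reports precision, recall and observed FDR of the
selected families against the planted truth, excluding forced entries;
empty-denominator conventions: precision 1.0 when nothing is selected,
recall 1.0 when the truth is empty.

## Numerical and interface choices

* Exact p-values are ratios of integer-valued counts accumulated in float64
  (largest count at `exact_limit`=16 is C(16,8)=12870, far below the 2⁵³
  integer-exact range).
* p-values are clamped to (0, 1]; a degenerate pooled sample (all values
  identical) returns p = 1.
* Report TSVs store floats at `repr` precision and the readers parse with
  correctly-rounded `float()`, so write→read round-trips are bit-exact
  (pandas' fast numeric parser is not round-trip safe and is bypassed).
* The rendered table rounds medians to 2 and p to 4 decimals with decimal
  half-away-from-zero rounding (0.03125 → 0.0313), matching the convention
  of published tables of this kind; full precision lives only in the TSV.
* Gene identifiers are normalized by case-folding and whitespace-stripping
  only. No ortholog or cross-species mapping is attempted — matching e.g.
  human miRNA target predictions to mouse transcripts is left to the caller
  via the `normalizer` hook on the readers.
* Cargo rank ties broken lexicographically; candidate output sorted by
  (ev_rank, family_id); scan output by (p, family_id).
* CLI exit codes: 0 ok, 2 input error, 3 config error, 4 empty result. When
  both flags and `--config` YAML are given, YAML keys take precedence.
* Duplicate fold-change gene ids: policy `error` (default), `first`, or
  `mean`; every drop or collapse is logged with line numbers.

## What passing tests do and do not show

The generator plants normal, homoscedastic, gene-independent noise and a
pure location shift. Real bulk RNA-seq fold changes are heavier-tailed,
variance depends on expression level, genes are co-regulated, and target
predictions contain false positives — all of which reduce effective power
and can distort calibration relative to the simulation. Passing the
calibration and recovery suites shows the machinery is correct and the test
is valid under its own assumptions; it does not certify power or FDR on real
data, and candidate identity on real inputs further depends on the
prediction-database release and the expression data used.
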