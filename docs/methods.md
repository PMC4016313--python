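# Methods

## The mining model

`coexmine` treats a corpus of pairwise differential-expression comparisons
as ARM transactions whose items are the differentially expressed genes. One
rule family is evaluated: *IF target THEN X* for every other item X in the
corpus. Fixing one item and the rule cardinality at 2 removes the need for
Apriori-style frequent-itemset search; the engine reduces each (comparison,
gene) pair to two boolean flags and tallies five counts per candidate.

**Presence and modulation.** A gene is *present* in a comparison when any of
its probes has adjusted p ≤ `adj_p_max`; it is *modulated* when a single
probe simultaneously passes the significance threshold and the LFC test.
Both clauses must hold on the same probe: a probe that fails significance
provides no evidence that its fold change is real. Threshold comparisons are
inclusive (`adj_p <= t`, `|lfc| >= t`). When probes of one gene disagree in
direction, the reported sign comes from the qualifying probe with the
largest |LFC| (ties broken by lexicographically smallest probe id) — a
deterministic convention, since the upstream corpus gives no rule for
resolving multi-probe conflicts. Directional tests (target or gene sign
±1) qualify only in *oriented* comparisons, i.e. those where a designated
control group defines the biological meaning of the sign; in unoriented
comparisons a directional query treats the gene as not modulated, while
presence is unaffected (it is direction-free).

Unmapped probes — identifiers with no official gene symbol — are retained in
the store and can surface in result lists as candidate items under their own
id, but cannot be chosen as the target.

**Indexes.** For counts N_Tp, N_Tp,Xp, N_Tm,Xm, N_Tm,Xp, N_Tp,Xm:

- co-presence = N_Tp,Xp / N_Tp. Applied first (default 40%), before any
  other index is computed, so Lift and χ² are never reported for candidates
  co-measured with the target too rarely to estimate them reliably.
- co-expression = N_Tm,Xm / N_Tp,Xp (the support analogue).
- Lift = (N_Tp,Xp · N_Tm,Xm) / (N_Tp,Xm · N_Tm,Xp). Under independence of
  the two modulation indicators, conditional on the margins, N_Tm,Xm is
  hypergeometric with mean N_Tm,Xp·N_Tp,Xm/N_Tp,Xp, so the expected Lift is
  exactly 1; the engine's null calibration tests exploit this.
- χ² p value: Pearson 1-df test, two-sided, without Yates continuity
  correction, on the 2×2 table (a, b; c, d) with a = N_Tm,Xm,
  b = N_Tm,Xp − a, c = N_Tp,Xm − a, d = N_Tp,Xp − N_Tm,Xp − N_Tp,Xm + a.
  The table is built over the co-present comparisons only — presence is the
  only regime in which modulation of both genes is observable. A zero
  statistic returns p = 1 exactly.

**Undefined values.** A ratio with a zero denominator (Lift with
N_Tp,Xm·N_Tm,Xp = 0; χ² with a zero marginal) is carried as NaN and printed
as `NA`. Undefined rows never pass a positive `lift_min` or the χ² filter;
`lift_min = 0` disables the Lift filter entirely. A target that is measured
but never present yields an empty result rather than an error. Note a row
with undefined Lift necessarily has a zero χ² marginal, so it can never be
emitted: the two conventions are mutually consistent.

**Ordering.** Output rows are sorted by descending Lift, ties by ascending
χ² p, then by symbol — a deterministic artifact convention.

**Dual computation paths.** `count_associations` evaluates per-record gene
states one pair at a time (the reference path); `run_query` computes boolean
item×comparison matrices and takes matrix–vector products. The test suite
asserts their exact agreement, and additionally checks `run_query` against a
brute-force transaction evaluator (independent loops and sets, χ² via
`scipy.stats.chi2_contingency`) exhaustively over all two-gene stores of up
to three comparisons in the full 3-state pattern space, plus 400 seeded
random stores up to 6 comparisons × 4 genes with all five probe states and
directional parameter sets.

## Preprocessing

A raw experiment enters as a log2 intensity matrix (probes × samples) and a
design table grouping samples by experimental factor. Groups with fewer than
two samples are dropped (no variance estimate is possible); a design left
with fewer than two groups is unusable and the experiment is discarded. The
usable groups form an all-groups-versus-group contrast matrix — k groups
give k(k−1)/2 pairs — optionally restricted by an externally curated
selection list that records which contrasts carry a biological rationale
(the curation itself is expert work, outside the package). A pair involving
the control group is oriented, with the control as the reference side:
LFC > 0 means up-regulation relative to control.

Per contrast and probe: LFC = mean(group A) − mean(group B) on the log2
scale; the p value comes from a Welch unequal-variance two-sample t test
(available-case over missing values, at least two usable values per side or
the probe is omitted with a reported count); adjusted p values are
Benjamini–Hochberg across all probes of the comparison. Degenerate
zero-variance probes get p = 1 when the means agree and p = 0 with a logged
warning when they differ, avoiding undefined t statistics. The store format
deliberately keeps both raw and adjusted p values so differential statistics
produced by external pipelines (e.g. moderated linear-model fits) can be
loaded unchanged; the mining engine is agnostic to how the measures were
produced.

## The synthetic-data generator

`generate_store` emulates the features of a real corpus that the mining
engine is sensitive to: per-gene measurement sparsity (`presence_rate`,
default 0.7 — a gene is reliably measured in ~70% of comparisons), a
background rate of spurious modulation among present genes
(`null_modulation_rate`, default 0.1), a majority of oriented comparisons
(`oriented_fraction` 0.9, matching a corpus where a control factor is
detectable in roughly nine of ten comparisons), and a gamma-Poisson number
of probes per gene (mean 2, dispersion 0.5, minimum 1).

Planted structure: a module is a driver gene plus member genes. The driver,
when present, modulates at `driver_modulation_rate` (default 0.4 — an
actively responsive gene, modulated in a substantial minority of its
reliably measured comparisons; this rate also leaves a comfortable
operating margin between planted members, whose expected Lift is then
1/0.4 = 2.5, and null genes at the default Lift ≥ 2 filter). Whenever the
driver is present and modulated, each present member modulates with
`co_modulation_prob` and copies the driver's direction with probability
`sign_concordance`. Members are coupled strictly to the driver — they carry
no background modulation of their own — which keeps the planted ground
truth unambiguous: every member modulation event is attributable to the
module.

Flags are realized as values second: modulated genes get |LFC| ≥ 1 and
adjusted p ≤ 0.05, present non-modulated genes |LFC| ≤ 0.9 with adjusted
p ≤ 0.05, and non-present genes are either absent from the comparison or
measured with adjusted p > 0.05 (probability ½ each). Extra probes beyond a
gene's first are always realized non-significantly, so they never perturb
the planted flags. Consequently the canonical thresholds (LFC 1, adjusted p
0.05) recover the simulated flags exactly, and distributional tests can
count over the generated store itself.

What the generator does **not** emulate: correlated presence patterns
between platforms, realistic marginal distributions of modulation breadth
across genes, p value/LFC dependence within a probe, or batch structure.
Passing tests therefore demonstrate the correctness and calibration of the
mining machinery under clean planted structure, not performance on any real
corpus.

`generate_experiment` produces raw inputs for the preprocessing pipeline:
per-probe baselines uniform in [4, 12] log2 units, planted per-group shifts,
Gaussian noise with σ = 0.3 by default (a typical within-group array SD on
the log2 scale).

## Defaults and problem sizes

The query defaults — target sign 0, target and gene LFC thresholds 1,
adjusted p 0.05, co-presence 40%, Lift 2, χ² p 0.05 — are the canonical
operating point for a general characterization of a target gene; tighter
Lift/χ² cut-offs trade recall for precision, and the suite verifies that the
output shrinks monotonically along both axes.

Calibration and recovery checks run on 200-comparison stores with 2,000
null candidates (Lift calibration; at these sizes the mean Lift over
candidates has a Monte-Carlo standard error of about 0.01) and with a
10-member planted module over 500 null genes (recovery; per-member recovery
probability ≈ 0.98 and per-null-gene false-positive probability ≈ 0.009
under the generator defaults, derived once from the generator's ground
truth and frozen as regression bounds: sensitivity ≥ 0.8, false-positive
rate ≤ 2%). The null χ² rejection rate is asserted within ±0.03 of the
0.05 nominal level rather than at Monte-Carlo precision: the co-present
2×2 tables have expected joint-modulation counts around 4, so the Pearson
test's finite-sample level carries a discreteness error larger than the
sampling noise.

## Numerical conventions

- Store files print floats with `repr` (shortest round-trip), so
  write→read is the identity on the binary values and repeated writes are
  byte-identical; result files print indexes with 6 significant digits and
  counts as integers, with `.` decimals regardless of locale.
- BH adjustment preserves input order and is computed with
  `statsmodels.stats.multitest.multipletests` (verified in tests against
  the textbook step-up formula).
- Welch p values use `scipy.stats.ttest_ind(equal_var=False)` (verified
  against the hand-coded Welch–Satterthwaite formula to 1e-12).
- χ² p values use the closed-form Pearson statistic with the χ²₁ survival
  function (verified against `scipy.stats.chi2_contingency` to 1e-10).

## Known limitations

- Rules are restricted to cardinality 2 with the target fixed; higher-order
  co-modulation patterns are out of scope.
- The χ² test is two-sided and unconditional on direction; a one-sided
  variant would be more powerful for enrichment-only questions but is not
  what the generic independence test computes.
- Preprocessing uses ordinary Welch statistics, not moderated
  (empirical-Bayes) ones; for small-replicate arrays, moderated statistics
  from an external pipeline can be loaded through the store format instead.
- The package never performs network access; corpus construction from
  public repositories is deliberately left to external tooling.
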