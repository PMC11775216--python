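# Methods

## Input model and filtering

The canonical input is a long panel of scores in [0, 100], one row per
(country, year, indicator). Scores are consumed as given: the package
performs no normalization or imputation of its own, on the grounds that
share-based specialization measures are ill-defined under imputed cells.
Per-year matrices are made complete in two deterministic steps: an
indicator observed for fewer than `coverage` × (countries present that
year) is dropped (default coverage 0.8 — the 0–100 scale carries no
numeric rule for "covers most countries", so 80% is our cut), then any
country still missing a cell is dropped rather than imputed. Both
dropped sets are reported on the result and logged. The selection is
idempotent. Country identifiers are opaque strings; nothing in the
method needs geography, so ISO3 codes are recommended but not enforced.

## Specialization (centered Balassa index)

For a complete year matrix the index compares a country's score share on
an indicator with the world's share; we store the centered form
(`ratio − 1`) so 0 is world-average. Two exact identities are enforced
and tested: the world-share-weighted mean of the centered index is 0 for
every country (share conservation, tolerance 1e−9 in tests, attained at
~1e−15), and the index is invariant to rescaling all scores by a
positive constant. Binarization is strict: advantage requires `RCA > 0`,
so a tie at exactly 0 is non-advantage. Regional profiles aggregate
member countries by unweighted mean score before applying the same
formula; score-weighted aggregation would be equally defensible, and the
choice is visible in one place (`region_rca`).

## CSI / GSI

The spectral route is canonical. The country projection
`W = D⁻¹ M U⁻¹ Mᵀ` is row-stochastic, so its leading eigenvector is
constant and uninformative; CSI is the eigenvector of the second-largest
eigenvalue. Numerically we diagonalize the symmetric similar matrix
`D^(−1/2) M U⁻¹ Mᵀ D^(−1/2)` and deflate its known leading eigenpair
(eigenvalue 1, direction `D^(1/2)·1`) before taking the top remaining
eigenvector. Deflation rather than rank-ordering matters when the
leading eigenvalue is degenerate — a disconnected advantage structure
has multiplicity ≥ 2 at eigenvalue 1, and the informative contrast
direction lives inside that eigenspace. A second eigenvalue that is not
separated from the next (gap < 1e−10), or an index vector with zero
variance, raises a degeneracy error instead of returning arbitrary
numbers.

The method of reflections is kept as an independently-implemented
cross-check. Raw alternating averaging collapses to a constant vector;
we therefore z-score both index vectors after every round, which turns
the iteration into power iteration on `W` with the constant direction
removed, and it converges to the spectral solution (asserted at
|Pearson r| ≥ 0.999 on random full-support instances). Initial values
are diversity and ubiquity. On perfectly regular matrices (constant
diversity *and* ubiquity — e.g. exactly planted blocks) that classic
initialization is constant and cannot break symmetry, so a deterministic
fallback ladder is used: ubiquity-weighted diversity, then a
column-position-weighted sum. The fallback is label-order dependent and
only ever reached on degenerate-regular structures; on generic data the
iteration is permutation-equivariant. Convergence is declared when the
largest absolute change of either standardized vector (after aligning
the arbitrary per-round sign with the previous iterate) falls below
`tol` (default 1e−10, `max_iter` 1000); non-convergence returns the last
iterate flagged `converged=False` with a warning.

Both vectors are z-scored per year (mean 0, sd 1; indices are never
pooled across years) and sign-anchored: CSI is flipped to correlate
non-negatively with the per-country total raw score, and GSI is aligned
with the CSI-implied indicator index so the pair stays coherent; a
secondary anchor (GSI vs indicator world-mean score) applies only when
the primary correlation is exactly zero, and a largest-entry-positive
rule is the last resort when no score anchor exists.

## Proximity and the spaces

The canonical proximity is the cosine similarity of binary advantage
columns, `S = co/√(k_i·k_j)`. The product of the two pairwise
conditional probabilities equals `co²/(k_i·k_j)`, which is `S²` — not
`S`; both formulas are implemented, the squared variant as a diagnostic,
and the identity `conditional_product = cosine²` is property-tested.
Thresholds (0.7 default, 0.5 floor in the robustness sweep) are phrased
on the cosine scale. Trade-off similarity is `1 − S`.

The backbone is a maximum spanning tree computed by Kruskal on
descending weights with a lexicographic tie-break on the sorted label
pair. Binary-derived proximities are full of exact ties, so the
tie-break is what makes the tree — and every downstream export —
deterministic. Overlay edges use `S ≥ threshold` (inclusive). Only
strictly positive proximities can enter the tree; a graph that is
disconnected under positive weights is an error by default. The
`allow_forest` option instead returns the maximum spanning forest: in
the perfectly polarized limit the two indicator clusters share no
co-specialization at all, the proximity matrix is exactly
block-diagonal, and a forest (whose components are then the communities)
is the only faithful backbone. The full pipeline enables this option so
the noise-free limit is handled rather than fatal.

Communities come from Girvan–Newman: repeatedly delete the edge of
maximum betweenness on the unweighted MST∪overlay graph (ties:
lexicographically smallest pair) until it splits into two components.
Running on the rendered graph rather than the full thresholded graph,
and ignoring weights in the betweenness, are deliberate choices — both
are checked against an exhaustive best-two-cut modularity oracle on
small planted graphs. Community 1 is the one with the higher mean node
score (GSI or CSI). Layout is Kamada–Kawai from a fixed circular
initialization of the sorted node list, rescaled to the unit bounding
box; it is deterministic by construction and used for export only. The
country space is the identical pipeline on `Mᵀ` with CSI as the node
score.

## Trajectories, stages, orphaned indicators

Countries are ranked ascending by the unweighted mean of their indicator
scores (an external composite index can be injected; official SDG-index
weighting is not recomputed here). Windows are rank-contiguous with
stride 1, so `N` countries and width `w` give `N − w + 1` windows; with
the study-scale 166 countries and the default width 50 that is 117.
Width 50 keeps the curves smooth without flattening the crossing
structure; widths 20–70 are compared in the robustness sweep. Crossings
of group curves are strict sign changes of the difference between
consecutive windows, reported at the right-hand window; touching zero
without sign reversal does not count.

Stages are contiguous rank quartiles by default; remainder countries go
to the outermost stages first (166 → 42, 41, 41, 42 — the remainder rule
is our construction). The top stage can be split into halves for
near-transition analysis. Stage summaries are unweighted mean RCA
profiles; deltas are exact consecutive differences (telescoping is
tested), and top/bottom-k lists break ties lexicographically.

"Orphaned" is a narrative notion that we operationalize with an explicit
rule: an indicator is flagged at transition s→s+1 when its mean RCA
falls (Δ < 0) into non-positive territory (mean at s+1 ≤ 0), and the
overall orphaned verdict additionally requires the flag at the final
transition plus membership in the low-GSI side (the low-score space
community when available, otherwise `GSI < 0`). The rule's parameters
are arguments, not constants, and we claim operational usefulness — not
equivalence with any qualitative description. GSI groups use cuts 0.5
and −1.0 (inclusive on the middle band) crossed with the environment
flag; the four-area classification splits on `RCA > 0` (strict,
mirroring the advantage threshold) and score ≥ the global average
(inclusive).

## Synthetic generator

The generator emulates the one robust feature the method is built to
detect: a polarized, two-cluster world. One country block sits at a
higher base level (default 72 vs 55 score points, bracketing the
observed global average of ~63) and over-performs by an additive boost
(default 8 points) on its own indicator block; the other block mirrors
this. Gaussian cell noise (default sd 3 points, a plausible measurement
scale relative to the ~17-point level separation) is added and the
result clipped to [0, 100]; clipping mass is negligible at the defaults.
All years share one drift term (default +0.3 points/year, ≈ +7 points
over 2000–2022). One global generator stream driven by a single seed
makes panels bit-reproducible. The additive boost keeps the binary
advantage pattern derivable in closed form: at zero noise, `M` equals
the planted block pattern exactly, which the tests verify cell by cell.

What the generator does *not* emulate: realistic marginal score
distributions, per-indicator heterogeneity, missing-data patterns,
regional autocorrelation, or more than two clusters. Tests passing on
this panel therefore demonstrate that the machinery recovers planted
structure under controlled noise — not that any real-world panel has
that structure.

Two conditioning choices in the stability checks follow from the
planted design. Partition-recovery and threshold-sweep checks run at the
default noise (and exactly, at zero noise). The window-size stability
check runs on the noise-free panel: the two-level construction produces
RCA trajectories with long flat plateaus, and on a plateau the window
ordering under any cell noise is arbitrary, which caps rank correlations
between smoothing widths near 0.75 no matter how strong the planted
signal is. The noise-free panel is the generator's "smooth" condition,
where the curves are deterministic functions of rank and the widths
20–70 agree at minimum pairwise Spearman 0.94.

## Numerical choices and degenerate inputs

- Eigen gap and zero-variance tolerances: 1e−10 / 1e−12.
- Z-scores use the population standard deviation (ddof 0).
- All CSV exports use fixed 9-decimal formatting, so write→load is the
  identity and repeated runs are byte-identical (hash-tested).
- Duplicate panel keys, out-of-range scores, unknown catalog
  vocabulary, zero row/column totals, empty regions/groups, windows
  wider than the ranking, and over-pruned advantage matrices all raise
  typed errors naming the offending entity.

## Problem sizes

The test-suite and the acceptance script exercise the method at the full
study scale — 166 countries × 96 indicators, 23 years — for the
structural counts and recovery checks, and at 8–32 entities for
exhaustive oracles (all spanning trees at n ≤ 6, all two-cuts at ≤ 10
nodes, brute-force eigendecomposition at 4 countries).

## Known limitations

- Printed index values from external score panels are not reproduced:
  official composite rankings use goal-level weighting this package
  deliberately does not re-implement, and the GSI z-scale depends on
  the exact indicator set retained.
- The orphaned rule and the regional mean aggregation are declared
  operationalizations of qualitative notions.
- Girvan–Newman with exhaustive betweenness recomputation is O(V·E²)
  per split and is intended for the ~100-node spaces it is used on, not
  for graphs orders of magnitude larger.
- With `allow_forest`, more than two components yield more than two
  communities; downstream sweeps flag (rather than fail on) degenerate
  single-community partitions.
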