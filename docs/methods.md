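# Methods

## Problem setting

CAM photosynthesis inverts the diel schedule of carbon fixation: CO₂ is
taken up at night by PEPC and refixed by RuBisCO during the day. Because
CAM arose independently in eudicot and monocot lineages, genes recruited
into CAM are expected to show two signatures of convergence relative to C3
relatives: (a) re-scheduled diel transcript expression shared by the CAM
lineages, and (b) parallel amino-acid substitutions in CAM copies of the
underlying proteins. The package implements both screens over a common
data model and ships generators that emulate the inputs with planted truth.

## Time representation

Time is hours after light onset on the half-open interval (0, 24], with
hour 24 identified with hour 0; all shifts are circular. The canonical
sampling grid is {2, 4, …, 24} (12 points, 2 h steps) under a 12 h light /
12 h dark photoperiod. The four analysis windows are dawn {22, 24, 2},
midday {4, 6, 8}, dusk {10, 12, 14} and midnight {16, 18, 20}; dawn↔dusk
and midday↔midnight are opposite pairs. Sparser grids (e.g. 4 h C3 data)
are accepted on input and brought onto the canonical grid by periodic
cubic-spline interpolation of the replicate mean before any comparison.
Periodic (rather than natural) boundary conditions are used because the
24 h cycle is genuinely circular; clipping at zero preserves FPKM
non-negativity.

## Expression screen

**Replicate handling.** Replicates are averaged per time point before
interpolation, correlation and shift estimation; the replicate-resolved
values feed only the window-contrast and flat-line tests. This mirrors the
usual practice of correlating one diel curve per gene while testing
abundance contrasts statistically.

**Normalization.** Each gene's 12-point mean series is z-scored
((x − mean)/sd, population sd). Zero-variance profiles are flagged
degenerate, excluded from correlation and shift estimation, and can never
be called convergent.

**Correlation.** Spearman's rank correlation with average ranks for ties,
on the canonical grid. Thresholds are strict: r > 0.8 counts as "in phase",
r < 0.5 as "not in phase"; boundary values fail.

**Circular shift.** Both z-scored profiles are upsampled to a 0.5 h grid by
periodic cubic spline; the shift is the signed lag in (−12, +12] maximizing
the Pearson correlation between a(t) and b(t + lag) over all 48 candidate
lags (positive = second profile lags first). Ties break toward the smaller
absolute lag, then toward the positive lag. The half-hour grid matches the
sub-sampling-interval resolution at which shifts such as 1.5 h are
reported in this literature. On noiseless rotations the estimator is exact
for every half-hour offset (verified in the tests), and it is antisymmetric
modulo the period.

**Window contrasts.** For each gene, a two-sided Welch t-test compares the
pooled per-replicate values of one window (3 time points × n replicates)
against the opposite window, for both opposite-window pairs. P-values are
BH-adjusted genome-wide within each species, pooling both contrasts into
one family; the choice of test and adjustment scope is a package decision —
the screen definition fixes only "significant difference at FDR < 0.01".
A gene's enriched window is the larger-mean window of its most significant
passing contrast.

**Classifier.** A focal gene is convergent iff all three criteria hold:
(1) max over CAM-partner orthologs r > 0.8 AND every C3 ortholog r < 0.5;
(2) the focal gene has a window contrast with q < 0.01 (required of the
focal gene only; the triangle network additionally requires the CAM
partner, matching the figure-style motif definition);
(3) |shift| ≤ 3 h to the best CAM-partner ortholog and ≥ 6 h from both CAM
genes to the single best-matched C3 ortholog, "best matched" meaning the
C3 ortholog with the highest Spearman correlation to the focal gene (the
matching rule is otherwise unspecified in this screen's definition).

**Flat-line filter.** Time structure is assessed by regressing
log₂(count + 1) of the replicate-resolved series on a cubic polynomial in
time and comparing with an intercept-only null by F-test; genes with
p < 0.05 are time-structured. Degree 3 is a default (configurable): the
lowest degree able to track one diel peak and trough with asymmetry. A
constant series (both residual sums zero) is defined as non-structured
(p = 1).

**Clustering.** Profiles are clustered by average-linkage hierarchical
clustering on 1 − Spearman distances, with inputs ordered lexicographically
by gene id so results are deterministic. The number of clusters is a
parameter (the analogous published analysis does not state whether a fixed
k or a cut height was used). Rank-based distances produce frequent exact
ties, so the test oracle validates the merge sequence as greedy-optimal
under O(n³) recomputation rather than comparing tie-dependent partners.

## Sequence screen

**Tribes.** The all-vs-all similarity graph (edge weight
−log₁₀ max(E, 10⁻¹⁸⁰)) is filtered at E ≤ 10⁻⁵ and clustered by Markov
clustering at inflation 5.0. Numerical details left open by the original
TRIBE-MCL description are fixed for determinism: self-loop weight = the
node's maximum incident weight (1 for isolates), pruning threshold 10⁻⁸,
convergence when the matrix changes by < 10⁻⁶, at most 100
expansion/inflation cycles; clusters are connected components of the
converged matrix's support.

**CAM-convergence clades.** On a rooted gene tree with species roles
{CAM_dicot, CAM_monocot, C3, C4, other}, a qualifying clade contains ≥ 1
CAM-dicot leaf, ≥ 1 CAM-monocot leaf and zero C3/C4 leaves; "other"-role
leaves (e.g. basal species, additional paralogs outside the focal roles)
are permitted inside. Maximal clades are reported (parent violates the
rule). Trees arriving with a basal polytomy are midpoint-rooted with a
warning when branch lengths exist, otherwise the caller is asked to root
first.

**Ancestral states.** Fitch parsimony per alignment column, gaps treated
as missing and excluded from state sets. The top-down pass resolves ties
by preferring the parent's state, then the alphabetically first state.
Polytomies are folded child-by-child, which is exact on binary trees and
an upper bound on multifurcations. The parsimony score is invariant under
re-rooting (verified in tests); the reported labeling is one minimum-change
assignment.

**Convergent/divergent counts.** For two non-adjacent branches, a column
contributes a convergent substitution when both branches change state and
arrive at the same residue, divergent when they arrive at different
residues. Adjacent branches are rejected (the comparison is undefined when
the branches share an endpoint). Counts are accompanied by a
frequency-based null: the probability Σₐ πₐ² that two independent
substitutions drawn from the alignment's amino-acid frequencies land on
the same residue. This simple null is an explicit stand-in — the screen's
verdict uses only the count, not the null.

**Shared-substitution sites.** A column is reported when all foreground
(clade CAM-member) residues are identical and non-gap, no background
(C3/C4) sequence carries that residue, and ≥ 80% of background sequences
are non-gap. Background residues may differ among themselves, covering the
canonical case of a shared CAM aspartate against a basic R/K/H background.
Foreground unanimity (no foreground gaps) is required by default.

**Screen.** Tribes lacking any required species (default: every species
with a declared role, mirroring the all-13-species tribe filter) are
skipped with a log entry. A focal gene is convergent iff it sits in a
CAM-convergence clade, parsimony counts ≥ 1 convergent substitution
between its terminal branch and a monocot-CAM terminal branch of the
clade, and the clade yields ≥ 1 shared-substitution site against the C3/C4
background. The convergent-substitution requirement stands in for the
unspecified "convergent amino-acid changes detected" step of the original
three-part definition; parsimony reconstruction is the most transparent
choice and is fully oracle-tested here.

## Synthetic data

**Expression.** Each ortholog group has one gene per species. Abundance is
log-normal around a cosinor mean: FPKM(t) = exp(B + A·cos(2π(t − φ_s)/24)
+ ε), ε ~ N(0, noise_sd) independent per time point and replicate. Per
group, φ ~ U(0, 24); CAM species get φ_s = φ + N(0, jitter); in convergent
groups the C3 species gets φ + 12 h (antiphase, matching the ~9–11 h
shifts typical of re-scheduled CAM genes), in non-convergent groups φ +
jitter like the others; null-flat groups have A = 0. Defaults: B ~
N(2.0, 1.0) natural-log units (median ≈ 7 FPKM, spanning the dynamic range
where the 0.01-FPKM filter is safely passed), A ~ |N(1.5, 0.3)| (strong
but realistic diel oscillation, ~4–20-fold peak-to-trough), jitter 0.5 h,
noise_sd 0.2 (~±20% multiplicative noise), 3 replicates. The generator is
a pure function of (params, seed). What it does **not** emulate: missing
time points, count overdispersion, correlated replicates, multi-gene
ortholog groups, partial phase convergence — so perfect recovery on
synthetic data demonstrates the screen logic, not performance on real
transcriptomes.

**Sequences.** Alignments evolve along a 13-species tree (1 CAM eudicot, 2
CAM monocots, 6 C3, 2 C4, 2 "other" basal species) by a Poisson process
(events per site ~ Poisson(branch length), replacement uniform among the
other 19 residues; no indels, no empirical exchangeability matrix — the
site logic, not realism, is the target). Convergent tribes use a gene-tree
topology whose CAM-convergence clade is ((Kf, other₁), (Peq, other₂));
planted columns overwrite the two CAM leaves with a residue absent from
all other leaves. The two "other" leaves give the clade a background
context so that parsimony reconstructs two independent substitutions on
the non-adjacent CAM terminal branches — a foreground-only clade would
collapse the planted signal into one ancestral change, and directly sister
CAM leaves would make the branch pair adjacent. The clade-internal context
branches have zero length so that context is deterministic; CAM terminal
branches and the rest of the tree use 0.05 substitutions/site. Three
columns are planted per convergent tribe.

**Similarity graphs.** Planted cliques with E ≈ 10⁻⁵⁰ (±1 decade) joined
by single bridges at E ≈ 10⁻³; with the default cutoff the filtered graph
decomposes into the planted tribes, and sub-cutoff bridges exercise MCL's
own splitting.

## Numerical choices and degenerate inputs

- Spline interpolation: periodic natural cubic; clipped at 0 only when the
  output is on the FPKM scale (not for z-scored series).
- Shift ties: resolved at 10⁻¹² correlation tolerance.
- Expression filter: strict inequality (FPKM > 0.01), so a gene at exactly
  the threshold everywhere is dropped.
- Welch test on fewer than 2 observations per window is an error; an
  all-equal contrast returns p = 1.
- BH adjustment via the standard step-up; a single p-value is returned
  unchanged.
- MCL on an empty graph returns an empty tribe set; isolated nodes become
  singleton tribes.
- Columns with all leaves gapped are skipped in parsimony counting.
- Results serialization uses 6 significant digits; verdict booleans
  round-trip exactly.

## Problem sizes used in the checks

The test suite and the acceptance script run the expression screen at 500
ortholog groups (10% convergent), the sequence screen at 50 tribes (10
planted), the flat-line null at 2000 genes, shift exactness at all 24
half-hour rotations plus hundreds of random noisy pairs, and each oracle
equivalence at ≥ 100 random small instances — sizes chosen so the full
suite completes in well under a minute per screen while keeping binomial
noise on the recovery rates small.

## Known limitations

- The screens' thresholds are taken as fixed constants; no attempt is made
  to calibrate them against data.
- The window-contrast test and FDR scope are package decisions (Welch +
  genome-wide BH per species); other reasonable choices would change
  borderline calls.
- Fitch parsimony ignores branch lengths and substitution biases;
  maximum-likelihood ancestral reconstruction is out of scope.
- The Σπ² convergence null ignores site heterogeneity and
  same-as-parent exclusion; it is reported for context only.
- Gene-tree inference is consumed, not performed; clade calls inherit any
  rooting or topology errors of the input trees.
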