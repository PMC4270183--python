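# Methods

This note documents the models, defaults and numerical choices behind
`nichegrn`, and what the synthetic study does and does not establish.

## Quartile expression

Equal-frequency discretization (EFD) sorts one region's median-summarized
gene values and splits them into k = 4 bins of (approximately) equal
occupancy; the bin index 1–4 is the gene's quartile expression (QE).
Differential expression between two regions is a quartile change
|QDE| ≥ 2; the ±2 margin trades sensitivity for robustness against genes
sitting near a quartile boundary.

*Ties.* EFD is underdetermined when tied values straddle a boundary. We
require (i) equal values receive equal QE, (ii) the assignment is monotone
in value, and (iii) among all such assignments the total deviation
Σ_bins |count − n/k| is minimal; remaining ties are broken by the
lexicographically smallest assignment in value order. This is computed
exactly by dynamic programming over tie blocks (integer arithmetic scaled
by k; O(k·m) per region via a sliding-window minimum), and is verified in
the tests against exhaustive enumeration on all small multisets. For
tie-free inputs with k | n every bin holds exactly n/k genes.

*Medians.* Probe-to-gene and replicate summarization both use medians
(even-count median = mean of the two central values); medians keep single
outlier probes or replicates from moving a gene across a quartile.

*Shape diagnostics.* Sample skewness (g1) and kurtosis (raw, non-excess,
by default; a flag switches to excess) are reported per region pooled over
all features and samples. Matching shapes across platforms is the
empirical justification for comparing rank-based quartiles across a
microarray-intensity scale and an FPKM scale.

## Boolean semantics

Synchronous threshold dynamics over a signed digraph: per gene, the counts
of activating (a) and inhibiting (i) edges whose *source is ON* are
compared; a > i turns the gene ON, i ≥ a > 0 (ties included) turns it OFF,
and a gene with no ON regulator holds its current value. The hold rule is
a deliberate choice where the semantics are underdetermined: without it,
any observed state in which a gene merely lacks an active regulator would
spontaneously decay, and no expression state could be an attractor of a
sparse network. A `no_input="decay"` flag provides the alternative.
"Binding" edges follow the same logic as transcription-regulation edges
once signed; a flag restricts simulation to transcription edges.

Fixed points are states reproduced by one update; trajectories are
simulated until a state repeats (guaranteed within 2^n steps) and
classified as fixed point or limit cycle with its period.

## Contextualization

Chromosome: one keep/remove bit per prior edge plus one sign bit per
originally unassigned edge. Fitness: mean per-state consistency (fraction
of genes whose update reproduces the observed value) minus
λ · removed/total. Defaults: λ = 0.1, population 200, generations 500,
uniform crossover 0.8, per-bit mutation 1/L, elitism 2, tournament
selection of size 3; the population always contains the keep-everything
individual, so a fully consistent prior is returned unchanged (with λ > 0
that is the unique optimum). Fitness evaluation is vectorized across the
population (edge-mask matrix products), which keeps the default budget at
well under a second for networks with tens of edges. Identical seeds give
bit-identical networks; on random priors with ≤ 12 edges the returned
fitness matches exhaustive enumeration of every keep/sign assignment
(tested over 50 seeded instances).

The focused variant searches only edges incident to a chosen gene,
requires the gene and its prior first neighbors to be perfectly consistent
in every state, and leaves all other edges untouched (their signs must
already be assigned). The incident space is enumerated exhaustively up to
2^18 assignments (seeded GA beyond); infeasibility raises an error
carrying the best report found.

## SCC analysis

Strongly connected components come from Tarjan-style linear-time
decomposition (networkx); only components with ≥ 2 genes are treated as
stability motifs (singletons, even self-looped, are excluded unless
requested). Out-degree interface counts a gene's outgoing edges whose
target stays inside its SCC; rankings sort by degree then gene id, so they
are deterministic and invariant to edge order. When two networks are
compared, the largest SCC of each is designated (overridable) and shared
genes are checked for agreement of the predicted Boolean states.

## Pair statistics

D = (g1_diff − g2_diff) − (g1_stem − g2_stem) on log2 median expression;
the stem-state ratio enters subtractively, which *is* the normalization by
the stem expression ratio (an alternative multiplicative reading — divide
by |g1_stem − g2_stem| with an ε-guard — is available behind a flag).
Robust z: after sorting, ⌊0.025·n⌋ values are trimmed per side; location
and scale are the mean and SD (ddof = 1) of the remaining central mass and
the same linear transform is applied to every value including the trimmed
ones. The trimmed SD systematically underestimates the full-population SD
(by ≈ 13% for a normal at 2.5% trimming), so it is divided by the
truncated-normal consistency factor sqrt(1 − 2·a·φ(a)/(1 − 2α)) with
a = Φ⁻¹(1 − α); this makes the z-test calibrated under a normal null
(raw p < 0.05 rate = 0.05), which the tests verify by simulation. BH
adjustment uses the standard step-up rule at α = 0.05.

Candidate filtering (all thresholds reuse the ±2 QDE margin): c1 — at
least one gene with QE(differentiated) − QE(baseline) ≥ 2; c2 — neither
gene with QE(stem) − QE(baseline) ≤ −2; c3 — both genes inside the
designated SCC with a direct prior edge between them; c4 — exactly one
inside and directly linked to its partner. A pair is kept iff adjusted
p < α and c1 ∧ c2 ∧ (c3 ∨ c4). The up/down calls are baseline-relative by
default because the stem-vs-differentiated reading of c2 is nearly
contradictory with c1 (a pair's up-gene is by definition "down in stem
relative to differentiated"); the literal alternative remains available
(`baseline_relative=False` / `--no-baseline`). Reported orientation puts
the differentiated-up gene first.

## Synthetic study

The generator reproduces the *structure* of the two-niche design: site A
(stemA/diffA) as microarray-like intensities with 1–3 probes per gene and
4 replicates per region; site B (stemB/diffB) as FPKM-like values, one
feature per gene, 3 replicates; a basal reference panel; and a signed
prior network. It makes no attempt to mimic real gene symbols, pathway
topology, or gene–gene covariance.

*Intensity model.* Gene base values are a stratified sample (quantile
grid, randomly permuted over gene ids) of an upper-truncated lognormal:
site A σ = 1.63 (ln units) over quantiles (0, 0.9986), scale 120; site B
σ = 1.55 with a hard dynamic-range cap at its 0.978 quantile, scale 8.
Replicate noise is lognormal with SD 0.25 in log2 units; site A probes
carry a per-probe affinity (SD 0.1 log2). Site A measurement noise tapers
with intensity (×0.4 above the 0.9 quantile) and vanishes for "saturated"
single-probe genes above the 0.99 quantile — the standard intensity-CV
behaviour of array scanners, and the feature that pins the pooled sample
moments: a plain lognormal cannot show skewness ≈ 6.4–7.2 together with
raw kurtosis ≈ 64–77 (its kurtosis/skewness² ratio is ~3 versus ~1.5
here), whereas the truncated-and-saturated model lands inside both bands
on every seed. Genes whose positions are overridden by planting are
barred from upper-tail quantile slots so the tail composition — which
dominates the moments — is seed-stable.

*Planting.* 10% of genes are differentially expressed between the sites
at QDE ±2 (positions on a deterministic grid inside quartile centrals);
the 30-gene core network consists of two mutually inhibiting activation
cycles whose two opposite expression patterns (stem: group P ON, group Q
OFF; differentiated: reversed) are exact fixed points; spurious edges
(20% of the prior) are constructed so each one alone breaks at least one
state and removal is the unique single-edge repair; 20% of core edges are
published with unassigned signs, each placed so the wrong sign also breaks
a state. Together with λ > 0 this makes "remove exactly the spurious set,
restore the true signs" the unique fitness optimum, which the generator
verifies at construction time. Two rival pairs are planted among 100 TFs:
the up-gene (a core gene of the ON-in-differentiated group) starts at Q2
balanced with its partner and quadruples (+2 log2) upon differentiation,
landing in Q3 with a Q1 baseline, so c1 holds as 3 − 1 ≥ 2; the partner is
an out-of-SCC node linked by a direct inhibiting prior edge (consistent
with both states) for c4. Two pairs — not more — keep the fraction of
disbalanced pairs below the robust z-test's 2.5%-per-side trimming
capacity; with many planted pairs the pooled scale estimate inflates and
a |D| = 2 effect is no longer reliably significant.

*What passing tests show.* Recovery and calibration results on this
generator demonstrate the correctness and internal consistency of the
algorithms under the declared noise model. They do not establish
performance on real niche transcriptomes, where probe effects are
sequence-dependent, expression is correlated across genes, prior networks
are incomplete in biased ways, and true differential structure is not
confined to clean ±2 quartile shifts.

## Problem sizes and runtime

Defaults throughout are the analysis conditions: 6,000 genes, 100 TFs
(4,950 pairs), 30-gene prior with ~40 edges, GA population 200 ×
500 generations. A full pipeline run takes a few seconds on one CPU;
the complete test suite, including the exhaustive-enumeration and
simulation-based checks, runs in well under a minute.

## Known limitations

- The focused contextualization requires assigned signs outside the focus
  neighborhood; it does not co-optimize distant unassigned edges.
- The GA offers no optimality certificate beyond the ≤ 12-edge regime
  where it is checked exhaustively; very rugged priors may need larger
  populations.
- EFD with k other than 4 is supported, but the ±2 differential margin
  and the Booleanization threshold (ON iff QE ≥ 3) are quartile-minded
  defaults; change them together when changing k.
- The robust z-test's calibration argument assumes an approximately
  normal null for D; heavy-tailed nulls shift the raw p-value rate.
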