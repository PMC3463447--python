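# Methods

This note records the models, parameter choices and numerical conventions
behind `pcwnet`, and what the synthetic benchmarks do and do not demonstrate.

## Discretization (`exprio`)

Each gene row is reduced to {−1, 0, +1} with a two-sided rank rule: the
`⌈q·m⌉` largest of its *m* condition values become +1 and the `⌈q·m⌉`
smallest become −1 (default q = 0.15, configurable; 0 < q < 0.5). Rank rules
are scale-free, so any strictly increasing per-gene transform of the data
leaves the discretization unchanged. Ties at the quantile boundary are
broken by condition order (the earlier condition takes the extreme label) —
determinism is preferred over statistical nicety. A constant row has no
distinguishable extremes and maps to all zeros. Missing values are rejected
at load rather than imputed: the intended input is a complete, normalized
compendium. Only the three-level alphabet (K = 1) is supported; wider
alphabets are rejected explicitly.

## Seeded bi-clustering (`qbiclust`)

**Consistency.** For a gene set × condition set, each condition's score is
the fraction of member genes sharing the dominant nonzero symbol in that
column; the bi-cluster's consistency is the minimum over its conditions, and
an all-zero column scores 0.

**Seed phase.** Gene pairs are weighted by the number of conditions with
identical nonzero symbols. Every edge, in decreasing weight order (ties by
id pair), grows a candidate: starting from the pair's shared conditions,
genes are added one at a time — each addition retains only the conditions
still meeting c₁, and a candidate gene must itself match the dominant symbol
on at least c₁ of the retained conditions, so that dilution alone can never
admit an unrelated (e.g. all-zero) gene. The largest-area snapshot along the
growth chain is kept and then closed by alternating condition and gene
additions. Candidates from all edges are emitted in decreasing area subject
to an overlap rule: no gene pair appears in two emitted bi-clusters. This
growth-with-condition-shrinking is what makes the procedure exact on small
inputs — on 900 random 8×8 three-symbol matrices the largest c = 1
bi-cluster equalled the exhaustively enumerated optimum in every case — while
remaining greedy (and fast) at scale. Minimum sizes default to 3 genes × 3
conditions (2 × 2 in the small-matrix tests).

**Expansion.** Conditions are frozen; a gene is recruited when its symbols
equal the bi-cluster's dominant per-condition symbol on ≥ c₂ of the
conditions. Recruited genes are tracked separately from seed-phase members.

**Grid search.** For each (c₁, c₂) on the grid {0.70, 0.75, …, 0.95, 0.98},
a fraction of the seed genes (default 0.3) is held out of the seed matrix,
bi-clusters are built and expanded, and every non-training gene is scored by
its best match fraction to any dominant profile, zeroed below c₂ (without
this, the AUC would not depend on c₂ at all). Held-out seeds are positives;
an equal-size uniform draw of non-seed genes are negatives; the AUC is the
Mann–Whitney rank statistic with midrank ties, averaged over repeats
(default 3). Ties on the best AUC resolve to the smaller c₁, then smaller
c₂. Note that the AUC can reach 1.0 only when the seed list covers the
co-expressed ground truth — otherwise the negative draw legitimately
contains co-expressed non-seed genes that score as high as the positives.
The zero-noise sanity check therefore uses seeds covering all planted genes.

## Networks and modules (`coexnet`)

Edges require |ρ| > 0.7 (strict), where ρ is Spearman's correlation —
Pearson on midranks, computed on the *raw* expression values over the
bi-cluster's conditions; zero-variance series yield a no-edge sentinel. A
bi-cluster with no qualifying pair is dropped. Both signs participate
equally in module topology; the sign is kept as an edge attribute.

Module extraction follows the molecular-complex-detection recipe with its
canonical published defaults (degree cutoff 2, node score cutoff 0.2, k-core
2, depth limit 100, haircut on, fluff off): vertex weight = (highest k-core
of the closed neighborhood) × (that core's density); complexes grow from the
highest-weight unassigned vertex, admitting unassigned neighbors with weight
≥ 0.8 × the seed's. Two refinements are applied after the haircut: a module
must contain a 2-core, and it must be *strictly* denser than its parent
network — the sparsest member (lowest degree, then weight, then id) is
removed until the inequality holds or the module falls below the minimum
size. The strict-density refinement is what guarantees
`density(module) > density(network)` numerically; its corollary is that a
*complete* network (density exactly 1.0) admits no module, since no subgraph
of a clique is denser than it. Modules are non-overlapping, ordered by
density × size, and numbered `<network>_<ordinal>`. Hot links are the edges
with |ρ| ≥ max(0.95, the 90th percentile of the module's |ρ|) lying strictly
above the module median, grouped into connected components; the rule is a
documented substitute for a concept the literature leaves without a formula.

## Motif discovery (`motiffind`)

Promoters are anchored on the *translation* start: the L bp (default 2,000;
rice 4,000) immediately upstream of the first CDS base, strand-aware,
reverse-complemented for minus-strand genes, truncated (never padded) at
contig edges. GFF3 input is parsed with `gffutils`; a DataFrame of CDS
records is accepted directly.

**Enumerative finder.** Candidate words are the exact w-mers observed in the
promoters (w ∈ {6, 8, 10, 12}); a candidate must occur within the per-width
mismatch budget e(w) = {6:1, 8:2, 10:3, 12:4} in *every* promoter (both
strands scanned). The score is Σ over sequences of log(best-match
likelihood / background likelihood), where the best match is the
fewest-mismatch window (leftmost, forward strand first on ties), a matching
position contributes 0.9 and a mismatch (1−0.9)/3, and the background is an
order-0 model estimated from the input promoters (a genome-wide model can be
supplied). The 15 highest-scoring motifs per width are reported with all
instances within the budget. The implementation one-hot encodes windows and
computes match counts by BLAS matrix products (a few seconds for 20 × 2,000
bp at width 8).

**Gibbs site-sampler.** One motif of width w (default 8): per sweep and
sequence, the sequence's sites are removed from the count matrix
(pseudocount 0.25/base), windows are scored by the PWM/background log ratio,
and two slots are re-sampled, each choosing among all positions (weight
`copy_prior · likelihood ratio`) and an "absent" option (weight
`(1−copy_prior) · n_positions`), so per-sequence copy number ∈ {0, 1, 2}
(copy_prior default 0.5). A greedy phase-shift move every 10 sweeps realigns
all sites by up to ±2 positions when that raises the total likelihood —
without it the sampler converges to shifted optima. After 150 sweeps a
deterministic maximum-likelihood pass fixes the final sites; the best of 20
restarts by total log-likelihood ratio is returned. The restart count was
set from measured nucleation rates (≈ 0.2–0.7 per restart depending on the
background); planted and spurious attractors are separated by a wide score
gap. The consensus takes each column's top base, adding IUPAC degeneracy for
any base reaching half the top count.

**Phylogenetic filter.** Enumerated motifs are retained only when the
consensus occurs (exact IUPAC scan, both strands) in the ortholog promoter
of ≥ 50% of carrier genes in at least one other species; carriers without a
resolvable ortholog count against the fraction.

## Integration and annotation (`motifint`)

Similarity of two IUPAC consensi: over all ungapped offsets and both
orientations (minimum overlap 4), `matched` counts aligned columns whose
base sets intersect; the best offset maximizes matched (ties → larger
overlap, smaller |offset|, forward orientation). Two fractions are exposed:
`ratio` = matched/overlap at the best offset, and `pct` = matched/min(w₁,w₂)
— the matched share of the maximum alignable span. The match rule ("matched
positions > 4 and ≥ 80% matched") and the clustering edge rule use `pct`:
under the overlap-based reading, partial overlaps of unrelated words (5 of 6
aligned columns matching by chance) would count as strong matches, and the
random-group specificity test would saturate. Markov clustering runs at
inflation 4 with self-loops, expansion/inflation to a 1e-6 fixed point, and
clusters read off the converged matrix's connected systems (a partition;
singletons allowed). Cluster consensus: members are stacked gaplessly at
their best offsets against the longest member, columns covered by ≥ 50% of
members and inside the reference span are retained, and each column takes
the minimal IUPAC code covering all bases with ≥ 0.5 frequency (falling back
to the plurality bases), base weights split evenly across a degenerate
member's base set. Database consensi are pre-integrated by the same
procedure before annotation; names and tags of a matched cluster propagate.
Palindromy is equality with the IUPAC reverse complement. A module counts as
putatively co-regulated when any motif covers ≥ 80% of its genes; the three
most reliable motifs rank by (conserved, module coverage, id).

## Conservation and statistics (`constats`)

Orthologs come from reciprocal unique best hits (ties discard the gene) or a
supplied one-to-one map. A motif is conserved when ≥ 1 carrier gene's
ortholog promoter contains the consensus (exact IUPAC scan, both strands, 0
mismatches; the support threshold is configurable); motifs whose carriers
have no ortholog are *unevaluable*, a distinct status. The specificity test
predicts motifs (enumerative finder only, for comparability) from the
modules and from `n_groups` random gene groups of the mean module size
(default n_groups = 1000 as in genome-scale use; the bundled benchmark uses
15 groups at its reduced problem size), counts distinct known motifs matched
on each side, and applies Pearson's chi-square (1 df, no continuity
correction — the intended regime has large expected counts) to the 2×2
matched/unmatched table. AC-element distances are measured from an
occurrence's 3′ end to the ATG (L − offset − width), binned at 250 bp and
normalized per element; AC-I/AC-II reference consensi default to the
literature forms ACCTACC and ACCAACC. Stage annotation requires a module's
seed members to share exactly one stage *and* a seed fraction strictly above
10% of the module's genes; recruited genes inherit the stage, accumulating
labels across qualifying modules. Module function labels are the seed groups
(cellulose, lignin, NDP-sugar, GT families) intersecting the module;
consistency compares them with the top-3 motif tags (lignin accepts
AC-I/AC-II/lignin/MYB; the others accept MYB), with modules whose top-3
motifs are all untagged reported separately and excluded from the adjusted
rate.

## Synthetic data (`synthdata`)

The generator emulates a seeded co-expression study at desk scale. The
default configuration — 500 genes × 60 conditions, three disjoint 30×15
planted blocks, noise σ = 0.25, five seed genes per block — is the standard
benchmark instance used throughout the tests. Background cells are standard
normal. A planted cell is the block's per-condition effect plus
N(0, noise_sd): effects are `shift ×` evenly spaced multipliers over
(0.3, 1.7), randomly assigned to the block's conditions and signed by the
pattern type (up / down / mixed). Two properties motivated this model over a
constant shift: (i) a constant shift induces no gene–gene rank correlation
within a block, so the |ρ| > 0.7 edge rule — the pipeline's own definition
of co-expression — would find nothing to recover; a shared condition profile
is precisely what "co-expressed" means; and (ii) the multipliers average 1
exactly, so the mean planted elevation equals `shift`. The default
shift = 2.5 corresponds to a ≈ 6-fold mean induction on a log2 scale — strong
but realistic for tightly co-regulated pathway genes — and keeps the planted
networks just below saturation (at saturation the network is a clique, and a
clique admits no strictly-denser module).

Promoters are i.i.d. with configurable GC content; planted motif copies are
placed at non-overlapping uniform offsets (joint bookkeeping across
co-planted motifs), exact by default with an optional per-position mutation
rate, forward strand by default. Ortholog promoters re-plant each
conserved-flagged motif with probability `conservation_fraction`. The motif
database combines named planted motifs (tags cycling MYB / AC-I / AC-II /
lignin) with rejection-sampled decoys. All generators are deterministic
under `rng_seed`.

**What the benchmarks do not show.** The generator has no probe-level noise,
no batch structure, no correlated background genes, no repeat families or
compositional bias in promoters, and its planted motifs are exact words.
Passing the planted benchmarks demonstrates the pipeline's correctness and
its sensitivity at a realistic signal-to-noise point — not its performance
on real compendia, where condition redundancy, weak motifs and annotation
noise all bite harder.

## Problem sizes in the bundled checks

The test suite and `scripts/acceptance.py` run the full standard instance
for recovery and grid-search checks; the motif benchmark uses 20 × 2,000 bp
promoters; the specificity test uses three 12-gene modules, 450 background
genes, 200 bp promoters, width 12 and 15 random groups; conservation checks
use 10 × 1,000 bp promoter pairs with 20 planted motifs. These sizes are the
package's chosen benchmark conditions and complete in minutes on one CPU.

## Known limitations

- The bi-clustering is greedy beyond small inputs; exactness is verified
  exhaustively only at the 8×8 scale.
- The expansion step never revisits conditions; a bi-cluster whose seed
  phase retained a poor condition set cannot repair it.
- The Gibbs sampler fits one motif per call; multiple motifs require masking
  or repeated calls, which the pipeline does not automate.
- fuzznuc-style scanning is exact (0 mismatches); a mismatch budget for
  conservation scanning is not currently exposed.
- The chi-square specificity test treats database entries as exchangeable;
  it ignores similarity structure within the database beyond the
  pre-integration step.
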