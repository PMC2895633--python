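# Methods

This note documents the models and procedures implemented in `subnetusage`,
the parameters that matter, what the synthetic generators do and do not
emulate, and the numerical choices made where the design was genuinely open.

## Network construction

The TRN is built from a TSV table of regulator → target interactions.  Three
normalisation steps precede any analysis:

* **dimer merging** — genes whose products regulate only as a hetero-dimer
  (ihfA/ihfB-style pairs) are collapsed to one node via an explicit,
  user-overridable mapping (`DEFAULT_DIMER_MAP` ships a small best-effort
  list); a gene mapped to two different merged nodes is a configuration
  error;
* **phantom-gene removal** — an explicit list (default empty) of entries
  demoted from gene status; interactions touching them are dropped;
* **self-loop policy** — autoregulatory edges are recorded in
  `self_loops` but excluded from the analysis graph.  Reachability and the
  triad census are insensitive to self-loops, so link counts, subnets and
  motif statistics all refer to the loop-free graph.

Gene identifiers are matched case-insensitively (first-seen spelling is
kept), because real interaction exports mix cases.  Interaction signs
(activation/repression/dual) are parsed and stored on edges but ignored by
every downstream stage; for duplicated edges the first sign seen wins.

## Subnets and hierarchical levels

The subnet of a root (any node with out-degree ≥ 1) is the root plus all
nodes reachable by directed paths.  The level of a member is its *maximal*
distance from the root.  With cycles, "maximal distance" is formalized on
the condensation: strongly connected components inside the subnet are
contracted, the level of a component is the longest condensation-path length
from the root's component, and all genes of a component share that level.
This reduces to the natural rule for mutually regulating pairs (equal
levels) and stays finite for longer cycles.  Default minimum subnet size for
enumeration is 5 members — below that, enrichment statistics are
uninformative.  Two size conventions appear in the literature; `Subnet`
exposes both `size` (root included) and `downstream_count` (root excluded).

## Static usage: SAM on the Wilcoxon statistic

Per gene, the two conditions are compared by the standardized Wilcoxon
rank-sum statistic (midranks; null mean and tie-corrected variance; fully
tied data scores 0).  No variance fudge factor is applied — the rank
statistic is already standardized.

The SAM procedure then: (1) sorts the observed statistics; (2) forms
expected order statistics as the mean of sorted statistics over label
permutations — all distinct assignments when C(n, n₁) ≤ `n_perm` (default
1000), otherwise `n_perm` sampled ones; (3) for a threshold δ finds the
least extreme observed value whose deviation from its expected order
statistic reaches δ (separately for each direction) and calls everything
beyond those cuts — the classic first-crossing rule, which keeps the most
extreme genes called even where their expected order statistics are also
extreme; (4) estimates FDR(δ) as the median over permutations of the number
of permuted statistics beyond the cuts, divided by the number called;
(5) returns the smallest δ with FDR ≤ q (default q = 0.05).  Called sets
are nested in q by construction.

A comparison with no called genes is recorded as skipped and contributes no
usage column.  Subnet enrichment uses the one-sided hypergeometric tail
(`scipy.stats.hypergeom.sf`); the background is, by default, the
intersection of network genes with the genes measured in the comparison
(configurable to all network genes), so genes absent from the array cannot
inflate enrichment.  Correction across subnets within a comparison is
Benjamini–Hochberg (configurable to Bonferroni/Holm); the significance level
α defaults to 0.05.

Replicates: the synthetic two-condition experiments use 8 arrays per
condition.  A rank-sum test's granularity is 1/C(n₁+n₂, n₁); with 3 + 3
samples the smallest attainable one-sided p is 0.05, so no per-gene call can
survive FDR control at q = 0.05 regardless of effect size.  Eight per group
(C(16,8) = 12870 distinct labelings) is the smallest design where the
permutation FDR machinery has room to work while staying desk-scale.

## Time-course usage: SVD entropy and pseudo-subnet z

For a subnet with ≥ 3 measured genes, the T × G submatrix (time points ×
genes) is decomposed by SVD; with pₖ = sₖ²/Σⱼsⱼ², the entropy is
H = −(1/ln N) Σ pₖ ln pₖ, N = number of retained singular values
(min(T, G); one fewer under `drop_principal`).  H is invariant under
row/column permutation and global rescaling, 0 iff rank 1, 1 iff all
retained singular values are equal.  The meta-analysis variant for large
heterogeneous compendia drops the principal singular value first, removing
chip-wide global variation.

The null is built by drawing `n_pseudo` (default 1000) same-size gene sets
without replacement from all genes measured in the experiment (not only
network genes — the open choice is resolved toward the larger, less biased
pool) and z = (H − mean)/sd of the sampled entropies.  Collective means
z ≤ z*.  A degenerate null (sd = 0) excludes the subnet with a warning.

The cutoff z* is either set directly or **calibrated**: scanning all
observed z values (plus a −∞ sentinel), the cutoff minimizing
|never-collective fraction − target| is returned, ties broken toward the
lower (more conservative) cutoff.  The default target of 0.25 mirrors the
share of never-used subnets in static data.  The calibration is monotone:
raising the target never raises the cutoff; target 1 yields −∞ (nothing
collective).

Detection power of the entropy z grows with subnet size and falls with the
planted fraction of the sampling pool: if planted collective genes are a
large share of all measured genes, pseudo-subnets become collective too and
the null contaminates (raising the signal amplitude then *lowers* |z|).
Recovery experiments therefore run at genome scale (~1540 genes, planted
pool ≤ ~10%), where planted subnets of ≥ 14 genes score z ≤ −3 at
signal-to-noise 3.

## Clustering

Usage rows are clustered on pairwise Manhattan distances with the Ward
criterion and the tree cut by count into k = 3 groups (configurable).  Ward
formally presumes squared Euclidean distances; the default variant
("ward.D") applies the Lance–Williams Ward update directly to the Manhattan
matrix — realized as scipy's ward linkage on the square roots of the
distances, since scipy squares its input internally — and a flag switches to
Ward on squared distances ("ward.D2").  Labels are assigned by descending
mean usage: *strong*, *medium*, *null* (for k ≠ 3: strong, medium_1…, null);
mean-usage ties rank the larger cluster higher (logged).  Columns that are
entirely missing (skipped comparisons) are dropped before clustering, and
rows are sorted lexicographically first so the partition is deterministic.
Cluster compositions from two data sets are compared by the relative overlap
|A∩B|/min(|A|,|B|) on the shared root universe.

## Motifs

Triads (weakly connected induced 3-node subgraphs, self-loops ignored) are
encoded row-major as 9-bit integers (bit 2⁸ = entry [0][0] … bit 2⁰ =
[2][2]); the canonical id is the minimum over the six node relabelings,
which makes the feed-forward loop id 38.  The census enumerates connected
triples from neighbor pairs around each node (cost Σᵥ C(deg v, 2), not
C(n,3)), emitting each triple from its unique center node — or, for
triangles, from the smallest of its three centers — so no deduplication set
is needed; a 64-entry lookup table maps off-diagonal bit patterns to
canonical ids.

Randomization is by pairwise edge swaps ((a→b, c→d) → (a→d, c→b)) that
preserve every in- and out-degree exactly and never create self-loops or
duplicates; `n_swap_multiplier` (default 100) attempts per edge.  z-scores
compare the real census with `n_random` (default 1000) randomizations; ids
with zero null spread are flagged (z = 0 when the real count equals the
constant null, undefined otherwise), and the triad significance profile is
the z-vector over defined ids scaled to unit norm.

Cluster-level motif analysis induces **one** subgraph per cluster — the
union of its subnets' members with all internal edges — so overlapping
subnets never double-count a motif.  Two null models check that a cluster's
FFL z is not a size artifact: model A scores induced subgraphs on uniformly
sampled node sets of the cluster's node count; model B draws as many random
subnets as the cluster has, subsamples each (root retained) to the cluster's
subnet-size profile — largest sampled subnet paired with largest profile
entry so targets are attainable — and scores the union-induced subgraph.

One structural fact matters when planting FFLs synthetically: with a heavy
out-degree tail, the degree sequence alone implies many chance feed-forward
closures (a hub regulating half the genome closes most 2-paths by chance),
so a modest number of planted triangles can sit *below* the
degree-preserving null.  Motif-significance experiments therefore use a
tamer tail (Zipf exponent 3.0) and 40–50 planted FFLs, where the planted
excess dominates chance closure.

## sRNA target enrichment

Targets are resolved case-insensitively and through the dimer map;
duplicates collapse and unresolved names are reported.  Subnet-level
enrichment is the same one-sided Fisher machinery with the full node set as
background and BH correction across subnets.  Motif-level enrichment counts,
per canonical id, the triad instances containing at least one target and
compares with `n_samples` uniformly redrawn target sets of equal size; the
empirical p is (1 + #{null ≥ observed})/(n_samples + 1), never exactly 0.
Per-cluster fractions (enriched subnets / cluster size) recombine, weighted
by cluster size, to the global fraction.

## Synthetic data

The generators emulate the salient statistics of a bacterial TRN and of
two-condition and time-course microarray data; they are test harnesses, not
models of transcription.  Not emulated: probe effects, normalization
artifacts, correlated noise, operon structure.

* **Network** (`generate_trn`): `n_regulators` TFs (default 40) wired over
  ≤ `hierarchy_depth` layers (default 4; layer sizes grow geometrically,
  non-top TFs get 1–2 parents from shallower layers), `n_targets`
  non-regulator genes (default 400) attached to TFs with probability
  proportional to Zipf(`out_degree_exponent`, default 2.0) weights —
  echoing master regulators — with 1 + Poisson(0.6) parents each.
  `two_cycle_count` mutual TF pairs (default 2) are added first; then
  exactly `ffl_count` (default 20) extra edges, each closing a 2-path whose
  end pair is edge-free in both directions, so every planted triple is
  exactly a feed-forward loop.  Infeasible requests raise.  All generators
  are pure functions of (spec, seed).
* **Static experiment**: gene values i.i.d. Normal(0, σ) (σ = 1); genes of
  used subnets shifted by `effect_size` (default 5σ) with probability
  `penetrance` (default 1) in condition 2; 8 replicates per condition.
* **Time course**: collective genes follow gene-specific scale (uniform
  0.5–1.5, sign flipped with probability 0.3) × a shared rise–decay impulse
  of amplitude `collective_amplitude` (default 3σ) over `n_timepoints`
  (default 8); all other genes pure noise.
* **sRNA targets**: each gene is a target with probability `base_rate`
  (default 0.02, the real TRN's ~1.5% scale), multiplied by `enrich_factor`
  (default 10, capped at 1) inside designated subnets.
* **Usage matrices** (`generate_usage_matrix`): three groups at usage rates
  0.25 / 0.05 / 0.0 over 80 conditions.  The strong and medium groups
  respond as blocks (a condition is group-active with probability
  rate/response; active conditions elicit a response from each group member
  with probability 0.9 / 0.85) — real usage matrices show exactly such
  blocks of coordinately used subnets, and i.i.d. usage at a few percent
  would be statistically indistinguishable from never-used rows.

**Recovery-test topology.**  In a hierarchical network every ancestor (and
nested descendant) of a planted subnet genuinely shares the planted signal —
its genes *are* enriched or collective — so "only the designated subnets
respond" is ill-posed there.  Planted-recovery experiments therefore use the
flat configuration (`hierarchy_depth=1`: disjoint-ish, regulon-like
single-input subnets); the hierarchical default is used for topology, motif
and pipeline tests.  sRNA and collectivity recovery additionally use
`n_targets=1500` (the real TRN's ~1515-node scale): enrichment power at
fixed rates grows with background size, and at 440 genes the planted target
pool inflates the background rate enough to mask itself.

## Problem sizes used in tests and the acceptance script

Permutations/randomizations are reduced to keep everything desk-scale:
SAM `n_perm` 50–100, pseudo-subnets 100–200, motif `n_random` 20–100 with
10 swap attempts per edge, 100 null-model samples, 20 seeded sRNA runs.
The full test suite runs in ~4 minutes and `scripts/acceptance.py` in about
one minute on a single CPU.

## Known limitations

* The SAM flavor is the two-class unpaired variant; paired designs and
  multi-class contrasts are out of scope.
* Time courses are treated as unordered sample collections by the SVD —
  no autocorrelation, smoothing or time-warp modeling.
* Ward-on-Manhattan ("ward.D") is a pragmatic classic, not a metrically
  consistent criterion; ward.D2 is available behind a flag.
* The triad census assumes the weakly-connected-triads convention; 4-node
  motifs and coherent/incoherent FFL subtypes are not implemented.
* Dimer and phantom lists ship as small defaults and must be curated for
  real data.
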