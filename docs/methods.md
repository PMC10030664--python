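# Methods

## Sample-specific weighted networks

A sample's network is the PPI scaffold restricted to genes with strictly
positive expression in that sample (genes absent from the expression matrix
count as zero-expression and are removed, with the count logged). Edge
weights are absolute expression differences, w_ij = |x_i − x_j| — the only
scalar distance between two expression values; whatever normalized scale
the matrix carries (the pipeline assumes a variance-stabilized scale) is
used as given. Weights are discretized into ⌊√N⌋ equal-width bins spanning
[min w, max w], with the right-most bin closed; if all weights coincide the
single occupied bin is the first. Equal-width binning is used rather than
quantile binning because the bin histogram *is* the observable — quantile
bins would flatten it by construction.

## Ensemble (network) entropy

The entropy of a sample network is the Shannon entropy of the canonical
(soft-constraint) maximum-entropy ensemble over all node pairs, where each
pair (i, j) is either unlinked or linked in exactly one weight bin q:

    p_ij(q) = x_i x_j y_q / (1 + x_i x_j Y),   Y = Σ_r y_r,
    p0_ij   = 1 / (1 + x_i x_j Y),

with multipliers fitted so that expected degrees equal k_i and expected bin
counts equal m_q. Because the bin factor y_q is shared by every pair, the
conditional bin distribution is global and the model factorizes exactly:

* the bin part is closed-form, y_q / Y = m_q / M;
* the link part is the binary configuration model fitted to k;
* S = S_links + M · H(m/M), where H is the Shannon entropy of the
  normalized bin histogram and S_links = −Σ_{i<j} [P ln P + (1−P) ln(1−P)].

Natural logarithms are used throughout (nats); any other base rescales all
entropies uniformly.

**Solver.** Nodes are collapsed into degree classes (equal degree ⇒ equal
multiplier, by uniqueness of the strictly concave problem). Nodes whose
degree equals the number of other active nodes force all their pair
probabilities to 1 and are peeled off analytically before fitting (a
complete graph reduces entirely to forced pairs, so its link entropy is 0
exactly); degree-0 remainders are likewise pinned to 0. The remaining
classes are solved by 20 damped multiplicative sweeps followed by Newton
iteration on θ = ln x. The solver iterates to a relative degree residual of
1e−12 internally while only *requiring* the configured tolerance (default
1e−8): near the graphical boundary the multipliers are large and the
entropy inherits an error of order residual × |θ|, so stopping at 1e−8
would leave ~1e−6 biases. Non-convergence within `max_iter` (default 10⁴)
raises, carrying the residual. Validated against an independent direct
maximizer (LP facial reduction + log-barrier path + interior polish over
per-pair probabilities) to ≤ 2×10⁻¹⁰ on random ≤ 6-node graphs, including
fully link-forced instances.

## Local entropy and the differential test

Local entropy is computed from raw (unbinned) incident weights:
p_ij = w_ij / Σ_j' w_ij', S_i = −Σ_j p_ij ln p_ij; zero-weight edges
contribute nothing and isolated or all-zero-weight nodes get S_i = 0. A
binned variant (weights replaced by bin midpoints) is available behind a
flag; the raw form is the default because the √N binning is a
global-distribution device, not a per-node one. Local entropies are not
degree-normalized, so the |Δ| > 0.03 shift filter applies on the nats
scale.

The young-vs-old test is a two-sided Wilcoxon rank-sum per node — exact
null when the combined sample size is ≤ 20 and tie-free, otherwise the
normal approximation with mid-ranked ties and continuity correction —
followed by Benjamini–Hochberg correction over all tested nodes. A node is
significant iff q < 0.05 (configurable) *and* |median_old − median_young| >
0.03 nats. The location statistic is the median by default; the mean is
exposed as `diff_statistic: mean` since both conventions circulate for this
filter. Nodes absent from every sample on one side are dropped (logged).

## Hub measures

* **MCC** sums (|C|−1)! over the maximal cliques containing a node,
  enumerated with Bron–Kerbosch (pivoting); an isolated node's maximal
  clique is itself (MCC = 0! = 1). An enumeration cap (default 10⁶ cliques)
  aborts pathological inputs.
* **Bottleneck** builds one shortest-path tree per source. The published
  definition leaves the tree non-unique; this implementation fixes a
  deterministic rule — BFS with the lexicographically smallest
  equal-distance parent — and records it as a divergence point from any
  particular legacy build. A node is a bottleneck in T_s when its
  descendant count (the number of tree paths s→t, t ≠ v, crossing it)
  strictly exceeds |V(T_s)|/4; the source contributes nothing to its own
  tree.
* **Betweenness** is the unnormalized Brandes sum over unordered pairs
  within the node's component, endpoints excluded.

Rank orders are dense (ties share a rank) with lexicographic tie-breaks, so
ranked outputs are byte-reproducible. Top-k tables expand ties at the k-th
score and report the cross-metric intersection.

## MCODE

Stage 1 weights each vertex by k × density of the highest k-core of its
closed neighbourhood; stage 2 grows node-disjoint complexes from the
highest-weighted unassigned seed, admitting neighbours whose weight is
≥ (1 − 0.2) × seed weight up to depth 100; stage 3 discards complexes
without a 2-core and (haircut) trims singly-connected members. Density is
2E/(V(V−1)) without self-loops, so cluster score = density × size makes a
K₅ score exactly 5, which is what makes the "score ≥ 5" filter a meaningful
boundary. Defaults are the published MCODE defaults (degree cutoff 2, node
score cutoff 0.2, k-core 2, haircut on, fluff off); all are exposed.

One behavioural note: when two cliques are joined by a *direct* bridge
edge, both bridge endpoints score as highly as clique interiors, so the
expansion legitimately crosses the bridge and merges the cliques into one
complex — that is the algorithm, not a bug. Separately identifiable planted
modules must therefore be joined through low-weight linker nodes, which is
how the synthetic module fixtures are built.

## Network proximity

d_AB is the mean over both sets of each gene's hop distance to the nearest
gene of the other set (unweighted shortest paths; the interactome carries
no distances). Genes with no finite distance to the other set are excluded
from numerator and denominator, with counts reported — preferable to
imputing a large constant because d_AB stays a mean of realized distances
and the exclusions remain auditable.

The null resamples both sets with degree matching: scaffold nodes are
binned by ⌊log₂ degree⌋, consecutive bins merged upward until each holds
≥ 100 nodes (one bin for smaller graphs), and each template gene is
replaced by a without-replacement draw from its bin, preserving the
degree-bin histogram exactly. Z uses the null mean and (population) SD over
1,000 resamples; an empirical p, (#{null ≤ observed}+1)/(n+1), accompanies
Z because the Z-score assumes a near-normal null. Significance is
Z < −1.5 with BH FDR < 0.05, the FDR taken across the condition pairs
tested in one invocation (the empirical p feeds BH; both p and q are
reported). σ_m = 0 yields Z = NaN, reported as such and never significant.

Proximity genes are collected from *all* A×B pairs (not only minimizing
pairs), taking every node v with d(a,v) + d(v,b) = d(a,b) for some pair —
all shortest paths, endpoints included. Roles follow set membership:
common (A∩B), endpoint-A, endpoint-B, intermediate.

Distances come from an all-pairs BFS matrix (float32) cached per scaffold;
at 10⁴ nodes this costs ~400 MB, fine for the scales this package targets.

## Synthetic data: what it emulates, and what it does not

`make_scaffold` draws a Barabási–Albert graph (default m = 3; edge count
m(n−m) in closed form), reproducing the heavy-tailed degree structure of a
curated PPI network. Optional planted K₆ cliques model detectable
complexes; any direct edge between two planted cliques is removed so each
is separately identifiable (see the MCODE note above). Optional degree-1
*satellite* nodes, each pendant on a distinct low-degree host, serve as
dedicated interaction partners for entropy planting.

`make_cohort` models ageing as rising within-group expression noise — the
minimal mechanism that flattens the edge-weight distribution and hence
raises ensemble entropy, without asserting any particular biology.
Baselines are bimodal (modes 2.0 and 5.5, jitter 0.2), mimicking the
characteristic low/expressed bimodality of variance-stabilized bulk
RNA-seq. This choice is load-bearing: binned-weight entropy is invariant
under rescaling, so only the noise-to-baseline-structure ratio matters, and
with the default noise schedule (SD 0.1 → 0.5 across five groups of four
replicates) a heavy-tailed unimodal baseline produces no detectable trend,
while the bimodal baseline yields strictly increasing group medians in
10/10 seeds. Defaults: groups (3, 9, 15, 21, 27) months, 4 replicates each
(matching the 3–4 replicates typical of ageing cohort designs), the last
two groups "old".

Planted **differential-entropy genes** work through their satellite
partner: in young groups the partner tracks its host's baseline (the
partner edge carries only noise-level weight); in old groups the partner is
strongly induced (+48 on the expression scale), so the partner edge
dominates the host's incident weight distribution and concentrates it — a
large, consistent local-entropy drop at the host. The construction is
neighbour-clean: the partner itself has a single edge (local entropy
identically 0, unchanged), and no other gene's weights move. A naive
alternative — displacing the planted gene's own expression — perturbs one
incident weight of *every* neighbour and, measured on these scaffolds,
produces roughly as many neighbour false positives as true positives,
making planted recovery unidentifiable at any useful FDR. Recovery is
benchmarked on a stationary-noise cohort (SD 0.2 in all groups): under the
rising-noise ageing cohort the global drift is itself signal, and hundreds
of unplanted genes *correctly* shift in entropy, so "false positive" is
only well-defined against a stationary background.

Planted **DEGs** gain `effect` × (terminal noise SD) in the last group
only. At the nominal effect 3 the 4-vs-4 Welch test recovers a minority of
planted genes after BH correction (simulated 2–21 of 50 across seeds —
Welch df ≈ 3–6 has little power at BH-corrected thresholds); near-complete
recovery (≥ 45/50) requires effect 6. Tests pin both simulated operating
points. The DE stand-in is deliberately simple (per-gene Welch t + BH) and
is not a substitute for a dispersion-modelling DE pipeline on real counts;
real-data users supply their own DEG lists.

`make_condition_sets` draws a proximal set from the reference's closed
one-hop neighbourhood (each proximal gene ≤ 1 hop from the reference by
construction) and a distal set from nodes ≥ 4 hops from every reference
gene, falling back to the maximum-distance stratum when that is empty
(logged) — preferential-attachment graphs have small diameter, so the
distal stratum thins quickly below ~300 nodes.

What passing on synthetic data does **not** show: behaviour under library-
size or dispersion artefacts (the generator emits normalized values by
contract), identifier-mapping noise (gene symbols are taken verbatim,
case-sensitive), correlated expression modules, or scaffolds whose degree
structure departs strongly from preferential attachment.

## Numerical and policy choices

* Confidence cutoff 0.9 for scaffold edges; edges without a score pass any
  cutoff so unscored synthetic graphs flow through the same reader.
* All tabular outputs are TSV with headers; networks are 2-column TSV edge
  lists; gene sets one symbol per line.
* Every stochastic step takes a seed; fixed seed + fixed inputs give
  byte-identical outputs end to end.
* Condition networks use one-hop expansion then the *full induced*
  subgraph (neighbour–neighbour edges kept), the reading that maximizes
  module detectability.
* Proximity FDR scope, the differential-entropy location statistic, and
  the deterministic Bottleneck tree rule are all declared conventions where
  the literature leaves the choice open; each is exposed in configuration
  or documented above rather than silently fixed.
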