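# Methods

## The model

A tumor sample is modeled as a mixture of a mutation-free normal cell
population plus `n` tumor subclones, each subclone defined by the
cumulative set of somatic mutation clusters it carries.  Evolution is
assumed to proceed by mitotic descent under two constraints: the same
mutation event never arises independently in two unrelated subclones,
and a mutation is never lost once acquired.  Under these assumptions a
subclone history is a rooted tree whose root is the normal ("null")
subclone and whose non-root nodes each introduce exactly one mutation
cluster; a node's cumulative mutation profile is the union of clusters
on its root path.

Every cluster has a *cell prevalence* (CP): the fraction of cells in
the sample carrying it.  Writing `SF(v)` for the *subclone frequency*
(the mass fraction of the sample occupied by subclone `v` itself), the
CP of a cluster equals the SF of its node plus all descendants.
Inverting this telescoping relation bottom-up gives

    SF(v) = CP(v) - sum of CP over v's children,   CP(root) := 1,

so the root SF is the normal-tissue contamination.  A topology is
*viable* when every SF is non-negative; viability depends only on the
CP vector, not on measurement noise models or priors.

Because a cluster cannot sit below a lower-CP cluster, the cluster of
rank `k` (by descending CP) has exactly `k` admissible parents (the
root or any cluster of rank `< k`), giving exactly `n!` candidate
topologies.  All are evaluated; the enumeration is exhaustive, not
sampled.  The linear accumulation chain — each cluster under the
previous one — is always viable, so the solution set is never empty.

## Cell-prevalence conversions

* CNV: `RCN = 2 * 2**log2_ratio`; with tumor purity `q`, the mixture is
  inverted as `(RCN - 2(1 - q)) / q` before ACN calling.  Deletions:
  RCN in (1, 2) is a heterozygous deletion (ACN 1) unless high LOH
  promotes it to homozygous (ACN 0); RCN <= 1 is ACN 0.  Amplified
  segments take the smallest integer ACN >= 3 with a feasible CP — the
  most parsimonious gain, chosen because under a uniform prior on the
  subclone fraction every feasible ACN explains the signal equally
  well, and parsimony keeps the call deterministic.  Then
  `CP = (RCN - 2) / (ACN - 2)`.
* LOH: BAF is mirrored onto [0.5, 1]; with segmental mean `u` and
  segment ACN `n`, `CP = (2u - 1) / (n(1 - u) + (2u - 1))`.
* SNV: diploid context only — `CP = 2 AF` (heterozygous, AF above 0.5
  is excluded as abnormal) or `CP = AF` (homozygous).  SNVs inside CNV
  regions need allele-specific CP estimation upstream; such CP values
  enter through the cluster-table input.

Out-of-range CPs within 1e-6 are clamped; beyond that the conversion
fails loudly rather than silently biasing downstream structures.

## Clustering

CP measurements of events created together scatter around a shared
modal value.  One sample: Gaussian KDE on a 512-point grid over
[-0.05, 1.05]; modal centers are strict local density maxima (plateau
maxima take their leftmost point), basins are delimited by the
intervening minima, and a cluster's CP is the mean of its members.
The bandwidth is the Sheather–Jones two-stage direct plug-in
("pilot estimation of derivatives"), implemented here because no
installed Python library provides it and validated against R's
`bw.SJ(method = "dpi")`; Silverman's rule is the fallback below three
points or at zero spread.  Multiple samples are clustered jointly by
mean-shift with a per-dimension product Gaussian kernel (per-dimension
SJ bandwidths), so that a cluster present in only one sample keeps its
own identity; an event missing from a sample has CP 0 there.

Projection to one sample drops clusters at CP <= `zero_threshold`
(default 0.05 — below that, presence is indistinguishable from noise)
and merges clusters closer than `tie_epsilon` (default 1e-3), because
enumeration requires strictly distinct CPs.  `sf_tolerance` (default
1e-9) is the slack on SF non-negativity: cluster means have already
absorbed the noise, so viability is tested near-exactly; the CLI
exposes the flag for noisier inputs.

## Cross-sample trimming

A relapse continues the primary's evolution, so a viable relapse tree
must graft onto a viable primary tree while preserving the two merge
conditions (children superset their parent's mutations; no mutation
arises on two unrelated branches).  Compatibility is tested on
profiles: for every relapse node, the shared-cluster part of its
cumulative profile must equal the full profile of some primary node
(its anchor).  Equality rather than subset is required: a relapse
profile containing a cluster without the clusters that always precede
it in the primary would imply independent recurrence or loss.  Grafted
trees are re-validated against both conditions; a rare ordering anomaly
(a shared cluster acquired after a relapse-only cluster) passes the
profile test but fails validation, and such pairs are treated as
incompatible during trimming.  Trees with no compatible partner in the
other sample are discarded; trimming is idempotent.  Merged trees are
structural only — SFs remain attached to the per-sample trees, since
each sample has its own subclone mass distribution.

## Co-localization and ordering

Over a solution set, `CLF(a, b) = sum_i PS_i * CL_i(a, b)` with
`CL_i = 1` when some node profile in solution `i` contains both
clusters and priors `PS_i` uniform by default (an optional prior
proportional to `exp(-lambda * #root children)` down-weights
biologically implausible multi-origin structures; off by default).
Calls at threshold `t`: co-localized when `CLF >= t`, not co-localized
when `CLF <= 1 - t`, ambiguous between — the symmetric band is the
natural three-status reading of a single threshold and collapses to
nothing at `t = 0.5` except exact ties.  Within a co-localized pair the
higher-CP cluster arose earlier.  The consensus structure keeps lineage
relations (x precedes y) supported by at least the chosen fraction of
solutions (closed comparison).

## Synthetic tumors

`simulate_structure` draws a uniform random increasing tree (cluster k
attaches to the root or any existing node with equal probability),
flat-Dirichlet SFs over the n+1 nodes, and rejects draws until all
pairwise CP gaps reach `min_cp_gap` (default 0.02, the resolution at
which clustering can be expected to separate modals); the truth's CP
vector is exact, so the generator exercises enumeration and
co-localization, not the noise-mitigation role of clustering.  Seeds:
one master seed; replicate r uses `SeedSequence([master, r])`.

What the generator does and does not emulate.  It produces polyclonal
tumors: several subclones may descend directly from normal tissue, and
flat-Dirichlet SFs make CP values crowd the low end.  Real tumors are
typically clonal (a truncal founder carried by every tumor cell), which
spreads CPs and shrinks the viable set sharply; with the default
generator the median viable count at six clusters is ~159 of 720,
whereas a truncal variant yields ~62.  Benchmark metrics depend
strongly on this choice: at six clusters and 1,000 replicates the
default generator gives a pooled co-localization sensitivity of ~43%
at threshold 0.7 and a pooled PPV of ~77% at threshold 0.5 (a truncal
variant gives ~59% and ~83%).  Passing benchmarks here therefore
demonstrates internal consistency of enumeration + CLF calling under a
deliberately uninformative tumor model, not call accuracy on any
particular real cohort.

Benchmark metric definitions: every pair has a true status
(co-localized iff one cluster is on the other's root path in the truth
tree).  Pooled *combined sensitivity* = correct non-ambiguous calls /
all pairs; pooled *combined PPV* = correct calls / all non-ambiguous
calls.  Ambiguous calls therefore cost sensitivity but not precision,
and sensitivity can never exceed PPV.

Problem sizes: the shipped experiments use 1,000 replicates (3–8
clusters for recovery, 6 for the call benchmark), matching the study
design the package targets; a full run of both experiments takes well
under a minute per thousand replicates on one core.

## Numerical and design notes

* Enumeration visits parent-choice vectors with per-position choices in
  descending order, so the always-viable chain is emitted first and
  orderings are reproducible; candidate SF evaluation is vectorized
  over the whole n! batch (chunked above n = 8).  `max_n` defaults to
  10 (10! = 3.6M candidates); raise it explicitly for larger inputs.
* `implied_cp` must reproduce the input CP vector to 1e-9 on every
  viable tree; `sum(SF) = 1` holds by telescoping and is asserted to
  1e-9 in tests.
* Empty cluster sets are valid and yield the single normal-only
  structure (root SF 1).
* Degenerate clustering inputs (singletons, zero spread) yield a single
  cluster rather than an error.
* More than two samples can be trimmed by iterating the pairwise trim
  against a designated reference sample; only pairs are exercised by
  the shipped experiments.

## Known limitations

* SNVs in copy-number-altered regions are not converted internally;
  supply externally estimated CPs through the cluster table.
* The n! enumeration is exact but factorial; above ~10 clusters,
  re-cluster more coarsely.
* Compatibility trimming assumes the relapse truly descends from the
  sampled primary clone; a relapse seeded by an unsampled lineage can
  empty the solution set (reported as a warning plus empty result, exit
  status 2 in the CLI).
* The co-localization benchmark's absolute numbers are properties of
  the synthetic tumor model as much as of the caller; see above.
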