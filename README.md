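# subclonetk

Tools for reconstructing the subclonal architecture of a tumor from
bulk sequencing or microarray measurements.  Bulk allele frequencies
destroy the linkage between somatic mutations — they say how *many*
cells carry each mutation, not *which* cells — so a single sample
usually admits many subclone evolutionary histories.  `subclonetk`
takes the exhaustive route: it converts somatic events to cell
prevalences, clusters them, enumerates **every** subclone tree
consistent with the data, trims the solution space using a second
sample (e.g. a relapse), and converts whatever ambiguity remains into
calibrated statements about which mutations co-occur in the same cells
and which came first.  It is aimed at cancer genomicists analyzing
matched tumor/normal (optionally plus relapse/metastasis) experiments.

## The model in brief

Each mutation cluster `i` has a cell prevalence `cp_i` (fraction of
cells carrying it).  A candidate history is a rooted tree: the root is
the mutation-free normal population, every other node adds one cluster.
Subclone frequencies follow from the CPs by the telescoping rule

    SF(v) = CP(v) − Σ_{c ∈ children(v)} CP(c),    CP(root) := 1,

and a tree is *viable* iff every SF ≥ 0 (equivalently, the structure
solves `[f¹ … fⁿ] × [B¹; …; Bⁿ] = CP` with non-negative subclone
fractions `fʲ` and cumulative mutation profiles `Bʲ`).  Ranking
clusters by descending CP, cluster `k` can attach only to the root or a
cluster of rank `< k`, giving exactly `n!` candidates — all evaluated,
none sampled.  The linear accumulation chain is always viable.  Over
the viable set, the co-localization frequency of a pair is

    CLF(a,b) = Σ_i PS_i · CL_i(a,b),   PS_i = 1/#solutions by default,

thresholded into co-localized / not co-localized / ambiguous calls;
within a co-localized pair, the higher-CP mutation arose earlier.

Cell prevalences are obtained from CNV log2 ratios
(`CP = (RCN−2)/(ACN−2)`), LOH mirrored-BAF segment means
(`CP = (2u−1)/(n(1−u)+(2u−1))`) or diploid SNV allele frequencies
(`CP = 2·AF` heterozygous, `AF` homozygous) — or supplied directly as a
cluster table if CP estimation was done elsewhere.

## Worked example

A primary sample has two mutation clusters at CP 0.6 and 0.3; in the
relapse the same clusters are at 0.9 and 0.85.

```sh
$ cat clusters.tsv
cluster_id  sample   cp
c1          primary  0.6
c2          primary  0.3
c1          relapse  0.9
c2          relapse  0.85

$ subclonetk run --clusters clusters.tsv \
    --primary-sample primary --relapse-sample relapse --outdir out
INFO subclonetk: stage cluster: 2 clusters read (bypass input)
INFO subclonetk: stage enum [primary]: 2 visited, 2 viable
INFO subclonetk: stage enum [relapse]: 2 visited, 1 viable
INFO subclonetk: stage merge: 1 compatible pairs (primary 2->1, relapse 1->1)
INFO subclonetk: stage coloc [primary]: {'ambiguous': 1}
INFO subclonetk: stage coloc [relapse]: {'co-localized': 1}
```

The primary alone is ambiguous — c2 could have arisen inside the c1
subclone (chain) or independently (branch), and both trees reproduce
the CPs exactly:

```sh
$ cat out/solutions_primary.nwk
((c2:0.3)c1:0.3)normal:0.4;
(c1:0.6,c2:0.3)normal:0.1;

$ cat out/coloc_primary.tsv
cluster_a  cluster_b  clf  status     earlier_cluster
c1         c2         0.5  ambiguous
```

(Newick branch lengths are subclone frequencies: in the chain solution
40% of the sample is normal tissue, 30% carries c1 only, 30% carries
c1+c2.)  In the relapse, `0.9 + 0.85 > 1` forces the chain — the two
clusters *must* share a lineage there — and since a relapse can only
extend the primary's evolution, trimming discards the primary branch
solution (`primary 2->1`): the pair resolves to a unique history in
which c1 precedes c2 in both samples.

The same stages are available per step (`cp`, `cluster`, `enum`,
`merge`, `coloc`, `simulate`, `benchmark`) and as a Python API:

```python
from subclonetk import ClusterSet, enumerate_structures, clf_matrix

sols = enumerate_structures(ClusterSet("primary", ("c1", "c2"), (0.6, 0.3)))
print(sols.viable, clf_matrix(sols).value("c1", "c2"))  # 2 0.5
```

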