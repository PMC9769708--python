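# cress-evolve

Analysis toolkit for the genetic diversity of CRESS-DNA viruses (circular
Rep-encoding single-stranded DNA viruses): similarity-network clustering of
replication-initiation (Rep) and capsid (Cap) proteins, Rep
domain-organization classification, recombination screening by Rep↔Cap
cluster cross-tabulation, and a full codon-usage selection-vs-mutation
suite for the corresponding genes. It is aimed at virologists and
molecular-evolution researchers working with diverse, largely
metagenome-derived ssDNA virus sequence sets.

## What it computes

**Similarity-network clustering.** All-vs-all Smith–Waterman local
alignment (BLOSUM45, affine gaps, open 15 / extend 2) is converted to
Karlin–Altschul statistics, E = K·m·n·e^(−λS) and P = 1 − e^(−E). Pairs
with P ≤ 10⁻² become edges of an undirected network; a force-directed
layout embeds it in 2D/3D, and clusters are read off as connected
components (or by an iterative attraction-offset method), with clusters
below 10 members routed to an unclustered pool.

**Rep domain organization.** The canonical Rep protein couples an
N-terminal HUH endonuclease (Viral_Rep) with a C-terminal superfamily-3
helicase (P-loop NTPase). Configurable motif signatures — the three
rolling-circle endonuclease motifs and Walker A/B — yield
complete/incomplete/absent calls per domain, an organization category
(both / Viral_Rep-only / P-loop-only / one-incomplete / none), and the
candidate virus groups for that category (e.g. Viral_Rep-only → CRESSV4/5,
P-loop-only → pCRESS-related, none → Smacoviridae and relatives).

**Trees, concordance and recombination.** Neighbor-joining trees from
local-alignment identity distances; a concordance check asking whether each
similarity cluster is separable by a single tree edge; and a Cap-cluster ×
Rep-group cross-tabulation that flags Cap clusters whose genomes carry Rep
proteins from more than one group — the recombination signature.

**Codon-usage suite.** Per-gene base composition with positional GC (GC1,
GC2, GC3, GC12, GC3s), RSCU (RSCU = 1 means no bias), Wright's effective
number of codons ENc ∈ [20, 61], the ENc–GC3s plot against the
mutation-only expectation ENc = 2 + s + 29/(s² + (1−s)²), the neutrality
regression of GC12 on GC3 — slope ≈ mutational share, 1 − slope ≈
selection share — and PR2 bias coordinates [G3/(G3+C3), A3/(A3+T3)].

**Synthetic data.** Seeded generators produce protein families with
controlled within-family identity, coding sequences whose GC12/GC3
covariation follows a tunable mutation–selection mixture (expected
neutrality slope 1 − w for selection weight w), and motif-planted proteins
with exact ground truth — so every stage is testable end to end.

## Worked example

```sh
python analysis/01_simulate_datasets.py --seed 1 --outdir results/data
python analysis/02_cluster_similarity_network.py --seed 1 --datadir results/data --outdir results
python analysis/05_codon_usage_selection.py --datadir results/data --outdir results
```

prints, among other lines:

```
  rep: 109 seqs, 986 edges, 5 clusters (min size 10), 9 unclustered; ARI vs planted truth = 1.000
  rep_like: n=200 genes | GC 51.4 +/- 8.09 | ENc 56.33 +/- 4.01 | RSCU>1: 31, RSCU<1: 28
    neutrality: slope 0.2855 (GC12 = 0.2855*GC3 + 37.23, r = 0.886, p = 7.31e-68) -> mutation 28.5%, selection 71.5%
```

The five planted 20-member families are recovered exactly (adjusted Rand
index 1.0) and the 9-member family falls below the minimum cluster size.
For the Rep-like coding set generated with selection weight 0.7, the
neutrality slope 0.2855 says ~29% of the GC12/GC3 covariation is
mutational and ~71% selective — the regime reported for real CRESS-DNA
virus Rep genes. `analysis/03_scan_rep_domains.py` and
`analysis/04_tree_concordance_crosstab.py` cover the domain and
recombination stages; `cress-evolve --help` exposes the same stages as a
CLI, including a one-shot `cress-evolve run`.

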