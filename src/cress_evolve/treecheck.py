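"""Distance-based trees, cluster-vs-tree concordance, and the Rep↔Cap crosstab.

The question answered here is topological: do similarity-network
clusters form clades of a tree built from the same sequences, and do members
of one capsid (Cap) cluster carry replication-protein (Rep) genes from
different groups (the signature of recombination)? Neighbor joining on local
alignment-identity distances is used as the tree builder; every check made
downstream is clade-membership only, so branch-length-sensitive inference is
deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO

import numpy as np
import pandas as pd
from skbio import DistanceMatrix as _SkbioDM
from skbio import TreeNode
from skbio.tree import nj as _skbio_nj

from .seqio import SequenceRecord
from .simnet import ScoringParams, make_aligner


@dataclass
class Tree:
    """An unrooted tree with non-negative branch lengths."""

    root: TreeNode

    @property
    def newick(self) -> str:
        buf = StringIO()
        self.root.write(buf)
        return buf.getvalue().strip()

    def leaf_names(self) -> set[str]:
        return {t.name for t in self.root.tips()}

    def path_distances(self) -> pd.DataFrame:
        """Leaf-to-leaf path-length matrix (for additivity checks)."""
        dm = self.root.tip_tip_distances()
        return pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids))


def distance_matrix(ids: list[str], matrix: np.ndarray) -> _SkbioDM:
    """Validated symmetric distance matrix (zero diagonal, finite entries)."""
    arr = np.asarray(matrix, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("distance matrix entries must be finite")
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(arr, arr.T):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(arr), 0):
        raise ValueError("distance matrix diagonal must be zero")
    if (arr < 0).any():
        raise ValueError("distances must be non-negative")
    return _SkbioDM(arr, ids)


def _alignment_identity(aligner, a: str, b: str) -> float | None:
    """Fraction of identical residue pairs over local-alignment columns."""
    if aligner.score(a, b) <= 0:
        return None
    aln = aligner.align(a, b)[0]
    columns = aln.shape[1]
    if columns == 0:
        return None
    ident = 0
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        ident += sum(x == y for x, y in zip(a[a0:a1], b[b0:b1]))
    return ident / columns


def distance_matrix_from_hits(
    records: list[SequenceRecord], params: ScoringParams | None = None
) -> _SkbioDM:
    """Pairwise distances d = 1 − local-alignment identity; no-hit pairs get 1."""
    if len(records) < 3:
        raise ValueError("need at least 3 records for a distance matrix")
    if params is None:
        params = ScoringParams.default()
    aligner = make_aligner(params)
    n = len(records)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ident = _alignment_identity(
                aligner, records[i].residues, records[j].residues
            )
            d[i, j] = d[j, i] = 1.0 if ident is None else 1.0 - ident
    return distance_matrix([r.id for r in records], d)


def nj_tree(dm: _SkbioDM) -> Tree:
    """Neighbor joining (Q-criterion); negative branch lengths clamped to 0."""
    if dm.shape[0] < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    tree = _skbio_nj(dm)
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return Tree(root=tree)


def _clade_tip_sets(tree: Tree) -> list[frozenset[str]]:
    sets = []
    for node in tree.root.non_tips(include_self=True):
        sets.append(frozenset(t.name for t in node.tips()))
    return sets


def cluster_concordance(tree: Tree, clusters) -> tuple[float, dict[str, bool]]:
    """Fraction of clusters separable from the rest by a single tree edge.

    A cluster is concordant iff its member set equals the tip set on one
    side of some edge (a clade or the complement of one). Singleton clusters
    are concordant by definition and excluded from the fraction, which is
    computed over clusters of size ≥ 2.
    """
    leaves = tree.leaf_names()
    clade_sets = set(_clade_tip_sets(tree))
    flags: dict[str, bool] = {}
    concordant = total = 0
    for label, members in clusters.clusters.items():
        mset = frozenset(members)
        missing = mset - leaves
        if missing:
            raise ValueError(f"cluster {label!r} member(s) absent from tree: {sorted(missing)}")
        if len(mset) == 1:
            flags[label] = True
            continue
        ok = mset in clade_sets or frozenset(leaves - mset) in clade_sets
        flags[label] = ok
        total += 1
        concordant += ok
    fraction = concordant / total if total else 1.0
    return fraction, flags


@dataclass
class CrossTab:
    """Cap-cluster × Rep-group contingency table with incongruence flags."""

    counts: pd.DataFrame  # rows = Cap clusters, columns = Rep groups
    distinct_rep_groups: pd.Series
    flagged: pd.Series  # True where a Cap cluster spans >1 Rep group
    n_shared: int

    def to_frame(self) -> pd.DataFrame:
        long = (
            self.counts.stack()
            .rename("count")
            .reset_index()
            .rename(columns={"level_0": "cap_cluster", "level_1": "rep_group"})
        )
        long = long[long["count"] > 0]
        long["distinct_rep_groups"] = long["cap_cluster"].map(self.distinct_rep_groups)
        long["flagged"] = long["cap_cluster"].map(self.flagged)
        return long.reset_index(drop=True)


def rep_cap_crosstab(
    cap_labels: dict[str, str], rep_labels: dict[str, str]
) -> CrossTab:
    """Cross-tabulate Cap cluster against Rep group over genomes with both labels.

    A Cap cluster whose members carry more than one distinct Rep group is
    flagged as incongruent — the recombination signal.
    """
    shared = sorted(set(cap_labels) & set(rep_labels))
    if not shared:
        raise ValueError("no ids shared between Cap and Rep label maps")
    df = pd.DataFrame(
        {
            "cap": [cap_labels[i] for i in shared],
            "rep": [rep_labels[i] for i in shared],
        }
    )
    counts = pd.crosstab(df["cap"], df["rep"])
    counts.index.name = "cap_cluster"
    counts.columns.name = "rep_group"
    distinct = (counts > 0).sum(axis=1)
    flagged = distinct > 1
    return CrossTab(
        counts=counts,
        distinct_rep_groups=distinct,
        flagged=flagged,
        n_shared=len(shared),
    )
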