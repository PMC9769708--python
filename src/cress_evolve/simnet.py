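"""CLANS-style all-vs-all similarity network, layout and clustering.

The pipeline mirrors the classic cluster-analysis-of-sequences approach:
optimal Smith–Waterman local alignment scores under BLOSUM45 with affine
gaps are converted to E-values via Karlin–Altschul statistics
(E = K·m·n·exp(−λ·S)) and to P-values (P = 1 − exp(−E)); sequence pairs
with P at or below a threshold (default 1e−2) become edges of an
undirected similarity network, which is embedded by a force-directed
layout and partitioned into clusters subject to a minimum-size rule
(default 10 members).

The Karlin–Altschul λ/K defaults come from a small built-in table. For
gapped scoring no analytic values exist; the shipped values were fitted by
simulating local alignments of unrelated uniform-composition proteins and
then deflating the fitted Gumbel decay by a factor of two as a safety
margin, because the per-pair m·n search-space convention used here
understates the multiplicity of an all-vs-all network search. The result
is a deliberately conservative E-value: unrelated sequences of typical
protein length score far above the edge threshold, while genuinely
homologous pairs (scores an order of magnitude above the random maximum)
are unaffected. Both constants are overridable per run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .seqio import PROTEIN, SequenceRecord, SequenceError

#: (matrix, gap_open, gap_extend) -> (lambda, K). Simulation-calibrated with a
#: 2x conservative deflation of lambda (see module docstring).
KARLIN_ALTSCHUL_TABLE: dict[tuple[str, float, float], tuple[float, float]] = {
    ("BLOSUM45", 15, 2): (0.08, 0.022),
    ("BLOSUM62", 11, 1): (0.13, 0.040),
}

#: P-values below this floor are clamped before the log in the attraction.
P_FLOOR = 1e-200
#: Normalization constant for edge attraction: a = min(1, -log10(P)/200).
ATTRACTION_NORM = 200.0


@dataclass(frozen=True)
class ScoringParams:
    """Alignment scoring and E-value statistics for one matrix/gap choice."""

    matrix: str = "BLOSUM45"
    gap_open: float = 15.0
    gap_extend: float = 2.0
    karlin_lambda: float = 0.08
    karlin_k: float = 0.022

    def __post_init__(self):
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.karlin_lambda <= 0 or self.karlin_k <= 0:
            raise ValueError("Karlin-Altschul lambda and K must be positive")

    @classmethod
    def default(
        cls, matrix: str = "BLOSUM45", gap_open: float = 15, gap_extend: float = 2
    ) -> "ScoringParams":
        key = (matrix, gap_open, gap_extend)
        if key in KARLIN_ALTSCHUL_TABLE:
            lam, k = KARLIN_ALTSCHUL_TABLE[key]
            return cls(matrix, gap_open, gap_extend, lam, k)
        raise KeyError(
            f"no built-in Karlin-Altschul parameters for {key}; "
            "construct ScoringParams explicitly"
        )


@dataclass(frozen=True)
class PairwiseHit:
    """One significant local alignment between two sequences."""

    query_id: str
    subject_id: str
    raw_score: float
    evalue: float
    pvalue: float
    attraction: float


def make_aligner(params: ScoringParams) -> Align.PairwiseAligner:
    """Smith–Waterman aligner under ``params``.

    Gap costs follow the BLAST convention (a gap of length k costs
    open + k·extend), translated to Biopython's first/extension scores.
    """
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(params.matrix)
    aligner.open_gap_score = -(params.gap_open + params.gap_extend)
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def evalue_to_pvalue(evalue: float) -> float:
    """P = 1 − exp(−E), the probability of at least one chance hit."""
    if evalue < 0:
        raise ValueError(f"E-value must be non-negative, got {evalue}")
    return -math.expm1(-evalue)


def attraction_from_pvalue(pvalue: float) -> float:
    """Edge attraction a = min(1, −log10(P)/200), clamped at P ≥ 1e−200."""
    p = max(pvalue, P_FLOOR)
    return min(1.0, -math.log10(p) / ATTRACTION_NORM)


def _check_protein(rec: SequenceRecord) -> None:
    if rec.alphabet != PROTEIN:
        raise SequenceError(f"record {rec.id!r}: similarity scoring needs protein input")


def score_pair(
    a: SequenceRecord,
    b: SequenceRecord,
    params: ScoringParams,
    aligner: Align.PairwiseAligner | None = None,
) -> PairwiseHit | None:
    """Score one ordered pair; returns ``None`` when no local alignment scores > 0.

    E = K·m·n·exp(−λ·S) with m, n the raw sequence lengths.
    """
    _check_protein(a)
    _check_protein(b)
    if aligner is None:
        aligner = make_aligner(params)
    score = float(aligner.score(a.residues, b.residues))
    if score <= 0:
        return None
    evalue = params.karlin_k * len(a) * len(b) * math.exp(-params.karlin_lambda * score)
    pvalue = evalue_to_pvalue(evalue)
    return PairwiseHit(
        query_id=a.id,
        subject_id=b.id,
        raw_score=score,
        evalue=evalue,
        pvalue=pvalue,
        attraction=attraction_from_pvalue(pvalue),
    )


def all_vs_all(
    records: list[SequenceRecord], params: ScoringParams
) -> list[PairwiseHit]:
    """All unordered pairs, one hit per pair with a positive score."""
    aligner = make_aligner(params)
    hits: list[PairwiseHit] = []
    for i, a in enumerate(records):
        for b in records[i + 1 :]:
            hit = score_pair(a, b, params, aligner=aligner)
            if hit is not None:
                hits.append(hit)
    return hits


@dataclass
class SimilarityNetwork:
    """Thresholded undirected similarity graph; isolated nodes retained."""

    graph: nx.Graph
    p_threshold: float

    @property
    def node_ids(self) -> list[str]:
        return sorted(self.graph.nodes)

    def edge_hits(self) -> list[PairwiseHit]:
        return [data["hit"] for _, _, data in self.graph.edges(data=True)]


def build_network(
    hits: list[PairwiseHit], ids: list[str], p_threshold: float
) -> SimilarityNetwork:
    """Merge reciprocal hits (keeping the smaller P-value), threshold, build graph."""
    known = set(ids)
    if len(known) != len(ids):
        raise ValueError("duplicate node ids")
    graph = nx.Graph()
    graph.add_nodes_from(ids)
    for hit in hits:
        if hit.query_id not in known or hit.subject_id not in known:
            raise ValueError(
                f"hit endpoint(s) {hit.query_id!r}/{hit.subject_id!r} not in node list"
            )
        if hit.query_id == hit.subject_id:
            continue
        u, v = hit.query_id, hit.subject_id
        if graph.has_edge(u, v):
            if hit.pvalue < graph.edges[u, v]["hit"].pvalue:
                graph.edges[u, v]["hit"] = hit
        else:
            graph.add_edge(u, v, hit=hit)
    drop = [
        (u, v)
        for u, v, data in graph.edges(data=True)
        if data["hit"].pvalue > p_threshold
    ]
    graph.remove_edges_from(drop)
    return SimilarityNetwork(graph=graph, p_threshold=p_threshold)


@dataclass
class LayoutState:
    """Force-directed embedding of the similarity network."""

    ids: list[str]
    coords: np.ndarray  # (n, dims)
    rounds_done: int
    rng_seed: int

    def as_dict(self) -> dict[str, np.ndarray]:
        return {i: self.coords[k] for k, i in enumerate(self.ids)}


def layout_network(
    net: SimilarityNetwork,
    dims: int = 2,
    rounds: int = 1000,
    seed: int = 0,
    step: float = 0.05,
    max_move: float = 0.3,
    repulsion: float = 0.05,
) -> LayoutState:
    """Deterministic force-directed layout.

    Each round, every node is pulled along its edges proportionally to the
    edge attraction (linear spring) and pushed away from every other node
    by an inverse-distance repulsion; the per-round displacement is capped
    at ``max_move``. Identical seed and inputs give identical coordinates.
    """
    if dims not in (2, 3):
        raise ValueError(f"layout dims must be 2 or 3, got {dims}")
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    ids = net.node_ids
    n = len(ids)
    index = {node: k for k, node in enumerate(ids)}
    rng = np.random.default_rng(seed)
    coords = rng.uniform(-1.0, 1.0, size=(n, dims))
    if n <= 1:
        return LayoutState(ids, coords, rounds, seed)

    att = np.zeros((n, n))
    for u, v, data in net.graph.edges(data=True):
        a = data["hit"].attraction
        att[index[u], index[v]] = a
        att[index[v], index[u]] = a

    eps = 1e-12
    for _ in range(rounds):
        diff = coords[None, :, :] - coords[:, None, :]  # diff[i,j] = x_j - x_i
        dist = np.sqrt((diff**2).sum(-1)) + eps
        pull = (att[:, :, None] * diff).sum(1)
        push = -repulsion * (diff / (dist**2)[:, :, None]).sum(1)
        move = step * (pull + push)
        norms = np.sqrt((move**2).sum(-1, keepdims=True))
        over = norms > max_move
        np.divide(move * max_move, norms, out=move, where=over)
        coords = coords + move
    return LayoutState(ids, coords, rounds, seed)


@dataclass
class ClusterAssignment:
    """Disjoint clusters plus an unclustered pool, under a minimum-size rule."""

    clusters: dict[str, list[str]]
    unclustered: list[str]
    min_size: int
    method: str

    def labels(self) -> dict[str, str]:
        """id -> cluster label; unclustered ids map to 'unclustered'."""
        out = {}
        for label, members in self.clusters.items():
            for m in members:
                out[m] = label
        for m in self.unclustered:
            out[m] = "unclustered"
        return out

    def all_ids(self) -> set[str]:
        ids = set(self.unclustered)
        for members in self.clusters.values():
            ids.update(members)
        return ids


def _finalize(
    groups: list[list[str]], min_size: int, method: str
) -> ClusterAssignment:
    groups = sorted((sorted(g) for g in groups), key=lambda g: (-len(g), g[0]))
    clusters: dict[str, list[str]] = {}
    unclustered: list[str] = []
    k = 0
    for members in groups:
        if len(members) >= min_size:
            k += 1
            clusters[f"cluster_{k}"] = members
        else:
            unclustered.extend(members)
    return ClusterAssignment(clusters, sorted(unclustered), min_size, method)


def extract_clusters(
    net: SimilarityNetwork,
    method: str = "components",
    min_size: int = 10,
    max_rounds: int = 10000,
    offset: float = 1.0,
) -> ClusterAssignment:
    """Partition the network into clusters.

    ``components``: connected components of the thresholded graph.
    ``network_offset``: starting from components, iteratively reassign each
    node (lexicographic scan order) to the cluster maximizing its average
    attraction to members, provided that average exceeds
    offset × global mean edge attraction; ties broken by lowest cluster
    index; at most ``max_rounds`` sweeps or until stable. Components or
    clusters smaller than ``min_size`` go to the unclustered pool.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    comps = [sorted(c) for c in nx.connected_components(net.graph)]
    if method == "components":
        return _finalize(comps, min_size, method)
    if method != "network_offset":
        raise ValueError(f"unknown clustering method {method!r}")

    edge_hits = net.edge_hits()
    global_mean = (
        float(np.mean([h.attraction for h in edge_hits])) if edge_hits else 0.0
    )
    threshold = offset * global_mean
    ids = net.node_ids
    membership: dict[str, int] = {}
    for ci, comp in enumerate(sorted(comps, key=lambda c: c[0])):
        for node in comp:
            membership[node] = ci
    att = {
        (u, v): data["hit"].attraction for u, v, data in net.graph.edges(data=True)
    }

    def attraction(u: str, v: str) -> float:
        return att.get((u, v)) or att.get((v, u)) or 0.0

    for _ in range(max_rounds):
        changed = False
        for node in ids:
            cluster_ids = sorted(set(membership.values()) - {-1})
            best_ci, best_avg = -1, 0.0
            for ci in cluster_ids:
                members = [
                    m for m in ids if membership[m] == ci and m != node
                ]
                if not members:
                    continue
                avg = sum(attraction(node, m) for m in members) / len(members)
                if avg > best_avg:
                    best_ci, best_avg = ci, avg
            target = best_ci if best_avg > threshold else -1
            if target != membership[node]:
                membership[node] = target
                changed = True
        if not changed:
            break
    groups: dict[int, list[str]] = {}
    singles: list[list[str]] = []
    for node, ci in membership.items():
        if ci == -1:
            singles.append([node])
        else:
            groups.setdefault(ci, []).append(node)
    return _finalize(list(groups.values()) + singles, min_size, method)
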