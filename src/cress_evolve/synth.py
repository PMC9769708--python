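"""Seeded synthetic-data generators for every analysis stage.

Three generators emulate the statistical structure the pipeline assumes:

* ``gen_protein_families`` — protein families with controlled within-family
  identity (each member is an i.i.d. substitution-mutated copy of an
  independent uniform-random consensus), the test double for a set of viral
  protein sequences with clear cluster structure;
* ``gen_cds`` — coding sequences whose GC12/GC3 covariation is governed by
  a tunable mutation–selection mixture: per gene a mutational GC pressure
  m ~ U(m_lo, m_hi) is drawn, third codon positions track m directly, and
  first/second positions are pulled toward a selective optimum c with
  weight w, so the neutrality regression of GC12 on GC3 has expected slope
  (1 − w) before binomial-sampling attenuation;
* ``plant_motifs`` — a motif-free random protein backbone with known motif
  strings copied in at known positions, the ground truth for domain
  scanning.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .domains import MotifSet
from .seqio import PROTEIN, CodingSequence, SequenceRecord, STANDARD_CODE

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
STOPS = ("TAA", "TAG", "TGA")


@dataclass(frozen=True)
class FamilyTruth:
    """Ground-truth labels and consensi for generated protein families."""

    labels: dict[str, str]  # member id -> family id
    consensi: dict[str, str]  # family id -> consensus sequence
    n_families: int
    members_per_family: int
    length: int
    within_sub_prob: float


def gen_protein_families(
    n_families: int,
    members_per_family: int,
    length: int,
    within_sub_prob: float,
    seed: int,
) -> tuple[list[SequenceRecord], FamilyTruth]:
    """Protein families from independent random consensi.

    Each member equals its family consensus with i.i.d. substitutions at
    probability ``within_sub_prob``, each to a uniformly chosen *different*
    residue; expected pairwise within-family identity is therefore
    (1−q)² + q²/19 for q = within_sub_prob.
    """
    if length < 50:
        raise ValueError("family length must be >= 50")
    if members_per_family < 2:
        raise ValueError("members_per_family must be >= 2")
    if not 0.0 <= within_sub_prob < 1.0:
        raise ValueError("within_sub_prob must be in [0, 1)")
    rng = np.random.default_rng(seed)
    aa = np.array(list(AMINO_ACIDS))
    records: list[SequenceRecord] = []
    labels: dict[str, str] = {}
    consensi: dict[str, str] = {}
    for f in range(n_families):
        fam = f"fam{f:02d}"
        cons = rng.integers(0, 20, size=length)
        consensi[fam] = "".join(aa[cons])
        for m in range(members_per_family):
            seq = cons.copy()
            mutate = rng.random(length) < within_sub_prob
            # shift by 1..19 mod 20: uniform over the 19 other residues
            shifts = rng.integers(1, 20, size=length)
            seq[mutate] = (seq[mutate] + shifts[mutate]) % 20
            rid = f"{fam}_m{m:02d}"
            records.append(
                SequenceRecord(rid, rid, "".join(aa[seq]), PROTEIN)
            )
            labels[rid] = fam
    truth = FamilyTruth(
        labels, consensi, n_families, members_per_family, length, within_sub_prob
    )
    return records, truth


@dataclass(frozen=True)
class MutSelParams:
    """Mutation–selection mixture controlling synthetic codon usage."""

    n_genes: int
    codons_per_gene: int
    m_lo: float = 0.25
    m_hi: float = 0.75
    selection_weight: float = 0.0  # w
    selection_anchor: float = 0.5  # c
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.m_lo < self.m_hi <= 1.0:
            raise ValueError("need 0 <= m_lo < m_hi <= 1")
        if not 0.0 <= self.selection_weight <= 1.0:
            raise ValueError("selection_weight must be in [0, 1]")
        if not 0.0 <= self.selection_anchor <= 1.0:
            raise ValueError("selection_anchor must be in [0, 1]")
        if self.n_genes < 1 or self.codons_per_gene < 1:
            raise ValueError("n_genes and codons_per_gene must be >= 1")


def _draw_codons(rng: np.random.Generator, n: int, p12: float, p3: float) -> list[str]:
    """``n`` stop-free codons; GC probability p12 at positions 1–2, p3 at 3.

    Bases are drawn position-wise (G/C equiprobable within GC, A/T within
    AT); whole codons that come out as stops are redrawn.
    """
    probs = np.array([p12, p12, p3])
    base_gc = np.array(["G", "C"])
    base_at = np.array(["A", "T"])

    def draw(k: int) -> np.ndarray:
        gc = rng.random((k, 3)) < probs
        pick = (rng.random((k, 3)) < 0.5).astype(int)
        out = np.where(gc, base_gc[pick], base_at[pick])
        return np.array(["".join(row) for row in out])

    codons = draw(n)
    while True:
        bad = np.isin(codons, STOPS)
        if not bad.any():
            return codons.tolist()
        codons[bad] = draw(int(bad.sum()))


def gen_cds(params: MutSelParams) -> tuple[list[CodingSequence], pd.DataFrame]:
    """Coding sequences under the mutation–selection mixture.

    Returns the genes plus a truth table with each gene's drawn mutational
    GC pressure m. Stop codons are rejection-sampled away, so every gene
    has exactly ``codons_per_gene`` codons.
    """
    rng = np.random.default_rng(params.seed)
    w, c = params.selection_weight, params.selection_anchor
    genes: list[CodingSequence] = []
    truth_rows = []
    for g in range(params.n_genes):
        m = rng.uniform(params.m_lo, params.m_hi)
        p12 = (1.0 - w) * m + w * c
        codons = _draw_codons(rng, params.codons_per_gene, p12, m)
        gid = f"gene{g:04d}"
        genes.append(CodingSequence(id=gid, codons=codons))
        truth_rows.append({"gene_id": gid, "m": m, "p12": p12})
    return genes, pd.DataFrame(truth_rows)


@dataclass(frozen=True)
class PlantedMotifs:
    """Ground truth for a motif-planted backbone."""

    plants: tuple[tuple[str, int, int], ...]  # (motif string, start, end)


def _any_motif_match(seq: str, patterns: list[str]) -> re.Match | None:
    for pat in patterns:
        m = re.search(pat, seq)
        if m:
            return m
    return None


def plant_motifs(
    backbone_length: int,
    plants: list[tuple[str, int]],
    seed: int,
    motifs: MotifSet | None = None,
    record_id: str = "planted",
    max_tries: int = 1000,
) -> tuple[SequenceRecord, PlantedMotifs]:
    """A motif-free random backbone with motif strings copied in.

    The background is rejection-sampled so that none of the motif patterns
    match anywhere (ignoring region constraints), before and after
    planting; planted strings must be non-overlapping and in bounds.
    """
    if motifs is None:
        motifs = MotifSet.default()
    patterns = [m.pattern for m in motifs]
    spans = sorted((pos, pos + len(s)) for s, pos in plants)
    for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
        if b0 < a1:
            raise ValueError(f"planted motifs overlap: [{a0},{a1}) and [{b0},{b1})")
    for s, pos in plants:
        if pos < 0 or pos + len(s) > backbone_length:
            raise ValueError(f"plant {s!r} at {pos} out of bounds")
    rng = np.random.default_rng(seed)
    aa = np.array(list(AMINO_ACIDS))
    planted_spans = {(pos, pos + len(s)) for s, pos in plants}

    for _ in range(max_tries):
        seq = list("".join(rng.choice(aa, backbone_length)))
        # scrub background motif matches by redrawing the matched window
        for _ in range(200):
            m = _any_motif_match("".join(seq), patterns)
            if m is None:
                break
            for i in range(m.start(), m.end()):
                seq[i] = rng.choice(aa)
        else:
            continue
        for s, pos in plants:
            seq[pos : pos + len(s)] = list(s)
        final = "".join(seq)
        # planting may create accidental matches at junctions; retry if so
        ok = True
        for pat in patterns:
            for m in re.finditer(pat, final):
                if not any(
                    a0 <= m.start() and m.end() <= a1 for a0, a1 in planted_spans
                ):
                    ok = False
                    break
            if not ok:
                break
        if ok:
            record = SequenceRecord(record_id, record_id, final, PROTEIN)
            truth = PlantedMotifs(
                tuple(sorted((s, pos, pos + len(s)) for s, pos in plants))
            )
            return record, truth
    raise RuntimeError("could not generate a clean motif-planted backbone")
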