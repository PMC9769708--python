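"""Motif-based Rep domain detection and organization classification.

Rep proteins of circular Rep-encoding ssDNA (CRESS-DNA) viruses canonically
carry an N-terminal HUH endonuclease region (the Viral_Rep domain) and a
C-terminal superfamily-3 helicase (a P-loop NTPase). This module detects
short sequence signatures of both — the three rolling-circle-replication
motifs for the endonuclease and Walker A/B for the helicase — and derives a
domain-organization category that maps onto the CRESS virus group scheme
(CRESSV1–5, pCRESS-related, Smacoviridae-related, ...).

The motif layer is a configurable stand-in for a full conserved-domain
database search: the downstream classification depends only on
presence/completeness calls, which regex signatures supply. Completeness is
operationalized as ≥2 of the 3 endonuclease motifs (Viral_Rep) and Walker A
plus Walker B starting within 120 residues after Walker A ends (P-loop);
exactly one motif of a domain present means "incomplete". Both cutoffs are
configurable, and outputs carry a ``motif_standin`` metadata flag.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .seqio import SequenceRecord

N_HALF = "N-half"
C_HALF = "C-half"
ANY = "any"

VIRAL_REP_MOTIFS = ("huh_motif_1", "huh_motif_2", "huh_motif_3")
PLOOP_MOTIFS = ("walker_a", "walker_b")

#: Spacing rule: Walker B must start within this many residues after Walker A ends.
DEFAULT_WALKER_SPAN = 120
#: Gap between domains beyond which an inserted extra domain is suspected.
DEFAULT_INSERT_GAP = 150

COMPLETE = "complete"
INCOMPLETE = "incomplete"
ABSENT = "absent"

CATEGORIES = ("both", "viral_rep_only", "ploop_only", "both_one_incomplete", "none")

#: Organization category -> candidate CRESS virus groups.
GROUP_MAP: dict[str, frozenset[str]] = {
    "both": frozenset(
        {
            "CRESSV1",
            "CRESSV2",
            "CRESSV3",
            "Circoviridae",
            "Circoviridae-related",
            "Nanoviridae",
        }
    ),
    "viral_rep_only": frozenset({"CRESSV4", "CRESSV5"}),
    "ploop_only": frozenset({"pCRESS-related"}),
    "none": frozenset(
        {
            "Smacoviridae",
            "Smacoviridae-related",
            "outgroup1",
            "outgroup2",
            "outgroup3",
            "outgroup4",
        }
    ),
    "both_one_incomplete": frozenset({"CRESSV2-related", "Nanoviridae"}),
}


@dataclass(frozen=True)
class Motif:
    name: str
    pattern: str
    region: str = ANY

    def __post_init__(self):
        if self.region not in (N_HALF, C_HALF, ANY):
            raise ValueError(f"motif {self.name!r}: unknown region {self.region!r}")
        try:
            re.compile(self.pattern)
        except re.error as exc:
            raise ValueError(f"motif {self.name!r}: bad pattern: {exc}") from exc


@dataclass(frozen=True)
class MotifSet:
    motifs: tuple[Motif, ...]
    walker_span: int = DEFAULT_WALKER_SPAN

    def __post_init__(self):
        names = [m.name for m in self.motifs]
        if len(set(names)) != len(names):
            raise ValueError("motif names must be unique")

    def __iter__(self):
        return iter(self.motifs)

    def get(self, name: str) -> Motif:
        for m in self.motifs:
            if m.name == name:
                return m
        raise KeyError(name)

    @classmethod
    def default(cls) -> "MotifSet":
        return cls(
            motifs=(
                Motif("huh_motif_1", "[FYWLIV]T[LIVF]", N_HALF),
                Motif("huh_motif_2", "H[ILVMFYWAC]H", N_HALF),
                Motif("huh_motif_3", "Y..[KR]", N_HALF),
                Motif("walker_a", "[GA]....GK[ST]", ANY),
                Motif("walker_b", "[ILVMFACW]{3}[DE][DE]", ANY),
            )
        )


@dataclass(frozen=True)
class MotifHit:
    motif: str
    start: int  # 0-based
    end: int  # half-open


@dataclass
class DomainAnnotation:
    """Motif hits plus derived completeness calls for one Rep protein."""

    sequence_id: str
    hits: list[MotifHit]
    viral_rep_status: str
    ploop_status: str
    insert_suspected: bool = False

    def hits_for(self, motif: str) -> list[MotifHit]:
        return [h for h in self.hits if h.motif == motif]


@dataclass(frozen=True)
class OrganizationClass:
    category: str
    candidate_groups: frozenset[str]


def _region_bounds(region: str, length: int) -> tuple[int, int]:
    mid = length // 2
    if region == N_HALF:
        return 0, mid
    if region == C_HALF:
        return mid, length
    return 0, length


def scan_motifs(
    protein: SequenceRecord,
    motifs: MotifSet | None = None,
    insert_gap: int = DEFAULT_INSERT_GAP,
) -> DomainAnnotation:
    """Find all non-overlapping leftmost matches of each motif and call statuses.

    A match counts only when it starts inside the motif's region (the
    sequence midpoint splits N-half from C-half).
    """
    if motifs is None:
        motifs = MotifSet.default()
    seq = protein.residues
    if len(seq) < 30:
        raise ValueError(
            f"record {protein.id!r}: too short for domain scanning ({len(seq)} < 30)"
        )
    hits: list[MotifHit] = []
    for motif in motifs:
        lo, hi = _region_bounds(motif.region, len(seq))
        for m in re.finditer(motif.pattern, seq):
            if lo <= m.start() < hi:
                hits.append(MotifHit(motif.name, m.start(), m.end()))
    hits.sort(key=lambda h: (h.start, h.motif))

    present_rep = {m for m in VIRAL_REP_MOTIFS if any(h.motif == m for h in hits)}
    if len(present_rep) >= 2:
        rep_status = COMPLETE
    elif len(present_rep) == 1:
        rep_status = INCOMPLETE
    else:
        rep_status = ABSENT

    walker_a = [h for h in hits if h.motif == "walker_a"]
    walker_b = [h for h in hits if h.motif == "walker_b"]
    if walker_a and walker_b:
        paired = any(
            0 <= b.start - a.end <= motifs.walker_span
            for a in walker_a
            for b in walker_b
        )
        ploop_status = COMPLETE if paired else INCOMPLETE
    elif walker_a or walker_b:
        ploop_status = INCOMPLETE
    else:
        ploop_status = ABSENT

    # Large gap between the endonuclease and helicase regions suggests an
    # inserted extra domain; flagged only, never identified.
    insert = False
    rep_hits = [h for h in hits if h.motif in VIRAL_REP_MOTIFS]
    ploop_hits = walker_a + walker_b
    if rep_hits and ploop_hits:
        gap = min(h.start for h in ploop_hits) - max(h.end for h in rep_hits)
        insert = gap > insert_gap
    return DomainAnnotation(
        sequence_id=protein.id,
        hits=hits,
        viral_rep_status=rep_status,
        ploop_status=ploop_status,
        insert_suspected=insert,
    )


def classify_organization(annotation: DomainAnnotation) -> OrganizationClass:
    """Map the (Viral_Rep, P-loop) status pair to an organization category."""
    rep, ploop = annotation.viral_rep_status, annotation.ploop_status
    for status in (rep, ploop):
        if status not in (COMPLETE, INCOMPLETE, ABSENT):
            raise ValueError(f"unknown domain status {status!r}")
    if rep == COMPLETE and ploop == COMPLETE:
        category = "both"
    elif ploop == ABSENT and rep in (COMPLETE, INCOMPLETE):
        category = "viral_rep_only"
    elif rep == ABSENT and ploop in (COMPLETE, INCOMPLETE):
        category = "ploop_only"
    elif rep == ABSENT and ploop == ABSENT:
        category = "none"
    else:
        # one complete + one incomplete, or both incomplete
        category = "both_one_incomplete"
    return OrganizationClass(category, map_candidate_groups(category))


def map_candidate_groups(category: str) -> frozenset[str]:
    """Candidate CRESS virus group labels for an organization category."""
    try:
        return GROUP_MAP[category]
    except KeyError:
        raise ValueError(f"unknown organization category {category!r}") from None
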