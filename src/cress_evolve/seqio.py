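"""Sequence input, validation and tabular output.

Every downstream stage consumes the two record types defined here:
:class:`SequenceRecord` for protein or nucleotide FASTA entries and
:class:`CodingSequence` for validated, codon-partitioned CDS. The genetic
code is wrapped in :class:`GeneticCode`, which precomputes the synonymous
families and degeneracy classes the codon-usage statistics need.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

PROTEIN = "protein"
NUCLEOTIDE = "nucleotide"

# 20 canonical amino acids plus X (unknown)
PROTEIN_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")
# ACGT, N and the IUPAC ambiguity codes
NUCLEOTIDE_RESIDUES = frozenset("ACGTNRYSWKMBDHV")


class SequenceError(ValueError):
    """Raised for malformed or invalid sequence input."""


@dataclass(frozen=True)
class SequenceRecord:
    """A single validated FASTA entry."""

    id: str
    description: str
    residues: str
    alphabet: str

    def __post_init__(self):
        if not self.id:
            raise SequenceError("record id must be non-empty")
        if not self.residues:
            raise SequenceError(f"record {self.id!r}: empty sequence")
        if self.alphabet not in (PROTEIN, NUCLEOTIDE):
            raise SequenceError(f"unknown alphabet {self.alphabet!r}")
        allowed = PROTEIN_RESIDUES if self.alphabet == PROTEIN else NUCLEOTIDE_RESIDUES
        bad = set(self.residues) - allowed
        if bad:
            raise SequenceError(
                f"record {self.id!r}: residue(s) {sorted(bad)} outside "
                f"{self.alphabet} alphabet"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class GeneticCode:
    """A genetic code with its synonymous-family structure.

    ``families`` maps each amino acid to the tuple of codons encoding it;
    ``degeneracy_classes`` groups amino acids by synonymous-codon count
    k ∈ {1, 2, 3, 4, 6}. Under the standard code there are 61 sense codons,
    3 stops, and the 18 degenerate amino acids split into nine 2-fold, one
    3-fold, five 4-fold and three 6-fold families (Met and Trp singletons).
    """

    id: int
    codon_to_aa: Mapping[str, str]
    stop_codons: frozenset[str]
    families: Mapping[str, tuple[str, ...]]
    degeneracy_classes: Mapping[int, tuple[str, ...]]

    @classmethod
    def from_ncbi_id(cls, code_id: int = 1) -> "GeneticCode":
        table = CodonTable.unambiguous_dna_by_id[code_id]
        codon_to_aa = dict(table.forward_table)
        stops = frozenset(table.stop_codons)
        fams: dict[str, list[str]] = {}
        for codon in sorted(codon_to_aa):
            fams.setdefault(codon_to_aa[codon], []).append(codon)
        families = {aa: tuple(cods) for aa, cods in fams.items()}
        classes: dict[int, list[str]] = {}
        for aa, cods in families.items():
            classes.setdefault(len(cods), []).append(aa)
        degeneracy = {k: tuple(sorted(v)) for k, v in classes.items()}
        return cls(code_id, codon_to_aa, stops, families, degeneracy)

    @property
    def sense_codons(self) -> tuple[str, ...]:
        return tuple(sorted(self.codon_to_aa))

    def degeneracy_of(self, codon: str) -> int:
        return len(self.families[self.codon_to_aa[codon]])


STANDARD_CODE = GeneticCode.from_ncbi_id(1)


@dataclass
class CodingSequence:
    """A codon-partitioned CDS that passed validation."""

    id: str
    codons: list[str]
    genetic_code_id: int = 1
    n_excluded_ambiguous: int = 0
    n_excluded_stops: int = 0
    terminal_stop_trimmed: bool = False

    def __post_init__(self):
        if not self.codons:
            raise SequenceError(f"CDS {self.id!r}: no codons left after validation")

    @property
    def sequence(self) -> str:
        return "".join(self.codons)

    def __len__(self) -> int:
        return len(self.codons)


def read_fasta(path: str | os.PathLike, alphabet: str) -> list[SequenceRecord]:
    """Read a FASTA file into validated :class:`SequenceRecord` objects.

    Record id is the first whitespace-delimited header token; residues are
    upper-cased; U is mapped to T for nucleotide input. Duplicate ids, empty
    files and out-of-alphabet residues raise :class:`SequenceError`.
    """
    records: list[SequenceRecord] = []
    seen: dict[str, int] = {}
    for entry in SeqIO.parse(str(path), "fasta"):
        residues = str(entry.seq).upper()
        if alphabet == NUCLEOTIDE:
            residues = residues.replace("U", "T")
        records.append(
            SequenceRecord(
                id=entry.id,
                description=entry.description,
                residues=residues,
                alphabet=alphabet,
            )
        )
        seen[entry.id] = seen.get(entry.id, 0) + 1
    if not records:
        raise SequenceError(f"{path}: no FASTA records found")
    dups = sorted(i for i, n in seen.items() if n > 1)
    if dups:
        raise SequenceError(f"{path}: duplicate record id(s): {dups}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | os.PathLike) -> None:
    """Write records to FASTA, preserving ids and residues exactly."""
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description="")
        for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


def validate_cds(
    record: SequenceRecord,
    code: GeneticCode = STANDARD_CODE,
    policy: str = "strict",
) -> CodingSequence:
    """Partition a nucleotide record into codons and apply the CDS rules.

    Length must be divisible by 3. A single terminal stop codon is trimmed
    and flagged. Codons containing non-ACGT characters are excluded and
    counted. ``strict`` rejects internal stops (naming the codon index);
    ``lenient`` excludes them like ambiguous codons.
    """
    if record.alphabet != NUCLEOTIDE:
        raise SequenceError(f"record {record.id!r}: validate_cds needs nucleotide input")
    if policy not in ("strict", "lenient"):
        raise SequenceError(f"unknown CDS policy {policy!r}")
    seq = record.residues
    if len(seq) % 3 != 0:
        raise SequenceError(
            f"CDS {record.id!r}: length {len(seq)} not divisible by 3"
        )
    raw = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    trimmed = False
    if raw and raw[-1] in code.stop_codons:
        raw = raw[:-1]
        trimmed = True
    kept: list[str] = []
    n_ambig = 0
    n_stop = 0
    for idx, codon in enumerate(raw):
        if any(base not in "ACGT" for base in codon):
            n_ambig += 1
            continue
        if codon in code.stop_codons:
            if policy == "strict":
                raise SequenceError(
                    f"CDS {record.id!r}: internal stop codon {codon} at codon index {idx}"
                )
            n_stop += 1
            continue
        kept.append(codon)
    if not kept:
        raise SequenceError(f"CDS {record.id!r}: all codons excluded")
    return CodingSequence(
        id=record.id,
        codons=kept,
        genetic_code_id=code.id,
        n_excluded_ambiguous=n_ambig + n_stop,
        n_excluded_stops=n_stop,
        terminal_stop_trimmed=trimmed,
    )


def write_outputs(
    tables: Mapping[str, pd.DataFrame],
    trees: Mapping[str, str],
    outdir: str | os.PathLike,
) -> pd.DataFrame:
    """Write result tables (TSV with header) and Newick trees to ``outdir``.

    Returns a manifest DataFrame listing every file with its row count
    (row count for trees = number of trees in the file, i.e. 1).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for name, table in tables.items():
        path = outdir / f"{name}.tsv"
        table.to_csv(path, sep="\t", index=False)
        rows.append({"file": path.name, "kind": "table", "rows": len(table)})
    for name, newick in trees.items():
        path = outdir / f"{name}.nwk"
        text = newick.strip()
        if not text.endswith(";"):
            text += ";"
        path.write_text(text + "\n")
        rows.append({"file": path.name, "kind": "tree", "rows": 1})
    return pd.DataFrame(rows, columns=["file", "kind", "rows"])
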