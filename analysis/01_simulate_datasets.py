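"""Generate the synthetic study datasets used by the downstream analyses.

Writes, under results/data:

* Rep and Cap protein sets: five planted families of 20 members each plus
  one 9-member family (to exercise the minimum-cluster-size rule), 300
  residues, 10% within-family divergence;
* Rep-like and Cap-like CDS sets: 200 genes x 300 codons under the
  mutation-selection mixture at selection weights 0.7 (Rep-like regime)
  and 0.0 / 1.0 (calibration extremes);
* a set of Rep proteins with planted endonuclease/helicase motifs covering
  every domain-organization category.

Every output FASTA is paired with a ground-truth TSV.
"""

import argparse
from pathlib import Path

import pandas as pd

from cress_evolve import seqio, synth


def protein_set(tag, seed, outdir):
    big, truth = synth.gen_protein_families(5, 20, 300, 0.1, seed=seed)
    small, _ = synth.gen_protein_families(1, 9, 300, 0.1, seed=seed + 1)
    small = [
        seqio.SequenceRecord(f"{tag}_small_{r.id}", r.description, r.residues, r.alphabet)
        for r in small
    ]
    records = [
        seqio.SequenceRecord(f"{tag}_{r.id}", r.description, r.residues, r.alphabet)
        for r in big
    ] + small
    labels = {f"{tag}_{i}": fam for i, fam in truth.labels.items()}
    labels.update({r.id: "fam_small" for r in small})
    seqio.write_fasta(records, outdir / f"{tag}_proteins.fasta")
    pd.DataFrame(
        [{"id": i, "family": f} for i, f in sorted(labels.items())]
    ).to_csv(outdir / f"{tag}_proteins_truth.tsv", sep="\t", index=False)
    print(f"  {tag}: {len(records)} proteins, 6 planted families (one of size 9)")


def cds_set(tag, w, seed, outdir):
    params = synth.MutSelParams(
        n_genes=200, codons_per_gene=300, selection_weight=w, seed=seed
    )
    genes, truth = synth.gen_cds(params)
    recs = [
        seqio.SequenceRecord(f"{tag}_{g.id}", g.id, g.sequence, seqio.NUCLEOTIDE)
        for g in genes
    ]
    seqio.write_fasta(recs, outdir / f"{tag}_cds.fasta")
    truth.to_csv(outdir / f"{tag}_cds_truth.tsv", sep="\t", index=False)
    print(f"  {tag}: 200 genes x 300 codons, selection weight {w}")


ORGANIZATIONS = {
    "both": [("HLH", 20), ("YASK", 60), ("GPSGSGKS", 220), ("ILLDD", 280)],
    "viral_rep_only": [("HLH", 20), ("YASK", 60)],
    "ploop_only": [("GPSGSGKS", 220), ("ILLDD", 280)],
    "both_one_incomplete": [("HLH", 20), ("YASK", 60), ("GPSGSGKS", 220)],
    "none": [],
}


def motif_set(seed, outdir):
    rows, records = [], []
    for k, (category, plants) in enumerate(sorted(ORGANIZATIONS.items())):
        for rep in range(3):
            rec, truth = synth.plant_motifs(
                400, plants, seed=seed + 10 * k + rep,
                record_id=f"{category}_{rep}",
            )
            records.append(rec)
            rows.append({"id": rec.id, "category": category,
                         "plants": ";".join(f"{s}@{a}" for s, a, _ in truth.plants)})
    seqio.write_fasta(records, outdir / "rep_motif_proteins.fasta")
    pd.DataFrame(rows).to_csv(outdir / "rep_motif_truth.tsv", sep="\t", index=False)
    print(f"  motifs: {len(records)} proteins across {len(ORGANIZATIONS)} organizations")


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", default="results/data")
    args = ap.parse_args()
    outdir = Path(args.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    print(f"simulating study datasets (seed {args.seed}) -> {outdir}")
    protein_set("rep", args.seed * 100 + 1, outdir)
    protein_set("cap", args.seed * 100 + 3, outdir)
    cds_set("rep_like", 0.7, args.seed * 100 + 5, outdir)
    cds_set("mutation_only", 0.0, args.seed * 100 + 6, outdir)
    cds_set("selection_only", 1.0, args.seed * 100 + 7, outdir)
    motif_set(args.seed * 100 + 8, outdir)


if __name__ == "__main__":
    main()
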