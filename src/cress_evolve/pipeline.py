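"""End-to-end orchestration: cluster → domains → tree/concordance → crosstab → codon suite."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import codonbias, domains, seqio, simnet, treecheck

log = logging.getLogger("cress_evolve")


@dataclass
class PipelineConfig:
    """Inputs and stage parameters for one full run.

    Rep and Cap records from the same genome are paired by shared record id
    for the recombination crosstab.
    """

    rep_protein: str
    cap_protein: str
    rep_cds: str
    cap_cds: str
    outdir: str
    p_threshold: float = 1e-2
    min_size: int = 10
    cluster_method: str = "components"
    cluster_max_rounds: int = 10000
    cluster_offset: float = 1.0
    layout_dims: int = 2
    layout_rounds: int = 2000
    seed: int = 0
    genetic_code: int = 1
    cds_policy: str = "strict"
    pr2_sites: str = "all"
    max_excluded_codon_frac: float = 0.10

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def validate_paths(self) -> None:
        for key in ("rep_protein", "cap_protein", "rep_cds", "cap_cds"):
            p = getattr(self, key)
            if not Path(p).exists():
                raise FileNotFoundError(f"{key}: input path {p!r} does not exist")


def _cluster_stage(records, config: PipelineConfig, tag: str):
    params = simnet.ScoringParams.default()
    hits = simnet.all_vs_all(records, params)
    net = simnet.build_network(hits, [r.id for r in records], config.p_threshold)
    layout = simnet.layout_network(
        net, dims=config.layout_dims, rounds=config.layout_rounds, seed=config.seed
    )
    clusters = simnet.extract_clusters(
        net,
        method=config.cluster_method,
        min_size=config.min_size,
        max_rounds=config.cluster_max_rounds,
        offset=config.cluster_offset,
    )
    log.info(
        "%s clustering: %d sequences, %d edges, %d clusters, %d unclustered",
        tag, len(records), net.graph.number_of_edges(),
        len(clusters.clusters), len(clusters.unclustered),
    )
    hit_table = pd.DataFrame(
        [
            {
                "query_id": h.query_id,
                "subject_id": h.subject_id,
                "raw_score": h.raw_score,
                "evalue": h.evalue,
                "pvalue": h.pvalue,
            }
            for h in hits
        ]
    )
    labels = clusters.labels()
    cluster_table = pd.DataFrame(
        [
            {"id": i, "cluster": labels[i], "method": clusters.method}
            for i in sorted(labels)
        ]
    )
    coord_cols = ["x", "y", "z"][: config.layout_dims]
    layout_table = pd.DataFrame(layout.coords, columns=coord_cols)
    layout_table.insert(0, "id", layout.ids)
    return clusters, {
        f"{tag}_hits": hit_table,
        f"{tag}_clusters": cluster_table,
        f"{tag}_layout": layout_table,
    }


def _domain_stage(records):
    motifs = domains.MotifSet.default()
    rows = []
    annotations = {}
    for rec in records:
        ann = domains.scan_motifs(rec, motifs)
        org = domains.classify_organization(ann)
        annotations[rec.id] = (ann, org)
        for hit in ann.hits:
            rows.append(
                {
                    "id": rec.id,
                    "motif": hit.motif,
                    "start": hit.start,
                    "end": hit.end,
                    "viral_rep_status": ann.viral_rep_status,
                    "ploop_status": ann.ploop_status,
                    "category": org.category,
                    "candidate_groups": ";".join(sorted(org.candidate_groups)),
                    "insert_suspected": ann.insert_suspected,
                    "motif_standin": True,
                }
            )
        if not ann.hits:
            rows.append(
                {
                    "id": rec.id,
                    "motif": "",
                    "start": -1,
                    "end": -1,
                    "viral_rep_status": ann.viral_rep_status,
                    "ploop_status": ann.ploop_status,
                    "category": org.category,
                    "candidate_groups": ";".join(sorted(org.candidate_groups)),
                    "insert_suspected": ann.insert_suspected,
                    "motif_standin": True,
                }
            )
    return annotations, pd.DataFrame(rows)


def _codon_stage(cds_path: str, config: PipelineConfig, tag: str):
    code = seqio.GeneticCode.from_ncbi_id(config.genetic_code)
    records = seqio.read_fasta(cds_path, seqio.NUCLEOTIDE)
    profiles = []
    n_dropped = 0
    for rec in records:
        cds = seqio.validate_cds(rec, code, policy=config.cds_policy)
        total = len(cds.codons) + cds.n_excluded_ambiguous
        if cds.n_excluded_ambiguous / total > config.max_excluded_codon_frac:
            log.warning(
                "%s: gene %s dropped from aggregates (%d/%d codons excluded)",
                tag, rec.id, cds.n_excluded_ambiguous, total,
            )
            n_dropped += 1
            continue
        profiles.append(codonbias.profile_gene(cds, code, pr2_sites=config.pr2_sites))
    summary = codonbias.summarize_dataset(profiles, code)
    neut = codonbias.neutrality_from_profiles(profiles)
    summary_table = pd.DataFrame(
        [
            {
                "dataset": tag,
                "n_genes": summary["n_genes"],
                "n_dropped": n_dropped,
                "n_enc_na": summary["n_enc_na"],
                "gc_mean": summary["gc_mean"],
                "gc_sd": summary["gc_sd"],
                "enc_mean": summary["enc_mean"],
                "enc_sd": summary["enc_sd"],
                "n_rscu_gt_1": summary["n_rscu_gt_1"],
                "n_rscu_lt_1": summary["n_rscu_lt_1"],
                "n_rscu_lt_0p7": summary["n_rscu_lt_0p7"],
                "n_rscu_gt_1p5": summary["n_rscu_gt_1p5"],
                "neutrality_slope": neut.slope,
                "neutrality_intercept": neut.intercept,
                "neutrality_r": neut.pearson_r,
                "neutrality_p": neut.p_value,
                "mutation_pct": neut.mutation_pct,
                "selection_pct": neut.selection_pct,
            }
        ]
    )
    return {
        f"{tag}_codon_profiles": codonbias.profiles_table(profiles),
        f"{tag}_rscu": codonbias.rscu_table(profiles, code),
        f"{tag}_codon_summary": summary_table,
    }


def run_pipeline(config: PipelineConfig) -> pd.DataFrame:
    """Run every stage and write all tables, trees and a manifest to outdir."""
    config.validate_paths()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    rep_prot = seqio.read_fasta(config.rep_protein, seqio.PROTEIN)
    cap_prot = seqio.read_fasta(config.cap_protein, seqio.PROTEIN)

    tables: dict[str, pd.DataFrame] = {}
    trees: dict[str, str] = {}

    rep_clusters, rep_tables = _cluster_stage(rep_prot, config, "rep")
    cap_clusters, cap_tables = _cluster_stage(cap_prot, config, "cap")
    tables.update(rep_tables)
    tables.update(cap_tables)

    _, domain_table = _domain_stage(rep_prot)
    tables["rep_domains"] = domain_table

    dm = treecheck.distance_matrix_from_hits(rep_prot)
    tree = treecheck.nj_tree(dm)
    trees["rep_nj"] = tree.newick
    fraction, flags = treecheck.cluster_concordance(tree, rep_clusters)
    tables["rep_concordance"] = pd.DataFrame(
        [{"cluster": c, "concordant": ok} for c, ok in sorted(flags.items())]
        + [{"cluster": "__fraction__", "concordant": fraction}]
    )

    crosstab = treecheck.rep_cap_crosstab(
        cap_clusters.labels(), rep_clusters.labels()
    )
    tables["rep_cap_crosstab"] = crosstab.to_frame()

    tables.update(_codon_stage(config.rep_cds, config, "rep"))
    tables.update(_codon_stage(config.cap_cds, config, "cap"))

    manifest = seqio.write_outputs(tables, trees, outdir)
    (outdir / "run.log").write_text(
        json.dumps({"config": asdict(config)}, indent=2, sort_keys=True) + "\n"
    )
    manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    return manifest
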