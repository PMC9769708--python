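"""Codon-usage bias and the selection-vs-mutation decomposition.

Runs the full codon suite on the three synthetic CDS datasets (selection
weight 0.7 = Rep-like regime; 0.0 and 1.0 = calibration extremes):
per-gene composition and ENc, pooled RSCU bias counts, the ENc-GC3s plot
against the mutation-only expectation, the neutrality regression of GC12 on
GC3 (slope = mutational share), and PR2 bias coordinates. Optional
matplotlib panels with --plots.
"""

import argparse
from pathlib import Path

import pandas as pd

from cress_evolve import codonbias, seqio


def analyze(tag, datadir, outdir, make_plots):
    records = seqio.read_fasta(datadir / f"{tag}_cds.fasta", seqio.NUCLEOTIDE)
    profiles = [
        codonbias.profile_gene(seqio.validate_cds(r)) for r in records
    ]
    neut = codonbias.neutrality_from_profiles(profiles)
    summary = codonbias.summarize_dataset(profiles)
    points = [p for p in map(codonbias.enc_gc3s_point, profiles) if p is not None]
    below = sum(p.residual < 0 for p in points) / len(points)

    print(
        f"  {tag}: n={summary['n_genes']} genes | GC {summary['gc_mean']:.1f}"
        f" +/- {summary['gc_sd']:.2f} | ENc {summary['enc_mean']:.2f}"
        f" +/- {summary['enc_sd']:.2f} | RSCU>1: {summary['n_rscu_gt_1']},"
        f" RSCU<1: {summary['n_rscu_lt_1']}"
    )
    print(
        f"    neutrality: slope {neut.slope:.4f} (GC12 = {neut.slope:.4f}*GC3 +"
        f" {neut.intercept:.2f}, r = {neut.pearson_r:.3f}, p = {neut.p_value:.2e})"
        f" -> mutation {neut.mutation_pct:.1f}%, selection {neut.selection_pct:.1f}%"
    )
    print(f"    ENc-GC3s: {below:.0%} of genes fall below the mutation-only curve")

    codonbias.profiles_table(profiles).to_csv(
        outdir / f"{tag}_codon_profiles.tsv", sep="\t", index=False
    )
    codonbias.rscu_table(profiles).to_csv(
        outdir / f"{tag}_rscu.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        [
            {
                "dataset": tag,
                "n_genes": summary["n_genes"],
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
                "mutation_pct": neut.mutation_pct,
                "selection_pct": neut.selection_pct,
                "frac_below_expected_enc": below,
            }
        ]
    ).to_csv(outdir / f"{tag}_codon_summary.tsv", sep="\t", index=False)

    if make_plots:
        plot_panels(tag, profiles, neut, outdir)


def plot_panels(tag, profiles, neut, outdir):
    import numpy as np
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 2, figsize=(9, 8))
    table = codonbias.profiles_table(profiles)

    axes[0, 0].boxplot([table[b] for b in "ATGC"], tick_labels=list("ATGC"))
    axes[0, 0].set_title("base composition")
    axes[0, 1].hist(table["ENc"].dropna(), bins=20)
    axes[0, 1].set_xlabel("ENc")
    axes[0, 1].set_title("effective number of codons")

    s = np.linspace(0, 1, 200)
    axes[1, 0].plot(100 * s, [codonbias.expected_enc(x) for x in s], "k-", lw=1)
    axes[1, 0].scatter(table["GC3s"], table["ENc"], s=6)
    axes[1, 0].set_xlabel("GC3s (%)")
    axes[1, 0].set_ylabel("ENc")
    axes[1, 0].set_title("ENc vs GC3s with mutation-only curve")

    axes[1, 1].scatter(table["GC3"], table["GC12"], s=6)
    xs = np.array([table["GC3"].min(), table["GC3"].max()])
    axes[1, 1].plot(xs, neut.slope * xs + neut.intercept, "r-")
    axes[1, 1].set_xlabel("GC3 (%)")
    axes[1, 1].set_ylabel("GC12 (%)")
    axes[1, 1].set_title(f"neutrality plot (slope {neut.slope:.3f})")
    fig.tight_layout()
    fig.savefig(outdir / f"{tag}_codon_panels.png", dpi=120)
    plt.close(fig)


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--datadir", default="results/data")
    ap.add_argument("--outdir", default="results")
    ap.add_argument("--plots", action="store_true")
    args = ap.parse_args()
    outdir = Path(args.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    print("codon-usage selection/mutation analysis")
    for tag in ("rep_like", "mutation_only", "selection_only"):
        analyze(tag, Path(args.datadir), outdir, args.plots)


if __name__ == "__main__":
    main()
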