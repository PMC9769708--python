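"""Codon-usage bias and the mutation-vs-selection decomposition.

Implements the standard synonymous-codon-usage toolkit for a set of coding
sequences:

* base composition, including positional GC (GC1, GC2, GC3), GC12 and GC3s
  (GC at synonymous third positions, i.e. excluding Met, Trp and stops);
* relative synonymous codon usage, RSCU_j = x_j / (N/k) within each
  synonymous family of size k (1 = no bias);
* Wright's effective number of codons, ENc ∈ [20, 61], from the family
  homozygosities F = (n·Σp² − 1)/(n − 1) averaged within degeneracy classes:
  ENc = 2 + 9/F̄2 + 1/F̄3 + 5/F̄4 + 3/F̄6;
* the ENc–GC3s null curve ENc_exp(s) = 2 + s + 29/(s² + (1−s)²), under
  which genes shaped by mutation pressure alone lie on the curve and genes
  under selection fall below it;
* the neutrality regression of GC12 on GC3 (percent scale): the slope is
  read as the share of mutational pressure, 1 − slope as selection;
* parity-rule-2 coordinates (G3/(G3+C3), A3/(A3+T3)), where (0.5, 0.5)
  means no strand/selection asymmetry at third positions.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .seqio import CodingSequence, GeneticCode, STANDARD_CODE

PR2_SITE_MODES = ("all", "fourfold")

ENC_MIN, ENC_MAX = 20.0, 61.0


@dataclass
class CodonUsageProfile:
    """Per-gene codon-usage statistics (percent scale for GC quantities)."""

    gene_id: str
    codon_counts: dict[str, int]
    base_fractions: dict[str, float]  # A, T, G, C over retained codon bases
    gc: float
    gc1: float
    gc2: float
    gc3: float
    gc12: float
    gc3s: float | None
    a3: int
    t3: int
    g3: int
    c3: int
    rscu: dict[str, float]  # NaN for unobserved families
    enc: float | None
    f_bar: dict[int, float | None]  # degeneracy class -> mean homozygosity


@dataclass(frozen=True)
class NeutralityResult:
    """OLS of GC12 on GC3; slope ≈ mutational share of codon-usage variation."""

    slope: float
    intercept: float
    pearson_r: float
    p_value: float
    n_genes: int

    @property
    def mutation_pct(self) -> float:
        return 100.0 * self.slope

    @property
    def selection_pct(self) -> float:
        return 100.0 * (1.0 - self.slope)


@dataclass(frozen=True)
class PR2Point:
    gene_id: str
    x: float | None  # G3/(G3+C3)
    y: float | None  # A3/(A3+T3)


@dataclass(frozen=True)
class ENcGC3sPoint:
    gene_id: str
    gc3s: float  # fraction in [0, 1]
    enc: float
    expected_enc: float
    residual: float


def _count_codons(cds: CodingSequence, code: GeneticCode) -> Counter:
    counts = Counter(cds.codons)
    unknown = set(counts) - set(code.codon_to_aa)
    if unknown:
        raise ValueError(f"gene {cds.id!r}: non-sense codon(s) {sorted(unknown)}")
    return counts


def base_composition(
    cds: CodingSequence,
    code: GeneticCode = STANDARD_CODE,
    pr2_sites: str = "all",
) -> dict:
    """Overall and positional composition of a CDS (over retained codons)."""
    if not cds.codons:
        raise ValueError(f"gene {cds.id!r}: empty codon list")
    if pr2_sites not in PR2_SITE_MODES:
        raise ValueError(f"unknown PR2 site mode {pr2_sites!r}")
    n = len(cds.codons)
    seq = cds.sequence
    total = len(seq)
    frac = {b: seq.count(b) / total for b in "ATGC"}
    gc = 100.0 * (frac["G"] + frac["C"])

    pos_gc = []
    for pos in range(3):
        bases = [c[pos] for c in cds.codons]
        pos_gc.append(100.0 * sum(b in "GC" for b in bases) / n)
    gc1, gc2, gc3 = pos_gc
    gc12 = (gc1 + gc2) / 2.0

    syn_third = [
        c[2] for c in cds.codons if code.degeneracy_of(c) >= 2
    ]
    gc3s = (
        100.0 * sum(b in "GC" for b in syn_third) / len(syn_third)
        if syn_third
        else None
    )

    if pr2_sites == "all":
        third = [c[2] for c in cds.codons]
    else:  # third positions of fourfold-degenerate families only
        third = [c[2] for c in cds.codons if code.degeneracy_of(c) == 4]
    third_counts = Counter(third)
    return {
        "base_fractions": frac,
        "gc": gc,
        "gc1": gc1,
        "gc2": gc2,
        "gc3": gc3,
        "gc12": gc12,
        "gc3s": gc3s,
        "a3": third_counts.get("A", 0),
        "t3": third_counts.get("T", 0),
        "g3": third_counts.get("G", 0),
        "c3": third_counts.get("C", 0),
    }


def rscu(counts: dict[str, int], code: GeneticCode = STANDARD_CODE) -> dict[str, float]:
    """RSCU_j = x_j / (N/k) per codon within its synonymous family.

    Families never observed get NaN; singleton families (Met, Trp) are
    excluded entirely.
    """
    if any(v < 0 for v in counts.values()):
        raise ValueError("codon counts must be non-negative")
    out: dict[str, float] = {}
    for aa, family in code.families.items():
        k = len(family)
        if k < 2:
            continue
        total = sum(counts.get(c, 0) for c in family)
        for c in family:
            out[c] = counts.get(c, 0) / (total / k) if total > 0 else math.nan
    return out


def family_homozygosity(counts: dict[str, int], code: GeneticCode = STANDARD_CODE):
    """Per-family F = (n·Σp² − 1)/(n − 1) for families with n ≥ 2 observations."""
    per_family: dict[str, float] = {}
    for aa, family in code.families.items():
        if len(family) < 2:
            continue
        obs = [counts.get(c, 0) for c in family]
        n = sum(obs)
        if n < 2:
            continue
        sum_p2 = sum((x / n) ** 2 for x in obs)
        f = (n * sum_p2 - 1.0) / (n - 1.0)
        per_family[aa] = f
    return per_family


def enc(
    counts: dict[str, int], code: GeneticCode = STANDARD_CODE
) -> tuple[float | None, dict[int, float | None]]:
    """Wright's effective number of codons with mean homozygosities per class.

    F̄k averages the defined, positive F over families of degeneracy k.
    Missing F̄3 is imputed as (F̄2 + F̄4)/2 and missing F̄6 as F̄4; the
    result is capped at 61 and is None when F̄2 or F̄4 is undefined.
    """
    per_family = family_homozygosity(counts, code)
    f_bar: dict[int, float | None] = {}
    for k in (2, 3, 4, 6):
        fs = [
            per_family[aa]
            for aa in code.degeneracy_classes.get(k, ())
            if aa in per_family and per_family[aa] > 0
        ]
        f_bar[k] = float(np.mean(fs)) if fs else None
    if f_bar[2] is None or f_bar[4] is None:
        return None, f_bar
    f3 = f_bar[3] if f_bar[3] is not None else (f_bar[2] + f_bar[4]) / 2.0
    f6 = f_bar[6] if f_bar[6] is not None else f_bar[4]
    value = 2.0 + 9.0 / f_bar[2] + 1.0 / f3 + 5.0 / f_bar[4] + 3.0 / f6
    return min(value, ENC_MAX), f_bar


def expected_enc(gc3s: float) -> float:
    """Null ENc under mutation pressure alone: 2 + s + 29/(s² + (1−s)²)."""
    if not 0.0 <= gc3s <= 1.0:
        raise ValueError(f"GC3s must be in [0, 1], got {gc3s}")
    return 2.0 + gc3s + 29.0 / (gc3s**2 + (1.0 - gc3s) ** 2)


def profile_gene(
    cds: CodingSequence,
    code: GeneticCode = STANDARD_CODE,
    pr2_sites: str = "all",
) -> CodonUsageProfile:
    """Full per-gene profile: composition, RSCU, ENc and PR2 counts."""
    counts = dict(_count_codons(cds, code))
    comp = base_composition(cds, code, pr2_sites=pr2_sites)
    enc_value, f_bar = enc(counts, code)
    return CodonUsageProfile(
        gene_id=cds.id,
        codon_counts=counts,
        base_fractions=comp["base_fractions"],
        gc=comp["gc"],
        gc1=comp["gc1"],
        gc2=comp["gc2"],
        gc3=comp["gc3"],
        gc12=comp["gc12"],
        gc3s=comp["gc3s"],
        a3=comp["a3"],
        t3=comp["t3"],
        g3=comp["g3"],
        c3=comp["c3"],
        rscu=rscu(counts, code),
        enc=enc_value,
        f_bar=f_bar,
    )


def pr2_point(profile: CodonUsageProfile) -> PR2Point:
    """PR2 coordinates; a coordinate is None when its denominator is zero."""
    gx = profile.g3 + profile.c3
    ay = profile.a3 + profile.t3
    return PR2Point(
        gene_id=profile.gene_id,
        x=profile.g3 / gx if gx else None,
        y=profile.a3 / ay if ay else None,
    )


def enc_gc3s_point(profile: CodonUsageProfile) -> ENcGC3sPoint | None:
    """ENc vs GC3s with the mutation-only expectation; None when either is NA."""
    if profile.enc is None or profile.gc3s is None:
        return None
    s = profile.gc3s / 100.0
    exp = expected_enc(s)
    return ENcGC3sPoint(
        gene_id=profile.gene_id,
        gc3s=s,
        enc=profile.enc,
        expected_enc=exp,
        residual=profile.enc - exp,
    )


def neutrality_regression(points: list[tuple[float, float]]) -> NeutralityResult:
    """OLS of GC12 on GC3 over per-gene (GC3, GC12) pairs on the percent scale."""
    if len(points) < 3:
        raise ValueError("neutrality regression needs at least 3 genes")
    arr = np.asarray(points, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("neutrality regression needs finite GC3/GC12 values")
    gc3, gc12 = arr[:, 0], arr[:, 1]
    if np.ptp(gc3) == 0:
        raise ValueError("GC3 has zero variance; slope undefined")
    fit = stats.linregress(gc3, gc12)
    rvalue = float(fit.rvalue)
    if math.isnan(rvalue) and np.ptp(gc12) == 0:
        rvalue = 0.0  # flat response: no correlation by convention
    return NeutralityResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        pearson_r=rvalue,
        p_value=float(fit.pvalue),
        n_genes=len(points),
    )


def neutrality_from_profiles(profiles: list[CodonUsageProfile]) -> NeutralityResult:
    return neutrality_regression([(p.gc3, p.gc12) for p in profiles])


def pooled_rscu(profiles: list[CodonUsageProfile], code: GeneticCode = STANDARD_CODE):
    """RSCU on codon counts summed over the whole dataset."""
    total: Counter = Counter()
    for p in profiles:
        total.update(p.codon_counts)
    return rscu(dict(total), code)


def summarize_dataset(
    profiles: list[CodonUsageProfile],
    code: GeneticCode = STANDARD_CODE,
) -> dict:
    """Dataset-level aggregates: mean ± SD of GC and ENc, pooled RSCU counts.

    Means use genes with defined values (NA counts are reported); SD uses
    the n−1 denominator. RSCU bias counts are computed on pooled codon
    counts: how many codons have pooled RSCU >1, <1, <0.7, >1.5.
    """
    if not profiles:
        raise ValueError("summarize_dataset needs at least one profile")
    gc = np.array([p.gc for p in profiles], dtype=float)
    enc_vals = np.array([p.enc for p in profiles if p.enc is not None], dtype=float)
    pooled = pooled_rscu(profiles, code)
    defined = {c: v for c, v in pooled.items() if not math.isnan(v)}
    return {
        "n_genes": len(profiles),
        "n_enc_na": len(profiles) - len(enc_vals),
        "gc_mean": float(gc.mean()),
        "gc_sd": float(gc.std(ddof=1)) if len(gc) > 1 else 0.0,
        "enc_mean": float(enc_vals.mean()) if len(enc_vals) else None,
        "enc_sd": float(enc_vals.std(ddof=1)) if len(enc_vals) > 1 else 0.0,
        "pooled_rscu": pooled,
        "n_rscu_gt_1": sum(v > 1.0 for v in defined.values()),
        "n_rscu_lt_1": sum(v < 1.0 for v in defined.values()),
        "n_rscu_lt_0p7": sum(v < 0.7 for v in defined.values()),
        "n_rscu_gt_1p5": sum(v > 1.5 for v in defined.values()),
    }


def profiles_table(profiles: list[CodonUsageProfile]) -> pd.DataFrame:
    """One row per gene: composition, GC metrics, ENc and PR2 coordinates."""
    rows = []
    for p in profiles:
        pr2 = pr2_point(p)
        rows.append(
            {
                "gene_id": p.gene_id,
                "n_codons": sum(p.codon_counts.values()),
                "A": p.base_fractions["A"],
                "T": p.base_fractions["T"],
                "G": p.base_fractions["G"],
                "C": p.base_fractions["C"],
                "GC": p.gc,
                "GC1": p.gc1,
                "GC2": p.gc2,
                "GC3": p.gc3,
                "GC12": p.gc12,
                "GC3s": p.gc3s,
                "ENc": p.enc,
                "PR2_x": pr2.x,
                "PR2_y": pr2.y,
            }
        )
    return pd.DataFrame(rows)


def rscu_table(profiles: list[CodonUsageProfile], code: GeneticCode = STANDARD_CODE):
    pooled = pooled_rscu(profiles, code)
    rows = [
        {"codon": c, "amino_acid": code.codon_to_aa[c], "rscu": v}
        for c, v in sorted(pooled.items())
    ]
    return pd.DataFrame(rows)
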