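# Methods

## Sequence handling

Protein records admit the 20 canonical amino acids plus X; nucleotide
records admit ACGT, N and the IUPAC ambiguity codes, with U mapped to T on
input. CDS validation requires length divisible by 3, trims (and flags) a
single terminal stop, and excludes codons containing non-ACGT characters,
counting them per gene. Internal stops are an error under the default
`strict` policy — curated CDS should be clean — and are excluded like
ambiguous codons under `lenient`. Genes with more than 10% excluded codons
(configurable) are dropped from aggregate summaries with a logged warning:
this preserves sample size while bounding composition noise. The genetic
code defaults to the standard code (NCBI table 1) and is configurable;
under it the 18 degenerate amino acids partition into nine 2-fold, one
3-fold, five 4-fold and three 6-fold synonymous families, with Met and Trp
singletons. The 6-fold amino acids (Leu, Ser, Arg) are treated as single
6-fold families rather than 2+4 splits.

## Similarity network

Pairwise scores are optimal Smith–Waterman local alignments under BLOSUM45
with affine gaps costing open + k·extend (defaults 15/2, the common gapped
setting for this matrix). E-values use the Karlin–Altschul form
E = K·m·n·e^(−λS) with m, n the raw sequence lengths: no edge-effect
correction is applied, which only shifts E by a smooth factor absorbed by
the edge threshold. P = 1 − e^(−E); reciprocal hits are merged keeping the
smaller P (which of min/mean/best the original CLANS protocol used is
unstated; min is the conservative merge and is order-independent).

λ and K come from a small built-in table keyed by (matrix, open, extend).
For gapped scoring no analytic values exist, so the shipped values were
calibrated by simulating thousands of local alignments of unrelated
uniform-composition 300-mers and fitting the Gumbel tail — and the fitted
decay was then deliberately halved (λ = 0.08, K = 0.022 for BLOSUM45
15/2). The per-pair m·n convention understates the multiplicity of an
all-vs-all network search (a database-style search space would be ~N times
larger), and at the standard P ≤ 10⁻² edge rule a perfectly calibrated
per-pair E-value would admit ~1% false edges — enough to bridge otherwise
clean components. The safety factor pushes the implied edge-score
threshold (~120 for 300-mers) far above the observed random-score maximum
(~100 over 4,000 simulated unrelated pairs) while leaving detection power
untouched: genuinely homologous pairs at 80% identity score ≥ 1,400, an
order of magnitude above the null. Both constants are overridable, and a
precomputed hit table (query, subject, E-value) can replace the built-in
aligner entirely.

Edge attraction is a = min(1, −log₁₀(max(P, 10⁻²⁰⁰))/200); the layout
moves each node by a linear spring along edges minus an inverse-distance
repulsion from all nodes, with the per-round displacement capped (defaults:
step 0.05, cap 0.3, repulsion 0.05). The layout is purely visual —
clustering never reads coordinates. Default clustering is connected
components (parameter-free, reproducible); the `network_offset` method
reassigns nodes to the cluster of maximal average attraction when that
average exceeds offset × the global mean edge attraction (default offset
1.0 — the original tool never states its value numerically), scanning
nodes in lexicographic order with ties to the lowest cluster index, for at
most 10,000 sweeps. Clusters below 10 members (configurable) are routed to
an unclustered pool.

## Domain organization

A conserved-domain database search is replaced by configurable motif
signatures, because everything downstream consumes only
presence/completeness calls. Defaults: HUH endonuclease motifs I–III
(`[FYWLIV]T[LIVF]`, `H[ILVMFYWAC]H`, `Y..[KR]`) constrained to the
N-terminal half (the endonuclease is canonically N-terminal, with the
midpoint as the half boundary), and Walker A/B (`[GA]....GK[ST]`,
`[ILVMFACW]{3}[DE][DE]`) allowed anywhere. Completeness is
operationalized as: Viral_Rep complete ⇔ ≥2 of the 3 endonuclease motifs;
P-loop complete ⇔ Walker A and B present with B starting within 120
residues after A ends. Exactly one motif of a domain ⇒ incomplete; a
Walker pair violating the spacing rule is also called incomplete (the
conservative reading). These cutoffs are stand-ins for partial
domain-database hits and are flagged as such (`motif_standin`) in outputs;
both are configurable. The (incomplete, incomplete) cell of the status
grid maps to the one-incomplete category, keeping the classification total.
A gap of more than 150 residues between the endonuclease and helicase
regions raises an "insert suspected" flag only; inserted domains are never
identified. The category→group map follows the published organization
scheme: both → {CRESSV1–3, Circoviridae, Circoviridae-related,
Nanoviridae}; Viral_Rep-only → {CRESSV4, CRESSV5}; P-loop-only →
{pCRESS-related}; none → {Smacoviridae, Smacoviridae-related,
outgroups 1–4}; one-incomplete → {CRESSV2-related, Nanoviridae}.

## Trees, concordance, crosstab

Maximum-likelihood phylogenetics is deliberately out of scope: every claim
checked here is topological (do clusters form clades), so neighbor joining
on d = 1 − (identical pairs / alignment columns) from the same local
aligner suffices, with no-hit pairs saturating at d = 1 and negative NJ
branch lengths clamped to 0. The NJ agglomeration is backed by scikit-bio
and is deterministic for a fixed input; tests verify exact recovery of
additive 4- and 8-taxon matrices against a brute-force least-squares
oracle. A cluster is concordant iff one tree edge separates exactly its
members; singletons are concordant by definition and excluded from the
reported fraction.

Because local-alignment identity is computed over the best-matching patch,
unrelated sequences do not sit at d = 1 exactly — short random patches
align at ~50% identity — which compresses the within/between separation
and makes tree concordance of planted families noisy (0.4–0.8 across
seeds) even when network clustering recovers them perfectly. This is a
property of patch-identity distances, not of the clustering; the
concordance statistic is reported as measured.

The recombination screen takes explicit genome→Cap-cluster and
genome→Rep-group maps (pairing Rep and Cap by shared genome id), counts
over genomes present in both, and flags Cap clusters spanning more than
one Rep group.

## Codon-usage statistics

GC3s excludes Met, Trp and stops from the third-position denominator; GC3
includes all sense codons — both symbols are standard and distinct. PR2
third-position counts default to all sense codons (matching the common
codon-usage toolchains); Sueoka's fourfold-degenerate-only site set is
available as an option. RSCU_j = x_j/(N/k); unobserved families give NA,
singleton families are excluded. ENc uses Wright's estimator with the
finite-sample homozygosity F = (nΣp² − 1)/(n − 1) per family (n ≥ 2, F > 0
required), class means F̄k, ENc = 2 + 9/F̄2 + 1/F̄3 + 5/F̄4 + 3/F̄6, a
missing F̄3 imputed as (F̄2 + F̄4)/2, a missing F̄6 imputed as F̄4 (the
nearest degeneracy class; in practice all three 6-fold amino acids are
common), NA if F̄2 or F̄4 is undefined, and a cap at 61. Note the n⁻¹
homozygosity correction makes ENc drift measurably with total counts
(≈0.26 per count-doubling at ~50 counts/codon), converging monotonically
to the proportion limit; dataset means are therefore tied to gene length.
Genes with NA ENc are excluded from dataset means and the exclusion count
is reported. Dataset RSCU bias counts (>1, <1, <0.7, >1.5) are computed on
pooled codon counts across genes, matching the one-profile-per-dataset
reporting convention of the standard tools; a per-gene-mean alternative
exists behind a flag. All regression quantities are on the percent scale
(0–100), which is what makes neutrality intercepts ~30 interpretable; the
neutrality fit is ordinary least squares of GC12 on GC3 with Pearson r and
a two-sided t-test p-value (r defined as 0 for a flat response).

## Synthetic generators

The protein-family generator draws an independent uniform-random consensus
per family and mutates each member i.i.d. at probability q to a uniformly
chosen different residue; expected within-family identity is
(1−q)² + q²/19. Defaults mirror the study conditions used throughout:
5 families × 20 members, length 300, q = 0.1 (≈81% within-family
identity, between-family ≈ random), plus a 9-member family to exercise the
minimum-size rule.

The mutation–selection CDS generator draws a per-gene mutational GC
pressure m ~ U(0.25, 0.75) and builds codons base-wise: third positions
are G/C with probability m (tracking mutation), first/second positions
with probability (1−w)m + wc for selection weight w and selective optimum
c = 0.5 (the protein-constraint proxy); G vs C and A vs T are
equiprobable, and stop codons are rejection-sampled so each gene has
exactly 300 codons (the default; 200 genes per dataset). The neutrality
slope then has analytic expectation (1−w) before attenuation; binomial
sampling of GC3 at L = 300 codons attenuates it by
Var(m)/(Var(m) + m(1−m)/L) ≈ 0.96. Measured slopes: w = 0 → ≈0.95,
w = 0.7 → ≈0.28–0.30 (the regime of real Rep genes), w = 1 → ≈0.
Selection weight 0.7 is the Rep-like default because it reproduces that
observed slope regime.

What the generator does *not* emulate: phylogenetic correlation between
genes, amino-acid-level fitness, and codon choice *within* synonymous
families. The mixture shapes GC12/GC3 covariation but leaves synonymous
usage near-uniform at a given GC, so synthetic ENc values stay high and do
not fall below the ENc–GC3s expectation the way selection-shaped real
genes do; the ENc–GC3s machinery is therefore validated on exact
identities (expected-curve reference points, boundary ENc values) rather
than on a planted below-curve signal. Passing tests demonstrate the
statistics and their decomposition logic, not realism of any particular
virus dataset.

## Determinism and problem sizes

Every stochastic component takes an explicit seed (numpy Generator);
identical config and seed give byte-identical outputs. Default analysis
sizes — 109 proteins per clustering run (~5,900 alignments, a few
seconds), 200×300-codon genes per codon dataset, 2,000 layout rounds —
were chosen so the full analysis and test suite run in about a minute on a
single CPU while keeping every statistical check well-powered.
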