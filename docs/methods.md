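# Methods

This note records the statistical definitions cubkit implements, the
conventions chosen where the literature is ambiguous, what the synthetic
data generator does and does not emulate, and the package's known
limitations.

## CDS filtering

Six predicates are checked in a fixed order: length ≥ `min_len`
(default 300 nt), length divisible by 3, ATG start, TAA/TAG/TGA stop, no
character outside ACGT, no internal stop codon. A rejected record is
attributed only to the *first* failing rule so reports are deterministic.
Divisibility by 3 is enforced explicitly even though it is implied by the
other conventions: codon decomposition requires it. The 300 nt threshold
is an exclusion bound for shorter sequences, so a sequence of exactly
300 nt is kept. Duplicate gene IDs (common in annotation dumps that
repeat isoform IDs) keep the first record and report later copies under a
separate `duplicate_id` rule. U is normalized to T so mRNA-style FASTA is
accepted. No isoform selection is attempted beyond this; input sets are
analyzed as given.

## Composition conventions

* **GC** — all positions of the CDS excluding the terminal stop codon.
* **GC1/GC2/GC3** — positional GC over all sense codons, ATG and TGG
  included.
* **GC3s, A3s..G3s** — third positions of synonymous codons only (the 18
  degenerate families; ATG, TGG, stops excluded). A3s is the plain
  fraction of synonymous codons ending in A, so A3s+T3s+C3s+G3s = 1.
  CodonW's historical per-availability normalization of these quantities
  is deliberately not replicated; small numeric differences from CodonW
  output are expected.
* **GC12** = (GC1 + GC2)/2.

## ENC

Wright's estimator with the classic class structure: 9 twofold, 1
threefold (Ile), 5 fourfold, and 3 sixfold families (Leu, Ser, Arg kept
whole rather than split 2+4). Families with total count ≤ 1 are excluded
from their class average. A missing threefold average is imputed as
(F̄₂+F̄₄)/2; any other missing class leaves ENC undefined (NaN, never an
exception). The raw value is clamped to [20, 61]; a class average of
exactly zero (perfectly even usage at tiny counts) maps to the 61 cap.

## CAI, CBI, FOP

CAI weights derive from a pooled reference of the lowest-ENC decile of
the same species — an internal high-expression proxy, chosen because the
pipeline is applied to genomes without expression data or an external
reference organism. Zero-count codons receive a 0.5 pseudocount before
normalization, so weights stay in (0, 1] and CAI is always defined for a
gene with ≥ 1 synonymous codon. CBI and FOP are computed over families
containing at least one optimal codon, with the optimal set taken from
the ΔRSCU procedure below (or supplied by the user).

## Mutation-vs-selection diagnostics

* Expected ENC under composition-only usage:
  `ENC_exp(s) = 2 + s + 29/(s² + (1−s)²)` with `s` = GC3s.
* Deviations `(ENC_exp − ENC_obs)/ENC_exp` are binned into the six
  conventional intervals from 0.3–0.4 down to −0.2–−0.1, half-open on
  the right (topmost closed), with an explicit out-of-range tally;
  percentages are rounded to 2 decimals.
* PR2 coordinates default to third positions of the five
  fourfold-degenerate families (Sueoka's parity convention); an
  all-synonymous-codons mode is available (`fourfold_only=False`) since
  usage varies between published analyses. The choice is recorded in the
  run manifest.
* The neutrality plot regresses GC12 on GC3 by ordinary least squares
  (scipy `linregress`), reporting slope, intercept, R², and the two-sided
  p-value for slope ≠ 0.
* The index-correlation matrix uses Pearson correlation by default
  (Spearman via config), pairwise deletion for missing values, and no
  multiple-testing correction — p-values are reported raw, as is
  customary for these descriptive panels; treat them accordingly.

## Correspondence analysis

CA runs on the gene × 59-codon RSCU matrix (not raw counts), matching
common practice for codon-usage ordinations. Standardized residuals
s_ij = (p_ij − r_i c_j)/√(r_i c_j) are decomposed by SVD; inertia
fractions are σ_k²/Σσ². Genes missing more than 10 of the 18 degenerate
families are excluded (configurable): zero-imputing many absent families
distorts the chi-square residuals. All-zero columns are dropped with a
warning. Axis signs are arbitrary in an SVD, so each axis is flipped if
needed to make its largest-magnitude column loading positive; repeated
runs on the same array are then identical. (Exact floating-point
reproducibility across different memory allocations of the same values is
BLAS-dependent; agreement is to ~1e-10.)

## Optimal codons

Genes sorted by ENC ascending (ties broken by gene ID); the lowest
⌊0.10·N⌋ form the high-expression library and the highest ⌊0.10·N⌋ the
low-expression library. Library RSCU comes from *pooled* counts, not
per-gene means. Calls use strict inequalities: high-frequency when
RSCU_high > 1, optimal when additionally ΔRSCU > 0.08. Fewer than 20
usable genes is an error (degenerate deciles). Stop-codon RSCU is
reported from pooled terminal stops treated as a 3-member family.

## Cross-species clustering

A species profile is the RSCU of summed codon counts over its kept genes
(pooling, not averaging, is what a single 59-value species table
implies), plus unweighted per-gene mean GC/GC3/GC3s. Euclidean distances
on either the 59-codon RSCU vector or the GC3 summary feed agglomerative
clustering; default linkage is average (UPGMA-like), configurable and
recorded in output metadata. Labels are sorted before linkage so results
are independent of input order; the dendrogram is serialized as Newick
with branch lengths derived from merge heights. Heatmap rendering is
left to downstream tools; the tested surface is the distance matrix and
tree. The tree is a usage-similarity dendrogram, not a phylogeny.

## Synthetic data generator

A snapshot generative model, not an evolutionary simulation. Per gene:

* a GC3 equilibrium `g` ~ Beta(α, β) models gene-to-gene mutational
  variation;
* amino acids are drawn i.i.d. from a fixed plant-like composition, and
  each residue's codon from
  `(1 − s)·mutation distribution + s·point mass on the family's
  preferred codon`, where the mutation distribution puts total mass `g`
  on the family's GC-ending codons and `1 − g` on its AT-ending codons
  (split evenly within each ending class). This makes the expected GC3s
  of every family exactly `g`;
* an optional high-expression class (fraction `high_fraction`) receives a
  larger selection strength `s_sel_high`;
* sequences are ATG + body + one stop drawn from TAA/TAG/TGA weights
  0.35/0.25/0.40 (a TGA-leaning usage typical of plant nuclear genomes);
  every simulated gene passes the CDS filter by construction, and equal
  (scenario, seed) pairs give byte-identical FASTA output.

In the **free amino-acid mode** used by the mutation-only preset, codon
probabilities are proportional to per-base weights at all three positions
(`g/2` for G/C, `(1−g)/2` for A/T at positions 1–2, family rule at
position 3), so amino-acid composition itself drifts with mutation
pressure. That is the textbook neutral regime in which GC12 tracks GC3
with slope near 1; with a fixed proteome GC12 barely responds to `g` and
the true neutrality slope is 0, so fixed-proteome scenarios exercise the
selection-dominated regime instead.

### Presets

| preset | n genes | lengths (codons) | GC3 eq. | selection |
|---|---|---|---|---|
| `mutation_only` | 2000 | 300–700 | Beta(25,25) | none (free aa mode) |
| `selection_dominated` | 2000 | 200–600 | Beta(8,11) | s = 0.5, A/T-ending set |
| `mixed` | 2000 | 200–600 | Beta(8,11) | s = 0.2 |
| `two_class_expression` | 1000 | 200–600 | Beta(8,11) | s = 0.05; 15% high class at s = 0.7 |
| `eight_species_panel` | 8 × 150 | 150–400 | dicots ~Beta(8,12), monocots ~Beta(11+,8) | s ≈ 0.2–0.3; clade-specific preferred sets |

The mutation-only preset centers its equilibrium on 0.5 — symmetric,
unbiased mutation pressure, which is also what makes its PR2 expectation
exactly (0.5, 0.5) — and uses longer genes (mean ~500 codons, i.e.
~1.5 kb CDS) so per-family sampling noise stays small relative to the
ENC–GC3s curve. The selection-flavored presets use an AT-shifted
equilibrium (mean GC3 ≈ 0.42) and gene lengths around 1.2 kb, the regime
typical of dicot nuclear genomes. The eight-species panel plants two
clades — five dicot-like species preferring A/T-ending codons and three
monocot-like species with higher GC3 preferring G/C-ending codons — with
small per-species parameter jitter within clades.

### What passing the simulation tests does and does not show

The generator emulates the *statistical signatures* the diagnostics are
designed to detect: composition-driven usage, preferred-codon selection
concentrated in a gene class, and clade-structured usage profiles. It
does not emulate amino-acid-composition constraints under selection,
gene-length/expression correlations, isochore structure, strand
asymmetries, or linkage between neighboring codons (codon-pair bias).
Recovery of planted parameters therefore validates the implementation and
the identifiability of each diagnostic under its intended regime — it
does not certify how sharply the same diagnostics separate forces in real
genomes, where effects are smaller and confounded.

## Numerical and degenerate-input choices

* Undefined statistics (ENC without computable classes, RSCU of absent
  families, PR2 with a zero denominator) are NaN flags, never exceptions;
  downstream stages pairwise-delete or impute as documented.
* RSCU of absent families is imputed as 0 only when building the CA
  matrix, where a dense matrix is required.
* ENC decile ties and clustering label ties are broken lexicographically.
* Pipeline tables are written with `%.6g` floats; two runs on identical
  inputs are checksum-identical (no stage consumes unseeded randomness).

## Problem sizes used in validation

The recovery studies run at the preset sizes above: 2000 genes for the
mutation-only and selection scenarios, 1000 for the two-class expression
scenario, and 100 seeded replicates of the 8 × 150-gene panel for
clustering recovery. Oracle-equivalence checks use 100 random codon
tables and 20 random 20 × 59 matrices.

## Known limitations

* CAI's internal lowest-ENC-decile reference is a proxy; with true
  expression data a user-supplied reference pool is preferable
  (`cai_weights` accepts any pooled table).
* ENC's 61-cap hides estimator overshoot for short genes; comparisons of
  near-unbiased short genes should use family counts directly.
* The correlation panel reports raw p-values (no multiplicity control).
* CA excludes highly incomplete genes rather than modeling missingness.
* The WRKY-style subset analysis expects a gene-ID list produced by
  external domain-search tooling; cubkit only applies the pipeline to the
  subset.
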