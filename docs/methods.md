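# Methods

## Scope and model

`amylatlas` operationalizes a genus-wide survey of the starch arms race in
*Streptomyces*-like cohorts: secreted amylases on one side, amylase
inhibitors (acarbose-like pseudooligosaccharides and tendamistat-like
peptides) on the other, and the association between them. The package
consumes the *outputs* of external annotation tools — CAZyme family
calls, signal-peptide calls, conserved-domain hits, ordered gene tables,
profile-HMM hit tables, alignments and trees — and never re-runs the
tools themselves. Alignments are consumed, not computed; tree support
labels are parsed and preserved verbatim, never interpreted as numbers.

## Secretome filter

A protein is a secreted amylase when three criteria hold, applied in
order:

1. **family** — the recommended CAZyme call contains GH13 after collapsing
   subfamily suffixes (GH13_32 → GH13); multi-family recommendations such
   as GH13 + CBM20 qualify. The recommended set is taken as authoritative
   because it already encodes the agreement between the two evidence
   sources; the per-source columns are retained for audit only.
2. **secretion** — a positive signal-peptide call. This separates
   extracellular amylases from cytoplasmic GH13 enzymes of trehalose and
   glycogen metabolism.
3. **domain** — at least one amylase-type or pullulanase-type conserved
   domain.

The two drop lists partition the GH13-recommended proteins that fail
exactly one criterion, with the signal criterion checked first. The
opposite order would move proteins failing both criteria from the
`no_signal` list to the `no_domain` list; the kept set is unaffected.

Clade typing uses domain content with precedence
pullulanase > cmd-like > α-1,4, because pullulanase-architecture proteins
carry an amylase catalytic domain *alongside* their pullulanase domains,
making the pullulanase domain the discriminating signal (the same logic
demotes the plain α-1,4 catalytic domain below the CMD-like one). The
domain vocabulary is an editable mapping; the defaults
(`pullul_strch`/`PUD` pullulanase-type; `AmyAc_bac_euk_AmyA` α-1,4;
`AmyAc_bac_CMD_like_2` CMD-like; `Aamy_C` amylase-accessory) cover the
three canonical clade architectures.

## Tree operations

**Midpoint rooting** places the root at the exact midpoint of the longest
leaf-to-leaf path (found by the double-sweep property of trees); after
rooting, the maximum root-to-leaf distance equals half the tree diameter
to 1e-9. Branch lengths are required on every edge; a single-leaf tree is
rejected.

**Clade extraction** is a greedy deepest-split rule: starting from one
clade (the whole rooted tree), k−1 cut edges are chosen; each step picks
the cut minimizing the maximum within-clade root-to-leaf span, with ties
broken by preorder position and cuts that would empty a clade
disallowed. This rule is an implementation choice — the number of clades
k is a parameter (default 3) and the rule is *not* claimed to reproduce
any particular published clade membership, which may have been drawn by
inspection. On trees whose between-clade stems are an order of magnitude
longer than within-clade branches it recovers the planted partition
exactly.

**Representatives** summarize a clade by the member most similar to the
clade consensus. The consensus takes the per-column majority residue,
ignoring gaps (an all-gap column emits `-`), ties to the
lexicographically smallest residue. Similarity is the fraction of
identical columns over positions ungapped in both sequences; ties go to
input order. Both tie-breaks make the selection deterministic.

## BGC neighborhood mining

Inhibitor clusters are sought as maximal runs of genes matching a query's
required ∪ optional role labels, allowing at most `max_gene_gap`
(default 5) non-matching genes between consecutive matches; a run
qualifies when it covers at least `required_fraction` (default 1.0) of
the required genes. The acarbose query requires the 15 *gac* core genes
of C₇N-aminocyclitol synthesis; amylases and known proteinaceous
inhibitors are optional members that extend the locus span.

Windows are counted in **genes, not base pairs**: the package's gene
model is ordinal (contig + gene rank), so base-pair windowing of the
homology-search tools it emulates is deliberately approximated by gene
ranks, and strand is ignored. Flanking amylases are counted inside the
locus span plus `flank_genes` (default 10) positions on either side,
clipped at contig boundaries. A locus is flagged as possibly truncated
when its span reaches within `max_gene_gap` genes of a contig boundary or
covers a gene annotated as lying at a contig edge.

Tendamistat-like carriage is a per-genome flag: at least one profile-HMM
hit with E-value ≤ 1e-10 (the conventional cutoff for this domain
search; configurable).

## Statistics

* **Fisher's exact test** (two-sided, probability-ordering convention):
  the p-value sums hypergeometric probabilities of all tables with the
  observed margins whose probability does not exceed the observed one; a
  relative tolerance of 1e-12 guards the ≤ comparison against
  floating-point ties. The reported odds ratio is the sample odds ratio
  ad/(bc), +∞ when bc = 0 < ad. Zero-margin tables are degenerate and
  return p = 1.
* **Mann–Whitney U** with midranks; the exact null distribution is used
  when the data are tie-free and C(n₁+n₂, n₁) ≤ 200,000, otherwise the
  tie-corrected normal approximation with continuity correction. The
  default effect size is the rank-biserial correlation
  r = 1 − 2U/(n₁n₂), signed so that r > 0 means the first (flagged) group
  has larger values; z/√N is available as an alternative definition since
  both conventions circulate and neither is claimed to match any
  particular published value. The distribution of counts is not tested
  for normality — the rank test is applied unconditionally.
* **χ²/φ** without Yates continuity correction by default (switchable);
  φ = sign(ad−bc)·√(χ²/n); zero-margin tables return χ² = 0, φ = 0,
  p = 1.
* **Multiple testing**: Benjamini–Hochberg step-up and Bonferroni, both
  always emitted; the family for the enrichment scan is *all* tested
  (column, residue) pairs of one alignment jointly.
* α = 0.05 throughout.

### Enrichment scan choices

Gapped sequences at a column are excluded from both margins by default
(`gap_policy="exclude"`); counting them as "without residue" is available
but conflates alignment uncertainty with residue absence. Pairs with
total residue count below `min_count` (default 3) are skipped to avoid
degenerate single-observation tables. Fold enrichment is
(a/n_A)/(c/n_B); when the comparison-group count c is zero, a
Haldane–Anscombe +0.5 is added to all cells (fold becomes
((a+0.5)/(n_A+1))/((0.5)/(n_B+1))), applied *only* in that case so that
finite folds are unperturbed. Columns are mapped to 1-based ungapped
positions of a named reference sequence; a hit where the reference
residue differs is labelled in standard substitution notation
(e.g. `H120N`).

The substitution census counts variant carriers at one column at either
sequence level or genome level (de-duplicating multi-copy genomes); the
two differ only when a genome carries two or more variant sequences.

## Synthetic cohorts

The generator emulates the study regime rather than real sequence
evolution. Defaults, chosen once to match the emulated cohort: 295
genomes; amylase counts 0–6 per genome from a base distribution with mean
2.2 (≈ 650 amylases genus-wide); BGC prevalence 12/295; tendamistat
prevalence 38/295; a planted cmd-like/tendamistat association of
φ = 0.16; genome sizes ~ N(8.5 Mb, 0.6 Mb). The generative model is:

1. BGC carriage ~ Bernoulli(p_bgc); counts of carriers are shifted by
   `amylase_count_shift_delta` (default 2) and clamped into 0..6 (with
   clamping switchable; disabling it rejects parameter sets that could
   overflow the regime).
2. cmd-like and tendamistat carriage are drawn *jointly* with the exact
   planted φ via the 2×2 cell probabilities
   p₁₁ = p₁p₂ + φ√(p₁(1−p₁)p₂(1−p₂)); a cmd-carrying genome always has
   at least one amylase (the cmd-like one), a small distortion of the
   count distribution accepted in exchange for exact φ planting.
3. remaining amylases split pullulanase vs α-1,4 by the renormalized
   clade mix.

BGC-carrying genomes receive the complete *gac* run mid-contig with 1–4
amylases (capped by the genome's count) placed immediately adjacent —
the planted flanking numbers that the neighborhood stage must recover.
Protein sequences are built from three fixed synthetic clade templates
(160 aa, not real proteins) plus i.i.d. point mutations at rate 0.05, so
clade identity and the alignment are exact by construction; BGC-adjacent
pullulanases carry a planted H→N substitution at template column 120
with probability 0.9. Each genome also carries decoy proteins exercising
every filter branch (GH13 without signal, secreted GH13 without an
informative domain, secreted non-GH13), and a fraction of
tendamistat-free genomes get weak above-cutoff HMM hits.

All randomness flows from the single `seed` parameter.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: phylogenetic sequence evolution (templates +
i.i.d. mutations, no substitution model, no indels), genome-scale FASTA,
base-pair coordinates, annotation-tool errors (family calls, secretion
calls and domains are planted noiselessly), horizontal transfer, or the
near-ubiquity of pullulanases and α-1,4-amylases in the real genus
(per-amylase clade assignment yields prevalences around 60–75% rather
than ~90%). Parameter-recovery results certify the *pipeline logic*, not
the upstream annotation quality.

## Problem sizes and numerics

The test suite and the acceptance script run at sizes chosen to make each
property measurable while staying lightweight: the Fisher oracle sweep
covers every 2×2 table with all margins ≤ 12 (5,550 tables,
exact-rational enumeration); Mann–Whitney exactness covers every tie-free
pair with n₁, n₂ ≤ 7 against full rank-arrangement enumeration, with the
normal approximation checked against the exact p at n₁ = n₂ = 30; null
calibration and power use 200 replicate cohorts of 295 genomes; the
enrichment-scan recovery uses alignments of 15 + 285 sequences × 400
columns with five planted sites at within-group frequencies 0.6 vs 0.04;
midpoint rooting is swept over 500 random 25-leaf trees. The
null-calibration check of the exact rank test uses n₁ = n₂ = 8, where the
attained two-sided level of the discrete exact test is 0.0499 — at most
other small sizes the attained level sits well below the nominal 0.05,
which would conflate discreteness with miscalibration.

Numerical tie-breaks are listed with their operations above; all are
deterministic, so every pipeline output is a pure function of (inputs,
configuration, seed), asserted byte-wise in the tests.

## Known limitations

* The clade-cut rule and the representative similarity metric are fixed,
  documented choices; other reasonable rules exist and may partition
  borderline trees differently.
* BGC detection is a role-label run model: it assumes role labels are
  already assigned in the gene table and does not perform homology
  search, does not discriminate acarbose from acarviostatin/trestatin
  chemistry, and measures distance in gene ranks.
* The enrichment scan treats columns independently; linkage between
  columns (shared phylogeny) inflates effective signal in real data and
  is not modelled.
* Exact Mann–Whitney p-values are conservative at very small sample
  sizes owing to the discreteness of the rank distribution.
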