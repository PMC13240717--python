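# amylatlas

Genus-wide mining of secreted amylases, amylase-inhibitor biosynthetic gene
clusters (BGCs) and candidate inhibitor-resistance substitutions in
*Streptomyces*-like genome cohorts.

## The problem

*Streptomyces* bacteria secrete amylases to break down environmental starch
and, in the same breath, synthesize amylase *inhibitors* — pseudo-
oligosaccharides such as acarbose, acarviostatin and trestatin, and small
peptides such as tendamistat — that handicap competitors. A genome-scale
view of this arms race requires answering, across hundreds of genomes:

1. which annotated proteins are genuine **secreted amylases** (CAZyme
   family GH13 with a signal peptide and an amylase/pullulanase domain);
2. how those amylases partition into **clades** — pullulanases,
   α-1,4-amylases and cyclomaltodextrin (CMD)-like amylases — on a
   midpoint-rooted phylogeny;
3. which genomes carry **inhibitor BGCs**, found as runs of required core
   genes (the *gac* genes of C₇N-aminocyclitol synthesis) in ordered gene
   tables, and how many amylase genes flank them;
4. whether inhibitor carriage **associates** with larger amylase
   repertoires, and which alignment columns are **enriched** for specific
   residues in inhibitor-associated amylases (candidate resistance
   substitutions, e.g. a catalytic histidine replaced by asparagine).

`amylatlas` implements this pipeline as a tested, reusable library and CLI.
Because the real inputs (hundreds of genome assemblies annotated with
external tools) are not desk-reproducible, the package ships a
synthetic-data generator that emulates the cohort with *planted* ground
truth — counts, flags, clades, BGC-adjacent amylases, enriched columns —
so every stage has a parameter-recovery test.

## Statistics

* count vs. flag: **Mann–Whitney U** with rank-biserial effect size
  r = 1 − 2U/(n₁n₂); exact null distribution when feasible, otherwise
  tie-corrected normal approximation with continuity correction;
* flag vs. flag: Pearson **χ²** on the 2×2 table with
  φ = sign(ad−bc)·√(χ²/n);
* column enrichment: two-sided **Fisher's exact test** per (column,
  residue) pair, corrected jointly by **Benjamini–Hochberg** and
  **Bonferroni**; fold enrichment (a/n_A)/(c/n_B) with a Haldane–Anscombe
  pseudocount when the comparison group count is zero;
* significance cutoff α = 0.05 throughout.

Every primitive is validated against an independent oracle (exact-rational
hypergeometric enumeration, full rank-arrangement enumeration, the step-up
formula) in the test suite.

## Worked example

```sh
amylatlas fixtures demo --seed 42 --n-genomes 60
amylatlas run demo demo_out
```

prints

```
fixtures written to demo
wrote 9 tables to demo_out
```

`demo_out/association_stats.tsv` then contains (seed 42):

```
test	statistic	p_value	effect_size
prevalence_pullulanase	75.0		
prevalence_alpha14	48.3333		
prevalence_cmd_like	23.3333		
mwu_total_amylases_vs_has_acarbose_bgc	409.0	0.00015191681384748223	0.7821350762527233
mwu_total_amylases_vs_has_tendamistat	256.5	0.9031745118258149	0.026000000000000023
chi2_cmd_like_vs_tendamistat	4.770186335403727	0.028956691473643062	0.28196295074009653
```

Reading: 75% of the 60 synthetic genomes encode at least one pullulanase;
genomes carrying an acarbose-like BGC have significantly more amylases
(rank-biserial r = 0.78, P = 1.5×10⁻⁴); the planted cmd-like/tendamistat
association is recovered as φ = 0.28 at this small cohort size. The
`enrichment.tsv` table lists every tested (column, residue) pair with its
2×2 counts, fold enrichment, raw/BH/Bonferroni p-values and the position
label in reference coordinates (e.g. `H120N`).

Stages can also be run separately (`mine`, `clades`, `bgc`, `associate`,
`scan`); see `amylatlas --help`.

## Layout

```
src/amylatlas/
  io.py            FASTA / aligned FASTA / Newick / TSV readers+writers
  simulate.py      synthetic cohorts, alignments and trees with planted truth
  secretome.py     GH13 filtering, signal/domain criteria, clade typing
  clades.py        midpoint rooting, clade extraction, consensus representatives
  stats.py         Fisher, Mann-Whitney, chi-square/phi, BH/Bonferroni
  neighborhood.py  required/optional-gene BGC detection, flanking counts
  associations.py  cohort summaries, association tests, enrichment scan
  pipeline.py      stage orchestration, config, manifest
  cli.py           the amylatlas command
```

See `docs/methods.md` for the model assumptions and design decisions.
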