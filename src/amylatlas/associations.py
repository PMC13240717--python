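"""Cohort-level association statistics and the MSA residue-enrichment scan.

The cohort table has one row per genome with amylase counts by clade and
boolean inhibitor flags (acarbose-like / acarviostatin / trestatin BGCs and
tendamistat carriage).  Count-vs-flag associations use the Mann-Whitney U
test with rank-biserial effect size; flag-vs-flag associations use the
chi-square test with phi.  The enrichment scan applies a two-sided Fisher's
exact test to every (alignment column, residue) pair, comparing inhibitor-
associated sequences (group A) against the rest (group B), corrects the
whole scan jointly by Benjamini-Hochberg and Bonferroni, and maps columns
onto ungapped coordinates of a named reference sequence so hits can be
reported in familiar residue notation (e.g. H235N).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from amylatlas.io import Alignment
from amylatlas.secretome import CLADES, AmylaseRecord
from amylatlas.stats import (
    BinaryAssociationResult,
    RankTestResult,
    TwoByTwo,
    benjamini_hochberg,
    bonferroni,
    chi_square_2x2,
    fisher_exact,
    mann_whitney_u,
)

GROUP_A = "A"  # inhibitor/BGC-associated sequences
GROUP_B = "B"

DEFAULT_MIN_COUNT = 3


@dataclass
class GenomeSummary:
    """Per-genome amylase repertoire and inhibitor flags."""

    genome_id: str
    amylase_counts: dict[str, int] = field(default_factory=dict)
    total_amylases: int = 0
    has_acarbose_bgc: bool = False
    has_acarviostatin_bgc: bool = False
    has_trestatin_bgc: bool = False
    has_tendamistat: bool = False
    genome_size_bp: int | None = None

    def __post_init__(self) -> None:
        if self.amylase_counts and self.total_amylases != sum(self.amylase_counts.values()):
            raise ValueError(f"{self.genome_id}: total_amylases inconsistent with per-clade counts")
        if any(v < 0 for v in self.amylase_counts.values()):
            raise ValueError(f"{self.genome_id}: negative amylase count")


@dataclass
class ColumnEnrichment:
    """One (MSA column, residue) enrichment result."""

    column: int  # 1-based
    residue: str
    table: TwoByTwo
    fold_enrichment: float
    p_raw: float
    p_bh: float = 1.0
    p_bonferroni: float = 1.0
    reference_position: int | None = None
    label: str = ""


# ---------------------------------------------------------------------------
# cohort summaries
# ---------------------------------------------------------------------------


def summarize_cohort(
    amylases: list[AmylaseRecord],
    bgc_flags: dict[str, dict[str, bool]] | None = None,
    tendamistat_flags: dict[str, bool] | None = None,
    genome_metadata: dict[str, int] | None = None,
    genome_ids=None,
) -> list[GenomeSummary]:
    """Build one :class:`GenomeSummary` row per genome.

    ``bgc_flags`` maps query name ("acarbose", "acarviostatin",
    "trestatin") to per-genome booleans; ``genome_metadata`` maps genome id
    to genome size in bp.  ``genome_ids`` fixes the cohort universe so
    genomes with zero amylases still get a row; by default the universe is
    the union of genomes seen in any input.  An amylase referencing a
    genome outside the universe is an error.
    """
    bgc_flags = bgc_flags or {}
    tendamistat_flags = tendamistat_flags or {}
    genome_metadata = genome_metadata or {}

    universe: set[str] = set(genome_ids) if genome_ids is not None else set()
    if genome_ids is None:
        universe |= {a.genome_id for a in amylases}
        for flags in bgc_flags.values():
            universe |= set(flags)
        universe |= set(tendamistat_flags)
        universe |= set(genome_metadata)
    else:
        unknown = {a.genome_id for a in amylases} - universe
        if unknown:
            raise ValueError(f"amylase(s) reference unknown genome(s): {', '.join(sorted(unknown))}")

    counts: dict[str, dict[str, int]] = {g: {c: 0 for c in CLADES} for g in sorted(universe)}
    for a in amylases:
        counts[a.genome_id].setdefault(a.clade, 0)
        counts[a.genome_id][a.clade] += 1

    return [
        GenomeSummary(
            genome_id=g,
            amylase_counts=dict(c),
            total_amylases=sum(c.values()),
            has_acarbose_bgc=bgc_flags.get("acarbose", {}).get(g, False),
            has_acarviostatin_bgc=bgc_flags.get("acarviostatin", {}).get(g, False),
            has_trestatin_bgc=bgc_flags.get("trestatin", {}).get(g, False),
            has_tendamistat=tendamistat_flags.get(g, False),
            genome_size_bp=genome_metadata.get(g),
        )
        for g, c in counts.items()
    ]


def clade_prevalence(summaries: list[GenomeSummary]) -> dict[str, float]:
    """Percentage of genomes carrying at least one amylase of each clade."""
    n = len(summaries)
    if n == 0:
        raise ValueError("empty cohort")
    return {
        clade: 100.0 * sum(1 for s in summaries if s.amylase_counts.get(clade, 0) > 0) / n
        for clade in CLADES
    }


def _get_field(summary: GenomeSummary, name: str):
    if name in summary.amylase_counts:
        return summary.amylase_counts[name]
    return getattr(summary, name)


def count_association(
    summaries: list[GenomeSummary], flag_field: str, count_field: str = "total_amylases"
) -> RankTestResult:
    """Mann-Whitney comparison of a count between flagged and unflagged genomes.

    r is signed so that positive means flagged genomes carry larger counts.
    Both groups must be non-empty.
    """
    flagged = [_get_field(s, count_field) for s in summaries if _get_field(s, flag_field)]
    unflagged = [_get_field(s, count_field) for s in summaries if not _get_field(s, flag_field)]
    if not flagged:
        raise ValueError(f"no genome has {flag_field} set")
    if not unflagged:
        raise ValueError(f"every genome has {flag_field} set")
    return mann_whitney_u(flagged, unflagged)


def binary_association(
    summaries: list[GenomeSummary], flag_a: str, flag_b: str
) -> BinaryAssociationResult:
    """Chi-square association between two boolean flags across genomes."""

    def as_bool(s: GenomeSummary, name: str) -> bool:
        return bool(_get_field(s, name))

    a = sum(1 for s in summaries if as_bool(s, flag_a) and as_bool(s, flag_b))
    b = sum(1 for s in summaries if as_bool(s, flag_a) and not as_bool(s, flag_b))
    c = sum(1 for s in summaries if not as_bool(s, flag_a) and as_bool(s, flag_b))
    d = sum(1 for s in summaries if not as_bool(s, flag_a) and not as_bool(s, flag_b))
    return chi_square_2x2(TwoByTwo(a, b, c, d))


# ---------------------------------------------------------------------------
# MSA enrichment scan
# ---------------------------------------------------------------------------


def map_column_to_reference(alignment: Alignment, reference_id: str, column: int) -> int | None:
    """1-based ungapped reference position of an alignment column, or None
    when the reference is gapped there."""
    ref = alignment[reference_id]
    if not 1 <= column <= alignment.length:
        raise IndexError(f"column {column} out of range 1..{alignment.length}")
    if ref[column - 1] == "-":
        return None
    return sum(1 for c in ref[:column] if c != "-")


def _fold_enrichment(a: int, n_a: int, c: int, n_b: int) -> float:
    # Haldane-Anscombe +0.5 on all cells only when the group-B count is zero
    if c == 0:
        return ((a + 0.5) / (n_a + 1)) / (0.5 / (n_b + 1))
    return (a / n_a) / (c / n_b)


def column_enrichment_scan(
    alignment: Alignment,
    group_labels: dict[str, str],
    reference_id: str,
    min_count: int = DEFAULT_MIN_COUNT,
    alpha: float = 0.05,
    gap_policy: str = "exclude",
) -> list[ColumnEnrichment]:
    """Fisher-exact residue enrichment of group A vs group B per column.

    For every (column, residue) whose total non-gap count is at least
    ``min_count``, builds the 2x2 table (group-A with residue, group-A
    without, group-B with, group-B without).  Under the default
    ``gap_policy="exclude"``, sequences gapped at the column are dropped
    from both margins; ``"count_absent"`` counts them as lacking the
    residue.  BH and Bonferroni are computed jointly over all tested pairs.
    Results are sorted by raw p-value.
    """
    ids = alignment.ids
    missing = [i for i in ids if i not in group_labels]
    if missing:
        raise ValueError(f"sequences without group label: {', '.join(missing[:5])}")
    if reference_id not in ids:
        raise ValueError(f"reference {reference_id!r} not in alignment")
    in_a = np.array([group_labels[i] == GROUP_A for i in ids])
    if in_a.all() or not in_a.any():
        raise ValueError("both groups must be non-empty")

    mat = np.array([list(r.residues) for r in alignment.records])
    results: list[ColumnEnrichment] = []
    for col in range(alignment.length):
        column = mat[:, col]
        non_gap = column != "-"
        if gap_policy == "exclude":
            mask_a = in_a & non_gap
            mask_b = ~in_a & non_gap
        elif gap_policy == "count_absent":
            mask_a, mask_b = in_a, ~in_a
        else:
            raise ValueError(f"unknown gap_policy {gap_policy!r}")
        n_a = int(mask_a.sum())
        n_b = int(mask_b.sum())
        if n_a == 0 or n_b == 0:
            continue
        residues, counts = np.unique(column[non_gap], return_counts=True)
        for residue, total in zip(residues, counts):
            if total < min_count:
                continue
            a = int(((column == residue) & mask_a).sum())
            c = int(((column == residue) & mask_b).sum())
            table = TwoByTwo(a, n_a - a, c, n_b - c)
            p_raw, _ = fisher_exact(table, "two_sided")
            results.append(
                ColumnEnrichment(
                    column=col + 1,
                    residue=str(residue),
                    table=table,
                    fold_enrichment=_fold_enrichment(a, n_a, c, n_b),
                    p_raw=p_raw,
                )
            )

    if results:
        p_bh = benjamini_hochberg([r.p_raw for r in results])
        p_bf = bonferroni([r.p_raw for r in results])
        ref_seq = alignment[reference_id]
        for r, bh, bf in zip(results, p_bh, p_bf):
            r.p_bh = float(bh)
            r.p_bonferroni = float(bf)
            r.reference_position = map_column_to_reference(alignment, reference_id, r.column)
            if r.reference_position is not None:
                ref_res = ref_seq[r.column - 1]
                if ref_res != r.residue:
                    r.label = f"{ref_res}{r.reference_position}{r.residue}"
                else:
                    r.label = f"{ref_res}{r.reference_position}"
    results.sort(key=lambda r: (r.p_raw, r.column, r.residue))
    return results


# ---------------------------------------------------------------------------
# substitution census
# ---------------------------------------------------------------------------


@dataclass
class SubstitutionCensus:
    sequence_counts: dict[str, int]  # group -> sequences carrying a variant
    genome_counts: dict[str, int]  # group -> genomes carrying >=1 variant
    table: TwoByTwo
    fold_enrichment: float
    p_value: float
    level: str


def substitution_census(
    alignment: Alignment,
    group_labels: dict[str, str],
    column: int,
    wildtype_residue: str,
    variant_residues,
    genome_of: dict[str, str] | None = None,
    level: str = "genome",
) -> SubstitutionCensus:
    """Census of sequences/genomes carrying a variant residue at a column.

    ``genome_of`` maps sequence id to genome id (identity by default, i.e.
    one sequence per genome).  At ``level="genome"`` the 2x2 table counts
    genomes with at least one variant-carrying sequence per group; at
    ``level="sequence"`` it counts sequences.  The Fisher p-value and the
    fold enrichment (with the zero-cell pseudocount rule) are computed at
    the chosen level.
    """
    variants = set(variant_residues)
    if not variants:
        raise ValueError("variant_residues must be non-empty")
    if wildtype_residue in variants:
        raise ValueError("wildtype residue cannot also be a variant")
    if level not in {"sequence", "genome"}:
        raise ValueError(f"unknown level {level!r}")
    genome_of = genome_of or {i: i for i in alignment.ids}

    seq_counts = {GROUP_A: 0, GROUP_B: 0}
    genome_variant: dict[str, set[str]] = {GROUP_A: set(), GROUP_B: set()}
    genome_all: dict[str, set[str]] = {GROUP_A: set(), GROUP_B: set()}
    seq_all = {GROUP_A: 0, GROUP_B: 0}
    for rec in alignment.records:
        grp = group_labels[rec.id]
        genome = genome_of[rec.id]
        seq_all[grp] += 1
        genome_all[grp].add(genome)
        if rec.residues[column - 1] in variants:
            seq_counts[grp] += 1
            genome_variant[grp].add(genome)

    genome_counts = {g: len(genome_variant[g]) for g in (GROUP_A, GROUP_B)}
    if level == "genome":
        a, na = genome_counts[GROUP_A], len(genome_all[GROUP_A])
        c, nb = genome_counts[GROUP_B], len(genome_all[GROUP_B])
    else:
        a, na = seq_counts[GROUP_A], seq_all[GROUP_A]
        c, nb = seq_counts[GROUP_B], seq_all[GROUP_B]
    table = TwoByTwo(a, na - a, c, nb - c)
    p, _ = fisher_exact(table, "two_sided")
    return SubstitutionCensus(
        sequence_counts=seq_counts,
        genome_counts=genome_counts,
        table=table,
        fold_enrichment=_fold_enrichment(a, na, c, nb),
        p_value=p,
        level=level,
    )
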