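"""Required/optional-gene cluster detection and flanking-amylase counting.

Inhibitor biosynthetic gene clusters (BGCs) are located by scanning ordered
per-contig gene tables for maximal runs of genes matching a query's
required or optional role labels, allowing up to ``max_gene_gap``
non-matching genes between consecutive matches.  A run qualifies as a locus
when it covers at least ``required_fraction`` of the query's required
genes.  The acarbose query's required roles are the core genes of
C7N-aminocyclitol synthesis, gacA/V/W/X/Y/U/S/R/K/I/Q/C/J/M/O; optional
roles include amylases and proteinaceous inhibitors from characterized
clusters.

Windows are counted in genes, not base pairs: the gene model here is
ordinal, so neighbourhoods are expressed as gene-rank offsets.  Strand is
ignored throughout.  Tendamistat-like peptide carriage is determined from
profile-HMM hit tables with an E-value cutoff (default 1e-10).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from amylatlas.io import GeneRow, HmmHit

#: gac core genes required for C7N-aminocyclitol synthesis
ACARBOSE_CORE_GENES = frozenset(
    f"gac{x}" for x in ("A", "V", "W", "X", "Y", "U", "S", "R", "K", "I", "Q", "C", "J", "M", "O")
)

DEFAULT_MAX_GENE_GAP = 5
DEFAULT_FLANK_GENES = 10
DEFAULT_REQUIRED_FRACTION = 1.0
DEFAULT_HMM_EVALUE_CUTOFF = 1e-10


@dataclass(frozen=True)
class BGCQuery:
    name: str
    required_genes: frozenset[str]
    optional_genes: frozenset[str] = frozenset()
    max_gene_gap: int = DEFAULT_MAX_GENE_GAP
    required_fraction: float = DEFAULT_REQUIRED_FRACTION

    def __post_init__(self) -> None:
        if not self.required_genes:
            raise ValueError("required_genes must be non-empty")
        if not 0 < self.required_fraction <= 1:
            raise ValueError("required_fraction must be in (0, 1]")


@dataclass
class BGCLocus:
    genome_id: str
    contig_id: str
    span: tuple[int, int]  # (first_gene_index, last_gene_index), inclusive
    matched_required: set[str] = field(default_factory=set)
    matched_optional: set[str] = field(default_factory=set)
    flanking_amylase_count: int = 0
    truncated_at_contig_edge: bool = False


def acarbose_query(**overrides) -> BGCQuery:
    """The default acarbose-like cluster query over the gac core genes."""
    params = dict(name="acarbose", required_genes=ACARBOSE_CORE_GENES)
    params.update(overrides)
    return BGCQuery(**params)


def _check_sorted(gene_table: list[GeneRow]) -> None:
    prev: tuple[str, str, int] | None = None
    for row in gene_table:
        key = (row.genome_id, row.contig_id, row.gene_index)
        if prev is not None and prev[:2] == key[:2] and key[2] <= prev[2]:
            raise ValueError(f"gene table not sorted by (contig, gene_index) at {row.protein_id}")
        prev = key


def find_bgc_loci(gene_table: list[GeneRow], query: BGCQuery) -> list[BGCLocus]:
    """Scan a sorted gene table for loci matching the query.

    A locus is a maximal run of genes whose role labels intersect the
    query's required or optional genes, with at most ``query.max_gene_gap``
    non-matching genes between consecutive matches, covering at least
    ``required_fraction`` of the required genes.  A locus whose span
    reaches within ``max_gene_gap`` genes of a contig boundary, or spans a
    gene flagged ``at_contig_edge``, is marked truncated.
    """
    _check_sorted(gene_table)
    targets = query.required_genes | query.optional_genes
    min_required = query.required_fraction * len(query.required_genes)

    # group rows per (genome, contig)
    contigs: dict[tuple[str, str], list[GeneRow]] = {}
    for row in gene_table:
        contigs.setdefault((row.genome_id, row.contig_id), []).append(row)

    loci: list[BGCLocus] = []
    for (genome, contig), rows in contigs.items():
        match_idx = [i for i, r in enumerate(rows) if r.role_labels & targets]
        if not match_idx:
            continue
        # segment matches into runs separated by <= max_gene_gap non-matches
        runs: list[list[int]] = [[match_idx[0]]]
        for i in match_idx[1:]:
            if i - runs[-1][-1] - 1 <= query.max_gene_gap:
                runs[-1].append(i)
            else:
                runs.append([i])
        for run in runs:
            members = [rows[i] for i in run]
            req = set().union(*(r.role_labels for r in members)) & query.required_genes
            if len(req) + 1e-9 < min_required:
                continue
            opt = set().union(*(r.role_labels for r in members)) & query.optional_genes
            first, last = rows[run[0]].gene_index, rows[run[-1]].gene_index
            contig_lo = rows[0].gene_index
            contig_hi = rows[-1].gene_index
            truncated = (
                first - contig_lo <= query.max_gene_gap
                or contig_hi - last <= query.max_gene_gap
                or any(r.at_contig_edge for r in members)
            )
            loci.append(
                BGCLocus(
                    genome_id=genome,
                    contig_id=contig,
                    span=(first, last),
                    matched_required=req,
                    matched_optional=opt,
                    truncated_at_contig_edge=truncated,
                )
            )
    return loci


def count_flanking_amylases(
    locus: BGCLocus,
    gene_table: list[GeneRow],
    flank_genes: int = DEFAULT_FLANK_GENES,
    amylase_role: str = "amylase",
) -> int:
    """Count amylase genes inside the locus span or within ``flank_genes``
    positions of either end, clipped at contig boundaries."""
    lo = locus.span[0] - flank_genes
    hi = locus.span[1] + flank_genes
    return sum(
        1
        for r in gene_table
        if r.genome_id == locus.genome_id
        and r.contig_id == locus.contig_id
        and lo <= r.gene_index <= hi
        and amylase_role in r.role_labels
    )


def annotate_flanking_amylases(
    loci: list[BGCLocus], gene_table: list[GeneRow], flank_genes: int = DEFAULT_FLANK_GENES
) -> list[BGCLocus]:
    for locus in loci:
        locus.flanking_amylase_count = count_flanking_amylases(locus, gene_table, flank_genes)
    return loci


def genome_bgc_flags(loci: list[BGCLocus], genome_ids) -> dict[str, bool]:
    """Per-genome boolean: does the genome carry at least one locus?"""
    with_locus = {l.genome_id for l in loci}
    return {g: g in with_locus for g in genome_ids}


def filter_tendamistat_hits(
    hits: list[HmmHit],
    cutoff: float = DEFAULT_HMM_EVALUE_CUTOFF,
    genome_ids=None,
) -> dict[str, bool]:
    """Flag genomes with at least one profile-HMM hit at or below the
    E-value cutoff (default 1e-10).

    ``genome_ids`` fixes the genome universe; by default it is the set of
    genomes appearing in the hit table.
    """
    if cutoff <= 0:
        raise ValueError("E-value cutoff must be positive")
    for h in hits:
        if h.e_value <= 0:
            raise ValueError(f"non-positive E-value on {h.protein_id}")
    universe = set(genome_ids) if genome_ids is not None else {h.genome_id for h in hits}
    flagged = {h.genome_id for h in hits if h.e_value <= cutoff}
    return {g: g in flagged for g in sorted(universe)}
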