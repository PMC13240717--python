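"""Synthetic cohorts, annotation tables, alignments and trees with planted
ground truth.

The generator emulates the study conditions of a genus-wide amylase survey:
a cohort of 295 genomes in which per-genome secreted-amylase counts range
from zero to six, a small fraction of genomes (about 4%) carry an
acarbose-like inhibitor BGC whose carriers have systematically more
amylases, roughly 13% of genomes encode a tendamistat-like peptide, and
carriage of a cyclomaltodextrin-like amylase is positively associated with
tendamistat.  Every planted quantity (counts, flags, clade identities,
BGC-adjacent amylase numbers, enriched alignment columns) is returned as
ground truth so downstream stages have parameter-recovery tests.

All randomness flows from the single ``seed`` field of the parameter
object; there is no hidden global state.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import dendropy
import numpy as np

from amylatlas.associations import GenomeSummary
from amylatlas.io import (
    Alignment,
    CazymeCall,
    DomainHit,
    GeneRow,
    HmmHit,
    SecretionCall,
    SequenceRecord,
)
from amylatlas.neighborhood import ACARBOSE_CORE_GENES
from amylatlas.secretome import (
    CLADE_ALPHA14,
    CLADE_CMD_LIKE,
    CLADE_PULLULANASE,
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: 1-based template column carrying the catalytic histidine whose
#: substitution to asparagine marks inhibitor resistance.
RESISTANCE_COLUMN = 120
TEMPLATE_LENGTH = 160

_CLADE_DOMAINS = {
    CLADE_PULLULANASE: ("pullul_strch", "AmyAc_bac_euk_AmyA"),
    CLADE_ALPHA14: ("AmyAc_bac_euk_AmyA",),
    CLADE_CMD_LIKE: ("AmyAc_bac_CMD_like_2", "Aamy_C"),
}

# default per-genome amylase-count distribution over 0..6 (mean 2.2,
# matching a cohort of ~295 genomes carrying ~645 amylases in total)
DEFAULT_COUNT_BASE = (0.10, 0.22, 0.30, 0.22, 0.10, 0.04, 0.02)


@dataclass(frozen=True)
class CohortParams:
    """Parameters of the synthetic genome cohort.

    Defaults mirror the study regime: 295 genomes, BGC prevalence 12/295,
    tendamistat prevalence 38/295, counts confined to 0..6, and a planted
    positive cmd-like/tendamistat association of phi = 0.16.
    """

    n_genomes: int = 295
    p_bgc: float = 12 / 295
    amylase_count_base: tuple[float, ...] = DEFAULT_COUNT_BASE
    amylase_count_shift_delta: int = 2
    clade_mix: dict[str, float] = field(
        default_factory=lambda: {CLADE_PULLULANASE: 0.44, CLADE_ALPHA14: 0.34, CLADE_CMD_LIKE: 0.22}
    )
    p_tendamistat: float = 38 / 295
    cmd_tendamistat_phi: float = 0.16
    genome_size_mean: float = 8.5e6
    genome_size_sd: float = 0.6e6
    clamp_counts: bool = True
    p_resistance: float = 0.9  # H->N at the resistance column, BGC-adjacent pullulanases
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.p_bgc < 1:
            raise ValueError("p_bgc must be in [0, 1)")
        if abs(sum(self.clade_mix.values()) - 1.0) > 1e-9:
            raise ValueError("clade_mix must sum to 1")
        if abs(sum(self.amylase_count_base) - 1.0) > 1e-9 or len(self.amylase_count_base) != 7:
            raise ValueError("amylase_count_base must be a 7-point distribution over 0..6")
        if self.amylase_count_shift_delta < 0:
            raise ValueError("shift delta must be >= 0")
        if not self.clamp_counts and self.amylase_count_shift_delta > 0:
            top = 6 + self.amylase_count_shift_delta
            if top > 6 and self.amylase_count_base[-1] > 0:
                raise ValueError(
                    "shift can push counts above 6 with clamping disabled; "
                    "enable clamp_counts or zero the upper tail of the base distribution"
                )


@dataclass(frozen=True)
class MsaParams:
    """Parameters of a two-group alignment with planted column effects."""

    n_group_a: int = 15
    n_group_b: int = 280
    n_columns: int = 400
    planted_columns: tuple[tuple[int, str, str, float, float], ...] = ()
    background_alphabet_frequencies: tuple[float, ...] | None = None  # uniform if None
    gap_probability: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        cols = [p[0] for p in self.planted_columns]
        if len(cols) != len(set(cols)):
            raise ValueError("planted columns must be distinct")
        for col, ra, rb, fa, fb in self.planted_columns:
            if not 1 <= col <= self.n_columns:
                raise ValueError(f"planted column {col} outside 1..{self.n_columns}")
            if not (0 <= fa <= 1 and 0 <= fb <= 1):
                raise ValueError("planted frequencies must lie in [0, 1]")
            if ra not in AMINO_ACIDS or rb not in AMINO_ACIDS:
                raise ValueError("planted residues must be amino acids")
        if not 0 <= self.gap_probability < 1:
            raise ValueError("gap_probability must be in [0, 1)")


@dataclass
class SyntheticCohort:
    """A generated cohort: ground truth plus every annotation artifact."""

    params: CohortParams
    summaries: list[GenomeSummary]
    gene_rows: list[GeneRow]
    cazyme_calls: list[CazymeCall]
    secretion_calls: list[SecretionCall]
    domain_hits: list[DomainHit]
    hmm_hits: list[HmmHit]
    proteins: list[SequenceRecord]
    amylase_clades: dict[str, str]  # protein id -> true clade
    planted_flank_counts: dict[str, int]  # genome id -> planted BGC-adjacent amylases
    resistant_proteins: set[str]  # protein ids carrying the H->N substitution


def clade_templates() -> dict[str, str]:
    """Three fixed clade template sequences (synthetic, not real proteins).

    Deterministic regardless of cohort seed; the pullulanase template
    carries 'H' at the resistance column.
    """
    rng = np.random.default_rng(915248)
    aas = np.array(list(AMINO_ACIDS))
    templates = {}
    for clade in (CLADE_PULLULANASE, CLADE_ALPHA14, CLADE_CMD_LIKE):
        seq = rng.choice(aas, size=TEMPLATE_LENGTH)
        seq[RESISTANCE_COLUMN - 1] = "H"
        templates[clade] = "".join(seq)
    return templates


def _mutate(template: str, rng: np.random.Generator, rate: float = 0.05,
            protect: tuple[int, ...] = (RESISTANCE_COLUMN,)) -> str:
    """Apply i.i.d. point mutations, never touching protected columns."""
    seq = list(template)
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in hits:
        if i + 1 in protect:
            continue
        choices = AMINO_ACIDS.replace(seq[i], "")
        seq[i] = choices[rng.integers(len(choices))]
    return "".join(seq)


# ---------------------------------------------------------------------------
# fast path: genome-level truth only
# ---------------------------------------------------------------------------


def _joint_bernoulli_probs(p1: float, p2: float, phi: float) -> tuple[float, float, float, float]:
    """Cell probabilities of two Bernoullis with given marginals and phi."""
    cov = phi * np.sqrt(p1 * (1 - p1) * p2 * (1 - p2))
    p11 = p1 * p2 + cov
    p10 = p1 - p11
    p01 = p2 - p11
    p00 = 1 - p11 - p10 - p01
    if min(p11, p10, p01, p00) < -1e-12:
        raise ValueError("requested phi incompatible with the marginals")
    return max(p11, 0.0), max(p10, 0.0), max(p01, 0.0), max(p00, 0.0)


def generate_summaries(params: CohortParams, rng: np.random.Generator | None = None) -> list[GenomeSummary]:
    """Draw the genome-level ground truth (counts, clades, flags, sizes).

    The generative model: BGC carriage ~ Bernoulli(p_bgc); the amylase
    count is drawn from the base distribution and shifted by delta for BGC
    carriers (clamped into 0..6 by default); cmd-like carriage and
    tendamistat carriage are drawn jointly with the planted phi; a genome
    drawn as cmd-carrying always has at least one amylase (the cmd-like
    one); remaining amylases split between pullulanase and alpha-1,4
    according to the renormalized clade mix.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n = params.n_genomes
    has_bgc = rng.random(n) < params.p_bgc
    counts = rng.choice(7, size=n, p=np.asarray(params.amylase_count_base))
    counts = counts + has_bgc * params.amylase_count_shift_delta
    if params.clamp_counts:
        counts = np.clip(counts, 0, 6)
    elif counts.max() > 6:
        raise ValueError("amylase count exceeded 6 with clamping disabled")

    p_cmd = params.clade_mix[CLADE_CMD_LIKE]
    p11, p10, p01, p00 = _joint_bernoulli_probs(p_cmd, params.p_tendamistat, params.cmd_tendamistat_phi)
    cell = rng.choice(4, size=n, p=[p11, p10, p01, p00])
    has_cmd = cell <= 1
    has_tend = (cell == 0) | (cell == 2)
    counts = np.maximum(counts, has_cmd.astype(int))

    p_pull = params.clade_mix[CLADE_PULLULANASE]
    p_alpha = params.clade_mix[CLADE_ALPHA14]
    frac_pull = p_pull / (p_pull + p_alpha)
    sizes = np.maximum(rng.normal(params.genome_size_mean, params.genome_size_sd, size=n), 1e6)

    summaries = []
    for i in range(n):
        n_cmd = int(has_cmd[i])
        n_rest = int(counts[i]) - n_cmd
        n_pull = int(rng.binomial(n_rest, frac_pull))
        summaries.append(
            GenomeSummary(
                genome_id=f"G{i:04d}",
                amylase_counts={
                    CLADE_PULLULANASE: n_pull,
                    CLADE_ALPHA14: n_rest - n_pull,
                    CLADE_CMD_LIKE: n_cmd,
                },
                total_amylases=int(counts[i]),
                has_acarbose_bgc=bool(has_bgc[i]),
                has_tendamistat=bool(has_tend[i]),
                genome_size_bp=int(sizes[i]),
            )
        )
    return summaries


# ---------------------------------------------------------------------------
# full cohort with annotation artifacts
# ---------------------------------------------------------------------------

_CONTIG_GENES = 60  # background genes per contig


def generate_cohort(params: CohortParams) -> SyntheticCohort:
    """Materialize a full synthetic cohort.

    BGC-carrying genomes receive the complete gac core-gene run placed
    contiguously in the middle of one contig with a planted number (1..4,
    capped by the genome's amylase count) of amylase genes immediately
    adjacent; the rest of the amylases are spread far apart on a second
    contig.  Every amylase gene has a GH13-recommended CAZyme call, a
    secreted signal-peptide call and its clade-defining conserved domains.
    Each genome also carries decoy proteins exercising every branch of the
    secretome filter: a non-secreted GH13 protein, a secreted GH13 protein
    without an informative domain, and a secreted non-GH13 CAZyme.
    BGC-adjacent pullulanases carry the planted H->N resistance
    substitution with probability ``p_resistance``.
    """
    rng = np.random.default_rng(params.seed)
    summaries = generate_summaries(params, rng)
    templates = clade_templates()

    gene_rows: list[GeneRow] = []
    cazymes: list[CazymeCall] = []
    secretions: list[SecretionCall] = []
    domains: list[DomainHit] = []
    hmm_hits: list[HmmHit] = []
    proteins: list[SequenceRecord] = []
    amylase_clades: dict[str, str] = {}
    planted_flanks: dict[str, int] = {}
    resistant: set[str] = set()

    gac_genes = sorted(ACARBOSE_CORE_GENES)

    for summary in summaries:
        g = summary.genome_id
        pid_counter = itertools.count(1)

        def new_pid() -> str:
            return f"{g}_p{next(pid_counter):03d}"

        # decide clade identity for each amylase
        clades = (
            [CLADE_PULLULANASE] * summary.amylase_counts[CLADE_PULLULANASE]
            + [CLADE_ALPHA14] * summary.amylase_counts[CLADE_ALPHA14]
            + [CLADE_CMD_LIKE] * summary.amylase_counts[CLADE_CMD_LIKE]
        )
        rng.shuffle(clades)

        if summary.has_acarbose_bgc and summary.total_amylases > 0:
            n_flank = int(min(summary.total_amylases, rng.integers(1, 5)))
            # prefer pullulanases in the BGC neighbourhood (resistance carriers)
            clades.sort(key=lambda c: c != CLADE_PULLULANASE)
            flank_clades = clades[:n_flank]
            rest_clades = clades[n_flank:]
        else:
            n_flank = 0
            flank_clades, rest_clades = [], list(clades)
        planted_flanks[g] = n_flank

        def add_amylase(clade: str, contig: str, index: int, in_bgc_flank: bool) -> str:
            pid = new_pid()
            seq = _mutate(templates[clade], rng)
            if in_bgc_flank and clade == CLADE_PULLULANASE and rng.random() < params.p_resistance:
                seq = seq[: RESISTANCE_COLUMN - 1] + "N" + seq[RESISTANCE_COLUMN:]
                resistant.add(pid)
            proteins.append(SequenceRecord(id=pid, residues=seq))
            amylase_clades[pid] = clade
            sub = "GH13_32" if rng.random() < 0.5 else "GH13"
            cazymes.append(CazymeCall(pid, {sub}, {sub}, {sub} if rng.random() < 0.7 else {sub, "CBM20"}))
            secretions.append(SecretionCall(pid, True, 0.99))
            for dom in _CLADE_DOMAINS[clade]:
                domains.append(DomainHit(pid, dom, 1, TEMPLATE_LENGTH, 1e-30))
            gene_rows.append(GeneRow(g, contig, index, pid, {"amylase"}, at_contig_edge=False))
            return pid

        # contig 1: background genes, optionally with the BGC + flanking amylases
        c1 = f"{g}_c1"
        bgc_start = 20
        occupied: dict[int, bool] = {}
        if summary.has_acarbose_bgc:
            for j, gac in enumerate(gac_genes):
                pid = new_pid()
                gene_rows.append(GeneRow(g, c1, bgc_start + j, pid, {gac}, at_contig_edge=False))
                occupied[bgc_start + j] = True
            pos = bgc_start + len(gac_genes)
            for clade in flank_clades:
                add_amylase(clade, c1, pos, in_bgc_flank=True)
                occupied[pos] = True
                pos += 1
        for idx in range(_CONTIG_GENES):
            if idx in occupied:
                continue
            pid = new_pid()
            gene_rows.append(GeneRow(g, c1, idx, pid, set(), at_contig_edge=idx in (0, _CONTIG_GENES - 1)))

        # contig 2: remaining amylases spread >= 10 genes apart + decoys
        c2 = f"{g}_c2"
        amylase_positions = [5 + 12 * j for j in range(len(rest_clades))]
        for clade, pos in zip(rest_clades, amylase_positions):
            add_amylase(clade, c2, pos, in_bgc_flank=False)
        n_c2 = max(_CONTIG_GENES, (amylase_positions[-1] + 5) if amylase_positions else _CONTIG_GENES)
        taken = set(amylase_positions)
        # decoy proteins
        decoys = []
        for idx in range(n_c2):
            if idx in taken:
                continue
            pid = new_pid()
            decoys.append(pid)
            gene_rows.append(GeneRow(g, c2, idx, pid, set(), at_contig_edge=idx in (0, n_c2 - 1)))
        d1, d2, d3 = decoys[:3]
        cazymes.append(CazymeCall(d1, {"GH13"}, {"GH13"}, {"GH13"}))  # GH13 but not secreted
        secretions.append(SecretionCall(d1, False, 0.01))
        domains.append(DomainHit(d1, "AmyAc_bac_euk_AmyA", 1, 100, 1e-20))
        cazymes.append(CazymeCall(d2, {"GH13"}, {"GH13"}, {"GH13"}))  # secreted, no informative domain
        secretions.append(SecretionCall(d2, True, 0.95))
        domains.append(DomainHit(d2, "FN3", 1, 90, 1e-8))
        cazymes.append(CazymeCall(d3, {"GH31"}, {"GH31"}, {"GH31"}))  # secreted non-amylase CAZyme
        secretions.append(SecretionCall(d3, True, 0.97))

        # tendamistat-like HMM hits: carriers get a strong hit, a random
        # subset of non-carriers gets a weak (above-cutoff) hit
        if summary.has_tendamistat:
            hmm_hits.append(HmmHit(f"{g}_tend", g, float(10.0 ** rng.uniform(-40, -12)), 120.0))
        elif rng.random() < 0.1:
            hmm_hits.append(HmmHit(f"{g}_weak", g, float(10.0 ** rng.uniform(-8, -2)), 15.0))

    gene_rows.sort(key=lambda r: (r.genome_id, r.contig_id, r.gene_index))
    return SyntheticCohort(
        params=params,
        summaries=summaries,
        gene_rows=gene_rows,
        cazyme_calls=cazymes,
        secretion_calls=secretions,
        domain_hits=domains,
        hmm_hits=hmm_hits,
        proteins=proteins,
        amylase_clades=amylase_clades,
        planted_flank_counts=planted_flanks,
        resistant_proteins=resistant,
    )


def cohort_alignment(cohort: SyntheticCohort) -> tuple[Alignment, dict[str, str]]:
    """The amylase protein alignment of a cohort with scan group labels.

    Template-derived sequences are equal-length, so stacking them yields a
    gap-free alignment.  Group A is the amylases of BGC-carrying genomes.
    """
    bgc_genomes = {s.genome_id for s in cohort.summaries if s.has_acarbose_bgc}
    amylase_ids = set(cohort.amylase_clades)
    records = [p for p in cohort.proteins if p.id in amylase_ids]
    labels = {p.id: ("A" if p.id.rsplit("_p", 1)[0] in bgc_genomes else "B") for p in records}
    return Alignment(records=records), labels


# ---------------------------------------------------------------------------
# MSA generator
# ---------------------------------------------------------------------------


def generate_msa(params: MsaParams) -> tuple[Alignment, dict[str, str]]:
    """Generate a two-group alignment with planted column-specific effects.

    At each planted column, group-A sequences carry ``residue_a`` with
    frequency ``freq_a`` and group-B sequences carry ``residue_b`` with
    frequency ``freq_b``; the complement in both groups is drawn from the
    background alphabet excluding the two planted residues, so the planted
    frequencies are exact in expectation (mirroring a resistance
    substitution concentrated in inhibitor-associated sequences).
    Background columns are i.i.d. draws from the background frequencies,
    gapped with ``gap_probability``; planted columns are never gapped.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_group_a + params.n_group_b
    aas = np.array(list(AMINO_ACIDS))
    freqs = (
        np.asarray(params.background_alphabet_frequencies)
        if params.background_alphabet_frequencies is not None
        else np.full(len(aas), 1 / len(aas))
    )
    if len(freqs) != len(aas) or abs(freqs.sum() - 1) > 1e-9:
        raise ValueError("background frequencies must be a distribution over the 20 amino acids")

    mat = rng.choice(aas, size=(n, params.n_columns), p=freqs)
    if params.gap_probability > 0:
        gaps = rng.random((n, params.n_columns)) < params.gap_probability
        mat[gaps] = "-"

    in_a = np.arange(n) < params.n_group_a
    for col, res_a, res_b, freq_a, freq_b in params.planted_columns:
        j = col - 1
        others = np.array([c for c in AMINO_ACIDS if c not in (res_a, res_b)])
        bg = rng.choice(others, size=n)
        draw = rng.random(n)
        freq = np.where(in_a, freq_a, freq_b)
        planted_res = np.where(in_a, res_a, res_b)
        mat[:, j] = np.where(draw < freq, planted_res, bg)

    records, labels = [], {}
    for i in range(n):
        sid = f"{'A' if in_a[i] else 'B'}_{i:04d}"
        records.append(SequenceRecord(id=sid, residues="".join(mat[i])))
        labels[sid] = "A" if in_a[i] else "B"
    return Alignment(records=records), labels


# ---------------------------------------------------------------------------
# random trees
# ---------------------------------------------------------------------------


def generate_tree(n_leaves: int, seed: int, mean_branch_length: float = 0.1) -> dendropy.Tree:
    """A random unrooted binary tree with exponential branch lengths.

    Built by sequential random edge attachment, giving 2n-3 edges for n
    leaves; the Newick string is deterministic given the seed.
    """
    if n_leaves < 3:
        raise ValueError("need at least 3 leaves for an unrooted tree")
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace([f"t{i}" for i in range(1, n_leaves + 1)])
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.is_rooted = False

    def blen() -> float:
        return float(rng.exponential(mean_branch_length))

    leaves = []
    for i in range(3):
        node = dendropy.Node(taxon=taxa[i], edge_length=blen())
        tree.seed_node.add_child(node)
        leaves.append(node)
    edges = list(tree.seed_node.child_nodes())  # nodes whose parent edge can be split
    for i in range(3, n_leaves):
        target = edges[rng.integers(len(edges))]
        parent = target.parent_node
        mid = dendropy.Node(edge_length=target.edge.length / 2)
        parent.remove_child(target)
        parent.add_child(mid)
        target.edge.length = target.edge.length / 2
        mid.add_child(target)
        leaf = dendropy.Node(taxon=taxa[i], edge_length=blen())
        mid.add_child(leaf)
        edges.extend([mid, leaf])
    return tree


def generate_clade_tree(
    n_per_clade: tuple[int, int, int],
    seed: int,
    within_scale: float = 0.05,
    separation: float = 0.5,
) -> tuple[dendropy.Tree, dict[str, int]]:
    """A tree of three well-separated clades with known membership.

    Between-clade stem branches are ``separation`` long (default 10x the
    within-clade branch scale), so a k=3 cut recovers the planted groups.
    Returns the tree and the leaf -> clade-index (1..3) ground truth.
    Empty clades are skipped; at least two must be non-empty.
    """
    if sum(1 for n in n_per_clade if n > 0) < 2:
        raise ValueError("need at least two non-empty clades")
    rng = np.random.default_rng(seed)
    labels = {
        f"c{ci + 1}_l{j + 1}": ci + 1 for ci in range(3) for j in range(n_per_clade[ci])
    }
    taxa = dendropy.TaxonNamespace(sorted(labels))
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.is_rooted = False

    def build_subtree(leaf_names: list[str]) -> dendropy.Node:
        if len(leaf_names) == 1:
            taxon = taxa.get_taxon(leaf_names[0])
            return dendropy.Node(taxon=taxon, edge_length=float(rng.exponential(within_scale)))
        split = int(rng.integers(1, len(leaf_names)))
        node = dendropy.Node(edge_length=float(rng.exponential(within_scale)))
        node.add_child(build_subtree(leaf_names[:split]))
        node.add_child(build_subtree(leaf_names[split:]))
        return node

    for ci in range(3):
        names = [l for l, c in sorted(labels.items()) if c == ci + 1]
        if not names:
            continue
        sub = build_subtree(names)
        sub.edge.length = separation
        tree.seed_node.add_child(sub)
    return tree, labels


# ---------------------------------------------------------------------------
# census fixture
# ---------------------------------------------------------------------------


def make_substitution_fixture(
    n_group_a_genomes: int = 12,
    n_group_b_genomes: int = 100,
    variant_a: tuple[int, int] = (7, 6),
    variant_b_genomes: int = 11,
    seed: int = 0,
) -> tuple[Alignment, dict[str, str], dict[str, str]]:
    """An alignment mirroring the resistance-substitution census structure.

    Group A (BGC-carrying genomes) contains exactly ``variant_a[0]``
    variant ('N') sequences spread over ``variant_a[1]`` genomes; exactly
    ``variant_b_genomes`` group-B genomes carry one variant sequence each.
    Every genome contributes two pullulanase sequences, wildtype 'H' at the
    resistance column unless planted otherwise.  Returns the alignment,
    group labels, and the sequence -> genome map.
    """
    n_var_seq, n_var_genomes = variant_a
    if n_var_seq < n_var_genomes or n_var_genomes > n_group_a_genomes:
        raise ValueError("infeasible variant placement in group A")
    if variant_b_genomes > n_group_b_genomes:
        raise ValueError("infeasible variant placement in group B")
    rng = np.random.default_rng(seed)
    template = clade_templates()[CLADE_PULLULANASE]

    records, labels, genome_of = [], {}, {}

    def add(genome: str, group: str, k: int, variant: bool) -> None:
        sid = f"{genome}_s{k}"
        seq = _mutate(template, rng)
        residue = "N" if variant else "H"
        seq = seq[: RESISTANCE_COLUMN - 1] + residue + seq[RESISTANCE_COLUMN:]
        records.append(SequenceRecord(id=sid, residues=seq))
        labels[sid] = group
        genome_of[sid] = genome

    # spread the A-group variant sequences: one genome gets the extra copy
    extra = n_var_seq - n_var_genomes
    for i in range(n_group_a_genomes):
        genome = f"A{i:03d}"
        n_var_here = 0
        if i < n_var_genomes:
            n_var_here = 1 + (extra if i == 0 else 0)
        for k in range(2):
            add(genome, "A", k, variant=k < n_var_here)
    for i in range(n_group_b_genomes):
        genome = f"B{i:03d}"
        for k in range(2):
            add(genome, "B", k, variant=(i < variant_b_genomes and k == 0))
    return Alignment(records=records), labels, genome_of
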