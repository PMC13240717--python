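"""Reduction of all annotated proteins to the set of secreted amylases.

Amylases belong to CAZyme family GH13.  A protein is retained when (i) GH13
is among its recommended family calls, with subfamily suffixes collapsed
(GH13_32 counts as GH13) and multi-family recommendations such as
GH13 + CBM20 accepted; (ii) it carries a secretion signal peptide, which
separates extracellular amylases from cytoplasmic GH13 enzymes of trehalose
and glycogen metabolism; and (iii) it carries at least one amylase-type or
pullulanase-type conserved domain.  The signal criterion is checked before
the domain criterion, so the audit lists report proteins dropped at the
first stage they fail.

Retained amylases are typed into one of three clades by domain content:
pullulanases (clade 1), alpha-1,4-acting amylases (clade 2) and
cyclomaltodextrin (CMD)-like amylases (clade 3).  Pullulanase-type domains
take precedence because clade-1 architectures carry an amylase catalytic
domain alongside their pullulanase domains, making the pullulanase domain
the discriminating signal; CMD-like takes precedence over plain alpha-1,4
for the same reason.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from amylatlas.io import CazymeCall, DomainHit, GeneRow, SecretionCall

CLADE_PULLULANASE = "pullulanase"
CLADE_ALPHA14 = "alpha14"
CLADE_CMD_LIKE = "cmd_like"
CLADE_UNASSIGNED = "unassigned"

CLADES = (CLADE_PULLULANASE, CLADE_ALPHA14, CLADE_CMD_LIKE)

_FAMILY_RE = re.compile(r"^([A-Za-z]+[0-9]+)(_[0-9]+)?$")


@dataclass(frozen=True)
class DomainVocabulary:
    """Maps conserved-domain names to functional classes.

    Defaults follow the canonical clade-defining architectures:
    ``pullul_strch`` / ``PUD`` are pullulanase-type; ``AmyAc_bac_euk_AmyA``
    is the alpha-1,4 amylase catalytic domain; ``AmyAc_bac_CMD_like_2`` is
    the catalytic domain of bacterial cyclomaltodextrinases; ``Aamy_C`` is
    an amylase-type accessory domain that defines no clade on its own.
    """

    pullulanase_domains: frozenset[str] = frozenset({"pullul_strch", "PUD"})
    cmd_domains: frozenset[str] = frozenset({"AmyAc_bac_CMD_like_2"})
    alpha14_domains: frozenset[str] = frozenset({"AmyAc_bac_euk_AmyA"})
    other_amylase_domains: frozenset[str] = frozenset({"Aamy_C"})

    @property
    def amylase_type(self) -> frozenset[str]:
        return self.cmd_domains | self.alpha14_domains | self.other_amylase_domains


DEFAULT_VOCABULARY = DomainVocabulary()


@dataclass
class AmylaseRecord:
    """A retained secreted amylase with its genomic locus and clade."""

    protein_id: str
    genome_id: str
    clade: str
    domain_names: set[str] = field(default_factory=set)
    locus: tuple[str, int] | None = None  # (contig_id, gene_index)


def collapse_family(family: str) -> str:
    """Collapse a CAZyme subfamily to its family: GH13_32 -> GH13."""
    m = _FAMILY_RE.match(family)
    if not m:
        raise ValueError(f"malformed CAZyme family string {family!r}")
    return m.group(1)


def is_recommended_gh13(call: CazymeCall) -> bool:
    """True iff GH13 (after subfamily collapse) is in the recommended set.

    Multi-family recommendations containing GH13 (e.g. GH13 + CBM20)
    qualify; an empty recommended set does not.
    """
    return any(collapse_family(f) == "GH13" for f in call.recommended)


def assign_clade(domain_names: set[str], vocabulary: DomainVocabulary = DEFAULT_VOCABULARY) -> str:
    """Type an amylase by its conserved domains.

    Precedence: pullulanase > cmd_like > alpha14; unassigned when no
    clade-defining domain is present.
    """
    if not domain_names:
        raise ValueError("domain_names must be non-empty")
    if domain_names & vocabulary.pullulanase_domains:
        return CLADE_PULLULANASE
    if domain_names & vocabulary.cmd_domains:
        return CLADE_CMD_LIKE
    if domain_names & vocabulary.alpha14_domains:
        return CLADE_ALPHA14
    return CLADE_UNASSIGNED


def filter_secreted_amylases(
    calls: list[CazymeCall],
    secretion_calls: list[SecretionCall],
    domain_hits: list[DomainHit],
    vocabulary: DomainVocabulary = DEFAULT_VOCABULARY,
    gene_rows: list[GeneRow] | None = None,
) -> tuple[list[AmylaseRecord], list[str], list[str]]:
    """Apply the three-stage secretome filter.

    Returns ``(kept, dropped_no_signal, dropped_no_domain)``.  The three
    lists partition the GH13-recommended proteins; the signal-peptide
    criterion is applied before the domain criterion, so a protein failing
    both is reported in ``dropped_no_signal``.  A GH13-recommended protein
    missing from the secretion table is an annotation-consistency error.

    When ``gene_rows`` is supplied, each kept record is stamped with its
    genome id and (contig, gene_index) locus.
    """
    secreted = {s.protein_id: s.is_secreted for s in secretion_calls}
    domains: dict[str, set[str]] = {}
    for h in domain_hits:
        domains.setdefault(h.protein_id, set()).add(h.domain_name)
    locus_of: dict[str, GeneRow] = {}
    if gene_rows is not None:
        locus_of = {g.protein_id: g for g in gene_rows}

    kept: list[AmylaseRecord] = []
    dropped_no_signal: list[str] = []
    dropped_no_domain: list[str] = []
    informative = vocabulary.pullulanase_domains | vocabulary.amylase_type

    for call in calls:
        if not is_recommended_gh13(call):
            continue
        pid = call.protein_id
        if pid not in secreted:
            raise ValueError(f"GH13 protein {pid} absent from secretion table (incomplete annotation)")
        if not secreted[pid]:
            dropped_no_signal.append(pid)
            continue
        doms = domains.get(pid, set())
        if not doms & informative:
            dropped_no_domain.append(pid)
            continue
        row = locus_of.get(pid)
        kept.append(
            AmylaseRecord(
                protein_id=pid,
                genome_id=row.genome_id if row else "",
                clade=assign_clade(doms, vocabulary),
                domain_names=doms,
                locus=(row.contig_id, row.gene_index) if row else None,
            )
        )
    return kept, dropped_no_signal, dropped_no_domain
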