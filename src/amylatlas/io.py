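"""Readers and writers for the external formats the pipeline consumes.

Sequence data travel as FASTA (plain or aligned), trees as Newick with
support values kept verbatim as internal-node labels, and annotation tables
as header-carrying TSV.  The TSV dialects mirror the merged "overview"-style
outputs of CAZyme annotators, signal-peptide predictors, conserved-domain
searches and ``hmmsearch`` tabular output; native files from specific tool
versions are expected to be column-mapped onto these schemas upstream.

All residue and column coordinates are 1-based inclusive.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger(__name__)

_FAMILY_RE = re.compile(r"^[A-Za-z]+[0-9]+(_[0-9]+)?$")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class SequenceRecord:
    """One protein (or aligned) sequence.

    ``residues`` is an uppercase amino-acid string; ``-`` is permitted only
    when the record belongs to an alignment.
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise FormatError(f"sequence id must be non-empty and whitespace-free: {self.id!r}")
        if not self.residues:
            raise FormatError(f"sequence {self.id!r} has empty residues")


@dataclass
class Alignment:
    """A rectangular multiple sequence alignment."""

    records: list[SequenceRecord]
    length: int = 0

    def __post_init__(self) -> None:
        if not self.records:
            raise FormatError("alignment has no records")
        lengths = {len(r.residues) for r in self.records}
        if len(lengths) != 1:
            bad = sorted({r.id for r in self.records if len(r.residues) != len(self.records[0].residues)})
            raise FormatError(f"ragged alignment; offending ids: {', '.join(bad)}")
        self.length = len(self.records[0].residues)
        if self.length < 1:
            raise FormatError("alignment length must be >= 1")

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def __getitem__(self, seq_id: str) -> str:
        for r in self.records:
            if r.id == seq_id:
                return r.residues
        raise KeyError(seq_id)

    def column(self, col: int) -> str:
        """Residues of 1-based column ``col``, in record order."""
        if not 1 <= col <= self.length:
            raise IndexError(f"column {col} out of range 1..{self.length}")
        return "".join(r.residues[col - 1] for r in self.records)


@dataclass
class CazymeCall:
    """CAZyme family calls for one protein from two evidence sources plus the
    tool's recommended (agreed) family set."""

    protein_id: str
    hmmer_families: set[str] = field(default_factory=set)
    diamond_families: set[str] = field(default_factory=set)
    recommended: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for fam in self.hmmer_families | self.diamond_families | self.recommended:
            if not _FAMILY_RE.match(fam):
                raise FormatError(f"malformed CAZyme family {fam!r} for protein {self.protein_id}")


@dataclass
class SecretionCall:
    protein_id: str
    is_secreted: bool
    probability: float | None = None

    def __post_init__(self) -> None:
        if self.probability is not None and not 0.0 <= self.probability <= 1.0:
            raise FormatError(f"secretion probability out of [0,1]: {self.probability}")


@dataclass
class DomainHit:
    """A conserved-domain hit on a protein, 1-based inclusive coordinates."""

    protein_id: str
    domain_name: str
    start: int
    end: int
    e_value: float

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise FormatError(f"bad domain coordinates {self.start}..{self.end} on {self.protein_id}")
        if self.e_value <= 0:
            raise FormatError(f"non-positive E-value {self.e_value} on {self.protein_id}")


@dataclass
class GeneRow:
    """One gene in the ordered per-contig gene table."""

    genome_id: str
    contig_id: str
    gene_index: int
    protein_id: str
    role_labels: set[str] = field(default_factory=set)
    at_contig_edge: bool = False


@dataclass
class HmmHit:
    protein_id: str
    genome_id: str
    e_value: float
    score: float

    def __post_init__(self) -> None:
        if self.e_value <= 0:
            raise FormatError(f"non-positive E-value {self.e_value} on {self.protein_id}")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    Duplicate ids and empty files are rejected.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description.startswith(rec.id) else rec.description
        records.append(SequenceRecord(id=rec.id, residues=str(rec.seq).upper(), description=desc))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(records: list[SequenceRecord], path, width: int = 60) -> None:
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def read_alignment(path) -> Alignment:
    """Read an aligned FASTA file; gap character ``-`` allowed."""
    return Alignment(records=read_fasta(path))


def write_alignment(alignment: Alignment, path) -> None:
    write_fasta(alignment.records, path)


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------


def read_newick(path) -> dendropy.Tree:
    """Parse a Newick tree.

    Internal-node labels (bootstrap support strings) are preserved verbatim
    and never converted to numbers.  Leaf labels must be unique.
    """
    try:
        tree = dendropy.Tree.get(
            path=str(path),
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse-error types
        raise FormatError(f"Newick parse error in {path}: {exc}") from exc
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise FormatError(f"duplicate leaf labels: {', '.join(dupes)}")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise FormatError(f"negative branch length {edge.length}")
    return tree


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", unquoted_underscores=True,
               suppress_rooting=True)


def tree_to_newick_string(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", unquoted_underscores=True, suppress_rooting=True).strip()


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

_SCHEMAS = {
    "cazyme": ["protein_id", "hmmer", "diamond", "recommended"],
    "secretion": ["protein_id", "call", "probability"],
    "domains": ["protein_id", "domain", "start", "end", "e_value"],
    "genes": ["genome_id", "contig_id", "gene_index", "protein_id", "roles", "at_contig_edge"],
    "hmm_hits": ["protein_id", "genome_id", "e_value", "score"],
}


def _read_table(path, schema: str) -> pd.DataFrame:
    cols = _SCHEMAS[schema]
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s) {', '.join(missing)} for {schema} table")
    extra = [c for c in df.columns if c not in cols]
    if extra:
        logger.warning("%s: ignoring unknown column(s) %s", path, ", ".join(extra))
    return df[cols]


def _split_families(cell: str) -> set[str]:
    return {f for f in (p.strip() for p in cell.split(";")) if f}


def read_cazyme_table(path) -> list[CazymeCall]:
    df = _read_table(path, "cazyme")
    return [
        CazymeCall(
            protein_id=row.protein_id,
            hmmer_families=_split_families(row.hmmer),
            diamond_families=_split_families(row.diamond),
            recommended=_split_families(row.recommended),
        )
        for row in df.itertuples()
    ]


def read_secretion_table(path) -> list[SecretionCall]:
    df = _read_table(path, "secretion")
    calls = []
    for row in df.itertuples():
        prob = float(row.probability) if row.probability != "" else None
        calls.append(SecretionCall(
            protein_id=row.protein_id,
            is_secreted=row.call.upper() in {"SP", "TRUE", "YES", "1"},
            probability=prob,
        ))
    return calls


def read_domain_table(path) -> list[DomainHit]:
    df = _read_table(path, "domains")
    return [
        DomainHit(
            protein_id=row.protein_id,
            domain_name=row.domain,
            start=int(row.start),
            end=int(row.end),
            e_value=float(row.e_value),
        )
        for row in df.itertuples()
    ]


def _parse_bool(cell: str) -> bool:
    if cell.lower() in {"true", "1", "yes"}:
        return True
    if cell.lower() in {"false", "0", "no", ""}:
        return False
    raise FormatError(f"unparseable boolean {cell!r}")


def read_gene_table(path) -> list[GeneRow]:
    df = _read_table(path, "genes")
    rows = [
        GeneRow(
            genome_id=row.genome_id,
            contig_id=row.contig_id,
            gene_index=int(row.gene_index),
            protein_id=row.protein_id,
            role_labels=_split_families(row.roles) if row.roles else set(),
            at_contig_edge=_parse_bool(row.at_contig_edge),
        )
        for row in df.itertuples()
    ]
    validate_gene_rows(rows)
    return rows


def validate_gene_rows(rows: list[GeneRow]) -> None:
    """Check (contig, gene_index) uniqueness and consecutive indexing."""
    by_contig: dict[tuple[str, str], list[int]] = {}
    for r in rows:
        by_contig.setdefault((r.genome_id, r.contig_id), []).append(r.gene_index)
    for (genome, contig), idx in by_contig.items():
        if len(idx) != len(set(idx)):
            raise FormatError(f"duplicate gene_index on {genome}/{contig}")
        srt = sorted(idx)
        if srt != list(range(srt[0], srt[0] + len(srt))):
            raise FormatError(f"gene_index not consecutive on {genome}/{contig}")


def read_hmm_hits(path) -> list[HmmHit]:
    df = _read_table(path, "hmm_hits")
    return [
        HmmHit(
            protein_id=row.protein_id,
            genome_id=row.genome_id,
            e_value=float(row.e_value),
            score=float(row.score),
        )
        for row in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# TSV writers (round-trip partners of the readers above)
# ---------------------------------------------------------------------------


def write_cazyme_table(calls: list[CazymeCall], path) -> None:
    pd.DataFrame(
        {
            "protein_id": [c.protein_id for c in calls],
            "hmmer": [";".join(sorted(c.hmmer_families)) for c in calls],
            "diamond": [";".join(sorted(c.diamond_families)) for c in calls],
            "recommended": [";".join(sorted(c.recommended)) for c in calls],
        }
    ).to_csv(path, sep="\t", index=False)


def write_secretion_table(calls: list[SecretionCall], path) -> None:
    pd.DataFrame(
        {
            "protein_id": [c.protein_id for c in calls],
            "call": ["SP" if c.is_secreted else "OTHER" for c in calls],
            "probability": ["" if c.probability is None else repr(c.probability) for c in calls],
        }
    ).to_csv(path, sep="\t", index=False)


def write_domain_table(hits: list[DomainHit], path) -> None:
    pd.DataFrame(
        {
            "protein_id": [h.protein_id for h in hits],
            "domain": [h.domain_name for h in hits],
            "start": [h.start for h in hits],
            "end": [h.end for h in hits],
            "e_value": [repr(h.e_value) for h in hits],
        }
    ).to_csv(path, sep="\t", index=False)


def write_gene_table(rows: list[GeneRow], path) -> None:
    pd.DataFrame(
        {
            "genome_id": [r.genome_id for r in rows],
            "contig_id": [r.contig_id for r in rows],
            "gene_index": [r.gene_index for r in rows],
            "protein_id": [r.protein_id for r in rows],
            "roles": [";".join(sorted(r.role_labels)) for r in rows],
            "at_contig_edge": [str(r.at_contig_edge).lower() for r in rows],
        }
    ).to_csv(path, sep="\t", index=False)


def write_hmm_hits(hits: list[HmmHit], path) -> None:
    pd.DataFrame(
        {
            "protein_id": [h.protein_id for h in hits],
            "genome_id": [h.genome_id for h in hits],
            "e_value": [repr(h.e_value) for h in hits],
            "score": [repr(h.score) for h in hits],
        }
    ).to_csv(path, sep="\t", index=False)
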