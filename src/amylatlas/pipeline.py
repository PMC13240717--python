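"""End-to-end orchestration: mine -> clades -> bgc -> associate -> scan.

The pipeline is a pure function of its inputs, configuration and seed;
reruns produce byte-identical TSV outputs and a machine-readable manifest
recording the package version, configuration hash and stage-wise record
counts (so the filter cascade can be audited, e.g. how many GH13 calls
survived the signal-peptide and domain criteria).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

import amylatlas
from amylatlas import clades as clade_tools
from amylatlas import io as aio
from amylatlas import neighborhood, secretome, simulate
from amylatlas.associations import (
    clade_prevalence,
    binary_association,
    column_enrichment_scan,
    count_association,
    summarize_cohort,
)

logger = logging.getLogger(__name__)

EXIT_VALIDATION_FAILURE = 2
EXIT_STATS_FAILURE = 3


@dataclass
class AnalysisConfig:
    """Every tunable of the pipeline with its default.

    alpha is the significance cutoff (0.05); hmm_evalue_cutoff gates
    tendamistat-like profile hits (1e-10); k_clades is the number of tree
    clades to extract (3: pullulanases, alpha-1,4, cmd-like).
    """

    alpha: float = 0.05
    hmm_evalue_cutoff: float = 1e-10
    k_clades: int = 3
    gap_policy: str = "exclude"
    min_count: int = 3
    census_level: str = "genome"
    max_gene_gap: int = neighborhood.DEFAULT_MAX_GENE_GAP
    flank_genes: int = neighborhood.DEFAULT_FLANK_GENES
    required_fraction: float = neighborhood.DEFAULT_REQUIRED_FRACTION
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.hmm_evalue_cutoff <= 0:
            raise ValueError("hmm_evalue_cutoff must be positive")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def digest(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    outdir: Path
    manifest: dict
    files: dict[str, Path] = field(default_factory=dict)


def _write_tsv(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def stage_mine(indir: Path, outdir: Path, config: AnalysisConfig) -> pd.DataFrame:
    """Secretome filter: annotation TSVs -> amylases.tsv + audit counts."""
    calls = aio.read_cazyme_table(indir / "cazymes.tsv")
    secretion = aio.read_secretion_table(indir / "secretion.tsv")
    domains = aio.read_domain_table(indir / "domains.tsv")
    genes = aio.read_gene_table(indir / "genes.tsv")
    kept, no_signal, no_domain = secretome.filter_secreted_amylases(
        calls, secretion, domains, gene_rows=genes
    )
    df = pd.DataFrame(
        {
            "protein_id": [a.protein_id for a in kept],
            "genome_id": [a.genome_id for a in kept],
            "clade": [a.clade for a in kept],
            "domains": [";".join(sorted(a.domain_names)) for a in kept],
            "contig_id": [a.locus[0] if a.locus else "" for a in kept],
            "gene_index": [a.locus[1] if a.locus else -1 for a in kept],
        }
    )
    _write_tsv(df, outdir / "amylases.tsv")
    audit = pd.DataFrame(
        {
            "stage": ["gh13_recommended", "kept", "dropped_no_signal", "dropped_no_domain"],
            "count": [len(kept) + len(no_signal) + len(no_domain), len(kept), len(no_signal), len(no_domain)],
        }
    )
    _write_tsv(audit, outdir / "filter_audit.tsv")
    logger.info("mine: %d GH13 calls -> %d secreted amylases", audit["count"][0], len(kept))
    return df


def stage_clades(indir: Path, outdir: Path, config: AnalysisConfig) -> pd.DataFrame:
    """Midpoint-root the amylase tree, cut k clades, pick representatives."""
    alignment = aio.read_alignment(indir / "amylases_msa.fasta")
    tree = aio.read_newick(indir / "amylases.nwk")
    rooted = clade_tools.midpoint_root(tree)
    partition = clade_tools.extract_clades(rooted, config.k_clades)
    df = pd.DataFrame(
        sorted(partition.assignments.items()), columns=["leaf", "clade"]
    )
    _write_tsv(df, outdir / "clades.tsv")
    reps = []
    aligned_ids = set(alignment.ids)
    for c in range(1, config.k_clades + 1):
        members = [m for m in partition.members(c) if m in aligned_ids]
        if members:
            reps.append({"clade": c, "representative": clade_tools.select_representative(alignment, members)})
    _write_tsv(pd.DataFrame(reps), outdir / "representatives.tsv")
    return df


def stage_bgc(indir: Path, outdir: Path, config: AnalysisConfig) -> pd.DataFrame:
    """Detect inhibitor BGC loci and per-genome flags from the gene table."""
    genes = aio.read_gene_table(indir / "genes.tsv")
    query_path = indir / "bgc_query.yaml"
    if query_path.exists():
        with open(query_path) as fh:
            qd = yaml.safe_load(fh)
        query = neighborhood.BGCQuery(
            name=qd.get("name", "acarbose"),
            required_genes=frozenset(qd["required_genes"]),
            optional_genes=frozenset(qd.get("optional_genes", [])),
            max_gene_gap=qd.get("max_gene_gap", config.max_gene_gap),
            required_fraction=qd.get("required_fraction", config.required_fraction),
        )
    else:
        query = neighborhood.acarbose_query(
            optional_genes=frozenset({"amylase", "tendamistat_like"}),
            max_gene_gap=config.max_gene_gap,
            required_fraction=config.required_fraction,
        )
    loci = neighborhood.find_bgc_loci(genes, query)
    neighborhood.annotate_flanking_amylases(loci, genes, config.flank_genes)
    df = pd.DataFrame(
        {
            "genome_id": [l.genome_id for l in loci],
            "contig_id": [l.contig_id for l in loci],
            "first_gene_index": [l.span[0] for l in loci],
            "last_gene_index": [l.span[1] for l in loci],
            "n_required_matched": [len(l.matched_required) for l in loci],
            "flanking_amylases": [l.flanking_amylase_count for l in loci],
            "truncated_at_contig_edge": [str(l.truncated_at_contig_edge).lower() for l in loci],
        }
    )
    _write_tsv(df, outdir / "bgc_loci.tsv")
    genomes = sorted({r.genome_id for r in genes})
    flags = neighborhood.genome_bgc_flags(loci, genomes)
    hits_path = indir / "hmm_hits.tsv"
    tend = (
        neighborhood.filter_tendamistat_hits(
            aio.read_hmm_hits(hits_path), config.hmm_evalue_cutoff, genome_ids=genomes
        )
        if hits_path.exists()
        else {g: False for g in genomes}
    )
    fdf = pd.DataFrame(
        {
            "genome_id": genomes,
            "has_acarbose_bgc": [str(flags[g]).lower() for g in genomes],
            "has_tendamistat": [str(tend[g]).lower() for g in genomes],
        }
    )
    _write_tsv(fdf, outdir / "genome_flags.tsv")
    return fdf


def _bool_column(series: pd.Series) -> pd.Series:
    # pandas parses lowercase true/false into bool dtype on its own
    if series.dtype == bool:
        return series
    return series.astype(str).str.lower() == "true"


def stage_associate(outdir: Path, config: AnalysisConfig) -> pd.DataFrame:
    """Cohort summaries + count/flag association statistics."""
    amylases = pd.read_csv(outdir / "amylases.tsv", sep="\t")
    flags = pd.read_csv(outdir / "genome_flags.tsv", sep="\t")
    records = [
        secretome.AmylaseRecord(
            protein_id=r.protein_id, genome_id=r.genome_id, clade=r.clade, domain_names=set()
        )
        for r in amylases.itertuples()
    ]
    bgc_flags = {"acarbose": dict(zip(flags.genome_id, _bool_column(flags.has_acarbose_bgc)))}
    tend_flags = dict(zip(flags.genome_id, _bool_column(flags.has_tendamistat)))
    summaries = summarize_cohort(
        records, bgc_flags, tend_flags, genome_ids=list(flags.genome_id)
    )
    sdf = pd.DataFrame(
        {
            "genome_id": [s.genome_id for s in summaries],
            "pullulanase": [s.amylase_counts.get("pullulanase", 0) for s in summaries],
            "alpha14": [s.amylase_counts.get("alpha14", 0) for s in summaries],
            "cmd_like": [s.amylase_counts.get("cmd_like", 0) for s in summaries],
            "total_amylases": [s.total_amylases for s in summaries],
            "has_acarbose_bgc": [str(s.has_acarbose_bgc).lower() for s in summaries],
            "has_tendamistat": [str(s.has_tendamistat).lower() for s in summaries],
        }
    )
    _write_tsv(sdf, outdir / "genome_summaries.tsv")

    rows = []
    prev = clade_prevalence(summaries)
    for clade, pct in prev.items():
        rows.append({"test": f"prevalence_{clade}", "statistic": round(pct, 4), "p_value": "", "effect_size": ""})
    for flag in ("has_acarbose_bgc", "has_tendamistat"):
        try:
            res = count_association(summaries, flag)
            rows.append(
                {
                    "test": f"mwu_total_amylases_vs_{flag}",
                    "statistic": res.u_statistic,
                    "p_value": res.p_value,
                    "effect_size": res.effect_size_r,
                }
            )
        except ValueError as exc:
            rows.append({"test": f"mwu_total_amylases_vs_{flag}", "statistic": "",
                         "p_value": "", "effect_size": f"failed: {exc}"})
    try:
        res = binary_association(summaries, "cmd_like", "has_tendamistat")
        rows.append(
            {"test": "chi2_cmd_like_vs_tendamistat", "statistic": res.chi2,
             "p_value": res.p_value, "effect_size": res.phi}
        )
    except ValueError as exc:
        rows.append({"test": "chi2_cmd_like_vs_tendamistat", "statistic": "",
                     "p_value": "", "effect_size": f"failed: {exc}"})
    adf = pd.DataFrame(rows)
    _write_tsv(adf, outdir / "association_stats.tsv")
    return adf


def stage_scan(indir: Path, outdir: Path, config: AnalysisConfig) -> pd.DataFrame:
    """Column-wise residue-enrichment scan over the amylase alignment."""
    alignment = aio.read_alignment(indir / "amylases_msa.fasta")
    labels_df = pd.read_csv(indir / "scan_groups.tsv", sep="\t")
    labels = dict(zip(labels_df.sequence_id, labels_df.group))
    reference_id = labels_df.sequence_id.iloc[0]
    ref_path = indir / "scan_reference.txt"
    if ref_path.exists():
        reference_id = ref_path.read_text().strip()
    results = column_enrichment_scan(
        alignment, labels, reference_id,
        min_count=config.min_count, alpha=config.alpha, gap_policy=config.gap_policy,
    )
    df = pd.DataFrame(
        {
            "column": [r.column for r in results],
            "residue": [r.residue for r in results],
            "a": [r.table.a for r in results],
            "b": [r.table.b for r in results],
            "c": [r.table.c for r in results],
            "d": [r.table.d for r in results],
            "fold": [r.fold_enrichment for r in results],
            "p_raw": [r.p_raw for r in results],
            "p_bh": [r.p_bh for r in results],
            "p_bonf": [r.p_bonferroni for r in results],
            "ref_position": [r.reference_position if r.reference_position is not None else "" for r in results],
            "label": [r.label for r in results],
        }
    )
    _write_tsv(df, outdir / "enrichment.tsv")
    return df


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

STAGES = ("mine", "clades", "bgc", "associate", "scan")


def run_pipeline(indir, outdir, config: AnalysisConfig | None = None) -> PipelineResult:
    """Run every stage in order; earlier outputs survive a later failure.

    A statistical-stage failure (e.g. an empty comparison group) is
    recorded in the manifest as a structured failure rather than silently
    dropped; validation errors abort with the stage name.
    """
    config = config or AnalysisConfig()
    indir, outdir = Path(indir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": amylatlas.__version__,
        "config": asdict(config),
        "config_digest": config.digest(),
        "seed": config.seed,
        "stages": {},
    }
    result = PipelineResult(outdir=outdir, manifest=manifest)
    for stage in STAGES:
        try:
            if stage == "mine":
                df = stage_mine(indir, outdir, config)
            elif stage == "clades":
                df = stage_clades(indir, outdir, config)
            elif stage == "bgc":
                df = stage_bgc(indir, outdir, config)
            elif stage == "associate":
                df = stage_associate(outdir, config)
            else:
                df = stage_scan(indir, outdir, config)
            manifest["stages"][stage] = {"status": "ok", "rows": int(len(df))}
        except ValueError as exc:
            manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
            logger.error("stage %s failed: %s", stage, exc)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    for f in sorted(outdir.glob("*.tsv")):
        result.files[f.stem] = f
    return result


def make_fixtures(seed: int, outdir, n_genomes: int = 60) -> Path:
    """Materialize a small synthetic cohort exercising every stage.

    Writes the annotation TSVs, gene table, HMM hits, amylase protein
    FASTA, amylase alignment, scan group labels and a clade-structured
    Newick tree into ``outdir``; byte-identical for a given seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = simulate.CohortParams(n_genomes=n_genomes, p_bgc=0.15, seed=seed)
    cohort = simulate.generate_cohort(params)
    aio.write_cazyme_table(cohort.cazyme_calls, outdir / "cazymes.tsv")
    aio.write_secretion_table(cohort.secretion_calls, outdir / "secretion.tsv")
    aio.write_domain_table(cohort.domain_hits, outdir / "domains.tsv")
    aio.write_gene_table(cohort.gene_rows, outdir / "genes.tsv")
    aio.write_hmm_hits(cohort.hmm_hits, outdir / "hmm_hits.tsv")
    aio.write_fasta(cohort.proteins, outdir / "proteins.fasta")

    alignment, labels = simulate.cohort_alignment(cohort)
    aio.write_alignment(alignment, outdir / "amylases_msa.fasta")
    pd.DataFrame(
        {"sequence_id": list(labels), "group": [labels[k] for k in labels]}
    ).to_csv(outdir / "scan_groups.tsv", sep="\t", index=False)
    # reference: a wildtype pullulanase from a non-BGC genome if available
    pull_ids = [p for p, c in cohort.amylase_clades.items()
                if c == "pullulanase" and labels.get(p) == "B"]
    reference = pull_ids[0] if pull_ids else alignment.ids[0]
    (outdir / "scan_reference.txt").write_text(reference + "\n")

    # clade-structured tree over the amylase ids, leaves relabeled so the
    # planted tree clades coincide with the true domain clades
    by_clade: dict[str, list[str]] = {"pullulanase": [], "alpha14": [], "cmd_like": []}
    for pid in alignment.ids:
        by_clade[cohort.amylase_clades[pid]].append(pid)
    order = [pid for c in ("pullulanase", "alpha14", "cmd_like") for pid in by_clade[c]]
    tree, _ = simulate.generate_clade_tree(
        (len(by_clade["pullulanase"]), len(by_clade["alpha14"]), len(by_clade["cmd_like"])),
        seed=seed,
    )
    for leaf, pid in zip(tree.leaf_node_iter(), order):
        leaf.taxon.label = pid
    aio.write_newick(tree, outdir / "amylases.nwk")
    return outdir
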