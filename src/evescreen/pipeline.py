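"""End-to-end orchestration: screen -> annotate -> phylo, with reporting.

One :class:`RunConfig` (YAML-loadable) drives a reproducible run; every
default lands in the provenance block so a run is self-describing.  A failure
while characterizing one locus flags that locus and moves on — it never
aborts the other loci.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, matrices
from .annotate import (
    DEFAULT_MIN_ORF_AA,
    DEFAULT_NS1_MOTIFS,
    DEFAULT_PLA2_MOTIFS,
    assess_integrity,
    call_gene_orf,
    classify_locus_status,
    detect_gene_overlap,
    extract_orfs,
    scan_motifs,
)
from .phylo import (
    Msa,
    annotate_supports,
    bootstrap_support,
    build_msa_center_star,
    midpoint_root,
    nj_tree,
    p_distance_matrix,
    read_metadata_tsv,
    tag_tips,
)
from .screen import (
    assign_taxon,
    filter_shadow_loci,
    merge_hits_to_loci,
    screen_assembly,
)
from .seqio import (
    Contig,
    Feature,
    Interval,
    read_fasta,
    read_probe_library,
    write_gff3,
)

logger = logging.getLogger("evescreen")


@dataclass
class RunConfig:
    assembly: str
    probes: str
    outdir: str
    metadata: str | None = None
    repeats: str | None = None
    gap_open: int = matrices.DEFAULT_GAP_OPEN
    gap_extend: int = matrices.DEFAULT_GAP_EXTEND
    min_score: int = matrices.DEFAULT_MIN_SCORE
    max_gap_nt: int = matrices.DEFAULT_MAX_GAP_NT
    margin_min: int = matrices.DEFAULT_MARGIN_MIN
    min_orf_aa: int = DEFAULT_MIN_ORF_AA
    ns1_motifs: dict = field(default_factory=lambda: dict(DEFAULT_NS1_MOTIFS))
    pla2_motifs: dict = field(default_factory=lambda: dict(DEFAULT_PLA2_MOTIFS))
    bootstrap_reps: int = 100
    region_aa: tuple[int, int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for attr in ("assembly", "probes"):
            p = getattr(self, attr)
            if not Path(p).exists():
                raise FileNotFoundError(f"{attr} file not found: {p}")
        for attr in ("metadata", "repeats"):
            p = getattr(self, attr)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{attr} file not found: {p}")
        if self.min_score < 1 or self.max_gap_nt < 0 or self.bootstrap_reps < 0:
            raise ValueError("numeric parameters out of range")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update(overrides)
        if "region_aa" in data and data["region_aa"] is not None:
            data["region_aa"] = tuple(data["region_aa"])
        return cls(**data)


@dataclass
class RunReport:
    loci: pd.DataFrame
    tree_newick: str | None
    provenance: dict
    outdir: str


def read_repeat_annotation(path: str | Path) -> list[Feature]:
    """Repeat/TE features from BED (0-based) or GFF3 (1-based)."""
    feats = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if str(path).endswith((".gff", ".gff3")):
                start, end = int(cols[3]) - 1, int(cols[4])
                strand = cols[6] if cols[6] in "+-" else "+"
                feats.append(Feature(cols[0], Interval(start, end, strand), cols[2]))
            else:
                feats.append(
                    Feature(cols[0], Interval(int(cols[1]), int(cols[2])), "repeat_region")
                )
    return feats


def _characterize_locus(locus, contig: Contig, cfg: RunConfig, repeat_feats, known):
    orfs = extract_orfs(contig, locus.strand, cfg.min_orf_aa)
    gene_orfs = call_gene_orf(locus, orfs)
    report = assess_integrity(locus, gene_orfs, repeat_feats, known)
    status = classify_locus_status(report)
    overlap_nt = None
    ns_orf, vp_orf = gene_orfs.get("NS"), gene_orfs.get("VP")
    if ns_orf is not None and vp_orf is not None:
        overlap_nt = detect_gene_overlap(ns_orf, vp_orf)

    def motif_names(gene, motifs, n_terminal_third=False):
        orf = gene_orfs.get(gene)
        if orf is not None:
            pep = orf.peptide
        else:
            gene_hits = [h for h in locus.member_hits if h.gene_label == gene]
            if not gene_hits:
                return []
            pep = max(gene_hits, key=lambda h: len(h.subject_peptide)).subject_peptide
        if n_terminal_third:
            pep = pep[: max(1, len(pep) // 3)]
        return sorted({m.motif_name for m in scan_motifs(pep, motifs)})

    ns1_found = motif_names("NS", cfg.ns1_motifs)
    pla2_found = motif_names("VP", cfg.pla2_motifs, n_terminal_third=True)

    best_ident = {
        gene: max(
            (h.percent_identity for h in locus.member_hits if h.gene_label == gene),
            default=None,
        )
        for gene in ("NS", "VP")
    }
    return {
        "locus_id": locus.locus_id,
        "contig_id": locus.contig_id,
        "start": locus.span_nt.start,
        "end": locus.span_nt.end,
        "strand": locus.strand,
        "assigned_taxon": locus.assigned_taxon,
        "assigned_gene": locus.assigned_gene,
        "n_hits": len(locus.member_hits),
        "best_score": locus.best_score,
        "score_margin": locus.score_margin,
        "status": status.status,
        "evidence": ",".join(status.evidence),
        "n_internal_stops": report.n_internal_stops,
        "n_frameshifts": report.n_frameshifts,
        "repeat_overlap": report.repeat_overlap,
        "has_full_length_NS": report.has_full_length_orf.get("NS", False),
        "has_full_length_VP": report.has_full_length_orf.get("VP", False),
        "ns_vp_overlap_nt": overlap_nt,
        "ns1_motifs": ",".join(ns1_found),
        "pla2_motifs": ",".join(pla2_found),
        "best_identity_NS": best_ident["NS"],
        "best_identity_VP": best_ident["VP"],
        "_ns_orf": ns_orf,
        "_vp_orf": vp_orf,
    }


def select_region(msa: Msa, ref_label: str, start: int, end: int) -> Msa:
    """Restrict an MSA to the columns spanning [start, end) of one reference
    row's ungapped coordinates (the conserved-region selection hook)."""
    idx = msa.taxa.index(ref_label)
    ref = msa.rows[idx]
    cols = []
    pos = 0
    for c, ch in enumerate(ref):
        if ch != "-":
            if start <= pos < end:
                cols.append(c)
            pos += 1
    rows = ["".join(r[c] for c in cols) for r in msa.rows]
    return Msa(list(msa.taxa), rows)


def run_pipeline(cfg: RunConfig) -> RunReport:
    """Execute screen -> annotate -> phylo and write all stage outputs."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    contigs = [Contig(r.id, r.seq) for r in read_fasta(cfg.assembly, "dna")]
    by_id = {c.id: c for c in contigs}
    probes = read_probe_library(cfg.probes)
    repeat_feats = read_repeat_annotation(cfg.repeats) if cfg.repeats else []
    metadata = read_metadata_tsv(cfg.metadata) if cfg.metadata else {}

    logger.info("screen: %d contigs x %d probes", len(contigs), len(probes))
    hits = screen_assembly(
        contigs,
        probes,
        gap_open=cfg.gap_open,
        gap_extend=cfg.gap_extend,
        min_score=cfg.min_score,
    )
    loci = merge_hits_to_loci(hits, cfg.max_gap_nt)
    for locus in loci:
        assign_taxon(locus, cfg.margin_min)
    loci = filter_shadow_loci(loci)

    _write_hits_tsv(hits, outdir / "hits.tsv")

    rows = []
    gff_feats = []
    known = set(by_id)
    for locus in loci:
        try:
            row = _characterize_locus(locus, by_id[locus.contig_id], cfg, repeat_feats, known)
        except Exception as exc:  # pragma: no cover - per-locus isolation
            logger.exception("locus %s failed", locus.locus_id)
            row = {"locus_id": locus.locus_id, "contig_id": locus.contig_id,
                   "status": "error", "evidence": str(exc)}
        rows.append(row)
        gff_feats.append(
            Feature(
                locus.contig_id,
                locus.span_nt,
                "viral_locus",
                {"ID": locus.locus_id, "taxon": locus.assigned_taxon,
                 "gene": locus.assigned_gene, "status": row.get("status", "error")},
            )
        )
        for gene_key in ("_ns_orf", "_vp_orf"):
            orf = row.get(gene_key)
            if orf is not None:
                gff_feats.append(
                    Feature(
                        orf.contig_id,
                        orf.interval_nt,
                        "CDS",
                        {"ID": f"{locus.locus_id}_{orf.gene_label}",
                         "Parent": locus.locus_id, "gene": orf.gene_label},
                    )
                )
    table = pd.DataFrame(rows)
    for col in ("_ns_orf", "_vp_orf"):
        if col in table.columns:
            table = table.drop(columns=[col])
    table.to_csv(outdir / "loci.tsv", sep="\t", index=False)
    write_gff3(gff_feats, outdir / "loci.gff3", {c.id: len(c.seq) for c in contigs})

    # phylogenetic placement of loci with a complete NS ORF, against NS probes
    tree_newick = None
    ns_seqs: dict[str, str] = {
        p.id: p.seq for p in probes if p.gene_label == "NS"
    }
    n_novel = 0
    for row, locus in zip(rows, loci):
        orf = row.get("_ns_orf")
        if orf is not None and row.get("has_full_length_NS"):
            ns_seqs[locus.locus_id] = orf.peptide
            n_novel += 1
    if n_novel >= 1 and len(ns_seqs) >= 4:
        msa = build_msa_center_star(
            ns_seqs, gap_open=cfg.gap_open, gap_extend=cfg.gap_extend
        )
        if cfg.region_aa is not None:
            ref_label = next(iter(ns_seqs))
            msa = select_region(msa, ref_label, *cfg.region_aa)
        dm = p_distance_matrix(msa)
        dm.to_tsv(outdir / "ns_distances.tsv")
        if cfg.bootstrap_reps > 0:
            tree, support = bootstrap_support(msa, cfg.bootstrap_reps, cfg.seed)
        else:
            tree, support = nj_tree(dm), {}
        rooted = midpoint_root(tree)
        annotate_supports(rooted, support)
        tag_tips(rooted, metadata)
        tree_newick = rooted.to_newick(annotations=True)
        (outdir / "ns_tree.nwk").write_text(tree_newick + "\n")

    provenance = {
        "config": {k: v for k, v in asdict(cfg).items()},
        "seed": cfg.seed,
        "version": __version__,
        "config_hash": hashlib.sha256(
            json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
        ).hexdigest()[:16],
        "n_hits": len(hits),
        "n_loci": len(loci),
    }
    (outdir / "provenance.json").write_text(json.dumps(provenance, indent=2, default=str))
    report = RunReport(table, tree_newick, provenance, str(outdir))
    (outdir / "summary.txt").write_text(summarize_report(report))
    return report


def _write_hits_tsv(hits, path) -> None:
    cols = ["contig_id", "probe_id", "taxon_label", "gene_label", "frame",
            "score", "q_start", "q_end", "nt_start", "nt_end", "strand",
            "percent_identity"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for h in hits:
            fh.write(
                "\t".join(
                    str(v)
                    for v in [
                        h.contig_id, h.probe_id, h.taxon_label, h.gene_label,
                        h.frame, h.score, h.query_interval[0], h.query_interval[1],
                        h.subject_interval_nt.start, h.subject_interval_nt.end,
                        h.strand, f"{h.percent_identity:.4f}",
                    ]
                )
                + "\n"
            )


def summarize_report(report: RunReport) -> str:
    """Plain-text run summary: counts by taxon and status, identity ranges
    per gene, and NS/VP overlap statistics."""
    df = report.loci
    lines = [f"loci: {len(df)}"]
    if len(df):
        for (taxon, status), group in df.groupby(["assigned_taxon", "status"]):
            lines.append(f"  {taxon} / {status}: {len(group)}")
        for gene in ("NS", "VP"):
            col = f"best_identity_{gene}"
            if col in df and df[col].notna().any():
                vals = df[col].dropna()
                lines.append(
                    f"identity vs references, {gene}: "
                    f"{100 * vals.min():.0f}-{100 * vals.max():.0f}%"
                )
        if "ns_vp_overlap_nt" in df and df["ns_vp_overlap_nt"].notna().any():
            ov = df["ns_vp_overlap_nt"].dropna().astype(int)
            lines.append(
                f"NS/VP ORF overlaps (nt): {sorted(ov.tolist())} "
                f"(mean {ov.mean():.1f})"
            )
    return "\n".join(lines) + "\n"
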