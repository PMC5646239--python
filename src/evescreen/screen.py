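"""Six-frame translated screening of contigs against a protein probe library.

This is an exhaustive, tBLASTn-style search: every probe is locally aligned
(affine-gap Smith–Waterman) against all six translated frames of every
contig.  All alignments at or above ``min_score`` are kept — not only the
best per probe/frame pair — because a degraded endogenous locus shows up as
a chain of same-strand fragments in different frames, and those fragments
are the frameshift evidence downstream.

Hits are merged into candidate viral loci per contig and strand, and each
locus is assigned a taxon by a score-margin rule (the explicit stand-in for
reciprocal-best-hit confirmation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from Bio.Data import CodonTable

from . import matrices
from ._align import LocalHit, sw_all_hits, sw_best, sw_single_best
from .seqio import Contig, Interval, ProteinProbe, revcomp

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_CODON_MAP = dict(_TABLE.forward_table)
for _stop in _TABLE.stop_codons:
    _CODON_MAP[_stop] = "*"

FRAMES = ("+1", "+2", "+3", "-1", "-2", "-3")


def translate_codons(seq: str) -> str:
    """Translate with the standard code; codons containing N become 'X'."""
    out = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i : i + 3]
        out.append("X" if "N" in codon else _CODON_MAP[codon])
    return "".join(out)


@dataclass
class TranslatedFrame:
    """One of the six reading frames of a contig, with its coordinate map."""

    contig_id: str
    frame: str  # +1..+3 / -1..-3
    frame_offset: int  # 0,1,2 from the reading strand's 5' end
    peptide: str
    contig_length: int

    @property
    def strand(self) -> str:
        return self.frame[0] if self.frame[0] == "-" else "+"

    def aa_to_nt(self, aa_start: int, aa_end: int) -> Interval:
        """Map a peptide interval to strand-resolved contig nt coordinates."""
        if self.strand == "+":
            return Interval(
                self.frame_offset + 3 * aa_start,
                self.frame_offset + 3 * aa_end,
                "+",
            )
        L = self.contig_length
        return Interval(
            L - self.frame_offset - 3 * aa_end,
            L - self.frame_offset - 3 * aa_start,
            "-",
        )


def translate_six_frames(contig: Contig) -> list[TranslatedFrame]:
    """All six reading frames; contigs shorter than 3 nt give empty peptides."""
    frames = []
    rc = revcomp(contig.seq)
    for strand, seq in (("+", contig.seq), ("-", rc)):
        for off in range(3):
            frames.append(
                TranslatedFrame(
                    contig_id=contig.id,
                    frame=f"{strand}{off + 1}",
                    frame_offset=off,
                    peptide=translate_codons(seq[off:]),
                    contig_length=len(contig.seq),
                )
            )
    return frames


@dataclass
class AlignmentHit:
    """A local alignment of one probe against one translated frame."""

    contig_id: str
    probe_id: str
    taxon_label: str
    gene_label: str
    frame: str
    score: int
    query_interval: tuple[int, int]  # on the probe, aa
    subject_interval_aa: tuple[int, int]  # on the translated frame, aa
    subject_interval_nt: Interval  # on the contig, strand-resolved
    percent_identity: float
    subject_peptide: str = ""
    probe_length: int = 0  # 0 = unknown (terminator-stop exclusion disabled)

    @property
    def strand(self) -> str:
        return self.subject_interval_nt.strand


def local_align_protein(
    query: str,
    subject: str,
    matrix=None,
    gap_open: int = matrices.DEFAULT_GAP_OPEN,
    gap_extend: int = matrices.DEFAULT_GAP_EXTEND,
) -> LocalHit | None:
    """Optimal affine-gap local alignment of two peptides, or None if score 0."""
    if not query or not subject:
        return None
    if matrix is None:
        matrix = matrices.DEFAULT_MATRIX
    return sw_single_best(
        matrices.encode(query), matrices.encode(subject), matrix, gap_open, gap_extend
    )


def screen_assembly(
    contigs: Sequence[Contig],
    probes: Sequence[ProteinProbe],
    matrix=None,
    gap_open: int = matrices.DEFAULT_GAP_OPEN,
    gap_extend: int = matrices.DEFAULT_GAP_EXTEND,
    min_score: int = matrices.DEFAULT_MIN_SCORE,
) -> list[AlignmentHit]:
    """Align every probe against every translated frame of every contig.

    Returns all hits with score >= min_score, sorted by (contig, nt start,
    probe id, frame) — the deterministic tie-break used throughout.
    """
    if not probes:
        raise ValueError("probe library is empty")
    if matrix is None:
        matrix = matrices.DEFAULT_MATRIX
    enc_probes = [(p, matrices.encode(p.seq)) for p in probes]
    hits: list[AlignmentHit] = []
    for contig in contigs:
        for frame in translate_six_frames(contig):
            if not frame.peptide:
                continue
            s_enc = matrices.encode(frame.peptide)
            for probe, q_enc in enc_probes:
                # cheap score-only pass first; full DP only when something is there
                if sw_best(q_enc, s_enc, matrix, gap_open, gap_extend) < min_score:
                    continue
                for lh in sw_all_hits(
                    q_enc, s_enc, matrix, gap_open, gap_extend, min_score
                ):
                    hits.append(
                        AlignmentHit(
                            contig_id=contig.id,
                            probe_id=probe.id,
                            taxon_label=probe.taxon_label,
                            gene_label=probe.gene_label,
                            frame=frame.frame,
                            score=lh.score,
                            query_interval=(lh.query_start, lh.query_end),
                            subject_interval_aa=(lh.subject_start, lh.subject_end),
                            subject_interval_nt=frame.aa_to_nt(
                                lh.subject_start, lh.subject_end
                            ),
                            percent_identity=lh.identity,
                            subject_peptide=frame.peptide[
                                lh.subject_start : lh.subject_end
                            ],
                            probe_length=len(probe.seq),
                        )
                    )
    hits.sort(
        key=lambda h: (h.contig_id, h.subject_interval_nt.start, h.probe_id, h.frame)
    )
    return hits


@dataclass
class ViralLocus:
    """A merged run of hits on one contig and strand: one candidate locus."""

    locus_id: str
    contig_id: str
    span_nt: Interval
    strand: str
    member_hits: list[AlignmentHit] = field(default_factory=list)
    assigned_taxon: str = "unclassified"
    assigned_gene: str = "unknown"
    best_score: int = 0
    score_margin: int = 0


def merge_hits_to_loci(
    hits: Sequence[AlignmentHit],
    max_gap_nt: int = matrices.DEFAULT_MAX_GAP_NT,
) -> list[ViralLocus]:
    """Chain hits on the same contig and strand within ``max_gap_nt`` of each
    other into loci.  Frame changes within a chain are deliberately allowed —
    they are evidence, not a reason to split."""
    if max_gap_nt < 0:
        raise ValueError("max_gap_nt must be >= 0")
    groups: dict[tuple[str, str], list[AlignmentHit]] = {}
    for h in hits:
        groups.setdefault((h.contig_id, h.strand), []).append(h)
    loci: list[ViralLocus] = []
    for (contig_id, strand), members in sorted(groups.items()):
        members.sort(key=lambda h: (h.subject_interval_nt.start, h.probe_id, h.frame))
        chain: list[AlignmentHit] = []
        chain_end = None
        for h in members:
            iv = h.subject_interval_nt
            if chain and iv.start - chain_end > max_gap_nt:
                loci.append(_make_locus(contig_id, strand, chain))
                chain = []
                chain_end = None
            chain.append(h)
            chain_end = iv.end if chain_end is None else max(chain_end, iv.end)
        if chain:
            loci.append(_make_locus(contig_id, strand, chain))
    loci.sort(key=lambda l: (l.contig_id, l.span_nt.start, l.strand))
    for idx, locus in enumerate(loci, start=1):
        locus.locus_id = f"locus_{idx:04d}"
    return loci


def _make_locus(contig_id: str, strand: str, chain: list[AlignmentHit]) -> ViralLocus:
    start = min(h.subject_interval_nt.start for h in chain)
    end = max(h.subject_interval_nt.end for h in chain)
    return ViralLocus(
        locus_id="",
        contig_id=contig_id,
        span_nt=Interval(start, end, strand),
        strand=strand,
        member_hits=list(chain),
    )


def filter_shadow_loci(loci: Sequence[ViralLocus]) -> list[ViralLocus]:
    """Drop antisense shadows of strong loci.

    The reverse-complement reading of a real viral gene can itself align
    weakly to the probe library, producing a low-scoring locus on the
    opposite strand at the same coordinates.  A locus is removed when >=80%
    of its span is covered by an opposite-strand locus on the same contig
    whose best score is at least twice its own.  Requires best_score to be
    populated (run assign_taxon first).
    """
    kept = []
    for locus in loci:
        shadowed = any(
            other is not locus
            and other.contig_id == locus.contig_id
            and other.strand != locus.strand
            and other.best_score >= 2 * locus.best_score
            and _overlap(other.span_nt, locus.span_nt) >= 0.8 * len(locus.span_nt)
            for other in loci
        )
        if not shadowed:
            kept.append(locus)
    return kept


def _overlap(a: Interval, b: Interval) -> int:
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def assign_taxon(
    locus: ViralLocus,
    margin_min: int = matrices.DEFAULT_MARGIN_MIN,
) -> tuple[str, str, int]:
    """Best-hit taxon assignment under a score-margin rule.

    The taxon of the highest-scoring member hit wins only when it beats the
    best score of every other taxon by at least ``margin_min``; otherwise the
    locus stays "unclassified".  The gene label is NS, VP, or "both" when the
    merged locus carries hits to both gene classes.
    """
    if not locus.member_hits:
        raise ValueError(f"locus {locus.locus_id} has no member hits")
    best_by_taxon: dict[str, int] = {}
    for h in locus.member_hits:
        best_by_taxon[h.taxon_label] = max(
            best_by_taxon.get(h.taxon_label, 0), h.score
        )
    best_taxon = max(sorted(best_by_taxon), key=lambda t: best_by_taxon[t])
    best_score = best_by_taxon[best_taxon]
    others = [v for t, v in best_by_taxon.items() if t != best_taxon]
    margin = best_score - max(others) if others else best_score
    taxon = best_taxon if margin >= margin_min else "unclassified"
    # gene content judged from the winning taxon's hits; weak cross-taxon
    # hits do not decide whether a locus spans NS, VP or both
    gene_hits = (
        [h for h in locus.member_hits if h.taxon_label == best_taxon]
        if margin >= margin_min
        else locus.member_hits
    )
    genes = {h.gene_label for h in gene_hits}
    if genes == {"NS"}:
        gene = "NS"
    elif genes == {"VP"}:
        gene = "VP"
    elif genes >= {"NS", "VP"}:
        gene = "both"
    else:  # pragma: no cover - gene labels are validated upstream
        gene = "unknown"
    locus.assigned_taxon = taxon
    locus.assigned_gene = gene
    locus.best_score = best_score
    locus.score_margin = margin
    return taxon, gene, margin
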