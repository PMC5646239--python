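"""Per-locus characterization: ORFs, motifs, integrity and EVE adjudication.

The adjudication logic mirrors how paleovirologists separate endogenous viral
elements (EVEs) from exogenous viral DNA caught in an assembly: a sequence
that has spent evolutionary time in the germline accumulates in-frame stops,
frameshifting indels and transposable-element insertions, while an exogenous
virus keeps intact, full-length ORFs.  A locus with none of the degradation
flags and at least one full-length gene ORF is called putative_exogenous;
any degradation flag makes it putative_eve; everything else (typically a
truncated contig with no complete ORF) stays ambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .screen import AlignmentHit, ViralLocus, translate_codons
from .seqio import Contig, Feature, Interval, revcomp

# NS1 replicase motifs: the HVH/HIH metal-coordination pairs of the
# endonuclease domain and the Walker-type helicase P-loop motifs.
DEFAULT_NS1_MOTIFS: dict[str, str] = {
    "HVH": "HVH",
    "GPXNTGKS": "GPXNTGKS",
    "HIH": "HIH",
    "GPASTGKS": "GPASTGKS",
}

# Canonical parvoviral capsid phospholipase A2 signatures: the calcium-binding
# loop (YXGXG) and the catalytic motif (HDXXY), expected in the VP N-terminus.
DEFAULT_PLA2_MOTIFS: dict[str, str] = {
    "PLA2_Ca_loop": "YXGXG",
    "PLA2_catalytic": "HDXXY",
}

DEFAULT_MIN_ORF_AA = 100
FULL_LENGTH_COVER_FRACTION = 0.8


@dataclass
class OrfCall:
    """An open reading frame in forward-contig coordinates.

    Complete ORFs run ATG..stop (interval includes the stop codon).
    Incomplete calls are stop-free open stretches abutting a contig end,
    reported for truncated-contig handling.
    """

    contig_id: str
    interval_nt: Interval
    strand: str
    peptide: str  # without the terminal stop
    gene_label: str = "unknown"
    complete: bool = True


@dataclass
class MotifHit:
    motif_name: str
    pattern: str
    start_aa: int
    end_aa: int


@dataclass
class IntegrityReport:
    """Degradation evidence for one locus."""

    locus_id: str
    n_internal_stops: int
    n_frameshifts: int
    repeat_overlap: bool
    has_full_length_orf: dict[str, bool]
    flank_genomic: bool = False
    stops_by_gene: dict[str, int] = field(default_factory=dict)


@dataclass
class LocusStatus:
    status: str  # putative_exogenous | putative_eve | ambiguous
    evidence: list[str]


def extract_orfs(
    contig: Contig, strand: str, min_len_aa: int = DEFAULT_MIN_ORF_AA
) -> list[OrfCall]:
    """All maximal ATG-to-stop ORFs with peptide >= min_len_aa on one strand,
    plus incomplete stop-free stretches touching a contig end in each frame."""
    if min_len_aa < 1:
        raise ValueError("min_len_aa must be >= 1")
    seq = contig.seq if strand == "+" else revcomp(contig.seq)
    L = len(seq)
    calls: list[OrfCall] = []
    for off in range(3):
        pep = translate_codons(seq[off:])
        n = len(pep)
        # complete ORFs: first M after the previous stop, through the stop
        prev_stop = -1
        for j in range(n):
            if pep[j] != "*":
                continue
            m = pep.find("M", prev_stop + 1, j)
            if m != -1 and j - m >= min_len_aa:
                calls.append(
                    _orf_from_frame(contig, strand, off, m, j + 1, pep[m:j], True)
                )
            prev_stop = j
        # incomplete stretches touching a frame end (truncated contigs)
        first_stop = pep.find("*")
        last_stop = pep.rfind("*")
        if first_stop == -1:
            if n >= min_len_aa:
                calls.append(_orf_from_frame(contig, strand, off, 0, n, pep, False))
        else:
            if first_stop >= min_len_aa:
                calls.append(
                    _orf_from_frame(
                        contig, strand, off, 0, first_stop, pep[:first_stop], False
                    )
                )
            if n - (last_stop + 1) >= min_len_aa:
                calls.append(
                    _orf_from_frame(
                        contig, strand, off, last_stop + 1, n, pep[last_stop + 1 :], False
                    )
                )
    calls.sort(key=lambda o: (o.interval_nt.start, o.interval_nt.end, not o.complete))
    return calls


def _orf_from_frame(
    contig: Contig,
    strand: str,
    frame_offset: int,
    aa_start: int,
    aa_end: int,
    peptide: str,
    complete: bool,
) -> OrfCall:
    L = len(contig.seq)
    nt0 = frame_offset + 3 * aa_start
    nt1 = frame_offset + 3 * aa_end
    if strand == "+":
        iv = Interval(nt0, nt1, "+")
    else:
        iv = Interval(L - nt1, L - nt0, "-")
    return OrfCall(contig.id, iv, strand, peptide, complete=complete)


# fragment-chain tolerances: genuine frameshift fragments of one probe tile
# the query with at most slight overlap; anything worse is a spurious echo
_CHAIN_MAX_Q_OVERLAP_AA = 30
_CHAIN_MAX_S_OVERLAP_NT = 90


def _best_chain(hits: list[AlignmentHit], strand: str) -> list[AlignmentHit]:
    """Maximum-score collinear fragment chain for one probe's hits.

    Fragments must advance along both the probe (query) and the contig
    (strand-aware), with bounded overlaps.  This is ordinary HSP chaining:
    it keeps the multi-frame fragment chains that frameshifted loci produce
    and discards low-scoring off-diagonal echoes of the same probe.
    """
    if len(hits) <= 1:
        return list(hits)
    hs = sorted(hits, key=lambda h: (h.query_interval[0], h.subject_interval_nt.start))

    def compatible(a: AlignmentHit, b: AlignmentHit) -> bool:
        # b follows a in query
        if b.query_interval[0] < a.query_interval[0]:
            return False
        if a.query_interval[1] - b.query_interval[0] > _CHAIN_MAX_Q_OVERLAP_AA:
            return False
        sa, sb = a.subject_interval_nt, b.subject_interval_nt
        if strand == "+":
            return sb.start >= sa.start and sa.end - sb.start <= _CHAIN_MAX_S_OVERLAP_NT
        return sb.end <= sa.end and sb.end - sa.start <= _CHAIN_MAX_S_OVERLAP_NT

    n = len(hs)
    best = [h.score for h in hs]
    prev = [-1] * n
    for i in range(n):
        for j in range(i):
            if compatible(hs[j], hs[i]) and best[j] + hs[i].score > best[i]:
                best[i] = best[j] + hs[i].score
                prev[i] = j
    end = max(range(n), key=lambda i: best[i])
    chain = []
    while end != -1:
        chain.append(hs[end])
        end = prev[end]
    chain.reverse()
    return chain


def evidence_hits(locus: ViralLocus) -> list[AlignmentHit]:
    """The member hits that count as gene-structure evidence.

    Hits are restricted to the assigned taxon (when the locus is classified)
    and reduced to the best collinear chain per probe; weak off-target hits
    from other genera, and off-diagonal echoes of the same probes, say
    nothing about the locus's own gene structure.
    """
    hits = locus.member_hits
    if locus.assigned_taxon and locus.assigned_taxon != "unclassified":
        taxon_hits = [h for h in hits if h.taxon_label == locus.assigned_taxon]
        if taxon_hits:
            hits = taxon_hits
    out: list[AlignmentHit] = []
    for probe_id in sorted({h.probe_id for h in hits}):
        out.extend(
            _best_chain([h for h in hits if h.probe_id == probe_id], locus.strand)
        )
    return out


def gene_hit_span(locus: ViralLocus, gene: str) -> Interval | None:
    """Union span of the locus's evidence hits carrying one gene label."""
    hits = [h for h in evidence_hits(locus) if h.gene_label == gene]
    if not hits:
        return None
    start = min(h.subject_interval_nt.start for h in hits)
    end = max(h.subject_interval_nt.end for h in hits)
    return Interval(start, end, locus.strand)


def call_gene_orf(
    locus: ViralLocus, orfs: Sequence[OrfCall]
) -> dict[str, OrfCall | None]:
    """Per gene label present in the locus, the complete ORF on the locus
    strand that best covers that gene's hit span (ties: longer ORF, then
    lower start).  Coverage, not raw length, decides: with slightly
    overlapping NS/VP genes the longer NS ORF also touches the VP span."""
    result: dict[str, OrfCall | None] = {}
    for gene in sorted({h.gene_label for h in evidence_hits(locus)}):
        span = gene_hit_span(locus, gene)
        candidates = [
            o
            for o in orfs
            if o.complete
            and o.contig_id == locus.contig_id
            and o.strand == locus.strand
            and o.interval_nt.overlaps(span)
        ]
        if candidates:
            best = max(
                candidates,
                key=lambda o: (
                    _overlap_len(o.interval_nt, span),
                    len(o.interval_nt),
                    -o.interval_nt.start,
                ),
            )
            best.gene_label = gene
            result[gene] = best
        else:
            result[gene] = None
    return result


def _motif_match(pattern: str, window: str) -> bool:
    return all(p == w or p == "X" or w == "X" for p, w in zip(pattern, window))


def scan_motifs(peptide: str, motif_set: Mapping[str, str]) -> list[MotifHit]:
    """Every occurrence of every pattern; X is a wildcard on either side."""
    if not motif_set:
        raise ValueError("motif set is empty")
    hits = []
    for name, pattern in motif_set.items():
        k = len(pattern)
        for i in range(len(peptide) - k + 1):
            if _motif_match(pattern, peptide[i : i + k]):
                hits.append(MotifHit(name, pattern, i, i + k))
    hits.sort(key=lambda h: (h.start_aa, h.motif_name))
    return hits


def _frame_changes(hits: list[AlignmentHit]) -> int:
    """Frame changes between consecutive fragments of the same probe.

    A frameshifting indel makes one probe align as a same-strand chain of
    fragments in different frames; frame differences between *different*
    probes carry no such signal (two probes can simply prefer different
    subregions), so changes are counted within each probe's own chain.
    """
    total = 0
    by_probe: dict[str, list[AlignmentHit]] = {}
    for h in hits:
        by_probe.setdefault(h.probe_id, []).append(h)
    for chain in by_probe.values():
        chain.sort(key=lambda h: h.subject_interval_nt.start)
        total += sum(1 for a, b in zip(chain, chain[1:]) if a.frame != b.frame)
    return total


# a '*' aligned in the outermost edges of the probe is the gene's own
# terminator (or an over-extension artefact), not a premature stop
_STOP_QUERY_FRACTION = (0.05, 0.9)


def _count_stops(hits: list[AlignmentHit]) -> int:
    """Premature stops in the union of hit-covered peptide regions.

    Counted per frame without double-counting overlaps.  A stop is internal
    (the EVE signal) only when its approximate probe coordinate falls inside
    the probe body; local alignments occasionally read one or two codons past
    the genuine gene terminator, which must not count as degradation.
    """
    total = 0
    by_frame: dict[str, list[AlignmentHit]] = {}
    for h in hits:
        by_frame.setdefault(h.frame, []).append(h)
    for frame_hits in by_frame.values():
        frame_hits.sort(key=lambda h: h.subject_interval_aa[0])
        covered_end = -1
        for h in frame_hits:
            a0, a1 = h.subject_interval_aa
            skip = max(0, covered_end - a0)
            q0, q1 = h.query_interval
            slen = max(1, len(h.subject_peptide))
            for i, ch in enumerate(h.subject_peptide):
                if ch != "*" or i < skip:
                    continue
                if h.probe_length > 0:
                    approx_q = q0 + (q1 - q0) * (i / slen)
                    lo, hi = _STOP_QUERY_FRACTION
                    if not (lo * h.probe_length <= approx_q < hi * h.probe_length):
                        continue
                total += 1
            covered_end = max(covered_end, a1)
    return total


def assess_integrity(
    locus: ViralLocus,
    gene_orfs: Mapping[str, OrfCall | None],
    repeat_features: Sequence[Feature] = (),
    known_contigs: set[str] | None = None,
    flank_genomic: bool = False,
) -> IntegrityReport:
    """Count degradation evidence for one locus.

    Internal stops are '*' residues inside the union of hit-covered peptide
    regions.  Frameshifts are frame changes between consecutive member hits
    of the same gene (NS and VP legitimately sit in different frames when the
    genes overlap, so cross-gene changes are not counted).  Repeat overlap is
    taken from an externally supplied repeat/TE annotation.
    """
    if not locus.member_hits:
        raise ValueError(f"locus {locus.locus_id} has no member hits")
    if known_contigs is not None:
        for feat in repeat_features:
            if feat.contig_id not in known_contigs:
                raise ValueError(f"repeat feature on unknown contig {feat.contig_id!r}")
    ev_hits = evidence_hits(locus)
    genes = sorted({h.gene_label for h in ev_hits})
    stops_by_gene = {}
    n_frameshifts = 0
    for gene in genes:
        gene_hits = [h for h in ev_hits if h.gene_label == gene]
        stops_by_gene[gene] = _count_stops(gene_hits)
        n_frameshifts += _frame_changes(gene_hits)
    n_stops = sum(stops_by_gene.values())
    repeat_overlap = any(
        feat.contig_id == locus.contig_id and feat.interval.overlaps(locus.span_nt)
        for feat in repeat_features
    )
    has_full: dict[str, bool] = {}
    for gene in genes:
        orf = gene_orfs.get(gene)
        span = gene_hit_span(locus, gene)
        covered = (
            orf is not None
            and orf.interval_nt.overlaps(span)
            and _overlap_len(orf.interval_nt, span) >= FULL_LENGTH_COVER_FRACTION * len(span)
        )
        has_full[gene] = bool(covered and stops_by_gene[gene] == 0)
    return IntegrityReport(
        locus_id=locus.locus_id,
        n_internal_stops=n_stops,
        n_frameshifts=n_frameshifts,
        repeat_overlap=repeat_overlap,
        has_full_length_orf=has_full,
        flank_genomic=flank_genomic,
        stops_by_gene=stops_by_gene,
    )


def _overlap_len(a: Interval, b: Interval) -> int:
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def classify_locus_status(report: IntegrityReport) -> LocusStatus:
    """Pure adjudication rule over the integrity flags."""
    evidence = []
    if report.n_internal_stops > 0:
        evidence.append("internal_stops")
    if report.n_frameshifts > 0:
        evidence.append("frameshifts")
    if report.repeat_overlap:
        evidence.append("repeat_overlap")
    if report.flank_genomic:
        evidence.append("flank_genomic")
    if evidence:
        return LocusStatus("putative_eve", evidence)
    full = [g for g, ok in report.has_full_length_orf.items() if ok]
    if full:
        return LocusStatus(
            "putative_exogenous", [f"full_length_orf:{g}" for g in full]
        )
    return LocusStatus("ambiguous", ["no_full_length_orf"])


def detect_gene_overlap(orf_a: OrfCall, orf_b: OrfCall) -> int:
    """Signed nt overlap between two ORF intervals: positive = overlap length,
    negative = gap length.  Frame-agnostic interval arithmetic; symmetric."""
    if orf_a.contig_id != orf_b.contig_id:
        raise ValueError(
            f"ORFs on different contigs: {orf_a.contig_id} vs {orf_b.contig_id}"
        )
    return min(orf_a.interval_nt.end, orf_b.interval_nt.end) - max(
        orf_a.interval_nt.start, orf_b.interval_nt.start
    )
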