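"""ORF calling, motif scanning, integrity assessment and EVE adjudication."""

import itertools
import re

import pytest

from evescreen.annotate import (
    DEFAULT_NS1_MOTIFS,
    DEFAULT_PLA2_MOTIFS,
    IntegrityReport,
    OrfCall,
    assess_integrity,
    call_gene_orf,
    classify_locus_status,
    detect_gene_overlap,
    extract_orfs,
    scan_motifs,
)
from evescreen.screen import merge_hits_to_loci, translate_codons
from evescreen.seqio import Contig, Feature, Interval, revcomp
from tests.test_screen import _hit


# ---------------------------------------------------------------------------
# ORF extraction


def test_extract_orfs_minimal_example():
    orfs = extract_orfs(Contig("c", "ATGAAATAA"), "+", min_len_aa=1)
    complete = [o for o in orfs if o.complete]
    assert len(complete) == 1
    o = complete[0]
    assert (o.interval_nt.start, o.interval_nt.end) == (0, 9)
    assert o.peptide == "MK"


def test_extract_orfs_no_atg_gives_incomplete_only():
    # stop-free frame without any ATG
    orfs = extract_orfs(Contig("c", "AAA" * 50), "+", min_len_aa=10)
    assert not any(o.complete for o in orfs)
    assert any(not o.complete for o in orfs)


def _naive_orf_scanner(seq: str, min_len_aa: int):
    """Independent regex-based ORF finder (complete ORFs, one strand)."""
    found = set()
    for off in range(3):
        pep = translate_codons(seq[off:])
        for m in re.finditer(r"M[^*]*\*", pep):
            # trim to the first M after the previous stop: regex already
            # anchors at an M; ensure maximality by checking the preceding
            # residue is a stop or start-of-frame, else skip (not maximal)
            s = m.start()
            prev_stop = pep.rfind("*", 0, s)
            first_m = pep.find("M", prev_stop + 1)
            if first_m != s:
                continue
            if (m.end() - s - 1) >= min_len_aa:
                found.add((off + 3 * s, off + 3 * m.end()))
    return found


def test_extract_orfs_agrees_with_naive_scanner(rng):
    for _ in range(5):
        seq = "".join(rng.choice(list("ACGT"), size=3000))
        contig = Contig("c", seq)
        got = {
            (o.interval_nt.start, o.interval_nt.end)
            for o in extract_orfs(contig, "+", min_len_aa=30)
            if o.complete
        }
        assert got == _naive_orf_scanner(seq, 30)


def test_extract_orfs_minus_strand_coordinates():
    plus = "ATGAAATAA"
    contig = Contig("c", revcomp(plus))
    orfs = [o for o in extract_orfs(contig, "-", min_len_aa=1) if o.complete]
    assert len(orfs) == 1
    assert (orfs[0].interval_nt.start, orfs[0].interval_nt.end) == (0, 9)
    assert orfs[0].strand == "-"
    assert orfs[0].peptide == "MK"


# ---------------------------------------------------------------------------
# gene ORF selection


def _orf(contig, start, end, strand="+", gene="unknown"):
    return OrfCall(
        contig,
        Interval(start, end, strand),
        strand,
        "M" + "A" * ((end - start) // 3 - 2),
        gene_label=gene,
    )


def test_call_gene_orf_prefers_best_covering_orf():
    hits = [
        _hit("c1", 0, 1950, score=2000, gene="NS"),
        _hit("c1", 1942, 3442, score=1500, gene="VP", probe="p2", frame="+2"),
    ]
    locus = merge_hits_to_loci(hits, 1000)[0]
    ns_orf = _orf("c1", 0, 1953)
    vp_orf = _orf("c1", 1942, 3445)
    result = call_gene_orf(locus, [ns_orf, vp_orf])
    assert result["NS"] is ns_orf
    assert result["VP"] is vp_orf


def test_call_gene_orf_longest_among_equal_coverage():
    hits = [_hit("c1", 0, 1950, score=2000, gene="NS")]
    locus = merge_hits_to_loci(hits, 1000)[0]
    long_orf = _orf("c1", 0, 1953)
    short_orf = _orf("c1", 0, 903)
    assert call_gene_orf(locus, [long_orf, short_orf])["NS"] is long_orf


def test_call_gene_orf_none_when_no_complete_orf():
    hits = [_hit("c1", 0, 300, gene="NS")]
    locus = merge_hits_to_loci(hits, 1000)[0]
    assert call_gene_orf(locus, [])["NS"] is None


# ---------------------------------------------------------------------------
# motifs


def test_scan_motif_wildcard_semantics():
    hits = scan_motifs("AAAGPANTGKSAAA", {"GPXNTGKS": "GPXNTGKS"})
    assert len(hits) == 1
    assert (hits[0].start_aa, hits[0].end_aa) == (3, 11)
    assert scan_motifs("AAAA", {"HIH": "HIH"}) == []
    # X in the peptide matches any pattern residue
    assert len(scan_motifs("HXH", {"HIH": "HIH"})) == 1


def test_all_four_ns1_motifs_present_in_chap_probes(probe_library):
    for probe in probe_library:
        if probe.taxon_label == "Chapparvovirus" and probe.gene_label == "NS":
            names = {m.motif_name for m in scan_motifs(probe.seq, DEFAULT_NS1_MOTIFS)}
            assert names == set(DEFAULT_NS1_MOTIFS)


def test_pla2_motifs_in_chap_vp_n_terminal_third(probe_library):
    for probe in probe_library:
        if probe.taxon_label == "Chapparvovirus" and probe.gene_label == "VP":
            n_third = probe.seq[: len(probe.seq) // 3]
            names = {m.motif_name for m in scan_motifs(n_third, DEFAULT_PLA2_MOTIFS)}
            assert names == set(DEFAULT_PLA2_MOTIFS)


def test_motif_false_positive_rate_on_random_peptides(rng):
    """8-mer motifs essentially never fire on random 300-aa peptides; 3-mers
    fire at roughly the (1/20)^3-per-window binomial rate."""
    from evescreen.matrices import AA20

    counts = {name: 0 for name in DEFAULT_NS1_MOTIFS}
    for _ in range(100):
        pep = "".join(rng.choice(list(AA20), size=300))
        for m in scan_motifs(pep, DEFAULT_NS1_MOTIFS):
            counts[m.motif_name] += 1
    assert counts["GPXNTGKS"] == 0
    assert counts["GPASTGKS"] == 0
    assert counts["HVH"] <= 12  # mean ~3.7 peptides with a hit
    assert counts["HIH"] <= 12


def test_scan_motifs_requires_patterns():
    with pytest.raises(ValueError):
        scan_motifs("MKV", {})


# ---------------------------------------------------------------------------
# integrity and status


def test_frameshift_count_from_same_probe_frame_changes():
    hits = [
        _hit("c1", 0, 300, frame="+1", probe="p1"),
        _hit("c1", 310, 610, frame="+2", probe="p1"),
        _hit("c1", 620, 920, frame="+1", probe="p1"),
    ]
    # make the chain query-collinear
    for i, h in enumerate(hits):
        h.query_interval = (i * 100, i * 100 + 100)
    locus = merge_hits_to_loci(hits, 1000)[0]
    report = assess_integrity(locus, {})
    assert report.n_frameshifts == 2


def test_stop_counting_in_hit_covered_regions():
    h1 = _hit("c1", 0, 300, frame="+1")
    h1.subject_peptide = "AAAA*AAAA*AA"
    h1.subject_interval_aa = (0, 12)
    h2 = _hit("c1", 12, 312, frame="+1", probe="p1")  # overlapping region
    h2.subject_peptide = "*AAA" + "A" * 96
    h2.subject_interval_aa = (4, 104)
    h2.query_interval = (30, 130)
    locus = merge_hits_to_loci([h1, h2], 1000)[0]
    report = assess_integrity(locus, {})
    # two stops in the first hit; the second hit's '*' lies in the already
    # counted overlap region and is not double-counted
    assert report.n_internal_stops == 2


def test_gene_terminator_stop_not_counted_as_internal():
    """A '*' aligned at the probe's C-terminal edge is the gene's own stop
    codon picked up by slight alignment over-extension, not degradation."""
    h = _hit("c1", 0, 1980)
    h.probe_length = 660
    h.query_interval = (0, 658)
    h.subject_interval_aa = (0, 660)
    h.subject_peptide = "A" * 320 + "*" + "A" * 337 + "*" + "A"  # body + terminator
    locus = merge_hits_to_loci([h], 1000)[0]
    report = assess_integrity(locus, {})
    assert report.n_internal_stops == 1  # only the mid-gene stop


def test_repeat_overlap_and_unknown_contig_error():
    locus = merge_hits_to_loci([_hit("c1", 100, 400)], 1000)[0]
    rep = Feature("c1", Interval(350, 700), "repeat_region")
    report = assess_integrity(locus, {}, [rep], known_contigs={"c1"})
    assert report.repeat_overlap
    with pytest.raises(ValueError, match="unknown contig"):
        assess_integrity(locus, {}, [Feature("cX", Interval(0, 10), "r")], {"c1"})


def _report(stops=0, fs=0, repeat=False, flank=False, full=True):
    return IntegrityReport(
        locus_id="L",
        n_internal_stops=stops,
        n_frameshifts=fs,
        repeat_overlap=repeat,
        has_full_length_orf={"NS": full},
        flank_genomic=flank,
    )


def test_classification_rule_exhaustive():
    """Status is total and deterministic over all flag combinations."""
    for stops, fs, repeat, flank, full in itertools.product(
        (0, 2), (0, 1), (False, True), (False, True), (False, True)
    ):
        status = classify_locus_status(_report(stops, fs, repeat, flank, full))
        if stops or fs or repeat or flank:
            assert status.status == "putative_eve"
            expect = []
            if stops:
                expect.append("internal_stops")
            if fs:
                expect.append("frameshifts")
            if repeat:
                expect.append("repeat_overlap")
            if flank:
                expect.append("flank_genomic")
            assert status.evidence == expect
        elif full:
            assert status.status == "putative_exogenous"
            assert status.evidence == ["full_length_orf:NS"]
        else:
            assert status.status == "ambiguous"


# ---------------------------------------------------------------------------
# gene overlap


def test_detect_gene_overlap_examples():
    a = _orf("c1", 0, 300)
    assert detect_gene_overlap(a, _orf("c1", 292, 800)) == 8
    assert detect_gene_overlap(a, _orf("c1", 310, 800)) == -10
    assert detect_gene_overlap(_orf("c1", 292, 800), a) == 8  # symmetric
    with pytest.raises(ValueError, match="different contigs"):
        detect_gene_overlap(a, _orf("c2", 0, 300))


# ---------------------------------------------------------------------------
# on simulated data


def test_degraded_planting_carries_engineered_evidence(screened_default_assembly):
    """Degraded plantings show exactly the engineered stop count and at
    least one frameshift; intact plantings show neither."""
    data = screened_default_assembly
    by_id = {c.id: c for c in data["contigs"]}
    truth_by_contig = {t.contig_id: t for t in data["truths"]}
    checked = 0
    for locus in data["loci"]:
        truth = truth_by_contig.get(locus.contig_id)
        if truth is None or locus.strand != truth.strand:
            continue
        orfs = extract_orfs(by_id[locus.contig_id], locus.strand)
        gene_orfs = call_gene_orf(locus, orfs)
        report = assess_integrity(locus, gene_orfs, data["repeats"], set(by_id))
        if truth.planted_class == "degraded":
            assert report.n_internal_stops == truth.planted_stops == 2
            assert report.n_frameshifts >= 1
        else:
            assert report.n_internal_stops == 0
            assert report.n_frameshifts == 0
        checked += 1
    assert checked == len(data["truths"])


def test_truncated_locus_is_ambiguous():
    """A locus whose contig ends mid-gene has no complete ORF: ambiguous."""
    hits = [_hit("c1", 0, 300, gene="NS")]
    locus = merge_hits_to_loci(hits, 1000)[0]
    report = assess_integrity(locus, {"NS": None})
    status = classify_locus_status(report)
    assert status.status == "ambiguous"
    assert status.evidence == ["no_full_length_orf"]
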