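"""Synthetic assemblies with planted viral loci and a ground-truth manifest.

The generator emulates the situation the screen faces in real WGS data: long
random host-background contigs, and embedded parvovirus-like loci with the
characteristic genome architecture — a ~660 aa replicase (NS) followed by a
shorter capsid (VP) on the same strand, their ORFs overlapping by a few
nucleotides because the VP start codon sits inside the NS stop region in a
different reading frame.  Intact plantings model exogenous viral DNA caught
in an assembly; degraded plantings model endogenous viral elements, carrying
engineered in-frame stops, frameshifting single-nt deletions and optional
repeat-element insertions.

Overlap geometry: an overlap of k nt between two complete ATG-to-stop ORFs
forces a frame difference of (-k mod 3), so k divisible by 3 would put VP in
the NS frame, where the NS stop codon becomes an internal VP stop.  Such
overlaps cannot exist between intact genes and are rejected; the default
overlap choices are {8, 10, 11}.

Everything is driven by one seeded generator: identical config + seed gives
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio.Data import CodonTable

from .annotate import extract_orfs
from .screen import translate_codons  # noqa: F401  (re-exported for validators)
from .seqio import Contig, Feature, Interval, ProteinProbe, revcomp, write_fasta

_TABLE = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = tuple(sorted(_TABLE.stop_codons))
_SENSE_CODONS = tuple(sorted(_TABLE.forward_table))
_BACK_TABLE: dict[str, tuple[str, ...]] = {}
for _codon in _SENSE_CODONS:
    _BACK_TABLE.setdefault(_TABLE.forward_table[_codon], tuple())
_BACK_TABLE = {
    aa: tuple(sorted(c for c in _SENSE_CODONS if _TABLE.forward_table[c] == aa))
    for aa in {_TABLE.forward_table[c] for c in _SENSE_CODONS}
}

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# Stops all three reading frames of the strand it is read on; planted on both
# sides of each locus so called ORFs cannot bleed into host background.
FRAME_INSULATOR = "TAAATAAATAAA"

# Fixed synthetic 300-nt "repeat element", also emitted as a BED annotation so
# the repeat-overlap adjudication path is testable without a repeat finder.
_repeat_rng = np.random.default_rng(424242)
REPEAT_SEQ = "".join(_repeat_rng.choice(list("ACGT"), size=300))

NS1_MOTIF_INSTANCES = {  # literal instances written into chapparvovirus NS probes
    90: "HVH",
    130: "HIH",
    380: "GPANTGKS",  # matches the GPXNTGKS wildcard pattern
    420: "GPASTGKS",
}
PLA2_MOTIF_INSTANCES = {25: "YLGLG", 55: "HDLRY"}  # VP N-terminal third

_LIBRARY_SEED = 7331  # the probe library is a fixed reference, not run-seeded


@dataclass
class SimulationConfig:
    n_contigs: int = 6
    contig_len_range: tuple[int, int] = (7000, 9000)
    gc_content: float = 0.41
    n_intact: int = 3
    n_degraded: int = 2
    divergence_aa: float = 0.3
    ns_vp_overlap_nt: int | None = None  # None: sample from overlap_choices
    overlap_choices: tuple[int, ...] = (8, 10, 11)
    n_stops: int = 2
    n_indels: int = 1
    insert_repeat: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.gc_content < 1):
            raise ValueError("gc_content must be in (0,1)")
        if not (0 <= self.divergence_aa <= 0.6):
            raise ValueError("divergence_aa must be in [0, 0.6]")
        if min(self.n_contigs, self.n_intact, self.n_degraded, self.n_stops, self.n_indels) < 0:
            raise ValueError("counts must be >= 0")
        if self.contig_len_range[0] < 1 or self.contig_len_range[0] > self.contig_len_range[1]:
            raise ValueError("invalid contig_len_range")
        for k in self.overlap_choices + (
            (self.ns_vp_overlap_nt,) if self.ns_vp_overlap_nt is not None else ()
        ):
            _check_overlap(k)
        if self.n_intact + self.n_degraded > self.n_contigs:
            raise ValueError("more plantings than contigs (one planting per contig)")


def _check_overlap(k: int) -> None:
    if k < 1:
        raise ValueError("overlap must be >= 1 nt")
    if k % 3 == 0:
        raise ValueError(
            f"NS/VP overlap of {k} nt is impossible between complete ORFs: "
            "an overlap divisible by 3 puts VP in the NS reading frame, where "
            "the NS stop codon becomes an internal VP stop"
        )


@dataclass
class TruthRecord:
    """Ground truth for one planting."""

    contig_id: str
    span: tuple[int, int]  # locus span on the forward strand, nt
    strand: str
    ns_probe_id: str
    vp_probe_id: str
    taxon_label: str
    planted_class: str  # intact | degraded
    planted_overlap_nt: int
    planted_stops: int
    planted_indels: int
    planted_repeat: bool
    ns_interval: tuple[int, int] | None = None  # intact only
    vp_interval: tuple[int, int] | None = None
    repeat_interval: tuple[int, int] | None = None


# ---------------------------------------------------------------------------
# elementary generators


def simulate_host_background(
    n: int, len_range: tuple[int, int], gc: float, rng: np.random.Generator
) -> list[Contig]:
    """i.i.d. nucleotide contigs at the stated GC content."""
    if not (0 < gc < 1):
        raise ValueError("gc must be in (0,1)")
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    contigs = []
    for i in range(n):
        length = int(rng.integers(len_range[0], len_range[1] + 1))
        seq = "".join(rng.choice(list("ACGT"), size=length, p=probs))
        contigs.append(Contig(id=f"contig_{i+1:03d}", seq=seq))
    return contigs


def evolve_protein(seq: str, divergence_aa: float, rng: np.random.Generator) -> str:
    """Site-independent substitution: each site replaced with probability
    ``divergence_aa`` by a uniform draw from the other 19 residues."""
    if not (0 <= divergence_aa <= 0.6):
        raise ValueError("divergence_aa must be in [0, 0.6]")
    out = list(seq)
    hit = rng.random(len(seq)) < divergence_aa
    for i in np.flatnonzero(hit):
        choices = [a for a in AA20 if a != seq[i]]
        out[i] = choices[int(rng.integers(len(choices)))]
    return "".join(out)


def reverse_translate(protein: str, rng: np.random.Generator) -> str:
    """Uniform synonymous-codon coding sequence plus one stop codon."""
    codons = []
    for aa in protein:
        if aa not in _BACK_TABLE:
            raise ValueError(f"cannot reverse-translate residue {aa!r}")
        options = _BACK_TABLE[aa]
        codons.append(options[int(rng.integers(len(options)))])
    codons.append(STOP_CODONS[int(rng.integers(len(STOP_CODONS)))])
    return "".join(codons)


def _random_protein(length: int, rng: np.random.Generator) -> str:
    body = "".join(rng.choice(list(AA20), size=length - 1))
    return "M" + body


def _impose_motifs(seq: str, instances: dict[int, str]) -> str:
    out = list(seq)
    for pos, motif in instances.items():
        out[pos : pos + len(motif)] = motif
    return "".join(out)


# ---------------------------------------------------------------------------
# probe library (synthetic stand-in for a curated reference set)


def default_probe_library() -> list[ProteinProbe]:
    """Deterministic synthetic probe library.

    Chapparvovirus NS probes carry the four conserved NS1 motifs (HVH, HIH
    and the GPXNTGKS/GPASTGKS helicase motifs) verbatim; chapparvovirus VP
    probes carry PLA2 instances in their N-terminal third.  Probes of the
    other genera are unrelated synthetic proteins so the score-margin
    assignment has real competitors.  Independent of any run seed.
    """
    rng = np.random.default_rng(_LIBRARY_SEED)
    probes: list[ProteinProbe] = []
    chap_ns = _impose_motifs(_random_protein(660, rng), NS1_MOTIF_INSTANCES)
    chap_vp = _impose_motifs(_random_protein(500, rng), PLA2_MOTIF_INSTANCES)
    probes.append(ProteinProbe("chap_ns_1", "Chapparvovirus", "NS", chap_ns))
    probes.append(
        ProteinProbe(
            "chap_ns_2",
            "Chapparvovirus",
            "NS",
            _impose_motifs(evolve_protein(chap_ns, 0.12, rng), NS1_MOTIF_INSTANCES),
        )
    )
    probes.append(ProteinProbe("chap_vp_1", "Chapparvovirus", "VP", chap_vp))
    probes.append(
        ProteinProbe(
            "chap_vp_2",
            "Chapparvovirus",
            "VP",
            _impose_motifs(evolve_protein(chap_vp, 0.12, rng), PLA2_MOTIF_INSTANCES),
        )
    )
    for genus, prefix in (
        ("Dependoparvovirus", "dep"),
        ("Protoparvovirus", "proto"),
        ("Amdoparvovirus", "amdo"),
    ):
        probes.append(
            ProteinProbe(f"{prefix}_ns_1", genus, "NS", _random_protein(660, rng))
        )
        probes.append(
            ProteinProbe(f"{prefix}_vp_1", genus, "VP", _random_protein(700, rng))
        )
    return probes


# ---------------------------------------------------------------------------
# locus construction


def _solve_junction(k: int, rng: np.random.Generator) -> tuple[str, list[str]]:
    """Choose the NS-tail partial codon and VP codons 2..4 realising an exact
    k-nt ORF overlap: the NS frame must read through the shared region and hit
    its first stop exactly at the last 3 nt of the overlap (= inside VP)."""
    _check_overlap(k)
    r = k % 3
    if r == 2:
        t_options = list("ACGT")  # C0 = t + "AT": never a stop
    else:
        t_options = [a + b for a in "ACGT" for b in "ACGT" if a + b not in ("TA", "TG")]
    t = t_options[int(rng.integers(len(t_options)))]
    for _ in range(10000):
        vp_codons = [
            _SENSE_CODONS[int(rng.integers(len(_SENSE_CODONS)))] for _ in range(3)
        ]
        v_head = "ATG" + "".join(vp_codons)  # V[0:12]
        stop_window = v_head[k - 3 : k]
        if stop_window not in STOP_CODONS:
            continue
        ok = True
        pos = r  # NS-frame codons inside V before the stop window
        while pos + 3 <= k - 3:
            if v_head[pos : pos + 3] in STOP_CODONS:
                ok = False
                break
            pos += 3
        if ok:
            return t, vp_codons
    raise RuntimeError(f"no junction solution found for overlap {k}")  # pragma: no cover


def _build_intact_locus(
    ns_protein: str, vp_protein: str, k: int, rng: np.random.Generator
) -> tuple[str, int, int, int]:
    """Return (locus_nt, ns_end, vp_start, vp_end); NS ORF is [0, ns_end)."""
    t, vp_codons = _solve_junction(k, rng)
    vp_cds = list(reverse_translate(vp_protein, rng))
    # reverse_translate returns a string; rebuild as codon list
    vp_str = "".join(vp_cds)
    vp_list = [vp_str[i : i + 3] for i in range(0, len(vp_str), 3)]
    vp_list[1:4] = vp_codons  # junction-determined codons (VP residues 2..4)
    V = "".join(vp_list)
    ns_cds_nostop = reverse_translate(ns_protein, rng)[:-3]
    P = ns_cds_nostop + t
    locus = P + V
    ns_end = len(P) + k
    return locus, ns_end, len(P), len(P) + len(V)


def _validate_intact(locus: str, ns_end: int, vp_start: int, vp_end: int) -> bool:
    """The ORF caller must recover exactly the planted NS and VP intervals."""
    cassette = FRAME_INSULATOR + locus + FRAME_INSULATOR
    contig = Contig("cassette", cassette)
    offs = len(FRAME_INSULATOR)
    orfs = [
        (o.interval_nt.start, o.interval_nt.end)
        for o in extract_orfs(contig, "+", min_len_aa=100)
        if o.complete
    ]
    return (offs, offs + ns_end) in orfs and (offs + vp_start, offs + vp_end) in orfs


def plant_locus(
    contig: Contig,
    ns_probe: ProteinProbe,
    vp_probe: ProteinProbe,
    config: SimulationConfig,
    rng: np.random.Generator,
    planted_class: str = "intact",
) -> tuple[Contig, TruthRecord]:
    """Plant one NS+VP locus (evolved to the configured divergence) into a
    background contig, on a random strand, with the configured ORF overlap.

    Degraded plantings additionally receive engineered stop codons in NS,
    frameshifting 1-nt deletions in VP, and optionally a repeat-element
    insertion into NS.
    """
    k = (
        config.ns_vp_overlap_nt
        if config.ns_vp_overlap_nt is not None
        else int(rng.choice(config.overlap_choices))
    )
    ns_p = "M" + evolve_protein(ns_probe.seq[1:], config.divergence_aa, rng)
    vp_p = "M" + evolve_protein(vp_probe.seq[1:], config.divergence_aa, rng)
    for _attempt in range(200):
        locus, ns_end, vp_start, vp_end = _build_intact_locus(ns_p, vp_p, k, rng)
        if _validate_intact(locus, ns_end, vp_start, vp_end):
            break
    else:  # pragma: no cover - construction converges well before 200 tries
        raise RuntimeError("could not construct a clean intact locus")

    n_stops = n_indels = 0
    repeat_local: tuple[int, int] | None = None
    if planted_class == "degraded":
        locus, n_stops, n_indels, repeat_local = _degrade(
            locus, ns_end, vp_start, vp_end, config, rng
        )
    strand = "+" if rng.random() < 0.5 else "-"
    cassette = FRAME_INSULATOR + locus + FRAME_INSULATOR
    if strand == "-":
        cassette = revcomp(cassette)

    margin = 200
    if len(contig.seq) < len(cassette) + 2 * margin:
        raise ValueError(
            f"contig {contig.id} too short for planting "
            f"({len(contig.seq)} < {len(cassette) + 2 * margin})"
        )
    pos = int(rng.integers(margin, len(contig.seq) - len(cassette) - margin + 1))
    new_seq = contig.seq[:pos] + cassette + contig.seq[pos + len(cassette) :]
    new_contig = Contig(contig.id, new_seq, contig.assembly_id)

    offs = pos + len(FRAME_INSULATOR)
    L = len(locus)
    span = (offs, offs + L)

    def local_to_contig(iv: tuple[int, int]) -> tuple[int, int]:
        a, b = iv
        if strand == "+":
            return (offs + a, offs + b)
        return (offs + L - b, offs + L - a)

    record = TruthRecord(
        contig_id=contig.id,
        span=span,
        strand=strand,
        ns_probe_id=ns_probe.id,
        vp_probe_id=vp_probe.id,
        taxon_label=ns_probe.taxon_label,
        planted_class=planted_class,
        planted_overlap_nt=k,
        planted_stops=n_stops,
        planted_indels=n_indels,
        planted_repeat=repeat_local is not None,
        ns_interval=local_to_contig((0, ns_end)) if planted_class == "intact" else None,
        vp_interval=local_to_contig((vp_start, vp_end)) if planted_class == "intact" else None,
        repeat_interval=local_to_contig(repeat_local) if repeat_local else None,
    )
    return new_contig, record


def _degrade(locus, ns_end, vp_start, vp_end, config, rng):
    """Engineer stops (NS), a repeat insertion (NS), and 1-nt deletions (VP)."""
    n_ns_codons = ns_end // 3
    # stop codons into NS, well inside the hit-covered body
    lo, hi = int(0.15 * n_ns_codons), int(0.45 * n_ns_codons)
    stop_positions = sorted(
        rng.choice(np.arange(lo, hi), size=config.n_stops, replace=False)
    ) if config.n_stops else []
    locus_list = list(locus)
    for c in stop_positions:
        stop = STOP_CODONS[int(rng.integers(len(STOP_CODONS)))]
        locus_list[3 * c : 3 * c + 3] = stop
    locus = "".join(locus_list)

    repeat_local = None
    if config.insert_repeat:
        ins_at = 3 * int(0.6 * n_ns_codons)
        locus = locus[:ins_at] + REPEAT_SEQ + locus[ins_at:]
        repeat_local = (ins_at, ins_at + len(REPEAT_SEQ))
        vp_start += len(REPEAT_SEQ)
        vp_end += len(REPEAT_SEQ)

    vp_len = vp_end - vp_start
    for i in range(config.n_indels):
        frac = 0.35 + 0.3 * rng.random()
        pos = vp_start + 3 * int(frac * vp_len / 3)
        locus = locus[:pos] + locus[pos + 1 :]
        vp_end -= 1
    return locus, len(stop_positions), config.n_indels, repeat_local


# ---------------------------------------------------------------------------
# whole-assembly generation


def generate_assembly_with_truth(
    config: SimulationConfig,
) -> tuple[list[Contig], list[TruthRecord], list[Feature]]:
    """Background plus all plantings (one per contig), fully seeded.

    Returns (contigs, truth records, repeat annotation features).
    """
    rng = np.random.default_rng(config.seed)
    contigs = simulate_host_background(
        config.n_contigs, config.contig_len_range, config.gc_content, rng
    )
    probes = default_probe_library()
    chap_ns = [p for p in probes if p.taxon_label == "Chapparvovirus" and p.gene_label == "NS"]
    chap_vp = [p for p in probes if p.taxon_label == "Chapparvovirus" and p.gene_label == "VP"]
    truths: list[TruthRecord] = []
    repeats: list[Feature] = []
    classes = ["intact"] * config.n_intact + ["degraded"] * config.n_degraded
    for i, cls in enumerate(classes):
        ns_probe = chap_ns[int(rng.integers(len(chap_ns)))]
        vp_probe = chap_vp[int(rng.integers(len(chap_vp)))]
        contigs[i], rec = plant_locus(
            contigs[i], ns_probe, vp_probe, config, rng, planted_class=cls
        )
        truths.append(rec)
        if rec.repeat_interval is not None:
            repeats.append(
                Feature(
                    rec.contig_id,
                    Interval(*rec.repeat_interval),
                    "repeat_region",
                    {"Name": "synthetic_repeat"},
                )
            )
    return contigs, truths, repeats


def write_truth_manifest(truths: list[TruthRecord], path: str | Path) -> None:
    cols = [
        "contig_id", "start", "end", "strand", "ns_probe_id", "vp_probe_id",
        "taxon_label", "planted_class", "planted_overlap_nt", "planted_stops",
        "planted_indels", "planted_repeat",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for t in truths:
            fh.write(
                "\t".join(
                    str(v)
                    for v in [
                        t.contig_id, t.span[0], t.span[1], t.strand, t.ns_probe_id,
                        t.vp_probe_id, t.taxon_label, t.planted_class,
                        t.planted_overlap_nt, t.planted_stops, t.planted_indels,
                        int(t.planted_repeat),
                    ]
                )
                + "\n"
            )


def write_repeat_bed(repeats: list[Feature], path: str | Path) -> None:
    with open(path, "w") as fh:
        for feat in repeats:
            fh.write(
                f"{feat.contig_id}\t{feat.interval.start}\t{feat.interval.end}\t"
                f"{feat.attributes.get('Name', 'repeat')}\n"
            )


def write_assembly(contigs: list[Contig], path: str | Path) -> None:
    write_fasta([(c.id, c.seq) for c in contigs], path)


# ---------------------------------------------------------------------------
# clade-structured protein families (for phylogeny testing)


def simulate_clade_family(
    seed: int,
    n_clades: int = 3,
    per_clade: int = 4,
    length: int = 160,
    intra_divergence: float = 0.05,
    inter_divergence: float = 0.25,
) -> tuple[dict[str, str], dict[str, str]]:
    """Protein tips evolved down a star-of-clades tree (e.g. the avian /
    reptilian / mammalian host-class structure of a genus-level phylogeny).

    Returns (label -> sequence, label -> clade name).
    """
    rng = np.random.default_rng(seed)
    root = _random_protein(length, rng)
    seqs: dict[str, str] = {}
    clades: dict[str, str] = {}
    for c in range(n_clades):
        clade_name = f"clade{c + 1}"
        ancestor = evolve_protein(root, inter_divergence, rng)
        for t in range(per_clade):
            label = f"{clade_name}_t{t + 1}"
            seqs[label] = evolve_protein(ancestor, intra_divergence, rng)
            clades[label] = clade_name
    return seqs, clades
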