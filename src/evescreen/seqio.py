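"""Sequence and interval primitives plus FASTA/GFF3 readers and writers.

All internal coordinates are 0-based, half-open.  GFF3 output is 1-based,
inclusive; :func:`to_gff3_coords` is the single place that conversion happens.
Only the unambiguous DNA alphabet plus ``N`` is accepted on read — the
downstream translator and aligner define behaviour for nothing else.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

from Bio import SeqIO

DNA_ALPHABET = frozenset("ACGTN")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

GENE_LABELS = ("NS", "VP")


class FastaRecord(NamedTuple):
    """One FASTA record; ``description`` is the text after the first whitespace."""

    id: str
    seq: str
    description: str = ""


@dataclass(frozen=True)
class Interval:
    """0-based half-open interval with a strand."""

    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass
class Contig:
    """A nucleotide contig, the unit being screened."""

    id: str
    seq: str
    assembly_id: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("contig id must be non-empty")
        if not self.seq:
            raise ValueError(f"contig {self.id}: empty sequence")
        _validate_alphabet(self.seq, DNA_ALPHABET, self.id)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class ProteinProbe:
    """A labelled reference polypeptide used as a search query.

    ``taxon_label`` is a genus-level label (e.g. ``Chapparvovirus``);
    ``gene_label`` is ``NS`` (replicase) or ``VP`` (capsid).
    """

    id: str
    taxon_label: str
    gene_label: str
    seq: str

    def __post_init__(self) -> None:
        if not self.taxon_label or self.gene_label not in GENE_LABELS:
            raise ValueError(
                f"probe {self.id}: taxon/gene labels required (gene in {GENE_LABELS})"
            )
        if len(self.seq) < 20:
            raise ValueError(f"probe {self.id}: sequence shorter than 20 aa")
        _validate_alphabet(self.seq, PROTEIN_ALPHABET, self.id)


@dataclass
class Feature:
    """A generic annotation tied to a contig (CDS, motif, repeat ...)."""

    contig_id: str
    interval: Interval
    feature_type: str
    attributes: dict = field(default_factory=dict)


def _validate_alphabet(seq: str, alphabet: frozenset, name: str) -> None:
    for pos, ch in enumerate(seq):
        if ch not in alphabet:
            raise ValueError(
                f"{name}: illegal character {ch!r} at position {pos}"
            )


def read_fasta(path: str | Path, alphabet: str = "dna") -> list[FastaRecord]:
    """Read a FASTA file, uppercasing sequences and validating the alphabet.

    Duplicate ids and illegal characters are hard errors; an empty file
    yields an empty list.
    """
    allowed = {"dna": DNA_ALPHABET, "protein": PROTEIN_ALPHABET}[alphabet]
    records: list[FastaRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        _validate_alphabet(seq, allowed, rec.id)
        desc = rec.description[len(rec.id):].strip()
        records.append(FastaRecord(rec.id, seq, desc))
    return records


def write_fasta(
    records: Iterable[tuple], path: str | Path, wrap: int = 70
) -> None:
    """Write ``(id, seq[, description])`` records, wrapping lines at ``wrap``."""
    if wrap < 1:
        raise ValueError("wrap must be >= 1")
    with open(path, "w") as fh:
        for rec in records:
            rid, seq = rec[0], rec[1]
            desc = rec[2] if len(rec) > 2 and rec[2] else ""
            header = f">{rid} {desc}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(seq), wrap):
                fh.write(seq[i : i + wrap] + "\n")


def revcomp(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; an involution."""
    _validate_alphabet(seq, DNA_ALPHABET, "revcomp input")
    return seq.translate(_COMPLEMENT)[::-1]


def to_gff3_coords(interval: Interval) -> tuple[int, int]:
    """Convert internal 0-based half-open to GFF3 1-based inclusive."""
    return interval.start + 1, interval.end


def write_gff3(
    features: Sequence[Feature],
    path: str | Path,
    contig_lengths: dict[str, int],
) -> None:
    """Serialize features as GFF3.  Features must resolve to known contigs."""
    for feat in features:
        if feat.contig_id not in contig_lengths:
            raise ValueError(f"feature on unknown contig {feat.contig_id!r}")
        if feat.interval.end > contig_lengths[feat.contig_id]:
            raise ValueError(
                f"feature [{feat.interval.start},{feat.interval.end}) extends "
                f"beyond contig {feat.contig_id} "
                f"(length {contig_lengths[feat.contig_id]})"
            )
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for cid in sorted({f.contig_id for f in features}):
            fh.write(f"##sequence-region {cid} 1 {contig_lengths[cid]}\n")
        for feat in sorted(
            features, key=lambda f: (f.contig_id, f.interval.start, f.interval.end)
        ):
            start, end = to_gff3_coords(feat.interval)
            attrs = ";".join(
                f"{k}={_gff3_escape(str(v))}" for k, v in feat.attributes.items()
            ) or "."
            phase = "0" if feat.feature_type == "CDS" else "."
            fh.write(
                "\t".join(
                    [
                        feat.contig_id,
                        "evescreen",
                        feat.feature_type,
                        str(start),
                        str(end),
                        ".",
                        feat.interval.strand,
                        phase,
                        attrs,
                    ]
                )
                + "\n"
            )


def _gff3_escape(value: str) -> str:
    return (
        value.replace("%", "%25")
        .replace(";", "%3B")
        .replace("=", "%3D")
        .replace(",", "%2C")
        .replace("\t", "%09")
    )


def read_probe_library(path: str | Path) -> list[ProteinProbe]:
    """Read a probe FASTA whose descriptions carry ``taxon=... gene=...`` tokens."""
    probes = []
    for rec in read_fasta(path, alphabet="protein"):
        tokens = dict(
            tok.split("=", 1) for tok in rec.description.split() if "=" in tok
        )
        if "taxon" not in tokens or "gene" not in tokens:
            raise ValueError(
                f"probe {rec.id}: description must contain taxon= and gene= tokens"
            )
        probes.append(ProteinProbe(rec.id, tokens["taxon"], tokens["gene"], rec.seq))
    return probes


def write_probe_library(probes: Sequence[ProteinProbe], path: str | Path) -> None:
    write_fasta(
        [
            (p.id, p.seq, f"taxon={p.taxon_label} gene={p.gene_label}")
            for p in probes
        ],
        path,
    )
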