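"""Core sequence and annotation data types, plus FASTA/GFF3 readers and writers.

Coordinates are 1-based inclusive throughout, matching the convention used in
baculovirus genome tables.  Reverse-strand features are stored with
``start < end`` on the forward strand plus ``strand='-'``.  Features spanning
the junction of a circular genome are stored with ``end > len(genome)``; the
GFF3 writer splits them into two segments so the representation stays lossless.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

ALPHABET = set("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


class FastaError(ValueError):
    """Malformed or unacceptable FASTA input."""


class CoordinateError(ValueError):
    """Feature coordinates incompatible with the genome."""


@dataclass
class Genome:
    """A nucleotide sequence with identifier and topology.

    ``circular=True`` makes coordinate arithmetic wrap modulo the length, the
    situation for alphabaculovirus genomes, which are covalently closed circles.
    """

    id: str
    seq: str
    circular: bool = False

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError("genome sequence must be non-empty")
        bad = set(self.seq) - ALPHABET
        if bad:
            raise ValueError(f"illegal characters in sequence: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.seq)

    def base(self, pos: int) -> str:
        """Base at a 1-based position, wrapping if circular."""
        n = len(self.seq)
        if self.circular:
            return self.seq[(pos - 1) % n]
        if not 1 <= pos <= n:
            raise CoordinateError(f"position {pos} outside linear genome of length {n}")
        return self.seq[pos - 1]

    def fetch(self, start: int, end: int) -> str:
        """Subsequence for 1-based inclusive [start, end]; wraps when circular.

        ``end`` may exceed the genome length on a circular genome (junction
        spanning feature).
        """
        n = len(self.seq)
        if end < start:
            raise CoordinateError(f"end {end} < start {start}")
        if not self.circular:
            if start < 1 or end > n:
                raise CoordinateError(
                    f"[{start}, {end}] outside linear genome of length {n}"
                )
            return self.seq[start - 1 : end]
        if end - start + 1 > n:
            raise CoordinateError("span longer than circular genome")
        doubled = self.seq + self.seq
        s = (start - 1) % n
        return doubled[s : s + (end - start + 1)]


@dataclass
class ORFRecord:
    """A called/annotated open reading frame.

    ``start``/``end`` delimit the full span from the first base of the start
    codon to the last base of the stop codon, as forward-strand coordinates
    (start < end even on the minus strand).  ``aa_length`` excludes the stop.
    """

    orf_id: int
    name: str
    start: int
    end: int
    strand: str  # '+' or '-'
    aa_length: int
    annotation_basis: str = "ab_initio"  # core_gene | alphabaculovirus_conserved | homolog | ab_initio

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        span = self.span_length()
        if span <= 0 or span % 3:
            raise ValueError(f"ORF span {span} is not a positive multiple of 3")
        expect = span // 3 - 1
        if self.aa_length != expect:
            raise ValueError(
                f"aa_length {self.aa_length} inconsistent with span {span} "
                f"(expected {expect})"
            )

    def span_length(self) -> int:
        return self.end - self.start + 1

    def interval(self, genome_length: int | None = None) -> tuple[int, int]:
        """Forward-strand interval, normalized into 1..L when a length is given."""
        if genome_length is None or self.end <= genome_length:
            return self.start, self.end
        return self.start, self.end  # junction ORFs keep end > L by design

    def key(self) -> str:
        """Stable coordinate key (``start:end:strand``) used by homology tables."""
        return f"{self.start}:{self.end}:{self.strand}"


@dataclass
class RepeatUnit:
    """One repeat copy inside an hr; orientation is relative to the consensus."""

    start: int
    end: int
    orientation: str = "forward"  # forward | reverse

    def __post_init__(self) -> None:
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"bad orientation {self.orientation!r}")


@dataclass
class Palindrome:
    """Best imperfect reverse-complement palindrome inside a consensus.

    ``center`` is the number of consensus bases left of the axis (the axis
    falls between positions ``center`` and ``center+1``, 1-based).
    """

    center: int
    arm_length: int
    mismatches: int


@dataclass
class HrRegion:
    """A homologous region: a cluster of near-identical short repeat units."""

    hr_id: str
    region_start: int
    region_end: int
    units: list[RepeatUnit]
    consensus: str
    palindrome: Palindrome
    frequencies: "list[dict[str, int]] | None" = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if len(self.units) < 2:
            raise ValueError("an hr needs at least 2 repeat units")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path, circular: bool = False) -> list[Genome]:
    """Read a multi-record FASTA file into :class:`Genome` objects.

    Sequences are upper-cased, RNA ``U`` is mapped to ``T``, and any character
    outside {A,C,G,T,N} raises :class:`FastaError`.  Duplicate record ids and
    empty files are rejected.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FastaError(f"no FASTA records in {path}")
    genomes: list[Genome] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise FastaError(f"duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper().replace("U", "T")
        bad = set(seq) - ALPHABET
        if bad:
            raise FastaError(
                f"illegal character(s) {sorted(bad)} in record {rec.id!r}"
            )
        if not seq:
            raise FastaError(f"empty sequence for record {rec.id!r}")
        genomes.append(Genome(id=rec.id, seq=seq, circular=circular))
    return genomes


def write_fasta(genomes: Iterable[Genome], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for g in genomes:
            fh.write(f">{g.id}\n")
            for i in range(0, len(g.seq), width):
                fh.write(g.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def write_gff3(genome: Genome, orfs: Sequence[ORFRecord], hrs: Sequence[HrRegion], path) -> None:
    """Write ORFs and hr regions as GFF3.

    ORFs become ``CDS`` features; hrs become ``repeat_region`` parents with
    ``repeat_unit`` children.  ORFs crossing the junction of a circular genome
    (stored with end > L) are emitted as two CDS segments sharing one ID.
    """
    n = len(genome)
    lines = ["##gff-version 3", f"##sequence-region {genome.id} 1 {n}"]
    for orf in orfs:
        if orf.start < 1 or (not genome.circular and orf.end > n):
            raise CoordinateError(f"ORF {orf.orf_id} outside genome bounds")
        if genome.circular and orf.end - orf.start + 1 > n:
            raise CoordinateError(f"ORF {orf.orf_id} longer than circular genome")
        attrs = (
            f"ID=orf{orf.orf_id};Name={orf.name};aa_length={orf.aa_length};"
            f"annotation_basis={orf.annotation_basis}"
        )
        segments = (
            [(orf.start, n), (1, orf.end - n)] if orf.end > n else [(orf.start, orf.end)]
        )
        for s, e in segments:
            lines.append(
                "\t".join(
                    [genome.id, "ophanno", "CDS", str(s), str(e), ".", orf.strand, "0", attrs]
                )
            )
    for hr in hrs:
        if hr.region_start < 1 or (not genome.circular and hr.region_end > n):
            raise CoordinateError(f"{hr.hr_id} outside genome bounds")
        pal = hr.palindrome
        attrs = (
            f"ID={hr.hr_id};consensus={hr.consensus};"
            f"palindrome_center={pal.center};palindrome_arm={pal.arm_length};"
            f"palindrome_mismatches={pal.mismatches}"
        )
        hr_segments = (
            [(hr.region_start, n), (1, hr.region_end - n)]
            if hr.region_end > n else [(hr.region_start, hr.region_end)]
        )
        for s, e in hr_segments:
            lines.append(
                "\t".join(
                    [genome.id, "ophanno", "repeat_region",
                     str(s), str(e), ".", "+", ".", attrs]
                )
            )
        for i, u in enumerate(hr.units, 1):
            uattrs = f"ID={hr.hr_id}_u{i};Parent={hr.hr_id};orientation={u.orientation}"
            u_segments = (
                [(u.start, n), (1, u.end - n)] if u.end > n else [(u.start, u.end)]
            )
            for s, e in u_segments:
                lines.append(
                    "\t".join(
                        [genome.id, "ophanno", "repeat_unit",
                         str(s), str(e), ".",
                         "+" if u.orientation == "forward" else "-", ".", uattrs]
                    )
                )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _parse_attrs(text: str) -> dict[str, str]:
    out = {}
    for part in text.split(";"):
        if part and "=" in part:
            k, v = part.split("=", 1)
            out[k] = v
    return out


def read_gff3(path, genome_length: int | None = None) -> tuple[list[ORFRecord], list[HrRegion]]:
    """Read back the GFF3 produced by :func:`write_gff3` (round-trip partner)."""
    orf_segments: dict[str, list] = {}
    hr_rows: dict[str, dict] = {}
    unit_rows: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            _, _, ftype, start, end, _, strand, _, attr_text = cols
            attrs = _parse_attrs(attr_text)
            if ftype == "CDS":
                orf_segments.setdefault(attrs["ID"], []).append(
                    (int(start), int(end), strand, attrs)
                )
            elif ftype == "repeat_region":
                row = hr_rows.setdefault(
                    attrs["ID"], {"segments": [], "attrs": attrs}
                )
                row["segments"].append((int(start), int(end)))
            elif ftype == "repeat_unit":
                unit_rows.setdefault(attrs["Parent"], {}).setdefault(
                    (attrs["ID"], attrs.get("orientation", "forward")), []
                ).append((int(start), int(end)))
    orfs = []
    for oid, segs in orf_segments.items():
        attrs = segs[0][3]
        if len(segs) == 1:
            start, end = segs[0][0], segs[0][1]
        else:
            # junction ORF split into [start, L] + [1, end-L]
            if genome_length is None:
                raise ValueError("genome_length required to rejoin junction ORFs")
            (s1, e1, _, _), (s2, e2, _, _) = sorted(segs, key=lambda t: t[0] == 1)
            start, end = s1, genome_length + e2
        orfs.append(
            ORFRecord(
                orf_id=int(oid.removeprefix("orf")),
                name=attrs.get("Name", oid),
                start=start,
                end=end,
                strand=segs[0][2],
                aa_length=int(attrs["aa_length"]),
                annotation_basis=attrs.get("annotation_basis", "ab_initio"),
            )
        )
    def _join(segments: list[tuple[int, int]]) -> tuple[int, int]:
        if len(segments) == 1:
            return segments[0]
        if genome_length is None:
            raise ValueError("genome_length required to rejoin junction features")
        tail = next(s for s in segments if s[0] == 1)
        head = next(s for s in segments if s[0] != 1)
        return head[0], genome_length + tail[1]

    hrs = []
    for hid, row in hr_rows.items():
        attrs = row["attrs"]
        units = [
            RepeatUnit(start=_join(segs)[0], end=_join(segs)[1], orientation=orient)
            for (_, orient), segs in unit_rows.get(hid, {}).items()
        ]
        start, end = _join(row["segments"])
        hrs.append(
            HrRegion(
                hr_id=hid,
                region_start=start,
                region_end=end,
                units=sorted(units, key=lambda u: u.start),
                consensus=attrs["consensus"],
                palindrome=Palindrome(
                    center=int(attrs["palindrome_center"]),
                    arm_length=int(attrs["palindrome_arm"]),
                    mismatches=int(attrs["palindrome_mismatches"]),
                ),
            )
        )
    orfs.sort(key=lambda o: o.orf_id)
    hrs.sort(key=lambda h: h.region_start)
    return orfs, hrs


# ---------------------------------------------------------------------------
# Rotation and GC content
# ---------------------------------------------------------------------------

def rotate_to_origin(genome: Genome, new_origin: int) -> tuple[Genome, Callable[[int], int]]:
    """Rotate a circular genome so that ``new_origin`` becomes position 1.

    Returns the rotated genome and a bijective coordinate map old -> new
    (1-based) for transferring annotations.  Conventionally used to place the
    first base of the polyhedrin ORF at position 1.
    """
    if not genome.circular:
        raise ValueError("cannot rotate linear sequence")
    n = len(genome)
    if not 1 <= new_origin <= n:
        raise CoordinateError(f"origin {new_origin} outside 1..{n}")
    k = new_origin - 1
    rotated = Genome(id=genome.id, seq=genome.seq[k:] + genome.seq[:k], circular=True)

    def coord_map(old: int) -> int:
        if not 1 <= old <= n:
            raise CoordinateError(f"coordinate {old} outside 1..{n}")
        return (old - new_origin) % n + 1

    return rotated, coord_map


def gc_content(genome: Genome | str) -> float:
    """GC fraction, with N excluded from the denominator."""
    seq = genome.seq if isinstance(genome, Genome) else genome
    counts = {b: seq.count(b) for b in "ACGT"}
    denom = sum(counts.values())
    if denom == 0:
        raise ValueError("GC content undefined: no unambiguous bases")
    return (counts["G"] + counts["C"]) / denom


def gc_percent(genome: Genome | str) -> float:
    """GC content as a percentage, rounded half-up to two decimals."""
    frac = gc_content(genome) * 100.0
    return math.floor(frac * 100 + 0.5) / 100
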