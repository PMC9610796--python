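"""Classification of intra-isolate variants against the genome annotation.

Variants at frequency > 10% are partitioned into: positions in hrs or
intergenic sequence; synonymous and nonsynonymous SNPs inside annotated ORFs;
and in-frame versus frameshift indels inside ORFs.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

from Bio.Seq import Seq

from .genome_model import Genome, HrRegion, ORFRecord
from .orf_annotator import orf_nucleotide_sequence

CLASSES = (
    "hr_or_intergenic",
    "synonymous",
    "nonsynonymous",
    "inframe_indel",
    "frameshift_indel",
)

_COMP = {"A": "T", "T": "A", "G": "C", "C": "G", "N": "N"}


@dataclass
class Variant:
    """A SNP or indel with 1-based position, alleles and population frequency."""

    position: int
    ref: str
    alt: str
    frequency: float
    var_class: str | None = None

    def __post_init__(self) -> None:
        if not self.ref and not self.alt:
            raise ValueError("ref and alt cannot both be empty")
        if len(self.ref) == len(self.alt) and len(self.ref) != 1:
            raise ValueError("multi-nucleotide substitutions are not supported")
        if not 0.0 <= self.frequency <= 1.0:
            raise ValueError(f"frequency {self.frequency} outside [0, 1]")

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def length_change(self) -> int:
        return abs(len(self.ref) - len(self.alt))


def filter_variants(variants: Sequence[Variant], min_freq: float = 0.10) -> list[Variant]:
    """Keep variants at frequency strictly greater than ``min_freq``."""
    return [v for v in variants if v.frequency > min_freq]


def _position_in(pos: int, start: int, end: int, n: int, circular: bool) -> bool:
    if end <= n:
        return start <= pos <= end
    if not circular:
        return False
    return pos >= start or pos <= end - n


def classify(
    variant: Variant,
    genome: Genome,
    orfs: Sequence[ORFRecord],
    hrs: Sequence[HrRegion],
) -> str:
    """Assign a variant class.

    hr membership takes precedence; positions outside every annotated ORF are
    intergenic; SNPs inside an ORF are translated strand-aware against ref and
    alt codons; indels are in-frame iff the length change is a multiple of 3.
    A position inside overlapping ORFs is classified against the longest one.
    """
    n = len(genome)
    pos = variant.position
    for hr in hrs:
        if _position_in(pos, hr.region_start, hr.region_end, n, genome.circular):
            return "hr_or_intergenic"
    hits = [
        o for o in orfs
        if _position_in(pos, o.start, o.end, n, genome.circular)
    ]
    if not hits:
        return "hr_or_intergenic"
    if len(hits) > 1:
        warnings.warn(
            f"position {pos} inside {len(hits)} overlapping ORFs; using the longest"
        )
    orf = max(hits, key=lambda o: (o.aa_length, -o.start))
    if not variant.is_snp:
        return "inframe_indel" if variant.length_change % 3 == 0 else "frameshift_indel"
    # locate the codon on the coding strand
    off_fwd = (pos - orf.start) % n if genome.circular else pos - orf.start
    span = orf.span_length()
    cod_off = off_fwd if orf.strand == "+" else span - 1 - off_fwd
    cds = orf_nucleotide_sequence(orf, genome)
    codon_i, within = divmod(cod_off, 3)
    codon = cds[codon_i * 3 : codon_i * 3 + 3]
    alt_base = variant.alt if orf.strand == "+" else _COMP[variant.alt]
    alt_codon = codon[:within] + alt_base + codon[within + 1 :]
    same = str(Seq(codon).translate(table=1)) == str(Seq(alt_codon).translate(table=1))
    return "synonymous" if same else "nonsynonymous"


def classify_all(
    variants: Sequence[Variant],
    genome: Genome,
    orfs: Sequence[ORFRecord],
    hrs: Sequence[HrRegion],
) -> list[Variant]:
    out = []
    for v in variants:
        out.append(
            Variant(
                position=v.position, ref=v.ref, alt=v.alt,
                frequency=v.frequency,
                var_class=classify(v, genome, orfs, hrs),
            )
        )
    return out


def summarize(variants: Sequence[Variant]) -> dict[str, int]:
    """Counts per class (all classes present; zeros included).

    Counts always sum to the number of classified input variants.
    """
    counts = Counter(v.var_class for v in variants)
    unknown = set(counts) - set(CLASSES) - {None}
    if unknown:
        raise ValueError(f"unknown variant classes: {sorted(unknown)}")
    return {c: counts.get(c, 0) for c in CLASSES}


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def read_variant_table(path) -> list[Variant]:
    """Read a TSV of position, ref, alt, frequency (optional header row)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0].lower() == "position":
                continue
            pos, ref, alt, freq = fields[:4]
            out.append(Variant(position=int(pos), ref=ref, alt=alt, frequency=float(freq)))
    return out


def read_vcf(path, af_field: str = "AF") -> list[Variant]:
    """Read a minimal uncompressed VCF; frequency taken from an INFO field."""
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            info = dict(
                kv.split("=", 1) for kv in cols[7].split(";") if "=" in kv
            )
            if af_field not in info:
                raise ValueError(f"VCF record lacks INFO/{af_field}: {line!r}")
            out.append(
                Variant(
                    position=int(cols[1]), ref=cols[3], alt=cols[4],
                    frequency=float(info[af_field].split(",")[0]),
                )
            )
    return out
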