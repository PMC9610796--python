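"""Six-frame ORF detection on circular genomes and annotation filter rules.

The caller reports, per stop codon and frame, the maximal ATG-initiated ORF
(nested in-frame starts are suppressed).  Annotation keeps every ORF backed by
a homology-table entry, and admits a homology-free ORF only when it is at
least ``min_codons`` long, does not sit inside an hr, overlaps no hr and no
larger annotated ORF by more than ``max_overlap`` bp, and is accepted by a
pluggable coding predicate.  Length ties are broken toward the earlier start.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqUtils.ProtParam import ProteinAnalysis

from .genome_model import Genome, HrRegion, ORFRecord, revcomp

STOP_CODONS = {"TAA", "TAG", "TGA"}

_SOURCE_TO_BASIS = {
    "core": "core_gene",
    "alpha_conserved": "alphabaculovirus_conserved",
    "other": "homolog",
}


# ---------------------------------------------------------------------------
# ORF calling
# ---------------------------------------------------------------------------

def _scan_plus_strand(seq: str, n: int, circular: bool, min_codons: int):
    """Maximal ORFs on the given (forward-oriented) sequence.

    Yields 0-based (start, stop_end_exclusive) pairs; for circular genomes the
    doubled sequence is scanned so frames continue across the junction, and
    results are deduplicated by stop position keeping the longest ORF.
    """
    s = seq + seq if circular else seq
    best: dict[tuple[int, int], tuple[int, int]] = {}
    for frame in range(3):
        start_atg: int | None = None
        for i in range(frame, len(s) - 2, 3):
            codon = s[i : i + 3]
            if codon in STOP_CODONS:
                if start_atg is not None:
                    span = i + 3 - start_atg
                    if span // 3 - 1 >= min_codons and span <= n and start_atg < n:
                        key = ((i + 3) % n if circular else i + 3, frame if not circular else 0)
                        # keep longest ORF per stop (maximality across junction)
                        prev = best.get(key)
                        if prev is None or span > prev[1] - prev[0]:
                            best[key] = (start_atg, i + 3)
                    start_atg = None
            elif codon == "ATG" and start_atg is None:
                start_atg = i
    return sorted(set(best.values()))


def find_orfs(genome: Genome, min_codons: int = 50) -> list[ORFRecord]:
    """All maximal ATG-to-stop ORFs of at least ``min_codons`` codons, both strands.

    The codon count includes the start codon and excludes the stop, so it
    equals the translated length.  Each ORF is reported once; junction ORFs of
    circular genomes carry ``end > len(genome)``.
    """
    n = len(genome)
    out: list[ORFRecord] = []
    for a, b in _scan_plus_strand(genome.seq, n, genome.circular, min_codons):
        out.append(
            ORFRecord(
                orf_id=0, name="", start=a + 1, end=b, strand="+",
                aa_length=(b - a) // 3 - 1,
            )
        )
    rc = revcomp(genome.seq)
    for a, b in _scan_plus_strand(rc, n, genome.circular, min_codons):
        span = b - a
        fstart = n - (b - 1) % n  # forward coord of the ORF's last base's mirror
        out.append(
            ORFRecord(
                orf_id=0, name="", start=fstart, end=fstart + span - 1, strand="-",
                aa_length=span // 3 - 1,
            )
        )
    out.sort(key=lambda o: (o.start, o.end, o.strand))
    return out


# ---------------------------------------------------------------------------
# Interval arithmetic (forward-strand projection, circular aware)
# ---------------------------------------------------------------------------

def _segments(start: int, end: int, n: int) -> list[tuple[int, int]]:
    """Normalize a possibly junction-spanning interval into 1..n segments."""
    if end <= n:
        return [(start, end)]
    return [(start, n), (1, end - n)]


def overlap_bp(a: tuple[int, int], b: tuple[int, int], n: int) -> int:
    """Overlap in bp between two 1-based inclusive intervals, wrapping at n."""
    total = 0
    for s1, e1 in _segments(*a, n):
        for s2, e2 in _segments(*b, n):
            total += max(0, min(e1, e2) - max(s1, s2) + 1)
    return total


def contained_in(inner: tuple[int, int], outer: tuple[int, int], n: int) -> bool:
    span = inner[1] - inner[0] + 1
    return overlap_bp(inner, outer, n) == span


# ---------------------------------------------------------------------------
# Annotation rules
# ---------------------------------------------------------------------------

def annotate(
    orfs: Sequence[ORFRecord],
    hrs: Sequence[HrRegion],
    homology_table: Mapping[str, tuple[str, str]],
    coding_predicate: Callable[[ORFRecord], bool],
    genome_length: int,
    max_overlap: int = 75,
) -> list[ORFRecord]:
    """Apply the annotation filter to called ORFs.

    ``homology_table`` maps ``start:end:strand`` keys to
    ``(homolog_name, source_tag)`` with source_tag in
    {core, alpha_conserved, other}; its entries are always kept and given the
    matching annotation basis.  Homology-free ORFs survive only if they are
    not contained in an hr, overlap every hr and every larger (or equal-length,
    earlier-start) kept ORF by at most ``max_overlap`` bp, and pass
    ``coding_predicate``.
    """
    kept: list[ORFRecord] = []
    candidates: list[ORFRecord] = []
    for orf in orfs:
        entry = homology_table.get(orf.key())
        if entry is not None:
            name, source = entry
            basis = _SOURCE_TO_BASIS.get(source, "homolog")
            kept.append(
                ORFRecord(
                    orf_id=orf.orf_id, name=name, start=orf.start, end=orf.end,
                    strand=orf.strand, aa_length=orf.aa_length,
                    annotation_basis=basis,
                )
            )
        else:
            candidates.append(orf)

    hr_ivs = [(hr.region_start, hr.region_end) for hr in hrs]
    # longer first; ties toward the earlier start coordinate
    candidates.sort(key=lambda o: (-o.aa_length, o.start, o.end, o.strand))
    for cand in candidates:
        iv = (cand.start, cand.end)
        if any(contained_in(iv, hiv, genome_length) for hiv in hr_ivs):
            continue
        if any(overlap_bp(iv, hiv, genome_length) > max_overlap for hiv in hr_ivs):
            continue
        blocked = False
        for k in kept:
            dominates = k.aa_length > cand.aa_length or (
                k.aa_length == cand.aa_length and k.start < cand.start
            )
            if dominates and overlap_bp(iv, (k.start, k.end), genome_length) > max_overlap:
                blocked = True
                break
        if blocked or not coding_predicate(cand):
            continue
        kept.append(
            ORFRecord(
                orf_id=cand.orf_id, name=cand.name or f"orf_{cand.start}",
                start=cand.start, end=cand.end, strand=cand.strand,
                aa_length=cand.aa_length, annotation_basis="ab_initio",
            )
        )
    kept.sort(key=lambda o: (o.start, o.end, o.strand))
    return kept


def renumber(orfs: Sequence[ORFRecord]) -> list[ORFRecord]:
    """Assign orf_id 1..N by start coordinate (polh is ORF 1 after rotation)."""
    starts = [o.start for o in orfs]
    if len(set(starts)) != len(starts):
        dup = sorted({s for s in starts if starts.count(s) > 1})
        raise ValueError(f"two ORFs share a start coordinate: {dup}")
    ordered = sorted(orfs, key=lambda o: o.start)
    out = []
    for i, o in enumerate(ordered, 1):
        out.append(
            ORFRecord(
                orf_id=i, name=o.name, start=o.start, end=o.end, strand=o.strand,
                aa_length=o.aa_length, annotation_basis=o.annotation_basis,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Translation and molecular weight
# ---------------------------------------------------------------------------

def orf_nucleotide_sequence(orf: ORFRecord, genome: Genome) -> str:
    """Coding-strand nucleotide sequence of the ORF, start through stop codon."""
    seq = genome.fetch(orf.start, orf.end)
    return seq if orf.strand == "+" else revcomp(seq)


def translate(orf: ORFRecord, genome: Genome) -> str:
    """Translate an ORF with the standard genetic code (table 1), stop excluded."""
    cds = orf_nucleotide_sequence(orf, genome)
    aa = str(Seq(cds).translate(table=1))
    if not aa.endswith("*"):
        raise ValueError("ORF does not end in a stop codon")
    body = aa[:-1]
    if "*" in body:
        raise ValueError("ORF interrupted: internal stop codon")
    return body


def molecular_weight(aa: str) -> float:
    """Average molecular weight of a peptide in Da (residue masses + one water)."""
    return ProteinAnalysis(aa).molecular_weight()


def molecular_weight_kda(aa: str) -> float:
    """Molecular weight in kDa, rounded half-up to one decimal (table style)."""
    kda = molecular_weight(aa) / 1000.0
    return math.floor(kda * 10 + 0.5) / 10


# ---------------------------------------------------------------------------
# Default coding predicate: codon-usage similarity to the homolog-backed set
# ---------------------------------------------------------------------------

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_SENSE_CODONS = sorted(_TABLE.forward_table)  # 61 codons
_FAMILIES: dict[str, list[str]] = {}
for _codon, _aa in _TABLE.forward_table.items():
    _FAMILIES.setdefault(_aa, []).append(_codon)


def rscu_vector(cds: str) -> np.ndarray:
    """Relative synonymous codon usage over the 61 sense codons.

    RSCU of a codon is its count divided by the mean count of its synonymous
    family; unobserved amino acids contribute zeros.
    """
    counts = {c: 0 for c in _SENSE_CODONS}
    for i in range(0, len(cds) - 2, 3):
        codon = cds[i : i + 3]
        if codon in counts:
            counts[codon] += 1
    out = np.zeros(len(_SENSE_CODONS))
    for aa, family in _FAMILIES.items():
        total = sum(counts[c] for c in family)
        if total == 0:
            continue
        mean = total / len(family)
        for c in family:
            out[_SENSE_CODONS.index(c)] = counts[c] / mean
    return out


def make_codon_usage_predicate(
    genome: Genome,
    reference_orfs: Sequence[ORFRecord],
    min_llr_per_codon: float = 0.0,
) -> Callable[[ORFRecord], bool]:
    """Coding predicate from synonymous codon-usage similarity.

    For each codon of a candidate ORF, the log-likelihood ratio of the
    synonymous codon choice is evaluated under (a) the pooled usage of the
    reference (homology-backed) ORF set versus (b) a background model in
    which codons follow the genome's base composition.  The mean LLR per
    codon must exceed ``min_llr_per_codon`` (zero is the natural decision
    boundary): genuine genes share the genome's coding codon bias, while
    spurious reading frames in intergenic sequence approximate the
    background.  Stands in for agreement between two ab initio predictors.
    """
    pooled = "".join(orf_nucleotide_sequence(o, genome)[:-3] for o in reference_orfs)
    if not pooled:
        return lambda orf: False
    counts = {c: 0.5 for c in _SENSE_CODONS}  # pseudocount
    for i in range(0, len(pooled) - 2, 3):
        codon = pooled[i : i + 3]
        if codon in counts:
            counts[codon] += 1

    base_p = {b: max(genome.seq.count(b), 1) / len(genome.seq) for b in "ACGT"}
    llr_table: dict[str, float] = {}
    for aa, family in _FAMILIES.items():
        if len(family) < 2:
            continue  # Met/Trp carry no synonymous information
        total = sum(counts[c] for c in family)
        bg = {c: base_p[c[0]] * base_p[c[1]] * base_p[c[2]] for c in family}
        bg_total = sum(bg.values())
        for c in family:
            llr_table[c] = math.log((counts[c] / total) / (bg[c] / bg_total))

    def predicate(orf: ORFRecord) -> bool:
        cds = orf_nucleotide_sequence(orf, genome)[:-3]
        llrs = [
            llr_table[cds[i : i + 3]]
            for i in range(0, len(cds) - 2, 3)
            if cds[i : i + 3] in llr_table
        ]
        if not llrs:
            return False
        return sum(llrs) / len(llrs) > min_llr_per_codon

    return predicate


def read_homology_table(path) -> dict[str, tuple[str, str]]:
    """Read a TSV of ``orf_key (start:end:strand), homolog_name, source_tag``."""
    table: dict[str, tuple[str, str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ValueError(f"homology table row needs 3 columns: {line!r}")
            key, name, source = fields
            if source not in _SOURCE_TO_BASIS:
                raise ValueError(f"unknown source_tag {source!r}")
            table[key] = (name, source)
    return table
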