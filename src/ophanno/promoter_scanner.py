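"""Early/late promoter motif classification for annotated ORFs.

Baculovirus early genes are transcribed by host RNA polymerase II from
CAKT (K = G/T) and TATAA elements, late genes by the viral RNA polymerase
from TAAG.  An ORF is labelled C, T and/or L according to which motifs occur
in the window immediately 5' of its start codon on the coding strand.
"""

from __future__ import annotations

import re
import warnings

from .genome_model import Genome, ORFRecord, revcomp

MOTIFS = {
    "C": re.compile("CA[GT]T"),
    "L": re.compile("TAAG"),
    "T": re.compile("TATAA"),
}

LABEL_ORDER = "CLT"


def upstream_window(genome: Genome, orf: ORFRecord, window: int = 200) -> str:
    """The ``window`` bp immediately 5' of the start codon, on the coding strand.

    The start codon itself is excluded.  Circular genomes wrap; on a linear
    genome a window running off the end is truncated with a warning.
    """
    n = len(genome)
    if orf.strand == "+":
        lo, hi = orf.start - window, orf.start - 1
        if not genome.circular:
            if lo < 1:
                warnings.warn(
                    f"promoter window for ORF at {orf.start} truncated at genome start"
                )
                lo = 1
            if hi < lo:
                return ""
            return genome.fetch(lo, hi)
        s = (lo - 1) % n + 1
        return genome.fetch(s, s + (hi - lo))
    # minus strand: upstream lies at higher forward coordinates
    lo, hi = orf.end + 1, orf.end + window
    if not genome.circular:
        if hi > n:
            warnings.warn(
                f"promoter window for ORF at {orf.end} truncated at genome end"
            )
            hi = n
        if hi < lo:
            return ""
        return revcomp(genome.fetch(lo, hi))
    s = (lo - 1) % n + 1
    return revcomp(genome.fetch(s, s + (hi - lo)))


def scan_promoters(genome: Genome, orf: ORFRecord, window: int = 200) -> set[str]:
    """Label set (subset of {C, L, T}) for the motifs present upstream.

    Motif occurrences may overlap (e.g. TATAAG scores both T and L).  Motifs
    are strand-specific cis elements, so only the coding strand is scanned.
    """
    region = upstream_window(genome, orf, window)
    return {label for label, pat in MOTIFS.items() if pat.search(region)}


def format_labels(labels: set[str]) -> str:
    """Render a label set in fixed C, L, T order (table style)."""
    return ", ".join(l for l in LABEL_ORDER if l in labels)
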