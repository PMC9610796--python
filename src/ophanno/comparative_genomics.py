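"""Pairwise nucleotide distances with species demarcation, and gene-parity
synteny / inversion analysis between two genomes.

The Kimura 2-parameter (K2P) distance separates transition (P) and
transversion (Q) proportions:

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

and, with gamma-distributed rate variation of shape a, each -ln(x) term is
replaced by a (x^(-1/a) - 1).  Baculovirus taxonomy demarcates species at
0.050 substitutions/site on marker-gene alignments: a pairwise distance above
the threshold places two isolates in distinct species.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

DEMARCATION_THRESHOLD = 0.050

_VALID = set("ACGT")
_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


@dataclass
class DistanceResult:
    """K2P distance with its components and species-demarcation verdict."""

    P: float
    Q: float
    a: float | None
    d: float
    verdict: str  # same_species_candidate | distinct_species
    valid_sites: int


def count_site_patterns(seq1: str, seq2: str) -> tuple[int, int, int]:
    """(transitions, transversions, valid sites) under pairwise deletion.

    Sites where either sequence has a gap, N or other ambiguity are excluded.
    """
    if len(seq1) != len(seq2):
        raise ValueError("aligned sequences must have equal length")
    ts = tv = valid = 0
    for x, y in zip(seq1.upper(), seq2.upper()):
        if x not in _VALID or y not in _VALID:
            continue
        valid += 1
        if x == y:
            continue
        if (x in _PURINES) == (y in _PURINES):
            ts += 1
        else:
            tv += 1
    return ts, tv, valid


def k2p_distance(
    seq1: str,
    seq2: str,
    gamma_shape: float | None = None,
    demarcation_threshold: float = DEMARCATION_THRESHOLD,
) -> DistanceResult:
    """Kimura 2-parameter distance between two aligned nucleotide sequences.

    Raises when the log arguments are non-positive (substitutional
    saturation), where the estimator is undefined.
    """
    ts, tv, valid = count_site_patterns(seq1, seq2)
    if valid == 0:
        raise ValueError("no valid sites (pairwise deletion removed everything)")
    P, Q = ts / valid, tv / valid
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise ValueError("distance undefined (saturation)")
    if gamma_shape is None:
        d = -0.5 * math.log(w1) - 0.25 * math.log(w2)
    else:
        a = gamma_shape
        d = 0.5 * a * (w1 ** (-1.0 / a) - 1.0) + 0.25 * a * (w2 ** (-1.0 / a) - 1.0)
    return DistanceResult(
        P=P, Q=Q, a=gamma_shape, d=d,
        verdict=demarcate(d, demarcation_threshold),
        valid_sites=valid,
    )


def demarcate(d: float, threshold: float = DEMARCATION_THRESHOLD) -> str:
    """Species verdict: distances strictly above the threshold are distinct.

    The boundary value d == threshold does not exceed the criterion and so
    remains a same-species candidate.
    """
    return "distinct_species" if d > threshold else "same_species_candidate"


# ---------------------------------------------------------------------------
# Gene parity and inversions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParityPoint:
    """Ordinal position of one ORF in each genome; 0 marks absence (on-axis)."""

    orf_index_A: int
    orf_index_B: int
    shared: bool


@dataclass(frozen=True)
class InversionBlock:
    """Maximal run of >= min_run shared ORFs whose B indices strictly descend."""

    a_start: int
    a_end: int


def gene_parity(
    homolog_map: Mapping[int, int],
    n_orfs_A: int,
    n_orfs_B: int,
) -> list[ParityPoint]:
    """Parity points for a partial injective ORF mapping A -> B.

    Shared ORFs plot at (iA, iB); ORFs private to one genome plot on that
    genome's axis (index 0 on the other axis).
    """
    mapped_b = list(homolog_map.values())
    if len(set(mapped_b)) != len(mapped_b):
        raise ValueError("homolog map is not injective")
    for ia, ib in homolog_map.items():
        if not (1 <= ia <= n_orfs_A and 1 <= ib <= n_orfs_B):
            raise ValueError(f"mapping {ia}->{ib} outside ORF index ranges")
    points = []
    b_used = set(mapped_b)
    for ia in range(1, n_orfs_A + 1):
        ib = homolog_map.get(ia)
        points.append(
            ParityPoint(ia, ib if ib else 0, shared=ib is not None)
        )
    for ib in range(1, n_orfs_B + 1):
        if ib not in b_used:
            points.append(ParityPoint(0, ib, shared=False))
    return points


def detect_inversions(
    points: Sequence[ParityPoint], min_run: int = 2
) -> list[InversionBlock]:
    """Inverted blocks: runs of consecutive shared points with descending B index.

    Points are considered in A-index order with unshared points skipped;
    strict descent is required, so plateaus (duplicate B indices) break runs.
    """
    shared = sorted((p for p in points if p.shared), key=lambda p: p.orf_index_A)
    blocks: list[InversionBlock] = []
    run_start = 0
    for i in range(1, len(shared) + 1):
        descending = (
            i < len(shared)
            and shared[i].orf_index_B < shared[i - 1].orf_index_B
        )
        if not descending:
            if i - run_start >= min_run:
                blocks.append(
                    InversionBlock(
                        a_start=shared[run_start].orf_index_A,
                        a_end=shared[i - 1].orf_index_A,
                    )
                )
            run_start = i
    return blocks


def read_homolog_map(path) -> dict[int, int]:
    """Read a TSV of orf_index_A, orf_index_B (optional header)."""
    out: dict[int, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            a, b = line.split("\t")[:2]
            if a.lower().startswith("orf_index"):
                continue
            out[int(a)] = int(b)
    return out
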