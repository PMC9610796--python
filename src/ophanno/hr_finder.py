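"""Detection of baculovirus homologous regions (hrs).

hrs are interspersed clusters of 2-6 near-identical short repeat units
(roughly 60 bp in alphabaculoviruses) carrying an imperfect reverse-complement
palindrome near the unit centre.  Detection proceeds in the classical way for
desk-scale genomes: shared-k-mer seeding marks candidate regions, a
phase/period search segments each region into repeat units, units are
orientation-normalised against a majority-vote consensus (repeat copies can
occur in either orientation), and clusters are filtered on unit count,
consensus length and palindrome strength.

Edit distances are computed with edlib; reverse-oriented copies are recognised
by comparing each unit against both the consensus and its reverse complement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np

from .genome_model import Genome, HrRegion, Palindrome, RepeatUnit, revcomp

_PAIR = {"A": "T", "T": "A", "G": "C", "C": "G"}


def _ed(a: str, b: str) -> int:
    return edlib.align(a, b, task="distance")["editDistance"]


@dataclass
class RepeatCluster:
    """A candidate hr before classification: units with absolute coordinates."""

    region_start: int
    region_end: int
    units: list[RepeatUnit]
    unit_seqs: list[str] = field(repr=False)
    consensus: str = ""
    frequencies: list[dict[str, int]] | None = field(default=None, repr=False)
    mean_divergence: float = 0.0


# ---------------------------------------------------------------------------
# Consensus construction
# ---------------------------------------------------------------------------

def build_consensus(units: list[str]) -> tuple[str, list[dict[str, int]]]:
    """Majority-vote consensus and per-position base frequencies.

    Units must already be orientation-normalised.  Equal-length units are
    stacked positionally; shorter/longer units are mapped onto the current
    consensus by edit-distance alignment (deletions are tallied under ``-`` so
    each position's counts still sum to the unit count).  Base ties go to the
    lexicographically smallest base.
    """
    if not units:
        raise ValueError("cannot build a consensus from zero units")
    lengths = [len(u) for u in units]
    ref_len = max(set(lengths), key=lambda L: (lengths.count(L), -L))
    stack = [u for u in units if len(u) == ref_len]
    counts = [dict.fromkeys("ACGTN-", 0) for _ in range(ref_len)]
    for u in stack:
        for i, b in enumerate(u):
            counts[i][b] += 1
    for u in units:
        if len(u) == ref_len:
            continue
        cons = _majority(counts)
        res = edlib.align(u, cons, task="path")
        qpos = 0
        tpos = 0
        for length, op in _cigar_ops(res["cigar"]):
            if op in "=XM":
                for t in range(length):
                    counts[tpos + t][u[qpos + t]] += 1
                qpos += length
                tpos += length
            elif op == "I":  # present in unit, absent from consensus
                qpos += length
            elif op == "D":  # consensus position the unit lacks
                for t in range(length):
                    counts[tpos + t]["-"] += 1
                tpos += length
    consensus = _majority(counts)
    return consensus, counts


def _majority(counts: list[dict[str, int]]) -> str:
    out = []
    for col in counts:
        top = max(col[b] for b in "ACGT")
        out.append(next(b for b in "ACGT" if col[b] == top))
    return "".join(out)


def _cigar_ops(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


def orient_units(unit_seqs: list[str]) -> tuple[list[str], list[str], str]:
    """Orientation-normalise repeat units against a consensus.

    Each unit is compared with the running consensus and its reverse
    complement; the better match decides the orientation (ties -> forward).
    Two passes stabilise the assignment.  Returns (normalised seqs,
    orientations, consensus).
    """
    oriented = list(unit_seqs)
    orientations = ["forward"] * len(unit_seqs)
    consensus = oriented[0]
    for _ in range(2):
        new_oriented = []
        new_orient = []
        for raw in unit_seqs:
            fwd, rev = _ed(raw, consensus), _ed(revcomp(raw), consensus)
            if rev < fwd:
                new_oriented.append(revcomp(raw))
                new_orient.append("reverse")
            else:
                new_oriented.append(raw)
                new_orient.append("forward")
        oriented, orientations = new_oriented, new_orient
        consensus, _ = build_consensus(oriented)
    return oriented, orientations, consensus


# ---------------------------------------------------------------------------
# Palindrome scoring
# ---------------------------------------------------------------------------

def palindrome_score(seq: str, min_arm: int = 1, max_mismatches: int = 0) -> Palindrome:
    """Best imperfect reverse-complement palindrome in ``seq``.

    All axis positions (between adjacent bases) and arm lengths >= ``min_arm``
    are searched; a position matches its mirror iff the bases are reverse
    complements.  The longest arm with at most ``max_mismatches`` mismatches
    wins; ties go to the fewest mismatches, then the leftmost axis.  Returns
    arm_length 0 when nothing qualifies.
    """
    n = len(seq)
    best = Palindrome(center=0, arm_length=0, mismatches=0)
    for c in range(1, n):  # axis between seq[c-1] and seq[c] (0-based)
        mm = 0
        max_arm = min(c, n - c)
        for arm in range(1, max_arm + 1):
            left, right = seq[c - arm], seq[c + arm - 1]
            if _PAIR.get(right) != left:
                mm += 1
            if mm > max_mismatches:
                break
            if arm >= min_arm and (
                arm > best.arm_length
                or (arm == best.arm_length and mm < best.mismatches)
            ):
                best = Palindrome(center=c, arm_length=arm, mismatches=mm)
    return best


# ---------------------------------------------------------------------------
# Tandem repeat detection
# ---------------------------------------------------------------------------

def _candidate_regions(
    seq: str, k: int, unit_max: int, cluster_gap: int, max_occ: int = 64
) -> list[tuple[int, int]]:
    """Merge shared-canonical-k-mer anchor pairs into candidate intervals."""
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        km = seq[i : i + k]
        if "N" in km:
            continue
        rc = revcomp(km)
        canon = km if km <= rc else rc
        index.setdefault(canon, []).append(i)
    window = 2 * unit_max + 40
    intervals = []
    for positions in index.values():
        if not 2 <= len(positions) <= max_occ:
            continue
        for a, b in zip(positions, positions[1:]):
            if b - a <= window:
                intervals.append((a, b + k))
    if not intervals:
        return []
    intervals.sort()
    merged = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s <= merged[-1][1] + cluster_gap:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _best_segmentation(
    region: str,
    unit_min: int,
    unit_max: int,
    min_units: int,
    max_div: float,
):
    """Search unit length and phase; return (phase, unit_len, unit list) or None.

    Units are cut on the lattice phase + m*unit_len and scored by the
    orientation-aware edit distance between adjacent cuts (robust to garbage
    flanks around the repeat stack); the candidate maximising the unit count
    and then minimising the mean normalised adjacent distance wins.
    """
    L = len(region)
    max_d = min(unit_max, L // min_units)
    if max_d < unit_min:
        return None
    arr = np.frombuffer(region.encode(), dtype=np.uint8)
    comp = arr.copy()
    for x, y in zip(b"ACGT", b"TGCA"):
        comp[arr == x] = y
    # PAL[a, t]: mismatches among the first t palindromic pairings around the
    # axis before position a (region[a-1-t'] against the complement of
    # region[a+t'])
    PAL = np.zeros((L + 1, max_d + 1), dtype=np.int32)
    for t in range(max_d):
        col = PAL[:, t].copy()
        hi = L - t
        lo = t + 1
        if lo < hi:
            mism = (arr[lo - 1 - t : hi - 1 - t] != comp[lo + t : hi + t]).astype(np.int32)
            col[lo:hi] += mism
        PAL[:, t + 1] = col

    shortlist: list[tuple[float, int, int, int, int]] = []
    for d in range(unit_min, max_d + 1):
        neq = (arr[: L - d] != arr[d:]).astype(np.int32)
        cs = np.concatenate([[0], np.cumsum(neq)])
        # Hamming upper-bounds the edit distance, so a substitution-dominated
        # repeat pair passing the edit ceiling also passes this cheap screen
        hamm_limit = max_div * d + 2
        n_pairs = L - 2 * d + 1
        if n_pairs <= 0:
            continue
        h_same = cs[d : d + n_pairs] - cs[:n_pairs]
        h_pal = PAL[d : d + n_pairs, d]
        ok_all = np.minimum(h_same, h_pal) <= hamm_limit
        per_d: list[tuple[int, float, int, int, int]] = []
        for p in range(d):
            m = (L - p) // d
            if m < min_units:
                continue
            ok = ok_all[p : p + (m - 1) * d : d]
            run = 0
            best_run = 0
            for flag in ok:
                run = run + 1 if flag else 0
                best_run = max(best_run, run)
            if best_run < min_units - 1:
                continue
            cuts = [region[p + j * d : p + (j + 1) * d] for j in range(m)]
            adj = [
                min(_ed(cuts[j], cuts[j + 1]), _ed(cuts[j], revcomp(cuts[j + 1]))) / d
                for j in range(m - 1)
            ]
            keep = _longest_ok_run(adj, max_div)
            if keep is None or keep[1] - keep[0] + 1 < min_units:
                continue
            j0, j1 = keep  # cuts j0 .. j1 inclusive form the run
            score = sum(adj[j0:j1]) / (j1 - j0)
            per_d.append((-(j1 - j0 + 1), score, p, j0, j1))
        per_d.sort()
        shortlist.extend((s, p, d, j0, j1) for neg, s, p, j0, j1 in per_d[:3])

    # judge shortlisted segmentations by consensus agreement: periods that
    # drift relative to the true repeat survive the adjacent-pair screen via
    # slip alignments but collapse once units are stacked against a consensus
    scored = []
    for _, p, d, j0, j1 in shortlist:
        cuts = [region[p + j * d : p + (j + 1) * d] for j in range(j0, j1 + 1)]
        oriented, _, consensus = orient_units(cuts)
        divs = unit_divergences(oriented, consensus)
        keep = _longest_ok_run(divs, max_div)
        if keep is None:
            continue
        k0, k1 = keep[0], keep[1] - 1  # valid contiguous units (trim garbage edges)
        n_valid = k1 - k0 + 1
        if n_valid < min_units:
            continue
        mean_div = sum(divs[k0 : k1 + 1]) / n_valid
        scored.append((n_valid, mean_div, p, d, j0 + k0, j0 + k1))
    if not scored:
        return None
    n_best = max(s[0] for s in scored)
    top = [s for s in scored if s[0] == n_best]
    best_div = min(s[1] for s in top)
    # among near-tied divergences prefer the largest covered length: a 2-copy
    # stack containing its own reverse complement admits shorter-unit
    # re-interpretations that score equally well but truncate the region
    close = [s for s in top if s[1] <= best_div + 0.02]
    _, _, p, d, j0, j1 = min(close, key=lambda s: (-s[0] * s[3], s[1], s[2]))
    starts = [p + j * d for j in range(j0, j1 + 1)]
    return p, d, [(s, region[s : s + d]) for s in starts]


def _extend_symmetric_pair(
    region: str, s1: int, d: int, unit_max: int, max_div: float
) -> tuple[int, int]:
    """Maximal extent of a 2-copy stack around a fixed centre.

    A stack whose second copy mirrors the first (u followed by its reverse
    complement) is internally palindromic: every window pair centred on the
    stack midpoint scores as well as the true unit, so the phase/period
    search may truncate the region.  The outer boundary is still
    identifiable — bases beyond the stack stop mirroring — so sweep the unit
    length with the centre fixed and keep the largest length whose pair
    divergence stays near the minimum.  Returns (new s1, new unit length).
    """
    centre = s1 + d
    edits: dict[int, int] = {}
    for dp in range(d, unit_max + 1):
        lo, hi = centre - dp, centre + dp
        if lo < 0 or hi > len(region):
            break
        u1, u2 = region[lo:centre], region[centre:hi]
        edits[dp] = min(_ed(u1, u2), _ed(u1, revcomp(u2)))
    if not edits:
        return s1, d
    # each extension step gains one base and costs ~0.08 edits inside the
    # repeat but ~0.5 edits against flanking sequence (random DNA aligns at
    # roughly half its length), so maximising dp - 4*edits stops at the
    # stack boundary (ties to the larger extent)
    ok = {dp: e for dp, e in edits.items() if e / dp <= max_div}
    if not ok:
        return s1, d
    dp = max(ok, key=lambda x: (x - 4 * ok[x], x))
    return centre - dp, dp


def unit_divergences(oriented: list[str], consensus: str) -> list[float]:
    """Per-unit divergence from the consensus.

    For two units the majority vote degenerates (every disagreeing column is a
    tie), which would halve the apparent divergence; the pairwise distance is
    used instead.
    """
    d = len(consensus)
    if len(oriented) == 2:
        pd = _ed(oriented[0], oriented[1]) / d
        return [pd, pd]
    return [_ed(u, consensus) / d for u in oriented]


def _longest_ok_run(divs: list[float], max_div: float):
    """Longest contiguous run of units within the divergence ceiling."""
    best = None
    start = None
    for i, dv in enumerate(divs + [max_div + 1]):
        if dv <= max_div:
            if start is None:
                start = i
        else:
            if start is not None:
                if best is None or i - start > best[1] - best[0]:
                    best = (start, i)
                start = None
    return best


def find_tandem_repeats(
    genome: Genome,
    unit_min: int = 40,
    unit_max: int = 80,
    min_units: int = 2,
    max_unit_divergence: float = 0.25,
    k: int = 10,
    cluster_gap: int = 250,
) -> list[RepeatCluster]:
    """Find clusters of near-identical repeat units (hr candidates).

    k-mer seeding (canonical k-mers, so inverted copies also seed) marks
    candidate regions; each region is segmented into units of a common length
    in [unit_min, unit_max]; units must lie within ``max_unit_divergence``
    (edit distance / unit length, orientation-aware) of the cluster consensus.
    Regions separated by more than ``cluster_gap`` bp are distinct clusters.
    On circular genomes detection wraps across the junction; junction-spanning
    clusters carry coordinates with end > genome length.
    """
    n = len(genome)
    pad = min(n, 6 * unit_max + 2 * cluster_gap)
    seq = genome.seq + genome.seq[:pad] if genome.circular else genome.seq
    out: list[RepeatCluster] = []
    pending: list[tuple[int, int]] = []
    # pad candidate regions by two unit lengths: the outermost unit of a stack
    # may share no k-mer with its neighbour (heavy mutation), leaving the
    # anchor interval up to ~2 units short of the true stack end
    pad_bp = 2 * unit_max
    for rs, re_ in _candidate_regions(seq, k, unit_max, cluster_gap):
        if rs >= n:  # duplicate of a region already seen near the sequence start
            continue
        pending.append((max(0, rs - pad_bp), min(len(seq), re_ + pad_bp)))
    while pending:
        lo, hi = pending.pop()
        if hi - lo < min_units * unit_min:
            continue
        seg = _best_segmentation(
            seq[lo:hi], unit_min, unit_max, min_units, max_unit_divergence
        )
        if seg is None:
            continue
        _, d, units = seg
        if len(units) == 2:
            s1, d = _extend_symmetric_pair(
                seq[lo:hi], units[0][0], d, unit_max, max_unit_divergence
            )
            units = [(s1, seq[lo + s1 : lo + s1 + d]),
                     (s1 + d, seq[lo + s1 + d : lo + s1 + 2 * d])]
        # a region may hold several nearby repeat stacks: re-examine the flanks
        first, last = units[0][0], units[-1][0] + d
        pending.append((lo, lo + first))
        pending.append((lo + last, hi))
        raw_seqs = [u for _, u in units]
        oriented, orientations, consensus = orient_units(raw_seqs)
        # enforce the ceiling against the final consensus
        divs0 = unit_divergences(oriented, consensus)
        sel = [i for i, dv in enumerate(divs0) if dv <= max_unit_divergence]
        if len(sel) < min_units:
            continue
        oriented = [oriented[i] for i in sel]
        orientations = [orientations[i] for i in sel]
        units = [units[i] for i in sel]
        consensus, freqs = build_consensus(oriented)
        divs = [_ed(u, consensus) / len(consensus) for u in oriented]
        unit_records = [
            RepeatUnit(start=lo + s + 1, end=lo + s + d, orientation=o)
            for (s, _), o in zip(units, orientations)
        ]
        out.append(
            RepeatCluster(
                region_start=unit_records[0].start,
                region_end=unit_records[-1].end,
                units=unit_records,
                unit_seqs=[u for _, u in units],
                consensus=consensus,
                frequencies=freqs,
                mean_divergence=sum(divs) / len(divs),
            )
        )
    # a junction-spanning cluster on a circular genome is also seeded from the
    # sequence start; drop any cluster whose footprint (mod n) lies inside
    # another's
    def footprint(c: RepeatCluster) -> set[int]:
        return {
            p % n for u in c.units for p in range(u.start - 1, u.end)
        }

    keep: list[RepeatCluster] = []
    for c in sorted(out, key=lambda c: -(c.region_end - c.region_start)):
        fp = footprint(c)
        if any(len(fp & footprint(k)) >= len(fp) / 2 for k in keep):
            continue
        keep.append(c)
    keep.sort(key=lambda c: c.region_start)
    return keep


def classify_hrs(
    clusters: list[RepeatCluster],
    unit_min: int = 40,
    unit_max: int = 80,
    min_units: int = 2,
    max_units: int = 6,
    palindrome_min_arm: int = 4,
    palindrome_max_mismatches: int = 2,
) -> list[HrRegion]:
    """Promote repeat clusters to hr regions.

    A cluster qualifies iff its unit count lies in [min_units, max_units], the
    consensus length lies in [unit_min, unit_max], and the consensus carries a
    palindrome of arm length >= ``palindrome_min_arm`` at the mismatch
    ceiling.  hr ids are assigned in genome order (hr1, hr2, ...).
    """
    hrs: list[HrRegion] = []
    for cluster in sorted(clusters, key=lambda c: c.region_start):
        if not min_units <= len(cluster.units) <= max_units:
            continue
        if not unit_min <= len(cluster.consensus) <= unit_max:
            continue
        pal = palindrome_score(
            cluster.consensus,
            min_arm=palindrome_min_arm,
            max_mismatches=palindrome_max_mismatches,
        )
        if pal.arm_length < palindrome_min_arm:
            continue
        hrs.append(
            HrRegion(
                hr_id=f"hr{len(hrs) + 1}",
                region_start=cluster.region_start,
                region_end=cluster.region_end,
                units=cluster.units,
                consensus=cluster.consensus,
                palindrome=pal,
                frequencies=cluster.frequencies,
            )
        )
    return hrs
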