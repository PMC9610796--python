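"""Independent brute-force oracles used to cross-check the implementation.

These are written directly from the definitions and deliberately share no
code with the package: the ORF oracle walks every ATG explicitly, the
palindrome oracle enumerates every (axis, arm) pair, and the inversion oracle
tests every candidate window of a permutation.
"""

STOPS = {"TAA", "TAG", "TGA"}
COMP = {"A": "T", "T": "A", "G": "C", "C": "G", "N": "N"}


def rc(seq):
    return "".join(COMP[b] for b in reversed(seq))


def _orfs_one_strand(seq, circular, min_codons):
    """All maximal ATG->stop ORFs as 0-based (start, end_exclusive) pairs."""
    n = len(seq)
    per_stop = {}
    s = seq + seq if circular else seq
    for i in range(n):
        if s[i : i + 3] != "ATG":
            continue
        # walk codons until a stop; bounded by one full genome
        j = i + 3
        limit = i + (n // 3) * 3
        stop = None
        while j + 3 <= (2 * n if circular else n) and j <= limit:
            if s[j : j + 3] in STOPS:
                stop = j
                break
            j += 3
        if stop is None:
            continue
        span = stop + 3 - i
        if span > n or span // 3 - 1 < min_codons:
            continue
        key = stop % n if circular else stop
        prev = per_stop.get(key)
        if prev is None or span > prev[1] - prev[0]:
            per_stop[key] = (i, stop + 3)
    return sorted(set(per_stop.values()))


def six_frame_orfs(seq, circular, min_codons):
    """Oracle: set of (start, end, strand) with 1-based inclusive coordinates."""
    n = len(seq)
    out = set()
    for a, b in _orfs_one_strand(seq, circular, min_codons):
        out.add((a + 1, b, "+"))
    for a, b in _orfs_one_strand(rc(seq), circular, min_codons):
        span = b - a
        fstart = n - (b - 1) % n
        out.add((fstart, fstart + span - 1, "-"))
    return out


def best_palindrome(seq, min_arm=1, max_mismatches=0):
    """Oracle: enumerate every axis and arm; same tie rules as the contract.

    Returns (center, arm_length, mismatches); arm 0 when nothing qualifies.
    """
    n = len(seq)
    best = (0, 0, 0)

    def better(cand, cur):
        (c1, a1, m1), (c2, a2, m2) = cand, cur
        return (a1, -m1, -c1) > (a2, -m2, -c2)

    for c in range(1, n):
        for arm in range(min_arm, min(c, n - c) + 1):
            mm = sum(
                1 for t in range(arm) if COMP.get(seq[c + t]) != seq[c - 1 - t]
            )
            if mm <= max_mismatches and better((c, arm, mm), best):
                best = (c, arm, mm)
    return best


def inversion_blocks(b_order, min_run=2):
    """Oracle: all maximal windows of a permutation with strictly descending
    values, tested exhaustively; returns [(a_start, a_end)] with 1-based
    A indices."""
    n = len(b_order)
    blocks = []
    for i in range(n):
        for j in range(i + min_run - 1, n):
            window = b_order[i : j + 1]
            if all(x > y for x, y in zip(window, window[1:])):
                left_ok = i == 0 or not b_order[i - 1] > b_order[i]
                right_ok = j == n - 1 or not b_order[j] > b_order[j + 1]
                if left_ok and right_ok:
                    blocks.append((i + 1, j + 1))
    return blocks
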