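"""Synthetic genomes, variant tables and alignments with known ground truth.

The genome generator emulates the statistical structure of an AT-rich
(~34% GC) circular alphabaculovirus genome of ~100 kbp: densely packed,
non-overlapping ORFs on both strands with skewed codon usage; a scrubbed
200-bp promoter region upstream of every start codon carrying a requested
early/late motif label set; hr cassettes built by stacking mutated copies of
a palindromic ~58-bp seed unit in mixed orientations; and i.i.d. intergenic
filler at the GC target.  The first ORF (the polyhedrin stand-in) starts at
position 1, so its promoter region wraps across the circular junction.

Every feature class draws from its own RNG stream, spawned from the user seed
via numpy's SeedSequence, so enabling one feature never perturbs another's
draws.  Truth tables are emitted alongside the sequence and are exact by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .genome_model import Genome, ORFRecord, RepeatUnit, revcomp
from .promoter_scanner import MOTIFS
from .variant_classifier import Variant

# published 58-nt consensus of an alphabaculovirus hr repeat unit
HR_SEED_UNIT = "TTGAACTCGCTTTACAAGTTTAAATGTACTCGTAAAGCAAGATCAGTGGATGATGTCA"

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_FAMILIES: dict[str, list[str]] = {}
for _codon, _aa in sorted(_TABLE.forward_table.items()):
    _FAMILIES.setdefault(_aa, []).append(_codon)
_AA20 = sorted(_FAMILIES)

# Fixed skewed codon-usage table: the AT-richest codon of each family carries
# most of the weight, emulating both the strong codon bias of real viral genes
# (a sharp signal for the coding predicate that i.i.d. filler lacks) and the
# AT-rich base composition of the genomes being modelled.
PREFERRED_CODON = {
    aa: min(fam, key=lambda c: (sum(b in "GC" for b in c), c))
    for aa, fam in _FAMILIES.items()
}
PREFERRED_WEIGHT = 0.90


@dataclass
class GenomeConfig:
    """Generator settings; defaults emulate the study genome's structure."""

    length: int = 100_000
    gc: float = 0.342
    n_orfs: int = 100
    orf_codons_min: int = 60
    orf_codons_max: int = 350
    minus_strand_prob: float = 0.5
    promoter_window: int = 200
    label_probs: dict = field(
        default_factory=lambda: {"C": 0.6, "L": 0.4, "T": 0.25}
    )
    homolog_fraction: float = 0.95
    n_hrs: int = 6
    hr_units_min: int = 2
    hr_units_max: int = 6
    hr_unit_seed: str = HR_SEED_UNIT
    hr_unit_mutation_rate: float = 0.05
    hr_reverse_prob: float = 0.3
    # guaranteed repeat-free flank around each hr cassette; real hrs are
    # dispersed, never back to back
    hr_margin: int = 300


@dataclass
class PlantedHr:
    region_start: int
    region_end: int
    units: list[RepeatUnit]
    seed_unit: str


@dataclass
class GenomeTruth:
    """Ground truth emitted with a simulated genome."""

    orfs: list[ORFRecord]
    hrs: list[PlantedHr]
    promoter_labels: dict[int, frozenset]
    homology_table: dict[str, tuple[str, str]]


@dataclass
class VariantCounts:
    """Requested variants per class; defaults mirror the study's partition."""

    synonymous: int = 40
    nonsynonymous: int = 46
    hr_intergenic_snp: int = 30
    hr_intergenic_indel: int = 12
    inframe_indel: int = 3
    frameshift_indel: int = 1


# ---------------------------------------------------------------------------
# Low-level builders
# ---------------------------------------------------------------------------

def _filler(length: int, gc: float, rng: np.random.Generator) -> str:
    p = [gc / 2, (1 - gc) / 2, (1 - gc) / 2, gc / 2]  # C, A, T, G
    return "".join(rng.choice(list("CATG"), size=length, p=p)) if length else ""


def _sample_codon(aa: str, rng: np.random.Generator) -> str:
    fam = _FAMILIES[aa]
    if len(fam) == 1:
        return fam[0]
    pref = PREFERRED_CODON[aa]
    if rng.random() < PREFERRED_WEIGHT:
        return pref
    others = [c for c in fam if c != pref]
    return others[rng.integers(len(others))]


def _make_orf_seq(n_aa: int, rng: np.random.Generator) -> str:
    aas = [_AA20[i] for i in rng.integers(0, 20, size=n_aa - 1)]
    stop = ["TAA", "TAG", "TGA"][rng.choice([0, 0, 1, 2])]
    return "ATG" + "".join(_sample_codon(a, rng) for a in aas) + stop


def _motif_instance(label: str, rng: np.random.Generator) -> str:
    if label == "C":
        return "CA" + ("G" if rng.random() < 0.5 else "T") + "T"
    return {"L": "TAAG", "T": "TATAA"}[label]


def _realized_labels(window: str) -> frozenset:
    return frozenset(l for l, pat in MOTIFS.items() if pat.search(window))


def _make_window(
    labels: frozenset, window: int, gc: float, rng: np.random.Generator
) -> str:
    """A promoter region whose realized motif label set is exactly ``labels``.

    The final three bases are an in-frame TAA so the downstream planted ATG is
    the maximal start for its stop codon.  Content is rejection-sampled until
    no unrequested motif survives.
    """
    for _ in range(20_000):
        w = list(_filler(window, gc, rng))
        w[-3:] = "TAA"
        free = window - 3
        placed: list[tuple[int, int]] = []
        ok = True
        for label in sorted(labels):
            motif = _motif_instance(label, rng)
            for _try in range(100):
                off = int(rng.integers(0, free - len(motif) + 1))
                if all(off + len(motif) <= s or off >= e for s, e in placed):
                    placed.append((off, off + len(motif)))
                    w[off : off + len(motif)] = motif
                    break
            else:
                ok = False
                break
        if not ok:
            continue
        ws = "".join(w)
        if _realized_labels(ws) == labels:
            return ws
    raise RuntimeError("could not scrub a promoter window to the requested labels")


def _make_hr_cassette(
    cfg: GenomeConfig, rng: np.random.Generator
) -> tuple[str, list[tuple[int, int, str]]]:
    """Tandem stack of mutated seed-unit copies; returns (seq, relative units)."""
    k = int(rng.integers(cfg.hr_units_min, cfg.hr_units_max + 1))
    unit_len = len(cfg.hr_unit_seed)
    parts = []
    units = []
    off = 0
    for _ in range(k):
        u = list(cfg.hr_unit_seed)
        for i in range(unit_len):
            if rng.random() < cfg.hr_unit_mutation_rate:
                u[i] = "ACGT"[rng.integers(4)]
        seq = "".join(u)
        orientation = "forward"
        if rng.random() < cfg.hr_reverse_prob:
            seq = revcomp(seq)
            orientation = "reverse"
        parts.append(seq)
        units.append((off, off + unit_len - 1, orientation))
        off += unit_len
    return "".join(parts), units


# ---------------------------------------------------------------------------
# Genome simulation
# ---------------------------------------------------------------------------

def simulate_genome(
    config: GenomeConfig | None = None, seed: int = 0
) -> tuple[Genome, GenomeTruth]:
    """Assemble a circular genome with planted ORFs, hrs and promoter motifs.

    Raises when the requested features cannot be packed into the requested
    length.  Identical (config, seed) pairs reproduce the genome bit-exactly.
    """
    cfg = config or GenomeConfig()
    streams = np.random.SeedSequence(seed).spawn(5)
    rng_layout, rng_orf, rng_hr, rng_prom, rng_fill = (
        np.random.default_rng(s) for s in streams
    )

    # --- draw feature content -------------------------------------------------
    orf_bodies: list[str] = []
    orf_strands: list[str] = []
    label_sets: list[frozenset] = []
    windows: list[str] = []
    w = cfg.promoter_window
    for i in range(cfg.n_orfs):
        n_aa = int(rng_orf.integers(cfg.orf_codons_min, cfg.orf_codons_max + 1))
        orf_bodies.append(_make_orf_seq(n_aa, rng_orf))
        strand = "+" if i == 0 else ("-" if rng_orf.random() < cfg.minus_strand_prob else "+")
        orf_strands.append(strand)
        labels = frozenset(
            l for l, p in cfg.label_probs.items() if rng_prom.random() < p
        )
        label_sets.append(labels)
        windows.append(_make_window(labels, w, cfg.gc, rng_prom))
    hr_cassettes = [_make_hr_cassette(cfg, rng_hr) for _ in range(cfg.n_hrs)]

    # --- pack cassettes -------------------------------------------------------
    # cassette items: ("orf", i) occupies window+body (body only for ORF 1,
    # whose window is appended at the genome end); ("hr", j) occupies its stack
    items: list[tuple[str, int]] = [("orf", i) for i in range(cfg.n_orfs)]
    hr_items: list[tuple[str, int]] = [("hr", j) for j in range(cfg.n_hrs)]
    if cfg.n_orfs > 1:
        for it in hr_items:  # never first: ORF 1 must start at position 1
            pos = int(rng_layout.integers(1, len(items) + 1))
            items.insert(pos, it)
    else:
        items += hr_items

    def item_len(it: tuple[str, int]) -> int:
        kind, idx = it
        if kind == "hr":
            return len(hr_cassettes[idx][0]) + 2 * cfg.hr_margin
        body = len(orf_bodies[idx])
        return body if idx == 0 and cfg.n_orfs else body + w

    content = sum(item_len(it) for it in items) + (w if cfg.n_orfs else 0)
    free = cfg.length - content
    if free < 0:
        raise ValueError(
            f"infeasible packing: features need {content} bp > length {cfg.length}"
        )
    n_slots = len(items) + 1
    cuts = np.sort(rng_layout.integers(0, free + 1, size=n_slots - 1)) if free else np.zeros(0, int)
    spacer_lens = np.diff(np.concatenate([[0], cuts, [free]])).astype(int)
    if cfg.n_orfs:  # no spacer before ORF 1: it must start at position 1
        spacer_lens[-1] += spacer_lens[0]
        spacer_lens[0] = 0

    parts: list[str] = []
    pos = 0  # 0-based offset
    orfs: list[ORFRecord] = []
    hrs: list[PlantedHr] = []
    promoter_labels: dict[int, frozenset] = {}
    order_of_orf: list[tuple[int, int, str, int]] = []  # start, end, strand, draw idx
    for slot, it in enumerate(items):
        sp = int(spacer_lens[slot])
        parts.append(_filler(sp, cfg.gc, rng_fill))
        pos += sp
        kind, idx = it
        if kind == "hr":
            seq, rel_units = hr_cassettes[idx]
            parts.append(_filler(cfg.hr_margin, cfg.gc, rng_fill))
            pos += cfg.hr_margin
            parts.append(seq)
            hrs.append(
                PlantedHr(
                    region_start=pos + 1,
                    region_end=pos + len(seq),
                    units=[
                        RepeatUnit(start=pos + s + 1, end=pos + e + 1, orientation=o)
                        for s, e, o in rel_units
                    ],
                    seed_unit=cfg.hr_unit_seed,
                )
            )
            pos += len(seq)
            parts.append(_filler(cfg.hr_margin, cfg.gc, rng_fill))
            pos += cfg.hr_margin
        else:
            body, strand = orf_bodies[idx], orf_strands[idx]
            if idx == 0:
                parts.append(body)  # window appended at genome end
                start, end = pos + 1, pos + len(body)
            elif strand == "+":
                parts.append(windows[idx] + body)
                start, end = pos + w + 1, pos + w + len(body)
            else:
                parts.append(revcomp(windows[idx] + body))
                start, end = pos + 1, pos + len(body)
            order_of_orf.append((start, end, strand, idx))
            pos += item_len(it)
    parts.append(_filler(int(spacer_lens[-1]), cfg.gc, rng_fill))
    if cfg.n_orfs:
        parts.append(windows[0])
    seq = "".join(parts)
    assert len(seq) == cfg.length

    homology: dict[str, tuple[str, str]] = {}
    for orf_id, (start, end, strand, idx) in enumerate(
        sorted(order_of_orf, key=lambda t: t[0]), 1
    ):
        span = end - start + 1
        rec = ORFRecord(
            orf_id=orf_id,
            name="polh" if idx == 0 else f"orf{orf_id}",
            start=start, end=end, strand=strand,
            aa_length=span // 3 - 1,
            annotation_basis="ab_initio",
        )
        if idx == 0 or rng_layout.random() < cfg.homolog_fraction:
            tag = ("core", "alpha_conserved", "other")[int(rng_layout.integers(3))]
            tag = "core" if idx == 0 else tag
            rec = replace(
                rec,
                annotation_basis={
                    "core": "core_gene",
                    "alpha_conserved": "alphabaculovirus_conserved",
                    "other": "homolog",
                }[tag],
            )
            homology[rec.key()] = (rec.name, tag)
        orfs.append(rec)
        promoter_labels[orf_id] = label_sets[idx]

    genome = Genome(id=f"synthetic_{seed}", seq=seq, circular=True)
    return genome, GenomeTruth(
        orfs=orfs, hrs=hrs, promoter_labels=promoter_labels, homology_table=homology
    )


# ---------------------------------------------------------------------------
# Variant simulation
# ---------------------------------------------------------------------------

def _occupied_intervals(truth: GenomeTruth) -> list[tuple[int, int]]:
    return sorted((o.start, o.end) for o in truth.orfs)


def _intergenic_positions(n: int, truth: GenomeTruth) -> np.ndarray:
    mask = np.ones(n + 1, dtype=bool)
    mask[0] = False
    for s, e in _occupied_intervals(truth):
        mask[s : e + 1] = False
    return np.flatnonzero(mask)


def simulate_variants(
    genome: Genome,
    truth: GenomeTruth,
    counts: VariantCounts | None = None,
    seed: int = 0,
    n_below_threshold: int = 0,
) -> tuple[list[Variant], list[str]]:
    """Plant variants with known classes; returns (variants, truth classes).

    SNP/indel positions are disjoint (3-bp exclusion zones).  Frequencies are
    Uniform(0.10, 1.0) drawn strictly above 0.10; ``n_below_threshold`` extra
    intergenic SNPs get frequencies below 0.10 to exercise the filter (their
    truth class is recorded like any other).
    """
    counts = counts or VariantCounts()
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    n = len(genome)
    used: set[int] = set()
    inter = _intergenic_positions(n, truth)
    hr_positions = np.concatenate(
        [np.arange(h.region_start, h.region_end + 1) for h in truth.hrs]
    ) if truth.hrs else np.zeros(0, int)
    coding_orfs = [o for o in truth.orfs if o.aa_length >= 10]

    def reserve(p: int, span: int = 1) -> bool:
        zone = set(range(p - 3, p + span + 3))
        if zone & used:
            return False
        used.update(zone)
        return True

    def freq(below: bool = False) -> float:
        if below:
            return float(rng.uniform(0.02, 0.099))
        while True:
            f = float(rng.uniform(0.10, 1.0))
            if f > 0.10:
                return f

    comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
    variants: list[Variant] = []
    classes: list[str] = []

    def add(v: Variant, cls: str) -> None:
        variants.append(v)
        classes.append(cls)

    def coding_snp(synonymous: bool) -> None:
        for _ in range(10_000):
            orf = coding_orfs[rng.integers(len(coding_orfs))]
            codon_i = int(rng.integers(1, orf.aa_length))  # internal codon
            within = int(rng.integers(3))
            cds_off = codon_i * 3 + within
            # forward-strand position of this coding-strand offset
            if orf.strand == "+":
                pos = orf.start + cds_off
            else:
                pos = orf.end - cds_off
            codon_start = cds_off - within
            if orf.strand == "+":
                codon = genome.fetch(orf.start + codon_start, orf.start + codon_start + 2)
            else:
                codon = revcomp(genome.fetch(orf.end - codon_start - 2, orf.end - codon_start))
            aa = str(Seq(codon).translate(table=1))
            alts = []
            for b in "ACGT":
                if b == codon[within]:
                    continue
                alt_codon = codon[:within] + b + codon[within + 1 :]
                same = str(Seq(alt_codon).translate(table=1)) == aa
                if same == synonymous:
                    alts.append(b)
            if not alts or not reserve(pos):
                continue
            alt_coding = alts[rng.integers(len(alts))]
            ref_fwd = genome.base(pos)
            alt_fwd = alt_coding if orf.strand == "+" else comp[alt_coding]
            add(
                Variant(position=int(pos), ref=ref_fwd, alt=alt_fwd, frequency=freq()),
                "synonymous" if synonymous else "nonsynonymous",
            )
            return
        raise RuntimeError("could not place a coding SNP")

    def noncoding_snp(below: bool = False) -> None:
        pool = np.concatenate([inter, hr_positions]) if len(hr_positions) else inter
        for _ in range(10_000):
            pos = int(pool[rng.integers(len(pool))])
            if not reserve(pos):
                continue
            ref = genome.base(pos)
            alt = "ACGT".replace(ref, "")[rng.integers(3)]
            add(
                Variant(position=pos, ref=ref, alt=alt, frequency=freq(below)),
                "hr_or_intergenic",
            )
            return
        raise RuntimeError("could not place a noncoding SNP")

    inter_set = set(int(p) for p in inter)

    def noncoding_indel() -> None:
        for _ in range(10_000):
            pos = int(inter[rng.integers(len(inter) - 5)])
            span = int(rng.integers(1, 4))
            inside = all(p in inter_set for p in range(pos, pos + span))
            if not inside or not reserve(pos, span):
                continue
            ref = genome.fetch(pos, pos + span - 1)
            add(
                Variant(position=pos, ref=ref, alt="", frequency=freq()),
                "hr_or_intergenic",
            )
            return
        raise RuntimeError("could not place a noncoding indel")

    def coding_indel(inframe: bool) -> None:
        for _ in range(10_000):
            orf = coding_orfs[rng.integers(len(coding_orfs))]
            span = 3 if inframe else int(rng.integers(1, 3))
            lo, hi = orf.start + 3, orf.end - 3 - span
            if hi <= lo:
                continue
            pos = int(rng.integers(lo, hi))
            if not reserve(pos, span):
                continue
            ref = genome.fetch(pos, pos + span - 1)
            add(
                Variant(position=pos, ref=ref, alt="", frequency=freq()),
                "inframe_indel" if inframe else "frameshift_indel",
            )
            return
        raise RuntimeError("could not place a coding indel")

    for _ in range(counts.synonymous):
        coding_snp(synonymous=True)
    for _ in range(counts.nonsynonymous):
        coding_snp(synonymous=False)
    for _ in range(counts.hr_intergenic_snp):
        noncoding_snp()
    for _ in range(counts.hr_intergenic_indel):
        noncoding_indel()
    for _ in range(counts.inframe_indel):
        coding_indel(inframe=True)
    for _ in range(counts.frameshift_indel):
        coding_indel(inframe=False)
    for _ in range(n_below_threshold):
        noncoding_snp(below=True)
    return variants, classes


# ---------------------------------------------------------------------------
# Sequence evolution (alignments with known divergence)
# ---------------------------------------------------------------------------

def _k2p_probs(t: float, kappa: float) -> tuple[float, float, float]:
    """(same, transition, each transversion) probabilities at distance t."""
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    e1 = np.exp(-4.0 * beta * t)
    e2 = np.exp(-2.0 * (alpha + beta) * t)
    p_tv = 0.25 - 0.25 * e1  # each of the two transversion targets
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_same = 1.0 - p_ts - 2.0 * p_tv
    return p_same, p_ts, p_tv

_NT = np.array(list("ACGT"))
_NT_INDEX = {b: i for i, b in enumerate("ACGT")}
# outcome rows per base index: (same, transition, transversion1, transversion2)
_K2P_TARGETS = np.array(
    [[_NT_INDEX[b] for b in row] for row in ("AGCT", "CTAG", "GACT", "TCAG")]
)


def _evolve_nt(parent: str, t: float, kappa: float, rates: np.ndarray, rng) -> str:
    parent_idx = np.array([_NT_INDEX[b] for b in parent])
    u = rng.random(len(parent))
    outcome = np.zeros(len(parent), dtype=int)
    for r in np.unique(rates):
        mask = rates == r
        p_same, p_ts, p_tv = _k2p_probs(t * r, kappa)
        cum = np.array([p_same, p_same + p_ts, p_same + p_ts + p_tv])
        outcome[mask] = np.searchsorted(cum, u[mask], side="right")
    child_idx = _K2P_TARGETS[parent_idx, outcome]
    return "".join(_NT[child_idx])


def _evolve_aa(parent: str, t: float, model, rates: np.ndarray, rng) -> str:
    from .phylo import AA_ORDER, _AA_INDEX

    parent_idx = np.array([_AA_INDEX[a] for a in parent])
    child_idx = np.zeros(len(parent), dtype=int)
    u = rng.random(len(parent))
    for r in np.unique(rates):
        mask = rates == r
        P = model.transition_matrix(t * r)
        cum = np.cumsum(P / P.sum(axis=1, keepdims=True), axis=1)
        child_idx[mask] = (u[mask, None] > cum[parent_idx[mask]]).sum(axis=1)
    aa_arr = np.array(list(AA_ORDER))
    return "".join(aa_arr[np.clip(child_idx, 0, 19)])


def evolve(
    root_seq: str | None,
    tree_or_t,
    model="k2p",
    seed: int = 0,
    kappa: float = 2.0,
    gamma_shape: float | None = None,
    length: int = 1000,
) -> dict[str, str]:
    """Simulate substitution-only evolution; the output is gap-free, hence aligned.

    ``model='k2p'`` evolves nucleotides with the given transition/transversion
    ratio; an :class:`ophanno.phylo.AAModel` evolves amino acids.  ``tree_or_t``
    is either a branch length (returns {'ancestor', 'descendant'}) or a Newick
    string with branch lengths (returns one sequence per leaf).  Rate
    heterogeneity uses four discrete gamma categories drawn per site.
    """
    from .phylo import AA_ORDER, discrete_gamma_rates

    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    is_nt = isinstance(model, str) and model == "k2p"
    if root_seq is None:
        if is_nt:
            root_seq = "".join(rng.choice(list("ACGT"), size=length))
        else:
            root_seq = "".join(
                rng.choice(list(AA_ORDER), size=length, p=model.freqs)
            )
    L = len(root_seq)
    if gamma_shape is None:
        rates = np.ones(L)
    else:
        cats = discrete_gamma_rates(gamma_shape, 4)
        rates = cats[rng.integers(0, 4, size=L)]

    def step(parent: str, t: float) -> str:
        if t == 0:
            return parent
        if is_nt:
            return _evolve_nt(parent, t, kappa, rates, rng)
        return _evolve_aa(parent, t, model, rates, rng)

    if isinstance(tree_or_t, (int, float)):
        return {"ancestor": root_seq, "descendant": step(root_seq, float(tree_or_t))}

    import dendropy

    tree = dendropy.Tree.get(data=str(tree_or_t), schema="newick")
    leaves: dict[str, str] = {}

    def walk(node, seq: str) -> None:
        for child in node.child_nodes():
            cseq = step(seq, child.edge.length or 0.0)
            if child.is_leaf():
                leaves[child.taxon.label] = cseq
            else:
                walk(child, cseq)

    walk(tree.seed_node, root_seq)
    return leaves
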