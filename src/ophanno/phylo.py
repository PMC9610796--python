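"""Distance-based phylogeny: ML pairwise amino-acid distances under empirical
substitution models, Saitou-Nei neighbor joining, and bootstrap support.

The pairwise distance between two aligned protein sequences is the branch
length t maximising the likelihood of the site pattern counts under a
reversible empirical model (JTT shipped as packaged data; a Poisson model is
provided as a closed-form check), optionally with rate heterogeneity across
sites modelled by four discrete gamma categories.  Neighbor joining plus
column-resampling bootstrap is the desk-scale stand-in for a minimum-evolution
search: ME analyses conventionally start from, and rarely move far from, the
NJ topology.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy.linalg import eigh
from scipy.optimize import minimize_scalar
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

AA_ORDER = "ARNDCQEGHILKMFPSTWYV"
_AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}


@dataclass
class AAModel:
    """A reversible amino-acid substitution model.

    ``rates`` is the symmetric exchangeability matrix S, ``freqs`` the
    equilibrium frequencies pi.  The generator Q (Q_ij = S_ij pi_j, rows
    summing to zero) is normalised to one expected substitution per site and
    eigendecomposed once so P(t) = exp(Qt) is cheap to evaluate.
    """

    name: str
    rates: np.ndarray
    freqs: np.ndarray

    def __post_init__(self) -> None:
        S = np.asarray(self.rates, dtype=float)
        pi = np.asarray(self.freqs, dtype=float)
        pi = pi / pi.sum()
        Q = S * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        scale = -(pi * np.diag(Q)).sum()
        Q /= scale
        self.freqs = pi
        self.Q = Q
        # symmetrise: B = D^{1/2} Q D^{-1/2} is symmetric for reversible Q
        d = np.sqrt(pi)
        B = (Q * d[:, None]) / d[None, :]
        w, U = eigh((B + B.T) / 2)
        self._w = w
        self._left = U / d[:, None] * 1.0
        self._right = (U * d[:, None]).T

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows sum to one."""
        P = (self._left * np.exp(self._w * t)) @ self._right
        return np.clip(P, 1e-300, None)


def _parse_paml_dat(text: str) -> tuple[np.ndarray, np.ndarray]:
    values = [
        float(tok)
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
        for tok in line.split()
    ]
    if len(values) != 190 + 20:
        raise ValueError(f"expected 210 numbers in PAML .dat file, got {len(values)}")
    S = np.zeros((20, 20))
    it = iter(values[:190])
    for i in range(1, 20):
        for j in range(i):
            S[i, j] = S[j, i] = next(it)
    freqs = np.array(values[190:])
    return S, freqs


def jtt_model() -> AAModel:
    """The JTT empirical model, loaded from the packaged PAML-format file."""
    text = resources.files("ophanno.data").joinpath("jtt.dat").read_text()
    S, freqs = _parse_paml_dat(text)
    return AAModel(name="JTT", rates=S, freqs=freqs)


def poisson_model() -> AAModel:
    """Uniform exchangeabilities and frequencies (closed-form check model)."""
    S = np.ones((20, 20))
    np.fill_diagonal(S, 0.0)
    return AAModel(name="Poisson", rates=S, freqs=np.full(20, 0.05))


def discrete_gamma_rates(shape: float, k: int = 4) -> np.ndarray:
    """Mean rates of k equal-probability discrete gamma categories (mean 1)."""
    cuts = gamma_dist.ppf(np.arange(1, k) / k, shape, scale=1.0 / shape)
    edges = np.concatenate([[0.0], cuts * shape, [np.inf]])
    upper = gammainc(shape + 1, edges[1:])
    lower = gammainc(shape + 1, edges[:-1])
    return k * (upper - lower)


def _pair_counts(seq1: str, seq2: str) -> np.ndarray:
    if len(seq1) != len(seq2):
        raise ValueError("aligned sequences must have equal length")
    N = np.zeros((20, 20))
    for a, b in zip(seq1.upper(), seq2.upper()):
        i = _AA_INDEX.get(a)
        j = _AA_INDEX.get(b)
        if i is not None and j is not None:
            N[i, j] += 1
    return N


def aa_distance(
    seq1: str,
    seq2: str,
    model: AAModel | None = None,
    gamma_shape: float | None = None,
    t_max: float = 10.0,
) -> float:
    """ML pairwise distance (substitutions/site) between aligned protein sequences.

    Sites with a gap or ambiguity in either sequence are excluded (pairwise
    deletion).  With ``gamma_shape``, rate variation uses four discrete gamma
    categories.  Raises on saturated pairs (optimum at the bracket ceiling).
    """
    model = model or jtt_model()
    N = _pair_counts(seq1, seq2)
    if N.sum() == 0:
        raise ValueError("no comparable sites")
    if N.sum() == np.trace(N):
        return 0.0
    rates = (
        discrete_gamma_rates(gamma_shape) if gamma_shape is not None else np.array([1.0])
    )
    log_pi = np.log(model.freqs)

    def neg_loglik(t: float) -> float:
        site_lik = np.zeros((20, 20))
        for r in rates:
            site_lik += model.transition_matrix(r * t)
        site_lik /= len(rates)
        return -float((N * (log_pi[:, None] + np.log(site_lik))).sum())

    res = minimize_scalar(
        neg_loglik, bounds=(1e-6, t_max), method="bounded",
        options={"xatol": 1e-8},
    )
    t_hat = float(res.x)
    if t_hat > t_max * 0.999:
        raise ValueError("saturated pair: distance optimisation hit the upper bracket")
    return t_hat


def distance_matrix(
    seqs: list[str],
    model: AAModel | None = None,
    gamma_shape: float | None = None,
) -> np.ndarray:
    model = model or jtt_model()
    n = len(seqs)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = aa_distance(seqs[i], seqs[j], model, gamma_shape)
    return D


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

class _Node:
    __slots__ = ("name", "children")

    def __init__(self, name: str | None = None, children=None):
        self.name = name
        self.children = children or []  # list of (child, branch_length)

    def leaves(self) -> frozenset:
        if self.name is not None:
            return frozenset([self.name])
        out = frozenset()
        for c, _ in self.children:
            out |= c.leaves()
        return out

    def newick(self, supports: dict[frozenset, float] | None = None, all_taxa=None) -> str:
        if self.name is not None:
            return self.name
        parts = []
        for c, bl in self.children:
            label = ""
            if supports is not None and c.name is None:
                split = _canonical_split(c.leaves(), all_taxa)
                if split in supports:
                    label = f"{supports[split]:g}"
            parts.append(f"{c.newick(supports, all_taxa)}{label}:{bl:.10g}")
        return "(" + ",".join(parts) + ")"


def _canonical_split(side: frozenset, all_taxa: frozenset) -> frozenset:
    anchor = min(all_taxa)
    return side if anchor not in side else all_taxa - side


def nj_tree(D: np.ndarray, names: list[str]) -> str:
    """Saitou-Nei neighbor joining; returns an unrooted tree in Newick form.

    Negative branch lengths are clamped to zero with the deficit moved to the
    sister branch.  Taxon input order does not affect the topology.
    """
    node, _ = _nj(D, names)
    return node.newick() + ";"


def _nj(D: np.ndarray, names: list[str]) -> tuple[_Node, frozenset]:
    D = np.asarray(D, dtype=float)
    n = len(names)
    if D.shape != (n, n):
        raise ValueError("distance matrix shape does not match taxon count")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if n < 3:
        raise ValueError("need at least 3 taxa")
    # deterministic order regardless of input order
    order = sorted(range(n), key=lambda i: names[i])
    D = D[np.ix_(order, order)].copy()
    nodes = [_Node(name=names[i]) for i in order]
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Qm = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Qm, np.inf)
        i_, j_ = np.unravel_index(np.argmin(Qm), Qm.shape)
        if i_ > j_:
            i_, j_ = j_, i_
        a, b = active[i_], active[j_]
        dij = D[a, b]
        li = 0.5 * dij + (r[i_] - r[j_]) / (2 * (m - 2))
        lj = dij - li
        if li < 0:
            li, lj = 0.0, dij
        elif lj < 0:
            li, lj = dij, 0.0
        parent = _Node(children=[(nodes[a], li), (nodes[b], lj)])
        # distances from the new node
        dnew = 0.5 * (D[a, :] + D[b, :] - dij)
        D = np.vstack([D, dnew])
        D = np.hstack([D, np.append(dnew, 0.0)[:, None]])
        nodes.append(parent)
        active = [x for x in active if x not in (a, b)] + [len(nodes) - 1]
    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    la, lb, lc = (max(0.0, x) for x in (la, lb, lc))
    root = _Node(children=[(nodes[a], la), (nodes[b], lb), (nodes[c], lc)])
    return root, root.leaves()


def tree_splits(node: _Node, all_taxa: frozenset) -> set[frozenset]:
    """Canonical internal bipartitions of an unrooted tree."""
    splits: set[frozenset] = set()

    def walk(nd: _Node, at_root: bool):
        for child, _ in nd.children:
            if child.name is None:
                leaves = child.leaves()
                if 1 < len(leaves) < len(all_taxa) - 1:
                    splits.add(_canonical_split(leaves, all_taxa))
                walk(child, False)

    walk(node, True)
    return splits


def bootstrap_support(
    alignment: dict[str, str],
    n_reps: int,
    seed: int,
    distance_fn=None,
    model: AAModel | None = None,
    gamma_shape: float | None = None,
) -> str:
    """NJ tree with bootstrap supports (0-100) on internal branches.

    Alignment columns are resampled with replacement ``n_reps`` times; support
    for a bipartition is the percentage of replicate NJ trees containing it.
    ``distance_fn(seq1, seq2) -> float`` overrides the default ML amino-acid
    distance.  With n_reps=0 the plain tree is returned without annotations.
    """
    names = sorted(alignment)
    seqs = [alignment[n] for n in names]
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("alignment rows must have equal length")
    if distance_fn is None:
        mdl = model or jtt_model()
        distance_fn = lambda a, b: aa_distance(a, b, mdl, gamma_shape)

    def dmat(cols_seqs: list[str]) -> np.ndarray:
        n = len(cols_seqs)
        D = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                D[i, j] = D[j, i] = distance_fn(cols_seqs[i], cols_seqs[j])
        return D

    base, taxa = _nj(dmat(seqs), names)
    if n_reps == 0:
        return base.newick() + ";"
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {}
    for _ in range(n_reps):
        idx = rng.integers(0, L, size=L)
        rep_seqs = ["".join(s[i] for i in idx) for s in seqs]
        rep, _ = _nj(dmat(rep_seqs), names)
        for split in tree_splits(rep, taxa):
            counts[split] = counts.get(split, 0) + 1
    supports = {s: 100.0 * c / n_reps for s, c in counts.items()}
    return base.newick(supports=supports, all_taxa=taxa) + ";"
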