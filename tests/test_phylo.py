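import math

import dendropy
import numpy as np
import pytest

from ophanno.phylo import (
    _parse_paml_dat,
    aa_distance,
    bootstrap_support,
    discrete_gamma_rates,
    jtt_model,
    nj_tree,
    poisson_model,
)
from ophanno.comparative_genomics import k2p_distance
from ophanno.synthetic_data import evolve


def _rf_zero(nwk1, nwk2):
    tns = dendropy.TaxonNamespace()
    t1 = dendropy.Tree.get(data=nwk1, schema="newick", taxon_namespace=tns)
    t2 = dendropy.Tree.get(data=nwk2, schema="newick", taxon_namespace=tns)
    t1.encode_bipartitions()
    t2.encode_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(t1, t2) == 0


class TestModels:
    def test_packaged_jtt_parses_to_a_valid_reversible_model(self):
        m = jtt_model()
        assert m.rates.shape == (20, 20)
        assert np.allclose(m.rates, m.rates.T)
        assert m.freqs.sum() == pytest.approx(1.0)
        # generator rows sum to zero, normalised to 1 substitution/site
        assert np.allclose(m.Q.sum(axis=1), 0.0, atol=1e-12)
        assert -(m.freqs * np.diag(m.Q)).sum() == pytest.approx(1.0)

    def test_transition_matrix_is_stochastic_and_respects_stationarity(self):
        m = jtt_model()
        P = m.transition_matrix(0.7)
        assert np.allclose(P.sum(axis=1), 1.0)
        assert np.allclose(m.freqs @ P, m.freqs, atol=1e-10)

    def test_malformed_dat_rejected(self):
        with pytest.raises(ValueError):
            _parse_paml_dat("1 2 3\n")


class TestGammaRates:
    def test_mean_one_and_monotone(self):
        rates = discrete_gamma_rates(0.79, 4)
        assert rates.mean() == pytest.approx(1.0, abs=1e-9)
        assert all(b > a for a, b in zip(rates, rates[1:]))

    def test_large_shape_collapses_to_uniform_rates(self):
        rates = discrete_gamma_rates(1e6, 4)
        assert np.allclose(rates, 1.0, atol=1e-2)


class TestAADistance:
    def test_identical_sequences_have_zero_distance(self):
        assert aa_distance("ACDEFGHIKL" * 10, "ACDEFGHIKL" * 10) == 0.0

    def test_poisson_special_case_matches_closed_form(self):
        pm = poisson_model()
        pair = evolve(None, 0.3, model=pm, seed=1, length=5000)
        d = aa_distance(pair["ancestor"], pair["descendant"], pm)
        p = np.mean(
            [a != b for a, b in zip(pair["ancestor"], pair["descendant"])]
        )
        closed = -19 / 20 * math.log(1 - 20 * p / 19)
        assert d == pytest.approx(closed, abs=1e-4)

    def test_jtt_simulation_recovery(self):
        """Sequences simulated under JTT at t=0.3 over 10,000 sites: the ML
        estimate lands within 0.03 in every one of 50 replicates."""
        m = jtt_model()
        errs = []
        for seed in range(50):
            pair = evolve(None, 0.3, model=m, seed=seed, length=10_000)
            errs.append(abs(aa_distance(pair["ancestor"], pair["descendant"], m) - 0.3))
        assert max(errs) < 0.03

    def test_gamma_rate_heterogeneity_recovered(self):
        m = jtt_model()
        pair = evolve(None, 0.5, model=m, seed=3, gamma_shape=0.79, length=20_000)
        d = aa_distance(pair["ancestor"], pair["descendant"], m, gamma_shape=0.79)
        assert d == pytest.approx(0.5, abs=0.05)

    def test_saturated_pair_raises(self):
        m = poisson_model()
        pair = evolve(None, 0.8, model=m, seed=5, length=2000)
        with pytest.raises(ValueError, match="saturated"):
            aa_distance(pair["ancestor"], pair["descendant"], m, t_max=0.5)

    def test_no_comparable_sites_raises(self):
        with pytest.raises(ValueError):
            aa_distance("---", "AC-")


ADDITIVE_D = np.array(
    [[0, 3, 8, 9], [3, 0, 9, 10], [8, 9, 0, 9], [9, 10, 9, 0]], float
)


class TestNeighborJoining:
    def test_additive_four_leaf_tree_recovered_exactly(self):
        nwk = nj_tree(ADDITIVE_D, ["A", "B", "C", "D"])
        assert _rf_zero(nwk, "((A:1,B:2):3,C:4,D:5);")
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        lengths = {
            leaf.taxon.label: leaf.edge.length for leaf in tree.leaf_node_iter()
        }
        assert lengths == {"A": 1.0, "B": 2.0, "C": 4.0, "D": 5.0}

    def test_three_taxa_closed_form(self):
        D = np.array([[0, 4, 6], [4, 0, 8], [6, 8, 0]], float)
        tree = dendropy.Tree.get(
            data=nj_tree(D, ["a", "b", "c"]), schema="newick"
        )
        lengths = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
        assert lengths == {"a": 1.0, "b": 3.0, "c": 5.0}

    def test_taxon_order_invariance(self):
        order1 = nj_tree(ADDITIVE_D, ["A", "B", "C", "D"])
        perm = [2, 0, 3, 1]
        D2 = ADDITIVE_D[np.ix_(perm, perm)]
        order2 = nj_tree(D2, [["A", "B", "C", "D"][i] for i in perm])
        assert order1 == order2

    def test_non_symmetric_matrix_rejected(self):
        bad = ADDITIVE_D.copy()
        bad[0, 1] = 99
        with pytest.raises(ValueError, match="symmetric"):
            nj_tree(bad, ["A", "B", "C", "D"])

    def test_matches_reference_nj_on_random_additive_matrices(self, rng):
        """Topology agrees with scikit-bio's NJ on additive matrices from
        random trees (n <= 10)."""
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        for trial in range(20):
            n = int(rng.integers(4, 11))
            D, names = _random_additive_matrix(rng, n)
            mine = nj_tree(D, names)
            ref_nwk = str(skbio_nj(DistanceMatrix(D, ids=names)))
            assert _rf_zero(mine, ref_nwk)


def _random_additive_matrix(rng, n):
    """Distance matrix of a random tree with random positive branch lengths."""
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n,
        rng=__import__("random").Random(int(rng.integers(2**31))),
    )
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = float(rng.uniform(0.1, 2.0))
    pdm = tree.phylogenetic_distance_matrix()
    taxa = list(tree.taxon_namespace)
    names = [t.label.replace(" ", "_") for t in taxa]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                D[i, j] = pdm.distance(taxa[i], taxa[j])
    return D, names


class TestBootstrap:
    def _two_clade_alignment(self, seed=0):
        nwk = "((a:0.02,b:0.02,c:0.02):0.5,(d:0.02,e:0.02,f:0.02):0.5);"
        return evolve(None, nwk, model="k2p", seed=seed, length=2000)

    @staticmethod
    def _k2p_fn(s1, s2):
        return k2p_distance(s1, s2).d

    def test_planted_split_gets_high_support(self):
        aln = self._two_clade_alignment()
        nwk = bootstrap_support(aln, n_reps=100, seed=7, distance_fn=self._k2p_fn)
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        supports = [
            float(nd.label) for nd in tree.preorder_node_iter()
            if nd.label and not nd.is_leaf()
        ]
        assert max(supports) >= 95

    def test_zero_reps_gives_unannotated_tree(self):
        aln = self._two_clade_alignment()
        nwk = bootstrap_support(aln, n_reps=0, seed=7, distance_fn=self._k2p_fn)
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        assert all(
            nd.label is None for nd in tree.preorder_node_iter() if not nd.is_leaf()
        )

    def test_same_seed_is_bit_exact(self):
        aln = self._two_clade_alignment()
        a = bootstrap_support(aln, n_reps=25, seed=3, distance_fn=self._k2p_fn)
        b = bootstrap_support(aln, n_reps=25, seed=3, distance_fn=self._k2p_fn)
        assert a == b
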