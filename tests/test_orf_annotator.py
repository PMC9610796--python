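import numpy as np
import pytest

from ophanno.genome_model import Genome, HrRegion, ORFRecord, Palindrome, RepeatUnit, revcomp
from ophanno.orf_annotator import (
    annotate,
    find_orfs,
    make_codon_usage_predicate,
    molecular_weight,
    molecular_weight_kda,
    orf_nucleotide_sequence,
    overlap_bp,
    read_homology_table,
    renumber,
    translate,
)

from oracles import six_frame_orfs


def _orf_set(orfs):
    return {(o.start, o.end, o.strand) for o in orfs}


class TestFindOrfs:
    def test_minimal_linear_orf(self):
        g = Genome(id="t", seq="ATGAAATAA")
        (orf,) = find_orfs(g, min_codons=2)
        assert (orf.start, orf.end, orf.strand, orf.aa_length) == (1, 9, "+", 2)

    def test_strand_symmetry(self):
        g = Genome(id="t", seq=revcomp("ATGAAATAA"))
        (orf,) = find_orfs(g, min_codons=2)
        assert (orf.start, orf.end, orf.strand) == (1, 9, "-")
        assert translate(orf, g) == "MK"

    def test_nested_in_frame_starts_suppressed(self):
        # ATG AAA ATG AAA TAA: one maximal ORF from the first ATG
        g = Genome(id="t", seq="ATGAAAATGAAATAA")
        orfs = find_orfs(g, min_codons=2)
        assert _orf_set(orfs) == {(1, 15, "+")}

    def test_junction_orf_on_circular_genome(self):
        body = "ATG" + "GCT" * 20 + "TAA"
        cut = 25
        seq = body[cut:] + "TTTCCGGATT" * 5 + body[:cut]
        g = Genome(id="c", seq=seq, circular=True)
        hits = [o for o in find_orfs(g, min_codons=10) if o.aa_length == 21]
        assert len(hits) == 1
        assert hits[0].end > len(seq) - cut  # wraps
        assert translate(hits[0], g) == "M" + "A" * 20

    @pytest.mark.parametrize("circular", [False, True])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, circular, seed, rng):
        r = np.random.default_rng(seed)
        seq = "".join(r.choice(list("ACGT"), size=3000))
        g = Genome(id="r", seq=seq, circular=circular)
        assert _orf_set(find_orfs(g, 20)) == six_frame_orfs(seq, circular, 20)

    def test_all_outputs_translate_cleanly(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=5000, p=[0.33, 0.17, 0.17, 0.33]))
        g = Genome(id="r", seq=seq, circular=True)
        for orf in find_orfs(g, 20):
            assert orf.span_length() % 3 == 0
            aa = translate(orf, g)
            assert "*" not in aa and len(aa) == orf.aa_length


def _mk_orf(start, end, strand="+", orf_id=0):
    return ORFRecord(
        orf_id=orf_id, name="", start=start, end=end, strand=strand,
        aa_length=(end - start + 1) // 3 - 1,
    )


def _mk_hr(start, end):
    return HrRegion(
        hr_id="hr1", region_start=start, region_end=end,
        units=[RepeatUnit(start, start + 3), RepeatUnit(start + 4, start + 7)],
        consensus="GATC", palindrome=Palindrome(2, 2, 0),
    )


ACCEPT = lambda orf: True
REJECT = lambda orf: False


class TestAnnotationRules:
    N = 10_000

    def test_hr_overlap_boundary_75_vs_76(self):
        """An unannotated ORF overlapping an hr by 76 bp is removed; 75 bp kept."""
        hr = _mk_hr(1000, 1500)
        keep = _mk_orf(1426, 1725)   # 75 bp inside the hr
        kept = annotate([keep], [hr], {}, ACCEPT, self.N)
        assert len(kept) == 1
        drop = _mk_orf(1425, 1724)   # 76 bp inside
        assert annotate([drop], [hr], {}, ACCEPT, self.N) == []

    def test_orf_inside_hr_removed_unless_homolog(self):
        hr = _mk_hr(1000, 2000)
        inside = _mk_orf(1100, 1399)
        assert annotate([inside], [hr], {}, ACCEPT, self.N) == []
        table = {inside.key(): ("vp91", "other")}
        kept = annotate([inside], [hr], table, REJECT, self.N)
        assert [o.annotation_basis for o in kept] == ["homolog"]

    def test_longer_orf_suppresses_heavily_overlapping_shorter(self):
        long = _mk_orf(1, 600)
        short = _mk_orf(100, 399)  # overlap 300 > 75
        kept = annotate([long, short], [], {}, ACCEPT, self.N)
        assert _orf_set(kept) == {(1, 600, "+")}

    def test_small_overlap_with_longer_orf_tolerated(self):
        long = _mk_orf(1, 600)
        short = _mk_orf(526, 825)  # overlap exactly 75
        kept = annotate([long, short], [], {}, ACCEPT, self.N)
        assert len(kept) == 2

    @pytest.mark.parametrize("offset", [30, 100, 150, 240, 300])
    def test_equal_length_tie_goes_to_earlier_start(self, offset):
        a = _mk_orf(200, 499)
        b = _mk_orf(200 + offset, 499 + offset)
        overlap = overlap_bp((a.start, a.end), (b.start, b.end), self.N)
        kept = annotate([b, a], [], {}, ACCEPT, self.N)
        if overlap <= 75:
            assert len(kept) == 2
        else:
            assert _orf_set(kept) == {(200, 499, "+")}

    def test_coding_predicate_gates_non_homologs(self):
        orf = _mk_orf(1, 300)
        assert annotate([orf], [], {}, REJECT, self.N) == []
        assert len(annotate([orf], [], {}, ACCEPT, self.N)) == 1

    def test_homology_sources_map_to_bases(self):
        orfs = [_mk_orf(1, 300), _mk_orf(400, 699), _mk_orf(800, 1099)]
        table = {
            orfs[0].key(): ("polh", "core"),
            orfs[1].key(): ("gp64", "alpha_conserved"),
            orfs[2].key(): ("ran", "other"),
        }
        kept = annotate(orfs, [], table, REJECT, self.N)
        assert [o.annotation_basis for o in kept] == [
            "core_gene", "alphabaculovirus_conserved", "homolog",
        ]


class TestRenumber:
    def test_sorted_by_start(self):
        orfs = [_mk_orf(1, 300), _mk_orf(500, 799), _mk_orf(301, 600)]
        out = renumber(orfs)
        assert [(o.orf_id, o.start) for o in out] == [(1, 1), (2, 301), (3, 500)]

    def test_shuffled_input_gives_same_ids(self):
        orfs = [_mk_orf(1, 300), _mk_orf(301, 600), _mk_orf(601, 900)]
        a = renumber(orfs)
        b = renumber(orfs[::-1])
        assert a == b

    def test_single_orf(self):
        assert renumber([_mk_orf(50, 349)])[0].orf_id == 1

    def test_duplicate_start_rejected(self):
        with pytest.raises(ValueError):
            renumber([_mk_orf(10, 309), _mk_orf(10, 309, strand="-")])


class TestTranslationAndWeight:
    @pytest.mark.parametrize(
        "start,end,expected_aa",
        [(11799, 12035, 78), (36077, 36721, 214), (95660, 96394, 244)],
    )
    def test_span_to_aa_arithmetic(self, start, end, expected_aa):
        orf = _mk_orf(start, end)
        assert orf.aa_length == expected_aa

    def test_tripeptide_average_mass(self):
        # 3 x Ala (71.0788) + water (18.0153), hand-summed
        assert molecular_weight("AAA") == pytest.approx(231.25, abs=0.01)

    def test_kda_rounding(self):
        assert molecular_weight_kda("AAA") == 0.2

    def test_internal_stop_is_an_error(self):
        g = Genome(id="t", seq="ATGTAAAAATAA")
        orf = _mk_orf(1, 12)
        with pytest.raises(ValueError, match="interrupted"):
            translate(orf, g)


class TestCodingPredicate:
    def test_separates_planted_from_spurious_frames(self, sim):
        genome, truth = sim
        called = find_orfs(genome, 50)
        homologs = [o for o in called if o.key() in truth.homology_table]
        predicate = make_codon_usage_predicate(genome, homologs)
        planted = {(o.start, o.end, o.strand) for o in truth.orfs}
        for orf in called:
            if (orf.start, orf.end, orf.strand) in planted:
                assert predicate(orf)
            else:
                assert not predicate(orf)

    def test_empty_reference_rejects_everything(self):
        g = Genome(id="t", seq="ATG" + "AAA" * 30 + "TAA")
        predicate = make_codon_usage_predicate(g, [])
        assert not predicate(_mk_orf(1, len(g.seq)))


def test_homology_table_io(tmp_path):
    p = tmp_path / "hom.tsv"
    p.write_text("1:300:+\tpolh\tcore\n400:699:-\tgp64\talpha_conserved\n")
    table = read_homology_table(p)
    assert table["1:300:+"] == ("polh", "core")
    p.write_text("1:300:+\tx\tnot_a_tag\n")
    with pytest.raises(ValueError):
        read_homology_table(p)
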