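import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ophanno.genome_model import Genome, revcomp
from ophanno.hr_finder import (
    RepeatCluster,
    build_consensus,
    classify_hrs,
    find_tandem_repeats,
    orient_units,
    palindrome_score,
)
from ophanno.genome_model import Palindrome, RepeatUnit
from ophanno.synthetic_data import HR_SEED_UNIT

from oracles import best_palindrome

UNIT = HR_SEED_UNIT  # printed 58-mer consensus of the hr repeat units


def _mutate(unit, n_mut, rng):
    u = list(unit)
    for i in rng.choice(len(u), size=n_mut, replace=False):
        u[i] = "ACGT"["ACGT".index(u[i]) - rng.integers(1, 4)]
    return "".join(u)


def _embed(rng, cassette, flank=1500):
    filler = "".join(rng.choice(list("ACGT"), size=2 * flank))
    return Genome(
        id="t", seq=filler[:flank] + cassette + filler[flank:], circular=False
    ), flank + 1


class TestBuildConsensus:
    def test_identical_copies_return_the_unit_verbatim(self):
        consensus, freqs = build_consensus([UNIT] * 3)
        assert consensus == UNIT
        assert all(col[b] == 3 for col, b in zip(freqs, UNIT))

    def test_majority_vote_with_tie_to_smallest_base(self):
        consensus, freqs = build_consensus(["ACGT", "ACGA", "ACGT"])
        assert consensus == "ACGT"
        assert freqs[3] == {"A": 1, "C": 0, "G": 0, "T": 2, "N": 0, "-": 0}
        # 1:1 tie resolved lexicographically
        assert build_consensus(["ACGA", "ACGT"])[0] == "ACGA"

    def test_empty_unit_list_rejected(self):
        with pytest.raises(ValueError):
            build_consensus([])

    def test_unequal_lengths_aligned_to_consensus(self):
        units = [UNIT, UNIT, UNIT[:30] + UNIT[31:]]  # one copy with a deletion
        consensus, _ = build_consensus(units)
        assert consensus == UNIT

    def test_mutated_copies_recover_unit_within_hamming_2(self):
        """6 copies at per-base error 0.05: consensus within Hamming distance
        2 of the truth in >=95% of 100 seeds."""
        ok = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            units = []
            for _ in range(6):
                u = [
                    b if rng.random() >= 0.05 else "ACGT"[rng.integers(4)]
                    for b in UNIT
                ]
                units.append("".join(u))
            consensus, _ = build_consensus(units)
            ham = sum(a != b for a, b in zip(consensus, UNIT))
            ok += ham <= 2
        assert ok >= 95


class TestOrientation:
    def test_reverse_units_flipped_and_labelled(self, rng):
        raw = [UNIT, revcomp(UNIT), UNIT]
        oriented, orientations, consensus = orient_units(raw)
        assert orientations == ["forward", "reverse", "forward"]
        assert consensus == UNIT
        assert oriented[1] == UNIT

    def test_orientation_tie_goes_forward(self):
        pal = "GAATTC" * 10  # reverse complement of itself
        _, orientations, _ = orient_units([pal, pal])
        assert orientations == ["forward", "forward"]


class TestPalindromeScore:
    def test_canonical_ecori_site(self):
        p = palindrome_score("GAATTC")
        assert (p.center, p.arm_length, p.mismatches) == (3, 3, 0)

    def test_homopolymer_is_not_a_palindrome(self):
        assert palindrome_score("AAAAAA").arm_length == 0

    @given(
        seq=st.text(alphabet="ACGT", min_size=4, max_size=60),
        mm=st.integers(min_value=0, max_value=2),
    )
    @settings(max_examples=150, derandomize=True, deadline=None)
    def test_matches_exhaustive_oracle(self, seq, mm):
        p = palindrome_score(seq, min_arm=1, max_mismatches=mm)
        assert (p.center, p.arm_length, p.mismatches) == best_palindrome(seq, 1, mm)

    def test_printed_unit_carries_an_imperfect_palindrome(self):
        p = palindrome_score(UNIT, min_arm=4, max_mismatches=2)
        assert p.arm_length >= 4


class TestFindTandemRepeats:
    def test_three_exact_copies_found_at_exact_coordinates(self, rng):
        g, start = _embed(rng, UNIT * 3)
        (cluster,) = find_tandem_repeats(g)
        assert (cluster.region_start, cluster.region_end) == (
            start, start + 3 * len(UNIT) - 1,
        )
        assert cluster.consensus == UNIT
        assert len(cluster.units) == 3

    def test_mutated_copies_recovered(self, rng):
        units = [_mutate(UNIT, 2, rng) for _ in range(3)]
        g, start = _embed(rng, "".join(units))
        (cluster,) = find_tandem_repeats(g)
        assert len(cluster.units) == 3
        assert abs(cluster.region_start - start) <= 2

    def test_mixed_orientations_detected(self, rng):
        units = [UNIT, revcomp(UNIT), UNIT, revcomp(UNIT)]
        g, start = _embed(rng, "".join(units))
        (cluster,) = find_tandem_repeats(g)
        assert [u.orientation for u in cluster.units] == [
            "forward", "reverse", "forward", "reverse",
        ]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_sequence_has_no_clusters(self, seed):
        rng = np.random.default_rng(seed)
        g = Genome(id="r", seq="".join(rng.choice(list("ACGT"), size=10_000)))
        assert find_tandem_repeats(g) == []

    def test_rotation_invariance(self, rng):
        from ophanno.genome_model import rotate_to_origin

        g, start = _embed(rng, UNIT * 3)
        g = Genome(id=g.id, seq=g.seq, circular=True)
        n = len(g.seq)
        base = find_tandem_repeats(g)
        # rotate so the hr spans the junction
        rotated, m = rotate_to_origin(g, start + 70)
        moved = find_tandem_repeats(rotated)
        assert len(base) == len(moved) == 1
        assert moved[0].consensus in (UNIT, revcomp(UNIT))
        assert (moved[0].region_start - 1) % n == m(base[0].region_start) - 1
        assert len(moved[0].units) == 3

    def test_reverse_complement_invariance(self, rng):
        g, _ = _embed(rng, UNIT * 3)
        flipped = Genome(id="f", seq=revcomp(g.seq))
        a = find_tandem_repeats(g)
        b = find_tandem_repeats(flipped)
        assert len(a) == len(b) == 1
        n = len(g.seq)
        assert b[0].region_start == n - a[0].region_end + 1
        assert b[0].region_end == n - a[0].region_start + 1


def _cluster(units_seqs, consensus, start=100):
    units = []
    pos = start
    for u in units_seqs:
        units.append(RepeatUnit(start=pos, end=pos + len(u) - 1))
        pos += len(u)
    return RepeatCluster(
        region_start=start, region_end=pos - 1, units=units,
        unit_seqs=units_seqs, consensus=consensus,
    )


class TestClassifyHrs:
    def test_two_unit_palindromic_cluster_is_an_hr(self):
        c = _cluster([UNIT, UNIT], UNIT)
        (hr,) = classify_hrs([c])
        assert hr.hr_id == "hr1"
        assert hr.palindrome.arm_length >= 4

    def test_cluster_without_palindrome_rejected(self):
        unit = "ACACACACAC" * 5  # AC-repeat: mirror pairs never complement
        c = _cluster([unit] * 5, unit)
        assert classify_hrs([c]) == []

    def test_unit_count_bounds(self):
        assert classify_hrs([_cluster([UNIT] * 7, UNIT)]) == []
        assert len(classify_hrs([_cluster([UNIT] * 6, UNIT)])) == 1

    def test_consensus_length_bounds(self):
        short = UNIT[:30]
        assert classify_hrs([_cluster([short] * 3, short)]) == []

    def test_ids_assigned_in_genome_order(self):
        c1 = _cluster([UNIT] * 2, UNIT, start=5000)
        c2 = _cluster([UNIT] * 3, UNIT, start=100)
        hrs = classify_hrs([c1, c2])
        assert [(h.hr_id, h.region_start) for h in hrs] == [
            ("hr1", 100), ("hr2", 5000),
        ]


class TestPlantedRecovery:
    def test_planted_hrs_recovered_with_exact_unit_counts(self, sim):
        """Every planted hr is recovered with its unit count; boundaries are
        localised to within a sub-unit offset (tandem phase ambiguity)."""
        genome, truth = sim
        hrs = classify_hrs(find_tandem_repeats(genome))
        assert len(hrs) == len(truth.hrs)
        for t in truth.hrs:
            matches = [
                h for h in hrs
                if abs(h.region_start - t.region_start) <= 10
                and abs(h.region_end - t.region_end) <= 10
                and len(h.units) == len(t.units)
            ]
            assert len(matches) == 1
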