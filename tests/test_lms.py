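import numpy as np
import pytest

from fragclust import (
    DistanceMatrix,
    ProteinRecord,
    diagonal_self_score,
    distance_matrix,
    fragment_index,
    lms_score,
    matched_coverage,
    pairwise_distance,
    read_distance_matrix,
    write_distance_matrix,
)
from _oracles import brute_coverage, brute_distance, brute_lms, random_protein


class TestFragmentIndex:
    def test_enumeration(self):
        assert fragment_index("ACDEFG") == {"ACDEF": [0], "CDEFG": [1]}

    def test_short_sequence_empty_index(self):
        assert fragment_index("ACD") == {}

    def test_repeated_kmer_collects_offsets(self):
        assert fragment_index("AAAAAA") == {"AAAAA": [0, 1]}

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            fragment_index("ACDEF", k=0)


class TestMatchedCoverage:
    def test_shared_fragment_example(self):
        pos_a, pos_b = matched_coverage("ACDEFGH", "MMACDEFYY")
        assert pos_a == set(range(5))
        assert pos_b == set(range(2, 7))

    def test_identical_sequences_fully_covered(self):
        s = "ACDEFGHIKL"
        pos_a, pos_b = matched_coverage(s, s)
        assert pos_a == pos_b == set(range(len(s)))

    def test_disjoint_alphabets_empty(self):
        assert matched_coverage("ACDEACDEA", "FGHIFGHIF") == (set(), set())

    def test_x_fragments_never_match(self):
        s = "ACDEFXGHIKL"  # windows crossing the X are excluded, even vs itself
        pos_a, pos_b = matched_coverage(s, s)
        assert pos_a == pos_b == set(range(5)) | set(range(6, 11))


class TestLmsScore:
    def test_worked_example(self, blosum):
        # shared 5-mer ACDEF covers A+C+D+E+F = 4+9+6+5+6 = 30 on each side
        assert lms_score("ACDEFGH", "MMACDEFYY", blosum) == 60

    def test_no_shared_fragment_scores_zero(self, blosum):
        assert lms_score("ACDEACDEA", "FGHIFGHIF", blosum) == 0

    def test_self_score_is_twice_diagonal_sum(self, blosum):
        s = "ACDEFGH"
        assert diagonal_self_score(s, blosum) == 44
        assert lms_score(s, s, blosum) == 2 * 44


class TestPairwiseDistance:
    def test_worked_example(self, blosum):
        d = pairwise_distance("ACDEFGH", "MMACDEFYY", blosum)
        assert d == pytest.approx(1 - 60 / 98, abs=1e-12)

    def test_identical_sequences_distance_zero(self, blosum):
        assert pairwise_distance("ACDEFGHIKL", "ACDEFGHIKL", blosum) == 0.0

    def test_no_shared_fragment_distance_one(self, blosum):
        assert pairwise_distance("ACDEACDEA", "FGHIFGHIF", blosum) == 1.0

    def test_sequences_shorter_than_fragment_distance_one(self, blosum):
        assert pairwise_distance("ACD", "ACD", blosum) == 1.0

    def test_symmetry_and_bounds_on_random_pairs(self, blosum):
        rng = np.random.default_rng(21)
        for _ in range(50):
            a = random_protein(rng, "a", int(rng.integers(5, 60))).residues
            b = random_protein(rng, "b", int(rng.integers(5, 60))).residues
            d_ab = pairwise_distance(a, b, blosum)
            d_ba = pairwise_distance(b, a, blosum)
            assert d_ab == d_ba
            assert 0.0 <= d_ab <= 1.0

    def test_appending_shared_block_never_increases_distance(self, blosum):
        # a novel shared 5-mer block adds equal positive weight to numerator
        # and denominator, pulling the ratio toward similarity
        rng = np.random.default_rng(22)
        for _ in range(30):
            a = random_protein(rng, "a", int(rng.integers(5, 40)), "ACDEFGHIKL").residues
            b = random_protein(rng, "b", int(rng.integers(5, 40)), "ACDEFGHIKL").residues
            block = random_protein(rng, "x", int(rng.integers(5, 15)), "MNPQRSTVWY").residues
            d0 = pairwise_distance(a, b, blosum)
            d1 = pairwise_distance(a + block, b + block, blosum)
            assert d1 <= d0 + 1e-12


class TestDistanceMatrix:
    def test_copy_and_unrelated_entries(self, blosum):
        a = ProteinRecord("a", "ACDEFGHIKL")
        a2 = ProteinRecord("a2", "ACDEFGHIKL")
        u = ProteinRecord("u", "MNPQRSTVWY")
        dm = distance_matrix([a, a2, u], blosum)
        assert dm.values[0, 1] == 0.0
        assert dm.values[0, 2] == 1.0
        assert dm.values[1, 2] == 1.0

    def test_matches_brute_force_oracle(self, blosum):
        rng = np.random.default_rng(23)
        records = [random_protein(rng, f"p{i}", 30) for i in range(10)]
        dm = distance_matrix(records, blosum)
        dm.validate()
        for i in range(10):
            for j in range(10):
                expect = 0.0 if i == j else brute_distance(
                    records[i].residues, records[j].residues, blosum
                )
                assert dm.values[i, j] == pytest.approx(expect, abs=1e-12)

    def test_symmetric_zero_diagonal(self, blosum):
        rng = np.random.default_rng(24)
        records = [random_protein(rng, f"p{i}", 25) for i in range(6)]
        dm = distance_matrix(records, blosum)
        assert np.array_equal(dm.values, dm.values.T)
        assert np.all(np.diag(dm.values) == 0)

    def test_requires_two_records(self, blosum):
        with pytest.raises(ValueError):
            distance_matrix([ProteinRecord("a", "ACDEF")], blosum)

    def test_tsv_round_trip(self, blosum, tmp_path):
        rng = np.random.default_rng(25)
        records = [random_protein(rng, f"p{i}", 30) for i in range(4)]
        dm = distance_matrix(records, blosum)
        path = tmp_path / "dm.tsv"
        write_distance_matrix(dm, path)
        back = read_distance_matrix(path)
        assert back.ids == dm.ids
        assert np.allclose(back.values, dm.values, atol=5e-7)  # 6 decimals

    def test_invariant_validation_rejects_bad_matrices(self):
        ids = ("a", "b")
        with pytest.raises(ValueError):
            DistanceMatrix(ids=ids, values=np.zeros((3, 3)))
        dm = DistanceMatrix(ids=ids, values=np.array([[0.0, 1.5], [1.5, 0.0]]))
        with pytest.raises(ValueError, match="outside"):
            dm.validate()


def test_coverage_and_score_agree_with_oracle_on_random_pairs(blosum):
    rng = np.random.default_rng(26)
    alphabet = "ACDEFGHIKLX"  # small alphabet forces collisions; X exercises exclusion
    for _ in range(60):
        a = random_protein(rng, "a", int(rng.integers(5, 61)), alphabet).residues
        b = random_protein(rng, "b", int(rng.integers(5, 61)), alphabet).residues
        assert matched_coverage(a, b) == brute_coverage(a, b)
        assert lms_score(a, b, blosum) == brute_lms(a, b, blosum)
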