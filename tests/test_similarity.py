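import math

import numpy as np
import pytest

from hostshift.alignment_io import GeneAlignment
from hostshift.errors import (
    AlignmentShapeError,
    DataValidationError,
    EmptyInputError,
)
from hostshift.similarity import (
    GAP_MODES,
    SimilarityMatrix,
    cross_group_stats,
    describe,
    jc_distance,
    jc_expected_identity,
    pairwise_identity,
    per_gene_pair_similarity,
    similarity_matrix,
)

from conftest import random_alignment


def oracle_identity(a: str, b: str, gap_mode: str) -> float:
    """Independent per-column counting oracle."""
    cols = [
        (ca, cb)
        for ca, cb in zip(a, b)
        if not (
            (gap_mode == "exclude_either" and ("-" in (ca, cb)))
            or (gap_mode == "exclude_both" and ca == "-" and cb == "-")
        )
    ]
    if not cols:
        return math.nan
    return sum(ca == cb for ca, cb in cols) / len(cols)


class TestPairwiseIdentity:
    @pytest.mark.parametrize(
        "a,b,mode,expected",
        [
            ("ACGT", "ACGT", "all", 1.0),
            ("ACGT", "ACGT", "exclude_either", 1.0),
            ("ACGT", "ACGT", "exclude_both", 1.0),
            ("AC-GT", "AC-GA", "all", 0.8),
            ("AC-GT", "AC-GA", "exclude_either", 0.75),
            ("AC-GT", "AC-GA", "exclude_both", 0.75),
            ("NN", "NN", "all", 1.0),
            ("A-CG", "AACG", "exclude_either", 1.0),
            ("A-CG", "AACG", "all", 0.75),
        ],
    )
    def test_examples(self, a, b, mode, expected):
        assert pairwise_identity(a, b, mode) == pytest.approx(expected)

    def test_all_gap_pair_undefined_when_gaps_excluded(self):
        assert math.isnan(pairwise_identity("----", "----", "exclude_either"))
        assert math.isnan(pairwise_identity("----", "----", "exclude_both"))
        assert pairwise_identity("----", "----", "all") == 1.0

    def test_length_mismatch(self):
        with pytest.raises(AlignmentShapeError):
            pairwise_identity("ACG", "AC")

    def test_gap_free_pairs_mode_independent(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            a = "".join(rng.choice(list("ACGT"), size=80))
            b = "".join(rng.choice(list("ACGT"), size=80))
            vals = {m: pairwise_identity(a, b, m) for m in GAP_MODES}
            assert len(set(vals.values())) == 1


class TestSimilarityMatrix:
    def test_trivial_matrix(self):
        m = similarity_matrix({"x": "AAAA", "y": "AAAA", "z": "TTTT"})
        assert m.value("x", "y") == 1.0
        assert m.value("x", "z") == 0.0
        assert m.value("y", "z") == 0.0
        assert np.allclose(m.values, m.values.T)
        assert np.allclose(np.diag(m.values), 1.0)

    def test_matches_counting_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            records = random_alignment(rng, int(rng.integers(2, 7)),
                                       int(rng.integers(5, 120)))
            for mode in GAP_MODES:
                m = similarity_matrix(records, mode)
                ids = list(records)
                for i, a in enumerate(ids):
                    for j, b in enumerate(ids):
                        want = oracle_identity(records[a], records[b], mode)
                        got = m.values[i, j]
                        assert (math.isnan(want) and math.isnan(got)) or got == want

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        records = random_alignment(rng, 5, 60)
        m1 = similarity_matrix(records)
        m2 = similarity_matrix(dict(reversed(records.items())))
        for a in records:
            for b in records:
                assert m1.value(a, b) == m2.value(a, b)

    def test_single_record_rejected(self):
        with pytest.raises(EmptyInputError):
            similarity_matrix({"x": "ACGT"})

    def test_csv_round_trip(self, tmp_path):
        rng = np.random.default_rng(4)
        m = similarity_matrix(random_alignment(rng, 4, 50))
        p = m.to_csv(tmp_path / "m.csv")
        back = SimilarityMatrix.from_csv(p)
        assert back.ids == m.ids
        assert np.allclose(back.values, np.round(m.values, 6), atol=1e-9)


class TestPerGenePair:
    def test_identical_everywhere(self):
        genes = [
            GeneAlignment("g1", {"x": "ACGT", "y": "ACGT"}),
            GeneAlignment("g2", {"x": "TTTT", "y": "TTTT"}),
        ]
        res = per_gene_pair_similarity(genes, "x", "y")
        assert list(res.values) == [1.0, 1.0]
        assert res.n_skipped == 0

    def test_missing_gene_skipped(self, toy_genes):
        res = per_gene_pair_similarity(toy_genes, "x", "y")
        assert len(res.values) == 2
        assert res.n_skipped == 1
        assert res.gene_ids == ["g1", "g2"]

    def test_absent_ids_error(self, toy_genes):
        with pytest.raises(EmptyInputError):
            per_gene_pair_similarity(toy_genes, "x", "nope")
        with pytest.raises(DataValidationError):
            per_gene_pair_similarity(toy_genes, "x", "x")


class TestDescribe:
    def test_single_value(self):
        s = describe([0.5])
        assert s.n_genes == 1
        assert s.mean == 0.5
        assert math.isnan(s.std)
        assert s.q25 == s.q50 == s.q75 == 0.5

    def test_linear_interpolation_quantiles(self):
        s = describe([0.1, 0.2, 0.3, 0.4])
        assert s.q25 == pytest.approx(0.175)
        assert s.q50 == pytest.approx(0.25)
        assert s.q75 == pytest.approx(0.325)

    def test_sample_std(self):
        s = describe([0.8, 0.9, 1.0])
        assert s.mean == pytest.approx(0.9)
        assert s.std == pytest.approx(0.1)
        assert (s.min, s.max) == (0.8, 1.0)

    def test_constant_vector(self):
        s = describe([0.7] * 5)
        assert s.std == 0.0
        assert s.q25 == s.q50 == s.q75 == s.mean == 0.7

    def test_empty_rejected(self):
        with pytest.raises(EmptyInputError):
            describe([])


class TestCrossGroupStats:
    def _matrix(self, block):
        # embed a 2x2 cross block into a 4x4 symmetric similarity matrix
        vals = np.ones((4, 4))
        vals[0:2, 2:4] = block
        vals[2:4, 0:2] = np.asarray(block).T
        return SimilarityMatrix(ids=["a1", "a2", "b1", "b2"], values=vals,
                                gap_mode="all")

    def test_hand_computed_block(self):
        m = self._matrix([[0.9, 0.8], [0.9, 0.7]])
        s = cross_group_stats(m, ["a1", "a2"], ["b1", "b2"])
        assert s.overall_mean == pytest.approx(0.825)
        assert s.overall_min == 0.7
        assert s.overall_max == 0.9
        assert s.row_max_mean == pytest.approx(0.9)
        assert s.row_max_mode == pytest.approx(0.9)

    def test_mode_tie_broken_by_smaller_value(self):
        m = self._matrix([[0.9, 0.8], [0.7, 0.85]])
        s = cross_group_stats(m, ["a1", "a2"], ["b1", "b2"])
        # row maxima 0.9 and 0.85 each occur once; the smaller wins
        assert s.row_max_mode == pytest.approx(0.85)

    def test_singleton_groups(self):
        m = self._matrix([[0.5, 0.2], [0.2, 0.2]])
        s = cross_group_stats(m, ["a1"], ["b1"])
        assert s.overall_mean == s.overall_min == s.overall_max == 0.5
        assert s.row_max_mode == 0.5

    def test_overlap_rejected(self):
        m = self._matrix([[0.5, 0.2], [0.2, 0.2]])
        with pytest.raises(DataValidationError):
            cross_group_stats(m, ["a1", "b1"], ["b1", "b2"])


def test_jc_identity_distance_inverse():
    for d in (0.01, 0.1, 0.5, 1.5):
        assert jc_distance(jc_expected_identity(d)) == pytest.approx(d)
    assert math.isnan(jc_distance(0.25))
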