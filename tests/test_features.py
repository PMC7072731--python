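"""Composition and profile feature blocks against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ubp_pred.features import (
    FeatureMatrix,
    compute_aac,
    compute_dc,
    compute_pssm_composition,
    dc_names,
    feature_names,
    featurize,
)
from ubp_pred.io_formats import STANDARD_AA, ProteinRecord, PssmMatrix

sequences = st.text(alphabet=STANDARD_AA, min_size=2, max_size=120)


def make_pssm(record: ProteinRecord, scores: np.ndarray, order: str = STANDARD_AA):
    return PssmMatrix(record.id, scores, order, row_residues=record.sequence)


class TestAac:
    def test_homopolymer(self):
        vec = compute_aac(ProteinRecord("p", "AAAA"))
        assert vec[0] == 1.0 and vec[1:].sum() == 0

    def test_mixed_counts(self):
        vec = compute_aac(ProteinRecord("p", "ACDC"))
        expect = {"A": 0.25, "C": 0.5, "D": 0.25}
        for i, aa in enumerate(STANDARD_AA):
            assert vec[i] == expect.get(aa, 0.0)

    def test_dimension_is_20(self):
        assert compute_aac(ProteinRecord("p", "WYV")).shape == (20,)

    @settings(max_examples=50, deadline=None)
    @given(seq=sequences)
    def test_sums_to_one(self, seq):
        assert compute_aac(ProteinRecord("p", seq)).sum() == pytest.approx(1.0, abs=1e-9)

    def test_permutation_invariance(self):
        a = compute_aac(ProteinRecord("p", "ACDEFG"))
        b = compute_aac(ProteinRecord("p", "GFEDCA"))
        assert np.array_equal(a, b)

    def test_nonstandard_residue_is_error(self):
        with pytest.raises(ValueError, match="nonstandard"):
            compute_aac(ProteinRecord("p", "ABCD"))


class TestDc:
    def test_homopolymer(self):
        vec = compute_dc(ProteinRecord("p", "AAA"))
        names = dc_names()
        assert vec[names.index("DC:AA")] == 1.0
        assert vec.sum() == 1.0

    def test_alternating(self):
        vec = compute_dc(ProteinRecord("p", "ACA"))
        names = dc_names()
        assert vec[names.index("DC:AC")] == 0.5
        assert vec[names.index("DC:CA")] == 0.5

    def test_dimension_is_400(self):
        assert compute_dc(ProteinRecord("p", "ACDE")).shape == (400,)

    def test_length_one_is_error(self):
        with pytest.raises(ValueError, match="sequence_too_short_for_dc"):
            compute_dc(ProteinRecord("p", "A"))

    @settings(max_examples=50, deadline=None)
    @given(seq=sequences)
    def test_sums_to_one(self, seq):
        assert compute_dc(ProteinRecord("p", seq)).sum() == pytest.approx(1.0, abs=1e-9)

    def test_permutation_changes_dc(self):
        # fixed counterexample: same composition, different adjacencies
        a = compute_dc(ProteinRecord("p", "AACC"))
        b = compute_dc(ProteinRecord("p", "ACAC"))
        assert not np.array_equal(a, b)


class TestPssmComposition:
    def test_forced_two_residue_example(self):
        rec = ProteinRecord("p", "AC")
        scores = np.zeros((2, 20))
        scores[0, STANDARD_AA.index("A")] = 2
        scores[1, STANDARD_AA.index("C")] = 3
        scores[1, STANDARD_AA.index("A")] = 7
        vec = compute_pssm_composition(rec, make_pssm(rec, scores))
        names = feature_names()[420:]
        out = dict(zip(names, vec))
        assert out["PSSM:A|A"] == 2
        assert out["PSSM:C|C"] == 3
        assert out["PSSM:C|A"] == 7
        assert sum(v for v in vec) == 12

    def test_all_zero_pssm(self):
        rec = ProteinRecord("p", "ACDEFG")
        vec = compute_pssm_composition(rec, make_pssm(rec, np.zeros((6, 20))))
        assert not vec.any()

    def test_brute_force_oracle_random_fixture(self):
        rng = np.random.default_rng(7)
        seq = "".join(rng.choice(list(STANDARD_AA), size=60))
        rec = ProteinRecord("p", seq)
        scores = rng.normal(size=(60, 20))
        vec = compute_pssm_composition(rec, make_pssm(rec, scores))
        # independent brute force: double loop over (position, column)
        expected = np.zeros((20, 20))
        for p, residue in enumerate(seq):
            for c in range(20):
                expected[STANDARD_AA.index(residue), c] += scores[p, c]
        assert np.allclose(vec, expected.ravel())

    def test_linear_in_scores(self):
        rng = np.random.default_rng(8)
        seq = "".join(rng.choice(list(STANDARD_AA), size=40))
        rec = ProteinRecord("p", seq)
        A = rng.normal(size=(40, 20))
        B = rng.normal(size=(40, 20))
        f = lambda s: compute_pssm_composition(rec, make_pssm(rec, s))
        assert np.allclose(f(A + B), f(A) + f(B))

    def test_column_order_contract(self):
        # a permuted file column order must give identical canonical features
        rng = np.random.default_rng(9)
        seq = "".join(rng.choice(list(STANDARD_AA), size=30))
        rec = ProteinRecord("p", seq)
        scores = rng.normal(size=(30, 20))
        canonical = compute_pssm_composition(rec, make_pssm(rec, scores))
        shuffled_order = "ARNDCQEGHILKMFPSTWYV"  # PSI-BLAST header order
        perm = [STANDARD_AA.index(a) for a in shuffled_order]
        permuted = compute_pssm_composition(
            rec, make_pssm(rec, scores[:, perm], order=shuffled_order)
        )
        assert np.allclose(canonical, permuted)

    def test_row_mismatch_is_error(self):
        rec = ProteinRecord("p", "ACDE")
        with pytest.raises(ValueError, match="rows"):
            compute_pssm_composition(rec, make_pssm(ProteinRecord("p", "ACD"), np.zeros((3, 20))))

    def test_normalize_by_length(self):
        rec = ProteinRecord("p", "AAAA")
        scores = np.ones((4, 20))
        vec = compute_pssm_composition(rec, make_pssm(rec, scores), normalize="by_length")
        assert vec[:20].sum() == pytest.approx(20.0)  # 4 positions * 1 / L=4 per column


class TestFeaturize:
    def test_length_and_block_boundaries(self):
        rng = np.random.default_rng(10)
        seq = "".join(rng.choice(list(STANDARD_AA), size=55))
        rec = ProteinRecord("p", seq)
        pssm = make_pssm(rec, rng.normal(size=(55, 20)))
        fv = featurize(rec, pssm)
        assert len(fv.values) == 820
        assert np.array_equal(fv.values[:20], compute_aac(rec))
        assert np.array_equal(fv.values[20:420], compute_dc(rec))
        assert np.array_equal(fv.values[420:], compute_pssm_composition(rec, pssm))

    def test_no_pssm_block_gives_420(self):
        fv = featurize(ProteinRecord("p", "ACDEF"), include_pssm=False)
        assert len(fv.values) == 420

    def test_missing_pssm_is_error(self):
        with pytest.raises(ValueError, match="PSSM"):
            featurize(ProteinRecord("p", "ACDEF"), None)

    def test_names_are_bijective_with_positions(self):
        names = feature_names()
        assert len(names) == 820
        assert len(set(names)) == 820


class TestFeatureMatrix:
    def test_tsv_round_trip(self, tmp_path, planted_matrix):
        path = tmp_path / "matrix.tsv"
        planted_matrix.to_tsv(path)
        loaded = FeatureMatrix.from_tsv(path)
        assert loaded.ids == planted_matrix.ids
        assert loaded.names == planted_matrix.names
        assert np.allclose(loaded.values, planted_matrix.values)
        assert np.array_equal(loaded.labels, planted_matrix.labels)

    def test_nan_rejected(self):
        with pytest.raises(ValueError, match="NaN"):
            FeatureMatrix(["a"], ["f"], np.array([[np.nan]]))

    def test_select_features_reorders(self, separable_matrix):
        sub = separable_matrix.select_features(["f3", "f0"])
        assert sub.names == ["f3", "f0"]
        assert np.array_equal(sub.values[:, 1], separable_matrix.values[:, 0])
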