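"""Natural-abundance correction: formula parsing, convolution, deconvolution."""

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from midflux.correction import (
    IsotopologueVector,
    build_correction_matrix,
    correct_mid,
    format_formula,
    load_isotope_table,
    natural_mid,
    parse_formula,
    tracked_label_fraction,
    validate_isotope_table,
)
from midflux.errors import FormulaError, ValidationError

from conftest import brute_force_matrix


class TestParseFormula:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("C3H6O3", {"C": 3, "H": 6, "O": 3}),
            ("C6H12O6", {"C": 6, "H": 12, "O": 6}),
            ("CH4", {"C": 1, "H": 4}),
            ("C5H8O5", {"C": 5, "H": 8, "O": 5}),
            ("C9H21O3Si3", {"C": 9, "H": 21, "O": 3, "Si": 3}),
            ("CHOC", {"C": 2, "H": 1, "O": 1}),  # repeats accumulate
        ],
    )
    def test_grammar(self, text, expected):
        assert parse_formula(text) == expected

    @pytest.mark.parametrize("bad", ["C3H6O3#", "3CH6", "", "c3h6", "C-3"])
    def test_malformed(self, bad):
        with pytest.raises(FormulaError):
            parse_formula(bad)

    def test_error_names_position(self):
        with pytest.raises(FormulaError, match="position 6"):
            parse_formula("C3H6O3#H2")

    @given(
        st.dictionaries(
            st.sampled_from(["C", "H", "N", "O", "S", "Si"]),
            st.integers(min_value=1, max_value=40),
            min_size=1,
        )
    )
    @settings(deadline=None, max_examples=50)
    def test_roundtrip_through_canonical_writer(self, counts):
        assert parse_formula(format_formula(counts)) == counts


class TestIsotopeTable:
    def test_packaged_table_valid(self, isotopes):
        validate_isotope_table(isotopes)
        assert isotopes["C"] == [(0, 0.9893), (1, 0.0107)]

    def test_rejects_bad_sum(self):
        with pytest.raises(ValidationError, match="sum"):
            validate_isotope_table({"C": [(0, 0.9), (1, 0.2)]})

    def test_rejects_non_increasing_shifts(self):
        with pytest.raises(ValidationError, match="increasing"):
            validate_isotope_table({"C": [(1, 0.5), (0, 0.5)]})


class TestNaturalMid:
    def test_single_atom_is_abundance_vector(self, isotopes):
        np.testing.assert_allclose(
            natural_mid({"C": 1}, isotopes, 1), [0.9893, 0.0107]
        )

    @pytest.mark.parametrize("n", [2, 3, 6, 20])
    def test_carbon_only_matches_binomial(self, isotopes, n):
        """For a C_n fragment the MID is the Binomial(n, a13C) pmf."""
        a13 = dict(isotopes["C"])[1]
        expected = scipy.stats.binom.pmf(np.arange(n + 1), n, a13)
        got = natural_mid({"C": n}, isotopes, n)
        np.testing.assert_allclose(got, expected, atol=1e-14)

    def test_pure_element_has_no_heavy_mass(self, pure_isotopes):
        np.testing.assert_array_equal(
            natural_mid({"C": 2}, pure_isotopes, 2), [1.0, 0.0, 0.0]
        )

    def test_untruncated_vector_sums_to_one(self, isotopes):
        v = natural_mid({"C": 6, "H": 12, "O": 6}, isotopes, 24 + 12)
        assert v.sum() == pytest.approx(1.0, abs=1e-12)

    def test_missing_element_rejected(self, isotopes):
        with pytest.raises(ValidationError, match="Xx"):
            natural_mid({"Xx": 1}, isotopes, 1)


class TestCorrectionMatrix:
    def test_identity_without_natural_abundance(self, pure_isotopes):
        A = build_correction_matrix({"C": 2}, "C", 2, pure_isotopes, max_shift=2)
        np.testing.assert_array_equal(A.matrix, np.eye(3))

    def test_unlabeled_column_is_fragment_mid(self, isotopes):
        A = build_correction_matrix({"C": 2}, "C", 2, isotopes)
        np.testing.assert_allclose(
            A.matrix[:3, 0], [0.9893**2, 2 * 0.9893 * 0.0107, 0.0107**2]
        )

    def test_label_exceeding_tracer_atoms_rejected(self, isotopes):
        with pytest.raises(ValidationError, match="exceeds"):
            build_correction_matrix({"C": 2}, "C", 3, isotopes)

    def test_columns_stochastic_up_to_truncation(self, isotopes):
        """Column deficit < 1e-6 even for a large (30-carbon) fragment."""
        A = build_correction_matrix({"C": 30, "H": 50, "O": 10}, "C", 6, isotopes)
        assert np.all(A.matrix >= 0) and np.all(A.matrix <= 1)
        assert np.all(A.column_deficits >= -1e-12)
        assert np.all(A.column_deficits < 1e-6)

    def test_no_mass_below_label_count(self, isotopes):
        """Natural abundance only adds mass: A[i, j] = 0 for i < j."""
        A = build_correction_matrix({"C": 6, "H": 8, "O": 7}, "C", 2, isotopes)
        for j in range(A.n_label + 1):
            assert np.all(A.matrix[:j, j] == 0)

    def test_unlabeled_column_spreads_upward(self, isotopes):
        """With heavy isotopes present, an unlabeled pool leaks mass into
        every retained m+k channel."""
        A = build_correction_matrix({"C": 3, "H": 6, "O": 3}, "C", 3, isotopes)
        assert np.all(A.matrix[1:, 0] > 0)

    def test_impure_tracer_column_is_binomial_mixture(self, pure_isotopes):
        """With no natural abundance, column j is the Binomial(j, purity)
        pmf over mass shifts."""
        purity = 0.99
        A = build_correction_matrix(
            {"C": 3}, "C", 3, pure_isotopes, tracer_purity=purity, max_shift=3
        )
        expected = scipy.stats.binom.pmf(np.arange(4), 3, purity)
        np.testing.assert_allclose(A.matrix[:, 3], expected, atol=1e-14)

    @pytest.mark.parametrize(
        "counts,n_label",
        [
            ({"C": 2}, 2),
            ({"C": 3}, 3),
            ({"C": 5}, 2),
            ({"C": 3, "O": 2}, 3),
            ({"C": 2, "H": 3}, 2),
            ({"C": 4, "O": 4}, 2),
        ],
    )
    def test_matches_brute_force_enumeration(self, isotopes, counts, n_label):
        """Convolution equals exhaustive enumeration over per-atom isotope
        assignments for small fragments."""
        max_shift = n_label + 3
        A = build_correction_matrix(counts, "C", n_label, isotopes,
                                    max_shift=max_shift)
        B = brute_force_matrix(counts, "C", n_label, isotopes, max_shift)
        np.testing.assert_allclose(A.matrix, B, atol=1e-12)


class TestCorrectMid:
    @pytest.fixture()
    def A(self, isotopes):
        return build_correction_matrix({"C": 3, "H": 6, "O": 3}, "C", 3, isotopes)

    @pytest.mark.parametrize("method", ["nnls", "pinv"])
    @pytest.mark.parametrize(
        "x_true", [[1, 0, 0, 0], [0.6, 0.1, 0.3, 0.0], [0.25, 0.25, 0.25, 0.25]]
    )
    def test_noiseless_roundtrip(self, A, method, x_true):
        x_true = np.array(x_true, float)
        raw = A.matrix @ x_true
        out = correct_mid(raw, A, method=method)
        np.testing.assert_allclose(out.values, x_true, atol=1e-10)
        assert out.status == "corrected"

    def test_identity_matrix_returns_normalized_raw(self, pure_isotopes):
        A = build_correction_matrix({"C": 3}, "C", 3, pure_isotopes, max_shift=3)
        raw = np.array([2.0, 1.0, 1.0, 4.0])
        out = correct_mid(raw, A)
        np.testing.assert_allclose(out.values, raw / raw.sum(), atol=1e-12)

    def test_noisy_roundtrip_within_tolerance(self, A):
        rng = np.random.default_rng(42)
        x_true = np.array([0.6, 0.1, 0.3, 0.0])
        raw = A.matrix @ x_true + 1e-4 * (rng.random(A.matrix.shape[0]) - 0.5)
        raw = np.clip(raw, 0, None)
        out = correct_mid(raw, A, method="nnls")
        np.testing.assert_allclose(out.values, x_true, atol=5e-3)
        assert out.residual < 1e-3

    def test_all_zero_raw_rejected(self, A):
        with pytest.raises(ValidationError, match="all-zero"):
            correct_mid(np.zeros(A.matrix.shape[0]), A)

    def test_length_mismatch_rejected(self, A):
        with pytest.raises(ValidationError, match="length"):
            correct_mid(np.ones(3), A)


class TestTrackedLabelFraction:
    def _vec(self, values, status="corrected"):
        return IsotopologueVector(metabolite="lactate", values=values, status=status)

    def test_direct_indexing(self):
        assert tracked_label_fraction(self._vec([0.75, 0, 0, 0.25]), 3) == 0.25

    def test_unlabeled_pool(self):
        assert tracked_label_fraction(self._vec([1.0, 0, 0]), 2) == 0.0

    def test_out_of_bounds(self):
        with pytest.raises(ValidationError, match="out of bounds"):
            tracked_label_fraction(self._vec([0.7, 0.1, 0.1, 0.1]), 5)

    def test_raw_input_rejected(self):
        with pytest.raises(ValidationError, match="corrected"):
            tracked_label_fraction(self._vec([1.0, 0, 0], status="raw"), 2)


def test_examples_rederive_from_shipped_table(tmp_path):
    """Loading an edited isotope file changes the computed values (nothing
    is hard-coded against the shipped abundances)."""
    custom = tmp_path / "iso.tsv"
    custom.write_text(
        "element\tshift\tabundance\nC\t0\t0.9\nC\t1\t0.1\n", encoding="utf-8"
    )
    iso = load_isotope_table(custom)
    np.testing.assert_allclose(natural_mid({"C": 1}, iso, 1), [0.9, 0.1])
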