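"""Correction-matrix construction, NNLS deconvolution, and kinetics fits."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import binom

from isoflux.errors import (
    EmptyMeasurementError,
    InsufficientRangeError,
    InvalidFormulaError,
    ParameterError,
)
from isoflux.isocorrect import (
    ElementFormula,
    FractionalEnrichment,
    RawMID,
    TracerConfig,
    build_correction_matrix,
    correct_mid,
    fit_labeling_kinetics,
    labeled_fraction,
    parse_formula,
)

A13C = 0.0107


class TestCorrectionMatrix:
    def test_pure_carbon_column_zero_is_natural_binomial(self, c2_formula, pure_tracer):
        cm = build_correction_matrix(c2_formula, pure_tracer, K=2)
        expected = [(1 - A13C) ** 2, 2 * A13C * (1 - A13C), A13C**2]
        np.testing.assert_allclose(cm.matrix[:, 0], expected, atol=1e-12)
        np.testing.assert_allclose(
            cm.matrix[:, 0], [0.97871449, 0.02117102, 0.00011449], atol=1e-8
        )

    def test_fully_labeled_column_is_purity_binomial(self, c2_formula):
        cm = build_correction_matrix(c2_formula, TracerConfig(purity=0.99), K=2)
        np.testing.assert_allclose(cm.matrix[:, 2], [0.0001, 0.0198, 0.9801], atol=1e-12)

    @pytest.mark.parametrize("n_carbon", [1, 3, 6])
    def test_all_columns_match_binomial_closed_form(self, n_carbon):
        """For pure-carbon fragments every column is a product of two binomials."""
        formula = ElementFormula({"C": n_carbon}, n_tracer=n_carbon)
        p = 0.97
        cm = build_correction_matrix(formula, TracerConfig(purity=p), K=n_carbon)
        for j in range(n_carbon + 1):
            natural = binom.pmf(np.arange(n_carbon - j + 1), n_carbon - j, A13C)
            label = binom.pmf(np.arange(j + 1), j, p)
            expected = np.convolve(natural, label)[: n_carbon + 1]
            np.testing.assert_allclose(cm.matrix[:, j], expected, atol=1e-12)

    def test_degenerate_isotopes_give_identity(self):
        formula = ElementFormula({"C": 3, "H": 4}, n_tracer=3)
        pure = {"C": [(0, 1.0)], "H": [(0, 1.0)]}
        cm = build_correction_matrix(formula, TracerConfig(purity=1.0), isotopes=pure, K=3)
        np.testing.assert_allclose(cm.matrix, np.eye(4), atol=1e-15)

    def test_full_support_columns_are_stochastic(self, tbdms_like_formula):
        from isoflux.isotopes import NATURAL_ABUNDANCE

        f = tbdms_like_formula
        # K large enough to hold the entire isotope envelope
        k_full = sum(
            n * max(shift for shift, _ in NATURAL_ABUNDANCE[el]) for el, n in f.counts.items()
        )
        cm = build_correction_matrix(f, TracerConfig(purity=0.99), K=k_full)
        np.testing.assert_allclose(cm.matrix.sum(axis=0), 1.0, atol=1e-9)

    def test_truncated_columns_sum_below_one(self, tbdms_like_formula):
        cm = build_correction_matrix(tbdms_like_formula, K=tbdms_like_formula.n_tracer + 3)
        sums = cm.matrix.sum(axis=0)
        assert np.all(sums <= 1.0 + 1e-12)

    def test_purity_monotonicity(self, c2_formula):
        """Diagonal entries shrink as tracer purity degrades."""
        purities = [1.0, 0.99, 0.95, 0.9]
        diagonals = []
        for p in purities:
            cm = build_correction_matrix(c2_formula, TracerConfig(purity=p), K=2)
            diagonals.append(np.diag(cm.matrix))
        for lo, hi in zip(diagonals[1:], diagonals[:-1]):
            assert np.all(lo <= hi + 1e-15)

    def test_invalid_formula_and_range_errors(self):
        with pytest.raises(InvalidFormulaError):
            build_correction_matrix(ElementFormula({"C": 2}, n_tracer=3), K=4)
        with pytest.raises(InsufficientRangeError):
            build_correction_matrix(ElementFormula({"C": 4}, n_tracer=4), K=2)


class TestCorrectMid:
    def test_identity_on_forward_image(self, c2_formula, pure_tracer):
        cm = build_correction_matrix(c2_formula, pure_tracer, K=2)
        raw = RawMID("m", c2_formula, 0.0, "r1", cm.matrix @ np.array([1.0, 0.0, 0.0]))
        np.testing.assert_allclose(correct_mid(raw, cm).fractions, [1, 0, 0], atol=1e-10)

    def test_derived_forward_convolution_example(self, c2_formula, pure_tracer):
        cm = build_correction_matrix(c2_formula, pure_tracer, K=2)
        raw = RawMID("m", c2_formula, 0.0, "r1",
                     np.array([0.48935725, 0.30737551, 0.20326725]))
        np.testing.assert_allclose(correct_mid(raw, cm).fractions, [0.5, 0.3, 0.2], atol=1e-6)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_round_trip_property(self, seed):
        """Noiseless convolve-then-correct recovers any simplex vector to 1e-8."""
        rng = np.random.default_rng(seed)
        n_tracer = int(rng.integers(1, 7))
        formula = ElementFormula(
            {"C": n_tracer + int(rng.integers(0, 10)), "H": int(rng.integers(0, 30)),
             "O": int(rng.integers(0, 6)), "Si": int(rng.integers(0, 3)),
             "N": int(rng.integers(0, 3))},
            n_tracer=n_tracer,
        )
        cm = build_correction_matrix(formula, TracerConfig(purity=0.99))
        x = rng.dirichlet(np.ones(n_tracer + 1))
        raw = RawMID("m", formula, 0.0, "r", cm.matrix @ x * rng.uniform(1e4, 1e7))
        np.testing.assert_allclose(correct_mid(raw, cm).fractions, x, atol=1e-8)

    def test_noise_recovery_is_unbiased(self, c2_formula, pure_tracer):
        cm = build_correction_matrix(c2_formula, pure_tracer, K=2)
        x = np.array([0.5, 0.3, 0.2])
        rng = np.random.default_rng(11)
        recovered = []
        for _ in range(300):
            obs = np.clip(cm.matrix @ x + rng.normal(0, 0.01, 3), 0, None)
            recovered.append(correct_mid(RawMID("m", c2_formula, 0, "r", obs), cm).fractions)
        mean_err = np.mean(recovered, axis=0) - x
        assert np.all(np.abs(mean_err) < 0.005)

    def test_empty_and_mismatched_measurements(self, c2_formula, pure_tracer):
        cm = build_correction_matrix(c2_formula, pure_tracer, K=2)
        with pytest.raises(EmptyMeasurementError):
            correct_mid(RawMID("m", c2_formula, 0.0, "r", np.zeros(3)), cm)
        with pytest.raises(ValueError):
            correct_mid(RawMID("m", c2_formula, 0.0, "r", np.ones(5)), cm)


class TestLabeledFraction:
    @pytest.mark.parametrize(
        "fractions, shifts, expected",
        [
            ([0.7, 0.2, 0.1], {1, 2}, 0.3),
            ([1.0, 0.0, 0.0], {1, 2}, 0.0),
            ([0.25, 0.25, 0.25, 0.25], {0, 1, 2, 3}, 1.0),
        ],
    )
    def test_examples(self, fractions, shifts, expected):
        fe = FractionalEnrichment("m", 0.0, np.array(fractions))
        assert labeled_fraction(fe, shifts) == pytest.approx(expected)

    def test_out_of_range_shift(self):
        fe = FractionalEnrichment("m", 0.0, np.array([0.5, 0.5]))
        with pytest.raises(ParameterError):
            labeled_fraction(fe, {3})


class TestKinetics:
    def test_exact_exponential_recovery(self):
        t = np.array([0.0, 1.0, 2.0, 4.0, 8.0])
        y = 0.8 * (1 - np.exp(-0.5 * t))
        plateau, rate = fit_labeling_kinetics(t, y)
        assert plateau == pytest.approx(0.8, abs=1e-6)
        assert rate == pytest.approx(0.5, abs=1e-6)

    def test_all_zero_fractions(self):
        plateau, _ = fit_labeling_kinetics([0, 1, 2], [0, 0, 0])
        assert plateau == 0.0

    def test_fast_saturation_plateau(self):
        t = np.linspace(0, 100, 60)
        y = 0.6 * (1 - np.exp(-50.0 * t))
        plateau, _ = fit_labeling_kinetics(t, y)
        assert plateau == pytest.approx(0.6, abs=1e-3)

    def test_underdetermined(self):
        with pytest.raises(ParameterError):
            fit_labeling_kinetics([0, 1], [0, 0.5])


class TestFormulaParsing:
    @pytest.mark.parametrize(
        "text, counts, n_tracer",
        [
            ("C6H12O6@6", {"C": 6, "H": 12, "O": 6}, 6),
            ("C20H39O7Si3@6", {"C": 20, "H": 39, "O": 7, "Si": 3}, 6),
            ("C5H10N2O3S", {"C": 5, "H": 10, "N": 2, "O": 3, "S": 1}, 5),
        ],
    )
    def test_parse(self, text, counts, n_tracer):
        f = parse_formula(text)
        assert f.counts == counts and f.n_tracer == n_tracer

    def test_parse_rejects_garbage(self):
        with pytest.raises(InvalidFormulaError):
            parse_formula("not a formula!")
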