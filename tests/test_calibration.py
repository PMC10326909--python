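"""Calibration: isotope correction, linear-range detection, RF estimation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sfcquant.calibration import (
    CalibrationSeries,
    NoLinearRangeError,
    NonPositiveSlopeError,
    correct_area,
    detect_linear_range,
    estimate_response_factor,
    monoisotopic_fraction,
    parse_formula,
)
from sfcquant.synthetic_data import SynthConfig, generate_dataset

# full isotope distributions over nominal mass shift, for the convolution
# oracle (same abundance source as the implementation's lightest-isotope
# table, but used through an independent computation)
_ISOTOPES = {
    "C": {0: 0.9893, 1: 0.0107},
    "H": {0: 0.999885, 1: 0.000115},
    "N": {0: 0.99636, 1: 0.00364},
    "O": {0: 0.99757, 1: 0.00038, 2: 0.00205},
    "S": {0: 0.9499, 1: 0.0075, 2: 0.0425, 4: 0.0001},
    "P": {0: 1.0},
    "F": {0: 1.0},
    "Cl": {0: 0.7576, 2: 0.2424},
    "Br": {0: 0.5069, 2: 0.4931},
    "I": {0: 1.0},
}


def _convolution_monoisotopic(formula: dict[str, int]) -> float:
    """Brute-force isotopologue envelope; returns P(total mass shift = 0)."""
    dist = {0: 1.0}
    for el, n in formula.items():
        for _ in range(n):
            new: dict[int, float] = {}
            for shift, p in dist.items():
                for dshift, q in _ISOTOPES[el].items():
                    new[shift + dshift] = new.get(shift + dshift, 0.0) + p * q
            dist = new
    return dist[0]


class TestMonoisotopicFraction:
    def test_empty_formula_is_unity(self):
        assert monoisotopic_fraction({}) == 1.0

    @pytest.mark.parametrize(
        "formula,expected",
        [("H2", 0.999885**2), ("C10H14N2", 0.8900479503120898)],
    )
    def test_known_molecules(self, formula, expected):
        assert monoisotopic_fraction(formula) == pytest.approx(expected, rel=1e-9)

    def test_unknown_element_named_in_error(self):
        with pytest.raises(ValueError, match="Se"):
            monoisotopic_fraction({"Se": 1})

    @given(
        st.dictionaries(
            st.sampled_from(sorted(_ISOTOPES)),
            st.integers(min_value=0, max_value=12),
            max_size=5,
        ).filter(lambda f: sum(f.values()) <= 50)
    )
    @settings(max_examples=120, deadline=None)
    def test_agrees_with_convolution_oracle(self, formula):
        assert monoisotopic_fraction(formula) == pytest.approx(
            _convolution_monoisotopic(formula), abs=1e-9
        )

    def test_formula_string_parsing(self):
        assert parse_formula("C10H14N2") == {"C": 10, "H": 14, "N": 2}
        with pytest.raises(ValueError):
            parse_formula("10C")


class TestCorrectArea:
    @pytest.mark.parametrize(
        "area,fraction,expected", [(0.0, 0.5, 0.0), (100.0, 1.0, 100.0), (100.0, 0.8, 125.0)]
    )
    def test_values(self, area, fraction, expected):
        assert correct_area(area, fraction) == pytest.approx(expected)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            correct_area(10.0, 0.0)
        with pytest.raises(ValueError):
            correct_area(10.0, 1.5)


def _series(conc, areas_per_level):
    return CalibrationSeries("x", np.asarray(conc), [np.atleast_1d(a) for a in areas_per_level])


class TestDetectLinearRange:
    def test_proportional_series_fully_retained(self):
        conc = np.geomspace(1e-8, 1e-6, 8)
        s = _series(conc, [1e16 * c for c in conc])
        assert detect_linear_range(s) == list(range(8))

    def test_hard_plateau_prunes_saturated_levels(self):
        # noiseless saturation above level index 5 (synthetic generator model)
        ds = generate_dataset(
            SynthConfig(n_chemicals=3, n_descriptors=10, n_informative=2,
                        sigma_instrument=0.0, sigma_area=0.0,
                        saturation_quantile=0.75, seed=5)
        )
        top = int(ds.truth.linear_top_level[0])
        assert top == 5
        for series in ds.calibration:
            assert detect_linear_range(series) == list(range(top + 1))

    def test_three_linear_levels_kept_but_saturated_triple_flagged(self):
        conc = np.array([1e-8, 1e-7, 1e-6])
        linear = _series(conc, [1e16 * c for c in conc])
        assert detect_linear_range(linear) == [0, 1, 2]
        saturated = _series(conc, [1e16 * conc[0], 1e16 * conc[1], 1e16 * conc[1]])
        with pytest.raises(NoLinearRangeError):
            detect_linear_range(saturated)

    def test_noisy_replicate_level_excluded_up_front(self):
        conc = np.geomspace(1e-8, 1e-6, 5)
        areas = [np.full(3, 1e16 * c) for c in conc]
        areas[2] = np.array([1e16 * conc[2] * f for f in (0.2, 1.0, 1.8)])  # RSD >> 0.3
        keep = detect_linear_range(_series(conc, areas))
        assert 2 not in keep

    def test_idempotent_on_retained_levels(self, default_dataset):
        for series in default_dataset.calibration[:20]:
            keep = detect_linear_range(series)
            sub = CalibrationSeries(
                series.chemical_id,
                series.concentrations[keep],
                [series.areas[i] for i in keep],
            )
            assert detect_linear_range(sub) == list(range(len(keep)))


class TestEstimateResponseFactor:
    def test_noiseless_rf_recovered_to_machine_precision(self, noiseless_dataset):
        ds = noiseless_dataset
        for series, chem, log_rf in zip(ds.calibration, ds.chemicals, ds.truth.log_rf):
            est = estimate_response_factor(series, chem.formula)
            assert est.rf == pytest.approx(10**log_rf, rel=1e-12)

    def test_area_scaling_scales_rf_linearly(self):
        conc = np.geomspace(1e-8, 1e-6, 6)
        base = _series(conc, [1e16 * c for c in conc])
        doubled = _series(conc, [2e16 * c for c in conc])
        assert estimate_response_factor(doubled).rf == pytest.approx(
            2 * estimate_response_factor(base).rf, rel=1e-12
        )

    def test_concentration_scaling_is_inverse(self):
        conc = np.geomspace(1e-8, 1e-6, 6)
        areas = [1e16 * c for c in conc]
        rf1 = estimate_response_factor(_series(conc, areas)).rf
        rf2 = estimate_response_factor(_series(conc * 3.0, areas)).rf
        assert rf2 == pytest.approx(rf1 / 3.0, rel=1e-12)

    def test_nonpositive_slope_flagged(self):
        # gently decreasing areas: response ratios stay within a loose
        # tolerance, but the fitted slope is negative
        conc = np.array([1.0e-8, 1.2e-8, 1.4e-8])
        with pytest.raises(NonPositiveSlopeError):
            estimate_response_factor(
                _series(conc, [1.0, 0.95, 0.9]), rel_residual_tol=0.3
            )

    def test_noisy_recovery_rate_matches_mc_oracle(self):
        # With multiplicative area noise (sigma=0.1, triplicates) the OLS
        # slope's relative SE is ~ sigma/sqrt(3) = 5.8% (top level dominates),
        # so P(|rel err| < 10%) ~ 2*Phi(0.10/0.058) - 1 ~ 0.92.
        ds = generate_dataset(
            SynthConfig(n_chemicals=200, sigma_area=0.1, saturation_quantile=1.0, seed=11)
        )
        ok = 0
        for series, chem, log_rf in zip(ds.calibration, ds.chemicals, ds.truth.log_rf):
            est = estimate_response_factor(series, chem.formula)
            ok += abs(est.rf / 10**log_rf - 1) < 0.10
        assert 0.85 <= ok / 200 <= 0.99

    def test_isotope_correction_factor_reported(self):
        conc = np.geomspace(1e-8, 1e-6, 6)
        est = estimate_response_factor(_series(conc, [1e16 * c for c in conc]), "C10H14N2")
        assert est.isotope_correction_factor == pytest.approx(1 / 0.8900479503120898, rel=1e-9)
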