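"""Rate estimation, rate-law inversion, decoupled derivative and MER."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from morphoeet import (
    AssayTimeSeries,
    CultureSnapshot,
    MER_BALANCED,
    ReductionRate,
    absorbance_to_conc,
    compare_rates,
    conc_difference,
    correlate_with_properties,
    fractional_differences,
    mass_transfer_coefficient,
    mean_reduction_rate,
    morphology_effect_ratio,
    normalise_by_chla,
    rate_length_derivative,
    reduction_rate,
)
from morphoeet.errors import DenominatorZeroWarning
from morphoeet.units import (
    mm_per_mm_chla_h_to_pm_per_nm_chla_min,
    nmol_per_1e6cells_h_to_mol_cell_s,
)


class TestAbsorbanceConversion:
    @pytest.mark.parametrize(
        "absorbance,expected_mM",
        [(1.05204, 1.0), (0.0, 0.0), (0.526, 0.5000)],
    )
    def test_examples(self, absorbance, expected_mM):
        assert absorbance_to_conc(absorbance) == pytest.approx(
            expected_mM, abs=1e-4
        )

    def test_invalid_coefficients(self):
        with pytest.raises(ValueError):
            absorbance_to_conc(1.0, extinction_mM_cm=0.0)
        with pytest.raises(ValueError):
            absorbance_to_conc(-0.1)


class TestReductionRate:
    def test_collinear_trace(self, collinear_assay):
        """Slope -1e-3 mM/min at 6.78e8 cells/ml -> 2.458e-20 mol/cell/s."""
        r = reduction_rate(collinear_assay)
        expected = (1e-3 * 1e-3 / 60.0) / (6.78e8 * 1e3)
        assert r.rate_mol_per_cell_s == pytest.approx(expected, rel=1e-12)
        assert r.rate_mol_per_cell_s == pytest.approx(2.458e-20, rel=1e-3)

    def test_constant_trace_is_zero(self):
        s = AssayTimeSeries((0, 10, 30, 120), (0.8,) * 4, 6.78e8)
        assert reduction_rate(s).rate_mol_per_cell_s == pytest.approx(
            0.0, abs=1e-30
        )

    def test_doubling_cells_halves_rate(self, collinear_assay):
        doubled = AssayTimeSeries(
            collinear_assay.times_min,
            collinear_assay.concentration_mM,
            2 * collinear_assay.cell_conc_per_ml,
        )
        assert reduction_rate(doubled).rate_mol_per_cell_s == pytest.approx(
            reduction_rate(collinear_assay).rate_mol_per_cell_s / 2, rel=1e-12
        )

    def test_replicate_sem(self, collinear_assay):
        shifted = AssayTimeSeries(
            (0, 10, 30, 120), (1.0, 0.988, 0.964, 0.856), 6.78e8
        )
        combined = mean_reduction_rate([collinear_assay, shifted])
        assert combined.sem > 0
        singles = [reduction_rate(s).rate_mol_per_cell_s
                   for s in (collinear_assay, shifted)]
        assert combined.rate_mol_per_cell_s == pytest.approx(
            np.mean(singles), rel=1e-12
        )

    def test_invalid_series(self):
        with pytest.raises(ValueError):
            AssayTimeSeries((0,), (1.0,), 1e8)
        with pytest.raises(ValueError):
            AssayTimeSeries((5, 10), (1.0, 0.9), 1e8)  # first time not 0
        with pytest.raises(ValueError):
            AssayTimeSeries((0, 0), (1.0, 0.9), 1e8)


class TestRateUnitConversions:
    def test_chlorella_literature_rate(self):
        assert nmol_per_1e6cells_h_to_mol_cell_s(3.0) == pytest.approx(
            8.33e-19, rel=1e-3
        )

    def test_chla_normalised_rate(self):
        assert mm_per_mm_chla_h_to_pm_per_nm_chla_min(0.9) == pytest.approx(
            15.0, rel=1e-12
        )

    def test_normalise_by_chla(self):
        assert normalise_by_chla(30.0, 2.0) == 15.0
        assert normalise_by_chla(0.0, 2.0) == 0.0
        with pytest.raises(ValueError):
            normalise_by_chla(1.0, 0.0)


class TestConcDifference:
    def test_inversion_identity(self):
        out = conc_difference(4e-4 * 1.4e-11 * 1.0, 4e-4, 1.4e-11)
        assert out.delta_c_molm3 == pytest.approx(1.0, rel=1e-12)

    def test_hand_value(self):
        out = conc_difference(2.458e-20, 4.23e-4, 1.4e-11)
        assert out.delta_c_molm3 == pytest.approx(4.151e-6, rel=1e-3)

    @given(
        k=st.floats(min_value=1e-5, max_value=1e-3),
        a=st.floats(min_value=1e-12, max_value=1e-10),
        dc=st.floats(min_value=1e-8, max_value=10.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_round_trip(self, k, a, dc):
        out = conc_difference(k * a * dc, k, a)
        assert out.delta_c_molm3 == pytest.approx(dc, rel=1e-12)

    def test_zero_errors_give_zero_sem(self):
        assert conc_difference(1e-20, 4e-4, 1.4e-11).sem == 0.0

    def test_sem_combines_in_quadrature(self):
        r = ReductionRate(1e-20, 1e-21)  # 10% relative
        out = conc_difference(r, 4e-4, 1.4e-11, k_sem=4e-5,
                              area_sem_m2=1.4e-12)
        rel = out.sem / out.delta_c_molm3
        assert rel == pytest.approx(math.sqrt(3 * 0.1**2), rel=1e-9)

    def test_zero_k_rejected(self):
        with pytest.raises(ValueError):
            conc_difference(1e-20, 0.0, 1.4e-11)


class TestRateLengthDerivative:
    def test_hand_example(self):
        k = mass_transfer_coefficient(4.0).k_ms
        area = math.pi * 1.1e-6 * 4.0e-6
        total, k_ch, a_ch = rate_length_derivative(4.0, 1.1, k, area, 1.0)
        assert k_ch == pytest.approx(-1.2855e-9, rel=1e-3)
        assert a_ch == pytest.approx(k * math.pi * 1.1e-6, rel=1e-12)
        assert a_ch == pytest.approx(1.36e-9, rel=2e-2)
        assert total > 0  # area gain outweighs flux loss

    def test_zero_delta_c(self):
        k = mass_transfer_coefficient(4.0).k_ms
        area = math.pi * 1.1e-6 * 4.0e-6
        assert rate_length_derivative(4.0, 1.1, k, area, 0.0) == (0, 0, 0)

    @pytest.mark.parametrize("length_um", np.linspace(2.0, 8.0, 13))
    def test_matches_finite_difference(self, length_um):
        """Analytic derivative vs central difference of r(L)=k(L)*piDL*dc."""
        width, dc = 1.1, 0.7

        def rate(l_um):
            k = mass_transfer_coefficient(l_um).k_ms
            return k * math.pi * width * 1e-6 * l_um * 1e-6 * dc

        h = 1e-3
        fd = (rate(length_um + h) - rate(length_um - h)) / (2 * h * 1e-6)
        k = mass_transfer_coefficient(length_um).k_ms
        area = math.pi * width * 1e-6 * length_um * 1e-6
        total, _, _ = rate_length_derivative(length_um, width, k, area, dc)
        assert total == pytest.approx(fd, rel=1e-6)

    def test_inconsistent_area_warns(self):
        k = mass_transfer_coefficient(4.0).k_ms
        with pytest.warns(UserWarning, match="not consistent"):
            rate_length_derivative(4.0, 1.1, k, 2e-11, 1.0)


def _snapshot(day, condition, k, area, rate, dc):
    return CultureSnapshot(
        day=day, condition=condition, mean_length_um=3.7, sem_length=0.1,
        mean_width_um=1.2, mean_area_um2=area, sem_area=0.0, k_ms=k,
        sem_k=0.0, rate_mol_cell_s=rate, sem_rate=0.0, delta_c_molm3=dc,
        sem_delta_c=0.0,
    )


class TestFractionalDifferences:
    def test_identical_snapshots(self):
        snap = _snapshot(5, "a", 4e-4, 14.0, 1e-20, 1.0)
        res = fractional_differences(snap, snap)
        assert (res.dk, res.dA, res.dkA, res.ddc, res.dr) == (0, 0, 0, 0, 0)
        assert res.mer == 0.5

    def test_multiplicative_composition(self):
        control = _snapshot(5, "c", 4e-4, 14.0, 1e-20, 1.0)
        test = _snapshot(5, "t", 4e-4 * 1.1, 14.0 * 1.2, 1e-20, 1.0)
        with pytest.warns(DenominatorZeroWarning):  # identical delta c
            res = fractional_differences(test, control)
        assert res.dkA == pytest.approx(0.32, rel=1e-12)

    def test_identity_on_consistent_cultures(self):
        """(1+dr) = (1+dk)(1+dA)(1+ddc) whenever r = k*A*dc on both sides."""
        k_c, a_c, dc_c = 4.0e-4, 1.4e-11, 2.0
        k_t, a_t, dc_t = 3.5e-4, 1.8e-11, 2.6
        control = _snapshot(9, "c", k_c, a_c * 1e12, k_c * a_c * dc_c, dc_c)
        test = _snapshot(9, "t", k_t, a_t * 1e12, k_t * a_t * dc_t, dc_t)
        res = fractional_differences(test, control)
        assert 1 + res.dr == pytest.approx(
            (1 + res.dk) * (1 + res.dA) * (1 + res.ddc), rel=1e-9
        )

    def test_zero_control_rejected(self):
        control = _snapshot(5, "c", 4e-4, 14.0, 0.0, 1.0)
        test = _snapshot(5, "t", 4e-4, 14.0, 1e-20, 1.0)
        with pytest.raises(ZeroDivisionError):
            fractional_differences(test, control)


class TestMorphologyEffectRatio:
    def test_unit_ratio(self):
        assert morphology_effect_ratio(0.25, 0.25) == pytest.approx(
            0.7311, abs=5e-5
        )
        assert MER_BALANCED == pytest.approx(0.7311, abs=5e-5)

    def test_zero_numerator(self):
        assert morphology_effect_ratio(0.0, 0.3) == 0.5

    def test_saturation(self):
        assert morphology_effect_ratio(100.0, 1e-6) == pytest.approx(1.0)

    def test_zero_denominator_flagged(self):
        with pytest.warns(DenominatorZeroWarning):
            assert morphology_effect_ratio(0.2, 0.0) == 1.0

    @given(
        dka=st.floats(min_value=1e-6, max_value=2.0),
        ddc=st.floats(min_value=0.5, max_value=50.0),
        bump=st.floats(min_value=1.01, max_value=2.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_and_bounded(self, dka, ddc, bump):
        """Strictly increasing in |d(kA)|, decreasing in |d(dc)|, inside
        (0.5, 1) away from the saturation regime."""
        base = morphology_effect_ratio(dka, ddc)
        assert 0.5 < base < 1.0
        assert morphology_effect_ratio(dka * bump, ddc) > base
        assert morphology_effect_ratio(dka, ddc * bump) < base

    def test_sign_of_inputs_is_ignored(self):
        assert morphology_effect_ratio(-0.2, 0.4) == morphology_effect_ratio(
            0.2, -0.4
        )


class TestCorrelation:
    def test_perfect_positive(self):
        x = np.arange(10, dtype=float)
        r, p = correlate_with_properties(x, 2 * x)
        assert r == pytest.approx(1.0)
        assert p < 1e-6

    def test_perfect_negative(self):
        x = np.arange(10, dtype=float)
        r, _ = correlate_with_properties(x, -x)
        assert r == pytest.approx(-1.0)

    def test_null_distribution(self):
        """Independent Gaussian pairs rarely show |r| > 0.3 at n = 100."""
        hits = 0
        n_rep = 200
        for i in range(n_rep):
            rep_rng = np.random.default_rng(5000 + i)
            r, _ = correlate_with_properties(
                rep_rng.normal(size=100), rep_rng.normal(size=100)
            )
            if abs(r) < 0.3:
                hits += 1
        assert hits / n_rep >= 0.95

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError):
            correlate_with_properties([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def test_compare_rates_one_tailed():
    rng = np.random.default_rng(7)
    control = rng.normal(1.0, 0.1, size=6)
    test = control + 0.5
    t, p = compare_rates(test, control)
    assert t > 0 and p < 0.05
    t_rev, p_rev = compare_rates(control, test)
    assert p_rev > 0.95
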