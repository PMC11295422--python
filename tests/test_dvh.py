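"""Dose-volume histogram metrics against hand computations and numeric
oracles."""

import numpy as np
import pytest
from scipy.optimize import brentq

import ntcpselect.dvh as dvh
from ntcpselect.errors import (
    BadOrigin,
    DomainError,
    LengthMismatch,
    NegativeBin,
    NonMonotoneVolume,
    ZeroDoseWithNegativeExponent,
)

from conftest import make_curve, random_curve


# ------------------------------------------------------------------ oracles
def oracle_mean(curve):
    """Dense-grid trapezoid integral of the interpolated cumulative curve."""
    grid = np.union1d(
        np.linspace(0.0, curve.dose_edges[-1], 20001), curve.dose_edges
    )
    v = np.interp(grid, curve.dose_edges, curve.cum_volume)
    return np.trapezoid(v, grid)


def oracle_dose_at_volume(curve, vf):
    """Root-find V(d) = vf on the interpolated curve (unique root for
    strictly decreasing curves)."""
    f = lambda d: np.interp(d, curve.dose_edges, curve.cum_volume) - vf
    return brentq(f, 0.0, curve.dose_edges[-1], xtol=1e-12)


def oracle_geud(curve, a):
    """Power mean of D^a by adaptive quadrature of the piecewise-constant
    dose density implied by the piecewise-linear cumulative curve."""
    from scipy.integrate import quad

    e, v = curve.dose_edges, curve.cum_volume
    density = (v[:-1] - v[1:]) / (e[1:] - e[:-1])

    def integrand(d):
        i = np.clip(np.searchsorted(e, d, side="right") - 1, 0, len(density) - 1)
        return density[i] * d**a

    moment, _ = quad(integrand, 0.0, e[-1], points=list(e), limit=200)
    return (moment / (v[0] - v[-1])) ** (1.0 / a)


# --------------------------------------------------------------- validation
class TestValidation:
    def test_minimal_two_point_curve_valid(self, step_curve):
        assert dvh.validate_dvh(step_curve) is step_curve

    @pytest.mark.parametrize(
        "edges,volumes,exc",
        [
            ([0, 20, 40], [1.0, 0.5, 0.6], NonMonotoneVolume),
            ([0, 20], [0.9, 0.0], BadOrigin),
            ([5, 20], [1.0, 0.0], BadOrigin),
            ([0, 20, 40], [1.0, 0.5], LengthMismatch),
            ([0], [1.0], LengthMismatch),
            ([0, 20, 20], [1.0, 0.5, 0.2], NonMonotoneVolume),
        ],
    )
    def test_invariant_violations_raise(self, edges, volumes, exc):
        with pytest.raises(exc):
            dvh.validate_dvh(make_curve(edges, volumes))


class TestConversions:
    def test_single_bin(self, step_curve):
        d = dvh.cumulative_to_differential(step_curve)
        assert d.bin_volume_fraction.tolist() == [1.0]
        assert (d.bin_lower[0], d.bin_upper[0]) == (0.0, 60.0)

    def test_pairwise_differences_sum_to_one(self, four_point_curve):
        d = dvh.cumulative_to_differential(four_point_curve)
        np.testing.assert_allclose(
            d.bin_volume_fraction, [0.2, 0.6, 0.2], atol=1e-15
        )
        assert d.bin_volume_fraction.sum() == pytest.approx(1.0, abs=1e-9)

    def test_differential_to_cumulative_fractions(self):
        d = dvh.DifferentialDVH(
            bin_lower=[0, 20, 40],
            bin_upper=[20, 40, 60],
            bin_volume_fraction=[0.2, 0.6, 0.2],
        )
        c = dvh.differential_to_cumulative(d)
        np.testing.assert_allclose(c.cum_volume, [1.0, 0.8, 0.2, 0.0], atol=1e-15)

    def test_negative_bin_rejected(self):
        d = dvh.DifferentialDVH(
            bin_lower=[0.0], bin_upper=[50.0], bin_volume_fraction=[-0.1]
        )
        with pytest.raises(NegativeBin):
            dvh.differential_to_cumulative(d)

    def test_round_trip_identity(self, rng):
        for _ in range(50):
            c = random_curve(rng)
            back = dvh.differential_to_cumulative(
                dvh.cumulative_to_differential(c)
            )
            np.testing.assert_allclose(back.dose_edges, c.dose_edges, atol=1e-12)
            np.testing.assert_allclose(back.cum_volume, c.cum_volume, atol=1e-12)


class TestDoseAtVolume:
    def test_linear_interpolation(self, four_point_curve):
        assert dvh.dose_at_volume(four_point_curve, 0.5) == pytest.approx(30.0)

    def test_full_volume_is_zero_dose(self, four_point_curve, step_curve):
        assert dvh.dose_at_volume(four_point_curve, 1.0) == 0.0
        assert dvh.dose_at_volume(step_curve, 1.0) == 0.0

    def test_ramp_curve_inversion(self, step_curve):
        # V(d) = 1 - d/60 on the two-point ramp: V(d) = 0.95 at d = 3 Gy
        assert dvh.dose_at_volume(step_curve, 0.95) == pytest.approx(3.0)

    def test_plateau_returns_lowest_dose(self):
        c = make_curve([0, 10, 20, 30], [1.0, 0.5, 0.5, 0.0])
        assert dvh.dose_at_volume(c, 0.5) == pytest.approx(10.0)

    def test_below_minimum_returns_last_edge(self):
        c = make_curve([0, 20, 40], [1.0, 0.5, 0.5])
        assert dvh.dose_at_volume(c, 0.1) == 40.0

    @pytest.mark.parametrize("vf", [0.0, -0.2, 1.2])
    def test_domain_error(self, four_point_curve, vf):
        with pytest.raises(DomainError):
            dvh.dose_at_volume(four_point_curve, vf)


class TestVolumeAtDose:
    def test_interpolation_and_boundaries(self, four_point_curve):
        assert dvh.volume_at_dose(four_point_curve, 30.0) == pytest.approx(0.5)
        assert dvh.volume_at_dose(four_point_curve, 0.0) == 1.0
        assert dvh.volume_at_dose(four_point_curve, 100.0) == 0.0

    def test_negative_dose_rejected(self, four_point_curve):
        with pytest.raises(DomainError):
            dvh.volume_at_dose(four_point_curve, -1.0)

    def test_mutual_inverse_on_strict_segments(self, rng):
        for _ in range(100):
            c = random_curve(rng)
            vf = rng.uniform(c.cum_volume[-1] + 1e-6, 1.0)
            d = dvh.dose_at_volume(c, vf)
            assert abs(dvh.volume_at_dose(c, d) - vf) < 1e-9


class TestMeanMaxDose:
    def test_worked_example(self, four_point_curve):
        assert dvh.mean_dose(four_point_curve) == pytest.approx(30.0)

    def test_ramp_and_near_step_uniform(self, step_curve):
        # the two-point ramp integrates to half the top dose; a true uniform
        # 50 Gy structure must be encoded as a near-step curve
        assert dvh.mean_dose(make_curve([0, 50], [1.0, 0.0])) == pytest.approx(25.0)
        near_step = make_curve([0, 49.999, 50], [1.0, 1.0, 0.0])
        assert dvh.mean_dose(near_step) == pytest.approx(49.9995)

    def test_zero_dose_structure(self):
        # contralateral organ fully spared by protons
        c = make_curve([0, 1e-6], [1.0, 0.0], sid="contralateral_parotid")
        assert dvh.mean_dose(c) == pytest.approx(0.0, abs=1e-6)

    def test_mean_matches_dense_grid_oracle(self, rng):
        for _ in range(200):
            c = random_curve(rng, reach_zero=bool(rng.random() < 0.7))
            got, want = dvh.mean_dose(c), oracle_mean(c)
            assert got == pytest.approx(want, rel=1e-6)

    @pytest.mark.parametrize(
        "edges,volumes,expected",
        [
            ([0, 60], [1.0, 0.0], 60.0),
            ([0, 20, 40, 60], [1.0, 0.8, 0.2, 0.0], 60.0),
            ([0, 20, 40], [1.0, 0.5, 0.5], 40.0),
        ],
    )
    def test_max_dose(self, edges, volumes, expected):
        assert dvh.max_dose(make_curve(edges, volumes)) == expected

    def test_dmean_not_above_dmax(self, rng):
        for _ in range(100):
            c = random_curve(rng)
            assert 0.0 <= dvh.mean_dose(c) <= dvh.max_dose(c) + 1e-12


class TestGeneralizedEUD:
    def test_a1_equals_differential_mean(self, four_point_curve):
        assert dvh.generalized_eud(four_point_curve, 1.0) == pytest.approx(30.0)
        assert dvh.generalized_eud(four_point_curve, 1.0) == pytest.approx(
            dvh.mean_dose(four_point_curve), abs=1e-12
        )

    def test_point_mass_closed_form(self):
        # half the volume at 60 Gy, half at 0 Gy: (0.5 * 60^2)^(1/2)
        got = dvh.geud_from_bins([0.5, 0.5], [60.0, 0.0], 2.0)
        assert got == pytest.approx(np.sqrt(0.5) * 60.0)

    def test_uniform_structure_geud_is_dose(self):
        # near-step encoding of a uniform 50 Gy structure
        c = make_curve([0, 49.999, 49.999 + 1e-3], [1.0, 1.0, 0.0])
        for a in (0.5, 1.0, 2.0, 4.0, 8.0):
            assert dvh.generalized_eud(c, a) == pytest.approx(50.0, rel=1e-4)

    def test_monotone_in_exponent(self, rng):
        for _ in range(100):
            c = random_curve(rng)
            vals = [dvh.generalized_eud(c, a) for a in (0.5, 1, 2, 4, 8)]
            assert all(
                v2 >= v1 - 1e-9 for v1, v2 in zip(vals, vals[1:])
            ), vals

    def test_matches_dense_grid_oracle(self, rng):
        for _ in range(100):
            c = random_curve(rng)
            for a in (0.5, 1.0, 2.0, 4.0):
                assert dvh.generalized_eud(c, a) == pytest.approx(
                    oracle_geud(c, a), rel=1e-6
                )

    def test_zero_exponent_rejected(self, four_point_curve):
        with pytest.raises(DomainError):
            dvh.generalized_eud(four_point_curve, 0.0)

    def test_negative_exponent_with_zero_dose_volume(self, four_point_curve):
        with pytest.raises(ZeroDoseWithNegativeExponent):
            dvh.generalized_eud(four_point_curve, -1.0)

    def test_negative_exponent_away_from_zero(self):
        c = make_curve([0, 40, 50, 60], [1.0, 1.0, 0.5, 0.0])
        got = dvh.generalized_eud(c, -2.0)
        assert 40.0 < got < 60.0
        assert got == pytest.approx(oracle_geud(c, -2.0), rel=1e-6)


class TestCoverage:
    def test_printed_thresholds(self):
        # prescription 60 Gy: D95 must exceed 58.8 Gy, D2 stay under 64.2 Gy
        c = make_curve(
            [0, 59.2, 59.2 + 1e-9, 62.0, 62.0 + 1e-9, 63.0],
            [1.0, 0.95, 0.95 - 1e-12, 0.02, 0.02 - 1e-12, 0.0],
        )
        rep = dvh.check_target_coverage(c, 60.0)
        assert rep.d95_gy == pytest.approx(59.2)
        assert rep.d2_gy == pytest.approx(62.0)
        assert rep.d95_ok and rep.d2_ok

    def test_boundary_is_strict(self):
        # D95 exactly at 98% of prescription fails the strict ">"
        c = make_curve([0, 58.8, 58.9], [1.0, 0.95, 0.0])
        rep = dvh.check_target_coverage(c, 60.0)
        assert rep.d95_gy == pytest.approx(58.8)
        assert not rep.d95_ok

    def test_uniform_at_prescription_passes(self):
        c = make_curve([0, 59.999, 60.0], [1.0, 1.0, 0.0])
        rep = dvh.check_target_coverage(c, 60.0)
        assert rep.d95_ok and rep.d2_ok

    def test_nonpositive_prescription_rejected(self, step_curve):
        with pytest.raises(DomainError):
            dvh.check_target_coverage(step_curve, 0.0)


class TestRBE:
    def test_scales_dose_axis_only(self, four_point_curve):
        scaled = dvh.apply_rbe(four_point_curve, 1.1)
        np.testing.assert_allclose(scaled.dose_edges, [0, 22, 44, 66])
        np.testing.assert_allclose(scaled.cum_volume, four_point_curve.cum_volume)
        assert dvh.mean_dose(scaled) == pytest.approx(33.0)

    def test_identity_and_domain(self, four_point_curve):
        assert dvh.apply_rbe(four_point_curve, 1.0) is four_point_curve
        with pytest.raises(DomainError):
            dvh.apply_rbe(four_point_curve, 0.0)
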