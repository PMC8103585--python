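"""Density interpolation, island-solid integration and the MC oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from prpsim import (
    DensityProfile,
    EquivalentDisc,
    OpticDiscSpec,
    Spot,
    calibrate,
    count_from_volume,
    count_in_spot,
    count_in_spot_converged,
    density_at,
    mc_count_in_spot,
    read_profile_csv,
    total_count,
    volume_from_count,
    write_profile_csv,
)


@pytest.fixture(scope="module")
def tabulated():
    return DensityProfile(np.array([0.0, 1.0, 3.0]), np.array([100.0, 400.0, 0.0]))


class TestInterpolation:
    def test_exact_at_nodes(self, tabulated):
        assert density_at(tabulated, 0.0) == 100.0
        assert density_at(tabulated, 1.0) == 400.0

    def test_midpoint_is_mean(self, tabulated):
        assert density_at(tabulated, 0.5) == pytest.approx(250.0)
        assert density_at(tabulated, 2.0) == pytest.approx(200.0)

    def test_zero_beyond_last_node(self, tabulated):
        assert density_at(tabulated, 4.0) == 0.0

    def test_negative_eccentricity_rejected(self, tabulated):
        with pytest.raises(ValueError):
            density_at(tabulated, -0.1)

    @pytest.mark.parametrize(
        "grid, dens",
        [
            ([0.5, 1.0], [1.0, 1.0]),  # does not start at 0
            ([0.0, 1.0, 1.0], [1.0, 1.0, 1.0]),  # not strictly increasing
            ([0.0, 1.0], [1.0, -1.0]),  # negative density
        ],
    )
    def test_invalid_profiles_rejected(self, grid, dens):
        with pytest.raises(ValueError):
            DensityProfile(np.array(grid, float), np.array(dens, float))


class TestTotalCount:
    def test_uniform_closed_form(self, uniform_profile, disc):
        expected = 1.0e4 * math.pi * disc.radius_total**2
        assert total_count(uniform_profile, disc) == pytest.approx(expected, rel=1e-12)

    def test_linear_closed_form(self, linear_profile, disc):
        # 2 pi k int_0^R e^2 de = 2 pi k R^3 / 3
        expected = 2.0 * math.pi * 1000.0 * disc.radius_total**3 / 3.0
        assert total_count(linear_profile, disc) == pytest.approx(expected, rel=1e-9)

    def test_zero_density_gives_zero(self, disc):
        p = DensityProfile(np.array([0.0, 18.6]), np.zeros(2))
        assert total_count(p, disc) == 0.0

    def test_optic_disc_subtracts_cylinder(self, disc):
        grid = np.linspace(0.0, disc.radius_total, 2)
        od = OpticDiscSpec(center_eccentricity=3.4, radius=0.75)
        with_disc = DensityProfile(grid, np.full(2, 1.0e4), optic_disc=od)
        without = DensityProfile(grid, np.full(2, 1.0e4))
        hole = math.pi * 0.75**2 * 1.0e4
        assert total_count(without, disc) - total_count(with_disc, disc) == pytest.approx(
            hole, rel=1e-12
        )

    def test_optic_disc_from_config(self):
        od = OpticDiscSpec.from_config({"optic_disc_radius_mm": 0.9})
        assert (od.radius, od.center_eccentricity) == (0.9, 3.4)
        assert OpticDiscSpec.from_config({"optic_disc_enabled": False}) is None

    def test_profile_beyond_retina_rejected(self, disc):
        p = DensityProfile(np.array([0.0, 30.0]), np.full(2, 1.0e4))
        with pytest.raises(ValueError):
            total_count(p, disc)


class TestSpotQuadrature:
    def test_uniform_spot_closed_form(self, uniform_profile):
        got = count_in_spot(uniform_profile, Spot(3.0, 4.0, diameter=0.4))
        assert got == pytest.approx(1.0e4 * math.pi * 0.2**2, rel=2e-3)

    def test_linear_origin_spot_closed_form(self, linear_profile):
        # int_spot k|p| dA over a disc of radius a at the origin = k 2 pi a^3 / 3
        a = 0.5
        got = count_in_spot(linear_profile, Spot(0.0, 0.0, diameter=2 * a), step=0.005)
        assert got == pytest.approx(1000.0 * 2.0 * math.pi * a**3 / 3.0, rel=2e-3)

    def test_zero_density_spot(self, disc):
        p = DensityProfile(np.array([0.0, 18.6]), np.zeros(2))
        assert count_in_spot(p, Spot(5.0, 0.0)) == 0.0

    def test_spot_outside_retina_rejected(self, uniform_profile, disc):
        with pytest.raises(ValueError):
            count_in_spot(uniform_profile, Spot(18.5, 0.0, diameter=0.4), disc=disc)

    def test_rotation_invariance(self, fixture_profile):
        """The profile is rotationally symmetric, so only |center| matters."""
        rng = np.random.default_rng(7)
        for _ in range(10):
            r = rng.uniform(1.0, 15.0)
            angles = rng.uniform(0, 2 * np.pi, size=3)
            vals = [
                count_in_spot(fixture_profile, Spot(r * np.cos(a), r * np.sin(a)))
                for a in angles
            ]
            assert max(vals) - min(vals) < 2e-3 * max(vals)

    def test_step_halving_convergence(self, fixture_profile):
        spot = Spot(8.0, 3.0, diameter=0.4)
        coarse = count_in_spot(fixture_profile, spot, step=0.01)
        fine, rel = count_in_spot_converged(fixture_profile, spot, step=0.01)
        assert abs(fine - coarse) / fine < 1e-3
        assert rel < 1e-3

    def test_small_spot_limit(self, fixture_profile):
        """count/area -> rho(center) with error shrinking ~ diameter^2."""
        center = Spot(7.0, 0.0)
        rho_c = density_at(fixture_profile, 7.0)
        errs = []
        for d in (0.8, 0.4, 0.2):
            got = count_in_spot(fixture_profile, Spot(7.0, 0.0, diameter=d), step=d / 80)
            area = math.pi * (d / 2) ** 2
            errs.append(abs(got / area - rho_c) / rho_c)
        assert errs[2] < errs[0]
        assert errs[2] < 1e-3

    def test_linearity_in_density(self, fixture_profile, disc):
        scaled = fixture_profile.scaled(3.0)
        spot = Spot(10.0, 2.0)
        assert count_in_spot(scaled, spot) == pytest.approx(
            3.0 * count_in_spot(fixture_profile, spot), rel=1e-9
        )
        assert total_count(scaled, disc) == pytest.approx(
            3.0 * total_count(fixture_profile, disc), rel=1e-9
        )


class TestMonteCarloOracle:
    def test_uniform_density_zero_variance(self, uniform_profile):
        est, se = mc_count_in_spot(uniform_profile, Spot(3.0, 0.0), 1000, seed=1)
        assert se == 0.0
        assert est == pytest.approx(1.0e4 * math.pi * 0.2**2, rel=1e-12)

    def test_linear_profile_matches_closed_form(self, linear_profile):
        a = 0.5
        est, se = mc_count_in_spot(linear_profile, Spot(0.0, 0.0, 2 * a), 200_000, seed=2)
        exact = 1000.0 * 2.0 * math.pi * a**3 / 3.0
        assert abs(est - exact) < 3.0 * se

    def test_same_seed_reproduces(self, fixture_profile):
        spot = Spot(6.0, 1.0)
        assert mc_count_in_spot(fixture_profile, spot, 5000, seed=9) == mc_count_in_spot(
            fixture_profile, spot, 5000, seed=9
        )

    def test_quadrature_agrees_with_oracle_on_random_spots(self, fixture_profile):
        """Deterministic quadrature within 3 SE of the MC estimate >= 95% of spots."""
        rng = np.random.default_rng(2024)
        hits = 0
        n_spots = 40
        for i in range(n_spots):
            r = rng.uniform(0.5, 17.0)
            theta = rng.uniform(0, 2 * np.pi)
            spot = Spot(r * np.cos(theta), r * np.sin(theta), diameter=0.4)
            exact = count_in_spot(fixture_profile, spot, step=0.005)
            est, se = mc_count_in_spot(fixture_profile, spot, 20_000, seed=1000 + i)
            if abs(exact - est) <= 3.0 * max(se, 1e-9):
                hits += 1
        assert hits >= 0.95 * n_spots

    def test_too_few_samples_rejected(self, uniform_profile):
        with pytest.raises(ValueError):
            mc_count_in_spot(uniform_profile, Spot(1.0, 0.0), 10, seed=0)


class TestCalibration:
    def test_identity_and_linearity(self, fixture_profile, disc):
        total = total_count(fixture_profile, disc)
        same = calibrate(fixture_profile, disc, total)
        assert np.allclose(same.density_values, fixture_profile.density_values, rtol=1e-12)
        doubled = calibrate(fixture_profile, disc, 2 * total)
        assert np.allclose(doubled.density_values, 2 * fixture_profile.density_values, rtol=1e-9)

    def test_hits_target(self, linear_profile, disc):
        cal = calibrate(linear_profile, disc, 5.0e7)
        assert total_count(cal, disc) == pytest.approx(5.0e7, rel=1e-9)

    def test_zero_profile_rejected(self, disc):
        p = DensityProfile(np.array([0.0, 18.6]), np.zeros(2))
        with pytest.raises(ValueError):
            calibrate(p, disc, 1.0e7)


class TestVolumeCountConversion:
    @pytest.mark.parametrize(
        "volume, count",
        [(9657.19, 96_571_900), (8096.37, 80_963_700), (7745.13, 77_451_300), (0.0, 0)],
    )
    def test_published_pairs(self, volume, count):
        assert count_from_volume(volume) == pytest.approx(count, rel=1e-12)
        assert volume_from_count(count) == pytest.approx(volume, rel=1e-12)

    @settings(deadline=None)
    @given(st.floats(0, 1e9, allow_nan=False))
    def test_round_trip(self, count):
        assert count_from_volume(volume_from_count(count)) == pytest.approx(count, rel=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            volume_from_count(-1.0)
        with pytest.raises(ValueError):
            count_from_volume(-1.0)


def test_profile_csv_round_trip(tmp_path, fixture_profile):
    path = tmp_path / "profile.csv"
    write_profile_csv(fixture_profile, path)
    back = read_profile_csv(path, optic_disc=fixture_profile.optic_disc)
    assert np.array_equal(back.eccentricity_grid, fixture_profile.eccentricity_grid)
    assert np.array_equal(back.density_values, fixture_profile.density_values)


def test_profile_csv_rejects_wrong_columns(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("a,b\n0,1\n")
    with pytest.raises(ValueError):
        read_profile_csv(path)
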