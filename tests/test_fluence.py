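import math

import numpy as np
import pytest

from protonfsf import (
    BeamGeometry,
    FsfRecord,
    SpotFluenceParams,
    central_fluence,
    fluence_at,
    fsf,
    read_fsf_table,
    spot_grid,
    write_fsf_table,
)
from protonfsf.geometry import projected_spacing


def naive_central_fluence(params, geom, z, field_size_mm):
    """Independent oracle: explicit double loop over the projected grid."""
    n = int(round(0.5 * field_size_mm / geom.spot_spacing_mm))
    ssx = projected_spacing(geom, z, "x")
    ssy = projected_spacing(geom, z, "y")
    total = 0.0
    for i in range(-n, n + 1):
        for j in range(-n, n + 1):
            r2 = (i * ssx) ** 2 + (j * ssy) ** 2
            g1 = (
                (1 - params.w2)
                / (2 * math.pi * params.sigma1_mm**2)
                * math.exp(-r2 / (2 * params.sigma1_mm**2))
            )
            g2 = (
                params.w2
                / (2 * math.pi * params.sigma2_mm**2)
                * math.exp(-r2 / (2 * params.sigma2_mm**2))
            )
            total += params.amplitude * (g1 + g2)
    return total


class TestFluenceAt:
    def test_single_gaussian_peak_value(self):
        p = SpotFluenceParams(sigma1_mm=5.0, sigma2_mm=5.0, w2=0.0)
        assert fluence_at(p, 0.0, 0.0) == pytest.approx(1.0 / (2 * math.pi * 25.0), rel=1e-12)

    def test_decays_to_zero_far_away(self, rs_params):
        assert fluence_at(rs_params, 1e4, 1e4) == 0.0

    def test_equals_sum_of_independent_gaussian_terms(self):
        p = SpotFluenceParams(sigma1_mm=7.0, sigma2_mm=20.0, w2=0.1)
        dx, dy = 10.0, 0.0
        r2 = dx**2 + dy**2
        term1 = (1 - 0.1) / (2 * math.pi * 49.0) * math.exp(-r2 / (2 * 49.0))
        term2 = 0.1 / (2 * math.pi * 400.0) * math.exp(-r2 / (2 * 400.0))
        assert fluence_at(p, dx, dy) == pytest.approx(term1 + term2, rel=1e-14)

    def test_integrates_to_amplitude(self, rs_params):
        # radial quadrature of the areal profile over the whole plane
        from scipy.integrate import quad

        integral, _ = quad(
            lambda r: 2 * math.pi * r * float(fluence_at(rs_params, r, 0.0)), 0, 500
        )
        assert integral == pytest.approx(rs_params.amplitude, abs=1e-9)


class TestSpotGrid:
    @pytest.mark.parametrize(
        "fs_cm, expected_count", [(2, 25), (4, 81), (10, 441), (20, 1681)]
    )
    def test_nested_square_counts(self, fs_cm, expected_count):
        grid = spot_grid(fs_cm * 10.0, 5.0)
        assert len(grid) == expected_count
        assert len(set(grid)) == expected_count
        n = int((math.isqrt(expected_count) - 1) / 2)
        assert max(max(abs(i), abs(j)) for i, j in grid) == n

    @pytest.mark.parametrize("fs_mm", [-10.0, 0.0, 3.0, 12.5])
    def test_invalid_sizes_rejected(self, fs_mm):
        with pytest.raises(ValueError):
            spot_grid(fs_mm, 5.0)


class TestCentralFluence:
    def test_matches_naive_double_loop_on_random_params(self, diverging_geom):
        rng = np.random.default_rng(42)
        for _ in range(10):
            s1 = rng.uniform(2.0, 12.0)
            p = SpotFluenceParams(s1, s1 * rng.uniform(1.5, 6.0), rng.uniform(0, 0.4))
            z = rng.choice([-200.0, -100.0, 0.0, 100.0, 200.0])
            fs = rng.choice([20.0, 40.0, 100.0, 200.0])
            fast = central_fluence(p, diverging_geom, z, fs)
            slow = naive_central_fluence(p, diverging_geom, z, fs)
            assert fast == pytest.approx(slow, rel=1e-12)

    def test_separable_product_form(self, parallel_geom):
        # sigma1=7, w2=0, FS=2 cm: the 2-D sum is the square of a 1-D sum
        p = SpotFluenceParams(7.0, 7.0, 0.0)
        i = np.arange(-2, 3)
        s = np.exp(-(25.0 * i**2) / (2 * 49.0)).sum()
        expected = s * s / (2 * math.pi * 49.0)
        assert central_fluence(p, parallel_geom, 0.0, 20.0) == pytest.approx(
            expected, rel=1e-12
        )

    def test_single_spot_limit_is_peak_value(self, parallel_geom):
        p = SpotFluenceParams(5.0, 5.0, 0.0)
        assert central_fluence(p, parallel_geom, 0.0, 0.0) == pytest.approx(
            1.0 / (2 * math.pi * 25.0), rel=1e-12
        )

    def test_strictly_increasing_in_field_size(self, rs_params, diverging_geom):
        vals = [
            central_fluence(rs_params, diverging_geom, 100.0, fs)
            for fs in (20.0, 40.0, 60.0, 100.0, 200.0)
        ]
        assert all(b > a for a, b in zip(vals, vals[1:]))


class TestFsf:
    def test_reference_field_is_exactly_one(self, rs_params, diverging_geom):
        assert fsf(rs_params, diverging_geom, -100.0, 10.0, 10.0) == 1.0

    def test_two_cm_single_gaussian_value(self, parallel_geom):
        # frozen from an independent brute-force double summation
        p = SpotFluenceParams(7.0, 20.0, 0.0)
        assert fsf(p, parallel_geom, 0.0, 2.0) == pytest.approx(
            0.8685824965883369, rel=1e-10
        )

    def test_tiny_spot_gives_unity_for_all_fields(self, parallel_geom):
        p = SpotFluenceParams(0.01, 0.02, 0.0)
        for fs in (1.0, 2.0, 20.0):
            assert fsf(p, parallel_geom, 0.0, fs) == pytest.approx(1.0, abs=1e-12)

    def test_monotone_in_field_size(self, rs_params, parallel_geom):
        vals = [fsf(rs_params, parallel_geom, 0.0, fs) for fs in (2, 4, 6, 8, 10, 20)]
        assert all(b > a for a, b in zip(vals, vals[1:]))
        assert vals[-1] >= vals[-2]  # FSF(20) >= FSF(10) = 1

    def test_amplitude_invariance(self, parallel_geom):
        a = SpotFluenceParams(7.0, 20.0, 0.1, amplitude=1.0)
        b = SpotFluenceParams(7.0, 20.0, 0.1, amplitude=123.4)
        assert fsf(a, parallel_geom, 0.0, 4.0) == pytest.approx(
            fsf(b, parallel_geom, 0.0, 4.0), rel=1e-14
        )

    def test_symmetric_under_axis_swap(self, rs_params):
        g1 = BeamGeometry(vsad_x_mm=2000.0, vsad_y_mm=1400.0)
        g2 = BeamGeometry(vsad_x_mm=1400.0, vsad_y_mm=2000.0)
        assert fsf(rs_params, g1, 150.0, 6.0) == pytest.approx(
            fsf(rs_params, g2, 150.0, 6.0), rel=1e-14
        )

    def test_zero_halo_weight_matches_single_gaussian(self, parallel_geom):
        single = SpotFluenceParams(6.0, 6.0, 0.0)
        wide_halo = SpotFluenceParams(6.0, 77.0, 0.0)
        for fs in (2.0, 8.0, 20.0):
            assert fsf(single, parallel_geom, 0.0, fs) == pytest.approx(
                fsf(wide_halo, parallel_geom, 0.0, fs), rel=1e-14
            )


class TestParamValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(sigma1_mm=0.0, sigma2_mm=5.0, w2=0.1),
            dict(sigma1_mm=5.0, sigma2_mm=4.0, w2=0.1),
            dict(sigma1_mm=5.0, sigma2_mm=9.0, w2=1.0),
            dict(sigma1_mm=5.0, sigma2_mm=9.0, w2=-0.1),
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SpotFluenceParams(**kwargs)


def test_fsf_table_round_trip(tmp_path):
    records = [
        FsfRecord(121.0, -200.0, 2.0, 0.6612),
        FsfRecord(121.0, 0.0, 20.0, 1.1021),
        FsfRecord(80.3, 100.0, 4.0, 0.8),
    ]
    path = tmp_path / "fsf.csv"
    write_fsf_table(records, path)
    back = read_fsf_table(path)
    assert back == records
    header = path.read_text().splitlines()[0]
    assert header == "energy_MeV,plane_z_mm,field_size_cm,ref_field_size_cm,fsf"


def test_fsf_table_missing_column_rejected(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("energy_MeV,plane_z_mm\n100,0\n")
    with pytest.raises(ValueError, match="missing columns"):
        read_fsf_table(path)
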