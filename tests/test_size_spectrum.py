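import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tepflux import (
    GridError,
    SpectrumFitError,
    TEPSample,
    abundance_with_error,
    average_diameter,
    build_log_size_classes,
    fit_spectral_slope,
    normalized_distribution,
    volume_concentration,
)
from tests.conftest import brute_force_loglog_slope


class TestGrid:
    def test_standard_grid_endpoints_and_ratio(self, grid15):
        assert grid15.n_classes == 15
        assert grid15.boundaries[0] == 1.0
        assert grid15.boundaries[-1] == 135.0
        ratios = grid15.boundaries[1:] / grid15.boundaries[:-1]
        assert np.allclose(ratios, 135.0 ** (1 / 15))
        assert grid15.widths[0] == pytest.approx(135.0 ** (1 / 15) - 1.0, rel=1e-12)

    def test_widths_sum_and_ratio_product(self, grid15):
        assert grid15.widths.sum() == pytest.approx(135.0 - 1.0, rel=1e-12)
        assert np.prod(grid15.boundaries[1:] / grid15.boundaries[:-1]) == pytest.approx(
            135.0, rel=1e-9
        )

    def test_single_class_grid(self):
        g = build_log_size_classes(2.0, 4.0, 1)
        assert g.midpoints[0] == pytest.approx(3.0)
        assert g.widths[0] == pytest.approx(2.0)

    def test_midpoints_inside_classes(self, grid15):
        for kind in ("arithmetic", "geometric"):
            g = grid15.with_midpoint_kind(kind)
            assert np.all(g.midpoints > g.boundaries[:-1])
            assert np.all(g.midpoints < g.boundaries[1:])

    def test_geometric_midpoints_below_arithmetic(self, grid15):
        assert np.all(
            grid15.with_midpoint_kind("geometric").midpoints < grid15.midpoints
        )

    @pytest.mark.parametrize("args", [(0, 135, 15), (-1, 10, 5), (10, 1, 5), (1, 135, 0)])
    def test_invalid_grid_rejected(self, args):
        with pytest.raises(GridError):
            build_log_size_classes(*args)


class TestNormalizedDistribution:
    def test_value_is_count_over_width(self, grid15):
        counts = np.zeros(15)
        counts[0] = 100.0
        dens = normalized_distribution(TEPSample(counts=counts), grid15)
        assert dens[0] == pytest.approx(100.0 / (135.0 ** (1 / 15) - 1.0))
        assert np.all(dens[1:] == 0.0)

    def test_linearity(self, grid15):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 500, size=15).astype(float)
        d1 = normalized_distribution(TEPSample(counts=counts), grid15)
        d2 = normalized_distribution(TEPSample(counts=2 * counts), grid15)
        assert np.allclose(d2, 2 * d1)

    def test_shape_mismatch(self, grid15):
        with pytest.raises(ValueError, match="classes"):
            normalized_distribution(TEPSample(counts=np.ones(10)), grid15)


class TestSpectralSlope:
    def test_exact_power_law_recovered(self, grid15, power_law_sample):
        fit = fit_spectral_slope(power_law_sample, grid15)
        assert fit.delta == pytest.approx(-2.0, abs=1e-9)
        assert fit.k == pytest.approx(1000.0, rel=1e-9)
        assert fit.n_bins_used == 15
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_zero_count_classes_excluded(self, grid15):
        dens = 1000.0 * grid15.midpoints**-2.0
        counts = dens * grid15.widths
        counts[7] = 0.0
        fit = fit_spectral_slope(TEPSample(counts=counts), grid15)
        assert fit.n_bins_used == 14
        assert fit.delta == pytest.approx(-2.0, abs=1e-9)

    def test_underdetermined_fit_raises(self, grid15):
        counts = np.zeros(15)
        counts[3] = 50.0
        with pytest.raises(SpectrumFitError):
            fit_spectral_slope(TEPSample(counts=counts), grid15)

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(
            st.floats(min_value=0.5, max_value=1e5),
            min_size=15,
            max_size=15,
        )
    )
    def test_matches_normal_equations_oracle(self, counts):
        grid = build_log_size_classes(1.0, 135.0, 15)
        sample = TEPSample(counts=np.array(counts))
        fit = fit_spectral_slope(sample, grid)
        oracle = brute_force_loglog_slope(
            grid.midpoints, np.array(counts) / grid.widths
        )
        assert fit.delta == pytest.approx(oracle, abs=1e-9)

    @settings(deadline=None, max_examples=30)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, grid15, scale):
        rng = np.random.default_rng(42)
        counts = rng.integers(1, 1000, size=15).astype(float)
        base = TEPSample(counts=counts)
        scaled = TEPSample(counts=scale * counts)
        f0, f1 = fit_spectral_slope(base, grid15), fit_spectral_slope(scaled, grid15)
        assert f1.delta == pytest.approx(f0.delta, abs=1e-9)
        assert average_diameter(scaled, grid15) == pytest.approx(
            average_diameter(base, grid15), rel=1e-12
        )
        assert scaled.abundance == pytest.approx(scale * base.abundance, rel=1e-12)
        assert volume_concentration(scaled, grid15) == pytest.approx(
            scale * volume_concentration(base, grid15), rel=1e-12
        )


class TestAverageDiameter:
    def test_single_occupied_class(self, grid15):
        counts = np.zeros(15)
        counts[6] = 500.0
        assert average_diameter(TEPSample(counts=counts), grid15) == pytest.approx(
            grid15.midpoints[6]
        )

    def test_weighted_mean_example(self):
        # two classes with midpoints 1.19 and 4.0 um
        from tepflux.size_spectrum import SizeClassGrid

        grid = SizeClassGrid(boundaries=np.array([1.0, 1.38, 3.0, 5.0]))
        counts = np.array([300.0, 0.0, 100.0])
        assert grid.midpoints[0] == pytest.approx(1.19)
        assert grid.midpoints[2] == pytest.approx(4.0)
        assert average_diameter(TEPSample(counts=counts), grid) == pytest.approx(1.8925)

    def test_bounded_by_midpoints(self, grid15):
        rng = np.random.default_rng(7)
        counts = rng.random(15) * 100
        d = average_diameter(TEPSample(counts=counts), grid15)
        assert grid15.midpoints[0] <= d <= grid15.midpoints[-1]

    def test_all_zero_counts_raise(self, grid15):
        with pytest.raises(SpectrumFitError):
            average_diameter(TEPSample(counts=np.zeros(15)), grid15)


class TestVolumeConcentration:
    def test_closed_form_single_class(self):
        from tepflux.size_spectrum import SizeClassGrid

        grid = SizeClassGrid(boundaries=np.array([5.0, 15.0]))  # midpoint 10 um
        cv = volume_concentration(TEPSample(counts=np.array([1000.0])), grid)
        assert cv == pytest.approx(np.pi / 6 * 1000.0**2 * 1e-6, rel=1e-12)
        assert cv == pytest.approx(0.5236, abs=5e-5)

    def test_zero_counts_zero_volume(self, grid15):
        assert volume_concentration(TEPSample(counts=np.zeros(15)), grid15) == 0.0

    def test_additive_over_samples(self, grid15):
        rng = np.random.default_rng(3)
        counts = rng.random(15) * 200
        split = rng.random(15)
        cv_a = volume_concentration(TEPSample(counts=counts * split), grid15)
        cv_b = volume_concentration(TEPSample(counts=counts * (1 - split)), grid15)
        cv = volume_concentration(TEPSample(counts=counts), grid15)
        assert cv_a + cv_b == pytest.approx(cv, rel=1e-12)


class TestAbundanceError:
    @pytest.mark.parametrize(
        "abundance,sd", [(14449, 2890), (10364, 2073), (0, 0)]
    )
    def test_twenty_percent_convention(self, abundance, sd):
        counts = np.zeros(15)
        counts[0] = abundance
        total, err = abundance_with_error(TEPSample(counts=counts))
        assert total == abundance
        assert round(err) == sd

    def test_custom_error_fraction(self):
        sample = TEPSample(counts=np.array([100.0]), counting_error_fraction=0.03)
        assert abundance_with_error(sample) == (100.0, pytest.approx(3.0))
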