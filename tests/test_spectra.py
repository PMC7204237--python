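"""Spectral preprocessing: absorbance, regions, derivatives, fusion, outliers."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from mirhp.calorimetry import brouwer_heat_production, metabolic_body_weight
from mirhp.spectra import (
    DEFAULT_REGIONS,
    WavenumberGrid,
    apply_derivative,
    combine_m1,
    combine_m2,
    combine_m3,
    detect_spectral_outliers,
    from_absorbance,
    select_regions,
    to_absorbance,
)
from mirhp.synthetic import GeneratorConfig, generate_dataset, inject_spectral_outlier


class TestAbsorbance:
    @pytest.mark.parametrize("t, a", [(1.0, 0.0), (0.1, 1.0), (0.01, 2.0)])
    def test_log10_convention(self, t, a):
        assert to_absorbance(np.array([t]))[0] == pytest.approx(a, abs=1e-12)

    @pytest.mark.parametrize("bad", [0.0, -0.2, 1.2])
    def test_out_of_range_names_channel(self, bad):
        with pytest.raises(ValueError, match="channel 1"):
            to_absorbance(np.array([0.5, bad, 0.5]))

    @given(arrays(float, 16, elements=st.floats(min_value=0.0, max_value=3.0)))
    @settings(max_examples=50, derandomize=True)
    def test_round_trip(self, absorbance):
        back = to_absorbance(from_absorbance(absorbance))
        assert np.allclose(back, absorbance, atol=1e-12)


class TestRegionSelection:
    def test_small_grid_enumeration(self):
        grid = WavenumberGrid(np.array([900, 1000, 1500, 1600, 1750, 2600, 3000.0]))
        kept, spec = select_regions(grid, np.arange(7.0), DEFAULT_REGIONS)
        assert list(kept.values) == [1000, 1500, 1750, 2600]
        assert list(spec) == [1, 2, 4, 5]

    def test_covering_regions_identity(self):
        grid = WavenumberGrid(np.linspace(925, 5008, 50))
        kept, spec = select_regions(grid, np.arange(50.0), [(900.0, 5100.0)])
        assert np.array_equal(kept.values, grid.values)
        assert np.array_equal(spec, np.arange(50.0))

    def test_default_grid_matches_bruteforce_count(self):
        grid = WavenumberGrid.uniform(925, 5008, 1060)
        spec = np.zeros(1060)
        kept, _ = select_regions(grid, spec, DEFAULT_REGIONS)
        expected = sum(
            1
            for w in grid.values
            if any(lo <= w <= hi for lo, hi in DEFAULT_REGIONS)
        )
        assert len(kept) == expected
        # idempotence
        again, _ = select_regions(kept, np.zeros(len(kept)), DEFAULT_REGIONS)
        assert np.array_equal(again.values, kept.values)

    def test_empty_retention_rejected(self):
        grid = WavenumberGrid(np.array([4000.0, 4500.0]))
        with pytest.raises(ValueError, match="no channels retained"):
            select_regions(grid, np.zeros(2), [(968.0, 1577.0)])

    def test_commutes_with_absorbance_and_combine(self, rng):
        grid = WavenumberGrid.uniform(925, 5008, 200)
        t_am = rng.uniform(0.05, 1.0, 200)
        t_pm = rng.uniform(0.05, 1.0, 200)
        _, t_am_r = select_regions(grid, t_am)
        a_then_select = select_regions(grid, to_absorbance(t_am))[1]
        assert np.allclose(a_then_select, to_absorbance(t_am_r), atol=1e-12)
        m1_full = combine_m1(to_absorbance(t_am), to_absorbance(t_pm))
        _, m1_r = select_regions(grid, m1_full)
        m1_after = combine_m1(
            select_regions(grid, to_absorbance(t_am))[1],
            select_regions(grid, to_absorbance(t_pm))[1],
        )
        assert np.allclose(m1_r, m1_after, atol=1e-12)


class TestDerivative:
    def test_constant_first_derivative_zero(self):
        assert np.allclose(apply_derivative(np.full(10, 3.2), 1, 1), 0.0)

    def test_linear_ramp_constant_slope(self):
        s = 0.7
        ramp = s * np.arange(12.0)
        out = apply_derivative(ramp, 1, 1)
        assert out.shape == (11,)
        assert np.allclose(out, s)

    def test_quadratic_constant_second_difference(self):
        x = np.arange(15.0)
        out = apply_derivative(2 * x**2, 2, 1)
        assert np.allclose(out, 4.0)

    def test_linearity(self, rng):
        a, b = rng.normal(size=30), rng.normal(size=30)
        lhs = apply_derivative(2 * a + 3 * b, 2, 2)
        rhs = 2 * apply_derivative(a, 2, 2) + 3 * apply_derivative(b, 2, 2)
        assert np.allclose(lhs, rhs, atol=1e-12)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            apply_derivative(np.zeros(4), 2, 2)


class TestCombineOperators:
    def test_m1_average_identities(self, rng):
        v = rng.uniform(0, 2, 40)
        assert np.allclose(combine_m1(v, v), v)
        assert np.allclose(combine_m1(np.zeros(40), v), v / 2)
        assert np.allclose(combine_m1(v, np.zeros(40)), combine_m1(np.zeros(40), v))

    def test_m2_reduces_to_m1_at_unit_yield(self, rng):
        a, b = rng.uniform(0, 2, 40), rng.uniform(0, 2, 40)
        assert np.allclose(combine_m2(a, b, 0.4, 0.6), combine_m1(a, b))
        assert np.allclose(combine_m2(a, b, 0.0, 0.0), 0.0)
        assert np.allclose(combine_m2(a, b, 4.0, 6.0), 2 * combine_m2(a, b, 2.0, 3.0))

    def test_m3_identities(self, rng):
        a, b = rng.uniform(0, 2, 40), rng.uniform(0, 2, 40)
        assert np.allclose(combine_m3(a, b, 1.0, 1.0), combine_m1(a, b))
        v = rng.uniform(0, 2, 40)
        y_am, y_pm = 11.0, 9.0
        assert np.allclose(combine_m3(v, v, y_am, y_pm), v * (y_am + y_pm) / 2)
        assert np.allclose(combine_m3(v, v, y_am, y_pm), combine_m2(v, v, y_am, y_pm) / 2 * 1)
        assert np.allclose(combine_m3(a, b, 3.0, 0.0), a * 1.5)

    def test_m2_m3_coincide_up_to_scale_for_equal_spectra(self, rng):
        v = rng.uniform(0, 2, 40)
        m2 = combine_m2(v, v, 7.0, 5.0)
        m3 = combine_m3(v, v, 7.0, 5.0)
        assert np.allclose(m2, 2 * m3)

    def test_m3_total_yield_divisor_is_weighted_mean(self, rng):
        a, b = rng.uniform(0, 2, 40), rng.uniform(0, 2, 40)
        out = combine_m3(a, b, 3.0, 1.0, divisor="total_yield")
        assert np.allclose(out, (3 * a + b) / 4)

    def test_linearity_in_each_spectrum(self, rng):
        a, b, c = (rng.uniform(0, 2, 40) for _ in range(3))
        for op in (
            lambda x, z: combine_m1(x, z),
            lambda x, z: combine_m2(x, z, 2.0, 3.0),
            lambda x, z: combine_m3(x, z, 2.0, 3.0),
        ):
            assert np.allclose(op(a + c, b), op(a, b) + op(c, b) - op(np.zeros(40), b))

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            combine_m1(np.zeros(10), np.zeros(11))


@pytest.fixture(scope="module")
def screened_dataset():
    cfg = GeneratorConfig(seed=3, n_cows=40, obs_per_cow=2)
    obs, _ = generate_dataset(cfg)
    grid = obs[0].am.grid
    spectra = [o.am.spectrum for o in obs]
    y = np.array(
        [brouwer_heat_production(o.gas) / metabolic_body_weight(o.bw) for o in obs]
    )
    return cfg, grid, spectra, y


class TestOutlierScreen:
    @staticmethod
    def _retained(grid, transmittances):
        absorbance = np.array([to_absorbance(t) for t in transmittances])
        _, X = select_regions(grid, absorbance)
        return X

    def test_artifact_in_retained_region_is_flagged(self, screened_dataset):
        cfg, grid, spectra, y = screened_dataset
        spectra = list(spectra)
        spectra[5] = inject_spectral_outlier(
            spectra[5], grid, 10 * cfg.spectral_noise_sd, center=1300.0
        )
        flags, d2 = detect_spectral_outliers(self._retained(grid, spectra), y, n_lv=10)
        assert flags[5]
        assert d2[5] == d2.max()

    def test_artifact_outside_retained_regions_not_seen(self, screened_dataset):
        cfg, grid, spectra, y = screened_dataset
        spectra = list(spectra)
        spectra[5] = inject_spectral_outlier(
            spectra[5], grid, 10 * cfg.spectral_noise_sd, center=4500.0
        )
        flags, _ = detect_spectral_outliers(self._retained(grid, spectra), y, n_lv=10)
        assert not flags[5]

    def test_duplicating_rows_keeps_original_flags(self, screened_dataset):
        cfg, grid, spectra, y = screened_dataset
        spectra = list(spectra)
        spectra[5] = inject_spectral_outlier(
            spectra[5], grid, 10 * cfg.spectral_noise_sd, center=1300.0
        )
        X = self._retained(grid, spectra)
        flags, _ = detect_spectral_outliers(X, y, n_lv=10)
        X2 = np.vstack([X, X[:20]])
        y2 = np.concatenate([y, y[:20]])
        flags2, _ = detect_spectral_outliers(X2, y2, n_lv=10)
        assert flags2[5]

    def test_zero_magnitude_is_identity(self, screened_dataset):
        _, grid, spectra, _ = screened_dataset
        out = inject_spectral_outlier(spectra[0], grid, 0.0, center=1300.0)
        assert np.allclose(out, spectra[0], atol=1e-12)
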