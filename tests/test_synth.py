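"""Synthetic-library generator: distributions, spectrum shape, planted signal."""

import numpy as np
import pytest
from scipy.stats import pearsonr

from canopy2sat import (
    Stage,
    StageGeneratorParams,
    generate_dataset,
    generate_spectrum,
    load_sensor,
    nitrogen_to_chlorophyll,
    sample_nitrogen,
    screen_band_pairs,
    simulate_sensor_table,
)
from canopy2sat.errors import ConfigurationError
from canopy2sat.synth import DEFAULT_STAGE_PARAMS, low_noise_params, stage_params


def rejection_truncnorm(mean, sd, low, high, n, seed):
    """Independent truncated-normal oracle: plain rejection sampling."""
    rng = np.random.default_rng(seed)
    out = []
    while len(out) < n:
        draw = rng.normal(mean, sd, size=4 * n)
        out.extend(draw[(draw >= low) & (draw <= high)][: n - len(out)])
    return np.asarray(out)


class TestSampleNitrogen:
    @pytest.mark.parametrize(
        "stage,target", [("NGS", 3.04), ("NSS", 2.82), ("ASS", 2.60)]
    )
    def test_means_match_stage_targets(self, stage, target):
        values = sample_nitrogen(stage, 10000, seed=1)
        assert abs(values.mean() - target) < 0.02

    def test_oracle_agreement_and_bounds(self):
        """The generator matches a rejection-sampling truncated normal."""
        values = sample_nitrogen("NSS", 10000, seed=7)
        p = stage_params("NSS")
        oracle = rejection_truncnorm(p.n_mean, p.n_sd, *p.n_bounds, 10000, seed=7)
        # same distribution family and parameters → means within MC error
        assert abs(values.mean() - 2.82) < 0.02
        assert abs(values.mean() - oracle.mean()) < 0.02
        assert values.min() >= 2.0 and values.max() <= 3.9

    def test_single_draw_inside_truncation_bounds(self):
        for seed in (0, 99, 2**30):
            (v,) = sample_nitrogen("ASS", 1, seed)
            assert 2.0 <= v <= 3.9

    def test_seed_determinism(self):
        a = sample_nitrogen("NGS", 50, seed=3)
        b = sample_nitrogen("NGS", 50, seed=3)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, sample_nitrogen("NGS", 50, seed=4))

    def test_errors(self):
        with pytest.raises(ConfigurationError):
            sample_nitrogen("WINTER", 10, 0)
        with pytest.raises(ValueError):
            sample_nitrogen("NGS", 0, 0)


class TestNitrogenToChlorophyll:
    def test_identity_and_clamp(self):
        assert nitrogen_to_chlorophyll(3.0, slope=1, intercept=0, noise_sd=0) == 3.0
        assert nitrogen_to_chlorophyll(0.0, slope=1, intercept=-1, noise_sd=0) == 0.0

    def test_monotone_at_zero_noise(self):
        n = np.linspace(2.0, 3.9, 25)
        chl = nitrogen_to_chlorophyll(n, noise_sd=0)
        assert np.all(np.diff(chl) > 0)

    def test_rejects_nonpositive_slope(self):
        with pytest.raises(ValueError):
            nitrogen_to_chlorophyll(3.0, slope=0)


class TestGenerateSpectrum:
    def test_grid_and_bounds(self):
        s = generate_spectrum(30.0, stage_params("NGS"), seed=5)
        assert len(s) == 2151
        assert s.wavelengths[0] == 350 and s.wavelengths[-1] == 2500
        assert np.all((s.reflectance >= 0) & (s.reflectance <= 1))

    def test_zero_chlorophyll_has_no_absorption_wells(self):
        """At chl=0 the 670 nm reflectance equals the absorption-free continuum."""
        from canopy2sat.synth import _continuum, _VIS_BASE
        from canopy2sat.library import WAVELENGTH_GRID

        params = low_noise_params("NGS")
        s = generate_spectrum(0.0, params, seed=11)
        # rebuild the continuum with the same per-sample factors
        rng = np.random.default_rng(np.random.SeedSequence([11, 5]))
        structure = rng.lognormal(0.0, params.structure_sigma)
        baseline = 1.0 + rng.normal(0.0, params.baseline_sigma)
        cont = _continuum(
            WAVELENGTH_GRID, 0.0, plateau=params.amplitude * structure,
            vis_base=_VIS_BASE * baseline,
        )
        idx = 670 - 350
        assert s.reflectance[idx] == pytest.approx(cont[idx], abs=1e-12)

    def test_red_reflectance_decreases_with_chlorophyll(self):
        params = low_noise_params("NGS")
        lo = generate_spectrum(30.0, params, seed=8)
        hi = generate_spectrum(60.0, params, seed=8)
        assert lo.at(670) > hi.at(670)

    def test_stage_amplitude_orders_nir_plateau(self):
        nir = {}
        for stage in ("NGS", "NSS", "ASS"):
            s = generate_spectrum(35.0, low_noise_params(stage), seed=21)
            mask = (s.wavelengths >= 760) & (s.wavelengths <= 900)
            nir[stage] = s.reflectance[mask].mean()
        assert nir["NGS"] > nir["NSS"] > nir["ASS"]

    def test_rejects_nonfinite_chl(self):
        with pytest.raises(ValueError):
            generate_spectrum(float("nan"), stage_params("NGS"), seed=0)


class TestGenerateDataset:
    def test_shapes_and_labels(self):
        lib = generate_dataset("NGS", 100, seed=42)
        assert len(lib) == 100
        assert lib.reflectance.shape == (100, 2151)
        assert len(set(lib.sample_ids)) == 100
        assert set(lib.stages) == {"NGS"}
        assert np.all((lib.nitrogen >= 2.0) & (lib.nitrogen <= 3.9))
        assert np.all((lib.reflectance >= 0) & (lib.reflectance <= 1))

    def test_bit_identical_under_same_seed(self):
        a = generate_dataset("NSS", 20, seed=9)
        b = generate_dataset("NSS", 20, seed=9)
        assert np.array_equal(a.reflectance, b.reflectance)
        assert np.array_equal(a.nitrogen, b.nitrogen)
        assert a.sample_ids == b.sample_ids

    def test_red_reflectance_anticorrelated_with_nitrogen(self, ngs_library):
        # independent correlation implementation as oracle
        r, _ = pearsonr(ngs_library.nitrogen, ngs_library.reflectance[:, 670 - 350])
        assert r < 0

    def test_stage_ordering_of_mean_nir(self):
        means = {}
        for stage in ("NGS", "NSS", "ASS"):
            lib = generate_dataset(stage, 50, seed=7, params=low_noise_params(stage))
            cols = slice(760 - 350, 900 - 350 + 1)
            means[stage] = lib.reflectance[:, cols].mean()
        assert means["NGS"] > means["NSS"] > means["ASS"]

    def test_planted_red_edge_signal_dominates_visible_pairs(self):
        """At vanishing noise a red-edge/NIR pair must out-correlate any
        visible–visible pair, so screening has a recoverable ground truth."""
        lib = generate_dataset("NGS", 500, seed=42, params=low_noise_params("NGS"))
        table = simulate_sensor_table(lib, load_sensor("sentinel2"))
        result = screen_band_pairs(table)
        visible = {"Coastal", "Blue", "Green", "Red"}
        vis_vis = [
            e.abs_r for e in result.entries
            if e.band_i in visible and e.band_j in visible
        ]
        red_edge_nir = [
            e.abs_r for e in result.entries
            if not (e.band_i in visible and e.band_j in visible)
        ]
        assert max(red_edge_nir) > max(vis_vis)

    def test_default_params_registry(self):
        amps = [DEFAULT_STAGE_PARAMS[s].amplitude for s in (Stage.NGS, Stage.NSS, Stage.ASS)]
        assert amps[0] > amps[1] > amps[2]

    def test_invalid_stage_params(self):
        with pytest.raises(ConfigurationError):
            StageGeneratorParams(Stage.NGS, n_mean=1.0)  # below the bounds
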