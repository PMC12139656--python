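"""Forward scattering models: sound speed, limits, resonance, classification."""

import numpy as np
import pytest

from escore import scattering as sc
from escore import scoring


@pytest.fixture(scope="module")
def medium():
    return sc.Medium(temperature_c=26.0, salinity_psu=35.5, depth_m=25.0)


class TestMackenzie:
    def test_constant_term_at_reference_conditions(self):
        # T=0, S=35, D=0: every correction term vanishes
        assert sc.mackenzie_sound_speed(0.0, 35.0, 0.0) == pytest.approx(1448.96)

    def test_monotone_in_temperature(self):
        c = [sc.mackenzie_sound_speed(t, 35.0, 0.0) for t in range(0, 31)]
        assert all(b > a for a, b in zip(c, c[1:]))

    def test_coefficient_table_value(self):
        # independent term-by-term evaluation at T=26, S=35.5, D=25
        T, S, D = 26.0, 35.5, 25.0
        terms = [
            1448.96,
            4.591 * T,
            -5.304e-2 * T * T,
            2.374e-4 * T**3,
            1.340 * (S - 35),
            1.630e-2 * D,
            1.675e-7 * D * D,
            -1.025e-2 * T * (S - 35),
            -7.139e-13 * T * D**3,
        ]
        assert sc.mackenzie_sound_speed(T, S, D) == pytest.approx(
            sum(terms), abs=1e-9
        )
        assert sum(terms) == pytest.approx(1537.588, abs=1e-3)

    def test_envelope_warning_and_nonfinite_error(self):
        with pytest.warns(UserWarning):
            sc.mackenzie_sound_speed(40.0, 35.0, 0.0)
        with pytest.raises(ValueError):
            sc.mackenzie_sound_speed(float("nan"), 35.0, 0.0)


class TestDwbaBentCylinder:
    def test_null_contrast_is_missing(self, medium):
        spec = sc.ScatterModelSpec("n", "dwba_bent_cylinder", length_mm=10, g=1.0, h=1.0)
        assert np.isnan(sc.ts_dwba_bent_cylinder(spec, medium, 38.0))

    def test_rayleigh_slope_40db_per_decade(self, medium):
        spec = sc.ScatterModelSpec(
            "cop", "dwba_bent_cylinder", length_mm=2.0, g=1.02, h=1.02,
            lw_ratio=4.0, orient_sd_deg=20.0,
        )
        t18 = sc.ts_dwba_bent_cylinder(spec, medium, 18.0)
        t38 = sc.ts_dwba_bent_cylinder(spec, medium, 38.0)
        slope = (t38 - t18) / np.log10(38.0 / 18.0)
        assert abs(slope - 40.0) < 2.0

    def test_small_copepod_rises_toward_38khz(self, medium):
        spec = sc.ScatterModelSpec(
            "cop", "dwba_bent_cylinder", length_mm=2.0, g=1.02, h=1.02,
            lw_ratio=2.5, orient_sd_deg=30.0,
        )
        resp = sc.frequency_response(spec, medium)
        assert resp.delta_triplet[0] < 0  # dSv(18-38) negative


class TestRandomFluidCylinder:
    def test_null_contrast(self, medium):
        spec = sc.ScatterModelSpec(
            "n", "fluid_bent_cylinder_random", length_mm=10, g=1.0, h=1.0
        )
        assert np.isnan(sc.ts_fluid_bent_cylinder_random(spec, medium, 38.0))

    def test_length_monotone_in_geometric_regime(self, medium):
        ts = [
            sc.ts_fluid_bent_cylinder_random(
                sc.ScatterModelSpec(
                    "s", "fluid_bent_cylinder_random", length_mm=L, g=1.04, h=1.04
                ),
                medium,
                120.0,
            )
            for L in (40.0, 80.0)
        ]
        assert ts[1] > ts[0]

    def test_agrees_with_dwba_in_rayleigh_regime(self, medium):
        kwargs = dict(length_mm=1.0, g=1.02, h=1.02, lw_ratio=4.0)
        rand = sc.ts_fluid_bent_cylinder_random(
            sc.ScatterModelSpec("r", "fluid_bent_cylinder_random", **kwargs),
            medium,
            18.0,
        )
        dwba = sc.ts_dwba_bent_cylinder(
            sc.ScatterModelSpec(
                "d", "dwba_bent_cylinder", orient_sd_deg=5.0, **kwargs
            ),
            medium,
            18.0,
        )
        assert abs(rand - dwba) < 3.0


class TestHighPassSphere:
    def test_rayleigh_slope(self, medium):
        spec = sc.ScatterModelSpec("g", "highpass_fluid_sphere", esr_mm=1.0,
                                   g=1.06, h=1.06)
        slope = (
            sc.ts_highpass_fluid_sphere(spec, medium, 2.0)
            - sc.ts_highpass_fluid_sphere(spec, medium, 1.0)
        ) / np.log10(2.0)
        assert abs(slope - 40.0) < 0.5

    def test_plateau_at_large_ka(self, medium):
        spec = sc.ScatterModelSpec("g", "highpass_fluid_sphere", esr_mm=50.0,
                                   g=1.06, h=1.06)
        diff = abs(
            sc.ts_highpass_fluid_sphere(spec, medium, 120.0)
            - sc.ts_highpass_fluid_sphere(spec, medium, 70.0)
        )
        assert diff < 1.0

    def test_rayleigh_a6_scaling(self, medium):
        small = sc.ScatterModelSpec("s", "highpass_fluid_sphere", esr_mm=0.05,
                                    g=1.06, h=1.06)
        big = sc.ScatterModelSpec("b", "highpass_fluid_sphere", esr_mm=0.10,
                                  g=1.06, h=1.06)
        gain = sc.ts_highpass_fluid_sphere(
            big, medium, 18.0
        ) - sc.ts_highpass_fluid_sphere(small, medium, 18.0)
        assert gain == pytest.approx(10 * np.log10(2**6), abs=0.5)


class TestGasBubble:
    def test_resonance_matches_minnaert(self, medium):
        spec = sc.ScatterModelSpec("b", "gas_bubble_spherical", esr_mm=0.16)
        f0 = sc.minnaert_frequency(0.16e-3, medium)
        freqs = np.linspace(5e3, 120e3, 4000)
        ts = np.array([sc.ts_gas_bubble(spec, medium, f / 1e3) for f in freqs])
        peak = freqs[np.argmax(ts)]
        assert abs(peak - f0) / f0 < 0.10
        assert 30e3 < peak < 45e3  # lands near the 38 kHz channel

    def test_geometric_limit_far_above_resonance(self, medium):
        a = 0.16e-3
        spec = sc.ScatterModelSpec("b", "gas_bubble_spherical", esr_mm=0.16)
        f = 100 * sc.minnaert_frequency(a, medium)  # f >> f0
        ts = sc.ts_gas_bubble(spec, medium, f / 1e3)
        k = medium.wavenumber(f)
        delta = k * a + 4 * sc.WATER_VISCOSITY / (
            medium.density_kg_m3 * 2 * np.pi * f * a * a
        )
        expected = 10 * np.log10(a * a / (1 + delta**2))
        assert ts == pytest.approx(expected, abs=0.1)

    def test_resonance_inverse_in_radius(self, medium):
        f_small = sc.minnaert_frequency(0.1e-3, medium)
        f_big = sc.minnaert_frequency(0.2e-3, medium)
        assert f_small == pytest.approx(2 * f_big, rel=1e-12)

    def test_minnaert_across_sizes_and_depths(self):
        # closed-form consistency of the resonance peak over a size/depth grid
        for a_mm in (0.1, 1.0, 10.0):
            for depth in (0.0, 200.0):
                m = sc.Medium(depth_m=depth)
                f0 = sc.minnaert_frequency(a_mm * 1e-3, m)
                spec = sc.ScatterModelSpec("b", "gas_bubble_spherical", esr_mm=a_mm)
                freqs = np.linspace(0.2 * f0, 3 * f0, 3000)
                ts = [sc.ts_gas_bubble(spec, m, f / 1e3) for f in freqs]
                peak = freqs[int(np.argmax(ts))]
                assert abs(peak - f0) / f0 < 0.10

    def test_ellipsoid_raises_resonance(self, medium):
        sph = sc.ScatterModelSpec("s", "gas_bubble_spherical", esr_mm=0.5)
        ell = sc.ScatterModelSpec("e", "gas_bubble_ellipsoid", esr_mm=0.5, aspect=4.0)
        f0 = sc.minnaert_frequency(0.5e-3, medium)
        freqs = np.linspace(0.3 * f0, 4 * f0, 3000)
        peak_s = freqs[int(np.argmax([sc.ts_gas_bubble(sph, medium, f / 1e3) for f in freqs]))]
        peak_e = freqs[int(np.argmax([sc.ts_gas_bubble(ell, medium, f / 1e3) for f in freqs]))]
        assert peak_e > peak_s


class TestHybrid:
    def test_no_gas_equals_body_only(self, medium):
        spec = sc.ScatterModelSpec(
            "h", "hybrid_gas_body", length_mm=30.0, g=1.04, h=1.04,
            gas_esr_mm=1e-12,
        )
        body = sc.ScatterModelSpec(
            "d", "dwba_bent_cylinder", length_mm=30.0, g=1.04, h=1.04
        )
        # vanishing gas inclusion: bubble cross-section negligible
        assert sc.ts_hybrid(spec, medium, 38.0) == pytest.approx(
            sc.ts_dwba_bent_cylinder(body, medium, 38.0), abs=0.01
        )

    def test_bubble_dominates_at_resonance(self, medium):
        gas_esr = 0.16
        spec = sc.ScatterModelSpec(
            "h", "hybrid_gas_body", length_mm=5.0, g=1.02, h=1.02,
            gas_esr_mm=gas_esr,
        )
        f0 = sc.minnaert_frequency(gas_esr * 1e-3, medium) / 1e3
        bubble = sc.ScatterModelSpec("b", "gas_bubble_spherical", esr_mm=gas_esr)
        assert abs(
            sc.ts_hybrid(spec, medium, f0) - sc.ts_gas_bubble(bubble, medium, f0)
        ) < 1.0

    def test_hybrid_at_least_each_component(self, medium):
        spec = sc.ScatterModelSpec(
            "h", "hybrid_gas_body", length_mm=65.0, g=1.04, h=1.04,
            gas_esr_mm=3.25,
        )
        bubble = sc.ScatterModelSpec("b", "gas_bubble_spherical", esr_mm=3.25)
        body = sc.ScatterModelSpec(
            "d", "dwba_bent_cylinder", length_mm=65.0, g=1.04, h=1.04
        )
        for f in (18.0, 38.0, 70.0, 120.0):
            hy = sc.ts_hybrid(spec, medium, f)
            assert hy >= sc.ts_gas_bubble(bubble, medium, f) - 1e-9
            assert hy >= sc.ts_dwba_bent_cylinder(body, medium, f) - 1e-9


class TestClassifyModel:
    def _library_model(self):
        # synthetic echo-class model: class 1 (18-dominant, near-flat falling)
        # built where swimbladder-bearing scatterers land; classes 2-3 are
        # 38-peaked zooplankton-like shapes far from it
        mu = np.array(
            [
                [1.0, -2.0, -4.5],
                [-9.0, -1.0, -2.0],
                [-14.0, -9.0, -13.0],
            ]
        )
        sigma = np.full((3, 3), 1.2)
        return scoring.EchoClassModel(mu=mu, sigma=sigma, threshold=25.0)

    def test_centroid_triplet_scores_zero(self, medium):
        model = self._library_model()
        labels, mins = scoring.classify_triplets(model.mu[1][None, :], model)
        assert labels[0] == 2 and mins[0] == 0.0

    def test_far_triplet_unclassified(self, medium):
        model = self._library_model()
        labels, _ = scoring.classify_triplets(
            np.array([[30.0, 30.0, 30.0]]), model
        )
        assert labels[0] == scoring.UNCLASSIFIED

    def test_hybrid_fish_lands_in_18khz_dominant_class(self, medium):
        model = self._library_model()
        fish = sc.ScatterModelSpec(
            "hybrid fish", "hybrid_gas_body", length_mm=65.0, g=1.04, h=1.04,
            lw_ratio=6.0,
        )
        label, score = sc.classify_model(fish, medium, model)
        assert label == 1
        assert score < 25.0

    def test_identical_to_single_cell_grid(self, medium):
        from tests.test_training import delta_grid

        model = self._library_model()
        fish = sc.ScatterModelSpec(
            "hybrid fish", "hybrid_gas_body", length_mm=45.0, g=1.04, h=1.04
        )
        label, score = sc.classify_model(fish, medium, model)
        resp = sc.frequency_response(fish, medium)
        grid_out = scoring.classify_cells(
            delta_grid(resp.delta_triplet[None, None, :]), model
        )
        assert grid_out.labels[0, 0] == label
        assert grid_out.min_escore[0, 0] == pytest.approx(score)

    def test_null_ts_gives_unclassified(self, medium):
        model = self._library_model()
        nul = sc.ScatterModelSpec("n", "dwba_bent_cylinder", length_mm=10,
                                  g=1.0, h=1.0)
        label, score = sc.classify_model(nul, medium, model)
        assert label == scoring.UNCLASSIFIED
        assert np.isnan(score)


class TestParameterTables:
    def test_model_csv_and_response_table(self, tmp_path, medium):
        p = tmp_path / "params.csv"
        p.write_text(
            "name,family,esr_mm_or_length_mm,g,h,lw_ratio,orient_mean_deg,"
            "orient_sd_deg,aspect,gamma\n"
            "copepod,dwba_bent_cylinder,2.0,1.02,1.02,2.5,0,30,1,1.4\n"
            "bubble,gas_bubble_spherical,0.16,1.04,1.04,4,0,20,1,1.4\n"
        )
        specs = sc.read_model_csv(p)
        assert specs[0].length_mm == 2.0 and specs[0].esr_mm is None
        assert specs[1].esr_mm == 0.16
        model = scoring.EchoClassModel(
            mu=np.zeros((1, 3)), sigma=np.ones((1, 3))
        )
        out = tmp_path / "resp.csv"
        df = sc.write_response_csv(specs, medium, model, out)
        assert len(df) == 8  # 2 specs x 4 frequencies
        assert set(df.columns) >= {
            "name", "f_khz", "ts_db", "sv_db", "d18_38", "d70_38",
            "d120_38", "class", "escore",
        }
        assert out.exists()
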