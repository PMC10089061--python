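"""Calibration, CCS distributions, CIU50 fitting, conformer detection, gating."""

import numpy as np
import pytest

from znmt import imms, synthetic
from znmt.imms import (ATD, CCSDistribution, TWCalibration, atd_to_ccsd,
                       build_fingerprint, calibrate_tw, detect_conformers,
                       fit_ciu50, gate_select, interconversion_metric, kde_ccs)
from znmt.synthetic import GeneratorConfig, synth_ciu_fingerprint

E_GRID = np.arange(50, 150.01, 2.5)
CAL_POINTS = [(500.0, 1, 2000.0), (800.0, 2, 5000.0), (1200.0, 2, 8000.0),
              (1500.0, 3, 12000.0), (2000.0, 3, 16000.0)]  # (ccs, z, mass)


def _synthetic_calibrants(A=280.0, B=0.55, noise=0.0, seed=0):
    ref = TWCalibration(A=A, B=B)
    rng = np.random.default_rng(seed)
    rows = []
    for ccs, z, m in CAL_POINTS:
        t = float(ref.time_from_ccs(ccs, z, m)) * (1 + noise * rng.normal())
        rows.append((t, ccs, z, m))
    return rows


class TestCalibration:
    def test_exact_recovery(self):
        cal = calibrate_tw(_synthetic_calibrants())
        assert cal.A == pytest.approx(280.0, rel=1e-6)
        assert cal.B == pytest.approx(0.55, rel=1e-6)
        assert cal.accepted

    def test_roundtrip_identity(self):
        cal = calibrate_tw(_synthetic_calibrants())
        ccs = np.array([700.0, 1000.0, 1300.0])
        back = cal.ccs_from_time(cal.time_from_ccs(ccs, 5, 6490.0), 5, 6490.0)
        np.testing.assert_allclose(back, ccs, rtol=1e-9)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            calibrate_tw(_synthetic_calibrants()[:2])

    def test_rank_deficient_identical_points(self):
        row = _synthetic_calibrants()[0]
        with pytest.raises(ValueError):
            calibrate_tw([row, row, row])

    def test_noisy_calibrants_still_accepted(self):
        cal = calibrate_tw(_synthetic_calibrants(noise=0.01, seed=4))
        assert cal.r2 >= 0.98


class TestATDTransform:
    @pytest.fixture(scope="class")
    def cal(self):
        return calibrate_tw(_synthetic_calibrants())

    def _gaussian_atd(self, cal, ccs0=1000.0, z=5, mass=6490.0, width_ms=0.4):
        tc = float(cal.time_from_ccs(ccs0, z, mass))
        t = np.linspace(tc - 3, tc + 3, 400)
        return ATD(t, np.exp(-0.5 * ((t - tc) / width_ms) ** 2), z=z, mass=mass)

    def test_centroid_recovered(self, cal):
        d = atd_to_ccsd(self._gaussian_atd(cal), cal)
        assert d.centroid == pytest.approx(1000.0, rel=0.005)

    def test_unit_area_preserved(self, cal):
        d = atd_to_ccsd(self._gaussian_atd(cal), cal)
        assert np.trapezoid(d.density, d.ccs) == pytest.approx(1.0, rel=1e-9)

    def test_width_ratio_preserved(self, cal):
        """A broad apo-like ATD maps to a proportionally broad CCSD."""
        narrow = atd_to_ccsd(self._gaussian_atd(cal, width_ms=0.2), cal)
        broad = atd_to_ccsd(self._gaussian_atd(cal, width_ms=0.6), cal)

        def sd(d):
            mu = d.centroid
            return np.sqrt(np.trapezoid((d.ccs - mu) ** 2 * d.density, d.ccs))

        assert sd(broad) / sd(narrow) == pytest.approx(3.0, rel=0.05)

    def test_rejected_calibration_refused(self, cal):
        bad = TWCalibration(A=cal.A, B=cal.B, r2=0.5)
        with pytest.raises(ValueError):
            atd_to_ccsd(self._gaussian_atd(cal), bad)


class TestFingerprint:
    def test_single_energy_column(self):
        d = CCSDistribution(np.linspace(900, 1300, 100),
                            np.exp(-0.5 * ((np.linspace(900, 1300, 100) - 1000) / 25) ** 2),
                            energy_eV=50.0)
        fp = build_fingerprint([d])
        assert fp.matrix.shape == (100, 1)
        assert fp.matrix.max() == pytest.approx(1.0)

    def test_duplicate_energies_rejected(self):
        g = np.linspace(900, 1300, 50)
        d = CCSDistribution(g, np.ones(50), energy_eV=50.0)
        with pytest.raises(ValueError):
            build_fingerprint([d, d])

    def test_column_maxima_one(self):
        fp = synth_ciu_fingerprint([1000, 1150], [25, 25], [90], [4], E_GRID,
                                   GeneratorConfig(seed=2, noise_sd=0.02))
        np.testing.assert_allclose(fp.matrix.max(axis=0), 1.0)


class TestCIU50:
    def test_noiseless_exact(self):
        fp = synth_ciu_fingerprint([1000, 1150], [25, 25], [90], [4], E_GRID,
                                   GeneratorConfig(noise_sd=0.0))
        res = fit_ciu50(fp, 2)
        assert res.converged
        assert res.midpoints_eV[0] == pytest.approx(90.0, abs=0.01)

    @pytest.mark.parametrize("true_mid", [90.0, 110.0])
    def test_seeded_noise_within_2ev(self, true_mid):
        for seed in range(10):
            fp = synth_ciu_fingerprint([1000, 1150], [25, 25], [true_mid], [4],
                                       E_GRID, GeneratorConfig(seed=seed, noise_sd=0.02))
            res = fit_ciu50(fp, 2)
            assert res.midpoints_eV[0] == pytest.approx(true_mid, abs=2.0)

    def test_bias_and_spread_over_replicates(self):
        """Midpoint estimator bias < 1 eV and sd < 3 eV over 200 noisy
        replicates on the default 50-150 eV grid."""
        errs = []
        for seed in range(200):
            fp = synth_ciu_fingerprint([1000, 1150], [25, 25], [100.0], [4],
                                       E_GRID, GeneratorConfig(seed=seed, noise_sd=0.02))
            errs.append(fit_ciu50(fp, 2).midpoints_eV[0] - 100.0)
        errs = np.asarray(errs)
        assert abs(errs.mean()) < 1.0
        assert errs.std() < 3.0

    def test_three_state_fingerprint(self):
        fp = synth_ciu_fingerprint([1000, 1100, 1200], [20, 20, 20], [80, 120],
                                   [3, 3], E_GRID, GeneratorConfig(noise_sd=0.0))
        res = fit_ciu50(fp, 3)
        assert res.midpoints_eV == pytest.approx([80.0, 120.0], abs=0.5)

    def test_plateau_levels(self):
        fp = synth_ciu_fingerprint([1000, 1150], [25, 25], [90], [4], E_GRID,
                                   GeneratorConfig(noise_sd=0.0))
        res = fit_ciu50(fp, 2)
        assert res.plateaus_A2[0] == pytest.approx(1000, abs=5)
        assert res.plateaus_A2[-1] == pytest.approx(1150, abs=5)

    def test_requires_two_states(self):
        fp = synth_ciu_fingerprint([1000], [25], [], [], E_GRID)
        with pytest.raises(ValueError):
            fit_ciu50(fp, 1)

    def test_edge_transition_flagged(self):
        fp = synth_ciu_fingerprint([1000, 1150], [25, 25], [149], [2], E_GRID,
                                   GeneratorConfig(noise_sd=0.0))
        res = fit_ciu50(fp, 2)
        assert any("edge" in f for f in res.flags)


class TestKDE:
    def test_mode_location(self):
        rng = np.random.default_rng(3)
        d = kde_ccs(rng.normal(1000, 20, 500))
        assert d.ccs[np.argmax(d.density)] == pytest.approx(1000, abs=3)

    def test_unit_area(self):
        rng = np.random.default_rng(3)
        d = kde_ccs(rng.normal(1000, 20, 500))
        assert np.trapezoid(d.density, d.ccs) == pytest.approx(1.0, rel=1e-6)

    def test_bimodal_resolved(self):
        rng = np.random.default_rng(3)
        s = np.concatenate([rng.normal(1000, 20, 400), rng.normal(1200, 20, 400)])
        cs = detect_conformers(kde_ccs(s))
        assert len(cs) == 2

    def test_needs_two_samples(self):
        with pytest.raises(ValueError):
            kde_ccs(np.array([1000.0]))

    def test_zero_variance_warns(self):
        with pytest.warns(UserWarning):
            kde_ccs(np.full(10, 1000.0))


class TestConformers:
    def test_single_gaussian_is_alpha(self):
        g = np.linspace(900, 1100, 300)
        d = CCSDistribution(g, np.exp(-0.5 * ((g - 1000) / 20) ** 2)).normalized()
        cs = detect_conformers(d)
        assert cs.labels == ["alpha"]
        assert cs.centroids[0] == pytest.approx(1000, abs=1)

    def test_four_component_mixture(self):
        rng = np.random.default_rng(4)
        s = np.concatenate([rng.normal(950, 12, 500), rng.normal(1060, 12, 300),
                            rng.normal(1170, 12, 150), rng.normal(1280, 12, 50)])
        cs = detect_conformers(kde_ccs(s, bandwidth=0.05))
        assert cs.labels == ["alpha", "beta", "gamma", "delta"]
        np.testing.assert_allclose(cs.weights, [0.5, 0.3, 0.15, 0.05], atol=0.05)
        assert cs.weights.sum() == pytest.approx(1.0)

    def test_minor_component_detected(self):
        """A 5%-weight, well-separated extended conformer survives the
        default 5% prominence threshold."""
        g = np.linspace(900, 1320, 600)
        dens = (0.95 * np.exp(-0.5 * ((g - 1000) / 15) ** 2)
                + 0.053 * np.exp(-0.5 * ((g - 1200) / 15) ** 2))
        cs = detect_conformers(CCSDistribution(g, dens).normalized(),
                               smooth_bandwidth=0.0)
        assert len(cs) == 2
        assert cs.weights[1] == pytest.approx(0.05, abs=0.01)

    def test_no_peak_raises(self):
        g = np.linspace(900, 1100, 100)
        with pytest.raises(ValueError):
            detect_conformers(CCSDistribution(g, np.ones(100)))


class TestGatingAndInterconversion:
    @pytest.fixture()
    def two_state(self):
        g = np.linspace(900, 1300, 400)
        dens = (0.6 * np.exp(-0.5 * ((g - 1000) / 20) ** 2)
                + 0.4 * np.exp(-0.5 * ((g - 1150) / 20) ** 2))
        return CCSDistribution(g, dens).normalized()

    def test_full_window_identity(self, two_state):
        out = gate_select(two_state, (two_state.ccs[0], two_state.ccs[-1]))
        np.testing.assert_allclose(out.density, two_state.density, rtol=1e-9)

    def test_gate_on_alpha_unimodal(self, two_state):
        out = gate_select(two_state, (950.0, 1060.0))
        cs = detect_conformers(out)
        assert len(cs) == 1
        assert cs.centroids[0] == pytest.approx(1000, abs=5)

    def test_empty_window_raises(self, two_state):
        with pytest.raises(ValueError):
            gate_select(two_state, (2000.0, 2100.0))

    def test_irreversible_activation(self):
        """Activating the gated extended conformer returns no density to the
        compact region: the emulated CA-IMS-CA-IMS outcome."""
        g = np.linspace(900, 1300, 400)
        pre = CCSDistribution(g, np.exp(-0.5 * ((g - 1000) / 20) ** 2)).normalized()
        post = CCSDistribution(g, np.exp(-0.5 * ((g - 1180) / 25) ** 2)).normalized()
        m = interconversion_metric(pre, post, (950.0, 1050.0))
        assert m["irreversible"]
        assert m["fraction_compact_post"] < 0.05

    def test_identical_distributions(self, two_state):
        m = interconversion_metric(two_state, two_state, (950.0, 1060.0))
        assert m["fraction_compact_post"] == pytest.approx(
            m["fraction_compact_pre"])

    def test_fully_reverted(self):
        g = np.linspace(900, 1300, 400)
        compact = CCSDistribution(g, np.exp(-0.5 * ((g - 1000) / 20) ** 2)).normalized()
        m = interconversion_metric(compact, compact, (900.0, 1100.0))
        assert m["fraction_compact_post"] == pytest.approx(1.0, abs=1e-6)

    def test_region_outside_grid_raises(self, two_state):
        with pytest.raises(ValueError):
            interconversion_metric(two_state, two_state, (2000.0, 2100.0))
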