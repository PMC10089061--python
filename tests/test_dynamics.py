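"""Langevin engine, unfolding protocols, metadynamics and correlations."""

import numpy as np
import pandas as pd
import pytest

from conftest import double_well
from znmt import cgmodel, dynamics, metrics
from znmt.cgmodel import KB, free_beads_topology
from znmt.dynamics import (BiasSpec, MDSchedule, correlate_observables,
                           run_langevin, smd_pull, thermal_unfold,
                           wt_metadynamics)


class TestLangevin:
    def test_equipartition(self, zn7_topology, zn7_structure):
        """Mean kinetic energy per bead ~ (3/2) kB T at 300 K."""
        sched = MDSchedule(n_steps=30_000, seed=3, stride=50, temperature=300.0)
        traj = run_langevin(zn7_topology, zn7_structure.coords, sched)
        ke = traj.kinetic[60:].mean()  # discard equilibration
        expect = 1.5 * zn7_topology.n_beads * KB * 300.0
        assert ke == pytest.approx(expect, rel=0.05)

    def test_zero_friction_energy_conservation(self, zn7_topology, zn7_structure):
        sched = MDSchedule(n_steps=10_000, timestep_fs=2.0, friction_per_ps=0.0,
                           temperature=300.0, seed=5, stride=100)
        traj = run_langevin(zn7_topology, zn7_structure.coords, sched)
        E = traj.kinetic + traj.potential
        assert (E.max() - E.min()) / abs(E[0]) < 1e-3

    def test_same_seed_identical(self, zn7_topology, zn7_structure):
        sched = MDSchedule(n_steps=2000, seed=7, stride=100)
        a = run_langevin(zn7_topology, zn7_structure.coords, sched)
        b = run_langevin(zn7_topology, zn7_structure.coords, sched)
        assert np.array_equal(a.coords, b.coords)

    def test_temperature_program(self):
        sched = MDSchedule(n_steps=100, temperature=[(50, 300.0), (50, 800.0)])
        temps = sched.temperatures()
        assert temps[0] == 300.0 and temps[-1] == 800.0

    def test_invalid_schedule(self):
        with pytest.raises(ValueError):
            MDSchedule(n_steps=10, timestep_fs=-1.0)


class TestThermalUnfold:
    def test_ramp_must_increase(self, zn7_topology, zn7_structure):
        with pytest.raises(ValueError):
            thermal_unfold(zn7_topology, zn7_structure.coords, temps=(800, 300))

    def test_300k_slice_stays_compact(self, zn7_topology, zn7_structure):
        """At 300 K the Zn-loaded ion keeps its initial compact CCS."""
        sched = MDSchedule(n_steps=0, seed=2, stride=200)
        _, df = thermal_unfold(zn7_topology, zn7_structure.coords,
                               temps=(300.0, 500.0), steps_per_temp=2000,
                               schedule=sched,
                               ccs_kwargs={"n_orientations": 8, "n_mc": 1000})
        cold = df[df["T"] == 300.0]
        assert cold.ccs.iloc[1:].mean() == pytest.approx(df.ccs.iloc[0], rel=0.05)


class TestSMD:
    def test_zero_force_constant_no_unfolding(self, zn7_topology, zn7_structure):
        bias = BiasSpec(cv="rg", mode="steered", k=0.0, target_end=40.0)
        sched = MDSchedule(n_steps=1500, seed=1, stride=100)
        profiles, summary = smd_pull(zn7_topology, zn7_structure.coords, bias,
                                     sched, n_replicates=2)
        assert summary.mean == pytest.approx(0.0, abs=1e-9)
        assert profiles[0].cv[-1] == pytest.approx(profiles[0].cv[0], abs=1.5)

    def test_pull_extends_and_summary_consistent(self, zn7_topology, zn7_structure):
        bias = BiasSpec(cv="rg", mode="steered", k=50.0, target_end=35.0)
        sched = MDSchedule(n_steps=3000, seed=2, stride=100)
        profiles, summary = smd_pull(zn7_topology, zn7_structure.coords, bias,
                                     sched, n_replicates=3, compute_ccs=True,
                                     ccs_kwargs={"n_orientations": 8, "n_mc": 1000})
        assert summary.n_replicates == 3
        assert min(p.peak_force for p in profiles) <= summary.mean <= max(
            p.peak_force for p in profiles)
        p = profiles[0]
        assert p.cv[-1] > p.cv[0]          # Rg driven up
        assert p.ccs[-1] > p.ccs[0]        # projection area follows

    def test_work_matches_trapezoid(self, zn7_topology, zn7_structure):
        bias = BiasSpec(cv="rg", mode="steered", k=25.0, target_end=30.0)
        sched = MDSchedule(n_steps=1000, seed=3, stride=50)
        profiles, _ = smd_pull(zn7_topology, zn7_structure.coords, bias, sched,
                               n_replicates=1)
        p = profiles[0]
        manual = np.trapezoid(p.force_pN / cgmodel.KCAL_PER_MOL_A_TO_PN, p.cv)
        assert p.work_kcal == pytest.approx(manual, rel=1e-9)

    def test_end_to_end_cv_supported(self, zn7_topology, zn7_structure):
        bias = BiasSpec(cv="end_to_end", mode="steered", k=25.0, target_end=60.0)
        sched = MDSchedule(n_steps=500, seed=4, stride=100)
        profiles, _ = smd_pull(zn7_topology, zn7_structure.coords, bias, sched,
                               n_replicates=1)
        assert np.all(np.isfinite(profiles[0].force_pN))

    def test_requires_steered_bias(self, zn7_topology, zn7_structure):
        bias = BiasSpec(cv="rg", mode="metadynamics")
        with pytest.raises(ValueError):
            smd_pull(zn7_topology, zn7_structure.coords, bias,
                     MDSchedule(n_steps=10), 1)


class TestMetadynamics:
    def test_double_well_barrier_recovered(self):
        """Well-tempered metadynamics recovers the closed-form 2 kcal/mol
        barrier of the analytic double well within 10%."""
        top = free_beads_topology(1, masses=50.0, external=double_well(2.0, 2.0))
        bias = BiasSpec(cv="x", mode="metadynamics", hill_height=0.2,
                        hill_width=0.25, deposit_stride=200, bias_factor=8.0)
        sched = MDSchedule(n_steps=200_000, seed=0, stride=10_000)
        res = wt_metadynamics(top, np.array([[-2.0, 0, 0]]), bias, sched,
                              cv_grid=np.linspace(-4, 4, 400))
        assert res.converged
        assert res.barrier(-2.0, 2.0) == pytest.approx(2.0, rel=0.10)

    def test_flat_potential_flat_fes(self):
        """On a flat-bottomed CV region the reconstructed free energy is
        flat to within the hill-height roughness scale."""

        def flat_bottom(x):
            s = x[0, 0]
            g = np.zeros_like(x)
            if abs(s) > 3.0:
                d = abs(s) - 3.0
                g[0, 0] = 10.0 * d * np.sign(s)
                return 5.0 * d * d, g
            return 0.0, g

        top = free_beads_topology(1, masses=50.0, external=flat_bottom)
        bias = BiasSpec(cv="x", mode="metadynamics", hill_height=0.2,
                        hill_width=0.5, deposit_stride=100, bias_factor=8.0)
        sched = MDSchedule(n_steps=60_000, seed=1, stride=5000)
        res = wt_metadynamics(top, np.zeros((1, 3)), bias, sched,
                              cv_grid=np.linspace(-4, 4, 200))
        inner = np.abs(res.cv_grid) < 2.5
        assert np.ptp(res.free_energy[inner]) < 3 * bias.hill_height

    def test_hill_heights_decay(self):
        top = free_beads_topology(1, masses=50.0, external=double_well(1.0, 1.5))
        bias = BiasSpec(cv="x", mode="metadynamics", hill_height=0.3,
                        hill_width=0.25, deposit_stride=100, bias_factor=6.0)
        sched = MDSchedule(n_steps=60_000, seed=2, stride=10_000)
        res = wt_metadynamics(top, np.array([[-1.5, 0, 0]]), bias, sched)
        n = len(res.hill_heights)
        early = res.hill_heights[: n // 4].mean()
        late = res.hill_heights[-n // 4:].mean()
        assert late < early

    def test_bias_factor_validated(self):
        with pytest.raises(ValueError):
            BiasSpec(cv="x", mode="metadynamics", bias_factor=1.0)

    def test_jarzynski_consistency(self):
        """Mean steered work between the wells is >= the metadynamics
        free-energy difference between the same endpoints (= 0 by
        symmetry), within noise."""
        pot = double_well(2.0, 2.0)
        top = free_beads_topology(1, masses=50.0, external=pot)
        bias = BiasSpec(cv="x", mode="steered", k=20_000.0,  # stiff spring
                        target_start=-2.0, target_end=2.0)
        sched = MDSchedule(n_steps=5000, seed=3, stride=50)
        profiles, _ = smd_pull(top, np.array([[-2.0, 0, 0]]), bias, sched,
                               n_replicates=25)
        works = np.array([p.work_kcal for p in profiles])
        assert works.mean() >= 0.0 - 3 * works.std() / np.sqrt(len(works))


class TestCorrelations:
    def test_perfect_linear(self):
        df = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [2.0, 4, 6, 8]})
        out = correlate_observables(df)
        assert out.r.iloc[0] == pytest.approx(1.0)

    def test_anticorrelated(self):
        df = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [8.0, 6, 4, 2]})
        assert correlate_observables(df).r.iloc[0] == pytest.approx(-1.0)

    def test_independent_columns_weak(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({"a": rng.normal(size=4), "b": rng.normal(size=4)})
        out = correlate_observables(df)
        assert abs(out.r.iloc[0]) < 0.95 and out.p.iloc[0] > 0.05

    def test_constant_column_flagged(self):
        df = pd.DataFrame({"a": [1.0, 1, 1, 1], "b": [1.0, 2, 3, 4]})
        out = correlate_observables(df)
        assert np.isnan(out.r.iloc[0]) and out.flag.iloc[0] == "constant column"

    def test_needs_three_species(self):
        with pytest.raises(ValueError):
            correlate_observables(pd.DataFrame({"a": [1, 2], "b": [3, 4]}))


class TestObservableCoupling:
    def test_rg_ccs_positive_correlation(self, apo_structure):
        """On an unfolding (thermal ramp) trajectory the radius of gyration
        tracks the projection CCS."""
        top = cgmodel.build_topology(apo_structure, z=5)
        sched = MDSchedule(n_steps=0, seed=2, stride=200)
        _, df = thermal_unfold(top, apo_structure.coords,
                               temps=(300.0, 800.0), steps_per_temp=4000,
                               schedule=sched,
                               ccs_kwargs={"n_orientations": 8, "n_mc": 1000})
        r = np.corrcoef(df.rg, df.ccs)[0, 1]
        assert r > 0.5

    def test_timeseries_alignment(self, zn7_topology, zn7_structure):
        sched = MDSchedule(n_steps=1000, seed=1, stride=100)
        traj = run_langevin(zn7_topology, zn7_structure.coords, sched)
        rg = metrics.timeseries(metrics.radius_of_gyration, traj)
        assert len(rg) == traj.n_frames
        assert np.all(rg > 0)
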