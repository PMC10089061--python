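"""End-to-end stages: species fitting, CIU analysis, CG unfolding.

Each stage reads/creates its inputs (real files or the synthetic
generators), runs the corresponding analysis and writes plain CSV/JSON
next to a copy of the effective configuration, so any run is reproducible
from its output directory alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cgmodel, dynamics, imms, isotopes, metrics, synthetic

log = logging.getLogger("znmt")

#: transition midpoints (eV) used for the synthetic CIU ground truth:
#: the Zn2Cys6/Zn3Cys9 clusters share ~90 eV stability; formation of the
#: Zn4Cys11 cluster raises the transition to ~110 eV.
CIU50_GROUND_TRUTH = {4: 90.0, 5: 90.0, 6: 110.0, 7: 110.0}
#: pre/post-activation CCS centroids (A^2) of the Zn-loaded 5+ species
CCS_STATES = (1000.0, 1150.0)
#: oxidized-species disulfide ground truth per Zn loading
SS_GROUND_TRUTH = {4: 8, 5: 8, 6: 7, 7: 2}


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "results"
    # ms stage
    ms_charges: tuple[int, ...] = (3, 4, 5)
    ms_noise_sd: float = 0.0
    ms_resolution: float = 10_000.0
    # ciu stage
    ciu_energies: tuple[float, float, float] = (50.0, 150.0, 2.5)  # lo, hi, step
    ciu_noise_sd: float = 0.02
    ciu_state_widths: tuple[float, float] = (25.0, 25.0)
    # sim stage
    sim_species: tuple[int, ...] = (0, 4, 7)
    sim_temps: tuple[float, ...] = (300.0, 500.0, 800.0)
    sim_steps_per_temp: int = 6000
    sim_smd_steps: int = 4000
    sim_replicates: int = 25
    sim_force_constant: float = 25.0   # kcal/mol/nm^2

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        d = json.loads(Path(path).read_text())
        d = {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}
        return cls(**d)


def _prepare(config: PipelineConfig, stage: str) -> Path:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.dump(out / f"config_{stage}.json")
    return out


def run_ms_stage(config: PipelineConfig) -> pd.DataFrame:
    """Species table from (synthetic) native mass spectra.

    For each charge state and Zn loading, a spectrum is generated with a
    known disulfide count (0 for reduced, the per-species ground truth for
    oxidized), then the grid-search fit recovers (n_ss, retention). The
    charge-state distribution summary lists the charges present.
    """
    out = _prepare(config, "ms")
    seq = synthetic.mt2_sequence()
    base = isotopes.composition_from_sequence(seq)
    cfg = synthetic.GeneratorConfig(seed=config.seed, noise_sd=config.ms_noise_sd,
                                    resolution=config.ms_resolution)
    rows = []
    for n_zn in (0,) + tuple(sorted(SS_GROUND_TRUTH)):
        for redox, n_ss in (("red", 0), ("ox", SS_GROUND_TRUTH.get(n_zn, 0))):
            if n_zn == 0 and redox == "ox":
                continue
            for z in config.ms_charges:
                sp = isotopes.apply_species(base, n_zn=n_zn, n_ss=n_ss, z=z)
                spec = synthetic.synth_spectrum([sp], [1.0], cfg)
                fit = isotopes.fit_species(spec, base, n_zn=n_zn, z=z,
                                           resolution=config.ms_resolution)
                rows.append({"n_zn": n_zn, "z": z, "redox": redox,
                             "true_n_ss": n_ss, "fit_n_ss": fit.best_n_ss,
                             "fit_retention": fit.best_retention,
                             "mz": sp.mz()})
    table = pd.DataFrame(rows)
    table.to_csv(out / "species_fits.csv", index=False)
    csd = (table.groupby(["n_zn", "redox"])["z"]
           .agg(["min", "max"]).reset_index()
           .rename(columns={"min": "z_min", "max": "z_max"}))
    csd.to_csv(out / "csd_summary.csv", index=False)
    log.info("ms stage: %d species fitted", len(table))
    return table


def run_ciu_stage(config: PipelineConfig) -> pd.DataFrame:
    """Fingerprints + fitted CIU50 table for the Zn4..Zn7 ladder."""
    out = _prepare(config, "ciu")
    lo, hi, step = config.ciu_energies
    energies = np.arange(lo, hi + step / 2, step)
    rows = []
    for i, (n_zn, mid) in enumerate(sorted(CIU50_GROUND_TRUTH.items())):
        cfg = synthetic.GeneratorConfig(seed=config.seed + i,
                                        noise_sd=config.ciu_noise_sd)
        fp = synthetic.synth_ciu_fingerprint(
            list(CCS_STATES), list(config.ciu_state_widths),
            [mid], [4.0], energies, cfg)
        fp.to_csv(out / f"fingerprint_zn{n_zn}.csv")
        res = imms.fit_ciu50(fp, n_states=2)
        if len(res.midpoints_eV):
            rows.append({"n_zn": n_zn, "true_ciu50_eV": mid,
                         "fit_ciu50_eV": float(res.midpoints_eV[0]),
                         "width_eV": float(res.widths_eV[0]),
                         "converged": res.converged})
    table = pd.DataFrame(rows)
    table.to_csv(out / "ciu50_table.csv", index=False)
    return table


def run_sim_stage(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    """CG unfolding report: thermal KDE slices, SMD forces, correlations."""
    out = _prepare(config, "sim")
    seq = synthetic.mt2_sequence()
    thermal_rows, force_rows, obs_rows = [], [], []
    for n_zn in config.sim_species:
        cmap = synthetic.cluster_map(n_zn)
        struct = synthetic.make_dumbbell_structure(
            seq, cmap, synthetic.GeneratorConfig(seed=config.seed + n_zn))
        top = cgmodel.build_topology(struct, cmap, z=5)
        sched = dynamics.MDSchedule(n_steps=0, seed=config.seed + n_zn, stride=200)
        _, df = dynamics.thermal_unfold(
            top, struct.coords, temps=config.sim_temps,
            steps_per_temp=config.sim_steps_per_temp, schedule=sched)
        df.insert(0, "n_zn", n_zn)
        thermal_rows.append(df)

        bias = dynamics.BiasSpec(cv="rg", mode="steered",
                                 k=config.sim_force_constant,
                                 target_end=35.0)
        profiles, summary = dynamics.smd_pull(
            top, struct.coords, bias,
            dynamics.MDSchedule(n_steps=config.sim_smd_steps,
                                seed=config.seed + 100 + n_zn, stride=100),
            n_replicates=config.sim_replicates)
        for r, p in enumerate(profiles):
            force_rows.append({"n_zn": n_zn, "replicate": r,
                               "peak_force_pN": p.peak_force,
                               "work_kcal": p.work_kcal})
        graph = metrics.zn_s_graph(struct)
        obs_rows.append({"n_zn": n_zn, "zn_s_bonds": graph.n_edges,
                         "mean_force_pN": summary.mean, "sd_force_pN": summary.sd,
                         "n_replicates": summary.n_replicates})
    thermal = pd.concat(thermal_rows, ignore_index=True)
    forces = pd.DataFrame(force_rows)
    obs = pd.DataFrame(obs_rows)
    thermal.to_csv(out / "thermal_ccs.csv", index=False)
    forces.to_csv(out / "smd_forces.csv", index=False)
    obs.to_csv(out / "species_observables.csv", index=False)
    if len(obs) >= 3:
        corr = dynamics.correlate_observables(
            obs[["n_zn", "zn_s_bonds", "mean_force_pN"]])
        corr.to_csv(out / "correlations.csv", index=False)
    return {"thermal": thermal, "forces": forces, "observables": obs}
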