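"""Langevin dynamics and the gas-phase unfolding protocols.

Three protocols mirror how collision-induced unfolding is emulated in
silico for metallothionein ions:

* ``thermal_unfold`` — stepwise temperature ramp (e.g. 300 -> 500 -> 800 K)
  with a projection-approximation CCS read-out per stored frame,
* ``smd_pull`` — steered MD: a harmonic restraint on a collective variable
  (radius of gyration or N-C end-to-end distance) whose target moves
  linearly in time; pulling force profiles and per-replicate peak forces
  are the observables (default 25 replicates),
* ``wt_metadynamics`` — well-tempered metadynamics on the same CV: Gaussian
  hills with height scaled by exp(-V/((gamma-1) kB T)) reconstruct the free
  energy as -(gamma/(gamma-1)) V_bias.

Integration is BAOAB-discretized Langevin dynamics; with zero friction it
reduces to velocity Verlet, which the energy-conservation checks use.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .cgmodel import (AKMA_FS, CV_FUNCS, KB, KCAL_PER_MOL_A_TO_PN, CGTopology,
                      potential_energy)


@dataclass
class MDSchedule:
    """Integration schedule; temperatures in K, timestep in fs."""

    n_steps: int
    timestep_fs: float = 10.0
    friction_per_ps: float = 1.0
    temperature: float | Sequence[tuple[int, float]] = 300.0
    seed: int = 0
    stride: int = 100

    def __post_init__(self) -> None:
        if self.timestep_fs <= 0:
            raise ValueError("timestep must be positive")
        for t in self.temperatures():
            if t < 0:
                raise ValueError("temperatures must be >= 0")

    def temperatures(self) -> np.ndarray:
        """Per-step temperature array."""
        if np.isscalar(self.temperature):
            return np.full(self.n_steps, float(self.temperature))
        out = np.empty(self.n_steps)
        pos = 0
        for steps, temp in self.temperature:
            out[pos: pos + steps] = temp
            pos += steps
        if pos < self.n_steps:
            out[pos:] = out[pos - 1]
        return out[: self.n_steps]


@dataclass
class BiasSpec:
    """Bias on a collective variable.

    ``k`` is the steering force constant in kcal/mol/nm^2 (the presets used
    for pulling are 10, 25 and 50); it is converted to Angstrom units
    internally. For metadynamics, ``hill_height`` is in kcal/mol,
    ``hill_width`` in CV units (Angstrom) and ``bias_factor`` is the
    well-tempered gamma (> 1).
    """

    cv: str = "rg"
    mode: str = "steered"
    k: float = 25.0
    target_start: float | None = None
    target_end: float | None = None
    hill_height: float = 0.5
    hill_width: float = 1.0
    deposit_stride: int = 250
    bias_factor: float = 10.0

    def __post_init__(self) -> None:
        if self.cv not in CV_FUNCS:
            raise ValueError(f"unknown CV {self.cv!r}")
        if self.mode not in ("steered", "metadynamics"):
            raise ValueError(f"unknown bias mode {self.mode!r}")
        if self.mode == "metadynamics" and self.bias_factor <= 1:
            raise ValueError("well-tempered bias factor must exceed 1")

    @property
    def k_per_A2(self) -> float:
        return self.k * 0.01  # kcal/mol/nm^2 -> kcal/mol/A^2


@dataclass
class Trajectory:
    """Stored frames of one run."""

    coords: np.ndarray          # (F, n, 3)
    times_ps: np.ndarray
    temperatures: np.ndarray
    cv: np.ndarray
    kinetic: np.ndarray         # kcal/mol
    potential: np.ndarray       # total, kcal/mol
    energy_terms: dict[str, np.ndarray]
    bias_force: np.ndarray | None = None   # kcal/mol/A, signed (steered runs)
    stride: int = 1

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]


class EnergyDivergence(RuntimeError):
    def __init__(self, step: int, coords: np.ndarray):
        super().__init__(f"energy diverged at step {step}")
        self.step = step
        self.coords = coords


def _hills_energy_force(s: float, centers: np.ndarray, heights: np.ndarray,
                        width: float) -> tuple[float, float]:
    if len(centers) == 0:
        return 0.0, 0.0
    d = s - centers
    g = heights * np.exp(-0.5 * (d / width) ** 2)
    return float(g.sum()), float(np.sum(-g * d / width ** 2))


def run_langevin(top: CGTopology, x0: np.ndarray, schedule: MDSchedule,
                 bias: BiasSpec | None = None,
                 v0: np.ndarray | None = None,
                 _collect_hills: list | None = None) -> Trajectory:
    """BAOAB Langevin integration with optional CV bias.

    Deterministic under ``schedule.seed``. Frames (coordinates, CV,
    per-term energies, kinetic energy and — for steered runs — the signed
    restraint force along the CV) are stored every ``schedule.stride``
    steps, including step 0.
    """
    rng = np.random.default_rng(schedule.seed)
    x = np.array(x0, float)
    n = x.shape[0]
    m = top.masses[:, None]
    dt = schedule.timestep_fs / AKMA_FS
    gamma = schedule.friction_per_ps * (AKMA_FS / 1000.0)
    temps = schedule.temperatures()
    c1 = np.exp(-gamma * dt)
    cv_fun = CV_FUNCS[bias.cv] if bias is not None else None
    subset = top.protein_beads

    if v0 is not None:
        v = np.array(v0, float)
    elif temps[0] > 0:
        v = rng.normal(0, 1, x.shape) * np.sqrt(KB * temps[0] / top.masses)[:, None]
    else:
        v = np.zeros_like(x)

    hill_centers: list[float] = []
    hill_heights: list[float] = []

    def eval_forces(x, step):
        e, f = potential_energy(top, x, return_forces=True)
        fb = 0.0
        s = np.nan
        if bias is not None:
            s, grad = cv_fun(x, top.masses, subset)
            if bias.mode == "steered":
                t0 = bias.target_start if bias.target_start is not None else s0_init
                t1 = bias.target_end if bias.target_end is not None else t0
                target = t0 + (t1 - t0) * step / max(schedule.n_steps, 1)
                fb = -bias.k_per_A2 * (s - target)   # restraint force along CV
                f += fb * grad
                e["bias"] = 0.5 * bias.k_per_A2 * (s - target) ** 2
            else:
                vb, dvds = _hills_energy_force(
                    s, np.asarray(hill_centers), np.asarray(hill_heights), bias.hill_width)
                f += -dvds * grad
                e["bias"] = vb
        return e, f, fb, s

    s0_init, _ = cv_fun(x, top.masses, subset) if cv_fun else (0.0, None)
    e, f, fb, s = eval_forces(x, 0)

    frames, times, Ts, cvs, kes, pes, fbs = [], [], [], [], [], [], []
    terms: dict[str, list] = {}

    def record(step, e, fb, s):
        frames.append(x.copy())
        times.append(step * schedule.timestep_fs / 1000.0)
        Ts.append(temps[min(step, len(temps) - 1)])
        cvs.append(s)
        kes.append(0.5 * float(np.sum(top.masses * np.sum(v ** 2, axis=1))))
        pes.append(e["total"])
        fbs.append(fb)
        for k_, v_ in e.items():
            terms.setdefault(k_, []).append(v_)

    record(0, e, fb, s)
    for step in range(1, schedule.n_steps + 1):
        T = temps[step - 1]
        v += 0.5 * dt * f / m
        x += 0.5 * dt * v
        if gamma > 0:
            c2 = np.sqrt((1 - c1 ** 2) * KB * T / top.masses)[:, None]
            v = c1 * v + c2 * rng.normal(0, 1, x.shape)
        x += 0.5 * dt * v
        if (bias is not None and bias.mode == "metadynamics"
                and step % bias.deposit_stride == 0):
            s_now, _ = cv_fun(x, top.masses, subset)
            vb, _ = _hills_energy_force(
                s_now, np.asarray(hill_centers), np.asarray(hill_heights), bias.hill_width)
            h = bias.hill_height * np.exp(-vb / ((bias.bias_factor - 1) * KB * max(T, 1.0)))
            hill_centers.append(s_now)
            hill_heights.append(h)
        e, f, fb, s = eval_forces(x, step)
        v += 0.5 * dt * f / m
        if not np.isfinite(e["total"]) or abs(e["total"]) > 1e12:
            raise EnergyDivergence(step, x)
        if step % schedule.stride == 0:
            record(step, e, fb, s)

    if _collect_hills is not None:
        _collect_hills.append((np.asarray(hill_centers), np.asarray(hill_heights)))
    return Trajectory(
        coords=np.asarray(frames), times_ps=np.asarray(times),
        temperatures=np.asarray(Ts), cv=np.asarray(cvs),
        kinetic=np.asarray(kes), potential=np.asarray(pes),
        energy_terms={k_: np.asarray(v_) for k_, v_ in terms.items()},
        bias_force=np.asarray(fbs) if bias is not None and bias.mode == "steered" else None,
        stride=schedule.stride,
    )


# --------------------------------------------------------------------------
# protocols


def traj_ccs(top: CGTopology, traj: Trajectory, n_orientations: int = 12,
             n_mc: int = 1500, seed: int = 0) -> np.ndarray:
    """Projection CCS per stored frame (the engine's CCS read-out)."""
    from .ccs import pa_ccs

    rng = np.random.default_rng(seed)
    out = np.empty(traj.n_frames)
    for i in range(traj.n_frames):
        out[i], _ = pa_ccs(traj.coords[i], top.radii, n_orientations=n_orientations,
                           n_mc=n_mc, seed=rng)
    return out


def thermal_unfold(top: CGTopology, x0: np.ndarray,
                   temps: Sequence[float] = (300.0, 500.0, 800.0),
                   steps_per_temp: int = 20_000,
                   schedule: MDSchedule | None = None,
                   ccs_kwargs: dict | None = None) -> tuple[Trajectory, pd.DataFrame]:
    """Stepwise thermal ramp with per-frame CCS.

    Returns the trajectory and a tidy frame (time_ps, T, cv/Rg, ccs); KDE
    slices per temperature are obtained downstream (``imms.kde_ccs`` on the
    rows of one temperature).
    """
    if any(np.diff(temps) <= 0):
        raise ValueError("temperature ramp must be increasing")
    base = schedule or MDSchedule(n_steps=0)
    program = [(steps_per_temp, float(t)) for t in temps]
    sched = MDSchedule(n_steps=steps_per_temp * len(temps),
                       timestep_fs=base.timestep_fs,
                       friction_per_ps=base.friction_per_ps,
                       temperature=program, seed=base.seed, stride=base.stride)
    traj = run_langevin(top, x0, sched, bias=BiasSpec(cv="rg", mode="steered", k=0.0))
    ccs = traj_ccs(top, traj, seed=sched.seed, **(ccs_kwargs or {}))
    df = pd.DataFrame({"time_ps": traj.times_ps, "T": traj.temperatures,
                       "rg": traj.cv, "ccs": ccs})
    return traj, df


@dataclass
class ForceProfile:
    """Pulling force vs time/CV/CCS from one steered replicate."""

    times_ps: np.ndarray
    cv: np.ndarray
    force_pN: np.ndarray
    ccs: np.ndarray | None = None

    @property
    def peak_force(self) -> float:
        return float(np.max(np.abs(self.force_pN)))

    @property
    def work_kcal(self) -> float:
        """Work done by the restraint, trapezoid over stored samples."""
        f = -self.force_pN / KCAL_PER_MOL_A_TO_PN  # force applied to the ion
        return float(np.trapezoid(-f, self.cv))


@dataclass
class UnfoldingForceSummary:
    peak_forces: np.ndarray
    n_replicates: int

    @property
    def mean(self) -> float:
        return float(np.mean(self.peak_forces))

    @property
    def sd(self) -> float:
        return float(np.std(self.peak_forces, ddof=1)) if self.n_replicates > 1 else 0.0


def smd_pull(top: CGTopology, x0: np.ndarray, bias: BiasSpec,
             schedule: MDSchedule, n_replicates: int = 25,
             compute_ccs: bool = False,
             ccs_kwargs: dict | None = None) -> tuple[list[ForceProfile], UnfoldingForceSummary]:
    """Steered pulls over seeded replicates with a force/CCS read-out."""
    if bias.mode != "steered":
        raise ValueError("smd_pull requires a steered bias")
    if bias.k < 0:
        raise ValueError("force constant must be >= 0")
    profiles = []
    for rep in range(n_replicates):
        sched = MDSchedule(n_steps=schedule.n_steps, timestep_fs=schedule.timestep_fs,
                           friction_per_ps=schedule.friction_per_ps,
                           temperature=schedule.temperature,
                           seed=schedule.seed + rep, stride=schedule.stride)
        traj = run_langevin(top, x0, sched, bias=bias)
        ccs = traj_ccs(top, traj, seed=sched.seed, **(ccs_kwargs or {})) if compute_ccs else None
        profiles.append(ForceProfile(
            times_ps=traj.times_ps, cv=traj.cv,
            force_pN=traj.bias_force * KCAL_PER_MOL_A_TO_PN, ccs=ccs))
    summary = UnfoldingForceSummary(
        peak_forces=np.array([p.peak_force for p in profiles]),
        n_replicates=n_replicates)
    return profiles, summary


@dataclass
class MetadynamicsResult:
    cv_grid: np.ndarray
    free_energy: np.ndarray      # kcal/mol, min-shifted to 0
    hill_centers: np.ndarray
    hill_heights: np.ndarray
    converged: bool

    def barrier(self, a: float, b: float) -> float:
        """Free-energy barrier between CV minima near a and b (max between)."""
        g = self.cv_grid
        ia, ib = np.argmin(np.abs(g - a)), np.argmin(np.abs(g - b))
        lo, hi = sorted((ia, ib))
        inner = self.free_energy[lo:hi + 1]
        return float(inner.max() - min(self.free_energy[ia], self.free_energy[ib]))


def wt_metadynamics(top: CGTopology, x0: np.ndarray, bias: BiasSpec,
                    schedule: MDSchedule,
                    cv_grid: np.ndarray | None = None) -> MetadynamicsResult:
    """Well-tempered metadynamics free-energy estimate along the CV.

    F(s) = -(gamma/(gamma-1)) * V_bias(s), min-shifted. Convergence is
    diagnosed from hill-height decay: the run is flagged converged when the
    mean height of the last tenth of the hills has dropped below half the
    initial height.
    """
    if bias.mode != "metadynamics":
        raise ValueError("requires a metadynamics bias")
    collected: list = []
    traj = run_langevin(top, x0, schedule, bias=bias, _collect_hills=collected)
    centers, heights = collected[0]
    if cv_grid is None:
        lo, hi = centers.min() - 3 * bias.hill_width, centers.max() + 3 * bias.hill_width
        cv_grid = np.linspace(lo, hi, 400)
    g = bias.bias_factor
    # time-averaged estimator: average the min-shifted FES over the second
    # half of the deposition history (reduces hill-noise variance)
    vb = np.zeros_like(cv_grid)
    fes_acc = np.zeros_like(cv_grid)
    n_avg = 0
    half = len(centers) // 2
    for i, (c, h) in enumerate(zip(centers, heights)):
        vb += h * np.exp(-0.5 * ((cv_grid - c) / bias.hill_width) ** 2)
        if i >= half:
            f = -(g / (g - 1.0)) * vb
            fes_acc += f - f.min()
            n_avg += 1
    fes = fes_acc / max(n_avg, 1) if n_avg else -(g / (g - 1.0)) * vb
    fes -= fes.min()
    ntail = max(len(heights) // 10, 1)
    converged = bool(len(heights) > 10 and
                     heights[-ntail:].mean() < 0.5 * bias.hill_height)
    return MetadynamicsResult(cv_grid=cv_grid, free_energy=fes,
                              hill_centers=centers, hill_heights=heights,
                              converged=converged)


def correlate_observables(table: pd.DataFrame,
                          pairs: list[tuple[str, str]] | None = None) -> pd.DataFrame:
    """Pearson correlations between per-species observables.

    ``table`` holds one row per species (needs >= 3) and one column per
    observable (h-bond count, Zn-S bond count, mean unfolding force, free
    energy, ...). Constant columns yield r = NaN with a flag.
    """
    from scipy.stats import pearsonr

    if len(table) < 3:
        raise ValueError("need at least 3 species to correlate")
    cols = list(table.columns)
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(cols) for b in cols[i + 1:]]
    rows = []
    for a, b in pairs:
        xa, xb = table[a].to_numpy(float), table[b].to_numpy(float)
        if np.ptp(xa) == 0 or np.ptp(xb) == 0:
            rows.append({"x": a, "y": b, "r": np.nan, "p": np.nan, "flag": "constant column"})
            continue
        r, p = pearsonr(xa, xb)
        rows.append({"x": a, "y": b, "r": float(r), "p": float(p), "flag": ""})
    return pd.DataFrame(rows)
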