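"""Travelling-wave ion mobility analysis and collision-induced unfolding.

A TWIMS measurement yields arrival-time distributions (ATDs) per collision
energy. Calibration against standards of known CCS follows the usual
power-law protocol: corrected drift time t' = t - c*sqrt(m/z), corrected
CCS' = CCS*sqrt(mu)/z with mu the ion-gas reduced mass, and a log-log fit
CCS' = A * t'^B.

Stacking calibrated CCS distributions over collision energy gives a CIU
fingerprint. The CIU50 of each transition — the energy at which half the
ions have moved to the next conformer family — is obtained by fitting the
intensity-weighted CCS centroid per energy with a sum of logistic steps
between fitted plateau levels (the convention popularized by CIUSuite).
Conformer families (labelled alpha, beta, gamma, ... by ascending CCS) are
picked from KDE-smoothed CCS distributions and refined as a Gaussian
mixture. Gating utilities emulate the selection logic of multistage
(IMS-CA-IMS) cyclic-IM experiments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde

N2_MASS = 28.0134
HE_MASS = 4.0026


# --------------------------------------------------------------------------
# containers


@dataclass
class ATD:
    """Arrival-time distribution for one species at one collision energy."""

    times_ms: np.ndarray
    intensity: np.ndarray
    z: int
    mass: float
    energy_eV: float = 0.0

    def __post_init__(self) -> None:
        self.times_ms = np.asarray(self.times_ms, float)
        self.intensity = np.asarray(self.intensity, float)
        if np.any(np.diff(self.times_ms) <= 0):
            raise ValueError("arrival times must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("negative intensities")

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#z={self.z}\n#mass={self.mass}\n#energy_eV={self.energy_eV}\n")
            pd.DataFrame({"time_ms": self.times_ms,
                          "intensity": self.intensity}).to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ATD":
        meta = {}
        with open(path) as fh:
            lines = fh.readlines()
        for ln in lines:
            if ln.startswith("#") and "=" in ln:
                k, v = ln[1:].strip().split("=", 1)
                meta[k] = float(v)
        df = pd.read_csv(path, comment="#")
        return cls(times_ms=df.iloc[:, 0].to_numpy(), intensity=df.iloc[:, 1].to_numpy(),
                   z=int(meta.get("z", 1)), mass=meta.get("mass", 0.0),
                   energy_eV=meta.get("energy_eV", 0.0))


@dataclass
class CCSDistribution:
    """Normalized (unit-area) CCS density for one species/energy."""

    ccs: np.ndarray
    density: np.ndarray
    z: int = 0
    energy_eV: float = 0.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ccs = np.asarray(self.ccs, float)
        self.density = np.asarray(self.density, float)
        if np.any(np.diff(self.ccs) <= 0):
            raise ValueError("CCS grid must be strictly increasing")
        if np.any(self.density < 0):
            raise ValueError("negative density")

    def normalized(self) -> "CCSDistribution":
        area = np.trapezoid(self.density, self.ccs)
        if area <= 0:
            raise ValueError("empty distribution")
        return CCSDistribution(self.ccs, self.density / area, self.z,
                               self.energy_eV, dict(self.metadata))

    @property
    def centroid(self) -> float:
        return float(np.trapezoid(self.ccs * self.density, self.ccs)
                     / np.trapezoid(self.density, self.ccs))


@dataclass
class CIUFingerprint:
    """CCS x collision-energy intensity matrix, each energy column max 1."""

    ccs_grid: np.ndarray
    energies_eV: np.ndarray
    matrix: np.ndarray           # (n_ccs, n_energies)
    normalization: str = "column-max"

    def __post_init__(self) -> None:
        self.ccs_grid = np.asarray(self.ccs_grid, float)
        self.energies_eV = np.asarray(self.energies_eV, float)
        self.matrix = np.asarray(self.matrix, float)
        if self.matrix.shape != (len(self.ccs_grid), len(self.energies_eV)):
            raise ValueError("matrix shape mismatch")

    def column(self, j: int) -> CCSDistribution:
        return CCSDistribution(self.ccs_grid, self.matrix[:, j],
                               energy_eV=float(self.energies_eV[j]))

    def centroid_curve(self) -> np.ndarray:
        w = self.matrix.sum(axis=0)
        return (self.ccs_grid[:, None] * self.matrix).sum(axis=0) / np.where(w > 0, w, 1.0)

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.matrix, index=self.ccs_grid,
                          columns=self.energies_eV)
        df.index.name = "ccs_A2"
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CIUFingerprint":
        df = pd.read_csv(path, index_col=0)
        return cls(ccs_grid=df.index.to_numpy(float),
                   energies_eV=np.array([float(c) for c in df.columns]),
                   matrix=df.to_numpy(float))


# --------------------------------------------------------------------------
# calibration


@dataclass
class TWCalibration:
    """Power-law TW calibration CCS' = A * t'^B."""

    A: float
    B: float
    gas_mass: float = N2_MASS
    edc: float = 1.41e-3         # ms per sqrt(Th); t' = t - edc*sqrt(m/z)
    r2: float = 1.0
    calibrants: pd.DataFrame | None = None
    time_span: tuple[float, float] = (0.0, np.inf)

    @property
    def accepted(self) -> bool:
        return self.r2 >= 0.98

    def _mu_factor(self, z: int, mass: float) -> float:
        mu = mass * self.gas_mass / (mass + self.gas_mass)
        return np.sqrt(mu) / z

    def ccs_from_time(self, t_ms, z: int, mass: float):
        tp = np.asarray(t_ms, float) - self.edc * np.sqrt(mass / z)
        if np.any(tp <= 0):
            raise ValueError("negative corrected drift time")
        return self.A * tp ** self.B / self._mu_factor(z, mass)

    def time_from_ccs(self, ccs, z: int, mass: float):
        ccsp = np.asarray(ccs, float) * self._mu_factor(z, mass)
        return (ccsp / self.A) ** (1.0 / self.B) + self.edc * np.sqrt(mass / z)


def calibrate_tw(calibrants: list[tuple[float, float, int, float]],
                 gas_mass: float = N2_MASS, edc: float = 1.41e-3) -> TWCalibration:
    """Fit the TW power law to (drift time ms, reference CCS A^2, z, mass).

    Log-log least squares on corrected times/CCS; the fit R^2 is recorded
    and the calibration is only ``accepted`` at R^2 >= 0.98.
    """
    if len(calibrants) < 3:
        raise ValueError("need at least 3 calibrant points")
    t, ccs, zz, mm = map(np.asarray, zip(*calibrants))
    tp = t - edc * np.sqrt(mm / zz)
    if np.any(tp <= 0):
        raise ValueError("negative corrected drift time among calibrants")
    mu = mm * gas_mass / (mm + gas_mass)
    ccsp = ccs * np.sqrt(mu) / zz
    lx, ly = np.log(tp), np.log(ccsp)
    if np.ptp(lx) < 1e-12:
        raise ValueError("calibrant drift times are rank-deficient (identical)")
    B, lnA = np.polyfit(lx, ly, 1)
    pred = lnA + B * lx
    ss_res = float(np.sum((ly - pred) ** 2))
    ss_tot = float(np.sum((ly - ly.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    table = pd.DataFrame({"t_ms": t, "ccs_A2": ccs, "z": zz, "mass_Da": mm})
    return TWCalibration(A=float(np.exp(lnA)), B=float(B), gas_mass=gas_mass,
                         edc=edc, r2=r2, calibrants=table,
                         time_span=(float(t.min()), float(t.max())))


def atd_to_ccsd(atd: ATD, cal: TWCalibration) -> CCSDistribution:
    """Transform an ATD through the calibration power law.

    The density is re-expressed per unit CCS with the Jacobian dt/dCCS so
    that unit area is preserved; points outside the calibrant time span are
    flagged as extrapolation in the metadata.
    """
    if not cal.accepted:
        raise ValueError(f"calibration rejected (R^2 = {cal.r2:.4f} < 0.98)")
    ccs = cal.ccs_from_time(atd.times_ms, atd.z, atd.mass)
    jac = np.gradient(atd.times_ms, ccs)    # dt/dCCS
    density = atd.intensity * np.abs(jac)
    extrap = bool(atd.times_ms.min() < cal.time_span[0]
                  or atd.times_ms.max() > cal.time_span[1])
    out = CCSDistribution(ccs=ccs, density=density, z=atd.z,
                          energy_eV=atd.energy_eV,
                          metadata={"extrapolated": extrap})
    return out.normalized()


# --------------------------------------------------------------------------
# fingerprints and CIU50


def build_fingerprint(ccsds: list[CCSDistribution],
                      grid: np.ndarray | None = None) -> CIUFingerprint:
    """Stack per-energy CCS distributions into a column-normalized matrix."""
    energies = [c.energy_eV for c in ccsds]
    if len(set(energies)) != len(energies):
        raise ValueError("duplicate collision-energy labels")
    order = np.argsort(energies)
    if grid is None:
        grid = ccsds[order[0]].ccs
    cols = []
    for j in order:
        c = ccsds[j]
        y = np.interp(grid, c.ccs, c.density, left=0.0, right=0.0)
        top = y.max()
        cols.append(y / top if top > 0 else y)
    return CIUFingerprint(ccs_grid=np.asarray(grid, float),
                          energies_eV=np.asarray(sorted(energies), float),
                          matrix=np.column_stack(cols))


@dataclass
class CIU50Result:
    midpoints_eV: np.ndarray
    widths_eV: np.ndarray
    plateaus_A2: np.ndarray      # n_states CCS levels
    covariance: np.ndarray | None
    residual: float
    converged: bool = True
    flags: list[str] = field(default_factory=list)


def _sequential_logistic(E, *params):
    # params: L0..L_{n-1}, m_1..m_{n-1}, w_1..w_{n-1}
    n = (len(params) + 1) // 3 + 0  # solves 3n-2 = len(params)
    n = (len(params) + 2) // 3
    L = np.asarray(params[:n])
    m = np.asarray(params[n:2 * n - 1])
    w = np.asarray(params[2 * n - 1:])
    out = np.full_like(np.asarray(E, float), L[0])
    for k in range(n - 1):
        out = out + (L[k + 1] - L[k]) / (1.0 + np.exp(-(E - m[k]) / w[k]))
    return out


def fit_ciu50(fp: CIUFingerprint, n_states: int = 2) -> CIU50Result:
    """Fit CIU50 transition midpoints from a fingerprint.

    The intensity-weighted CCS centroid per energy column is fitted with a
    sum of ``n_states - 1`` logistic steps between fitted plateau levels.
    Midpoints are initialized at the steepest-gradient energies, plateaus
    at the first/last column centroids, and bounded by the energy span.
    """
    if n_states < 2:
        raise ValueError("need at least 2 states for a CIU transition")
    E = fp.energies_eV
    c = fp.centroid_curve()
    span = (E.min(), E.max())
    grad = np.abs(np.gradient(c, E))
    # initial midpoints: highest-gradient energies, kept ordered
    idx = np.argsort(grad)[::-1]
    mids = np.sort(E[idx[: n_states - 1]].astype(float))
    L0 = np.linspace(c[0], c[-1], n_states)
    w0 = np.full(n_states - 1, (span[1] - span[0]) / 20.0)
    p0 = np.concatenate([L0, mids, w0])
    lb = np.concatenate([np.full(n_states, c.min() - np.ptp(c) - 1.0),
                         np.full(n_states - 1, span[0]),
                         np.full(n_states - 1, 1e-3)])
    ub = np.concatenate([np.full(n_states, c.max() + np.ptp(c) + 1.0),
                         np.full(n_states - 1, span[1]),
                         np.full(n_states - 1, span[1] - span[0])])
    flags = []
    try:
        popt, pcov = curve_fit(_sequential_logistic, E, c, p0=p0,
                               bounds=(lb, ub), maxfev=20000)
        converged = True
    except RuntimeError:
        popt, pcov = p0, None
        converged = False
        flags.append("non-convergence: returning initial guess")
    resid = float(np.sum((c - _sequential_logistic(E, *popt)) ** 2))
    L = popt[:n_states]
    m = popt[n_states:2 * n_states - 1]
    w = popt[2 * n_states - 1:]
    order = np.argsort(m)
    m, w = m[order], np.abs(w[order])
    edge = 0.02 * (span[1] - span[0])
    if np.any(m < span[0] + edge) or np.any(m > span[1] - edge):
        flags.append("transition at edge of energy span")
    return CIU50Result(midpoints_eV=m, widths_eV=w, plateaus_A2=L,
                       covariance=pcov, residual=resid, converged=converged,
                       flags=flags)


# --------------------------------------------------------------------------
# KDE, conformer detection, gating


def kde_ccs(samples: np.ndarray, bandwidth: str | float = "silverman",
            grid: np.ndarray | None = None) -> CCSDistribution:
    """Gaussian KDE of CCS samples (Silverman bandwidth by default)."""
    samples = np.asarray(samples, float)
    if samples.size < 2:
        raise ValueError("need at least 2 samples")
    if np.ptp(samples) == 0:
        warnings.warn("zero-variance samples: KDE degenerates to a delta")
        samples = samples + 1e-6 * np.linspace(-1, 1, samples.size)
    kde = gaussian_kde(samples, bw_method=bandwidth)
    if grid is None:
        pad = 4 * samples.std()
        grid = np.linspace(samples.min() - pad, samples.max() + pad, 512)
    dens = kde(grid)
    bw = float(kde.factor * samples.std(ddof=1))
    return CCSDistribution(ccs=grid, density=dens,
                           metadata={"bandwidth_A2": bw}).normalized()


@dataclass
class ConformerSet:
    """Detected conformer families, labelled by ascending CCS."""

    labels: list[str]
    centroids: np.ndarray
    widths: np.ndarray
    weights: np.ndarray

    def __len__(self) -> int:
        return len(self.labels)


GREEK = ["alpha", "beta", "gamma", "delta", "epsilon", "zeta", "eta", "theta"]


def _gauss_mix(x, *params):
    n = len(params) // 3
    out = np.zeros_like(np.asarray(x, float))
    for k in range(n):
        a, mu, sig = params[3 * k: 3 * k + 3]
        out += a * np.exp(-0.5 * ((x - mu) / sig) ** 2)
    return out


def detect_conformers(ccsd: CCSDistribution, max_peaks: int = 6,
                      prominence: float = 0.05,
                      smooth_bandwidth: float | None = None) -> ConformerSet:
    """Peak-pick a KDE-smoothed CCS density and refine as a Gaussian mixture.

    The density is first smoothed with a Gaussian kernel of bandwidth
    ``smooth_bandwidth`` (default 0.5% of the CCS span — narrow enough to
    keep real conformer peaks, wide enough to suppress single-bin intensity
    noise). Peaks with prominence above ``prominence`` x max are kept (the
    default 5% retains minor extended conformers); centroids/widths/weights
    are refined by least squares and labelled alpha, beta, ... by ascending
    CCS. Weights are normalized to sum to 1.
    """
    from scipy.ndimage import gaussian_filter1d

    x = ccsd.ccs
    bw = 0.005 * np.ptp(x) if smooth_bandwidth is None else smooth_bandwidth
    dx = np.median(np.diff(x))
    y = gaussian_filter1d(ccsd.density, max(bw / dx, 1e-9)) if bw > 0 else ccsd.density
    y = y / y.max()
    peaks, props = find_peaks(y, prominence=prominence)
    if len(peaks) == 0:
        raise ValueError("no conformer peak above the prominence threshold")
    if len(peaks) > max_peaks:
        keep = np.argsort(props["prominences"])[::-1][:max_peaks]
        peaks = np.sort(peaks[keep])
    p0 = []
    for pk in peaks:
        p0 += [y[pk], x[pk], max(5 * dx, 0.02 * np.ptp(x))]
    lb = [0.0, x.min(), dx] * len(peaks)
    ub = [2.0, x.max(), np.ptp(x)] * len(peaks)
    try:
        popt, _ = curve_fit(_gauss_mix, x, y, p0=p0, bounds=(lb, ub), maxfev=20000)
    except RuntimeError:
        popt = np.asarray(p0)
    amps = popt[0::3]
    mus = popt[1::3]
    sigs = np.abs(popt[2::3])
    order = np.argsort(mus)
    amps, mus, sigs = amps[order], mus[order], sigs[order]
    w = amps * sigs
    w = w / w.sum()
    return ConformerSet(labels=GREEK[: len(mus)], centroids=mus, widths=sigs,
                        weights=w)


def gate_select(dist: CCSDistribution | ATD,
                window: tuple[float, float]) -> CCSDistribution | ATD:
    """Emulate mobility gating: zero everything outside the window.

    This is the selection step of the multistage IMS-CA-IMS workflow in
    which one conformer family is isolated before re-activation.
    """
    lo, hi = window
    if isinstance(dist, ATD):
        axis, val = dist.times_ms, dist.intensity
    else:
        axis, val = dist.ccs, dist.density
    mask = (axis >= lo) & (axis <= hi)
    if not mask.any() or val[mask].sum() == 0:
        raise ValueError("gate window selects no intensity")
    out = np.where(mask, val, 0.0)
    if isinstance(dist, ATD):
        return ATD(dist.times_ms, out, dist.z, dist.mass, dist.energy_eV)
    return CCSDistribution(dist.ccs, out, dist.z, dist.energy_eV,
                           dict(dist.metadata)).normalized()


def interconversion_metric(pre: CCSDistribution, post: CCSDistribution,
                           compact_region: tuple[float, float],
                           epsilon: float = 0.05) -> dict:
    """Fraction of post-activation density inside the compact CCS region.

    A fraction <= ``epsilon`` supports an irreversible unfolding verdict:
    activated extended conformers do not repopulate the compact family.
    """
    lo, hi = compact_region
    if hi < post.ccs.min() or lo > post.ccs.max():
        raise ValueError("compact region outside the CCS grid")
    if not np.array_equal(pre.ccs, post.ccs):
        raise ValueError("pre/post distributions must share a grid")

    def frac(d: CCSDistribution) -> float:
        mask = (d.ccs >= lo) & (d.ccs <= hi)
        total = np.trapezoid(d.density, d.ccs)
        return float(np.trapezoid(np.where(mask, d.density, 0.0), d.ccs) / total)

    f_post = frac(post)
    return {"fraction_compact_pre": frac(pre), "fraction_compact_post": f_post,
            "irreversible": f_post <= epsilon, "epsilon": epsilon}
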