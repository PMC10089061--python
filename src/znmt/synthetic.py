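"""Synthetic ground-truth generators standing in for instrument and MD data.

Everything the pipeline consumes can be generated here with known ground
truth: the packaged human MT2 sequence, Zn-thiolate cluster maps for the
Zn4..Zn7 loading ladder, dumbbell bead structures, native mass spectra with
isotope structure, and two-or-more-state CIU fingerprints with sigmoidal
transitions. Seeded generators are bitwise reproducible.

The Zn-loading ladder follows the stepwise cluster assembly of MT2:

* Zn4 — two Zn2+ per domain, two Zn2Cys6 clusters,
* Zn5 — fifth Zn2+ joins the alpha-domain (alpha Zn3Cys9),
* Zn6 — alpha-domain saturates (alpha Zn4Cys11),
* Zn7 — seventh Zn2+ completes the beta Zn3Cys9 cluster.

The specific cysteines wired to each metal are not experimentally resolved
for every loading state; the packaged maps place the beta-domain on the
N-terminal 9 Cys and the alpha-domain on the C-terminal 11 Cys (the known
MT fold) with a fixed, documented edge assignment. They are plausible
placeholders, overridable via JSON.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .imms import CIUFingerprint
from .isotopes import MassSpectrum, SpeciesModel, render_spectrum
from .structures import BeadStructure, ClusterMap, ProteinSequence


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic instrument."""

    seed: int = 0
    noise_sd: float = 0.02        # relative intensity units
    resolution: float = 10_000.0  # m/z FWHM resolving power
    bin_width: float = 0.02       # m/z (spectra) or ms (ATDs)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def mt2_sequence() -> ProteinSequence:
    """The packaged 61-residue, 20-cysteine human MT2 sequence.

    Canonical MT2A with the initiator Met retained and no acetylation;
    average apo mass ~6.04 kDa. Any FASTA can be substituted via
    ``ProteinSequence.from_fasta``.
    """
    path = resources.files("znmt.data").joinpath("mt2.fasta")
    with resources.as_file(path) as p:
        return ProteinSequence.from_fasta(p)


def _ladder(metal_count: int, cys: list[int]) -> list[list[int]]:
    """Fixed edge assignment: metal m takes 4 consecutive cysteines starting
    at 3m, wrapping onto the first cysteines once the domain list is spent.
    Produces the shared-thiolate (bridging) counts of the known clusters:
    2 metals/6 Cys -> 2 bridging, 3/9 -> 3, 4/11 -> 5."""
    n_cys = {2: 6, 3: 9, 4: 11}[metal_count]
    pool = cys[:n_cys]
    out = []
    for m in range(metal_count):
        out.append([pool[(3 * m + j) % n_cys] for j in range(4)])
    return out


def cluster_map(n_zn: int, seq: ProteinSequence | None = None) -> ClusterMap:
    """Zn-thiolate connectivity for one loading state (0 or 4..7).

    Every metal is tetrathiolate. Domain occupancies follow the loading
    ladder (see module docstring); ``n_zn=0`` returns the empty apo map.
    """
    if n_zn == 0:
        return ClusterMap(n_zn=0)
    if n_zn not in (4, 5, 6, 7):
        raise ValueError("n_zn must be 0 or 4..7 (intermediate maps not characterized)")
    seq = seq or mt2_sequence()
    cys = seq.cys_positions
    beta_cys, alpha_cys = cys[:9], cys[9:]
    n_alpha = {4: 2, 5: 3, 6: 4, 7: 4}[n_zn]
    n_beta = n_zn - n_alpha
    edges: list[tuple[int, int]] = []
    domains: list[str] = []
    m = 0
    for quad in _ladder(n_alpha, alpha_cys):
        edges += [(m, c) for c in quad]
        domains.append("alpha")
        m += 1
    for quad in _ladder(n_beta, beta_cys):
        edges += [(m, c) for c in quad]
        domains.append("beta")
        m += 1
    return ClusterMap(n_zn=n_zn, edges=edges, domain_of_metal=domains)


# --------------------------------------------------------------------------
# dumbbell bead structures


def _random_walk_in_sphere(rng, n, start, center, radius, bond=3.8, min_sep=3.4):
    """Compact self-avoiding-ish random walk confined to a sphere."""
    pts = [start]
    for _ in range(n - 1):
        best, best_pen = None, np.inf
        for _ in range(60):
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            cand = pts[-1] + bond * d
            pen = max(0.0, np.linalg.norm(cand - center) - radius) * 10.0
            if len(pts) > 1:
                dists = np.linalg.norm(np.asarray(pts[:-1]) - cand, axis=1)
                pen += np.sum(np.maximum(0.0, min_sep - dists))
            if pen < best_pen:
                best, best_pen = cand, pen
            if pen == 0.0:
                break
        pts.append(best)
    return np.asarray(pts)


def make_dumbbell_structure(seq: ProteinSequence, cmap: ClusterMap,
                            cfg: GeneratorConfig | None = None,
                            domain_sep: float = 20.0,
                            domain_radius: float = 9.5,
                            max_attempts: int = 5) -> BeadStructure:
    """Two compact globular domains joined by a short linker.

    One bead per residue plus one per metal; metals start at the centroid of
    their four cysteines and an energy minimization (chain bonds, Zn-S
    harmonics at the 2.3 A rest length, excluded volume, weak domain-center
    tethers) settles all Zn-S edges near the bond rest length. Deterministic
    under the config seed; residual clashes trigger a seeded regeneration
    (reported as a warning).
    """
    from .cgmodel import CGParams, CGTopology, minimize_structure
    from .structures import RESIDUE_MASS, ZN_MASS

    cfg = cfg or GeneratorConfig()
    for c in {c for _, c in cmap.edges}:
        if c >= len(seq) or seq.residues[c] != "C":
            raise ValueError(f"cluster map cysteine index {c} invalid for sequence")

    cys = seq.cys_positions
    boundary = (cys[8] + cys[9] + 1) // 2 if len(cys) >= 10 else len(seq) // 2
    c_beta = np.array([-domain_sep / 2, 0.0, 0.0])
    c_alpha = np.array([domain_sep / 2, 0.0, 0.0])

    for attempt in range(max_attempts):
        rng = np.random.default_rng(cfg.seed + 1000 * attempt)
        n_res = len(seq)
        beta_part = _random_walk_in_sphere(
            rng, boundary, c_beta + rng.normal(scale=1.0, size=3), c_beta, domain_radius)
        bridge = beta_part[-1] + 3.8 * (c_alpha - beta_part[-1]) / np.linalg.norm(c_alpha - beta_part[-1])
        alpha_part = _random_walk_in_sphere(
            rng, n_res - boundary, bridge, c_alpha, domain_radius + 2.0)
        coords = np.vstack([beta_part, alpha_part])
        metals = []
        for m, quad in cluster_map_quads(cmap).items():
            metals.append(coords[quad].mean(axis=0) + rng.normal(scale=0.3, size=3))
        if metals:
            coords = np.vstack([coords, np.asarray(metals)])
        structure = BeadStructure(sequence=seq, coords=coords, cluster_map=cmap)

        top = _builder_topology(structure, boundary, c_beta, c_alpha)
        relaxed = minimize_structure(top, structure.coords, maxiter=1500)
        structure = BeadStructure(sequence=seq, coords=relaxed, cluster_map=cmap)
        if _min_nonbonded_distance(structure, top) > 2.0:
            return structure
        warnings.warn(f"clashing beads after relaxation (attempt {attempt}); "
                      "regenerating with perturbed seed")
    return structure


def cluster_map_quads(cmap: ClusterMap) -> dict[int, list[int]]:
    return cmap.cys_of_metal


def _builder_topology(structure: BeadStructure, boundary: int,
                      c_beta: np.ndarray, c_alpha: np.ndarray):
    """Relaxation-only topology: bonds, Zn-S links, excluded volume and weak
    domain-center tethers; no native contacts yet."""
    from .cgmodel import CGParams, CGTopology

    p = CGParams()
    n_res = structure.n_residues
    n = n_res + structure.n_metals
    x = structure.coords
    bonds = np.array([(i, i + 1) for i in range(n_res - 1)], int)
    znlinks = np.array([(n_res + m, c) for m, c in structure.cluster_map.edges],
                       int).reshape(-1, 2)
    sigma = np.where(np.arange(n) < n_res, p.sigma_res, p.sigma_zn)
    excluded = {tuple(sorted(b)) for b in bonds} | {tuple(sorted(l)) for l in znlinks}
    nb = np.array([(i, j) for i in range(n) for j in range(i + 1, n)
                   if (i, j) not in excluded], int).reshape(-1, 2)
    centers = np.array([c_beta if i < boundary else c_alpha for i in range(n_res)])

    def tether(xx):
        d = xx[:n_res] - centers
        k = 0.05
        grad = np.zeros_like(xx)
        grad[:n_res] = k * d
        return 0.5 * k * float(np.sum(d ** 2)), grad

    return CGTopology(
        masses=structure.masses, charges=np.zeros(n),
        radii=np.where(np.arange(n) < n_res, p.radius_res, p.radius_zn),
        bonds=bonds, bond_r0=np.full(len(bonds), 3.8),
        bond_k=np.full(len(bonds), p.bond_k),
        angles=np.empty((0, 3), int), angle_theta0=np.empty(0), angle_k=np.empty(0),
        contacts=np.empty((0, 2), int), contact_r0=np.empty(0),
        contact_eps=np.empty(0), contact_class=np.empty(0, object),
        znlinks=znlinks, zn_r0=np.full(len(znlinks), p.zn_r0),
        zn_k=np.full(len(znlinks), p.zn_k),
        nb_pairs=nb, nb_sigma=0.5 * (sigma[nb[:, 0]] + sigma[nb[:, 1]]) if len(nb) else np.empty(0),
        z=0, n_residues=n_res, protein_beads=np.arange(n_res), params=p,
        external=tether,
    )


def _min_nonbonded_distance(structure: BeadStructure, top) -> float:
    if len(top.nb_pairs) == 0:
        return np.inf
    x = structure.coords
    d = np.linalg.norm(x[top.nb_pairs[:, 0]] - x[top.nb_pairs[:, 1]], axis=1)
    return float(d.min())


# --------------------------------------------------------------------------
# synthetic CIU fingerprints and spectra


def synth_ciu_fingerprint(state_centroids: list[float], state_widths: list[float],
                          transition_midpoints: list[float],
                          transition_widths: list[float],
                          energies: np.ndarray,
                          cfg: GeneratorConfig | None = None,
                          ccs_grid: np.ndarray | None = None) -> CIUFingerprint:
    """Sequential-logistic multi-state CIU fingerprint with Gaussian states.

    Occupancy hands off from state k to k+1 through a logistic step at each
    transition midpoint; each occupied state contributes a Gaussian in CCS.
    Gaussian intensity noise (sd ``cfg.noise_sd``, truncated at 0) is added
    and every energy column is normalized to maximum 1.
    """
    cfg = cfg or GeneratorConfig()
    n = len(state_centroids)
    if n < 1 or len(state_widths) != n:
        raise ValueError("need >= 1 state with matching widths")
    if len(transition_midpoints) != n - 1 or len(transition_widths) != n - 1:
        raise ValueError("need n_states - 1 transitions")
    mids = np.asarray(transition_midpoints, float)
    if np.any(np.diff(mids) <= 0):
        raise ValueError("transition midpoints must be strictly increasing")
    E = np.asarray(energies, float)
    if np.any(np.diff(E) <= 0):
        raise ValueError("energies must be sorted increasing")
    if ccs_grid is None:
        lo = min(c - 4 * w for c, w in zip(state_centroids, state_widths))
        hi = max(c + 4 * w for c, w in zip(state_centroids, state_widths))
        ccs_grid = np.linspace(lo, hi, 400)

    sig = [1.0 / (1.0 + np.exp(-(E - m) / w))
           for m, w in zip(mids, transition_widths)]
    occ = []
    for k in range(n):
        lower = sig[k - 1] if k >= 1 else np.ones_like(E)
        upper = sig[k] if k < n - 1 else np.zeros_like(E)
        occ.append(lower - upper)
    rng = cfg.rng()
    mat = np.zeros((len(ccs_grid), len(E)))
    for k, (c, w) in enumerate(zip(state_centroids, state_widths)):
        g = np.exp(-0.5 * ((ccs_grid - c) / w) ** 2)
        mat += occ[k][None, :] * g[:, None]
    if cfg.noise_sd > 0:
        mat = np.maximum(mat + rng.normal(0, cfg.noise_sd, mat.shape), 0.0)
    colmax = mat.max(axis=0)
    mat = mat / np.where(colmax > 0, colmax, 1.0)
    return CIUFingerprint(ccs_grid=ccs_grid, energies_eV=E, matrix=mat)


def synth_spectrum(species: list[SpeciesModel], abundances: list[float],
                   cfg: GeneratorConfig | None = None,
                   grid: np.ndarray | None = None,
                   pad: float = 3.0) -> MassSpectrum:
    """Sum of rendered isotope envelopes plus truncated Gaussian noise."""
    cfg = cfg or GeneratorConfig()
    if not species:
        raise ValueError("empty species list")
    if grid is None:
        mzs = [sp.mz() for sp in species]
        grid = np.arange(min(mzs) - pad, max(mzs) + pad, cfg.bin_width)
    spec = render_spectrum(species, abundances, cfg.resolution, grid)
    y = spec.intensity
    if cfg.noise_sd > 0:
        rng = cfg.rng()
        y = np.maximum(y + rng.normal(0, cfg.noise_sd * max(y.max(), 1e-12), y.shape), 0.0)
    return MassSpectrum(mz=spec.mz, intensity=y, metadata=dict(spec.metadata))
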