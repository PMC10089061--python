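"""Coarse-grained gas-phase model of metallothionein ions.

One bead per residue plus one bead per Zn2+.  The Hamiltonian is a
structure-based (Go-like) potential:

* harmonic bonds between sequence neighbours,
* harmonic angles along the chain,
* 12-6 native contacts taken from the reference structure, partitioned into
  intra-alpha, intra-beta and inter-domain sets (the inter-domain set is the
  one the unfolding analyses interrogate),
* WCA excluded volume between all remaining pairs,
* in-vacuo Coulomb between the charge-carrying beads,
* harmonic Zn-S cross-links mirroring the cluster map (4 per metal; the
  links strain but never break — covalent-scale rupture is out of scope).

Units: kcal/mol, Angstrom, amu; the internal time unit is
48.8882 fs (the AKMA convention), converted at the interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .structures import BeadStructure, ClusterMap

KB = 0.0019872041          # kcal/mol/K
COULOMB = 332.0637         # kcal*A/(mol*e^2)
AKMA_FS = 48.8882          # fs per internal time unit
KCAL_PER_MOL_A_TO_PN = 69.4786  # force conversion

BASIC_RESIDUES = set("KRH")


@dataclass
class CGParams:
    """Force-field parameters (kcal/mol, Angstrom)."""

    bond_k: float = 100.0
    angle_k: float = 10.0           # kcal/mol/rad^2
    contact_eps: float = 1.0
    contact_cutoff: float = 8.0     # native-contact detection cutoff
    contact_min_seq_sep: int = 3
    zn_k: float = 50.0
    zn_r0: float = 2.3
    wca_eps: float = 1.0
    sigma_res: float = 3.8          # WCA sigma for residue beads
    sigma_zn: float = 2.0
    dielectric: float = 1.0
    radius_res: float = 3.8         # collision radii for the CCS read-out
    radius_zn: float = 1.4


@dataclass
class CGTopology:
    """Bonded + nonbonded interaction lists for one bead structure."""

    masses: np.ndarray
    charges: np.ndarray
    radii: np.ndarray
    bonds: np.ndarray               # (nb, 2)
    bond_r0: np.ndarray
    bond_k: np.ndarray
    angles: np.ndarray              # (na, 3)
    angle_theta0: np.ndarray
    angle_k: np.ndarray
    contacts: np.ndarray            # (nc, 2)
    contact_r0: np.ndarray
    contact_eps: np.ndarray
    contact_class: np.ndarray       # 'alpha' | 'beta' | 'inter'
    znlinks: np.ndarray             # (nz, 2) = (metal bead, cys bead)
    zn_r0: np.ndarray
    zn_k: np.ndarray
    nb_pairs: np.ndarray            # (np, 2) pairs subject to WCA + Coulomb
    nb_sigma: np.ndarray
    z: int = 0
    n_residues: int = 0
    protein_beads: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    params: CGParams = field(default_factory=CGParams)
    external: Callable[[np.ndarray], tuple[float, np.ndarray]] | None = None

    @property
    def n_beads(self) -> int:
        return len(self.masses)


def _domain_boundary(structure: BeadStructure) -> int:
    """First residue index of the alpha (C-terminal) domain.

    The beta-domain carries the N-terminal 9 cysteines, alpha the
    C-terminal 11; the split is placed midway between Cys 9 and Cys 10.
    """
    cys = structure.sequence.cys_positions
    if len(cys) < 10:
        return len(structure.sequence) // 2
    return (cys[8] + cys[9] + 1) // 2


def build_topology(structure: BeadStructure, cmap: ClusterMap | None = None,
                   z: int = 5, params: CGParams | None = None) -> CGTopology:
    """Derive a Go-like topology from a reference bead structure.

    Native contacts are residue pairs separated by >= ``contact_min_seq_sep``
    in sequence and closer than ``contact_cutoff`` in the reference, minus
    pairs already covered by bonds or Zn-S links.  The ``z`` unit charges
    are placed on the ``z`` most peripheral basic residues (Lys/Arg/His,
    ranked by distance from the centre of mass), falling back to the most
    peripheral remaining beads if the protein is short of basic residues.
    """
    params = params or CGParams()
    cmap = cmap if cmap is not None else structure.cluster_map
    if cmap.n_zn != structure.n_metals:
        raise ValueError("cluster map does not match structure metal count")
    n_res = structure.n_residues
    n = structure.n_beads if hasattr(structure, "n_beads") else n_res + cmap.n_zn
    n = n_res + cmap.n_zn
    x = structure.coords
    masses = structure.masses
    radii = np.where(np.arange(n) < n_res, params.radius_res, params.radius_zn)
    sigma = np.where(np.arange(n) < n_res, params.sigma_res, params.sigma_zn)

    bonds = np.array([(i, i + 1) for i in range(n_res - 1)], int)
    bond_r0 = np.linalg.norm(x[bonds[:, 0]] - x[bonds[:, 1]], axis=1)
    angles = np.array([(i, i + 1, i + 2) for i in range(n_res - 2)], int)
    u = x[angles[:, 0]] - x[angles[:, 1]]
    v = x[angles[:, 2]] - x[angles[:, 1]]
    cos = np.sum(u * v, axis=1) / (np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1))
    theta0 = np.arccos(np.clip(cos, -1, 1))

    znlinks = np.array([(n_res + m, c) for m, c in cmap.edges], int).reshape(-1, 2)

    boundary = _domain_boundary(structure)
    excluded = {tuple(sorted(b)) for b in bonds}
    excluded |= {tuple(sorted(l)) for l in znlinks}
    excluded |= {(i, i + 2) for i in range(n_res - 2)}  # 1-3 angle pairs

    contacts, c_r0, c_cls = [], [], []
    for i in range(n_res):
        for j in range(i + params.contact_min_seq_sep, n_res):
            if (i, j) in excluded:
                continue
            r = np.linalg.norm(x[i] - x[j])
            if r < params.contact_cutoff:
                contacts.append((i, j))
                c_r0.append(r)
                if j < boundary:
                    c_cls.append("beta")
                elif i >= boundary:
                    c_cls.append("alpha")
                else:
                    c_cls.append("inter")
    contacts = np.array(contacts, int).reshape(-1, 2)
    excluded |= {tuple(p) for p in contacts}

    nb = [(i, j) for i in range(n) for j in range(i + 1, n)
          if (i, j) not in excluded]
    nb = np.array(nb, int).reshape(-1, 2)
    nb_sigma = 0.5 * (sigma[nb[:, 0]] + sigma[nb[:, 1]]) if len(nb) else np.empty(0)

    charges = np.zeros(n)
    com = np.average(x[:n_res], axis=0, weights=masses[:n_res])
    dist = np.linalg.norm(x[:n_res] - com, axis=1)
    basic = [i for i, a in enumerate(structure.sequence.residues) if a in BASIC_RESIDUES]
    order = sorted(basic, key=lambda i: -dist[i])
    if len(order) < z:
        rest = sorted((i for i in range(n_res) if i not in basic), key=lambda i: -dist[i])
        order += rest
    for i in order[:z]:
        charges[i] = 1.0

    return CGTopology(
        masses=masses, charges=charges, radii=radii,
        bonds=bonds, bond_r0=bond_r0, bond_k=np.full(len(bonds), params.bond_k),
        angles=angles, angle_theta0=theta0, angle_k=np.full(len(angles), params.angle_k),
        contacts=contacts, contact_r0=np.asarray(c_r0),
        contact_eps=np.full(len(contacts), params.contact_eps),
        contact_class=np.asarray(c_cls, dtype=object),
        znlinks=znlinks, zn_r0=np.full(len(znlinks), params.zn_r0),
        zn_k=np.full(len(znlinks), params.zn_k),
        nb_pairs=nb, nb_sigma=nb_sigma, z=z, n_residues=n_res,
        protein_beads=np.arange(n_res), params=params,
    )


# --------------------------------------------------------------------------
# energy and forces

_RMIN = 0.05  # clamp to keep overlapping beads at a large finite energy


def _pair_vectors(x: np.ndarray, pairs: np.ndarray):
    d = x[pairs[:, 0]] - x[pairs[:, 1]]
    r = np.maximum(np.linalg.norm(d, axis=1), _RMIN)
    return d, r


def _harmonic(x, pairs, r0, k, forces):
    if len(pairs) == 0:
        return 0.0
    d, r = _pair_vectors(x, pairs)
    dr = r - r0
    e = float(np.sum(0.5 * k * dr ** 2))
    f = (-(k * dr) / r)[:, None] * d
    np.add.at(forces, pairs[:, 0], f)
    np.add.at(forces, pairs[:, 1], -f)
    return e


def potential_energy(top: CGTopology, coords: np.ndarray,
                     return_forces: bool = False):
    """Per-term potential energy (and optionally forces) at ``coords``.

    Returns a dict with keys bond, angle, contact, wca, coulomb, zn_s,
    external and total; overlapping beads give a large but finite WCA
    energy (distances clamped), never NaN.
    """
    x = np.asarray(coords, float).reshape(-1, 3)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite coordinates")
    forces = np.zeros_like(x)
    e = {}
    e["bond"] = _harmonic(x, top.bonds, top.bond_r0, top.bond_k, forces)
    e["zn_s"] = _harmonic(x, top.znlinks, top.zn_r0, top.zn_k, forces)

    # angles
    e["angle"] = 0.0
    if len(top.angles):
        i, j, k = top.angles.T
        u = x[i] - x[j]
        v = x[k] - x[j]
        nu = np.maximum(np.linalg.norm(u, axis=1), _RMIN)
        nv = np.maximum(np.linalg.norm(v, axis=1), _RMIN)
        cos = np.clip(np.sum(u * v, axis=1) / (nu * nv), -1 + 1e-10, 1 - 1e-10)
        th = np.arccos(cos)
        dth = th - top.angle_theta0
        e["angle"] = float(np.sum(0.5 * top.angle_k * dth ** 2))
        sin = np.sqrt(1 - cos ** 2)
        dEdth = (top.angle_k * dth)[:, None]
        uh = u / nu[:, None]
        vh = v / nv[:, None]
        dthdi = (cos[:, None] * uh - vh) / (nu * sin)[:, None]
        dthdk = (cos[:, None] * vh - uh) / (nv * sin)[:, None]
        np.add.at(forces, i, -dEdth * dthdi)
        np.add.at(forces, k, -dEdth * dthdk)
        np.add.at(forces, j, dEdth * (dthdi + dthdk))

    # native contacts: 12-6 with minimum at r0
    e["contact"] = 0.0
    if len(top.contacts):
        d, r = _pair_vectors(x, top.contacts)
        s = top.contact_r0 / r
        s6 = s ** 6
        e["contact"] = float(np.sum(top.contact_eps * (s6 ** 2 - 2 * s6)))
        # dE/dr = eps * (-12 s^12 + 12 s^6)/r
        dEdr = 12.0 * top.contact_eps * (s6 - s6 ** 2) / r
        f = (-dEdr / r)[:, None] * d
        np.add.at(forces, top.contacts[:, 0], f)
        np.add.at(forces, top.contacts[:, 1], -f)

    # WCA + Coulomb over the remaining pairs
    e["wca"] = 0.0
    e["coulomb"] = 0.0
    if len(top.nb_pairs):
        d, r = _pair_vectors(x, top.nb_pairs)
        cut = top.nb_sigma * 2.0 ** (1.0 / 6.0)
        inside = r < cut
        if inside.any():
            s6 = (top.nb_sigma[inside] / r[inside]) ** 6
            e["wca"] = float(np.sum(4 * top.params.wca_eps * (s6 ** 2 - s6) + top.params.wca_eps))
            dEdr = 4 * top.params.wca_eps * (-12 * s6 ** 2 + 6 * s6) / r[inside]
            f = (-dEdr / r[inside])[:, None] * d[inside]
            np.add.at(forces, top.nb_pairs[inside, 0], f)
            np.add.at(forces, top.nb_pairs[inside, 1], -f)
        qq = top.charges[top.nb_pairs[:, 0]] * top.charges[top.nb_pairs[:, 1]]
        charged = qq != 0
        if charged.any():
            kq = COULOMB / top.params.dielectric
            e["coulomb"] = float(np.sum(kq * qq[charged] / r[charged]))
            dEdr = -kq * qq[charged] / r[charged] ** 2
            f = (-dEdr / r[charged])[:, None] * d[charged]
            np.add.at(forces, top.nb_pairs[charged, 0], f)
            np.add.at(forces, top.nb_pairs[charged, 1], -f)

    e["external"] = 0.0
    if top.external is not None:
        ee, grad = top.external(x)
        e["external"] = float(ee)
        forces -= grad

    e["total"] = sum(v for k, v in e.items() if k != "total")
    if return_forces:
        return e, forces
    return e


def minimize_structure(top: CGTopology, coords: np.ndarray,
                       maxiter: int = 2000) -> np.ndarray:
    """L-BFGS energy minimization; returns relaxed coordinates."""
    from scipy.optimize import minimize

    shape = coords.shape

    def fun(flat):
        e, f = potential_energy(top, flat.reshape(shape), return_forces=True)
        return e["total"], -f.ravel()

    res = minimize(fun, np.asarray(coords, float).ravel(), jac=True,
                   method="L-BFGS-B", options={"maxiter": maxiter})
    return res.x.reshape(shape)


# --------------------------------------------------------------------------
# collective variables


def rg_cv(x: np.ndarray, masses: np.ndarray, subset: np.ndarray):
    """Mass-weighted radius of gyration of ``subset`` and its gradient."""
    xs = x[subset]
    m = masses[subset]
    M = m.sum()
    com = np.average(xs, axis=0, weights=m)
    dx = xs - com
    rg2 = float(np.sum(m * np.sum(dx ** 2, axis=1)) / M)
    rg = np.sqrt(max(rg2, 1e-12))
    grad = np.zeros_like(x)
    grad[subset] = (m[:, None] * dx) / (M * rg)
    return rg, grad


def end_to_end_cv(x: np.ndarray, masses: np.ndarray, subset: np.ndarray):
    """Distance between the first and last bead of ``subset``."""
    i, j = subset[0], subset[-1]
    d = x[j] - x[i]
    r = float(np.linalg.norm(d))
    grad = np.zeros_like(x)
    if r > 1e-12:
        grad[j] = d / r
        grad[i] = -d / r
    return r, grad


def x_coordinate_cv(x: np.ndarray, masses: np.ndarray, subset: np.ndarray):
    """x-coordinate of the first subset bead (1-D toy systems / oracles)."""
    grad = np.zeros_like(x)
    grad[subset[0], 0] = 1.0
    return float(x[subset[0], 0]), grad


CV_FUNCS = {"rg": rg_cv, "end_to_end": end_to_end_cv, "x": x_coordinate_cv}


def free_beads_topology(n_beads: int, masses: float | np.ndarray = 50.0,
                        external: Callable | None = None,
                        params: CGParams | None = None) -> CGTopology:
    """Interaction-free topology (plus optional external potential).

    Used for analytic oracles: a single particle in a closed-form
    potential, ideal-gas equipartition checks, etc.
    """
    m = np.broadcast_to(np.asarray(masses, float), (n_beads,)).copy()
    empty_pairs = np.empty((0, 2), int)
    return CGTopology(
        masses=m, charges=np.zeros(n_beads), radii=np.full(n_beads, 3.8),
        bonds=empty_pairs, bond_r0=np.empty(0), bond_k=np.empty(0),
        angles=np.empty((0, 3), int), angle_theta0=np.empty(0), angle_k=np.empty(0),
        contacts=empty_pairs, contact_r0=np.empty(0), contact_eps=np.empty(0),
        contact_class=np.empty(0, object),
        znlinks=empty_pairs, zn_r0=np.empty(0), zn_k=np.empty(0),
        nb_pairs=empty_pairs, nb_sigma=np.empty(0),
        z=0, n_residues=n_beads, protein_beads=np.arange(n_beads),
        params=params or CGParams(), external=external,
    )
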