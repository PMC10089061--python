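"""Structure-derived observables: Rg, h-bonds, salt bridges, Zn-S graphs.

These are the per-frame metrics correlated with the CCS read-out during
desolvation and unfolding analyses. All-atom metrics take a biotite
``AtomArray``; coarse-grained metrics take a ``BeadStructure``. Hydrogen
bonds are undefined for one-bead-per-residue models and raise on CG input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .structures import BeadStructure


def radius_of_gyration(coords: np.ndarray, masses: np.ndarray | None = None) -> float:
    """Mass-weighted radius of gyration about the centre of mass (Angstrom)."""
    x = np.asarray(coords, float).reshape(-1, 3)
    if x.shape[0] < 1:
        raise ValueError("need at least one bead")
    m = np.ones(x.shape[0]) if masses is None else np.asarray(masses, float)
    if m.sum() <= 0:
        raise ValueError("zero total mass")
    com = np.average(x, axis=0, weights=m)
    return float(np.sqrt(np.sum(m * np.sum((x - com) ** 2, axis=1)) / m.sum()))


def end_to_end_distance(coords: np.ndarray) -> float:
    """Distance between the first and last bead/atom (N-C termini proxy)."""
    x = np.asarray(coords, float).reshape(-1, 3)
    return float(np.linalg.norm(x[-1] - x[0]))


# --------------------------------------------------------------------------
# hydrogen bonds and salt bridges (all-atom)


def _require_atom_array(structure, what: str):
    import biotite.structure as struc

    if isinstance(structure, BeadStructure):
        raise TypeError(f"{what} undefined for coarse-grained bead input")
    if not isinstance(structure, struc.AtomArray):
        raise TypeError(f"{what} requires a biotite AtomArray")
    return structure


def count_hbonds(structure, distance_cutoff: float = 3.5,
                 angle_cutoff_deg: float = 120.0,
                 min_residue_sep: int = 2) -> int:
    """Geometric hydrogen-bond count.

    Donor/acceptor atoms are N and O. With explicit polar hydrogens the
    criterion is donor-acceptor distance <= ``distance_cutoff`` and a
    donor-H-acceptor angle >= ``angle_cutoff_deg``; without hydrogens the
    angle test is skipped (distance-only, flagged by a warning). Pairs
    closer than ``min_residue_sep`` residues are excluded so that covalent
    peptide-bond geometry is not miscounted.
    """
    atoms = _require_atom_array(structure, "hydrogen bonds")
    is_no = np.isin(atoms.element, ("N", "O"))
    has_h = bool(np.any(atoms.element == "H"))
    idx = np.flatnonzero(is_no)
    coords = atoms.coord[idx]
    resid = atoms.res_id[idx]
    if not has_h:
        warnings.warn("no hydrogens in input: donor angle test skipped "
                      "(distance-only criterion)")
    # attached hydrogens per heavy atom (for the angle test)
    h_of: dict[int, list[np.ndarray]] = {}
    if has_h:
        h_idx = np.flatnonzero(atoms.element == "H")
        for hi in h_idx:
            d = np.linalg.norm(atoms.coord[idx] - atoms.coord[hi], axis=1)
            j = int(np.argmin(d))
            if d[j] < 1.3:
                h_of.setdefault(j, []).append(atoms.coord[hi])
    count = 0
    for a in range(len(idx)):
        for b in range(a + 1, len(idx)):
            if abs(int(resid[a]) - int(resid[b])) < min_residue_sep:
                continue
            r = np.linalg.norm(coords[a] - coords[b])
            if r > distance_cutoff:
                continue
            if has_h:
                ok = False
                for da, ac in ((a, b), (b, a)):
                    for h in h_of.get(da, []):
                        v1 = coords[da] - h
                        v2 = coords[ac] - h
                        cos = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
                        ang = np.degrees(np.arccos(np.clip(cos, -1, 1)))
                        if ang >= angle_cutoff_deg:
                            ok = True
                if not ok:
                    continue
            count += 1
    return count


_BASIC_ATOMS = {"LYS": ("NZ",), "ARG": ("NE", "NH1", "NH2"), "HIS": ("ND1", "NE2")}
_ACIDIC_ATOMS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}


def count_salt_bridges(structure, cutoff: float = 4.0) -> int:
    """Salt bridges: charged side-chain groups (Lys/Arg/His vs Asp/Glu or
    the C-terminal carboxylate OXT) whose closest heavy-atom distance is
    <= ``cutoff`` (default 4.0 A). Counts residue pairs."""
    atoms = _require_atom_array(structure, "salt bridges")

    def group_atoms(table):
        groups: dict[int, list[np.ndarray]] = {}
        for i in range(len(atoms)):
            names = table.get(atoms.res_name[i], ())
            if atoms.atom_name[i] in names:
                groups.setdefault(int(atoms.res_id[i]), []).append(atoms.coord[i])
        return groups

    basic = group_atoms(_BASIC_ATOMS)
    acidic = group_atoms(_ACIDIC_ATOMS)
    oxt = [atoms.coord[i] for i in range(len(atoms)) if atoms.atom_name[i] == "OXT"]
    if oxt:
        acidic.setdefault(-1, []).extend(oxt)
    count = 0
    for rb, ga in basic.items():
        for ra, gb in acidic.items():
            dmin = min(np.linalg.norm(p - q) for p in ga for q in gb)
            if dmin <= cutoff:
                count += 1
    return count


# --------------------------------------------------------------------------
# Zn-S connectivity


@dataclass
class ClusterGraph:
    """Bipartite metal-thiolate graph with bridging/terminal labels."""

    edges: list[tuple[int, int]]            # (metal id, cys id)
    metal_degree: dict[int, int]
    cys_degree: dict[int, int]
    bridging_cys: list[int] = field(default_factory=list)   # degree 2
    terminal_cys: list[int] = field(default_factory=list)   # degree 1
    components: list[set[int]] = field(default_factory=list)  # cys ids per cluster
    flags: list[str] = field(default_factory=list)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def zn_s_graph(structure, cutoff: float | None = None) -> ClusterGraph:
    """Distance-based Zn-S connectivity.

    For a ``BeadStructure`` an edge joins a metal bead and a Cys bead
    within ``cutoff`` (default 3.0 A, bead centres); for an all-atom
    ``AtomArray`` it joins ZN and cysteine SG atoms within 2.6 A. Bridging
    cysteines have degree 2 (coordinating two metals), terminal degree 1;
    metals exceeding tetrathiolate coordination are flagged. Connected
    components correspond to the metal-thiolate clusters (two for the
    dumbbell: alpha and beta).
    """
    if isinstance(structure, BeadStructure):
        cutoff = 3.0 if cutoff is None else cutoff
        cys = structure.sequence.cys_positions
        s_coords = {c: structure.coords[c] for c in cys}
        zn_coords = {m: structure.coords[structure.n_residues + m]
                     for m in range(structure.n_metals)}
    else:
        import biotite.structure as struc

        atoms = _require_atom_array(structure, "Zn-S graph")
        cutoff = 2.6 if cutoff is None else cutoff
        s_coords, zn_coords = {}, {}
        for i in range(len(atoms)):
            if atoms.res_name[i] == "CYS" and atoms.atom_name[i] == "SG":
                s_coords[int(atoms.res_id[i])] = atoms.coord[i]
            if atoms.element[i] == "ZN":
                zn_coords[len(zn_coords)] = atoms.coord[i]

    edges = [(m, c) for m, zx in zn_coords.items() for c, sx in s_coords.items()
             if np.linalg.norm(zx - sx) <= cutoff]
    g = nx.Graph()
    g.add_nodes_from((("zn", m) for m in zn_coords))
    g.add_edges_from((("zn", m), ("cys", c)) for m, c in edges)
    metal_degree = {m: g.degree(("zn", m)) for m in zn_coords}
    cys_degree = {c: g.degree(("cys", c)) for c in s_coords if g.has_node(("cys", c))}
    flags = [f"metal {m} exceeds tetrathiolate coordination (degree {d})"
             for m, d in metal_degree.items() if d > 4]
    comps = []
    for comp in nx.connected_components(g):
        cs = {n[1] for n in comp if n[0] == "cys"}
        if cs:
            comps.append(cs)
    return ClusterGraph(
        edges=edges, metal_degree=metal_degree, cys_degree=cys_degree,
        bridging_cys=sorted(c for c, d in cys_degree.items() if d == 2),
        terminal_cys=sorted(c for c, d in cys_degree.items() if d == 1),
        components=comps, flags=flags)


def timeseries(metric, trajectory) -> np.ndarray:
    """Apply a per-frame metric to a trajectory (``Trajectory`` or an
    (F, n, 3) coordinate stack), aligned to stored frames."""
    frames = getattr(trajectory, "coords", trajectory)
    return np.asarray([metric(np.asarray(f)) for f in frames])
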