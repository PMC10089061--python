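"""Core domain objects: sequences, metal-thiolate cluster maps, bead structures.

Metallothionein-2 (MT2) is a 61-residue, 20-cysteine protein that binds up
to seven Zn2+ in two thiolate clusters: an N-terminal beta-domain (9 Cys,
up to 3 metals) and a C-terminal alpha-domain (11 Cys, up to 4 metals).
The objects here carry that connectivity explicitly so that mass-spectral,
ion-mobility and coarse-grained simulation layers all share one picture of
which cysteines coordinate which metal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}

# average residue masses (Da) for the coarse-grained beads
RESIDUE_MASS = {
    "A": 71.08, "C": 103.14, "D": 115.09, "E": 129.12, "F": 147.18,
    "G": 57.05, "H": 137.14, "I": 113.16, "K": 128.17, "L": 113.16,
    "M": 131.19, "N": 114.10, "P": 97.12, "Q": 128.13, "R": 156.19,
    "S": 87.08, "T": 101.10, "V": 99.13, "W": 186.21, "Y": 163.18,
}
ZN_MASS = 65.409


@dataclass(frozen=True)
class ProteinSequence:
    """One-letter amino-acid sequence with a label."""

    residues: str
    name: str = "protein"

    def __post_init__(self) -> None:
        bad = set(self.residues) - AMINO_ACIDS
        if bad:
            raise ValueError(f"non-canonical residues: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def cys_positions(self) -> list[int]:
        """0-based indices of cysteines (the thiolate donors)."""
        return [i for i, a in enumerate(self.residues) if a == "C"]

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ProteinSequence":
        from Bio import SeqIO

        rec = next(SeqIO.parse(str(path), "fasta"))
        return cls(residues=str(rec.seq), name=rec.id)


@dataclass
class ClusterMap:
    """Bipartite Zn--thiolate connectivity for one Znx species.

    ``edges`` are (metal_index, cys_residue_index) pairs; every metal is
    tetrathiolate (exactly 4 edges).  ``domain_of_metal[m]`` is ``"alpha"``
    or ``"beta"``.
    """

    n_zn: int
    edges: list[tuple[int, int]] = field(default_factory=list)
    domain_of_metal: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0 <= self.n_zn <= 7:
            raise ValueError("n_zn must be 0..7")
        if len(self.domain_of_metal) != self.n_zn:
            raise ValueError("domain_of_metal length must equal n_zn")
        for m in range(self.n_zn):
            deg = sum(1 for mi, _ in self.edges if mi == m)
            if deg != 4:
                raise ValueError(f"metal {m} has {deg} thiolate edges, expected 4")

    @property
    def cys_of_metal(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {m: [] for m in range(self.n_zn)}
        for m, c in self.edges:
            out[m].append(c)
        return out

    def domain_cys(self, domain: str) -> set[int]:
        return {c for m, c in self.edges if self.domain_of_metal[m] == domain}

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "n_zn": self.n_zn,
            "edges": [list(e) for e in self.edges],
            "domain_of_metal": self.domain_of_metal,
        }, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ClusterMap":
        d = json.loads(Path(path).read_text())
        return cls(n_zn=d["n_zn"],
                   edges=[tuple(e) for e in d["edges"]],
                   domain_of_metal=list(d["domain_of_metal"]))


@dataclass
class BeadStructure:
    """One-bead-per-residue structure plus one bead per metal.

    Residue beads come first (in sequence order), metal beads after.
    Coordinates are in Angstrom.
    """

    sequence: ProteinSequence
    coords: np.ndarray            # (n_residues + n_metals, 3)
    cluster_map: ClusterMap
    name: str = "structure"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        expect = len(self.sequence) + self.cluster_map.n_zn
        if self.coords.shape != (expect, 3):
            raise ValueError(f"coords shape {self.coords.shape}, expected ({expect}, 3)")

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    @property
    def n_metals(self) -> int:
        return self.cluster_map.n_zn

    @property
    def metal_indices(self) -> np.ndarray:
        return np.arange(self.n_residues, self.n_residues + self.n_metals)

    @property
    def residue_coords(self) -> np.ndarray:
        return self.coords[: self.n_residues]

    @property
    def masses(self) -> np.ndarray:
        m = [RESIDUE_MASS[a] for a in self.sequence.residues]
        m += [ZN_MASS] * self.n_metals
        return np.asarray(m)

    def zn_s_distances(self) -> np.ndarray:
        """Distance of every mapped Zn--S(Cys) pair, in map edge order."""
        if self.cluster_map.n_zn == 0:
            return np.empty(0)
        d = []
        for m, c in self.cluster_map.edges:
            d.append(np.linalg.norm(self.coords[self.n_residues + m] - self.coords[c]))
        return np.asarray(d)

    # ---- IO ----------------------------------------------------------------

    def to_pdb(self, path: str | Path) -> None:
        import biotite.structure as struc
        from biotite.structure.io.pdb import PDBFile

        n = self.n_residues + self.n_metals
        arr = struc.AtomArray(n)
        arr.coord = self.coords.astype(np.float32)
        for i, a in enumerate(self.sequence.residues):
            arr.chain_id[i] = "A"
            arr.res_id[i] = i + 1
            arr.res_name[i] = _THREE[a]
            arr.atom_name[i] = "CA"
            arr.element[i] = "C"
            arr.hetero[i] = False
        for j in range(self.n_metals):
            i = self.n_residues + j
            arr.chain_id[i] = "Z"
            arr.res_id[i] = j + 1
            arr.res_name[i] = "ZN"
            arr.atom_name[i] = "ZN"
            arr.element[i] = "ZN"
            arr.hetero[i] = True
        f = PDBFile()
        f.set_structure(arr)
        f.write(str(path))

    def to_xyz(self, path: str | Path) -> None:
        lines = [str(self.n_residues + self.n_metals), self.name]
        for i, a in enumerate(self.sequence.residues):
            x, y, z = self.coords[i]
            lines.append(f"{a} {x:.4f} {y:.4f} {z:.4f}")
        for j in range(self.n_metals):
            x, y, z = self.coords[self.n_residues + j]
            lines.append(f"Zn {x:.4f} {y:.4f} {z:.4f}")
        Path(path).write_text("\n".join(lines) + "\n")


def read_xyz(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Minimal XYZ reader: returns (symbols, coords)."""
    lines = Path(path).read_text().splitlines()
    n = int(lines[0].split()[0])
    syms, xyz = [], []
    for ln in lines[2 : 2 + n]:
        parts = ln.split()
        syms.append(parts[0])
        xyz.append([float(v) for v in parts[1:4]])
    return syms, np.asarray(xyz)
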