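"""Shared fixtures: packaged sequence/structures and generated geometries."""

import numpy as np
import pytest

from znmt import cgmodel, isotopes, synthetic


@pytest.fixture(scope="session")
def mt2_seq():
    return synthetic.mt2_sequence()


@pytest.fixture(scope="session")
def mt2_base(mt2_seq):
    return isotopes.composition_from_sequence(mt2_seq)


@pytest.fixture(scope="session")
def zn7_structure(mt2_seq):
    return synthetic.make_dumbbell_structure(
        mt2_seq, synthetic.cluster_map(7, mt2_seq), synthetic.GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def zn7_topology(zn7_structure):
    return cgmodel.build_topology(zn7_structure, z=5)


@pytest.fixture(scope="session")
def apo_structure(mt2_seq):
    return synthetic.make_dumbbell_structure(
        mt2_seq, synthetic.cluster_map(0), synthetic.GeneratorConfig(seed=1))


def double_well(height: float = 2.0, half_sep: float = 2.0):
    """Analytic 1-D double well on the x coordinate of bead 0.

    V(x) = h ((x^2 - a^2)/a^2)^2: minima at +-a, barrier exactly h.
    """

    def potential(x):
        s = x[0, 0]
        e = height * ((s ** 2 - half_sep ** 2) / half_sep ** 2) ** 2
        g = np.zeros_like(x)
        g[0, 0] = height * 2 * ((s ** 2 - half_sep ** 2) / half_sep ** 2) * (2 * s / half_sep ** 2)
        return e, g

    return potential


def ideal_helix_atoms(n_res: int = 20):
    """Synthetic idealized helix backbone (N and carbonyl O pseudo-atoms).

    Built so that exactly the i -> i+4 amide pairs satisfy the 3.5 A
    h-bond distance criterion: the carbonyl O of residue i sits 2.9 A
    radially outside the amide N of residue i+4; the last four carbonyls
    (which have no i+4 partner) are parked far from the helix.
    """
    import biotite.structure as struc

    R, twist, rise = 2.3, np.radians(100.0), 1.5
    th = twist * np.arange(n_res)
    N = np.column_stack([R * np.cos(th), R * np.sin(th), rise * np.arange(n_res)])
    O = np.empty((n_res, 3))
    for i in range(n_res):
        if i + 4 < n_res:
            u = N[i + 4].copy()
            u[2] = 0.0
            u /= np.linalg.norm(u)
            O[i] = N[i + 4] + 2.9 * u
        else:
            O[i] = np.array([100.0 + 10 * i, 100.0, 100.0])
    arr = struc.AtomArray(2 * n_res)
    for i in range(n_res):
        arr.coord[2 * i] = N[i]
        arr.coord[2 * i + 1] = O[i]
        for k, (name, el) in ((2 * i, ("N", "N")), (2 * i + 1, ("O", "O"))):
            arr.atom_name[k] = name
            arr.element[k] = el
            arr.res_id[k] = i + 1
            arr.res_name[k] = "ALA"
            arr.chain_id[k] = "A"
    return arr
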