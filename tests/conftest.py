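"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from itertools import permutations

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from cugraft.structure import Atom, Chain, Residue, Structure


@pytest.fixture
def poly_ala3():
    """Tiny 3-residue poly-Ala chain (15 atoms) built by hand."""
    from cugraft.synth import make_ideal_helix

    return make_ideal_helix(3)


def single_atom_structure(element: str = "C", coord=(0.0, 0.0, 0.0), chain: str = "A") -> Structure:
    res = Residue(chain, 1, "UNK", [Atom("X1", element, np.array(coord, float))])
    return Structure("one", chains=[Chain(chain, [res])])


def free_atoms_structure(specs) -> Structure:
    """specs: list of (chain_id, element, coord); one single-atom residue each."""
    chains: dict[str, Chain] = {}
    for i, (cid, el, coord) in enumerate(specs, start=1):
        chains.setdefault(cid, Chain(cid))
        chains[cid].residues.append(
            Residue(cid, len(chains[cid].residues) + 1, "UNK", [Atom("X1", el, np.array(coord, float))])
        )
    return Structure("atoms", chains=list(chains.values()))


def grid_rmsd_oracle(metal, donors, ideal, step: float = 8.0) -> float:
    """Brute-force RMSD-to-ideal by scanning rotations on an Euler grid over
    SO(3) and all 24 donor-to-vertex assignments. Independent of the Kabsch
    path; by construction an upper bound on the optimal value."""
    v = np.asarray(donors, float) - np.asarray(metal, float)
    scale = np.linalg.norm(v, axis=1).mean()
    ref = ideal.unit_vertices * scale
    a = np.arange(0.0, 360.0, step)
    b = np.arange(0.0, 180.0, step)
    eul = np.array(np.meshgrid(a, b, a, indexing="ij")).reshape(3, -1).T
    Rs = Rotation.from_euler("zyz", eul, degrees=True).as_matrix()
    best = np.inf
    for perm in permutations(range(4)):
        rot = np.einsum("nij,kj->nki", Rs, ref[list(perm)])
        d2 = np.sum((rot - v[None]) ** 2, axis=(1, 2)) / 4.0
        best = min(best, float(np.sqrt(d2.min())))
    return best


def random_donor_site(rng: np.random.Generator, n: int = 4) -> np.ndarray:
    """Random 4-donor constellation at 1.8-2.5 Å bond lengths around the origin."""
    d = rng.normal(0.0, 1.0, (n, 3))
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    return d * rng.uniform(1.8, 2.5, (n, 1))


def spherical_cap_bsa(r1: float, r2: float, probe: float) -> float:
    """Closed-form buried area of two touching spheres (centers at r1+r2):
    the two expanded-sphere caps each sphere loses inside the other."""
    R1, R2, d = r1 + probe, r2 + probe, r1 + r2
    h1 = R1 - (d * d + R1 * R1 - R2 * R2) / (2 * d)
    h2 = R2 - (d * d + R2 * R2 - R1 * R1) / (2 * d)
    return 2.0 * np.pi * (R1 * h1 + R2 * h2)
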