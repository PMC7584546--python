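"""Synthetic scaffolds and fixtures with known ground truth.

Because no coordinates are deposited for the modelled enzymes, every pipeline
stage is exercised on generated inputs:

* :func:`make_site_scaffold` — ligand residues (His/Asp/Cys/Met, plus a water
  for the CuC motif) whose donor atoms sit *exactly* at the template-mean
  geometry around planted Cu position(s); the Cu ions themselves are withheld
  (grafting has to find them) but recorded in :class:`GroundTruth` together
  with every restraint value re-measured from the emitted coordinates.
  Optional Gaussian coordinate noise (donor atoms only by default) emulates
  model error. Ligand residues are built from idealized internal-coordinate
  templates, not copied from any structure database; they satisfy the
  restraints exactly but are not rotamer-realistic.
* :func:`make_c3_trimer` — exactly C3-symmetric homotrimer for symmetrization
  tests.
* :func:`make_helix_dimer` — two ideal poly-Ala α-helices at a controllable
  axis separation for interface/SASA tests.
* :func:`make_toy_alignment` — aligned-FASTA text with planted gaps,
  substitutions and unresolved template intervals, plus per-position
  ground-truth coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial.transform import Rotation

from ._vec import orthonormal_to, place_atom, rotation_about_axis
from .geometry import donor_sets, measure_restraint
from .restraints import SiteTemplate, builtin_site_template
from .structure import Atom, Chain, Residue, Structure

__all__ = [
    "ScaffoldSpec",
    "GroundTruth",
    "make_site_scaffold",
    "default_assignment",
    "make_c3_trimer",
    "make_helix_dimer",
    "make_ideal_helix",
    "make_toy_alignment",
]


@dataclass
class ScaffoldSpec:
    site_name: str
    #: standard deviation (Å) of the total 3D displacement applied to each
    #: perturbed atom (per-coordinate sd is bond_noise_sd/sqrt(3))
    bond_noise_sd: float = 0.0
    seed: int = 0
    decoration: int = 0  # number of non-ligand padding residues (poly-Ala helix)
    whole_residue_noise: bool = False

    def __post_init__(self) -> None:
        if self.bond_noise_sd < 0:
            raise ValueError("bond_noise_sd must be >= 0")


@dataclass
class GroundTruth:
    cu_positions: list[np.ndarray]
    water_position: Optional[np.ndarray] = None
    restraint_values: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "cu_positions": [list(map(float, p)) for p in self.cu_positions],
            "water_position": (
                None if self.water_position is None else list(map(float, self.water_position))
            ),
            "restraint_values": {k: float(v) for k, v in self.restraint_values.items()},
        }


# --- imidazole ring construction ----------------------------------------------
#
# The ring is laid out in a local 2D frame with the coordinating N at the
# origin and the metal on the -x axis, so that (a) both metal-N-C angles are
# exactly 120 deg and (b) the metal lies exactly in the ring plane, i.e. the
# ring-planarity torsions are exactly 180 deg. The ring interior angle at the
# coordinating N is therefore 120 deg (an idealization; ~108 in a real
# imidazole).


def _rot2(v: np.ndarray, deg: float) -> np.ndarray:
    th = np.radians(deg)
    c, s = np.cos(th), np.sin(th)
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1]])


def _unit2(deg: float) -> np.ndarray:
    th = np.radians(deg)
    return np.array([np.cos(th), np.sin(th)])


def _imidazole_local(donor: str) -> dict[str, np.ndarray]:
    """2D ring coordinates keyed by PDB atom name; donor atom at the origin."""
    if donor == "ND1":
        minus, b_minus, minus_next, b_mn = "CE1", 1.32, "NE2", 1.33
        plus, b_plus, plus_next, b_pn = "CG", 1.38, "CD2", 1.37
    elif donor == "NE2":
        minus, b_minus, minus_next, b_mn = "CE1", 1.32, "ND1", 1.33
        plus, b_plus, plus_next, b_pn = "CD2", 1.36, "CG", 1.37
    else:
        raise ValueError(f"His donor must be ND1 or NE2, got {donor}")
    out = {donor: np.zeros(2)}
    p_minus = b_minus * _unit2(-60.0)
    p_plus = b_plus * _unit2(+60.0)
    out[minus] = p_minus
    out[plus] = p_plus
    back_minus = -p_minus / np.linalg.norm(p_minus)
    out[minus_next] = p_minus + b_mn * _rot2(back_minus, -106.0)
    back_plus = -p_plus / np.linalg.norm(p_plus)
    out[plus_next] = p_plus + b_pn * _rot2(back_plus, +106.0)
    return out


def _to3d(origin: np.ndarray, u: np.ndarray, w: np.ndarray, p2d: np.ndarray) -> np.ndarray:
    return origin + p2d[0] * u + p2d[1] * w


def _backbone_from_cb(
    atoms: dict[str, np.ndarray], outward: np.ndarray, perp: np.ndarray, anchor: str = "CB"
) -> None:
    """Attach CA/N/C/O beyond an existing CB with standard bond lengths.

    Directions are deterministic and point away from the site; none of these
    atoms carry restraints, so only bond lengths need to be sensible.
    """
    cb = atoms[anchor]
    outward = outward / np.linalg.norm(outward)
    perp = perp / np.linalg.norm(perp)
    ca = cb + 1.53 * _norm3(outward + 0.7 * perp)
    atoms["CA"] = ca
    atoms.setdefault("N", ca + 1.46 * _norm3(outward - 0.9 * perp))
    c = ca + 1.52 * _norm3(perp + 0.4 * outward)
    atoms["C"] = c
    atoms["O"] = c + 1.23 * _norm3(perp - 0.5 * outward)


def _norm3(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


_ELEMENTS = {
    "N": "N",
    "ND1": "N",
    "NE2": "N",
    "CA": "C",
    "CB": "C",
    "CG": "C",
    "CD2": "C",
    "CE1": "C",
    "C": "C",
    "O": "O",
    "OD1": "O",
    "OD2": "O",
    "SG": "S",
    "SD": "S",
    "CE": "C",
}


def _mk_res(chain_id: str, seq: int, name: str, atoms: dict[str, np.ndarray]) -> Residue:
    order = ["N", "CA", "C", "O", "CB", "CG", "SG", "SD", "CE", "OD1", "OD2", "ND1", "CD2", "CE1", "NE2"]
    alist = [
        Atom(n, _ELEMENTS[n], atoms[n]) for n in order if n in atoms
    ]
    return Residue(chain_id, seq, name, alist)


def _build_his(
    cu: np.ndarray,
    u: np.ndarray,
    w: np.ndarray,
    donor: str,
    bond: float,
    chain_id: str,
    seq: int,
    backbone_n: Optional[tuple[np.ndarray, float, float]] = None,
) -> Residue:
    """His with the donor N at ``cu + bond*u`` and the metal exactly in the
    ring plane (spanned by u, w). ``backbone_n`` = (direction, distance,
    cu_n_ca_angle) places a metal-coordinating backbone amino group too (the
    N-terminal CuB arrangement)."""
    n_pos = cu + bond * u
    ring2d = _imidazole_local(donor)
    atoms = {name: _to3d(n_pos, u, w, p) for name, p in ring2d.items()}
    centroid = np.mean([atoms[k] for k in ring2d], axis=0)
    perp = np.cross(u, w)
    cg = atoms["CG"]
    atoms["CB"] = cg + 1.50 * _norm3(cg - centroid)
    if backbone_n is None:
        _backbone_from_cb(atoms, outward=atoms["CB"] - centroid, perp=perp)
    else:
        un, dn, ang = backbone_n
        n_bb = cu + dn * un
        atoms["N"] = n_bb
        # CA on the (Cu, N, CA) = ang cone, azimuth toward the ring side
        toward = _norm3(atoms["CB"] - n_bb)
        toward = _norm3(toward - np.dot(toward, un) * un)
        th = np.radians(ang)
        ca = n_bb + 1.46 * (np.cos(th) * (-un) + np.sin(th) * toward)
        atoms["CA"] = ca
        atoms["CB"] = ca + 1.53 * _norm3(cg - ca)
        c = ca + 1.52 * _norm3(un + 0.5 * perp)
        atoms["C"] = c
        atoms["O"] = c + 1.23 * _norm3(perp)
    return _mk_res(chain_id, seq, "HIS", atoms)


def _build_asp(
    cu: np.ndarray, u: np.ndarray, bond: float, chain_id: str, seq: int
) -> Residue:
    od1 = cu + bond * u
    w = orthonormal_to(u)
    th = np.radians(109.0)
    cg = od1 + 1.25 * (np.cos(th) * (-u) + np.sin(th) * w)
    to_od1 = _norm3(od1 - cg)
    perp = np.cross(u, w)
    od2 = cg + 1.25 * _norm3(rotation_about_axis(perp, 126.0) @ to_od1)
    cb = cg + 1.52 * _norm3(rotation_about_axis(perp, -117.0) @ to_od1)
    atoms = {"OD1": od1, "CG": cg, "OD2": od2, "CB": cb}
    _backbone_from_cb(atoms, outward=cb - cu, perp=perp)
    return _mk_res(chain_id, seq, "ASP", atoms)


def _build_met(
    cu: np.ndarray, u: np.ndarray, bond: float, chain_id: str, seq: int
) -> Residue:
    """Met thioether ligand: both Cu-Sδ-Cβ and Cu-Sδ-Cε exactly 109 deg."""
    sd = cu + bond * u
    w = orthonormal_to(u)
    perp = np.cross(u, w)
    th = np.radians(109.0)

    def on_cone(azimuth_deg: float, dist: float) -> np.ndarray:
        t = np.radians(azimuth_deg)
        lateral = np.cos(t) * w + np.sin(t) * perp
        return sd + dist * (np.cos(th) * (-u) + np.sin(th) * lateral)

    ce = on_cone(0.0, 1.79)
    cb = on_cone(180.0, 2.78)  # two bonds away through CG
    cg = sd + 1.81 * _norm3(0.85 * _norm3(cb - sd) + 0.4 * u)
    atoms = {"SD": sd, "CE": ce, "CG": cg, "CB": cb}
    _backbone_from_cb(atoms, outward=cb - cu, perp=perp)
    return _mk_res(chain_id, seq, "MET", atoms)


def _build_cys_bridging(
    sg: np.ndarray, cu1: np.ndarray, cu2: np.ndarray, chain_id: str, seq: int
) -> Residue:
    """Bridging thiolate: Cβ placed so that BOTH Cu-Sγ-Cβ angles are exactly 109 deg
    (intersection of the two 109 deg cones about the Sγ→Cu axes)."""
    a1 = _norm3(cu1 - sg)
    a2 = _norm3(cu2 - sg)
    m = _norm3(a1 + a2)
    gamma = np.degrees(np.arccos(np.clip(np.dot(a1, a2), -1, 1)))
    cos_alpha = np.cos(np.radians(109.0)) / np.cos(np.radians(gamma / 2.0))
    cos_alpha = float(np.clip(cos_alpha, -1.0, 1.0))
    n = _norm3(np.cross(a1, a2))
    alpha = np.arccos(cos_alpha)
    direction = np.cos(alpha) * m + np.sin(alpha) * n
    cb = sg + 1.81 * direction
    atoms = {"SG": sg, "CB": cb}
    mid = 0.5 * (cu1 + cu2)
    _backbone_from_cb(atoms, outward=cb - mid, perp=n)
    return _mk_res(chain_id, seq, "CYS", atoms)


def _water(pos: np.ndarray, chain_id: str, seq: int) -> Residue:
    return Residue(chain_id, seq, "HOH", [Atom("O", "O", pos)])


_SQ3 = np.sqrt(3.0)
_TET = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float) / _SQ3


def default_assignment(site_name: str) -> dict[str, tuple[str, int]]:
    """Role → (chain, seq_id) map matching :func:`make_site_scaffold` output."""
    if site_name == "CuB":
        return {"his38": ("A", 38), "his142": ("A", 142), "his144": ("A", 144)}
    if site_name == "CuC":
        return {
            "asp136": ("A", 136),
            "his140": ("A", 140),
            "his153": ("A", 153),
            "water": ("A", 201),
        }
    if site_name == "CuA2":
        return {
            "cys58A": ("A", 58),
            "met66A": ("A", 66),
            "his68A": ("A", 68),
            "cys58B": ("B", 58),
            "met66B": ("B", 66),
            "his68B": ("B", 68),
        }
    raise KeyError(f"unknown site {site_name!r}")


def _build_cub_site() -> tuple[dict[str, Residue], list[np.ndarray], Optional[np.ndarray]]:
    cu = np.zeros(3)
    # square-planar donor directions (flattened-tetrahedral site)
    ex, ey, ez = np.eye(3)
    his38 = _build_his(
        cu, ey, -ez, "ND1", 1.8, "A", 38, backbone_n=(ex, 2.2, 109.0)
    )
    his142 = _build_his(cu, -ex, ez, "NE2", 2.1, "A", 142)
    his144 = _build_his(cu, -ey, ez, "NE2", 1.9, "A", 144)
    return {"A:38": his38, "A:142": his142, "A:144": his144}, [cu], None


def _build_cuc_site() -> tuple[dict[str, Residue], list[np.ndarray], Optional[np.ndarray]]:
    cu = np.zeros(3)
    t = _TET
    asp = _build_asp(cu, t[0], 2.0, "A", 136)
    his140 = _build_his(cu, t[1], orthonormal_to(t[1]), "NE2", 1.9, "A", 140)
    his153 = _build_his(cu, t[2], orthonormal_to(t[2]), "NE2", 1.9, "A", 153)
    wat_pos = cu + 1.9 * t[3]
    water = _water(wat_pos, "A", 201)
    return (
        {"A:136": asp, "A:140": his140, "A:153": his153, "A:201": water},
        [cu],
        wat_pos,
    )


def _build_cua2_site() -> tuple[dict[str, Residue], list[np.ndarray], Optional[np.ndarray]]:
    half = 2.50 / 2.0
    cu1 = np.array([-half, 0.0, 0.0])
    cu2 = np.array([+half, 0.0, 0.0])
    sy = np.sqrt(2.30**2 - half**2)
    sga = np.array([0.0, +sy, 0.0])
    sgb = np.array([0.0, -sy, 0.0])
    cysA = _build_cys_bridging(sga, cu1, cu2, "A", 58)
    cysB = _build_cys_bridging(sgb, cu1, cu2, "B", 58)
    # Met Sδ and His Nδ complete a distorted tetrahedron on each Cu,
    # pointing away from the partner Cu and out of the rhombus plane
    out1 = np.array([-np.cos(np.radians(50)), 0.0, +np.sin(np.radians(50))])
    dn1 = np.array([-np.cos(np.radians(50)), 0.0, -np.sin(np.radians(50))])
    out2 = out1 * np.array([-1, 1, 1])
    dn2 = dn1 * np.array([-1, 1, 1])
    metA = _build_met(cu1, out1, 2.50, "A", 66)
    metB = _build_met(cu2, out2, 2.50, "B", 66)
    hisA = _build_his(cu1, dn1, _norm3(np.cross(dn1, np.array([0.0, 1.0, 0.0]))), "ND1", 2.10, "A", 68)
    hisB = _build_his(cu2, dn2, _norm3(np.cross(dn2, np.array([0.0, 1.0, 0.0]))), "ND1", 2.10, "B", 68)
    return (
        {"A:58": cysA, "A:66": metA, "A:68": hisA, "B:58": cysB, "B:66": metB, "B:68": hisB},
        [cu1, cu2],
        None,
    )


_SITE_BUILDERS = {"CuB": _build_cub_site, "CuC": _build_cuc_site, "CuA2": _build_cua2_site}


def make_site_scaffold(spec: ScaffoldSpec) -> tuple[Structure, GroundTruth]:
    """Build a scaffold presenting the donor constellation of one site.

    Donor atoms start exactly at template-mean geometry around planted Cu
    position(s), then receive Gaussian noise of sd ``bond_noise_sd`` (donor
    atoms only, unless ``whole_residue_noise``). The Cu ions (and their exact
    positions) live only in the returned :class:`GroundTruth`; the structure
    contains no CU entity. The whole assembly is put through a seeded random
    rigid transform so nothing is axis-aligned."""
    if spec.site_name not in _SITE_BUILDERS:
        raise KeyError(f"unknown site {spec.site_name!r}; available: {', '.join(_SITE_BUILDERS)}")
    template = builtin_site_template(spec.site_name)
    residues, cu_positions, water_pos = _SITE_BUILDERS[spec.site_name]()
    rng = np.random.default_rng(spec.seed)

    assignment = default_assignment(spec.site_name)
    roles = {role: residues[f"{ch}:{seq}"] for role, (ch, seq) in assignment.items()}

    # noise on donor atoms (those bound by metal-ligand distance terms)
    donor_atoms: set[tuple[int, str]] = set()
    for sels in donor_sets(template).values():
        for sel in sels:
            donor_atoms.add((id(roles[sel.role]), sel.atom))
    # rigid transform drawn before the noise so scaffolds with the same seed
    # share a frame regardless of the noise level (noise is isotropic, so
    # applying it in the transformed frame is distributionally identical)
    R = Rotation.random(rng=rng).as_matrix()
    t = rng.uniform(-5.0, 5.0, 3)

    per_axis_sd = spec.bond_noise_sd / np.sqrt(3.0)
    for res in residues.values():
        for atom in res.atoms:
            if spec.whole_residue_noise or (id(res), atom.name) in donor_atoms:
                if spec.bond_noise_sd > 0:
                    atom.coord = atom.coord + rng.normal(0.0, per_axis_sd, 3)

    # assemble chains (polymer residues) + hetero (water)
    s = Structure(id=f"{spec.site_name}-scaffold-seed{spec.seed}")
    chains: dict[str, Chain] = {}
    for res in residues.values():
        if res.res_name == "HOH":
            s.hetero.append(res)
            continue
        chains.setdefault(res.chain_id, Chain(res.chain_id))
        chains[res.chain_id].residues.append(res)
    for cid in sorted(chains):
        chains[cid].residues.sort(key=lambda r: r.seq_id)
        s.chains.append(chains[cid])

    if spec.decoration > 0:
        site_coords = s.coords()
        extent = float(np.max(np.linalg.norm(site_coords, axis=1)))
        helix = make_ideal_helix(spec.decoration, chain_id="P", start_seq=301)
        offset = np.array([0.0, 0.0, extent + 12.0])
        for r in helix.chains[0].residues:
            for a in r.atoms:
                a.coord = a.coord + offset
        s.chains.append(helix.chains[0])

    # seeded random rigid transform of everything (incl. ground truth)
    for _, a in s.iter_atoms():
        a.coord = R @ a.coord + t
    cu_positions = [R @ p + t for p in cu_positions]
    if water_pos is not None:
        water_pos = R @ water_pos + t  # planted (pre-noise) position

    metal_pos = {f"CU{i + 1}": p for i, p in enumerate(cu_positions)}
    truth = GroundTruth(
        cu_positions=cu_positions,
        water_position=water_pos,
        restraint_values={
            r.label: measure_restraint(r, roles, metal_pos) for r in template.restraints
        },
    )
    s.validate()
    return s, truth


# --- ideal helices, trimers, dimers ---------------------------------------------

_HELIX_PHI, _HELIX_PSI, _OMEGA = -57.0, -47.0, 180.0
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_CA_CB = 1.458, 1.525, 1.329, 1.231, 1.53
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA = 111.2, 116.2, 121.7


def make_ideal_helix(n_res: int, chain_id: str = "A", start_seq: int = 1) -> Structure:
    """Ideal poly-Ala α-helix (φ = −57°, ψ = −47°, ω = 180°)."""
    if n_res < 1:
        raise ValueError("n_res must be >= 1")
    bb: list[dict[str, np.ndarray]] = []
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = n0 + np.array([_B_N_CA, 0.0, 0.0])
    th = np.radians(180.0 - _A_N_CA_C)
    c0 = ca0 + _B_CA_C * np.array([np.cos(th), np.sin(th), 0.0])
    prev = {"N": n0, "CA": ca0, "C": c0}
    bb.append(prev)
    for _ in range(1, n_res):
        n = place_atom(prev["N"], prev["CA"], prev["C"], _B_C_N, _A_CA_C_N, _HELIX_PSI)
        ca = place_atom(prev["CA"], prev["C"], n, _B_N_CA, _A_C_N_CA, _OMEGA)
        c = place_atom(prev["C"], n, ca, _B_CA_C, _A_N_CA_C, _HELIX_PHI)
        prev = {"N": n, "CA": ca, "C": c}
        bb.append(prev)
    residues = []
    for i, atoms in enumerate(bb):
        full = dict(atoms)
        nxt_n = bb[i + 1]["N"] if i + 1 < len(bb) else place_atom(
            atoms["N"], atoms["CA"], atoms["C"], _B_C_N, _A_CA_C_N, _HELIX_PSI
        )
        full["O"] = place_atom(nxt_n, atoms["CA"], atoms["C"], _B_C_O, 120.5, 180.0)
        full["CB"] = place_atom(atoms["C"], atoms["N"], atoms["CA"], _B_CA_CB, 110.5, -122.0)
        alist = [Atom(nm, nm[0], full[nm]) for nm in ("N", "CA", "C", "O", "CB")]
        residues.append(Residue(chain_id, start_seq + i, "ALA", alist))
    return Structure(id=f"helix{n_res}", chains=[Chain(chain_id, residues)])


class SymmetryError(ValueError):
    pass


def make_c3_trimer(monomer: Structure, radius: float) -> Structure:
    """Three copies of ``monomer`` rotated by 0/120/240° about z, each displaced
    by ``radius`` along its rotated x axis. Exactly C3-symmetric by construction.
    Chain ids are reassigned alphabetically (A, B, C, ... per copy)."""
    if monomer.n_atoms == 0:
        raise SymmetryError("monomer has no atoms")
    out = Structure(id=f"{monomer.id}-c3")
    letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    if 3 * len(monomer.chains) > len(letters):
        raise SymmetryError("too many chains to relabel")
    shift = np.array([radius, 0.0, 0.0])
    idx = 0
    for k in range(3):
        R = rotation_about_axis(np.array([0.0, 0.0, 1.0]), 120.0 * k)
        for c in monomer.chains:
            new_id = letters[idx]
            idx += 1
            nc = Chain(new_id)
            for r in c.residues:
                nr = Residue(new_id, r.seq_id, r.res_name, [], r.insertion_code)
                for a in r.atoms:
                    nr.atoms.append(Atom(a.name, a.element, R @ (a.coord + shift), a.occupancy, a.b_factor))
                nc.residues.append(nr)
            out.chains.append(nc)
        for r in monomer.hetero:
            nr = Residue(out.chains[-1].id, r.seq_id, r.res_name, [], r.insertion_code)
            for a in r.atoms:
                nr.atoms.append(Atom(a.name, a.element, R @ (a.coord + shift), a.occupancy, a.b_factor))
            out.hetero.append(nr)
    return out


def make_helix_dimer(separation: float, seed: int = 0, n_res: int = 12) -> Structure:
    """Two ideal poly-Ala helices with axes ``separation`` Å apart (chains A, B).

    The second helix is rotated about its own axis by a seeded random azimuth,
    so different seeds present different interface faces."""
    rng = np.random.default_rng(seed)
    h1 = make_ideal_helix(n_res, chain_id="A")
    h2 = make_ideal_helix(n_res, chain_id="B")
    # helix axis ≈ principal component of CA positions
    cas = np.array([r.atom("CA").coord for r in h1.chains[0].residues])
    centroid = cas.mean(axis=0)
    _, _, vt = np.linalg.svd(cas - centroid)
    axis = vt[0]
    azimuth = rng.uniform(0.0, 360.0)
    R = rotation_about_axis(axis, azimuth)
    # displacement perpendicular to the axis
    perp = orthonormal_to(axis)
    for r in h2.chains[0].residues:
        for a in r.atoms:
            a.coord = R @ (a.coord - centroid) + centroid + separation * perp
    return Structure(id=f"helixdimer-sep{separation:g}", chains=[h1.chains[0], h2.chains[0]])


# --- toy alignments --------------------------------------------------------------

_AA = "ACDEFGHIKLMNPQRSTVWY"


def make_toy_alignment(
    target_length: int,
    template_specs: list[dict],
    seed: int = 0,
    target_id: str = "target",
) -> tuple[str, dict]:
    """Aligned FASTA (target first) with planted template gaps and substitutions.

    Each template spec is a dict with keys ``id``, optional ``gap_positions``
    (1-based target positions the template does not align), optional ``subs``
    (map of 1-based target position → replacement letter) and optional
    ``unresolved`` (list of [start, end] template intervals, recorded for
    downstream coverage accounting). Returns (fasta_text, ground_truth) where
    ground_truth holds the target sequence, per-template unresolved intervals
    and the brute-force per-position covered flags."""
    rng = np.random.default_rng(seed)
    target = "".join(rng.choice(list(_AA), size=target_length))
    rows = [(target_id, target)]
    unresolved: dict[str, list[list[int]]] = {}
    covered = np.zeros(target_length, dtype=bool)
    for spec in template_specs:
        tid = spec["id"]
        gaps = set(spec.get("gap_positions", ()))
        subs = {int(k): v for k, v in spec.get("subs", {}).items()}
        unres = [list(map(int, iv)) for iv in spec.get("unresolved", ())]
        unresolved[tid] = unres
        row = []
        tpos = 0
        cov_here = np.zeros(target_length, dtype=bool)
        for i, aa in enumerate(target, start=1):
            if i in gaps:
                row.append("-")
                continue
            tpos += 1
            row.append(subs.get(i, aa))
            if not any(s <= tpos <= e for s, e in unres):
                cov_here[i - 1] = True
        rows.append((tid, "".join(row)))
        covered |= cov_here
    fasta = "".join(f">{rid}\n{seq}\n" for rid, seq in rows)
    truth = {
        "target": target,
        "unresolved": unresolved,
        "covered": covered.tolist(),
        "n_uncovered": int((~covered).sum()),
    }
    return fasta, truth
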