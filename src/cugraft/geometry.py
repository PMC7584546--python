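"""Coordination-geometry validation for mono- and dinuclear Cu sites.

Metrics:

* RMSD of the four donor atoms from an ideal coordination polyhedron
  (tetrahedral or square planar), minimised over all rotations (Kabsch) and
  all donor-to-vertex assignments, with the metal pinned at the origin and
  the ideal scaled to the mean observed bond length. This is the label-free
  convention that returns exactly 0 for a perfect polyhedron.
* Dinuclear Cu₂S₂ descriptors: Cu–Cu separation, maximum (and rms) deviation
  of the four core atoms from their least-squares plane, and the fold angle
  between the two CuS₂ planes along the S–S hinge (180° = planar rhombus).
* Backbone φ/ψ torsions as a coarse model check.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import permutations
from typing import NamedTuple, Optional

import numpy as np
from scipy.spatial.transform import Rotation

from ._vec import angle_deg, dihedral_deg, distance
from .restraints import AtomSel, GaussianRestraint, SiteTemplate
from .structure import Residue, Structure

__all__ = [
    "IdealGeometry",
    "ideal_geometry",
    "SiteGeometryReport",
    "DinuclearMetrics",
    "rmsd_to_ideal",
    "dinuclear_metrics",
    "site_report",
    "backbone_dihedrals",
    "resolve_roles",
    "measure_restraint",
    "AssignmentError",
    "DegenerateGeometryError",
    "SiteReportError",
]

logger = logging.getLogger(__name__)


class AssignmentError(ValueError):
    """A role could not be bound to a suitable residue/atom."""


class DegenerateGeometryError(ValueError):
    pass


class SiteReportError(ValueError):
    pass


@dataclass(frozen=True)
class IdealGeometry:
    name: str
    unit_vertices: np.ndarray  # (4, 3), unit length


_SQRT3 = np.sqrt(3.0)

_IDEALS = {
    "tetrahedral": np.array(
        [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
    )
    / _SQRT3,
    "square_planar": np.array(
        [[1, 0, 0], [0, 1, 0], [-1, 0, 0], [0, -1, 0]], dtype=float
    ),
}

#: ideal coordination polyhedron used to score each bundled site
SITE_IDEALS = {"CuB": "square_planar", "CuC": "tetrahedral", "CuA2": "tetrahedral"}


def ideal_geometry(name: str) -> IdealGeometry:
    try:
        return IdealGeometry(name, _IDEALS[name].copy())
    except KeyError:
        raise KeyError(f"unknown ideal geometry {name!r}; available: {', '.join(_IDEALS)}") from None


def rmsd_to_ideal(metal: np.ndarray, donors: np.ndarray, ideal: IdealGeometry) -> float:
    """Minimal RMSD (Å) of 4 donor atoms from the ideal polyhedron around the metal.

    The metal is translated to the origin, the ideal vertices are scaled to the
    mean observed metal–donor distance, and the RMSD is minimised over all
    rotations (Kabsch) and all 24 donor-to-vertex assignments.
    """
    donors = np.asarray(donors, float)
    if donors.shape != (4, 3):
        raise ValueError(f"need exactly 4 donors, got shape {donors.shape}")
    v = donors - np.asarray(metal, float)
    norms = np.linalg.norm(v, axis=1)
    if np.any(norms < 1e-6):
        raise DegenerateGeometryError("donor coincides with the metal")
    ref = ideal.unit_vertices * norms.mean()
    best = np.inf
    with warnings.catch_warnings():
        # coplanar vertex sets make the optimal rotation non-unique; the
        # residual (all we use) is still well defined
        warnings.filterwarnings("ignore", message="Optimal rotation is not uniquely")
        for perm in permutations(range(4)):
            _, rssd = Rotation.align_vectors(v, ref[list(perm)])
            best = min(best, rssd / 2.0)  # rmsd over 4 points
    return float(best)


class DinuclearMetrics(NamedTuple):
    cu_cu: float
    rhombus_max_dev: float
    rhombus_rms_dev: float
    plane_fold_angle: float


def dinuclear_metrics(cu1, cu2, s1, s2) -> DinuclearMetrics:
    """Cu–Cu distance, Cu₂S₂ planarity and CuS₂/CuS₂ fold angle.

    The fold angle is measured along the S1–S2 hinge between the (Cu1,S1,S2)
    and (Cu2,S1,S2) planes, mapped so that a planar rhombus gives 180°. With
    coincident Cu positions the fold angle degenerates to 0° and cu_cu to 0.
    """
    cu1, cu2, s1, s2 = (np.asarray(p, float) for p in (cu1, cu2, s1, s2))
    hinge = s2 - s1
    if np.linalg.norm(hinge) < 1e-9:
        raise DegenerateGeometryError("bridging S atoms coincide")
    for cu, name in ((cu1, "Cu1"), (cu2, "Cu2")):
        area2 = np.linalg.norm(np.cross(hinge, cu - s1))
        if area2 < 1e-9:
            raise DegenerateGeometryError(f"{name} collinear with the S–S hinge")
    pts = np.stack([cu1, s1, cu2, s2])
    centroid = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - centroid)
    dev = (pts - centroid) @ vt[-1]
    cu_cu = distance(cu1, cu2)
    if cu_cu < 1e-9:
        fold = 0.0
    else:
        fold = abs(dihedral_deg(cu1, s1, s2, cu2))
    return DinuclearMetrics(
        cu_cu=cu_cu,
        rhombus_max_dev=float(np.max(np.abs(dev))),
        rhombus_rms_dev=float(np.sqrt(np.mean(dev**2))),
        plane_fold_angle=fold,
    )


# --- role resolution shared with grafting -------------------------------------


def resolve_roles(
    s: Structure, template: SiteTemplate, assignment: dict[str, tuple[str, int]]
) -> dict[str, Residue]:
    """Bind template roles to residues of ``s``; validates residue type and
    presence of the donor atom."""
    roles: dict[str, Residue] = {}
    for role, (res_type, donor) in template.ligand_roles.items():
        if role not in assignment:
            raise AssignmentError(f"role {role!r} not assigned")
        chain_id, seq_id = assignment[role]
        res = s.residue(chain_id, seq_id)
        if res is None:
            raise AssignmentError(f"role {role!r}: no residue {chain_id}:{seq_id}")
        if res.res_name != res_type:
            raise AssignmentError(
                f"role {role!r}: residue {res.label} is {res.res_name}, expected {res_type}"
            )
        if res.atom(donor) is None:
            raise AssignmentError(f"role {role!r}: residue {res.label} lacks donor atom {donor}")
        roles[role] = res
    return roles


def sel_coord(
    sel: AtomSel, roles: dict[str, Residue], metal_pos: dict[str, np.ndarray]
) -> np.ndarray:
    if sel.is_metal:
        return metal_pos[sel.role]
    atom = roles[sel.role].atom(sel.atom)
    if atom is None:
        raise AssignmentError(f"role {sel.role!r}: atom {sel.atom} missing")
    return atom.coord


def measure_restraint(
    r: GaussianRestraint, roles: dict[str, Residue], metal_pos: dict[str, np.ndarray]
) -> float:
    pts = [sel_coord(a, roles, metal_pos) for a in r.atoms]
    if r.kind == "distance":
        return distance(pts[0], pts[1])
    if r.kind == "angle":
        return angle_deg(*pts)
    return dihedral_deg(*pts)


# --- per-site report -----------------------------------------------------------


@dataclass
class SiteGeometryReport:
    site_name: str
    ideal_name: str
    metal_donor_distances: list[tuple[str, float]]
    rmsd_to_ideal: dict[str, float]  # metal label -> Å
    cu_cu: Optional[float] = None
    rhombus_max_dev: Optional[float] = None
    rhombus_rms_dev: Optional[float] = None
    plane_fold_angle: Optional[float] = None
    restraint_values: list[tuple[str, float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "site_name": self.site_name,
            "ideal_name": self.ideal_name,
            "metal_donor_distances": [[k, v] for k, v in self.metal_donor_distances],
            "rmsd_to_ideal": dict(self.rmsd_to_ideal),
            "cu_cu": self.cu_cu,
            "rhombus_max_dev": self.rhombus_max_dev,
            "rhombus_rms_dev": self.rhombus_rms_dev,
            "plane_fold_angle": self.plane_fold_angle,
            "restraint_values": [[k, v] for k, v in self.restraint_values],
        }


def _metal_positions(s: Structure, template: SiteTemplate) -> dict[str, np.ndarray]:
    cus = s.cu_entities()
    if len(cus) < template.n_metals:
        raise SiteReportError(
            f"structure has {len(cus)} CU entities, site {template.name} needs {template.n_metals}"
        )
    return {f"CU{i + 1}": cus[i].atoms[0].coord for i in range(template.n_metals)}


def donor_sets(template: SiteTemplate) -> dict[str, list[AtomSel]]:
    """Donor atoms per metal, taken from the template's metal–ligand distance terms."""
    out: dict[str, list[AtomSel]] = {f"CU{i + 1}": [] for i in range(template.n_metals)}
    for r in template.by_kind("distance"):
        a, b = r.atoms
        if a.is_metal and not b.is_metal:
            out[a.role].append(b)
        elif b.is_metal and not a.is_metal:
            out[b.role].append(a)
    return out


def site_report(
    s: Structure, template: SiteTemplate, assignment: dict[str, tuple[str, int]]
) -> SiteGeometryReport:
    """Full geometry report for a grafted site: bond lengths, per-metal RMSD to
    the ideal polyhedron, dinuclear Cu₂S₂ metrics where applicable, and every
    template restraint re-measured on the coordinates."""
    roles = resolve_roles(s, template, assignment)
    metal_pos = _metal_positions(s, template)
    ideal_name = SITE_IDEALS.get(template.name, "tetrahedral")
    ideal = ideal_geometry(ideal_name)

    dists: list[tuple[str, float]] = []
    rmsds: dict[str, float] = {}
    for metal, sels in donor_sets(template).items():
        coords = []
        for sel in sels:
            c = sel_coord(sel, roles, metal_pos)
            coords.append(c)
            dists.append((f"{metal}-{roles[sel.role].label}.{sel.atom}", distance(metal_pos[metal], c)))
        if len(coords) == 4:
            rmsds[metal] = rmsd_to_ideal(metal_pos[metal], np.array(coords), ideal)

    rep = SiteGeometryReport(
        site_name=template.name,
        ideal_name=ideal_name,
        metal_donor_distances=dists,
        rmsd_to_ideal=rmsds,
        restraint_values=[
            (r.label, measure_restraint(r, roles, metal_pos)) for r in template.restraints
        ],
    )
    if template.n_metals == 2:
        # bridging thiolates = ligands bound to both metals
        ds = donor_sets(template)
        bridging = [sel for sel in ds["CU1"] if sel in ds["CU2"]]
        if len(bridging) == 2:
            m = dinuclear_metrics(
                metal_pos["CU1"],
                metal_pos["CU2"],
                sel_coord(bridging[0], roles, metal_pos),
                sel_coord(bridging[1], roles, metal_pos),
            )
            rep.cu_cu = m.cu_cu
            rep.rhombus_max_dev = m.rhombus_max_dev
            rep.rhombus_rms_dev = m.rhombus_rms_dev
            rep.plane_fold_angle = m.plane_fold_angle
    return rep


# --- backbone torsions ----------------------------------------------------------

_PEPTIDE_BOND_MAX = 2.0  # Å, C(i)–N(i+1) above this is a chain break


def backbone_dihedrals(s: Structure) -> list[tuple[Residue, float, float]]:
    """Backbone (φ, ψ) per residue; termini and residues flanking chain breaks
    are omitted. Breaks (C–N distance > 2 Å) are logged."""
    out: list[tuple[Residue, float, float]] = []
    for chain in s.chains:
        residues = [r for r in chain.residues if all(r.atom(n) for n in ("N", "CA", "C"))]
        for i in range(1, len(residues) - 1):
            prev, cur, nxt = residues[i - 1], residues[i], residues[i + 1]
            if distance(prev.atom("C").coord, cur.atom("N").coord) > _PEPTIDE_BOND_MAX:
                logger.info("chain break before %s", cur.label)
                continue
            if distance(cur.atom("C").coord, nxt.atom("N").coord) > _PEPTIDE_BOND_MAX:
                logger.info("chain break after %s", cur.label)
                continue
            phi = dihedral_deg(
                prev.atom("C").coord, cur.atom("N").coord, cur.atom("CA").coord, cur.atom("C").coord
            )
            psi = dihedral_deg(
                cur.atom("N").coord, cur.atom("CA").coord, cur.atom("C").coord, nxt.atom("N").coord
            )
            out.append((cur, phi, psi))
    return out
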