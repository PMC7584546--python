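"""Solvent-accessible surface area, buried interface area, and contacts.

SASA uses Shrake–Rupley sphere sampling with a fixed quasi-uniform (Fibonacci
lattice) point set, so results are deterministic for a given ``n_points``.
Buried surface area of a complex is BSA = SASA(A) + SASA(B) − SASA(AB), i.e.
the *total* buried area summed over both sides.

Contacts between two chains are classified as hydrogen bonds (heavy-atom
criterion: N/O donor–acceptor distance ≤ 3.5 Å and antecedent–donor–acceptor
angle ≥ 90°, since homology models carry no hydrogens) or van der Waals
contacts (distance ≤ r_vdw(a) + r_vdw(b) + 0.5 Å); per residue pair and kind,
only the closest atom pair is reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from ._vec import angle_deg
from .structure import AtomRef, Structure

__all__ = [
    "VDW_RADII",
    "SasaResult",
    "Contact",
    "sasa",
    "buried_area",
    "find_contacts",
    "RadiusTableError",
]

#: Bondi-style van der Waals radii (Å) per element
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "SE": 1.90,
    "CU": 1.40,
    "ZN": 1.39,
    "FE": 1.40,
}

DEFAULT_PROBE = 1.4  # Å, water probe
DEFAULT_N_POINTS = 960


class RadiusTableError(KeyError):
    pass


def vdw_radius(element: str, radii: Optional[dict[str, float]] = None) -> float:
    table = VDW_RADII if radii is None else radii
    el = element.upper()
    if el not in table:
        raise RadiusTableError(f"no vdW radius for element {el!r}")
    return table[el]


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform points on the unit sphere (golden-angle lattice)."""
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


@dataclass
class SasaResult:
    per_atom: dict[str, float]  # atom label -> Å²
    total: float
    probe_radius: float
    n_points: int
    refs: list[AtomRef]


def _collect(s: Structure, radii: Optional[dict[str, float]]) -> tuple[list[AtomRef], np.ndarray, np.ndarray]:
    refs = [AtomRef(r.chain_id, r, a) for r, a in s.iter_atoms()]
    coords = np.array([ref.coord for ref in refs]).reshape(-1, 3)
    rr = np.array([vdw_radius(ref.atom.element, radii) for ref in refs])
    return refs, coords, rr


def sasa(
    s: Structure,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
    radii: Optional[dict[str, float]] = None,
) -> SasaResult:
    """Shrake–Rupley solvent-accessible surface area (Å²)."""
    refs, coords, rr = _collect(s, radii)
    if len(refs) == 0:
        return SasaResult({}, 0.0, probe, n_points, [])
    sphere = _fibonacci_sphere(n_points)
    R = rr + probe
    tree = cKDTree(coords)
    max_R = R.max()
    per = np.zeros(len(refs))
    for i in range(len(refs)):
        pts = coords[i] + R[i] * sphere
        neighbors = [j for j in tree.query_ball_point(coords[i], R[i] + max_R) if j != i]
        if neighbors:
            nb_c = coords[neighbors]
            nb_R = R[np.array(neighbors)]
            d2 = np.sum((pts[:, None, :] - nb_c[None, :, :]) ** 2, axis=2)
            buried = np.any(d2 < (nb_R**2)[None, :], axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        per[i] = frac * 4.0 * np.pi * R[i] ** 2
    per_atom = {ref.label: float(v) for ref, v in zip(refs, per)}
    return SasaResult(per_atom, float(per.sum()), probe, n_points, refs)


def _subset(s: Structure, chain_ids: set[str]) -> Structure:
    sub = Structure(id=s.id)
    for c in s.chains:
        if c.id in chain_ids:
            sub.chains.append(c)
    for r in s.hetero:
        if r.chain_id in chain_ids:
            sub.hetero.append(r)
    return sub


def buried_area(
    s: Structure,
    a: set[str],
    b: set[str],
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
    radii: Optional[dict[str, float]] = None,
) -> float:
    """Total buried surface area between chain sets a and b:
    SASA(a) + SASA(b) − SASA(a∪b). Symmetric in (a, b)."""
    a, b = set(a), set(b)
    if a & b:
        raise ValueError(f"chain sets overlap: {sorted(a & b)}")
    sa = sasa(_subset(s, a), probe, n_points, radii).total
    sb = sasa(_subset(s, b), probe, n_points, radii).total
    sab = sasa(_subset(s, a | b), probe, n_points, radii).total
    return sa + sb - sab


# --- contacts ---------------------------------------------------------------------

HBOND_DIST = 3.5  # Å, heavy-atom donor–acceptor cutoff
HBOND_ANGLE = 90.0  # deg, antecedent–donor–acceptor minimum
VDW_SLACK = 0.5  # Å beyond radii sum
_BOND_MAX = 1.8  # Å, intra-residue covalent bond heuristic


@dataclass
class Contact:
    kind: str  # "hbond" | "vdw"
    atom_a: AtomRef
    atom_b: AtomRef
    distance: float
    angle: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "atom_a": self.atom_a.label,
            "atom_b": self.atom_b.label,
            "distance": self.distance,
            "angle": self.angle,
        }


def _antecedents(ref: AtomRef) -> list[AtomRef]:
    """Covalently bonded heavy atoms within the same residue (≤ 1.8 Å)."""
    out = []
    for a in ref.residue.atoms:
        if a is ref.atom or a.element.upper() == "H":
            continue
        if np.linalg.norm(a.coord - ref.coord) <= _BOND_MAX:
            out.append(AtomRef(ref.chain_id, ref.residue, a))
    return out


def _is_hbond(a: AtomRef, b: AtomRef, d: float) -> Optional[float]:
    """Return the best antecedent angle if (a→b or b→a) qualifies as an H-bond."""
    if d > HBOND_DIST:
        return None
    ea, eb = a.atom.element.upper(), b.atom.element.upper()
    if ea not in ("N", "O") or eb not in ("N", "O"):
        return None
    best = None
    for donor, acceptor in ((a, b), (b, a)):
        for ante in _antecedents(donor):
            ang = angle_deg(ante.coord, donor.coord, acceptor.coord)
            if ang >= HBOND_ANGLE and (best is None or ang > best):
                best = ang
    return best


def find_contacts(
    s: Structure,
    between: tuple[str, str],
    radii: Optional[dict[str, float]] = None,
) -> list[Contact]:
    """Inter-chain contacts between two chains, collapsed to the closest atom
    pair per residue pair and kind."""
    c1, c2 = between
    for cid in (c1, c2):
        if s.chain(cid) is None and not any(r.chain_id == cid for r in s.hetero):
            raise KeyError(f"chain {cid!r} not in structure")

    def chain_refs(cid: str) -> list[AtomRef]:
        refs = []
        ch = s.chain(cid)
        if ch is not None:
            for r in ch.residues:
                refs.extend(AtomRef(cid, r, a) for a in r.atoms if a.element.upper() != "H")
        for r in s.hetero:
            if r.chain_id == cid:
                refs.extend(AtomRef(cid, r, a) for a in r.atoms if a.element.upper() != "H")
        return refs

    refs1, refs2 = chain_refs(c1), chain_refs(c2)
    if not refs1 or not refs2:
        return []
    coords2 = np.array([r.coord for r in refs2])
    tree = cKDTree(coords2)
    max_r = max(VDW_RADII.values()) if radii is None else max(radii.values())
    cutoff = max(2 * max_r + VDW_SLACK, HBOND_DIST)

    best: dict[tuple, Contact] = {}
    for ra in refs1:
        for j in tree.query_ball_point(ra.coord, cutoff):
            rb = refs2[j]
            d = float(np.linalg.norm(ra.coord - rb.coord))
            if d <= 0:
                continue
            reskey = (id(ra.residue), id(rb.residue))
            ang = _is_hbond(ra, rb, d)
            if ang is not None:
                key = (*reskey, "hbond")
                if key not in best or d < best[key].distance:
                    best[key] = Contact("hbond", ra, rb, d, ang)
            rsum = vdw_radius(ra.atom.element, radii) + vdw_radius(rb.atom.element, radii)
            if d <= rsum + VDW_SLACK:
                key = (*reskey, "vdw")
                if key not in best or d < best[key].distance:
                    best[key] = Contact("vdw", ra, rb, d)
    return sorted(
        best.values(),
        key=lambda c: (c.atom_a.residue.seq_id, c.atom_b.residue.seq_id, c.kind, c.distance),
    )
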