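"""Gaussian geometric restraints and the bundled copper-site template library.

A restraint is a distance, angle or torsion with a mean and a standard
deviation; its energy is the negative log of a Gaussian up to a constant,
E = Δ²/(2σ²), dimensionless. Three coordination-site templates are bundled:

* ``CuB`` — mononuclear Cu(II) of the B subunit: N-terminal amino group plus
  His Nδ and two His Nε donors (flattened-tetrahedral / distorted square
  planar site).
* ``CuC`` — mononuclear Cu(II) of the C subunit: Asp Oδ1, two His Nε and a
  water O in a distorted tetrahedral arrangement.
* ``CuA2`` — dinuclear CuA-like site at a homodimer interface: a Cu₂S₂ core
  bridged by two Cys thiolates, each Cu additionally ligated by a Met Sδ and
  a His Nδ, with a direct Cu–Cu term and two rhombus-planarity torsions.

Restraints are expressed over *roles* (``his38``, ``cys58A``, ``water``, …)
plus the metal labels ``CU1``/``CU2``; a role is bound to a concrete residue
only at graft/validation time, so the same template applies to any scaffold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal, Optional

import pandas as pd

from ._vec import wrap_deg

__all__ = [
    "AtomSel",
    "GaussianRestraint",
    "SiteTemplate",
    "VdwParams",
    "METAL_ROLES",
    "SITE_NAMES",
    "builtin_site_template",
    "restraint_energy",
    "derive_cu_vdw",
    "load_restraints_tsv",
    "save_restraints_tsv",
    "RestraintValidationError",
]

Kind = Literal["distance", "angle", "dihedral"]
_ARITY = {"distance": 2, "angle": 3, "dihedral": 4}

METAL_ROLES = ("CU1", "CU2")
SITE_NAMES = ("CuB", "CuC", "CuA2")


class RestraintValidationError(ValueError):
    pass


@dataclass(frozen=True)
class AtomSel:
    """One atom selector: a role label plus an atom name within that role.

    Metal selectors use role ``CU1``/``CU2`` with atom name ``CU``.
    """

    role: str
    atom: str

    def __str__(self) -> str:
        return f"{self.role}:{self.atom}"

    @classmethod
    def parse(cls, text: str) -> "AtomSel":
        role, _, atom = text.partition(":")
        if not role or not atom:
            raise RestraintValidationError(f"bad atom selector {text!r} (expected role:atom)")
        return cls(role, atom)

    @property
    def is_metal(self) -> bool:
        return self.role in METAL_ROLES


def metal_sel(index: int = 1) -> AtomSel:
    return AtomSel(METAL_ROLES[index - 1], "CU")


@dataclass(frozen=True)
class GaussianRestraint:
    kind: Kind
    atoms: tuple[AtomSel, ...]
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.kind not in _ARITY:
            raise RestraintValidationError(f"unknown restraint kind {self.kind!r}")
        if len(self.atoms) != _ARITY[self.kind]:
            raise RestraintValidationError(
                f"{self.kind} restraint needs {_ARITY[self.kind]} atoms, got {len(self.atoms)}"
            )
        if not self.sd > 0:
            raise RestraintValidationError(f"sd must be positive, got {self.sd}")
        if self.kind == "angle" and not 0.0 <= self.mean <= 180.0:
            raise RestraintValidationError(f"angle mean {self.mean} outside [0, 180]")
        if self.kind == "dihedral" and not -180.0 < self.mean <= 180.0:
            raise RestraintValidationError(f"dihedral mean {self.mean} outside (-180, 180]")

    def deviation(self, value: float) -> float:
        """Signed deviation of an observed value from the mean (wrapped for torsions)."""
        if self.kind == "dihedral":
            return wrap_deg(value - self.mean)
        return float(value) - self.mean

    @property
    def label(self) -> str:
        return f"{self.kind}({'-'.join(map(str, self.atoms))})"


def restraint_energy(r: GaussianRestraint, geometry_value: float) -> float:
    """Dimensionless Gaussian-restraint energy (Δ/σ)²/2; zero iff at the mean."""
    d = r.deviation(geometry_value)
    return 0.5 * (d / r.sd) ** 2


@dataclass
class SiteTemplate:
    """A named coordination motif binding restraints to ligand-residue roles."""

    name: str
    n_metals: int
    ligand_roles: dict[str, tuple[str, str]]  # role -> (residue type, donor atom name)
    restraints: list[GaussianRestraint] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_metals not in (1, 2):
            raise RestraintValidationError("n_metals must be 1 or 2")
        declared = set(self.ligand_roles) | set(METAL_ROLES[: self.n_metals])
        for r in self.restraints:
            for sel in r.atoms:
                if sel.role not in declared:
                    raise RestraintValidationError(
                        f"{self.name}: restraint {r.label} references undeclared role {sel.role!r}"
                    )
        if self.n_metals == 2:
            has_mm = any(
                r.kind == "distance" and all(s.is_metal for s in r.atoms) for r in self.restraints
            )
            if not has_mm:
                raise RestraintValidationError(f"{self.name}: dinuclear site needs a metal-metal term")

    def by_kind(self, kind: Kind) -> list[GaussianRestraint]:
        return [r for r in self.restraints if r.kind == kind]

    @property
    def has_water(self) -> bool:
        return any(rt == "HOH" for rt, _ in self.ligand_roles.values())

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "n_metals": self.n_metals,
            "ligand_roles": {k: list(v) for k, v in self.ligand_roles.items()},
            "restraints": [
                {
                    "kind": r.kind,
                    "atoms": [str(a) for a in r.atoms],
                    "mean": r.mean,
                    "sd": r.sd,
                }
                for r in self.restraints
            ],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def _dist(cu: AtomSel, role: str, atom: str, mean: float, sd: float) -> GaussianRestraint:
    return GaussianRestraint("distance", (cu, AtomSel(role, atom)), mean, sd)


def _ang(cu: AtomSel, role: str, a1: str, a2: str, mean: float, sd: float) -> GaussianRestraint:
    return GaussianRestraint("angle", (cu, AtomSel(role, a1), AtomSel(role, a2)), mean, sd)


def _dih(cu: AtomSel, role: str, a1: str, a2: str, a3: str, mean: float, sd: float) -> GaussianRestraint:
    return GaussianRestraint(
        "dihedral", (cu, AtomSel(role, a1), AtomSel(role, a2), AtomSel(role, a3)), mean, sd
    )


def _his_ring_terms(cu: AtomSel, role: str, donor: str) -> list[GaussianRestraint]:
    """Angle + ring-planarity torsion family for a His ligand.

    Nδ coordination: Cu–Nδ–Cγ / Cu–Nδ–Cε angles at 120°±10°; torsions
    Cu–Nδ–Cε–Nε and Cu–Nδ–Cγ–Cδ at 180°±10° keep Cu in the imidazole plane.
    Nε coordination is the mirror-image family through Cδ/Cε.
    """
    if donor == "ND1":
        return [
            _ang(cu, role, "ND1", "CG", 120.0, 10.0),
            _ang(cu, role, "ND1", "CE1", 120.0, 10.0),
            _dih(cu, role, "ND1", "CE1", "NE2", 180.0, 10.0),
            _dih(cu, role, "ND1", "CG", "CD2", 180.0, 10.0),
        ]
    if donor == "NE2":
        return [
            _ang(cu, role, "NE2", "CD2", 120.0, 10.0),
            _ang(cu, role, "NE2", "CE1", 120.0, 10.0),
            _dih(cu, role, "NE2", "CE1", "ND1", 180.0, 10.0),
            _dih(cu, role, "NE2", "CD2", "CG", 180.0, 10.0),
        ]
    raise RestraintValidationError(f"His donor must be ND1 or NE2, got {donor}")


def _build_cub() -> SiteTemplate:
    cu = metal_sel(1)
    roles = {"his38": ("HIS", "ND1"), "his142": ("HIS", "NE2"), "his144": ("HIS", "NE2")}
    rs: list[GaussianRestraint] = [
        _dist(cu, "his38", "N", 2.2, 0.1),  # N-terminal amino group
        _dist(cu, "his38", "ND1", 1.8, 0.1),
        _dist(cu, "his142", "NE2", 2.1, 0.1),
        _dist(cu, "his144", "NE2", 1.9, 0.1),
        _ang(cu, "his38", "N", "CA", 109.0, 5.0),
    ]
    hs = _his_ring_terms(cu, "his38", "ND1")
    rs += [h for h in hs if h.kind == "angle"]
    for role in ("his142", "his144"):
        rs += [h for h in _his_ring_terms(cu, role, "NE2") if h.kind == "angle"]
    rs += [h for h in hs if h.kind == "dihedral"]
    for role in ("his142", "his144"):
        rs += [h for h in _his_ring_terms(cu, role, "NE2") if h.kind == "dihedral"]
    return SiteTemplate("CuB", 1, roles, rs)


def _build_cuc() -> SiteTemplate:
    cu = metal_sel(1)
    roles = {
        "asp136": ("ASP", "OD1"),
        "his140": ("HIS", "NE2"),
        "his153": ("HIS", "NE2"),
        "water": ("HOH", "O"),
    }
    rs: list[GaussianRestraint] = [
        _dist(cu, "asp136", "OD1", 2.0, 0.1),
        _dist(cu, "his140", "NE2", 1.9, 0.1),
        _dist(cu, "his153", "NE2", 1.9, 0.1),
        _dist(cu, "water", "O", 1.9, 0.1),
        _ang(cu, "asp136", "OD1", "CG", 109.0, 5.0),
    ]
    for role in ("his140", "his153"):
        rs += [h for h in _his_ring_terms(cu, role, "NE2") if h.kind == "angle"]
    for role in ("his140", "his153"):
        rs += [h for h in _his_ring_terms(cu, role, "NE2") if h.kind == "dihedral"]
    return SiteTemplate("CuC", 1, roles, rs)


def _build_cua2() -> SiteTemplate:
    cu1, cu2 = metal_sel(1), metal_sel(2)
    roles = {
        "cys58A": ("CYS", "SG"),
        "cys58B": ("CYS", "SG"),
        "met66A": ("MET", "SD"),
        "met66B": ("MET", "SD"),
        "his68A": ("HIS", "ND1"),
        "his68B": ("HIS", "ND1"),
    }
    rs: list[GaussianRestraint] = [
        _dist(cu1, "cys58A", "SG", 2.30, 0.10),
        _dist(cu1, "cys58B", "SG", 2.30, 0.10),
        _dist(cu2, "cys58A", "SG", 2.30, 0.10),
        _dist(cu2, "cys58B", "SG", 2.30, 0.10),
        _dist(cu1, "met66A", "SD", 2.50, 0.10),
        _dist(cu2, "met66B", "SD", 2.50, 0.10),
        _dist(cu1, "his68A", "ND1", 2.10, 0.10),
        _dist(cu2, "his68B", "ND1", 2.10, 0.10),
        GaussianRestraint("distance", (cu1, cu2), 2.50, 0.10),
    ]
    for cu, cys in ((cu1, "cys58A"), (cu1, "cys58B"), (cu2, "cys58A"), (cu2, "cys58B")):
        rs.append(_ang(cu, cys, "SG", "CB", 109.0, 5.0))
    for cu, met in ((cu1, "met66A"), (cu2, "met66B")):
        rs.append(_ang(cu, met, "SD", "CB", 109.0, 5.0))
        rs.append(_ang(cu, met, "SD", "CE", 109.0, 5.0))
    for cu, his in ((cu1, "his68A"), (cu2, "his68B")):
        rs += [h for h in _his_ring_terms(cu, his, "ND1") if h.kind == "angle"]
    for cu, his in ((cu1, "his68A"), (cu2, "his68B")):
        rs += [h for h in _his_ring_terms(cu, his, "ND1") if h.kind == "dihedral"]
    # Cu2S2 rhombus planarity: both improper torsions through the bridging thiolates
    rs.append(
        GaussianRestraint(
            "dihedral",
            (cu1, AtomSel("cys58A", "SG"), cu2, AtomSel("cys58B", "SG")),
            0.0,
            10.0,
        )
    )
    rs.append(
        GaussianRestraint(
            "dihedral",
            (cu2, AtomSel("cys58B", "SG"), cu1, AtomSel("cys58A", "SG")),
            0.0,
            10.0,
        )
    )
    return SiteTemplate("CuA2", 2, roles, rs)


_BUILDERS = {"CuB": _build_cub, "CuC": _build_cuc, "CuA2": _build_cua2}


def builtin_site_template(name: str) -> SiteTemplate:
    """Return a fresh copy of one of the bundled site templates (CuB, CuC, CuA2)."""
    try:
        return _BUILDERS[name]()
    except KeyError:
        raise KeyError(f"unknown site template {name!r}; available: {', '.join(SITE_NAMES)}") from None


# --- Cu(II) van der Waals parameters -----------------------------------------


@dataclass(frozen=True)
class VdwParams:
    r_min: float  # Å
    well_depth: float  # dimensionless internal energy scale

    def __post_init__(self) -> None:
        if not self.r_min > 0:
            raise ValueError("r_min must be positive")
        if self.well_depth < 0:
            raise ValueError("well_depth must be non-negative")


#: Zn(II) Lennard-Jones parameters (CHARMM-style Rmin/2 in Å, |epsilon|);
#: the Cu(II) parameters are derived from these by an ionic-radius scale factor.
ZN_VDW = VdwParams(r_min=1.09, well_depth=0.25)

CU_RADIUS_SCALE = 1.01


def derive_cu_vdw(zn: VdwParams = ZN_VDW, radius_scale: float = CU_RADIUS_SCALE) -> VdwParams:
    """Cu(II) vdW parameters from Zn(II): r_min scaled by the Cu(II)/Zn(II)
    ionic-radius ratio (default 1.01), well depth unchanged."""
    if not radius_scale > 0:
        raise ValueError(f"radius_scale must be positive, got {radius_scale}")
    return VdwParams(r_min=zn.r_min * radius_scale, well_depth=zn.well_depth)


# --- TSV round trip -----------------------------------------------------------

_TSV_COLUMNS = ["kind", "atoms", "mean", "sd"]


def save_restraints_tsv(restraints: list[GaussianRestraint], path: str) -> None:
    """Write restraints as TSV with columns kind / atoms (pipe-joined role:atom) / mean / sd."""
    rows = [
        {"kind": r.kind, "atoms": "|".join(map(str, r.atoms)), "mean": r.mean, "sd": r.sd}
        for r in restraints
    ]
    pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def load_restraints_tsv(path: str) -> list[GaussianRestraint]:
    try:
        df = pd.read_csv(path, sep="\t", dtype={"kind": str, "atoms": str})
    except pd.errors.EmptyDataError:
        return []
    missing = [c for c in _TSV_COLUMNS if c not in df.columns]
    if missing:
        raise RestraintValidationError(f"{path}: missing column(s) {', '.join(missing)}")
    out: list[GaussianRestraint] = []
    for i, row in df.iterrows():
        try:
            atoms = tuple(AtomSel.parse(t) for t in str(row["atoms"]).split("|"))
            out.append(GaussianRestraint(str(row["kind"]), atoms, float(row["mean"]), float(row["sd"])))
        except (RestraintValidationError, ValueError) as exc:
            raise RestraintValidationError(f"{path}: row {i + 2}: {exc}") from exc
    return out
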