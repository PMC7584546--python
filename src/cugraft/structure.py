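"""Hierarchical coordinate model (structure → chain → residue → atom) and PDB I/O.

Coordinates are in Å throughout. Author (1-based) residue numbering is kept
as-is; no renumbering ever happens, so sites can be addressed the way the
literature does ("His38", "Cys58"). Reading goes through gemmi; writing uses a
fixed-column v3.3 emitter so that TER/HETATM placement follows the container
layout exactly (polymer chains as ATOM + trailing TER, hetero entities as
HETATM). mmCIF is not supported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "Structure",
    "AtomRef",
    "PdbParseError",
    "PdbFormatError",
    "SelectionSyntaxError",
    "read_pdb",
    "write_pdb",
    "select_atoms",
]

WATER_NAMES = {"HOH", "WAT"}


class PdbParseError(ValueError):
    """Raised when a PDB file cannot be parsed (message names the offending line)."""


class PdbFormatError(ValueError):
    """Raised when a Structure cannot be expressed in fixed-column PDB."""


class SelectionSyntaxError(ValueError):
    """Raised for a malformed atom-selection expression."""


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name!r}: coord must be a finite 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.name!r}: element must be non-empty")


@dataclass
class Residue:
    chain_id: str
    seq_id: int
    res_name: str
    atoms: list[Atom] = field(default_factory=list)
    insertion_code: Optional[str] = None

    def atom(self, name: str) -> Optional[Atom]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def label(self) -> str:
        icode = self.insertion_code or ""
        return f"{self.chain_id}:{self.res_name}{self.seq_id}{icode}"


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)


@dataclass
class Structure:
    id: str = ""
    chains: list[Chain] = field(default_factory=list)
    hetero: list[Residue] = field(default_factory=list)

    def chain(self, chain_id: str) -> Optional[Chain]:
        for c in self.chains:
            if c.id == chain_id:
                return c
        return None

    def residue(self, chain_id: str, seq_id: int) -> Optional[Residue]:
        c = self.chain(chain_id)
        if c is not None:
            for r in c.residues:
                if r.seq_id == seq_id:
                    return r
        for r in self.hetero:
            if r.chain_id == chain_id and r.seq_id == seq_id:
                return r
        return None

    def iter_residues(self) -> Iterator[Residue]:
        for c in self.chains:
            yield from c.residues
        yield from self.hetero

    def iter_atoms(self) -> Iterator[tuple[Residue, Atom]]:
        for r in self.iter_residues():
            for a in r.atoms:
                yield r, a

    @property
    def n_atoms(self) -> int:
        return sum(1 for _ in self.iter_atoms())

    def coords(self) -> np.ndarray:
        """All coordinates, structure order, shape (n_atoms, 3)."""
        arr = [a.coord for _, a in self.iter_atoms()]
        return np.array(arr, dtype=float).reshape(-1, 3)

    def copy(self) -> "Structure":
        def copy_res(r: Residue) -> Residue:
            return Residue(
                r.chain_id,
                r.seq_id,
                r.res_name,
                [Atom(a.name, a.element, a.coord.copy(), a.occupancy, a.b_factor) for a in r.atoms],
                r.insertion_code,
            )

        return Structure(
            self.id,
            [Chain(c.id, [copy_res(r) for r in c.residues]) for c in self.chains],
            [copy_res(r) for r in self.hetero],
        )

    def cu_entities(self) -> list[Residue]:
        return [r for r in self.hetero if r.res_name == "CU"]

    def validate(self) -> None:
        ids = [c.id for c in self.chains]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate chain ids")
        for r in self.iter_residues():
            names = [a.name for a in r.atoms]
            if len(names) != len(set(names)):
                raise ValueError(f"duplicate atom names in {r.label}")
        for r in self.cu_entities():
            cu_atoms = [a for a in r.atoms if a.element.upper() == "CU"]
            if len(cu_atoms) != 1 or len(r.atoms) != 1:
                raise ValueError(f"Cu entity {r.label} must have exactly one Cu atom")


@dataclass(frozen=False)
class AtomRef:
    """Reference to one atom in its residue context (coordinates are shared)."""

    chain_id: str
    residue: Residue
    atom: Atom

    @property
    def coord(self) -> np.ndarray:
        return self.atom.coord

    @property
    def label(self) -> str:
        return f"{self.residue.label}.{self.atom.name}"


def _pick_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    # highest occupancy wins; ties broken by altloc letter order
    return sorted(atoms, key=lambda a: (-a.occ, a.altloc))[0]


def read_pdb(path: str) -> Structure:
    """Read a fixed-column PDB file into a :class:`Structure`.

    Only MODEL 1 is used. Alternate conformers are reduced to the
    highest-occupancy one (ties → altloc letter order). HETATM residues
    (Cu ions, waters, other non-polymer entities) go to ``Structure.hetero``.
    """
    # strict record validation (gemmi is lenient); errors name the line
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            if len(line.rstrip("\n")) < 54:
                raise PdbParseError(f"{path}: line {lineno}: record too short")
            try:
                float(line[30:38])
                float(line[38:46])
                float(line[46:54])
            except ValueError:
                raise PdbParseError(
                    f"{path}: line {lineno}: unparseable coordinate fields"
                ) from None
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise PdbParseError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise PdbParseError(f"{path}: no models / zero atoms")

    out = Structure(id=st.name or "")
    model = st[0]
    for gchain in model:
        chain = Chain(id=gchain.name)
        for gres in gchain:
            by_name: dict[str, list[gemmi.Atom]] = {}
            for ga in gres:
                by_name.setdefault(ga.name, []).append(ga)
            atoms = []
            for name, group in by_name.items():
                ga = _pick_altloc(group)
                atoms.append(
                    Atom(
                        name=name,
                        element=ga.element.name,
                        coord=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                        occupancy=ga.occ,
                        b_factor=ga.b_iso,
                    )
                )
            res = Residue(
                chain_id=gchain.name,
                seq_id=gres.seqid.num,
                res_name=gres.name.strip(),
                atoms=atoms,
                insertion_code=(gres.seqid.icode.strip() or None),
            )
            if gres.het_flag == "H" or res.res_name in WATER_NAMES | {"CU"}:
                out.hetero.append(res)
            else:
                chain.residues.append(res)
        if chain.residues:
            out.chains.append(chain)
    if out.n_atoms == 0:
        raise PdbParseError(f"{path}: zero atoms")
    out.validate()
    return out


def _format_atom_name(name: str, element: str) -> str:
    # PDB columns 13-16: element right-justified in 13-14 for 1-2 letter elements
    if len(name) >= 4:
        return name[:4]
    if len(element) == 2:
        return f"{name:<4s}"[:4]
    return f" {name:<3s}"


def _atom_line(record: str, serial: int, res: Residue, atom: Atom) -> str:
    icode = res.insertion_code or " "
    return (
        f"{record:<6s}{serial:>5d} {_format_atom_name(atom.name, atom.element)}"
        f" {res.res_name:>3s} {res.chain_id}{res.seq_id:>4d}{icode}   "
        f"{atom.coord[0]:8.3f}{atom.coord[1]:8.3f}{atom.coord[2]:8.3f}"
        f"{atom.occupancy:6.2f}{atom.b_factor:6.2f}          "
        f"{atom.element.upper():>2s}  "
    )


def write_pdb(s: Structure, path: str) -> None:
    """Write fixed-column PDB v3.3: ATOM for polymer chains (TER after each),
    HETATM for hetero entities, END last. Re-readable by :func:`read_pdb`."""
    for c in s.chains:
        if len(c.id) != 1:
            raise PdbFormatError(f"chain id {c.id!r} must be a single character")
        if not c.residues:
            raise PdbFormatError(f"chain {c.id}: empty chain")
        for r in c.residues:
            if not r.atoms:
                raise PdbFormatError(f"residue {r.label}: no atoms")
    for r in s.hetero:
        if len(r.chain_id) != 1:
            raise PdbFormatError(f"hetero chain id {r.chain_id!r} must be a single character")
        if not r.atoms:
            raise PdbFormatError(f"hetero residue {r.label}: no atoms")

    lines: list[str] = []
    serial = 0
    for c in s.chains:
        last = None
        for r in c.residues:
            for a in r.atoms:
                serial += 1
                lines.append(_atom_line("ATOM", serial, r, a))
            last = r
        serial += 1
        icode = last.insertion_code or " "
        lines.append(
            f"TER   {serial:>5d}      {last.res_name:>3s} {last.chain_id}{last.seq_id:>4d}{icode}"
        )
    for r in s.hetero:
        for a in r.atoms:
            serial += 1
            lines.append(_atom_line("HETATM", serial, r, a))
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


_SELECTION_KEYS = ("chain", "res", "resname", "atom")


def parse_selection(spec: str) -> dict[str, str]:
    tokens = spec.split()
    if len(tokens) % 2 != 0:
        raise SelectionSyntaxError(f"selection {spec!r}: expected key/value pairs")
    sel: dict[str, str] = {}
    for key, value in zip(tokens[::2], tokens[1::2]):
        if key not in _SELECTION_KEYS:
            raise SelectionSyntaxError(
                f"selection {spec!r}: unknown key {key!r} (allowed: {', '.join(_SELECTION_KEYS)})"
            )
        if key in sel:
            raise SelectionSyntaxError(f"selection {spec!r}: duplicate key {key!r}")
        sel[key] = value
    if "res" in sel:
        try:
            int(sel["res"])
        except ValueError as exc:
            raise SelectionSyntaxError(f"selection {spec!r}: res must be an integer") from exc
    return sel


def select_atoms(s: Structure, spec: str) -> list[AtomRef]:
    """Select atoms with a mini-grammar of optional ``chain``, ``res`` (number),
    ``resname`` and ``atom`` clauses, e.g. ``"chain A res 38 atom ND1"``.

    Returns references in structure order; an empty result is not an error.
    """
    sel = parse_selection(spec)
    want_res = int(sel["res"]) if "res" in sel else None
    out: list[AtomRef] = []
    for r in s.iter_residues():
        if "chain" in sel and r.chain_id != sel["chain"]:
            continue
        if want_res is not None and r.seq_id != want_res:
            continue
        if "resname" in sel and r.res_name != sel["resname"]:
            continue
        for a in r.atoms:
            if "atom" in sel and a.name != sel["atom"]:
                continue
            out.append(AtomRef(r.chain_id, r, a))
    return out
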