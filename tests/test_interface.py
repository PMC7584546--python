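"""SASA, buried surface area, and contact detection."""

import numpy as np
import pytest

from conftest import free_atoms_structure, single_atom_structure, spherical_cap_bsa
from cugraft.interface import (
    RadiusTableError,
    buried_area,
    find_contacts,
    sasa,
    vdw_radius,
)
from cugraft.structure import Atom, Chain, Residue, Structure
from cugraft.synth import make_helix_dimer


def test_single_atom_sasa_matches_sphere_area():
    s = single_atom_structure("C")  # r = 1.7, probe 1.4
    result = sasa(s)
    exact = 4.0 * np.pi * 3.1**2
    assert result.total == pytest.approx(exact, rel=0.02)
    assert result.total == pytest.approx(sum(result.per_atom.values()), abs=1e-6)


def test_disjoint_spheres_are_additive():
    s = free_atoms_structure([("A", "C", (0, 0, 0)), ("B", "C", (100, 0, 0))])
    one = sasa(single_atom_structure("C")).total
    assert sasa(s).total == pytest.approx(2 * one, abs=1e-6)


def test_fully_buried_atom_has_zero_sasa():
    # central atom caged by 26 overlapping neighbors on a 2 Å lattice
    specs = [("A", "C", (0.0, 0.0, 0.0))]
    for dx in (-2.0, 0.0, 2.0):
        for dy in (-2.0, 0.0, 2.0):
            for dz in (-2.0, 0.0, 2.0):
                if (dx, dy, dz) != (0.0, 0.0, 0.0):
                    specs.append(("B", "C", (dx, dy, dz)))
    s = free_atoms_structure(specs)
    result = sasa(s)
    central_label = result.refs[0].label
    assert result.per_atom[central_label] == 0.0


def test_sasa_unknown_element():
    with pytest.raises(RadiusTableError):
        sasa(single_atom_structure("XX"))
    assert vdw_radius("cu") == 1.40


def test_bsa_distant_chains_zero_and_symmetric():
    s = free_atoms_structure([("A", "C", (0, 0, 0)), ("B", "C", (100, 0, 0))])
    assert buried_area(s, {"A"}, {"B"}) == pytest.approx(0.0, abs=1e-6)
    dimer = make_helix_dimer(9.0, seed=2)
    ab = buried_area(dimer, {"A"}, {"B"})
    ba = buried_area(dimer, {"B"}, {"A"})
    assert ab == ba  # exact symmetry
    assert ab > 0.0
    with pytest.raises(ValueError):
        buried_area(dimer, {"A"}, {"A", "B"})


def test_bsa_touching_spheres_matches_cap_formula():
    r = 1.7
    s = free_atoms_structure([("A", "C", (0, 0, 0)), ("B", "C", (2 * r, 0, 0))])
    analytic = spherical_cap_bsa(r, r, 1.4)
    measured = buried_area(s, {"A"}, {"B"}, n_points=2000)
    assert measured == pytest.approx(analytic, rel=0.03)


def test_sasa_decreases_as_chains_approach():
    totals = []
    for sep in (100.0, 30.0, 12.0, 8.0):
        dimer = make_helix_dimer(sep, seed=4)
        totals.append(sasa(dimer).total)
    for far, near in zip(totals, totals[1:]):
        assert near <= far * 1.01  # monotone within sampling tolerance


def _brute_force_contacts(s, pair):
    """O(n²) all-pairs rescan with the same thresholds (no spatial indexing)."""
    from cugraft.interface import HBOND_DIST, VDW_SLACK, _is_hbond
    from cugraft.structure import AtomRef

    def refs(cid):
        out = []
        ch = s.chain(cid)
        if ch:
            for r in ch.residues:
                out.extend(AtomRef(cid, r, a) for a in r.atoms if a.element.upper() != "H")
        for r in s.hetero:
            if r.chain_id == cid:
                out.extend(AtomRef(cid, r, a) for a in r.atoms if a.element.upper() != "H")
        return out

    best = {}
    for ra in refs(pair[0]):
        for rb in refs(pair[1]):
            d = float(np.linalg.norm(ra.coord - rb.coord))
            if d <= 0:
                continue
            if _is_hbond(ra, rb, d) is not None:
                key = (id(ra.residue), id(rb.residue), "hbond")
                if key not in best or d < best[key][2]:
                    best[key] = (ra, rb, d)
            if d <= vdw_radius(ra.atom.element) + vdw_radius(rb.atom.element) + VDW_SLACK:
                key = (id(ra.residue), id(rb.residue), "vdw")
                if key not in best or d < best[key][2]:
                    best[key] = (ra, rb, d)
    return {
        (k[2], v[0].label, v[1].label, round(v[2], 9)) for k, v in best.items()
    }


def test_contacts_match_brute_force_on_helix_dimer():
    dimer = make_helix_dimer(8.5, seed=6)
    found = find_contacts(dimer, ("A", "B"))
    assert found, "expected contacts at 8.5 Å separation"
    got = {(c.kind, c.atom_a.label, c.atom_b.label, round(c.distance, 9)) for c in found}
    assert got == _brute_force_contacts(dimer, ("A", "B"))


def test_hbond_detection_geometry():
    # serine-like Oγ donor 2.8 Å from a glutamate-like Oε, antecedent at 109°
    og = np.array([0.0, 0.0, 0.0])
    cb = og + 1.43 * np.array([np.cos(np.radians(109.0)), np.sin(np.radians(109.0)), 0.0])
    oe = np.array([2.8, 0.0, 0.0])
    # acceptor antecedent placed at 60° so only the Ser side qualifies as donor
    cd = oe + 1.25 * np.array([-np.cos(np.radians(60.0)), np.sin(np.radians(60.0)), 0.0])
    ser = Residue("A", 1, "SER", [Atom("CB", "C", cb), Atom("OG", "O", og)])
    glu = Residue("B", 1, "GLU", [Atom("CD", "C", cd), Atom("OE1", "O", oe)])
    s = Structure("hb", chains=[Chain("A", [ser]), Chain("B", [glu])])
    contacts = find_contacts(s, ("A", "B"))
    hbonds = [c for c in contacts if c.kind == "hbond"]
    assert len(hbonds) == 1
    assert hbonds[0].distance == pytest.approx(2.8)
    assert hbonds[0].angle == pytest.approx(109.0, abs=0.1)


def test_no_contacts_between_distant_side_chains():
    s = free_atoms_structure([("A", "C", (0, 0, 0)), ("B", "C", (10, 0, 0))])
    assert find_contacts(s, ("A", "B")) == []
    with pytest.raises(KeyError):
        find_contacts(s, ("A", "Q"))


def test_sasa_against_independent_implementation():
    """Cross-check Shrake-Rupley totals against biotite with matched radii."""
    import biotite.structure as struc

    dimer = make_helix_dimer(9.0, seed=1)
    refs = [(r, a) for r, a in dimer.iter_atoms()]
    arr = struc.AtomArray(len(refs))
    arr.coord = np.array([a.coord for _, a in refs], dtype=np.float32)
    arr.chain_id = np.array([r.chain_id for r, _ in refs])
    arr.res_id = np.array([r.seq_id for r, _ in refs])
    arr.res_name = np.array([r.res_name for r, _ in refs])
    arr.atom_name = np.array([a.name for _, a in refs])
    arr.element = np.array([a.element.upper() for _, a in refs])
    radii = np.array([vdw_radius(a.element) for _, a in refs])
    reference = float(np.nansum(struc.sasa(arr, probe_radius=1.4, point_number=960, vdw_radii=radii)))
    ours = sasa(dimer, 1.4, 960).total
    assert ours == pytest.approx(reference, rel=0.01)
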