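"""Restrained metal placement, clash penalty, and C3 symmetrization."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from conftest import free_atoms_structure
from cugraft._vec import rotation_about_axis
from cugraft.geometry import AssignmentError
from cugraft.grafting import (
    GraftProblem,
    SymmetryError,
    clash_penalty,
    graft_site,
    symmetrize_c3,
)
from cugraft.restraints import VdwParams, builtin_site_template
from cugraft.synth import ScaffoldSpec, default_assignment, make_c3_trimer, make_ideal_helix, make_site_scaffold


@pytest.mark.parametrize("site", ["CuB", "CuC"])
def test_zero_noise_graft_is_zero_residual(site):
    s, gt = make_site_scaffold(ScaffoldSpec(site, 0.0, seed=1))
    res = graft_site(
        GraftProblem(s, builtin_site_template(site), default_assignment(site), seed=3, n_starts=4)
    )
    assert res.converged
    assert res.final_energy < 1e-3
    for placed, truth in zip(res.cu_positions, gt.cu_positions):
        assert np.linalg.norm(placed - truth) < 1e-2
    assert len(res.structure.cu_entities()) == builtin_site_template(site).n_metals
    assert len(res.per_restraint) == len(builtin_site_template(site).restraints)


def test_cua2_graft_recovers_cu_cu_distance():
    s, gt = make_site_scaffold(ScaffoldSpec("CuA2", 0.3, seed=7))
    res = graft_site(
        GraftProblem(s, builtin_site_template("CuA2"), default_assignment("CuA2"), seed=7, n_starts=4)
    )
    cu_cu = float(np.linalg.norm(res.cu_positions[0] - res.cu_positions[1]))
    assert cu_cu == pytest.approx(2.50, abs=0.30)
    # planted positions recovered to well under the donor noise
    for placed, truth in zip(res.cu_positions, gt.cu_positions):
        assert np.linalg.norm(placed - truth) < 0.3


def test_graft_descent_is_monotone():
    s, _ = make_site_scaffold(ScaffoldSpec("CuC", 0.2, seed=5))
    res = graft_site(
        GraftProblem(s, builtin_site_template("CuC"), default_assignment("CuC"), seed=5, n_starts=2)
    )
    traj = res.trajectory
    assert len(traj) >= 2
    assert all(a >= b - 1e-9 for a, b in zip(traj, traj[1:]))


def test_graft_is_deterministic_for_fixed_seed():
    s, _ = make_site_scaffold(ScaffoldSpec("CuC", 0.2, seed=9))
    tpl, asn = builtin_site_template("CuC"), default_assignment("CuC")
    r1 = graft_site(GraftProblem(s, tpl, asn, seed=42, n_starts=3))
    r2 = graft_site(GraftProblem(s, tpl, asn, seed=42, n_starts=3))
    assert r1.final_energy == r2.final_energy
    np.testing.assert_array_equal(r1.cu_positions[0], r2.cu_positions[0])


def test_graft_frame_equivariance():
    """A rigid rotation+translation of the scaffold must yield the same site
    geometry (all restraint values) as grafting in the original frame."""
    s, _ = make_site_scaffold(ScaffoldSpec("CuC", 0.1, seed=6))
    tpl, asn = builtin_site_template("CuC"), default_assignment("CuC")
    base = graft_site(GraftProblem(s, tpl, asn, seed=8, n_starts=2))

    rng = np.random.default_rng(13)
    R = Rotation.random(rng=rng).as_matrix()
    t = rng.uniform(-20, 20, 3)
    moved = s.copy()
    for _, a in moved.iter_atoms():
        a.coord = R @ a.coord + t
    res = graft_site(GraftProblem(moved, tpl, asn, seed=8, n_starts=2))

    v1 = {r.label: v for r, v, _ in base.per_restraint}
    v2 = {r.label: v for r, v, _ in res.per_restraint}
    for label, val in v1.items():
        assert v2[label] == pytest.approx(val, abs=1e-3)


def test_graft_missing_donor_raises_assignment_error():
    s, _ = make_site_scaffold(ScaffoldSpec("CuC", 0.0, seed=1))
    res136 = s.residue("A", 136)
    res136.atoms = [a for a in res136.atoms if a.name != "OD1"]
    with pytest.raises(AssignmentError, match="OD1"):
        graft_site(GraftProblem(s, builtin_site_template("CuC"), default_assignment("CuC"), seed=1))


def test_clash_penalty_values():
    vdw = {"C": VdwParams(1.7, 0.1)}
    two_c_overlapping = free_atoms_structure([("A", "C", (0, 0, 0)), ("B", "C", (0, 0, 0))])
    assert clash_penalty(two_c_overlapping, vdw, k=10.0) == pytest.approx(10.0 * 3.4**2)
    at_contact = free_atoms_structure([("A", "C", (0, 0, 0)), ("B", "C", (3.4, 0, 0))])
    assert clash_penalty(at_contact, vdw, k=10.0) == 0.0
    lone = free_atoms_structure([("A", "C", (0, 0, 0))])
    assert clash_penalty(lone, vdw) == 0.0
    with pytest.raises(KeyError):
        clash_penalty(free_atoms_structure([("A", "XX", (0, 0, 0))]), vdw)


def _max_c3_deviation(s, groups):
    """Largest mismatch between symmetry-mapped copies under a 120° rotation
    about the structure's own C3 axis (explicit rotate-and-compare)."""
    from cugraft.grafting import _group_atoms

    X = [np.array([a.coord for a in _group_atoms(s, g)]) for g in groups]
    cents = [x.mean(axis=0) for x in X]
    center = np.mean(cents, axis=0)
    n = np.cross(cents[1] - cents[0], cents[2] - cents[0])
    n /= np.linalg.norm(n)
    R = rotation_about_axis(n, 120.0)
    if np.linalg.norm(R @ (cents[0] - center) - (cents[1] - center)) > np.linalg.norm(
        R @ (cents[0] - center) - (cents[2] - center)
    ):
        R = rotation_about_axis(-n, 120.0)
    dev = 0.0
    for k in range(3):
        mapped = (X[k] - center) @ R.T + center
        dev = max(dev, float(np.max(np.linalg.norm(mapped - X[(k + 1) % 3], axis=1))))
    return dev


def test_symmetrize_c3_fixed_point():
    trimer = make_c3_trimer(make_ideal_helix(6), radius=12.0)
    groups = (("A",), ("B",), ("C",))
    out = symmetrize_c3(trimer, groups)
    np.testing.assert_allclose(out.coords(), trimer.coords(), atol=1e-6)


def test_symmetrize_c3_restores_symmetry_of_noisy_trimer():
    trimer = make_c3_trimer(make_ideal_helix(6), radius=12.0)
    rng = np.random.default_rng(3)
    for r in trimer.chains[1].residues:  # perturb one chain only
        for a in r.atoms:
            a.coord = a.coord + rng.normal(0.0, 0.5, 3)
    groups = (("A",), ("B",), ("C",))
    assert _max_c3_deviation(trimer, groups) > 0.1
    out = symmetrize_c3(trimer, groups)
    assert _max_c3_deviation(out, groups) < 1e-6


def test_symmetrize_c3_composition_mismatch():
    trimer = make_c3_trimer(make_ideal_helix(6), radius=12.0)
    trimer.chains[2].residues.pop()
    with pytest.raises(SymmetryError):
        symmetrize_c3(trimer, (("A",), ("B",), ("C",)))
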