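"""Coordination-geometry metrics: ideal-polyhedron RMSD, dinuclear Cu2S2
descriptors, and backbone torsions."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from conftest import grid_rmsd_oracle, random_donor_site
from cugraft._vec import rotation_about_axis
from cugraft.geometry import (
    DegenerateGeometryError,
    SiteReportError,
    backbone_dihedrals,
    dinuclear_metrics,
    ideal_geometry,
    rmsd_to_ideal,
    site_report,
)
from cugraft.grafting import GraftProblem, graft_site
from cugraft.restraints import builtin_site_template
from cugraft.synth import ScaffoldSpec, default_assignment, make_ideal_helix, make_site_scaffold

TET = ideal_geometry("tetrahedral")
SQP = ideal_geometry("square_planar")


def test_exact_polyhedra_score_zero():
    # zero up to the float precision of the rotation solve (rssd ~ sqrt(eps))
    donors = TET.unit_vertices * 2.0
    assert rmsd_to_ideal(np.zeros(3), donors, TET) == pytest.approx(0.0, abs=1e-6)
    donors = SQP.unit_vertices * 2.1
    assert rmsd_to_ideal(np.zeros(3), donors, SQP) == pytest.approx(0.0, abs=1e-6)


def test_square_vs_tetrahedron_mismatch_matches_grid_oracle():
    """Scoring exact square-planar donors against the tetrahedral ideal gives
    the square↔tetrahedron mismatch; the Kabsch result must not exceed the
    brute-force rotation-grid value."""
    donors = SQP.unit_vertices * 2.0
    kabsch = rmsd_to_ideal(np.zeros(3), donors, TET)
    grid = grid_rmsd_oracle(np.zeros(3), donors, TET, step=8.0)
    assert kabsch > 0.3  # genuinely different geometries at 2 Å bonds
    assert kabsch <= grid + 1e-3


def test_kabsch_beats_grid_on_random_sites():
    rng = np.random.default_rng(11)
    for _ in range(8):
        donors = random_donor_site(rng)
        k = rmsd_to_ideal(np.zeros(3), donors, TET)
        g = grid_rmsd_oracle(np.zeros(3), donors, TET, step=10.0)
        assert k <= g + 1e-3


def test_rmsd_rigid_motion_and_relabeling_invariance():
    rng = np.random.default_rng(5)
    donors = TET.unit_vertices * 2.0 + rng.normal(0.0, 0.1, (4, 3))
    base = rmsd_to_ideal(np.zeros(3), donors, TET)
    R = Rotation.random(rng=rng).as_matrix()
    t = rng.uniform(-10, 10, 3)
    moved = donors @ R.T + t
    assert rmsd_to_ideal(t, moved, TET) == pytest.approx(base, abs=1e-9)
    perm = rng.permutation(4)
    assert rmsd_to_ideal(np.zeros(3), donors[perm], TET) == pytest.approx(base, abs=1e-9)


def test_noisy_tetrahedra_land_in_expected_band():
    rng = np.random.default_rng(7)
    vals = []
    for _ in range(100):
        donors = TET.unit_vertices * 2.0 + rng.normal(0.0, 0.1, (4, 3))
        vals.append(rmsd_to_ideal(np.zeros(3), donors, TET))
    mean = float(np.mean(vals))
    assert 0.0 < mean < 0.2


def test_rmsd_arity_and_degeneracy_errors():
    with pytest.raises(ValueError):
        rmsd_to_ideal(np.zeros(3), TET.unit_vertices[:3] * 2.0, TET)
    bad = TET.unit_vertices * 2.0
    bad[0] = 0.0
    with pytest.raises(DegenerateGeometryError):
        rmsd_to_ideal(np.zeros(3), bad, TET)


def _folded_rhombus(theta: float):
    s1 = np.array([0.0, 1.93, 0.0])
    s2 = np.array([0.0, -1.93, 0.0])
    cu1 = np.array([-1.25, 0.0, 0.0])
    cu2 = rotation_about_axis(s2 - s1, 180.0 - theta) @ np.array([1.25, 0.0, 0.0])
    return cu1, cu2, s1, s2


def test_planar_rhombus_metrics():
    m = dinuclear_metrics(*_folded_rhombus(180.0))
    assert m.plane_fold_angle == pytest.approx(180.0, abs=1e-9)
    assert m.rhombus_max_dev == pytest.approx(0.0, abs=1e-9)
    assert m.cu_cu == pytest.approx(2.5, abs=1e-9)


@pytest.mark.parametrize("theta", [90.0, 110.0, 135.0, 160.0, 170.0, 179.5])
def test_fold_angle_recovers_construction(theta):
    m = dinuclear_metrics(*_folded_rhombus(theta))
    assert m.plane_fold_angle == pytest.approx(theta, abs=0.1)


def test_dinuclear_swap_invariance():
    cu1, cu2, s1, s2 = _folded_rhombus(147.0)
    a = dinuclear_metrics(cu1, cu2, s1, s2)
    b = dinuclear_metrics(cu2, cu1, s1, s2)
    c = dinuclear_metrics(cu1, cu2, s2, s1)
    for x in (b, c):
        assert x.cu_cu == pytest.approx(a.cu_cu, abs=1e-12)
        assert x.rhombus_max_dev == pytest.approx(a.rhombus_max_dev, abs=1e-9)
        assert x.plane_fold_angle == pytest.approx(a.plane_fold_angle, abs=1e-9)


def test_dinuclear_degenerate_cases():
    cu1, cu2, s1, s2 = _folded_rhombus(170.0)
    m = dinuclear_metrics(cu1, cu1.copy(), s1, s2)  # coincident metals
    assert m.cu_cu == 0.0 and m.plane_fold_angle == 0.0
    with pytest.raises(DegenerateGeometryError):
        dinuclear_metrics(cu1, cu2, s1, s1.copy())  # coincident thiolates
    on_hinge = s1 + 0.5 * (s2 - s1)
    with pytest.raises(DegenerateGeometryError):
        dinuclear_metrics(on_hinge, cu2, s1, s2)  # Cu collinear with hinge


def test_site_report_cua2_at_table_means():
    s, _ = make_site_scaffold(ScaffoldSpec("CuA2", 0.0, seed=1))
    res = graft_site(
        GraftProblem(s, builtin_site_template("CuA2"), default_assignment("CuA2"), seed=2, n_starts=2)
    )
    rep = site_report(res.structure, builtin_site_template("CuA2"), default_assignment("CuA2"))
    assert rep.cu_cu == pytest.approx(2.50, abs=0.05)
    assert rep.plane_fold_angle == pytest.approx(180.0, abs=2.0)
    assert rep.rhombus_max_dev == pytest.approx(0.0, abs=0.05)
    assert set(rep.rmsd_to_ideal) == {"CU1", "CU2"}
    assert rep.ideal_name == "tetrahedral"
    # every donor bond within 1 sd of its restraint mean
    means = {  # donor atom -> (mean, sd)
        "SG": (2.30, 0.10), "SD": (2.50, 0.10), "ND1": (2.10, 0.10),
    }
    for label, d in rep.metal_donor_distances:
        atom = label.rsplit(".", 1)[1]
        mean, sd = means[atom]
        assert abs(d - mean) <= sd


def test_site_report_cuc_distances_within_one_sd():
    s, _ = make_site_scaffold(ScaffoldSpec("CuC", 0.0, seed=1))
    res = graft_site(
        GraftProblem(s, builtin_site_template("CuC"), default_assignment("CuC"), seed=2, n_starts=2)
    )
    rep = site_report(res.structure, builtin_site_template("CuC"), default_assignment("CuC"))
    means = {"OD1": (2.0, 0.1), "NE2": (1.9, 0.1), "O": (1.9, 0.1)}
    assert len(rep.metal_donor_distances) == 4
    for label, d in rep.metal_donor_distances:
        mean, sd = means[label.rsplit(".", 1)[1]]
        assert abs(d - mean) <= sd


def test_site_report_requires_metals():
    s, _ = make_site_scaffold(ScaffoldSpec("CuC", 0.0, seed=1))
    with pytest.raises(SiteReportError):
        site_report(s, builtin_site_template("CuC"), default_assignment("CuC"))


def test_backbone_dihedrals_ideal_helix():
    helix = make_ideal_helix(8)
    out = backbone_dihedrals(helix)
    assert len(out) == 6  # termini omitted
    for _, phi, psi in out:
        assert phi == pytest.approx(-57.0, abs=2.0)
        assert psi == pytest.approx(-47.0, abs=2.0)


def test_backbone_dihedrals_short_and_broken_chains():
    assert backbone_dihedrals(make_ideal_helix(2)) == []
    helix = make_ideal_helix(8)
    for r in helix.chains[0].residues[4:]:
        for a in r.atoms:
            a.coord = a.coord + np.array([50.0, 0.0, 0.0])
    out = backbone_dihedrals(helix)
    spanning = [r.seq_id for r, _, _ in out]
    assert 4 not in spanning and 5 not in spanning
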