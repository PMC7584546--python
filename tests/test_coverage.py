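"""Template-coverage accounting vs per-position brute force."""

import numpy as np
import pytest

from cugraft.coverage import (
    AlignmentFormatError,
    AlignmentPair,
    IntervalError,
    bundled_unresolved_intervals,
    check_site_conservation,
    coverage,
    parse_fasta_alignment,
    percent_identity,
)
from cugraft.synth import make_toy_alignment


def brute_force_covered(pairs, unresolved, target_length):
    """Independent per-position scan: position p is covered iff some pair
    aligns it to a resolved, non-gap template position."""
    covered = [False] * target_length
    for p in range(1, target_length + 1):
        for pair in pairs:
            tpos = spos = 0
            for a, b in zip(pair.target_row, pair.template_row):
                if a != "-":
                    tpos += 1
                if b != "-":
                    spos += 1
                if a != "-" and tpos == p:
                    if b != "-" and not any(
                        s <= spos <= e for s, e in unresolved.get(pair.template_id, [])
                    ):
                        covered[p - 1] = True
                    break
    return covered


def _report_covered_flags(report):
    flags = [False] * report.target_length
    for s, e in report.covered:
        for i in range(s, e + 1):
            flags[i - 1] = True
    return flags


def test_gapless_single_template_full_coverage():
    pair = AlignmentPair("t", "x", "ACDEFGHIKL", "ACDEFGHIKL")
    rep = coverage([pair], {}, 10)
    assert rep.uncovered == [] and rep.n_uncovered == 0
    assert rep.covered == [(1, 10)]


def test_unresolved_ends_leave_ten_uncovered():
    row = "A" * 20
    pair = AlignmentPair("t", "x", row, row)
    rep = coverage([pair], {"x": [(1, 5), (16, 20)]}, 20)
    assert rep.uncovered == [(1, 5), (16, 20)]
    assert rep.covered == [(6, 15)]
    assert rep.n_uncovered == 10


def test_complementary_templates_cover_everything():
    row = "M" * 30
    pairs = [AlignmentPair("t", "x", row, row), AlignmentPair("t", "y", row, row)]
    unres = {"x": [(1, 15)], "y": [(16, 30)]}
    rep = coverage(pairs, unres, 30)
    assert rep.n_uncovered == 0


def test_coverage_matches_brute_force_on_random_instances():
    rng = np.random.default_rng(17)
    for trial in range(100):
        L = int(rng.integers(5, 40))
        n_templates = int(rng.integers(1, 4))
        specs = []
        for j in range(n_templates):
            gaps = sorted(rng.choice(np.arange(1, L + 1), size=int(rng.integers(0, L // 3 + 1)), replace=False))
            tlen = L - len(gaps)
            unres = []
            if tlen >= 2 and rng.random() < 0.8:
                s = int(rng.integers(1, tlen))
                e = int(rng.integers(s, tlen + 1))
                unres.append([s, min(e, tlen)])
            specs.append({"id": f"tmpl{j}", "gap_positions": [int(g) for g in gaps], "unresolved": unres})
        fasta, truth = make_toy_alignment(L, specs, seed=trial)
        pairs = [
            AlignmentPair("target", spec["id"], fasta.split("\n")[1], fasta.split("\n")[2 * (k + 1) + 1])
            for k, spec in enumerate(specs)
        ]
        unresolved = {k: [tuple(iv) for iv in v] for k, v in truth["unresolved"].items()}
        rep = coverage(pairs, unresolved, L)
        assert _report_covered_flags(rep) == brute_force_covered(pairs, unresolved, L)
        assert _report_covered_flags(rep) == truth["covered"]
        # partition invariants
        all_iv = sorted(rep.covered + rep.uncovered)
        assert sum(e - s + 1 for s, e in all_iv) == L


def test_coverage_monotone_under_added_templates():
    rng = np.random.default_rng(23)
    L = 25
    specs = [
        {"id": "a", "unresolved": [[1, 10]]},
        {"id": "b", "gap_positions": [3, 4, 5], "unresolved": [[15, 22]]},
        {"id": "c", "unresolved": [[5, 6]]},
    ]
    fasta, truth = make_toy_alignment(L, specs, seed=int(rng.integers(1 << 16)))
    rows = fasta.strip().split("\n")
    pairs = [AlignmentPair("t", specs[k]["id"], rows[1], rows[2 * (k + 1) + 1]) for k in range(3)]
    unres = {k: [tuple(iv) for iv in v] for k, v in truth["unresolved"].items()}
    prev = L + 1
    for k in range(1, 4):
        rep = coverage(pairs[:k], unres, L)
        assert rep.n_uncovered <= prev
        prev = rep.n_uncovered


def test_coverage_validates_intervals_and_lengths():
    pair = AlignmentPair("t", "x", "AAAA", "AAAA")
    with pytest.raises(IntervalError):
        coverage([pair], {"x": [(0, 2)]}, 4)
    with pytest.raises(IntervalError):
        coverage([pair], {"x": [(1, 9)]}, 4)
    with pytest.raises(IntervalError):
        coverage([pair], {}, 7)  # declared target length mismatch


def test_site_conservation_flags():
    pair = AlignmentPair("t", "x", "HAH-K", "HCHQK")
    # identity at ligand columns
    assert check_site_conservation(pair, [(1, "H"), (3, "H")]) == [(1, "H", True), (3, "H", True)]
    # substitution
    assert check_site_conservation(pair, [(2, "C")]) == [(2, "A", False)]
    # ligand aligned to a target gap
    assert check_site_conservation(pair, [(4, "Q")]) == [(4, "", False)]
    with pytest.raises(IntervalError):
        check_site_conservation(pair, [(6, "K")])


def test_parse_fasta_alignment(tmp_path):
    good = tmp_path / "aln.fasta"
    good.write_text(">target\nAC-DE\n>t1\nACQDE\n>t2\nAC-D-\n>t3\nGCKDE\n")
    pairs = parse_fasta_alignment(str(good))
    assert len(pairs) == 3
    assert pairs[0].template_id == "t1"
    assert percent_identity(pairs[0]) == pytest.approx(100.0)
    # target gap at col 3; of the 4 remaining columns only G/A differs -> 3/4
    assert percent_identity(pairs[2]) == pytest.approx(75.0)

    two = tmp_path / "two.fasta"
    two.write_text(">target\nACDE\n>t1\nACDE\n")
    assert len(parse_fasta_alignment(str(two))) == 1

    ragged = tmp_path / "ragged.fasta"
    ragged.write_text(">target\nACDE\n>t1\nACD\n")
    with pytest.raises(AlignmentFormatError):
        parse_fasta_alignment(str(ragged))


def test_percent_identity_equals_column_count():
    pair = AlignmentPair("t", "x", "AAC-G", "A-CTG")
    # aligned non-gap columns: 1 (A/A), 3 (C/C), 5 (G/G) -> 3/3 identical
    assert percent_identity(pair) == pytest.approx(100.0)
    pair2 = AlignmentPair("t", "x", "AACCG", "AATTG")
    assert percent_identity(pair2) == pytest.approx(60.0)


def test_bundled_interval_fixture_loads():
    table = bundled_unresolved_intervals()
    assert set(table) == {"AmoA", "AmoB", "AmoC"}
    entry = table["AmoA"]["3RGB"]
    assert entry["unresolved"] == [[1, 6], [192, 212], [246, 247]]
    assert entry["length"] == 247
    # every interval is valid for its declared length
    for sub in table.values():
        for tmpl in sub.values():
            for s, e in tmpl["unresolved"]:
                assert 1 <= s <= e <= tmpl["length"]
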