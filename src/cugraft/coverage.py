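"""Template-coverage accounting for homology-model targets.

Given pairwise target/template alignments and the intervals of each template
that are unresolved in its crystal structure, a target position counts as
covered when at least one alignment pairs it with a template position that is
both aligned (no gap) and resolved. Intervals are 1-based and inclusive
throughout, matching the conventional "1–6, 192–212 / 247" bookkeeping style.

Ligand-conservation checks map template ligand positions through an alignment
and compare residue letters, flagging substitutions (e.g. a His→Gln swap that
disqualifies a candidate metal site) and unaligned ligands.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Optional

import numpy as np
from Bio import AlignIO

__all__ = [
    "AlignmentPair",
    "CoverageReport",
    "coverage",
    "check_site_conservation",
    "parse_fasta_alignment",
    "percent_identity",
    "bundled_unresolved_intervals",
    "AlignmentFormatError",
    "IntervalError",
]

Interval = tuple[int, int]


class AlignmentFormatError(ValueError):
    pass


class IntervalError(ValueError):
    pass


@dataclass
class AlignmentPair:
    target_id: str
    template_id: str
    target_row: str
    template_row: str

    def __post_init__(self) -> None:
        if len(self.target_row) != len(self.template_row):
            raise AlignmentFormatError(
                f"{self.target_id}/{self.template_id}: rows differ in length "
                f"({len(self.target_row)} vs {len(self.template_row)})"
            )

    @property
    def target_length(self) -> int:
        return sum(1 for c in self.target_row if c != "-")

    @property
    def template_length(self) -> int:
        return sum(1 for c in self.template_row if c != "-")

    def columns(self) -> Iterable[tuple[Optional[int], str, Optional[int], str]]:
        """Yield (target_pos, target_char, template_pos, template_char) per column;
        positions are 1-based, None at gaps."""
        tp = sp = 0
        for a, b in zip(self.target_row, self.template_row):
            ta = sa = None
            if a != "-":
                tp += 1
                ta = tp
            if b != "-":
                sp += 1
                sa = sp
            yield ta, a, sa, b


@dataclass
class CoverageReport:
    target_length: int
    covered: list[Interval]
    uncovered: list[Interval]
    n_uncovered: int

    def to_dict(self) -> dict:
        return {
            "target_length": self.target_length,
            "covered": [list(iv) for iv in self.covered],
            "uncovered": [list(iv) for iv in self.uncovered],
            "n_uncovered": self.n_uncovered,
        }


def _mask_to_intervals(mask: np.ndarray) -> list[Interval]:
    """1-based inclusive intervals of True runs."""
    out: list[Interval] = []
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    for start, stop in zip(edges[::2], edges[1::2]):
        out.append((int(start) + 1, int(stop)))
    return out


def _validate_intervals(intervals: Iterable[Interval], length: int, label: str) -> list[Interval]:
    out = []
    for iv in intervals:
        s, e = int(iv[0]), int(iv[1])
        if not (1 <= s <= e <= length):
            raise IntervalError(f"{label}: interval {s}-{e} outside 1..{length}")
        out.append((s, e))
    return out


def coverage(
    aln: list[AlignmentPair],
    template_unresolved: dict[str, list[Interval]],
    target_length: int,
) -> CoverageReport:
    """Which target positions have support from at least one resolved template
    position. ``template_unresolved`` maps template id → 1-based inclusive
    intervals missing from that template's structure."""
    covered = np.zeros(target_length, dtype=bool)
    for pair in aln:
        if pair.target_length != target_length:
            raise IntervalError(
                f"{pair.target_id}: ungapped target length {pair.target_length} != {target_length}"
            )
        unres = _validate_intervals(
            template_unresolved.get(pair.template_id, ()), pair.template_length, pair.template_id
        )
        resolved = np.ones(pair.template_length + 1, dtype=bool)  # 1-based
        for s, e in unres:
            resolved[s : e + 1] = False
        for tpos, _, spos, _ in pair.columns():
            if tpos is not None and spos is not None and resolved[spos]:
                covered[tpos - 1] = True
    cov_iv = _mask_to_intervals(covered)
    unc_iv = _mask_to_intervals(~covered)
    return CoverageReport(
        target_length=target_length,
        covered=cov_iv,
        uncovered=unc_iv,
        n_uncovered=int((~covered).sum()),
    )


def check_site_conservation(
    aln: AlignmentPair, template_ligands: list[tuple[int, str]]
) -> list[tuple[int, str, bool]]:
    """Map template ligand positions (1-based, with expected residue letter)
    through the alignment; returns (position, target letter, conserved)."""
    tlen = aln.template_length
    by_template_pos: dict[int, str] = {}
    for tpos, tchar, spos, _ in aln.columns():
        if spos is not None:
            by_template_pos[spos] = tchar if tpos is not None else ""
    out = []
    for pos, letter in template_ligands:
        if not 1 <= pos <= tlen:
            raise IntervalError(f"ligand position {pos} outside template 1..{tlen}")
        target_letter = by_template_pos.get(pos, "")
        out.append((pos, target_letter, target_letter == letter))
    return out


def percent_identity(pair: AlignmentPair) -> float:
    """Identical columns / aligned (both non-gap) columns, in percent."""
    same = aligned = 0
    for _, a, _, b in pair.columns():
        if a != "-" and b != "-":
            aligned += 1
            if a == b:
                same += 1
    return 100.0 * same / aligned if aligned else 0.0


def parse_fasta_alignment(path: str) -> list[AlignmentPair]:
    """Read aligned FASTA; the first record is the target, each later record a
    template → one AlignmentPair per template."""
    try:
        msa = AlignIO.read(str(path), "fasta")
    except ValueError as exc:
        raise AlignmentFormatError(f"{path}: {exc}") from exc
    if len(msa) < 2:
        raise AlignmentFormatError(f"{path}: need a target and at least one template record")
    target = msa[0]
    return [
        AlignmentPair(target.id, rec.id, str(target.seq).upper(), str(rec.seq).upper())
        for rec in msa[1:]
    ]


def bundled_unresolved_intervals() -> dict:
    """Published-style unresolved-region bookkeeping for the candidate template
    structures of each modelling target (per subunit: template id → intervals
    and total length). Sequences are not bundled; this fixture only supports
    interval arithmetic examples."""
    text = resources.files("cugraft.data").joinpath("template_unresolved.json").read_text()
    return json.loads(text)
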