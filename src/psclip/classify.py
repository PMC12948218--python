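"""Motif tree: family registry, motif classification and latch-anchored
sequence comparison.

All Pseudomonas CLiPs with a partially exocyclic oligopeptide (l > m) fold
into a left-handed alpha-helix (alphaL) and adopt one of two conformational
motifs, determined entirely by the macrocycle size m:

* ``stapled_helix`` (m > 5): the helix proceeds into the macrocycle for
  almost a full turn, so the C-terminus is stapled onto the helix body via
  the depsi bond.  Four macrocycle residues belong to the helix, leaving
  ``c = m - 4`` residues to close the loop.
* ``catch_pole`` (m <= 5): the helix terminates at the latch residue and the
  macrocycle forms a separate closed loop crowning the exocyclic helix.

Fully cyclic CLiPs (l = m, the Mycins) are not helical and form a separate
offshoot of the tree.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from typing import Iterable

from .sequence import ClipSequence

__all__ = [
    "FamilyRecord",
    "MotifAssignment",
    "AlignmentReport",
    "classify_motif",
    "loop_residue_count",
    "branch_census",
    "latch_anchored_align",
    "load_family_registry",
]

STAPLED = "stapled_helix"
CATCH_POLE = "catch_pole"
OFFSHOOT = "full_cycle_offshoot"

CLUSTERS = ("Acidilin", "Peptin", "Mycin")
CLADES = ("Fluorescens", "Putida", "Syringae")
_CLADE_ABBREV = {"F": "Fluorescens", "P": "Putida", "S": "Syringae"}


@dataclass(frozen=True)
class FamilyRecord:
    """One (l:m)-tagged CLiP family of the motif tree."""

    family_name: str
    l: int  # noqa: E741
    m: int
    cluster: str
    clades: frozenset[str] = frozenset()

    def __post_init__(self):
        if self.l < self.m:
            raise ValueError(f"{self.family_name}: l must be >= m")
        if self.cluster not in CLUSTERS:
            raise ValueError(f"unknown cluster {self.cluster!r}")
        if (self.cluster == "Mycin") != (self.l == self.m):
            raise ValueError(
                f"{self.family_name}: the Mycin cluster is exactly the "
                "fully cyclic (l = m) case")
        if not self.clades <= set(CLADES):
            raise ValueError(f"unknown clade in {set(self.clades)}")

    @property
    def tag(self) -> str:
        return f"{self.l}:{self.m}"


@dataclass(frozen=True)
class MotifAssignment:
    """Placement of an (l:m) tag in the motif tree.

    ``helix_span``/``loop_span`` are inclusive 1-based residue intervals;
    ``loop_count`` is the number of loop-closing residues c = m - 4
    (stapled-helix motif only).
    """

    motif: str
    helix_span: tuple[int, int] | None
    loop_span: tuple[int, int] | None
    loop_count: int | None


def classify_motif(l: int, m: int) -> MotifAssignment:  # noqa: E741
    """Classify an (l:m) tag into its conformational motif.

    A total, deterministic function on the domain ``4 <= m <= l``; the three
    motifs partition it.  The stapled helix runs from residue 1 through
    latch+3 (the latch contributes the first of four helical macrocycle
    residues); the catch-pole helix terminates at the latch itself.
    """
    if m < 4:
        raise ValueError(f"macrocycle size m={m} below minimum of 4")
    if m > l:
        raise ValueError(f"macrocycle size m={m} exceeds peptide length l={l}")
    latch = l - m + 1
    if l == m:
        return MotifAssignment(OFFSHOOT, None, (1, l), None)
    if m > 5:
        return MotifAssignment(
            STAPLED,
            helix_span=(1, latch + 3),
            loop_span=(latch + 4, l),
            loop_count=m - 4,
        )
    return MotifAssignment(
        CATCH_POLE,
        helix_span=(1, latch),
        loop_span=(latch + 1, l),
        loop_count=None,
    )


def loop_residue_count(l: int, m: int) -> int:  # noqa: E741
    """Residues available to close the macrocycle loop, c = m - 4, for a
    stapled-helix CLiP."""
    assignment = classify_motif(l, m)
    if assignment.motif != STAPLED:
        raise ValueError(
            f"loop rule c = m - 4 applies to stapled-helix CLiPs only; "
            f"({l}:{m}) is {assignment.motif}")
    return assignment.loop_count


def branch_census(registry: Iterable[FamilyRecord]) -> dict[str, int]:
    """Count families per branch of the motif tree."""
    counts = {STAPLED: 0, CATCH_POLE: 0, OFFSHOOT: 0}
    for rec in registry:
        counts[classify_motif(rec.l, rec.m).motif] += 1
    return counts


@dataclass(frozen=True)
class AlignmentReport:
    """Pairwise latch-anchored comparison over the overlapping window.

    Positions are paired by their offset from the latch residue (offset 0 =
    latch; negative = exocyclic side).  ``positions`` lists the paired
    (offset, pos_a, pos_b) triples.
    """

    positions: tuple[tuple[int, int, int], ...]
    config_matches: int
    hclass_matches: int
    identity_matches: int

    @property
    def window(self) -> int:
        return len(self.positions)

    @property
    def config_fraction(self) -> float:
        return self.config_matches / self.window

    @property
    def hclass_fraction(self) -> float:
        return self.hclass_matches / self.window

    @property
    def identity_fraction(self) -> float:
        return self.identity_matches / self.window


def latch_anchored_align(a: ClipSequence, b: ClipSequence) -> "AlignmentReport":
    """Compare two CLiPs position-by-position after anchoring both at the
    latch residue (the field's reference point for CLiP alignment), with no
    gaps.  Reports configuration, hydrophobicity-class and residue-identity
    conservation over the overlapping window."""
    lo = max(1 - a.latch_pos, 1 - b.latch_pos)
    hi = min(a.l - a.latch_pos, b.l - b.latch_pos)
    positions = []
    config = hclass = identity = 0
    for off in range(lo, hi + 1):
        pa, pb = a.latch_pos + off, b.latch_pos + off
        ra, rb = a.residue(pa), b.residue(pb)
        positions.append((off, pa, pb))
        config += ra.config == rb.config
        hclass += ra.hclass == rb.hclass
        identity += ra.code == rb.code
    return AlignmentReport(
        positions=tuple(positions),
        config_matches=config,
        hclass_matches=hclass,
        identity_matches=identity,
    )


def alignment_mismatches(a: ClipSequence, b: ClipSequence,
                         what: str = "config") -> list[int]:
    """Latch offsets at which the two sequences disagree on ``what``
    ('config', 'hclass' or 'identity')."""
    rep = latch_anchored_align(a, b)
    out = []
    for off, pa, pb in rep.positions:
        ra, rb = a.residue(pa), b.residue(pb)
        same = {"config": ra.config == rb.config,
                "hclass": ra.hclass == rb.hclass,
                "identity": ra.code == rb.code}[what]
        if not same:
            out.append(off)
    return out


def load_family_registry(path=None) -> list[FamilyRecord]:
    """Load the family registry (shipped 17-family table by default)."""
    if path is None:
        text = (resources.files("psclip.data") / "families.tsv").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    lines = [ln for ln in text.splitlines()
             if ln.strip() and not ln.startswith("#")]
    reader = csv.DictReader(lines, delimiter="\t")
    out = []
    for row in reader:
        clades = frozenset(
            _CLADE_ABBREV[c.strip()] for c in row["clades"].split(",")
            if c.strip())
        out.append(FamilyRecord(
            family_name=row["family"], l=int(row["l"]), m=int(row["m"]),
            cluster=row["cluster"], clades=clades))
    return out
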