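"""NOE-derived distance restraints: classification by residue separation,
summary statistics and violation analysis.

Restraints are classified by the residue-index separation of their two
atoms: intraresidual (0), sequential (1), mid-range (2-4), long-range (>= 5).
Restraints touching acyl-chain atoms are kept apart and excluded from the
peptide statistics.  Ambiguous restraints (methylene/methyl groups without
stereospecific assignment) carry OR-lists of candidate atoms and are
evaluated with an r^-6-summed effective distance; in summaries they are
counted in the total but not in the per-category rows.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np

from .structure import Structure

__all__ = [
    "load_noe_table",
    "AtomRef",
    "DistanceRestraint",
    "classify_restraint",
    "restraint_summary",
    "RestraintSummary",
    "check_violations",
    "ViolationReport",
    "parse_restraints",
]

CATEGORIES = ("intraresidual", "sequential", "mid_range", "long_range",
              "acyl")


@dataclass(frozen=True)
class AtomRef:
    """One atom selector: residue index + atom name.  Residue index 0 marks
    acyl-chain atoms."""

    res_index: int
    name: str


@dataclass(frozen=True)
class DistanceRestraint:
    """Upper-bound distance restraint between two (possibly ambiguous)
    atom groups."""

    a: tuple[AtomRef, ...]
    b: tuple[AtomRef, ...]
    upper: float
    ambiguous: bool = False

    def __post_init__(self):
        if self.upper <= 0:
            raise ValueError("upper bound must be positive")
        if not self.a or not self.b:
            raise ValueError("empty atom group")

    @classmethod
    def simple(cls, res_a: int, name_a: str, res_b: int, name_b: str,
               upper: float) -> "DistanceRestraint":
        return cls(a=(AtomRef(res_a, name_a),), b=(AtomRef(res_b, name_b),),
                   upper=upper)


def classify_restraint(r: DistanceRestraint) -> str:
    """Category by residue separation; symmetric in atom order.  Ambiguous
    groups use their minimum separation; any acyl atom makes the restraint
    'acyl'."""
    if any(ref.res_index == 0 for ref in r.a + r.b):
        return "acyl"
    delta = min(abs(ra.res_index - rb.res_index)
                for ra in r.a for rb in r.b)
    if delta == 0:
        return "intraresidual"
    if delta == 1:
        return "sequential"
    if delta <= 4:
        return "mid_range"
    return "long_range"


@dataclass(frozen=True)
class RestraintSummary:
    counts: dict[str, int]       # unambiguous counts per peptide category
    ambiguous: int               # ambiguous restraints (total only)
    acyl: int                    # acyl restraints (excluded from stats)
    total: int                   # categorized + ambiguous, acyl excluded
    density: float               # total / l
    mid_long_fraction: float     # (mid + long) / total


def restraint_summary(rs: Iterable[DistanceRestraint], l: int  # noqa: E741
                      ) -> RestraintSummary:
    """Summarize a restraint list for an l-residue peptide."""
    if l < 1:
        raise ValueError("l must be >= 1")
    counts = {c: 0 for c in ("intraresidual", "sequential", "mid_range",
                             "long_range")}
    ambiguous = acyl = 0
    for r in rs:
        cat = classify_restraint(r)
        if cat == "acyl":
            acyl += 1
        elif r.ambiguous:
            ambiguous += 1
        else:
            counts[cat] += 1
    total = sum(counts.values()) + ambiguous
    mid_long = counts["mid_range"] + counts["long_range"]
    return RestraintSummary(
        counts=counts, ambiguous=ambiguous, acyl=acyl, total=total,
        density=total / l,
        mid_long_fraction=mid_long / total if total else 0.0)


@dataclass(frozen=True)
class ViolationReport:
    violations: tuple[tuple[int, float], ...]  # (restraint index, excess)
    unmatched: tuple[int, ...]                 # unresolvable restraints
    n_evaluated: int

    @property
    def count(self) -> int:
        return len(self.violations)

    @property
    def fraction(self) -> float:
        return self.count / self.n_evaluated if self.n_evaluated else 0.0


def _effective_distance(s: Structure, r: DistanceRestraint, model: int
                        ) -> float | None:
    dists = []
    for ra in r.a:
        for rb in r.b:
            try:
                pa = s.xyz(ra.res_index, ra.name, model)
                pb = s.xyz(rb.res_index, rb.name, model)
            except KeyError:
                continue
            dists.append(float(np.linalg.norm(pa - pb)))
    if not dists:
        return None
    if len(dists) == 1:
        return dists[0]
    # r^-6 summation over the ambiguous group
    return float(np.sum(np.asarray(dists) ** -6.0) ** (-1.0 / 6.0))


def check_violations(s: Structure, rs: Sequence[DistanceRestraint],
                     threshold: float = 0.5, model: int = 0
                     ) -> ViolationReport:
    """List restraints whose effective distance exceeds the upper bound by
    more than ``threshold`` A.  Restraints with no resolvable atom pair are
    reported as unmatched, not fatal."""
    violations = []
    unmatched = []
    n_eval = 0
    for idx, r in enumerate(rs):
        d = _effective_distance(s, r, model)
        if d is None:
            unmatched.append(idx)
            continue
        n_eval += 1
        excess = d - r.upper
        if excess > threshold:
            violations.append((idx, float(excess)))
    return ViolationReport(violations=tuple(violations),
                           unmatched=tuple(unmatched), n_evaluated=n_eval)


def load_noe_table() -> list[dict]:
    """Shipped per-CLiP NOE restraint count and ensemble precision table
    (integer count columns, float RMSD columns)."""
    text = (resources.files("psclip.data") / "noe_stats.tsv").read_text()
    lines = [ln for ln in text.splitlines()
             if ln.strip() and not ln.startswith("#")]
    rows = []
    for row in csv.DictReader(lines, delimiter="\t"):
        out: dict = {"clip": row["clip"]}
        for key in ("l", "m", "intraresidual", "sequential", "mid_range",
                    "long_range", "total", "ambiguous"):
            out[key] = int(row[key])
        out["rmsd_backbone"] = float(row["rmsd_backbone"])
        out["rmsd_backbone_sd"] = float(row["rmsd_backbone_sd"])
        rows.append(out)
    return rows


# -- restraint file parsing ------------------------------------------------

_SELECTOR_RE = re.compile(
    r"resid(?:ue)?\s+(\d+)\s+and\s+name\s+([A-Za-z0-9#*']+)",
    re.IGNORECASE)
_ASSIGN_RE = re.compile(
    r"assign\s*(\(.*?\))\s*(\(.*?\))\s*"
    r"([-+0-9.eE]+)\s+([-+0-9.eE]+)\s+([-+0-9.eE]+)",
    re.IGNORECASE | re.DOTALL)


def _parse_selection(text: str) -> tuple[AtomRef, ...]:
    refs = tuple(AtomRef(int(res), name.upper())
                 for res, name in _SELECTOR_RE.findall(text))
    if not refs:
        raise ValueError(f"unparseable atom selection: {text!r}")
    return refs


def parse_restraints(text: str) -> list[DistanceRestraint]:
    """Parse restraints from text supporting two dialects:

    * CNS-style ``assign (resid I and name X) (resid J and name Y) d dm dp``
      statements (upper bound = d + dp), with ``or``-joined selectors
      forming ambiguous groups;
    * a minimal generic format, one per line: ``I X J Y upper``.
    """
    out = []
    remaining = text
    for mobj in _ASSIGN_RE.finditer(text):
        sel_a, sel_b, d, _dm, dp = mobj.groups()
        a = _parse_selection(sel_a)
        b = _parse_selection(sel_b)
        out.append(DistanceRestraint(
            a=a, b=b, upper=float(d) + float(dp),
            ambiguous=len(a) > 1 or len(b) > 1))
        remaining = remaining.replace(mobj.group(0), "", 1)
    for line in remaining.splitlines():
        line = line.strip()
        if not line or line.startswith(("#", "!")):
            continue
        parts = line.split()
        if len(parts) != 5:
            raise ValueError(f"malformed restraint line: {line!r}")
        res_a, name_a, res_b, name_b, upper = parts
        out.append(DistanceRestraint.simple(
            int(res_a), name_a.upper(), int(res_b), name_b.upper(),
            float(upper)))
    return out
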