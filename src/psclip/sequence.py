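"""Sequence model for Pseudomonas cyclic lipodepsipeptides (CLiPs).

A CLiP is an oligopeptide of ``l`` residues, N-capped by a fatty-acyl chain
and cyclized through an ester ("depsi") bond between the side-chain hydroxyl
of an internal residue (the *latch*, a d-Ser or d-allo-Thr in all natural
family representatives) and the C-terminal carboxyl.  The ``m`` C-terminal
residues from the latch onward form the macrocycle, giving the ``(l:m)``
family tag with ``m = l - latch_pos + 1``.

Sequences are written in a compact one-line notation::

    viscosin | 3OH-C10:0 | L.l E.d aT.d* V.d L.l S.d L.l S.d I.l

i.e. ``name | acyl | residue tokens``, each token ``<code>.<cfg>`` with an
optional ``*`` marking the latch.  Configuration ``l``/``d``/``x`` denotes
L, D or achiral.  Residue codes cover the proteinogenic residues seen in
Acidilins plus the nonproteinogenic ones of Peptins (aThr, aIle, Hse, Dab,
Dhb).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable

__all__ = [
    "ResidueSpec",
    "AcylDescriptor",
    "ClipSequence",
    "ClipError",
    "ClipParseError",
    "parse_clip",
    "lm_tag",
    "amphipathicity_profile",
    "charge_profile",
    "load_reference_clips",
]


class ClipError(ValueError):
    """Invalid CLiP sequence (violated invariant)."""


class ClipParseError(ClipError):
    """Malformed CLiP notation."""


# Canonical residue codes with short aliases accepted by the parser.
_ALIASES = {
    "L": "Leu", "I": "Ile", "aI": "aIle", "V": "Val", "A": "Ala",
    "F": "Phe", "P": "Pro", "G": "Gly", "S": "Ser", "T": "Thr",
    "aT": "aThr", "Q": "Gln", "E": "Glu", "D": "Asp", "N": "Asn",
    "K": "Lys",
}
_SHORT = {v: k for k, v in _ALIASES.items()}

# Hydrophobicity class of the side chain (two-class scheme used for the
# amphipathicity profile; Gly carries no side chain and faces the solvent in
# amphipathic helices, hence hydrophilic).
_HYDROPHOBIC = {"Leu", "Ile", "aIle", "Val", "Ala", "Phe", "Pro", "Dhb"}
_HYDROPHILIC = {"Ser", "Thr", "aThr", "Gln", "Glu", "Asp", "Asn", "Gly",
                "Hse", "Dab", "Lys"}

# Net side-chain charge at physiological pH.
_NEGATIVE = {"Glu", "Asp"}
_POSITIVE = {"Lys", "Dab"}

# Residues whose side chain carries the hydroxyl needed for ester formation.
HYDROXYL_CODES = frozenset({"Ser", "Thr", "aThr", "Hse"})

# Achiral residues (no side chain, or sp2 alpha carbon for Dhb).
_ACHIRAL = {"Gly", "Dhb"}

KNOWN_CODES = frozenset(_HYDROPHOBIC | _HYDROPHILIC)


def hclass_of(code: str) -> str:
    if code in _HYDROPHOBIC:
        return "hydrophobic"
    if code in _HYDROPHILIC:
        return "hydrophilic"
    raise ClipError(f"unknown residue code: {code!r}")


def charge_of(code: str) -> str:
    if code in _NEGATIVE:
        return "negative"
    if code in _POSITIVE:
        return "positive"
    return "neutral"


@dataclass(frozen=True)
class ResidueSpec:
    """One residue: identity, chirality and derived physicochemical class."""

    code: str
    config: str  # 'L', 'D' or 'achiral'
    is_latch: bool = False

    def __post_init__(self):
        if self.code not in KNOWN_CODES:
            raise ClipError(f"unknown residue code: {self.code!r}")
        if self.config not in ("L", "D", "achiral"):
            raise ClipError(f"invalid configuration: {self.config!r}")
        if self.code in _ACHIRAL and self.config != "achiral":
            raise ClipError(f"{self.code} is achiral")
        if self.code not in _ACHIRAL and self.config == "achiral":
            raise ClipError(f"{self.code} is chiral; config must be L or D")
        if self.is_latch and self.code not in HYDROXYL_CODES:
            raise ClipError(
                f"invalid latch: {self.code} has no side-chain hydroxyl")

    @property
    def hclass(self) -> str:
        return hclass_of(self.code)

    @property
    def charge(self) -> str:
        return charge_of(self.code)


@dataclass(frozen=True)
class AcylDescriptor:
    """N-terminal fatty-acyl chain: length, unsaturations, 3-OH flag."""

    carbons: int
    unsaturations: int = 0
    hydroxyl_c3: bool = False

    def __post_init__(self):
        if self.carbons < 4:
            raise ClipError("acyl chain must have at least 4 carbons")
        if self.unsaturations < 0:
            raise ClipError("unsaturation count must be non-negative")

    def __str__(self) -> str:
        prefix = "3OH-" if self.hydroxyl_c3 else ""
        return f"{prefix}C{self.carbons}:{self.unsaturations}"


@dataclass(frozen=True)
class ClipSequence:
    """A full CLiP: named residue sequence with acyl cap and latch position.

    Positions are 1-based from the N-terminal (acylated) residue; the
    macrocycle is the closed interval ``[latch_pos, l]``.
    """

    name: str
    residues: tuple[ResidueSpec, ...]
    acyl: AcylDescriptor
    latch_pos: int

    def __post_init__(self):
        latches = [i for i, r in enumerate(self.residues, start=1)
                   if r.is_latch]
        if latches != [self.latch_pos]:
            raise ClipError(
                f"{self.name}: exactly one latch residue required at "
                f"position {self.latch_pos}, found at {latches}")
        if self.m < 4:
            raise ClipError(
                f"{self.name}: macrocycle of {self.m} residues is too small "
                "(minimum 4)")

    @property
    def l(self) -> int:  # noqa: E743 - field name from the (l:m) tag
        return len(self.residues)

    @property
    def m(self) -> int:
        return self.l - self.latch_pos + 1

    @property
    def macrocycle(self) -> range:
        """1-based positions inside the macrocycle."""
        return range(self.latch_pos, self.l + 1)

    def residue(self, pos: int) -> ResidueSpec:
        """Residue at 1-based position ``pos``."""
        return self.residues[pos - 1]

    def to_notation(self) -> str:
        tokens = []
        for r in self.residues:
            code = _SHORT.get(r.code, r.code)
            cfg = {"L": "l", "D": "d", "achiral": "x"}[r.config]
            tokens.append(f"{code}.{cfg}{'*' if r.is_latch else ''}")
        return f"{self.name} | {self.acyl} | {' '.join(tokens)}"

    def relabel(self, name: str) -> "ClipSequence":
        return replace(self, name=name)


_ACYL_RE = re.compile(r"^(3OH-)?C(\d+):(\d+)$")
_TOKEN_RE = re.compile(r"^([A-Za-z]{1,3})\.([ldx])(\*?)$")


def parse_acyl(text: str) -> AcylDescriptor:
    m = _ACYL_RE.match(text.strip())
    if not m:
        raise ClipParseError(f"malformed acyl descriptor: {text!r}")
    return AcylDescriptor(carbons=int(m.group(2)),
                          unsaturations=int(m.group(3)),
                          hydroxyl_c3=bool(m.group(1)))


def parse_clip(notation: str) -> ClipSequence:
    """Parse one line of CLiP notation into a :class:`ClipSequence`.

    Raises :class:`ClipParseError` on malformed tokens (with the offending
    position), a missing latch marker, or a latch residue without a
    side-chain hydroxyl.
    """
    parts = [p.strip() for p in notation.split("|")]
    if len(parts) != 3:
        raise ClipParseError(
            "notation must have three '|'-separated fields: "
            "name | acyl | residues")
    name, acyl_text, residue_text = parts
    if not name:
        raise ClipParseError("empty name field")
    acyl = parse_acyl(acyl_text)

    residues: list[ResidueSpec] = []
    latch_pos = None
    for pos, token in enumerate(residue_text.split(), start=1):
        m = _TOKEN_RE.match(token)
        if not m:
            raise ClipParseError(
                f"malformed residue token {token!r} at position {pos}")
        raw_code, cfg, star = m.groups()
        code = _ALIASES.get(raw_code, raw_code)
        if code not in KNOWN_CODES:
            raise ClipParseError(
                f"unknown residue code {raw_code!r} at position {pos}")
        config = {"l": "L", "d": "D", "x": "achiral"}[cfg]
        is_latch = bool(star)
        if is_latch:
            if code not in HYDROXYL_CODES:
                raise ClipParseError(
                    f"invalid latch at position {pos}: {code} has no "
                    "side-chain hydroxyl")
            if latch_pos is not None:
                raise ClipParseError(
                    f"duplicate latch marker at position {pos}")
            latch_pos = pos
        residues.append(ResidueSpec(code=code, config=config,
                                    is_latch=is_latch))
    if latch_pos is None:
        raise ClipParseError("missing latch: no residue marked with '*'")
    return ClipSequence(name=name, residues=tuple(residues), acyl=acyl,
                        latch_pos=latch_pos)


def lm_tag(seq: ClipSequence) -> tuple[int, int]:
    """The (l:m) family tag: total residues and macrocycle size."""
    return seq.l, seq.m


def amphipathicity_profile(seq: ClipSequence) -> tuple[str, ...]:
    """Per-residue hydrophobicity class, N- to C-terminus."""
    return tuple(r.hclass for r in seq.residues)


def charge_profile(seq: ClipSequence) -> tuple[str, ...]:
    """Per-residue side-chain charge at physiological pH."""
    return tuple(r.charge for r in seq.residues)


def parse_clip_file(lines: Iterable[str]) -> list[ClipSequence]:
    out = []
    for line in lines:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        out.append(parse_clip(line))
    return out


def load_reference_clips() -> dict[str, ClipSequence]:
    """The shipped registry of reference CLiP sequences (one per family
    studied structurally, plus the synthetic pentorfamide analogue of
    orfamide A), keyed by name."""
    text = (resources.files("psclip.data") / "clip_sequences.txt").read_text()
    seqs = parse_clip_file(text.splitlines())
    return {s.name: s for s in seqs}
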