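"""Lightweight 3D structure container and internal-coordinate primitives.

A :class:`Structure` holds an ordered atom table shared by one or more
coordinate models (an NMR-style ensemble), plus covalent links beyond the
peptide chain (the depsi ester).  Coordinates are in Angstrom, in a
right-handed frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["Atom", "Link", "Structure", "dihedral_angle", "bond_angle",
           "place_atom", "rotation_about_axis"]


@dataclass(frozen=True)
class Atom:
    """One atom record; ``res_index`` 0 denotes the acyl-chain carbonyl cap."""

    res_index: int
    res_code: str
    name: str
    element: str


@dataclass(frozen=True)
class Link:
    """A covalent link outside the backbone chain (e.g. the depsi ester
    between the latch side-chain oxygen and the C-terminal carbonyl)."""

    res_a: int
    atom_a: str
    res_b: int
    atom_b: str
    kind: str = "ester"


@dataclass
class Structure:
    """Ordered atoms with ``(n_models, n_atoms, 3)`` coordinates."""

    atoms: tuple[Atom, ...]
    coords: np.ndarray
    links: tuple[Link, ...] = ()

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim == 2:
            self.coords = self.coords[None]
        if self.coords.shape[1:] != (len(self.atoms), 3):
            raise ValueError(
                f"coordinate array {self.coords.shape} does not match "
                f"{len(self.atoms)} atoms")
        self.atoms = tuple(self.atoms)
        self.links = tuple(self.links)

    # -- basic accessors ---------------------------------------------------
    @property
    def n_models(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_residues(self) -> int:
        return max((a.res_index for a in self.atoms), default=0)

    def index_of(self, res_index: int, name: str) -> int:
        for i, a in enumerate(self.atoms):
            if a.res_index == res_index and a.name == name:
                return i
        raise KeyError(f"no atom {name!r} in residue {res_index}")

    def has_atom(self, res_index: int, name: str) -> bool:
        return any(a.res_index == res_index and a.name == name
                   for a in self.atoms)

    def xyz(self, res_index: int, name: str, model: int = 0) -> np.ndarray:
        return self.coords[model, self.index_of(res_index, name)]

    def model(self, k: int) -> "Structure":
        """Single-model view (copy) of model ``k``."""
        return replace(self, coords=self.coords[k:k + 1].copy())

    def select(self, names=None, res_range=None, exclude_acyl=True
               ) -> np.ndarray:
        """Atom indices matching the given backbone/atom-name filter.

        ``names``: iterable of atom names (None = all); ``res_range``:
        inclusive (first, last) 1-based residue interval (None = all);
        ``exclude_acyl``: drop the acyl-cap pseudo-residue 0.
        """
        names = set(names) if names is not None else None
        idx = []
        for i, a in enumerate(self.atoms):
            if exclude_acyl and a.res_index == 0:
                continue
            if names is not None and a.name not in names:
                continue
            if res_range is not None and not (
                    res_range[0] <= a.res_index <= res_range[1]):
                continue
            idx.append(i)
        return np.asarray(idx, dtype=int)

    def with_coords(self, coords: np.ndarray) -> "Structure":
        return replace(self, coords=np.asarray(coords, dtype=float))

    def with_links(self, links) -> "Structure":
        return replace(self, links=tuple(links))

    def transformed(self, rotation: np.ndarray, translation: np.ndarray
                    ) -> "Structure":
        """Rigidly transformed copy: ``x -> x @ R.T + t`` for every model."""
        new = self.coords @ np.asarray(rotation).T + np.asarray(translation)
        return self.with_coords(new)

    def mirrored(self) -> "Structure":
        """Reflection through the yz-plane; inverts all chirality and
        negates every dihedral."""
        new = self.coords.copy()
        new[..., 0] *= -1.0
        return self.with_coords(new)


# -- internal-coordinate primitives ---------------------------------------

def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    return v / n


def dihedral_angle(p0, p1, p2, p3) -> float:
    """Signed torsion angle in degrees, IUPAC convention, in (-180, 180]."""
    p0, p1, p2, p3 = (np.asarray(p) for p in (p0, p1, p2, p3))
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, _unit(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    ang = np.degrees(np.arctan2(y, x))
    return float(180.0 if np.isclose(ang, -180.0) else ang)


def bond_angle(p0, p1, p2) -> float:
    """Angle at ``p1`` in degrees."""
    v1 = _unit(np.asarray(p0) - np.asarray(p1))
    v2 = _unit(np.asarray(p2) - np.asarray(p1))
    return float(np.degrees(np.arccos(np.clip(np.dot(v1, v2), -1.0, 1.0))))


def place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float
               ) -> np.ndarray:
    """Natural-extension-reference-frame placement of atom D bonded to C,
    given chain A-B-C, the C-D bond length, the B-C-D angle and the
    A-B-C-D torsion."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    ang = np.radians(angle_deg)
    tor = np.radians(torsion_deg)
    d_local = np.array([
        -bond * np.cos(ang),
        bond * np.sin(ang) * np.cos(tor),
        -bond * np.sin(ang) * np.sin(tor),
    ])
    bc = _unit(c - b)
    n = _unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    frame = np.column_stack([bc, m, n])
    return c + frame @ d_local


def rotation_about_axis(origin: np.ndarray, axis: np.ndarray,
                        angle_rad: float):
    """Rodrigues rotation; returns a function mapping (n,3) points."""
    k = _unit(np.asarray(axis, dtype=float))
    o = np.asarray(origin, dtype=float)
    c, s = np.cos(angle_rad), np.sin(angle_rad)

    def apply(pts: np.ndarray) -> np.ndarray:
        v = np.atleast_2d(pts) - o
        rot = (v * c + np.cross(k, v) * s
               + np.outer(v @ k, k) * (1.0 - c))
        out = rot + o
        return out.reshape(np.shape(pts))

    return apply
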