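"""Measurement suite: dihedrals, helix handedness, hydrogen bonds,
superposition and ensemble RMSD statistics, helix axis, macrocycle
ellipsoid/bend angle and amphipathic face segregation.

All scalar measurements are invariant under rigid motion; directional
outputs (helix axis, ellipsoid axes) are equivariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sequence import ClipSequence
from .structure import Structure, dihedral_angle

__all__ = [
    "dihedrals",
    "handedness",
    "HBond",
    "detect_hbonds",
    "superpose",
    "ensemble_rmsd_stats",
    "HelixAxis",
    "helix_axis",
    "EllipsoidFit",
    "macrocycle_bend",
    "amphipathic_segregation",
    "detect_motif",
    "backbone_selection",
]

# Acceptance window around the canonical helix dihedrals for per-residue
# handedness classification (the observed deviations of helical CLiP
# residues stay well within; loop residues fall far outside).
HANDEDNESS_WINDOW = 40.0
_ALPHA_L = (57.0, 47.0)
_ALPHA_R = (-57.0, -47.0)

# Geometric hydrogen-bond criterion (Baker-Hubbard-style):
HBOND_MAX_ON = 3.5    # O...N distance, A
HBOND_MIN_CON = 90.0  # C=O...N angle, degrees
HBOND_MIN_NHO = 120.0  # N-H...O angle, degrees (when H present)


def dihedrals(s: Structure, model: int = 0
              ) -> dict[int, tuple[float | None, float | None, float | None]]:
    """Per-residue (phi, psi, omega) in degrees, IUPAC sign convention.

    phi of residue 1 is measured against the acyl carbonyl carbon when
    present; psi of the last residue is recovered from its carbonyl oxygen
    (anti to the hypothetical next amide nitrogen).  Angles whose defining
    atoms are missing are reported as None rather than raising.
    """
    n = s.n_residues
    out = {}

    def get(i, name):
        try:
            return s.xyz(i, name, model)
        except KeyError:
            return None

    for i in range(1, n + 1):
        ni, cai, ci = get(i, "N"), get(i, "CA"), get(i, "C")
        c_prev = get(i - 1, "C")
        ca_prev = get(i - 1, "CA") if i > 1 else None
        n_next = get(i + 1, "N") if i < n else None
        phi = psi = omega = None
        if all(p is not None for p in (c_prev, ni, cai, ci)):
            phi = dihedral_angle(c_prev, ni, cai, ci)
        if all(p is not None for p in (ni, cai, ci, n_next)):
            psi = dihedral_angle(ni, cai, ci, n_next)
        elif i == n:
            oi = get(i, "O")
            if all(p is not None for p in (ni, cai, ci, oi)):
                a = dihedral_angle(ni, cai, ci, oi) - 180.0
                psi = float((a + 180.0) % 360.0 - 180.0)
        if all(p is not None for p in (ca_prev, c_prev, ni, cai)):
            omega = dihedral_angle(ca_prev, c_prev, ni, cai)
        out[i] = (phi, psi, omega)
    return out


def handedness(s: Structure, span: tuple[int, int] | None = None,
               model: int = 0) -> dict[int, str]:
    """Classify each residue as 'alphaL', 'alphaR' or 'other' from its
    (phi, psi) position relative to the canonical helix windows."""
    tors = dihedrals(s, model)
    span = span or (1, s.n_residues)
    out = {}
    for i in range(span[0], span[1] + 1):
        phi, psi, _ = tors[i]
        if phi is None or psi is None:
            out[i] = "other"
        elif (abs(phi - _ALPHA_L[0]) <= HANDEDNESS_WINDOW
              and abs(psi - _ALPHA_L[1]) <= HANDEDNESS_WINDOW):
            out[i] = "alphaL"
        elif (abs(phi - _ALPHA_R[0]) <= HANDEDNESS_WINDOW
              and abs(psi - _ALPHA_R[1]) <= HANDEDNESS_WINDOW):
            out[i] = "alphaR"
        else:
            out[i] = "other"
    return out


@dataclass(frozen=True)
class HBond:
    """Backbone hydrogen bond CO(acceptor) <- HN(donor); separation is
    donor minus acceptor residue index (+4 for the classic i,i+4)."""

    donor: int
    acceptor: int
    distance: float
    angle: float

    @property
    def separation(self) -> int:
        return self.donor - self.acceptor


def detect_hbonds(s: Structure, model: int = 0,
                  min_separation: int = 2) -> list[HBond]:
    """Detect backbone amide hydrogen bonds by geometric criterion.

    Donors are backbone NH groups; acceptors are backbone carbonyls,
    including the acyl-chain carbonyl cap (residue index 0).  Only bonds
    with |separation| >= ``min_separation`` are reported.
    """
    donors = [a.res_index for a in s.atoms if a.name == "N"]
    acceptors = sorted({a.res_index for a in s.atoms if a.name == "C"
                        and s.has_atom(a.res_index, "O")})
    bonds = []
    for di in donors:
        n_xyz = s.xyz(di, "N", model)
        h_xyz = s.xyz(di, "H", model) if s.has_atom(di, "H") else None
        for ai in acceptors:
            if abs(di - ai) < min_separation:
                continue
            c_xyz = s.xyz(ai, "C", model)
            o_xyz = s.xyz(ai, "O", model)
            d_on = float(np.linalg.norm(o_xyz - n_xyz))
            if d_on >= HBOND_MAX_ON:
                continue
            cos_con = np.dot(c_xyz - o_xyz, n_xyz - o_xyz) / (
                np.linalg.norm(c_xyz - o_xyz) * np.linalg.norm(n_xyz - o_xyz))
            ang_con = float(np.degrees(np.arccos(np.clip(cos_con, -1, 1))))
            if ang_con <= HBOND_MIN_CON:
                continue
            ang_nho = 180.0
            if h_xyz is not None:
                cos_nho = np.dot(n_xyz - h_xyz, o_xyz - h_xyz) / (
                    np.linalg.norm(n_xyz - h_xyz)
                    * np.linalg.norm(o_xyz - h_xyz))
                ang_nho = float(np.degrees(np.arccos(np.clip(cos_nho, -1, 1))))
                if ang_nho <= HBOND_MIN_NHO:
                    continue
            bonds.append(HBond(donor=di, acceptor=ai, distance=d_on,
                               angle=ang_nho))
    return bonds


def backbone_selection(s: Structure, res_range=None) -> np.ndarray:
    """Backbone N, CA, C, O atom indices; acyl-cap atoms always excluded
    (they are not restrained by experiment)."""
    return s.select(names=("N", "CA", "C", "O"), res_range=res_range,
                    exclude_acyl=True)


def superpose(a: Structure, b: Structure,
              selection: np.ndarray | None = None,
              model_a: int = 0, model_b: int = 0
              ) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``b`` onto ``a`` (Kabsch).

    Returns (rotation, translation, rmsd) such that
    ``b @ R.T + t`` optimally matches ``a`` over the selection.
    """
    sel_a = selection if selection is not None else backbone_selection(a)
    sel_b = selection if selection is not None else backbone_selection(b)
    pa = a.coords[model_a, sel_a]
    pb = b.coords[model_b, sel_b]
    if pa.shape != pb.shape:
        raise ValueError("selections differ in atom count")
    if len(pa) < 3:
        raise ValueError("superposition requires at least 3 atoms")
    rot, t, rmsd = _kabsch(pa, pb)
    return rot, t, rmsd


def _kabsch(pa: np.ndarray, pb: np.ndarray):
    ca, cb = pa.mean(axis=0), pb.mean(axis=0)
    qa, qb = pa - ca, pb - cb
    h = qb.T @ qa
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    moved = qb @ rot.T
    rmsd = float(np.sqrt(np.mean(np.sum((moved - qa) ** 2, axis=1))))
    t = ca - cb @ rot.T
    return rot, t, rmsd


def ensemble_rmsd_stats(s: Structure,
                        selection: np.ndarray | None = None
                        ) -> tuple[float, float]:
    """Ensemble precision statistic: mean +/- s.d. of per-model RMSDs to the
    mean structure, after aligning every model to the first (lowest-energy)
    model over the selection.  Acyl atoms are excluded by the default
    backbone selection."""
    if s.n_models < 2:
        raise ValueError("ensemble statistics require at least 2 models")
    sel = selection if selection is not None else backbone_selection(s)
    ref = s.coords[0, sel]
    aligned = np.empty((s.n_models, len(sel), 3))
    aligned[0] = ref
    for k in range(1, s.n_models):
        rot, t, _ = _kabsch(ref, s.coords[k, sel])
        aligned[k] = s.coords[k, sel] @ rot.T + t
    mean = aligned.mean(axis=0)
    per_model = np.sqrt(np.mean(np.sum((aligned - mean) ** 2, axis=2),
                                axis=1))
    sd = float(per_model.std(ddof=1)) if s.n_models > 1 else 0.0
    return float(per_model.mean()), sd


@dataclass(frozen=True)
class HelixAxis:
    direction: np.ndarray  # unit vector, N- to C-terminal
    point: np.ndarray      # a point on the axis (centroid)
    residual: float        # RMS distance of smoothed CA trace to the axis


def helix_axis(s: Structure, span: tuple[int, int], model: int = 0
               ) -> HelixAxis:
    """Helix axis by total least squares through the 4-residue sliding-window
    average of the CA trace (the averaging removes the helical wobble, so
    the smoothed points lie on the axis for an ideal helix)."""
    first, last = span
    if last - first + 1 < 5:
        raise ValueError("helix axis requires a span of at least 5 residues")
    ca = np.array([s.xyz(i, "CA", model) for i in range(first, last + 1)])
    win = 4
    smoothed = np.array([ca[i:i + win].mean(axis=0)
                         for i in range(len(ca) - win + 1)])
    centroid = smoothed.mean(axis=0)
    _, _, vt = np.linalg.svd(smoothed - centroid)
    direction = vt[0]
    if np.dot(direction, smoothed[-1] - smoothed[0]) < 0:
        direction = -direction
    diffs = smoothed - centroid
    perp = diffs - np.outer(diffs @ direction, direction)
    residual = float(np.sqrt(np.mean(np.sum(perp ** 2, axis=1))))
    return HelixAxis(direction=direction, point=centroid, residual=residual)


@dataclass(frozen=True)
class EllipsoidFit:
    """Principal-axis (second-moment) ellipsoid of the macrocycle backbone,
    with the bend angle between its long axis and the helix axis."""

    center: np.ndarray
    axes: np.ndarray      # rows: orthonormal directions, descending extent
    lengths: np.ndarray   # RMS semi-axis extents, descending, A
    bend_angle: float     # degrees, in [0, 180]


def macrocycle_bend(s: Structure, ring_span: tuple[int, int],
                    helix_span: tuple[int, int], model: int = 0
                    ) -> EllipsoidFit:
    """Fit an ellipsoid to the macrocycle backbone (N, CA, C atoms) and
    report the angle between its long axis and the helix axis.

    The long axis is oriented to point away from the helix-proximal side of
    the ring (from the latch CA toward the ring centroid), which makes the
    bend angle single-valued in [0, 180] — roughly 140 deg for the
    entolysin-like catch-pole geometry versus 45 deg for the
    putisolvin-like one.
    """
    if ring_span[1] - ring_span[0] + 1 < 4:
        raise ValueError("degenerate ring: fewer than 4 residues")
    pts = []
    for i in range(ring_span[0], ring_span[1] + 1):
        for name in ("N", "CA", "C"):
            pts.append(s.xyz(i, name, model))
    pts = np.asarray(pts)
    center = pts.mean(axis=0)
    cov = np.cov((pts - center).T)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order].T
    long_axis = evecs[0]
    anchor = s.xyz(ring_span[0], "CA", model)
    if np.dot(long_axis, center - anchor) < 0:
        long_axis = -long_axis
        evecs = evecs.copy()
        evecs[0] = long_axis
    haxis = helix_axis(s, helix_span, model)
    cosang = np.clip(np.dot(long_axis, haxis.direction), -1.0, 1.0)
    bend = float(np.degrees(np.arccos(cosang)))
    return EllipsoidFit(center=center, axes=evecs,
                        lengths=np.sqrt(np.clip(evals, 0, None)),
                        bend_angle=bend)


def amphipathic_segregation(seq: ClipSequence, s: Structure,
                            helix_span: tuple[int, int], model: int = 0
                            ) -> tuple[float, dict[int, str]]:
    """Helical-wheel segregation score of hydrophobic vs hydrophilic side
    chains over the helix span, plus a per-residue face assignment.

    CA->CB directions are projected onto the plane perpendicular to the
    helix axis; hydrophobicity weights (+1 hydrophobic, -1 hydrophilic) are
    mean-centered and the score is the magnitude of the weighted vector sum
    normalized by the sum of absolute weights.  1 means perfectly segregated
    faces; 0 means no amphipathic moment (e.g. a uniform sequence).
    """
    axis = helix_axis(s, helix_span, model).direction
    offs, weights = [], []
    residues = []
    for i in range(helix_span[0], helix_span[1] + 1):
        if not s.has_atom(i, "CB"):
            continue
        v = s.xyz(i, "CB", model) - s.xyz(i, "CA", model)
        v = v - np.dot(v, axis) * axis
        norm = np.linalg.norm(v)
        if norm < 1e-9:
            continue
        offs.append(v / norm)
        weights.append(1.0 if seq.residue(i).hclass == "hydrophobic"
                       else -1.0)
        residues.append(i)
    if not residues:
        return 0.0, {}
    offs = np.asarray(offs)
    w = np.asarray(weights)
    wc = w - w.mean()
    denom = np.abs(wc).sum()
    if denom < 1e-12:
        return 0.0, {i: "none" for i in residues}
    moment = (wc[:, None] * offs).sum(axis=0)
    score = float(np.linalg.norm(moment) / denom)
    mu = moment / (np.linalg.norm(moment) + 1e-12)
    faces = {}
    for i, u in zip(residues, offs):
        faces[i] = "hydrophobic" if np.dot(u, mu) > 0 else "hydrophilic"
    return score, faces


def detect_motif(s: Structure, seq: ClipSequence, model: int = 0) -> str:
    """Geometry-level motif call: stapled if the initial alphaL run extends
    past the latch into the macrocycle, catch-pole if it terminates at the
    latch, offshoot for fully cyclic (l = m) peptides."""
    if seq.l == seq.m:
        return "full_cycle_offshoot"
    hand = handedness(s, model=model)
    run_end = 0
    for i in range(1, seq.l + 1):
        if hand[i] == "alphaL":
            run_end = i
        else:
            break
    return "stapled_helix" if run_end > seq.latch_pos else "catch_pole"
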