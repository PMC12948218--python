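"""Backbone model construction for CLiPs.

Models are built residue-by-residue in internal coordinates (natural
extension reference frame) from a per-residue phi/psi/omega template, with
idealized bond lengths and angles.  D/L configuration is realized through
the chirality of the CB placement.  The N-terminal acyl chain is represented
only by its carbonyl (C, O) capping the first amide nitrogen, since the
chain beyond C1 is conformationally ill-defined and excluded from all
geometric analysis.  The macrocycle is closed by an ester ("depsi") bond
between the latch side-chain oxygen and the C-terminal carbonyl carbon;
closure can be refined by cyclic coordinate descent (CCD) restricted to the
loop residues.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classify import classify_motif
from .sequence import ClipSequence, HYDROXYL_CODES
from .structure import (Atom, Link, Structure, dihedral_angle, place_atom,
                        rotation_about_axis)

__all__ = [
    "DihedralTemplate",
    "ALPHA_L",
    "ALPHA_R",
    "canonical_template",
    "build_backbone",
    "close_depsi",
    "closure_gap",
    "check_closure",
    "homology_build",
    "mirror",
    "ClosureError",
    "HomologyError",
]

# Idealized backbone geometry (standard peptide values), Angstrom / degrees.
B_N_CA, B_CA_C, B_C_N = 1.46, 1.52, 1.33
B_C_O, B_N_H = 1.23, 1.01
B_CA_CB, B_CB_OG = 1.53, 1.42
B_ESTER = 1.33
A_N_CA_C, A_CA_C_N, A_C_N_CA = 111.0, 116.0, 122.0
A_CA_C_O, A_N_C_O, A_C_N_H = 121.0, 123.0, 119.0
A_N_CA_CB, A_CA_CB_OG = 110.5, 109.5

# Canonical helix dihedrals.  The left-handed alpha-helix favored by
# D-residue-rich CLiPs is the mirror image of the standard right-handed one.
ALPHA_L = (57.0, 47.0)
ALPHA_R = (-57.0, -47.0)

_TETRA_HALF = 54.75  # half the CB/HA tetrahedral split about the NC bisector


class ClosureError(RuntimeError):
    """Depsi-bond closure failed to reach tolerance."""

    def __init__(self, msg, gap=None):
        super().__init__(msg)
        self.gap = gap


class HomologyError(ValueError):
    """Template and target are not homologous at the macrocycle level."""


def _wrap_angle(a: float) -> float:
    a = (float(a) + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


@dataclass(frozen=True)
class DihedralTemplate:
    """Per-residue (phi, psi, omega) set defining a buildable backbone."""

    phi: tuple[float, ...]
    psi: tuple[float, ...]
    omega: tuple[float, ...]
    source: str = "user"

    def __post_init__(self):
        n = len(self.phi)
        if n < 1 or len(self.psi) != n or len(self.omega) != n:
            raise ValueError("phi/psi/omega must have equal nonzero length")
        for series in (self.phi, self.psi, self.omega):
            for a in series:
                if not -180.0 < a <= 180.0:
                    raise ValueError(f"angle {a} outside (-180, 180]")

    def __len__(self) -> int:
        return len(self.phi)

    @classmethod
    def from_arrays(cls, phi, psi, omega=None, source="user"):
        phi = tuple(_wrap_angle(a) for a in phi)
        psi = tuple(_wrap_angle(a) for a in psi)
        if omega is None:
            omega = (180.0,) * len(phi)
        else:
            omega = tuple(_wrap_angle(a) for a in omega)
        return cls(phi=phi, psi=psi, omega=omega, source=source)


def canonical_template(n: int, handed: str = "L") -> DihedralTemplate:
    """Ideal left- (``handed='L'``) or right-handed alpha-helix template."""
    phi, psi = ALPHA_L if handed.upper() == "L" else ALPHA_R
    return DihedralTemplate.from_arrays(
        [phi] * n, [psi] * n, source=f"canonical_alpha{handed.upper()}")


# -- residue plans ---------------------------------------------------------

@dataclass(frozen=True)
class _ResiduePlan:
    code: str
    config: str       # 'L', 'D', 'achiral'
    has_cb: bool
    og_name: str | None  # side-chain hydroxyl oxygen name, latch only
    chi1: float = 180.0


def _plan_from_sequence(seq: ClipSequence, latch_chi1: float
                        ) -> list[_ResiduePlan]:
    plans = []
    for r in seq.residues:
        og = None
        if r.is_latch:
            og = "OG1" if r.code in ("Thr", "aThr") else "OG"
        plans.append(_ResiduePlan(
            code=r.code, config=r.config, has_cb=r.code != "Gly",
            og_name=og, chi1=latch_chi1))
    return plans


def _plan_from_structure(s: Structure, model: int = 0) -> list[_ResiduePlan]:
    """Recover a residue plan (codes, CB chirality, latch oxygen, chi1) from
    an existing model, for dihedral-space rebuilds."""
    plans = []
    for i in range(1, s.n_residues + 1):
        code = next(a.res_code for a in s.atoms if a.res_index == i)
        has_cb = s.has_atom(i, "CB")
        config = "achiral"
        if has_cb:
            imp = dihedral_angle(s.xyz(i, "N", model), s.xyz(i, "CA", model),
                                 s.xyz(i, "C", model), s.xyz(i, "CB", model))
            config = "L" if imp < 0 else "D"
        og = next((a.name for a in s.atoms
                   if a.res_index == i and a.name in ("OG", "OG1")), None)
        chi1 = 180.0
        if og is not None:
            chi1 = dihedral_angle(s.xyz(i, "N", model), s.xyz(i, "CA", model),
                                  s.xyz(i, "CB", model), s.xyz(i, og, model))
        plans.append(_ResiduePlan(code, config, has_cb, og, chi1))
    return plans


def _build_model(plans: list[_ResiduePlan], template: DihedralTemplate
                 ) -> tuple[list[Atom], np.ndarray]:
    n = len(plans)
    phi, psi, omega = template.phi, template.psi, template.omega
    pos: dict[tuple[int, str], np.ndarray] = {}

    # canonical frame: N1 at the origin, CA1 on +x, C1 in the xy-plane
    pos[(1, "N")] = np.zeros(3)
    pos[(1, "CA")] = np.array([B_N_CA, 0.0, 0.0])
    ang = np.radians(A_N_CA_C)
    pos[(1, "C")] = pos[(1, "CA")] + B_CA_C * np.array(
        [-np.cos(ang), np.sin(ang), 0.0])

    # acyl-chain carbonyl cap on N1 (phi1 is defined against its carbon)
    pos[(0, "C")] = place_atom(pos[(1, "C")], pos[(1, "CA")], pos[(1, "N")],
                               B_C_N, A_C_N_CA, phi[0])
    pos[(0, "O")] = place_atom(pos[(1, "CA")], pos[(1, "N")], pos[(0, "C")],
                               B_C_O, A_N_C_O, 0.0)
    pos[(1, "H")] = place_atom(pos[(0, "O")], pos[(0, "C")], pos[(1, "N")],
                               B_N_H, A_C_N_H, 180.0)

    for i in range(2, n + 1):
        pos[(i, "N")] = place_atom(
            pos[(i - 1, "N")], pos[(i - 1, "CA")], pos[(i - 1, "C")],
            B_C_N, A_CA_C_N, psi[i - 2])
        pos[(i, "CA")] = place_atom(
            pos[(i - 1, "CA")], pos[(i - 1, "C")], pos[(i, "N")],
            B_N_CA, A_C_N_CA, omega[i - 1])
        pos[(i, "C")] = place_atom(
            pos[(i - 1, "C")], pos[(i, "N")], pos[(i, "CA")],
            B_CA_C, A_N_CA_C, phi[i - 1])
        pos[(i - 1, "O")] = place_atom(
            pos[(i, "CA")], pos[(i, "N")], pos[(i - 1, "C")],
            B_C_O, A_N_C_O, 0.0)
        pos[(i, "H")] = place_atom(
            pos[(i - 1, "O")], pos[(i - 1, "C")], pos[(i, "N")],
            B_N_H, A_C_N_H, 180.0)

    # C-terminal carbonyl oxygen encodes psi of the last residue
    pos[(n, "O")] = place_atom(
        pos[(n, "N")], pos[(n, "CA")], pos[(n, "C")],
        B_C_O, A_CA_C_O, _wrap_angle(psi[n - 1] + 180.0))

    # side chains: CB by tetrahedral construction (chirality via the normal
    # component), latch hydroxyl oxygen from chi1
    for i, plan in enumerate(plans, start=1):
        if not plan.has_cb:
            continue
        ca = pos[(i, "CA")]
        u1 = pos[(i, "N")] - ca
        u1 /= np.linalg.norm(u1)
        u2 = pos[(i, "C")] - ca
        u2 /= np.linalg.norm(u2)
        bis = -(u1 + u2)
        bis /= np.linalg.norm(bis)
        nrm = np.cross(u1, u2)
        nrm /= np.linalg.norm(nrm)
        sign = {"L": -1.0, "D": +1.0, "achiral": -1.0}[plan.config]
        half = np.radians(_TETRA_HALF)
        pos[(i, "CB")] = ca + B_CA_CB * (
            np.cos(half) * bis + sign * np.sin(half) * nrm)
        if plan.og_name is not None:
            pos[(i, plan.og_name)] = place_atom(
                pos[(i, "N")], ca, pos[(i, "CB")],
                B_CB_OG, A_CA_CB_OG, plan.chi1)

    atoms: list[Atom] = [Atom(0, "ACY", "C", "C"), Atom(0, "ACY", "O", "O")]
    coords = [pos[(0, "C")], pos[(0, "O")]]
    for i, plan in enumerate(plans, start=1):
        names = ["N", "H", "CA"]
        if plan.has_cb:
            names.append("CB")
        if plan.og_name is not None:
            names.append(plan.og_name)
        names += ["C", "O"]
        for name in names:
            element = name[0]
            atoms.append(Atom(i, plan.code, name, element))
            coords.append(pos[(i, name)])
    return atoms, np.asarray(coords)


def build_backbone(seq: ClipSequence, template: DihedralTemplate,
                   latch_chi1: float = 180.0) -> Structure:
    """Build a single-model backbone structure from a dihedral template.

    The template must provide one (phi, psi, omega) record per residue;
    phi of residue 1 is defined against the acyl carbonyl carbon.
    """
    if len(template) != seq.l:
        raise ValueError(
            f"template length {len(template)} does not match l={seq.l}")
    plans = _plan_from_sequence(seq, latch_chi1)
    atoms, coords = _build_model(plans, template)
    return Structure(atoms=tuple(atoms), coords=coords[None])


def rebuild_with_dihedrals(s: Structure, template: DihedralTemplate
                           ) -> Structure:
    """Rebuild a structure's model 0 from new dihedrals, keeping its residue
    composition, CB chirality and latch chi1."""
    plans = _plan_from_structure(s, model=0)
    if len(template) != len(plans):
        raise ValueError("template length mismatch")
    atoms, coords = _build_model(plans, template)
    out = Structure(atoms=tuple(atoms), coords=coords[None])
    return out.with_links(s.links)


# -- depsi-bond closure ----------------------------------------------------

def _latch_oxygen(s: Structure, latch_pos: int) -> str:
    for name in ("OG", "OG1"):
        if s.has_atom(latch_pos, name):
            return name
    raise ValueError(
        f"latch residue {latch_pos} has no side-chain hydroxyl oxygen")


def closure_gap(s: Structure, latch_pos: int, model: int = 0) -> float:
    """Signed closure gap: latch-O to C-terminal-C distance minus the ideal
    ester bond length (1.33 A)."""
    og = _latch_oxygen(s, latch_pos)
    d = np.linalg.norm(s.xyz(s.n_residues, "C", model)
                       - s.xyz(latch_pos, og, model))
    return float(d - B_ESTER)


@dataclass(frozen=True)
class ClosureReport:
    closed: bool
    gap: float
    linked: bool


def check_closure(s: Structure, latch_pos: int, tol: float = 0.2,
                  model: int = 0) -> ClosureReport:
    """Report whether the depsi macrocycle is closed ('open' structures are
    linearized variants: no ester link, or a large gap)."""
    gap = closure_gap(s, latch_pos, model)
    og = _latch_oxygen(s, latch_pos)
    linked = any(
        lk.kind == "ester" and {(lk.res_a, lk.atom_a), (lk.res_b, lk.atom_b)}
        == {(latch_pos, og), (s.n_residues, "C")}
        for lk in s.links)
    return ClosureReport(closed=linked and abs(gap) <= tol, gap=gap,
                         linked=linked)


def _loop_bonds(s: Structure, loop_span: tuple[int, int]) -> list[tuple]:
    """CCD-rotatable bonds: (axis_from, axis_to, moving_atom_indices) for
    phi and psi of each loop residue (psi of the last residue only reorients
    its carbonyl oxygen and is skipped)."""
    n = s.n_residues
    bonds = []
    for i in range(loop_span[0], loop_span[1] + 1):
        # phi_i: rotate about N-CA; moves residue i (except N, H) + downstream
        moving = [k for k, a in enumerate(s.atoms)
                  if a.res_index > i
                  or (a.res_index == i and a.name not in ("N", "H"))]
        bonds.append((s.index_of(i, "N"), s.index_of(i, "CA"), moving))
        if i < n:
            # psi_i: rotate about CA-C; moves O_i + downstream residues
            moving = [k for k, a in enumerate(s.atoms)
                      if a.res_index > i
                      or (a.res_index == i and a.name == "O")]
            bonds.append((s.index_of(i, "CA"), s.index_of(i, "C"), moving))
    return bonds


def close_depsi(s: Structure, latch_pos: int, refine: bool = False,
                tol: float = 0.1, max_iter: int = 500,
                loop_span: tuple[int, int] | None = None) -> Structure:
    """Record the depsi ester link and, optionally, refine loop dihedrals by
    cyclic coordinate descent until the closure gap is below ``tol``.

    CCD sweeps the loop residues N- to C-terminally, rotating each phi/psi
    bond to bring the C-terminal carbonyl carbon onto the sphere of ideal
    ester bond length around the latch oxygen.  Only loop-span atoms (and
    downstream) move; the helix and the latch oxygen stay fixed.  Raises
    :class:`ClosureError` with the residual gap if refinement fails.
    """
    n = s.n_residues
    m = n - latch_pos + 1
    if loop_span is None:
        loop_span = classify_motif(n, m).loop_span
    # the latch oxygen must stay fixed: never rotate latch-or-earlier bonds
    loop_span = (max(loop_span[0], latch_pos + 1), loop_span[1])
    og = _latch_oxygen(s, latch_pos)
    coords = s.coords.copy()
    if refine:
        bonds = _loop_bonds(s, loop_span)
        c_idx = s.index_of(n, "C")
        og_idx = s.index_of(latch_pos, og)
        for model in range(s.n_models):
            coords[model] = _ccd_close(
                coords[model], bonds, c_idx, og_idx, tol, max_iter)
    link = Link(latch_pos, og, n, "C", kind="ester")
    links = s.links if any(lk == link for lk in s.links) else s.links + (link,)
    out = s.with_coords(coords).with_links(links)
    if refine:
        gap = closure_gap(out, latch_pos)
        if abs(gap) > tol:
            raise ClosureError(
                f"closure failure: residual gap {gap:.3f} A after "
                f"{max_iter} CCD sweeps", gap=gap)
    return out


def _ccd_close(xyz: np.ndarray, bonds, c_idx: int, og_idx: int,
               tol: float, max_iter: int) -> np.ndarray:
    xyz = xyz.copy()
    target_d = B_ESTER
    for _ in range(max_iter):
        gap = abs(np.linalg.norm(xyz[c_idx] - xyz[og_idx]) - target_d)
        if gap <= tol:
            return xyz
        for a_idx, b_idx, moving in bonds:
            p = xyz[a_idx]
            k = xyz[b_idx] - p
            k = k / np.linalg.norm(k)
            e = xyz[c_idx]
            o = xyz[og_idx]
            v = e - p
            v_perp = v - (v @ k) * k
            u = o - p
            u_par = (u @ k) * k
            u_perp = u - u_par
            r = np.linalg.norm(v_perp)
            q = np.linalg.norm(u_perp)
            if r < 1e-9 or q < 1e-9:
                continue
            # |e(theta) - o|^2 = A - B cos(alpha), alpha = angle(u_perp ->
            # v_perp) about k; pick alpha reaching the ideal ester distance
            a_const = (np.linalg.norm(u_par - (v @ k) * k) ** 2
                       + r ** 2 + q ** 2)
            b_const = 2.0 * r * q
            cos_new = np.clip((a_const - target_d ** 2) / b_const, -1.0, 1.0)
            alpha_new = np.arccos(cos_new)
            alpha_cur = np.arctan2(np.cross(u_perp, v_perp) @ k,
                                   u_perp @ v_perp)
            # two symmetric solutions; take the smaller rotation
            d1 = _wrap_rad(alpha_new - alpha_cur)
            d2 = _wrap_rad(-alpha_new - alpha_cur)
            delta = d1 if abs(d1) <= abs(d2) else d2
            if abs(delta) < 1e-12:
                continue
            rot = rotation_about_axis(p, k, delta)
            xyz[moving] = rot(xyz[moving])
    return xyz


def _wrap_rad(a: float) -> float:
    return (a + np.pi) % (2.0 * np.pi) - np.pi


# -- homology extension / truncation --------------------------------------

def homology_build(template_seq: ClipSequence, template_struct: Structure,
                   target_seq: ClipSequence,
                   model: int = 0) -> Structure:
    """Build a target CLiP from a solved template of the same macrocycle
    size: macrocycle dihedrals are copied, and the alphaL-helix is extended
    or truncated at the N-terminus with canonical helix residues.

    Refuses (``HomologyError``) if the macrocycle sizes or macrocycle
    backbone configurations differ, since such CLiPs may adopt alternative
    macrocycle conformations.
    """
    if target_seq.m != template_seq.m:
        raise HomologyError(
            f"macrocycle size differs: target m={target_seq.m} vs template "
            f"m={template_seq.m}")
    mism = [off for off in range(template_seq.m)
            if template_seq.residue(template_seq.latch_pos + off).config
            != target_seq.residue(target_seq.latch_pos + off).config]
    if mism:
        raise HomologyError(
            "macrocycle configuration mismatch at latch offsets "
            f"{mism}: same-m CLiPs with different macrocycle stereochemistry "
            "may adopt alternative backbone conformations")

    from .geometry import dihedrals as measure_dihedrals
    tpl = measure_dihedrals(template_struct, model=model)
    phi_c, psi_c = ALPHA_L
    phi, psi, omega = [], [], []
    for p in range(1, target_seq.l + 1):
        q = template_seq.latch_pos + (p - target_seq.latch_pos)
        if 1 <= q <= template_seq.l:
            rec = tpl[q]
            phi.append(rec[0] if rec[0] is not None else phi_c)
            psi.append(rec[1] if rec[1] is not None else psi_c)
            omega.append(rec[2] if rec[2] is not None else 180.0)
        else:
            phi.append(phi_c)
            psi.append(psi_c)
            omega.append(180.0)
    template = DihedralTemplate.from_arrays(phi, psi, omega,
                                            source="homology")
    chi1 = 180.0
    try:
        og = _latch_oxygen(template_struct, template_seq.latch_pos)
        chi1 = dihedral_angle(
            template_struct.xyz(template_seq.latch_pos, "N", model),
            template_struct.xyz(template_seq.latch_pos, "CA", model),
            template_struct.xyz(template_seq.latch_pos, "CB", model),
            template_struct.xyz(template_seq.latch_pos, og, model))
    except (ValueError, KeyError):
        pass
    built = build_backbone(target_seq, template, latch_chi1=chi1)
    return close_depsi(built, target_seq.latch_pos, refine=False)


# Deterministic seed conformations tried for the macrocycle loop before CCD
# refinement, paired with latch chi1 rotamers.
LOOP_SEEDS = ((-60.0, -30.0), (-80.0, 80.0), (70.0, 40.0),
              (-140.0, 140.0), (60.0, -120.0))
CHI1_ROTAMERS = (180.0, 60.0, -60.0)


def build_clip_model(seq: ClipSequence, tol: float = 0.1,
                     max_iter: int = 500) -> Structure:
    """De novo closed model for a CLiP sequence: canonical alphaL helix over
    the motif's helix span, loop residues seeded from a small deterministic
    conformer set and refined by CCD until the depsi ester closes.

    Raises :class:`ClosureError` if no seed/rotamer combination closes.
    """
    assign = classify_motif(seq.l, seq.m)
    latch = seq.latch_pos
    if assign.motif == "full_cycle_offshoot":
        # fully cyclic peptide: no helix, everything past the latch is loop
        loop = (2, seq.l)
        spans = [loop]
    else:
        loop = assign.loop_span
        spans = [loop]
        if assign.motif == "stapled_helix":
            # short macrocycles strain the helix terminus; allow the last
            # helical turn's dihedrals to relax if loop-only closure fails
            spans.append((latch + 2, seq.l))
    last_err: Exception | None = None
    for span in spans:
        for chi1 in CHI1_ROTAMERS:
            for loop_phi, loop_psi in LOOP_SEEDS:
                phi = [ALPHA_L[0]] * seq.l
                psi = [ALPHA_L[1]] * seq.l
                for i in range(loop[0], loop[1] + 1):
                    phi[i - 1] = loop_phi
                    psi[i - 1] = loop_psi
                template = DihedralTemplate.from_arrays(phi, psi,
                                                        source="de_novo")
                built = build_backbone(seq, template, latch_chi1=chi1)
                try:
                    return close_depsi(built, latch, refine=True,
                                       tol=tol, max_iter=max_iter,
                                       loop_span=span)
                except ClosureError as err:
                    last_err = err
    raise ClosureError(
        f"closure infeasible for ({seq.l}:{seq.m}) with available loop "
        "seeds", gap=getattr(last_err, "gap", None))


def mirror(s: Structure) -> Structure:
    """Mirror image: coordinates reflected through the yz-plane, which
    negates every dihedral and swaps all chirality (alphaL <-> alphaR)."""
    return s.mirrored()
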