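"""Synthetic fixture generators: helices, full CLiP sequence/structure
pairs, perturbed ensembles and NOE-style restraint lists.

All generators are pure functions of their parameters and a seed, so every
downstream analysis can be exercised reproducibly without external data.
The sequence generator emulates the Acidilin blueprint: an acylated, mostly-D
helix with occasional L-Leu, an acidic residue at position 2, a d-Ser latch
at ``l - m + 1`` and an amphipathic hydrophilic spacing; the structure
generator combines a canonical left-handed helix with a loop closed through
the depsi ester by cyclic coordinate descent.
"""

from __future__ import annotations

import numpy as np

from .build import (ALPHA_L, ALPHA_R, ClosureError, DihedralTemplate,
                    build_backbone, build_clip_model, close_depsi,
                    rebuild_with_dihedrals)
from .classify import CATCH_POLE, STAPLED, classify_motif
from .geometry import dihedrals as measure_dihedrals
from .restraints import DistanceRestraint
from .sequence import AcylDescriptor, ClipSequence, ResidueSpec
from .structure import Structure

__all__ = ["gen_helix", "gen_clip", "gen_clip_sequence", "gen_ensemble",
           "gen_restraints"]

# Frequency of L-Leu substitutions inside the otherwise-D helix, mimicking
# the reference sequence set (roughly one per four helix positions).
L_LEU_PROB = 0.25

def _helix_sequence(n: int, name: str = "synthetic-helix") -> ClipSequence:
    """All-Leu helix carrier sequence with a C-terminal Ser latch (smallest
    legal macrocycle), used when only a backbone is needed."""
    residues = []
    for i in range(1, n + 1):
        if i == max(1, n - 3):
            residues.append(ResidueSpec("Ser", "D", is_latch=True))
        else:
            residues.append(ResidueSpec("Leu", "D"))
    return ClipSequence(name=name, residues=tuple(residues),
                        acyl=AcylDescriptor(10, 0, True),
                        latch_pos=max(1, n - 3))


def gen_helix(n: int, handed: str = "L", noise_deg: float = 0.0,
              seed: int = 0) -> Structure:
    """Canonical left- or right-handed alpha-helical backbone of ``n``
    residues with i.i.d. Gaussian phi/psi noise (omega stays planar)."""
    if n < 4:
        raise ValueError("helix needs at least 4 residues")
    if noise_deg < 0:
        raise ValueError("noise must be non-negative")
    rng = np.random.default_rng(seed)
    phi0, psi0 = ALPHA_L if handed.upper() == "L" else ALPHA_R
    phi = phi0 + rng.normal(0.0, noise_deg, size=n)
    psi = psi0 + rng.normal(0.0, noise_deg, size=n)
    template = DihedralTemplate.from_arrays(
        phi, psi, source=f"canonical_alpha{handed.upper()}")
    seq = _helix_sequence(n)
    return build_backbone(seq, template)


def gen_clip_sequence(l: int, m: int, seed: int = 0,  # noqa: E741
                      name: str | None = None) -> ClipSequence:
    """Random Acidilin-like CLiP sequence with the requested (l:m) tag."""
    if not 4 <= m <= l:
        raise ValueError(f"need 4 <= m <= l, got ({l}:{m})")
    rng = np.random.default_rng(seed)
    latch = l - m + 1
    assign = classify_motif(l, m)
    helix_end = assign.helix_span[1] if assign.helix_span else l
    residues: list[ResidueSpec] = []
    for i in range(1, l + 1):
        if i == latch:
            residues.append(ResidueSpec("Ser", "D", is_latch=True))
        elif i == 2:
            residues.append(ResidueSpec("Glu", "D"))
        elif i <= helix_end:
            # D-dominant helix with occasional L-Leu; hydrophilic residues
            # spaced roughly every 3-4 positions for amphipathicity
            if i % 4 == 0:
                residues.append(ResidueSpec("Ser", "D"))
            elif rng.random() < L_LEU_PROB:
                residues.append(ResidueSpec("Leu", "L"))
            else:
                residues.append(ResidueSpec(
                    "Leu" if rng.random() < 0.7 else "Val", "D"))
        else:
            # loop: mixed configuration, L-residues tolerated
            code = ("Ser", "Leu", "Ile", "Val")[int(rng.integers(4))]
            cfg = "L" if rng.random() < 0.5 else "D"
            residues.append(ResidueSpec(code, cfg))
    return ClipSequence(
        name=name or f"synthetic-{l}-{m}", residues=tuple(residues),
        acyl=AcylDescriptor(10, 0, True), latch_pos=latch)


def gen_clip(l: int, m: int, motif_consistent: bool = True,  # noqa: E741
             seed: int = 0) -> tuple[ClipSequence, Structure]:
    """Sequence plus closed 3D model for an (l:m) CLiP.

    The helix span takes canonical alphaL dihedrals; loop residues start
    from a small set of deterministic seed conformations and are refined by
    CCD until the depsi ester closes.  With ``motif_consistent`` the built
    geometry realizes the motif the (l:m) rule assigns.
    """
    seq = gen_clip_sequence(l, m, seed=seed)
    return seq, build_clip_model(seq)


def gen_ensemble(base: Structure, k: int, noise_deg: float = 5.0,
                 seed: int = 0) -> Structure:
    """k-model ensemble: model 1 is ``base``; further models perturb phi/psi
    by Gaussian noise and re-close the macrocycle when an ester link is
    present.  Mimics the spread of an NMR ensemble."""
    if k < 2:
        raise ValueError("ensemble needs at least 2 models")
    rng = np.random.default_rng(seed)
    base0 = base.model(0)
    tors = measure_dihedrals(base0)
    n = base0.n_residues
    ester = next((lk for lk in base0.links if lk.kind == "ester"), None)
    models = [base0.coords[0]]
    attempts_per_model = 8
    for _ in range(1, k):
        for _attempt in range(attempts_per_model):
            phi = [tors[i][0] if tors[i][0] is not None else ALPHA_L[0]
                   for i in range(1, n + 1)]
            psi = [tors[i][1] if tors[i][1] is not None else ALPHA_L[1]
                   for i in range(1, n + 1)]
            omega = [tors[i][2] if tors[i][2] is not None else 180.0
                     for i in range(1, n + 1)]
            phi = np.asarray(phi) + rng.normal(0, noise_deg, n)
            psi = np.asarray(psi) + rng.normal(0, noise_deg, n)
            template = DihedralTemplate.from_arrays(phi, psi, omega,
                                                    source="gen_ensemble")
            candidate = rebuild_with_dihedrals(base0, template)
            if ester is None or noise_deg == 0.0:
                models.append(candidate.coords[0])
                break
            try:
                closed = close_depsi(candidate, ester.res_a, refine=True,
                                     tol=0.1, max_iter=200)
                models.append(closed.coords[0])
                break
            except ClosureError:
                continue
        else:
            # keep the unclosed perturbation rather than fail the ensemble
            models.append(candidate.coords[0])
    return base0.with_coords(np.stack(models))


def gen_restraints(s: Structure, cutoff: float = 4.5, slack: float = 0.5,
                   seed: int = 0) -> list[DistanceRestraint]:
    """NOE-style upper-bound restraints for every backbone amide-proton pair
    closer than ``cutoff`` in model 0, with bound = distance + slack (so the
    source structure itself never violates them)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    protons = [(a.res_index, a.name) for a in s.atoms if a.element == "H"]
    out = []
    for ia, (res_a, name_a) in enumerate(protons):
        for res_b, name_b in protons[ia + 1:]:
            d = float(np.linalg.norm(s.xyz(res_a, name_a, 0)
                                     - s.xyz(res_b, name_b, 0)))
            if d < cutoff:
                out.append(DistanceRestraint.simple(
                    res_a, name_a, res_b, name_b, d + slack))
    return out
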