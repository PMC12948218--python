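"""Measurement suite: handedness, hydrogen bonds, superposition, ensemble
statistics, helix axis, macrocycle bend and amphipathic segregation."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from psclip.build import build_backbone, canonical_template, mirror
from psclip.geometry import (amphipathic_segregation, detect_hbonds,
                             detect_motif, dihedrals, ensemble_rmsd_stats,
                             handedness, helix_axis, macrocycle_bend,
                             superpose)
from psclip.sequence import parse_clip
from psclip.structure import Atom, Structure
from psclip.synthetic import gen_clip, gen_ensemble, gen_helix


def _random_rigid(seed):
    rng = np.random.default_rng(seed)
    rot = Rotation.random(random_state=seed).as_matrix()
    return rot, rng.normal(0, 5, 3)


class TestDihedralsAndHandedness:
    def test_canonical_alpha_l_values(self, alpha_l_helix):
        tors = dihedrals(alpha_l_helix)
        for i in range(2, 10):
            assert tors[i][0] == pytest.approx(57.0, abs=1e-6)
            assert tors[i][1] == pytest.approx(47.0, abs=1e-6)

    def test_mirrored_values_negated(self, alpha_l_helix):
        tors = dihedrals(mirror(alpha_l_helix))
        for i in range(2, 10):
            assert tors[i][0] == pytest.approx(-57.0, abs=1e-6)
            assert tors[i][1] == pytest.approx(-47.0, abs=1e-6)

    def test_handedness_classification(self, alpha_l_helix):
        assert set(handedness(alpha_l_helix).values()) == {"alphaL"}
        assert set(handedness(mirror(alpha_l_helix)).values()) == {"alphaR"}

    def test_mirror_swaps_handedness_exactly(self):
        """handedness(mirror(s)) swaps alphaL <-> alphaR residue by residue,
        including on a structure with helix, loop and 'other' residues."""
        _, s = gen_clip(10, 8, seed=5)
        h, hm = handedness(s), handedness(mirror(s))
        swap = {"alphaL": "alphaR", "alphaR": "alphaL", "other": "other"}
        assert hm == {i: swap[v] for i, v in h.items()}

    def test_missing_atoms_yield_none_not_error(self, alpha_l_helix):
        # drop the acyl cap: phi of residue 1 becomes undefined
        keep = [k for k, a in enumerate(alpha_l_helix.atoms)
                if a.res_index > 0]
        bare = Structure(
            atoms=tuple(alpha_l_helix.atoms[k] for k in keep),
            coords=alpha_l_helix.coords[:, keep])
        tors = dihedrals(bare)
        assert tors[1][0] is None
        assert tors[2][0] is not None


class TestHydrogenBonds:
    def test_alpha_l_helix_has_all_i_i4_bonds(self, alpha_l_helix):
        """Every eligible CO(i) -> NH(i+4) pair of the ideal helix is
        detected, including the acyl-cap carbonyl."""
        bonds = {(hb.acceptor, hb.donor)
                 for hb in detect_hbonds(alpha_l_helix)}
        expected = {(i, i + 4) for i in range(0, 7)}  # acceptors 0..6
        assert expected <= bonds
        assert all(hb.separation == 4 for hb in detect_hbonds(alpha_l_helix))

    def test_extended_chain_has_no_bonds(self):
        seq = parse_clip("ext | C6:0 | " + " ".join(
            "S.d*" if i == 7 else "L.d" for i in range(1, 11)))
        from psclip.build import DihedralTemplate
        s = build_backbone(seq, DihedralTemplate.from_arrays(
            [180.0] * 10, [179.0] * 10))
        assert detect_hbonds(s) == []

    def test_bond_geometry_reported(self, alpha_l_helix):
        for hb in detect_hbonds(alpha_l_helix):
            assert 0 < hb.distance < 3.5
            assert hb.angle > 120.0


class TestSuperposition:
    def test_self_rmsd_zero(self, alpha_l_helix):
        *_, rmsd = superpose(alpha_l_helix, alpha_l_helix)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_rigid_transform_rmsd_zero(self, alpha_l_helix):
        rot, t = _random_rigid(3)
        moved = alpha_l_helix.transformed(rot, t)
        *_, rmsd = superpose(alpha_l_helix, moved)
        assert rmsd == pytest.approx(0.0, abs=1e-6)

    def test_matches_bruteforce_rotational_search(self):
        """On small point clouds the Kabsch result agrees with exhaustive
        numeric minimization over rotations to within 1e-3 A."""
        rng = np.random.default_rng(11)
        for n in (4, 5, 6):
            pa = rng.normal(0, 3, (n, 3))
            pb = pa @ Rotation.random(random_state=n).as_matrix().T \
                + rng.normal(0, 0.3, (n, 3))
            atoms = tuple(Atom(i + 1, "Leu", "CA", "C") for i in range(n))
            sa = Structure(atoms=atoms, coords=pa[None])
            sb = Structure(atoms=atoms, coords=pb[None])
            sel = np.arange(n)
            *_, rmsd = superpose(sa, sb, selection=sel)

            qa = pa - pa.mean(axis=0)
            qb = pb - pb.mean(axis=0)

            def objective(rotvec, qa=qa, qb=qb):
                r = Rotation.from_rotvec(rotvec).as_matrix()
                return np.sqrt(np.mean(np.sum((qb @ r.T - qa) ** 2,
                                              axis=1)))

            best = np.inf
            for seed_rot in Rotation.create_group("O"):  # 24 orientations
                res = minimize(objective, seed_rot.as_rotvec(),
                               method="Nelder-Mead",
                               options={"xatol": 1e-8, "fatol": 1e-12})
                best = min(best, res.fun)
            assert rmsd == pytest.approx(best, abs=1e-3)

    def test_too_few_atoms_rejected(self, alpha_l_helix):
        with pytest.raises(ValueError, match="at least 3"):
            superpose(alpha_l_helix, alpha_l_helix, selection=np.array([2,
                                                                        5]))


class TestEnsembleStats:
    def test_identical_models_zero(self, alpha_l_helix):
        stack = alpha_l_helix.with_coords(
            np.repeat(alpha_l_helix.coords, 10, axis=0))
        assert ensemble_rmsd_stats(stack) == pytest.approx((0.0, 0.0),
                                                           abs=1e-12)

    def test_single_displacement_closed_form(self, alpha_l_helix):
        """Two models differing by displacement d on one atom of n: each
        model sits d/(2*sqrt(n)) from the mean structure (the optimal
        alignment correction is second order for small d)."""
        sel = alpha_l_helix.select(names=("N", "CA", "C", "O"))
        n = len(sel)
        d = 0.01
        coords2 = alpha_l_helix.coords[0].copy()
        # radial displacement: invisible to the optimal rotation, so the
        # direct closed form holds up to the O(1/n) translation term
        u = coords2[sel[5]] - coords2[sel].mean(axis=0)
        coords2[sel[5]] += d * u / np.linalg.norm(u)
        stack = alpha_l_helix.with_coords(
            np.stack([alpha_l_helix.coords[0], coords2]))
        mean, sd = ensemble_rmsd_stats(stack, selection=sel)
        assert mean == pytest.approx(d / (2 * np.sqrt(n)), rel=0.02)
        assert sd == pytest.approx(0.0, abs=1e-6)

    def test_acyl_atoms_excluded_by_default(self, alpha_l_helix):
        """Displacing only the acyl cap leaves the backbone statistic at
        zero."""
        coords2 = alpha_l_helix.coords[0].copy()
        coords2[0] += 5.0
        stack = alpha_l_helix.with_coords(
            np.stack([alpha_l_helix.coords[0], coords2]))
        mean, _ = ensemble_rmsd_stats(stack)
        assert mean == pytest.approx(0.0, abs=1e-9)

    def test_requires_two_models(self, alpha_l_helix):
        with pytest.raises(ValueError):
            ensemble_rmsd_stats(alpha_l_helix)


class TestHelixAxis:
    def test_axis_equivariant_under_rotation(self, alpha_l_helix):
        ax = helix_axis(alpha_l_helix, (1, 10))
        rot, t = _random_rigid(17)
        moved = alpha_l_helix.transformed(rot, t)
        ax2 = helix_axis(moved, (1, 10))
        assert np.allclose(ax2.direction, rot @ ax.direction, atol=1e-9)

    def test_axis_along_z_after_alignment(self, alpha_l_helix):
        """Rotating the helix so its axis maps onto z and re-fitting
        recovers (0, 0, 1)."""
        ax = helix_axis(alpha_l_helix, (1, 10))
        z = np.array([0.0, 0.0, 1.0])
        rot = Rotation.align_vectors(z[None], ax.direction[None])[0]
        moved = alpha_l_helix.transformed(rot.as_matrix(), np.zeros(3))
        ax2 = helix_axis(moved, (1, 10))
        assert np.allclose(ax2.direction, z, atol=1e-6)

    def test_noisy_helix_axis_stable(self):
        """Dihedral noise accumulates along the chain, so a 5-degree kick
        tilts the fitted axis by roughly twice that (simulated bound); the
        tilt shrinks as the noise does."""
        def tilt(noise, seed):
            clean = gen_helix(12, "L", 0.0, seed=seed)
            noisy = gen_helix(12, "L", noise, seed=seed)
            a = helix_axis(clean, (1, 12)).direction
            b = helix_axis(noisy, (1, 12)).direction
            return np.degrees(np.arccos(np.clip(abs(np.dot(a, b)), -1, 1)))

        assert tilt(5.0, seed=0) < 15.0
        mean_small = np.mean([tilt(1.0, s) for s in range(8)])
        mean_large = np.mean([tilt(5.0, s) for s in range(8)])
        assert mean_small < mean_large

    def test_residual_small_for_ideal_helix(self, alpha_l_helix):
        assert helix_axis(alpha_l_helix, (1, 10)).residual < 1.0

    def test_short_span_rejected(self, alpha_l_helix):
        with pytest.raises(ValueError):
            helix_axis(alpha_l_helix, (1, 4))


def _toy_helix_plus_ring(long_axis_dir):
    """Six collinear 'helix' residues along z plus a 4-residue planar
    elliptical ring whose long axis points along ``long_axis_dir``."""
    atoms, coords = [], []
    for i in range(1, 7):  # helix CA trace along +z
        for name in ("N", "CA", "C"):
            atoms.append(Atom(i, "Leu", name, name[0]))
            jitter = {"N": (0.3, 0.0), "CA": (0.0, 0.0), "C": (-0.3, 0.0)}
            coords.append([jitter[name][0], jitter[name][1], 1.5 * i])
    u = np.asarray(long_axis_dir, dtype=float)
    u /= np.linalg.norm(u)
    v = np.cross([0.57, -0.71, 0.41], u)
    v /= np.linalg.norm(v)
    center = np.array([0.0, 0.0, 11.0])
    k = 0
    for i in range(7, 11):  # ring backbone on an ellipse, a=4 >> b=1
        for name in ("N", "CA", "C"):
            # start at the -u end so the first (latch-side) residue is the
            # helix-proximal edge of the ring
            theta = np.pi + 2 * np.pi * k / 12.0
            atoms.append(Atom(i, "Leu", name, name[0]))
            coords.append(center + 4.0 * np.cos(theta) * u
                          + 1.0 * np.sin(theta) * v)
            k += 1
    return Structure(atoms=tuple(atoms), coords=np.asarray(coords)[None])


class TestMacrocycleBend:
    def test_ring_long_axis_parallel_to_helix(self):
        s = _toy_helix_plus_ring([0.0, 0.0, 1.0])
        fit = macrocycle_bend(s, (7, 10), (1, 6))
        assert fit.bend_angle == pytest.approx(0.0, abs=5.0)

    def test_ring_perpendicular_to_helix(self):
        s = _toy_helix_plus_ring([1.0, 0.0, 0.0])
        fit = macrocycle_bend(s, (7, 10), (1, 6))
        assert fit.bend_angle == pytest.approx(90.0, abs=5.0)

    def test_axes_orthonormal_descending(self):
        _, s = gen_clip(14, 5, seed=0)
        fit = macrocycle_bend(s, (10, 14), (1, 10))
        assert np.allclose(fit.axes @ fit.axes.T, np.eye(3), atol=1e-9)
        assert fit.lengths[0] >= fit.lengths[1] >= fit.lengths[2]

    def test_invariant_under_rotation_about_helix_axis(self):
        _, s = gen_clip(14, 5, seed=0)
        fit = macrocycle_bend(s, (10, 14), (1, 10))
        axis = helix_axis(s, (1, 10)).direction
        rot = Rotation.from_rotvec(np.radians(70) * axis).as_matrix()
        fit2 = macrocycle_bend(s.transformed(rot, np.zeros(3)),
                               (10, 14), (1, 10))
        assert fit2.bend_angle == pytest.approx(fit.bend_angle, abs=1e-6)

    def test_degenerate_ring_rejected(self, alpha_l_helix):
        with pytest.raises(ValueError, match="degenerate"):
            macrocycle_bend(alpha_l_helix, (7, 9), (1, 6))


class TestAmphipathicSegregation:
    def test_uniform_sequence_scores_zero(self):
        seq = parse_clip("uni | C6:0 | " + " ".join(
            "S.d*" if i == 9 else "S.d" for i in range(1, 13)))
        s = build_backbone(seq, canonical_template(12))
        score, _ = amphipathic_segregation(seq, s, (1, 12))
        assert score == pytest.approx(0.0, abs=1e-12)

    def test_ideal_amphipathic_helix_segregates(self, clips):
        """The viscosin hexapeptide core (hydrophilic at wheel-adjacent
        positions 2, 3, 6) gives a strongly one-sided moment."""
        seq = clips["viscosin"]
        s = build_backbone(seq, canonical_template(9))
        score, faces = amphipathic_segregation(seq, s, (1, 6))
        assert score > 0.7
        # hydrophilic residues cluster on the face opposite the moment
        for i in (2, 3, 6):
            assert faces[i] == "hydrophilic"

    def test_score_invariant_under_rigid_motion(self, clips):
        seq = clips["viscosin"]
        s = build_backbone(seq, canonical_template(9))
        rot, t = _random_rigid(23)
        score_a, _ = amphipathic_segregation(seq, s, (1, 6))
        score_b, _ = amphipathic_segregation(seq, s.transformed(rot, t),
                                             (1, 6))
        assert score_a == pytest.approx(score_b, abs=1e-9)

    def test_score_bounded(self, clips, orfamide_model):
        score, _ = amphipathic_segregation(clips["orfamide A"],
                                           orfamide_model, (1, 6))
        assert 0.0 <= score <= 1.0


class TestMotifDetection:
    @pytest.mark.parametrize("l,m", [(10, 8), (12, 4), (9, 9)])
    def test_generated_geometry_matches_tag_rule(self, l, m):
        from psclip.classify import classify_motif
        seq, s = gen_clip(l, m, seed=1)
        assert detect_motif(s, seq) == classify_motif(l, m).motif
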