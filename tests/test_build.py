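"""Backbone construction: internal-coordinate builds, chirality, depsi
closure and homology extension."""

import numpy as np
import pytest

from psclip.build import (ALPHA_L, B_C_N, B_CA_C, B_N_CA, ClosureError,
                          DihedralTemplate, HomologyError, build_backbone,
                          build_clip_model, canonical_template, check_closure,
                          close_depsi, closure_gap, homology_build, mirror,
                          rebuild_with_dihedrals)
from psclip.geometry import dihedrals, handedness, helix_axis, superpose
from psclip.sequence import parse_clip
from psclip.structure import dihedral_angle


def _template_roundtrip_errors(seq, template):
    s = build_backbone(seq, template)
    measured = dihedrals(s)
    errs = []
    for i in range(1, seq.l + 1):
        phi, psi, omega = measured[i]
        errs.append(abs(phi - template.phi[i - 1]))
        errs.append(abs(psi - template.psi[i - 1]))
        if i >= 2:  # omega of residue 1 has no preceding CA
            errs.append(abs(omega - template.omega[i - 1]))
    return errs


class TestBuildRoundTrip:
    def test_dihedral_roundtrip_random_templates(self):
        """Build/measure round trip: recomputed dihedrals match the input
        template to far better than 0.1 degrees, over 100 seeded random
        templates."""
        seq = parse_clip("rt | C6:0 | L.d E.d S.d* L.l V.d I.l S.l L.d")
        rng = np.random.default_rng(2024)
        worst = 0.0
        for _ in range(100):
            template = DihedralTemplate.from_arrays(
                rng.uniform(-179.0, 180.0, seq.l),
                rng.uniform(-179.0, 180.0, seq.l),
                rng.uniform(150.0, 180.0, seq.l))
            worst = max(worst, *_template_roundtrip_errors(seq, template))
        assert worst < 0.1

    def test_template_length_mismatch(self):
        seq = parse_clip("x | C6:0 | L.d S.d* L.l V.d I.l")
        with pytest.raises(ValueError, match="length"):
            build_backbone(seq, canonical_template(7))


@pytest.fixture(scope="module")
def helix12():
    seq = parse_clip(
        "h12 | C6:0 | " + " ".join(
            "S.d*" if i == 9 else "L.d" for i in range(1, 13)))
    return seq, build_backbone(seq, canonical_template(12))


class TestCanonicalHelix:

    def test_rise_per_residue(self, helix12):
        _, s = helix12
        ax = helix_axis(s, (1, 12))
        ca = np.array([s.xyz(i, "CA") for i in range(1, 13)])
        rises = np.diff(ca @ ax.direction)
        assert rises.mean() == pytest.approx(1.5, abs=0.15)

    def test_residues_per_turn(self, helix12):
        _, s = helix12
        ax = helix_axis(s, (1, 12))
        ca = np.array([s.xyz(i, "CA") for i in range(1, 13)])
        rel = ca - ax.point
        perp = rel - np.outer(rel @ ax.direction, ax.direction)
        perp /= np.linalg.norm(perp, axis=1)[:, None]
        twists = [np.degrees(np.arctan2(np.cross(perp[i], perp[i + 1])
                                        @ ax.direction,
                                        perp[i] @ perp[i + 1]))
                  for i in range(11)]
        assert 360.0 / abs(np.mean(twists)) == pytest.approx(3.6, abs=0.2)

    def test_all_interior_residues_left_handed(self, helix12):
        _, s = helix12
        assert set(handedness(s).values()) == {"alphaL"}

    def test_bond_lengths_ideal(self, helix12):
        _, s = helix12
        for i in range(1, 13):
            n, ca, c = (s.xyz(i, a) for a in ("N", "CA", "C"))
            assert np.linalg.norm(ca - n) == pytest.approx(B_N_CA, abs=0.05)
            assert np.linalg.norm(c - ca) == pytest.approx(B_CA_C, abs=0.05)
            if i < 12:
                assert np.linalg.norm(s.xyz(i + 1, "N") - c) == \
                    pytest.approx(B_C_N, abs=0.05)


class TestChirality:
    def test_improper_sign_by_configuration(self):
        seq = parse_clip("chi | C6:0 | L.l S.d* L.d L.l V.d")
        s = build_backbone(seq, canonical_template(5))
        for i in range(1, 6):
            imp = dihedral_angle(s.xyz(i, "N"), s.xyz(i, "CA"),
                                 s.xyz(i, "C"), s.xyz(i, "CB"))
            if seq.residue(i).config == "L":
                assert imp < 0
            else:
                assert imp > 0

    def test_mirror_flips_improper_signs(self):
        seq = parse_clip("chi | C6:0 | L.l S.d* L.d L.l V.d")
        s = build_backbone(seq, canonical_template(5))
        m = mirror(s)
        for i in range(1, 6):
            a = dihedral_angle(s.xyz(i, "N"), s.xyz(i, "CA"),
                               s.xyz(i, "C"), s.xyz(i, "CB"))
            b = dihedral_angle(m.xyz(i, "N"), m.xyz(i, "CA"),
                               m.xyz(i, "C"), m.xyz(i, "CB"))
            assert a == pytest.approx(-b, abs=1e-9)


class TestMirror:
    def test_involution(self, alpha_l_helix):
        twice = mirror(mirror(alpha_l_helix))
        assert np.allclose(twice.coords, alpha_l_helix.coords)

    def test_mirrored_helix_right_handed(self, alpha_l_helix):
        assert set(handedness(mirror(alpha_l_helix)).values()) == {"alphaR"}

    def test_dihedrals_negated(self, alpha_l_helix):
        orig = dihedrals(alpha_l_helix)
        mirr = dihedrals(mirror(alpha_l_helix))
        for i in orig:
            for a, b in zip(orig[i], mirr[i]):
                if a is None or abs(abs(a) - 180.0) < 1e-6:
                    continue
                assert a == pytest.approx(-b, abs=0.1)


class TestDepsiClosure:
    def test_built_model_closes(self, clips, orfamide_model):
        gap = closure_gap(orfamide_model, clips["orfamide A"].latch_pos)
        assert abs(gap) <= 0.1
        rep = check_closure(orfamide_model, clips["orfamide A"].latch_pos)
        assert rep.closed and rep.linked

    def test_linearized_variant_reports_open(self, clips, orfamide_model):
        linear = orfamide_model.with_links(())
        rep = check_closure(linear, clips["orfamide A"].latch_pos)
        assert not rep.closed and not rep.linked

    def test_ccd_restores_perturbed_loop(self, clips, orfamide_model):
        """A +20 degree psi kick on a loop residue reopens the ring; CCD on
        the loop alone restores closure."""
        seq = clips["orfamide A"]
        tors = dihedrals(orfamide_model)
        phi = [tors[i][0] for i in range(1, 11)]
        psi = [tors[i][1] for i in range(1, 11)]
        omega = [tors[i][2] or 180.0 for i in range(1, 11)]
        psi[7] += 20.0  # residue 8: inside the loop span (7..10)
        kicked = rebuild_with_dihedrals(
            orfamide_model,
            DihedralTemplate.from_arrays(phi, psi, omega))
        assert abs(closure_gap(kicked, seq.latch_pos)) > 0.1
        healed = close_depsi(kicked, seq.latch_pos, refine=True, tol=0.1)
        assert abs(closure_gap(healed, seq.latch_pos)) <= 0.1

    def test_helix_untouched_by_ccd(self, clips, orfamide_model):
        seq = clips["orfamide A"]
        healed = close_depsi(orfamide_model, seq.latch_pos, refine=True)
        sel = orfamide_model.select(names=("N", "CA", "C"), res_range=(1, 6))
        assert np.allclose(healed.coords[0, sel],
                           orfamide_model.coords[0, sel])

    def test_closure_failure_raises_with_gap(self):
        # an extended chain cannot reach back over one sweep of iterations
        seq = parse_clip("far | C6:0 | L.d S.d* L.d L.l V.d L.d L.l I.l")
        s = build_backbone(seq, DihedralTemplate.from_arrays(
            [180.0] * 8, [179.0] * 8))
        with pytest.raises(ClosureError) as err:
            close_depsi(s, seq.latch_pos, refine=True, tol=0.01, max_iter=3)
        assert err.value.gap is not None


class TestHomology:
    def test_orfamide_template_builds_xantholysin(self, clips,
                                                  orfamide_model):
        """Same m = 8 macrocycle: the model extends the helix by four
        N-terminal residues and keeps the macrocycle conformation."""
        xan = clips["xantholysin A"]
        built = homology_build(clips["orfamide A"], orfamide_model, xan)
        assert built.n_residues == 14
        assert abs(closure_gap(built, xan.latch_pos)) <= 0.1
        sel_t = orfamide_model.select(names=("N", "CA", "C"),
                                      res_range=(3, 10))
        sel_b = built.select(names=("N", "CA", "C"), res_range=(7, 14))
        from psclip.geometry import _kabsch
        *_, rmsd = _kabsch(orfamide_model.coords[0, sel_t],
                           built.coords[0, sel_b])
        assert rmsd < 1e-6

    def test_zero_extension_preserves_dihedrals(self, clips, orfamide_model):
        orf = clips["orfamide A"]
        rebuilt = homology_build(orf, orfamide_model, orf.relabel("copy"))
        a, b = dihedrals(orfamide_model), dihedrals(rebuilt)
        for i in range(2, 11):
            assert a[i][0] == pytest.approx(b[i][0], abs=0.1)
            assert a[i][1] == pytest.approx(b[i][1], abs=0.1)

    def test_refuses_different_macrocycle_size(self, clips, orfamide_model):
        with pytest.raises(HomologyError, match="size differs"):
            homology_build(clips["orfamide A"], orfamide_model,
                           clips["pentorfamide A"])

    def test_refuses_macrocycle_configuration_mismatch(self, clips,
                                                       orfamide_model):
        target = parse_clip(
            "flip | 3OH-C14:0 | L.l E.d aT.d* aI.d L.l S.d L.l L.l S.l V.l")
        with pytest.raises(HomologyError, match="configuration"):
            homology_build(clips["orfamide A"], orfamide_model, target)


class TestBuildClipModel:
    def test_helix_span_is_canonical(self, clips, orfamide_model):
        hand = handedness(orfamide_model)
        assert all(hand[i] == "alphaL" for i in range(1, 7))

    def test_latch_oxygen_present(self, clips, orfamide_model):
        assert orfamide_model.has_atom(3, "OG1")
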