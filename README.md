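# psclip

Structural classification and backbone modelling of *Pseudomonas* cyclic
lipodepsipeptides (CLiPs).

CLiPs are membrane-targeting specialized metabolites: an oligopeptide of
*l* residues, N-capped by a fatty-acyl chain and cyclized through an ester
("depsi") bond between the side-chain hydroxyl of an internal d-Ser or
d-*allo*-Thr (the *latch*) and the C-terminal carboxyl.  The *m* C-terminal
residues from the latch onward form the macrocycle, so each family carries
an (*l*:*m*) tag with latch position *l* − *m* + 1.  Being rich in
d-amino acids, CLiPs fold into a **left-handed α-helix (α_L)**, and the
macrocycle size alone dictates one of two conformational motifs:

* **stapled helix** (*m* > 5): the α_L-helix runs from residue 1 through
  latch + 3, i.e. four macrocycle residues are helical and the C-terminus
  is stapled onto the helix body, leaving *c* = *m* − 4 residues to close
  the loop;
* **catch-pole helix** (*m* ≤ 5): the helix terminates at the latch and the
  macrocycle forms a separate closed loop crowning the exocyclic helix.

Fully cyclic CLiPs (*l* = *m*, the Mycins) form a non-helical offshoot.
The motif is mirrored in the producers' NRPS gene clusters: genes A+B
encode the helix (the latch module opens gene B for stapled CLiPs and
closes it for catch-pole CLiPs), gene C the loop, and the condensation
domain of module *i* + 1 fixes the D/L configuration of residue *i*
(C/E → D, ^L^C_L → L).

The package is aimed at natural-product and structural-biology researchers
working on lipopeptide classification, homology modelling and
BGC-to-structure prediction.  It provides:

* a sequence model with a compact one-line notation, stereochemistry,
  hydrophobicity/charge profiles and latch-anchored pairwise comparison;
* the 17-family motif-tree registry with the (l:m) classification rule and
  branch census;
* an internal-coordinate backbone builder (NeRF) with D/L chirality,
  depsi-bond closure by cyclic coordinate descent, mirror-image and
  homology extension/truncation operations;
* a geometry suite: dihedrals, α_L/α_R handedness, hydrogen bonds, Kabsch
  superposition, NMR-style ensemble RMSD statistics, helix axis,
  macrocycle ellipsoid/bend angle and amphipathic-face segregation;
* NRPS architecture parsing and topology/stereochemistry prediction;
* NOE distance-restraint classification, summaries and violation checks;
* seeded synthetic generators for helices, CLiPs, ensembles and restraints.

## Worked example

```python
from psclip import (parse_clip, lm_tag, classify_motif, build_clip_model,
                    latch_anchored_align, load_reference_clips)
from psclip.geometry import detect_hbonds, handedness

clips = load_reference_clips()
orf = clips["orfamide A"]
print(lm_tag(orf))                       # (10, 8)
print(classify_motif(*lm_tag(orf)).motif)  # stapled_helix

rep = latch_anchored_align(orf, clips["xantholysin A"])
print(rep.window, rep.hclass_matches, rep.config_matches)  # 10 10 9

model = build_clip_model(orf)            # closed 3D backbone model
print(handedness(model)[4])              # alphaL
print(len(detect_hbonds(model)))         # 4 (the helical i,i+4 network)
```

The alignment line reproduces the family-level finding that orfamide and
xantholysin share a fully conserved amphipathicity profile (10/10) and all
but one configuration (9/10) over the C-terminal decapeptide, anchored at
their latch residues.

From the shell:

```sh
$ psclip census
{"families": 17, "stapled": 10, "catch_pole": 6, "offshoot": 1,
 "clusters": {"Acidilin": 10, "Peptin": 6, "Mycin": 1}}
$ psclip classify --tag 12:10
{"tag": "12:10", "motif": "stapled_helix", "helix_span": [1, 6],
 "loop_span": [7, 12], "loop_count": 6}
```

Ten of the seventeen known (l:m) families fall on the stapled-helix branch,
six on the catch-pole branch, and the Mycins are the single l = m offshoot.

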