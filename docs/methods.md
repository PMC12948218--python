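# Methods

This note records the models, conventions and numerical choices behind
psclip, what the synthetic generators emulate, and the known limits of
both.

## Sequence model and classification rule

A CLiP sequence is an ordered list of residues (1-based from the acylated
N-terminus), each carrying an identity code, a chirality (L/D/achiral) and
derived hydrophobicity and charge classes, plus an acyl descriptor and the
latch position.  The two-class hydrophobicity lookup is fixed: Leu, Ile,
aIle, Val, Ala, Phe, Pro and Dhb are hydrophobic; Ser, Thr, aThr, Gln, Glu,
Asp, Asn, Gly, Hse, Dab and Lys are hydrophilic.  Gly is assigned
hydrophilic because it carries no side chain and faces the solvent in
amphipathic helices.  Charges at physiological pH: Asp/Glu negative,
Lys/Dab positive, everything else neutral.  Latch residues must carry a
side-chain hydroxyl (Ser, Thr, aThr, Hse); the parser rejects anything
else.

The classification rule is purely arithmetic in (l, m): l = m is the fully
cyclic offshoot; m > 5 is the stapled helix with helix span
[1, latch + 3] and c = m − 4 loop residues; m ≤ 5 is the catch-pole with
helix span [1, latch].  The three outcomes partition the domain
4 ≤ m ≤ l, and the shipped 17-family registry reproduces the published
branch populations (10 stapled / 6 catch-pole / 1 offshoot).

The shipped reference sequences were transcribed from the textual
constraints of the source compounds' descriptions (latch identities,
positions of L-residues and acidic residues, the orfamide/xantholysin
conservation statistics, the pentorfamide/entolysin penultimate-residue
inversion) together with the original isolation literature.  Pairwise
comparison anchors both sequences at the latch and pairs positions by
offset, with no gaps — the field's block-wise alignment convention for
CLiPs.

## Backbone construction

Models are built in internal coordinates (natural extension reference
frame) with idealized geometry: N–CA 1.46 Å, CA–C 1.52 Å, C–N 1.33 Å,
C=O 1.23 Å, N–H 1.01 Å, CA–CB 1.53 Å, CB–OG 1.42 Å; angles N–CA–C 111°,
CA–C–N 116°, C–N–CA 122°; trans ω = 180° unless the template says
otherwise.  The canonical left-handed helix uses (φ, ψ) = (+57°, +47°),
the mirror image of the standard right-handed values; a built 12-mer
measures ≈1.55 Å rise and ≈3.6 residues per turn.  Chirality is realized
through the CB placement: the improper dihedral (N, CA, C, CB) is negative
for L residues and positive for D.  The acyl chain is represented only by
its carbonyl (C, O) capping the first amide nitrogen — the chain beyond C3
is experimentally unconstrained and conformationally ill-defined, so it is
excluded from every geometric statistic.  φ of residue 1 is defined
against this cap.

Coordinates are Å in a right-handed frame; the first residue's N sits at
the origin with its CA on +x.  Build/measure round trips reproduce
templates to ≈1e-13 degrees; the 0.1° tolerance asserted in tests is very
conservative.

## Depsi-bond closure

Closure adds an ester link (latch Oγ → C-terminal carbonyl C, ideal length
1.33 Å) and reports the signed gap (current O–C distance minus 1.33 Å).
Refinement is cyclic coordinate descent: sweeping the loop residues N→C,
each φ/ψ bond is rotated by the closed-form angle that brings the
C-terminal carbon onto the ideal-ester sphere around the latch oxygen
(two symmetric solutions exist; the smaller rotation is taken, which keeps
the refinement deterministic).  Defaults: tolerance 0.1 Å, 500 sweeps.
The latch oxygen and everything N-terminal of the loop stay fixed.

De novo model building seeds the loop from a small deterministic conformer
set — (φ, ψ) ∈ {(−60, −30), (−80, 80), (70, 40), (−140, 140),
(60, −120)} — crossed with latch χ1 rotamers {180°, 60°, −60°}, and takes
the first combination that closes.  For stapled macrocycles with short
loops the ring is geometrically unreachable from a rigid ideal helix (for
m = 6 the best loop-only gap is ≈0.9 Å); in that case the refinement span
is widened by the last two helical residues.  This mirrors the physical
situation: in the solved structures the helix-terminating amide plane
deviates from helicity when the macrocycle is short, and the φ/ψ values of
the two residues preceding the loop absorb the closure strain.  The
geometric motif detector (initial α_L run extending past the latch versus
terminating at it) is insensitive to this relaxation.

Homology building for a target with the same m and identical macrocycle
configuration copies the macrocycle dihedrals from the template and
extends or truncates the helix at the N-terminus with canonical α_L
residues; targets with a different macrocycle stereochemistry are refused
rather than modelled, because same-m macrocycles with inverted
configurations are known to adopt alternative backbone conformations.

## Geometry measurements

* **Handedness**: per-residue window of ±40° around (+57, +47) for α_L and
  around (−57, −47) for α_R; everything else is "other".  The window is
  wide enough to absorb the ≈10–20° deviations seen at strained positions
  while cleanly excluding loop conformations.
* **Hydrogen bonds**: geometric criterion — O···N < 3.5 Å, C=O···N angle
  > 90°, and N–H···O angle > 120° when the amide H is present (it is
  placed at 1.01 Å in the peptide plane, anti to the carbonyl O).  The
  acyl cap is a valid acceptor (residue index 0), which is how the
  N-terminal i,i+4 bond of the helix is counted.
* **Superposition**: Kabsch SVD with proper-rotation correction; ensemble
  statistics align every model to the first (lowest-energy) model over the
  backbone N/CA/C/O selection (acyl excluded), average the aligned
  coordinates, and report mean ± sd (ddof = 1) of per-model RMSDs to that
  mean.
* **Helix axis**: total least squares through the 4-residue sliding-window
  average of the CA trace (one-turn averaging cancels the helical wobble;
  the residual of an ideal helix is ≈0.24 Å, and 1.0 Å is the acceptance
  bound for "helical").  The axis is oriented N→C.
* **Macrocycle bend**: principal axes (second central moment) of the ring
  backbone N/CA/C atoms; side-chain atoms, including the latch Oγ, are
  excluded.  Semi-axis lengths are RMS extents.  The long axis is oriented
  from the helix-proximal ring edge (the latch CA) toward the ring
  centroid, which makes the bend angle against the helix axis
  single-valued in [0, 180°] and reproduces the catch-pole dichotomy
  (entolysin-like rings lean back over the helix, putisolvin-like rings
  point away).
* **Amphipathic segregation**: CA→CB directions projected onto the plane
  perpendicular to the helix axis; weights +1 (hydrophobic) / −1
  (hydrophilic) are mean-centered and the score is the magnitude of the
  weighted vector sum normalized by the sum of absolute centered weights.
  A uniform sequence scores exactly 0; tightly segregated short spans
  (e.g. the viscosin hexapeptide core) score > 0.7.  Because residues sit
  at discrete 100° wheel positions, perfectly alternating full-length
  patterns plateau near 0.65 — the score rewards face purity, not pattern
  periodicity.

All scalar measurements are rigid-motion invariant and all directional
outputs equivariant; both properties are tested.

## NRPS prediction

Topology: l is the module count; the latch module is either flagged or
inferred as the hydroxyl-loading module at the gene B boundary (first
module of B preferred — the stapled reading — else last); m and the motif
follow arithmetically, and helix length is |A| + |B|.  The inverse
bookkeeping (architecture from an (l:m) tag) places the latch module per
motif and yields the helix-encoding module counts used for the gacamide
(7) and asplenin (9) predictions.  Stereochemistry: residue i is D when
module i+1 carries a C/E domain and L when it carries ^L^C_L; every
C/E-derived D call is flagged as potentially L (epimerization-inactive C/E
domains exist and cannot be identified from the architecture — the
predictor deliberately does not guess).  The C-terminal residue has no
downstream condensation domain and is reported unknown.

## Restraint statistics

Categories by residue separation: 0 intraresidual, 1 sequential, 2–4
mid-range, ≥5 long-range; anything touching acyl atoms is kept apart and
excluded from peptide statistics.  In the shipped per-CLiP count table the
per-category rows exclude ambiguous restraints and the totals are
categorized + ambiguous; this convention reproduces every printed total
arithmetically, which is how the ambiguity bookkeeping question was
resolved.  Violation analysis uses r⁻⁶-summed effective distances for
ambiguous OR-groups and reports positive excesses over the upper bound
beyond the chosen threshold (default 0.5 Å); unresolvable atoms are
reported, not fatal.  Pseudo-atom corrections are assumed already applied
in input files.

## Synthetic generators

All generators are pure functions of (parameters, seed) via a local
`numpy` Generator.  `gen_helix` applies i.i.d. Gaussian noise to φ/ψ only
(ω stays planar, matching the rigid-peptide-plane assumption).
`gen_clip_sequence` emulates the Acidilin blueprint: acylated position 1,
acidic d-residue at position 2, d-Ser latch at l − m + 1, D-dominant helix
with L-Leu substitutions at probability 0.25 per position (the approximate
frequency in the reference set), hydrophilic spacing every ~4 residues,
mixed-configuration loop.  `gen_ensemble` perturbs dihedrals and re-closes
the ring per model (a model that fails to re-close after several draws is
kept unclosed rather than aborting the ensemble).  `gen_restraints` bounds
every backbone amide-proton pair within the cutoff at distance + slack, so
the source structure never violates its own restraints by construction.

What the generators do *not* emulate: side chains beyond CB, solvent or
micelle context, NOE intensity statistics, spin diffusion, or the
energetics that select real loop conformations.  Passing the synthetic
end-to-end checks therefore demonstrates the internal consistency of the
classification/building/measurement stack, not agreement of de novo loop
conformations with experimental ones — de novo loops close the ring but
their dihedrals (and hence synthetic bend angles) are not predictions of
the deposited values.  Quantitative geometry against experiment is
exercised by running the measurement operations on deposited multi-model
ensembles, which this package reads but does not ship.

## Problem sizes and determinism

The test suite and acceptance script run entirely on in-package data and
generated fixtures: the 17-family registry, the nine reference sequences,
the published restraint count table, and generated models over the full
(l, m) grid l ∈ 8..14, m ∈ 4..10 (46 closed builds, seconds in total).
Ensembles in tests use 4–10 models, matching the deposited ensemble size.
Every stochastic step takes an explicit integer seed; reruns are
bit-identical.

## Known limitations

* De novo loop conformations are geometric solutions, not energetic ones;
  no force field, sterics or rotamer library is applied beyond CB and the
  latch oxygen.
* The helix-axis fit needs ≥5 residues and degrades gracefully but
  measurably under dihedral noise (a 5° σ kick tilts the fitted axis of a
  12-mer by ~10° on average, since backbone noise accumulates along the
  chain).
* The PDB reader maps residue names through a fixed dictionary; D-residues
  use standard PDB component codes where they exist, package-defined codes
  otherwise, and unknown names degrade to generic residues with a warning.
* NRPS input is a minimal module table; no genome scanning, adenylation
  specificity prediction or antiSMASH integration.
* Peptin-length helices (l up to 25) are classified and buildable, but the
  registry's clade annotations are informational only.
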