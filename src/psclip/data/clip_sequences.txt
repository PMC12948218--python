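# Reference CLiP sequences, one notation line per compound:
#   name | acyl | residue tokens (<code>.<cfg>, '*' marks the latch)
# cfg: l = L, d = D, x = achiral.  Positions are 1-based from the acylated
# N-terminus.  The eight natural compounds are the structurally characterized
# family representatives; pentorfamide A is the synthetic orfamide A analogue
# with the macrocycle closed at d-Ser6 instead of d-allo-Thr3.
MDN-0066 | 3OH-C10:0 | L.d D.d aT.d* L.d L.l S.d L.l I.l
viscosin | 3OH-C10:0 | L.l E.d aT.d* V.d L.l S.d L.l S.d I.l
orfamide A | 3OH-C14:0 | L.l E.d aT.d* aI.d L.l S.d L.l L.l S.d V.l
arthrofactin A | 3OH-C10:0 | L.d D.d aT.d* L.d L.d S.d L.l S.d I.l I.l D.l
tanniamide A | 3OH-C14:0 | L.d E.d aT.d* L.d L.l S.d L.l S.d I.l L.l V.d D.l
putisolvin I | C6:0 | L.l E.d Q.d L.l I.d Q.d V.d I.d S.d* L.l S.l V.l
entolysin A | 3OH-C10:0 | L.l E.d Q.d V.d L.d Q.d V.d L.d Q.d S.d* V.d L.l S.l I.l
xantholysin A | 3OH-C12:1 | L.l E.d Q.d V.d L.l Q.l S.d* V.d L.l Q.d L.l L.l Q.d I.l
pentorfamide A | 3OH-C14:0 | L.l E.d aT.d aI.d L.l S.d* L.l L.l S.d V.l
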