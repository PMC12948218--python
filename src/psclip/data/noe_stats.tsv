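# NOE restraint and ensemble statistics for the structurally characterized
# CLiPs (per-category counts exclude ambiguous restraints; total =
# categorized + ambiguous; acyl-chain restraints were never counted).
# rmsd columns: ensemble backbone RMSD statistic (mean [s.d.]) in Angstrom.
clip	l	m	intraresidual	sequential	mid_range	long_range	total	ambiguous	rmsd_backbone	rmsd_backbone_sd
MDN-0066	8	6	48	33	14	5	111	11	0.10	0.02
viscosin	9	7	45	32	22	4	109	6	0.13	0.05
orfamide A	10	8	40	33	16	2	115	24	0.39	0.04
arthrofactin A	11	9	53	53	32	4	156	14	0.25	0.12
tanniamide A	12	10	73	63	57	3	203	7	0.39	0.06
putisolvin I	12	4	42	34	20	2	132	34	0.30	0.08
entolysin A	14	5	72	57	32	0	201	40	0.34	0.08
xantholysin A	14	8	94	74	70	3	310	69	0.25	0.13
pentorfamide A	10	5	55	23	16	0	103	9	0.54	0.27
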