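# The 17 Pseudomonas CLiP (l:m) families of the motif tree.
# cluster: Acidilin (acidic), Peptin (basic), Mycin (mixed, l = m).
# clades: producer phylogenetic clades, F = Fluorescens, P = Putida,
# S = Syringae (comma-separated).
family	l	m	cluster	clades
Bananamide	8	6	Acidilin	F
Viscosin	9	7	Acidilin	F,P
Orfamide	10	8	Acidilin	F
Amphisin	11	9	Acidilin	F
Tanniamide	12	10	Acidilin	F
Putisolvin	12	4	Acidilin	P
Entolysin	14	5	Acidilin	P
Xantholysin	14	8	Acidilin	P
Gacamide	11	5	Acidilin	F
Asplenin	13	8	Acidilin	P
Tolaasin	18	5	Peptin	F,S
Fuscopeptin	19	5	Peptin	S
Corpeptin	22	5	Peptin	S
Brassicapeptin	22	6	Peptin	S
Syringopeptin-22	22	8	Peptin	S
Syringopeptin-25	25	8	Peptin	S
Syringomycin	9	9	Mycin	S
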