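"""Prediction of CLiP topology and stereochemistry from NRPS/BGC module
architecture.

Acidilin biosynthetic gene clusters comprise three genes A, B and C encoding
multimodular non-ribosomal peptide synthetases; each module extends the
oligopeptide by one residue.  Gene A is always di-modular (the acylated Leu1
plus the acidic residue 2).  The condensation-domain type of module ``i+1``
fixes the configuration of residue ``i``: a dual condensation/epimerization
(C/E) domain epimerizes the preceding residue to D (unless its epimerization
activity is lost, which is how occasional L-Leu residues enter the helix),
whereas an LCL domain leaves it L.  LCL domains occur only in gene C, so the
helix (genes A+B) is predicted all-D, and L-residues in the macrocycle loop
are always LCL-incorporated.

The module that loads the latch residue sits at the gene B boundary: first
module of B for stapled-helix CLiPs (B then completes the helix), final
module of B for catch-pole CLiPs (gene C alone then provides the loop).
Genes A+B together therefore encode the alphaL-helix, of length
``latch_pos + 3`` (stapled) or ``latch_pos`` (catch-pole).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .classify import CATCH_POLE, STAPLED, classify_motif
from .sequence import ClipSequence, HYDROXYL_CODES

__all__ = [
    "NrpsModule",
    "BgcArchitecture",
    "TopologyPrediction",
    "StereoPrediction",
    "predict_stereochemistry",
    "predict_topology",
    "architecture_from_tag",
    "architecture_from_sequence",
    "reference_architectures",
    "parse_module_table",
]

C_START = "C_start"
C_E = "C/E"
LCL = "LCL"
_CDOMAINS = (C_START, C_E, LCL)


@dataclass(frozen=True)
class NrpsModule:
    """One NRPS extension module: condensation-domain type plus (optionally)
    its adenylation-domain substrate."""

    cdomain: str
    substrate: str | None = None
    is_latch: bool = False

    def __post_init__(self):
        if self.cdomain not in _CDOMAINS:
            raise ValueError(f"unknown condensation domain {self.cdomain!r}")


@dataclass(frozen=True)
class BgcArchitecture:
    """Ordered NRPS genes (A, B, C) of one biosynthetic gene cluster."""

    gene_a: tuple[NrpsModule, ...]
    gene_b: tuple[NrpsModule, ...]
    gene_c: tuple[NrpsModule, ...]
    split_locus: bool = False  # recorded only; no effect on prediction
    name: str = ""

    def __post_init__(self):
        mods = self.modules
        starts = [i for i, m in enumerate(mods) if m.cdomain == C_START]
        if starts != [0]:
            raise ValueError(
                "exactly one C_start domain is allowed, as module 1 of "
                "gene A")

    @property
    def modules(self) -> tuple[NrpsModule, ...]:
        return self.gene_a + self.gene_b + self.gene_c

    @property
    def sizes(self) -> tuple[int, int, int]:
        return len(self.gene_a), len(self.gene_b), len(self.gene_c)

    @property
    def l(self) -> int:  # noqa: E743
        return len(self.modules)


@dataclass(frozen=True)
class StereoPrediction:
    """Per-position D/L call with provenance flags.

    ``configs[i]`` is 'D', 'L' or 'unknown' for 1-based position i;
    ``may_be_l`` lists D-called positions that would be L if the C/E domain
    of the following module lacks epimerization activity (the predictor
    cannot tell which); ``warnings`` collects architecture anomalies.
    """

    configs: tuple[str, ...]
    may_be_l: tuple[int, ...]
    warnings: tuple[str, ...]


def predict_stereochemistry(bgc: BgcArchitecture) -> StereoPrediction:
    """Predict the D/L configuration of each residue from condensation-domain
    types.  The configuration of the C-terminal residue is not encoded by any
    condensation domain (the thioesterase gives no rule) and is reported as
    'unknown'."""
    mods = bgc.modules
    warnings = []
    n_ab = len(bgc.gene_a) + len(bgc.gene_b)
    for j, mod in enumerate(mods, start=1):
        if mod.cdomain == LCL and j <= n_ab:
            warnings.append(
                f"LCL domain at module {j} inside gene "
                f"{'A' if j <= len(bgc.gene_a) else 'B'}; LCL domains are "
                "expected only in gene C")
    configs = []
    may_be_l = []
    for i in range(1, bgc.l + 1):
        if i == bgc.l:
            configs.append("unknown")
            continue
        nxt = mods[i]  # module i+1, 0-based
        if nxt.cdomain == C_E:
            configs.append("D")
            may_be_l.append(i)
        elif nxt.cdomain == LCL:
            configs.append("L")
        else:
            configs.append("unknown")
    return StereoPrediction(configs=tuple(configs),
                            may_be_l=tuple(may_be_l),
                            warnings=tuple(warnings))


@dataclass(frozen=True)
class TopologyPrediction:
    l: int  # noqa: E741
    m: int
    latch_pos: int
    motif: str
    helix_len: int


def _find_latch(bgc: BgcArchitecture) -> int:
    """1-based overall position of the latch module.

    Honors an explicit ``is_latch`` flag; otherwise infers it from the
    hydroxyl-bearing substrate (Ser/Thr) at the gene B boundary: the first
    module of B if hydroxyl-loaded (stapled-helix reading), else the last
    module of B (catch-pole reading).
    """
    mods = bgc.modules
    flagged = [i for i, m in enumerate(mods, start=1) if m.is_latch]
    if len(flagged) > 1:
        raise ValueError(f"multiple latch modules flagged: {flagged}")
    if flagged:
        return flagged[0]

    def hydroxyl(mod: NrpsModule) -> bool:
        return mod.substrate in HYDROXYL_CODES

    first_b = len(bgc.gene_a) + 1
    last_b = len(bgc.gene_a) + len(bgc.gene_b)
    if bgc.gene_b and hydroxyl(bgc.gene_b[0]):
        return first_b
    if bgc.gene_b and hydroxyl(bgc.gene_b[-1]):
        return last_b
    raise ValueError(
        "no latch: no module flagged and no Ser/Thr substrate at the gene B "
        "boundary")


def predict_topology(bgc: BgcArchitecture) -> TopologyPrediction:
    """Predict (l, m, latch position, motif, helix length) from the module
    architecture.  Genes A+B jointly encode the alphaL-helix."""
    l = bgc.l  # noqa: E741
    latch_pos = _find_latch(bgc)
    m = l - latch_pos + 1
    motif = classify_motif(l, m).motif
    helix_len = len(bgc.gene_a) + len(bgc.gene_b)
    return TopologyPrediction(l=l, m=m, latch_pos=latch_pos, motif=motif,
                              helix_len=helix_len)


def architecture_from_tag(l: int, m: int, name: str = "") -> BgcArchitecture:  # noqa: E741
    """Inverse bookkeeping: the minimal Acidilin-style architecture implied
    by an (l:m) tag under the latch-module placement rules.

    Gene A is di-modular; for a stapled-helix tag the latch module is the
    first module of gene B and B runs through the helix end (latch + 3);
    for a catch-pole tag the latch module is the last module of gene B.
    Gene C provides the remaining (loop) modules.
    """
    motif = classify_motif(l, m).motif
    latch_pos = l - m + 1
    helix_len = latch_pos + 3 if motif == STAPLED else latch_pos
    if motif not in (STAPLED, CATCH_POLE):
        raise ValueError("fully cyclic (l = m) CLiPs have no Acidilin-style "
                         "A/B/C architecture")
    if helix_len < 3:
        raise ValueError(f"tag ({l}:{m}) leaves no room for gene B")
    n_b = helix_len - 2
    n_c = l - helix_len
    mods = []
    for j in range(1, l + 1):
        cdomain = C_START if j == 1 else C_E
        substrate = "Ser" if j == latch_pos else None
        mods.append(NrpsModule(cdomain=cdomain, substrate=substrate,
                               is_latch=j == latch_pos))
    return BgcArchitecture(
        gene_a=tuple(mods[:2]),
        gene_b=tuple(mods[2:2 + n_b]),
        gene_c=tuple(mods[2 + n_b:]),
        name=name or f"({l}:{m})")


def architecture_from_sequence(seq: ClipSequence) -> BgcArchitecture:
    """Architecture consistent with an annotated sequence: module substrates
    from residue identities, LCL domains for loop L-residues (helix
    L-residues arise from epimerization-inactive C/E domains and remain
    C/E)."""
    assign = classify_motif(seq.l, seq.m)
    helix_end = assign.helix_span[1] if assign.helix_span else seq.l
    mods = []
    for j in range(1, seq.l + 1):
        if j == 1:
            cdomain = C_START
        else:
            prev = seq.residue(j - 1)
            in_loop = j - 1 > helix_end
            cdomain = LCL if (in_loop and prev.config == "L") else C_E
        res = seq.residue(j)
        mods.append(NrpsModule(cdomain=cdomain, substrate=res.code,
                               is_latch=res.is_latch))
    n_b = helix_end - 2
    return BgcArchitecture(
        gene_a=tuple(mods[:2]),
        gene_b=tuple(mods[2:2 + n_b]),
        gene_c=tuple(mods[2 + n_b:]),
        name=seq.name)


def reference_architectures() -> dict[str, BgcArchitecture]:
    """Module architectures of the eight structurally characterized Acidilin
    producers, derived from their annotated sequences (gene A di-modular;
    core-set gene B tetramodular; split-locus gene A noted for orfamide-
    family poaeamides only, which does not affect prediction)."""
    from .sequence import load_reference_clips
    out = {}
    for name, seq in load_reference_clips().items():
        if name == "pentorfamide A":
            continue  # synthetic; no producer BGC
        out[name] = architecture_from_sequence(seq)
    return out


def parse_module_table(lines) -> BgcArchitecture:
    """Parse a minimal module table, one line per module:
    ``gene,index,cdomain,substrate[,latch]`` with gene in {A, B, C}."""
    genes = {"A": [], "B": [], "C": []}
    for line in lines:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = [p.strip() for p in line.split(",")]
        if len(parts) < 3:
            raise ValueError(f"malformed module line: {line!r}")
        gene, _idx, cdomain = parts[0].upper(), parts[1], parts[2]
        substrate = parts[3] if len(parts) > 3 and parts[3] else None
        is_latch = len(parts) > 4 and parts[4].lower() in ("latch", "1",
                                                           "true")
        if gene not in genes:
            raise ValueError(f"unknown gene {gene!r}")
        genes[gene].append(NrpsModule(cdomain=cdomain, substrate=substrate,
                                      is_latch=is_latch))
    return BgcArchitecture(gene_a=tuple(genes["A"]),
                           gene_b=tuple(genes["B"]),
                           gene_c=tuple(genes["C"]))
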