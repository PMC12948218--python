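"""PDB reading and writing for CLiP models and ensembles.

Multi-model PDB is the primary format (the deposits are small peptides and
the depsi ester needs LINK semantics).  D-residues map to their standard
PDB component codes where these exist (DLE, DSN, DTH, ...); the remaining
nonproteinogenic residues use package-defined three-letter codes shipped in
the dictionary below.  Writing is done with an explicit fixed-column
emitter so that MODEL/ENDMDL pairing, LINK records and HETATM usage are
fully controlled; reading goes through gemmi.
"""

from __future__ import annotations

import warnings

import gemmi
import numpy as np

from .structure import Atom, Link, Structure

__all__ = ["read_structure", "write_structure", "RESNAME_TABLE"]

# (code, config) -> PDB residue name.  Package-defined codes (no standard
# PDB chemical component) are marked with a trailing comment.
RESNAME_TABLE: dict[tuple[str, str], str] = {
    ("Leu", "L"): "LEU", ("Leu", "D"): "DLE",
    ("Ile", "L"): "ILE", ("Ile", "D"): "DIL",
    ("aIle", "L"): "IIL", ("aIle", "D"): "DAI",   # DAI package-defined
    ("Val", "L"): "VAL", ("Val", "D"): "DVA",
    ("Ala", "L"): "ALA", ("Ala", "D"): "DAL",
    ("Phe", "L"): "PHE", ("Phe", "D"): "DPN",
    ("Pro", "L"): "PRO", ("Pro", "D"): "DPR",
    ("Gly", "achiral"): "GLY",
    ("Ser", "L"): "SER", ("Ser", "D"): "DSN",
    ("Thr", "L"): "THR", ("Thr", "D"): "DTH",
    ("aThr", "L"): "ALO", ("aThr", "D"): "DAO",   # DAO package-defined
    ("Gln", "L"): "GLN", ("Gln", "D"): "DGN",
    ("Glu", "L"): "GLU", ("Glu", "D"): "DGL",
    ("Asp", "L"): "ASP", ("Asp", "D"): "DAS",
    ("Asn", "L"): "ASN", ("Asn", "D"): "DSG",
    ("Lys", "L"): "LYS", ("Lys", "D"): "DLY",
    ("Hse", "L"): "HSE", ("Hse", "D"): "DHS",     # DHS package-defined
    ("Dab", "L"): "DAB", ("Dab", "D"): "DDB",     # DDB package-defined
    ("Dhb", "achiral"): "DBU",
}
_CODE_OF_RESNAME = {v: k for k, v in RESNAME_TABLE.items()}
_STANDARD_AA = {"LEU", "ILE", "VAL", "ALA", "PHE", "PRO", "GLY", "SER",
                "THR", "GLN", "GLU", "ASP", "ASN", "LYS"}
ACYL_RESNAME = "ACY"


def _resname_for(atom: Atom, config: str | None) -> str:
    if atom.res_index == 0:
        return ACYL_RESNAME
    key = (atom.res_code, config or "L")
    if atom.res_code in ("Gly", "Dhb"):
        key = (atom.res_code, "achiral")
    return RESNAME_TABLE.get(key, atom.res_code.upper()[:3].ljust(3))


def _infer_configs(s: Structure) -> dict[int, str]:
    """CB-improper chirality per residue, so written residue names carry
    the D/L information."""
    from .structure import dihedral_angle
    out = {}
    for i in range(1, s.n_residues + 1):
        if s.has_atom(i, "CB"):
            try:
                imp = dihedral_angle(s.xyz(i, "N"), s.xyz(i, "CA"),
                                     s.xyz(i, "C"), s.xyz(i, "CB"))
                out[i] = "L" if imp < 0 else "D"
            except KeyError:
                out[i] = "L"
        else:
            out[i] = "achiral"
    return out


def _format_atom_name(name: str) -> str:
    # column 13 stays blank for single-letter element names shorter than 4
    return f" {name:<3}" if len(name) < 4 else name[:4]


def write_structure(s: Structure, path, configs: dict[int, str] | None = None
                    ) -> None:
    """Write a (multi-model) PDB file with LINK records for ester links.

    ``configs`` optionally maps residue index to 'L'/'D'/'achiral'; by
    default chirality is inferred from the CB improper dihedral.
    """
    configs = configs if configs is not None else _infer_configs(s)
    resnames = {}
    for a in s.atoms:
        resnames[a.res_index] = _resname_for(a, configs.get(a.res_index))
    lines = []
    for lk in s.links:
        lines.append(
            "LINK        "
            f"{_format_atom_name(lk.atom_a)} {resnames[lk.res_a]:>3} "
            f"A{lk.res_a:>4}{'':16}"
            f"{_format_atom_name(lk.atom_b)} {resnames[lk.res_b]:>3} "
            f"A{lk.res_b:>4}")
    multi = s.n_models > 1
    for model in range(s.n_models):
        if multi:
            lines.append(f"MODEL     {model + 1:>4}")
        serial = 1
        for idx, a in enumerate(s.atoms):
            resname = resnames[a.res_index]
            hetatm = a.res_index == 0 or resname not in _STANDARD_AA
            record = "HETATM" if hetatm else "ATOM  "
            x, y, z = s.coords[model, idx]
            lines.append(
                f"{record}{serial:>5} {_format_atom_name(a.name)} "
                f"{resname:>3} A{a.res_index:>4}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {a.element:>2}")
            serial += 1
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_structure(path) -> Structure:
    """Read a single- or multi-model PDB file into a :class:`Structure`.

    Residue names are mapped back through the shipped dictionary; unknown
    names trigger a warning and keep the raw name.  LINK records become
    ester links.  All models must share the atom table.
    """
    st = gemmi.read_pdb(str(path))
    if len(st) == 0:
        raise ValueError(f"no models in {path}")
    atoms: list[Atom] = []
    model_coords = []
    ref_key: list[tuple[int, str]] | None = None
    for model in st:
        key = []
        coords = []
        cur_atoms: list[Atom] = []
        for chain in model:
            for res in chain:
                num = res.seqid.num
                if res.name == ACYL_RESNAME:
                    code = "ACY"
                elif res.name in _CODE_OF_RESNAME:
                    code = _CODE_OF_RESNAME[res.name][0]
                else:
                    warnings.warn(f"unknown residue name {res.name!r}; "
                                  "keeping as generic residue")
                    code = res.name
                for at in res:
                    key.append((num, at.name))
                    cur_atoms.append(Atom(
                        res_index=num, res_code=code, name=at.name,
                        element=(at.element.name or at.name[0]).upper()))
                    coords.append([at.pos.x, at.pos.y, at.pos.z])
        if ref_key is None:
            ref_key = key
            atoms = cur_atoms
        elif key != ref_key:
            raise ValueError(
                f"{path}: models do not share an identical atom table")
        model_coords.append(np.asarray(coords))
    links = []
    for con in st.connections:
        links.append(Link(
            res_a=con.partner1.res_id.seqid.num,
            atom_a=con.partner1.atom_name,
            res_b=con.partner2.res_id.seqid.num,
            atom_b=con.partner2.atom_name,
            kind="ester" if con.type == gemmi.ConnectionType.Covale
            or con.type == gemmi.ConnectionType.Unknown else "other"))
    return Structure(atoms=tuple(atoms), coords=np.stack(model_coords),
                     links=tuple(links))
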