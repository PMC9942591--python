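"""Mapping conservation grades onto 3-D structures.

Parses PDB or mmCIF files (via gemmi), extracts per-chain polymer sequences
including HETATM-flagged modified residues (MSE, SEP, PTR, ...), aligns the
query sequence onto a chain, writes the grades into the temperature-factor
column of a copy of the structure, propagates grades across byte-identical
chains of homo-oligomers, and emits PyMOL/ChimeraX coloring scripts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import gemmi
from Bio import Align
from Bio.Align import substitution_matrices

from .errors import (
    EmptyStructureError,
    MappingError,
    ParseError,
    UnknownChainError,
)
from .grading import COLORS_COLOR_BLIND, COLORS_STANDARD, N_GRADES

import warnings

# one-letter codes for common modified / non-standard polymer residues,
# applied before gemmi's tabulated lookup; editable by callers
MODIFIED_RESIDUES: dict[str, str] = {
    "MSE": "M",  # selenomethionine
    "SEC": "C",  # selenocysteine (closest standard: Cys)
    "PYL": "K",  # pyrrolysine
    "SEP": "S",  # phosphoserine
    "TPO": "T",  # phosphothreonine
    "PTR": "Y",  # phosphotyrosine
    "PCA": "Q",  # pyroglutamate
    "HYP": "P",  # hydroxyproline
    "KCX": "K",  # carboxylysine
    "LLP": "K",  # lysine-PLP adduct
    "MLY": "K",  # dimethyllysine
    "M3L": "K",  # trimethyllysine
    "ALY": "K",  # acetyllysine
    "CSO": "C",  # S-hydroxycysteine
    "CSD": "C",  # S-cysteinesulfinic acid
    "CME": "C",  # S,S-(2-hydroxyethyl)thiocysteine
    "CSX": "C",  # S-oxy cysteine
    "OCS": "C",  # cysteine sulfonic acid
    "SMC": "C",  # S-methylcysteine
    "SCY": "C",  # S-acetylcysteine
    "MHO": "M",  # S-oxymethionine
    "FME": "M",  # N-formylmethionine
    "NLE": "L",  # norleucine
    "AIB": "A",  # aminoisobutyric acid
    "DAL": "A",  # D-alanine
    "DSN": "S",  # D-serine
    "MVA": "V",  # N-methylvaline
    "SAR": "G",  # sarcosine
    "ABA": "A",  # aminobutyric acid
    "ORN": "K",  # ornithine
    "CGU": "E",  # gamma-carboxyglutamate
    "TYS": "Y",  # sulfotyrosine
    "NEP": "H",  # N1-phosphohistidine
    "HIC": "H",  # 4-methylhistidine
    "MLZ": "K",  # N-methyllysine
    "5MC": "C",  # 5-methylcytidine
    "PSU": "U",  # pseudouridine
    "1MA": "A",  # 1-methyladenosine
    "7MG": "G",  # 7-methylguanosine
    "5MU": "T",  # 5-methyluridine
    "UNK": "X",
    "N": "X",
}

WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


@dataclass(frozen=True)
class AtomRecord:
    name: str
    xyz: tuple[float, float, float]
    occupancy: float
    b_factor: float


@dataclass(frozen=True)
class ResidueEntry:
    chain_id: str
    res_seq: int
    icode: str
    name3: str
    record_kind: Literal["ATOM", "HETATM"]
    one_letter: str
    atoms: tuple[AtomRecord, ...]

    @property
    def key(self) -> tuple[int, str]:
        return (self.res_seq, self.icode)


@dataclass
class StructureModel:
    chains: dict[str, list[ResidueEntry]]
    source_format: Literal["pdb", "mmcif"]
    _gemmi: gemmi.Structure = field(repr=False, default=None)

    @property
    def chain_ids(self) -> list[str]:
        return list(self.chains.keys())


@dataclass
class ChainGradeMap:
    """Per-residue grade assignment for one chain (None = unmapped)."""

    chain_id: str
    grades: dict[tuple[int, str], int]
    identity_to_query: float


def one_letter_code(name3: str) -> str:
    """Map a residue name to a one-letter code: shipped modified-residue
    table first, then the tabulated standard code, else 'X'."""
    name = name3.strip().upper()
    if name in MODIFIED_RESIDUES:
        return MODIFIED_RESIDUES[name]
    info = gemmi.find_tabulated_residue(name)
    if info is not None:
        code = info.one_letter_code.upper()
        if code.strip() and code != " ":
            return "U" if code == "U" and info.is_nucleic_acid() else code
    return "X"


def _is_polymer_residue(name3: str) -> bool:
    name = name3.strip().upper()
    if name in WATER_NAMES:
        return False
    if name in MODIFIED_RESIDUES:
        return True
    info = gemmi.find_tabulated_residue(name)
    if info is None:
        return False
    return info.is_amino_acid() or info.is_nucleic_acid()


def _detect_format(path: Path) -> Literal["pdb", "mmcif"]:
    suffix = path.suffix.lower()
    if suffix in (".cif", ".mmcif"):
        return "mmcif"
    if suffix in (".pdb", ".ent"):
        return "pdb"
    head = path.read_text(errors="replace")[:4096]
    if head.lstrip().startswith("data_") or "_atom_site." in head:
        return "mmcif"
    return "pdb"


def _best_altloc_atoms(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Collapse alternate locations: keep the highest-occupancy copy of each
    atom name (first wins on ties)."""
    best: dict[str, gemmi.Atom] = {}
    for atom in residue:
        prev = best.get(atom.name)
        if prev is None or atom.occ > prev.occ:
            best[atom.name] = atom
    return list(best.values())


def parse_structure(
    path: str | Path, format: Literal["auto", "pdb", "mmcif"] = "auto"
) -> StructureModel:
    """Parse a PDB or mmCIF file into a StructureModel.

    Only the first model is used. Waters and non-polymer HETATM groups
    (ligands, ions) are excluded from chain sequences but are retained in
    the underlying structure for write-through.
    """
    path = Path(path)
    fmt = _detect_format(path) if format == "auto" else format
    coor_format = gemmi.CoorFormat.Mmcif if fmt == "mmcif" else gemmi.CoorFormat.Pdb
    try:
        st = gemmi.read_structure(str(path), format=coor_format)
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise ParseError(f"cannot parse {path} as {fmt}: {exc}") from exc
    st.setup_entities()
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models")
    model = st[0]
    chains: dict[str, list[ResidueEntry]] = {}
    for chain in model:
        entries: list[ResidueEntry] = []
        for residue in chain:
            if not _is_polymer_residue(residue.name):
                continue
            atoms = tuple(
                AtomRecord(
                    name=a.name,
                    xyz=(a.pos.x, a.pos.y, a.pos.z),
                    occupancy=a.occ,
                    b_factor=a.b_iso,
                )
                for a in _best_altloc_atoms(residue)
            )
            icode = residue.seqid.icode.strip()
            kind = "HETATM" if residue.het_flag == "H" else "ATOM"
            entries.append(
                ResidueEntry(
                    chain_id=chain.name,
                    res_seq=residue.seqid.num,
                    icode=icode,
                    name3=residue.name,
                    record_kind=kind,
                    one_letter=one_letter_code(residue.name),
                    atoms=atoms,
                )
            )
        if entries:
            entries.sort(key=lambda r: (r.res_seq, r.icode))
            chains[chain.name] = entries
    if not chains:
        raise EmptyStructureError(f"{path}: no polymer residues found")
    return StructureModel(chains=chains, source_format=fmt, _gemmi=st)


def chain_sequence(model: StructureModel, chain_id: str) -> str:
    """One-letter sequence of a chain's polymer residues, including
    HETATM-flagged modified residues."""
    if chain_id not in model.chains:
        raise UnknownChainError(
            f"chain {chain_id!r} not in structure (has {model.chain_ids})"
        )
    return "".join(r.one_letter for r in model.chains[chain_id])


_map_aligners: dict[str, Align.PairwiseAligner] = {}


def _get_map_aligner(alphabet: str) -> Align.PairwiseAligner:
    if alphabet not in _map_aligners:
        a = Align.PairwiseAligner()
        a.mode = "global"
        a.open_gap_score = -10.0
        a.extend_gap_score = -0.5
        if alphabet == "protein":
            m = substitution_matrices.load("BLOSUM62")
            a.substitution_matrix = m
            a.wildcard = "X"
        else:
            a.match_score = 2.0
            a.mismatch_score = -1.0
            a.wildcard = "N"
        _map_aligners[alphabet] = a
    return _map_aligners[alphabet]


def map_query_to_chain(
    query_seq: str,
    chain_seq: str,
    alphabet: str = "protein",
    warn_identity: float = 0.95,
    min_identity: float = 0.60,
) -> tuple[dict[int, int], float]:
    """Globally align the query onto a chain sequence.

    Returns a mapping (1-based query position -> 0-based chain residue
    index) over aligned non-gap pairs, plus the identity over aligned
    columns. Warns below 95% identity; raises MappingError below 60%.
    """
    if not query_seq or not chain_seq:
        raise MappingError("empty sequence")
    aligner = _get_map_aligner(alphabet)
    aln = aligner.align(query_seq, chain_seq)[0]
    mapping: dict[int, int] = {}
    matches = 0
    aligned_cols = 0
    for (q0, q1), (c0, c1) in zip(*aln.aligned):
        for dq in range(q1 - q0):
            qi, ci = q0 + dq, c0 + dq
            aligned_cols += 1
            if query_seq[qi] == chain_seq[ci]:
                matches += 1
            mapping[qi + 1] = ci
    if aligned_cols == 0:
        raise MappingError("no aligned columns between query and chain")
    identity = matches / aligned_cols
    if identity < min_identity:
        raise MappingError(
            f"query/chain identity {identity:.2f} is below {min_identity:.2f}; "
            "these do not look like the same molecule"
        )
    if identity < warn_identity:
        warnings.warn(
            f"query/chain identity is only {identity:.2f}",
            UserWarning,
            stacklevel=2,
        )
    return mapping, identity


def build_chain_grade_map(
    model: StructureModel,
    chain_id: str,
    query_seq: str,
    grades_by_query_pos: Mapping[int, int],
    alphabet: str = "protein",
) -> ChainGradeMap:
    """Align the query to the chain and assign grades to chain residues."""
    cseq = chain_sequence(model, chain_id)
    mapping, identity = map_query_to_chain(query_seq, cseq, alphabet)
    residues = model.chains[chain_id]
    grades: dict[tuple[int, str], int] = {}
    for qpos, ci in mapping.items():
        g = grades_by_query_pos.get(qpos)
        if g is not None:
            grades[residues[ci].key] = int(g)
    return ChainGradeMap(chain_id=chain_id, grades=grades, identity_to_query=identity)


def propagate_identical_chains(
    model: StructureModel, graded: ChainGradeMap
) -> list[ChainGradeMap]:
    """Copy grades (by residue rank) to every other chain whose normalized
    sequence is byte-identical to the graded chain's."""
    ref_seq = chain_sequence(model, graded.chain_id)
    ref_residues = model.chains[graded.chain_id]
    rank_grades = {
        i: graded.grades[r.key]
        for i, r in enumerate(ref_residues)
        if r.key in graded.grades
    }
    out = [graded]
    for cid in model.chain_ids:
        if cid == graded.chain_id:
            continue
        if chain_sequence(model, cid) != ref_seq:
            continue
        residues = model.chains[cid]
        grades = {residues[i].key: g for i, g in rank_grades.items()}
        out.append(
            ChainGradeMap(
                chain_id=cid,
                grades=grades,
                identity_to_query=graded.identity_to_query,
            )
        )
    return out


def write_graded_structure(
    model: StructureModel,
    grade_maps: Sequence[ChainGradeMap],
    out_path: str | Path,
    format: Literal["pdb", "mmcif"] | None = None,
) -> None:
    """Copy of the structure with grades in the temperature-factor column.

    Every atom of a mapped residue carries its grade; atoms of unmapped
    residues (including ligands and waters) get 0.00.
    """
    if not any(gm.grades for gm in grade_maps):
        raise ValueError("no mapped residues to write")
    fmt = format or model.source_format
    by_chain = {gm.chain_id: gm.grades for gm in grade_maps}
    st = model._gemmi.clone()
    for mdl in st:
        for chain in mdl:
            grades = by_chain.get(chain.name, {})
            for residue in chain:
                key = (residue.seqid.num, residue.seqid.icode.strip())
                b = float(grades.get(key, 0))
                for atom in residue:
                    atom.b_iso = b
    out_path = str(out_path)
    if fmt == "pdb":
        st.write_pdb(out_path)
    else:
        st.make_mmcif_document().write_file(out_path)


PML_HEADER = "# conservation coloring script (PyMOL dialect)\n"
CXC_HEADER = "# conservation coloring script (ChimeraX dialect)\n"


def emit_coloring_scripts(
    grade_maps: Sequence[ChainGradeMap],
    out_dir: str | Path,
    structure_filename: str,
    scale: str = "standard",
) -> dict[str, Path]:
    """Plain-text PyMOL (.pml) and ChimeraX (.cxc) scripts coloring residues
    by grade; they reference the graded structure file by relative path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table = COLORS_STANDARD if scale == "standard" else COLORS_COLOR_BLIND

    # grade -> list of (chain, resi) selections
    per_grade: dict[int, list[tuple[int, str]]] = {g: [] for g in range(1, N_GRADES + 1)}
    for gm in grade_maps:
        for (num, icode), g in sorted(gm.grades.items()):
            per_grade[g].append((num, gm.chain_id))

    pml_path = out_dir / "color_by_grade.pml"
    cxc_path = out_dir / "color_by_grade.cxc"

    with open(pml_path, "w") as fh:
        fh.write(PML_HEADER)
        if any(per_grade.values()):
            fh.write(f"load {structure_filename}\n")
            fh.write("hide everything\nshow cartoon\ncolor gray80\n")
            for g in range(1, N_GRADES + 1):
                r, gg, b = (c / 255.0 for c in table[g - 1])
                fh.write(f"set_color grade{g}, [{r:.4f}, {gg:.4f}, {b:.4f}]\n")
            for g in range(1, N_GRADES + 1):
                sel = per_grade[g]
                if not sel:
                    continue
                by_chain: dict[str, list[int]] = {}
                for num, cid in sel:
                    by_chain.setdefault(cid, []).append(num)
                parts = [
                    f"(chain {cid} and resi {'+'.join(str(n) for n in nums)})"
                    for cid, nums in by_chain.items()
                ]
                fh.write(f"color grade{g}, {' or '.join(parts)}\n")
        else:
            fh.write("# no graded residues\n")

    with open(cxc_path, "w") as fh:
        fh.write(CXC_HEADER)
        if any(per_grade.values()):
            fh.write(f"open {structure_filename}\n")
            fh.write("hide atoms\nshow cartoons\ncolor gray\n")
            for g in range(1, N_GRADES + 1):
                sel = per_grade[g]
                if not sel:
                    continue
                r, gg, b = table[g - 1]
                by_chain: dict[str, list[int]] = {}
                for num, cid in sel:
                    by_chain.setdefault(cid, []).append(num)
                spec = " ".join(
                    f"/{cid}:{','.join(str(n) for n in nums)}"
                    for cid, nums in by_chain.items()
                )
                fh.write(f"color {spec} rgb({r},{gg},{b})\n")
        else:
            fh.write("# no graded residues\n")

    return {"pymol": pml_path, "chimerax": cxc_path}
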