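"""Read and write PDB-format structures as a uniform atom/residue/chain model.

Parsing is backed by :mod:`gemmi`; the records are then mapped into the
lightweight dataclasses used throughout the package, applying the house
rules for alternate locations (keep the highest-occupancy conformer, first
in file on ties), waters and monoatomic ions (excluded from polymer
chains), and multi-MODEL files (first model only unless an ensemble is
requested).

Coordinates are in Angstrom throughout and residues keep their original
numbering: a residue identifier is the triple
``(chain_id, residue_seq, insertion_code)``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import gemmi
import numpy as np

from .errors import (
    ChainClassError,
    EmptySelectionError,
    EmptyStructureError,
    ParseError,
)

__all__ = [
    "AtomRecord",
    "ResidueModel",
    "ChainModel",
    "AssemblyStructure",
    "ResidueId",
    "CalphaSelection",
    "parse_structure",
    "parse_ensemble",
    "write_structure",
    "classify_chain",
    "extract_sequence",
    "calpha_coordinates",
    "three_to_one",
]

# Standard amino acids plus common mappable modifications.
AA_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # modified residues kept when mappable to a parent
    "MSE": "M", "SEC": "C", "PYL": "K", "HYP": "P", "MLY": "K",
    "CSO": "C", "PTR": "Y", "SEP": "S", "TPO": "T",
}

# RNA nucleotides; modified bases map to their parent.
RNA_PARENT = {
    "A": "A", "U": "U", "G": "G", "C": "C",
    "PSU": "U", "5MU": "U", "4SU": "U", "H2U": "U", "UR3": "U",
    "1MA": "A", "2MA": "A", "MA6": "A", "A2M": "A",
    "2MG": "G", "7MG": "G", "M2G": "G", "OMG": "G", "1MG": "G", "G7M": "G",
    "5MC": "C", "OMC": "C", "4OC": "C",
}

_ION_RESIDUES = {
    "MG", "K", "NA", "CL", "ZN", "CA", "MN", "FE", "CD", "NI", "CO",
    "CU", "BR", "IOD", "SR", "CS", "RB", "BA", "OS", "IR",
}
_WATER_RESIDUES = {"HOH", "WAT", "DOD"}


class ResidueId(NamedTuple):
    """Identifier of a residue: original chain id, sequence number, insertion code."""

    chain_id: str
    residue_seq: int
    insertion_code: str


@dataclass
class AtomRecord:
    serial: int
    name: str
    alt_loc: str
    residue_name: str
    chain_id: str
    residue_seq: int
    insertion_code: str
    xyz: np.ndarray
    occupancy: float
    element: str

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (3,) or not np.all(np.isfinite(self.xyz)):
            raise ParseError(
                f"atom {self.serial} {self.name}: coordinates must be a finite 3-vector"
            )


@dataclass
class ResidueModel:
    residue_name: str
    residue_seq: int
    insertion_code: str
    atoms: list[AtomRecord] = field(default_factory=list)

    @property
    def one_letter(self) -> str:
        return three_to_one(self.residue_name)

    def residue_id(self, chain_id: str) -> ResidueId:
        return ResidueId(chain_id, self.residue_seq, self.insertion_code)

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class ChainModel:
    chain_id: str
    polymer_class: str  # "protein" | "rna" | "other"
    residues: list[ResidueModel] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)

    def residue_ids(self) -> list[ResidueId]:
        return [r.residue_id(self.chain_id) for r in self.residues]


@dataclass
class AssemblyStructure:
    structure_id: str
    chains: list[ChainModel] = field(default_factory=list)

    def chain(self, chain_id: str) -> ChainModel:
        for ch in self.chains:
            if ch.chain_id == chain_id:
                return ch
        raise KeyError(f"no chain {chain_id!r} in structure {self.structure_id!r}")

    def chains_of_class(self, polymer_class: str) -> list[ChainModel]:
        return [c for c in self.chains if c.polymer_class == polymer_class]


@dataclass
class CalphaSelection:
    """Ordered C-alpha coordinates of a protein chain plus the residues lacking one."""

    residue_ids: list[ResidueId]
    coords: np.ndarray  # (n, 3)
    missing: list[ResidueId]


def three_to_one(residue_name: str) -> str:
    """Map a residue name to its one-letter amino-acid code, ``'X'`` if unknown."""
    return AA_THREE_TO_ONE.get(residue_name.strip().upper(), "X")


def _is_amino(residue_name: str) -> bool:
    return residue_name.strip().upper() in AA_THREE_TO_ONE


def _is_rna(residue_name: str) -> bool:
    return residue_name.strip().upper() in RNA_PARENT


def _resolve_altlocs(atoms: list[AtomRecord]) -> list[AtomRecord]:
    """Keep one atom per atom name: highest occupancy, first in file on ties."""
    best: dict[str, AtomRecord] = {}
    order: list[str] = []
    for atom in atoms:
        prev = best.get(atom.name)
        if prev is None:
            best[atom.name] = atom
            order.append(atom.name)
        elif atom.occupancy > prev.occupancy:
            best[atom.name] = atom
    return [best[name] for name in order]


def _read_gemmi(source) -> gemmi.Structure:
    if isinstance(source, gemmi.Structure):
        return source
    if isinstance(source, Path):
        text = source.read_text()
    elif isinstance(source, str) and "\n" not in source and Path(source).exists():
        text = Path(source).read_text()
    elif isinstance(source, str):
        text = source
    elif isinstance(source, io.IOBase) or hasattr(source, "read"):
        text = source.read()
    else:
        raise TypeError(f"cannot read a structure from {type(source)!r}")
    try:
        structure = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:  # gemmi names the offending line
        raise ParseError(f"malformed PDB input: {exc}") from exc
    if sum(len(ch) for model in structure for ch in model) == 0:
        raise ParseError("input contains no ATOM/HETATM records")
    return structure


def _convert_model(model: gemmi.Model, structure_id: str) -> AssemblyStructure:
    chains: list[ChainModel] = []
    for gchain in model:
        residues: list[ResidueModel] = []
        for gres in gchain:
            name = gres.name.strip().upper()
            if gres.is_water() or name in _WATER_RESIDUES:
                continue
            if name in _ION_RESIDUES and len(gres) == 1:
                continue
            icode = gres.seqid.icode.strip()
            atoms = [
                AtomRecord(
                    serial=atom.serial,
                    name=atom.name,
                    alt_loc="" if atom.altloc in ("\x00", " ") else atom.altloc,
                    residue_name=gres.name.strip(),
                    chain_id=gchain.name,
                    residue_seq=gres.seqid.num,
                    insertion_code=icode,
                    xyz=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    occupancy=atom.occ,
                    element=atom.element.name,
                )
                for atom in gres
            ]
            residues.append(
                ResidueModel(
                    residue_name=gres.name.strip(),
                    residue_seq=gres.seqid.num,
                    insertion_code=icode,
                    atoms=_resolve_altlocs(atoms),
                )
            )
        if residues:
            chain = ChainModel(gchain.name, "other", residues)
            chain.polymer_class = classify_chain(chain)
            chains.append(chain)
    structure = AssemblyStructure(structure_id=structure_id, chains=chains)
    if not any(c.polymer_class in ("protein", "rna") for c in chains):
        raise EmptyStructureError(
            f"structure {structure_id!r} contains no protein or RNA chains"
        )
    return structure


def parse_structure(source, structure_id: str | None = None) -> AssemblyStructure:
    """Parse PDB text (string, path or file object) into an :class:`AssemblyStructure`.

    Only the first MODEL of a multi-model file is used; see
    :func:`parse_ensemble` for loading all models as coordinate frames.
    Waters and monoatomic ions are excluded, alternate locations resolved
    to the highest-occupancy conformer.
    """
    gstruct = _read_gemmi(source)
    sid = structure_id or gstruct.name or "structure"
    return _convert_model(gstruct[0], sid)


def parse_ensemble(source, structure_id: str | None = None) -> list[AssemblyStructure]:
    """Parse every MODEL of a multi-model PDB file as a separate structure frame."""
    gstruct = _read_gemmi(source)
    sid = structure_id or gstruct.name or "structure"
    return [
        _convert_model(model, f"{sid}/model{i + 1}")
        for i, model in enumerate(gstruct)
    ]


def classify_chain(chain: ChainModel) -> str:
    """Classify a chain as ``protein``, ``rna`` or ``other`` by majority residue vote.

    The vote is over residue names, so the result is invariant under any
    permutation of the residue order.
    """
    if not chain.residues:
        return "other"
    n_aa = sum(_is_amino(r.residue_name) for r in chain.residues)
    n_nt = sum(_is_rna(r.residue_name) for r in chain.residues)
    n = len(chain.residues)
    if n_aa * 2 > n and n_aa >= n_nt:
        return "protein"
    if n_nt * 2 > n:
        return "rna"
    return "other"


def extract_sequence(chain: ChainModel) -> str:
    """One-letter sequence of a protein chain; non-standard residues become ``'X'``."""
    if chain.polymer_class != "protein":
        raise ChainClassError(
            f"chain {chain.chain_id!r} is {chain.polymer_class}, not protein"
        )
    return "".join(r.one_letter for r in chain.residues)


def calpha_coordinates(chain: ChainModel) -> CalphaSelection:
    """Ordered C-alpha coordinates of a protein chain.

    Residues without a C-alpha atom (after alternate-location resolution)
    are reported in ``missing`` rather than silently dropped.
    """
    if chain.polymer_class != "protein":
        raise ChainClassError(
            f"chain {chain.chain_id!r} is {chain.polymer_class}, not protein"
        )
    ids: list[ResidueId] = []
    coords: list[np.ndarray] = []
    missing: list[ResidueId] = []
    for res in chain.residues:
        ca = res.atom("CA")
        rid = res.residue_id(chain.chain_id)
        if ca is None:
            missing.append(rid)
        else:
            ids.append(rid)
            coords.append(ca.xyz)
    if not ids:
        raise EmptySelectionError(
            f"chain {chain.chain_id!r} has no C-alpha atoms"
        )
    return CalphaSelection(ids, np.asarray(coords, dtype=float), missing)


def _format_atom_name(name: str) -> str:
    # PDB columns 13-16: names shorter than 4 characters start in column 14.
    return name if len(name) >= 4 else f" {name:<3s}"


def write_structure(structure: AssemblyStructure) -> str:
    """Serialize an :class:`AssemblyStructure` as PDB text (ATOM/TER/END records)."""
    lines: list[str] = []
    serial = 0
    for chain in structure.chains:
        for res in chain.residues:
            for atom in res.atoms:
                serial += 1
                lines.append(
                    "ATOM  {serial:5d} {name}{alt:1s}{res:>3s} {ch:1s}{seq:4d}{ic:1s}   "
                    "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {el:>2s}".format(
                        serial=serial,
                        name=_format_atom_name(atom.name),
                        alt=atom.alt_loc or " ",
                        res=atom.residue_name,
                        ch=chain.chain_id[:1] or "A",
                        seq=atom.residue_seq,
                        ic=atom.insertion_code or " ",
                        x=atom.xyz[0],
                        y=atom.xyz[1],
                        z=atom.xyz[2],
                        occ=atom.occupancy,
                        b=0.0,
                        el=atom.element,
                    )
                )
        serial += 1
        lines.append(f"TER   {serial:5d}")
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_fasta(chains: Iterable[ChainModel], structure_id: str = "") -> str:
    """Export protein chain sequences as FASTA text."""
    out = []
    for chain in chains:
        if chain.polymer_class != "protein":
            continue
        header = f">{structure_id}|{chain.chain_id}" if structure_id else f">{chain.chain_id}"
        out.append(header)
        out.append(extract_sequence(chain))
    return "\n".join(out) + "\n"
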