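"""Protein-rRNA contact detection and charge/composition statistics.

A protein residue is a *contact residue* when any of its atoms lies within
a distance cutoff (default 3.5 Angstrom, inclusive) of any atom of an RNA
nucleotide.  A residue touching several nucleotides yields several contact
pairs, so the number of pairs can exceed the number of contact residues.

Charge bookkeeping follows the simple titratable-residue convention:
Lys and Arg count +1, Asp and Glu count -1, everything else (including
His) is neutral.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import ChainClassError, EmptySelectionError, ParameterError
from .structure_io import (
    AssemblyStructure,
    ChainModel,
    ResidueId,
    three_to_one,
)

__all__ = [
    "ContactPair",
    "ContactMap",
    "ChargeReport",
    "ContactSummary",
    "RESIDUE_CLASSES",
    "find_contacts",
    "find_contacts_bruteforce",
    "summarize_contacts",
    "net_charge",
    "classify_residue",
    "class_census",
    "composition_stats",
]

DEFAULT_CUTOFF = 3.5  # Angstrom, inclusive

POSITIVE_RESIDUES = {"LYS", "ARG"}
NEGATIVE_RESIDUES = {"ASP", "GLU"}

# Six-way side-chain classification. His is its own class (neutral at the
# level of the charge census but a frequent rRNA hydrogen-bond donor);
# Cys is grouped with the polar residues. Tyr is aromatic (and polar, but
# each residue belongs to exactly one class here).
RESIDUE_CLASSES: dict[str, str] = {
    "K": "basic", "R": "basic",
    "D": "acidic", "E": "acidic",
    "H": "histidine",
    "F": "aromatic", "W": "aromatic", "Y": "aromatic",
    "S": "polar", "T": "polar", "N": "polar", "Q": "polar", "C": "polar",
    "G": "nonpolar", "A": "nonpolar", "V": "nonpolar", "L": "nonpolar",
    "I": "nonpolar", "P": "nonpolar", "M": "nonpolar",
}


@dataclass(frozen=True)
class ContactPair:
    protein_residue_id: ResidueId
    protein_residue_name: str
    nucleotide_id: ResidueId
    nucleotide_name: str
    min_atom_distance: float


@dataclass
class ContactMap:
    protein_chain_id: str
    rna_chain_ids: tuple[str, ...]
    cutoff: float
    pairs: list[ContactPair] = field(default_factory=list)

    @property
    def contact_residues(self) -> set[ResidueId]:
        return {p.protein_residue_id for p in self.pairs}

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class ChargeReport:
    protein_name: str
    length: int
    n_pos: int
    n_neg: int
    net_charge: int
    pct_lys_arg: float
    pct_asp_glu: float


@dataclass
class ContactSummary:
    protein_name: str
    total_pairs: int
    pos_pairs: int
    neg_pairs: int
    frac_pos: float | None
    pct_pos: int | None  # display-rounded integer percent, as in the source tables


def _chain_atoms(chain: ChainModel) -> tuple[np.ndarray, list[int]]:
    """All atom coordinates of a chain plus, per atom, its residue index."""
    coords: list[np.ndarray] = []
    res_index: list[int] = []
    for i, res in enumerate(chain.residues):
        for atom in res.atoms:
            coords.append(atom.xyz)
            res_index.append(i)
    if not coords:
        raise EmptySelectionError(f"chain {chain.chain_id!r} has no atoms")
    return np.asarray(coords), res_index


def find_contacts(
    structure: AssemblyStructure,
    protein_chain: str,
    rna_chains,
    cutoff: float = DEFAULT_CUTOFF,
) -> ContactMap:
    """All protein-residue / nucleotide pairs with an atom pair within ``cutoff``.

    The comparison is inclusive (``distance <= cutoff``).  Neighbor search
    uses a k-d tree over the RNA atoms; the result is identical to the
    all-pairs computation (see :func:`find_contacts_bruteforce`) but scales
    to ribosome-sized structures.  Pairs are ordered by protein residue,
    then nucleotide, in chain order.
    """
    if cutoff <= 0:
        raise ParameterError(f"cutoff must be positive, got {cutoff}")
    if isinstance(rna_chains, str):
        rna_chains = [rna_chains]
    pchain = structure.chain(protein_chain)
    if pchain.polymer_class != "protein":
        raise ChainClassError(f"chain {protein_chain!r} is not a protein chain")
    rchains = [structure.chain(c) for c in rna_chains]
    for rc in rchains:
        if rc.polymer_class != "rna":
            raise ChainClassError(f"chain {rc.chain_id!r} is not an RNA chain")

    p_xyz, p_res = _chain_atoms(pchain)
    p_ids = pchain.residue_ids()
    p_names = [r.residue_name for r in pchain.residues]

    # minimum atom-atom distance per (protein residue, nucleotide) pair
    min_dist: dict[tuple[int, int], float] = {}
    nt_ids: list[ResidueId] = []
    nt_names: list[str] = []
    nt_offset = 0
    for rc in rchains:
        r_xyz, r_res = _chain_atoms(rc)
        nt_ids.extend(rc.residue_ids())
        nt_names.extend(r.residue_name for r in rc.residues)
        tree = cKDTree(r_xyz)
        neighbors = tree.query_ball_point(p_xyz, r=cutoff)
        for a, hits in enumerate(neighbors):
            if not hits:
                continue
            d = np.linalg.norm(r_xyz[hits] - p_xyz[a], axis=1)
            for b, dist in zip(hits, d):
                key = (p_res[a], nt_offset + r_res[b])
                if dist <= cutoff and dist < min_dist.get(key, np.inf):
                    min_dist[key] = float(dist)
        nt_offset += len(rc.residues)

    pairs = [
        ContactPair(
            protein_residue_id=p_ids[i],
            protein_residue_name=p_names[i],
            nucleotide_id=nt_ids[j],
            nucleotide_name=nt_names[j],
            min_atom_distance=d,
        )
        for (i, j), d in sorted(min_dist.items())
    ]
    return ContactMap(
        protein_chain_id=protein_chain,
        rna_chain_ids=tuple(rc.chain_id for rc in rchains),
        cutoff=cutoff,
        pairs=pairs,
    )


def find_contacts_bruteforce(
    structure: AssemblyStructure,
    protein_chain: str,
    rna_chains,
    cutoff: float = DEFAULT_CUTOFF,
) -> ContactMap:
    """All-pairs O(N*M) reference implementation of :func:`find_contacts`."""
    if cutoff <= 0:
        raise ParameterError(f"cutoff must be positive, got {cutoff}")
    if isinstance(rna_chains, str):
        rna_chains = [rna_chains]
    pchain = structure.chain(protein_chain)
    rchains = [structure.chain(c) for c in rna_chains]
    pairs: list[ContactPair] = []
    for i, pres in enumerate(pchain.residues):
        for rc in rchains:
            for nres in rc.residues:
                dmin = min(
                    float(np.linalg.norm(pa.xyz - na.xyz))
                    for pa in pres.atoms
                    for na in nres.atoms
                )
                if dmin <= cutoff:
                    pairs.append(
                        ContactPair(
                            protein_residue_id=pres.residue_id(pchain.chain_id),
                            protein_residue_name=pres.residue_name,
                            nucleotide_id=nres.residue_id(rc.chain_id),
                            nucleotide_name=nres.residue_name,
                            min_atom_distance=dmin,
                        )
                    )
    return ContactMap(
        protein_chain_id=protein_chain,
        rna_chain_ids=tuple(c.chain_id for c in rchains),
        cutoff=cutoff,
        pairs=pairs,
    )


def summarize_contacts(cmap: ContactMap, protein_name: str | None = None) -> ContactSummary:
    """Pair counts split by protein-residue charge, as in the per-protein contact tables."""
    total = len(cmap.pairs)
    pos = sum(p.protein_residue_name.upper() in POSITIVE_RESIDUES for p in cmap.pairs)
    neg = sum(p.protein_residue_name.upper() in NEGATIVE_RESIDUES for p in cmap.pairs)
    if total == 0:
        frac = pct = None
    else:
        frac = pos / total
        pct = round(100.0 * frac)
    return ContactSummary(
        protein_name=protein_name or cmap.protein_chain_id,
        total_pairs=total,
        pos_pairs=pos,
        neg_pairs=neg,
        frac_pos=frac,
        pct_pos=pct,
    )


def net_charge(sequence: str, protein_name: str = "") -> ChargeReport:
    """Sequence net charge: +1 per Lys/Arg, -1 per Asp/Glu, all else neutral."""
    if not sequence:
        raise ParameterError("sequence must be nonempty")
    seq = sequence.upper()
    n_pos = seq.count("K") + seq.count("R")
    n_neg = seq.count("D") + seq.count("E")
    n = len(seq)
    return ChargeReport(
        protein_name=protein_name,
        length=n,
        n_pos=n_pos,
        n_neg=n_neg,
        net_charge=n_pos - n_neg,
        pct_lys_arg=100.0 * n_pos / n,
        pct_asp_glu=100.0 * n_neg / n,
    )


def classify_residue(residue_name: str) -> str:
    """Six-way side-chain class of a standard amino acid (1- or 3-letter name)."""
    code = residue_name.strip().upper()
    if len(code) != 1:
        code = three_to_one(code)
    cls = RESIDUE_CLASSES.get(code)
    if cls is None:
        raise ParameterError(f"cannot classify residue {residue_name!r}")
    return cls


def class_census(residue_names) -> Counter:
    """Count residues per side-chain class; the counts partition the input."""
    return Counter(classify_residue(name) for name in residue_names)


def composition_stats(sequences, protein_name: str = "all") -> ChargeReport:
    """Charge composition over the concatenation of several sequences (residue-weighted)."""
    seqs = [s for s in sequences if s]
    if not seqs:
        raise ParameterError("need at least one nonempty sequence")
    return net_charge("".join(seqs), protein_name=protein_name)
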