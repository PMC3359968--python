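"""Synthetic fixtures: toy protein-RNA complexes with planted contacts,
elastic-network geometries with known spectra, and mobility profiles with
a planted contacting/non-contacting enrichment.

Everything is deterministic under a fixed seed.  Planted contact distances
must stay away from the 3.5 Angstrom decision boundary (<= 3.4 or >= 3.6)
so that recovery tests are immune to floating-point noise.  Toy RNA
nucleotides carry a minimal atom set (P, C1', N9/N1) -- enough for the
any-atom distance rule, with no pretense of realistic nucleotide geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .contact_analysis import ContactMap, ContactPair
from .elastic_network import MobilityProfile
from .errors import GenerationError, ParameterError
from .structure_io import (
    AA_THREE_TO_ONE,
    AssemblyStructure,
    AtomRecord,
    ChainModel,
    ResidueId,
    ResidueModel,
    write_structure,
)

__all__ = [
    "ToyComplexSpec",
    "MobilitySampleSpec",
    "ANMFixture",
    "make_toy_complex",
    "make_anm_fixture",
    "make_mobility_sample",
]

_ONE_TO_THREE = {v: k for k, v in reversed(list(AA_THREE_TO_ONE.items()))}
_PROTEIN_SPACING = 6.0  # Angstrom between consecutive toy residues
_RNA_SPACING = 7.0
_RNA_OFFSET = 30.0  # separation between the protein and RNA strands
_MIN_CLEARANCE = 2.0  # steric floor for planted atoms


@dataclass(frozen=True)
class ToyComplexSpec:
    """Blueprint of a toy complex: chain sizes, sequence and planted contacts.

    ``planted_contacts`` holds ``(protein_res_index, nucleotide_index,
    target_distance)`` triples with 0-based indices; distances <= 3.4 A are
    true contacts under the 3.5 A rule, >= 3.6 A are planted near-misses.
    """

    n_protein_res: int = 6
    n_rna_nt: int = 4
    protein_sequence: str | None = None
    planted_contacts: frozenset = frozenset()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_protein_res < 1 or self.n_rna_nt < 1:
            raise ParameterError("toy complex needs at least one residue and one nucleotide")
        if self.protein_sequence is not None and len(self.protein_sequence) != self.n_protein_res:
            raise ParameterError("protein_sequence length must equal n_protein_res")
        pairs = [(i, j) for i, j, _ in self.planted_contacts]
        if len(pairs) != len(set(pairs)):
            raise ParameterError("duplicate (residue, nucleotide) planted contacts")
        for i, j, d in self.planted_contacts:
            if not (0 <= i < self.n_protein_res and 0 <= j < self.n_rna_nt):
                raise ParameterError(f"planted contact ({i}, {j}) out of range")
            if not (d <= 3.4 or d >= 3.6):
                raise ParameterError(
                    f"target distance {d} is ambiguous against the 3.5 A rule"
                )
            if d < _MIN_CLEARANCE:
                raise ParameterError(f"target distance {d} below steric floor")


@dataclass(frozen=True)
class MobilitySampleSpec:
    """Blueprint of a mobility profile with a planted enrichment.

    ``effect`` is the ratio of the contacting-residue mean RMSF to the
    non-contacting mean (1.0 gives an exchangeable null); ``noise_sd`` is
    the per-residue spread around either mean.
    """

    N: int = 100
    C: int = 20
    effect: float = 2.0
    noise_sd: float = 0.1
    distribution: str = "normal"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.N > self.C >= 1):
            raise ParameterError(f"need N > C >= 1, got N={self.N}, C={self.C}")
        if self.effect <= 0 or self.noise_sd < 0:
            raise ParameterError("effect must be positive and noise_sd non-negative")
        if self.distribution not in ("normal", "lognormal"):
            raise ParameterError(f"unknown distribution {self.distribution!r}")


@dataclass
class ANMFixture:
    kind: str
    coords: np.ndarray
    facts: dict = field(default_factory=dict)


def _toy_residue(index: int, three: str) -> ResidueModel:
    x = index * _PROTEIN_SPACING
    atoms = [
        ("N", np.array([x - 0.7, 0.5, 0.0]), "N"),
        ("CA", np.array([x, 0.0, 0.0]), "C"),
        ("C", np.array([x + 0.7, 0.5, 0.0]), "C"),
    ]
    return ResidueModel(
        residue_name=three,
        residue_seq=index + 1,
        insertion_code="",
        atoms=[
            AtomRecord(0, name, "", three, "A", index + 1, "", xyz, 1.0, el)
            for name, xyz, el in atoms
        ],
    )


def _toy_nucleotide(index: int, base: str) -> ResidueModel:
    x = index * _RNA_SPACING
    glyco = "N9" if base in ("A", "G") else "N1"
    atoms = [
        ("P", np.array([x, _RNA_OFFSET, 0.0]), "P"),
        ("C1'", np.array([x + 1.2, _RNA_OFFSET + 0.8, 0.0]), "C"),
        (glyco, np.array([x + 2.0, _RNA_OFFSET + 1.5, 0.0]), "N"),
    ]
    return ResidueModel(
        residue_name=base,
        residue_seq=index + 1,
        insertion_code="",
        atoms=[
            AtomRecord(0, name, "", base, "B", index + 1, "", xyz, 1.0, el)
            for name, xyz, el in atoms
        ],
    )


def make_toy_complex(
    spec: ToyComplexSpec,
) -> tuple[AssemblyStructure, ContactMap, str]:
    """Build a toy protein-RNA complex realizing the planted contacts exactly.

    The protein and RNA strands run parallel 30 A apart, so the only
    protein atoms within reach of the RNA are the pseudo side-chain atoms
    placed at the requested target distance from the partner nucleotide's
    C1' atom.  Returns the structure, the ground-truth contact map (pairs
    with target distance <= 3.4 A) and the PDB text.
    """
    rng = np.random.default_rng(spec.seed)
    seq = spec.protein_sequence or "".join(
        rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=spec.n_protein_res)
    )
    bases = rng.choice(list("AUGC"), size=spec.n_rna_nt)
    protein = [
        _toy_residue(i, _ONE_TO_THREE[aa.upper()]) for i, aa in enumerate(seq)
    ]
    rna = [_toy_nucleotide(j, b) for j, b in enumerate(bases)]

    placed: list[np.ndarray] = []
    sidechain_names = {}
    plants_on_nt: dict[int, int] = {}
    # successive plants on one nucleotide go into disjoint out-of-plane bands
    # so their pseudo side-chain atoms keep the 2 A steric clearance
    z_bands = [(-0.15, 0.15), (1.5, 2.0), (-2.0, -1.5)]
    truth_pairs: list[ContactPair] = []
    for i, j, d in sorted(spec.planted_contacts):
        anchor_atom = rna[j].atom("C1'")
        anchor = anchor_atom.xyz
        band = z_bands[plants_on_nt.get(j, 0)] if plants_on_nt.get(j, 0) < 3 else (-2.0, 2.0)
        plants_on_nt[j] = plants_on_nt.get(j, 0) + 1
        ok = False
        for _ in range(1000):
            # direction with non-positive projection onto both intra-nucleotide
            # offsets (P and the base nitrogen), so those atoms end up strictly
            # farther than d and the anchor is the unique nearest RNA atom
            direction = np.array(
                [rng.uniform(0.68, 0.87), -1.0, rng.uniform(*band)]
            )
            direction /= np.linalg.norm(direction)
            pos = anchor + d * direction
            same_nt_clear = all(
                np.linalg.norm(pos - atom.xyz) > d + 1e-9
                for atom in rna[j].atoms
                if atom is not anchor_atom
            )
            other_nt_clear = all(
                np.linalg.norm(pos - atom.xyz) >= 3.6
                for jj, nres in enumerate(rna)
                if jj != j
                for atom in nres.atoms
            )
            clear = (
                same_nt_clear
                and other_nt_clear
                and all(np.linalg.norm(pos - p) >= _MIN_CLEARANCE for p in placed)
            )
            if clear:
                ok = True
                break
        if not ok:
            raise GenerationError(
                f"could not realize planted contact ({i}, {j}, {d}) in 1000 attempts"
            )
        placed.append(pos)
        k = sidechain_names.get(i, 0)
        sidechain_names[i] = k + 1
        name = f"S{k + 1}B"  # pseudo side-chain atoms S1B, S2B, ...
        res = protein[i]
        res.atoms.append(
            AtomRecord(0, name, "", res.residue_name, "A", res.residue_seq, "", pos, 1.0, "C")
        )
        if d <= 3.4:
            truth_pairs.append(
                ContactPair(
                    protein_residue_id=ResidueId("A", res.residue_seq, ""),
                    protein_residue_name=res.residue_name,
                    nucleotide_id=ResidueId("B", rna[j].residue_seq, ""),
                    nucleotide_name=rna[j].residue_name,
                    min_atom_distance=d,
                )
            )

    chains = [ChainModel("A", "protein", protein), ChainModel("B", "rna", rna)]
    structure = AssemblyStructure(structure_id=f"toy-{spec.seed}", chains=chains)
    truth = ContactMap(
        protein_chain_id="A", rna_chain_ids=("B",), cutoff=3.5, pairs=truth_pairs
    )
    return structure, truth, write_structure(structure)


def make_anm_fixture(
    kind: str,
    n: int | None = None,
    spacing: float = 3.8,
    seed: int | None = None,
    gamma: float = 1.0,
) -> ANMFixture:
    """Coordinates with analytically known spectral facts for ANM tests.

    Kinds: ``two_body`` (one nonzero eigenvalue, exactly ``2*gamma``),
    ``tetrahedron`` (connected, 6 rigid modes), ``square`` (planar,
    symmetry-equivalent nodes), ``random_cloud`` (reproducible generic
    3-D network).
    """
    if spacing <= 0:
        raise ParameterError("spacing must be positive")
    if kind == "two_body":
        coords = np.array([[0.0, 0.0, 0.0], [spacing, 0.0, 0.0]])
        facts = {"n_zero_modes": 5, "nonzero_eigenvalues": [2.0 * gamma]}
    elif kind == "tetrahedron":
        a = spacing / (2.0 * np.sqrt(2.0))
        coords = a * np.array(
            [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
        )
        facts = {"n_zero_modes": 6, "edge_length": spacing, "symmetric_nodes": True}
    elif kind == "square":
        s = spacing
        coords = np.array(
            [[0, 0, 0], [s, 0, 0], [s, s, 0], [0, s, 0]], dtype=float
        )
        facts = {"symmetric_nodes": True, "planar": True}
    elif kind == "random_cloud":
        if n is None or n < 4:
            raise ParameterError("random_cloud needs n >= 4")
        rng = np.random.default_rng(seed)
        for _ in range(100):
            coords = rng.uniform(0.0, max(3.0 * spacing, 10.0), size=(n, 3))
            centered = coords - coords.mean(axis=0)
            if np.linalg.matrix_rank(centered, tol=1e-6) == 3:
                break
        else:
            raise GenerationError("could not draw a non-degenerate 3-D cloud")
        facts = {"n_zero_modes": 6}
    else:
        raise ParameterError(f"unknown fixture kind {kind!r}")
    return ANMFixture(kind=kind, coords=coords, facts=facts)


def _positive_draws(
    rng: np.random.Generator, mean: float, sd: float, size: int, distribution: str
) -> np.ndarray:
    if distribution == "lognormal":
        sigma2 = np.log1p((sd / mean) ** 2)
        mu = np.log(mean) - sigma2 / 2.0
        return rng.lognormal(mu, np.sqrt(sigma2), size=size)
    out = rng.normal(mean, sd, size=size)
    for _ in range(100):
        bad = out <= 0
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    raise GenerationError("could not draw strictly positive mobility values")


def make_mobility_sample(
    spec: MobilitySampleSpec,
) -> tuple[MobilityProfile, set, float]:
    """Mobility profile with a planted contacting/non-contacting enrichment.

    Non-contacting residues have mean RMSF 1.0 and contacting residues mean
    ``effect``; contact positions are drawn uniformly.  With ``effect = 1``
    the profile is exchangeable, which is the null of the permutation test.
    """
    rng = np.random.default_rng(spec.seed)
    contact_idx = rng.choice(spec.N, size=spec.C, replace=False)
    is_contact = np.zeros(spec.N, dtype=bool)
    is_contact[contact_idx] = True
    rmsf = np.empty(spec.N)
    rmsf[~is_contact] = _positive_draws(
        rng, 1.0, spec.noise_sd, spec.N - spec.C, spec.distribution
    )
    rmsf[is_contact] = _positive_draws(
        rng, spec.effect, spec.noise_sd, spec.C, spec.distribution
    )
    profile = MobilityProfile(
        residue_ids=list(range(spec.N)),
        rmsf=rmsf,
        excluded=np.zeros(spec.N, dtype=bool),
        source="external",
    )
    return profile, set(int(i) for i in contact_idx), spec.effect
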