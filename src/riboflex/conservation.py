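"""Cross-species comparison of ribosomal proteins.

Pairwise global (Needleman-Wunsch) alignment with BLOSUM62 and affine gaps
(open 10, extend 0.5), percent identity and percent conserved side-chain
class, per-species conservation of rRNA-contacting residues, and C-alpha
superposition RMSD over the aligned pairs.

The identity denominator is the number of alignment columns where both
sequences have a residue (gap columns excluded).  Class conservation uses
the same six-way partition as the contact census, so identity always
implies class conservation and the class percentage can never be lower
than the identity percentage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices

from .contact_analysis import classify_residue
from .errors import MappingError, ParameterError
from .geometry import superpose

__all__ = [
    "PairwiseAlignment",
    "ConservationReport",
    "global_align",
    "conservation_report",
    "kabsch_rmsd",
]

_AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class PairwiseAlignment:
    aligned_a: str
    aligned_b: str
    matched_pairs: list[tuple[int, int]]  # 0-based indices into the ungapped sequences
    score: float

    @property
    def sequence_a(self) -> str:
        return self.aligned_a.replace("-", "")

    @property
    def sequence_b(self) -> str:
        return self.aligned_b.replace("-", "")


@dataclass
class ConservationReport:
    pct_identity: float
    pct_class_conserved: float
    contact_identity_a: float | None
    contact_identity_b: float | None
    contact_class_a: float | None
    contact_class_b: float | None
    n_matched_columns: int


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def global_align(a: str, b: str) -> PairwiseAlignment:
    """Needleman-Wunsch global alignment (BLOSUM62, gap open 10, extend 0.5).

    Traceback ties are broken deterministically by taking the first optimal
    alignment in the aligner's enumeration order.
    """
    a, b = a.upper(), b.upper()
    if not a or not b:
        raise ParameterError("both sequences must be nonempty")
    for seq, label in ((a, "a"), (b, "b")):
        bad = set(seq) - _AA_ALPHABET
        if bad:
            raise ParameterError(
                f"sequence {label} contains non-amino-acid characters: {sorted(bad)!r}"
            )
    aln = _make_aligner().align(a, b)[0]
    matched: list[tuple[int, int]] = []
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        matched.extend(zip(range(a0, a1), range(b0, b1)))
    return PairwiseAlignment(
        aligned_a=str(aln[0]),
        aligned_b=str(aln[1]),
        matched_pairs=matched,
        score=float(aln.score),
    )


def _contact_fraction(
    contacts: set[int], seq_self: str, seq_other: str, match_self_to_other: dict[int, int],
    by_class: bool,
) -> float | None:
    if not contacts:
        return None
    hits = 0
    for pos in contacts:
        j = match_self_to_other.get(pos)
        if j is None:
            continue
        if by_class:
            hits += classify_residue(seq_self[pos]) == classify_residue(seq_other[j])
        else:
            hits += seq_self[pos] == seq_other[j]
    return 100.0 * hits / len(contacts)


def conservation_report(
    aln: PairwiseAlignment,
    contacts_a=None,
    contacts_b=None,
) -> ConservationReport:
    """Identity / class-conservation percentages, overall and for contact residues.

    ``contacts_a`` / ``contacts_b`` are 0-based positions into the ungapped
    sequences.  Contact conservation is computed per species over its own
    contact list (an unmatched contact counts as non-conserved), so the two
    directions generally differ.
    """
    seq_a, seq_b = aln.sequence_a, aln.sequence_b
    for contacts, seq, label in ((contacts_a, seq_a, "a"), (contacts_b, seq_b, "b")):
        if contacts:
            out = [p for p in contacts if not (0 <= p < len(seq))]
            if out:
                raise MappingError(
                    f"contact positions {out!r} outside sequence {label} (length {len(seq)})"
                )
    if not aln.matched_pairs:
        raise ParameterError("alignment has no matched columns")
    ident = sum(seq_a[i] == seq_b[j] for i, j in aln.matched_pairs)
    same_class = sum(
        classify_residue(seq_a[i]) == classify_residue(seq_b[j])
        for i, j in aln.matched_pairs
    )
    n_cols = len(aln.matched_pairs)
    a_to_b = dict(aln.matched_pairs)
    b_to_a = {j: i for i, j in aln.matched_pairs}
    ca = set(contacts_a or ())
    cb = set(contacts_b or ())
    return ConservationReport(
        pct_identity=100.0 * ident / n_cols,
        pct_class_conserved=100.0 * same_class / n_cols,
        contact_identity_a=_contact_fraction(ca, seq_a, seq_b, a_to_b, by_class=False),
        contact_identity_b=_contact_fraction(cb, seq_b, seq_a, b_to_a, by_class=False),
        contact_class_a=_contact_fraction(ca, seq_a, seq_b, a_to_b, by_class=True),
        contact_class_b=_contact_fraction(cb, seq_b, seq_a, b_to_a, by_class=True),
        n_matched_columns=n_cols,
    )


def kabsch_rmsd(coords_a, coords_b) -> float:
    """RMSD between matched C-alpha sets after optimal (proper-rotation) superposition."""
    coords_a = np.asarray(coords_a, dtype=float)
    coords_b = np.asarray(coords_b, dtype=float)
    if len(coords_a) < 3:
        raise ParameterError("superposition needs at least 3 matched points")
    _, rmsd = superpose(coords_a, coords_b)
    return rmsd
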