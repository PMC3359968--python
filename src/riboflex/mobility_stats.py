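"""Contact-residue mobility statistics and ensemble reductions.

The central statistic is the *enrichment factor*

    EF = mean RMSF over contacting residues / mean RMSF over the rest,

with EF > 1 meaning the rRNA-contacting residues are more mobile than the
non-contacting ones.  Its significance comes from a permutation test: for
a protein with N usable residues of which C are contacting, random subsets
of size C are drawn (without replacement within a draw) and the analogous
ratio recomputed; the p-value is the fraction of null draws at least as
enriched as the observation.  Ties count as extreme and the add-one
(permutation-inclusive) correction is applied, so

    p = (1 + #{EF_null >= EF_obs}) / (1 + n_perm)

which keeps p within [1/(1+n_perm), 1] and never reports an exact zero.

The module also provides the reductions used to turn coordinate ensembles
(e.g. solution-dynamics snapshots loaded from multi-MODEL PDB files) into
profiles: per-frame RMSD against a reference, per-residue RMSF about the
iteratively superposed mean structure, Pearson correlation between two
profiles, and the crystallographic conversion B = (8/3) * pi^2 * RMSF^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .elastic_network import MobilityProfile
from .errors import AlignmentError, ParameterError
from .geometry import superpose

__all__ = [
    "EnrichmentResult",
    "EnrichmentTest",
    "enrichment_factor",
    "permutation_pvalue",
    "bfactor_from_rmsf",
    "rmsf_from_bfactor",
    "ensemble_rmsd",
    "ensemble_rmsf",
    "profile_correlation",
]


def _split_means(profile: MobilityProfile, contact_residues) -> tuple[float, float, int, int]:
    contacts = set(contact_residues)
    is_contact = np.array([rid in contacts for rid in profile.residue_ids])
    use = profile.active
    c_vals = profile.rmsf[use & is_contact]
    n_vals = profile.rmsf[use & ~is_contact]
    if c_vals.size == 0 or n_vals.size == 0:
        raise ParameterError(
            "enrichment needs both contacting and non-contacting non-excluded residues "
            f"(got {c_vals.size} and {n_vals.size})"
        )
    n_usable = int(use.sum())
    return float(c_vals.mean()), float(n_vals.mean()), n_usable, int(c_vals.size)


def enrichment_factor(profile: MobilityProfile, contact_residues) -> float:
    """EF = mean RMSF of contacting residues over mean RMSF of the others.

    Excluded residues (tip outliers, manual masks) are ignored on both
    sides.  The statistic is invariant to any overall rescaling of the
    profile, so ANM profiles in arbitrary units are fine.
    """
    c_mean, n_mean, _, _ = _split_means(profile, contact_residues)
    return c_mean / n_mean


@dataclass
class EnrichmentResult:
    """Observed EF with its permutation-null summary and p-value."""

    observed: float
    n_residues: int  # usable (non-excluded) residues, N
    n_contacts: int  # contacting residues among them, C
    n_perm: int
    p_value: float
    null_mean: float
    null_quantiles: dict[float, float]
    seed: int | None

    def summary(self) -> pd.DataFrame:
        rows = {
            "EF": self.observed,
            "N": self.n_residues,
            "C": self.n_contacts,
            "n_perm": self.n_perm,
            "p_value": self.p_value,
            "null_mean": self.null_mean,
        }
        rows.update({f"null_q{int(q * 100):02d}": v for q, v in self.null_quantiles.items()})
        return pd.DataFrame({"value": rows})

    def __repr__(self) -> str:
        return (
            f"EnrichmentResult(EF={self.observed:.3f}, N={self.n_residues}, "
            f"C={self.n_contacts}, p={self.p_value:.4g}, n_perm={self.n_perm})"
        )


def permutation_pvalue(
    profile: MobilityProfile,
    contact_residues,
    n_perm: int = 10_000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> EnrichmentResult:
    """Permutation test of the enrichment factor.

    Draws C residues uniformly without replacement from the non-excluded
    residues ``n_perm`` times, recomputes the contact/non-contact ratio for
    each draw, and reports the tie-inclusive add-one p-value.  Bitwise
    reproducible for a fixed ``(seed, n_perm)``.
    """
    if n_perm < 1:
        raise ParameterError(f"n_perm must be >= 1, got {n_perm}")
    c_mean, n_mean, n_usable, n_contact = _split_means(profile, contact_residues)
    observed = c_mean / n_mean
    if rng is None:
        rng = np.random.default_rng(seed)
    values = profile.rmsf[profile.active]
    n, c = n_usable, n_contact
    # vectorized draws: each row of ranks is a uniform random permutation of 0..n-1
    ranks = np.argsort(rng.random((n_perm, n)), axis=1)
    picked = np.take(values, ranks[:, :c])
    total = values.sum()
    c_sums = picked.sum(axis=1)
    null_ef = (c_sums / c) / ((total - c_sums) / (n - c))
    exceed = int(np.sum(null_ef >= observed))
    p = (1 + exceed) / (1 + n_perm)
    qs = (0.05, 0.25, 0.50, 0.75, 0.95)
    return EnrichmentResult(
        observed=observed,
        n_residues=n,
        n_contacts=c,
        n_perm=n_perm,
        p_value=p,
        null_mean=float(null_ef.mean()),
        null_quantiles={q: float(v) for q, v in zip(qs, np.quantile(null_ef, qs))},
        seed=seed,
    )


class EnrichmentTest:
    """Model-style wrapper: profile + contact set in, :class:`EnrichmentResult` out."""

    def __init__(self, profile: MobilityProfile, contact_residues):
        self.profile = profile
        self.contact_residues = set(contact_residues)

    def fit(self, n_perm: int = 10_000, seed: int | None = None) -> EnrichmentResult:
        return permutation_pvalue(
            self.profile, self.contact_residues, n_perm=n_perm, seed=seed
        )


_B_PREFACTOR = (8.0 / 3.0) * np.pi**2


def bfactor_from_rmsf(rmsf):
    """Crystallographic temperature factor B = (8/3) * pi^2 * RMSF^2 (Angstrom^2)."""
    rmsf = np.asarray(rmsf, dtype=float)
    if np.any(rmsf < 0):
        raise ParameterError("rmsf must be non-negative")
    out = _B_PREFACTOR * rmsf**2
    return float(out) if out.ndim == 0 else out


def rmsf_from_bfactor(bfactor):
    """Inverse of :func:`bfactor_from_rmsf`."""
    bfactor = np.asarray(bfactor, dtype=float)
    if np.any(bfactor < 0):
        raise ParameterError("B-factor must be non-negative")
    out = np.sqrt(bfactor / _B_PREFACTOR)
    return float(out) if out.ndim == 0 else out


def _check_frames(frames: np.ndarray) -> np.ndarray:
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[2] != 3:
        raise AlignmentError(f"frames must be (n_frames, n_atoms, 3), got {frames.shape}")
    return frames


def ensemble_rmsd(frames, reference: np.ndarray | None = None) -> np.ndarray:
    """Per-frame all-atom RMSD against a reference after optimal superposition.

    ``reference`` defaults to the first frame (the starting structure).
    """
    frames = _check_frames(frames)
    ref = frames[0] if reference is None else np.asarray(reference, dtype=float)
    if ref.shape != frames.shape[1:]:
        raise AlignmentError(
            f"reference shape {ref.shape} does not match frames {frames.shape[1:]}"
        )
    return np.array([superpose(f, ref)[1] for f in frames])


def ensemble_rmsf(
    frames,
    residue_index=None,
    residue_ids=None,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> MobilityProfile:
    """Per-residue RMSF about the mean conformation of an ensemble (Angstrom).

    Frames are superposed onto their running mean structure, which is
    recomputed until it moves by less than ``tol`` Angstrom (the standard
    iterative mean/superpose scheme).  Per-atom RMSF is the square root of
    the mean squared displacement about the converged mean; with
    ``residue_index`` (one residue label per atom) the per-residue value is
    the mean over that residue's atoms.
    """
    frames = _check_frames(frames)
    n_frames, n_atoms, _ = frames.shape
    if n_frames < 2:
        raise ParameterError("an ensemble needs at least 2 frames")
    fitted = frames.copy()
    mean = fitted[0]
    for _ in range(max_iter):
        fitted = np.array([superpose(f, mean)[0] for f in fitted])
        new_mean = fitted.mean(axis=0)
        shift = float(np.max(np.abs(new_mean - mean)))
        mean = new_mean
        if shift < tol:
            break
    atom_rmsf = np.sqrt(np.mean(np.sum((fitted - mean) ** 2, axis=2), axis=0))
    if residue_index is None:
        values = atom_rmsf
        ids = residue_ids if residue_ids is not None else list(range(n_atoms))
    else:
        residue_index = np.asarray(residue_index)
        if residue_index.shape != (n_atoms,):
            raise ParameterError("residue_index must give one residue label per atom")
        uniq = list(dict.fromkeys(residue_index.tolist()))  # preserve order
        values = np.array([atom_rmsf[residue_index == u].mean() for u in uniq])
        ids = residue_ids if residue_ids is not None else uniq
    return MobilityProfile(
        residue_ids=list(ids),
        rmsf=values,
        excluded=np.zeros(len(values), dtype=bool),
        source="ensemble",
    )


def profile_correlation(
    a: MobilityProfile, b: MobilityProfile, exclude_termini: int = 0
) -> float:
    """Pearson correlation between two profiles over shared, non-excluded residues.

    ``exclude_termini=k`` drops the first and last ``k`` shared residues
    symmetrically before correlating (useful when the two methods disagree
    mostly at chain termini).
    """
    if exclude_termini < 0:
        raise ParameterError("exclude_termini must be >= 0")
    b_map = {
        rid: v for rid, v, excl in zip(b.residue_ids, b.rmsf, b.excluded) if not excl
    }
    shared = [
        (va, b_map[rid])
        for rid, va, excl in zip(a.residue_ids, a.rmsf, a.excluded)
        if not excl and rid in b_map
    ]
    if exclude_termini:
        shared = shared[exclude_termini:-exclude_termini or None]
    if len(shared) < 3:
        raise ParameterError(f"need >= 3 shared residues, got {len(shared)}")
    xs, ys = map(np.array, zip(*shared))
    return float(pearsonr(xs, ys).statistic)
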