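"""Anisotropic network models (ANM) of single proteins on C-alpha nodes.

The ANM places every C-alpha on a node and connects node pairs closer than
a distance cutoff (default 13 Angstrom) with identical Hookean springs.
For a pair (i, j) at equilibrium separation ``d`` with unit direction
``r_ij``, the off-diagonal 3x3 Hessian block is ``-(gamma/d^2) r_ij r_ij^T``
(with ``r_ij`` the unnormalized difference vector, hence the ``1/d^2``);
diagonal blocks are minus the sum of the off-diagonals, which enforces
translational invariance.  Mean-square fluctuations come from the
pseudo-inverse over the non-rigid modes:

    msf_i = sum_k  (1/lambda_k) * |v_k restricted to node i|^2

The spring constant and the k_B*T prefactor are left out, so ANM RMSF
values are in arbitrary units; every downstream statistic (enrichment
factor, profile correlations) is invariant to this overall scale.

Coarse-grained networks exaggerate the motion of highly extended terminal
nodes (the "tip effect"); :func:`flag_tip_outliers` prunes such residues
with an iterative median + 5*IQR rule before any statistics are computed.

The module exposes both the low-level operations and a statsmodels-style
pair :class:`AnisotropicNetworkModel` / :class:`ANMResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import squareform, pdist

from .errors import (
    DegenerateSpectrumError,
    ParameterError,
    SpectralSanityError,
    TipFilterError,
)

__all__ = [
    "ANMConfig",
    "ModeSpectrum",
    "MobilityProfile",
    "AnisotropicNetworkModel",
    "ANMResults",
    "build_anm_hessian",
    "decompose_modes",
    "anm_rmsf",
    "flag_tip_outliers",
]


@dataclass(frozen=True)
class ANMConfig:
    """ANM parameters: interaction cutoff (Angstrom), spring constant, rigid-mode tolerance."""

    cutoff: float = 13.0
    gamma: float = 1.0
    zero_mode_tolerance: float = 1e-8  # relative to the largest eigenvalue

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ParameterError(f"cutoff must be positive, got {self.cutoff}")
        if self.gamma <= 0:
            raise ParameterError(f"gamma must be positive, got {self.gamma}")


@dataclass
class ModeSpectrum:
    n_nodes: int
    eigenvalues: np.ndarray  # ascending, length 3n
    eigenvectors: np.ndarray  # (3n, 3n), column k is mode k
    n_zero_modes: int

    @property
    def nonrigid(self) -> slice:
        return slice(self.n_zero_modes, None)


@dataclass
class MobilityProfile:
    """Per-residue scalar fluctuation values with an exclusion mask.

    ``source`` records provenance: ``anm`` (arbitrary units), ``ensemble``
    (Angstrom, from coordinate frames) or ``external`` (ingested table).
    """

    residue_ids: list
    rmsf: np.ndarray
    excluded: np.ndarray
    source: str = "anm"

    def __post_init__(self) -> None:
        self.rmsf = np.asarray(self.rmsf, dtype=float)
        self.excluded = np.asarray(self.excluded, dtype=bool)
        if self.rmsf.shape != (len(self.residue_ids),) or self.excluded.shape != self.rmsf.shape:
            raise ParameterError("residue_ids, rmsf and excluded must have equal length")
        if np.any(self.rmsf < 0) or not np.all(np.isfinite(self.rmsf)):
            raise ParameterError("rmsf values must be finite and non-negative")

    def __len__(self) -> int:
        return len(self.residue_ids)

    @property
    def active(self) -> np.ndarray:
        return ~self.excluded

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"residue_id": self.residue_ids, "rmsf": self.rmsf, "excluded": self.excluded}
        )


def _contact_matrix(coords: np.ndarray, cutoff: float) -> np.ndarray:
    d = squareform(pdist(coords))
    adj = (d <= cutoff) & ~np.eye(len(coords), dtype=bool)
    return adj


def build_anm_hessian(coords: np.ndarray, config: ANMConfig = ANMConfig()) -> np.ndarray:
    """Assemble the 3n x 3n ANM Hessian from C-alpha coordinates.

    Raises on fewer than two nodes; a disconnected network is allowed but
    reported via a warning (its extra rigid modes surface in
    :func:`decompose_modes`).
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ParameterError(f"coords must be (n, 3), got {coords.shape}")
    n = coords.shape[0]
    if n < 2:
        raise ParameterError("an elastic network needs at least 2 nodes")
    adj = _contact_matrix(coords, config.cutoff)
    n_comp, _ = connected_components(adj, directed=False)
    if n_comp > 1:
        import warnings

        warnings.warn(
            f"elastic network is disconnected ({n_comp} components) at "
            f"cutoff {config.cutoff} A",
            stacklevel=2,
        )
    hessian = np.zeros((3 * n, 3 * n))
    ii, jj = np.nonzero(np.triu(adj, k=1))
    for i, j in zip(ii, jj):
        rij = coords[j] - coords[i]
        d2 = float(rij @ rij)
        block = -(config.gamma / d2) * np.outer(rij, rij)
        hessian[3 * i : 3 * i + 3, 3 * j : 3 * j + 3] = block
        hessian[3 * j : 3 * j + 3, 3 * i : 3 * i + 3] = block
        hessian[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] -= block
        hessian[3 * j : 3 * j + 3, 3 * j : 3 * j + 3] -= block
    return hessian


def _expected_rigid_modes(coords: np.ndarray) -> int | None:
    """6 for a 3-D point cloud; None (no assertion) for degenerate geometries."""
    centered = coords - coords.mean(axis=0)
    rank = np.linalg.matrix_rank(centered, tol=1e-8)
    return 6 if rank == 3 else None


def decompose_modes(
    hessian: np.ndarray,
    config: ANMConfig = ANMConfig(),
    coords: np.ndarray | None = None,
) -> ModeSpectrum:
    """Eigendecomposition of the ANM Hessian with rigid-mode bookkeeping.

    Eigenvalues are sorted ascending; each eigenvector's sign is fixed so
    that its first component of non-negligible magnitude is positive, which
    makes the decomposition deterministic.  When ``coords`` are supplied
    for a connected, genuinely three-dimensional network, exactly six
    rigid modes are asserted.
    """
    hessian = np.asarray(hessian, dtype=float)
    if hessian.ndim != 2 or hessian.shape[0] != hessian.shape[1] or hessian.shape[0] % 3:
        raise ParameterError(f"hessian must be square 3n x 3n, got {hessian.shape}")
    if not np.allclose(hessian, hessian.T, atol=1e-10):
        raise ParameterError("hessian must be symmetric")
    vals, vecs = eigh(hessian)
    # deterministic sign convention
    for k in range(vecs.shape[1]):
        v = vecs[:, k]
        nz = np.nonzero(np.abs(v) > 1e-8 * np.max(np.abs(v)))[0]
        if nz.size and v[nz[0]] < 0:
            vecs[:, k] = -v
    vmax = float(vals[-1]) if vals[-1] > 0 else 1.0
    n_zero = int(np.sum(vals < config.zero_mode_tolerance * vmax))
    n = hessian.shape[0] // 3
    if coords is not None:
        coords = np.asarray(coords, dtype=float)
        adj = _contact_matrix(coords, config.cutoff)
        n_comp, _ = connected_components(adj, directed=False)
        expected = _expected_rigid_modes(coords)
        if n_comp == 1 and expected is not None and n_zero != expected:
            raise SpectralSanityError(
                f"connected 3-D network has {n_zero} rigid modes, expected {expected}"
            )
    return ModeSpectrum(
        n_nodes=n, eigenvalues=vals, eigenvectors=vecs, n_zero_modes=n_zero
    )


def anm_rmsf(spectrum: ModeSpectrum, residue_ids=None) -> MobilityProfile:
    """Per-residue RMSF from the non-rigid modes (arbitrary units).

    ``msf_i = sum_k (1/lambda_k) * (v_k,3i^2 + v_k,3i+1^2 + v_k,3i+2^2)``
    over non-rigid modes k; RMSF is its square root.
    """
    nr = spectrum.nonrigid
    vals = spectrum.eigenvalues[nr]
    if vals.size == 0:
        raise DegenerateSpectrumError("all modes are rigid; no fluctuations to report")
    vecs = spectrum.eigenvectors[:, nr]
    per_coord = (vecs**2) / vals[np.newaxis, :]
    msf = per_coord.sum(axis=1).reshape(spectrum.n_nodes, 3).sum(axis=1)
    if residue_ids is None:
        residue_ids = list(range(spectrum.n_nodes))
    return MobilityProfile(
        residue_ids=list(residue_ids),
        rmsf=np.sqrt(msf),
        excluded=np.zeros(spectrum.n_nodes, dtype=bool),
        source="anm",
    )


@dataclass
class TipFilterReport:
    flagged: list
    n_iterations: int
    threshold: float | None


def flag_tip_outliers(
    profile: MobilityProfile,
    iqr_factor: float = 5.0,
    max_fraction: float = 0.10,
    manual_exclusions=None,
) -> tuple[MobilityProfile, TipFilterReport]:
    """Mark tip-effect outliers: RMSF above median + ``iqr_factor``*IQR, iterated to a fixed point.

    A manual exclusion list of residue ids overrides the automatic rule
    entirely.  The automatic rule refuses (raises :class:`TipFilterError`)
    if it would exclude more than ``max_fraction`` of the residues.
    """
    if manual_exclusions is not None:
        manual = set(manual_exclusions)
        mask = np.array([rid in manual for rid in profile.residue_ids])
        missing = manual - set(profile.residue_ids)
        if missing:
            raise ParameterError(f"manual exclusions not in profile: {sorted(missing)!r}")
        out = replace(profile, excluded=profile.excluded | mask)
        return out, TipFilterReport(
            flagged=[r for r, m in zip(profile.residue_ids, mask) if m],
            n_iterations=0,
            threshold=None,
        )
    if len(profile) < 8:
        raise ParameterError("tip filtering needs at least 8 residues")
    excluded = profile.excluded.copy()
    threshold = None
    for iteration in range(1, len(profile) + 1):
        vals = profile.rmsf[~excluded]
        med = np.median(vals)
        q1, q3 = np.percentile(vals, [25, 75])
        threshold = med + iqr_factor * (q3 - q1)
        new = (~excluded) & (profile.rmsf > threshold)
        if not new.any():
            break
        excluded |= new
    flagged_mask = excluded & ~profile.excluded
    if flagged_mask.sum() > max_fraction * len(profile):
        raise TipFilterError(
            f"automatic tip rule would exclude {int(flagged_mask.sum())} of "
            f"{len(profile)} residues (> {max_fraction:.0%}); supply a manual list"
        )
    out = replace(profile, excluded=excluded)
    return out, TipFilterReport(
        flagged=[r for r, m in zip(profile.residue_ids, flagged_mask) if m],
        n_iterations=iteration,
        threshold=threshold,
    )


class AnisotropicNetworkModel:
    """ANM for one protein, built from C-alpha coordinates.

    Parameters
    ----------
    coords : (n, 3) array
        C-alpha coordinates in Angstrom.
    residue_ids : sequence, optional
        Identifier per node; defaults to 0..n-1.
    config : ANMConfig
        Cutoff, spring constant and rigid-mode tolerance.
    """

    def __init__(self, coords, residue_ids=None, config: ANMConfig = ANMConfig()):
        self.coords = np.asarray(coords, dtype=float)
        self.residue_ids = (
            list(residue_ids) if residue_ids is not None else list(range(len(self.coords)))
        )
        if len(self.residue_ids) != len(self.coords):
            raise ParameterError("residue_ids must match the number of coordinates")
        self.config = config

    @classmethod
    def from_chain(cls, chain, config: ANMConfig = ANMConfig()):
        """Build from a protein :class:`~riboflex.structure_io.ChainModel`."""
        from .structure_io import calpha_coordinates

        sel = calpha_coordinates(chain)
        return cls(sel.coords, residue_ids=sel.residue_ids, config=config)

    def fit(self, tip_filter: bool = True, manual_exclusions=None) -> "ANMResults":
        hessian = build_anm_hessian(self.coords, self.config)
        spectrum = decompose_modes(hessian, self.config, coords=self.coords)
        profile = anm_rmsf(spectrum, residue_ids=self.residue_ids)
        report = None
        if manual_exclusions is not None:
            profile, report = flag_tip_outliers(profile, manual_exclusions=manual_exclusions)
        elif tip_filter and len(profile) >= 8:
            profile, report = flag_tip_outliers(profile)
        return ANMResults(model=self, spectrum=spectrum, profile=profile, tip_report=report)


@dataclass
class ANMResults:
    """Fitted ANM: mode spectrum, per-residue mobility profile, tip-filter report."""

    model: AnisotropicNetworkModel
    spectrum: ModeSpectrum
    profile: MobilityProfile
    tip_report: TipFilterReport | None = None

    @property
    def rmsf(self) -> np.ndarray:
        return self.profile.rmsf

    def summary(self) -> pd.DataFrame:
        frame = self.profile.to_frame()
        frame["msf"] = frame["rmsf"] ** 2
        return frame
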