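"""Rigid-body superposition helpers (Kabsch-style optimal alignment).

The rotation is obtained from :func:`scipy.spatial.transform.Rotation.align_vectors`,
which solves the orthogonal Procrustes problem restricted to proper
rotations, so reflections are never introduced.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import AlignmentError, ParameterError

__all__ = ["superpose", "superposed_rmsd"]


def superpose(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares fit ``mobile`` onto ``reference``.

    Returns the transformed copy of ``mobile`` and the post-fit RMSD in the
    units of the inputs. Both arrays must be (n, 3) with matched rows.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise AlignmentError(
            f"coordinate sets must match in shape, got {mobile.shape} vs {reference.shape}"
        )
    n = mobile.shape[0]
    if n < 3:
        raise ParameterError("superposition needs at least 3 matched points")
    mob_c = mobile - mobile.mean(axis=0)
    ref_c = reference - reference.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref_c, mob_c)
    fitted = rot.apply(mob_c) + reference.mean(axis=0)
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - reference) ** 2, axis=1))))
    return fitted, rmsd


def superposed_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """RMSD between two matched coordinate sets after optimal superposition."""
    _, rmsd = superpose(a, b)
    return rmsd
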