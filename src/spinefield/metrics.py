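"""Lead-field comparison metrics and eigenfield orientation analysis.

Two field topographies (channel vectors) are compared with

* the symmetric relative error  RE(a, b) = |a - b| / (|a| + |b|)  in [0, 1]
  (0 identical, 1 maximally dissimilar, e.g. sign-flipped), and
* the squared Pearson correlation CC^2 in [0, 1], invariant to affine
  rescaling of either topography.

The orientation sensitivity of a source location is summarised by the SVD of
its cardinal-dipole triplet L = [l_x, l_y, l_z]: the columns of U are the
"eigenfields", the singular values their intensities, and the rows of the
right factor the source orientations that generate them.  The ratio s1/s2
measures how anisotropic the sensitivity is, and the angle between the first
orientation and the inferior-superior axis shows which current direction
dominates the measurable field.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "relative_error", "squared_correlation", "eigenfields",
    "principal_orientation_angle", "LeadFieldTriplet", "EigenfieldResult",
]


def relative_error(l_a: np.ndarray, l_b: np.ndarray) -> float:
    """Symmetric normalised L2 difference of two topographies, in [0, 1]."""
    l_a = np.asarray(l_a, dtype=np.float64).ravel()
    l_b = np.asarray(l_b, dtype=np.float64).ravel()
    if l_a.shape != l_b.shape:
        raise ValueError("topographies must have equal length")
    na, nb = np.linalg.norm(l_a), np.linalg.norm(l_b)
    if na == 0.0 and nb == 0.0:
        raise ValueError("relative error undefined for two zero topographies")
    return float(np.linalg.norm(l_a - l_b) / (na + nb))


def squared_correlation(l_a: np.ndarray, l_b: np.ndarray) -> float:
    """Squared Pearson correlation of two topographies, in [0, 1]."""
    l_a = np.asarray(l_a, dtype=np.float64).ravel()
    l_b = np.asarray(l_b, dtype=np.float64).ravel()
    if l_a.shape != l_b.shape or l_a.size < 2:
        raise ValueError("topographies must have equal length >= 2")
    da = l_a - l_a.mean()
    db = l_b - l_b.mean()
    na, nb = np.linalg.norm(da), np.linalg.norm(db)
    if na == 0.0 or nb == 0.0:
        raise ValueError("squared correlation undefined for a constant vector")
    return float(np.dot(da / na, db / nb) ** 2)


@dataclass
class LeadFieldTriplet:
    """Topographies of the three cardinal unit dipoles at one location."""

    L: np.ndarray   # (channels, 3)

    def __post_init__(self) -> None:
        self.L = np.asarray(self.L, dtype=np.float64)
        if self.L.ndim != 2 or self.L.shape[1] != 3 or self.L.shape[0] < 2:
            raise ValueError("triplet must be (channels >= 2, 3)")


@dataclass
class EigenfieldResult:
    """SVD of a lead-field triplet with deterministic sign fixing."""

    U: np.ndarray           # (channels, 3) orthonormal eigenfields
    S: np.ndarray           # (3,) descending singular values
    V: np.ndarray           # (3, 3) rows = source orientations
    ratio12: float
    ratio13: float

    def scaled_eigenfields(self) -> np.ndarray:
        """Un-normalised eigenfields (columns of U S), as plotted."""
        return self.U * self.S[None, :]


def eigenfields(triplet: LeadFieldTriplet | np.ndarray) -> EigenfieldResult:
    """SVD of the triplet; rows of V are the generating source orientations.

    Signs are fixed so each eigenfield's largest-magnitude channel is
    positive, making stored eigenfields reproducible.  Singular-value ratios
    use the descending order (ratio12 = s1/s2 >= 1); a rank-0 matrix raises.
    """
    if not isinstance(triplet, LeadFieldTriplet):
        triplet = LeadFieldTriplet(np.asarray(triplet))
    U, S, Vt = np.linalg.svd(triplet.L, full_matrices=False)
    if S[0] == 0.0:
        raise ValueError("rank-0 lead-field triplet")
    flip = np.sign(U[np.argmax(np.abs(U), axis=0), np.arange(3)])
    flip[flip == 0] = 1.0
    U = U * flip[None, :]
    V = Vt * flip[:, None]
    with np.errstate(divide="ignore"):
        r12 = S[0] / S[1] if S[1] > 0 else np.inf
        r13 = S[0] / S[2] if S[2] > 0 else np.inf
    return EigenfieldResult(U, S, V, float(r12), float(r13))


def principal_orientation_angle(result: EigenfieldResult,
                                axis: np.ndarray) -> float:
    """Acute angle (degrees) between the first orientation and ``axis``."""
    axis = np.asarray(axis, dtype=np.float64).ravel()
    n = np.linalg.norm(axis)
    if n == 0.0:
        raise ValueError("axis must be non-zero")
    c = abs(float(np.dot(result.V[0], axis / n))) / np.linalg.norm(result.V[0])
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))
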