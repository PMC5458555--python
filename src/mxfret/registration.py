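"""Donor/acceptor channel registration from matched fiducial beads.

In a two-colour TIRF setup the donor and acceptor images land on different
halves of the camera; multi-colour beads visible in both channels provide
matched point pairs from which the channel mapping is recovered.  A full
6-parameter affine transform is fitted by least squares — it subsumes the
similarity and translation models a split-view optical path can produce.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["AffineMap", "fit_affine", "apply_affine", "RegistrationError"]


class RegistrationError(ValueError):
    """Raised when the bead geometry cannot constrain an affine map."""


@dataclass
class AffineMap:
    """q = matrix @ p + offset, with the least-squares fit residual."""

    matrix: np.ndarray
    offset: np.ndarray
    residual_rms: float = 0.0
    n_points: int = 0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(2, 2)
        self.offset = np.asarray(self.offset, dtype=float).reshape(2)
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise RegistrationError("affine linear part is singular")

    def inverse(self) -> "AffineMap":
        inv = np.linalg.inv(self.matrix)
        return AffineMap(
            matrix=inv,
            offset=-inv @ self.offset,
            residual_rms=self.residual_rms,
            n_points=self.n_points,
        )

    def to_json(self, path=None) -> str:
        d = {
            "matrix": self.matrix.tolist(),
            "offset": self.offset.tolist(),
            "residual_rms": self.residual_rms,
            "n_points": self.n_points,
        }
        text = json.dumps(d, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, path) -> "AffineMap":
        with open(path) as fh:
            return cls(**json.load(fh))


def fit_affine(donor_points, acceptor_points) -> AffineMap:
    """Least-squares affine map taking donor-channel points to acceptor ones.

    Minimises ``sum || A p + b - q ||^2`` over the 6 affine parameters.
    Requires at least 3 non-collinear pairs; fewer than 10 pairs triggers a
    warning (sparse bead fields give poorly conditioned maps).
    """
    p = np.asarray(donor_points, dtype=float)
    q = np.asarray(acceptor_points, dtype=float)
    if p.shape != q.shape or p.ndim != 2 or p.shape[1] != 2:
        raise ValueError("point sets must be matching (n, 2) arrays")
    n = p.shape[0]
    if n < 3:
        raise RegistrationError("need at least 3 bead pairs")
    if n < 10:
        warnings.warn(
            f"only {n} bead pairs; at least 10 are recommended for a stable map",
            stacklevel=2,
        )
    design = np.column_stack([p, np.ones(n)])
    if np.linalg.matrix_rank(design) < 3:
        raise RegistrationError("bead positions are collinear")
    coeffs, *_ = np.linalg.lstsq(design, q, rcond=None)
    matrix = coeffs[:2].T
    offset = coeffs[2]
    residuals = q - (p @ matrix.T + offset)
    rms = float(np.sqrt(np.mean(np.sum(residuals**2, axis=1))))
    return AffineMap(matrix=matrix, offset=offset, residual_rms=rms, n_points=n)


def apply_affine(affine: AffineMap, points) -> np.ndarray:
    """Apply ``q = A p + b`` to an (n, 2) point set (or a single point)."""
    pts = np.asarray(points, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    out = pts @ affine.matrix.T + affine.offset
    return out[0] if single else out
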