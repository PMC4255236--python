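"""Penalized B-spline bases with shrinkage penalties.

P-spline construction: cubic B-splines on equally spaced knots with a
second-difference penalty on the coefficients.  The usual difference
penalty leaves a linear null space; a small identity "shrinkage" component
is added so that as the smoothing parameter grows the whole term — slope
included — shrinks to zero, letting the smoother select terms out of the
model entirely.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import BSpline


class BSplineBasis1D:
    """Cubic B-spline basis on an equally spaced knot grid over [lo, hi]."""

    def __init__(self, lo: float, hi: float, n_basis: int = 10, degree: int = 3):
        if n_basis <= degree:
            raise ValueError("n_basis must exceed the spline degree")
        if hi <= lo:
            hi = lo + 1.0  # degenerate covariate: harmless flat basis
        self.lo, self.hi, self.n_basis, self.degree = lo, hi, n_basis, degree
        n_seg = n_basis - degree
        h = (hi - lo) / n_seg
        interior = np.linspace(lo, hi, n_seg + 1)
        self.knots = np.concatenate([
            lo + h * np.arange(-degree, 0), interior,
            hi + h * np.arange(1, degree + 1)])

    @classmethod
    def for_data(cls, x, n_basis: int = 10, degree: int = 3) -> "BSplineBasis1D":
        x = np.asarray(x, dtype=float)
        return cls(float(np.nanmin(x)), float(np.nanmax(x)), n_basis, degree)

    def design(self, x) -> np.ndarray:
        # clip to the base interval; guard the edges against float drift
        lo = self.knots[self.degree]
        hi = self.knots[-self.degree - 1]
        x = np.clip(np.asarray(x, dtype=float), lo, hi)
        return BSpline.design_matrix(x, self.knots, self.degree,
                                     extrapolate=False).toarray()

    def penalty(self, shrinkage: float = 1e-2) -> np.ndarray:
        d2 = np.diff(np.eye(self.n_basis), n=2, axis=0)
        s = d2.T @ d2
        return s + shrinkage * np.eye(self.n_basis)


def tensor_design(bx: BSplineBasis1D, by: BSplineBasis1D, x, y) -> np.ndarray:
    """Row-wise tensor (Khatri-Rao) product design for a 2-D smooth."""
    dx = bx.design(x)
    dy = by.design(y)
    return (dx[:, :, None] * dy[:, None, :]).reshape(len(dx), -1)


def tensor_penalty(bx: BSplineBasis1D, by: BSplineBasis1D,
                   shrinkage: float = 1e-2) -> np.ndarray:
    sx = bx.penalty(0.0)
    sy = by.penalty(0.0)
    s = (np.kron(sx, np.eye(by.n_basis)) + np.kron(np.eye(bx.n_basis), sy))
    return s + shrinkage * np.eye(s.shape[0])
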