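"""Classical reference interpolators (linear and natural cubic spline).

The constrained split pulls each pair of child values toward a pair of
classical interpolation points ``(hu_l, hu_r)`` evaluated half a voxel
below and above the parent's center.  This module computes those reference
points, plus the *purely classical* split values used when comparing the
conserving method against plain linear / spline interpolation.

Profiles are 1D HU sequences along the processing axis with knots at
integer index coordinates (unit spacing); physical voxel size does not
enter the interpolation.  Out-of-range neighbors are replicate-padded
(``profile[-1] := profile[0]``, ``profile[n] := profile[n-1]``), which
keeps alpha bounded at volume boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
from scipy.interpolate import CubicSpline


@dataclass(frozen=True)
class SplinePiece:
    """One cubic segment of a fitted spline.

    ``coefficients`` are ``(c3, c2, c1, c0)`` in the local coordinate
    ``t = x - interval_index``, i.e. the piece evaluates as
    ``c3*t**3 + c2*t**2 + c1*t + c0`` for ``t`` in ``[0, 1]``.
    """

    interval_index: int
    coefficients: Tuple[float, float, float, float]

    def __call__(self, x: float) -> float:
        t = x - self.interval_index
        c3, c2, c1, c0 = self.coefficients
        return ((c3 * t + c2) * t + c1) * t + c0


class NaturalSpline:
    """Natural cubic spline through ``(i, profile[i])`` with unit knots.

    Callable on scalar or array coordinates.  Evaluations outside
    ``[0, n-1]`` use the nearest piece's polynomial (the resampler only
    ever steps half a voxel beyond the ends).  Degenerate profiles degrade
    gracefully: two points give the straight line, one point the constant.
    """

    def __init__(self, profile: Sequence[float]):
        y = np.asarray(profile, dtype=np.float64)
        if y.ndim != 1 or y.size == 0:
            raise ValueError("profile must be a non-empty 1D sequence")
        self._n = y.size
        if self._n == 1:
            self._const = float(y[0])
            self._cs = None
        else:
            x = np.arange(self._n, dtype=np.float64)
            # With 2 points the natural boundary condition yields the line.
            self._cs = CubicSpline(x, y, bc_type="natural", extrapolate=True)
            self._const = None

    def __call__(self, x):
        if self._cs is None:
            x = np.asarray(x, dtype=np.float64)
            out = np.full_like(x, self._const)
            return float(out) if out.ndim == 0 else out
        out = self._cs(x)
        return float(out) if np.ndim(out) == 0 else out

    @property
    def pieces(self) -> List[SplinePiece]:
        """The cubic segments, in ascending interval order."""
        if self._cs is None:
            return [SplinePiece(0, (0.0, 0.0, 0.0, self._const))]
        c = self._cs.c  # (4, n_intervals), highest degree first
        return [
            SplinePiece(i, tuple(float(v) for v in c[:, i]))
            for i in range(c.shape[1])
        ]


def _padded_neighbor(profile: np.ndarray, i: int) -> float:
    """profile[i] with replicate padding at both ends."""
    return float(profile[min(max(i, 0), profile.size - 1)])


def linear_face_refs(profile: Sequence[float], index: int) -> Tuple[float, float]:
    """Linear reference pair for the voxel at *index* of a 1D profile.

    ``hu_l`` is the midpoint average of the voxel and its lower-index
    neighbor, ``hu_r`` of the voxel and its upper-index neighbor;
    out-of-range neighbors replicate the edge value.
    """
    p = np.asarray(profile, dtype=np.float64)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("profile must be a non-empty 1D sequence")
    if not (0 <= index < p.size):
        raise IndexError(f"index {index} out of range for profile of length {p.size}")
    hu0 = float(p[index])
    hu_l = (_padded_neighbor(p, index - 1) + hu0) / 2.0
    hu_r = (hu0 + _padded_neighbor(p, index + 1)) / 2.0
    return (hu_l, hu_r)


def fit_natural_spline(profile: Sequence[float]) -> NaturalSpline:
    """Fit the unique natural cubic spline through ``(i, profile[i])``.

    Returns a :class:`NaturalSpline`; its ``pieces`` attribute exposes the
    per-interval cubic coefficients.  Evaluating at the knots reproduces
    the profile exactly.
    """
    return NaturalSpline(profile)


def spline_face_refs(profile: Sequence[float], index: int) -> Tuple[float, float]:
    """Spline reference pair: the natural spline evaluated at index -/+ 0.5."""
    p = np.asarray(profile, dtype=np.float64)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("profile must be a non-empty 1D sequence")
    if not (0 <= index < p.size):
        raise IndexError(f"index {index} out of range for profile of length {p.size}")
    s = NaturalSpline(p)
    return (s(index - 0.5), s(index + 0.5))


def classical_linear_split(hu_prev: float, hu0: float, hu_next: float) -> Tuple[float, float]:
    """Plain linear interpolation children: midpoints with each neighbor.

    Does not in general preserve the parent average; listed for comparison
    against the conserving split.
    """
    return ((hu_prev + hu0) / 2.0, (hu0 + hu_next) / 2.0)


def classical_spline_split(profile: Sequence[float], index: int = 1) -> Tuple[float, float]:
    """Plain natural-spline children for a 3-point profile.

    Returns the spline evaluated at ``index - 0.5`` and ``index + 0.5`` —
    for the canonical 3-point case, ``q1(0.5)`` and ``q2(1.5)``.
    """
    p = np.asarray(profile, dtype=np.float64)
    if p.size != 3:
        raise ValueError(f"classical_spline_split expects a length-3 profile, got {p.size}")
    s = NaturalSpline(p)
    return (s(index - 0.5), s(index + 0.5))
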