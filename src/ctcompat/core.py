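"""The constrained split: closed-form alpha, objective, and the delta audit.

Splitting a voxel of value ``hu0`` into two congruent halves must keep the
parent equal to the mean of the children (exponential X-ray attenuation
makes HU averages physical).  Writing the children as ``hu1 = hu0 - alpha``
and ``hu2 = hu0 + alpha`` bakes that constraint in; alpha is then chosen to
minimize the squared HU distance to a pair of classical reference points
``(hu_l, hu_r)``:

    f(alpha) = (hu0 - alpha - hu_l)^2 + (hu0 + alpha - hu_r)^2

a quadratic whose minimum is at ``alpha = (hu_r - hu_l) / 2`` — notably
independent of ``hu0``.  With the linear reference the two midpoint
averages cancel the center value and alpha reduces to
``(hu_next - hu_prev) / 4``.
"""

from __future__ import annotations

from typing import Optional

from ctcompat.volume import SplitComputation


def alpha_min(hu_l: float, hu_r: float) -> float:
    """Optimal half-difference of the children: ``(hu_r - hu_l) / 2``."""
    return (hu_r - hu_l) / 2.0


def alpha_from_neighbors(hu_prev: float, hu_next: float) -> float:
    """Optimal alpha for the linear reference: ``(hu_next - hu_prev) / 4``.

    Algebraically identical to ``alpha_min(*linear_face_refs(...))`` — the
    center value cancels out of the difference of midpoint averages.
    """
    return (hu_next - hu_prev) / 4.0


def split_voxel(
    hu0: float, alpha: float, clamp_floor: Optional[float] = None
) -> SplitComputation:
    """Split one voxel into ``(hu0 - alpha, hu0 + alpha)``.

    With *clamp_floor* set, any child below the floor is raised to it and
    the ``clamped`` flag records that the parent average is no longer
    exactly preserved.  ``hu_l``/``hu_r`` in the returned record are the
    implied symmetric references ``hu0 -/+ alpha``; use the reference
    interpolators when the true references matter.
    """
    hu1 = hu0 - alpha
    hu2 = hu0 + alpha
    clamped = False
    if clamp_floor is not None:
        if hu1 < clamp_floor:
            hu1 = clamp_floor
            clamped = True
        if hu2 < clamp_floor:
            hu2 = clamp_floor
            clamped = True
    return SplitComputation(
        hu0=hu0,
        hu_l=hu0 - alpha,
        hu_r=hu0 + alpha,
        alpha=alpha,
        hu1=hu1,
        hu2=hu2,
        clamped=clamped,
    )


def objective(alpha: float, hu0: float, hu_l: float, hu_r: float) -> float:
    """Squared HU distance of the constrained children to the references.

    Kept explicit as an independent oracle for the closed-form minimizer;
    the resampler never evaluates it.
    """
    d1 = hu0 - alpha - hu_l
    d2 = hu0 + alpha - hu_r
    return d1 * d1 + d2 * d2


def delta_measure(hu0: float, hu1: float, hu2: float) -> float:
    """Conservation defect: ``|(hu1 + hu2) / 2 - hu0|``.

    Zero exactly when the parent average is preserved; nonzero for
    classical linear/spline splits and for clamped conserving splits.
    """
    return abs((hu1 + hu2) / 2.0 - hu0)
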