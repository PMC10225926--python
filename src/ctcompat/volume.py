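"""Core data types for HU volumes, spacing metadata and configuration.

The array convention is ``values[z][y][x]`` (slice index first, then row,
then column), 0-based, with each voxel value located at the voxel center.
Logical dimensions are reported as ``(n_x, n_y, n_z)`` to match the way CT
series are usually described (in-plane resolution plus slice count).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional, Tuple

import numpy as np

#: Scanner floor: the HU value of air as most scanners encode it.
AIR_HU = -1024.0

REFERENCE_MODES = ("linear", "spline")
AXIS_ORDERS = ("x_then_y", "y_then_x")


@dataclass(frozen=True)
class VoxelSpacing:
    """Physical voxel sizes in millimetres.

    ``dx`` and ``dy`` are the in-plane pixel sizes; ``dz`` is the slice
    thickness.  All strictly positive.
    """

    dx: float
    dy: float
    dz: float

    def __post_init__(self) -> None:
        for name in ("dx", "dy", "dz"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"spacing component {name} must be finite and > 0, got {v}")

    def halved(self, axis: str) -> "VoxelSpacing":
        """Return a new spacing with the component along *axis* halved."""
        if axis not in ("x", "y", "z"):
            raise ValueError(f"unknown axis {axis!r}")
        key = "d" + axis
        return replace(self, **{key: getattr(self, key) / 2.0})

    def doubled(self, axis: str) -> "VoxelSpacing":
        if axis not in ("x", "y", "z"):
            raise ValueError(f"unknown axis {axis!r}")
        key = "d" + axis
        return replace(self, **{key: getattr(self, key) * 2.0})


@dataclass
class HUVolume:
    """A 3D Hounsfield-unit array plus its spacing metadata.

    ``values`` is indexed ``[z][y][x]``; ``dims`` is the logical
    ``(n_x, n_y, n_z)`` tuple derived from the array shape.
    ``declared_dims``, when given (e.g. parsed from a metadata file), must
    agree with the array shape; :func:`validate_volume` reports mismatches.
    """

    values: np.ndarray
    spacing: VoxelSpacing
    declared_dims: Optional[Tuple[int, int, int]] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"values must be a 3D array, got ndim={self.values.ndim}")

    @property
    def dims(self) -> Tuple[int, int, int]:
        """(n_x, n_y, n_z)."""
        n_z, n_y, n_x = self.values.shape
        return (n_x, n_y, n_z)

    @property
    def n_x(self) -> int:
        return self.values.shape[2]

    @property
    def n_y(self) -> int:
        return self.values.shape[1]

    @property
    def n_z(self) -> int:
        return self.values.shape[0]

    def copy(self) -> "HUVolume":
        return HUVolume(self.values.copy(), self.spacing)


@dataclass(frozen=True)
class InterpConfig:
    """Configuration of an upsampling run.

    Parameters
    ----------
    reference_mode:
        ``"linear"`` pulls child values toward the midpoint averages of the
        two axial neighbors; ``"spline"`` toward natural-cubic-spline
        evaluations at half-integer coordinates.
    clamp_floor:
        Children below this HU value are raised to it (``None`` disables
        clamping).  Defaults to air (-1024), the scanner floor.
    axis_order_xy:
        Order of the two 1D passes inside the in-plane ("XY") flavor.
    output_precision:
        Decimal places used when writing CSV series; ``None`` keeps full
        ``repr`` precision.
    """

    reference_mode: str = "linear"
    clamp_floor: Optional[float] = AIR_HU
    axis_order_xy: str = "x_then_y"
    output_precision: Optional[int] = None

    def __post_init__(self) -> None:
        if self.reference_mode not in REFERENCE_MODES:
            raise ValueError(
                f"reference_mode must be one of {REFERENCE_MODES}, got {self.reference_mode!r}"
            )
        if self.axis_order_xy not in AXIS_ORDERS:
            raise ValueError(
                f"axis_order_xy must be one of {AXIS_ORDERS}, got {self.axis_order_xy!r}"
            )


@dataclass(frozen=True)
class SplitComputation:
    """Per-voxel record of one constrained split.

    ``hu1 = hu0 - alpha`` and ``hu2 = hu0 + alpha`` before clamping, so the
    children average back to the parent exactly whenever ``clamped`` is
    false.
    """

    hu0: float
    hu_l: float
    hu_r: float
    alpha: float
    hu1: float
    hu2: float
    clamped: bool = False


@dataclass(frozen=True)
class ConservationReport:
    """Summary of how well an upsampling run preserved parent averages.

    ``max_delta`` / ``mean_delta`` are statistics of |mean(children) -
    parent| over all parent voxels; both are identically zero whenever no
    child was clamped.  ``n_clamped`` counts clamped child values.
    """

    max_delta: float
    mean_delta: float
    n_clamped: int
    n_voxels: int

    def merged(self, other: "ConservationReport") -> "ConservationReport":
        """Aggregate two passes (weighted mean, max of maxima, summed counts)."""
        n = self.n_voxels + other.n_voxels
        mean = (
            self.mean_delta * self.n_voxels + other.mean_delta * other.n_voxels
        ) / n
        return ConservationReport(
            max_delta=max(self.max_delta, other.max_delta),
            mean_delta=mean,
            n_clamped=self.n_clamped + other.n_clamped,
            n_voxels=n,
        )


def validate_volume(volume: HUVolume, clamp_floor: Optional[float] = None) -> List[str]:
    """Check an :class:`HUVolume` against its structural invariants.

    Returns a list of human-readable violation descriptions (empty when the
    volume is valid); never raises.  Each violation names the failed
    invariant and the first offending index in ``(z, y, x)`` order.  When
    *clamp_floor* is given, values below it are also reported -- useful for
    auditing volumes produced with clamping enabled.
    """
    violations: List[str] = []
    values = volume.values

    if values.ndim != 3:
        violations.append(f"values array must be 3D, got ndim={values.ndim}")
        return violations

    nonfinite = ~np.isfinite(values)
    if nonfinite.any():
        idx = tuple(int(i) for i in np.argwhere(nonfinite)[0])
        violations.append(f"non-finite value at (z, y, x)={idx}")

    if clamp_floor is not None:
        below = np.isfinite(values) & (values < clamp_floor)
        if below.any():
            idx = tuple(int(i) for i in np.argwhere(below)[0])
            violations.append(
                f"value below clamp floor {clamp_floor} at (z, y, x)={idx}"
            )

    if any(n < 1 for n in volume.dims):
        violations.append(f"dims must all be positive, got {volume.dims}")

    if volume.declared_dims is not None and tuple(volume.declared_dims) != volume.dims:
        violations.append(
            "declared dims "
            f"{tuple(volume.declared_dims)} do not match array shape-derived dims {volume.dims}"
        )

    return violations
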