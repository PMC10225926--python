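"""Synthetic HU phantoms and the one-dimensional method-comparison table.

Clinical CT series are rarely shareable, so tests and demos run on
phantoms with known structure instead: uniform blocks, axial ramps,
spheres, a crude multi-ellipse head-like slice, and seeded random noise.
Default HU magnitudes follow clinical convention (air -1000, water 0,
soft tissue ~40, bone ~700) purely for realism; they carry no special
meaning to the algorithms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from ctcompat.core import alpha_from_neighbors, delta_measure, split_voxel
from ctcompat.references import classical_linear_split, classical_spline_split
from ctcompat.volume import HUVolume, VoxelSpacing

PHANTOM_KINDS = ("uniform", "axial_ramp", "sphere", "shepp_like_ellipses", "random")

HU_RANGE = (-1024.0, 3071.0)


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for one synthetic volume.

    ``dims`` is ``(n_x, n_y, n_z)``.  Kind-specific parameters:

    * ``uniform``: ``value`` (HU everywhere).
    * ``axial_ramp``: ``ramp_start`` + ``ramp_slope`` HU per slice along z.
    * ``sphere``: ``center`` (z, y, x voxel coordinates; defaults to the
      volume center), ``radius`` in voxels, ``inside_hu`` / ``outside_hu``.
    * ``shepp_like_ellipses``: nested soft-tissue/bone/air ellipses, same
      pattern on every slice.
    * ``random``: uniform noise in ``[low, high]``, seeded by ``seed``.
    """

    kind: str
    dims: Tuple[int, int, int] = (8, 8, 8)
    spacing: VoxelSpacing = field(default_factory=lambda: VoxelSpacing(0.7, 0.7, 1.5))
    value: float = 0.0
    ramp_start: float = 0.0
    ramp_slope: float = 50.0
    center: Optional[Tuple[float, float, float]] = None
    radius: float = 2.5
    inside_hu: float = 700.0
    outside_hu: float = -1000.0
    low: float = -1000.0
    high: float = 2000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in PHANTOM_KINDS:
            raise ValueError(f"unknown phantom kind {self.kind!r}; expected one of {PHANTOM_KINDS}")
        if any(n < 1 for n in self.dims):
            raise ValueError(f"dims must be positive, got {self.dims}")


def generate(spec: PhantomSpec) -> HUVolume:
    """Build the phantom volume; deterministic for a given spec (and seed)."""
    n_x, n_y, n_z = spec.dims
    shape = (n_z, n_y, n_x)

    if spec.kind == "uniform":
        values = np.full(shape, float(spec.value))
    elif spec.kind == "axial_ramp":
        z = np.arange(n_z, dtype=np.float64)
        values = np.broadcast_to(
            (spec.ramp_start + spec.ramp_slope * z)[:, None, None], shape
        ).copy()
    elif spec.kind == "sphere":
        center = spec.center
        if center is None:
            center = ((n_z - 1) / 2.0, (n_y - 1) / 2.0, (n_x - 1) / 2.0)
        zz, yy, xx = np.indices(shape, dtype=np.float64)
        dist2 = (
            (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2
        )
        values = np.where(dist2 <= spec.radius**2, spec.inside_hu, spec.outside_hu)
    elif spec.kind == "shepp_like_ellipses":
        values = _shepp_like_slice(n_x, n_y)[None, :, :] * np.ones((n_z, 1, 1))
    elif spec.kind == "random":
        rng = np.random.default_rng(spec.seed)
        values = rng.uniform(spec.low, spec.high, size=shape)
    else:  # pragma: no cover - guarded by PhantomSpec validation
        raise ValueError(f"unknown phantom kind {spec.kind!r}")

    return HUVolume(np.ascontiguousarray(values, dtype=np.float64), spec.spacing)


def _shepp_like_slice(n_x: int, n_y: int) -> np.ndarray:
    """A crude head-like slice: air, a soft-tissue body ellipse, a bone rim
    and two internal low-density ellipses."""
    y, x = np.mgrid[0:n_y, 0:n_x].astype(np.float64)
    cy, cx = (n_y - 1) / 2.0, (n_x - 1) / 2.0
    ry, rx = max(n_y * 0.42, 1.0), max(n_x * 0.45, 1.0)

    def inside(fy: float, fx: float, oy: float = 0.0, ox: float = 0.0) -> np.ndarray:
        return ((y - cy - oy) / (ry * fy)) ** 2 + ((x - cx - ox) / (rx * fx)) ** 2 <= 1.0

    img = np.full((n_y, n_x), -1000.0)  # air
    img[inside(1.0, 1.0)] = 700.0       # bone rim
    img[inside(0.85, 0.85)] = 40.0      # soft tissue
    img[inside(0.3, 0.25, -n_y * 0.1, -n_x * 0.12)] = -200.0
    img[inside(0.3, 0.25, -n_y * 0.1, n_x * 0.12)] = -200.0
    return img


#: Reference values for the worked comparison table (hu0_b, then
#: hu1/hu2/delta for linear, spline, and conserving splits).  Used as a
#: self-check by the ``table1`` command; all entries are reproduced exactly
#: by :func:`table1_cases`.
TABLE1_EXPECTED: Tuple[Tuple[float, ...], ...] = (
    (-50, -25, 25, 50, -43.75, 6.25, 31.25, -75, -25, 0),
    (-40, -20, 30, 45, -36.875, 13.125, 28.125, -65, -15, 0),
    (-30, -15, 35, 40, -30, 20, 25, -55, -5, 0),
    (-20, -10, 40, 35, -23.125, 26.875, 21.875, -45, 5, 0),
    (-10, -5, 45, 30, -16.25, 33.75, 18.75, -35, 15, 0),
    (0, 0, 50, 25, -9.375, 40.625, 15.625, -25, 25, 0),
    (10, 5, 55, 20, -2.5, 47.5, 12.5, -15, 35, 0),
    (20, 10, 60, 15, 4.375, 54.375, 9.375, -5, 45, 0),
    (30, 15, 65, 10, 11.25, 61.25, 6.25, 5, 55, 0),
    (40, 20, 70, 5, 18.125, 68.125, 3.125, 15, 65, 0),
    (50, 25, 75, 0, 25, 75, 0, 25, 75, 0),
    (60, 30, 80, 5, 31.875, 81.875, 3.125, 35, 85, 0),
    (70, 35, 85, 10, 38.75, 88.75, 6.25, 45, 95, 0),
    (80, 40, 90, 15, 45.625, 95.625, 9.375, 55, 105, 0),
    (90, 45, 95, 20, 52.5, 102.5, 12.5, 65, 115, 0),
    (100, 50, 100, 25, 59.375, 109.375, 15.625, 75, 125, 0),
    (110, 55, 105, 30, 66.25, 116.25, 18.75, 85, 135, 0),
    (120, 60, 110, 35, 73.125, 123.125, 21.875, 95, 145, 0),
    (130, 65, 115, 40, 80, 130, 25, 105, 155, 0),
    (140, 70, 120, 45, 86.875, 136.875, 28.125, 115, 165, 0),
    (150, 75, 125, 50, 93.75, 143.75, 31.25, 125, 175, 0),
)


@dataclass(frozen=True)
class Table1Row:
    """One row of the worked 1D comparison of split methods.

    Three collinear equidistant segments carry HU values 0, ``hu0_b`` and
    100; the middle one is split in two.  Each method column holds
    ``(hu1, hu2, delta)`` where delta is the conservation defect of that
    method's children.
    """

    hu0_b: float
    linear: Tuple[float, float, float]
    spline: Tuple[float, float, float]
    ct: Tuple[float, float, float]


def table1_cases(
    hu0_a: float = 0.0,
    hu0_c: float = 100.0,
    hu0_b_values: Optional[Tuple[float, ...]] = None,
) -> List[Table1Row]:
    """Compute the 21-row comparison of linear, spline and conserving splits.

    For each middle value in -50..150 (step 10) the row holds the two
    children and the conservation defect delta for plain linear
    interpolation, natural cubic spline interpolation, and the conserving
    split (linear reference).  Delta is zero only for the conserving
    method, except where the profile is an exact ramp and all three
    coincide.
    """
    if hu0_b_values is None:
        hu0_b_values = tuple(float(v) for v in range(-50, 151, 10))

    rows: List[Table1Row] = []
    for hu0_b in hu0_b_values:
        lin1, lin2 = classical_linear_split(hu0_a, hu0_b, hu0_c)
        sp1, sp2 = classical_spline_split((hu0_a, hu0_b, hu0_c), index=1)
        split = split_voxel(hu0_b, alpha_from_neighbors(hu0_a, hu0_c), clamp_floor=None)
        rows.append(
            Table1Row(
                hu0_b=hu0_b,
                linear=(lin1, lin2, delta_measure(hu0_b, lin1, lin2)),
                spline=(sp1, sp2, delta_measure(hu0_b, sp1, sp2)),
                ct=(split.hu1, split.hu2, delta_measure(hu0_b, split.hu1, split.hu2)),
            )
        )
    return rows
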