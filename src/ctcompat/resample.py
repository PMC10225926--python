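"""Whole-volume resampling: Z and XY doubling flavors, chains, mean-pool
downsampling and conservation audits.

A pass along one axis replaces every voxel by two children whose mean is
the parent, so mean-pooling the output in adjacent pairs reproduces the
input bit-for-bit (as long as no child hit the clamp floor).  "Z" is a
single pass along the slice axis; "XY" is two sequential 1D passes (x then
y by default), which reuses the same per-voxel machinery and conserves by
construction.  Chains apply flavors left to right; spacing metadata halves
along each processed axis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Optional, Tuple, Union

import numpy as np
from scipy.interpolate import CubicSpline

from ctcompat.volume import ConservationReport, HUVolume, InterpConfig

#: map axis name -> numpy axis of the [z][y][x] array
_AXIS_INDEX = {"x": 2, "y": 1, "z": 0}

FLAVOR_TOKENS = ("Z", "XY")

#: absolute HU tolerance for "identical" round-trip comparisons
CONSERVATION_TOL = 1e-9


@dataclass(frozen=True)
class FlavorChain:
    """An ordered sequence of resolution-doubling flavors (Z and/or XY)."""

    tokens: Tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.tokens:
            raise ValueError("flavor chain must be non-empty")
        for t in self.tokens:
            if t not in FLAVOR_TOKENS:
                raise ValueError(
                    f"unknown flavor token {t!r}; expected one of {FLAVOR_TOKENS}"
                )

    @classmethod
    def parse(cls, text: str) -> "FlavorChain":
        """Parse a comma-separated chain, case-insensitively ("z, xy ,Z" is fine)."""
        tokens = tuple(t.strip().upper() for t in text.split(",") if t.strip())
        return cls(tokens)

    def __iter__(self) -> Iterator[str]:
        return iter(self.tokens)

    def __len__(self) -> int:
        return len(self.tokens)

    def __str__(self) -> str:
        return ",".join(self.tokens)


def _half_point_refs(
    profiles: np.ndarray, mode: str
) -> Tuple[np.ndarray, np.ndarray]:
    """Reference pairs (hu_l, hu_r) for every voxel of 1D profiles.

    *profiles* has the processing axis last.  Linear mode averages each
    voxel with its replicate-padded neighbors; spline mode evaluates the
    natural cubic spline (knots at integer indices) at the half-integer
    coordinates, using the nearest piece's polynomial half a voxel beyond
    the ends.
    """
    n = profiles.shape[-1]
    if mode == "linear":
        padded = np.concatenate(
            [profiles[..., :1], profiles, profiles[..., -1:]], axis=-1
        )
        hu_l = (padded[..., :-2] + profiles) / 2.0
        hu_r = (profiles + padded[..., 2:]) / 2.0
        return hu_l, hu_r
    if mode == "spline":
        if n == 1:
            return profiles.copy(), profiles.copy()
        x = np.arange(n, dtype=np.float64)
        cs = CubicSpline(x, profiles, axis=-1, bc_type="natural", extrapolate=True)
        halves = cs(np.arange(n + 1, dtype=np.float64) - 0.5)
        return halves[..., :-1], halves[..., 1:]
    raise ValueError(f"unknown reference mode {mode!r}")


def upsample_axis(
    volume: HUVolume, axis: str, config: Optional[InterpConfig] = None
) -> Tuple[HUVolume, ConservationReport]:
    """Double the volume along one axis by conserving voxel splits.

    Each parent voxel becomes two children ``hu0 -/+ alpha`` with alpha
    from the configured reference; the child carrying ``hu0 - alpha`` sits
    on the lower-index side, so it tracks the lower-index neighbor.
    Spacing along the axis is halved.  The report summarizes |mean(children)
    - parent| (nonzero only where clamping intervened) and the number of
    clamped child values.
    """
    if config is None:
        config = InterpConfig()
    if axis not in _AXIS_INDEX:
        raise ValueError(f"unknown axis {axis!r}; expected one of ('x', 'y', 'z')")
    ax = _AXIS_INDEX[axis]
    values = volume.values
    n = values.shape[ax]
    if n < 1:
        raise ValueError(f"cannot upsample axis {axis!r} of length 0")

    profiles = np.moveaxis(values, ax, -1)
    hu_l, hu_r = _half_point_refs(profiles, config.reference_mode)
    alpha = (hu_r - hu_l) / 2.0

    child_lo = profiles - alpha
    child_hi = profiles + alpha

    n_clamped = 0
    if config.clamp_floor is not None:
        floor = config.clamp_floor
        n_clamped = int((child_lo < floor).sum() + (child_hi < floor).sum())
        np.maximum(child_lo, floor, out=child_lo)
        np.maximum(child_hi, floor, out=child_hi)

    delta = np.abs((child_lo + child_hi) / 2.0 - profiles)
    report = ConservationReport(
        max_delta=float(delta.max()),
        mean_delta=float(delta.mean()),
        n_clamped=n_clamped,
        n_voxels=int(profiles.size),
    )

    out = np.empty(profiles.shape[:-1] + (2 * n,), dtype=np.float64)
    out[..., 0::2] = child_lo
    out[..., 1::2] = child_hi
    out = np.moveaxis(out, -1, ax)

    return HUVolume(np.ascontiguousarray(out), volume.spacing.halved(axis)), report


def upsample_z(
    volume: HUVolume, config: Optional[InterpConfig] = None
) -> Tuple[HUVolume, ConservationReport]:
    """The "Z" flavor: double the number of slices; slice thickness halves."""
    return upsample_axis(volume, "z", config)


def upsample_xy(
    volume: HUVolume, config: Optional[InterpConfig] = None
) -> Tuple[HUVolume, ConservationReport]:
    """The "XY" flavor: double in-plane resolution via two sequential 1D passes.

    Pass order follows ``config.axis_order_xy`` (x then y by default; the
    two orders differ in general).  Both passes conserve, so each parent's
    2x2 children average back to the parent when nothing was clamped.
    """
    if config is None:
        config = InterpConfig()
    order = ("x", "y") if config.axis_order_xy == "x_then_y" else ("y", "x")
    out, report = upsample_axis(volume, order[0], config)
    out, second = upsample_axis(out, order[1], config)
    return out, report.merged(second)


def _apply_flavor(
    volume: HUVolume, token: str, config: InterpConfig
) -> Tuple[HUVolume, ConservationReport]:
    if token == "Z":
        return upsample_z(volume, config)
    if token == "XY":
        return upsample_xy(volume, config)
    raise ValueError(f"unknown flavor token {token!r}")


def apply_chain(
    volume: HUVolume,
    chain: Union[FlavorChain, str, Iterable[str]],
    config: Optional[InterpConfig] = None,
) -> Tuple[HUVolume, ConservationReport]:
    """Apply a flavor chain left to right, aggregating conservation reports.

    "Z,XY,Z" quarters the slice thickness and halves the in-plane pixel
    sizes.  The chain is parsed and validated before any computation.
    """
    if config is None:
        config = InterpConfig()
    if isinstance(chain, str):
        chain = FlavorChain.parse(chain)
    elif not isinstance(chain, FlavorChain):
        chain = FlavorChain(tuple(chain))

    out = volume
    report: Optional[ConservationReport] = None
    for token in chain:
        out, r = _apply_flavor(out, token, config)
        report = r if report is None else report.merged(r)
    assert report is not None
    return out, report


def downsample_axis(volume: HUVolume, axis: str) -> HUVolume:
    """Halve the volume along one axis by averaging adjacent disjoint pairs.

    The exact inverse direction of the conserving upsampler: mean pooling
    an unclamped upsampled volume reproduces the original.  Spacing along
    the axis doubles.  The axis length must be even.
    """
    if axis not in _AXIS_INDEX:
        raise ValueError(f"unknown axis {axis!r}; expected one of ('x', 'y', 'z')")
    ax = _AXIS_INDEX[axis]
    n = volume.values.shape[ax]
    if n % 2 != 0:
        raise ValueError(
            f"axis {axis!r} has odd length {n}; cannot mean-pool in pairs"
        )
    profiles = np.moveaxis(volume.values, ax, -1)
    pooled = (profiles[..., 0::2] + profiles[..., 1::2]) / 2.0
    pooled = np.moveaxis(pooled, -1, ax)
    return HUVolume(np.ascontiguousarray(pooled), volume.spacing.doubled(axis))


def _downsample_flavor(volume: HUVolume, token: str) -> HUVolume:
    if token == "Z":
        return downsample_axis(volume, "z")
    if token == "XY":
        out = downsample_axis(volume, "y")
        return downsample_axis(out, "x")
    raise ValueError(f"unknown flavor token {token!r}")


def downsample_chain(
    volume: HUVolume, chain: Union[FlavorChain, str, Iterable[str]]
) -> HUVolume:
    """Undo a flavor chain by mean pooling, right to left."""
    if isinstance(chain, str):
        chain = FlavorChain.parse(chain)
    elif not isinstance(chain, FlavorChain):
        chain = FlavorChain(tuple(chain))
    out = volume
    for token in reversed(chain.tokens):
        out = _downsample_flavor(out, token)
    return out


def conservation_audit(
    parent: HUVolume,
    child: HUVolume,
    axis_or_flavor: Union[str, FlavorChain],
) -> ConservationReport:
    """Audit |mean(children) - parent| for an upsampled volume.

    *axis_or_flavor* is an axis name ("x", "y", "z"), a flavor token
    ("Z", "XY") or a chain ("Z,XY,Z"); the child dims must be the
    correspondingly doubled parent dims.  ``n_clamped`` here counts parent
    voxels whose defect exceeds the conservation tolerance (1e-9 HU).
    """
    if isinstance(axis_or_flavor, FlavorChain):
        pooled = downsample_chain(child, axis_or_flavor)
    else:
        text = str(axis_or_flavor)
        if text.lower() in _AXIS_INDEX:
            pooled = downsample_axis(child, text.lower())
        else:
            pooled = downsample_chain(child, FlavorChain.parse(text))

    if pooled.values.shape != parent.values.shape:
        raise ValueError(
            "child dims are not the doubled parent dims for "
            f"{axis_or_flavor!r}: pooled shape {pooled.values.shape} vs "
            f"parent shape {parent.values.shape}"
        )
    delta = np.abs(pooled.values - parent.values)
    return ConservationReport(
        max_delta=float(delta.max()),
        mean_delta=float(delta.mean()),
        n_clamped=int((delta > CONSERVATION_TOL).sum()),
        n_voxels=int(parent.values.size),
    )
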