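"""Shared image types, the Rodrigues distance and pixel neighborhoods.

Both connectivity filters walk over pixels using an adjacency relation
derived from the Rodrigues distance, a weighted sum of a Minkowski and a
Chebyshev term between pixel coordinates:

    d(a, b) = w1 * (|dr|**p + |dc|**p)**(1/p) + w2 * max(|dr|, |dc|)

With the standard weights ``w1 = w2 = p = 1`` a distance threshold
(`radius`) of 2 yields the 4-neighborhood and 3 yields the 8-neighborhood,
so the same parameterisation covers both classic pixel adjacencies and, for
larger radii, longer-range jumps.

Coordinates are 0-based, row-major ``(row, col)`` throughout the package;
image-style ``(x, y)`` positions are converted only at I/O boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import NamedTuple, Optional, Tuple

import numpy as np

Offset = Tuple[int, int]


class PixelCoord(NamedTuple):
    """A 0-based, row-major pixel position."""

    row: int
    col: int


@dataclass(frozen=True)
class NeighborhoodSpec:
    """Rodrigues-distance parameters plus the radius defining adjacency.

    Parameters
    ----------
    w1 : float
        Weight of the Minkowski (order ``p``) term. Nonnegative.
    w2 : float
        Weight of the Chebyshev (max) term. Nonnegative.
    p : float
        Minkowski order, ``>= 1``.
    radius : float
        Inclusive distance threshold: every nonzero offset whose Rodrigues
        distance from the origin is ``<= radius`` is a neighbor. With the
        default weights, ``radius=2`` gives 4-connectivity and ``radius=3``
        gives 8-connectivity (the package default — vessels run diagonally).
    """

    w1: float = 1.0
    w2: float = 1.0
    p: float = 1.0
    radius: float = 3.0

    def __post_init__(self) -> None:
        if self.w1 < 0 or self.w2 < 0:
            raise ValueError("w1 and w2 must be nonnegative")
        if self.w1 == 0 and self.w2 == 0:
            raise ValueError("w1 and w2 must not both be zero")
        if self.p < 1:
            raise ValueError("p must be >= 1")
        if self.radius <= 0:
            raise ValueError("radius must be positive")


#: Default adjacency used by both connectivity filters (8-connectivity).
DEFAULT_NEIGHBORHOOD = NeighborhoodSpec()


def rodrigues_distance(a, b, spec: NeighborhoodSpec = DEFAULT_NEIGHBORHOOD) -> float:
    """Rodrigues distance between two pixel coordinates.

    Evaluates ``w1 * (|dr|^p + |dc|^p)^(1/p) + w2 * max(|dr|, |dc|)`` in two
    dimensions. Symmetric, nonnegative, and zero iff ``a == b``.
    """
    dr = abs(a[0] - b[0])
    dc = abs(a[1] - b[1])
    if spec.p == 1:
        minkowski = float(dr + dc)
    else:
        minkowski = float((dr ** spec.p + dc ** spec.p) ** (1.0 / spec.p))
    return spec.w1 * minkowski + spec.w2 * float(max(dr, dc))


def _clockwise_angle(offset: Offset) -> float:
    """Angle of an offset measured clockwise from North (up = -row)."""
    dr, dc = offset
    return math.atan2(dc, -dr) % (2.0 * math.pi)


@lru_cache(maxsize=None)
def _canonical_offsets(w1: float, w2: float, p: float, radius: float) -> Tuple[Offset, ...]:
    spec = NeighborhoodSpec(w1=w1, w2=w2, p=p, radius=radius)
    # Brute-force enumeration over a window of side 2*ceil(radius)+1 is a
    # superset of any offset within `radius`: each unit of displacement
    # contributes at least min-step cost 1 for either weight configuration.
    reach = math.ceil(radius)
    offsets = []
    for dr in range(-reach, reach + 1):
        for dc in range(-reach, reach + 1):
            if (dr, dc) == (0, 0):
                continue
            if rodrigues_distance((0, 0), (dr, dc), spec) <= radius:
                offsets.append((dr, dc))
    # Canonical order: clockwise starting from North; nearer offsets first
    # within one direction. For radius=3 this is N, NE, E, SE, S, SW, W, NW.
    offsets.sort(key=lambda o: (_clockwise_angle(o), rodrigues_distance((0, 0), o, spec)))
    return tuple(offsets)


def neighborhood_offsets(
    spec: NeighborhoodSpec = DEFAULT_NEIGHBORHOOD,
    momentum: Optional[Offset] = None,
) -> Tuple[Offset, ...]:
    """Ordered neighbor offsets for a neighborhood specification.

    Returns every nonzero ``(drow, dcol)`` whose Rodrigues distance from the
    origin is at most ``spec.radius``, in a fixed deterministic order.

    When ``momentum`` (the offset of the previous move) is given, the list is
    rotated so that the momentum offset comes first and the rest follow in
    the canonical clockwise order — the traversal keeps the "momentum" of a
    brush stroke, preferring to continue in its previous direction.

    Raises
    ------
    ValueError
        If ``momentum`` is not itself a neighbor offset of ``spec``.
    """
    canonical = _canonical_offsets(spec.w1, spec.w2, spec.p, spec.radius)
    if momentum is None:
        return canonical
    momentum = (int(momentum[0]), int(momentum[1]))
    try:
        i = canonical.index(momentum)
    except ValueError:
        raise ValueError(
            f"momentum {momentum!r} is not a neighbor offset for {spec!r}"
        ) from None
    return canonical[i:] + canonical[:i]


def require_binary_mask(arr, name: str = "mask") -> np.ndarray:
    """Validate and return a 2-D boolean mask."""
    a = np.asarray(arr)
    if a.ndim != 2 or a.size == 0:
        raise ValueError(f"{name} must be a non-empty 2-D array, got shape {a.shape}")
    if a.dtype != bool:
        a = a.astype(bool)
    return a


def require_gray_image(arr, name: str = "image") -> np.ndarray:
    """Validate and return a 2-D uint8 gray image."""
    a = np.asarray(arr)
    if a.ndim != 2 or a.size == 0:
        raise ValueError(f"{name} must be a non-empty 2-D array, got shape {a.shape}")
    if a.dtype != np.uint8:
        if np.any((a < 0) | (a > 255)):
            raise ValueError(f"{name} values must lie in [0, 255]")
        a = a.astype(np.uint8)
    return a
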