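"""Synthetic binary vessel fixtures with known structure.

Generates vessel-tree masks (correlated random walks with controlled
widths, emulating a thresholded vesselness response), punches gaps of
known length and orientation along branch directions (emulating vessel
disconnections), and sprinkles isolated salt-noise pixels (the failure
mode of thresholded vesselness). Every operation is deterministic for a
fixed seed, so the whole test corpus is bit-reproducible without any
dataset download.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np

from .core import PixelCoord, require_binary_mask

# 8 compass headings in clockwise order starting from North
COMPASS: Tuple[Tuple[int, int], ...] = (
    (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)
)


@dataclass(frozen=True)
class VesselTreeSpec:
    """Parameters of the random vessel-tree generator.

    Branches are correlated random walks over the 8 compass headings: at
    each step the heading turns by ±45° with probability ``turn_prob``.
    The first branch starts at a random interior point; subsequent branches
    sprout from a random pixel of the existing centerline, so the tree is a
    single connected component. Branch width is stamped as a ``w``×``w``
    square around each centerline pixel.

    Walks keep a ``clearance`` of background pixels from every branch
    already drawn (except near their own sprout point): distinct vessel
    segments do not run alongside each other at sub-clearance separation,
    so the mask stays acyclic like a real vessel tree and a punched gap
    genuinely disconnects its branch. A branch is cut short when it cannot
    continue without violating the clearance.
    """

    image_size: Tuple[int, int] = (176, 176)
    n_branches: int = 7
    branch_length_range: Tuple[int, int] = (30, 70)
    width_range: Tuple[int, int] = (1, 2)
    turn_prob: float = 0.12
    clearance: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.image_size
        if h < 8 or w < 8:
            raise ValueError("image_size too small for vessel trees")
        if self.n_branches < 1:
            raise ValueError("n_branches must be >= 1")
        if not (0.0 <= self.turn_prob <= 1.0):
            raise ValueError("turn_prob must lie in [0, 1]")
        if self.branch_length_range[0] < 2 or self.width_range[0] < 1:
            raise ValueError("branch length must be >= 2 and width >= 1")


@dataclass(frozen=True)
class GapSpec:
    """Gaps to punch: ``n_gaps`` runs of ``gap_length_range`` pixels."""

    n_gaps: int = 10
    gap_length_range: Tuple[int, int] = (2, 3)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_gaps < 0:
            raise ValueError("n_gaps must be >= 0")
        if self.gap_length_range[0] < 1:
            raise ValueError("gap lengths must be >= 1")


@dataclass
class Fixture:
    """A test fixture: ground truth, observed mask and the injected defects.

    ``observed`` equals ``truth`` minus the punched gap pixels plus the
    noise pixels; every noise pixel is isolated (no foreground in its
    8-neighborhood).
    """

    truth: np.ndarray
    observed: np.ndarray
    gaps: List[Tuple[List[PixelCoord], int]] = field(default_factory=list)
    noise_pixels: List[PixelCoord] = field(default_factory=list)
    meta: dict = field(default_factory=dict)


def _stamp(mask: np.ndarray, r: int, c: int, width: int) -> None:
    h, w = mask.shape
    lo = -(width // 2)
    hi = width - width // 2
    r0, r1 = max(0, r + lo), min(h, r + hi)
    c0, c1 = max(0, c + lo), min(w, c + hi)
    mask[r0:r1, c0:c1] = True


def _walk_branch(mask, rng, spec, start, heading, length, width):
    """Trace one branch path without stamping; respects the clearance.

    Returns the centerline positions, possibly shorter than ``length`` if
    the branch runs out of clear space.
    """
    h, w = mask.shape
    margin = 2
    clr = spec.clearance
    r, c = start
    path = [(r, c)]
    for step in range(length - 1):
        if rng.random() < spec.turn_prob:
            heading = (heading + int(rng.choice((-1, 1)))) % 8
        dr, dc = COMPASS[heading]
        nr, nc = r + dr, c + dc
        # bounce off the frame: flip the offending heading component
        if not (margin <= nr <= h - 1 - margin) or not (margin <= nc <= w - 1 - margin):
            if not (margin <= nr <= h - 1 - margin):
                dr = -dr
            if not (margin <= nc <= w - 1 - margin):
                dc = -dc
            heading = COMPASS.index((dr, dc))
            nr, nc = r + dr, c + dc
            if not (margin <= nr <= h - 1 - margin and margin <= nc <= w - 1 - margin):
                break
        # clearance against previously drawn branches (the sprout origin
        # region is exempt while the branch leaves its parent)
        reach = width // 2 + clr
        r0, r1 = max(0, nr - reach), min(h, nr + reach + 1)
        c0, c1 = max(0, nc - reach), min(w, nc + reach + 1)
        win = mask[r0:r1, c0:c1]
        if win.any():
            sr, sc = path[0]
            exempt = step < 3 * (width // 2 + 1) + 2
            blocked = False
            for fr, fc in zip(*np.nonzero(win)):
                fr, fc = fr + r0, fc + c0
                if exempt and max(abs(fr - sr), abs(fc - sc)) <= reach + 2:
                    continue
                blocked = True
                break
            if blocked:
                break
        r, c = nr, nc
        path.append((r, c))
    return path


def generate_vessel_tree(spec: VesselTreeSpec) -> np.ndarray:
    """Draw a random vessel tree; deterministic for a fixed seed."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    margin = 2
    mask = np.zeros((h, w), dtype=bool)
    centerline: List[Tuple[int, int]] = []

    for b in range(spec.n_branches):
        length = int(rng.integers(spec.branch_length_range[0], spec.branch_length_range[1] + 1))
        width = int(rng.integers(spec.width_range[0], spec.width_range[1] + 1))
        best: List[Tuple[int, int]] = []
        for _attempt in range(10):
            heading = int(rng.integers(8))
            if b == 0:
                # start so that the straight-line extent of the branch fits
                dr, dc = COMPASS[heading]
                ext_r, ext_c = dr * (length - 1), dc * (length - 1)
                lo_r = margin - min(0, ext_r)
                hi_r = h - 1 - margin - max(0, ext_r)
                lo_c = margin - min(0, ext_c)
                hi_c = w - 1 - margin - max(0, ext_c)
                if hi_r < lo_r or hi_c < lo_c:  # branch longer than the frame
                    lo_r = hi_r = h // 2
                    lo_c = hi_c = w // 2
                start = (int(rng.integers(lo_r, hi_r + 1)), int(rng.integers(lo_c, hi_c + 1)))
            else:
                start = centerline[int(rng.integers(len(centerline)))]
            path = _walk_branch(mask, rng, spec, start, heading, length, width)
            if len(path) > len(best):
                best = path
            if len(path) >= min(length, 10):
                break
        for r, c in best:
            _stamp(mask, r, c, width)
        centerline.extend(best)

    return mask


def _local_direction(mask: np.ndarray, r: int, c: int, half: int = 4):
    """Principal direction of the foreground in a local window.

    Returns (unit vector, anisotropy ratio); the ratio is the quotient of
    the two covariance eigenvalues (>= 1 means elongated along the vector).
    """
    h, w = mask.shape
    r0, r1 = max(0, r - half), min(h, r + half + 1)
    c0, c1 = max(0, c - half), min(w, c + half + 1)
    ys, xs = np.nonzero(mask[r0:r1, c0:c1])
    pts = np.stack([ys + r0 - r, xs + c0 - c], axis=1).astype(float)
    if len(pts) < 3:
        return None
    cov = np.cov(pts.T)
    vals, vecs = np.linalg.eigh(cov)
    if vals[1] <= 1e-9:
        return None
    ratio = vals[1] / max(vals[0], 1e-9)
    u = vecs[:, 1]
    return u, ratio


def punch_gaps(mask, gspec: GapSpec) -> Fixture:
    """Remove ``n_gaps`` runs of foreground along local branch directions.

    Gap sites are chosen at elongated interior points of the mask so that
    the removed slab cuts across the full branch width and the bridge
    length needed to reconnect it is approximately the requested gap
    length. The removed pixels are recorded exactly.
    """
    truth = require_binary_mask(mask)
    if not truth.any():
        raise ValueError("cannot punch gaps into an empty mask")
    rng = np.random.default_rng(gspec.seed)
    observed = truth.copy()
    gaps: List[Tuple[List[PixelCoord], int]] = []

    if gspec.n_gaps == 0:
        return Fixture(truth=truth, observed=observed, gaps=gaps)

    h, w = truth.shape
    gmax = gspec.gap_length_range[1]
    # interior candidates: foreground with at least 2 foreground neighbors
    from scipy import ndimage

    nb = ndimage.convolve(truth.astype(np.int32), np.ones((3, 3), np.int32), mode="constant") - truth
    cand = np.argwhere(truth & (nb >= 2))
    if len(cand) == 0:
        raise ValueError("mask too small to host requested gaps")
    order = rng.permutation(len(cand))
    centers: List[Tuple[int, int]] = []
    min_sep = gmax + 4  # keeps slabs disjoint with foreground in between

    for idx in order:
        if len(gaps) >= gspec.n_gaps:
            break
        r, c = map(int, cand[idx])
        if any(max(abs(r - rr), abs(c - cc)) < min_sep for rr, cc in centers):
            continue
        est = _local_direction(observed, r, c)
        if est is None:
            continue
        u, ratio = est
        if ratio < 2.0:  # junction or blob: direction ill-defined
            continue
        g = int(rng.integers(gspec.gap_length_range[0], gspec.gap_length_range[1] + 1))
        # slab across the branch: |along| within the gap run, |perp| within
        # the *local branch width*, so the punched run is width x length and
        # the bridge needed to reconnect it is about the gap length
        half_win = g + 2
        r0, r1 = max(0, r - half_win), min(h, r + half_win + 1)
        c0, c1 = max(0, c - half_win), min(w, c + half_win + 1)
        win = observed[r0:r1, c0:c1]
        ys, xs = np.nonzero(win)
        rel = np.stack([ys + r0 - r, xs + c0 - c], axis=1).astype(float)
        along = rel @ u
        perp = rel @ np.array([-u[1], u[0]])
        # local half-width: grow the cross-section's perp interval from the
        # centre outward, so a parallel branch in the window is not cut
        section = np.sort(perp[np.abs(along) <= 0.6])
        if len(section) == 0:
            continue
        lo = hi = section[np.argmin(np.abs(section))]
        for v in section:
            if lo - 1.2 <= v <= hi + 1.2:
                lo, hi = min(lo, v), max(hi, v)
        base_width = max(abs(lo), abs(hi)) + 0.3
        half_len = (g - 1) / 2.0 + 0.45
        placed = False
        for half_width in (base_width, base_width + 0.5, base_width + 1.0):
            if half_width > 2.5:
                break
            sel = (np.abs(along) <= half_len) & (np.abs(perp) <= half_width)
            if not sel.any():
                continue
            # require remaining foreground on both sides of the slab
            side_a = (along > half_len) & (np.abs(perp) <= half_width)
            side_b = (along < -half_len) & (np.abs(perp) <= half_width)
            if not side_a.any() or not side_b.any():
                break
            # the slab must genuinely sever the branch: no 8-connected route
            # between the two sides inside the window once it is removed
            trial = win.copy()
            trial[ys[sel], xs[sel]] = False
            lab, _ = ndimage.label(trial, structure=np.ones((3, 3)))
            la = {int(v) for v in lab[ys[side_a], xs[side_a]] if v}
            lb = {int(v) for v in lab[ys[side_b], xs[side_b]] if v}
            if la & lb:
                continue  # partial cut; widen the slab and retry
            removed = [PixelCoord(int(ys[i] + r0), int(xs[i] + c0)) for i in np.nonzero(sel)[0]]
            for pr, pc in removed:
                observed[pr, pc] = False
            gaps.append((removed, g))
            centers.append((r, c))
            placed = True
            break
        if not placed:
            continue

    if len(gaps) < gspec.n_gaps:
        raise ValueError(
            f"mask too small to host {gspec.n_gaps} gaps (placed {len(gaps)})"
        )
    return Fixture(truth=truth, observed=observed, gaps=gaps)


def add_salt_noise(mask, density: float, seed: int) -> np.ndarray:
    """Add isolated single foreground pixels at the stated density.

    Candidate positions whose 8-neighborhood touches existing foreground
    (including previously added noise) are rejected, so every added pixel
    is a one-pixel connected component. Deterministic per seed.
    """
    m = require_binary_mask(mask).copy()
    if not (0.0 <= density <= 1.0):
        raise ValueError("density must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    h, w = m.shape
    n_target = int(round(density * h * w))
    if n_target == 0:
        return m
    count = 0
    for flat in rng.permutation(h * w):
        if count >= n_target:
            break
        r, c = divmod(int(flat), w)
        r0, r1 = max(0, r - 1), min(h, r + 2)
        c0, c1 = max(0, c - 1), min(w, c + 2)
        if m[r0:r1, c0:c1].any():
            continue
        m[r, c] = True
        count += 1
    return m


def build_fixture(
    tree_spec: VesselTreeSpec,
    gap_spec: Optional[GapSpec] = None,
    noise_density: float = 0.00025,
    noise_seed: int = 0,
) -> Fixture:
    """Compose tree generation, gap punching and salt noise into one fixture."""
    truth = generate_vessel_tree(tree_spec)
    if gap_spec is None:
        gap_spec = GapSpec(seed=tree_spec.seed)
    fx = punch_gaps(truth, gap_spec)
    noisy = add_salt_noise(fx.observed, noise_density, noise_seed)
    fx.noise_pixels = [PixelCoord(int(r), int(c)) for r, c in np.argwhere(noisy & ~fx.observed)]
    fx.observed = noisy
    fx.meta = {
        "tree_seed": tree_spec.seed,
        "gap_seed": gap_spec.seed,
        "noise_seed": noise_seed,
        "noise_density": noise_density,
    }
    return fx


def two_segment_fixture(
    direction: Tuple[int, int],
    gap_len: int,
    seg_len: int = 5,
    margin: int = 8,
) -> Fixture:
    """Two collinear segments of ``seg_len`` pixels separated by a gap.

    ``direction`` is one of the 8 compass offsets; the truth is a straight
    line of ``2*seg_len + gap_len`` pixels and the observed mask has the
    middle ``gap_len`` pixels removed. The canvas leaves ``margin`` pixels
    of background around the line so excursions are unconstrained.
    """
    if direction not in COMPASS:
        raise ValueError(f"direction must be one of {COMPASS}")
    if gap_len < 1 or seg_len < 1:
        raise ValueError("gap_len and seg_len must be >= 1")
    dr, dc = direction
    total = 2 * seg_len + gap_len
    ext_r, ext_c = abs(dr) * (total - 1), abs(dc) * (total - 1)
    h, w = ext_r + 2 * margin + 1, ext_c + 2 * margin + 1
    r = margin if dr >= 0 else h - 1 - margin
    c = margin if dc >= 0 else w - 1 - margin
    truth = np.zeros((h, w), dtype=bool)
    observed = np.zeros((h, w), dtype=bool)
    gap_pixels: List[PixelCoord] = []
    for k in range(total):
        pr, pc = r + k * dr, c + k * dc
        truth[pr, pc] = True
        if seg_len <= k < seg_len + gap_len:
            gap_pixels.append(PixelCoord(pr, pc))
        else:
            observed[pr, pc] = True
    return Fixture(truth=truth, observed=observed, gaps=[(gap_pixels, gap_len)])


def save_fixture(fx: Fixture, out_dir) -> None:
    """Export a fixture as paired PNGs plus a JSON sidecar."""
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    iio.imwrite(out / "observed.png", fx.observed.astype(np.uint8) * 255)
    iio.imwrite(out / "truth.png", fx.truth.astype(np.uint8) * 255)
    sidecar = {
        "meta": fx.meta,
        "gaps": [
            {"length": g, "pixels": [[int(p.row), int(p.col)] for p in px]}
            for px, g in fx.gaps
        ],
        "noise_pixels": [[int(p.row), int(p.col)] for p in fx.noise_pixels],
    }
    (out / "fixture.json").write_text(json.dumps(sidecar, indent=2))
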