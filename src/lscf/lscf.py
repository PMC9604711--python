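"""The Local-Sensitive Connectivity Filter (LS-CF).

The naive Connectivity Filter scores and cleans a binary vesselness mask
but cannot repair the disconnections the vesselness stage produces: a
broken branch stays broken. The LS-CF extends the flood-fill traversal
with a *tolerance*: from a vessel pixel the walk may step onto background
pixels ("excursions"), incrementing a tolerance counter per off-vessel
pixel visited, in the hope of regaining vessel a few pixels further on.
When an excursion does reach another vessel pixel, every background pixel
on the realized path is painted as vessel (the bridge), the two components
merge, and the walk continues on-vessel. Excursions that exhaust their
budget contribute nothing.

Two budgets bound an excursion:

``max_dist``
    The maximum excursion depth — the number of off-vessel pixels a single
    excursion path may contain, each step drawn from the Rodrigues
    neighborhood. A gap of length ``g`` along a branch is bridgeable iff
    ``g <= max_dist``, in any orientation.
``max_score``
    The cap on the tolerance counter — the total number of off-vessel
    pixels one excursion may visit (including abandoned side branches of
    the search). It resets whenever the walk regains vessel. For small
    ``max_dist`` the depth bound is reached first; ``max_score`` is the
    outer cap that keeps the search bounded when ``max_dist`` is large.

Traversal order is fully deterministic. Components are discovered in
raster order and each component is flood-filled completely before its
excursions are launched, so a component never "bridges" to itself through
the background and existing vessel bodies are never dilated: bridging adds
pixels only along successful excursion paths. An excursion departs from
every component pixel that has a reconnection target within reach (cut
branch ends first) and expands breadth-first by depth with neighbors
ordered momentum-first — the walk prefers to continue in the direction of
the stroke, emulating a brush — so the realized bridge is a shortest
admissible path and, on a severed straight branch, runs exactly along the
missing run of vessel.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .cf import threshold_scores
from .core import (
    DEFAULT_NEIGHBORHOOD,
    NeighborhoodSpec,
    neighborhood_offsets,
    require_binary_mask,
)


@dataclass(frozen=True)
class LSCFParams:
    """Tolerance and distance budgets governing gap bridging.

    Parameters
    ----------
    max_score : int
        Tolerance budget: maximum number of background pixels a single
        excursion may visit. ``0`` disables excursions entirely, making the
        LS-CF degenerate to the naive CF.
    max_dist : float
        Distance budget: maximum number of off-vessel pixels in one
        excursion path (the excursion depth). Non-integer values are
        truncated. ``0`` likewise disables excursions.

    The defaults (350 and 4) are the reference operating point for retinal
    imagery; raising them bridges longer gaps at the cost of connecting
    more noise.
    """

    max_score: int = 350
    max_dist: float = 4.0

    def __post_init__(self) -> None:
        if self.max_score < 0 or int(self.max_score) != self.max_score:
            raise ValueError("max_score must be a nonnegative integer")
        if self.max_dist < 0:
            raise ValueError("max_dist must be nonnegative")


@dataclass
class LSCFResult:
    """Output of the LS-CF traversal.

    Attributes
    ----------
    scores : numpy.ndarray of int64
        Connectivity score map; every pixel of a (merged) component carries
        the component's total cardinality, bridge pixels included.
    bridged : numpy.ndarray of bool
        Pixels painted vessel that were background in the input. Disjoint
        from the input foreground by construction.
    segmented : numpy.ndarray of bool or None
        Final thresholded mask; filled in by :func:`lscf_segment`.
    """

    scores: np.ndarray
    bridged: np.ndarray
    segmented: Optional[np.ndarray] = None


def ls_connectivity(
    mask,
    spec: NeighborhoodSpec = DEFAULT_NEIGHBORHOOD,
    params: LSCFParams = LSCFParams(),
) -> LSCFResult:
    """Run the local-sensitive connectivity traversal on a binary mask.

    Returns the score map and the bridged-pixel mask (before the final
    score threshold). With ``max_score=0`` or ``max_dist < 1`` the scores
    are identical to :func:`lscf.cf.connectivity_scores`.
    """
    fg = require_binary_mask(mask)
    occ = fg.copy()  # current foreground: input vessels plus painted bridges
    h, w = occ.shape
    visited = np.zeros((h, w), dtype=bool)
    bridged = np.zeros((h, w), dtype=bool)
    scores = np.zeros((h, w), dtype=np.int64)

    canonical = neighborhood_offsets(spec)
    # momentum-rotated neighbor orders, precomputed once
    order = {None: canonical}
    for i, off in enumerate(canonical):
        order[off] = canonical[i:] + canonical[:i]

    max_depth = int(params.max_dist)
    do_excursions = params.max_score >= 1 and max_depth >= 1
    win = max_depth + 2  # any reachable bridge target lies in this window

    def flood(r0: int, c0: int, mom0, out: list) -> None:
        """Flood-fill current foreground from (r0, c0); append
        (row, col, arrival momentum) in discovery order."""
        visited[r0, c0] = True
        stack = [(r0, c0, mom0)]
        while stack:
            r, c, mom = stack.pop()
            out.append((r, c, mom))
            for dr, dc in order[mom]:
                nr, nc = r + dr, c + dc
                if 0 <= nr < h and 0 <= nc < w and occ[nr, nc] and not visited[nr, nc]:
                    visited[nr, nc] = True
                    stack.append((nr, nc, (dr, dc)))

    def stroke_momentum(r: int, c: int, mom):
        """Momentum of the brush stroke at a departure pixel.

        The arrival offset zigzags on vessels wider than one pixel, so the
        stroke direction is estimated as the compass direction pointing
        from the local centroid of the component toward the pixel — at a
        cut branch end this is the outward continuation of the branch.
        Falls back to the arrival offset for interior pixels.
        """
        r0, r1 = max(0, r - 3), min(h, r + 4)
        c0, c1 = max(0, c - 3), min(w, c + 4)
        patch = occ[r0:r1, c0:c1] & visited[r0:r1, c0:c1]
        ys, xs = np.nonzero(patch)
        if len(ys) < 2:
            return mom
        vr = r - (float(ys.mean()) + r0)
        vc = c - (float(xs.mean()) + c0)
        if abs(vr) < 0.25 and abs(vc) < 0.25:
            return mom
        dr = 0 if abs(vr) < 0.4142 * abs(vc) else (1 if vr > 0 else -1)
        dc = 0 if abs(vc) < 0.4142 * abs(vr) else (1 if vc > 0 else -1)
        if (dr, dc) == (0, 0) or (dr, dc) not in order:
            return mom
        return (dr, dc)

    def targets_near(r: int, c: int) -> bool:
        """Any not-yet-traversed foreground within excursion reach of (r, c)?"""
        r0, r1 = max(0, r - win), min(h, r + win + 1)
        c0, c1 = max(0, c - win), min(w, c + win + 1)
        return bool(np.any(occ[r0:r1, c0:c1] & ~visited[r0:r1, c0:c1]))

    def excursion(seeds) -> Optional[tuple]:
        """One off-vessel excursion of the component.

        ``seeds`` are departure vessel pixels (with stroke momenta), in
        reverse discovery order — branch tips first. The search expands
        background pixels outward by depth (breadth-first): the frontier is
        seeded with every departure pixel's background neighbors in
        momentum-first order and each frontier pixel expands its neighbors
        momentum-first, so the realized bridge is a shortest admissible
        path from the component, with ties broken toward the stroke
        direction of the earliest departure. Each background pixel visited
        increments the tolerance counter; the excursion aborts when the
        counter would exceed ``max_score`` and stops deepening after
        ``max_dist`` off-vessel pixels. Returns (path, target, last_step)
        on success, None on failure.
        """
        tol = 0
        queue = deque()
        local = set()
        for pr, pc, mom in seeds:
            for dr, dc in order[mom]:
                nr, nc = pr + dr, pc + dc
                if 0 <= nr < h and 0 <= nc < w and not occ[nr, nc] and (nr, nc) not in local:
                    local.add((nr, nc))
                    queue.append((nr, nc, (dr, dc), 1, ((nr, nc),)))
        while queue:
            r, c, qmom, depth, path = queue.popleft()
            tol += 1
            if tol > params.max_score:
                return None  # tolerance budget exhausted
            offs = order[qmom]
            for dr, dc in offs:
                nr, nc = r + dr, c + dc
                if 0 <= nr < h and 0 <= nc < w and occ[nr, nc] and not visited[nr, nc]:
                    return path, (nr, nc), (dr, dc)
            if depth < max_depth:
                for dr, dc in offs:
                    nr, nc = r + dr, c + dc
                    if (
                        0 <= nr < h
                        and 0 <= nc < w
                        and not occ[nr, nc]
                        and (nr, nc) not in local
                    ):
                        local.add((nr, nc))
                        queue.append((nr, nc, (dr, dc), depth + 1, path + ((nr, nc),)))
        return None

    rows, cols = np.nonzero(occ)
    for r0, c0 in zip(rows.tolist(), cols.tolist()):
        if visited[r0, c0]:
            continue
        comp: list = []
        flood(r0, c0, None, comp)

        while do_excursions:
            # departures: pixels with a not-yet-traversed target in reach,
            # tips (reverse discovery order) first
            seeds = [
                (r, c, stroke_momentum(r, c, mom))
                for r, c, mom in reversed(comp)
                if targets_near(r, c)
            ]
            if not seeds:
                break
            hit = excursion(seeds)
            if hit is None:
                break
            path, (tr, tc), last = hit
            grown: list = []
            for i, (br, bc) in enumerate(path):
                if i > 0:
                    mom = (br - path[i - 1][0], bc - path[i - 1][1])
                elif len(path) > 1:  # direction of travel stands in for arrival
                    mom = (path[1][0] - br, path[1][1] - bc)
                else:
                    mom = last
                bridged[br, bc] = True
                occ[br, bc] = True
                visited[br, bc] = True
                grown.append((br, bc, mom))
            # the walker regains vessel and continues on it
            flood(tr, tc, last, grown)
            comp.extend(grown)

        n = len(comp)
        for r, c, _ in comp:
            scores[r, c] = n

    return LSCFResult(scores=scores, bridged=bridged)


def lscf_segment(
    mask,
    spec: NeighborhoodSpec = DEFAULT_NEIGHBORHOOD,
    params: LSCFParams = LSCFParams(),
    s_min: int = 1,
) -> np.ndarray:
    """Full LS-CF pipeline stage: traversal followed by the score threshold.

    Equivalent to ``threshold_scores(ls_connectivity(...).scores, s_min)``;
    the output is contained in the union of the input foreground and the
    bridged pixels (scores are zero elsewhere).
    """
    result = ls_connectivity(mask, spec=spec, params=params)
    segmented = threshold_scores(result.scores, s_min)
    result.segmented = segmented
    return segmented
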