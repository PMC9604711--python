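"""The Connectivity Filter (CF).

The CF takes a binary vessel mask (typically a thresholded vesselness
response) and assigns every foreground pixel a *connectivity score*: the
number of foreground pixels reachable from it under the chosen adjacency,
i.e. the cardinality of its connected component (a pixel counts itself).
Thresholding the score map then deletes small components — an isolated
pixel scores 1 and is removed by the default threshold "score > 1", which
is exactly the salt noise a thresholded vesselness response produces.

Scores are kept as unbounded integers; retinal vessel trees routinely
exceed 255 pixels, and the score threshold must act on true counts.
Clamping to 8 bits happens only when rendering for display/export.
"""

from __future__ import annotations

import numpy as np

from .core import DEFAULT_NEIGHBORHOOD, NeighborhoodSpec, neighborhood_offsets, require_binary_mask


def connectivity_scores(
    mask, spec: NeighborhoodSpec = DEFAULT_NEIGHBORHOOD
) -> np.ndarray:
    """Per-pixel connectivity scores of a binary mask.

    Flood-fills each connected component under ``spec`` adjacency with an
    explicit worklist (no recursion, so component size is never limited by
    call-stack depth) and writes the component's pixel count to every one of
    its pixels. Background pixels score 0.

    Parameters
    ----------
    mask : array-like of bool, shape (H, W)
        Binary vessel mask.
    spec : NeighborhoodSpec
        Pixel adjacency; the default is 8-connectivity.

    Returns
    -------
    numpy.ndarray of int64, shape (H, W)
        The score map. The result does not depend on the order in which
        seed pixels are processed: scores are a per-component property.
    """
    fg = require_binary_mask(mask)
    h, w = fg.shape
    offsets = neighborhood_offsets(spec)
    visited = np.zeros((h, w), dtype=bool)
    scores = np.zeros((h, w), dtype=np.int64)

    rows, cols = np.nonzero(fg)
    for r0, c0 in zip(rows.tolist(), cols.tolist()):
        if visited[r0, c0]:
            continue
        # iterative flood fill of one component
        comp = [(r0, c0)]
        visited[r0, c0] = True
        stack = [(r0, c0)]
        while stack:
            r, c = stack.pop()
            for dr, dc in offsets:
                nr, nc = r + dr, c + dc
                if 0 <= nr < h and 0 <= nc < w and fg[nr, nc] and not visited[nr, nc]:
                    visited[nr, nc] = True
                    comp.append((nr, nc))
                    stack.append((nr, nc))
        n = len(comp)
        for r, c in comp:
            scores[r, c] = n
    return scores


def threshold_scores(scores, s_min: int = 1) -> np.ndarray:
    """Binary mask of pixels whose connectivity score is strictly > ``s_min``.

    The default ``s_min=1`` removes exactly the isolated single pixels
    (score 1) while keeping every component of two or more pixels. With
    ``s_min=0`` the output equals the foreground support of the score map.
    The threshold is configurable for other segmentation scenarios.
    """
    s = np.asarray(scores)
    if s.ndim != 2:
        raise ValueError(f"score map must be 2-D, got shape {s.shape}")
    if s_min < 0 or int(s_min) != s_min:
        raise ValueError("s_min must be a nonnegative integer")
    return s > int(s_min)


def render_scores_8bit(scores) -> np.ndarray:
    """Clamp a score map to [0, 255] for display as a gray-level image.

    Large components saturate at 255; the raw score map itself is never
    clamped internally.
    """
    s = np.asarray(scores)
    if s.ndim != 2:
        raise ValueError(f"score map must be 2-D, got shape {s.shape}")
    if np.any(s < 0):
        raise ValueError("score map must be nonnegative")
    return np.minimum(s, 255).astype(np.uint8)
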