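"""Point-to-polyline distance, vectorized and memory-bounded."""

from __future__ import annotations

import numpy as np


def polyline_distances(
    points: np.ndarray, vertices: np.ndarray, chunk: int = 256
) -> np.ndarray:
    """Minimum Euclidean distance from each point to an open polyline.

    ``points`` is (n, 2), ``vertices`` (m, 2) with m >= 2.  Distances are to
    the nearest point on any segment (orthogonal projection clamped to the
    segment), not merely to the nearest vertex.  Work is chunked over points
    to keep the (chunk, m) intermediates small.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    vertices = np.asarray(vertices, dtype=float)
    if vertices.ndim != 2 or vertices.shape[0] < 2 or vertices.shape[1] != 2:
        raise ValueError("polyline needs at least 2 (x, y) vertices")
    a = vertices[:-1]
    ab = np.diff(vertices, axis=0)
    ab_len2 = np.einsum("ij,ij->i", ab, ab)
    ab_len2 = np.where(ab_len2 == 0.0, 1.0, ab_len2)  # degenerate segments
    out = np.empty(len(points))
    for lo in range(0, len(points), chunk):
        p = points[lo : lo + chunk]
        diff = p[:, None, :] - a[None, :, :]
        s = np.clip(np.einsum("pij,ij->pi", diff, ab) / ab_len2[None], 0.0, 1.0)
        closest = a[None] + s[..., None] * ab[None]
        d2 = ((p[:, None, :] - closest) ** 2).sum(-1)
        out[lo : lo + chunk] = np.sqrt(d2.min(axis=1))
    return out
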