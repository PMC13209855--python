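"""Minimum enclosing circle of a planar point set.

The smallest circle containing every point of a particle's contour gives a
diameter estimate that is robust to partial lateral occlusion: as long as
more than half of a spherical particle's silhouette is visible, the visible
arc still pins down the full circle.  This module implements Welzl's
randomized incremental algorithm (expected O(n)) with a seeded shuffle so
output is deterministic for a fixed point set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Circle", "min_enclosing_circle", "min_enclosing_circle_bruteforce"]

# Relative containment tolerance used both internally and by Circle.contains.
_REL_TOL = 1e-7


@dataclass(frozen=True)
class Circle:
    """A circle in (row, col) pixel coordinates."""

    center: tuple[float, float]
    radius: float

    @property
    def diameter(self) -> float:
        return 2.0 * self.radius

    def contains(self, point, tol: float = _REL_TOL) -> bool:
        """True if *point* lies within ``radius * (1 + tol)`` of the center."""
        d = np.hypot(point[0] - self.center[0], point[1] - self.center[1])
        return d <= self.radius * (1.0 + tol) + 1e-12


def _circle_two(p, q) -> Circle:
    c = ((p[0] + q[0]) / 2.0, (p[1] + q[1]) / 2.0)
    r = np.hypot(p[0] - q[0], p[1] - q[1]) / 2.0
    return Circle(c, float(r))


def _circumcircle(a, b, c) -> Circle:
    """Circle through three points; for (near-)collinear triples fall back to
    the largest two-point circle, which is the correct enclosing circle."""
    ax, ay = a
    bx, by = b
    cx, cy = c
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    scale = max(abs(ax), abs(ay), abs(bx), abs(by), abs(cx), abs(cy), 1.0)
    if abs(d) < 1e-12 * scale * scale:
        cands = [_circle_two(a, b), _circle_two(a, c), _circle_two(b, c)]
        return max(cands, key=lambda circ: circ.radius)
    a2 = ax * ax + ay * ay
    b2 = bx * bx + by * by
    c2 = cx * cx + cy * cy
    ux = (a2 * (by - cy) + b2 * (cy - ay) + c2 * (ay - by)) / d
    uy = (a2 * (cx - bx) + b2 * (ax - cx) + c2 * (bx - ax)) / d
    r = np.hypot(ax - ux, ay - uy)
    return Circle((float(ux), float(uy)), float(r))


def _inside(c: Circle, p) -> bool:
    return np.hypot(p[0] - c.center[0], p[1] - c.center[1]) <= c.radius * (
        1.0 + 1e-10
    ) + 1e-12


def min_enclosing_circle(points, seed: int = 0) -> Circle:
    """Smallest circle containing all *points* (an (n, 2) array-like).

    Uses Welzl's move-to-front algorithm on a seeded shuffle of the input,
    so the result is deterministic for a fixed point set and seed.

    Raises
    ------
    ValueError
        If the point set is empty or not 2-D.
    """
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        raise ValueError("min_enclosing_circle requires at least one point")
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError(f"expected an (n, 2) point array, got shape {pts.shape}")

    pts = pts[np.random.default_rng(seed).permutation(len(pts))]
    pts = [tuple(p) for p in pts]

    c = Circle(pts[0], 0.0)
    for i in range(1, len(pts)):
        if not _inside(c, pts[i]):
            c = _mec_with_one(pts[:i], pts[i])
    return c


def _mec_with_one(pts, p) -> Circle:
    c = Circle(p, 0.0)
    for j in range(len(pts)):
        if not _inside(c, pts[j]):
            c = _mec_with_two(pts[:j], p, pts[j])
    return c


def _mec_with_two(pts, p, q) -> Circle:
    c = _circle_two(p, q)
    for r in pts:
        if not _inside(c, r):
            c = _circumcircle(p, q, r)
    return c


def min_enclosing_circle_bruteforce(points) -> Circle:
    """O(n^4) reference: the minimum over all circles determined by point
    pairs (as diameters) and triples (as circumcircles) that cover the set.

    Exists purely as an independent oracle for tests; do not use on large
    inputs.
    """
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        raise ValueError("empty point set")
    if len(pts) == 1:
        return Circle((float(pts[0][0]), float(pts[0][1])), 0.0)

    n = len(pts)
    best: Circle | None = None

    def covers(c: Circle) -> bool:
        d = np.hypot(pts[:, 0] - c.center[0], pts[:, 1] - c.center[1])
        return bool(np.all(d <= c.radius * (1.0 + _REL_TOL) + 1e-12))

    for i in range(n):
        for j in range(i + 1, n):
            c = _circle_two(tuple(pts[i]), tuple(pts[j]))
            if covers(c) and (best is None or c.radius < best.radius):
                best = c
    for i in range(n):
        for j in range(i + 1, n):
            for k in range(j + 1, n):
                c = _circumcircle(tuple(pts[i]), tuple(pts[j]), tuple(pts[k]))
                if covers(c) and (best is None or c.radius < best.radius):
                    best = c
    assert best is not None
    return best
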