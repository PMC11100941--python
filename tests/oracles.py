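"""Independent brute-force oracles used by the tests.

These deliberately re-derive geometry from first principles (no calls into
the package's distance/winding code paths) so agreement is meaningful.
"""

from __future__ import annotations

import numpy as np


def point_triangle_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Exact distance from point p to triangle (a, b, c) (Ericson's method)."""
    ab, ac, ap = b - a, c - a, p - a
    d1, d2 = ab @ ap, ac @ ap
    if d1 <= 0 and d2 <= 0:
        return float(np.linalg.norm(p - a))
    bp = p - b
    d3, d4 = ab @ bp, ac @ bp
    if d3 >= 0 and d4 <= d3:
        return float(np.linalg.norm(p - b))
    vc = d1 * d4 - d3 * d2
    if vc <= 0 and d1 >= 0 and d3 <= 0:
        v = d1 / (d1 - d3)
        return float(np.linalg.norm(p - (a + v * ab)))
    cp = p - c
    d5, d6 = ab @ cp, ac @ cp
    if d6 >= 0 and d5 <= d6:
        return float(np.linalg.norm(p - c))
    vb = d5 * d2 - d1 * d6
    if vb <= 0 and d2 >= 0 and d6 <= 0:
        w = d2 / (d2 - d6)
        return float(np.linalg.norm(p - (a + w * ac)))
    va = d3 * d6 - d5 * d4
    if va <= 0 and (d4 - d3) >= 0 and (d5 - d6) >= 0:
        w = (d4 - d3) / ((d4 - d3) + (d5 - d6))
        return float(np.linalg.norm(p - (b + w * (c - b))))
    denom = 1.0 / (va + vb + vc)
    v = vb * denom
    w = vc * denom
    return float(np.linalg.norm(p - (a + v * ab + w * ac)))


def brute_unsigned_distance(vertices: np.ndarray, faces: np.ndarray, points: np.ndarray) -> np.ndarray:
    out = np.empty(len(points))
    tris = vertices[faces]
    for i, p in enumerate(points):
        out[i] = min(point_triangle_distance(p, *t) for t in tris)
    return out


def brute_winding_sign(vertices: np.ndarray, faces: np.ndarray, points: np.ndarray) -> np.ndarray:
    """-1 inside / +1 outside via per-triangle solid angles (loop form)."""
    out = np.empty(len(points))
    for i, p in enumerate(points):
        total = 0.0
        for f in faces:
            a, b, c = vertices[f] - p
            la, lb, lc = np.linalg.norm(a), np.linalg.norm(b), np.linalg.norm(c)
            num = a @ np.cross(b, c)
            den = la * lb * lc + (a @ b) * lc + (b @ c) * la + (c @ a) * lb
            total += 2.0 * np.arctan2(num, den)
        out[i] = -1.0 if total / (4.0 * np.pi) >= 0.5 else 1.0
    return out


def brute_signed_distance(vertices: np.ndarray, faces: np.ndarray, points: np.ndarray) -> np.ndarray:
    return brute_winding_sign(vertices, faces, points) * brute_unsigned_distance(
        vertices, faces, points
    )


def brute_assd(va, fa, vb, fb) -> float:
    d_ab = brute_unsigned_distance(vb, fb, va)
    d_ba = brute_unsigned_distance(va, fa, vb)
    return float((d_ab.sum() + d_ba.sum()) / (len(d_ab) + len(d_ba)))
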