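"""Independent brute-force oracles the fast implementations are checked against.

These deliberately avoid the package's vectorized code paths: plain
Python loops, scalar math, and matrix inverses computed numerically.
"""

import math

import numpy as np


# ---------------------------------------------------------------------------
# ray casting


def _ray_collider_distance(origin, direction, collider):
    """All positive intersection distances of one ray with one collider."""
    from gaze3d.geometry import Box, Quad, Sphere

    m_inv = np.linalg.inv(collider.pose.matrix)
    o = m_inv[:3, :3] @ origin + m_inv[:3, 3]
    d = m_inv[:3, :3] @ direction
    shape = collider.shape
    ts = []
    if isinstance(shape, Sphere):
        a = float(d @ d)
        b = 2.0 * float(o @ d)
        c = float(o @ o) - shape.radius**2
        disc = b * b - 4 * a * c
        if disc >= 0:
            for sign in (-1.0, 1.0):
                t = (-b + sign * math.sqrt(disc)) / (2 * a)
                if t > 1e-9:
                    ts.append(t)
    elif isinstance(shape, Quad):
        if abs(d[2]) > 1e-9:
            t = -o[2] / d[2]
            x, y = o[0] + t * d[0], o[1] + t * d[1]
            if t > 1e-9 and abs(x) <= shape.width / 2 and abs(y) <= shape.height / 2:
                ts.append(t)
    elif isinstance(shape, Box):
        h = shape.half_extents
        lo, hi = -np.inf, np.inf
        ok = True
        for k in range(3):
            if abs(d[k]) < 1e-9:
                if abs(o[k]) > h[k]:
                    ok = False
                    break
                continue
            t1, t2 = (-h[k] - o[k]) / d[k], (h[k] - o[k]) / d[k]
            lo, hi = max(lo, min(t1, t2)), min(hi, max(t1, t2))
        if ok and lo <= hi and lo > 1e-9:
            ts.append(lo)
    return ts


def cast_ray_bruteforce(origin, direction, colliders, aoi_only=False):
    """Intersect every eligible collider, then take the global minimum."""
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    origin = np.asarray(origin, dtype=float)
    best = (np.inf, None)
    for coll in colliders:
        if aoi_only and not coll.is_aoi:
            continue
        for t in _ray_collider_distance(origin, direction, coll):
            if t < best[0]:
                best = (t, coll)
    if best[1] is None:
        return None
    return best[0], best[1].name


# ---------------------------------------------------------------------------
# I-DT window loop


def _angle_deg(u, v):
    du = math.sqrt(u[0] ** 2 + u[1] ** 2 + u[2] ** 2)
    dv = math.sqrt(v[0] ** 2 + v[1] ** 2 + v[2] ** 2)
    dot = (u[0] * v[0] + u[1] * v[1] + u[2] * v[2]) / (du * dv)
    return math.degrees(math.acos(max(-1.0, min(1.0, dot))))


def _dispersion(points, origins, lo, hi):
    """Max pairwise visual angle in window [lo, hi] from the mean origin."""
    k = hi - lo + 1
    ox = sum(origins[i][0] for i in range(lo, hi + 1)) / k
    oy = sum(origins[i][1] for i in range(lo, hi + 1)) / k
    oz = sum(origins[i][2] for i in range(lo, hi + 1)) / k
    worst = 0.0
    for i in range(lo, hi + 1):
        u = (points[i][0] - ox, points[i][1] - oy, points[i][2] - oz)
        for j in range(i + 1, hi + 1):
            v = (points[j][0] - ox, points[j][1] - oy, points[j][2] - oz)
            a = _angle_deg(u, v)
            if a > worst:
                worst = a
    return worst


def idt_bruteforce(ts, points, origins, valid, threshold, window_ms):
    """Literal transcription of the dispersion-threshold window loop.

    Returns fixations as (first_index, last_index) pairs.  A window
    spanning the configured duration is initialized at the current
    sample, moved forward while its dispersion exceeds the threshold,
    then extended until the threshold is exceeded; the window samples
    excluding the last form a fixation and the next window starts at
    that last sample.  Invalid samples split the stream.
    """
    points = [tuple(p) for p in points]
    origins = [tuple(o) for o in origins]
    fixations = []
    n = len(ts)
    seg_start = 0
    while seg_start < n:
        if not valid[seg_start]:
            seg_start += 1
            continue
        seg_end = seg_start
        while seg_end + 1 < n and valid[seg_end + 1]:
            seg_end += 1
        i = seg_start
        while i <= seg_end:
            j = i
            while j <= seg_end and ts[j] - ts[i] < window_ms:
                j += 1
            if j > seg_end:
                break
            if _dispersion(points, origins, i, j) > threshold:
                i += 1
                continue
            j += 1
            while j <= seg_end and _dispersion(points, origins, i, j) <= threshold:
                j += 1
            if j <= seg_end:
                fixations.append((i, j - 1))
                i = j
            else:
                fixations.append((i, seg_end))
                i = seg_end + 1
        seg_start = seg_end + 1
    return fixations
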