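"""Independent reference implementations used as test oracles.

Deliberately written in the most literal way possible (pure-Python
loops, recomputation from scratch at every step) so they share no code
path with the package implementations they check.
"""

import numpy as np


def brute_multiotsu(counts, top):
    """Exhaustive search over every ordered triple t1 < t2 < t3 in [0, top).

    Valid when every occupied bin is below ``top`` (the smallest
    maximizing triple then lies in that range).  Returns the
    lexicographically smallest maximizer of the between-class criterion
    sum_k S_k^2 / W_k.
    """
    counts = np.asarray(counts, dtype=float)
    idx = np.arange(len(counts))
    best, best_score = None, -np.inf
    last = len(counts) - 1
    for t1 in range(top):
        for t2 in range(t1 + 1, top):
            for t3 in range(t2 + 1, top):
                s = 0.0
                for a, b in ((0, t1), (t1 + 1, t2), (t2 + 1, t3), (t3 + 1, last)):
                    w = counts[a:b + 1].sum()
                    if w > 0:
                        m = (counts[a:b + 1] * idx[a:b + 1]).sum()
                        s += m * m / w
                if s > best_score:
                    best_score, best = s, (t1, t2, t3)
    return best


def point_in_polygon_crossing(px, py, polygon):
    """Scalar even-odd ray-casting test, one pixel at a time."""
    inside = False
    n = len(polygon)
    for i in range(n):
        x1, y1 = polygon[i]
        x2, y2 = polygon[(i + 1) % n]
        if (y1 > py) != (y2 > py):
            x_cross = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < x_cross:
                inside = not inside
    return inside


def simulate_region_growth(image, wall, seed, max_deviation):
    """Literal step-by-step simulation of min-deviation region growing.

    Region statistics are recomputed from scratch every iteration; the
    candidate list is rebuilt every iteration from the 4-connected
    frontier restricted to the wall; ties break on (row, col).
    """
    rows, cols = image.shape
    region = {tuple(seed)}
    while True:
        candidates = set()
        for (r, c) in region:
            for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                p = (r + dr, c + dc)
                if 0 <= p[0] < rows and 0 <= p[1] < cols and wall[p] and p not in region:
                    candidates.add(p)
        if not candidates:
            break
        mean = sum(float(image[p]) for p in region) / len(region)
        best = min(candidates, key=lambda p: (abs(float(image[p]) - mean), p))
        if abs(float(image[best]) - mean) > max_deviation:
            break
        region.add(best)
    return region


def wall_run_length(line_point, direction, endo, epi, span, step=0.01):
    """Dense sampling oracle for chord wall thickness (in pixels).

    Walks the chord line in tiny steps and counts the samples whose
    point is inside the epicardial polygon but not the endocardial one.
    """
    p = np.asarray(line_point, dtype=float)
    d = np.asarray(direction, dtype=float)
    d = d / np.hypot(*d)
    ts = np.arange(-span, span, step)
    n_wall = 0
    for t in ts:
        x, y = p + t * d
        if point_in_polygon_crossing(x, y, epi) and not point_in_polygon_crossing(x, y, endo):
            n_wall += 1
    return n_wall * step
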