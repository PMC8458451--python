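"""Independent brute-force reference implementations used by the tests.

These deliberately use naive loops and direct formula transcriptions so they
share no code path with the package; they are only feasible on tiny inputs.
"""

from __future__ import annotations

import numpy as np


def vi_bruteforce(pa: np.ndarray, pb: np.ndarray) -> float:
    """Volume of intersection by an explicit cell loop."""
    total = 0.0
    for i in range(pa.shape[0]):
        for j in range(pa.shape[1]):
            total += min(pa[i, j], pb[i, j])
    return total


def overlap2d_bruteforce(cells_a, cells_b) -> tuple[float, float]:
    """Directional proportional overlap from explicit cell sets."""
    sa, sb = set(map(int, cells_a)), set(map(int, cells_b))
    inter = len(sa & sb)
    return inter / len(sa), inter / len(sb)


def match_bruteforce(ta, tb, tol) -> list[tuple[int, int]]:
    """Greedy one-to-one matching on |dt| by explicit enumeration."""
    cand = []
    for i, t1 in enumerate(ta):
        for j, t2 in enumerate(tb):
            dt = abs(int(t1) - int(t2))
            if dt < tol:
                cand.append((dt, int(t1), int(t2), i, j))
    cand.sort()
    used_a, used_b, pairs = set(), set(), []
    for dt, _, _, i, j in cand:
        if i not in used_a and j not in used_b:
            used_a.add(i)
            used_b.add(j)
            pairs.append((i, j))
    return sorted(pairs)


def prox_bruteforce(a, b, dc, tc):
    """Proximity ratio via the brute-force matcher and a distance loop."""
    pairs = match_bruteforce(a.times, b.times, tc)
    if not pairs:
        return None, 0, 0
    n_st = 0
    for i, j in pairs:
        d = ((a.x[i] - b.x[j]) ** 2 + (a.y[i] - b.y[j]) ** 2) ** 0.5
        if d < dc:
            n_st += 1
    return n_st / len(pairs), len(pairs), n_st


def hai_bruteforce(a, b, poly, dc, tc):
    """Half-weight association via explicit loops and shapely point tests."""
    from shapely.geometry import Point

    in_a = [poly.covers(Point(x, y)) for x, y in zip(a.x, a.y)]
    in_b = [poly.covers(Point(x, y)) for x, y in zip(b.x, b.y)]
    pairs = match_bruteforce(a.times, b.times, tc)
    joint_a, joint_b = set(), set()
    for i, j in pairs:
        d = ((a.x[i] - b.x[j]) ** 2 + (a.y[i] - b.y[j]) ** 2) ** 0.5
        if d < dc and in_a[i] and in_b[j]:
            joint_a.add(i)
            joint_b.add(j)
    n_joint = len(joint_a)
    n_a_solo = sum(1 for i in range(len(a)) if in_a[i] and i not in joint_a)
    n_b_solo = sum(1 for j in range(len(b)) if in_b[j] and j not in joint_b)
    if n_joint + n_a_solo + n_b_solo == 0:
        return None
    return n_joint / (n_joint + 0.5 * (n_a_solo + n_b_solo))
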