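"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written with plain Python loops and
elementary vector math, sharing no code path with the package's vectorised
detectors (which go through scipy cdist and SVD ring fitting).
"""

from __future__ import annotations

import math


def _dist(p, q) -> float:
    return math.sqrt(sum((a - b) ** 2 for a, b in zip(p, q)))


def brute_min_distance(frame, idx_a, idx_b) -> float:
    return min(_dist(frame[i], frame[j]) for i in idx_a for j in idx_b)


def brute_ionic(frame, idx_a, idx_b, cutoff) -> bool:
    return brute_min_distance(frame, idx_a, idx_b) <= cutoff


def brute_hydrophobic(frame, idx_a, idx_b, elements, cutoff) -> bool:
    aa = [i for i in idx_a if elements[i] in ("C", "S")]
    bb = [i for i in idx_b if elements[i] in ("C", "S")]
    if not aa or not bb:
        return False
    return brute_min_distance(frame, aa, bb) <= cutoff


def _angle(a, apex, b) -> float:
    v1 = [x - y for x, y in zip(a, apex)]
    v2 = [x - y for x, y in zip(b, apex)]
    n1 = math.sqrt(sum(x * x for x in v1))
    n2 = math.sqrt(sum(x * x for x in v2))
    c = sum(x * y for x, y in zip(v1, v2)) / (n1 * n2)
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def brute_hbond(frame, donor_idx, acceptor_idx, max_dist, min_angle,
                root_idx=None) -> bool:
    best = None
    for i in donor_idx:
        for j in acceptor_idx:
            d = _dist(frame[i], frame[j])
            if best is None or d < best[0]:
                best = (d, i, j)
    d, i, j = best
    if d > max_dist:
        return False
    if root_idx:
        ang = max(_angle(frame[r], frame[i], frame[j]) for r in root_idx)
        if ang < min_angle:
            return False
    return True


def brute_water_mediated(frame, ligand_idx, receptor_idx, waters, max_dist) -> bool:
    for w_idx in waters.values():
        if len(w_idx) == 0:
            continue
        d1 = brute_min_distance(frame, ligand_idx, w_idx)
        d2 = brute_min_distance(frame, receptor_idx, w_idx)
        if d1 <= max_dist and d2 <= max_dist:
            return True
    return False


def brute_cation_pi(frame, cation_idx, ring_idx, max_dist, max_offset) -> bool:
    pts = [frame[i] for i in ring_idx]
    n = len(pts)
    cen = [sum(p[k] for p in pts) / n for k in range(3)]
    # ring normal from averaged consecutive cross products (not SVD)
    nx = ny = nz = 0.0
    for k in range(n):
        a = [pts[k][m] - cen[m] for m in range(3)]
        b = [pts[(k + 1) % n][m] - cen[m] for m in range(3)]
        nx += a[1] * b[2] - a[2] * b[1]
        ny += a[2] * b[0] - a[0] * b[2]
        nz += a[0] * b[1] - a[1] * b[0]
    norm = math.sqrt(nx * nx + ny * ny + nz * nz)
    normal = (nx / norm, ny / norm, nz / norm)
    for c in cation_idx:
        v = [frame[c][m] - cen[m] for m in range(3)]
        d = math.sqrt(sum(x * x for x in v))
        if d == 0 or d > max_dist:
            continue
        cosang = abs(sum(v[m] * normal[m] for m in range(3))) / d
        offset = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
        if offset <= max_offset:
            return True
    return False


def brute_clash_count(frame, idx_a, idx_b, elements, radii, overlap) -> int:
    n = 0
    for i in idx_a:
        for j in idx_b:
            vdw = radii[elements[i].upper()] + radii[elements[j].upper()]
            if vdw - _dist(frame[i], frame[j]) >= overlap:
                n += 1
    return n


def nw_linear(seq_a: str, seq_b: str, matrix, gap: float):
    """Needleman–Wunsch with linear gap cost; returns (score, aligned_a, aligned_b).

    Tie-break order: diagonal, up, left — deterministic traceback.
    """
    n, m = len(seq_a), len(seq_b)
    score = [[0.0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        score[i][0] = -gap * i
    for j in range(1, m + 1):
        score[0][j] = -gap * j
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            score[i][j] = max(
                score[i - 1][j - 1] + matrix[seq_a[i - 1], seq_b[j - 1]],
                score[i - 1][j] - gap,
                score[i][j - 1] - gap,
            )
    a_out, b_out = [], []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and score[i][j] == score[i - 1][j - 1] + \
                matrix[seq_a[i - 1], seq_b[j - 1]]:
            a_out.append(seq_a[i - 1]); b_out.append(seq_b[j - 1])
            i, j = i - 1, j - 1
        elif i > 0 and score[i][j] == score[i - 1][j] - gap:
            a_out.append(seq_a[i - 1]); b_out.append("-")
            i -= 1
        else:
            a_out.append("-"); b_out.append(seq_b[j - 1])
            j -= 1
    return score[n][m], "".join(reversed(a_out)), "".join(reversed(b_out))


def quantiles_by_sorting(values, qs):
    """Linear-interpolation quantiles computed by explicit sort-and-index."""
    xs = sorted(values)
    n = len(xs)
    out = []
    for q in qs:
        pos = q * (n - 1)
        lo = int(math.floor(pos))
        hi = min(lo + 1, n - 1)
        frac = pos - lo
        out.append(xs[lo] * (1 - frac) + xs[hi] * frac)
    return out
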