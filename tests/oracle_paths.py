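"""Independent brute-force oracle for alignment-path optimization.

Recomputes every edge cost directly from the bond-probability formulas and
enumerates every admissible source-to-sink path (start within the first
K+1 locus orders, steps of 1..C orders, end within the last K+1), returning
the exact minimum total cost.  Deliberately shares no code with the
package's graph builder or Dijkstra.
"""

import math

import numpy as np


def _bond(R_px, S2, spherical):
    w = 1.5 * math.log(2 * math.pi * S2) + R_px * R_px / (2 * S2)
    if spherical:
        w -= math.log(4 * math.pi * R_px * R_px)
    return w


def _variance_px2(L, si, sj, p):
    return (si * si + sj * sj) / p.pixel_nm**2 + \
        (2 / 3) * p.tau**2 * p.l_p * L / p.pixel_nm**2


def enumerate_best_score(orders, xyz, sigmas, ref, p):
    """Exact minimum path cost by exhaustive enumeration, or None."""
    pos = ref.positions_bp
    T = ref.n_loci
    n = len(orders)
    med = float(np.median(np.diff(pos)))
    s2_med = _variance_px2(med, p.sigma_default_nm, p.sigma_default_nm, p)
    gext = _bond(math.sqrt(3 * s2_med), s2_med, p.spherical_term) + \
        p.skip_margin * 1.5

    def edge(i, j):
        c = orders[j] - orders[i]
        L = pos[orders[j] - 1] - pos[orders[i] - 1]
        R = np.linalg.norm(xyz[j] - xyz[i]) / p.pixel_nm
        w = _bond(R, _variance_px2(L, sigmas[i], sigmas[j], p), p.spherical_term)
        if p.gap_mode == "affine":
            w = w + (c - 1) * gext
        else:
            w = p.gamma ** (c - 1) * w
        return max(w, 0.0)

    def terminal(k, L, sigma):
        if k == 0:
            return 0.0
        s2 = _variance_px2(L, sigma, 0.0, p)
        w = _bond(p.alpha * math.sqrt(3 * s2), s2, p.spherical_term)
        if p.gap_mode == "affine":
            w = w + (k - 1) * gext
        else:
            w = p.gamma**k * w
        return max(w, 0.0)

    best = [math.inf]

    def extend(i, cost):
        t = orders[i]
        if t >= T - p.K:
            total = cost + terminal(T - t, pos[T - 1] - pos[t - 1], sigmas[i])
            if total < best[0]:
                best[0] = total
        for j in range(n):
            if 1 <= orders[j] - t <= p.C:
                extend(j, cost + edge(i, j))

    for i in range(n):
        if orders[i] <= p.K + 1:
            start = terminal(orders[i] - 1, pos[orders[i] - 1] - pos[0], sigmas[i])
            extend(i, start)
    return None if math.isinf(best[0]) else best[0]


def random_instance(rng, p, max_loci=8, max_candidates=3):
    """A small random reference + candidate cloud for oracle comparison."""
    from fiberalign import ReferenceMap
    T = int(rng.integers(4, max_loci + 1))
    pos = 3e6 + np.cumsum(rng.uniform(0.3e6, 1.9e6, size=T))
    ref = ReferenceMap("chrO", pos)
    orders, xyz = [], []
    scale = p.tau * math.sqrt(2 * p.l_p * 1e6)  # ~RMS 1-Mb separation, nm
    anchor = rng.normal(scale=scale, size=3)
    for t in range(1, T + 1):
        for _ in range(int(rng.integers(0, max_candidates + 1))):
            orders.append(t)
            xyz.append(anchor * t / T + rng.normal(scale=scale, size=3))
    return ref, np.array(orders, dtype=int), np.array(xyz, dtype=float)
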