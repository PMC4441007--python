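"""Independent brute-force oracles used by the tests.

These deliberately re-derive results by the most literal method available
(O(n^3) agglomeration, per-element loops, full SVD reconstruction) so the
package's vectorized/ library-backed implementations are checked against an
independent route.
"""

from __future__ import annotations

import numpy as np


def brute_force_complete_linkage(dist: np.ndarray):
    """Literal agglomerative clustering with complete linkage.

    Returns a list of (leafset_a, leafset_b, height) merges, each step taking
    the globally closest pair under max-linkage between current clusters.
    """
    n = dist.shape[0]
    clusters: dict[int, frozenset[int]] = {i: frozenset([i]) for i in range(n)}
    merges = []
    next_id = n
    while len(clusters) > 1:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if a >= b:
                    continue
                d = max(
                    dist[i, j] for i in clusters[a] for j in clusters[b]
                )
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        merges.append((clusters[a], clusters[b], d))
        clusters[next_id] = clusters[a] | clusters[b]
        del clusters[a], clusters[b]
        next_id += 1
    return merges


def linkage_to_leafsets(Z: np.ndarray, n: int):
    """Convert a scipy linkage matrix to the oracle's merge representation."""
    members: dict[int, frozenset[int]] = {i: frozenset([i]) for i in range(n)}
    merges = []
    for step, (a, b, h, _) in enumerate(Z):
        sa, sb = members[int(a)], members[int(b)]
        merges.append((sa, sb, float(h)))
        members[n + step] = sa | sb
    return merges


def snr_by_hand(values: np.ndarray, cols_a, cols_b):
    """Per-gene signal-to-noise ratio computed gene by gene with plain loops."""
    out = []
    for row in values:
        a = [row[i] for i in cols_a]
        b = [row[i] for i in cols_b]
        mu_a = sum(a) / len(a)
        mu_b = sum(b) / len(b)
        sd_a = (sum((x - mu_a) ** 2 for x in a) / (len(a) - 1)) ** 0.5
        sd_b = (sum((x - mu_b) ** 2 for x in b) / (len(b) - 1)) ** 0.5
        out.append((mu_a - mu_b) / (sd_a + sd_b) if sd_a + sd_b > 0 else np.nan)
    return np.array(out)


def bisect_sigmoid_crossing(params, target: float, lo: float, hi: float,
                            tol: float = 1e-12) -> float:
    """Plain interval bisection for the dose at which a rising/falling single
    sigmoid crosses ``target`` (independent of the package's analytic inverse)."""
    from tregscreen import sigmoid_response

    f = lambda d: float(sigmoid_response(d, params)) - target
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        raise ValueError("target not bracketed")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        fm = f(mid)
        if flo * fm <= 0:
            hi = mid
        else:
            lo, flo = mid, fm
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)
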