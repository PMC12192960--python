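"""Plain O(n^2) Python oracles for dominance machinery, independent of the
package's vectorised implementation."""

import numpy as np


def oracle_dominates(a, b):
    return all(x <= y for x, y in zip(a, b)) and any(x < y for x, y in zip(a, b))


def oracle_fronts(F):
    remaining = list(range(len(F)))
    fronts = []
    while remaining:
        front = [
            i
            for i in remaining
            if not any(oracle_dominates(F[j], F[i]) for j in remaining if j != i)
        ]
        fronts.append(front)
        remaining = [i for i in remaining if i not in front]
    return fronts


def oracle_crowding(F):
    F = np.asarray(F, dtype=float)
    n, m = F.shape
    if n <= 2:
        return np.full(n, np.inf)
    d = np.zeros(n)
    for j in range(m):
        order = np.argsort(F[:, j], kind="stable")
        d[order[0]] = d[order[-1]] = np.inf
        span = F[order[-1], j] - F[order[0], j]
        if span > 0:
            for pos in range(1, n - 1):
                i = order[pos]
                if np.isfinite(d[i]):
                    d[i] += (F[order[pos + 1], j] - F[order[pos - 1], j]) / span
    return d


def oracle_select(F, n):
    fronts = oracle_fronts(F)
    chosen = []
    for front in fronts:
        if len(chosen) + len(front) <= n:
            chosen.extend(front)
        else:
            d = oracle_crowding(np.asarray(F)[front])
            ranked = sorted(range(len(front)), key=lambda t: (-d[t], front[t]))
            chosen.extend(front[t] for t in ranked[: n - len(chosen)])
            break
    return sorted(chosen)
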