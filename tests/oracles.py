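"""Independent oracles used by the unit and acceptance tests.

These deliberately re-derive results through a different route than the
package (exhaustive enumeration, classical NIPALS) so agreement is evidence,
not tautology.
"""

from itertools import combinations

import numpy as np
from scipy.cluster.hierarchy import linkage


def oracle_normalizer_select(profiles: np.ndarray, names: list[str], k: int = 3) -> list[str]:
    """Brute force: every size-k subset that co-occurs in a bottom-up cluster
    at the moment its size first reaches k, scored by summed distance to the
    subset centroid; lexicographic names break ties."""
    n = len(names)
    link = linkage(profiles, method="ward", metric="euclidean")
    members = {i: {i} for i in range(n)}
    admissible: set[tuple[int, ...]] = set()
    for step, (a, b, _d, _s) in enumerate(link):
        a, b = int(a), int(b)
        merged = members[a] | members[b]
        members[n + step] = merged
        if len(merged) >= k and len(members[a]) < k and len(members[b]) < k:
            for combo in combinations(sorted(merged), k):
                admissible.add(combo)
    best, best_key = None, None
    for combo in admissible:
        pts = profiles[list(combo)]
        disp = float(np.linalg.norm(pts - pts.mean(axis=0), axis=1).sum())
        key = (disp, sorted(names[i] for i in combo))
        if best_key is None or key < best_key:
            best, best_key = key[1], key
    return best


def nipals_first_component(X: np.ndarray, Y: np.ndarray, max_iter=1000, tol=1e-12):
    """Classical NIPALS PLS2 first-component score vector."""
    u = Y[:, 0].astype(float).copy()
    t = None
    for _ in range(max_iter):
        w = X.T @ u
        w /= np.linalg.norm(w)
        t_new = X @ w
        q = Y.T @ t_new
        q /= np.linalg.norm(q)
        u = Y @ q
        if t is not None and np.linalg.norm(t_new - t) < tol:
            return t_new
        t = t_new
    return t
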