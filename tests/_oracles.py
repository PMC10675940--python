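"""Independent brute-force oracles: naive per-voxel / per-pair enumerations
used to cross-check the vectorized implementations.  Everything here is
deliberately written as plain loops with no shared code with the package."""

from __future__ import annotations

import itertools
import math

import numpy as np

OFFSETS_13 = [
    (0, 0, 1),
    (0, 1, -1),
    (0, 1, 0),
    (0, 1, 1),
    (1, -1, -1),
    (1, -1, 0),
    (1, -1, 1),
    (1, 0, -1),
    (1, 0, 0),
    (1, 0, 1),
    (1, 1, -1),
    (1, 1, 0),
    (1, 1, 1),
]

OFFSETS_26 = [
    o
    for o in itertools.product((-1, 0, 1), repeat=3)
    if o != (0, 0, 0)
]


def _inside(shape, p):
    return all(0 <= c < s for c, s in zip(p, shape))


def naive_glcm(levels: np.ndarray, ng: int) -> np.ndarray:
    """Direction-averaged symmetric co-occurrence probabilities (0 = outside)."""
    shape = levels.shape
    acc = np.zeros((ng, ng))
    n_dir = 0
    for off in OFFSETS_13:
        mat = np.zeros((ng, ng))
        for p in itertools.product(*[range(s) for s in shape]):
            a = levels[p]
            if a == 0:
                continue
            q = tuple(c + o for c, o in zip(p, off))
            if _inside(shape, q) and levels[q] > 0:
                b = levels[q]
                mat[a - 1, b - 1] += 1
                mat[b - 1, a - 1] += 1
        if mat.sum() > 0:
            acc += mat / mat.sum()
            n_dir += 1
    return acc / n_dir if n_dir else acc


def naive_glrlm(levels: np.ndarray) -> np.ndarray:
    """Run-length counts averaged over the 13 directions."""
    shape = levels.shape
    max_run = max(shape)
    ng = int(levels.max())
    acc = np.zeros((ng, max_run))
    for off in OFFSETS_13:
        mat = np.zeros((ng, max_run))
        for p in itertools.product(*[range(s) for s in shape]):
            lvl = levels[p]
            if lvl == 0:
                continue
            prev = tuple(c - o for c, o in zip(p, off))
            if _inside(shape, prev) and levels[prev] == lvl:
                continue  # not a run start
            length = 1
            cur = p
            while True:
                nxt = tuple(c + o for c, o in zip(cur, off))
                if _inside(shape, nxt) and levels[nxt] == lvl:
                    length += 1
                    cur = nxt
                else:
                    break
            mat[lvl - 1, length - 1] += 1
        acc += mat
    return acc / len(OFFSETS_13)


def naive_glszm(levels: np.ndarray) -> np.ndarray:
    """Zone counts via BFS over 26-connected same-level components."""
    shape = levels.shape
    ng = int(levels.max())
    n_vox = int((levels > 0).sum())
    mat = np.zeros((ng, n_vox))
    seen = np.zeros(shape, dtype=bool)
    for start in itertools.product(*[range(s) for s in shape]):
        if levels[start] == 0 or seen[start]:
            continue
        lvl = levels[start]
        stack, size = [start], 0
        seen[start] = True
        while stack:
            cur = stack.pop()
            size += 1
            for off in OFFSETS_26:
                q = tuple(c + o for c, o in zip(cur, off))
                if _inside(shape, q) and not seen[q] and levels[q] == lvl:
                    seen[q] = True
                    stack.append(q)
        mat[lvl - 1, size - 1] += 1
    return mat


def naive_gldm(levels: np.ndarray, alpha: int = 0) -> np.ndarray:
    """Dependence counts: size = 1 + neighbors within alpha gray levels."""
    shape = levels.shape
    ng = int(levels.max())
    mat = np.zeros((ng, 27))
    for p in itertools.product(*[range(s) for s in shape]):
        lvl = levels[p]
        if lvl == 0:
            continue
        dep = 0
        for off in OFFSETS_26:
            q = tuple(c + o for c, o in zip(p, off))
            if _inside(shape, q) and levels[q] > 0 and abs(int(levels[q]) - int(lvl)) <= alpha:
                dep += 1
        mat[lvl - 1, dep] += 1  # column index = dep size - 1 = dep
    return mat


def naive_ngtdm(levels: np.ndarray, ng: int):
    """Per-level (n_i, p_i, s_i) from direct neighborhood-mean enumeration."""
    shape = levels.shape
    n_i = np.zeros(ng)
    s_i = np.zeros(ng)
    for p in itertools.product(*[range(s) for s in shape]):
        lvl = levels[p]
        if lvl == 0:
            continue
        vals = []
        for off in OFFSETS_26:
            q = tuple(c + o for c, o in zip(p, off))
            if _inside(shape, q) and levels[q] > 0:
                vals.append(levels[q])
        if not vals:
            continue
        n_i[lvl - 1] += 1
        s_i[lvl - 1] += abs(lvl - sum(vals) / len(vals))
    nv = n_i.sum()
    p_i = n_i / nv if nv else n_i
    return n_i, p_i, s_i, int(nv)


# ---------------------------------------------------------------------------
# graph topology


def naive_topology(adj: np.ndarray) -> dict[str, float]:
    """Topology panel from an adjacency matrix, via Floyd-Warshall and direct
    degree formulas; isolated nodes are discarded first."""
    deg_all = adj.sum(axis=1)
    keep = np.nonzero(deg_all >= 1)[0]
    n = len(keep)
    if n == 0:
        return {
            "node_number": 0, "edge_number": 0, "network_density": 0.0,
            "network_diameter": 0.0, "characteristic_path_length": 0.0,
            "clustering_coefficient": 0.0, "network_centralization": 0.0,
            "network_heterogeneity": 0.0, "mean_degree": 0.0,
        }
    a = adj[np.ix_(keep, keep)]
    deg = a.sum(axis=1)
    e = int(a.sum() / 2)
    density = 2 * e / (n * (n - 1)) if n > 1 else 0.0

    inf = math.inf
    dist = [[0 if i == j else (1 if a[i][j] else inf) for j in range(n)] for i in range(n)]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if dist[i][k] + dist[k][j] < dist[i][j]:
                    dist[i][j] = dist[i][k] + dist[k][j]
    # largest connected component by membership sets
    comps, assigned = [], set()
    for i in range(n):
        if i in assigned:
            continue
        comp = {j for j in range(n) if dist[i][j] < inf}
        comps.append(comp)
        assigned |= comp
    giant = max(comps, key=len)
    pairs = [(i, j) for i in giant for j in giant if i < j]
    if pairs:
        dvals = [dist[i][j] for i, j in pairs]
        diameter = float(max(dvals))
        cpl = float(sum(dvals) / len(dvals))
    else:
        diameter = cpl = 0.0

    cc = []
    for i in range(n):
        if deg[i] >= 2:
            nbrs = [j for j in range(n) if a[i][j]]
            links = sum(
                a[u][v] for ui, u in enumerate(nbrs) for v in nbrs[ui + 1 :]
            )
            cc.append(2 * links / (deg[i] * (deg[i] - 1)))
    clustering = float(np.mean(cc)) if cc else 0.0

    centralization = (n / (n - 2)) * (deg.max() / (n - 1) - density) if n > 2 else 0.0
    mean_deg = float(deg.mean())
    het = float(np.sqrt(np.var(deg)) / mean_deg) if mean_deg > 0 else 0.0
    return {
        "node_number": n,
        "edge_number": e,
        "network_density": float(density),
        "network_diameter": diameter,
        "characteristic_path_length": cpl,
        "clustering_coefficient": clustering,
        "network_centralization": float(centralization),
        "network_heterogeneity": het,
        "mean_degree": float(2 * e / n),
    }


# ---------------------------------------------------------------------------
# statistics


def pair_count_auc(scores, labels_binary) -> float:
    """AUC as the concordant-pair fraction (ties count one half)."""
    pos = [s for s, y in zip(scores, labels_binary) if y == 1]
    neg = [s for s, y in zip(scores, labels_binary) if y == 0]
    total = len(pos) * len(neg)
    conc = sum(
        1.0 if sp > sn else (0.5 if sp == sn else 0.0) for sp in pos for sn in neg
    )
    return conc / total


def logrank_by_hand(times_a, events_a, times_b, events_b):
    """Two-group log-rank chi-square from the expected/observed table."""
    all_events = sorted(
        {t for t, e in zip(list(times_a) + list(times_b), list(events_a) + list(events_b)) if e}
    )
    o_minus_e = 0.0
    var = 0.0
    for t in all_events:
        n_a = sum(1 for x in times_a if x >= t)
        n_b = sum(1 for x in times_b if x >= t)
        d_a = sum(1 for x, e in zip(times_a, events_a) if x == t and e)
        d_b = sum(1 for x, e in zip(times_b, events_b) if x == t and e)
        n, d = n_a + n_b, d_a + d_b
        if n == 0:
            continue
        o_minus_e += d_a - d * n_a / n
        if n > 1:
            var += d * (n_a / n) * (n_b / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


def wilcoxon_exact_p(diffs) -> float:
    """Exact two-sided signed-rank p by enumerating all 2^n sign assignments."""
    d = [x for x in diffs if x != 0]
    n = len(d)
    ranks = _rank(np.abs(np.array(d)))
    w_obs = min(
        sum(r for x, r in zip(d, ranks) if x > 0),
        sum(r for x, r in zip(d, ranks) if x < 0),
    )
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        w_plus = sum(r for s, r in zip(signs, ranks) if s)
        w = min(w_plus, sum(ranks) - w_plus)
        if w <= w_obs + 1e-12:
            count += 1
    return count / 2**n


def _rank(x):
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x))
    i = 0
    sorted_x = x[order]
    while i < len(x):
        j = i
        while j < len(x) and sorted_x[j] == sorted_x[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0  # average rank, 1-based
        i = j
    return ranks
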