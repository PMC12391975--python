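"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations — O(N²) loops, exhaustive enumeration —
kept free of any code path from the package under test.
"""

from __future__ import annotations

import numpy as np


def brute_contact_edges(coords: np.ndarray, threshold: float) -> set[tuple[int, int]]:
    """All pairs (i<j) with Euclidean distance strictly below threshold."""
    n = len(coords)
    out = set()
    for i in range(n):
        for j in range(i + 1, n):
            if float(np.linalg.norm(coords[i] - coords[j])) < threshold:
                out.add((i, j))
    return out


def brute_transition(
    adjacency: np.ndarray,
    weights: np.ndarray,
    prev: int | None,
    curr: int,
    p: float,
    q: float,
) -> dict[int, float]:
    """Second-order walk distribution by literal evaluation of the bias rule.

    Shortest-path distance from ``prev`` to each candidate is computed by
    breadth-first search (not the local 0/1/2 shortcut used in the package).
    """
    n = adjacency.shape[0]
    neighbors = [x for x in range(n) if adjacency[curr, x] and x != curr]
    if prev is None:
        un = {x: float(weights[curr, x]) for x in neighbors}
    else:
        dist = _bfs_distances(adjacency, prev)
        un = {}
        for x in neighbors:
            d = dist[x]
            if d == 0:
                alpha = 1.0 / p
            elif d == 1:
                alpha = 1.0
            else:
                alpha = 1.0 / q
            un[x] = alpha * float(weights[curr, x])
    z = sum(un.values())
    return {x: v / z for x, v in un.items()}


def _bfs_distances(adjacency: np.ndarray, source: int) -> np.ndarray:
    n = adjacency.shape[0]
    dist = np.full(n, np.inf)
    dist[source] = 0
    frontier = [source]
    d = 0
    while frontier:
        d += 1
        nxt = []
        for u in frontier:
            for v in range(n):
                if adjacency[u, v] and v != u and dist[v] == np.inf:
                    dist[v] = d
                    nxt.append(v)
        frontier = nxt
    return dist


def brute_fmax(labels: np.ndarray, scores: np.ndarray, thresholds) -> float:
    """Protein-centric Fmax by explicit per-protein loops."""
    keep = [i for i in range(len(labels)) if labels[i].sum() > 0]
    labels = labels[keep]
    scores = scores[keep]
    n = len(labels)
    best = 0.0
    for tau in thresholds:
        prs = []
        rcs = []
        for i in range(n):
            pred = {j for j in range(labels.shape[1]) if scores[i, j] >= tau}
            true = {j for j in range(labels.shape[1]) if labels[i, j] > 0}
            if pred:
                prs.append(len(pred & true) / len(pred))
            rcs.append(len(pred & true) / len(true))
        if not prs:
            continue
        pr = sum(prs) / len(prs)
        rc = sum(rcs) / n
        if pr + rc > 0:
            best = max(best, 2 * pr * rc / (pr + rc))
    return best


def brute_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Concordant-pair count over all positive/negative cell pairs."""
    y = np.asarray(labels).ravel()
    s = np.asarray(scores).ravel()
    pos = s[y > 0]
    neg = s[y == 0]
    total = len(pos) * len(neg)
    conc = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                conc += 1.0
            elif a == b:
                conc += 0.5
    return conc / total


def brute_aupr(labels: np.ndarray, scores: np.ndarray) -> float:
    """Average precision: sum over recall steps of precision at each step."""
    y = np.asarray(labels).ravel().astype(int)
    s = np.asarray(scores).ravel()
    order = np.argsort(-s, kind="stable")
    # ties: group scores so equal scores enter together
    uniq = sorted(set(s), reverse=True)
    n_pos = y.sum()
    tp = 0
    fp = 0
    area = 0.0
    prev_recall = 0.0
    for threshold in uniq:
        sel = s >= threshold
        tp = int((y[sel] == 1).sum())
        fp = int((y[sel] == 0).sum())
        precision = tp / (tp + fp)
        recall = tp / n_pos
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return area


def brute_topk(scores: np.ndarray, k: int) -> list[int]:
    """Indices of the k highest scores, ties to the lower index, sorted."""
    order = sorted(range(len(scores)), key=lambda i: (-scores[i], i))
    return sorted(order[:k])
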