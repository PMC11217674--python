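"""Independent brute-force reference implementations used only by tests.

Every function here recomputes a pipeline quantity from first principles
(path enumeration, exhaustive search, integer arithmetic) without touching
the package's own closure caches or vectorized code paths.
"""

from __future__ import annotations

import math
from itertools import combinations


def enumerate_paths_up(edges: dict[str, set[str]], start: str):
    """All simple upward paths (child->parent steps) starting at *start*.

    *edges* maps child -> set of parents.  Yields paths as term lists,
    including the trivial single-node path.
    """
    stack = [[start]]
    while stack:
        path = stack.pop()
        yield path
        for parent in sorted(edges.get(path[-1], set())):
            if parent not in path:
                stack.append(path + [parent])


def brute_ancestors(edges: dict[str, set[str]], term: str) -> set[str]:
    """Ancestors by exhaustive path enumeration."""
    out: set[str] = set()
    for path in enumerate_paths_up(edges, term):
        out.update(path[1:])
    return out


def brute_depth(edges: dict[str, set[str]], term: str, root: str) -> int:
    """Shortest number of upward jumps from *term* to *root*, by full path search."""
    best = None
    for path in enumerate_paths_up(edges, term):
        if path[-1] == root:
            n = len(path) - 1
            best = n if best is None else min(best, n)
    if best is None:
        raise ValueError(f"{term} cannot reach {root}")
    return best


def brute_relation(edges: dict[str, set[str]], predicted: str, annotated: set[str]) -> str:
    """Best precision class over the annotation set, via path enumeration.

    Distances between predicted and each annotated term are taken as the
    shortest purely-upward path connecting them (one is an ancestor of the
    other); parent/child means distance 1.
    """
    if predicted in annotated:
        return "HIT"
    best = "Unrelated"
    rank = {"HIT": 0, "Close": 1, "Related": 2, "Unrelated": 3}
    for a in annotated:
        dist = None
        for path in enumerate_paths_up(edges, predicted):
            if a in path:
                d = path.index(a)
                dist = d if dist is None else min(dist, d)
        for path in enumerate_paths_up(edges, a):
            if predicted in path:
                d = path.index(predicted)
                dist = d if dist is None else min(dist, d)
        if dist is None:
            continue
        label = "Close" if dist == 1 else "Related"
        if rank[label] < rank[best]:
            best = label
    return best


def brute_svalues(weighted_edges: dict[str, dict[str, float]], term: str) -> dict[str, float]:
    """Wang S-values as max path-weight-products over all upward paths.

    *weighted_edges* maps child -> {parent: weight}.
    """
    svals: dict[str, float] = {term: 1.0}
    edges = {c: set(ps) for c, ps in weighted_edges.items()}
    for path in enumerate_paths_up(edges, term):
        product = 1.0
        for child, parent in zip(path, path[1:]):
            product *= weighted_edges[child][parent]
            svals[parent] = max(svals.get(parent, 0.0), product)
    return svals


def brute_wang(weighted_edges, a: str, b: str) -> float:
    sa = brute_svalues(weighted_edges, a)
    sb = brute_svalues(weighted_edges, b)
    common = set(sa) & set(sb)
    return sum(sa[t] + sb[t] for t in common) / (sum(sa.values()) + sum(sb.values()))


def brute_bma(matrix) -> float:
    rows = [max(row) for row in matrix]
    cols = [max(col) for col in zip(*matrix)]
    return (sum(rows) + sum(cols)) / (len(rows) + len(cols))


def brute_set_sim(weighted_edges, set1, set2) -> float:
    matrix = [[brute_wang(weighted_edges, a, b) for b in sorted(set2)] for a in sorted(set1)]
    return brute_bma(matrix)


def hypergeom_tail(a: int, b: int, c: int, d: int) -> float:
    """P(X >= a) for the 2x2 table by explicit integer enumeration."""
    population, marked, drawn = a + b + c + d, a + c, a + b
    lo = max(0, drawn - (population - marked))
    hi = min(marked, drawn)
    numerator = sum(
        math.comb(marked, k) * math.comb(population - marked, drawn - k)
        for k in range(max(a, lo), hi + 1)
    )
    return numerator / math.comb(population, drawn)


def quantile_type7(values, q: float) -> float:
    """Linear interpolation of order statistics (R type-7), computed directly."""
    xs = sorted(values)
    if len(xs) == 1:
        return float(xs[0])
    h = (len(xs) - 1) * q
    lo = math.floor(h)
    if lo == len(xs) - 1:
        return float(xs[-1])
    return float(xs[lo] + (h - lo) * (xs[lo + 1] - xs[lo]))


def max_nonoverlapping(intervals) -> list[int]:
    """Indices of a maximum-cardinality pairwise non-overlapping subset.

    *intervals* is a list of 1-based inclusive (start, end) pairs; exhaustive
    search over all subsets (fixtures stay tiny).
    """
    n = len(intervals)
    best: list[int] = []
    for size in range(n, 0, -1):
        for subset in combinations(range(n), size):
            ok = all(
                intervals[i][1] < intervals[j][0] or intervals[i][0] > intervals[j][1]
                for i, j in combinations(subset, 2)
            )
            if ok:
                return list(subset)
    return best
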