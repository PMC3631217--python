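"""Independent brute-force oracles used to validate the implementation.

Everything here is written with plain loops and set arithmetic, deliberately
avoiding the code paths (and libraries) the package uses, so agreement is a
meaningful check rather than a tautology.  Only intended for graphs of a
dozen or so nodes.
"""

import itertools
from collections import Counter


def neighbors(net, x):
    out = set()
    for (a, b) in net.edges:
        if a == x:
            out.add(b)
        if b == x:
            out.add(a)
    return out


def jaccard(s1, s2):
    union = s1 | s2
    return len(s1 & s2) / len(union) if union else 0.0


def neighbor_jaccard(net, i, j):
    return jaccard(neighbors(net, i) - {i, j}, neighbors(net, j) - {i, j})


def top2mean(vals):
    if not vals:
        return 0.0
    vals = sorted(vals, reverse=True)[:2]
    return sum(vals) / len(vals)


def jaccard_max2_mean(net, i, j):
    si = top2mean([neighbor_jaccard(net, i, u) for u in neighbors(net, j) - {i}])
    sj = top2mean([neighbor_jaccard(net, j, u) for u in neighbors(net, i) - {j}])
    return (si + sj) / 2.0


def all_shortest_paths(net, s, t):
    """Every shortest s-t path, by breadth-limited exhaustive enumeration."""
    ids = list(net.drugs)
    best, found = len(ids), []
    frontier = [[s]]
    while frontier and len(frontier[0]) <= best + 1:
        nxt = []
        for path in frontier:
            if path[-1] == t:
                if len(path) < best:
                    best, found = len(path), [path]
                elif len(path) == best:
                    found.append(path)
                continue
            for u in neighbors(net, path[-1]):
                if u not in path:
                    nxt.append(path + [u])
        frontier = nxt
    return found


def betweenness(net, v):
    """Normalized shortest-path betweenness by explicit path enumeration."""
    ids = sorted(net.drugs)
    n = len(ids)
    if n < 3:
        return 0.0
    total = 0.0
    for s, t in itertools.combinations(ids, 2):
        if v in (s, t):
            continue
        paths = all_shortest_paths(net, s, t)
        if not paths:
            continue
        total += sum(1 for p in paths if v in p) / len(paths)
    return total * 2.0 / ((n - 1) * (n - 2))


def clustering(net, v):
    nb = sorted(neighbors(net, v))
    k = len(nb)
    if k < 2:
        return 0.0
    links = sum(
        1 for a, b in itertools.combinations(nb, 2)
        if (min(a, b), max(a, b)) in net.edges
    )
    return 2.0 * links / (k * (k - 1))


def atc_min(tax, d1, d2):
    def leaf_chain(code):
        return [code[:cut] for cut in tax.level_prefixes]

    best = None
    for c1 in d1.atc_codes:
        for c2 in d2.atc_codes:
            p1, p2 = leaf_chain(c1), leaf_chain(c2)
            shared = 0
            for a, b in zip(p1, p2):
                if a != b:
                    break
                shared += 1
            d = (len(p1) - shared) + (len(p2) - shared)
            best = d if best is None else min(best, d)
    return best


def atc_min_prod(net, tax, i, j):
    dmax = 2 * len(tax.level_prefixes)

    def t(endpoint, other):
        nbrs = neighbors(net, other) - {endpoint}
        if not nbrs:
            return float(dmax)
        return float(min(atc_min(tax, net.drugs[endpoint], net.drugs[u]) for u in nbrs))

    return t(i, j) * t(j, i)


def str_max_prod(net, i, j):
    def m(endpoint, other):
        nbrs = neighbors(net, other) - {endpoint}
        if not nbrs:
            return 0.0
        return max(
            jaccard(net.drugs[endpoint].substructures, net.drugs[u].substructures)
            for u in nbrs
        )

    return m(i, j) * m(j, i)


def mann_whitney_auroc(scores, labels):
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum(1.0 for p in pos for q in neg if p > q)
    ties = sum(1.0 for p in pos for q in neg if p == q)
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def operating_point_sweep(scores, labels, target):
    """Exhaustive threshold sweep: smallest cut with specificity >= target."""
    n_pos = sum(labels)
    n_neg = len(labels) - n_pos
    best = None
    for t in sorted(set(scores)):
        tp = sum(1 for s, y in zip(scores, labels) if s >= t and y == 1)
        fp = sum(1 for s, y in zip(scores, labels) if s >= t and y == 0)
        if (n_neg - fp) / n_neg >= target:
            best = (t, tp, fp, n_neg - fp, n_pos - tp)
            break
    if best is None:
        return None
    return best


def nearest_rank_percentile(values, p):
    import math

    values = sorted(values)
    rank = max(1, math.ceil(p * len(values)))
    return values[rank - 1]


def type_counts(net, i, j):
    counts = Counter()
    for (a, b), e in net.edges.items():
        if (a, b) == (min(i, j), max(i, j)):
            continue
        if a in (i, j) or b in (i, j):
            counts[e.type_label] += 1
    return dict(counts)
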