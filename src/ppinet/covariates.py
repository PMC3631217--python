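"""Pair covariates for DDI link prediction.

Nine covariates are computed per unordered drug pair, in three families:

* network — ``degree_prod`` (popularity), ``betw_prod`` (centrality),
  ``cccnw_max`` (local clustering), ``jackard`` (neighborhood Jaccard
  similarity) and ``jackard_max2_mean`` (its first-order extension through
  the pair's network neighbors);
* taxonomic — ``atc_min`` (minimum tree distance between the drugs' taxonomy
  codes) and ``atc_min_prod`` (its first-order extension);
* intrinsic — ``str_jackard`` (Tanimoto similarity of chemical-substructure
  fingerprints) and ``str_max_prod`` (its first-order extension).

Zeroth-order covariates depend on the two drugs alone; first-order covariates
also aggregate over the drugs' network neighbors, which is where most of the
predictive signal lives.  Endpoints are removed from each other's
neighborhoods before any similarity computation so that a training edge
(i, j) cannot inflate its own covariate.

Each covariate is registered by name in :data:`COVARIATE_NAMES`; the table
builder evaluates the whole family with vectorized adjacency/similarity
matrices, while the per-pair functions remain the reference definitions used
by tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .network import DDINetwork, Drug, canonical_pair

__all__ = [
    "ATCTaxonomy",
    "COVARIATE_NAMES",
    "neighbor_jaccard",
    "jaccard_max2_mean",
    "topology_covariates",
    "atc_min_distance",
    "atc_min_prod",
    "structural_jaccard",
    "str_max_prod",
    "build_covariate_table",
]

#: canonical covariate order used by the table builder and the models
COVARIATE_NAMES = [
    "degree_prod",
    "betw_prod",
    "cccnw_max",
    "jackard",
    "jackard_max2_mean",
    "atc_min",
    "atc_min_prod",
    "str_jackard",
    "str_max_prod",
]

#: character offsets at which an ATC-style code nests: A / A01 / A01B / A01BC / A01BC01
ATC_LEVEL_PREFIXES = (1, 3, 4, 5, 7)


class ATCTaxonomy:
    """Rooted tree over hierarchical drug-classification codes.

    The tree has a virtual root above the first level; a full code decomposes
    into nested prefixes (one per level) that form its root-to-leaf path.
    Distance between two codes is the tree-path length between their leaves:
    steps up to the lowest common ancestor plus steps down, i.e.
    ``2 * (depth - shared_levels)`` for a uniform-depth taxonomy.
    """

    def __init__(self, codes: Iterable[str], level_prefixes: Sequence[int] = ATC_LEVEL_PREFIXES):
        self.level_prefixes = tuple(level_prefixes)
        self.depth = len(self.level_prefixes)
        self.codes: frozenset[str] = frozenset(str(c).strip() for c in codes)
        if not self.codes:
            raise ValueError("taxonomy requires at least one code")
        full_len = self.level_prefixes[-1]
        bad = [c for c in self.codes if len(c) != full_len]
        if bad:
            raise ValueError(
                f"codes not parseable into {self.depth} levels "
                f"(expected length {full_len}): {sorted(bad)[:5]}"
            )
        # node set: every prefix of every code, plus the virtual root ""
        self._nodes: set[str] = {""}
        for c in self.codes:
            for cut in self.level_prefixes:
                self._nodes.add(c[:cut])

    def __contains__(self, code: str) -> bool:
        return code in self.codes

    @property
    def max_distance(self) -> int:
        """Largest possible leaf-to-leaf path length (through the root)."""
        return 2 * self.depth

    def path(self, code: str) -> tuple[str, ...]:
        """Root-to-leaf prefix chain of a full code."""
        if code not in self.codes:
            raise KeyError(f"code not in taxonomy: {code!r}")
        return tuple(code[:cut] for cut in self.level_prefixes)

    def distance(self, code1: str, code2: str) -> int:
        """Tree-path length between two leaf codes."""
        p1, p2 = self.path(code1), self.path(code2)
        shared = 0
        for a, b in zip(p1, p2):
            if a != b:
                break
            shared += 1
        return (self.depth - shared) * 2

    def to_tree(self) -> nx.DiGraph:
        """The explicit tree as a directed graph (root ``""`` at the top)."""
        g = nx.DiGraph()
        for code in self.codes:
            chain = ("",) + self.path(code)
            for parent, child in zip(chain, chain[1:]):
                g.add_edge(parent, child)
        return g


# ---------------------------------------------------------------------------
# per-pair reference definitions

def _check_pair(net: DDINetwork, i: str, j: str) -> None:
    for d in (i, j):
        if d not in net.drugs:
            raise KeyError(f"unknown drug: {d!r}")
    if i == j:
        raise ValueError(f"pair endpoints must be distinct: {i!r}")


def neighbor_jaccard(net: DDINetwork, i: str, j: str) -> float:
    """Jaccard similarity of the two drugs' neighbor sets (covariate ``jackard``).

    Both endpoints are excluded from both neighborhoods, so an existing edge
    (i, j) does not count toward its own similarity.  Returns 0 when the
    union is empty.
    """
    _check_pair(net, i, j)
    ni = net.neighbors(i) - {i, j}
    nj = net.neighbors(j) - {i, j}
    union = ni | nj
    if not union:
        return 0.0
    return len(ni & nj) / len(union)


def _top2_mean(values: Sequence[float]) -> float:
    if not values:
        return 0.0
    top = sorted(values, reverse=True)[:2]
    return float(sum(top) / len(top))


def jaccard_max2_mean(net: DDINetwork, i: str, j: str) -> float:
    """First-order neighborhood similarity (covariate ``jackard_max2_mean``).

    For each endpoint, take the neighbor-Jaccard similarities between it and
    the *other* endpoint's neighbors, average the two largest (fewer if fewer
    exist, 0 if none), and return the mean of the two per-endpoint values.
    High values mean each drug closely resembles drugs the other is already
    known to interact with.
    """
    _check_pair(net, i, j)
    s_i = _top2_mean([neighbor_jaccard(net, i, u) for u in net.neighbors(j) - {i}])
    s_j = _top2_mean([neighbor_jaccard(net, j, u) for u in net.neighbors(i) - {j}])
    return (s_i + s_j) / 2.0


def topology_covariates(net: DDINetwork, i: str, j: str) -> tuple[float, float, float]:
    """(degree_prod, betw_prod, cccnw_max) for one pair.

    Betweenness is normalized shortest-path betweenness on the unweighted
    network; clustering is the local clustering coefficient (0 for degree<2);
    ``cccnw_max`` takes the max over the two endpoints.
    """
    _check_pair(net, i, j)
    g = net.to_networkx()
    betw = nx.betweenness_centrality(g, normalized=True)
    return (
        float(g.degree[i] * g.degree[j]),
        float(betw[i] * betw[j]),
        float(max(nx.clustering(g, i), nx.clustering(g, j))),
    )


def atc_min_distance(tax: ATCTaxonomy, d1: Drug, d2: Drug) -> int:
    """Minimum taxonomy tree distance over all code pairs (covariate ``atc_min``).

    A drug may occupy several taxonomy positions; the covariate takes the
    minimum path length over every (code of d1, code of d2) combination.
    """
    for d in (d1, d2):
        codes = [c for c in d.atc_codes if c in tax]
        if not codes:
            raise ValueError(f"drug {d.drug_id!r} has no code resolvable in the taxonomy")
    return min(
        tax.distance(c1, c2)
        for c1 in d1.atc_codes if c1 in tax
        for c2 in d2.atc_codes if c2 in tax
    )


def atc_min_prod(net: DDINetwork, tax: ATCTaxonomy, i: str, j: str) -> float:
    """First-order taxonomic covariate.

    ``t_i`` is the minimum taxonomy distance between drug i and any neighbor
    of j (excluding i itself); ``t_j`` symmetric; the covariate is their
    product.  An empty neighbor set falls back to the maximum possible tree
    distance, so isolated neighborhoods read as maximally dissimilar.
    """
    _check_pair(net, i, j)
    d_max = float(tax.max_distance)

    def t(endpoint: str, other: str) -> float:
        nbrs = net.neighbors(other) - {endpoint}
        if not nbrs:
            return d_max
        return float(min(
            atc_min_distance(tax, net.drugs[endpoint], net.drugs[u]) for u in nbrs
        ))

    return t(i, j) * t(j, i)


def structural_jaccard(d1: Drug, d2: Drug) -> float:
    """Tanimoto similarity of substructure fingerprints (covariate ``str_jackard``)."""
    union = d1.substructures | d2.substructures
    if not union:
        return 0.0
    return len(d1.substructures & d2.substructures) / len(union)


def str_max_prod(net: DDINetwork, i: str, j: str) -> float:
    """First-order intrinsic covariate.

    ``m_i`` is the maximum fingerprint similarity between drug i and any
    neighbor of j (0 if j has no other neighbors); ``m_j`` symmetric; the
    covariate is their product — near 1 exactly when each drug is chemically
    close to something the other already interacts with.
    """
    _check_pair(net, i, j)

    def m(endpoint: str, other: str) -> float:
        nbrs = net.neighbors(other) - {endpoint}
        if not nbrs:
            return 0.0
        return max(
            structural_jaccard(net.drugs[endpoint], net.drugs[u]) for u in nbrs
        )

    return m(i, j) * m(j, i)


# ---------------------------------------------------------------------------
# vectorized pairwise matrices

def pairwise_atc_min(drug_list: Sequence[Drug], tax: ATCTaxonomy) -> np.ndarray:
    """Dense matrix of minimum taxonomy distances between all drug pairs."""
    n = len(drug_list)
    missing = [d.drug_id for d in drug_list if not any(c in tax for c in d.atc_codes)]
    if missing:
        raise ValueError(
            "drugs with no code resolvable in the taxonomy: "
            + ", ".join(sorted(missing)[:10])
        )
    code_list = sorted({c for d in drug_list for c in d.atc_codes if c in tax})
    code_idx = {c: k for k, c in enumerate(code_list)}
    prefix_ids: dict[str, int] = {}
    paths = np.array([
        [prefix_ids.setdefault(p, len(prefix_ids)) for p in tax.path(c)]
        for c in code_list
    ])
    eq = paths[:, None, :] == paths[None, :, :]
    shared = np.cumprod(eq, axis=2).sum(axis=2)
    code_dist = 2.0 * (tax.depth - shared)
    drug_codes = [np.array([code_idx[c] for c in d.atc_codes if c in tax])
                  for d in drug_list]
    out = np.empty((n, n), dtype=float)
    for a in range(n):
        sub = code_dist[drug_codes[a]]
        for b in range(a, n):
            v = sub[:, drug_codes[b]].min()
            out[a, b] = v
            out[b, a] = v
    return out


def pairwise_structural_jaccard(drug_list: Sequence[Drug]) -> np.ndarray:
    """Dense matrix of fingerprint Tanimoto similarities between all drugs."""
    n = len(drug_list)
    feats = sorted({s for d in drug_list for s in d.substructures})
    fidx = {f: k for k, f in enumerate(feats)}
    fp = np.zeros((n, max(len(feats), 1)), dtype=np.int32)
    for k, d in enumerate(drug_list):
        for s in d.substructures:
            fp[k, fidx[s]] = 1
    finter = (fp @ fp.T).astype(float)
    fsize = fp.sum(axis=1)
    funion = fsize[:, None] + fsize[None, :] - finter
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(funion > 0, finter / np.maximum(funion, 1e-300), 0.0)


# ---------------------------------------------------------------------------
# vectorized table builder

@dataclass
class _PairwiseCache:
    """Dense pairwise matrices reused across all requested pairs."""

    ids: list[str]
    index: dict[str, int]
    adj: np.ndarray            # n x n bool
    degree: np.ndarray         # n
    betweenness: np.ndarray    # n, normalized
    clustering: np.ndarray     # n
    jaccard: np.ndarray        # n x n endpoint-removed neighbor Jaccard
    atc_dist: np.ndarray       # n x n min taxonomy distance
    str_sim: np.ndarray        # n x n fingerprint Tanimoto
    nbrs: list[np.ndarray]     # neighbor index arrays


def _pairwise_cache(net: DDINetwork, tax: ATCTaxonomy) -> _PairwiseCache:
    ids = sorted(net.drugs)
    index = {d: k for k, d in enumerate(ids)}
    n = len(ids)
    adj = np.zeros((n, n), dtype=bool)
    for a, b in net.edges:
        adj[index[a], index[b]] = True
        adj[index[b], index[a]] = True
    deg = adj.sum(axis=1)

    g = net.to_networkx()
    betw_map = nx.betweenness_centrality(g, normalized=True)
    clus_map = nx.clustering(g)
    betw = np.array([betw_map[d] for d in ids], dtype=float)
    clus = np.array([clus_map[d] for d in ids], dtype=float)

    # Endpoint-removed neighbor Jaccard.  With no self-loops the intersection
    # N(i) ∩ N(j) can contain neither i nor j, so only the union shrinks —
    # by 2 exactly when (i, j) is an edge (i ∈ N(j) and j ∈ N(i)).
    inter = (adj.astype(np.int32) @ adj.astype(np.int32)).astype(float)
    union = deg[:, None] + deg[None, :] - inter - 2.0 * adj
    with np.errstate(invalid="ignore", divide="ignore"):
        jac = np.where(union > 0, inter / np.maximum(union, 1e-300), 0.0)
    np.fill_diagonal(jac, 0.0)

    drug_list = [net.drugs[d] for d in ids]
    atc = pairwise_atc_min(drug_list, tax)
    ssim = pairwise_structural_jaccard(drug_list)

    nbrs = [np.flatnonzero(adj[k]) for k in range(n)]
    return _PairwiseCache(ids, index, adj, deg.astype(float), betw, clus,
                          jac, atc, ssim, nbrs)


def build_covariate_table(
    net: DDINetwork,
    tax: ATCTaxonomy,
    pairs: Iterable[tuple[str, str]],
) -> pd.DataFrame:
    """Assemble the pair-level covariate table.

    One row per requested unordered pair, in canonical (sorted-key) order,
    with all nine covariates and ``response`` = 1 iff the pair is an edge of
    ``net``.  Covariates are computed on ``net`` itself, so passing a
    severity sub-network evaluates everything on that sub-network.
    """
    pair_keys = sorted({canonical_pair(*p) for p in pairs})
    for a, b in pair_keys:
        for d in (a, b):
            if d not in net.drugs:
                raise KeyError(f"pair drug not in network: {d!r}")
    cols = ["drug_a", "drug_b", *COVARIATE_NAMES, "response"]
    if not pair_keys:
        return pd.DataFrame(columns=cols)

    cache = _pairwise_cache(net, tax)
    d_max = float(tax.max_distance)
    out = np.empty((len(pair_keys), len(COVARIATE_NAMES) + 1), dtype=float)
    for r, (da, db) in enumerate(pair_keys):
        a, b = cache.index[da], cache.index[db]
        na = cache.nbrs[a]
        nb = cache.nbrs[b]
        nb_not_a = nb[nb != a]
        na_not_b = na[na != b]

        jrow_a = cache.jaccard[a, nb_not_a]
        jrow_b = cache.jaccard[b, na_not_b]
        s_a = _top2_mean_np(jrow_a)
        s_b = _top2_mean_np(jrow_b)

        t_a = cache.atc_dist[a, nb_not_a].min() if nb_not_a.size else d_max
        t_b = cache.atc_dist[b, na_not_b].min() if na_not_b.size else d_max

        m_a = cache.str_sim[a, nb_not_a].max() if nb_not_a.size else 0.0
        m_b = cache.str_sim[b, na_not_b].max() if na_not_b.size else 0.0

        out[r] = (
            cache.degree[a] * cache.degree[b],
            cache.betweenness[a] * cache.betweenness[b],
            max(cache.clustering[a], cache.clustering[b]),
            cache.jaccard[a, b],
            (s_a + s_b) / 2.0,
            cache.atc_dist[a, b],
            t_a * t_b,
            cache.str_sim[a, b],
            m_a * m_b,
            1.0 if cache.adj[a, b] else 0.0,
        )
    df = pd.DataFrame(out, columns=[*COVARIATE_NAMES, "response"])
    df.insert(0, "drug_b", [p[1] for p in pair_keys])
    df.insert(0, "drug_a", [p[0] for p in pair_keys])
    df["response"] = df["response"].astype(int)
    return df


def _top2_mean_np(values: np.ndarray) -> float:
    if values.size == 0:
        return 0.0
    if values.size == 1:
        return float(values[0])
    top = np.partition(values, values.size - 2)[-2:]
    return float(top.mean())
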