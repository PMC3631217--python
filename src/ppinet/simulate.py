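"""Synthetic drug universes and DDI snapshots with planted structure.

The real inputs the method was developed on — two chronological snapshots of
a proprietary drug-safety database, plus taxonomy codes and chemical
fingerprints per drug — cannot be redistributed, so every pipeline stage is
exercised on generated data with known ground truth:

* a complete synthetic taxonomy tree with configurable per-level branching;
* drugs carrying one or two taxonomy leaf codes and a class-correlated
  binary fingerprint (same-leaf drugs share a bit template, so structural
  similarity tracks taxonomic class);
* a training snapshot whose edge probabilities follow a logistic model with
  planted coefficients on taxonomy and fingerprint similarity plus per-drug
  Gaussian propensities (degree heterogeneity / heavy tail), with the
  intercept calibrated by bisection to a target edge density;
* a later snapshot adding future edges sampled from the *same* planted
  model among the training non-edges, calibrated to a target new-edge rate —
  the premise under test being that present network structure predicts
  future reports.

Defaults mirror the scale of the motivating study where stated: ~15% training
edge density, future edges covering 1.4% of training non-edges, the published
severity mix, and 300 drugs (a desk-scale stand-in for the 856-drug network).
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.special import expit

from .covariates import ATCTaxonomy, pairwise_atc_min, pairwise_structural_jaccard
from .network import DDINetwork, Drug, Interaction, Severity

__all__ = [
    "GeneratorConfig",
    "SyntheticTruth",
    "generate_taxonomy",
    "generate_drugs",
    "generate_snapshot",
    "generate_future_edges",
    "generate_benchmark",
    "null_config",
]

#: severity proportions of the 2009-style training snapshot
#: (minor, moderate, major, contraindicated) — moderate is the remainder
DEFAULT_SEVERITY_MIX = (0.0760, 0.7515, 0.1307, 0.0418)

SEVERITY_ORDER = (
    Severity.MINOR, Severity.MODERATE, Severity.MAJOR, Severity.CONTRAINDICATED
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Stated world of the synthetic benchmark.

    ``beta`` carries the planted coefficients on the two pair-similarity
    terms used inside the generator: taxonomy similarity ``exp(-d_atc/2)``
    and fingerprint Jaccard.  ``propensity_sd`` is the SD of per-drug
    additive log-odds propensities producing degree heterogeneity.
    """

    n_drugs: int = 300
    taxonomy_shape: tuple[int, ...] = (2, 2, 2, 1, 1)
    fingerprint_bits: int = 128
    class_bias: float = 0.9
    template_mutation: float = 0.10
    second_code_rate: float = 0.15
    beta: tuple[float, float] = (4.0, 4.0)
    propensity_sd: float = 0.8
    target_density: float = 0.15
    future_rate: float = 0.014
    severity_mix: tuple[float, ...] = DEFAULT_SEVERITY_MIX
    n_types: int = 20
    type_clustering: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.severity_mix) - 1.0) > 1e-9:
            raise ValueError("severity_mix must sum to 1")
        if not 0.0 < self.target_density < 1.0:
            raise ValueError("target_density must be in (0, 1)")
        if not 0.0 < self.future_rate < 1.0:
            raise ValueError("future_rate must be in (0, 1)")
        if not 0.0 <= self.class_bias <= 1.0:
            raise ValueError("class_bias must be in [0, 1]")
        if self.propensity_sd < 0:
            raise ValueError("propensity_sd must be >= 0")


@dataclass
class SyntheticTruth:
    """Ground truth behind one generated benchmark."""

    beta0: float
    beta: tuple[float, float]
    propensities: dict[str, float]
    pair_ids: list[tuple[str, str]]
    edge_probabilities: np.ndarray       # aligned with pair_ids
    leaf_type: dict[str, str] = field(default_factory=dict)
    future_positives: set[tuple[str, str]] = field(default_factory=set)

    def to_dict(self) -> dict:
        return {
            "beta0": self.beta0,
            "beta": list(self.beta),
            "propensities": self.propensities,
            "pairs": ["|".join(p) for p in self.pair_ids],
            "edge_probabilities": self.edge_probabilities.tolist(),
            "future_positives": sorted("|".join(p) for p in self.future_positives),
        }


def generate_taxonomy(config: GeneratorConfig) -> ATCTaxonomy:
    """Complete taxonomy tree with the configured per-level branching.

    Leaves get synthetic full codes in the standard 7-character dialect
    (letter / two digits / letter / letter / two digits), so the leaf count
    is the product of the branching factors.
    """
    shape = tuple(config.taxonomy_shape)
    if len(shape) != 5:
        raise ValueError("taxonomy_shape must give branching for 5 levels")
    if any(b < 1 for b in shape):
        raise ValueError("branching factors must be >= 1")
    if shape[0] > 26 or shape[2] > 26 or shape[3] > 26:
        raise ValueError("letter levels support at most 26 branches")
    if shape[1] > 100 or shape[4] > 100:
        raise ValueError("digit levels support at most 100 branches")
    letters = string.ascii_uppercase
    codes = [
        f"{letters[i1]}{i2:02d}{letters[i3]}{letters[i4]}{i5:02d}"
        for i1 in range(shape[0])
        for i2 in range(shape[1])
        for i3 in range(shape[2])
        for i4 in range(shape[3])
        for i5 in range(shape[4])
    ]
    return ATCTaxonomy(codes)


def generate_drugs(
    config: GeneratorConfig, tax: ATCTaxonomy, rng: np.random.Generator | None = None
) -> dict[str, Drug]:
    """Drug universe with class-correlated attributes.

    Each drug draws a primary taxonomy leaf (and a second leaf with
    probability ``second_code_rate``, mirroring multi-position drugs) and a
    fingerprint built from its primary leaf's bit template with each bit
    flipped independently with probability ``(1 - class_bias) / 2`` — at
    ``class_bias=1`` same-leaf drugs are structurally identical, at 0 the
    fingerprint is independent of class.

    Leaf templates are not independent: a root template mutates down the
    taxonomy tree with per-bit rate ``template_mutation`` at each level, so
    structural similarity grades continuously with taxonomic proximity, as
    it does for real chemical classes.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    leaves = sorted(tax.codes)
    templates = _evolve_templates(config, tax, leaves, rng)
    flip_p = (1.0 - config.class_bias) / 2.0
    width = max(4, len(str(config.n_drugs)))
    drugs: dict[str, Drug] = {}
    for k in range(config.n_drugs):
        drug_id = f"D{k:0{width}d}"
        primary = int(rng.integers(len(leaves)))
        codes = {leaves[primary]}
        if rng.random() < config.second_code_rate:
            codes.add(leaves[int(rng.integers(len(leaves)))])
        flips = rng.random(config.fingerprint_bits) < flip_p
        bits = np.where(flips, 1 - templates[primary], templates[primary])
        subs = frozenset(f"S{b:04d}" for b in np.flatnonzero(bits))
        drugs[drug_id] = Drug(drug_id=drug_id, atc_codes=frozenset(codes),
                              substructures=subs)
    return drugs


def _evolve_templates(
    config: GeneratorConfig, tax: ATCTaxonomy, leaves: list[str],
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-leaf bit templates mutated down the taxonomy from a shared root."""
    bits = config.fingerprint_bits
    node_template: dict[str, np.ndarray] = {"": rng.integers(0, 2, size=bits)}
    # breadth-first by prefix length so parents are materialized first
    prefixes = sorted({p for leaf in leaves for p in tax.path(leaf)}, key=len)
    chains = {leaf: ("",) + tax.path(leaf) for leaf in leaves}
    parent_of = {}
    for leaf in leaves:
        chain = chains[leaf]
        for par, child in zip(chain, chain[1:]):
            parent_of[child] = par
    for node in prefixes:
        flips = rng.random(bits) < config.template_mutation
        node_template[node] = np.where(flips, 1 - node_template[parent_of[node]],
                                       node_template[parent_of[node]])
    return np.stack([node_template[leaf] for leaf in leaves])


def _primary_leaf(drug: Drug) -> str:
    return min(drug.atc_codes)


def _pair_logits(
    config: GeneratorConfig,
    drugs: dict[str, Drug],
    tax: ATCTaxonomy,
    propensities: np.ndarray,
):
    ids = sorted(drugs)
    drug_list = [drugs[d] for d in ids]
    atc = pairwise_atc_min(drug_list, tax)
    ssim = pairwise_structural_jaccard(drug_list)
    iu = np.triu_indices(len(ids), k=1)
    taxsim = np.exp(-atc[iu] / 2.0)
    strsim = ssim[iu]
    base = (config.beta[0] * taxsim + config.beta[1] * strsim
            + propensities[iu[0]] + propensities[iu[1]])
    pairs = [(ids[a], ids[b]) for a, b in zip(*iu)]
    return pairs, base


def _calibrate_intercept(base: np.ndarray, target: float) -> float:
    """Bisection on the intercept so the mean edge probability hits target."""
    lo, hi = -40.0, 40.0
    if not expit(lo + base).mean() < target < expit(hi + base).mean():
        raise ValueError(f"target density {target} unattainable for this model")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        mean_p = float(expit(mid + base).mean())
        if mean_p < target:
            lo = mid
        else:
            hi = mid
        if abs(mean_p - target) <= 1e-4 * target:
            return mid
    return 0.5 * (lo + hi)


def _draw_label(
    config: GeneratorConfig, drugs: dict[str, Drug], a: str, b: str,
    leaf_type: dict[str, str], rng: np.random.Generator,
) -> tuple[Severity, str]:
    sev = SEVERITY_ORDER[rng.choice(len(SEVERITY_ORDER), p=np.asarray(config.severity_mix))]
    if rng.random() < config.type_clustering:
        endpoint = a if rng.random() < 0.5 else b
        label = leaf_type[_primary_leaf(drugs[endpoint])]
    else:
        label = f"T{int(rng.integers(config.n_types)):03d}"
    return sev, label


def _leaf_type_map(config: GeneratorConfig, tax: ATCTaxonomy) -> dict[str, str]:
    return {leaf: f"T{k % config.n_types:03d}"
            for k, leaf in enumerate(sorted(tax.codes))}


def generate_snapshot(
    config: GeneratorConfig,
    drugs: dict[str, Drug],
    tax: ATCTaxonomy,
    rng: np.random.Generator | None = None,
) -> tuple[DDINetwork, SyntheticTruth]:
    """Training snapshot sampled from the planted edge-probability model.

    Edge probability for pair (i, j) is
    ``expit(beta0 + beta . (exp(-d_atc/2), str_jaccard) + a_i + a_j)`` with
    ``a ~ Normal(0, propensity_sd^2)`` and ``beta0`` calibrated so the
    expected density equals ``target_density``.  Edges are sampled
    independently; severities follow ``severity_mix``; type labels come from
    a leaf-class-linked type with probability ``type_clustering``, else
    uniformly from the type alphabet.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    ids = sorted(drugs)
    prop = rng.normal(0.0, config.propensity_sd, size=len(ids))
    pairs, base = _pair_logits(config, drugs, tax, prop)
    beta0 = _calibrate_intercept(base, config.target_density)
    probs = expit(beta0 + base)
    sampled = rng.random(len(pairs)) < probs
    leaf_type = _leaf_type_map(config, tax)
    edges = {}
    for (a, b), hit in zip(pairs, sampled):
        if hit:
            sev, label = _draw_label(config, drugs, a, b, leaf_type, rng)
            edges[(a, b)] = Interaction((a, b), sev, label)
    net = DDINetwork(drugs=dict(drugs), edges=edges, snapshot_label="train")
    truth = SyntheticTruth(
        beta0=beta0,
        beta=config.beta,
        propensities={d: float(p) for d, p in zip(ids, prop)},
        pair_ids=pairs,
        edge_probabilities=probs,
        leaf_type=leaf_type,
    )
    return net, truth


def generate_future_edges(
    truth: SyntheticTruth,
    net: DDINetwork,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> DDINetwork:
    """Later snapshot: the training edges plus newly reported ones.

    New edges are sampled among the training non-edges with probability
    proportional to their planted edge probability (capped at 1), with the
    proportionality constant bisected so the expected positive fraction of
    non-edges equals ``future_rate``.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    prob_of = dict(zip(truth.pair_ids, truth.edge_probabilities))
    nonedge_pairs = [p for p in truth.pair_ids if p not in net.edges]
    if not nonedge_pairs:
        raise ValueError("training network is complete; no non-edges to report")
    p = np.array([prob_of[pair] for pair in nonedge_pairs])
    if config.future_rate >= 1.0 or p.max() <= 0:
        raise ValueError("future_rate unattainable for this non-edge set")

    def mean_q(c: float) -> float:
        return float(np.minimum(1.0, c * p).mean())

    lo, hi = 0.0, 1.0
    while mean_q(hi) < config.future_rate:
        hi *= 2.0
        if hi > 1e12:
            raise ValueError("future_rate unattainable: non-edge probabilities too small")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if mean_q(mid) < config.future_rate:
            lo = mid
        else:
            hi = mid
    q = np.minimum(1.0, 0.5 * (lo + hi) * p)
    hits = rng.random(len(nonedge_pairs)) < q
    # new edges reuse the training snapshot's clustered type process
    leaf_type = truth.leaf_type
    edges = dict(net.edges)
    new_pairs = set()
    for pair, hit in zip(nonedge_pairs, hits):
        if hit:
            sev, label = _draw_label(config, net.drugs, pair[0], pair[1],
                                     leaf_type, rng)
            edges[pair] = Interaction(pair, sev, label)
            new_pairs.add(pair)
    truth.future_positives = new_pairs
    return DDINetwork(drugs=dict(net.drugs), edges=edges, snapshot_label="later")


def generate_benchmark(
    config: GeneratorConfig | None = None,
) -> tuple[DDINetwork, DDINetwork, ATCTaxonomy, SyntheticTruth]:
    """Run all generator stages: (train, later, taxonomy, truth)."""
    config = config if config is not None else GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    tax = generate_taxonomy(config)
    drugs = generate_drugs(config, tax, rng)
    train, truth = generate_snapshot(config, drugs, tax, rng)
    later = generate_future_edges(truth, train, config, rng)
    return train, later, tax, truth


def null_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """The no-signal world: flat edge probabilities, no degree heterogeneity."""
    return replace(GeneratorConfig(seed=seed, **overrides),
                   beta=(0.0, 0.0), propensity_sd=0.0)
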