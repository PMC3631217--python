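"""Severity-labelled drug-drug interaction (DDI) networks.

A DDI network is an undirected simple graph whose nodes are drugs (generic-name
keyed active pharmaceutical ingredients) and whose edges are known interactions,
each carrying a clinical severity level and an interaction-type label.  The
module builds such networks from edge-record tables, induces the per-severity
sub-networks used for stratified analysis, enumerates non-edges (the candidate
space for link prediction), and constructs the simulated-prospective validation
split between two chronological snapshots: the model trains on the earlier
snapshot and is evaluated on which of its non-edges appear as newly reported
interactions in the later one.
"""

from __future__ import annotations

import enum
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger("ppinet")

__all__ = [
    "Severity",
    "Drug",
    "Interaction",
    "DDINetwork",
    "ValidationSplit",
    "canonical_pair",
    "build_network",
    "induce_severity_subnetwork",
    "non_edges",
    "make_validation_split",
    "summarize",
    "read_edge_list",
    "write_edge_list",
    "read_drug_attributes",
    "write_drug_attributes",
    "read_network_json",
    "write_network_json",
]


class Severity(enum.Enum):
    """Clinical-significance class of an interaction.

    Ordered by increasing severity; ``unspecified`` sorts lowest so that a
    labelled duplicate always wins over an unlabelled one.
    """

    UNSPECIFIED = 0
    MINOR = 1
    MODERATE = 2
    MAJOR = 3
    CONTRAINDICATED = 4

    @classmethod
    def parse(cls, value: "str | Severity") -> "Severity":
        if isinstance(value, cls):
            return value
        try:
            return cls[str(value).strip().upper()]
        except KeyError:
            raise ValueError(f"unknown severity level: {value!r}") from None

    def __str__(self) -> str:  # TSV serialization form
        return self.name.lower()


@dataclass(frozen=True)
class Drug:
    """A drug node: identifier plus taxonomy codes and substructure fingerprint.

    ``atc_codes`` are full hierarchical taxonomy codes (WHO ATC style, five
    nested levels); ``substructures`` is the set of "on" bits of a binary
    chemical fingerprint.
    """

    drug_id: str
    atc_codes: frozenset[str] = frozenset()
    substructures: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.drug_id:
            raise ValueError("drug_id must be nonempty")
        object.__setattr__(self, "atc_codes", frozenset(self.atc_codes))
        object.__setattr__(self, "substructures", frozenset(self.substructures))


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Canonical unordered-pair key: lexicographically sorted endpoint ids."""
    if a == b:
        raise ValueError(f"self-pair not allowed: {a!r}")
    return (a, b) if a < b else (b, a)


@dataclass(frozen=True)
class Interaction:
    """One undirected interaction edge with severity and type label."""

    pair: tuple[str, str]
    severity: Severity = Severity.UNSPECIFIED
    type_label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "pair", canonical_pair(*self.pair))


@dataclass
class DDINetwork:
    """Undirected simple graph over drugs with severity/type-labelled edges."""

    drugs: dict[str, Drug]
    edges: dict[tuple[str, str], Interaction] = field(default_factory=dict)
    snapshot_label: str = ""

    @property
    def n_drugs(self) -> int:
        return len(self.drugs)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_pairs(self) -> int:
        n = self.n_drugs
        return n * (n - 1) // 2

    def has_edge(self, a: str, b: str) -> bool:
        return canonical_pair(a, b) in self.edges

    def neighbors(self, drug_id: str) -> set[str]:
        if drug_id not in self.drugs:
            raise KeyError(f"unknown drug: {drug_id!r}")
        out = set()
        for a, b in self.edges:
            if a == drug_id:
                out.add(b)
            elif b == drug_id:
                out.add(a)
        return out

    def degree(self, drug_id: str) -> int:
        return len(self.neighbors(drug_id))

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.drugs)
        for (a, b), inter in self.edges.items():
            g.add_edge(a, b, severity=inter.severity, type_label=inter.type_label)
        return g


@dataclass
class ValidationSplit:
    """Simulated-prospective split: train network, its non-edges, and the
    subset of those non-edges newly reported in the later snapshot."""

    train: DDINetwork
    candidate_pairs: set[tuple[str, str]]
    positives: set[tuple[str, str]]

    def labels(self, pairs: Sequence[tuple[str, str]]) -> list[int]:
        """Binary outcome (newly-reported interaction) per candidate pair."""
        return [1 if p in self.positives else 0 for p in pairs]


# ---------------------------------------------------------------------------
# construction

def build_network(
    edge_records: Iterable[tuple],
    attributes: "Mapping[str, Drug] | Iterable[Drug] | pd.DataFrame",
    snapshot_label: str = "",
) -> DDINetwork:
    """Build a DDI network from interaction records and per-drug attributes.

    Parameters
    ----------
    edge_records
        Iterable of ``(drug_a, drug_b, severity, type_label)`` records.
        Duplicate records of the same unordered pair collapse to a single
        edge; conflicting severities keep the most severe (conservative
        safety semantics) with a warning.
    attributes
        The drug universe: a mapping/iterable of :class:`Drug`, or a frame
        with columns ``drug_id``, ``atc_codes``, ``substructures``.  The
        network contains exactly these drugs, including isolated ones.

    Raises
    ------
    ValueError
        On a self-loop record, or on records naming drugs missing from
        ``attributes`` (all missing ids are listed).
    """
    drugs = _coerce_drugs(attributes)
    edges: dict[tuple[str, str], Interaction] = {}
    missing: set[str] = set()
    for rec in edge_records:
        a, b, severity, type_label = rec
        if a == b:
            raise ValueError(f"self-loop record rejected: {rec!r}")
        for d in (a, b):
            if d not in drugs:
                missing.add(d)
        if missing:
            continue
        pair = canonical_pair(a, b)
        sev = Severity.parse(severity)
        prev = edges.get(pair)
        if prev is None:
            edges[pair] = Interaction(pair, sev, str(type_label))
        elif sev.value > prev.severity.value:
            warnings.warn(
                f"conflicting severities for pair {pair}: keeping most severe "
                f"{sev} over {prev.severity}",
                stacklevel=2,
            )
            edges[pair] = Interaction(pair, sev, str(type_label))
        elif sev.value < prev.severity.value:
            warnings.warn(
                f"conflicting severities for pair {pair}: keeping most severe "
                f"{prev.severity} over {sev}",
                stacklevel=2,
            )
    if missing:
        raise ValueError(
            "edge records reference drugs missing from attributes: "
            + ", ".join(sorted(missing))
        )
    return DDINetwork(drugs=drugs, edges=edges, snapshot_label=snapshot_label)


def _coerce_drugs(attributes) -> dict[str, Drug]:
    if isinstance(attributes, pd.DataFrame):
        out: dict[str, Drug] = {}
        for row in attributes.itertuples(index=False):
            d = Drug(
                drug_id=str(row.drug_id),
                atc_codes=_split_field(getattr(row, "atc_codes", "")),
                substructures=_split_field(getattr(row, "substructures", "")),
            )
            if d.drug_id in out:
                raise ValueError(f"duplicate drug_id in attributes: {d.drug_id!r}")
            out[d.drug_id] = d
        return out
    if isinstance(attributes, Mapping):
        return dict(attributes)
    out = {}
    for d in attributes:
        if d.drug_id in out:
            raise ValueError(f"duplicate drug_id in attributes: {d.drug_id!r}")
        out[d.drug_id] = d
    return out


def _split_field(raw) -> frozenset[str]:
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return frozenset()
    items = [s.strip() for s in str(raw).split(";")]
    return frozenset(s for s in items if s)


def induce_severity_subnetwork(net: DDINetwork, severity: "Severity | str") -> DDINetwork:
    """Sub-network induced by the edges of one severity class.

    Contains exactly the matching edges plus the drugs incident to at least
    one of them (isolated drugs are dropped; an empty class yields an empty
    network).
    """
    sev = Severity.parse(severity)
    edges = {p: e for p, e in net.edges.items() if e.severity is sev}
    node_ids = {d for pair in edges for d in pair}
    return DDINetwork(
        drugs={d: net.drugs[d] for d in node_ids},
        edges=edges,
        snapshot_label=f"{net.snapshot_label}:{sev}",
    )


def non_edges(net: DDINetwork) -> set[tuple[str, str]]:
    """All unordered drug pairs of the network that are not edges."""
    ids = sorted(net.drugs)
    out: set[tuple[str, str]] = set()
    for idx, a in enumerate(ids):
        for b in ids[idx + 1:]:
            if (a, b) not in net.edges:
                out.add((a, b))
    return out


def make_validation_split(train: DDINetwork, later: DDINetwork) -> ValidationSplit:
    """Simulated-prospective split between two chronological snapshots.

    Candidate pairs are the train non-edges; positives are those candidates
    reported as edges in the later snapshot.  The drug universe is fixed at
    the training drugs: later-only drugs are ignored, and a train drug absent
    from the later snapshot only triggers a warning (its candidate pairs stay,
    with no possible positives).
    """
    for d in train.drugs:
        if d not in later.drugs:
            warnings.warn(
                f"train drug {d!r} absent from later snapshot; its candidate "
                "pairs are retained with no possible positives",
                stacklevel=2,
            )
    candidates = non_edges(train)
    positives = {p for p in candidates if p in later.edges}
    return ValidationSplit(train=train, candidate_pairs=candidates, positives=positives)


def summarize(net: DDINetwork) -> dict:
    """Summary record: node/edge/non-edge counts, density, per-severity counts."""
    n, m = net.n_drugs, net.n_edges
    pairs = net.n_pairs
    by_severity = {str(s): 0 for s in Severity}
    for e in net.edges.values():
        by_severity[str(e.severity)] += 1
    return {
        "snapshot_label": net.snapshot_label,
        "n_drugs": n,
        "n_edges": m,
        "n_non_edges": pairs - m,
        "density": (m / pairs) if pairs else 0.0,
        "edges_by_severity": by_severity,
    }


# ---------------------------------------------------------------------------
# on-disk dialects (plain TSV, UTF-8)

EDGE_COLUMNS = ["drug_a", "drug_b", "severity", "type_label"]
ATTR_COLUMNS = ["drug_id", "atc_codes", "substructures"]


def write_edge_list(net: DDINetwork, path) -> None:
    rows = [
        (a, b, str(e.severity), e.type_label)
        for (a, b), e in sorted(net.edges.items())
    ]
    pd.DataFrame(rows, columns=EDGE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_edge_list(path) -> list[tuple[str, str, str, str]]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in EDGE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"edge list {path} missing columns: {missing}")
    return [tuple(r) for r in df[EDGE_COLUMNS].itertuples(index=False, name=None)]


def write_drug_attributes(drugs: Mapping[str, Drug], path) -> None:
    rows = [
        (d.drug_id, ";".join(sorted(d.atc_codes)), ";".join(sorted(d.substructures)))
        for d in sorted(drugs.values(), key=lambda d: d.drug_id)
    ]
    pd.DataFrame(rows, columns=ATTR_COLUMNS).to_csv(path, sep="\t", index=False)


def read_drug_attributes(path) -> dict[str, Drug]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ATTR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"attribute table {path} missing columns: {missing}")
    return _coerce_drugs(df)


def write_network_json(net: DDINetwork, path) -> None:
    """Self-contained JSON serialization of a network (drugs + edges)."""
    import json

    payload = {
        "snapshot_label": net.snapshot_label,
        "drugs": [
            {
                "drug_id": d.drug_id,
                "atc_codes": sorted(d.atc_codes),
                "substructures": sorted(d.substructures),
            }
            for d in sorted(net.drugs.values(), key=lambda d: d.drug_id)
        ],
        "edges": [
            [a, b, str(e.severity), e.type_label]
            for (a, b), e in sorted(net.edges.items())
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)


def read_network_json(path) -> DDINetwork:
    import json

    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    drugs = {
        d["drug_id"]: Drug(
            drug_id=d["drug_id"],
            atc_codes=frozenset(d.get("atc_codes", [])),
            substructures=frozenset(d.get("substructures", [])),
        )
        for d in payload["drugs"]
    }
    return build_network(payload["edges"], drugs,
                         snapshot_label=payload.get("snapshot_label", ""))
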