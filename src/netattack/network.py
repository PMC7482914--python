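"""Bipartite market-network data model and file I/O.

The central object is :class:`MarketNetwork`: an unweighted bipartite
graph between buyers and vendors, where a tie records that the buyer has
purchased from the vendor at least once, together with a per-vendor
reputation score (cumulative sales rating).  A :class:`NetworkPanel`
bundles two or more observations of the same actor set in time order and
is the input to estimation.

Ties are binary: repeat purchases collapse onto a single tie.  Buyer and
vendor ids live in disjoint namespaces (generated data uses ``b####`` /
``v###`` prefixes), which makes accidental bipartition violations loud.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .errors import SchemaError, UnknownActorError, ValidationError

__all__ = [
    "MarketNetwork",
    "NetworkPanel",
    "degree",
    "tie_count",
    "isolates",
    "read_network",
    "write_network",
    "to_networkx",
    "write_graphml",
]


@dataclass
class MarketNetwork:
    """Bipartite buyer-vendor network with vendor reputations.

    Parameters
    ----------
    buyers, vendors
        Disjoint actor-id sets.
    ties
        Set of ``(buyer_id, vendor_id)`` pairs; undirected across the
        bipartition, no duplicates (set semantics).
    reputation
        Map ``vendor_id -> cumulative sales rating`` (non-negative,
        rating units); must be defined for every vendor.
    """

    buyers: set[str]
    vendors: set[str]
    ties: set[tuple[str, str]]
    reputation: dict[str, float]

    def __post_init__(self) -> None:
        self.buyers = set(self.buyers)
        self.vendors = set(self.vendors)
        self.ties = set(self.ties)
        self.reputation = dict(self.reputation)
        self.validate()

    def validate(self) -> None:
        """Check every structural invariant; raise ValidationError on failure."""
        overlap = self.buyers & self.vendors
        if overlap:
            raise ValidationError(f"actor ids in both roles: {sorted(overlap)[:5]}")
        for b, v in self.ties:
            if b not in self.buyers:
                raise ValidationError(f"tie endpoint {b!r} is not a declared buyer")
            if v not in self.vendors:
                raise ValidationError(f"tie endpoint {v!r} is not a declared vendor")
        missing = self.vendors - self.reputation.keys()
        if missing:
            raise ValidationError(f"vendors without reputation: {sorted(missing)[:5]}")
        for v, r in self.reputation.items():
            if v not in self.vendors:
                raise ValidationError(f"reputation for undeclared vendor {v!r}")
            if r < 0:
                raise ValidationError(f"negative reputation {r} for vendor {v!r}")

    # -- basic accounting -------------------------------------------------

    def degrees(self) -> dict[str, int]:
        """Degree of every actor (buyers and vendors), isolates included."""
        deg = dict.fromkeys(self.buyers, 0)
        deg.update(dict.fromkeys(self.vendors, 0))
        for b, v in self.ties:
            deg[b] += 1
            deg[v] += 1
        return deg

    def degree(self, actor_id: str) -> int:
        if actor_id in self.buyers:
            return sum(1 for b, _ in self.ties if b == actor_id)
        if actor_id in self.vendors:
            return sum(1 for _, v in self.ties if v == actor_id)
        raise UnknownActorError(actor_id)

    def tie_count(self) -> int:
        return len(self.ties)

    def isolates(self) -> set[str]:
        """Actors of either role with no incident tie."""
        connected = {b for b, _ in self.ties} | {v for _, v in self.ties}
        return (self.buyers | self.vendors) - connected

    def copy(self) -> "MarketNetwork":
        return MarketNetwork(
            buyers=set(self.buyers),
            vendors=set(self.vendors),
            ties=set(self.ties),
            reputation=dict(self.reputation),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MarketNetwork):
            return NotImplemented
        return (
            self.buyers == other.buyers
            and self.vendors == other.vendors
            and self.ties == other.ties
            and self.reputation == other.reputation
        )


# Module-level aliases matching the functional surface used elsewhere.

def degree(net: MarketNetwork, actor_id: str) -> int:
    """Raw number of ties incident to the actor."""
    return net.degree(actor_id)


def tie_count(net: MarketNetwork) -> int:
    return net.tie_count()


def isolates(net: MarketNetwork) -> set[str]:
    return net.isolates()


@dataclass
class NetworkPanel:
    """Ordered sequence (length >= 2) of observations of one actor set.

    ``wave_times`` are nominal labels; only their strict ordering matters
    because the change process is a continuous-time chain and the real
    clock between observations is arbitrary.
    """

    waves: Sequence[MarketNetwork]
    wave_times: Sequence[float] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.waves = list(self.waves)
        if len(self.waves) < 2:
            raise ValidationError("a panel needs at least two waves")
        if self.wave_times is None:
            self.wave_times = list(range(len(self.waves)))
        self.wave_times = list(self.wave_times)
        if len(self.wave_times) != len(self.waves):
            raise ValidationError("wave_times length must match waves")
        if any(t1 >= t2 for t1, t2 in zip(self.wave_times, self.wave_times[1:])):
            raise ValidationError("wave_times must be strictly increasing")
        first = self.waves[0]
        for w in self.waves[1:]:
            if w.buyers != first.buyers or w.vendors != first.vendors:
                raise ValidationError("actor sets must be constant across waves")


# -- file I/O -------------------------------------------------------------

_EDGE_COLS = ["buyer_id", "vendor_id"]
_ATTR_COLS = ["vendor_id", "reputation"]


def read_network(edge_path, attr_path, buyers_path=None) -> MarketNetwork:
    """Read a network from an edge-list CSV and a vendor-attribute CSV.

    The edge file needs columns ``buyer_id,vendor_id``; the attribute
    file ``vendor_id,reputation``.  Duplicate edge rows collapse onto a
    single tie with a warning.  An optional ``buyers_path`` (one
    ``buyer_id`` column) declares buyers with no edges, which an edge
    list alone cannot represent.
    """
    edges = pd.read_csv(edge_path, dtype=str)
    if list(edges.columns) != _EDGE_COLS:
        raise SchemaError(f"edge file must have columns {_EDGE_COLS}, got {list(edges.columns)}")
    attrs = pd.read_csv(attr_path, dtype={"vendor_id": str})
    if list(attrs.columns) != _ATTR_COLS:
        raise SchemaError(f"attribute file must have columns {_ATTR_COLS}, got {list(attrs.columns)}")
    if attrs["vendor_id"].duplicated().any():
        raise SchemaError("duplicate vendor rows in attribute file")

    vendors = set(attrs["vendor_id"])
    reputation = dict(zip(attrs["vendor_id"], attrs["reputation"].astype(float)))
    if any(r < 0 for r in reputation.values()):
        raise ValidationError("negative reputation in attribute file")

    n_rows = len(edges)
    tie_set = set(zip(edges["buyer_id"], edges["vendor_id"]))
    if len(tie_set) < n_rows:
        warnings.warn(
            f"{n_rows - len(tie_set)} duplicate edge row(s) collapsed to single ties",
            stacklevel=2,
        )
    undeclared = {v for _, v in tie_set} - vendors
    if undeclared:
        raise SchemaError(f"edges reference undeclared vendors: {sorted(undeclared)[:5]}")

    buyers = {b for b, _ in tie_set}
    if buyers_path is not None:
        extra = pd.read_csv(buyers_path, dtype=str)
        if list(extra.columns) != ["buyer_id"]:
            raise SchemaError("buyers file must have a single buyer_id column")
        buyers |= set(extra["buyer_id"])
    return MarketNetwork(buyers=buyers, vendors=vendors, ties=tie_set, reputation=reputation)


def write_network(net: MarketNetwork, edge_path, attr_path, buyers_path=None) -> None:
    """Write a network as edge-list + vendor-attribute CSVs (sorted, so
    output is byte-stable for a given network)."""
    edges = pd.DataFrame(sorted(net.ties), columns=_EDGE_COLS)
    edges.to_csv(edge_path, index=False)
    attrs = pd.DataFrame(
        [(v, net.reputation[v]) for v in sorted(net.vendors)], columns=_ATTR_COLS
    )
    attrs.to_csv(attr_path, index=False)
    if buyers_path is not None:
        pd.DataFrame({"buyer_id": sorted(net.buyers)}).to_csv(buyers_path, index=False)


def to_networkx(net: MarketNetwork):
    """Convert to a networkx Graph with ``role`` and ``reputation`` node
    attributes (bipartite 0 = buyers, 1 = vendors)."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(net.buyers, role="buyer", bipartite=0)
    g.add_nodes_from(
        ((v, {"role": "vendor", "bipartite": 1, "reputation": float(net.reputation[v])}) for v in net.vendors)
    )
    g.add_edges_from(net.ties)
    return g


def write_graphml(net: MarketNetwork, path) -> None:
    import networkx as nx

    nx.write_graphml(to_networkx(net), path)
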