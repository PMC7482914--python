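"""Stochastic actor-oriented simulation engine.

Network change is a continuous-time Markov chain: buyers receive
tie-change opportunities at a constant rate, and at each opportunity the
buyer compares candidate states — toggling each possible tie to a vendor
(create if absent, dissolve if present) plus "no change" — through a
linear objective function

    f(beta, x) = sum_k beta_k * s_k(x)

evaluated on the buyer's personal network in the candidate state, and
picks a candidate by multinomial logit over the f values.  Vendors are
passive alters; reputations are frozen covariates during a chain.

Effects (the statistics ``s_k``) are registered classes so alternative
functional forms can be added without touching the engine.  The default
effect set is:

``outdegree``
    number of the buyer's ties (its negative coefficient is the cost of
    maintaining ties);
``alter_reputation``
    summed cumulative sales rating over tied vendors (reputation-driven
    attachment);
``alter_popularity``
    summed sqrt(vendor degree) over tied vendors (degree popularity with
    the conventional bounded-influence square root).

Two code paths compute identical quantities: a slow, readable path over
:class:`MarketNetwork` objects (``effect_statistics``,
``choice_probabilities``, ``micro_step``) and a vectorized path over an
array-backed :class:`ChainState` used by :func:`simulate_chain`.  Tests
pin the two paths together.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ContractError, ValidationError
from .network import MarketNetwork

__all__ = [
    "Effect",
    "OutdegreeEffect",
    "AlterReputationEffect",
    "AlterPopularityEffect",
    "EffectSet",
    "default_effects",
    "ParameterVector",
    "SimState",
    "ChainState",
    "effect_statistics",
    "objective",
    "choice_probabilities",
    "micro_step",
    "simulate_chain",
    "simulate_chain_conditional",
]


# -- effects --------------------------------------------------------------


class Effect:
    """One statistic s_k of a buyer's personal network.

    Subclasses implement the slow per-network form :meth:`statistic`, the
    vectorized candidate-delta form :meth:`candidate_deltas` (change in
    s_k for toggling each vendor, given the current array state), and the
    network total :meth:`total` used as a method-of-moments target.
    """

    name: str

    def statistic(self, buyer: str, net: MarketNetwork) -> float:
        raise NotImplementedError

    def candidate_deltas(self, state: "ChainState", b: int) -> np.ndarray:
        raise NotImplementedError

    def total(self, state: "ChainState") -> float:
        raise NotImplementedError


class OutdegreeEffect(Effect):
    name = "outdegree"

    def statistic(self, buyer, net):
        return float(sum(1 for bb, _ in net.ties if bb == buyer))

    def candidate_deltas(self, state, b):
        return 1.0 - 2.0 * state.adj[b]

    def total(self, state):
        return float(state.adj.sum())


class AlterReputationEffect(Effect):
    name = "alter_reputation"

    def statistic(self, buyer, net):
        missing = net.vendors - net.reputation.keys()
        if missing:
            raise ValidationError(f"vendors missing reputation: {sorted(missing)[:5]}")
        return float(sum(net.reputation[v] for bb, v in net.ties if bb == buyer))

    def candidate_deltas(self, state, b):
        return state.rep * (1.0 - 2.0 * state.adj[b])

    def total(self, state):
        return float(state.vdeg @ state.rep)


class AlterPopularityEffect(Effect):
    """Sum over tied vendors of sqrt(vendor degree), evaluated on the
    candidate state (so creating a tie to v contributes sqrt(deg_v + 1))."""

    name = "alter_popularity"

    def statistic(self, buyer, net):
        deg = net.degrees()
        return float(sum(math.sqrt(deg[v]) for bb, v in net.ties if bb == buyer))

    def candidate_deltas(self, state, b):
        row = state.adj[b]
        return np.where(row, -np.sqrt(state.vdeg), np.sqrt(state.vdeg + 1.0))

    def total(self, state):
        return float(np.sum(state.vdeg ** 1.5))


@dataclass(frozen=True)
class EffectSet:
    """Ordered list of effects; the order fixes the parameter-vector order."""

    effects: tuple[Effect, ...]

    def __post_init__(self):
        names = [e.name for e in self.effects]
        if len(set(names)) != len(names):
            raise ValidationError(f"duplicate effect names: {names}")

    def __len__(self) -> int:
        return len(self.effects)

    def __iter__(self):
        return iter(self.effects)

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.effects]


def default_effects() -> EffectSet:
    return EffectSet((OutdegreeEffect(), AlterReputationEffect(), AlterPopularityEffect()))


@dataclass(frozen=True)
class ParameterVector:
    """Objective-function coefficients plus the opportunity rate
    (expected tie-change opportunities per buyer per period)."""

    beta: np.ndarray
    rate: float

    def __post_init__(self):
        object.__setattr__(self, "beta", np.asarray(self.beta, dtype=float))
        if self.rate <= 0:
            raise ContractError("rate must be positive")


# -- array-backed chain state --------------------------------------------


class ChainState:
    """Dense bipartite adjacency plus cached vendor degrees/reputations.

    ``adj`` is a (n_buyers, n_vendors) boolean matrix; ``buyers`` and
    ``vendors`` are the sorted id lists fixing row/column order.
    """

    __slots__ = ("buyers", "vendors", "adj", "vdeg", "rep")

    def __init__(self, net: MarketNetwork):
        self.buyers = sorted(net.buyers)
        self.vendors = sorted(net.vendors)
        b_ix = {b: i for i, b in enumerate(self.buyers)}
        v_ix = {v: j for j, v in enumerate(self.vendors)}
        self.adj = np.zeros((len(self.buyers), len(self.vendors)), dtype=bool)
        for b, v in net.ties:
            self.adj[b_ix[b], v_ix[v]] = True
        self.vdeg = self.adj.sum(axis=0).astype(float)
        self.rep = np.array([net.reputation[v] for v in self.vendors], dtype=float)

    def to_network(self) -> MarketNetwork:
        bi, vi = np.nonzero(self.adj)
        ties = {(self.buyers[i], self.vendors[j]) for i, j in zip(bi, vi)}
        return MarketNetwork(
            buyers=set(self.buyers),
            vendors=set(self.vendors),
            ties=ties,
            reputation={v: float(r) for v, r in zip(self.vendors, self.rep)},
        )


@dataclass
class SimState:
    """Mutable simulation state: the network, nominal elapsed time, and
    the RNG stream driving the chain."""

    network: MarketNetwork
    elapsed: float = 0.0
    rng: np.random.Generator = field(default_factory=np.random.default_rng)


# -- objective and choice -------------------------------------------------


def effect_statistics(buyer: str, net: MarketNetwork, effects: EffectSet) -> np.ndarray:
    """s(x) for the buyer's current personal network."""
    if buyer not in net.buyers:
        raise ContractError(f"{buyer!r} is not a buyer in this network")
    return np.array([e.statistic(buyer, net) for e in effects], dtype=float)


def objective(buyer: str, net: MarketNetwork, beta: np.ndarray, effects: EffectSet) -> float:
    """f(beta, x) = beta . s(x); linear in beta."""
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (len(effects),):
        raise ContractError(f"beta has shape {beta.shape}, expected ({len(effects)},)")
    return float(beta @ effect_statistics(buyer, net, effects))


def _toggle(net: MarketNetwork, buyer: str, vendor: str) -> MarketNetwork:
    out = net.copy()
    tie = (buyer, vendor)
    if tie in out.ties:
        out.ties.discard(tie)
    else:
        out.ties.add(tie)
    return out


def choice_probabilities(
    buyer: str, net: MarketNetwork, beta: np.ndarray, effects: EffectSet
) -> dict[str | None, float]:
    """Multinomial-logit probabilities over candidate states.

    Candidates are toggling each buyer-vendor tie plus ``None`` for "no
    change"; P(c) = exp(f_c) / sum exp(f_c'), computed with a max shift
    for overflow safety.  With no vendors, returns ``{None: 1.0}``.
    """
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (len(effects),):
        raise ContractError(f"beta has shape {beta.shape}, expected ({len(effects)},)")
    vendors = sorted(net.vendors)
    if not vendors:
        return {None: 1.0}
    fs = np.array(
        [objective(buyer, _toggle(net, buyer, v), beta, effects) for v in vendors]
        + [objective(buyer, net, beta, effects)]
    )
    fs -= fs.max()
    p = np.exp(fs)
    p /= p.sum()
    return {**dict(zip(vendors, p[:-1])), None: float(p[-1])}


# -- chain dynamics -------------------------------------------------------


def _candidate_logits(state: ChainState, b: int, beta: np.ndarray, effects: EffectSet) -> np.ndarray:
    """Objective gain of toggling each vendor relative to no change."""
    df = np.zeros(len(state.vendors))
    for k, e in enumerate(effects):
        bk = beta[k]
        if bk != 0.0:
            df += bk * e.candidate_deltas(state, b)
    return df


def _step(
    state: ChainState, beta: np.ndarray, effects: EffectSet, rng: np.random.Generator
) -> tuple[int, int] | None:
    """One micro-step in place: uniform buyer, logit candidate, toggle.
    Returns the toggled (buyer, vendor) index pair, or None for "no
    change"."""
    n_b, n_v = state.adj.shape
    b = int(rng.integers(n_b))
    if n_v == 0:
        return None
    df = _candidate_logits(state, b, beta, effects)
    # candidate n_v is "no change" with gain 0
    m = max(df.max(), 0.0)
    p = np.empty(n_v + 1)
    np.exp(df - m, out=p[:n_v])
    p[n_v] = math.exp(-m)
    cum = np.cumsum(p)
    c = int(np.searchsorted(cum, rng.random() * cum[-1], side="right"))
    if c >= n_v:
        return None
    if state.adj[b, c]:
        state.adj[b, c] = False
        state.vdeg[c] -= 1.0
    else:
        state.adj[b, c] = True
        state.vdeg[c] += 1.0
    return (b, c)


def micro_step(state: SimState, beta: np.ndarray, effects: EffectSet) -> SimState:
    """Apply one tie-change opportunity to ``state`` and return it.

    One buyer is selected uniformly at random (constant rate function), a
    candidate is sampled from :func:`choice_probabilities`, and the
    toggle (or nothing) is applied.  Nominal elapsed time advances by
    1/n_buyers.
    """
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (len(effects),):
        raise ContractError(f"beta has shape {beta.shape}, expected ({len(effects)},)")
    if not state.network.buyers:
        raise ContractError("network has no buyers")
    chain = ChainState(state.network)
    _step(chain, beta, effects, state.rng)
    state.network = chain.to_network()
    state.elapsed += 1.0 / len(chain.buyers)
    return state


def simulate_chain(
    start: MarketNetwork,
    params: ParameterVector,
    effects: EffectSet | None = None,
    seed: int | np.random.Generator = 0,
) -> MarketNetwork:
    """Run one chain between observation moments and return the end state.

    The number of micro-steps is M ~ Poisson(rate * n_buyers) — the
    passage of real time between observations is arbitrary, so only the
    expected number of opportunities per buyer (the rate) matters.
    Deterministic given ``seed``.
    """
    if effects is None:
        effects = default_effects()
    beta = np.asarray(params.beta, dtype=float)
    if beta.shape != (len(effects),):
        raise ContractError(f"beta has shape {beta.shape}, expected ({len(effects)},)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    state = ChainState(start)
    n_b = len(state.buyers)
    if n_b == 0:
        raise ContractError("network has no buyers")
    m = int(rng.poisson(params.rate * n_b))
    for _ in range(m):
        _step(state, beta, effects, rng)
    return state.to_network()


def _copy_state(start: ChainState) -> ChainState:
    state = ChainState.__new__(ChainState)
    state.buyers = start.buyers
    state.vendors = start.vendors
    state.adj = start.adj.copy()
    state.vdeg = start.vdeg.copy()
    state.rep = start.rep
    return state


def simulate_chain_state(
    start: ChainState,
    params: ParameterVector,
    effects: EffectSet,
    rng: np.random.Generator,
) -> ChainState:
    """Array-level variant of :func:`simulate_chain` for hot loops:
    starts from a ChainState (copied), reuses a live RNG."""
    state = _copy_state(start)
    beta = np.asarray(params.beta, dtype=float)
    m = int(rng.poisson(params.rate * len(state.buyers)))
    for _ in range(m):
        _step(state, beta, effects, rng)
    return state


def simulate_chain_conditional(
    start: ChainState,
    beta: np.ndarray,
    effects: EffectSet,
    rng: np.random.Generator,
    target_hamming: int,
    max_steps: int | None = None,
) -> tuple[ChainState, int]:
    """Run micro-steps until the tie Hamming distance from ``start``
    reaches ``target_hamming`` (conditional simulation: the chain is
    conditioned on the observed amount of change instead of a rate).

    Returns the end state and the number of opportunities used.  The
    distance performs a drifting walk, so a step cap (default
    ``50 * n_buyers``) guards against targets the dynamics cannot reach;
    hitting the cap returns the state as-is.
    """
    state = _copy_state(start)
    beta = np.asarray(beta, dtype=float)
    n_b = len(state.buyers)
    if max_steps is None:
        max_steps = 50 * n_b
    hamming = 0
    steps = 0
    while hamming < target_hamming and steps < max_steps:
        toggled = _step(state, beta, effects, rng)
        steps += 1
        if toggled is not None:
            i, j = toggled
            hamming += 1 if state.adj[i, j] != start.adj[i, j] else -1
    return state, steps
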