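"""Attack operators applied to an observed network before forward simulation.

Three strategies, each at intervention levels 20/40/60/80 (percent):

* **targeted** — delete the ``floor(level/100 * n_vendors)`` vendors of
  highest degree (law-enforcement seizure of market leaders);
* **weak_link** — delete the ``floor(level/100 * n_buyers)`` buyers of
  lowest degree (street-sweep arrests of peripheral participants);
* **signal** — multiply every vendor's cumulative sales rating by
  ``1 - level/100`` (flooding the reputation system with noise), leaving
  the tie structure untouched.

All operators are pure (the input network is never mutated) and use
deterministic tie-breaking: vendors rank by degree, then reputation,
then id; buyers by degree then id.  Deleted actors leave the actor set
entirely — post-attack isolate counts then measure deterrence, not the
mechanical footprint of the deletion itself.  The "top/bottom nth
percentile" rule deletes exactly floor(n% of the side), the conservative
rounding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .errors import ContractError
from .network import MarketNetwork

__all__ = [
    "AttackSpec",
    "STRATEGIES",
    "LEVELS",
    "targeted_attack",
    "weak_link_attack",
    "signal_attack",
    "apply_attack",
]

STRATEGIES = ("targeted", "weak_link", "signal")
LEVELS = (20, 40, 60, 80)


@dataclass(frozen=True)
class AttackSpec:
    """strategy in {targeted, weak_link, signal, control}; level in
    {20, 40, 60, 80}, or 0 for (and only for) control."""

    strategy: str
    level: int

    def __post_init__(self):
        if self.strategy == "control":
            if self.level != 0:
                raise ContractError("control requires level 0")
        elif self.strategy in STRATEGIES:
            if self.level not in LEVELS:
                raise ContractError(f"level must be one of {LEVELS}, got {self.level}")
        else:
            raise ContractError(f"unknown strategy {self.strategy!r}")


def _check_level(level: int) -> None:
    if level not in LEVELS:
        raise ContractError(f"level must be one of {LEVELS}, got {level}")


def targeted_attack(net: MarketNetwork, level: int) -> MarketNetwork:
    """Delete the floor(level% of vendors) highest-degree vendors and
    their incident ties; buyers are retained (possibly as isolates).
    Equal-degree ranks break by descending reputation, then id."""
    _check_level(level)
    out = net.copy()
    if not out.vendors:
        warnings.warn("targeted attack on a network with no vendors: no-op", stacklevel=2)
        return out
    deg = out.degrees()
    k = int(level / 100 * len(out.vendors))
    ranked = sorted(out.vendors, key=lambda v: (-deg[v], -out.reputation[v], v))
    doomed = set(ranked[:k])
    out.vendors -= doomed
    out.ties = {(b, v) for b, v in out.ties if v not in doomed}
    out.reputation = {v: r for v, r in out.reputation.items() if v not in doomed}
    return out


def weak_link_attack(net: MarketNetwork, level: int) -> MarketNetwork:
    """Delete the floor(level% of buyers) lowest-degree buyers and their
    incident ties; vendors are retained.  Ties break by id."""
    _check_level(level)
    out = net.copy()
    if not out.buyers:
        warnings.warn("weak-link attack on a network with no buyers: no-op", stacklevel=2)
        return out
    deg = out.degrees()
    k = int(level / 100 * len(out.buyers))
    ranked = sorted(out.buyers, key=lambda b: (deg[b], b))
    doomed = set(ranked[:k])
    out.buyers -= doomed
    out.ties = {(b, v) for b, v in out.ties if b not in doomed}
    return out


def signal_attack(net: MarketNetwork, level: int) -> MarketNetwork:
    """Multiply every vendor's reputation by (1 - level/100); ties and
    actors untouched.  Not idempotent: applying level-80 twice leaves
    4% of the original rating, not 20%."""
    _check_level(level)
    out = net.copy()
    factor = 1.0 - level / 100.0
    out.reputation = {v: r * factor for v, r in out.reputation.items()}
    return out


def apply_attack(net: MarketNetwork, spec: AttackSpec) -> MarketNetwork:
    """Dispatch to the matching operator; control returns a deep copy."""
    if spec.strategy == "control":
        return net.copy()
    if spec.strategy == "targeted":
        return targeted_attack(net, spec.level)
    if spec.strategy == "weak_link":
        return weak_link_attack(net, spec.level)
    if spec.strategy == "signal":
        return signal_attack(net, spec.level)
    raise ContractError(f"unknown strategy {spec.strategy!r}")
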