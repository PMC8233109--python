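"""Attack simulations: how stable are the identified drivers?

Nodes or edges are perturbed with increasing intensity (a fraction of the
node or edge count, up to 20% by default) and, per repetition, each original
driver is re-examined on the perturbed network: it is *lost* when it can no
longer control any surviving target (tau = 0), or when it was removed
itself.  Reported is the mean +/- sd percentage of lost drivers.

Since tau > 0 reduces exactly to "some surviving target is forward-reachable
from the driver" (see :func:`targetcontrol.stepwise.is_potential_driver`),
the default loss computation is a reachability test; ``full_stepwise=True``
re-runs the whole greedy instead and gives identical losses.
"""
from __future__ import annotations

from collections.abc import Iterable, Sequence
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd

from .network import DirectedNetwork, RankedTargetSet
from .stepwise import is_potential_driver, stepwise_target_control

__all__ = ["PERTURBATION_KINDS", "PerturbationConfig", "perturb", "driver_loss_curve"]

PERTURBATION_KINDS = (
    "node-random",
    "node-high-degree",
    "node-low-degree",
    "edge-add",
    "edge-remove",
    "edge-rewire",
)


@dataclass(frozen=True)
class PerturbationConfig:
    """One attack campaign: a kind, an intensity grid and a repetition count."""

    kind: str
    intensities: tuple[float, ...] = (0.0, 0.05, 0.10, 0.15, 0.20)
    repetitions: int = 1000
    seed: Optional[int] = None
    max_intensity: float = 0.20
    recompute_degrees: bool = False  # update degree weights during sequential removal
    rewire: str = "head"  # which endpoint moves when rewiring

    def __post_init__(self):
        if self.kind not in PERTURBATION_KINDS:
            raise ValueError(f"unknown perturbation kind {self.kind!r}")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        for x in self.intensities:
            if not 0.0 <= x <= self.max_intensity:
                raise ValueError(
                    f"intensity {x} outside [0, {self.max_intensity}]"
                )
        if self.rewire not in ("head", "tail"):
            raise ValueError("rewire must be 'head' or 'tail'")


def _weighted_sample_without_replacement(
    items: Sequence, weights: np.ndarray, k: int, rng: np.random.Generator
) -> list:
    """Sequential draws with probability proportional to weight."""
    idx = list(range(len(items)))
    w = np.asarray(weights, dtype=float).copy()
    picked = []
    for _ in range(k):
        p = w[idx]
        total = p.sum()
        if total <= 0:
            choice = idx[int(rng.integers(len(idx)))]
        else:
            choice = int(rng.choice(idx, p=p / total))
        picked.append(items[choice])
        idx.remove(choice)
    return picked


def perturb(
    network: DirectedNetwork,
    kind: str,
    intensity: float,
    rng: np.random.Generator,
    recompute_degrees: bool = False,
    rewire: str = "head",
) -> DirectedNetwork:
    """Return a perturbed copy of the network.

    The number of affected items is round(intensity * N) for node kinds and
    round(intensity * L) for edge kinds.  Preferential node attacks draw
    sequentially without replacement with probability proportional to the
    total degree k (high-degree) or to k_max + 1 - k (low-degree; the
    literal "p proportional to -k" is not a probability).  Degree weights
    are computed once on the unperturbed network unless
    ``recompute_degrees``.  Rewiring keeps one endpoint (the tail by
    default) and reassigns the other to a uniformly random node avoiding
    self-loops and duplicate edges.
    """
    if kind not in PERTURBATION_KINDS:
        raise ValueError(f"unknown perturbation kind {kind!r}")
    if intensity < 0:
        raise ValueError("intensity must be nonnegative")
    if intensity == 0:
        return network.copy()
    nodes = list(network.nodes)
    edges = list(network.edges())
    if kind.startswith("node-"):
        count = round(intensity * len(nodes))
        if count == 0:
            return network.copy()
        if count >= len(nodes):
            raise ValueError("perturbation would remove every node")
        if kind == "node-random":
            remove = [nodes[i] for i in rng.choice(len(nodes), size=count, replace=False)]
        else:
            degrees = np.array([network.total_degree(n) for n in nodes], dtype=float)
            if kind == "node-low-degree":
                degrees = degrees.max() + 1.0 - degrees
            if recompute_degrees:
                remove = []
                current = network
                for _ in range(count):
                    pool = list(current.nodes)
                    k = np.array([current.total_degree(n) for n in pool], dtype=float)
                    if kind == "node-low-degree":
                        k = k.max() + 1.0 - k
                    pick = _weighted_sample_without_replacement(pool, k, 1, rng)[0]
                    remove.append(pick)
                    current = current.without_nodes([pick])
            else:
                remove = _weighted_sample_without_replacement(nodes, degrees, count, rng)
        return network.without_nodes(remove)

    count = round(intensity * len(edges))
    if count == 0:
        return network.copy()
    graph = network.graph.copy()
    if kind == "edge-remove":
        drop = [edges[i] for i in rng.choice(len(edges), size=count, replace=False)]
        graph.remove_edges_from(drop)
    elif kind == "edge-add":
        existing = set(edges)
        free = [
            (u, v)
            for u in nodes
            for v in nodes
            if u != v and (u, v) not in existing
        ]
        if count > len(free):
            raise ValueError(
                f"cannot add {count} edges: only {len(free)} slots remain"
            )
        for i in rng.choice(len(free), size=count, replace=False):
            graph.add_edge(*free[i])
    elif kind == "edge-rewire":
        chosen = [edges[i] for i in rng.choice(len(edges), size=count, replace=False)]
        for u, v in chosen:
            keep, old = (u, v) if rewire == "head" else (v, u)
            candidates = [
                w
                for w in nodes
                if w != keep
                and (
                    not graph.has_edge(keep, w)
                    if rewire == "head"
                    else not graph.has_edge(w, keep)
                )
            ]
            if not candidates:
                continue  # saturated endpoint: leave the edge in place
            w = candidates[int(rng.integers(len(candidates)))]
            graph.remove_edge(u, v)
            if rewire == "head":
                graph.add_edge(keep, w)
            else:
                graph.add_edge(w, keep)
    return DirectedNetwork(graph)


def driver_loss_curve(
    network: DirectedNetwork,
    drivers: Iterable[str],
    ranked_targets: Union[RankedTargetSet, Sequence[str]],
    config: PerturbationConfig,
    full_stepwise: bool = False,
    log_transform: bool = True,
) -> pd.DataFrame:
    """Mean percentage of drivers that lose all control, per intensity.

    ``drivers`` should be the tau > 0 nodes of the unperturbed network.  Per
    repetition the network is perturbed, the original ranking is restricted
    to surviving targets, and each driver is scored lost when it was removed,
    no target survives, or its tau on the perturbed network is zero.
    """
    drivers = sorted(drivers)
    if not drivers:
        raise ValueError("no drivers to attack")
    if not isinstance(ranked_targets, RankedTargetSet):
        ranked_targets = RankedTargetSet(ranked_targets)
    rng = np.random.default_rng(config.seed)
    records = []
    for intensity in config.intensities:
        pct = np.empty(config.repetitions)
        for rep in range(config.repetitions):
            perturbed = perturb(
                network,
                config.kind,
                intensity,
                rng,
                recompute_degrees=config.recompute_degrees,
                rewire=config.rewire,
            )
            surviving = ranked_targets.restricted_to(perturbed.nodes)
            lost = 0
            for d in drivers:
                if d not in perturbed or surviving is None:
                    lost += 1
                elif full_stepwise:
                    res = stepwise_target_control(
                        perturbed, d, surviving, log_transform=log_transform
                    )
                    lost += res.tau == 0
                else:
                    lost += not is_potential_driver(perturbed, d, surviving)
            pct[rep] = 100.0 * lost / len(drivers)
        records.append(
            {
                "kind": config.kind,
                "intensity": intensity,
                "mean_pct_lost": float(pct.mean()),
                "sd_pct_lost": float(pct.std(ddof=1)) if len(pct) > 1 else 0.0,
                "repetitions": config.repetitions,
            }
        )
    return pd.DataFrame.from_records(records)
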