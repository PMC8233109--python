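"""Generators for benchmark networks and simulated expression data.

Three families of fixtures, all bit-reproducible under a fixed seed:

* the binary-tree benchmark (a full directed tree plus a short cycle through
  the root) that demonstrates why the subgraph reduction rescues the rank
  computation;
* uniform random directed networks for the complexity study;
* simulated two-group (HC / MS), two-condition (alert / pro-inflammatory)
  expression tables with planted activation, dysregulation and coactivation
  effects, returned together with their ground truth.
"""
from __future__ import annotations

import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .activation import ExpressionTable
from .network import DirectedNetwork, RankedTargetSet
from .stepwise import full_matrix_rank, stepwise_target_control

__all__ = [
    "TreeBenchmark",
    "RandomNetSpec",
    "CoactivationEffect",
    "ExpressionEffects",
    "make_tree_benchmark",
    "make_random_network",
    "run_complexity_study",
    "simulate_expression",
]


# ---------------------------------------------------------------------------
# Tree benchmark
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TreeBenchmark:
    """Full binary tree of ``h`` levels with a cycle through the root.

    Node count is 2^h - 1 (the root is level 1).  One target is placed
    uniformly at random in each level; the ranking is the level order with
    the root level first.
    """

    network: DirectedNetwork
    targets: RankedTargetSet
    h: int
    root: str
    cycle: str


def _tree_node(i: int, width: int) -> str:
    return f"n{i:0{width}d}"


def make_tree_benchmark(
    h: int, seed: Optional[int] = None, cycle: str = "back-edges"
) -> TreeBenchmark:
    """Build the tree benchmark.

    ``cycle`` selects how the "simple cycle among the first three nodes"
    (root r and its children c1, c2) is wired:

    * ``"back-edges"`` (default): add c1->r and c2->r, closing two 2-cycles
      through the root and hence directed cycles among the three;
    * ``"three-cycle"``: add c1->c2 and c2->r, which together with the tree
      edge r->c1 closes the directed 3-cycle r->c1->c2->r.

    Both variants leave every per-level target controllable from the root.
    """
    if h < 2:
        raise ValueError("tree benchmark needs at least 2 levels")
    if cycle not in ("back-edges", "three-cycle"):
        raise ValueError(f"unknown cycle style {cycle!r}")
    n = 2**h - 1
    width = len(str(n))
    edges = []
    for i in range(1, n + 1):
        for child in (2 * i, 2 * i + 1):
            if child <= n:
                edges.append((_tree_node(i, width), _tree_node(child, width)))
    r, c1, c2 = (_tree_node(i, width) for i in (1, 2, 3))
    if cycle == "back-edges":
        edges += [(c1, r), (c2, r)]
    else:
        edges += [(c1, c2), (c2, r)]
    network = DirectedNetwork.from_edges(edges)
    rng = np.random.default_rng(seed)
    targets = []
    for level in range(1, h + 1):
        lo, hi = 2 ** (level - 1), 2**level - 1
        targets.append(_tree_node(int(rng.integers(lo, hi + 1)), width))
    return TreeBenchmark(
        network=network,
        targets=RankedTargetSet(targets, network),
        h=h,
        root=r,
        cycle=cycle,
    )


# ---------------------------------------------------------------------------
# Random directed networks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RandomNetSpec:
    """Parameters of one uniform random directed network.

    Density follows the directed convention d = L / (N (N - 1)) without
    self-loops; the realized edge count is round(d * N * (N - 1)).
    """

    n: int
    density: float
    target_fraction: float = 0.05
    seed: Optional[int] = None

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("need at least 2 nodes")
        if not 0.0 < self.density < 1.0:
            raise ValueError("density must lie strictly between 0 and 1")
        n_edges = round(self.density * self.n * (self.n - 1))
        if n_edges < 1:
            raise ValueError("density too low: no edges would be realized")

    @property
    def n_edges(self) -> int:
        return round(self.density * self.n * (self.n - 1))


def make_random_network(spec: RandomNetSpec, seed: Optional[int] = None) -> DirectedNetwork:
    """Sample ``spec.n_edges`` distinct directed edges uniformly (no self-loops)."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = spec.n
    width = len(str(n - 1))
    # ordered pairs (i, j), i != j, flattened as i * (n - 1) + offset
    picks = rng.choice(n * (n - 1), size=spec.n_edges, replace=False)
    edges = []
    for p in picks:
        i, off = divmod(int(p), n - 1)
        j = off if off < i else off + 1
        edges.append((f"v{i:0{width}d}", f"v{j:0{width}d}"))
    nodes = [f"v{i:0{width}d}" for i in range(n)]
    return DirectedNetwork.from_edges(edges, nodes=nodes)


def run_complexity_study(
    ns: Sequence[int],
    densities: Sequence[float],
    target_fractions: Sequence[float],
    reps: int,
    seed: Optional[int] = None,
    log_transform: bool = True,
) -> pd.DataFrame:
    """Stepwise-reduced vs full-matrix controllable-target counts on a grid.

    For each (N, density, target fraction) cell, ``reps`` random networks are
    drawn; on each, a random driver and a randomly ranked target subset are
    chosen, and the number of controllable targets is computed twice: by the
    stepwise procedure with subgraph reduction (the package's method, log
    transform per ``log_transform``) and by the rank of the raw full-network
    matrix (the standard baseline).  Cell means of both are returned.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    records = []
    for n in ns:
        for d in densities:
            for frac in target_fractions:
                s = max(1, round(frac * n))
                taus_step, taus_full = [], []
                for _ in range(reps):
                    net = make_random_network(
                        RandomNetSpec(n=n, density=d, target_fraction=frac),
                        seed=int(rng.integers(2**31)),
                    )
                    nodes = list(net.nodes)
                    chosen = rng.choice(len(nodes), size=s + 1, replace=False)
                    driver = nodes[int(chosen[0])]
                    ranked = RankedTargetSet([nodes[int(i)] for i in chosen[1:]])
                    res = stepwise_target_control(
                        net, driver, ranked, log_transform=log_transform
                    )
                    taus_step.append(res.tau)
                    taus_full.append(full_matrix_rank(net, driver, ranked))
                records.append(
                    {
                        "n": n,
                        "density": d,
                        "target_fraction": frac,
                        "n_targets": s,
                        "reps": reps,
                        "mean_tau_stepwise": float(np.mean(taus_step)),
                        "mean_tau_full_matrix": float(np.mean(taus_full)),
                    }
                )
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# Simulated expression data
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoactivationEffect:
    """Planted driver-target coactivation.

    The target's activation noise is ``loading * (driver noise) +
    sqrt(1 - loading^2) * independent noise`` within the listed groups, so the
    pair's latent correlation equals ``loading`` there.
    """

    driver: str
    target: str
    loading: float = 0.9
    groups: tuple[str, ...] = ("HC", "MS")


@dataclass(frozen=True)
class ExpressionEffects:
    """Planted effect sizes for :func:`simulate_expression`.

    Defaults emulate the study conditions: a roughly 2-fold pro-inflammatory
    activation per gene with moderate between-subject spread, and (when
    requested) group dysregulation expressed as a multiplicative fold on the
    MS activation.
    """

    condition_log2_mean: float = 1.0   # mean log2 activation (pro / alert)
    condition_log2_sd: float = 0.5     # gene-to-gene spread of that mean
    subject_log2_sd: float = 0.5       # subject-to-subject activation noise
    baseline_log_mean: float = math.log(500.0)
    baseline_log_sd: float = 1.0
    alert_log2_sd: float = 0.1         # measurement noise on alert expression
    dysregulated: Mapping[str, float] = field(default_factory=dict)  # gene -> fold (MS)
    coactivated: tuple[CoactivationEffect, ...] = ()


def simulate_expression(
    genes: Sequence[str],
    n_per_group: int = 8,
    effects: Optional[ExpressionEffects] = None,
    seed: Optional[int] = None,
    groups: tuple[str, str] = ("HC", "MS"),
) -> tuple[ExpressionTable, dict]:
    """Simulate a two-group, two-condition expression experiment.

    Per gene g and subject s the alert expression is log-normal and the
    pro-inflammatory expression multiplies it by the per-subject activation
    2^(a_gs), where a_gs = gene activation mean + dysregulation shift (MS
    only) + subject noise.  Planted coactivations correlate the subject noise
    of a driver-target pair.  Returns the expression table and a ground-truth
    record of every planted parameter.
    """
    if effects is None:
        effects = ExpressionEffects()
    genes = [str(g) for g in genes]
    if len(set(genes)) != len(genes):
        raise ValueError("duplicate gene names")
    for g in effects.dysregulated:
        if g not in genes:
            raise KeyError(f"dysregulated gene {g!r} not in gene list")
    for c in effects.coactivated:
        if c.driver not in genes or c.target not in genes:
            raise KeyError(f"coactivated pair ({c.driver}, {c.target}) not in gene list")
    rng = np.random.default_rng(seed)
    gi = {g: k for k, g in enumerate(genes)}
    n_genes = len(genes)

    log2_alpha = rng.normal(
        effects.condition_log2_mean, effects.condition_log2_sd, size=n_genes
    )
    baseline = np.exp(
        rng.normal(effects.baseline_log_mean, effects.baseline_log_sd, size=n_genes)
    )

    subjects, group_of = [], {}
    for grp in groups:
        for i in range(n_per_group):
            s = f"{grp}{i + 1:02d}"
            subjects.append(s)
            group_of[s] = grp

    columns, data = [], []
    for s in subjects:
        grp = group_of[s]
        noise = rng.normal(0.0, 1.0, size=n_genes)
        for c in effects.coactivated:
            if grp in c.groups:
                lam = c.loading
                noise[gi[c.target]] = lam * noise[gi[c.driver]] + math.sqrt(
                    max(0.0, 1.0 - lam**2)
                ) * rng.normal()
        a = log2_alpha + effects.subject_log2_sd * noise
        if grp == groups[1] and effects.dysregulated:
            for g, fold in effects.dysregulated.items():
                a[gi[g]] += math.log2(fold)
        alert = baseline * 2.0 ** rng.normal(0.0, effects.alert_log2_sd, size=n_genes)
        pro = alert * 2.0**a
        columns += [f"{s}_alert", f"{s}_pro"]
        data += [alert, pro]

    values = pd.DataFrame(np.column_stack(data), index=genes, columns=columns)
    meta = pd.DataFrame(
        {
            "sample": columns,
            "subject": [c.rsplit("_", 1)[0] for c in columns],
            "group": [group_of[c.rsplit("_", 1)[0]] for c in columns],
            "condition": [
                "alert" if c.endswith("_alert") else "pro-inflammatory"
                for c in columns
            ],
        }
    ).set_index("sample")
    table = ExpressionTable(values=values, meta=meta)
    truth = {
        "seed": seed,
        "genes": genes,
        "n_per_group": n_per_group,
        "log2_activation_mean": dict(zip(genes, map(float, log2_alpha))),
        "dysregulated": {g: float(f) for g, f in effects.dysregulated.items()},
        "coactivated": [
            {
                "driver": c.driver,
                "target": c.target,
                "loading": c.loading,
                "groups": list(c.groups),
            }
            for c in effects.coactivated
        ],
    }
    return table, truth
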