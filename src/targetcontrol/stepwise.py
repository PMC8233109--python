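"""Kalman-rank target controllability and the stepwise greedy procedure.

For linear time-invariant dynamics x'(n) = A x(n) - B u(n), y(n) = C x(n) on
a directed network with binary adjacency A, a single driver node (B) controls
the whole network iff the Kalman matrix Q = [B, AB, ..., A^(N-1)B] has full
row rank.  When only a target set T of S nodes matters, C selects the target
rows and the rank of the target controllability matrix Q_T = C Q counts the
controllable targets.

Entry (i, j) of Q_T is the number of distinct directed walks of length j-1
from the driver to target i, which is why every node that lies on no
driver-to-target walk can be deleted before computing the rank: the matrix
shrinks from S x N to S x N' and round-off has far less room to accumulate.

Walk counts are accumulated in exact arbitrary-precision integers (they grow
exponentially with walk length); floating point enters only at the optional
log(q+1) transform and at the SVD used for the numerical rank.
"""
from __future__ import annotations

import math
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy import stats

from .network import DirectedNetwork, RankedTargetSet

__all__ = [
    "TargetControllabilityMatrix",
    "StepRecord",
    "StepwiseResult",
    "walk_count_matrix",
    "numerical_rank",
    "full_matrix_rank",
    "stepwise_target_control",
    "target_control_centrality",
    "is_potential_driver",
]

_FLOAT_MAX = np.finfo(np.float64).max


def _walk_count_rows(
    network: DirectedNetwork, driver: str, targets: Sequence[str], n_cols: int
) -> list[list[int]]:
    """Exact walk counts driver -> target for lengths 0 .. n_cols-1.

    Row order follows ``targets``.  Targets absent from ``network`` yield
    all-zero rows (they sit on no walk and simply cannot contribute rank).
    """
    nodes = network.nodes
    index = {n: i for i, n in enumerate(nodes)}
    preds: list[list[int]] = [[] for _ in nodes]
    for u, v in network.edges():
        preds[index[v]].append(index[u])
    w = [0] * len(nodes)
    w[index[driver]] = 1
    t_idx = [index.get(t) for t in targets]
    rows: list[list[int]] = [[] for _ in targets]
    for _ in range(n_cols):
        for r, ti in zip(rows, t_idx):
            r.append(w[ti] if ti is not None else 0)
        w = [sum(w[u] for u in preds[v]) for v in range(len(nodes))]
    return rows


@dataclass(frozen=True)
class TargetControllabilityMatrix:
    """Q_T: integer walk counts, rows = targets, columns = walk lengths 0..N'-1."""

    driver: str
    targets: tuple[str, ...]
    counts: tuple[tuple[int, ...], ...]
    n_state: int  # N': size of the (possibly reduced) network the walks live on
    log_transform: bool  # whether values() applies log(q+1)

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.targets), self.n_state)

    def values(self) -> np.ndarray:
        """Float matrix handed to the rank computation.

        With the log transform, each exact count q becomes log(q+1) (computed
        on the integer, so arbitrarily large counts never overflow).  Without
        it, counts beyond float64 range are clamped to the largest finite
        float -- by then the raw matrix is numerically meaningless anyway,
        which is precisely the failure mode the reduction avoids.
        """
        if self.log_transform:
            return np.array(
                [[math.log(q + 1) for q in row] for row in self.counts], dtype=float
            )
        out = np.empty(self.shape, dtype=float)
        for i, row in enumerate(self.counts):
            for j, q in enumerate(row):
                out[i, j] = float(q) if q.bit_length() < 1024 else _FLOAT_MAX
        return out


def walk_count_matrix(
    network: DirectedNetwork,
    driver: str,
    targets: Union[RankedTargetSet, Sequence[str]],
    reduce: bool = True,
    log_transform: bool = True,
) -> TargetControllabilityMatrix:
    """Build Q_T for one driver, optionally on the reduced control subgraph.

    With ``reduce`` the matrix is computed on
    :meth:`DirectedNetwork.control_subgraph` (N' columns); otherwise on the
    full network (N columns).  A target unreachable from the driver gets an
    all-zero row, never an error: the rank bookkeeping handles it.
    """
    targets = tuple(targets.targets if isinstance(targets, RankedTargetSet) else targets)
    network._require(driver)
    for t in targets:
        network._require(t)
    base = network.control_subgraph(driver, targets) if reduce else network
    rows = _walk_count_rows(base, driver, targets, base.n_nodes)
    return TargetControllabilityMatrix(
        driver=driver,
        targets=targets,
        counts=tuple(tuple(r) for r in rows),
        n_state=base.n_nodes,
        log_transform=log_transform,
    )


def numerical_rank(
    matrix: Union[np.ndarray, TargetControllabilityMatrix],
    tol: Optional[float] = None,
) -> int:
    """SVD-based rank with threshold max(n_rows, n_cols) * eps * sigma_max.

    The tolerance is scale-aware (it follows the largest singular value) and
    can be overridden.  An all-zero matrix has rank 0.
    """
    if isinstance(matrix, TargetControllabilityMatrix):
        matrix = matrix.values()
    m = np.asarray(matrix, dtype=float)
    if m.size == 0:
        raise ValueError("rank of an empty matrix is undefined")
    s = np.linalg.svd(m, compute_uv=False)
    if s[0] == 0.0:
        return 0
    if tol is None:
        tol = max(m.shape) * np.finfo(np.float64).eps * s[0]
    return int(np.count_nonzero(s > tol))


def full_matrix_rank(
    network: DirectedNetwork,
    driver: str,
    targets: Union[RankedTargetSet, Sequence[str]],
    log_transform: bool = False,
    tol: Optional[float] = None,
) -> int:
    """Rank of Q_T on the *full* network: the standard, no-reduction approach.

    This is the baseline the stepwise-reduced method is compared against.
    Default is the raw walk-count matrix (no log stabilization): the counts
    grow exponentially with walk length, so for deep or dense networks the
    float64 conversion degrades and the returned rank collapses -- the
    round-off failure the subgraph reduction was designed to avoid.
    """
    tcm = walk_count_matrix(
        network, driver, targets, reduce=False, log_transform=log_transform
    )
    return numerical_rank(tcm, tol=tol)


@dataclass(frozen=True)
class StepRecord:
    """One greedy step: the tested target and the rank decision."""

    target: str
    n_reduced: int
    rank: int
    retained: bool


@dataclass(frozen=True)
class StepwiseResult:
    """Outcome of the stepwise procedure for one driver.

    ``tau`` is the target control centrality: the number of controllable
    targets.  ``controllable`` is T', the retained targets in ranking order.
    """

    driver: str
    tau: int
    controllable: tuple[str, ...]
    ranked_targets: tuple[str, ...]
    steps: tuple[StepRecord, ...] = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "driver": self.driver,
            "tau": self.tau,
            "controllable_targets": list(self.controllable),
            "ranked_targets": list(self.ranked_targets),
            "steps": [
                {
                    "target": s.target,
                    "n_reduced": s.n_reduced,
                    "rank": s.rank,
                    "retained": s.retained,
                }
                for s in self.steps
            ],
        }


def stepwise_target_control(
    network: DirectedNetwork,
    driver: str,
    ranked_targets: Union[RankedTargetSet, Sequence[str]],
    log_transform: bool = True,
    tol: Optional[float] = None,
) -> StepwiseResult:
    """Greedy rank-ordered selection of the controllable target subset.

    Starting from an empty T', targets are tentatively added in ranking
    order; after each addition the control subgraph is rebuilt, Q_T' is
    recomputed on it, and the target is retained iff the numerical rank
    equals |T'| + 1 (full row rank).  Unreachable targets have an all-zero
    row and are always discarded.

    Because the full-rank row subsets of Q_T form the independent sets of a
    linear matroid, in exact arithmetic this greedy returns a maximum
    controllable subset, and specifically the lexicographically best one
    under the ranking.  The driver may itself be a target (the length-0 walk
    makes its own row e_1).
    """
    if not isinstance(ranked_targets, RankedTargetSet):
        ranked_targets = RankedTargetSet(ranked_targets)
    network._require(driver)
    retained: list[str] = []
    steps: list[StepRecord] = []
    for t in ranked_targets:
        candidate = retained + [t]
        tcm = walk_count_matrix(
            network, driver, candidate, reduce=True, log_transform=log_transform
        )
        rank = numerical_rank(tcm, tol=tol)
        ok = rank == len(candidate)
        if ok:
            retained = candidate
        steps.append(StepRecord(t, tcm.n_state, rank, ok))
    return StepwiseResult(
        driver=driver,
        tau=len(retained),
        controllable=tuple(retained),
        ranked_targets=ranked_targets.targets,
        steps=tuple(steps),
    )


def is_potential_driver(
    network: DirectedNetwork, driver: str, targets: Iterable[str]
) -> bool:
    """True iff tau > 0, i.e. at least one target is reachable from the driver.

    A single reachable target always yields a non-zero 1-row matrix of rank 1,
    so the stepwise loop retains at least one such target; conversely with no
    reachable target every row is zero.  This makes the tau > 0 test a pure
    reachability question, which the robustness attacks exploit.
    """
    forward = network.reachable_set(driver, "forward")
    return any(t in forward for t in targets)


def target_control_centrality(
    network: DirectedNetwork,
    drivers: Iterable[str],
    ranked_targets: Union[RankedTargetSet, Sequence[str]],
    log_transform: bool = True,
    tol: Optional[float] = None,
    with_degree_correlation: bool = False,
):
    """Run the stepwise procedure for every candidate driver.

    Returns a DataFrame indexed by driver with columns ``tau``,
    ``controllable_targets`` (semicolon-joined), ``is_driver`` (tau > 0) and
    ``total_degree``.  With ``with_degree_correlation`` a
    ``(table, (rho, p))`` pair is returned instead, the Spearman correlation
    between tau and total degree across the tested nodes.
    """
    drivers = list(drivers)
    if not drivers:
        raise ValueError("no candidate drivers given")
    if not isinstance(ranked_targets, RankedTargetSet):
        ranked_targets = RankedTargetSet(ranked_targets)
    records = []
    for d in sorted(drivers):
        res = stepwise_target_control(
            network, d, ranked_targets, log_transform=log_transform, tol=tol
        )
        records.append(
            {
                "driver": d,
                "tau": res.tau,
                "controllable_targets": ";".join(res.controllable),
                "n_steps": len(res.steps),
                "is_driver": res.tau > 0,
                "total_degree": network.total_degree(d),
            }
        )
    table = pd.DataFrame.from_records(records).set_index("driver")
    if not with_degree_correlation:
        return table
    rho, p = stats.spearmanr(table["tau"], table["total_degree"])
    return table, (float(rho), float(p))
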