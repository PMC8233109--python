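"""Exact-arithmetic validation oracle.

Small-instance ground truth for the stepwise greedy: rank over the rationals
via Bareiss fraction-free elimination (integers only, no floating point) and
brute-force enumeration of every target subset.  The oracle exists for tests
and validation runs; it is deliberately not built to scale.
"""
from __future__ import annotations

import itertools
from collections.abc import Sequence
from dataclasses import dataclass
from typing import Optional, Union

from .network import DirectedNetwork, RankedTargetSet
from .stepwise import stepwise_target_control, walk_count_matrix

__all__ = ["OracleReport", "exact_rank", "brute_force_best_config", "stepwise_agreement"]

MAX_TARGETS = 15  # 2^S - 1 subsets are enumerated


def exact_rank(matrix: Sequence[Sequence[int]]) -> int:
    """Rank over the rationals of an integer matrix, by fraction-free elimination.

    Bareiss elimination keeps every intermediate value an exact integer (each
    division is exact), so there is no floating point anywhere and therefore
    no tolerance to choose.
    """
    rows = [list(r) for r in matrix]
    for r in rows:
        for x in r:
            if not isinstance(x, (int,)) or isinstance(x, bool):
                raise TypeError(f"exact_rank requires integer entries, got {x!r}")
    if not rows or not rows[0]:
        return 0
    n_rows, n_cols = len(rows), len(rows[0])
    rank = 0
    prev_pivot = 1
    pivot_row = 0
    for col in range(n_cols):
        pivot = next(
            (r for r in range(pivot_row, n_rows) if rows[r][col] != 0), None
        )
        if pivot is None:
            continue
        rows[pivot_row], rows[pivot] = rows[pivot], rows[pivot_row]
        for r in range(pivot_row + 1, n_rows):
            for c in range(col + 1, n_cols):
                rows[r][c] = (
                    rows[r][c] * rows[pivot_row][col]
                    - rows[r][col] * rows[pivot_row][c]
                ) // prev_pivot
            rows[r][col] = 0
        prev_pivot = rows[pivot_row][col]
        pivot_row += 1
        rank += 1
        if pivot_row == n_rows:
            break
    return rank


@dataclass(frozen=True)
class OracleReport:
    """Ground truth for one instance, plus agreement with the stepwise result."""

    driver: str
    tau_star: int
    best_subset: tuple[str, ...]
    stepwise_tau: Optional[int] = None
    stepwise_subset: Optional[tuple[str, ...]] = None

    @property
    def agreement(self) -> Optional[bool]:
        if self.stepwise_tau is None:
            return None
        return (
            self.stepwise_tau == self.tau_star
            and self.stepwise_subset == self.best_subset
        )


def _subset_controllable(
    network: DirectedNetwork, driver: str, subset: Sequence[str]
) -> bool:
    tcm = walk_count_matrix(network, driver, subset, reduce=True, log_transform=False)
    return exact_rank([list(r) for r in tcm.counts]) == len(subset)


def brute_force_best_config(
    network: DirectedNetwork,
    driver: str,
    ranked_targets: Union[RankedTargetSet, Sequence[str]],
) -> OracleReport:
    """Enumerate all 2^S - 1 subsets; return the best controllable configuration.

    A subset is controllable iff the exact rational rank of its raw reduced
    walk-count matrix equals its size.  Among maximum-cardinality controllable
    subsets, "best" is the one whose rank-position vector is lexicographically
    earliest, i.e. the one preferring higher-ranked targets -- the same
    preference the greedy encodes.
    """
    if not isinstance(ranked_targets, RankedTargetSet):
        ranked_targets = RankedTargetSet(ranked_targets)
    if len(ranked_targets) > MAX_TARGETS:
        raise ValueError(
            f"brute force guard: at most {MAX_TARGETS} targets "
            f"(got {len(ranked_targets)})"
        )
    network._require(driver)
    positions = range(len(ranked_targets))
    best: tuple[int, ...] = ()
    for size in range(1, len(ranked_targets) + 1):
        for combo in itertools.combinations(positions, size):
            subset = [ranked_targets[i] for i in combo]
            if _subset_controllable(network, driver, subset):
                # combinations() yields lexicographically increasing tuples,
                # so the first controllable combo of each size is the best one
                best = combo
                break
    return OracleReport(
        driver=driver,
        tau_star=len(best),
        best_subset=tuple(ranked_targets[i] for i in best),
    )


def stepwise_agreement(
    network: DirectedNetwork,
    driver: str,
    ranked_targets: Union[RankedTargetSet, Sequence[str]],
    tol: Optional[float] = None,
) -> OracleReport:
    """Compare the stepwise result (log transform off) against the oracle.

    The comparison runs with raw walk counts because the log(q+1) transform
    is nonlinear and can legitimately change the rank of the raw matrix; the
    matroid argument only applies to the untransformed Q_T.
    """
    if not isinstance(ranked_targets, RankedTargetSet):
        ranked_targets = RankedTargetSet(ranked_targets)
    truth = brute_force_best_config(network, driver, ranked_targets)
    res = stepwise_target_control(
        network, driver, ranked_targets, log_transform=False, tol=tol
    )
    return OracleReport(
        driver=driver,
        tau_star=truth.tau_star,
        best_subset=truth.best_subset,
        stepwise_tau=res.tau,
        stepwise_subset=res.controllable,
    )
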