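"""Driver-target coactivation screening.

A controllable driver-target pair is *coactivated* in a subject group when
the Spearman correlation between the two genes' activation vectors is
significant (two-sided p < alpha, raw by default -- no multiple-testing
correction, though Benjamini-Hochberg is available behind a flag).  Only
pairs with a controllable walk (target retained by the stepwise procedure
for that driver) are tested at all.

For small samples without ties the p-value is exact: the full permutation
null of the Spearman statistic (all n! rank pairings) is enumerated and
cached per sample size.  Larger samples or ties fall back to the asymptotic
test.
"""
from __future__ import annotations

import itertools
import logging
import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy import stats

from .activation import ActivationTable
from .network import DirectedNetwork
from .stepwise import StepwiseResult

__all__ = [
    "CoactivationMatrix",
    "spearman_pair",
    "coactivation_screen",
    "differential_coactivation",
    "dysregulated_on_walk",
]

logger = logging.getLogger(__name__)

#: Cell states of the driver x target grid.
NO_WALK = "no-controllable-walk"
NOT_SIGNIFICANT = "controllable-not-significant"
COACTIVATED = "coactivated"
UNTESTABLE = "untestable"

EXACT_MAX_N = 9  # n! permutations are enumerated up to this sample size


@lru_cache(maxsize=8)
def _exact_null_abs_rho(n: int) -> np.ndarray:
    """Sorted |rho| over all n! rank pairings (exact Spearman null, no ties)."""
    perms = np.array(list(itertools.permutations(range(n))), dtype=float)
    ref = np.arange(n, dtype=float)
    d2 = ((perms - ref) ** 2).sum(axis=1)
    rho = 1.0 - 6.0 * d2 / (n * (n**2 - 1))
    return np.sort(np.abs(rho))


def _exact_p(rho: float, n: int) -> float:
    null = _exact_null_abs_rho(n)
    # two-sided: share of permutations at least as extreme (1e-12 guards
    # against float noise in theoretically tied statistics)
    k = null.size - np.searchsorted(null, abs(rho) - 1e-12, side="left")
    return float(k) / null.size


def spearman_pair(
    x: Sequence[float], y: Sequence[float], method: str = "auto"
) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    ``method``: ``"exact"`` enumerates the permutation null (requires
    n <= 9 and no ties), ``"asymptotic"`` uses the large-sample test,
    ``"auto"`` picks exact whenever it applies.  Ties use the average-rank
    convention (asymptotic path).  A constant vector has undefined rho; it
    is reported as (nan, 1.0) with a warning, i.e. never significant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        logger.warning("constant activation vector: Spearman rho undefined")
        return (float("nan"), 1.0)
    ties = np.unique(x).size < n or np.unique(y).size < n
    if method == "auto":
        method = "exact" if (n <= EXACT_MAX_N and not ties) else "asymptotic"
    if method == "exact":
        if n > EXACT_MAX_N:
            raise ValueError(f"exact method limited to n <= {EXACT_MAX_N}")
        if ties:
            raise ValueError("exact method requires untied data")
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        rho = 1.0 - 6.0 * float(((rx - ry) ** 2).sum()) / (n * (n**2 - 1))
        return (rho, _exact_p(rho, n))
    if method != "asymptotic":
        raise ValueError(f"unknown method {method!r}")
    rho, p = stats.spearmanr(x, y)
    return (float(rho), float(p))


@dataclass(frozen=True)
class CoactivationMatrix:
    """Driver x target coactivation grid for one subject group.

    ``state`` partitions the grid into no-controllable-walk, controllable-
    not-significant, coactivated (and untestable when a gene is missing from
    the activation table); ``rho`` and ``p`` hold the per-cell statistics for
    the tested cells (NaN elsewhere).
    """

    group: str
    state: pd.DataFrame
    rho: pd.DataFrame
    p: pd.DataFrame
    alpha: float

    def coactivated_pairs(self) -> set[tuple[str, str]]:
        mask = self.state == COACTIVATED
        return {
            (d, t)
            for d in self.state.index
            for t in self.state.columns
            if mask.loc[d, t]
        }

    def controllable_pairs(self) -> set[tuple[str, str]]:
        mask = self.state.isin([COACTIVATED, NOT_SIGNIFICANT])
        return {
            (d, t)
            for d in self.state.index
            for t in self.state.columns
            if mask.loc[d, t]
        }


def coactivation_screen(
    activation: ActivationTable,
    stepwise_results: Mapping[str, StepwiseResult],
    alpha: float = 0.05,
    method: str = "auto",
    correction: Optional[str] = None,
) -> dict[str, CoactivationMatrix]:
    """Screen every controllable driver-target pair in every group.

    Returns one :class:`CoactivationMatrix` per group label found in the
    activation table.  Columns are the union of ranked targets across
    results; rows are the drivers.  Only pairs (d, t) with t in T'(d) are
    tested; with ``correction="bh"`` a Benjamini-Hochberg adjustment is
    applied per group across the tested pairs (off by default: the raw
    p < alpha convention).
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    if correction not in (None, "bh"):
        raise ValueError(f"unknown correction {correction!r}")
    if correction == "bh":
        logger.info("applying Benjamini-Hochberg correction to screen p-values")
    drivers = sorted(stepwise_results)
    targets = sorted({t for r in stepwise_results.values() for t in r.ranked_targets})
    out: dict[str, CoactivationMatrix] = {}
    for group in activation.group_labels:
        sub = activation.group_values(group)
        state = pd.DataFrame(NO_WALK, index=drivers, columns=targets)
        rho = pd.DataFrame(np.nan, index=drivers, columns=targets)
        pval = pd.DataFrame(np.nan, index=drivers, columns=targets)
        tested: list[tuple[str, str]] = []
        for d in drivers:
            controllable = set(stepwise_results[d].controllable)
            for t in targets:
                if t not in controllable:
                    continue
                if d not in sub.index or t not in sub.index:
                    state.loc[d, t] = UNTESTABLE
                    continue
                r, p = spearman_pair(sub.loc[d], sub.loc[t], method=method)
                rho.loc[d, t] = r
                pval.loc[d, t] = p
                tested.append((d, t))
        p_use = pval.copy()
        if correction == "bh" and tested:
            raw = np.array([pval.loc[d, t] for d, t in tested])
            adj = _benjamini_hochberg(raw)
            for (d, t), q in zip(tested, adj):
                p_use.loc[d, t] = q
        for d, t in tested:
            state.loc[d, t] = (
                COACTIVATED if p_use.loc[d, t] < alpha else NOT_SIGNIFICANT
            )
        out[group] = CoactivationMatrix(
            group=group, state=state, rho=rho, p=p_use, alpha=alpha
        )
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        i = m - rank_from_top  # 1-based rank of this p-value
        running = min(running, p[idx] * m / i)
        adj[idx] = running
    return adj


def differential_coactivation(
    mat_a: CoactivationMatrix, mat_b: CoactivationMatrix
) -> set[tuple[str, str]]:
    """Pairs whose coactivation appears or disappears between the two groups.

    The symmetric difference of coactivated cells, restricted to pairs
    controllable in both groups (group relabeling therefore leaves the
    result unchanged).
    """
    both = mat_a.controllable_pairs() & mat_b.controllable_pairs()
    return (mat_a.coactivated_pairs() ^ mat_b.coactivated_pairs()) & both


def dysregulated_on_walk(
    network: DirectedNetwork,
    driver: str,
    target: str,
    dysregulated: set[str],
) -> tuple[bool, tuple[str, ...]]:
    """Does any dysregulated gene lie on a walk from driver to target?

    The driver and the target themselves count.  Returns the flag and the
    sorted witnesses.
    """
    sub = network.control_subgraph(driver, {target})
    witnesses = tuple(sorted(set(sub.nodes) & set(dysregulated)))
    return (bool(witnesses), witnesses)
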