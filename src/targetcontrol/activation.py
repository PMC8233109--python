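"""Gene activation, fold change, target ranking and dysregulation calls.

Gene activation is the per-subject ratio of a gene's expression under
pro-inflammatory stimulation to its alert (unstimulated) expression.  The
fold change Delta = mu_MS / mu_HC compares group means of that activation;
its base-2 logarithm delta = log2(Delta) is the signed score used for
ranking and dysregulation: positive delta means over-activation in the
patient group, negative delta under-activation.
"""
from __future__ import annotations

import logging
from collections.abc import Iterable
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .network import RankedTargetSet

__all__ = [
    "ExpressionTable",
    "ActivationTable",
    "FoldChangeVector",
    "gene_activation",
    "fold_change",
    "rank_targets",
    "dysregulated_genes",
]

logger = logging.getLogger(__name__)

CONDITIONS = ("alert", "pro-inflammatory")


@dataclass(frozen=True)
class ExpressionTable:
    """Normalized expression, genes x samples, with sample metadata.

    ``meta`` is indexed by sample name with columns ``subject``, ``group``
    and ``condition`` (one of ``alert`` / ``pro-inflammatory``).  Every
    subject must contribute both conditions.
    """

    values: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self):
        missing = set(self.values.columns) - set(self.meta.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")
        for col in ("subject", "group", "condition"):
            if col not in self.meta.columns:
                raise ValueError(f"metadata lacks required column {col!r}")
        bad = set(self.meta["condition"]) - set(CONDITIONS)
        if bad:
            raise ValueError(
                f"unknown conditions {sorted(bad)}; expected one of {CONDITIONS}"
            )
        if (np.asarray(self.values, dtype=float) < 0).any():
            raise ValueError("expression values must be nonnegative")

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(self.values.index)

    @property
    def subjects(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self.meta["subject"]))

    def sample_for(self, subject: str, condition: str) -> str:
        sel = self.meta[
            (self.meta["subject"] == subject) & (self.meta["condition"] == condition)
        ]
        if len(sel) == 0:
            raise ValueError(f"subject {subject!r} lacks condition {condition!r}")
        if len(sel) > 1:
            raise ValueError(f"subject {subject!r} has replicate {condition!r} samples")
        return sel.index[0]


@dataclass(frozen=True)
class ActivationTable:
    """Per-subject gene activation (pro-inflammatory / alert ratio).

    ``values`` is genes x subjects; ``groups`` maps subject -> group label.
    ``excluded`` lists genes dropped because their alert expression was zero
    for at least one subject (the ratio would be undefined).
    """

    values: pd.DataFrame
    groups: pd.Series
    excluded: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self):
        missing = set(self.values.columns) - set(self.groups.index)
        if missing:
            raise ValueError(f"subjects without group label: {sorted(missing)}")

    def group_values(self, group: str) -> pd.DataFrame:
        subs = [s for s in self.values.columns if self.groups[s] == group]
        if not subs:
            raise ValueError(f"no subjects in group {group!r}")
        return self.values[subs]

    @property
    def group_labels(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self.groups[self.values.columns]))


def gene_activation(expr: ExpressionTable) -> ActivationTable:
    """Elementwise pro/alert expression ratio, one column per subject.

    Genes with zero alert expression in any subject are excluded from the
    result (logged); a subject missing either condition raises.
    """
    cols = {}
    for subject in expr.subjects:
        alert = expr.values[expr.sample_for(subject, "alert")].astype(float)
        pro = expr.values[expr.sample_for(subject, "pro-inflammatory")].astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            cols[subject] = pro / alert
    ratios = pd.DataFrame(cols, index=expr.values.index)
    bad = ratios.index[~np.isfinite(ratios).all(axis=1)]
    if len(bad):
        logger.warning(
            "excluding %d gene(s) with zero alert expression: %s",
            len(bad),
            ", ".join(map(str, bad)),
        )
    ratios = ratios.drop(index=bad)
    groups = (
        expr.meta.drop_duplicates("subject").set_index("subject")["group"]
    )
    return ActivationTable(values=ratios, groups=groups, excluded=tuple(map(str, bad)))


@dataclass(frozen=True)
class FoldChangeVector:
    """Per-gene fold change Delta = mu_MS / mu_HC and score delta = log2(Delta).

    ``groups`` records the (reference, test) labels the ratio was computed
    with, reference in the denominator.
    """

    delta: pd.Series
    score: pd.Series
    groups: tuple[str, str]

    def abs_score(self, use_log: bool = True) -> pd.Series:
        """Ranking magnitude: |log2 Delta| (default) or raw Delta."""
        return self.score.abs() if use_log else self.delta


def fold_change(
    activation: ActivationTable, groups: tuple[str, str] = ("HC", "MS")
) -> FoldChangeVector:
    """Group-mean activation ratio, test group over reference group.

    The group mean mu is the arithmetic mean of the per-subject activation
    ratios (not the ratio of mean expressions).
    """
    ref, test = groups
    mu_ref = activation.group_values(ref).mean(axis=1)
    mu_test = activation.group_values(test).mean(axis=1)
    if (mu_ref == 0).any():
        zero = list(mu_ref.index[mu_ref == 0])
        raise ValueError(f"reference group mean activation is zero for {zero}")
    delta = mu_test / mu_ref
    return FoldChangeVector(delta=delta, score=np.log2(delta), groups=(ref, test))


def rank_targets(
    foldchange: FoldChangeVector,
    targets: Iterable[str],
    use_log: bool = True,
) -> RankedTargetSet:
    """Total order on the targets: highest |delta| first, ties by ascending id."""
    targets = [str(t) for t in targets]
    missing = [t for t in targets if t not in foldchange.score.index]
    if missing:
        raise KeyError(f"targets without fold-change values: {missing}")
    magnitude = foldchange.abs_score(use_log=use_log)
    ordered = sorted(targets, key=lambda t: (-float(magnitude[t]), t))
    return RankedTargetSet(ordered)


def dysregulated_genes(
    foldchange: FoldChangeVector,
    percentile: float = 75.0,
    use_log: bool = True,
    genes: Optional[Iterable[str]] = None,
) -> set[str]:
    """Genes whose |delta| lies strictly above the given percentile.

    The percentile is computed with linear interpolation over the evaluated
    gene set (all genes with a fold change by default); "above" is strict,
    so when every score ties the result is empty.
    """
    magnitude = foldchange.abs_score(use_log=use_log)
    if genes is not None:
        magnitude = magnitude.loc[[str(g) for g in genes]]
    if len(magnitude) < 4:
        raise ValueError("need at least 4 evaluated genes for a percentile call")
    threshold = float(np.percentile(magnitude.to_numpy(dtype=float), percentile))
    return set(magnitude.index[magnitude > threshold])
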