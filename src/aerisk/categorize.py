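"""Regulatory categorization of AE risks and relative effects.

Absolute risks map to the SmPC/CIOMS frequency classes (very rare ... very
common) by percent thresholds; relative effects map to benefit-assessment
style evidence classes (no effect / minor / considerable / major) from their
confidence-interval bounds.  Cross-tabulating the classes reached with a
comparator estimator against those reached with the gold standard shows how
estimator bias propagates into regulatory conclusions.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import Sequence

import numpy as np
import pandas as pd


class FrequencyCategory(IntEnum):
    """SmPC/CIOMS frequency class of an AE probability (ordered)."""

    VERY_RARE = 0
    RARE = 1
    UNCOMMON = 2
    COMMON = 3
    VERY_COMMON = 4

    @property
    def label(self) -> str:
        return self.name.lower().replace("_", " ")


class EvidenceCategory(IntEnum):
    """Evidence class of a relative effect (ordered by severity)."""

    NO_EFFECT = 0
    MINOR = 1
    CONSIDERABLE = 2
    MAJOR = 3

    @property
    def label(self) -> str:
        return self.name.lower().replace("_", " ")


# One central constants table so every boundary convention lives in one place.
# Frequency classes: risk < 0.01% very rare, < 0.1% rare, < 1% uncommon,
# < 10% common, >= 10% very common (strict "<" at each upper edge, ">=" closes
# the top class).
FREQUENCY_EDGES = (1e-4, 1e-3, 1e-2, 1e-1)
# Evidence classes for an effect > 1, judged by the CI's LOWER bound; the
# printed intervals overlap at the edges, resolved here toward the LESS severe
# class (a bound exactly on an edge takes the milder category).
EVIDENCE_EDGES_HIGH = (1.11, 1.33)   # lower bound <= 1.11 minor, <= 1.33 considerable, else major
# For an effect < 1, judged by the CI's UPPER bound, symmetrically.
EVIDENCE_EDGES_LOW = (0.90, 0.75)    # upper bound >= 0.90 minor, >= 0.75 considerable, else major


def frequency_category(p: float) -> FrequencyCategory:
    """Frequency class of an AE probability ``p`` in [0, 1]."""
    p = float(p)
    if not np.isfinite(p) or p < 0 or p > 1:
        raise ValueError(f"probability must lie in [0, 1], got {p}")
    idx = int(np.searchsorted(FREQUENCY_EDGES, p, side="right"))
    return FrequencyCategory(idx)


def evidence_category_from_ci(point: float, lower: float, upper: float) -> EvidenceCategory:
    """Evidence class from a relative-effect point estimate and CI bounds."""
    if not (np.isfinite(point) and np.isfinite(lower) and np.isfinite(upper)):
        raise ValueError("evidence categorization needs finite point estimate and CI bounds")
    if lower <= 1.0 <= upper:
        return EvidenceCategory.NO_EFFECT
    if point > 1.0:
        if lower <= EVIDENCE_EDGES_HIGH[0]:
            return EvidenceCategory.MINOR
        if lower <= EVIDENCE_EDGES_HIGH[1]:
            return EvidenceCategory.CONSIDERABLE
        return EvidenceCategory.MAJOR
    if upper >= EVIDENCE_EDGES_LOW[0]:
        return EvidenceCategory.MINOR
    if upper >= EVIDENCE_EDGES_LOW[1]:
        return EvidenceCategory.CONSIDERABLE
    return EvidenceCategory.MAJOR


def evidence_category(effect) -> EvidenceCategory:
    """Evidence class of a :class:`~aerisk.relative.RelativeEffect`."""
    if not getattr(effect, "defined", True):
        raise ValueError("cannot categorize an undefined relative effect")
    return evidence_category_from_ci(effect.point, effect.lower, effect.upper)


@dataclass
class SwitchTable:
    """Cross-tabulation of gold-standard (rows) vs comparator (columns) classes.

    Diagonal entries are agreements; off-diagonal entries are category
    switches induced by the comparator estimator.  Pairs in which either
    member could not be classified are dropped and counted in ``n_dropped``.
    """

    counts: pd.DataFrame
    n_dropped: int = 0

    @property
    def grand_total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def marginals(self) -> tuple[pd.Series, pd.Series]:
        """(gold row totals, comparator column totals)."""
        return self.counts.sum(axis=1), self.counts.sum(axis=0)

    def net_upgrades(self) -> int:
        """Pairs above the diagonal (comparator more severe) minus below."""
        m = self.counts.to_numpy()
        upper = int(np.triu(m, 1).sum())
        lower = int(np.tril(m, -1).sum())
        return upper - lower

    def to_csv(self, path) -> None:
        self.counts.to_csv(path)


def switch_table(gold: Sequence, comparator: Sequence) -> SwitchTable:
    """Cross-tabulate paired category lists (same AEs, same order).

    Entries may be ``None`` for AEs that could not be classified (undefined
    effects); a pair with any ``None`` is dropped and counted.
    """
    if len(gold) != len(comparator):
        raise ValueError(
            f"paired category lists must have equal length, got {len(gold)} and {len(comparator)}"
        )
    pairs = [(g, c) for g, c in zip(gold, comparator) if g is not None and c is not None]
    dropped = len(gold) - len(pairs)
    cat_type = type(pairs[0][0]) if pairs else FrequencyCategory
    labels = list(cat_type)
    m = pd.DataFrame(
        0, index=[c.label for c in labels], columns=[c.label for c in labels], dtype=int
    )
    for g, c in pairs:
        m.loc[g.label, c.label] += 1
    m.index.name = "gold"
    m.columns.name = "comparator"
    return SwitchTable(m, n_dropped=dropped)
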