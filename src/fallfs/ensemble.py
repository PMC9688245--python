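"""The feature-selection ensemble: threshold each filter ranking, then combine.

Four filter rankings (chi-square, information gain, MRMR, ReliefF) are each
cut to their top fraction of features; the four filter subsets are then
merged by a membership-count rule:

* ``union``        — kept if present in at least one subset,
* ``union2``       — at least two,
* ``union3``       — at least three,
* ``intersection`` — in all four.

Threshold-then-combine is deliberate (combining full rankings first performs
worse); a threshold of 1.0 is the no-selection baseline and ignores the
combination rule. An empty final subset (possible with disjoint rankings at
tight thresholds) is flagged infeasible rather than raised, so a grid run can
skip it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from fallfs.rankers import RANKERS, RankedList, rank_relieff

logger = logging.getLogger(__name__)

THRESHOLDS = (1.0, 0.50, 0.25, 0.10)
COMBINATIONS = ("union", "union2", "union3", "intersection")
_MIN_COUNT = {"union": 1, "union2": 2, "union3": 3, "intersection": 4}


@dataclass(frozen=True)
class EnsembleConfig:
    threshold: float
    combination: str | None = "union"

    def __post_init__(self) -> None:
        if self.threshold not in THRESHOLDS:
            raise ValueError(f"threshold must be one of {THRESHOLDS}, got {self.threshold}")
        if self.threshold != 1.0 and self.combination not in COMBINATIONS:
            raise ValueError(f"combination must be one of {COMBINATIONS}, got {self.combination}")

    @property
    def label(self) -> str:
        pct = f"{self.threshold:.0%}"
        return pct if self.threshold == 1.0 else f"{pct}+{self.combination}"


@dataclass
class FinalSubset:
    """Selected features with per-filter provenance counts.

    ``features`` are ordered by descending membership count, then name.
    """

    features: list[str]
    provenance: dict[str, int] = field(default_factory=dict)
    infeasible: bool = False

    def __len__(self) -> int:
        return len(self.features)


def subset_size(p: int, threshold: float) -> int:
    """Top-m size: round threshold*p half away from zero, floor 1; all at 1.0."""
    if p < 1:
        raise ValueError("empty ranking")
    if threshold == 1.0:
        return p
    return max(1, int(math.floor(threshold * p + 0.5)))


def apply_threshold(ranked: RankedList, threshold: float) -> list[str]:
    """The top fraction of a ranked list, in rank order."""
    if threshold not in THRESHOLDS:
        raise ValueError(f"threshold must be one of {THRESHOLDS}")
    return ranked.top(subset_size(len(ranked.features), threshold))


def combine_subsets(subsets, combination: str) -> FinalSubset:
    """Merge exactly four filter subsets by membership count."""
    subsets = list(subsets)
    if len(subsets) != 4:
        raise ValueError(f"expected exactly 4 filter subsets, got {len(subsets)}")
    if combination not in _MIN_COUNT:
        raise ValueError(f"unknown combination {combination!r}")
    counts: dict[str, int] = {}
    for sub in subsets:
        for f in set(sub):
            counts[f] = counts.get(f, 0) + 1
    need = _MIN_COUNT[combination]
    selected = sorted((f for f, c in counts.items() if c >= need), key=lambda f: (-counts[f], f))
    infeasible = not selected
    if infeasible:
        logger.info("combination %r produced an empty final subset; flagged infeasible", combination)
    return FinalSubset(selected, counts, infeasible)


def run_fs_ensemble(X, y, config: EnsembleConfig, relieff_kwargs: dict | None = None) -> FinalSubset:
    """Rank with all four filters, threshold each, combine — in that order."""
    rankings = rank_all(X, y, relieff_kwargs)
    return ensemble_from_rankings(rankings, config)


def rank_all(X, y, relieff_kwargs: dict | None = None) -> dict[str, RankedList]:
    """All four filter rankings of the same data (reusable across thresholds)."""
    out: dict[str, RankedList] = {}
    for method, fn in RANKERS.items():
        if fn is rank_relieff:
            out[method] = fn(X, y, **(relieff_kwargs or {}))
        else:
            out[method] = fn(X, y)
    return out


def ensemble_from_rankings(rankings: dict[str, RankedList], config: EnsembleConfig) -> FinalSubset:
    """Threshold precomputed rankings and combine them."""
    if set(rankings) != set(RANKERS):
        raise ValueError(f"need rankings for exactly {sorted(RANKERS)}")
    if config.threshold == 1.0:
        all_features = list(rankings["chi_square"].features)
        return FinalSubset(sorted(all_features), {f: 4 for f in all_features})
    subsets = [apply_threshold(rankings[m], config.threshold) for m in sorted(rankings)]
    return combine_subsets(subsets, config.combination)
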