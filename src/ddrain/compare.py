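"""Method-comparison statistics for VAF measurements.

Compares two quantification routes sample-by-sample: Spearman rank
correlation of the paired VAFs, a 2x2 qualitative concordance table of
positive/negative calls, and replicate-variability summaries (maximal
and mean repetition differences, mean of per-sample SDs).  Samples used
to train the k-NN classifier can be excluded so the comparison is not
flattered by its own training material.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .classify import TrainingSet

__all__ = [
    "PairedVafs",
    "ConcordanceTable",
    "RepetitionStats",
    "spearman_correlation",
    "concordance",
    "repetition_stats",
    "exclude_training",
]


@dataclass(frozen=True)
class PairedVafs:
    """Sample-aligned VAF pairs from two methods (percent)."""

    sample_ids: tuple[str, ...]
    vaf_a: tuple[float, ...]
    vaf_b: tuple[float, ...]
    excluded: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (len(self.sample_ids) == len(self.vaf_a) == len(self.vaf_b)):
            raise ValueError("sample_ids, vaf_a and vaf_b must be aligned")
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        object.__setattr__(self, "vaf_a", tuple(float(v) for v in self.vaf_a))
        object.__setattr__(self, "vaf_b", tuple(float(v) for v in self.vaf_b))
        object.__setattr__(self, "excluded", tuple(self.excluded))

    @classmethod
    def from_dicts(
        cls, vafs_a: Mapping[str, float], vafs_b: Mapping[str, float]
    ) -> "PairedVafs":
        """Pair by sample id, keeping only samples present in both."""
        common = [s for s in vafs_a if s in vafs_b]
        return cls(
            sample_ids=tuple(common),
            vaf_a=tuple(vafs_a[s] for s in common),
            vaf_b=tuple(vafs_b[s] for s in common),
        )

    def __len__(self) -> int:
        return len(self.sample_ids)


@dataclass(frozen=True)
class ConcordanceTable:
    """2x2 qualitative agreement between two call vectors.

    ``pos_neg`` counts samples positive by method A but negative by B,
    etc.; ``discordant_total`` is the off-diagonal sum.
    """

    pos_pos: int
    pos_neg: int
    neg_pos: int
    neg_neg: int

    @property
    def discordant_total(self) -> int:
        return self.pos_neg + self.neg_pos

    @property
    def n(self) -> int:
        return self.pos_pos + self.pos_neg + self.neg_pos + self.neg_neg


@dataclass(frozen=True)
class RepetitionStats:
    """Replicate-variability summary in VAF percentage points.

    ``max_difference`` / ``mean_difference`` are the largest and the
    average of the per-sample mean pairwise |difference|; ``mean_sd``
    averages the per-sample sample SDs.  Samples with fewer than two
    replicates do not contribute; when none has two the fields are
    ``None``.
    """

    per_sample_max: dict[str, float]
    max_difference: float | None
    mean_difference: float | None
    mean_sd: float | None
    n_samples: int


def spearman_correlation(
    pairs: PairedVafs, *, method: str = "approx", seed: int = 0
) -> tuple[float, float]:
    """Spearman rank correlation R and p-value for paired VAFs.

    Ranks use mid-ranks for ties; ``method="approx"`` (default) takes
    the p-value from the t approximation
    ``t = R * sqrt((n-2) / (1-R^2))``; ``method="exact"`` enumerates all
    pairings (only for n <= 8).

    Raises
    ------
    ValueError
        Fewer than 3 pairs, zero variance in either variable, or an
        exact request with n > 8.
    """
    n = len(pairs)
    if n < 3:
        raise ValueError("need >= 3 pairs for a rank correlation")
    x = np.asarray(pairs.vaf_a)
    y = np.asarray(pairs.vaf_b)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one variable; correlation undefined")
    res = stats.spearmanr(x, y)
    r = float(res.statistic)
    if method == "approx":
        return r, float(res.pvalue)
    if method != "exact":
        raise ValueError(f"unknown method {method!r}")
    if n > 8:
        raise ValueError("exact permutation p only supported for n <= 8")
    # Exact two-sided permutation distribution of |R| over all pairings.
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    hits = 0
    total = 0
    r_abs = abs(r) - 1e-12
    for perm in itertools.permutations(range(n)):
        rp = np.corrcoef(rx, ry[list(perm)])[0, 1]
        hits += abs(rp) >= r_abs
        total += 1
    return r, hits / total


def concordance(calls_a: Sequence[str], calls_b: Sequence[str]) -> ConcordanceTable:
    """Tabulate qualitative positive/negative agreement.

    Inputs must be aligned vectors of ``"positive"``/``"negative"``;
    no-calls must be dropped (and counted) upstream.
    """
    if len(calls_a) != len(calls_b):
        raise ValueError("call vectors must have the same length")
    valid = {"positive", "negative"}
    tally = {("positive", "positive"): 0, ("positive", "negative"): 0,
             ("negative", "positive"): 0, ("negative", "negative"): 0}
    for a, b in zip(calls_a, calls_b):
        if a not in valid or b not in valid:
            raise ValueError(f"calls must be positive/negative, got ({a!r}, {b!r})")
        tally[(a, b)] += 1
    return ConcordanceTable(
        pos_pos=tally[("positive", "positive")],
        pos_neg=tally[("positive", "negative")],
        neg_pos=tally[("negative", "positive")],
        neg_neg=tally[("negative", "negative")],
    )


def repetition_stats(
    replicate_vafs: Mapping[str, Sequence[float]]
) -> RepetitionStats:
    """Summarise replicate-to-replicate VAF scatter per sample."""
    per_sample_max: dict[str, float] = {}
    mean_diffs: list[float] = []
    sds: list[float] = []
    for sample, values in replicate_vafs.items():
        vals = np.asarray(list(values), dtype=float)
        if vals.size < 2:
            continue
        diffs = np.abs(vals[:, None] - vals[None, :])
        iu = np.triu_indices(vals.size, k=1)
        pair = diffs[iu]
        per_sample_max[sample] = float(pair.max())
        mean_diffs.append(float(pair.mean()))
        sds.append(float(np.std(vals, ddof=1)))
    if not per_sample_max:
        return RepetitionStats(
            per_sample_max={},
            max_difference=None,
            mean_difference=None,
            mean_sd=None,
            n_samples=0,
        )
    return RepetitionStats(
        per_sample_max=per_sample_max,
        max_difference=max(per_sample_max.values()),
        mean_difference=float(np.mean(mean_diffs)),
        mean_sd=float(np.mean(sds)),
        n_samples=len(per_sample_max),
    )


def exclude_training(pairs: PairedVafs, training: TrainingSet) -> PairedVafs:
    """Drop pairs whose sample served as k-NN training material.

    Matches on the training set's recorded source sample ids (falling
    back to source well ids), so a classifier is never evaluated on its
    own training wells.  Removed ids are recorded in ``excluded``.
    """
    banned = set(training.source_samples) | set(training.source_wells)
    keep = [i for i, s in enumerate(pairs.sample_ids) if s not in banned]
    removed = tuple(s for s in pairs.sample_ids if s in banned)
    return PairedVafs(
        sample_ids=tuple(pairs.sample_ids[i] for i in keep),
        vaf_a=tuple(pairs.vaf_a[i] for i in keep),
        vaf_b=tuple(pairs.vaf_b[i] for i in keep),
        excluded=pairs.excluded + removed,
    )
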