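"""Droplet classification: NTC-anchored manual gating and supervised k-NN.

Two classification routes, mirroring how duplex ddPCR wells are read in
practice:

* **Manual gating** places one amplitude cut per channel just above the
  no-template-control (NTC) cloud and assigns each droplet to the
  quadrant it falls in.
* **k-NN** labels each droplet by majority vote of its k nearest
  manually-labeled training droplets (Euclidean distance in raw
  (ch1, ch2) amplitude space, k = 3 by default).

Either route can be followed by a *rain filter* that relabels
unclassifiable droplets as RAIN: droplets outside an amplitude band
(broken / multi-template outliers) and droplets too far from their
assigned cluster's training centroid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .model import CLASS_LABELS, RAIN, ClassifiedWell, Well

__all__ = [
    "GateThresholds",
    "TrainingSet",
    "RainPolicy",
    "fit_ntc_gate",
    "manual_gate",
    "knn_classify",
    "apply_rain_filter",
    "build_training_set",
]

_CODE = {lab: i for i, lab in enumerate(CLASS_LABELS)}


@dataclass(frozen=True)
class GateThresholds:
    """Per-channel amplitude cuts; droplets strictly above are positive."""

    ch1_cut: float
    ch2_cut: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.ch1_cut) and math.isfinite(self.ch2_cut)):
            raise ValueError("gate thresholds must be finite")


@dataclass(frozen=True)
class TrainingSet:
    """Manually labeled droplets pooled from training wells.

    ``labels`` must use only the four countable classes (RAIN carries
    no cluster identity and cannot train a classifier).
    ``source_wells``/``source_samples`` record provenance so that
    training material can be excluded from method comparisons.
    """

    amplitudes: np.ndarray
    labels: np.ndarray
    source_wells: tuple[str, ...] = ()
    source_samples: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        amps = np.asarray(self.amplitudes, dtype=float)
        labels = np.asarray(self.labels, dtype="<U4")
        if amps.ndim != 2 or amps.shape[1] != 2:
            raise ValueError("training amplitudes must be (n, 2)")
        if labels.shape != (amps.shape[0],):
            raise ValueError("training labels must align with amplitudes")
        bad = set(np.unique(labels)) - set(CLASS_LABELS)
        if bad:
            raise ValueError(f"training labels must be in {CLASS_LABELS}; got {sorted(bad)}")
        object.__setattr__(self, "amplitudes", amps)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "source_wells", tuple(self.source_wells))
        object.__setattr__(self, "source_samples", tuple(self.source_samples))

    def __len__(self) -> int:
        return int(self.amplitudes.shape[0])

    @property
    def codes(self) -> np.ndarray:
        return np.array([_CODE[lab] for lab in self.labels], dtype=np.int64)

    def centroids(self) -> dict[str, np.ndarray]:
        """Per-class mean amplitude of the training droplets."""
        out: dict[str, np.ndarray] = {}
        for lab in CLASS_LABELS:
            mask = self.labels == lab
            if np.any(mask):
                out[lab] = self.amplitudes[mask].mean(axis=0)
        return out

    def pooled_within_class_sd(self) -> float:
        """Pooled within-class, per-channel amplitude SD.

        Square root of the df-weighted average of the per-class,
        per-channel sample variances; the natural amplitude-noise scale
        of the training data.
        """
        ss = 0.0
        df = 0
        for lab in CLASS_LABELS:
            pts = self.amplitudes[self.labels == lab]
            if pts.shape[0] >= 2:
                ss += float(((pts - pts.mean(axis=0)) ** 2).sum())
                df += 2 * (pts.shape[0] - 1)
        if df == 0:
            raise ValueError("no class has >= 2 training droplets; SD undefined")
        return math.sqrt(ss / df)


@dataclass(frozen=True)
class RainPolicy:
    """Which droplets to set aside as RAIN.

    ``low_bound``/``high_bound`` bracket acceptable amplitudes: a droplet
    whose larger channel amplitude falls below ``low_bound`` is treated
    as broken, above ``high_bound`` as a multi-template/outlier droplet.
    ``rain_distance`` is the maximal Euclidean distance from a droplet
    to its assigned class's training centroid; ``None`` derives it from
    the training data as 3x the pooled within-class SD, ``inf`` disables
    the rule.
    """

    rain_distance: float | None = None
    low_bound: float = 300.0
    high_bound: float = 12_000.0

    def __post_init__(self) -> None:
        if self.rain_distance is not None and not self.rain_distance > 0:
            raise ValueError("rain_distance must be > 0 (or None/inf)")
        if not self.low_bound < self.high_bound:
            raise ValueError("low_bound must be < high_bound")

    def resolve_distance(self, training: TrainingSet) -> float:
        if self.rain_distance is not None:
            return float(self.rain_distance)
        return 3.0 * training.pooled_within_class_sd()


def fit_ntc_gate(ntc_well: Well, multiplier: float = 5.0) -> GateThresholds:
    """Place per-channel cuts just above the NTC droplet cloud.

    Each cut is ``mean + multiplier * SD`` of the NTC amplitudes in that
    channel (sample SD), i.e. gating within the limits of detection of
    the no-template control.
    """
    if multiplier <= 0:
        raise ValueError("multiplier must be > 0")
    if ntc_well.n_droplets < 2:
        raise ValueError(
            f"NTC well {ntc_well.well_id!r} has {ntc_well.n_droplets} droplet(s); "
            "need >= 2 to estimate spread"
        )
    mean = ntc_well.amplitudes.mean(axis=0)
    sd = ntc_well.amplitudes.std(axis=0, ddof=1)
    cuts = mean + multiplier * sd
    return GateThresholds(ch1_cut=float(cuts[0]), ch2_cut=float(cuts[1]))


def manual_gate(well: Well, gate: GateThresholds) -> ClassifiedWell:
    """Quadrant classification against per-channel cuts.

    A droplet is channel-positive only when strictly above the cut
    (boundary droplets count as negative): PN = ch1-positive only,
    NP = ch2-positive only, PP = both, NN = neither.  Manual gating
    never emits RAIN.
    """
    if well.n_droplets == 0:
        raise ValueError(f"well {well.well_id!r} has no droplets")
    mut_pos = well.ch1 > gate.ch1_cut
    wt_pos = well.ch2 > gate.ch2_cut
    codes = wt_pos.astype(np.int64) + 2 * mut_pos.astype(np.int64)
    labels = np.asarray(CLASS_LABELS, dtype="<U4")[codes]
    return ClassifiedWell(well=well, labels=labels)


def _vote(codes_nb: np.ndarray) -> np.ndarray:
    """Majority vote over neighbor class codes, rows sorted by distance.

    Ties between top-voted classes go to the class of the nearest
    neighbor belonging to one of them.
    """
    n, k = codes_nb.shape
    counts = np.zeros((n, len(CLASS_LABELS)), dtype=np.int64)
    rows = np.repeat(np.arange(n), k)
    np.add.at(counts, (rows, codes_nb.ravel()), 1)
    top = counts.max(axis=1)
    tied = counts == top[:, None]  # (n, 4): classes at the max count
    nb_is_tied = tied[np.arange(n)[:, None], codes_nb]  # (n, k)
    first = nb_is_tied.argmax(axis=1)  # nearest neighbor in a tied class
    return codes_nb[np.arange(n), first]


def knn_classify(well: Well, training: TrainingSet, k: int = 3) -> ClassifiedWell:
    """Label each droplet by its k nearest training droplets.

    Euclidean distance in raw (ch1, ch2) amplitude space; majority vote
    among the k neighbors, ties resolved toward the nearest tied class.
    Never emits RAIN (rain handling is a separate filter).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(training) == 0:
        raise ValueError("training set is empty")
    if k > len(training):
        raise ValueError(f"k={k} exceeds training size {len(training)}")
    if well.n_droplets == 0:
        raise ValueError(f"well {well.well_id!r} has no droplets")
    nn = NearestNeighbors(n_neighbors=k).fit(training.amplitudes)
    _, idx = nn.kneighbors(well.amplitudes)  # rows sorted by distance
    codes = _vote(training.codes[idx])
    labels = np.asarray(CLASS_LABELS, dtype="<U4")[codes]
    return ClassifiedWell(well=well, labels=labels)


def apply_rain_filter(
    classified: ClassifiedWell, training: TrainingSet, policy: RainPolicy
) -> ClassifiedWell:
    """Relabel unclassifiable droplets as RAIN.

    Two rules, applied to the incoming labels:

    1. amplitude bounds -- droplets whose larger channel amplitude is
       below ``low_bound`` (broken) or above ``high_bound`` (outlier)
       become RAIN;
    2. cluster distance -- droplets farther than the rain distance from
       the centroid of their assigned class's training droplets become
       RAIN.

    Droplets already labeled RAIN stay RAIN; the filter is idempotent
    and shrinking the rain distance can only grow the RAIN count.
    """
    labels = classified.labels.copy()
    amps = classified.well.amplitudes
    dist_cut = policy.resolve_distance(training)

    peak = amps.max(axis=1)
    out_of_band = (peak < policy.low_bound) | (peak > policy.high_bound)
    labels[out_of_band] = RAIN

    if np.isfinite(dist_cut):
        centroids = training.centroids()
        for lab in CLASS_LABELS:
            mask = labels == lab
            if not np.any(mask):
                continue
            if lab not in centroids:
                raise ValueError(
                    f"class {lab!r} was assigned but has no training droplets"
                )
            d = np.linalg.norm(amps[mask] - centroids[lab], axis=1)
            sel = np.flatnonzero(mask)
            labels[sel[d > dist_cut]] = RAIN

    return classified.relabeled(labels)


def build_training_set(
    plates: Sequence[Sequence[ClassifiedWell]],
    wells_per_plate: int = 3,
    seed: int | np.random.Generator = 0,
) -> TrainingSet:
    """Randomly pick manually classified wells per plate and pool them.

    ``plates`` holds, per plate, the eligible manually classified sample
    wells (QC-passing, low-noise — eligibility is the caller's filter).
    ``wells_per_plate`` wells are drawn per plate without replacement
    with a seeded generator; their droplets are pooled, dropping any
    droplet already set aside as RAIN.  The default 3 wells over 6
    plates reproduces an 18-well training corpus.
    """
    if wells_per_plate < 1:
        raise ValueError("wells_per_plate must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chosen: list[ClassifiedWell] = []
    for i, eligible in enumerate(plates):
        eligible = list(eligible)
        if len(eligible) < wells_per_plate:
            raise ValueError(
                f"plate index {i} has {len(eligible)} eligible wells; "
                f"need >= {wells_per_plate}"
            )
        picks = rng.choice(len(eligible), size=wells_per_plate, replace=False)
        chosen.extend(eligible[int(j)] for j in sorted(picks))

    amps: list[np.ndarray] = []
    labels: list[np.ndarray] = []
    wells: list[str] = []
    samples: list[str] = []
    for cw in chosen:
        keep = cw.labels != RAIN
        amps.append(cw.well.amplitudes[keep])
        labels.append(cw.labels[keep])
        wells.append(cw.well.well_id)
        if cw.well.sample_id:
            samples.append(cw.well.sample_id)
    return TrainingSet(
        amplitudes=np.concatenate(amps, axis=0),
        labels=np.concatenate(labels),
        source_wells=tuple(wells),
        source_samples=tuple(samples),
    )
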