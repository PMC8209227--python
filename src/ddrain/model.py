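"""Core data types for duplex droplet digital PCR (ddPCR).

A duplex ddPCR reaction partitions template DNA into ~10,000-20,000
droplets, each an end-point PCR scored on two fluorescence channels:
channel 1 carries the mutation-specific probe (VIC), channel 2 the
wild-type probe (FAM).  Each droplet is classified into one of four
clusters -- NN (no template), NP (wild type only), PN (mutant only),
PP (both) -- or set aside as RAIN: droplets of intermediate, very low
(broken) or abnormally high (multi-template/outlier) amplitude that
cannot be counted with confidence and are excluded from quantification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, NamedTuple, Sequence

import numpy as np

__all__ = [
    "LABELS",
    "CLASS_LABELS",
    "RAIN",
    "WELL_ROLES",
    "Droplet",
    "Well",
    "Plate",
    "ClassifiedWell",
    "tally_labels",
]

#: The four countable droplet classes, in canonical order.
CLASS_LABELS: tuple[str, ...] = ("NN", "NP", "PN", "PP")

#: Label for droplets excluded from quantification.
RAIN: str = "RAIN"

#: Every label a droplet may carry.
LABELS: tuple[str, ...] = CLASS_LABELS + (RAIN,)

#: Allowed well roles on a plate.
WELL_ROLES: tuple[str, ...] = (
    "sample",
    "ntc",
    "positive_control",
    "negative_control",
)


class Droplet(NamedTuple):
    """One partition's two-channel fluorescence amplitudes.

    ``ch1`` is the mutation-probe (VIC) amplitude, ``ch2`` the
    wild-type-probe (FAM) amplitude, both in arbitrary fluorescence
    units.  Amplitudes may sit near zero for broken droplets but must
    be finite.
    """

    ch1: float
    ch2: float


def _as_amplitude_array(amplitudes: object) -> np.ndarray:
    arr = np.asarray(amplitudes, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError(
            f"amplitudes must be an (n, 2) array of (ch1, ch2) values, "
            f"got shape {arr.shape}"
        )
    if not np.all(np.isfinite(arr)):
        raise ValueError("droplet amplitudes must be finite")
    return arr


@dataclass(frozen=True)
class Well:
    """A reaction well: droplet amplitudes plus role metadata.

    Parameters
    ----------
    well_id:
        Identifier unique within a plate (e.g. ``"A01"``).
    amplitudes:
        ``(n_droplets, 2)`` float array; column 0 is ch1 (mutant probe),
        column 1 is ch2 (wild-type probe).  Row order is preserved from
        the source file or simulation.
    role:
        One of ``sample``, ``ntc``, ``positive_control``,
        ``negative_control``.
    sample_id:
        Biological sample identifier; replicate wells of the same sample
        share it.  Empty for NTC wells.
    replicate_index:
        Non-negative ordinal distinguishing replicate reactions of the
        same sample.
    is_training:
        Flags wells whose manual classification may be pooled into a
        k-NN training set.
    """

    well_id: str
    amplitudes: np.ndarray
    role: str = "sample"
    sample_id: str = ""
    replicate_index: int = 0
    is_training: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "amplitudes", _as_amplitude_array(self.amplitudes))
        if self.role not in WELL_ROLES:
            raise ValueError(
                f"unknown well role {self.role!r}; allowed roles: "
                + ", ".join(WELL_ROLES)
            )
        if self.replicate_index < 0:
            raise ValueError("replicate_index must be non-negative")

    @property
    def n_droplets(self) -> int:
        return int(self.amplitudes.shape[0])

    @property
    def ch1(self) -> np.ndarray:
        """Channel-1 (mutant probe) amplitudes."""
        return self.amplitudes[:, 0]

    @property
    def ch2(self) -> np.ndarray:
        """Channel-2 (wild-type probe) amplitudes."""
        return self.amplitudes[:, 1]

    @property
    def droplets(self) -> list[Droplet]:
        """The droplets as an ordered list of :class:`Droplet` tuples."""
        return [Droplet(float(a), float(b)) for a, b in self.amplitudes]

    def __iter__(self) -> Iterator[Droplet]:
        for a, b in self.amplitudes:
            yield Droplet(float(a), float(b))

    def __len__(self) -> int:
        return self.n_droplets


@dataclass(frozen=True)
class Plate:
    """A set of wells run together; well ids must be unique."""

    plate_id: str
    wells: tuple[Well, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "wells", tuple(self.wells))
        seen: set[str] = set()
        for w in self.wells:
            if w.well_id in seen:
                raise ValueError(f"duplicate well_id {w.well_id!r} in plate {self.plate_id!r}")
            seen.add(w.well_id)

    def well(self, well_id: str) -> Well:
        for w in self.wells:
            if w.well_id == well_id:
                return w
        raise KeyError(well_id)

    def wells_with_role(self, role: str) -> list[Well]:
        return [w for w in self.wells if w.role == role]

    def __len__(self) -> int:
        return len(self.wells)


def tally_labels(labels: np.ndarray) -> dict[str, int]:
    """Count droplets per label, always reporting all five labels."""
    labels = np.asarray(labels)
    return {lab: int(np.sum(labels == lab)) for lab in LABELS}


@dataclass(frozen=True)
class ClassifiedWell:
    """A well together with one label per droplet and the class tally.

    ``labels`` is aligned index-for-index with ``well.amplitudes``;
    ``counts`` always maps all five labels (NN, NP, PN, PP, RAIN) and
    sums to the droplet count.
    """

    well: Well
    labels: np.ndarray
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype="<U4")
        object.__setattr__(self, "labels", labels)
        if labels.shape != (self.well.n_droplets,):
            raise ValueError(
                f"labels (len {labels.shape}) must align with droplets "
                f"(n={self.well.n_droplets})"
            )
        bad = set(np.unique(labels)) - set(LABELS)
        if bad:
            raise ValueError(f"unknown droplet labels: {sorted(bad)}")
        tally = tally_labels(labels)
        if self.counts:
            full = {lab: int(self.counts.get(lab, 0)) for lab in LABELS}
            if full != tally:
                raise ValueError("counts do not match the label tally")
            object.__setattr__(self, "counts", full)
        else:
            object.__setattr__(self, "counts", tally)

    def relabeled(self, labels: Sequence[str] | np.ndarray) -> "ClassifiedWell":
        """Return a copy of this well with new labels (counts recomputed)."""
        return ClassifiedWell(well=self.well, labels=np.asarray(labels, dtype="<U4"))

    @property
    def n_rain(self) -> int:
        return self.counts[RAIN]

    @property
    def n_accepted(self) -> int:
        """Droplets entering quantification (everything but RAIN)."""
        return self.well.n_droplets - self.counts[RAIN]
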