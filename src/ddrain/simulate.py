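"""Synthetic duplex-ddPCR droplet generator with FFPE artifacts.

The generator reproduces the statistical structure the downstream
analysis assumes.  Template copies per droplet are Poisson: a droplet
receives ``Poisson(lambda_mut)`` mutant and ``Poisson(lambda_wt)``
wild-type copies, which fixes its true class (NN/NP/PN/PP).  End-point
fluorescence saturates, so amplitude depends only on presence/absence:
each droplet's two-channel amplitude is Gaussian around its class
center.  FFPE-derived DNA then corrupts a fraction of droplets:

* **rain** -- a degraded positive droplet is pulled linearly toward the
  NN center (diminished fluorescence); symmetrically, an NN droplet can
  be raised toward a positive center (elevated background);
* **broken** droplets collapse to near-zero amplitude in both channels;
* **outliers** have abnormally high amplitude (multiple templates or
  reader artifacts).

Artifacts corrupt amplitudes only, never the true copy counts, so the
ground-truth variant allele frequency (VAF) of a simulated well is
always ``100 * lambda_mut / (lambda_mut + lambda_wt)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .model import CLASS_LABELS, Plate, Well

__all__ = [
    "SimulationConfig",
    "WellSpec",
    "SimulatedPlate",
    "simulate_well",
    "simulate_ntc",
    "simulate_plate",
    "simulate_reference_vaf",
    "config_for_vaf",
]

#: Default cluster centers (ch1, ch2) in fluorescence units.  Chosen to be
#: well separated with plausible rain geometry; the negative cloud sits
#: near (1000, 1000) and saturated positives near 9000 on their channel.
DEFAULT_CENTERS: dict[str, tuple[float, float]] = {
    "NN": (1000.0, 1000.0),
    "NP": (1200.0, 9000.0),
    "PN": (9000.0, 1200.0),
    "PP": (9000.0, 9000.0),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated well.

    Parameters
    ----------
    n_droplets:
        Droplets generated per well; default 15,000, the middle of the
        10,000-20,000 band a droplet generator produces.
    lambda_wt, lambda_mut:
        Mean wild-type / mutant template copies per droplet (the Poisson
        rates).  The ground-truth VAF is
        ``100 * lambda_mut / (lambda_mut + lambda_wt)``.
    cluster_centers:
        Mapping NN/NP/PN/PP -> (ch1 mean, ch2 mean).
    cluster_sd:
        Per-channel Gaussian amplitude noise (fluorescence units).
    rain_fraction:
        Probability a droplet is degraded: positives are pulled toward
        the NN center, NN droplets raised toward a random positive
        center.
    broken_fraction:
        Probability a droplet collapses to near-zero amplitude.
    outlier_fraction:
        Probability a droplet's amplitudes are multiplied by a factor
        drawn from Uniform(2.5, 4).
    degradation_depth:
        ``(lo, hi)`` range of the uniform pull factor for rain droplets;
        1 would move a droplet all the way to the target center.
    contamination_rate:
        NTC-only: probability a droplet is emitted from a random
        positive cluster (template contamination); default 0.
    seed:
        Seed of the per-well random stream.
    """

    n_droplets: int = 15_000
    lambda_wt: float = 0.5
    lambda_mut: float = 0.05
    cluster_centers: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CENTERS)
    )
    cluster_sd: float = 400.0
    rain_fraction: float = 0.0
    broken_fraction: float = 0.0
    outlier_fraction: float = 0.0
    degradation_depth: tuple[float, float] = (0.2, 0.9)
    contamination_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_droplets < 1:
            raise ValueError("n_droplets must be >= 1")
        if self.lambda_wt < 0 or self.lambda_mut < 0:
            raise ValueError("lambda values must be >= 0")
        for name in ("rain_fraction", "broken_fraction", "outlier_fraction", "contamination_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.rain_fraction + self.broken_fraction + self.outlier_fraction > 1.0:
            raise ValueError("artifact fractions must sum to <= 1")
        lo, hi = self.degradation_depth
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("degradation_depth must satisfy 0 < lo <= hi <= 1")
        if set(self.cluster_centers) != set(CLASS_LABELS):
            raise ValueError(f"cluster_centers must map exactly {CLASS_LABELS}")
        if self.cluster_sd <= 0:
            raise ValueError("cluster_sd must be > 0")

    @property
    def true_vaf(self) -> float:
        """Ground-truth VAF in percent (undefined -> nan)."""
        total = self.lambda_mut + self.lambda_wt
        if total == 0:
            return float("nan")
        return 100.0 * self.lambda_mut / total


def config_for_vaf(
    vaf_percent: float, *, lambda_wt: float = 0.5, **kwargs: object
) -> SimulationConfig:
    """Build a config whose ground-truth VAF equals ``vaf_percent``.

    Keeps ``lambda_wt`` fixed and solves
    ``lambda_mut = lambda_wt * v / (100 - v)``; ``vaf_percent`` must be
    below 100.
    """
    if not 0.0 <= vaf_percent < 100.0:
        raise ValueError("vaf_percent must lie in [0, 100)")
    lam_mut = lambda_wt * vaf_percent / (100.0 - vaf_percent)
    return SimulationConfig(lambda_wt=lambda_wt, lambda_mut=lam_mut, **kwargs)


def _centers_array(config: SimulationConfig) -> np.ndarray:
    return np.array([config.cluster_centers[lab] for lab in CLASS_LABELS], dtype=float)


def _emit(config: SimulationConfig, codes: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Gaussian amplitudes around each droplet's class center, then artifacts."""
    centers = _centers_array(config)
    n = codes.size
    amps = centers[codes] + rng.normal(0.0, config.cluster_sd, size=(n, 2))

    # One categorical artifact draw per droplet keeps the three artifact
    # fractions mutually exclusive (their sum is capped at 1).
    u = rng.random(n)
    rain = u < config.rain_fraction
    broken = (~rain) & (u < config.rain_fraction + config.broken_fraction)
    outlier = (
        (~rain)
        & (~broken)
        & (u < config.rain_fraction + config.broken_fraction + config.outlier_fraction)
    )

    if np.any(rain):
        idx = np.flatnonzero(rain)
        lo, hi = config.degradation_depth
        depth = rng.uniform(lo, hi, size=idx.size)
        # Positives degrade toward NN; NN droplets rise toward a random
        # positive cluster (NP, PN or PP).
        targets = np.empty((idx.size, 2))
        is_nn = codes[idx] == 0
        targets[~is_nn] = centers[0]
        if np.any(is_nn):
            pos_choice = rng.integers(1, 4, size=int(is_nn.sum()))
            targets[is_nn] = centers[pos_choice]
        amps[idx] += depth[:, None] * (targets - amps[idx])

    if np.any(broken):
        idx = np.flatnonzero(broken)
        amps[idx] = np.abs(rng.normal(0.0, 50.0, size=(idx.size, 2)))

    if np.any(outlier):
        idx = np.flatnonzero(outlier)
        amps[idx] *= rng.uniform(2.5, 4.0, size=(idx.size, 1))

    return amps


def simulate_well(
    config: SimulationConfig,
    *,
    well_id: str = "sim",
    role: str = "sample",
    sample_id: str = "",
    replicate_index: int = 0,
    is_training: bool = False,
) -> tuple[Well, np.ndarray]:
    """Simulate one well; returns ``(well, true_labels)``.

    ``true_labels`` are the pre-artifact class labels fixed by the
    Poisson copy draws: PP if the droplet received both mutant and
    wild-type copies, PN mutant-only, NP wild-type-only, NN empty.
    Identical configs (including seed) give identical output.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_droplets
    mut = rng.poisson(config.lambda_mut, size=n)
    wt = rng.poisson(config.lambda_wt, size=n)
    # Class code: 0=NN, 1=NP (wt only), 2=PN (mut only), 3=PP.
    codes = (wt > 0).astype(np.int64) + 2 * (mut > 0).astype(np.int64)
    amps = _emit(config, codes, rng)
    labels = np.asarray(CLASS_LABELS, dtype="<U4")[codes]
    well = Well(
        well_id=well_id,
        amplitudes=amps,
        role=role,
        sample_id=sample_id,
        replicate_index=replicate_index,
        is_training=is_training,
    )
    return well, labels


def simulate_ntc(config: SimulationConfig, *, well_id: str = "ntc") -> Well:
    """Simulate a no-template control: every droplet from the NN cluster.

    A nonzero ``contamination_rate`` emits that fraction of droplets
    from a random positive cluster, emulating rare template carry-over.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_droplets
    codes = np.zeros(n, dtype=np.int64)
    if config.contamination_rate > 0:
        contaminated = rng.random(n) < config.contamination_rate
        if np.any(contaminated):
            codes[contaminated] = rng.integers(1, 4, size=int(contaminated.sum()))
    amps = _emit(config, codes, rng)
    return Well(well_id=well_id, amplitudes=amps, role="ntc")


@dataclass(frozen=True)
class WellSpec:
    """One well's slot in a simulated plate."""

    config: SimulationConfig
    role: str = "sample"
    sample_id: str = ""
    replicate_index: int = 0
    well_id: str | None = None
    is_training: bool = False


@dataclass(frozen=True)
class SimulatedPlate:
    """A simulated plate with its ground truth.

    ``true_labels`` maps well_id -> pre-artifact labels; ``true_vaf``
    maps each sample well's id to its ground-truth VAF percent.
    """

    plate: Plate
    true_labels: dict[str, np.ndarray]
    true_vaf: dict[str, float]


def simulate_plate(
    specs: Sequence[WellSpec], *, plate_id: str = "simplate", seed: int = 0
) -> SimulatedPlate:
    """Assemble a plate from well specs with per-well derived seeds.

    Each well's stream is seeded ``seed + index``, so wells are
    independent and the whole plate reproducible from one global seed.
    NTC specs (role ``ntc``) go through :func:`simulate_ntc`.
    """
    wells: list[Well] = []
    true_labels: dict[str, np.ndarray] = {}
    true_vaf: dict[str, float] = {}
    for i, spec in enumerate(specs):
        cfg = replace(spec.config, seed=seed + i)
        wid = spec.well_id if spec.well_id is not None else f"W{i + 1:02d}"
        if spec.role == "ntc":
            well = simulate_ntc(cfg, well_id=wid)
            labels = np.full(cfg.n_droplets, "NN", dtype="<U4")
        else:
            well, labels = simulate_well(
                cfg,
                well_id=wid,
                role=spec.role,
                sample_id=spec.sample_id,
                replicate_index=spec.replicate_index,
                is_training=spec.is_training,
            )
        wells.append(well)
        true_labels[wid] = labels
        if spec.role == "sample":
            true_vaf[wid] = cfg.true_vaf
    return SimulatedPlate(
        plate=Plate(plate_id=plate_id, wells=tuple(wells)),
        true_labels=true_labels,
        true_vaf=true_vaf,
    )


def simulate_reference_vaf(
    true_vaf: float, noise_sd: float = 1.32, seed: int | np.random.Generator = 0
) -> float:
    """Emulate a reference-method (pyrosequencing-like) VAF measurement.

    Gaussian scatter of ``noise_sd`` percentage points (default 1.32,
    a realistic replicate SD for pyrosequencing) around the true VAF,
    clamped to [0, 100].
    """
    if not 0.0 <= true_vaf <= 100.0:
        raise ValueError("true_vaf must lie in [0, 100]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return float(np.clip(true_vaf + rng.normal(0.0, noise_sd), 0.0, 100.0))
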