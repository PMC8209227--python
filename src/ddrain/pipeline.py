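"""End-to-end orchestration: simulate/load -> classify -> quantify -> compare.

A run is described by one :class:`RunConfig` (loadable from YAML) and
produces, inside its output directory: the resolved config echo, a
per-droplet labels CSV, per-well class counts before and after rain
exclusion, per-well quantification results, per-sample selected VAFs
with positivity calls, a JSON comparison report and a plain-text log.
Reruns with an identical config are byte-identical.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml

from . import io as dio
from .classify import (
    RainPolicy,
    TrainingSet,
    apply_rain_filter,
    build_training_set,
    fit_ntc_gate,
    knn_classify,
    manual_gate,
)
from .compare import (
    PairedVafs,
    concordance,
    exclude_training,
    repetition_stats,
    spearman_correlation,
)
from .model import LABELS, ClassifiedWell, Plate
from .quantify import (
    ClassCounts,
    NoPassingReplicateError,
    PositivityThreshold,
    call_sample,
    positivity_threshold,
    quantify_well,
    select_replicate,
)
from .simulate import (
    SimulationConfig,
    SimulatedPlate,
    WellSpec,
    config_for_vaf,
    simulate_plate,
    simulate_reference_vaf,
)

__all__ = ["RunConfig", "SimStudyConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass(frozen=True)
class SimStudyConfig:
    """Shape of a simulated study (plates of FFPE-like samples).

    Each plate carries ``samples_per_plate`` distinct samples (times
    ``n_replicates`` replicate wells), one NTC, one positive control
    (high-VAF) and one negative control (VAF 0).  The first
    ``training_wells_per_plate`` samples of each plate are flagged as
    k-NN training candidates.  True sample VAFs are drawn from a
    two-population mixture: with probability ``negative_rate`` a
    near-zero VAF (wild-type sample), otherwise a broad positive
    population — emulating a cohort in which most samples carry the
    mutation at widely varying allele fractions.
    """

    n_plates: int = 2
    samples_per_plate: int = 6
    n_replicates: int = 2
    training_wells_per_plate: int = 3
    n_droplets: int = 15_000
    lambda_wt: float = 0.5
    rain_fraction: float = 0.05
    broken_fraction: float = 0.01
    outlier_fraction: float = 0.005
    negative_rate: float = 0.2
    reference_noise_sd: float = 1.32
    positive_control_vaf: float = 50.0


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a run.

    Either ``manifests`` (plate manifest CSVs, plus optionally
    ``reference_csv`` with columns ``sample_id, vaf``) or ``simulation``
    must be set.  ``threshold_percent=None`` derives the positivity
    threshold from negative-control wells at ``confidence``; the fixed
    default of 9.82% is a documented legacy pyrosequencing-derived
    cut-off.
    """

    output_dir: str
    manifests: tuple[str, ...] = ()
    reference_csv: str | None = None
    simulation: SimStudyConfig | None = None
    stages: tuple[str, ...] = ("classify", "quantify", "compare")
    method: str = "knn"
    k: int = 3
    rain: bool = True
    rain_distance: float | None = None
    low_bound: float = 300.0
    high_bound: float = 12_000.0
    ntc_multiplier: float = 5.0
    training_wells_per_plate: int = 3
    min_droplets: int = 10_000
    threshold_percent: float | None = 9.82
    confidence: float = 0.9998
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        sim = raw.get("simulation")
        if isinstance(sim, dict):
            raw["simulation"] = SimStudyConfig(**sim)
        if "manifests" in raw and raw["manifests"] is not None:
            raw["manifests"] = tuple(raw["manifests"])
        if "stages" in raw and raw["stages"] is not None:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["manifests"] = list(self.manifests)
        d["stages"] = list(self.stages)
        return d


# ---------------------------------------------------------------------------
# simulation of a whole study


def _draw_true_vaf(rng: np.random.Generator, sim: SimStudyConfig) -> float:
    if rng.random() < sim.negative_rate:
        return float(rng.uniform(0.0, 2.0))
    v = rng.normal(30.0, 15.0)
    return float(np.clip(v, 5.0, 70.0))


def _simulate_study(
    config: RunConfig, log: list[str]
) -> tuple[list[SimulatedPlate], dict[str, float], dict[str, float]]:
    """Returns (plates, reference VAF per sample, true VAF per sample)."""
    sim = config.simulation
    assert sim is not None
    rng = np.random.default_rng(config.seed)
    plates: list[SimulatedPlate] = []
    reference: dict[str, float] = {}
    true_vafs: dict[str, float] = {}
    base = SimulationConfig(
        n_droplets=sim.n_droplets,
        lambda_wt=sim.lambda_wt,
        rain_fraction=sim.rain_fraction,
        broken_fraction=sim.broken_fraction,
        outlier_fraction=sim.outlier_fraction,
    )
    for p in range(sim.n_plates):
        specs: list[WellSpec] = []
        w = 0
        for s in range(sim.samples_per_plate):
            sample_id = f"S{p + 1:02d}-{s + 1:02d}"
            vaf = _draw_true_vaf(rng, sim)
            true_vafs[sample_id] = vaf
            reference[sample_id] = simulate_reference_vaf(
                vaf, noise_sd=sim.reference_noise_sd, seed=rng
            )
            cfg = config_for_vaf(
                vaf,
                lambda_wt=base.lambda_wt,
                n_droplets=base.n_droplets,
                rain_fraction=base.rain_fraction,
                broken_fraction=base.broken_fraction,
                outlier_fraction=base.outlier_fraction,
            )
            for r in range(sim.n_replicates):
                w += 1
                specs.append(
                    WellSpec(
                        config=cfg,
                        role="sample",
                        sample_id=sample_id,
                        replicate_index=r,
                        well_id=f"W{w:02d}",
                        is_training=s < sim.training_wells_per_plate and r == 0,
                    )
                )
        w += 1
        specs.append(
            WellSpec(config=base, role="ntc", sample_id="", well_id=f"W{w:02d}")
        )
        w += 1
        specs.append(
            WellSpec(
                config=config_for_vaf(
                    sim.positive_control_vaf,
                    lambda_wt=base.lambda_wt,
                    n_droplets=base.n_droplets,
                    rain_fraction=base.rain_fraction,
                    broken_fraction=base.broken_fraction,
                    outlier_fraction=base.outlier_fraction,
                ),
                role="positive_control",
                sample_id=f"PC{p + 1:02d}",
                well_id=f"W{w:02d}",
            )
        )
        w += 1
        specs.append(
            WellSpec(
                config=config_for_vaf(
                    0.0,
                    lambda_wt=base.lambda_wt,
                    n_droplets=base.n_droplets,
                    rain_fraction=base.rain_fraction,
                    broken_fraction=base.broken_fraction,
                    outlier_fraction=base.outlier_fraction,
                ),
                role="negative_control",
                sample_id=f"NC{p + 1:02d}",
                well_id=f"W{w:02d}",
            )
        )
        plate = simulate_plate(
            specs, plate_id=f"P{p + 1:02d}", seed=config.seed + 1000 * (p + 1)
        )
        plates.append(plate)
        log.append(f"simulate: plate {plate.plate.plate_id} with {len(specs)} wells")
    return plates, reference, true_vafs


def _load_reference(path: str) -> dict[str, float]:
    out: dict[str, float] = {}
    with open(path) as fh:
        for row in csv.DictReader(fh):
            out[row["sample_id"]] = float(row["vaf"])
    return out


# ---------------------------------------------------------------------------
# classification stage


def _classify_plate(
    plate: Plate, config: RunConfig, log: list[str]
) -> tuple[dict[str, ClassifiedWell], TrainingSet]:
    """Manual-gate everything; optionally re-label by k-NN; rain-filter."""
    ntcs = plate.wells_with_role("ntc")
    if not ntcs:
        raise PipelineError("classify", f"plate {plate.plate_id!r} has no NTC well")
    gate = fit_ntc_gate(ntcs[0], multiplier=config.ntc_multiplier)
    log.append(
        f"classify: plate {plate.plate_id} NTC gate "
        f"ch1={gate.ch1_cut:.1f} ch2={gate.ch2_cut:.1f}"
    )
    manual = {w.well_id: manual_gate(w, gate) for w in plate.wells}

    eligible = [manual[w.well_id] for w in plate.wells if w.is_training]
    if len(eligible) < config.training_wells_per_plate:
        raise PipelineError(
            "classify",
            f"plate {plate.plate_id!r} has {len(eligible)} training-flagged "
            f"wells; need >= {config.training_wells_per_plate}",
        )
    training = build_training_set(
        [eligible],
        wells_per_plate=config.training_wells_per_plate,
        seed=config.seed + 17,
    )

    if config.method == "knn":
        classified = {
            w.well_id: knn_classify(w, training, k=config.k) for w in plate.wells
        }
    elif config.method == "manual":
        classified = manual
    else:
        raise PipelineError("classify", f"unknown method {config.method!r}")

    if config.rain:
        policy = RainPolicy(
            rain_distance=config.rain_distance,
            low_bound=config.low_bound,
            high_bound=config.high_bound,
        )
        filtered: dict[str, ClassifiedWell] = {}
        for wid, cw in classified.items():
            fcw = apply_rain_filter(cw, training, policy)
            log.append(
                f"classify: {plate.plate_id}/{wid} droplets={cw.well.n_droplets} "
                f"accepted_before_rain={cw.n_accepted} "
                f"accepted_after_rain={fcw.n_accepted} rain={fcw.n_rain}"
            )
            filtered[wid] = fcw
        classified = filtered
    else:
        for wid, cw in classified.items():
            log.append(
                f"classify: {plate.plate_id}/{wid} droplets={cw.well.n_droplets} "
                f"accepted={cw.n_accepted} rain={cw.n_rain}"
            )
    return classified, training


# ---------------------------------------------------------------------------
# output writers (deterministic: fixed ordering and float formats)


def _fmt(x: float | None) -> str:
    return "" if x is None else format(x, ".6f")


def _write_labels(path: str, plates: Sequence[Plate], classified: dict) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["plate_id", "well_id", "droplet_index", "label"])
        for plate in plates:
            for well in plate.wells:
                cw = classified[plate.plate_id][well.well_id]
                for i, lab in enumerate(cw.labels):
                    w.writerow([plate.plate_id, well.well_id, i, lab])


def _write_counts(path: str, plates: Sequence[Plate], classified: dict) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["plate_id", "well_id", "role", "sample_id"] + list(LABELS) + ["accepted"])
        for plate in plates:
            for well in plate.wells:
                cw = classified[plate.plate_id][well.well_id]
                w.writerow(
                    [plate.plate_id, well.well_id, well.role, well.sample_id]
                    + [cw.counts[lab] for lab in LABELS]
                    + [cw.n_accepted]
                )


def _write_quant(path: str, results: Sequence) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["plate_id", "well_id", "sample_id", "replicate_index", "lambda_mut",
             "lambda_wt", "vaf_percent", "accepted", "qc_pass", "qc_reasons"]
        )
        for plate_id, r in results:
            w.writerow(
                [plate_id, r.well_id, r.sample_id, r.replicate_index,
                 _fmt(r.lambda_mut), _fmt(r.lambda_wt), _fmt(r.vaf_percent),
                 r.accepted_droplets, int(r.qc_pass), "; ".join(r.qc_reasons)]
            )


# ---------------------------------------------------------------------------


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the JSON-ready run report.

    Stage order is fixed (simulate/load, classify, quantify, compare);
    later stages are skipped when absent from ``config.stages``.  Every
    intermediate table is written to ``config.output_dir`` together
    with the resolved config and a log; failures raise
    :class:`PipelineError` naming the stage, keeping earlier outputs on
    disk.
    """
    os.makedirs(config.output_dir, exist_ok=True)
    log: list[str] = [f"seed={config.seed}", f"stages={','.join(config.stages)}"]
    report: dict = {"seed": config.seed, "method": config.method}

    with open(os.path.join(config.output_dir, "config.yaml"), "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)

    # --- obtain plates -----------------------------------------------------
    reference: dict[str, float] = {}
    true_vafs: dict[str, float] = {}
    if config.simulation is not None:
        simulated, reference, true_vafs = _simulate_study(config, log)
        plates = [sp.plate for sp in simulated]
    elif config.manifests:
        try:
            plates = [dio.read_plate_manifest(m) for m in config.manifests]
        except Exception as exc:
            raise PipelineError("load", str(exc)) from exc
        log.extend(f"load: plate {p.plate_id} with {len(p)} wells" for p in plates)
        if config.reference_csv is not None:
            if not os.path.exists(config.reference_csv):
                raise PipelineError(
                    "load", f"reference file {config.reference_csv!r} not found"
                )
            reference = _load_reference(config.reference_csv)
    else:
        raise PipelineError("load", "config needs either simulation or manifests")
    if "compare" in config.stages and not reference:
        raise PipelineError(
            "compare", "comparison requested but no reference VAFs available"
        )

    # --- classify ----------------------------------------------------------
    classified: dict[str, dict[str, ClassifiedWell]] = {}
    trainings: dict[str, TrainingSet] = {}
    if "classify" in config.stages:
        for plate in plates:
            cls, training = _classify_plate(plate, config, log)
            classified[plate.plate_id] = cls
            trainings[plate.plate_id] = training
        _write_labels(os.path.join(config.output_dir, "labels.csv"), plates, classified)
        _write_counts(os.path.join(config.output_dir, "counts.csv"), plates, classified)
        report["n_plates"] = len(plates)
        report["n_wells"] = sum(len(p) for p in plates)

    # --- quantify ----------------------------------------------------------
    sample_vafs: dict[str, float] = {}
    calls: dict[str, str] = {}
    threshold: PositivityThreshold | None = None
    if "quantify" in config.stages:
        if not classified:
            raise PipelineError("quantify", "no classified wells (classify stage missing)")
        results = []
        by_sample: dict[str, list] = {}
        control_vafs: list[float] = []
        for plate in plates:
            ntc_counts = [
                ClassCounts.from_classified(classified[plate.plate_id][w.well_id])
                for w in plate.wells_with_role("ntc")
            ]
            for well in plate.wells:
                cw = classified[plate.plate_id][well.well_id]
                r = quantify_well(
                    cw,
                    ntc_counts if well.role != "ntc" else None,
                    min_droplets=config.min_droplets,
                )
                results.append((plate.plate_id, r))
                if well.role == "sample":
                    by_sample.setdefault(well.sample_id, []).append(r)
                elif well.role == "negative_control" and r.vaf_percent is not None:
                    control_vafs.append(r.vaf_percent)
        _write_quant(os.path.join(config.output_dir, "quant.csv"), results)

        if config.threshold_percent is not None:
            threshold = PositivityThreshold(
                threshold_percent=config.threshold_percent,
                confidence=config.confidence,
                n_controls=0,
            )
        else:
            if len(control_vafs) < 2:
                raise PipelineError(
                    "quantify",
                    "threshold derivation needs >= 2 negative-control wells",
                )
            threshold = positivity_threshold(control_vafs, confidence=config.confidence)
        log.append(f"quantify: positivity threshold {threshold.threshold_percent:.4f}%")

        excluded_samples: list[str] = []
        for sample_id in sorted(by_sample):
            reps = by_sample[sample_id]
            try:
                if sample_id in reference:
                    best = select_replicate(reps, reference[sample_id])
                else:
                    best = _select_first(reps)
            except NoPassingReplicateError:
                excluded_samples.append(sample_id)
                log.append(f"quantify: sample {sample_id} excluded (no passing replicate)")
                continue
            sample_vafs[sample_id] = best.vaf_percent
            calls[sample_id] = call_sample(best.vaf_percent, threshold)
        _write_samples(
            os.path.join(config.output_dir, "samples.csv"),
            sample_vafs,
            calls,
            reference,
            true_vafs,
        )
        report["threshold_percent"] = round(threshold.threshold_percent, 6)
        report["n_samples_quantified"] = len(sample_vafs)
        report["n_samples_excluded"] = len(excluded_samples)
        report["n_positive_calls"] = sum(1 for c in calls.values() if c == "positive")

    # --- compare -----------------------------------------------------------
    if "compare" in config.stages:
        if not sample_vafs:
            raise PipelineError("compare", "no quantified samples to compare")
        pairs = PairedVafs.from_dicts(sample_vafs, reference)
        pooled_training = trainings[plates[0].plate_id]
        for plate in plates[1:]:
            t = trainings[plate.plate_id]
            pooled_training = TrainingSet(
                amplitudes=np.concatenate([pooled_training.amplitudes, t.amplitudes]),
                labels=np.concatenate([pooled_training.labels, t.labels]),
                source_wells=pooled_training.source_wells + t.source_wells,
                source_samples=pooled_training.source_samples + t.source_samples,
            )
        pairs = exclude_training(pairs, pooled_training)
        if len(pairs) < 3:
            raise PipelineError(
                "compare", f"only {len(pairs)} comparable samples after exclusions"
            )
        r, p = spearman_correlation(pairs)
        ref_calls = [
            call_sample(v, threshold) for v in pairs.vaf_b
        ]
        dd_calls = [call_sample(v, threshold) for v in pairs.vaf_a]
        table = concordance(dd_calls, ref_calls)
        rep_map: dict[str, list[float]] = {}
        for plate_id, res in _iter_sample_results(plates, classified, config):
            if res.vaf_percent is not None and res.qc_pass:
                rep_map.setdefault(res.sample_id, []).append(res.vaf_percent)
        reps = repetition_stats(rep_map)
        report["comparison"] = {
            "n_pairs": len(pairs),
            "n_excluded_training": len(pairs.excluded),
            "spearman_r": round(r, 6),
            "spearman_p": float(p),
            "concordance": {
                "pos_pos": table.pos_pos,
                "pos_neg": table.pos_neg,
                "neg_pos": table.neg_pos,
                "neg_neg": table.neg_neg,
                "discordant_total": table.discordant_total,
            },
            "repetition": {
                "max_difference": reps.max_difference,
                "mean_difference": reps.mean_difference,
                "mean_sd": reps.mean_sd,
                "n_samples": reps.n_samples,
            },
        }
        log.append(
            f"compare: n={len(pairs)} spearman_r={r:.4f} "
            f"discordant={table.discordant_total}"
        )

    with open(os.path.join(config.output_dir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(os.path.join(config.output_dir, "run.log"), "w") as fh:
        fh.write("\n".join(log) + "\n")
    return report


def _select_first(reps):
    eligible = [r for r in reps if r.qc_pass and r.vaf_percent is not None]
    if not eligible:
        raise NoPassingReplicateError("no QC-passing replicate with a defined VAF")
    return min(eligible, key=lambda r: r.replicate_index)


def _iter_sample_results(plates, classified, config):
    for plate in plates:
        ntc_counts = [
            ClassCounts.from_classified(classified[plate.plate_id][w.well_id])
            for w in plate.wells_with_role("ntc")
        ]
        for well in plate.wells:
            if well.role != "sample":
                continue
            cw = classified[plate.plate_id][well.well_id]
            yield plate.plate_id, quantify_well(
                cw, ntc_counts, min_droplets=config.min_droplets
            )


def _write_samples(path, sample_vafs, calls, reference, true_vafs):
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["sample_id", "vaf_percent", "call", "reference_vaf", "true_vaf"])
        for sid in sorted(sample_vafs):
            w.writerow(
                [
                    sid,
                    _fmt(sample_vafs[sid]),
                    calls[sid],
                    _fmt(reference.get(sid)),
                    _fmt(true_vafs.get(sid)),
                ]
            )
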