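"""Poisson absolute quantification, reaction QC and positivity calling.

With templates distributed over droplets at random, the number of
copies in a droplet is Poisson with mean lambda, so the fraction of
droplets *negative* in a channel estimates ``exp(-lambda)`` and

    lambda = -ln(n_negative / n_accepted)

recovers the mean copies per droplet for that channel.  RAIN droplets
are excluded from both numerator and denominator.  The variant allele
frequency is the rate ratio

    VAF% = 100 * lambda_mut / (lambda_mut + lambda_wt).

A reaction is trusted only if it passes QC (enough accepted droplets;
more positive signal than the no-template control), and a sample is
called mutation-positive when its VAF exceeds a threshold derived from
negative controls via a t-distribution confidence interval on their
mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from scipy import stats

from .model import ClassifiedWell

__all__ = [
    "ClassCounts",
    "QuantResult",
    "PositivityThreshold",
    "SaturationError",
    "NoPassingReplicateError",
    "lambda_from_counts",
    "vaf_from_counts",
    "qc_reaction",
    "select_replicate",
    "positivity_threshold",
    "call_sample",
    "quantify_well",
]


class SaturationError(ValueError):
    """A channel has zero negative droplets; lambda is unbounded."""


class NoPassingReplicateError(ValueError):
    """No QC-passing replicate is available for a sample."""


@dataclass(frozen=True)
class ClassCounts:
    """Droplet tallies per class for one reaction (RAIN kept separate)."""

    nn: int
    np: int
    pn: int
    pp: int
    rain: int = 0

    def __post_init__(self) -> None:
        for name in ("nn", "np", "pn", "pp", "rain"):
            if getattr(self, name) < 0:
                raise ValueError(f"count {name} must be non-negative")

    @classmethod
    def from_classified(cls, classified: ClassifiedWell) -> "ClassCounts":
        c = classified.counts
        return cls(nn=c["NN"], np=c["NP"], pn=c["PN"], pp=c["PP"], rain=c["RAIN"])

    @property
    def accepted(self) -> int:
        """Droplets entering quantification: NN + NP + PN + PP."""
        return self.nn + self.np + self.pn + self.pp

    @property
    def mutant_negative(self) -> int:
        """Droplets negative in the mutant channel (NN + NP)."""
        return self.nn + self.np

    @property
    def wildtype_negative(self) -> int:
        """Droplets negative in the wild-type channel (NN + PN)."""
        return self.nn + self.pn

    @property
    def positive_mean(self) -> float:
        """Mean of the three positive-class counts (PP, PN, NP)."""
        return (self.pp + self.pn + self.np) / 3.0


@dataclass(frozen=True)
class QuantResult:
    """Per-reaction quantification outcome.

    ``vaf_percent`` is ``None`` when undefined (no template in either
    channel, or a saturated channel); every such case carries an
    explanatory entry in ``qc_reasons`` and ``qc_pass=False``.
    """

    lambda_mut: float | None
    lambda_wt: float | None
    vaf_percent: float | None
    accepted_droplets: int
    qc_pass: bool = True
    qc_reasons: tuple[str, ...] = ()
    well_id: str = ""
    sample_id: str = ""
    replicate_index: int = 0

    def with_qc(self, qc_pass: bool, qc_reasons: Sequence[str]) -> "QuantResult":
        merged = tuple(self.qc_reasons) + tuple(qc_reasons)
        return QuantResult(
            lambda_mut=self.lambda_mut,
            lambda_wt=self.lambda_wt,
            vaf_percent=self.vaf_percent,
            accepted_droplets=self.accepted_droplets,
            qc_pass=self.qc_pass and qc_pass,
            qc_reasons=merged,
            well_id=self.well_id,
            sample_id=self.sample_id,
            replicate_index=self.replicate_index,
        )


@dataclass(frozen=True)
class PositivityThreshold:
    """VAF cut-off above which a sample is called mutation-positive."""

    threshold_percent: float
    confidence: float
    n_controls: int


def lambda_from_counts(n_channel_negative: int, n_accepted: int) -> float:
    """Poisson zero-class estimator: ``-ln(n_negative / n_accepted)``.

    For the mutant channel pass ``nn + np`` negatives, for the
    wild-type channel ``nn + pn``; ``n_accepted`` excludes RAIN.

    Raises
    ------
    SaturationError
        If no droplet is negative (every partition occupied; the
        estimator diverges).
    ValueError
        If ``n_accepted`` is zero or negatives exceed accepted.
    """
    if n_accepted <= 0:
        raise ValueError("n_accepted must be positive")
    if n_channel_negative < 0 or n_channel_negative > n_accepted:
        raise ValueError("need 0 <= n_channel_negative <= n_accepted")
    if n_channel_negative == 0:
        raise SaturationError(
            "channel saturated: zero negative droplets, lambda is unbounded"
        )
    return -math.log(n_channel_negative / n_accepted)


def vaf_from_counts(counts: ClassCounts) -> QuantResult:
    """Estimate both channel rates and the VAF from class counts.

    Saturated channels and the no-template case (both rates zero) yield
    a flagged result (``vaf_percent=None``, ``qc_pass=False``) rather
    than a number or an exception.
    """
    if counts.accepted < 1:
        raise ValueError("no accepted droplets; cannot quantify")
    reasons: list[str] = []
    lam_mut: float | None = None
    lam_wt: float | None = None
    try:
        lam_mut = lambda_from_counts(counts.mutant_negative, counts.accepted)
    except SaturationError:
        reasons.append("mutant channel saturated (no negative droplets)")
    try:
        lam_wt = lambda_from_counts(counts.wildtype_negative, counts.accepted)
    except SaturationError:
        reasons.append("wild-type channel saturated (no negative droplets)")

    vaf: float | None = None
    if lam_mut is not None and lam_wt is not None:
        total = lam_mut + lam_wt
        if total == 0.0:
            reasons.append("no template detected in either channel; VAF undefined")
        else:
            vaf = 100.0 * lam_mut / total
    return QuantResult(
        lambda_mut=lam_mut,
        lambda_wt=lam_wt,
        vaf_percent=vaf,
        accepted_droplets=counts.accepted,
        qc_pass=not reasons,
        qc_reasons=tuple(reasons),
    )


def qc_reaction(
    counts: ClassCounts,
    ntc_counts: ClassCounts | Sequence[ClassCounts],
    min_droplets: int = 10_000,
) -> tuple[bool, list[str]]:
    """Reaction-level QC against droplet yield and the NTC signal.

    Fails when (1) fewer than ``min_droplets`` accepted droplets remain
    after rain exclusion, or (2) the mean of the three positive-class
    counts (PP, PN, NP) is below the same mean in the no-template
    control.  With several NTC wells the per-well positive means are
    averaged.  Returns ``(qc_pass, reasons)`` with one reason per
    failed rule.
    """
    if isinstance(ntc_counts, ClassCounts):
        ntc_list = [ntc_counts]
    else:
        ntc_list = list(ntc_counts)
        if not ntc_list:
            raise ValueError("at least one NTC count set is required")
    reasons: list[str] = []
    if counts.accepted < min_droplets:
        reasons.append(
            f"only {counts.accepted} accepted droplets (< {min_droplets})"
        )
    ntc_mean = sum(c.positive_mean for c in ntc_list) / len(ntc_list)
    if counts.positive_mean < ntc_mean:
        reasons.append(
            f"mean positive droplets {counts.positive_mean:.2f} below "
            f"NTC mean {ntc_mean:.2f}"
        )
    return (not reasons, reasons)


def select_replicate(
    replicates: Sequence[QuantResult], reference_vaf: float
) -> QuantResult:
    """Pick the QC-passing replicate closest to the reference VAF.

    Ties in |VAF - reference| go to the lowest replicate index.

    Raises
    ------
    NoPassingReplicateError
        If no replicate passes QC with a defined VAF (the sample is
        excluded from analysis).
    """
    eligible = [r for r in replicates if r.qc_pass and r.vaf_percent is not None]
    if not eligible:
        raise NoPassingReplicateError(
            "no QC-passing replicate with a defined VAF; sample excluded"
        )
    return min(
        eligible,
        key=lambda r: (abs(r.vaf_percent - reference_vaf), r.replicate_index),
    )


def positivity_threshold(
    control_vafs: Sequence[float], confidence: float = 0.9998
) -> PositivityThreshold:
    """Upper CI bound of the negative-control mean VAF.

    ``mean + t_{1-(1-confidence)/2, n-1} * s / sqrt(n)`` with ``s`` the
    sample SD — the upper limit of the two-sided ``confidence`` interval
    for the mean under the t distribution.  The default 99.98% interval
    gives a deliberately strict limit of detection.
    """
    vals = [float(v) for v in control_vafs]
    n = len(vals)
    if n < 2:
        raise ValueError("need >= 2 negative-control values")
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must lie in (0, 1)")
    mean = sum(vals) / n
    s = math.sqrt(sum((v - mean) ** 2 for v in vals) / (n - 1))
    t = float(stats.t.ppf(1.0 - (1.0 - confidence) / 2.0, df=n - 1))
    return PositivityThreshold(
        threshold_percent=mean + t * s / math.sqrt(n),
        confidence=confidence,
        n_controls=n,
    )


def call_sample(vaf: float | None, threshold: PositivityThreshold) -> str:
    """Call a sample ``positive``/``negative`` against the threshold.

    Strictly above the threshold is positive; an undefined VAF yields
    ``no-call`` (distinct from negative).
    """
    if vaf is None:
        return "no-call"
    return "positive" if vaf > threshold.threshold_percent else "negative"


def quantify_well(
    classified: ClassifiedWell,
    ntc_counts: ClassCounts | Sequence[ClassCounts] | None = None,
    min_droplets: int = 10_000,
) -> QuantResult:
    """Convenience: counts -> VAF -> QC for one classified well."""
    counts = ClassCounts.from_classified(classified)
    result = vaf_from_counts(counts)
    w = classified.well
    result = QuantResult(
        lambda_mut=result.lambda_mut,
        lambda_wt=result.lambda_wt,
        vaf_percent=result.vaf_percent,
        accepted_droplets=result.accepted_droplets,
        qc_pass=result.qc_pass,
        qc_reasons=result.qc_reasons,
        well_id=w.well_id,
        sample_id=w.sample_id,
        replicate_index=w.replicate_index,
    )
    if ntc_counts is not None:
        ok, reasons = qc_reaction(counts, ntc_counts, min_droplets=min_droplets)
        result = result.with_qc(ok, reasons)
    return result
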