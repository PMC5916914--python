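"""Sample- and probe-level quality filtering of beta matrices.

Standard array-QC rules for Infinium methylation data:

* samples are dropped when too many probes fail detection (detection
  p-value >= 0.05 at more than 4500 CpGs, ~1% of the array);
* probes are dropped when they fail detection in at least one retained
  sample, have beadcount < 3 in >= 5% of retained samples, or carry an
  annotation flag (sex chromosome, SNP probe, SNP at the CpG site,
  cross-reactive).

Sample filtering runs first; probe fractions are then computed over the
retained samples only.  Each exclusion carries exactly one primary reason
code with precedence detection > beadcount > flags > unannotated.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import pandas as pd

from .core import (BetaMatrix, ConfigurationError, ProbeAnnotation,
                   QCMetrics, PROBE_FLAGS)

log = logging.getLogger("methvar")

#: tie-break order when a probe carries several exclusion flags
FLAG_PRECEDENCE = ("sex_chromosome", "snp_probe", "snp_at_cpg", "cross_reactive")


@dataclass
class QCReport:
    """Exclusions with reason codes plus the thresholds that produced them."""

    excluded_samples: list[tuple[str, str]] = field(default_factory=list)
    excluded_probes: list[tuple[str, str]] = field(default_factory=list)
    n_samples_in: int = 0
    n_samples_retained: int = 0
    n_probes_in: int = 0
    n_probes_retained: int = 0
    thresholds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert self.n_samples_in == self.n_samples_retained + len(self.excluded_samples)
        assert self.n_probes_in == self.n_probes_retained + len(self.excluded_probes)

    def reason_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for _, reason in [*self.excluded_samples, *self.excluded_probes]:
            counts[reason] = counts.get(reason, 0) + 1
        return counts

    def to_dict(self) -> dict:
        return {
            "excluded_samples": [list(t) for t in self.excluded_samples],
            "excluded_probes": [list(t) for t in self.excluded_probes],
            "n_samples_in": self.n_samples_in,
            "n_samples_retained": self.n_samples_retained,
            "n_probes_in": self.n_probes_in,
            "n_probes_retained": self.n_probes_retained,
            "reason_counts": self.reason_counts(),
            "thresholds": self.thresholds,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def filter_samples(betas: BetaMatrix, qc: QCMetrics,
                   max_failed_cpgs: int = 4500,
                   p_thresh: float = 0.05) -> tuple[BetaMatrix, QCReport]:
    """Drop samples with more than ``max_failed_cpgs`` failing probes.

    A probe fails in a sample when detection_p >= ``p_thresh`` (inclusive);
    a sample is excluded when its failure count is strictly greater than
    ``max_failed_cpgs``.  Missing detection p-values count as passing.
    """
    if qc.detection_p is None:
        raise ConfigurationError("sample filtering requires detection p-values")
    detp = qc.aligned_to(betas).detection_p
    fail_counts = (detp >= p_thresh).sum(axis=0)
    dropped = fail_counts.index[fail_counts > max_failed_cpgs].tolist()
    kept = [s for s in betas.sample_ids if s not in set(dropped)]
    report = QCReport(
        excluded_samples=[(s, "detection") for s in dropped],
        n_samples_in=len(betas.sample_ids), n_samples_retained=len(kept),
        n_probes_in=len(betas.probe_ids), n_probes_retained=len(betas.probe_ids),
        thresholds={"max_failed_cpgs": max_failed_cpgs, "p_thresh": p_thresh},
    )
    if dropped:
        log.info("filter_samples: excluded %d sample(s): %s", len(dropped), dropped)
    return betas.subset(samples=kept), report


def filter_probes(betas: BetaMatrix, qc: QCMetrics, ann: ProbeAnnotation,
                  p_thresh: float = 0.05, beadcount_min: int = 3,
                  beadcount_frac: float = 0.05) -> tuple[BetaMatrix, QCReport]:
    """Drop probes failing any exclusion rule.

    Rules, in reason-precedence order:

    1. ``detection``: detection_p >= ``p_thresh`` in at least one sample;
    2. ``beadcount``: beadcount < ``beadcount_min`` in >= ``beadcount_frac``
       of samples (exact rational comparison, no floating-point boundary);
    3. annotation flags (one primary reason per FLAG_PRECEDENCE);
    4. ``unannotated``: probe absent from the annotation.

    Detection/beadcount rules are applied only when the corresponding QC
    matrix is provided; fractions are computed over the samples present in
    ``betas`` (i.e. after any sample-level filtering).
    """
    qc = qc.aligned_to(betas)
    n_samples = len(betas.sample_ids)
    reason: dict[str, str] = {}

    if qc.detection_p is not None:
        failing = (qc.detection_p >= p_thresh).any(axis=1)
        for probe in failing.index[failing]:
            reason.setdefault(probe, "detection")

    if qc.beadcount is not None:
        frac = Fraction(str(beadcount_frac))
        low = (qc.beadcount < beadcount_min).sum(axis=1)
        # count/n >= frac  <=>  count * den >= num * n
        bad = low * frac.denominator >= frac.numerator * n_samples
        for probe in bad.index[bad]:
            reason.setdefault(probe, "beadcount")

    annotated = set(ann.data.index)
    for probe in betas.probe_ids:
        if probe in reason:
            continue
        if probe not in annotated:
            reason[probe] = "unannotated"
            continue
        flags = ann.flags_for(probe)
        for flag in FLAG_PRECEDENCE:
            if flag in flags:
                reason[probe] = flag
                break

    kept = [p for p in betas.probe_ids if p not in reason]
    report = QCReport(
        excluded_probes=[(p, reason[p]) for p in betas.probe_ids if p in reason],
        n_samples_in=n_samples, n_samples_retained=n_samples,
        n_probes_in=len(betas.probe_ids), n_probes_retained=len(kept),
        thresholds={"p_thresh": p_thresh, "beadcount_min": beadcount_min,
                    "beadcount_frac": beadcount_frac},
    )
    log.info("filter_probes: retained %d/%d probes", len(kept), len(betas.probe_ids))
    return betas.subset(probes=kept), report


def genotype_concordance_check(betas: BetaMatrix, *args, **kwargs) -> None:
    """Placeholder hook for raw-array identity checks (gender and genotype
    concordance), which need array internals this pipeline does not consume.
    Always a no-op."""
    return None
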