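"""End-to-end run orchestration: QC -> VMP detection -> epimutation scan.

Every stage persists its result table under the output directory and
contributes counts to a JSON run report.  Outputs are a pure function of
(inputs, config, seed); the report records the package version, the
resolved configuration and a hash of it, so identical runs are
byte-identical apart from the timestamp field.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .core import (BetaMatrix, ConfigurationError, MethvarError, QCMetrics,
                   SampleSheet, read_beta_matrix, read_probe_annotation,
                   read_qc_matrix, read_sample_sheet)
from .datasets import load_epimutation_panel
from . import epimutation as epi
from . import qc as qcmod
from . import vmp as vmpmod

log = logging.getLogger("methvar")


class StageError(MethvarError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """All inputs, thresholds and switches of a pipeline run."""

    betas: str | None = None          # combined matrix (M0 + MF samples)
    sheet: str | None = None
    annotation: str | None = None
    detection_p: str | None = None
    beadcount: str | None = None
    out_dir: str = "methvar_run"
    # thresholds
    vmp_threshold: float = vmpmod.DEFAULT_THRESHOLD
    vmp_mode: str = "abs_of_median"
    alpha: float = epi.DEFAULT_ALPHA
    dev_threshold: float = epi.DEFAULT_DEV_THRESHOLD
    list_mode: str = "between-group"
    qc_p_thresh: float = 0.05
    qc_max_failed_cpgs: int = 4500
    qc_beadcount_min: int = 3
    qc_beadcount_frac: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("vmp_threshold", "alpha", "dev_threshold", "qc_p_thresh",
                     "qc_beadcount_frac"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigurationError(f"{name} must be in (0, 1), got {v}")
        if self.vmp_mode not in vmpmod.MODES:
            raise ConfigurationError(f"unknown vmp_mode {self.vmp_mode!r}")
        if self.list_mode not in epi.LIST_MODES:
            raise ConfigurationError(f"unknown list_mode {self.list_mode!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def validate_paths(self) -> None:
        for name in ("betas", "sheet", "annotation", "detection_p", "beadcount"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ConfigurationError(f"{name} file not found: {p}")


def _config_hash(config: RunConfig) -> str:
    return hashlib.sha256(
        json.dumps(asdict(config), sort_keys=True).encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute QC, VMP detection and the epimutation scan on real inputs."""
    if config.betas is None or config.sheet is None:
        raise ConfigurationError("run_pipeline requires betas and sheet paths")
    config.validate_paths()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "config": asdict(config),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stages": {},
    }

    stage = "load"
    try:
        betas = read_beta_matrix(config.betas)
        sheet = read_sample_sheet(config.sheet)
        qc = QCMetrics(
            detection_p=read_qc_matrix(config.detection_p) if config.detection_p else None,
            beadcount=read_qc_matrix(config.beadcount) if config.beadcount else None,
        )
        ann = read_probe_annotation(config.annotation) if config.annotation else None
        report["stages"]["load"] = {"n_probes": len(betas.probe_ids),
                                    "n_samples": len(betas.sample_ids)}

        stage = "qc"
        if qc.detection_p is not None:
            betas, sample_report = qcmod.filter_samples(
                betas, qc, config.qc_max_failed_cpgs, config.qc_p_thresh)
            sample_report.to_json(out_dir / "qc_samples.json")
        else:
            sample_report = None
        if ann is not None:
            betas, probe_report = qcmod.filter_probes(
                betas, qc, ann, config.qc_p_thresh, config.qc_beadcount_min,
                config.qc_beadcount_frac)
            probe_report.to_json(out_dir / "qc_probes.json")
            betas.to_file(out_dir / "betas_filtered.tsv")
        else:
            probe_report = None
        report["stages"]["qc"] = {
            "samples_excluded": len(sample_report.excluded_samples) if sample_report else 0,
            "probes_excluded": len(probe_report.excluded_probes) if probe_report else 0,
            "n_probes_retained": len(betas.probe_ids),
            "n_samples_retained": len(betas.sample_ids),
        }

        stage = "vmp"
        delta = vmpmod.compute_delta(betas, sheet)
        vmp_counts = {}
        stats_by_group = {}
        for group in ("converter", "nonconverter"):
            stats = vmpmod.group_median_statistic(delta, group, config.vmp_mode)
            stats_by_group[group] = stats
            result = vmpmod.detect_vmps(stats, group, config.vmp_threshold,
                                        config.vmp_mode)
            result.to_csv(out_dir / f"vmp_{group}.tsv", sep="\t", index=False)
            vmp_counts[group] = int(result["is_vmp"].sum())
        vmpmod.violin_summary(stats_by_group, config.vmp_threshold).to_csv(
            out_dir / "vmp_violin_summary.tsv", sep="\t", index=False)
        report["stages"]["vmp"] = {"vmp_count": vmp_counts,
                                   "mode": config.vmp_mode,
                                   "threshold": config.vmp_threshold}

        stage = "epimutation"
        scan_m0 = epi.scan_variances(betas, sheet, "M0")
        scan_mf = epi.scan_variances(betas, sheet, "MF")
        scan_m0.to_csv(out_dir / "scan_M0.tsv", sep="\t")
        scan_mf.to_csv(out_dir / "scan_MF.tsv", sep="\t")
        exclude = None
        if config.list_mode == "longitudinal":
            exclude = epi.longitudinal_significant_set(
                betas, sheet, "nonconverter", config.alpha)
        candidates = epi.select_candidates(scan_m0, scan_mf, config.alpha,
                                           nonconverter_significant=exclude)
        candidates.to_csv(out_dir / "candidates.tsv", sep="\t")
        cand_probes = list(candidates.index[candidates["is_candidate"]])

        n_calls = 0
        histogram: dict[str, int] = {}
        if cand_probes:
            dev_mf = epi.compute_deviations(betas, sheet, "converter", "MF",
                                            cand_probes)
            dev_m0 = epi.compute_deviations(betas, sheet, "converter", "M0",
                                            cand_probes)
            dev_mf.to_file(out_dir / "deviations_MF.tsv")
            dev_m0.to_file(out_dir / "deviations_M0.tsv")
            calls = epi.call_epimutations(dev_mf, config.dev_threshold)
            calls.to_csv(out_dir / "calls.tsv", sep="\t", index=False)
            summary = epi.summarize_calls(calls, sheet.subjects("converter"))
            n_calls = summary.n_calls
            histogram = {str(k): v for k, v in summary.histogram.items()}
            (out_dir / "summary.json").write_text(
                json.dumps(summary.to_dict(), indent=2) + "\n")
        report["stages"]["epimutation"] = {
            "candidate_count": len(cand_probes),
            "call_count": n_calls,
            "per_subject_histogram": histogram,
            "list_mode": config.list_mode,
        }
    except MethvarError as err:
        if isinstance(err, StageError):
            raise
        raise StageError(stage, str(err)) from err

    report["timestamp"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    _write_report(report, out_dir)
    return report


def run_reference_panel(out_dir: str | Path,
                        dev_threshold: float = epi.DEFAULT_DEV_THRESHOLD) -> dict:
    """Run the epimutation caller on the packaged deviation panel.

    The panel's after-transition block is the worked example: 12 candidate
    CpGs carry calls, 16 calls in total, with the strict >0.10 rule.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    before, after, candidates = load_epimutation_panel()
    calls = epi.call_epimutations(after, dev_threshold)
    calls = calls.merge(candidates["gene"], left_on="probe_id",
                        right_index=True, how="left")
    summary = epi.summarize_calls(calls, after.subject_ids)
    calls.to_csv(out_dir / "panel_calls.tsv", sep="\t", index=False)
    report = {
        "version": __version__,
        "fixture": "epimutation_panel",
        "dev_threshold": dev_threshold,
        "n_panel_probes": len(after.probe_ids),
        "n_subjects": len(after.subject_ids),
        "candidate_loci_with_calls": summary.n_probes_called,
        "call_count": summary.n_calls,
        "per_subject_histogram": {str(k): v for k, v in summary.histogram.items()},
        "multi_carrier": summary.multi_carrier.to_dict(orient="records"),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    _write_report(report, out_dir)
    return report


def _write_report(report: dict, out_dir: Path) -> None:
    (out_dir / "report.json").write_text(json.dumps(report, indent=2) + "\n")
    lines = [f"methvar {report['version']} run report"]
    for key, value in report.items():
        if key in ("version", "stages"):
            continue
        lines.append(f"  {key}: {value}")
    for stage, counts in report.get("stages", {}).items():
        lines.append(f"  [{stage}] {counts}")
    (out_dir / "report.txt").write_text("\n".join(lines) + "\n")
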