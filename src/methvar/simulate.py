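"""Synthetic longitudinal two-group methylome cohorts with planted truth.

The generator emulates the structure of a whole-blood Infinium beta-value
study with two outcome groups (default 14 converters vs 25 non-converters)
sampled at baseline (M0) and follow-up (MF):

* per-probe baseline means are bimodal, a mixture of a low-methylation mode
  (~0.1) and a high mode (~0.85), jittered on the logit scale — the familiar
  two-humped marginal of array betas;
* within-group noise and M0->MF drift are additive Gaussians on the logit
  scale, which keeps betas in (0, 1) without ad hoc truncation and makes
  beta-scale spread proportional to beta*(1-beta);
* planted signals are beta-scale shifts applied at MF only: group-level
  shifts on selected probes (true VMPs) and single-(probe, subject) offsets
  (true private epimutations).  Shifted betas are clipped to
  [eps, 1 - eps] and any clipping is recorded in the truth table.

Everything is a deterministic function of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .core import BetaMatrix, QCMetrics, SampleSheet, ValidationError

EPS = 1e-6


@dataclass
class SimConfig:
    """Study conditions for one simulated cohort.

    Noise and drift standard deviations are on the logit scale; planted
    shift/offset magnitudes are on the beta scale.
    """

    n_converters: int = 14
    n_nonconverters: int = 25
    n_probes: int = 10_000
    low_mode: float = 0.1
    high_mode: float = 0.85
    high_weight: float = 0.5
    baseline_logit_sd: float = 0.5
    noise_sd: float = 0.02
    drift_sd: float = 0.02
    n_vmp: int = 0
    vmp_group: str = "converter"
    vmp_shift: float = 0.15
    n_epimutations: int = 0
    epi_group: str = "converter"
    epi_offset: float = 0.25
    detp_fail_rate: float = 0.0
    low_beadcount_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_converters", "n_nonconverters", "n_probes",
                     "n_vmp", "n_epimutations"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for name in ("vmp_shift", "epi_offset"):
            if not 0.0 < getattr(self, name) < 1.0:
                raise ValidationError(f"{name} must be in (0, 1)")
        if self.n_vmp + self.n_epimutations > self.n_probes:
            raise ValidationError("more planted probes than probes")


@dataclass
class TruthTable:
    """Planted signals: what a perfect detector should recover."""

    vmps: pd.DataFrame           # probe_id, group, shift
    epimutations: pd.DataFrame   # probe_id, subject_id, timepoint, offset, direction
    clipped: pd.DataFrame        # probe_id, sample_id (plants clipped to range)

    @property
    def vmp_probes(self) -> set[str]:
        return set(self.vmps["probe_id"])

    @property
    def epimutation_pairs(self) -> set[tuple[str, str]]:
        return set(zip(self.epimutations["probe_id"],
                       self.epimutations["subject_id"]))


@dataclass
class SimulatedCohort:
    betas: BetaMatrix        # M0 and MF samples side by side
    sheet: SampleSheet
    qc: QCMetrics
    truth: TruthTable
    config: SimConfig


def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    """Generate one cohort under ``config`` (deterministic per seed)."""
    rng = np.random.default_rng(config.seed)
    n_c, n_n, n_p = config.n_converters, config.n_nonconverters, config.n_probes
    n_subj = n_c + n_n

    subjects = ([f"C{i + 1:03d}" for i in range(n_c)]
                + [f"N{i + 1:03d}" for i in range(n_n)])
    groups = ["converter"] * n_c + ["nonconverter"] * n_n
    probes = [f"cg{i:08d}" for i in range(n_p)]
    sheet = SampleSheet(pd.DataFrame({
        "sample_id": [f"{s}_{tp}" for tp in ("M0", "MF") for s in subjects],
        "subject_id": subjects * 2,
        "group": groups * 2,
        "timepoint": ["M0"] * n_subj + ["MF"] * n_subj,
    }))

    high = rng.random(n_p) < config.high_weight
    base = np.where(high, config.high_mode, config.low_mode)
    l_base = logit(base) + rng.normal(0.0, config.baseline_logit_sd, n_p)

    noise = rng.normal(0.0, config.noise_sd, (n_p, n_subj)) if config.noise_sd > 0 \
        else np.zeros((n_p, n_subj))
    drift = rng.normal(0.0, config.drift_sd, (n_p, n_subj)) if config.drift_sd > 0 \
        else np.zeros((n_p, n_subj))
    l0 = l_base[:, None] + noise
    b0 = expit(l0)
    bf = expit(l0 + drift)

    # plant on disjoint probe sets, fixed draw order for determinism
    planted = rng.choice(n_p, size=config.n_vmp + config.n_epimutations,
                         replace=False) if config.n_vmp + config.n_epimutations else np.array([], dtype=int)
    vmp_idx = planted[:config.n_vmp]
    epi_idx = planted[config.n_vmp:]
    group_cols = np.array([g == config.vmp_group for g in groups])

    # shifts point toward mid-methylation so the full magnitude stays in
    # range; overshoots (large offsets) are still clipped and recorded
    plant_sign = np.where(expit(l_base) < 0.5, 1.0, -1.0)

    vmp_rows = []
    for j in vmp_idx:
        sign = plant_sign[j]
        bf[j, group_cols] += sign * config.vmp_shift
        vmp_rows.append({"probe_id": probes[j], "group": config.vmp_group,
                         "shift": sign * config.vmp_shift})

    epi_members = [i for i, g in enumerate(groups) if g == config.epi_group]
    epi_rows = []
    for j in epi_idx:
        i = int(rng.choice(epi_members))
        sign = plant_sign[j]
        bf[j, i] += sign * config.epi_offset
        epi_rows.append({"probe_id": probes[j], "subject_id": subjects[i],
                         "timepoint": "MF", "offset": sign * config.epi_offset,
                         "direction": "hyper" if sign > 0 else "hypo"})

    clip_mask = (bf < EPS) | (bf > 1.0 - EPS)
    clipped = pd.DataFrame(
        [{"probe_id": probes[j], "sample_id": f"{subjects[i]}_MF"}
         for j, i in zip(*np.nonzero(clip_mask))],
        columns=["probe_id", "sample_id"])
    bf = np.clip(bf, EPS, 1.0 - EPS)
    b0 = np.clip(b0, EPS, 1.0 - EPS)

    cols_m0 = [f"{s}_M0" for s in subjects]
    cols_mf = [f"{s}_MF" for s in subjects]
    betas = BetaMatrix(pd.DataFrame(
        np.hstack([b0, bf]), index=pd.Index(probes, name="probe_id"),
        columns=cols_m0 + cols_mf))

    all_cols = cols_m0 + cols_mf
    detp = rng.uniform(0.0, 0.01, (n_p, 2 * n_subj))
    if config.detp_fail_rate > 0:
        fail = rng.random((n_p, 2 * n_subj)) < config.detp_fail_rate
        detp = np.where(fail, rng.uniform(0.05, 1.0, detp.shape), detp)
    beadcount = rng.poisson(12.0, (n_p, 2 * n_subj)) + 3
    if config.low_beadcount_rate > 0:
        low = rng.random((n_p, 2 * n_subj)) < config.low_beadcount_rate
        beadcount = np.where(low, rng.integers(0, 3, beadcount.shape), beadcount)
    qc = QCMetrics(
        detection_p=pd.DataFrame(detp, index=probes, columns=all_cols),
        beadcount=pd.DataFrame(beadcount, index=probes, columns=all_cols),
    )

    truth = TruthTable(
        vmps=pd.DataFrame(vmp_rows, columns=["probe_id", "group", "shift"]),
        epimutations=pd.DataFrame(
            epi_rows, columns=["probe_id", "subject_id", "timepoint",
                               "offset", "direction"]),
        clipped=clipped,
    )
    return SimulatedCohort(betas=betas, sheet=sheet, qc=qc, truth=truth,
                           config=config)


def _pr(n_tp: int, n_pred: int, n_truth: int) -> dict:
    precision = n_tp / n_pred if n_pred else float("nan")
    recall = n_tp / n_truth if n_truth else float("nan")
    return {"precision": precision, "recall": recall, "tp": n_tp,
            "fp": n_pred - n_tp, "fn": n_truth - n_tp}


def evaluate_recovery(truth: TruthTable,
                      vmp_results: pd.DataFrame | None = None,
                      calls: pd.DataFrame | None = None) -> dict:
    """Precision/recall of detections against the planted truth.

    VMPs match on probe; epimutations on (probe, subject).  Precision is
    NaN (undefined) when there are no predictions; recall is NaN when
    nothing was planted.
    """
    out: dict[str, dict] = {}
    if vmp_results is not None:
        pred = set(vmp_results.loc[vmp_results["is_vmp"], "probe_id"])
        out["vmp"] = _pr(len(pred & truth.vmp_probes), len(pred),
                         len(truth.vmp_probes))
    if calls is not None:
        pred_pairs = set(zip(calls["probe_id"], calls["subject_id"]))
        out["epimutation"] = _pr(len(pred_pairs & truth.epimutation_pairs),
                                 len(pred_pairs), len(truth.epimutation_pairs))
    return out
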