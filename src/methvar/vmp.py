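"""Variably methylated probe (VMP) detection in a longitudinal design.

Each paired subject contributes a per-probe longitudinal methylation change
delta_beta = beta(MF) - beta(M0).  Per outcome group a robust central
statistic of the deltas is computed per probe — by default the absolute
value of the group median, |median(delta_beta)| — and a probe is called
variably methylated when the statistic reaches the 0.1 threshold (a 10%
methylation difference, the conventional floor for biological rather than
technical effects on Infinium arrays; the rule is inclusive, >= 0.1).

Two statistic modes exist because "median absolute difference" is ambiguous:
``abs_of_median`` (default) takes |median(delta)| and so cancels symmetric
two-sided changes, while ``median_of_abs`` takes median(|delta|) and counts
change in either direction.  The mode used is recorded in the output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import BetaMatrix, SampleSheet, ValidationError, GROUPS

log = logging.getLogger("methvar")

MODES = ("abs_of_median", "median_of_abs")
DEFAULT_THRESHOLD = 0.1
#: probes missing in more than this fraction of a group's subjects get a
#: missing statistic instead of a biased one
MAX_MISSING_FRAC = 0.2


@dataclass
class DeltaMatrix:
    """Per-(probe, subject) longitudinal differences beta(MF) - beta(M0)."""

    data: pd.DataFrame          # probes x subjects
    groups: pd.Series           # subject -> group label

    def __post_init__(self) -> None:
        vals = self.data.to_numpy(dtype=float)
        if np.any(np.nan_to_num(np.abs(vals), nan=0.0) > 1.0 + 1e-9):
            raise ValidationError("delta magnitude exceeds 1")
        missing = [s for s in self.data.columns if s not in self.groups.index]
        if missing:
            raise ValidationError(f"subjects without group label: {missing[:5]}")

    def subjects(self, group: str) -> list[str]:
        if group not in GROUPS:
            raise ValidationError(f"unknown group {group!r}")
        return [s for s in self.data.columns if self.groups[s] == group]


def compute_delta(betas: BetaMatrix, sheet: SampleSheet) -> DeltaMatrix:
    """Per-subject longitudinal differences for every paired subject.

    Subjects lacking either timepoint in ``betas`` are skipped with a
    warning; a missing beta on either side yields a missing delta.
    """
    pairs = sheet.paired_subjects()
    have = set(betas.sample_ids)
    usable = pairs[pairs["sample_m0"].isin(have) & pairs["sample_mf"].isin(have)]
    skipped = sorted(set(pairs["subject_id"]) - set(usable["subject_id"]))
    unpaired = sorted(set(sheet.data["subject_id"]) - set(pairs["subject_id"]))
    for subj in [*unpaired, *skipped]:
        log.warning("compute_delta: subject %s lacks a complete M0/MF pair; skipped", subj)

    mf = betas.data[list(usable["sample_mf"])].to_numpy(dtype=float)
    m0 = betas.data[list(usable["sample_m0"])].to_numpy(dtype=float)
    data = pd.DataFrame(mf - m0, index=betas.data.index,
                        columns=list(usable["subject_id"]))
    groups = usable.set_index("subject_id")["group"]
    return DeltaMatrix(data, groups)


def group_median_statistic(delta: DeltaMatrix, group: str,
                           mode: str = "abs_of_median") -> pd.DataFrame:
    """Per-probe central statistic of the group's deltas.

    Returns a frame indexed by probe with columns ``statistic``,
    ``signed_median`` (the raw group median delta) and ``n_used``.  A probe
    needs at least two non-missing deltas and at most MAX_MISSING_FRAC of
    the group missing; otherwise its statistic is missing.  Even-sized
    groups use the mean-of-middle-two median.
    """
    if mode not in MODES:
        raise ValidationError(f"unknown mode {mode!r}; expected one of {MODES}")
    subjects = delta.subjects(group)
    vals = delta.data[subjects].to_numpy(dtype=float)
    n_group = len(subjects)
    n_used = np.sum(~np.isnan(vals), axis=1)

    with np.errstate(invalid="ignore"):
        signed = np.nanmedian(np.where(np.isnan(vals), np.nan, vals), axis=1)
        med_abs = np.nanmedian(np.abs(vals), axis=1)
    stat = np.abs(signed) if mode == "abs_of_median" else med_abs

    ok = (n_used >= 2) & (n_group - n_used <= MAX_MISSING_FRAC * n_group)
    stat = np.where(ok, stat, np.nan)
    signed = np.where(ok, signed, np.nan)
    n_masked = int((~ok).sum())
    if n_masked:
        log.info("group_median_statistic(%s): %d probe(s) with too many "
                 "missing deltas -> missing statistic", group, n_masked)
    return pd.DataFrame({"statistic": stat, "signed_median": signed,
                         "n_used": n_used}, index=delta.data.index)


def detect_vmps(stats: pd.DataFrame, group: str,
                threshold: float = DEFAULT_THRESHOLD,
                mode: str = "abs_of_median") -> pd.DataFrame:
    """Call VMPs from a ``group_median_statistic`` table.

    ``is_vmp`` is True when statistic >= threshold (inclusive).  Output has
    columns probe_id, group, mode, statistic, signed_median, is_vmp, sorted
    by statistic descending with ties broken by probe id; probes with a
    missing statistic sort last and are never VMPs.
    """
    out = pd.DataFrame({
        "probe_id": stats.index,
        "group": group,
        "mode": mode,
        "statistic": stats["statistic"].to_numpy(),
        "signed_median": stats["signed_median"].to_numpy(),
    })
    out["is_vmp"] = out["statistic"] >= threshold
    out = out.sort_values(["statistic", "probe_id"],
                          ascending=[False, True], na_position="last")
    return out.reset_index(drop=True)


def violin_summary(stats_by_group: dict[str, pd.DataFrame],
                   threshold: float = DEFAULT_THRESHOLD) -> pd.DataFrame:
    """Distribution summary of the per-probe statistic per group.

    One row per group: n (non-missing statistics), count_above (statistics
    >= threshold, matching ``detect_vmps``), and quantiles q00..q100.
    Groups with no probes yield an all-NaN quantile row with n = 0.
    """
    rows = []
    for group, stats in stats_by_group.items():
        vals = stats["statistic"].dropna().to_numpy() if len(stats) else np.array([])
        row = {"group": group, "n": int(vals.size),
               "count_above": int((vals >= threshold).sum())}
        qs = (np.percentile(vals, [0, 25, 50, 75, 100]) if vals.size
              else [np.nan] * 5)
        row.update(zip(["q00", "q25", "q50", "q75", "q100"], qs))
        rows.append(row)
    return pd.DataFrame(rows)
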