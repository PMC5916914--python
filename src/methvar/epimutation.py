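"""Private epimutation detection by per-CpG variance scanning.

The model of a private epimutation: a CpG whose beta-value dispersion is
larger in converters than non-converters at follow-up (MF), where the extra
dispersion is driven by one or a few individuals.  The scan:

1. per CpG, a two-sided F-test of equal beta-value variance between the two
   outcome groups, at M0 and at MF, with Benjamini-Hochberg FDR across all
   non-degenerate CpGs per timepoint;
2. candidate filters: FDR-significant at MF with the converters the
   higher-variance group, converter variance strictly increasing from M0 to
   MF, and no significant excess variance in non-converters (converter
   specificity);
3. per candidate CpG, each converter's deviation from the converter-group
   median beta; a deviation strictly exceeding 0.10 in absolute value is an
   epimutation call (hyper- or hypomethylation by sign).

Variances are unbiased (n-1).  Group medians for even group sizes are the
mean of the two middle values.  The strictness of the 0.10 rule matters:
deviations of exactly 0.10 are not calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .core import (BetaMatrix, DeviationMatrix, SampleSheet,
                   ValidationError, GROUPS)

log = logging.getLogger("methvar")

DEFAULT_ALPHA = 0.05
DEFAULT_DEV_THRESHOLD = 0.10
LIST_MODES = ("between-group", "longitudinal")


class FTestResult(NamedTuple):
    F: float
    df1: int
    df2: int
    p_two_sided: float
    degenerate: str | None = None


def variance_ftest(x, y) -> FTestResult:
    """Two-sided F-test of equal variances, F = var(x)/var(y).

    Unbiased (n-1) variances; p = 2 * min(P(F <= f), P(F >= f)) capped at 1.
    Degenerate inputs are flagged rather than raised: both variances zero
    gives p = 1 (a constant probe carries no evidence either way), a single
    zero variance gives the p -> 0 limit.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if x.size < 2 or y.size < 2:
        raise ValidationError("variance_ftest needs >= 2 observations per group")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    df1, df2 = x.size - 1, y.size - 1
    if vx == 0.0 and vy == 0.0:
        return FTestResult(np.nan, df1, df2, 1.0, "constant")
    if vy == 0.0:
        return FTestResult(np.inf, df1, df2, 0.0, "zero_variance")
    if vx == 0.0:
        return FTestResult(0.0, df1, df2, 0.0, "zero_variance")
    f = vx / vy
    p = 2.0 * min(sps.f.cdf(f, df1, df2), sps.f.sf(f, df1, df2))
    return FTestResult(f, df1, df2, min(p, 1.0), None)


def scan_variances(betas: BetaMatrix, sheet: SampleSheet,
                   timepoint: str) -> pd.DataFrame:
    """Per-probe converter-vs-nonconverter variance F-test at one timepoint.

    Returns a frame indexed by probe with columns var_converters,
    var_nonconverters, F, df1, df2, p, q, higher_variance_group and
    ``degenerate``.  BH-FDR (``q``) is computed across the non-degenerate
    probes only; degenerate probes (a zero variance, or fewer than two
    non-missing values in a group) keep q = NaN.
    """
    if timepoint not in set(sheet.data["timepoint"]):
        raise ValidationError(f"timepoint {timepoint!r} absent from sample sheet")
    conv = sheet.samples_at(timepoint, "converter")["sample_id"].tolist()
    nonc = sheet.samples_at(timepoint, "nonconverter")["sample_id"].tolist()
    conv = [s for s in conv if s in set(betas.sample_ids)]
    nonc = [s for s in nonc if s in set(betas.sample_ids)]
    if len(conv) < 2 or len(nonc) < 2:
        raise ValidationError(
            f"need >= 2 samples per group at {timepoint}; have "
            f"{len(conv)} converters, {len(nonc)} nonconverters")

    xc = betas.data[conv].to_numpy(dtype=float)
    xn = betas.data[nonc].to_numpy(dtype=float)
    nc = np.sum(~np.isnan(xc), axis=1)
    nn = np.sum(~np.isnan(xn), axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        vc = np.nanvar(xc, axis=1, ddof=1)
        vn = np.nanvar(xn, axis=1, ddof=1)
    vc = np.where(nc >= 2, vc, np.nan)
    vn = np.where(nn >= 2, vn, np.nan)

    degenerate = np.full(len(betas.probe_ids), None, dtype=object)
    degenerate[(nc < 2) | (nn < 2)] = "insufficient_n"
    both_zero = (vc == 0.0) & (vn == 0.0)
    one_zero = ((vc == 0.0) ^ (vn == 0.0)) & (degenerate == None)  # noqa: E711
    degenerate[both_zero] = "constant"
    degenerate[one_zero] = "zero_variance"

    with np.errstate(invalid="ignore", divide="ignore"):
        F = vc / vn
    df1, df2 = nc - 1, nn - 1
    ok = degenerate == None  # noqa: E711
    p = np.full(F.shape, np.nan)
    p[both_zero] = 1.0
    p[one_zero] = 0.0
    if ok.any():
        cdf = sps.f.cdf(F[ok], df1[ok], df2[ok])
        sf = sps.f.sf(F[ok], df1[ok], df2[ok])
        p[ok] = np.minimum(2.0 * np.minimum(cdf, sf), 1.0)

    q = np.full(F.shape, np.nan)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]

    higher = np.where(vc > vn, "converters",
                      np.where(vn > vc, "nonconverters", "tie"))
    out = pd.DataFrame({
        "timepoint": timepoint,
        "n_converters": nc, "n_nonconverters": nn,
        "var_converters": vc, "var_nonconverters": vn,
        "F": F, "df1": df1, "df2": df2, "p": p, "q": q,
        "higher_variance_group": higher,
        "degenerate": degenerate,
    }, index=pd.Index(betas.probe_ids, name="probe_id"))
    n_deg = int((~ok).sum())
    if n_deg:
        log.info("scan_variances(%s): %d degenerate probe(s) excluded from FDR",
                 timepoint, n_deg)
    return out


def longitudinal_significant_set(betas: BetaMatrix, sheet: SampleSheet,
                                 group: str, alpha: float = DEFAULT_ALPHA) -> set[str]:
    """Probes with an FDR-significant within-group variance change M0 -> MF.

    The alternative reading of "significant in a group": per probe, an
    F-test of the group's MF variance against its own M0 variance, BH-FDR
    across probes.
    """
    if group not in GROUPS:
        raise ValidationError(f"unknown group {group!r}")
    m0 = [s for s in sheet.samples_at("M0", group)["sample_id"]
          if s in set(betas.sample_ids)]
    mf = [s for s in sheet.samples_at("MF", group)["sample_id"]
          if s in set(betas.sample_ids)]
    if len(m0) < 2 or len(mf) < 2:
        raise ValidationError(f"need >= 2 {group} samples at each timepoint")
    x0 = betas.data[m0].to_numpy(dtype=float)
    xf = betas.data[mf].to_numpy(dtype=float)
    n0 = np.sum(~np.isnan(x0), axis=1)
    nf = np.sum(~np.isnan(xf), axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        v0 = np.nanvar(x0, axis=1, ddof=1)
        vf = np.nanvar(xf, axis=1, ddof=1)
        F = vf / v0
    ok = (n0 >= 2) & (nf >= 2) & (v0 > 0) & (vf > 0)
    p = np.full(F.shape, np.nan)
    cdf = sps.f.cdf(F[ok], nf[ok] - 1, n0[ok] - 1)
    sf = sps.f.sf(F[ok], nf[ok] - 1, n0[ok] - 1)
    p[ok] = np.minimum(2.0 * np.minimum(cdf, sf), 1.0)
    q = np.full(F.shape, np.nan)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    probes = np.asarray(betas.probe_ids, dtype=object)
    return set(probes[np.where(np.isnan(q), False, q < alpha)])


def select_candidates(scan_m0: pd.DataFrame, scan_mf: pd.DataFrame,
                      alpha: float = DEFAULT_ALPHA,
                      nonconverter_significant: set[str] | None = None) -> pd.DataFrame:
    """Apply the three clinical-relevance filters to the two variance scans.

    Per probe: ``passes_mf_significance`` — q < alpha at MF with converters
    the higher-variance group; ``passes_variance_increase`` — converter
    variance strictly greater at MF than M0; ``passes_converter_specificity``
    — probe not in the non-converter significant set.  When that set is not
    supplied it defaults to the between-group reading: probes FDR-significant
    at M0 or MF with the non-converters the higher-variance group.
    ``is_candidate`` is the conjunction.  Sorted by MF q ascending.
    """
    if not scan_m0.index.equals(scan_mf.index):
        scan_m0 = scan_m0.reindex(scan_mf.index)
        if scan_m0["F"].isna().all():
            raise ValidationError("scans cover disjoint probe sets")
    if nonconverter_significant is None:
        nonconverter_significant = set()
        for scan in (scan_m0, scan_mf):
            sig = scan["q"].lt(alpha) & (scan["higher_variance_group"] == "nonconverters")
            nonconverter_significant |= set(scan.index[sig.fillna(False)])

    sig_mf = (scan_mf["q"].lt(alpha)
              & (scan_mf["higher_variance_group"] == "converters")).fillna(False)
    var_up = (scan_mf["var_converters"] > scan_m0["var_converters"]).fillna(False)
    specific = ~scan_mf.index.isin(sorted(nonconverter_significant))

    out = pd.DataFrame({
        "passes_mf_significance": sig_mf.to_numpy(),
        "passes_variance_increase": var_up.to_numpy(),
        "passes_converter_specificity": specific,
        "q_mf": scan_mf["q"].to_numpy(),
    }, index=scan_mf.index)
    out["is_candidate"] = (out["passes_mf_significance"]
                           & out["passes_variance_increase"]
                           & out["passes_converter_specificity"])
    return out.sort_values("q_mf", na_position="last")


def compute_deviations(betas: BetaMatrix, sheet: SampleSheet, group: str,
                       timepoint: str, probes=None) -> DeviationMatrix:
    """Each group member's beta minus the group median beta, per probe.

    ``probes`` defaults to all probes in ``betas``; a probe missing from
    the matrix raises, naming it.  The group needs at least three members
    at the timepoint for a median an individual cannot dominate.
    """
    if probes is None:
        probes = betas.probe_ids
    missing = [p for p in probes if p not in set(betas.probe_ids)]
    if missing:
        raise ValidationError(f"probe(s) absent from beta matrix: {missing[:5]}")
    members = sheet.samples_at(timepoint, group)
    members = members[members["sample_id"].isin(set(betas.sample_ids))]
    if len(members) < 3:
        raise ValidationError(
            f"group {group!r} has {len(members)} member(s) at {timepoint}; need >= 3")
    sub = betas.data.loc[list(probes), list(members["sample_id"])]
    med = sub.median(axis=1, skipna=True)
    dev = sub.sub(med, axis=0)
    dev.columns = list(members["subject_id"])
    return DeviationMatrix(dev, timepoint=timepoint, group=group)


def call_epimutations(dev: DeviationMatrix,
                      threshold: float = DEFAULT_DEV_THRESHOLD,
                      strict: bool = True) -> pd.DataFrame:
    """Emit one call per (probe, subject) whose |deviation| exceeds threshold.

    ``strict`` (default) requires |deviation| > threshold, so a deviation of
    exactly 0.10 is not a call; with ``strict=False`` the rule is >=.
    Direction is ``hyper`` for positive deviations, ``hypo`` for negative.
    Output columns: probe_id, subject_id, timepoint, deviation, direction;
    sorted by probe then subject.
    """
    long = dev.data.stack()
    mag = long.abs()
    hit = mag > threshold if strict else mag >= threshold
    calls = long[hit]
    out = pd.DataFrame({
        "probe_id": calls.index.get_level_values(0),
        "subject_id": calls.index.get_level_values(1),
        "timepoint": dev.timepoint,
        "deviation": calls.to_numpy(),
    })
    out["direction"] = np.where(out["deviation"] > 0, "hyper", "hypo")
    return out.sort_values(["probe_id", "subject_id"]).reset_index(drop=True)


@dataclass
class CallSummary:
    """Aggregate view of an epimutation call table."""

    n_calls: int
    n_probes_called: int
    per_subject: dict[str, int]
    histogram: dict[int, int]                  # calls-per-subject -> n subjects
    multi_carrier: pd.DataFrame = field(repr=False)  # probes with >= 2 carriers

    def to_dict(self) -> dict:
        return {
            "n_calls": self.n_calls,
            "n_probes_called": self.n_probes_called,
            "per_subject": self.per_subject,
            "histogram": {str(k): v for k, v in self.histogram.items()},
            "multi_carrier": self.multi_carrier.to_dict(orient="records"),
        }


def summarize_calls(calls: pd.DataFrame, subjects) -> CallSummary:
    """Summarize calls over the FULL subject list (zero-call subjects count).

    For every probe with at least two carriers, reports whether all carriers
    share the direction of change and, if so, which.
    """
    subjects = list(subjects)
    extra = set(calls["subject_id"]) - set(subjects)
    if extra:
        raise ValidationError(f"calls name unknown subject(s): {sorted(extra)[:5]}")
    per_subject = {s: 0 for s in subjects}
    for s in calls["subject_id"]:
        per_subject[s] += 1
    histogram: dict[int, int] = {}
    for n in per_subject.values():
        histogram[n] = histogram.get(n, 0) + 1

    rows = []
    for probe, grp in calls.groupby("probe_id"):
        if len(grp) < 2:
            continue
        dirs = set(grp["direction"])
        rows.append({"probe_id": probe, "n_carriers": len(grp),
                     "shared_direction": len(dirs) == 1,
                     "direction": dirs.pop() if len(dirs) == 1 else None})
    multi = pd.DataFrame(rows, columns=["probe_id", "n_carriers",
                                        "shared_direction", "direction"])
    return CallSummary(
        n_calls=len(calls),
        n_probes_called=calls["probe_id"].nunique(),
        per_subject=per_subject,
        histogram=dict(sorted(histogram.items())),
        multi_carrier=multi,
    )
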