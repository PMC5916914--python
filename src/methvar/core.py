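"""Core containers and tabular I/O for methylation-array data.

The central object is the beta-value matrix: probes (CpG sites) in rows,
samples in columns, each cell the methylation fraction beta in [0, 1] as
reported by an Infinium-style array after normalization.  Longitudinal
designs attach a sample sheet mapping each sample to a subject, an outcome
group (converter / nonconverter) and a timepoint (M0 baseline, MF
follow-up).  Everything is stored in pandas and validated on construction.

All text formats are plain TSV/CSV with ``NA`` as the missing marker.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger("methvar")

MISSING = "NA"
#: tolerance for beta values straying outside [0, 1] (rounding in upstream files)
BETA_TOL = 1e-9

TIMEPOINTS = ("M0", "MF")
GROUPS = ("converter", "nonconverter")

_GROUP_SYNONYMS = {
    "converter": "converter",
    "c": "converter",
    "nonconverter": "nonconverter",
    "non-converter": "nonconverter",
    "nc": "nonconverter",
}

PROBE_FLAGS = ("sex_chromosome", "snp_probe", "snp_at_cpg", "cross_reactive")
SEX_CHROMS = {"chrX", "chrY"}


class MethvarError(Exception):
    """Base class for all package errors."""


class FormatError(MethvarError):
    """Structural problem in an input table (duplicate ids, bad header...)."""


class BetaParseError(FormatError):
    """A cell could not be parsed as a beta value; names the offending cell."""


class ValidationError(MethvarError):
    """A container invariant is violated."""


class ConfigurationError(MethvarError):
    """A required input or setting is absent or inconsistent."""


def _sep(dialect: str) -> str:
    if dialect == "tsv":
        return "\t"
    if dialect == "csv":
        return ","
    raise ConfigurationError(f"unknown dialect {dialect!r}; use 'tsv' or 'csv'")


# ---------------------------------------------------------------------------
# BetaMatrix
# ---------------------------------------------------------------------------

@dataclass
class BetaMatrix:
    """Probes x samples methylation fractions in [0, 1], NaN = missing."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        idx, cols = self.data.index, self.data.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise FormatError(f"duplicate probe ids: {dups[:5]}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups[:5]}")
        vals = self.data.to_numpy(dtype=float)
        bad = (vals < -BETA_TOL) | (vals > 1.0 + BETA_TOL)
        if np.any(np.nan_to_num(bad, nan=False)):
            i, j = np.argwhere(np.where(np.isnan(vals), False, bad))[0]
            raise ValidationError(
                f"beta value {vals[i, j]!r} outside [0, 1] at "
                f"probe {idx[i]!r}, sample {cols[j]!r}"
            )

    @property
    def probe_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset(self, probes: Sequence[str] | None = None,
               samples: Sequence[str] | None = None) -> "BetaMatrix":
        data = self.data
        if probes is not None:
            missing = [p for p in probes if p not in data.index]
            if missing:
                raise KeyError(f"probes not in matrix: {missing[:5]}")
            data = data.loc[list(probes)]
        if samples is not None:
            missing = [s for s in samples if s not in data.columns]
            if missing:
                raise KeyError(f"samples not in matrix: {missing[:5]}")
            data = data[list(samples)]
        return BetaMatrix(data)

    def to_file(self, path: str | Path, dialect: str = "tsv",
                decimals: int = 6) -> None:
        """Write the matrix with the first column holding probe ids."""
        self.data.to_csv(
            path, sep=_sep(dialect), na_rep=MISSING,
            float_format=f"%.{decimals}f", index_label="probe_id",
        )


def read_beta_matrix(path: str | Path, dialect: str = "tsv") -> BetaMatrix:
    """Read a probes x samples beta matrix from a delimited text file.

    First column: probe ids; header row: sample ids; cells numeric or the
    missing marker ``NA``.  Values outside [0, 1] (beyond 1e-9) and
    non-numeric cells are rejected with the offending cell named.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep=_sep(dialect), index_col=0, dtype=str,
                      keep_default_na=False)
    raw.index = raw.index.astype(str)
    parsed = {}
    for col in raw.columns:
        cells = raw[col].str.strip()
        numeric = pd.to_numeric(cells.mask(cells == MISSING), errors="coerce")
        bad = numeric.isna() & (cells != MISSING) & (cells != "")
        if bad.any():
            probe = raw.index[bad.argmax()]
            raise BetaParseError(
                f"{path.name}: non-numeric cell {cells[bad].iloc[0]!r} at "
                f"probe {probe!r}, sample {col!r}"
            )
        parsed[col] = numeric
    frame = pd.DataFrame(parsed, index=raw.index)
    frame.index.name = None
    frame.columns.name = None
    # name range violations precisely before handing off to the container
    vals = frame.to_numpy(dtype=float)
    out = np.where(np.isnan(vals), False,
                   (vals < -BETA_TOL) | (vals > 1.0 + BETA_TOL))
    if out.any():
        i, j = np.argwhere(out)[0]
        raise BetaParseError(
            f"{path.name}: value {vals[i, j]} outside [0, 1] at probe "
            f"{frame.index[i]!r}, sample {frame.columns[j]!r}"
        )
    return BetaMatrix(frame)


# ---------------------------------------------------------------------------
# SampleSheet
# ---------------------------------------------------------------------------

@dataclass
class SampleSheet:
    """Maps samples to subject, outcome group and timepoint.

    Invariants: sample ids unique; (subject, timepoint) unique; group
    constant within subject; timepoint in {M0, MF}.
    """

    data: pd.DataFrame  # columns: sample_id, subject_id, group, timepoint

    def __post_init__(self) -> None:
        required = {"sample_id", "subject_id", "group", "timepoint"}
        missing = required - set(self.data.columns)
        if missing:
            raise FormatError(f"sample sheet missing columns: {sorted(missing)}")
        df = self.data
        if df["sample_id"].duplicated().any():
            raise FormatError("duplicate sample ids in sample sheet")
        bad_tp = ~df["timepoint"].isin(TIMEPOINTS)
        if bad_tp.any():
            raise ValidationError(
                f"unknown timepoint(s): {sorted(df.loc[bad_tp, 'timepoint'].unique())}")
        bad_gr = ~df["group"].isin(GROUPS)
        if bad_gr.any():
            raise ValidationError(
                f"unknown group(s): {sorted(df.loc[bad_gr, 'group'].unique())}")
        dup = df.duplicated(subset=["subject_id", "timepoint"])
        if dup.any():
            pairs = df.loc[dup, ["subject_id", "timepoint"]].values.tolist()
            raise ValidationError(
                f"duplicate (subject, timepoint) pairs: {pairs[:5]}")
        ngroups = df.groupby("subject_id")["group"].nunique()
        mixed = ngroups[ngroups > 1].index.tolist()
        if mixed:
            raise ValidationError(f"subjects with inconsistent group: {mixed[:5]}")

    def samples_at(self, timepoint: str, group: str | None = None) -> pd.DataFrame:
        df = self.data[self.data["timepoint"] == timepoint]
        if group is not None:
            if group not in GROUPS:
                raise ValidationError(f"unknown group {group!r}")
            df = df[df["group"] == group]
        return df.reset_index(drop=True)

    def paired_subjects(self) -> pd.DataFrame:
        """Subjects with exactly one M0 and one MF sample.

        Returns columns subject_id, group, sample_m0, sample_mf.
        """
        wide = self.data.pivot(index="subject_id", columns="timepoint",
                               values="sample_id")
        groups = self.data.drop_duplicates("subject_id").set_index("subject_id")["group"]
        paired = wide.dropna(subset=[tp for tp in TIMEPOINTS if tp in wide])
        if not {"M0", "MF"} <= set(wide.columns):
            paired = wide.iloc[0:0].reindex(columns=["M0", "MF"])
        out = pd.DataFrame({
            "subject_id": paired.index,
            "group": groups.loc[paired.index].to_numpy(),
            "sample_m0": paired["M0"].to_numpy(),
            "sample_mf": paired["MF"].to_numpy(),
        }).reset_index(drop=True)
        return out

    def subjects(self, group: str | None = None) -> list[str]:
        df = self.data
        if group is not None:
            df = df[df["group"] == group]
        return sorted(df["subject_id"].unique())

    def to_file(self, path: str | Path, dialect: str = "tsv") -> None:
        self.data.to_csv(path, sep=_sep(dialect), index=False)


def read_sample_sheet(path: str | Path, dialect: str = "tsv") -> SampleSheet:
    """Read a sample sheet; column names case-insensitive, group synonyms
    (``C``/``NC``, ``non-converter``) normalized, timepoints upper-cased."""
    df = pd.read_csv(path, sep=_sep(dialect), dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    df = df.rename(columns={"sample": "sample_id", "subject": "subject_id"})
    if "group" in df.columns:
        norm = df["group"].str.strip().str.lower().map(_GROUP_SYNONYMS)
        bad = norm.isna() & df["group"].notna()
        if bad.any():
            raise ValidationError(
                f"unrecognized group label(s): {sorted(df.loc[bad, 'group'].unique())}")
        df["group"] = norm
    if "timepoint" in df.columns:
        df["timepoint"] = df["timepoint"].str.strip().str.upper()
    return SampleSheet(df)


# ---------------------------------------------------------------------------
# ProbeAnnotation
# ---------------------------------------------------------------------------

@dataclass
class ProbeAnnotation:
    """Per-probe genomic annotation (hg19 naming, 1-based positions).

    ``flags`` is a frozenset per probe drawn from
    {sex_chromosome, snp_probe, snp_at_cpg, cross_reactive}.  The
    sex_chromosome flag is derived from ``chrom`` and must agree with it.
    """

    data: pd.DataFrame  # index probe_id; columns chrom, pos, gene, flags

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate probe ids in annotation: {dups[:5]}")
        if (df["pos"] < 1).any():
            bad = df.index[df["pos"] < 1][0]
            raise ValidationError(f"position < 1 for probe {bad!r}")
        for probe, row in df.iterrows():
            unknown = set(row["flags"]) - set(PROBE_FLAGS)
            if unknown:
                raise ValidationError(
                    f"unknown flag(s) {sorted(unknown)} for probe {probe!r}")
            is_sex = row["chrom"] in SEX_CHROMS
            if ("sex_chromosome" in row["flags"]) != is_sex:
                raise ValidationError(
                    f"sex_chromosome flag inconsistent with chrom "
                    f"{row['chrom']!r} for probe {probe!r}")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.data.index)

    def flags_for(self, probe: str) -> frozenset:
        return self.data.at[probe, "flags"]


def build_probe_annotation(table: pd.DataFrame) -> ProbeAnnotation:
    """Normalize a raw annotation table (probe_id, chrom, pos, gene, flags).

    ``flags`` may be a semicolon/comma-joined string or an iterable; the
    sex_chromosome flag is added automatically for chrX/chrY probes.
    """
    df = table.copy()
    if "probe_id" in df.columns:
        df = df.set_index("probe_id")
    df.index = df.index.astype(str)
    df["pos"] = df["pos"].astype(int)
    df["gene"] = df.get("gene", pd.Series("", index=df.index)).fillna("")

    def _parse(flags, chrom) -> frozenset:
        if flags is None or (isinstance(flags, float) and np.isnan(flags)):
            items: set[str] = set()
        elif isinstance(flags, str):
            items = {t.strip() for t in flags.replace(",", ";").split(";") if t.strip()}
        else:
            items = set(flags)
        if chrom in SEX_CHROMS:
            items.add("sex_chromosome")
        return frozenset(items)

    raw_flags = df["flags"] if "flags" in df.columns else pd.Series(None, index=df.index, dtype=object)
    df["flags"] = [_parse(f, c) for f, c in zip(raw_flags, df["chrom"])]
    return ProbeAnnotation(df[["chrom", "pos", "gene", "flags"]])


def read_probe_annotation(path: str | Path, dialect: str = "tsv") -> ProbeAnnotation:
    df = pd.read_csv(path, sep=_sep(dialect), dtype={"probe_id": str, "chrom": str,
                                                     "gene": str, "flags": str})
    return build_probe_annotation(df)


# ---------------------------------------------------------------------------
# QCMetrics
# ---------------------------------------------------------------------------

@dataclass
class QCMetrics:
    """Optional per-(probe, sample) array QC matrices.

    ``detection_p``: detection p-values in [0, 1]; ``beadcount``:
    non-negative integer bead counts.  Either may be None.
    """

    detection_p: pd.DataFrame | None = None
    beadcount: pd.DataFrame | None = None

    def aligned_to(self, betas: BetaMatrix) -> "QCMetrics":
        """Subset both matrices to the betas' probes and samples.

        Raises ConfigurationError if a present metric does not cover them.
        """
        def _align(df: pd.DataFrame | None, name: str) -> pd.DataFrame | None:
            if df is None:
                return None
            missing_p = [p for p in betas.probe_ids if p not in df.index]
            missing_s = [s for s in betas.sample_ids if s not in df.columns]
            if missing_p or missing_s:
                raise ConfigurationError(
                    f"{name} does not cover the beta matrix "
                    f"(missing probes {missing_p[:3]}, samples {missing_s[:3]})")
            return df.loc[betas.probe_ids, betas.sample_ids]

        return QCMetrics(detection_p=_align(self.detection_p, "detection_p"),
                         beadcount=_align(self.beadcount, "beadcount"))


def read_qc_matrix(path: str | Path, dialect: str = "tsv") -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep(dialect), index_col=0)
    df.index = df.index.astype(str)
    return df


# ---------------------------------------------------------------------------
# DeviationMatrix
# ---------------------------------------------------------------------------

@dataclass
class DeviationMatrix:
    """Per-(probe, subject) deviation of an individual beta from the group
    median beta at one timepoint; values in [-1, 1] and each probe's
    deviations re-median to zero by construction."""

    data: pd.DataFrame  # probes x subjects
    timepoint: str
    group: str = "converter"
    median_tol: float = 1e-9

    def __post_init__(self) -> None:
        vals = self.data.to_numpy(dtype=float)
        if np.any(np.nan_to_num(np.abs(vals), nan=0.0) > 1.0 + BETA_TOL):
            raise ValidationError("deviation magnitude exceeds 1")
        med = np.nanmedian(vals, axis=1)
        off = np.abs(med) > self.median_tol
        if off.any():
            probe = self.data.index[int(np.argmax(off))]
            raise ValidationError(
                f"per-probe deviation median not 0 (probe {probe!r}, "
                f"median {med[off][0]:.3g}, tol {self.median_tol:g})")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def subject_ids(self) -> list[str]:
        return list(self.data.columns)

    def to_file(self, path: str | Path, dialect: str = "tsv",
                decimals: int = 4) -> None:
        self.data.to_csv(path, sep=_sep(dialect), na_rep=MISSING,
                         float_format=f"%.{decimals}f", index_label="probe_id")


# ---------------------------------------------------------------------------
# BED export
# ---------------------------------------------------------------------------

def export_bed(results: pd.DataFrame, annotation: ProbeAnnotation,
               path: str | Path, statistic: str = "statistic") -> Path:
    """Write probe-level results as single-base BED intervals.

    Annotation positions are 1-based; BED is 0-based half-open, so a probe
    at chrN:pos becomes ``chrN  pos-1  pos``.  The name column is the probe
    id and the score is the statistic mapped to [0, 1000]: statistics
    already in [0, 1] are multiplied by 1000, otherwise min-max scaled.
    Probes without an annotation entry are written to a ``.rejects.txt``
    sidecar instead of being silently dropped.
    """
    path = Path(path)
    if "probe_id" in results.columns:
        probes = results["probe_id"].astype(str)
        stats = results[statistic] if statistic in results else pd.Series(0.0, index=results.index)
    else:
        probes = pd.Series(results.index.astype(str), index=results.index)
        stats = results[statistic] if statistic in results else pd.Series(0.0, index=results.index)
    stats = pd.to_numeric(stats, errors="coerce").fillna(0.0)

    known = probes.isin(annotation.data.index)
    rejects = probes[~known].tolist()

    vals = stats[known].to_numpy(dtype=float)
    if vals.size and (vals.max() > 1.0 or vals.min() < 0.0):
        lo, hi = vals.min(), vals.max()
        scaled = np.zeros_like(vals) if hi == lo else (vals - lo) / (hi - lo) * 1000
    else:
        scaled = vals * 1000
    scores = np.round(scaled).astype(int)

    with open(path, "w") as fh:
        for probe, score in zip(probes[known], scores):
            chrom = annotation.data.at[probe, "chrom"]
            pos = int(annotation.data.at[probe, "pos"])
            fh.write(f"{chrom}\t{pos - 1}\t{pos}\t{probe}\t{score}\n")
    if rejects:
        sidecar = path.with_suffix(path.suffix + ".rejects.txt")
        sidecar.write_text("\n".join(rejects) + "\n")
        log.warning("export_bed: %d unannotated probe(s) written to %s",
                    len(rejects), sidecar)
    return path
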