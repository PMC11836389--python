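"""Readers and writers for the package's tabular dialects.

TSV with a header row is the universal tabular format (count tables,
time courses, DMP tables, summaries); BED3/BED4 (0-based, half-open) carries
interval tracks; JSON carries scalar summaries.  Floats are serialized with
9 significant digits so write/read round-trips are stable.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError
from .kinetics import NOTimeCourse

__all__ = [
    "read_counts_table",
    "read_bed",
    "read_timecourse",
    "write_timecourse",
    "write_dmps",
    "write_summary",
    "write_json",
]

COUNT_COLUMNS = ["chrom", "pos", "strand", "condition", "replicate",
                 "assay", "meth", "total"]

_FLOAT_FMT = "%.9g"


def read_counts_table(path) -> pd.DataFrame:
    """Read a per-CpG BS/oxBS count table (TSV with header).

    Malformed rows (meth > total, negative counts, unknown assay) are dropped
    with a warning and collected in ``df.attrs["rejected_rows"]``.  Missing
    columns raise :class:`SchemaError` listing the absences.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file") from exc
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    df = df[COUNT_COLUMNS].copy()
    df["assay"] = df["assay"].astype(str)
    bad = (
        (df["meth"] > df["total"])
        | (df["meth"] < 0)
        | (df["total"] < 0)
        | (df["pos"] < 0)
        | ~df["assay"].isin(["BS", "oxBS"])
    )
    rejected = df[bad]
    if len(rejected):
        warnings.warn(
            f"{path}: rejected {len(rejected)} malformed rows "
            f"(meth > total, negative counts, or unknown assay)",
            stacklevel=2,
        )
    df = df[~bad].reset_index(drop=True)
    df.attrs["rejected_rows"] = rejected.reset_index(drop=True)
    return df


def read_bed(path) -> pd.DataFrame:
    """Read BED3/BED4 intervals (0-based half-open) into a sorted DataFrame.

    Rows with start >= end or negative start are rejected with a warning;
    overlapping intervals are permitted.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file") from exc
    if df.shape[1] < 3:
        raise SchemaError(f"{path}: BED needs at least 3 columns")
    df = df.iloc[:, :4] if df.shape[1] >= 4 else df
    df.columns = ["chrom", "start", "end", "label"][: df.shape[1]]
    if "label" not in df.columns:
        df["label"] = "."
    bad = (df["start"] >= df["end"]) | (df["start"] < 0)
    if bad.any():
        warnings.warn(f"{path}: rejected {int(bad.sum())} invalid intervals",
                      stacklevel=2)
    df = df[~bad]
    return df.sort_values(["chrom", "start", "end"]).reset_index(drop=True)


def _write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_timecourse(tc: NOTimeCourse, path) -> None:
    """Write an NO time course as TSV (time_s, donor_uM, no_uM, o2_uM, no_consumed_uM)."""
    df = pd.DataFrame({
        "time_s": tc.times,
        "donor_uM": tc.donor,
        "no_uM": tc.no,
        "o2_uM": tc.o2,
        "no_consumed_uM": tc.no_consumed,
    })
    _write_tsv(df, path)


def read_timecourse(path) -> NOTimeCourse:
    """Read a time-course TSV back into an :class:`NOTimeCourse`."""
    df = pd.read_csv(path, sep="\t")
    need = ["time_s", "donor_uM", "no_uM", "o2_uM", "no_consumed_uM"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    return NOTimeCourse(
        times=df["time_s"].to_numpy(float),
        donor=df["donor_uM"].to_numpy(float),
        no=df["no_uM"].to_numpy(float),
        o2=df["o2_uM"].to_numpy(float),
        no_consumed=df["no_consumed_uM"].to_numpy(float),
        dose=float(df["donor_uM"].iloc[0]),
    )


def write_dmps(dmps: pd.DataFrame, path) -> None:
    """Write a DMP table as TSV with a deterministic column order."""
    lead = [c for c in ("chrom", "pos", "mark", "beta_control", "beta_treated",
                        "delta_beta", "p_value", "fdr", "call", "cpg_class",
                        "feature") if c in dmps.columns]
    rest = [c for c in dmps.columns if c not in lead]
    _write_tsv(dmps[lead + rest], path)


def write_summary(summary: pd.DataFrame, path) -> None:
    """Write an annotation summary table as TSV."""
    _write_tsv(summary, path)


def write_json(obj: dict, path) -> None:
    """Write a scalar summary as deterministic, sorted-key JSON."""

    def _coerce(v):
        if isinstance(v, (np.floating, np.integer)):
            return v.item()
        return v

    with open(path, "w") as fh:
        json.dump({k: _coerce(v) for k, v in obj.items()}, fh, indent=2,
                  sort_keys=True)
        fh.write("\n")
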