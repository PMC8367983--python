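"""Reading/writing the tabular formats the pipeline touches.

The central per-read format is the ten-column TSV emitted by the Nanopolish
``polya`` subcommand (one row per sequenced read, with a signal-derived
poly(A)-tail length estimate and a QC tag).  Annotation is 6-column BED with
a seventh biotype column; the sample sheet is a plain TSV mapping read tables
to strain/condition/fraction/replicate.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Exact header of a Nanopolish ``polya`` table, in column order.
POLYA_COLUMNS = (
    "readname",
    "contig",
    "position",
    "leader_start",
    "adapter_start",
    "polya_start",
    "transcript_start",
    "read_rate",
    "polya_length",
    "qc_tag",
)

#: QC-tag vocabulary of Nanopolish polya.
QC_TAGS = frozenset({"PASS", "ADAPTER", "NOREGION", "READ_FAILED_LOAD", "SUFFCLIP"})
QC_FAIL_TAGS = tuple(sorted(QC_TAGS - {"PASS"}))

#: Columns of the in-memory read-record table used throughout the pipeline.
READ_RECORD_COLUMNS = ("read_id", "transcript_id", "position", "polya_length", "qc_tag", "sample_id")

#: Biotype vocabulary carried on annotation features.
BIOTYPES = ("mRNA", "CUT", "SUT", "XUT", "sn_snoRNA", "rRNA", "other_nc")
NONCODING_BIOTYPES = frozenset(BIOTYPES) - {"mRNA"}

#: Biotypes removed outright when building the custom annotation.
DEFAULT_EXCLUDED_BIOTYPES = frozenset({"LTR", "transposon", "tRNA", "replication_origin"})

ANNOTATION_COLUMNS = ("chrom", "start", "end", "feature_id", "score", "strand", "biotype")
SAMPLE_SHEET_COLUMNS = ("sample_id", "strain", "condition", "fraction", "replicate", "path")
FRACTIONS = ("polyA_plus", "total")


class FormatError(ValueError):
    """A file does not conform to its expected tabular schema."""


def read_polya_table(path: str | os.PathLike, sample_id: str) -> pd.DataFrame:
    """Read one Nanopolish polya TSV into a read-record table.

    Parameters
    ----------
    path:
        TSV with the ten-column Nanopolish polya header.
    sample_id:
        Library identifier attached to every record.

    Returns
    -------
    DataFrame with columns ``read_id, transcript_id, position, polya_length,
    qc_tag, sample_id``, one row per input row, input order preserved.
    """
    try:
        raw = pd.read_csv(path, sep="\t", dtype=str, encoding="utf-8")
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file, expected Nanopolish polya header") from None
    missing = [c for c in POLYA_COLUMNS if c not in raw.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s): {', '.join(missing)}")
    lengths = pd.to_numeric(raw["polya_length"], errors="coerce")
    # Nanopolish reports -1/NaN lengths only on failed reads; the record
    # contract requires a finite, non-negative number.
    bad = ~np.isfinite(lengths.to_numpy(dtype=float)) | (lengths.to_numpy(dtype=float) < 0)
    if bad.any():
        # +2: one for the header line, one for 1-based numbering.
        line = int(np.flatnonzero(bad)[0]) + 2
        raise FormatError(f"{path}: unparseable or negative polya_length on line {line}")
    unknown = set(raw["qc_tag"].unique()) - QC_TAGS
    if unknown:
        raise FormatError(f"{path}: unknown qc_tag value(s): {', '.join(sorted(unknown))}")
    return pd.DataFrame(
        {
            "read_id": raw["readname"].to_numpy(),
            "transcript_id": raw["contig"].to_numpy(),
            "position": pd.to_numeric(raw["position"]).astype(np.int64).to_numpy(),
            "polya_length": lengths.astype(float).to_numpy(),
            "qc_tag": raw["qc_tag"].to_numpy(),
            "sample_id": sample_id,
        }
    )


def write_polya_table(records: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a read-record table back out in the Nanopolish polya dialect.

    Columns the record model does not retain (segmentation boundaries and the
    translocation rate) are emitted as ``-1`` placeholders; the retained
    columns round-trip bit-exactly through :func:`read_polya_table`.
    """
    out = pd.DataFrame(
        {
            "readname": records["read_id"].to_numpy(),
            "contig": records["transcript_id"].to_numpy(),
            "position": records["position"].to_numpy(),
            "leader_start": -1,
            "adapter_start": -1,
            "polya_start": -1,
            "transcript_start": -1,
            "read_rate": -1,
            "polya_length": records["polya_length"].to_numpy(),
            "qc_tag": records["qc_tag"].to_numpy(),
        }
    )
    out.to_csv(path, sep="\t", index=False)


def filter_qc_pass(records: pd.DataFrame) -> pd.DataFrame:
    """Keep exactly the records whose QC tag is PASS, order preserved.

    Only PASS estimates carry a trustworthy tail length; every downstream
    statistic is computed on PASS reads only.
    """
    return records.loc[records["qc_tag"] == "PASS"].reset_index(drop=True)


def read_annotation(path: str | os.PathLike) -> pd.DataFrame:
    """Read BED6 + biotype annotation (tab-separated, no header)."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=ANNOTATION_COLUMNS, dtype=str)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=ANNOTATION_COLUMNS)
    df["start"] = pd.to_numeric(df["start"]).astype(np.int64)
    df["end"] = pd.to_numeric(df["end"]).astype(np.int64)
    if (df["end"] <= df["start"]).any():
        raise FormatError(f"{path}: feature with end <= start")
    return df


def write_annotation(features: pd.DataFrame, path: str | os.PathLike) -> None:
    features.loc[:, list(ANNOTATION_COLUMNS)].to_csv(path, sep="\t", header=False, index=False)


def read_sample_sheet(path: str | os.PathLike) -> pd.DataFrame:
    """Read a sample sheet TSV; requires the mandatory columns and unique
    (strain, condition, fraction, replicate)."""
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise FormatError(f"{path}: sample sheet missing column(s): {', '.join(missing)}")
    sheet["replicate"] = pd.to_numeric(sheet["replicate"]).astype(int)
    if "qpcr_coefficient" in sheet.columns:
        sheet["qpcr_coefficient"] = pd.to_numeric(sheet["qpcr_coefficient"]).astype(float)
    else:
        sheet["qpcr_coefficient"] = 1.0
    bad_fraction = set(sheet["fraction"]) - set(FRACTIONS)
    if bad_fraction:
        raise FormatError(f"{path}: unknown fraction value(s): {', '.join(sorted(bad_fraction))}")
    key = sheet[["strain", "condition", "fraction", "replicate"]]
    if key.duplicated().any():
        raise FormatError(f"{path}: duplicate (strain, condition, fraction, replicate) entries")
    # relative read-table paths are resolved against the sheet's directory
    base = os.path.dirname(os.fspath(path))
    sheet["path"] = [p if os.path.isabs(p) else os.path.join(base, p) for p in sheet["path"]]
    return sheet


def write_sample_sheet(sheet: pd.DataFrame, path: str | os.PathLike) -> None:
    sheet.to_csv(path, sep="\t", index=False)


def _merge_noncoding(features: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping same-strand noncoding features into union intervals.

    Feature ids of the constituents are concatenated with ``|`` in coordinate
    order; the merged biotype is the first constituent's. 0-based half-open
    intervals: touching features (end == start) do not overlap.
    """
    merged_rows = []
    for (chrom, strand), block in features.groupby(["chrom", "strand"], sort=True):
        block = block.sort_values(["start", "end"], kind="mergesort")
        cur = None
        for row in block.itertuples(index=False):
            if cur is None or row.start >= cur["end"]:
                if cur is not None:
                    merged_rows.append(cur)
                cur = {
                    "chrom": chrom,
                    "start": row.start,
                    "end": row.end,
                    "feature_id": row.feature_id,
                    "score": row.score,
                    "strand": strand,
                    "biotype": row.biotype,
                }
            else:
                cur["end"] = max(cur["end"], row.end)
                cur["feature_id"] = f"{cur['feature_id']}|{row.feature_id}"
        if cur is not None:
            merged_rows.append(cur)
    return pd.DataFrame(merged_rows, columns=ANNOTATION_COLUMNS)


def build_custom_annotation(
    feature_sets: Sequence[pd.DataFrame] | Iterable[pd.DataFrame],
    min_nc_length: int = 50,
    excluded_biotypes: frozenset[str] | set[str] = DEFAULT_EXCLUDED_BIOTYPES,
) -> pd.DataFrame:
    """Combine annotation sources into one custom feature set.

    The union of the inputs is taken, then features of excluded biotypes (LTRs,
    transposons, tRNAs, replication origins by default) are discarded,
    noncoding features shorter than ``min_nc_length`` (unmappable at DRS read
    lengths) are dropped, and overlapping same-strand noncoding features are
    merged into single union-span features.  mRNAs are exempt from both the
    length filter and the merge.
    """
    frames = [f for f in feature_sets if len(f)]
    if not frames:
        return pd.DataFrame(columns=ANNOTATION_COLUMNS)
    allf = pd.concat(frames, ignore_index=True)
    if (allf["end"] <= allf["start"]).any():
        raise FormatError("annotation feature with end <= start")
    allf = allf.loc[~allf["biotype"].isin(set(excluded_biotypes))]
    is_coding = allf["biotype"] == "mRNA"
    long_enough = (allf["end"] - allf["start"]) >= min_nc_length
    allf = allf.loc[is_coding | long_enough]
    coding = allf.loc[allf["biotype"] == "mRNA"]
    noncoding = _merge_noncoding(allf.loc[allf["biotype"] != "mRNA"])
    out = pd.concat([coding, noncoding], ignore_index=True)
    return out.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
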