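"""Detection filtering, library-size normalization, and expression binning.

Abundances are expressed as library fractions (count / total mapped PASS
reads).  For display the fraction is multiplied by a fixed scale of 1,600,000
— roughly the largest yeast DRS library — so normalized counts read like read
counts; binning and all log2 comparisons operate on the raw fraction, where
the printed bin cutoffs (-10, -12, -14) correspond to fractions 2^-10 etc.
"""

from __future__ import annotations

from enum import Enum
from typing import Mapping

import numpy as np
import pandas as pd

#: Display multiplier for library-fraction counts.
DISPLAY_SCALE = 1_600_000

#: Sentinel written in place of both the normalized count and every tail
#: statistic of a transcript detected by too few reads.
PLACEHOLDER = 0.01

#: Detection threshold: a transcript seen by <= MIN_READS reads is treated as
#: not reliably measured.
MIN_READS = 5


class ExpressionBin(str, Enum):
    """Four expression classes on log2 library fraction.

    high: x >= -10; mod_high: -12 < x < -10; mod_min: -14 < x <= -12;
    minimal: x <= -14.  The value -10 sits in two classes as printed in the
    source convention; it is assigned to the higher bin.
    """

    high = "high"
    mod_high = "mod_high"
    mod_min = "mod_min"
    minimal = "minimal"


#: Bins ordered from highest to lowest expression.
BIN_ORDER = (
    ExpressionBin.high,
    ExpressionBin.mod_high,
    ExpressionBin.mod_min,
    ExpressionBin.minimal,
)

HIGH_CUTOFF = -10.0
MOD_MIN_CUTOFF = -12.0
MINIMAL_CUTOFF = -14.0


def apply_min_read_filter(
    summaries: pd.DataFrame,
    min_reads: int = MIN_READS,
    placeholder: float = PLACEHOLDER,
) -> pd.DataFrame:
    """Mark transcripts detected by <= ``min_reads`` reads as placeholders.

    Flagged rows keep their raw read count (used for the library total) but
    every tail statistic is replaced by the ``placeholder`` sentinel, and a
    ``placeholder_flag`` column is added.  No rows are dropped, so flagged
    transcripts still participate in cross-library comparisons.
    """
    out = summaries.copy()
    flag = out["n_reads"].to_numpy() <= min_reads
    for col in ("mean_tail", "median_tail", "geom_mean_tail"):
        if col in out.columns:
            out.loc[flag, col] = placeholder
    out["placeholder_flag"] = flag
    return out


def normalize_library_size(
    summaries: pd.DataFrame,
    display_scale: float = DISPLAY_SCALE,
    qpcr_coefficient: float = 1.0,
    library_total: int | None = None,
    placeholder: float = PLACEHOLDER,
) -> pd.DataFrame:
    """Convert raw read counts to normalized abundances.

    ``norm_count = raw_count / library_total * display_scale * qpcr_coefficient``
    for detected transcripts; ``log2_abundance`` is taken on the library
    fraction (before display scaling).  The library total is the sum of all
    mapped PASS reads — including reads on transcripts subsequently flagged by
    the detection filter — so normalization is independent of that filter.
    The optional qPCR coefficient corrects libraries whose poly(A)+ yield
    differs systematically between strains.

    Input must come from :func:`apply_min_read_filter` (it needs the
    ``placeholder_flag`` column).  Placeholder rows keep the 0.01 sentinel as
    their norm_count and get no bin.
    """
    if "placeholder_flag" not in summaries.columns:
        raise ValueError("normalize_library_size expects apply_min_read_filter output")
    out = summaries.copy()
    raw = out["n_reads"].to_numpy(dtype=float)
    total = float(np.sum(raw)) if library_total is None else float(library_total)
    if total <= 0:
        raise ValueError("zero library total")
    flag = out["placeholder_flag"].to_numpy(dtype=bool)
    fraction = raw / total * qpcr_coefficient
    out["raw_count"] = out["n_reads"]
    out["norm_count"] = np.where(flag, placeholder, fraction * display_scale)
    out["log2_abundance"] = np.where(flag, np.nan, np.log2(np.where(fraction > 0, fraction, np.nan)))
    out["bin"] = [None if f else bin_by_expression(a).value for f, a in zip(flag, out["log2_abundance"])]
    return out


def bin_by_expression(log2_abundance: float) -> ExpressionBin:
    """Assign one log2 library-fraction value to its expression bin."""
    x = float(log2_abundance)
    if not np.isfinite(x):
        raise ValueError("bin_by_expression requires a finite log2 abundance")
    if x >= HIGH_CUTOFF:
        return ExpressionBin.high
    if x > MOD_MIN_CUTOFF:
        return ExpressionBin.mod_high
    if x > MINIMAL_CUTOFF:
        return ExpressionBin.mod_min
    return ExpressionBin.minimal


def ncrna_load_ratio(
    summaries: pd.DataFrame,
    biotypes: Mapping[str, str] | None = None,
) -> dict[str, float]:
    """Per-class ncRNA read load relative to the protein-coding load.

    For each noncoding biotype present, returns (sum of raw counts at loci of
    that class) / (sum of raw counts at mRNA loci).  Annotated loci with zero
    detected reads contribute zero to the numerator, so undetected classes
    yield 0.  The biotype column of ``summaries`` is used unless an explicit
    mapping is given.
    """
    counts = summaries["n_reads"].to_numpy(dtype=float)
    if biotypes is not None:
        bt = summaries["transcript_id"].map(biotypes).fillna("mRNA")
        classes = set(biotypes.values())  # annotated classes, detected or not
    else:
        bt = summaries["biotype"]
        classes = set(bt)
    mrna_total = float(counts[(bt == "mRNA").to_numpy()].sum())
    if mrna_total <= 0:
        raise ValueError("no protein-coding reads: zero denominator")
    ratios: dict[str, float] = {}
    for biotype in sorted(classes - {"mRNA"}):
        ratios[biotype] = float(counts[(bt == biotype).to_numpy()].sum()) / mrna_total
    return ratios
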