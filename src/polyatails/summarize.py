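"""Per-transcript tail-length summaries and replicate pooling.

Every statistic is computed over QC-PASS reads only; callers are expected to
have applied :func:`polyatails.io.filter_qc_pass` first.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Floor applied to tail lengths before the geometric mean, so zero-length
#: tails do not annihilate it.  Matches the pipeline-wide 0.01 placeholder
#: scale used for undetected transcripts.
GEOMEAN_FLOOR = 0.01

SUMMARY_COLUMNS = (
    "transcript_id",
    "biotype",
    "n_reads",
    "mean_tail",
    "median_tail",
    "geom_mean_tail",
    "sample_id",
)


def summarize_transcripts(
    records: pd.DataFrame,
    biotypes: Mapping[str, str] | None = None,
    sample_id: str | None = None,
) -> pd.DataFrame:
    """Collapse read records to one summary row per transcript.

    Reports read count, arithmetic mean, median (mean-of-middle-two for even
    n), and geometric mean (computed after flooring each tail at
    :data:`GEOMEAN_FLOOR`) of the per-read tail-length estimates.

    Parameters
    ----------
    records:
        Read-record table (QC-filtered).
    biotypes:
        Optional transcript_id -> biotype mapping; unknown ids get "mRNA".
    sample_id:
        Label for the output; defaults to the (unique) sample_id of the input.
    """
    if len(records) == 0:
        return pd.DataFrame(columns=SUMMARY_COLUMNS)
    if sample_id is None:
        ids = records["sample_id"].unique()
        sample_id = ids[0] if len(ids) == 1 else "+".join(sorted(ids))
    tails = records["polya_length"].to_numpy(dtype=float)
    grouped = pd.DataFrame({"transcript_id": records["transcript_id"].to_numpy(), "tail": tails})
    agg = grouped.groupby("transcript_id", sort=True)["tail"].agg(
        n_reads="size",
        mean_tail="mean",
        median_tail="median",
        geom_mean_tail=lambda t: float(np.exp(np.mean(np.log(np.maximum(t, GEOMEAN_FLOOR))))),
    )
    out = agg.reset_index()
    out["biotype"] = (
        out["transcript_id"].map(biotypes).fillna("mRNA") if biotypes is not None else "mRNA"
    )
    out["sample_id"] = sample_id
    return out.loc[:, list(SUMMARY_COLUMNS)]


def pool_replicates(
    replicate_records: Sequence[pd.DataFrame],
    fractions: Sequence[str] | None = None,
    pooled_id: str | None = None,
) -> pd.DataFrame:
    """Concatenate replicate read tables of one strain/condition/fraction.

    Pooling happens at read level — counts add and tail statistics computed
    downstream are read-depth weighted.  Mixing RNA fractions (poly(A)+ with
    total) is refused because their tail distributions are not comparable.
    """
    if len(replicate_records) == 0:
        raise ValueError("pool_replicates requires at least one replicate")
    if fractions is not None and len(set(fractions)) > 1:
        raise ValueError(f"cannot pool replicates from different fractions: {sorted(set(fractions))}")
    pooled = pd.concat(list(replicate_records), ignore_index=True)
    if pooled_id is not None:
        pooled = pooled.assign(sample_id=pooled_id)
    return pooled


def tail_quantile(tails: pd.DataFrame | np.ndarray | Sequence[float], q: float) -> float:
    """Empirical tail-length quantile (linear interpolation convention).

    With ``q=0.995`` this reports the practical upper limit of a gene set's
    tail lengths, robust to the single longest reads.
    """
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0, 1)")
    if isinstance(tails, pd.DataFrame):
        values = tails["polya_length"].to_numpy(dtype=float)
    else:
        values = np.asarray(tails, dtype=float)
    if values.size == 0:
        raise ValueError("tail_quantile requires at least one tail")
    return float(np.quantile(values, q))
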