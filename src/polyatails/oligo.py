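"""Calling mRNAs with a substantial oligoadenylated fraction.

Oligo-(dT) selection loses molecules with very short (~<10 A) tails.  A
transcript with a sizeable short-tailed subpopulation therefore shows up in a
total-RNA DRS library as (i) more abundant and (ii) shorter-tailed than in the
matched poly(A)+ library.  The caller flags transcripts satisfying both
criteria: abundance more than 1.2-fold up in total vs poly(A)+, and a mean
tail decrease exceeding an expression-bin-specific noise cutoff.

The cutoffs are the typical replicate-to-replicate standard deviations of the
per-transcript mean-tail estimate; precision degrades with expression, so one
cutoff is computed per expression bin.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .normalize import BIN_ORDER, ExpressionBin, bin_by_expression

#: Default fold threshold for total vs poly(A)+ abundance.
FOLD_THRESHOLD = 1.2

#: Reference per-bin cutoffs (adenosines, positive magnitudes) derived from
#: nine wild-type replicate libraries of the original yeast DRS study; use
#: these to apply the published rule when replicate data are unavailable.
DEFAULT_BIN_SD_CUTOFFS: dict[ExpressionBin, float] = {
    ExpressionBin.high: 1.727579,
    ExpressionBin.mod_high: 2.080906,
    ExpressionBin.mod_min: 2.763902,
    ExpressionBin.minimal: 4.157491,
}

OLIGO_CALL_COLUMNS = (
    "transcript_id",
    "fold_change_total_vs_polyA",
    "delta_mean_tail",
    "bin",
    "cutoff_used",
    "flagged",
)


def compute_bin_sd_cutoffs(
    replicate_summaries: Sequence[pd.DataFrame],
    aggregate: str = "mean",
) -> dict[ExpressionBin, float]:
    """Estimate the per-bin mean-tail noise cutoffs from replicate libraries.

    For every transcript detected (non-placeholder) in at least two replicate
    libraries, the sample SD of its per-replicate mean-tail estimates is
    taken; each expression bin's cutoff is then the mean (or, with
    ``aggregate="pooled"``, the root-mean-square) of those per-transcript SDs
    over the transcripts the bin contains.  Bin assignment uses the
    transcript's log2 abundance averaged over the replicates.

    Parameters
    ----------
    replicate_summaries:
        >= 2 normalized summary tables (outputs of
        :func:`polyatails.normalize.normalize_library_size`) from replicate
        libraries of the reference strain.
    aggregate:
        "mean" (default) or "pooled".

    Raises
    ------
    ValueError
        With fewer than two replicates, if a bin has no transcript detected in
        >= 2 replicates, or if a bin's cutoff degenerates to zero.
    """
    if len(replicate_summaries) < 2:
        raise ValueError("compute_bin_sd_cutoffs requires >= 2 replicate libraries")
    if aggregate not in {"mean", "pooled"}:
        raise ValueError(f"unknown aggregate: {aggregate!r}")
    detected = pd.concat(
        [s.loc[~s["placeholder_flag"], ["transcript_id", "mean_tail", "log2_abundance"]]
         for s in replicate_summaries],
        ignore_index=True,
    )
    per_transcript = detected.groupby("transcript_id").agg(
        n=("mean_tail", "size"),
        sd=("mean_tail", lambda v: float(np.std(v, ddof=1)) if len(v) > 1 else np.nan),
        log2_abundance=("log2_abundance", "mean"),
    )
    per_transcript = per_transcript.loc[per_transcript["n"] >= 2]
    cutoffs: dict[ExpressionBin, float] = {}
    bins = per_transcript["log2_abundance"].map(lambda a: bin_by_expression(a))
    for bin_ in BIN_ORDER:
        sds = per_transcript.loc[(bins == bin_).to_numpy(), "sd"].to_numpy(dtype=float)
        if sds.size == 0:
            raise ValueError(f"no transcript detected in >=2 replicates in bin {bin_.value}")
        cutoff = float(np.mean(sds)) if aggregate == "mean" else float(np.sqrt(np.mean(sds**2)))
        if cutoff <= 0:
            raise ValueError(f"degenerate (zero) cutoff in bin {bin_.value}")
        cutoffs[bin_] = cutoff
    return cutoffs


def call_oligo_fraction(
    total: pd.DataFrame,
    polya: pd.DataFrame,
    cutoffs: Mapping[ExpressionBin, float] | None = None,
    fold_threshold: float = FOLD_THRESHOLD,
) -> pd.DataFrame:
    """Flag transcripts with a substantial oligoadenylated fraction.

    Only transcripts detected (non-placeholder) in both the total and the
    poly(A)+ library are evaluated.  A transcript is flagged when its
    normalized abundance is more than ``fold_threshold``-fold higher in total
    than in poly(A)+ AND its mean tail in total is below the poly(A)+ value by
    at least the cutoff of its expression bin (bin taken from the poly(A)+
    library, the reference fraction).

    Parameters
    ----------
    total, polya:
        Normalized summary tables for the two fractions of one strain.
    cutoffs:
        ExpressionBin -> positive cutoff magnitude in adenosines; defaults to
        :data:`DEFAULT_BIN_SD_CUTOFFS`.

    Returns
    -------
    One row per evaluated transcript with the decision columns
    ``fold_change_total_vs_polyA, delta_mean_tail, bin, cutoff_used, flagged``.
    """
    if cutoffs is None:
        cutoffs = DEFAULT_BIN_SD_CUTOFFS
    cutoffs = {ExpressionBin(k): float(v) for k, v in cutoffs.items()}
    missing = [b.value for b in BIN_ORDER if b not in cutoffs]
    if missing:
        raise ValueError(f"missing bin cutoff(s): {', '.join(missing)}")
    t = total.loc[~total["placeholder_flag"]].set_index("transcript_id")
    p = polya.loc[~polya["placeholder_flag"]].set_index("transcript_id")
    shared = t.index.intersection(p.index)
    t = t.loc[shared]
    p = p.loc[shared]
    fold = t["norm_count"].to_numpy(dtype=float) / p["norm_count"].to_numpy(dtype=float)
    delta = t["mean_tail"].to_numpy(dtype=float) - p["mean_tail"].to_numpy(dtype=float)
    bins = [ExpressionBin(b) for b in p["bin"]]
    cut = np.array([cutoffs[b] for b in bins], dtype=float)
    flagged = (fold > fold_threshold) & (delta <= -cut)
    return pd.DataFrame(
        {
            "transcript_id": shared.to_numpy(),
            "fold_change_total_vs_polyA": fold,
            "delta_mean_tail": delta,
            "bin": [b.value for b in bins],
            "cutoff_used": cut,
            "flagged": flagged,
        },
        columns=list(OLIGO_CALL_COLUMNS),
    )
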