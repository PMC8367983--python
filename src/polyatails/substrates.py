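"""Strain-vs-strain tail/abundance deltas and nuclease-substrate classes.

Replicate-to-replicate comparisons of wild-type libraries show per-transcript
mean-tail estimates oscillating within roughly +/-10 adenosines, so a mean
tail at least 10 A longer in a nuclease-deficient strain than in its matched
control marks the transcript as a confident substrate of that nuclease.
Combining the flags from exosome-depleted (Dis3/Rrp6) and deadenylase-deleted
(pan2, ccr4) strains partitions the annotated mRNA set into substrate
categories.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Set

import numpy as np
import pandas as pd

#: Minimum mean-tail elongation (adenosines) to call a confident substrate.
ELONGATION_THRESHOLD = 10.0

CATEGORIES = ("exosome_only", "cytoplasmic_only", "both", "unaffected", "undetected")

DELTA_COLUMNS = ("transcript_id", "delta_mean_tail", "log2_fold_change_abundance")


def compute_deltas(mutant: pd.DataFrame, reference: pd.DataFrame) -> pd.DataFrame:
    """Per-transcript mean-tail and abundance change, mutant minus reference.

    Only transcripts detected (non-placeholder) in both normalized tables are
    emitted; the abundance change is the log2 ratio of normalized counts.
    """
    m = mutant.loc[~mutant["placeholder_flag"]].set_index("transcript_id")
    r = reference.loc[~reference["placeholder_flag"]].set_index("transcript_id")
    shared = m.index.intersection(r.index)
    m = m.loc[shared]
    r = r.loc[shared]
    return pd.DataFrame(
        {
            "transcript_id": shared.to_numpy(),
            "delta_mean_tail": m["mean_tail"].to_numpy(dtype=float)
            - r["mean_tail"].to_numpy(dtype=float),
            "log2_fold_change_abundance": np.log2(
                m["norm_count"].to_numpy(dtype=float) / r["norm_count"].to_numpy(dtype=float)
            ),
        },
        columns=list(DELTA_COLUMNS),
    )


def flag_strong_targets(
    deltas: pd.DataFrame, elongation_threshold: float = ELONGATION_THRESHOLD
) -> set[str]:
    """Transcripts whose mean tail grew by at least the threshold (inclusive)."""
    hit = deltas["delta_mean_tail"].to_numpy(dtype=float) >= elongation_threshold
    return set(deltas.loc[hit, "transcript_id"])


@dataclass(frozen=True)
class SubstrateCounts:
    exosome_only: int
    cytoplasmic_only: int
    both: int
    unaffected: int
    undetected: int

    @property
    def substrates(self) -> int:
        return self.exosome_only + self.cytoplasmic_only + self.both

    @property
    def total(self) -> int:
        return self.substrates + self.unaffected + self.undetected


def classify_substrates(
    exosome_set: Set[str],
    pan2_set: Set[str],
    ccr4_set: Set[str],
    detected_set: Set[str],
    annotated_mrnas: Iterable[str],
) -> pd.DataFrame:
    """Partition annotated mRNAs into nuclease-substrate categories.

    The cytoplasmic-deadenylase set is the union of pan2 and ccr4 targets.
    Categories: ``exosome_only``, ``cytoplasmic_only``, ``both`` (exosome and
    at least one cytoplasmic deadenylase), ``unaffected`` (detected, no flag),
    ``undetected`` (annotated but not reliably detected by DRS).
    """
    annotated = list(dict.fromkeys(annotated_mrnas))
    universe = set(annotated)
    for name, s in (
        ("exosome_set", exosome_set),
        ("pan2_set", pan2_set),
        ("ccr4_set", ccr4_set),
        ("detected_set", detected_set),
    ):
        stray = set(s) - universe
        if stray:
            raise ValueError(f"{name} contains ids outside the annotation: {sorted(stray)[:5]}")
    cyto = set(pan2_set) | set(ccr4_set)
    rows = []
    for tid in annotated:
        exo = tid in exosome_set
        cy = tid in cyto
        if tid not in detected_set:
            category = "undetected"
        elif exo and cy:
            category = "both"
        elif exo:
            category = "exosome_only"
        elif cy:
            category = "cytoplasmic_only"
        else:
            category = "unaffected"
        rows.append(
            {
                "transcript_id": tid,
                "exosome_target": exo,
                "pan2_target": tid in pan2_set,
                "ccr4_target": tid in ccr4_set,
                "category": category,
            }
        )
    return pd.DataFrame(rows)


def count_categories(classification: pd.DataFrame) -> SubstrateCounts:
    counts = classification["category"].value_counts()
    return SubstrateCounts(**{c: int(counts.get(c, 0)) for c in CATEGORIES})


def substrate_fractions(
    counts: SubstrateCounts | pd.DataFrame,
    n_annotated: int | None = None,
    n_detected: int | None = None,
) -> dict[str, float]:
    """Percentages of detected and of annotated mRNAs that are substrates.

    Accepts either a classification table or pre-tallied
    :class:`SubstrateCounts`.  ``n_annotated`` defaults to the category total
    and ``n_detected`` to substrates + unaffected; both can be given
    explicitly, e.g. when recomputing percentages from published counts.
    """
    if isinstance(counts, pd.DataFrame):
        counts = count_categories(counts)
    if n_detected is None:
        n_detected = counts.substrates + counts.unaffected
    if n_annotated is None:
        n_annotated = counts.total
    if n_annotated < n_detected:
        raise ValueError("n_annotated smaller than the detected count")
    if n_detected == 0 or n_annotated == 0:
        raise ValueError("zero denominator in substrate_fractions")
    return {
        "pct_of_detected": 100.0 * counts.substrates / n_detected,
        "pct_of_annotated": 100.0 * counts.substrates / n_annotated,
    }
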