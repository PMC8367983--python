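"""End-to-end orchestration: ingest -> QC -> pool -> summarize -> normalize ->
oligo calling -> substrate classification -> group statistics.

Stages are plain functions over pandas tables so they compose identically
whether run one at a time (CLI subcommands) or through :func:`run_pipeline`,
which additionally writes TSV outputs and a JSON run manifest with config and
input checksums for reproducibility.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from . import io as pio
from . import normalize as norm
from . import oligo as oligo_mod
from . import stats as stats_mod
from . import substrates as sub
from .summarize import pool_replicates, summarize_transcripts

log = logging.getLogger("polyatails")


@dataclass
class RunConfig:
    """All paths and analysis constants for one pipeline run."""

    sample_sheet: str
    annotation: str | None
    outdir: str
    min_reads: int = norm.MIN_READS
    placeholder: float = norm.PLACEHOLDER
    display_scale: float = norm.DISPLAY_SCALE
    fold_threshold: float = oligo_mod.FOLD_THRESHOLD
    elongation_threshold: float = sub.ELONGATION_THRESHOLD
    quantile: float = 0.995
    cutoffs: str | dict = "default"  # "default", "auto", or bin -> adenosines
    reference_strain: str = "WT"
    exosome_strains: tuple = ()
    pan2_strain: str | None = None
    ccr4_strain: str | None = None
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        for name in ("min_reads", "placeholder", "display_scale", "fold_threshold",
                     "elongation_threshold", "quantile"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def ingest_and_pool(sheet: pd.DataFrame) -> dict:
    """Read, QC-filter, and replicate-pool every library in the sample sheet.

    Returns ``(strain, condition, fraction) -> (pooled records, qpcr coeff)``.
    Replicates of one group must share their qPCR coefficient.
    """
    missing = [p for p in sheet["path"] if not Path(p).exists()]
    if missing:
        raise FileNotFoundError(f"sample sheet references missing file(s): {missing}")
    pooled: dict = {}
    for (strain, condition, fraction), group in sheet.groupby(
        ["strain", "condition", "fraction"], sort=True
    ):
        tables = [
            pio.filter_qc_pass(pio.read_polya_table(row.path, row.sample_id))
            for row in group.itertuples(index=False)
        ]
        coeffs = set(float(c) for c in group["qpcr_coefficient"])
        if len(coeffs) > 1:
            raise ValueError(
                f"replicates of {strain}/{condition}/{fraction} disagree on qpcr_coefficient"
            )
        pooled_id = f"{strain}__{condition}__{fraction}"
        pooled[(strain, condition, fraction)] = (
            pool_replicates(tables, fractions=[fraction] * len(tables), pooled_id=pooled_id),
            coeffs.pop(),
        )
    return pooled


def normalized_tables(
    pooled: dict, biotypes: dict | None, config: RunConfig
) -> dict:
    """Summarize and normalize each pooled library."""
    out = {}
    for key, (records, coeff) in pooled.items():
        summaries = summarize_transcripts(records, biotypes=biotypes)
        filtered = norm.apply_min_read_filter(
            summaries, min_reads=config.min_reads, placeholder=config.placeholder
        )
        out[key] = norm.normalize_library_size(
            filtered,
            display_scale=config.display_scale,
            qpcr_coefficient=coeff,
            placeholder=config.placeholder,
        )
    return out


def resolve_cutoffs(config: RunConfig, tables: dict) -> dict:
    """Turn the cutoffs setting into an ExpressionBin -> adenosines mapping.

    "default" uses the published per-bin SDs; "auto" recomputes them from the
    reference strain's poly(A)+ replicate libraries (requires >= 2 replicates
    in ``tables`` under distinct conditions); a mapping is used as given.
    """
    if config.cutoffs == "default":
        return dict(oligo_mod.DEFAULT_BIN_SD_CUTOFFS)
    if config.cutoffs == "auto":
        refs = [t for (s, _c, f), t in tables.items()
                if s == config.reference_strain and f == "polyA_plus"]
        return oligo_mod.compute_bin_sd_cutoffs(refs)
    return {norm.ExpressionBin(k): float(v) for k, v in dict(config.cutoffs).items()}


def run_pipeline(config: RunConfig) -> dict:
    """Execute every applicable stage and write the report bundle.

    Returns the manifest dictionary.  On error, files already written for
    this run are removed so a failed run leaves no partial bundle.
    """
    config.validate()
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    sheet = pio.read_sample_sheet(config.sample_sheet)
    biotypes = None
    if config.annotation:
        ann = pio.read_annotation(config.annotation)
        biotypes = dict(zip(ann["feature_id"], ann["biotype"]))
    pooled = ingest_and_pool(sheet)  # validates inputs before any output
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(frame: pd.DataFrame, name: str) -> None:
        p = outdir / name
        frame.to_csv(p, sep="\t", index=False)
        written.append(p)

    try:
        tables = normalized_tables(pooled, biotypes, config)
        for (strain, condition, fraction), table in tables.items():
            emit(table, f"normalized.{strain}.{condition}.{fraction}.tsv")

        oligo_frames = []
        by_strain_cond: dict = {}
        for (strain, condition, fraction), table in tables.items():
            by_strain_cond.setdefault((strain, condition), {})[fraction] = table
        for (strain, condition), fr in sorted(by_strain_cond.items()):
            if {"total", "polyA_plus"} <= set(fr):
                cutoffs = resolve_cutoffs(config, tables)
                calls = oligo_mod.call_oligo_fraction(
                    fr["total"], fr["polyA_plus"], cutoffs, config.fold_threshold
                )
                calls.insert(0, "strain", strain)
                calls.insert(1, "condition", condition)
                oligo_frames.append(calls)
        if oligo_frames:
            emit(pd.concat(oligo_frames, ignore_index=True), "oligo_calls.tsv")

        polya = {s: t for (s, _c, f), t in sorted(tables.items()) if f == "polyA_plus"}
        classification = None
        if config.reference_strain in polya:
            ref = polya[config.reference_strain]

            def strong(strain: str) -> set:
                deltas = sub.compute_deltas(polya[strain], ref)
                return sub.flag_strong_targets(deltas, config.elongation_threshold)

            roles = {
                "exosome": [s for s in config.exosome_strains if s in polya],
                "pan2": [config.pan2_strain] if config.pan2_strain in polya else [],
                "ccr4": [config.ccr4_strain] if config.ccr4_strain in polya else [],
            }
            if any(roles.values()):
                mrnas = (
                    ref.loc[ref["biotype"] == "mRNA", "transcript_id"] if biotypes else ref["transcript_id"]
                )
                annotated = list(mrnas)
                universe = set(annotated)
                detected = set(ref.loc[~ref["placeholder_flag"], "transcript_id"]) & universe
                for strains in roles.values():
                    for s in strains:
                        t = polya[s]
                        detected &= set(t.loc[~t["placeholder_flag"], "transcript_id"])
                sets = {
                    role: set().union(*(strong(s) for s in strains)) & detected if strains else set()
                    for role, strains in roles.items()
                }
                classification = sub.classify_substrates(
                    sets["exosome"], sets["pan2"], sets["ccr4"], detected, annotated
                )
                emit(classification, "substrate_classification.tsv")
                counts = sub.count_categories(classification)
                emit(
                    pd.DataFrame([dataclasses.asdict(counts) | sub.substrate_fractions(counts)]),
                    "substrate_counts.tsv",
                )

        stats_frame = _strain_stats(polya)
        if stats_frame is not None:
            emit(stats_frame, "group_stats.tsv")

        manifest = {
            "package": "polyatails",
            "version": __version__,
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in dataclasses.asdict(config).items()},
            "inputs": {
                str(p): _sha256(p)
                for p in [config.sample_sheet]
                + ([config.annotation] if config.annotation else [])
                + list(sheet["path"])
            },
            "outputs": sorted(p.name for p in written),
        }
        manifest_path = outdir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        written.append(manifest_path)
        return manifest
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise


def _strain_stats(polya: dict) -> pd.DataFrame | None:
    """Kruskal-Wallis + Dunn/Holm family over per-transcript mean tails of
    transcripts detected in every poly(A)+ library."""
    if len(polya) < 2:
        return None
    detected = None
    for table in polya.values():
        ids = set(table.loc[~table["placeholder_flag"], "transcript_id"])
        detected = ids if detected is None else detected & ids
    if not detected or sum(len(detected) for _ in polya) < 3:
        return None
    labels = sorted(polya)
    groups = []
    for s in labels:
        t = polya[s].set_index("transcript_id")
        groups.append(t.loc[sorted(detected), "mean_tail"].to_numpy(dtype=float))
    result, pairs = stats_mod.compare_groups(groups, labels)
    rows = [
        {
            "comparison": "omnibus",
            "group_a": "",
            "group_b": "",
            "statistic": result.H,
            "p_raw": result.p_value,
            "p_holm": result.p_value,
            "epsilon_sq": result.epsilon_sq,
            "n_total": result.n_total,
            "significant": result.p_value <= stats_mod.SIGNIFICANCE_LEVEL,
        }
    ]
    for pr in pairs:
        rows.append(
            {
                "comparison": "dunn",
                "group_a": pr.group_a,
                "group_b": pr.group_b,
                "statistic": pr.z,
                "p_raw": pr.p_raw,
                "p_holm": pr.p_holm,
                "epsilon_sq": float("nan"),
                "n_total": result.n_total,
                "significant": pr.significant,
            }
        )
    return pd.DataFrame(rows)
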