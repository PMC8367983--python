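"""Seeded synthetic DRS poly(A) datasets with known ground truth.

The generator emulates the statistical structure of yeast direct-RNA-seq
tail-length libraries so every downstream stage can be exercised and
validated without sequencing data:

* per-transcript expression spread over several log2 decades (log-normal
  weights; read counts multinomial over the weights);
* steady-state mean tails that shorten with expression (linear interpolation
  in log2 expression between a short high-expression mean, ~30 A, and a long
  low-expression mean, ~55 A), around a global mean of ~40 A;
* "de novo" strains (export-blocked, so tails reflect nuclear polyadenylation
  only) drawing from a truncated normal with mean 50 A capped at 200 A;
* mutant strains applying an additive tail shift and an abundance fold factor
  to a designated target-transcript set;
* a short-tailed (oligoadenylated, < ~10 A) subpopulation on a subset of
  transcripts, and logistic tail-dependent retention modelling oligo-(dT)
  capture for paired total vs poly(A)+ libraries;
* additive Gaussian per-read estimation noise floored at 0, non-PASS QC tags,
  and spike-in reads of designed lengths.

Each sample file gets its own RNG stream keyed by (seed, sample id), so
adding a sample never perturbs the others; identical config + seed gives
byte-identical outputs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import truncnorm

from . import io as pio

__all__ = [
    "TailEffect",
    "SimConfig",
    "GroundTruth",
    "SimulatedExperiment",
    "simulate_experiment",
    "simulate_total_vs_polyA",
    "simulate_spikeins",
    "write_experiment",
]


@dataclass(frozen=True)
class TailEffect:
    """Effect of one mutant strain on its target transcripts."""

    targets: frozenset
    tail_shift: float = 0.0  # adenosines, additive on the mean
    abundance_fold: float = 1.0  # multiplies expression weight


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the synthetic experiment (see module docstring).

    Length parameters are in adenosines.  ``reads_per_replicate=None`` derives
    the library size so the least-expressed transcript expects
    ``min_expected_reads`` reads.
    """

    n_transcripts: int = 1000
    expression_log2_mean: float = 0.0
    expression_log2_sd: float = 2.0
    wt_tail_mean_high: float = 30.0  # mean tail at the highest expression
    wt_tail_mean_low: float = 55.0  # mean tail at the lowest expression
    tail_sd: float = 10.0  # within-transcript biological spread
    denovo_mean: float = 50.0
    denovo_cap: float = 200.0
    oligo_transcript_fraction: float = 0.1
    oligo_weight: float = 0.4  # per-read probability of the oligo component
    oligo_tail_max: float = 9.0
    capture_midpoint: float = 10.0  # adenosines
    capture_steepness: float = 2.0  # per adenosine; may be numpy.inf
    estimation_noise_sd: float = 5.0
    qc_fail_rate: float = 0.1
    strains: tuple = ("WT",)
    denovo_strains: frozenset = frozenset()
    effect_map: Mapping[str, TailEffect] = field(default_factory=dict)
    n_replicates: int = 2
    reads_per_replicate: int | None = None
    min_expected_reads: int = 50
    ncrna_fractions: Mapping[str, float] = field(default_factory=dict)
    spikein_lengths: tuple = (10, 20, 30, 40, 50, 60, 70, 80, 90)
    seed: int = 0

    def validate(self) -> None:
        if self.n_transcripts <= 0:
            raise ValueError("n_transcripts must be positive")
        for name in (
            "wt_tail_mean_high",
            "wt_tail_mean_low",
            "tail_sd",
            "denovo_mean",
            "denovo_cap",
            "oligo_tail_max",
            "capture_midpoint",
            "estimation_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.denovo_cap < self.denovo_mean:
            raise ValueError("denovo_cap must be >= denovo_mean")
        if not 0.0 <= self.oligo_weight <= 1.0:
            raise ValueError("oligo_weight must lie in [0, 1]")
        if not 0.0 <= self.qc_fail_rate < 1.0:
            raise ValueError("qc_fail_rate must lie in [0, 1)")
        if self.capture_steepness <= 0:
            raise ValueError("capture_steepness must be positive")
        if len(self.spikein_lengths) and min(self.spikein_lengths) <= 0:
            raise ValueError("spike-in lengths must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """Planted truth for one simulated experiment.

    ``per_transcript`` has one row per (strain, transcript): the true
    noise-free mean tail, expression weight, target/oligo status.
    """

    per_transcript: pd.DataFrame
    library_sizes: dict
    spikein_lengths: tuple

    def targets(self, strain: str) -> set:
        df = self.per_transcript
        return set(df.loc[(df["strain"] == strain) & df["is_target"], "transcript_id"])

    def oligo_transcripts(self) -> set:
        df = self.per_transcript
        return set(df.loc[df["is_oligo"], "transcript_id"])

    def expected_global_mean_tail(self, strain: str) -> float:
        """Read-weighted true mean tail for one strain's libraries."""
        df = self.per_transcript[self.per_transcript["strain"] == strain]
        w = df["expression_weight"].to_numpy()
        return float(np.sum(w * df["true_mean_tail"].to_numpy()) / np.sum(w))


@dataclass(frozen=True)
class SimulatedExperiment:
    reads: dict  # sample_id -> read-record DataFrame
    annotation: pd.DataFrame
    sample_sheet: pd.DataFrame
    truth: GroundTruth


def _sample_rng(seed: int, sample_id: str, stream: int = 0) -> np.random.Generator:
    """Independent, reproducible stream per sample file."""
    return np.random.default_rng([seed, zlib.crc32(sample_id.encode()), stream])


def _transcript_layout(cfg: SimConfig, rng: np.random.Generator):
    """Transcript ids, biotypes, expression weights, and baseline tail means."""
    ids = np.array([f"T{i:05d}" for i in range(cfg.n_transcripts)])
    biotypes = np.full(cfg.n_transcripts, "mRNA", dtype=object)
    if cfg.ncrna_fractions:
        order = rng.permutation(cfg.n_transcripts)
        pos = 0
        for biotype, frac in sorted(cfg.ncrna_fractions.items()):
            k = int(round(frac * cfg.n_transcripts))
            biotypes[order[pos : pos + k]] = biotype
            pos += k
    log2_expr = rng.normal(cfg.expression_log2_mean, cfg.expression_log2_sd, cfg.n_transcripts)
    weights = np.exp2(log2_expr)
    if cfg.n_transcripts > 1 and log2_expr.max() > log2_expr.min():
        frac_up = (log2_expr - log2_expr.min()) / (log2_expr.max() - log2_expr.min())
    else:
        frac_up = np.ones(cfg.n_transcripts)
    base_mean = cfg.wt_tail_mean_low + frac_up * (cfg.wt_tail_mean_high - cfg.wt_tail_mean_low)
    return ids, biotypes, weights, base_mean


def _annotation_frame(ids: np.ndarray, biotypes: np.ndarray) -> pd.DataFrame:
    n = len(ids)
    starts = np.arange(n, dtype=np.int64) * 2000
    return pd.DataFrame(
        {
            "chrom": "chr_sim",
            "start": starts,
            "end": starts + 1500,
            "feature_id": ids,
            "score": ".",
            "strand": "+",
            "biotype": biotypes,
        }
    )


def _draw_strain_tails(
    cfg: SimConfig,
    strain: str,
    counts: np.ndarray,
    strain_means: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Noise-free per-read component tails for one library, transcript-ordered."""
    n_reads = int(counts.sum())
    if strain in cfg.denovo_strains:
        if cfg.tail_sd == 0:
            tails = np.full(n_reads, float(np.clip(cfg.denovo_mean, 0, cfg.denovo_cap)))
        else:
            a = (0.0 - cfg.denovo_mean) / cfg.tail_sd
            b = (cfg.denovo_cap - cfg.denovo_mean) / cfg.tail_sd
            tails = truncnorm.rvs(
                a, b, loc=cfg.denovo_mean, scale=cfg.tail_sd, size=n_reads, random_state=rng
            )
    else:
        means = np.repeat(strain_means, counts)
        tails = np.maximum(rng.normal(means, cfg.tail_sd) if cfg.tail_sd > 0 else means, 0.0)
    return np.asarray(tails, dtype=float)


def _finish_reads(
    cfg: SimConfig,
    sample_id: str,
    transcript_ids: np.ndarray,
    tails: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Apply estimation noise and QC tags; assemble the read-record frame."""
    n = len(tails)
    estimates = tails.copy()
    if cfg.estimation_noise_sd > 0:
        estimates = estimates + rng.normal(0.0, cfg.estimation_noise_sd, n)
    estimates = np.maximum(estimates, 0.0)
    qc = np.full(n, "PASS", dtype=object)
    if cfg.qc_fail_rate > 0 and n:
        fail = rng.random(n) < cfg.qc_fail_rate
        qc[fail] = rng.choice(pio.QC_FAIL_TAGS, size=int(fail.sum()))
    return pd.DataFrame(
        {
            "read_id": [f"{sample_id}_r{i:08d}" for i in range(n)],
            "transcript_id": transcript_ids,
            "position": 0,
            "polya_length": np.round(estimates, 2),
            "qc_tag": qc,
            "sample_id": sample_id,
        }
    )


def _library_size(cfg: SimConfig, weights: np.ndarray) -> int:
    if cfg.reads_per_replicate is not None:
        return int(cfg.reads_per_replicate)
    return int(np.ceil(cfg.min_expected_reads * weights.sum() / weights.min()))


def simulate_experiment(cfg: SimConfig) -> SimulatedExperiment:
    """Generate one full multi-strain, replicated poly(A)+ experiment.

    For each strain and replicate: read counts per transcript are multinomial
    over the (effect-adjusted) expression weights; component tails come from
    the strain's tail model; estimation noise and QC tags are added per read.
    Returns the in-memory tables plus the planted :class:`GroundTruth`;
    :func:`write_experiment` serializes them.
    """
    cfg.validate()
    master = _sample_rng(cfg.seed, "__layout__")
    ids, biotypes, weights, base_mean = _transcript_layout(cfg, master)
    known = set(ids)
    for strain, effect in cfg.effect_map.items():
        stray = set(effect.targets) - known
        if stray:
            raise ValueError(f"effect_map[{strain!r}] references unknown transcripts: {sorted(stray)[:5]}")

    reads: dict = {}
    sheet_rows = []
    truth_rows = []
    library_sizes: dict = {}
    for strain in cfg.strains:
        effect = cfg.effect_map.get(strain)
        target_mask = np.isin(ids, list(effect.targets)) if effect else np.zeros(len(ids), bool)
        strain_weights = weights * np.where(target_mask, effect.abundance_fold if effect else 1.0, 1.0)
        strain_means = base_mean + np.where(target_mask, effect.tail_shift if effect else 0.0, 0.0)
        if strain in cfg.denovo_strains:
            if cfg.tail_sd > 0:
                a = (0.0 - cfg.denovo_mean) / cfg.tail_sd
                b = (cfg.denovo_cap - cfg.denovo_mean) / cfg.tail_sd
                true_mean = float(truncnorm.mean(a, b, loc=cfg.denovo_mean, scale=cfg.tail_sd))
            else:
                true_mean = float(cfg.denovo_mean)
            strain_true_means = np.full(len(ids), true_mean)
        else:
            strain_true_means = strain_means
        probs = strain_weights / strain_weights.sum()
        size = _library_size(cfg, strain_weights)
        for rep in range(1, cfg.n_replicates + 1):
            sample_id = f"{strain}_rep{rep}"
            rng = _sample_rng(cfg.seed, sample_id)
            counts = rng.multinomial(size, probs)
            tails = _draw_strain_tails(cfg, strain, counts, strain_means, rng)
            tid = np.repeat(ids, counts)
            reads[sample_id] = _finish_reads(cfg, sample_id, tid, tails, rng)
            library_sizes[sample_id] = size
            sheet_rows.append(
                {
                    "sample_id": sample_id,
                    "strain": strain,
                    "condition": "simulated",
                    "fraction": "polyA_plus",
                    "replicate": rep,
                    "path": f"{sample_id}.polya.tsv",
                    "qpcr_coefficient": 1.0,
                }
            )
        truth_rows.append(
            pd.DataFrame(
                {
                    "strain": strain,
                    "transcript_id": ids,
                    "biotype": biotypes,
                    "expression_weight": strain_weights,
                    "true_mean_tail": strain_true_means,
                    "is_target": target_mask,
                    "tail_shift": np.where(target_mask, effect.tail_shift if effect else 0.0, 0.0),
                    "is_oligo": False,
                    "oligo_weight": 0.0,
                }
            )
        )
    truth = GroundTruth(
        per_transcript=pd.concat(truth_rows, ignore_index=True),
        library_sizes=library_sizes,
        spikein_lengths=tuple(cfg.spikein_lengths),
    )
    return SimulatedExperiment(
        reads=reads,
        annotation=_annotation_frame(ids, biotypes),
        sample_sheet=pd.DataFrame(sheet_rows),
        truth=truth,
    )


def simulate_total_vs_polyA(cfg: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Paired total-RNA and poly(A)+ read tables from one underlying library.

    A fraction of transcripts carries an oligoadenylated subpopulation: each
    of their reads is, with probability ``oligo_weight``, drawn from
    Uniform(0, oligo_tail_max) instead of the steady-state tail model.  The
    total table holds every read; the poly(A)+ table retains each read with
    probability ``logistic((tail - capture_midpoint) * capture_steepness)``
    computed on the noise-free tail (capture acts on the molecule, not on the
    estimate).  An infinite steepness gives a hard step at the midpoint.
    """
    cfg.validate()
    master = _sample_rng(cfg.seed, "__layout__")
    ids, biotypes, weights, base_mean = _transcript_layout(cfg, master)
    n_oligo = int(round(cfg.oligo_transcript_fraction * cfg.n_transcripts))
    oligo_mask = np.zeros(len(ids), dtype=bool)
    if n_oligo:
        oligo_mask[master.choice(len(ids), size=n_oligo, replace=False)] = True

    sample_id = "total_rep1"
    rng = _sample_rng(cfg.seed, sample_id)
    probs = weights / weights.sum()
    size = _library_size(cfg, weights)
    counts = rng.multinomial(size, probs)
    tails = _draw_strain_tails(cfg, "WT", counts, base_mean, rng)
    tid = np.repeat(ids, counts)
    read_oligo = np.repeat(oligo_mask, counts) & (rng.random(len(tails)) < cfg.oligo_weight)
    tails[read_oligo] = rng.uniform(0.0, cfg.oligo_tail_max, int(read_oligo.sum()))
    total = _finish_reads(cfg, sample_id, tid, tails, rng)

    capture_rng = _sample_rng(cfg.seed, sample_id, stream=1)
    if np.isinf(cfg.capture_steepness):
        retain_p = (tails > cfg.capture_midpoint).astype(float)
    else:
        retain_p = expit((tails - cfg.capture_midpoint) * cfg.capture_steepness)
    keep = capture_rng.random(len(tails)) < retain_p
    polya = total.loc[keep].reset_index(drop=True).assign(sample_id="polyA_rep1")

    truth = GroundTruth(
        per_transcript=pd.DataFrame(
            {
                "strain": "WT",
                "transcript_id": ids,
                "biotype": biotypes,
                "expression_weight": weights,
                "true_mean_tail": base_mean,
                "is_target": False,
                "tail_shift": 0.0,
                "is_oligo": oligo_mask,
                "oligo_weight": np.where(oligo_mask, cfg.oligo_weight, 0.0),
            }
        ),
        library_sizes={"total_rep1": size, "polyA_rep1": int(keep.sum())},
        spikein_lengths=tuple(cfg.spikein_lengths),
    )
    return total, polya, truth


def simulate_spikeins(
    lengths: Sequence[float],
    n_reads_each: int,
    noise_sd: float,
    seed: int = 0,
    sample_id: str = "spikein",
) -> pd.DataFrame:
    """Reads from in vitro standards with designed tail lengths.

    Emits ``n_reads_each`` PASS records per designed length; estimates are
    the designed length plus Gaussian noise, floored at 0.  The contigs are
    named ``spike_<length>A`` so each standard summarizes separately.
    """
    lengths = [float(x) for x in lengths]
    if not lengths:
        raise ValueError("simulate_spikeins requires at least one designed length")
    if min(lengths) <= 0:
        raise ValueError("spike-in lengths must be positive")
    if n_reads_each <= 0:
        raise ValueError("n_reads_each must be positive")
    rng = _sample_rng(seed, sample_id)
    designed = np.repeat(lengths, n_reads_each)
    estimates = designed + (rng.normal(0.0, noise_sd, designed.size) if noise_sd > 0 else 0.0)
    estimates = np.maximum(estimates, 0.0)
    return pd.DataFrame(
        {
            "read_id": [f"{sample_id}_r{i:08d}" for i in range(designed.size)],
            "transcript_id": [f"spike_{int(d) if float(d).is_integer() else d}A" for d in designed],
            "position": 0,
            "polya_length": np.round(estimates, 2),
            "qc_tag": "PASS",
            "sample_id": sample_id,
        }
    )


def write_experiment(experiment: SimulatedExperiment, outdir: str | Path) -> dict:
    """Serialize a simulated experiment (read TSVs, BED, sample sheet, truth).

    Returns a mapping of logical names to written paths.  Identical
    experiment objects produce byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for sample_id, table in experiment.reads.items():
        p = outdir / f"{sample_id}.polya.tsv"
        pio.write_polya_table(table, p)
        paths[sample_id] = p
    pio.write_annotation(experiment.annotation, outdir / "annotation.bed")
    paths["annotation"] = outdir / "annotation.bed"
    # paths are relative to the sheet so the bundle is relocatable (and
    # byte-identical across output directories for one config+seed)
    pio.write_sample_sheet(experiment.sample_sheet, outdir / "sample_sheet.tsv")
    paths["sample_sheet"] = outdir / "sample_sheet.tsv"
    experiment.truth.per_transcript.to_csv(outdir / "ground_truth.tsv", sep="\t", index=False)
    paths["ground_truth"] = outdir / "ground_truth.tsv"
    return paths
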