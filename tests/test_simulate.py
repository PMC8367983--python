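import numpy as np
import pytest
from scipy.stats import truncnorm

from polyatails.simulate import (
    SimConfig,
    TailEffect,
    simulate_experiment,
    simulate_spikeins,
    simulate_total_vs_polyA,
    write_experiment,
)


def _noise_free_cfg(**kw):
    base = dict(
        n_transcripts=1,
        wt_tail_mean_high=50.0,
        wt_tail_mean_low=50.0,
        tail_sd=0.0,
        estimation_noise_sd=0.0,
        qc_fail_rate=0.0,
        n_replicates=1,
        reads_per_replicate=100,
        seed=3,
    )
    base.update(kw)
    return SimConfig(**base)


class TestSimulateExperiment:
    def test_noise_free_single_transcript_is_exact(self):
        exp = simulate_experiment(_noise_free_cfg())
        reads = exp.reads["WT_rep1"]
        assert len(reads) == 100
        assert (reads["qc_tag"] == "PASS").all()
        assert (reads["polya_length"] == 50.0).all()

    def test_seeded_determinism_gives_identical_files(self, tmp_path):
        cfg = SimConfig(n_transcripts=40, reads_per_replicate=2000, seed=7)
        for d in ("a", "b"):
            write_experiment(simulate_experiment(cfg), tmp_path / d)
        for p in sorted((tmp_path / "a").iterdir()):
            assert p.read_bytes() == (tmp_path / "b" / p.name).read_bytes()

    def test_adding_a_strain_does_not_perturb_existing_samples(self):
        cfg1 = SimConfig(n_transcripts=30, reads_per_replicate=1000, seed=5)
        cfg2 = SimConfig(n_transcripts=30, reads_per_replicate=1000, seed=5,
                         strains=("WT", "mut"))
        a = simulate_experiment(cfg1).reads["WT_rep1"]
        b = simulate_experiment(cfg2).reads["WT_rep1"]
        assert a.equals(b)

    def test_read_conservation(self):
        cfg = SimConfig(n_transcripts=25, reads_per_replicate=3000, seed=11)
        exp = simulate_experiment(cfg)
        for sid, table in exp.reads.items():
            assert len(table) == exp.truth.library_sizes[sid] == 3000

    def test_de_novo_mean_matches_truncated_normal_integral(self):
        cfg = _noise_free_cfg(
            n_transcripts=1, tail_sd=15.0, denovo_mean=50.0, denovo_cap=200.0,
            reads_per_replicate=10_000, strains=("denovo",),
            denovo_strains=frozenset({"denovo"}),
        )
        exp = simulate_experiment(cfg)
        tails = exp.reads["denovo_rep1"]["polya_length"]
        a, b = (0 - 50.0) / 15.0, (200.0 - 50.0) / 15.0
        expected = truncnorm.mean(a, b, loc=50.0, scale=15.0)
        assert tails.max() <= 200.0
        assert tails.mean() == pytest.approx(expected, abs=3 * 15.0 / np.sqrt(10_000))

    def test_effect_map_shifts_only_targets(self):
        cfg = _noise_free_cfg(
            n_transcripts=10, reads_per_replicate=5000,
            strains=("WT", "mut"),
            effect_map={"mut": TailEffect(targets=frozenset({"T00003"}), tail_shift=12.0)},
        )
        exp = simulate_experiment(cfg)
        mut = exp.reads["mut_rep1"]
        on_target = mut.loc[mut["transcript_id"] == "T00003", "polya_length"]
        off_target = mut.loc[mut["transcript_id"] != "T00003", "polya_length"]
        assert (on_target == 62.0).all()
        assert (off_target == 50.0).all()
        assert exp.truth.targets("mut") == {"T00003"}

    def test_unknown_effect_target_rejected(self):
        cfg = _noise_free_cfg(
            strains=("WT", "mut"),
            effect_map={"mut": TailEffect(targets=frozenset({"ghost"}))},
        )
        with pytest.raises(ValueError, match="ghost"):
            simulate_experiment(cfg)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            simulate_experiment(SimConfig(n_transcripts=0))
        with pytest.raises(ValueError):
            SimConfig(denovo_mean=100, denovo_cap=50).validate()
        with pytest.raises(ValueError):
            SimConfig(oligo_weight=1.5).validate()
        with pytest.raises(ValueError):
            SimConfig(capture_steepness=0.0).validate()

    def test_qc_fail_rate_produces_non_pass_tags(self):
        cfg = _noise_free_cfg(reads_per_replicate=5000, qc_fail_rate=0.3)
        reads = simulate_experiment(cfg).reads["WT_rep1"]
        frac = (reads["qc_tag"] != "PASS").mean()
        assert abs(frac - 0.3) <= 3 * np.sqrt(0.3 * 0.7 / 5000)
        assert set(reads["qc_tag"]) <= {"PASS", "ADAPTER", "NOREGION", "READ_FAILED_LOAD", "SUFFCLIP"}


class TestSimulateTotalVsPolyA:
    def test_step_capture_keeps_exactly_long_tails(self):
        cfg = _noise_free_cfg(
            n_transcripts=20, reads_per_replicate=4000,
            oligo_transcript_fraction=0.5, oligo_weight=0.5,
            capture_steepness=np.inf, capture_midpoint=10.0,
        )
        total, polya, _ = simulate_total_vs_polyA(cfg)
        kept = set(polya["read_id"])
        for row in total.itertuples(index=False):
            assert (row.read_id in kept) == (row.polya_length > 10.0)

    def test_polya_is_subset_of_total(self):
        cfg = SimConfig(n_transcripts=50, reads_per_replicate=5000, seed=9)
        total, polya, _ = simulate_total_vs_polyA(cfg)
        assert set(polya["read_id"]) <= set(total["read_id"])

    def test_no_oligo_component_means_near_unit_ratio(self):
        cfg = _noise_free_cfg(
            n_transcripts=5, reads_per_replicate=5000, oligo_weight=0.0,
            wt_tail_mean_high=40.0, wt_tail_mean_low=40.0,
            capture_steepness=np.inf, capture_midpoint=10.0,
        )
        total, polya, _ = simulate_total_vs_polyA(cfg)
        assert len(polya) == len(total)  # every 40 A tail clears a 10 A step

    def test_count_ratio_matches_analytic_retention(self):
        cfg = _noise_free_cfg(
            n_transcripts=1, reads_per_replicate=5000,
            oligo_transcript_fraction=1.0, oligo_weight=0.4,
            capture_steepness=np.inf, capture_midpoint=10.0,
            wt_tail_mean_high=50.0, wt_tail_mean_low=50.0,
        )
        total, polya, truth = simulate_total_vs_polyA(cfg)
        ratio = len(total) / len(polya)
        se_p = np.sqrt(0.6 * 0.4 / 5000)
        assert ratio == pytest.approx(1 / 0.6, abs=3 * se_p / 0.6**2)
        assert truth.oligo_transcripts() == {"T00000"}

    def test_oligo_transcripts_have_shorter_total_tails(self):
        cfg = SimConfig(n_transcripts=100, reads_per_replicate=50_000, seed=21,
                        oligo_transcript_fraction=0.2, oligo_weight=0.4)
        total, polya, truth = simulate_total_vs_polyA(cfg)
        oligo = truth.oligo_transcripts()
        t_means = total.groupby("transcript_id")["polya_length"].mean()
        p_means = polya.groupby("transcript_id")["polya_length"].mean()
        delta = (t_means - p_means).dropna()
        assert delta[list(oligo & set(delta.index))].mean() < -5
        assert abs(delta[list(set(delta.index) - oligo)].mean()) < 2


class TestSimulateSpikeins:
    def test_noise_free_means_are_exact(self):
        table = simulate_spikeins([10, 90], 100, noise_sd=0.0, seed=1)
        means = table.groupby("transcript_id")["polya_length"].mean()
        assert means["spike_10A"] == 10.0
        assert means["spike_90A"] == 90.0

    def test_designed_lengths_form_distinct_groups(self):
        table = simulate_spikeins(range(10, 100, 10), 50, noise_sd=2.0, seed=2)
        assert table["transcript_id"].nunique() == 9
        assert (table["qc_tag"] == "PASS").all()

    def test_noisy_means_within_clt_bound(self):
        table = simulate_spikeins(range(10, 100, 10), 10_000, noise_sd=2.0, seed=3)
        means = table.groupby("transcript_id")["polya_length"].mean()
        for d in range(10, 100, 10):
            assert abs(means[f"spike_{d}A"] - d) <= 3 * 2.0 / np.sqrt(10_000)

    def test_contract_errors(self):
        with pytest.raises(ValueError):
            simulate_spikeins([], 10, 1.0)
        with pytest.raises(ValueError):
            simulate_spikeins([0], 10, 1.0)
        with pytest.raises(ValueError):
            simulate_spikeins([10], 0, 1.0)
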