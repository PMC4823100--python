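import numpy as np
import pandas as pd
import pytest
from scipy import stats

from aerlnc.cis_regulation import bin_signal
from aerlnc.models import GenomicInterval
from aerlnc.qpcr_harmonization import delta_ct
from aerlnc.synthetic_data import (
    SimulationConfig,
    gen_annotation,
    gen_binding_sites,
    gen_chip_tags,
    gen_coexpression_panel,
    gen_counts,
    gen_ct,
    gen_panel,
)

LNC_ONLY = {"lincRNA": 0.5, "antisense": 0.5}


class TestConfig:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SimulationConfig(biotype_fractions={"lincRNA": 0.6, "antisense": 0.3})

    def test_dispersion_must_be_positive(self):
        with pytest.raises(ValueError, match="dispersion"):
            SimulationConfig(dispersion=0.0)


class TestAnnotation:
    def test_biotype_counts_match_fractions(self):
        cfg = SimulationConfig(seed=0, n_genes=100, biotype_fractions=LNC_ONLY)
        genes = gen_annotation(cfg)
        counts = pd.Series([g.biotype for g in genes.values()]).value_counts()
        assert counts["lincRNA"] == 50 and counts["antisense"] == 50

    def test_same_seed_reproduces_annotation(self):
        cfg = SimulationConfig(seed=11, n_genes=60)
        assert gen_annotation(cfg) == gen_annotation(cfg)

    def test_overfull_chromosome_raises(self):
        cfg = SimulationConfig(seed=0, n_genes=1000, n_chromosomes=1, chrom_length=1_000_000)
        with pytest.raises(ValueError, match="capacity"):
            gen_annotation(cfg)

    def test_tss_spacing_and_transcripts(self):
        cfg = SimulationConfig(seed=2, n_genes=200)
        genes = gen_annotation(cfg)
        by_chrom = {}
        for g in genes.values():
            by_chrom.setdefault(g.chrom, []).append(g.tss)
            assert 1 <= len(g.transcript_lengths) <= 4
            assert min(g.transcript_lengths) >= 100
        for tsses in by_chrom.values():
            tsses = np.sort(tsses)
            assert np.all(np.diff(tsses) >= 1000)


class TestBindingSites:
    def test_zero_scale_puts_sites_at_tss(self):
        cfg = SimulationConfig(seed=0, n_genes=50, proximity_scale=0.0)
        genes = gen_annotation(cfg)
        targets = list(genes)[:10]
        sites, truth = gen_binding_sites(genes, targets, cfg, n_background=0)
        planted = {(genes[t].chrom, genes[t].tss) for t in targets}
        observed = {(c, int(s)) for c, s in zip(sites.chroms, sites.summits)}
        assert observed == planted
        assert (truth["offset"] == 0).all()

    def test_no_background_yields_one_site_per_target(self):
        cfg = SimulationConfig(seed=0, n_genes=50)
        genes = gen_annotation(cfg)
        sites, _ = gen_binding_sites(genes, list(genes)[:7], cfg, n_background=0)
        assert len(sites) == 7

    def test_unknown_target_raises(self):
        cfg = SimulationConfig(seed=0, n_genes=20)
        genes = gen_annotation(cfg)
        with pytest.raises(ValueError, match="absent"):
            gen_binding_sites(genes, ["nope"], cfg)

    def test_offset_magnitudes_follow_exponential_scale(self):
        cfg = SimulationConfig(
            seed=3, n_genes=10_000, proximity_scale=10_000.0, biotype_fractions=LNC_ONLY
        )
        genes = gen_annotation(cfg)
        _sites, truth = gen_binding_sites(genes, list(genes), cfg, n_background=0)
        assert truth["offset"].abs().mean() == pytest.approx(10_000.0, rel=0.05)


class TestCounts:
    def test_zero_lfc_means_empty_truth(self):
        cfg = SimulationConfig(seed=0, n_genes=50, lfc=0.0)
        genes = gen_annotation(cfg)
        _cm, truth = gen_counts(genes, cfg)
        assert truth.empty

    def test_identical_seeds_identical_matrices(self):
        cfg = SimulationConfig(seed=9, n_genes=80)
        genes = gen_annotation(cfg)
        cm1, t1 = gen_counts(genes, cfg)
        cm2, t2 = gen_counts(genes, cfg)
        pd.testing.assert_frame_equal(cm1.counts, cm2.counts)
        pd.testing.assert_frame_equal(t1, t2)

    def test_single_replicate_raises(self):
        cfg = SimulationConfig(seed=0, n_genes=20, n_reps=1)
        genes = gen_annotation(cfg)
        with pytest.raises(ValueError, match="replicates"):
            gen_counts(genes, cfg)

    def test_planted_fold_change_recovered_across_replicates(self):
        cfg = SimulationConfig(
            seed=4, n_genes=200, n_reps=50, lfc=4.0, de_fraction=0.2,
            biotype_fractions=LNC_ONLY,
        )
        genes = gen_annotation(cfg)
        cm, truth = gen_counts(genes, cfg)
        gid = truth["gene_id"].iloc[0]
        expected = truth["lfc"].iloc[0]
        ctrl = cm.counts.loc[gid, cm.samples_of("ctrl")].mean()
        ko = cm.counts.loc[gid, cm.samples_of("ko")].mean()
        assert np.log2(ko / ctrl) == pytest.approx(expected, abs=0.3)

    def test_down_up_split_follows_down_fraction(self):
        cfg = SimulationConfig(seed=1, n_genes=500, biotype_fractions=LNC_ONLY, de_fraction=0.4)
        genes = gen_annotation(cfg)
        _cm, truth = gen_counts(genes, cfg)
        n_down = (truth["direction"] == "down").sum()
        assert n_down == round(0.65 * len(truth))


class TestPanel:
    def test_subtype_design_respected_exactly(self):
        cfg = SimulationConfig(seed=0, n_genes=100, biotype_fractions=LNC_ONLY)
        genes = gen_annotation(cfg)
        panel, _ = gen_panel(genes, cfg)
        assert panel.n_samples == 55
        assert panel.subtype.value_counts().to_dict() == {
            "luminal": 14, "basal": 14, "claudin_low": 14, "normal_like": 13}

    def test_oversized_signature_raises(self):
        cfg = SimulationConfig(seed=0, n_genes=40, signature_size=1000)
        genes = gen_annotation(cfg)
        with pytest.raises(ValueError, match="signature_size"):
            gen_panel(genes, cfg)

    def test_zero_effect_means_equal_group_means(self):
        cfg = SimulationConfig(
            seed=5, n_genes=200, biotype_fractions=LNC_ONLY,
            signature_effect=0.0, subtype_separation=0.0,
        )
        genes = gen_annotation(cfg)
        panel, truth = gen_panel(genes, cfg)
        log_vals = np.log10(panel.values.to_numpy())
        lum = panel.subtype.to_numpy() == "luminal"
        diff = log_vals[:, lum].mean() - log_vals[:, ~lum].mean()
        assert abs(diff) < 0.05

    def test_planted_gene_detected_by_t_test(self):
        # effect 3 sd, n = 14 vs 41: rejects at alpha=0.001 in >=99/100 seeds
        rejections = 0
        for seed in range(100):
            cfg = SimulationConfig(
                seed=seed, n_genes=60, biotype_fractions=LNC_ONLY,
                signature_size=5, signature_effect=3.0,
            )
            genes = gen_annotation(cfg)
            panel, truth = gen_panel(genes, cfg)
            gid = truth["gene_id"].iloc[0]
            vals = np.log10(panel.values.loc[gid].to_numpy())
            lum = panel.subtype.to_numpy() == "luminal"
            p = stats.ttest_ind(vals[lum], vals[~lum], equal_var=False).pvalue
            rejections += p < 0.001
        assert rejections >= 99


class TestChipTags:
    def test_zero_tags_gives_empty_tracks(self):
        a, b = gen_chip_tags([GenomicInterval("chr1", 5000, 5001)], "promoter", 0, seed=0)
        assert len(a) == 0 and len(b) == 0

    def test_same_seed_identical(self):
        regions = [GenomicInterval("chr1", 5000, 5001)]
        a1, b1 = gen_chip_tags(regions, "promoter", 100, seed=4)
        a2, b2 = gen_chip_tags(regions, "promoter", 100, seed=4)
        assert np.array_equal(a1.pos, a2.pos) and np.array_equal(b1.pos, b2.pos)

    def test_promoter_profile_cpm_ratio_near_four(self):
        regions = [GenomicInterval("chr1", 50_000, 50_001)]
        a, b = gen_chip_tags(regions, "promoter", 10_000, seed=1)
        anchors = [("r0", "chr1", 50_000, "+")]
        sig_a = bin_signal(a, anchors)
        sig_b = bin_signal(b, anchors)
        ratio = sig_a.sum(axis=1)["r0"] / sig_b.sum(axis=1)["r0"]
        assert 3.0 <= ratio <= 5.0

    def test_equal_library_sizes(self):
        regions = [GenomicInterval("chr1", 50_000, 50_001), GenomicInterval("chr2", 9_000, 9_001)]
        a, b = gen_chip_tags(regions, "enhancer", 500, seed=2)
        assert len(a) == len(b) == 1000


class TestCt:
    def test_default_run_sizes_are_22_and_20(self):
        r1, r2, truth = gen_ct(SimulationConfig(seed=0))
        assert (len(r1), len(r2)) == (22, 20)
        assert truth["run_sizes"] == [22, 20]

    def test_no_batch_effect_runs_are_exchangeable(self):
        # with (a, b) = (0, 1) the KS p between runs is uniform over seeds
        ps = []
        for seed in range(60):
            cfg = SimulationConfig(seed=seed, ct_shift=(0.0, 1.0), group_delta=0.0)
            r1, r2, _ = gen_ct(cfg)
            v1 = delta_ct(r1).to_numpy()
            v2 = delta_ct(r2).to_numpy()
            ps.append(stats.ks_2samp(v1, v2).pvalue)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_no_group_effect_wilcoxon_p_uniform(self):
        ps = []
        for seed in range(100):
            cfg = SimulationConfig(seed=seed, ct_shift=(0.0, 1.0), group_delta=0.0)
            r1, _r2, _ = gen_ct(cfg)
            v1 = delta_ct(r1).to_numpy()
            g = r1.groups.to_numpy()
            ps.append(stats.mannwhitneyu(v1[g == "ER_pos"], v1[g == "ER_neg"],
                                         alternative="two-sided").pvalue)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestCoexpressionPanel:
    def test_shapes_and_truth(self):
        panel, truth = gen_coexpression_panel(n_samples=20, n_correlated=10,
                                              n_background=100, r=0.9, seed=0)
        assert panel.values.shape == (111, 20)
        assert truth["focal"] == "FOCAL" and len(truth["correlated"]) == 10

    def test_planted_correlation_close_to_target(self):
        panel, truth = gen_coexpression_panel(n_samples=2000, n_correlated=3, r=0.9, seed=1)
        logv = np.log10(panel.values.to_numpy())
        focal = logv[0]
        for i in (1, 2, 3):
            r = np.corrcoef(focal, logv[i])[0, 1]
            assert r == pytest.approx(0.9, abs=0.03)
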