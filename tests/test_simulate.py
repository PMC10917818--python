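"""Synthetic study generator: determinism, planted structure, round trips."""

import dataclasses
import filecmp

import numpy as np
import pytest
from scipy.stats import chisquare

from faceenh.catalog import WEEKS
from faceenh.conservation import read_chain_file
from faceenh.gwas import expand_ld, read_snp_table
from faceenh.intervals import read_bed
from faceenh.pairs import spearman_rows
from faceenh.simulate import (
    TruthConfig,
    generate_truth,
    lead_snp_ids,
    simulate_sample_peaks,
    simulate_signal_and_expression,
    simulate_snps,
    write_study,
)
from faceenh.temporal import classify_temporal


def small_cfg(**kw):
    base = dict(seed=5, n_enhancers=200, n_true_pairs=30,
                n_associated_snps=1000, snp_density=0.0005)
    base.update(kw)
    return TruthConfig(**base)


class TestGenerateTruth:
    def test_deterministic_given_seed(self):
        t1, t2 = generate_truth(small_cfg()), generate_truth(small_cfg())
        assert [iv.sort_key() for iv in t1.enhancers] == [iv.sort_key() for iv in t2.enhancers]
        assert t1.classes == t2.classes
        assert (t1.activity == t2.activity).all()
        assert t1.conservation == t2.conservation
        assert t1.pairs == t2.pairs

    def test_enhancers_disjoint_and_distal(self):
        truth = generate_truth(small_cfg())
        ivs = list(truth.enhancers)
        for a, b in zip(ivs, ivs[1:]):
            if a.chrom == b.chrom:
                assert a.end < b.start
        tss_positions = {(c, p) for c, p, _, _ in truth.genes.tss}
        for iv in ivs:
            for c, p in tss_positions:
                if c == iv.chrom:
                    assert not (iv.start < p + 1000 and p - 1000 < iv.end)

    def test_all_constant_proportions(self):
        cfg = small_cfg(class_proportions={"constant": 1.0})
        truth = generate_truth(cfg)
        assert truth.activity.all()

    def test_activity_vectors_consistent_with_class(self):
        truth = generate_truth(small_cfg())
        for i, cname in enumerate(truth.classes):
            assert classify_temporal(truth.activity[i]) == cname

    def test_class_counts_multinomial(self):
        """Empirical class counts at n=10,000 match the configured mix."""
        cfg = small_cfg(n_chrom=6, chrom_length=15_000_000, n_enhancers=10_000)
        truth = generate_truth(cfg)
        names = list(cfg.class_proportions)
        observed = np.array([truth.classes.count(k) for k in names])
        expected = np.array([cfg.class_proportions[k] for k in names]) * len(truth.classes)
        assert chisquare(observed, expected).pvalue > 0.001

    def test_infeasible_packing_rejected(self):
        with pytest.raises(ValueError, match="pack"):
            generate_truth(small_cfg(n_chrom=1, chrom_length=300_000, n_enhancers=500))

    def test_pairs_unique_genes(self):
        truth = generate_truth(small_cfg())
        genes = [g for _, g in truth.pairs]
        assert len(genes) == len(set(genes))


class TestSamplePeaks:
    def test_noise_free_equals_truth(self):
        cfg = small_cfg(peak_dropout=0.0, peak_jitter_sd=0.0, background_peak_rate=0.0)
        truth = generate_truth(cfg)
        active = truth.active_in_week(7)
        peaks = simulate_sample_peaks(truth, 7, "s1")
        expect = sorted(
            truth.enhancers[int(i)].sort_key() for i in np.flatnonzero(active)
        )
        assert sorted(iv.sort_key() for iv in peaks) == expect

    def test_full_dropout_leaves_only_background(self):
        cfg = small_cfg(peak_dropout=1.0, background_peak_rate=10.0)
        truth = generate_truth(cfg)
        peaks = simulate_sample_peaks(truth, 7, "s1")
        enh = {(iv.chrom, iv.start, iv.end) for iv in truth.enhancers}
        assert all((p.chrom, p.start, p.end) not in enh for p in peaks)

    def test_support_counts_binomial(self):
        """Across 5 samples at dropout 0.2, per-enhancer support ~ Bin(5, 0.8)."""
        cfg = small_cfg(
            n_chrom=4, chrom_length=12_000_000, n_enhancers=2_000,
            class_proportions={"constant": 1.0}, peak_dropout=0.2,
            peak_jitter_sd=0.0, background_peak_rate=0.0,
            samples_per_week={7: 5},
        )
        truth = generate_truth(cfg)
        counts = np.zeros(2_000, dtype=int)
        enh_index = {iv.sort_key(): i for i, iv in enumerate(truth.enhancers)}
        for s in range(5):
            for p in simulate_sample_peaks(truth, 7, f"s{s}"):
                counts[enh_index[p.sort_key()]] += 1
        observed = np.bincount(counts, minlength=6)
        from scipy.stats import binom
        expected = binom.pmf(np.arange(6), 5, 0.8) * 2_000
        assert chisquare(observed, expected, ddof=0).pvalue > 0.001

    def test_distinct_samples_get_distinct_noise(self):
        cfg = small_cfg()
        truth = generate_truth(cfg)
        p1 = simulate_sample_peaks(truth, 7, "s1")
        p2 = simulate_sample_peaks(truth, 7, "s2")
        assert [iv.sort_key() for iv in p1] != [iv.sort_key() for iv in p2]


class TestSnps:
    def test_null_odds_ratio_rates_match(self):
        cfg = small_cfg(planted_or=1.0, n_associated_snps=20_000, snp_density=0.002)
        truth = generate_truth(cfg)
        cat = simulate_snps(truth)
        from faceenh.gwas import build_contingency
        assoc = set(cat.snps.loc[cat.snps["associated"], "snp_id"])
        t, _ = build_contingency(cat, assoc, truth.enhancers)
        rate_a = t.a / (t.a + t.b)
        rate_b = t.c / (t.c + t.d)
        assert rate_a == pytest.approx(rate_b, rel=0.15)

    def test_ld_expansion_recovers_associated_set(self):
        truth = generate_truth(small_cfg())
        cat = simulate_snps(truth)
        leads = lead_snp_ids(cat)
        expanded = expand_ld(leads, cat, r2_min=0.8)
        assoc = set(cat.snps.loc[cat.snps["associated"], "snp_id"])
        assert expanded == assoc

    def test_decoy_partners_straddle_threshold(self):
        truth = generate_truth(small_cfg())
        cat = simulate_snps(truth)
        r2 = cat.ld_pairs["r2"].to_numpy()
        assert (r2 >= 0.8).any() and (r2 < 0.8).any()
        below = cat.ld_pairs.loc[cat.ld_pairs["r2"] < 0.8, "partner_id"]
        assoc = set(cat.snps.loc[cat.snps["associated"], "snp_id"])
        assert not (set(below) & assoc)


class TestSignalExpression:
    def test_perfect_coupling_perfect_correlation(self):
        cfg = small_cfg(pair_effect=1.0, composition_bias=1.0)
        truth = generate_truth(cfg)
        sig, exp = simulate_signal_and_expression(truth)
        keys = truth.pair_signal_keys()
        rhos = spearman_rows(
            sig.loc[[e for e, _ in keys]].to_numpy(),
            exp.loc[[g for _, g in keys]].to_numpy(),
        )
        assert rhos == pytest.approx(np.ones(len(keys)))

    def test_matrices_positive_and_matched(self):
        truth = generate_truth(small_cfg())
        sig, exp = simulate_signal_and_expression(truth)
        assert (sig.to_numpy() > 0).all() and (exp.to_numpy() > 0).all()
        assert list(sig.columns) == list(exp.columns)


class TestStudyEmission:
    def test_byte_identical_reruns(self, tmp_path):
        cfg = small_cfg()
        for d in ("a", "b"):
            write_study(tmp_path / d, generate_truth(cfg))
        for name in ("manifest.tsv", "snps.tsv", "ld.tsv", "signal.tsv",
                     "study.chain", "truth.json", "peaks/wk7_s1.bed"):
            assert filecmp.cmp(tmp_path / "a" / name, tmp_path / "b" / name,
                               shallow=False), name

    def test_files_roundtrip_through_readers(self, lossless_study, lossless_truth):
        peaks = read_bed(lossless_study / "peaks" / "wk4_s1.bed")
        assert len(peaks) > 0
        snps = read_snp_table(lossless_study / "snps.tsv", one_based=True)
        cat = simulate_snps(lossless_truth)
        assert (snps["pos"].to_numpy() == cat.snps["pos"].to_numpy()).all()
        cf = read_chain_file(lossless_study / "study.chain")  # validates arithmetic
        assert len(cf.chains) == lossless_truth.cfg.n_chrom

    def test_config_yaml_roundtrip(self, tmp_path):
        cfg = small_cfg()
        cfg.to_yaml(tmp_path / "c.yaml")
        back = TruthConfig.from_yaml(tmp_path / "c.yaml")
        assert dataclasses.asdict(back) == dataclasses.asdict(cfg)
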