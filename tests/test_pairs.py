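"""Target assignment, TMM normalization, Spearman and Mann-Whitney tests."""

import itertools
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from faceenh.catalog import EnhancerCatalog
from faceenh.intervals import GenomicInterval, IntervalSet
from faceenh.pairs import (
    InteractionMap,
    assign_targets,
    normalize_tmm,
    pair_vs_background_test,
    spearman,
    spearman_rows,
    tmm_factors,
)


def make_catalog(coords):
    return EnhancerCatalog(
        regions=IntervalSet([GenomicInterval(*c) for c in coords], sorted=True),
        ids=[f"E{i}" for i in range(len(coords))],
        support=[{7: frozenset({"s1", "s2"})} for _ in coords],
    )


class TestAssignTargets:
    def test_enhancer_inside_fragment(self):
        cat = make_catalog([("chr1", 1000, 1500)])
        imap = InteractionMap([(GenomicInterval("chr1", 900, 1600), "GENE1")])
        assert assign_targets(cat, imap) == [("E0", "GENE1")]

    def test_two_fragments_same_gene_dedup(self):
        cat = make_catalog([("chr1", 1000, 2000)])
        imap = InteractionMap([
            (GenomicInterval("chr1", 900, 1100), "GENE1"),
            (GenomicInterval("chr1", 1900, 2100), "GENE1"),
        ])
        assert assign_targets(cat, imap) == [("E0", "GENE1")]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_double_loop(self, seed):
        rng = np.random.default_rng(500 + seed)
        coords = []
        pos = 0
        for _ in range(20):
            pos += int(rng.integers(100, 500))
            coords.append(("chr1", pos, pos + int(rng.integers(50, 300))))
            pos = coords[-1][2]
        cat = make_catalog(coords)
        frags = [
            (GenomicInterval("chr1", int(s), int(s) + int(rng.integers(50, 400))),
             f"G{int(rng.integers(0, 8))}")
            for s in rng.integers(0, pos, size=30)
        ]
        imap = InteractionMap(frags)
        expected = sorted({
            (cat.ids[i], g)
            for i, iv in enumerate(cat.regions)
            for fiv, g in frags
            if fiv.chrom == iv.chrom and min(iv.end, fiv.end) - max(iv.start, fiv.start) >= 1
        })
        assert assign_targets(cat, imap) == expected


class TestTmm:
    def test_identical_libraries(self):
        m = pd.DataFrame(np.tile([[10.0], [20], [30], [40]], (1, 4)))
        assert tmm_factors(m) == pytest.approx(np.ones(4))

    def test_pure_depth_shift(self):
        base = np.array([10.0, 25, 40, 5, 100])
        m = pd.DataFrame({"a": base, "b": 2 * base, "c": base, "d": 7 * base})
        assert tmm_factors(m) == pytest.approx(np.ones(4))

    def test_geometric_mean_is_one(self, rng):
        m = pd.DataFrame(rng.poisson(50, size=(200, 5)).astype(float))
        f = tmm_factors(m)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-9)

    def test_all_zero_library_rejected(self):
        m = pd.DataFrame({"a": [1.0, 2], "b": [0.0, 0]})
        with pytest.raises(ValueError, match="b"):
            tmm_factors(m)

    def test_matches_edger_calcnormfactors(self, rng, tmp_path):
        """Independent oracle: edgeR's TMM implementation on a small matrix."""
        counts = rng.poisson(60, size=(80, 4)).astype(float) + 1
        counts[:20, 0] *= 6  # composition bias in library 1
        csv = tmp_path / "counts.csv"
        pd.DataFrame(counts).to_csv(csv, index=False)
        script = (
            f"suppressMessages(library(edgeR));"
            f"x <- as.matrix(read.csv('{csv}'));"
            f"f <- calcNormFactors(x, method='TMM');"
            f"cat(sprintf('%.10f', f), sep='\\n')"
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        expected = np.array([float(v) for v in out.stdout.strip().splitlines()])
        got = tmm_factors(pd.DataFrame(counts))
        assert got == pytest.approx(expected, rel=1e-6)

    def test_normalize_rescales_biased_library(self, rng):
        counts = rng.poisson(60, size=(300, 4)).astype(float) + 1
        counts[:90, 0] *= 5
        f = tmm_factors(pd.DataFrame(counts))
        # trimming discards the inflated minority rows, so the biased
        # library's M-values skew negative and its factor is the smallest
        assert f[0] < f[1:].min()
        norm = normalize_tmm(pd.DataFrame(counts))
        assert norm.shape == counts.shape and (norm.to_numpy() >= 0).all()


class TestSpearman:
    def test_monotone_pairs(self):
        assert spearman([1, 2, 3, 4], [10, 20, 25, 80]) == 1.0
        assert spearman([1, 2, 3, 4], [8, 7, 3, 1]) == -1.0

    def test_ties_match_scipy(self, rng):
        for _ in range(20):
            x = rng.integers(0, 4, size=6).astype(float)
            y = rng.integers(0, 4, size=6).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            assert spearman(x, y) == pytest.approx(spearmanr(x, y).statistic, abs=1e-12)

    def test_zero_variance_is_nan(self):
        assert np.isnan(spearman([1, 1, 1], [1, 2, 3]))

    def test_invariant_under_monotone_transform(self, rng):
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        assert spearman(np.exp(x), y) == pytest.approx(spearman(x, y))
        assert spearman(x, 3 * y + 7) == pytest.approx(spearman(x, y))

    def test_rowwise_matches_scalar(self, rng):
        X = rng.normal(size=(15, 8))
        Y = rng.normal(size=(15, 8))
        rows = spearman_rows(X, Y)
        for i in range(15):
            assert rows[i] == pytest.approx(spearman(X[i], Y[i]))


def mwu_exact_oracle(x, y):
    """One-sided (greater) exact p by enumerating all group assignments."""
    pooled = list(x) + list(y)
    n1 = len(x)

    def u_stat(xs, ys):
        return sum(
            1.0 if a > b else (0.5 if a == b else 0.0) for a in xs for b in ys
        )

    observed = u_stat(x, y)
    count = total = 0
    for comb in itertools.combinations(range(len(pooled)), n1):
        xs = [pooled[i] for i in comb]
        ys = [pooled[i] for i in range(len(pooled)) if i not in comb]
        if u_stat(xs, ys) >= observed - 1e-12:
            count += 1
        total += 1
    return count / total


class TestMannWhitney:
    def test_identical_groups(self):
        res = pair_vs_background_test([1, 2, 3], [1, 2, 3], alternative="two_sided")
        assert res.u_statistic == pytest.approx(len(res.pair_rhos) ** 2 / 2)
        assert res.p_value == pytest.approx(1.0, abs=0.05)

    def test_complete_separation_exact(self):
        res = pair_vs_background_test([3, 4, 5], [0, 1, 2], alternative="greater")
        assert res.method == "exact"
        assert res.u_statistic == 9
        assert res.p_value == pytest.approx(1 / 20)

    @pytest.mark.parametrize("seed", range(10))
    def test_small_sample_matches_enumeration(self, seed):
        rng = np.random.default_rng(600 + seed)
        x = rng.normal(size=int(rng.integers(3, 7)))
        y = rng.normal(size=int(rng.integers(3, 7)))
        res = pair_vs_background_test(x, y, alternative="greater")
        assert res.method == "exact"
        assert res.p_value == pytest.approx(mwu_exact_oracle(x, y), abs=1e-10)

    def test_large_groups_use_normal_approximation(self, rng):
        x = rng.normal(0.5, 1, size=40)
        y = rng.normal(0.0, 1, size=60)
        res = pair_vs_background_test(x, y)
        assert res.method == "asymptotic"
        assert 0 <= res.p_value <= 1

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            pair_vs_background_test([], [1.0])
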