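"""Chain parsing, liftover block-walking, synteny and conservation calls."""

import io

import numpy as np
import pytest

from faceenh.conservation import (
    Chain,
    ChainFile,
    ChainParseError,
    OrthologyTable,
    classify_conservation,
    liftover_interval,
    read_chain_file,
    synteny_check,
    write_chain_file,
)
from faceenh.intervals import GenomicInterval, IntervalSet, TssAnnotation


def identity_chain(chrom="chr1", length=10_000, target="tchr1"):
    return ChainFile([Chain(
        score=100, t_name=chrom, t_size=length, t_strand="+", t_start=0,
        t_end=length, q_name=target, q_size=length, q_strand="+", q_start=0,
        q_end=length, chain_id="1", blocks=[(length, 0, 0)],
    )])


THREE_BLOCK = """\
chain 1000 chr1 10000 + 1000 2050 tchr1 20000 + 5000 6100 7
500 50 0
200 0 100
300
"""


class TestChainParsing:
    def test_three_block_fixture(self):
        cf = read_chain_file(io.StringIO(THREE_BLOCK))
        (c,) = cf.chains
        assert c.blocks == [(500, 50, 0), (200, 0, 100), (300, 0, 0)]
        c.validate()

    def test_bad_arithmetic_rejected(self):
        bad = THREE_BLOCK.replace("500 50 0", "500 51 0")
        with pytest.raises(ChainParseError, match="source range"):
            read_chain_file(io.StringIO(bad))

    def test_roundtrip(self, tmp_path):
        cf = read_chain_file(io.StringIO(THREE_BLOCK))
        p = tmp_path / "x.chain"
        write_chain_file(cf, p)
        back = read_chain_file(p)
        assert back.chains[0].blocks == cf.chains[0].blocks
        assert back.chains[0].q_start == cf.chains[0].q_start


class TestLiftover:
    def test_identity_chain_is_identity(self, rng):
        cf = identity_chain()
        for _ in range(10):
            start = int(rng.integers(0, 9_000))
            iv = GenomicInterval("chr1", start, start + int(rng.integers(1, 500)))
            out = liftover_interval(iv, cf)
            assert out is not None
            assert (out.chrom, out.start, out.end) == ("tchr1", iv.start, iv.end)

    def test_target_insertion_spans_gap(self):
        """A 50 bp target-side insertion inside a 500 bp interval: every
        source base maps (fraction 1.0) and the target span grows to 550."""
        cf = ChainFile([Chain(
            score=1, t_name="chr1", t_size=10_000, t_strand="+", t_start=1000,
            t_end=1500, q_name="tchr1", q_size=10_000, q_strand="+",
            q_start=2000, q_end=2550, chain_id="1",
            blocks=[(250, 0, 50), (250, 0, 0)],
        )])
        out = liftover_interval(GenomicInterval("chr1", 1000, 1500), cf)
        assert out is not None and out.width == 550
        assert (out.start, out.end) == (2000, 2550)

    def test_unmapped_off_chain(self):
        assert liftover_interval(GenomicInterval("chr2", 0, 100), identity_chain()) is None

    def test_source_gap_fails_min_match(self):
        # 100 of 200 bases deleted in the target: fraction 0.5 < 0.95
        cf = ChainFile([Chain(
            score=1, t_name="chr1", t_size=10_000, t_strand="+", t_start=0,
            t_end=200, q_name="tchr1", q_size=10_000, q_strand="+",
            q_start=0, q_end=100, chain_id="1",
            blocks=[(50, 100, 0), (50, 0, 0)],
        )])
        iv = GenomicInterval("chr1", 0, 200)
        assert liftover_interval(iv, cf, min_match=0.95) is None
        assert liftover_interval(iv, cf, min_match=0.5) is not None

    def test_minus_strand_flipped_to_forward(self):
        # q coordinates in minus-strand chains count from the reverse end
        cf = ChainFile([Chain(
            score=1, t_name="chr1", t_size=1_000, t_strand="+", t_start=100,
            t_end=200, q_name="tchr1", q_size=5_000, q_strand="-",
            q_start=400, q_end=500, chain_id="1", blocks=[(100, 0, 0)],
        )])
        out = liftover_interval(GenomicInterval("chr1", 100, 200), cf)
        assert (out.chrom, out.start, out.end) == ("tchr1", 5_000 - 500, 5_000 - 400)

    def test_two_qualifying_chains_ambiguous(self):
        a = identity_chain().chains[0]
        b = identity_chain(target="tchr2").chains[0]
        b.chain_id = "2"
        cf = ChainFile([a, b])
        assert liftover_interval(GenomicInterval("chr1", 10, 50), cf) is None

    def test_min_match_one_is_stricter(self, rng):
        cf = read_chain_file(io.StringIO(THREE_BLOCK))
        mapped_95, mapped_100 = set(), set()
        for _ in range(50):
            start = int(rng.integers(900, 2100))
            iv = GenomicInterval("chr1", start, start + int(rng.integers(10, 300)))
            if liftover_interval(iv, cf, 0.95) is not None:
                mapped_95.add((iv.start, iv.end))
            if liftover_interval(iv, cf, 1.0) is not None:
                mapped_100.add((iv.start, iv.end))
        assert mapped_100 <= mapped_95

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_basewise_oracle(self, seed):
        """Random chains vs a per-base mapping dictionary oracle."""
        rng = np.random.default_rng(700 + seed)
        blocks = []
        for i in range(int(rng.integers(1, 5))):
            blocks.append((int(rng.integers(5, 60)),
                           int(rng.integers(0, 30)),
                           int(rng.integers(0, 30))))
        blocks[-1] = (blocks[-1][0], 0, 0)
        t_len = sum(s + dt for s, dt, _ in blocks)
        q_len = sum(s + dq for s, _, dq in blocks)
        t_start, q_start = 100, 250
        chain = Chain(
            score=1, t_name="chr1", t_size=5_000, t_strand="+",
            t_start=t_start, t_end=t_start + t_len,
            q_name="tchr1", q_size=5_000, q_strand="+",
            q_start=q_start, q_end=q_start + q_len,
            chain_id="1", blocks=blocks,
        )
        chain.validate()
        base_map = {}
        t, q = t_start, q_start
        for size, dt, dq in blocks:
            for k in range(size):
                base_map[t + k] = q + k
            t += size + dt
            q += size + dq
        cf = ChainFile([chain])
        for _ in range(10):
            s = int(rng.integers(0, t_start + t_len + 50))
            iv = GenomicInterval("chr1", s, s + int(rng.integers(1, 80)))
            mapped_bases = [base_map[p] for p in range(iv.start, iv.end) if p in base_map]
            frac = len(mapped_bases) / iv.width
            out = liftover_interval(iv, cf, min_match=0.95)
            if frac >= 0.95:
                assert out is not None
                assert out.start == min(mapped_bases)
                assert out.end == max(mapped_bases) + 1
            else:
                assert out is None


def annotation(genes):
    """genes: list of (chrom, tss_pos, gene_id)."""
    return TssAnnotation(tss=[(c, p, g, "+") for c, p, g in genes])


class TestSynteny:
    src = annotation([("chr1", 1_000, "A"), ("chr1", 9_000, "B")])
    orth = OrthologyTable({"A": "mA", "B": "mB"})
    iv = GenomicInterval("chr1", 4_000, 5_000)

    def test_both_flanks_preserved(self):
        tgt = annotation([("tchr1", 500, "mA"), ("tchr1", 8_000, "mB")])
        mapped = GenomicInterval("tchr1", 4_000, 5_000)
        assert synteny_check(self.iv, mapped, self.src, tgt, self.orth)

    def test_no_orthologous_context(self):
        tgt = annotation([("tchr1", 500, "mX"), ("tchr1", 8_000, "mY")])
        mapped = GenomicInterval("tchr1", 4_000, 5_000)
        assert not synteny_check(self.iv, mapped, self.src, tgt, self.orth)

    def test_one_flank_lost(self):
        tgt = annotation([("tchr1", 500, "mA"), ("tchr1", 8_000, "mZ")])
        mapped = GenomicInterval("tchr1", 4_000, 5_000)
        assert synteny_check(self.iv, mapped, self.src, tgt, self.orth, mode="any")
        assert not synteny_check(self.iv, mapped, self.src, tgt, self.orth, mode="both")

    def test_no_flanking_gene_within_window(self):
        src = annotation([])
        tgt = annotation([])
        mapped = GenomicInterval("tchr1", 0, 10)
        assert synteny_check(self.iv, mapped, src, tgt, self.orth)

    def test_nearest_gene_by_linear_scan(self, rng):
        """Flanking genes agree with an exhaustive nearest-TSS search."""
        positions = sorted(int(p) for p in rng.choice(20_000, size=12, replace=False))
        src = annotation([("chr1", p, f"g{i}") for i, p in enumerate(positions)])
        orth = OrthologyTable({f"g{i}": f"mg{i}" for i in range(12)})
        tgt = annotation([("tchr1", p, f"mg{i}") for i, p in enumerate(positions)])
        for _ in range(10):
            s = int(rng.integers(0, 19_000))
            iv = GenomicInterval("chr1", s, s + 200)
            mapped = GenomicInterval("tchr1", s, s + 200)
            ups = [p for p in positions if p <= iv.start]
            downs = [p for p in positions if p >= iv.end]
            has_flank = bool(ups or downs)
            assert synteny_check(iv, mapped, src, tgt, orth) == True  # noqa: E712
            if has_flank:
                # drop all orthologs: must fail when flanks exist
                assert not synteny_check(iv, mapped, src, tgt, OrthologyTable({}))


class TestClassify:
    def make_setup(self):
        cf = identity_chain(length=20_000)
        regions = IntervalSet([
            GenomicInterval("chr1", 1_000, 1_500),
            GenomicInterval("chr1", 5_000, 5_500),
        ], sorted=True)
        ann = annotation([])
        return cf, regions, ann

    def test_empty_target_peaks_no_active(self):
        cf, regions, ann = self.make_setup()
        calls = classify_conservation(
            regions, ["e1", "e2"], cf, ann, ann, OrthologyTable({}), IntervalSet()
        )
        assert {c.status for c in calls} == {"conserved_inactive"}

    def test_bookended_peak_is_inactive(self):
        cf, regions, ann = self.make_setup()
        peaks = IntervalSet([GenomicInterval("tchr1", 1_500, 1_600)], sorted=True)
        calls = classify_conservation(
            regions, ["e1", "e2"], cf, ann, ann, OrthologyTable({}), peaks
        )
        assert calls[0].status == "conserved_inactive"

    def test_statuses_partition(self):
        cf, regions, ann = self.make_setup()
        peaks = IntervalSet([GenomicInterval("tchr1", 1_400, 1_600)], sorted=True)
        off_chain = IntervalSet(
            list(regions) + [GenomicInterval("chrUn", 0, 100)]
        )
        calls = classify_conservation(
            off_chain, ["e1", "e2", "e3"], cf, ann, ann, OrthologyTable({}), peaks
        )
        statuses = [c.status for c in calls]
        assert statuses == ["conserved_active", "conserved_inactive", "not_alignable"]
        for c in calls:
            assert (c.mapped_interval is None) == (c.status == "not_alignable")
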