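# faceenh

Tools and analyses for building **reproducible developmental enhancer
catalogs** from H3K27ac ChIP-seq peak calls and characterizing them:
temporal activity windows across gestational weeks, cross-species
conservation, enrichment of trait-associated variants, and
enhancer–target-gene association. The package is aimed at regulatory
genomicists working with multi-sample, multi-stage embryonic tissue
panels (the motivating setting is human craniofacial development,
Carnegie stages CS13–CS23, gestational weeks 4–8).

## What it computes

**Catalog.** Per-sample peak sets are merged with bedtools semantics
(bookended intervals merge at `max_gap = 0`), merged regions within 1 kb of
any transcription start site are removed (distal filter), and a region is
kept iff it is supported by ≥ 2 distinct biological samples *within a
single week* (a pooled-across-weeks mode is available).

**Temporal classes.** Each enhancer gets a boolean activity vector over
weeks 4–8 (active = ≥ 2 supporting samples that week) and one of four
labels: *constant* (all five weeks), *week-specific* (exactly one),
*continuous* (one contiguous run of 2–4), *non-continuous* (≥ 2 active
weeks with a gap).

**Conservation.** Enhancers are mapped to a target genome by walking UCSC
chain alignments (≥ 95% of bases must map through a single chain), checked
for preserved flanking protein-coding gene context via an orthology table,
and classified `not_alignable` / `conserved_inactive` / `conserved_active`
(mapped location overlaps a target-species H3K27ac peak).

**SNP enrichment.** GWAS lead SNPs are expanded to LD partners with
r² ≥ 0.8, and the full SNP catalog is partitioned into the 2×2 table
(trait-associated × inside-enhancer). The test reports the odds ratio
OR = (a/b)/(c/d) and Pearson's chi-squared with Yates' continuity
correction,

```
X² = N · max(0, |ad − bc| − N/2)² / ((a+b)(c+d)(a+c)(b+d)),   df = 1.
```

**Enhancer–gene pairs.** Enhancers are linked to genes through
promoter-interaction fragments; enhancer signal is TMM-normalized
(trimmed mean of M-values, 30%/5% trims, precision-weighted); each pair is
scored with Spearman's ρ across matched samples and the pair ρ
distribution is compared against all other enhancer × gene combinations
with a one-sided Mann–Whitney U test.

**Synthetic studies.** `faceenh.simulate` generates a fully self-contained
study with planted ground truth — genome, genes, enhancers with temporal
classes, per-sample peaks with dropout/jitter, chain file and target peaks
with planted conservation fractions, SNPs with a planted enrichment odds
ratio, and signal/expression matrices with coupled true pairs — so every
stage can be validated against known truth.

## Worked example

Running the numbered analyses in order regenerates the default synthetic
study (2,000 enhancers, 17 H3K27ac samples, seed 1) and analyzes it:

```
$ python analysis/01_simulate_study.py
$ python analysis/05_snp_enrichment.py
770 lead SNPs -> 20000 after LD expansion
contingency a=2039 b=17961 c=14541 d=165459
OR = 1.292 (95% CI 1.230-1.356); Yates X^2 = 105.795, p = 8.18e-25
2039 associated SNPs hit 1288 enhancer regions
```

Here 2,039 of 20,000 LD-expanded trait-associated SNPs fall inside
catalog enhancers versus 14,541 of 180,000 background SNPs; the estimated
odds ratio 1.29 recovers the planted value of 1.27 within its confidence
interval. The other scripts report the catalog size and ATAC support
(script 02), the temporal class mix (03), the conservation split (04), and
the pair test (06); `analysis/07_full_pipeline.py` runs everything through
the orchestrated pipeline and writes `summary.json`.

As a library:

```python
from faceenh.gwas import ContingencyTable, enrichment_test
res = enrichment_test(ContingencyTable(a=605, b=26781, c=245727, d=13838215))
print(round(res.odds_ratio, 2), round(res.chi2, 3))   # 1.27 34.102
```

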