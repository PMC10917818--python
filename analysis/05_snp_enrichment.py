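"""Test trait-associated SNPs for enrichment inside the enhancer catalog.

Expands lead SNPs to their LD partners (r^2 >= 0.8), partitions the whole
SNP catalog by association status and enhancer overlap, and runs the
odds-ratio / Yates chi-squared enrichment test.
"""

import importlib
import json

paths = importlib.import_module("00_paths")

from faceenh.catalog import build_catalog, read_manifest
from faceenh.gwas import (
    SnpCatalog, build_contingency, enrichment_test, expand_ld,
    odds_ratio_ci, read_ld_table, read_snp_table,
)
from faceenh.intervals import read_tss_table


def main():
    tracks = [t for t in read_manifest(paths.STUDY_DIR / "manifest.tsv")
              if t.assay == "H3K27ac"]
    tss = read_tss_table(paths.STUDY_DIR / "tss.tsv")
    catalog = build_catalog(tracks, tss)

    snps = read_snp_table(paths.STUDY_DIR / "snps.tsv", one_based=True)
    ld = read_ld_table(paths.STUDY_DIR / "ld.tsv")
    snp_cat = SnpCatalog(snps=snps, ld_pairs=ld)
    leads = {ln.strip() for ln in
             (paths.STUDY_DIR / "lead_snps.txt").read_text().splitlines() if ln.strip()}

    associated = expand_ld(leads, snp_cat, r2_min=0.8)
    table, per_region = build_contingency(snp_cat, associated, catalog.regions)
    result = enrichment_test(table, per_region_hits=per_region)
    lo, hi = odds_ratio_ci(table)

    print(f"{len(leads)} lead SNPs -> {len(associated)} after LD expansion")
    print(f"contingency a={table.a} b={table.b} c={table.c} d={table.d}")
    print(f"OR = {result.odds_ratio:.3f} (95% CI {lo:.3f}-{hi:.3f}); "
          f"Yates X^2 = {result.chi2:.3f}, p = {result.p_value:.3g}")
    print(f"{result.n_snps_in_regions} associated SNPs hit "
          f"{result.n_regions_hit} enhancer regions")

    (paths.RESULTS_DIR / "05_enrichment.json").write_text(json.dumps({
        "n_leads": len(leads), "n_ld_expanded": len(associated),
        "a": table.a, "b": table.b, "c": table.c, "d": table.d,
        "odds_ratio": result.odds_ratio, "or_ci": [lo, hi],
        "chi2": result.chi2, "p_value": result.p_value,
        "n_regions_hit": result.n_regions_hit,
    }, indent=1))


if __name__ == "__main__":
    main()
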