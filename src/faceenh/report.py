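"""Pipeline orchestration, validated-element annotation, summary report.

``run_pipeline`` composes every stage — catalog construction, temporal
classification, conservation, SNP enrichment, enhancer:gene association and
validated-element annotation — over a study directory (as written by
:func:`faceenh.simulate.write_study` or assembled from real files with the
same layout), writes per-stage tables and a machine-readable JSON summary,
and is deterministic given inputs plus seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .catalog import (
    EnhancerCatalog, SampleTrack, WEEKS, atac_support_fraction, build_catalog,
    read_manifest,
)
from .conservation import (
    classify_conservation, conservation_to_rows, read_chain_file,
    read_orthology_table,
)
from .gwas import (
    SnpCatalog, build_contingency, enrichment_test, read_ld_table, read_snp_table,
)
from .intervals import GenomicInterval, IntervalSet, count_overlaps, read_tss_table
from .pairs import correlate_pairs, read_interactions, assign_targets

log = logging.getLogger("faceenh")

REPORT_SCHEMA_VERSION = 1

__all__ = ["PipelineConfig", "annotate_validated", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Paths and thresholds for one end-to-end run."""

    study_dir: str
    out_dir: str
    seed: int = 0
    min_samples: int = 2
    tss_radius: int = 1000
    reproducibility_scope: str = "week"
    min_match: float = 0.95
    r2_min: float = 0.8
    vista_min_overlap: int = 100
    pair_alternative: str = "greater"
    max_background_pairs: int = 20_000

    def __post_init__(self) -> None:
        if not (0 < self.min_match <= 1):
            raise ValueError("min_match must be in (0, 1]")
        if not (0 <= self.r2_min <= 1):
            raise ValueError("r2_min must be in [0, 1]")
        if self.vista_min_overlap < 1:
            raise ValueError("vista_min_overlap must be >= 1")
        if self.min_samples < 1:
            raise ValueError("min_samples must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "rt") as fh:
            return cls(**yaml.safe_load(fh))


def annotate_validated(
    catalog: EnhancerCatalog, validated: pd.DataFrame, min_overlap: int = 100
) -> tuple[pd.DataFrame, dict]:
    """Intersect validated (in vivo tested) elements with the catalog.

    ``validated`` columns: chrom, start, end, element_id, activity. An
    element counts as recovered when some catalog enhancer overlaps it by at
    least ``min_overlap`` bp. Returns the per-element overlap table and
    summary counts.
    """
    elements = IntervalSet([
        GenomicInterval(r.chrom, int(r.start), int(r.end), str(r.element_id))
        for r in validated.itertuples(index=False)
    ])
    hits = count_overlaps(elements, catalog.regions, min_overlap=min_overlap)
    rows = []
    for i, rec in enumerate(hits):
        for j, width in rec:
            rows.append({
                "element_id": elements[i].name,
                "activity": validated.iloc[i]["activity"],
                "enhancer_id": catalog.ids[j],
                "overlap_bp": width,
            })
    table = pd.DataFrame(rows, columns=["element_id", "activity", "enhancer_id", "overlap_bp"])
    n_hit = sum(1 for rec in hits if rec)
    counts = {
        "n_validated": len(elements),
        "n_overlapping": n_hit,
        "fraction_overlapping": n_hit / len(elements) if len(elements) else 0.0,
    }
    return table, counts


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages in order and write per-stage outputs plus a
    summary JSON. Any stage error aborts with a stage-qualified message."""
    study = Path(cfg.study_dir)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "parameters": asdict(cfg),
    }

    def stage(name):
        log.info("stage %s", name)
        return name

    # --- catalog ---------------------------------------------------------
    name = stage("catalog")
    try:
        tracks = read_manifest(study / "manifest.tsv", base_dir=study)
        h3k = [t for t in tracks if t.assay == "H3K27ac"]
        atac = [t for t in tracks if t.assay == "ATAC"]
        tss = read_tss_table(study / "tss.tsv")
        catalog = build_catalog(
            h3k, tss, min_samples=cfg.min_samples, tss_radius=cfg.tss_radius,
            reproducibility_scope=cfg.reproducibility_scope,
        )
        catalog.write(out / "catalog.bed", out / "catalog_support.tsv")
        summary["catalog"] = {
            "n_enhancers": len(catalog),
            "n_h3k27ac_samples": len(h3k),
        }
        if atac:
            wk7_idx = [
                i for i in range(len(catalog))
                if len(catalog.support[i].get(7, frozenset())) >= cfg.min_samples
            ]
            wk7_regions = IntervalSet([catalog.regions[i] for i in wk7_idx], sorted=True)
            frac = atac_support_fraction(wk7_regions, atac) if len(wk7_regions) else 0.0
            summary["catalog"]["atac_support_fraction_week7"] = frac
    except Exception as exc:
        raise RuntimeError(f"stage catalog failed: {exc}") from exc

    # --- temporal --------------------------------------------------------
    from .temporal import build_activity_matrix, classify_all, week_transition_summary

    stage("temporal")
    try:
        matrix = build_activity_matrix(catalog, min_samples_per_week=cfg.min_samples)
        classes = classify_all(matrix)
        classes.to_csv(out / "temporal_classes.tsv", sep="\t", index=False)
        counts = classes["temporal_class"].value_counts().to_dict()
        transitions = week_transition_summary(matrix)
        transitions.to_csv(out / "week_transitions.tsv", sep="\t", index=False)
        summary["temporal"] = {
            "class_counts": {k: int(counts.get(k, 0)) for k in
                             ("constant", "week_specific", "continuous", "non_continuous")},
            "class_fractions": {
                k: (counts.get(k, 0) / len(classes) if len(classes) else 0.0)
                for k in ("constant", "week_specific", "continuous", "non_continuous")
            },
        }
    except Exception as exc:
        raise RuntimeError(f"stage temporal failed: {exc}") from exc

    # --- conservation ----------------------------------------------------
    stage("conservation")
    try:
        chains = read_chain_file(study / "study.chain")
        target_ann = read_tss_table(study / "target_tss.tsv")
        orth = read_orthology_table(study / "orthology.tsv")
        from .intervals import read_bed
        target_peaks = read_bed(study / "target_peaks.bed").sort()
        calls = classify_conservation(
            catalog.regions, catalog.ids, chains, tss, target_ann, orth,
            target_peaks, min_match=cfg.min_match,
        )
        pd.DataFrame(conservation_to_rows(calls)).to_csv(
            out / "conservation.tsv", sep="\t", index=False
        )
        n = len(calls)
        ccounts = {s: sum(1 for c in calls if c.status == s)
                   for s in ("conserved_active", "conserved_inactive", "not_alignable")}
        summary["conservation"] = {
            "counts": ccounts,
            "fractions": {k: (v / n if n else 0.0) for k, v in ccounts.items()},
            "fraction_alignable": (
                (ccounts["conserved_active"] + ccounts["conserved_inactive"]) / n if n else 0.0
            ),
        }
    except Exception as exc:
        raise RuntimeError(f"stage conservation failed: {exc}") from exc

    # --- snp enrichment --------------------------------------------------
    stage("enrichment")
    try:
        snps = read_snp_table(study / "snps.tsv", one_based=True)
        ld = read_ld_table(study / "ld.tsv")
        snp_cat = SnpCatalog(snps=snps, ld_pairs=ld)
        from .gwas import expand_ld
        leads = {
            line.strip()
            for line in (study / "lead_snps.txt").read_text().splitlines()
            if line.strip()
        }
        associated = expand_ld(leads, snp_cat, r2_min=cfg.r2_min)
        table, per_region = build_contingency(snp_cat, associated, catalog.regions)
        result = enrichment_test(table, per_region_hits=per_region)
        with open(out / "enrichment.json", "wt") as fh:
            json.dump({
                "odds_ratio": result.odds_ratio, "chi2": result.chi2,
                "df": result.df, "p_value": result.p_value,
                "table": asdict(table),
                "n_ld_snps": len(associated),
                "n_snps_in_regions": result.n_snps_in_regions,
                "n_regions_hit": result.n_regions_hit,
            }, fh, indent=1)
        hit_rows = [
            {"enhancer_id": catalog.ids[i], "snp_ids": ",".join(sids)}
            for i, sids in result.per_region_hits.items()
        ]
        pd.DataFrame(hit_rows, columns=["enhancer_id", "snp_ids"]).to_csv(
            out / "enrichment_hits.tsv", sep="\t", index=False
        )
        from .gwas import snp_region_overlap
        by_class = {}
        for tclass in ("disease", "normal_variation"):
            ids = set(
                snps.loc[snps["trait_class"] == tclass, "snp_id"]
            ) & associated
            n_in, n_regions, _ = snp_region_overlap(ids, catalog.regions, snp_cat)
            by_class[tclass] = {"n_snps_in_regions": n_in, "n_regions_hit": n_regions}
        summary["enrichment"] = {
            "odds_ratio": result.odds_ratio, "chi2": result.chi2,
            "p_value": result.p_value,
            "n_snps_in_regions": result.n_snps_in_regions,
            "n_regions_hit": result.n_regions_hit,
            "by_trait_class": by_class,
        }
    except Exception as exc:
        raise RuntimeError(f"stage enrichment failed: {exc}") from exc

    # --- enhancer:gene pairs --------------------------------------------
    stage("pairs")
    try:
        imap = read_interactions(study / "interactions.tsv")
        predicted = assign_targets(catalog, imap)
        signal = pd.read_csv(study / "signal.tsv", sep="\t", index_col=0)
        expression = pd.read_csv(study / "expression.tsv", sep="\t", index_col=0)
        # signal rows are true-enhancer ids; match catalog regions to them by
        # coordinate identity of names assigned upstream
        rho_table, test = correlate_pairs(
            _pairs_with_signal_ids(predicted, catalog, signal),
            signal, expression,
            max_background=cfg.max_background_pairs,
            rng=np.random.default_rng(cfg.seed),
            alternative=cfg.pair_alternative,
        )
        rho_table.to_csv(out / "pair_correlations.tsv", sep="\t", index=False)
        summary["pairs"] = {
            "n_predicted_pairs": len(predicted),
            "n_tested_pairs": test.n_pairs,
            "n_background": test.n_background,
            "u_statistic": test.u_statistic,
            "p_value": test.p_value,
        }
    except Exception as exc:
        raise RuntimeError(f"stage pairs failed: {exc}") from exc

    # --- validated elements ---------------------------------------------
    stage("validated")
    try:
        vpath = study / "validated.tsv"
        if vpath.exists():
            validated = pd.read_csv(vpath, sep="\t")
            vtable, vcounts = annotate_validated(
                catalog, validated, min_overlap=cfg.vista_min_overlap
            )
            vtable.to_csv(out / "validated_overlaps.tsv", sep="\t", index=False)
            summary["validated"] = vcounts
    except Exception as exc:
        raise RuntimeError(f"stage validated failed: {exc}") from exc

    with open(out / "summary.json", "wt") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return summary


def _pairs_with_signal_ids(
    predicted: list[tuple[str, str]], catalog: EnhancerCatalog, signal: pd.DataFrame
) -> list[tuple[str, str]]:
    """Re-key predicted pairs onto the signal matrix's row ids.

    When the signal matrix is already keyed by catalog enhancer ids, pairs
    pass through unchanged. Otherwise rows are expected to be keyed by the
    quantified region's coordinates (``chrom:start-end``); each catalog
    region is matched to the signal row it overlaps most.
    """
    if predicted and all(e in signal.index for e, _ in predicted):
        return predicted
    sig_ivs = []
    for key in signal.index:
        chrom, span = str(key).split(":")
        start, end = span.split("-")
        sig_ivs.append(GenomicInterval(chrom, int(start), int(end), str(key)))
    sig_set = IntervalSet(sig_ivs)
    hits = count_overlaps(catalog.regions, sig_set, min_overlap=1)
    key_for_catalog: dict[str, str] = {}
    for i, rec in enumerate(hits):
        if rec:
            j, _w = max(rec, key=lambda t: t[1])
            key_for_catalog[catalog.ids[i]] = sig_ivs[j].name
    return sorted({
        (key_for_catalog[e], g) for e, g in predicted if e in key_for_catalog
    })
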