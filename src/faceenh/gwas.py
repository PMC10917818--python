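"""LD expansion of GWAS lead SNPs and enhancer-overlap enrichment testing.

Lead SNPs from association studies are expanded to their LD partners at
r^2 >= 0.8, intersected with the enhancer catalog, and the full SNP catalog
is partitioned into a 2x2 contingency table (trait-associated x in-enhancer)
tested with the odds ratio and Pearson's chi-squared with Yates' continuity
correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .intervals import IntervalSet

__all__ = [
    "SnpCatalog",
    "ContingencyTable",
    "EnrichmentResult",
    "read_snp_table",
    "read_ld_table",
    "expand_ld",
    "snp_region_overlap",
    "build_contingency",
    "enrichment_test",
    "odds_ratio_ci",
]

TRAIT_CLASSES = ("disease", "normal_variation", "none")


@dataclass
class SnpCatalog:
    """SNP positions (0-based) with association flags plus an LD-pair table.

    ``snps`` columns: chrom, pos, snp_id, associated, trait_class.
    ``ld_pairs`` columns: lead_id, partner_id, r2, population.
    """

    snps: pd.DataFrame
    ld_pairs: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["lead_id", "partner_id", "r2", "population"]
        )
    )

    def __post_init__(self) -> None:
        if self.snps["snp_id"].duplicated().any():
            raise ValueError("snp_ids must be unique")
        r2 = self.ld_pairs["r2"].to_numpy(dtype=float) if len(self.ld_pairs) else np.array([])
        if len(r2) and not ((r2 >= 0) & (r2 <= 1)).all():
            raise ValueError("r2 values must lie in [0, 1]")

    def ids(self) -> set[str]:
        return set(self.snps["snp_id"])


def read_snp_table(path: str | Path, one_based: bool = True) -> pd.DataFrame:
    """Read a SNP TSV (chrom, pos, id, associated_flag[, trait_class]).

    dbSNP-style 1-based positions are converted to 0-based at this boundary.
    """
    df = pd.read_csv(
        path, sep="\t", comment="#",
        names=["chrom", "pos", "snp_id", "associated", "trait_class"],
        dtype={"chrom": str, "pos": np.int64, "snp_id": str},
    )
    if one_based:
        df["pos"] = df["pos"] - 1
    df["associated"] = df["associated"].astype(int).astype(bool)
    df["trait_class"] = df["trait_class"].fillna("none")
    return df


def read_ld_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", comment="#",
        names=["lead_id", "partner_id", "r2", "population"],
        dtype={"lead_id": str, "partner_id": str, "r2": float, "population": str},
    )


def expand_ld(lead_ids: set[str], catalog: SnpCatalog, r2_min: float = 0.8) -> set[str]:
    """Leads plus all partners with r^2 >= ``r2_min``, deduplicated.

    Unknown lead ids produce a warning and are skipped (the LD resource and
    the SNP catalog never match perfectly in practice).
    """
    if not (0 <= r2_min <= 1):
        raise ValueError("r2_min must be in [0, 1]")
    known = catalog.ids()
    unknown = set(lead_ids) - known
    if unknown:
        warnings.warn(f"{len(unknown)} lead SNP ids absent from catalog; skipped")
    leads = set(lead_ids) & known
    lp = catalog.ld_pairs
    if len(lp):
        mask = lp["lead_id"].isin(leads) & (lp["r2"] >= r2_min)
        partners = set(lp.loc[mask, "partner_id"]) & known
    else:
        partners = set()
    return leads | partners


def snp_region_overlap(
    snp_ids: set[str], regions: IntervalSet, catalog: SnpCatalog
) -> tuple[int, int, dict[int, list[str]]]:
    """Overlap a SNP id set with disjoint regions.

    A SNP at position p lies in region [s, e) iff s <= p < e. Returns
    (number of SNPs inside any region, number of regions hit,
    region_index -> sorted SNP id list).
    """
    sub = catalog.snps[catalog.snps["snp_id"].isin(snp_ids)]
    per_region: dict[int, list[str]] = {}
    n_in = 0
    regs = regions.sort() if not regions.sorted else regions
    idx_map = _region_index_map(regions, regs)
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, grp in _regions_by_chrom(regs).items():
        starts = np.array([iv.start for iv in grp[0]])
        ends = np.array([iv.end for iv in grp[0]])
        by_chrom[chrom] = (starts, ends, np.array(grp[1]))
    for chrom, chunk in sub.groupby("chrom"):
        if chrom not in by_chrom:
            continue
        starts, ends, orig_idx = by_chrom[chrom]
        pos = chunk["pos"].to_numpy()
        j = np.searchsorted(starts, pos, side="right") - 1
        ok = (j >= 0) & (pos < ends[np.clip(j, 0, None)])
        n_in += int(ok.sum())
        for sid, jj in zip(chunk["snp_id"].to_numpy()[ok], j[ok]):
            per_region.setdefault(int(idx_map[int(orig_idx[jj])]), []).append(sid)
    per_region = {k: sorted(v) for k, v in sorted(per_region.items())}
    return n_in, len(per_region), per_region


def _regions_by_chrom(regs: IntervalSet):
    out: dict[str, tuple[list, list[int]]] = {}
    for i, iv in enumerate(regs):
        out.setdefault(iv.chrom, ([], []))[0].append(iv)
        out[iv.chrom][1].append(i)
    return out


def _region_index_map(original: IntervalSet, sorted_set: IntervalSet) -> dict[int, int]:
    """Map indices in the sorted view back to the caller's region indices."""
    if original is sorted_set:
        return {i: i for i in range(len(original))}
    key_to_orig = {
        (iv.chrom, iv.start, iv.end): i for i, iv in enumerate(original)
    }
    return {
        j: key_to_orig[(iv.chrom, iv.start, iv.end)] for j, iv in enumerate(sorted_set)
    }


@dataclass
class ContingencyTable:
    """2x2 partition of a SNP catalog: association status x enhancer overlap."""

    a: int  # associated, in regions
    b: int  # associated, outside
    c: int  # background, in regions
    d: int  # background, outside

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be nonnegative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class EnrichmentResult:
    odds_ratio: float
    chi2: float
    df: int
    p_value: float
    table: ContingencyTable
    per_region_hits: dict[int, list[str]] = field(default_factory=dict)

    @property
    def n_snps_in_regions(self) -> int:
        return self.table.a

    @property
    def n_regions_hit(self) -> int:
        return len(self.per_region_hits)


def enrichment_test(
    t: ContingencyTable,
    haldane: bool = False,
    per_region_hits: dict[int, list[str]] | None = None,
) -> EnrichmentResult:
    """Odds ratio + Yates-corrected chi-squared test on a 2x2 table.

    OR = (a/b)/(c/d); chi2 uses the clamped Yates form
    N * max(0, |ad - bc| - N/2)^2 / ((a+b)(c+d)(a+c)(b+d)).
    A zero cell raises unless ``haldane``, which adds 0.5 to every cell for
    the odds ratio only.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    if 0 in (a, b, c, d):
        if not haldane:
            raise ValueError("zero cell in contingency table (enable haldane)")
        orr = ((a + 0.5) / (b + 0.5)) / ((c + 0.5) / (d + 0.5))
    else:
        orr = (a / b) / (c / d)
    n = t.n
    margins = (a + b) * (c + d) * (a + c) * (b + d)
    if margins == 0:
        raise ValueError("degenerate margin in contingency table")
    disc = max(0.0, abs(a * d - b * c) - n / 2)
    stat = n * disc * disc / margins
    p = float(chi2.sf(stat, df=1))
    return EnrichmentResult(
        odds_ratio=float(orr), chi2=float(stat), df=1, p_value=p,
        table=t, per_region_hits=per_region_hits or {},
    )


def odds_ratio_ci(t: ContingencyTable, level: float = 0.95) -> tuple[float, float]:
    """Woolf logit confidence interval for the odds ratio."""
    from scipy.stats import norm

    a, b, c, d = t.a, t.b, t.c, t.d
    if 0 in (a, b, c, d):
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    log_or = np.log((a / b) / (c / d))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = norm.ppf(0.5 + level / 2)
    return float(np.exp(log_or - z * se)), float(np.exp(log_or + z * se))


def _in_region_mask(df: pd.DataFrame, regions: IntervalSet) -> np.ndarray:
    """Vectorized point-in-disjoint-interval membership for a SNP frame."""
    regs = regions.sort() if not regions.sorted else regions
    tmp: dict[str, list[list[int]]] = {}
    for iv in regs:
        tmp.setdefault(iv.chrom, [[], []])
        tmp[iv.chrom][0].append(iv.start)
        tmp[iv.chrom][1].append(iv.end)
    mask = np.zeros(len(df), dtype=bool)
    pos_all = df["pos"].to_numpy()
    chrom_codes, uniques = pd.factorize(df["chrom"])
    for ci, chrom in enumerate(uniques):
        if chrom not in tmp:
            continue
        starts = np.asarray(tmp[chrom][0])
        ends = np.asarray(tmp[chrom][1])
        sel = chrom_codes == ci
        pos = pos_all[sel]
        j = np.searchsorted(starts, pos, side="right") - 1
        ok = (j >= 0) & (pos < ends[np.clip(j, 0, None)])
        mask[sel] = ok
    return mask


def build_contingency(
    catalog: SnpCatalog, associated_ids: set[str], regions: IntervalSet
) -> tuple[ContingencyTable, dict[int, list[str]]]:
    """Partition the whole SNP catalog by membership in ``associated_ids``
    and overlap with ``regions``; also returns per-region associated hits."""
    df = catalog.snps
    assoc_mask = df["snp_id"].isin(associated_ids).to_numpy()
    in_mask = _in_region_mask(df, regions)
    a = int((assoc_mask & in_mask).sum())
    b = int(assoc_mask.sum()) - a
    c = int((~assoc_mask & in_mask).sum())
    d = int((~assoc_mask).sum()) - c
    assoc_in = df.loc[assoc_mask & in_mask, "snp_id"]
    _, _, per_region = snp_region_overlap(set(assoc_in), regions, catalog)
    return ContingencyTable(a=a, b=b, c=c, d=d), per_region
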