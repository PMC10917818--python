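"""Distal reproducible enhancer catalog construction.

Per-sample H3K27ac peak sets are merged across all samples (bedtools-merge
semantics, bookended peaks merge), merged regions within a fixed radius of
any transcription start site are dropped (distal filter), and the survivors
are kept only when supported by at least ``min_samples`` distinct samples —
by default within a single gestational week (``reproducibility_scope =
'week'``); the looser pooled-across-weeks reading is available as
``'global'``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .intervals import (
    GenomicInterval,
    IntervalSet,
    TssAnnotation,
    count_overlaps,
    merge_intervals,
    read_bed,
    remove_near_tss,
    write_bed,
)

__all__ = [
    "SampleTrack",
    "EnhancerCatalog",
    "DEFAULT_STAGE_WEEK_MAP",
    "read_manifest",
    "build_catalog",
    "atac_support_fraction",
]

WEEKS = (4, 5, 6, 7, 8)

# Carnegie stage -> gestational week. Only week 7 (CS18+CS19) is pinned by
# the study design; the rest is a documented, configurable default.
DEFAULT_STAGE_WEEK_MAP: dict[str, int] = {
    "CS13": 4,
    "CS14": 5, "CS15": 5,
    "CS16": 6, "CS17": 6,
    "CS18": 7, "CS19": 7,
    "CS20": 8, "CS22": 8, "CS23": 8,
}


@dataclass
class SampleTrack:
    """One biological sample's peak set plus staging metadata."""

    sample_id: str
    carnegie_stage: str
    week: int
    assay: str  # {"H3K27ac", "ATAC"}
    peaks: IntervalSet

    def __post_init__(self) -> None:
        if self.assay not in ("H3K27ac", "ATAC"):
            raise ValueError(f"unknown assay {self.assay!r}")
        if self.week not in WEEKS:
            raise ValueError(f"week {self.week} outside 4..8")
        expected = DEFAULT_STAGE_WEEK_MAP.get(self.carnegie_stage)
        if expected is not None and expected != self.week:
            raise ValueError(
                f"sample {self.sample_id}: stage {self.carnegie_stage} maps to "
                f"week {expected}, not {self.week}"
            )


@dataclass
class EnhancerCatalog:
    """Merged distal reproducible regions with per-week sample support."""

    regions: IntervalSet
    ids: list[str]
    support: list[dict[int, frozenset[str]]]  # per region: week -> sample ids
    params: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.regions)

    def max_weekly_support(self, i: int) -> int:
        sup = self.support[i]
        return max((len(v) for v in sup.values()), default=0)

    def validate(self, min_samples: int, scope: str = "week") -> None:
        for i in range(len(self)):
            if scope == "week":
                ok = any(len(v) >= min_samples for v in self.support[i].values())
            else:
                ok = len(set().union(*self.support[i].values() or [set()])) >= min_samples
            if not ok:
                raise AssertionError(f"region {self.ids[i]} violates support invariant")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, iv in enumerate(self.regions):
            row = {
                "enhancer_id": self.ids[i],
                "chrom": iv.chrom, "start": iv.start, "end": iv.end,
            }
            for w in WEEKS:
                row[f"wk{w}_samples"] = ",".join(sorted(self.support[i].get(w, frozenset())))
            rows.append(row)
        return pd.DataFrame(rows)

    def write(self, bed_path: str | Path, support_path: str | Path) -> None:
        named = IntervalSet(
            [GenomicInterval(iv.chrom, iv.start, iv.end, self.ids[i])
             for i, iv in enumerate(self.regions)],
            sorted=self.regions.sorted,
        )
        write_bed(
            named, bed_path,
            provenance=f"faceenh enhancer catalog; params={self.params}",
            scores=[self.max_weekly_support(i) for i in range(len(self))],
        )
        with open(support_path, "wt") as fh:
            fh.write("enhancer_id\tweek\tsample_ids\n")
            for i, rid in enumerate(self.ids):
                for w in WEEKS:
                    samples = self.support[i].get(w, frozenset())
                    if samples:
                        fh.write(f"{rid}\t{w}\t{','.join(sorted(samples))}\n")


def read_manifest(path: str | Path, base_dir: str | Path | None = None) -> list[SampleTrack]:
    """Load a sample manifest TSV (sample_id, stage, week, assay, bed_path)."""
    base = Path(base_dir) if base_dir is not None else Path(path).parent
    df = pd.read_csv(path, sep="\t", comment="#")
    tracks = []
    for rec in df.itertuples(index=False):
        bed = Path(rec.bed_path)
        if not bed.is_absolute():
            bed = base / bed
        tracks.append(SampleTrack(
            sample_id=str(rec.sample_id),
            carnegie_stage=str(rec.stage),
            week=int(rec.week),
            assay=str(rec.assay),
            peaks=read_bed(bed),
        ))
    return tracks


def build_catalog(
    tracks: list[SampleTrack],
    tss: TssAnnotation,
    min_samples: int = 2,
    tss_radius: int = 1000,
    reproducibility_scope: str = "week",
) -> EnhancerCatalog:
    """Merge all samples' peaks, drop TSS-proximal regions, keep reproducible ones.

    A region is reproducible when >= ``min_samples`` distinct samples overlap
    it (>= 1 bp) within at least one week (scope ``'week'``), or pooled over
    all weeks (scope ``'global'``).
    """
    if not tracks:
        raise ValueError("at least one sample track is required")
    assays = {t.assay for t in tracks}
    if len(assays) != 1:
        raise ValueError(f"tracks mix assays: {sorted(assays)}")
    if reproducibility_scope not in ("week", "global"):
        raise ValueError("reproducibility_scope must be 'week' or 'global'")

    labelled = IntervalSet([
        GenomicInterval(iv.chrom, iv.start, iv.end, t.sample_id)
        for t in tracks for iv in t.peaks
    ])
    merged = merge_intervals(labelled, max_gap=0)
    distal = remove_near_tss(merged, tss, radius=tss_radius)

    # support bookkeeping: which samples in which weeks overlap each region
    supports: list[dict[int, set[str]]] = [dict() for _ in range(len(distal))]
    for t in tracks:
        hits = count_overlaps(distal, t.peaks, min_overlap=1)
        for i, rec in enumerate(hits):
            if rec:
                supports[i].setdefault(t.week, set()).add(t.sample_id)

    kept: list[int] = []
    for i in range(len(distal)):
        if reproducibility_scope == "week":
            ok = any(len(s) >= min_samples for s in supports[i].values())
        else:
            all_samples: set[str] = set()
            for s in supports[i].values():
                all_samples |= s
            ok = len(all_samples) >= min_samples
        if ok:
            kept.append(i)

    width = max(6, len(str(len(kept))))
    catalog = EnhancerCatalog(
        regions=IntervalSet([distal[i] for i in kept], sorted=True),
        ids=[f"ENH{j + 1:0{width}d}" for j in range(len(kept))],
        support=[
            {w: frozenset(s) for w, s in sorted(supports[i].items())} for i in kept
        ],
        params={
            "min_samples": min_samples,
            "tss_radius": tss_radius,
            "reproducibility_scope": reproducibility_scope,
            "n_tracks": len(tracks),
        },
    )
    catalog.validate(min_samples, reproducibility_scope)
    return catalog


def atac_support_fraction(
    catalog_regions: IntervalSet, atac_tracks: list[SampleTrack]
) -> float:
    """Fraction of regions overlapping (>=1 bp) the union of ATAC peaks."""
    if not atac_tracks:
        raise ValueError("at least one ATAC track is required")
    pooled = IntervalSet([iv for t in atac_tracks for iv in t.peaks])
    union = merge_intervals(pooled, max_gap=0)
    if len(catalog_regions) == 0:
        return 0.0
    hits = count_overlaps(catalog_regions, union, min_overlap=1)
    return sum(1 for rec in hits if rec) / len(catalog_regions)
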