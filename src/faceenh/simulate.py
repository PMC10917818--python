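"""Self-contained synthetic study generator with planted ground truth.

Emulates a multi-sample developmental H3K27ac study: a small genome with
protein-coding genes, non-overlapping distal enhancers with planted temporal
classes over gestational weeks 4-8, per-sample peak calls with dropout and
edge jitter, cross-species chain alignments with planted conservation
labels, a SNP catalog with a planted in-enhancer enrichment odds ratio plus
LD blocks straddling the r^2 = 0.8 threshold, and matched signal/expression
matrices where true enhancer:gene pairs share a latent per-sample activity
factor.

Everything is deterministic given the config seed; all outputs round-trip
through the package readers.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .catalog import DEFAULT_STAGE_WEEK_MAP, SampleTrack, WEEKS
from .conservation import Chain, ChainFile, OrthologyTable, write_chain_file
from .gwas import SnpCatalog
from .intervals import GenomicInterval, IntervalSet, TssAnnotation, write_bed, write_tss_table

__all__ = ["TruthConfig", "TruthSet", "generate_truth", "simulate_sample_peaks",
           "simulate_snps", "simulate_signal_and_expression", "simulate_atac_tracks",
           "write_study"]

_OBSERVED_CLASS_MIX = {  # observed catalog class mix, normalized at use
    "constant": 1624.0,
    "week_specific": 6347.0,
    "continuous": 3749.0,
    "non_continuous": 2236.0,
}

_STAGE_FOR_WEEK = {4: "CS13", 5: "CS14", 6: "CS16", 7: "CS18", 8: "CS22"}


def _class_vectors() -> dict[str, list[tuple[bool, ...]]]:
    """Enumerate the weekly activity vectors consistent with each class.

    Defined here by direct construction (constant = all five; week-specific
    = one bit; continuous = one contiguous run of 2-4; non-continuous = the
    rest), independently of the downstream classifier.
    """
    out: dict[str, list[tuple[bool, ...]]] = {k: [] for k in _OBSERVED_CLASS_MIX}
    n = len(WEEKS)
    for mask in range(1, 2 ** n):
        vec = tuple(bool(mask >> i & 1) for i in range(n))
        k = sum(vec)
        if k == n:
            out["constant"].append(vec)
        elif k == 1:
            out["week_specific"].append(vec)
        else:
            idx = [i for i, v in enumerate(vec) if v]
            if idx[-1] - idx[0] + 1 == k:
                out["continuous"].append(vec)
            else:
                out["non_continuous"].append(vec)
    return out


CLASS_VECTORS = _class_vectors()


@dataclass
class TruthConfig:
    """Study-design parameters; defaults mirror the real study's structure
    at a desk-scale genome."""

    seed: int = 0
    n_chrom: int = 4
    chrom_length: int = 10_000_000
    n_enhancers: int = 2000
    enhancer_width: int = 1500
    enhancer_separation: int = 4000
    gene_spacing: int = 100_000
    gene_width: int = 10_000
    tss_radius: int = 1000
    class_proportions: dict[str, float] = field(
        default_factory=lambda: dict(_OBSERVED_CLASS_MIX)
    )
    samples_per_week: dict[int, int] = field(
        default_factory=lambda: {4: 3, 5: 3, 6: 4, 7: 6, 8: 4}
    )
    peak_dropout: float = 0.05
    peak_jitter_sd: float = 50.0
    background_peak_rate: float = 25.0
    frac_alignable: float = 0.87
    frac_functionally_conserved: float = 0.59
    snp_density: float = 0.0045
    n_associated_snps: int = 20_000
    planted_or: float = 1.27
    ld_block_size: int = 50_000
    n_true_pairs: int = 200
    pair_effect: float = 0.6
    n_matched_samples: int = 10
    signal_sd: float = 1.0
    composition_bias: float = 4.0       # fold-change applied to biased rows
    composition_bias_rows: float = 0.3  # fraction of enhancer rows biased
    atac_cover_fraction: float = 0.70
    n_validated: int = 130
    validated_overlap_fraction: float = 0.29
    n_decoy_fragments: int = 200
    n_background_target_peaks: int = 200

    def __post_init__(self) -> None:
        total = sum(self.class_proportions.values())
        if total <= 0:
            raise ValueError("class_proportions must have positive mass")
        self.class_proportions = {
            k: v / total for k, v in self.class_proportions.items()
        }
        if abs(sum(self.class_proportions.values()) - 1.0) > 1e-9:
            raise ValueError("class_proportions must sum to 1")
        for name in ("peak_dropout", "frac_alignable", "frac_functionally_conserved",
                     "atac_cover_fraction", "validated_overlap_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.planted_or <= 0:
            raise ValueError("planted_or must be > 0")
        if self.frac_functionally_conserved > self.frac_alignable:
            raise ValueError(
                "frac_functionally_conserved cannot exceed frac_alignable"
            )
        if not (0 <= self.pair_effect <= 1):
            raise ValueError("pair_effect must be in [0, 1]")
        self.samples_per_week = {int(k): int(v) for k, v in self.samples_per_week.items()}

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "wt") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TruthConfig":
        with open(path, "rt") as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class TruthSet:
    """Planted ground truth for one synthetic study."""

    cfg: TruthConfig
    chrom_lengths: dict[str, int]
    enhancers: IntervalSet                      # names = enhancer ids
    classes: list[str]
    activity: np.ndarray                        # bool, (n_enhancers, 5)
    conservation: list[str]
    genes: TssAnnotation
    pairs: list[tuple[str, str]]                # (enhancer_id, gene_id)
    background_slots: list[GenomicInterval]     # free space for decoy features

    @property
    def enhancer_ids(self) -> list[str]:
        return [iv.name for iv in self.enhancers]

    def signal_keys(self) -> dict[str, str]:
        """enhancer id -> coordinate key used by the signal matrix rows."""
        return {iv.name: f"{iv.chrom}:{iv.start}-{iv.end}" for iv in self.enhancers}

    def pair_signal_keys(self) -> list[tuple[str, str]]:
        """True pairs re-keyed onto signal-matrix row ids."""
        keys = self.signal_keys()
        return [(keys[e], g) for e, g in self.pairs]

    def active_in_week(self, week: int) -> np.ndarray:
        return self.activity[:, WEEKS.index(week)]

    def enhancer_bp(self) -> int:
        return sum(iv.width for iv in self.enhancers)

    def genome_bp(self) -> int:
        return sum(self.chrom_lengths.values())

    def to_json(self, path: str | Path) -> None:
        payload = {
            "chrom_lengths": self.chrom_lengths,
            "enhancers": [
                {
                    "id": iv.name, "chrom": iv.chrom, "start": iv.start, "end": iv.end,
                    "class": self.classes[i],
                    "activity": [bool(x) for x in self.activity[i]],
                    "conservation": self.conservation[i],
                }
                for i, iv in enumerate(self.enhancers)
            ],
            "pairs": [list(p) for p in self.pairs],
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _rng(cfg: TruthConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg.seed % (2**31), *key]))


def _sample_key(sample_id: str) -> int:
    return zlib.crc32(sample_id.encode())


def generate_truth(cfg: TruthConfig) -> TruthSet:
    """Lay out genes and enhancers, draw temporal classes, weekly activity
    vectors, conservation labels and true enhancer:gene pairs."""
    rng = _rng(cfg, 1)
    chrom_lengths = {
        f"chr{i + 1}": cfg.chrom_length for i in range(cfg.n_chrom)
    }

    # genes on a jittered grid; TSS at the gene start (forward strand)
    tss_rows: list[tuple[str, int, str, str]] = []
    genes: dict[str, tuple[GenomicInterval, str]] = {}
    gid = 0
    for chrom, length in chrom_lengths.items():
        pos = cfg.gene_spacing
        while pos + cfg.gene_width < length - cfg.gene_spacing // 2:
            start = pos + int(rng.integers(0, cfg.gene_spacing // 10))
            gene_id = f"G{gid:05d}"
            strand = "+" if rng.random() < 0.5 else "-"
            iv = GenomicInterval(chrom, start, start + cfg.gene_width, gene_id, strand)
            tss_pos = start if strand == "+" else start + cfg.gene_width - 1
            tss_rows.append((chrom, tss_pos, gene_id, strand))
            genes[gene_id] = (iv, "protein_coding")
            gid += 1
            pos += cfg.gene_spacing
    ann = TssAnnotation(tss=tss_rows, genes=genes)

    # forbidden zones: TSS windows padded so jittered peaks stay distal
    pad = cfg.tss_radius + max(500, int(4 * cfg.peak_jitter_sd))
    forbidden: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_lengths}
    for chrom, p, _, _ in tss_rows:
        forbidden[chrom].append((max(0, p - pad), p + pad))

    # free segments -> fixed-width placement slots
    slot = cfg.enhancer_width + cfg.enhancer_separation
    slots: list[tuple[str, int]] = []
    for chrom, length in chrom_lengths.items():
        zones = sorted(forbidden[chrom])
        cursor = cfg.enhancer_separation
        for zs, ze in zones + [(length, length)]:
            seg_end = min(zs, length)
            while cursor + slot <= seg_end:
                slots.append((chrom, cursor))
                cursor += slot
            cursor = max(cursor, ze)
    if cfg.n_enhancers > len(slots):
        raise ValueError(
            f"cannot pack {cfg.n_enhancers} enhancers into {len(slots)} free slots; "
            "enlarge the genome or shrink the enhancer set"
        )
    pick = np.sort(rng.choice(len(slots), size=cfg.n_enhancers, replace=False))
    width_id = max(6, len(str(cfg.n_enhancers)))
    enhancers = []
    for j, si in enumerate(pick):
        chrom, base = slots[si]
        offset = int(rng.integers(0, cfg.enhancer_separation // 2))
        enhancers.append(GenomicInterval(
            chrom, base + offset, base + offset + cfg.enhancer_width,
            f"E{j + 1:0{width_id}d}",
        ))
    background_slots = [
        GenomicInterval(slots[i][0], slots[i][1], slots[i][1] + cfg.enhancer_width)
        for i in range(len(slots)) if i not in set(pick.tolist())
    ]

    # temporal classes and consistent weekly activity vectors
    class_names = list(cfg.class_proportions)
    probs = np.array([cfg.class_proportions[k] for k in class_names])
    cls_idx = rng.choice(len(class_names), size=cfg.n_enhancers, p=probs)
    classes = [class_names[i] for i in cls_idx]
    activity = np.zeros((cfg.n_enhancers, len(WEEKS)), dtype=bool)
    for i, cname in enumerate(classes):
        vecs = CLASS_VECTORS[cname]
        activity[i] = vecs[int(rng.integers(0, len(vecs)))]

    # conservation labels
    p_active = cfg.frac_functionally_conserved
    p_inactive = cfg.frac_alignable - cfg.frac_functionally_conserved
    conservation = list(rng.choice(
        ["conserved_active", "conserved_inactive", "not_alignable"],
        size=cfg.n_enhancers,
        p=[p_active, p_inactive, 1.0 - cfg.frac_alignable],
    ))

    # true enhancer:gene pairs — each paired with a nearby unused gene
    if cfg.n_true_pairs > cfg.n_enhancers:
        raise ValueError("n_true_pairs cannot exceed n_enhancers")
    tss_by_chrom: dict[str, list[tuple[int, str]]] = {}
    for chrom, p, g, _ in tss_rows:
        tss_by_chrom.setdefault(chrom, []).append((p, g))
    for chrom in tss_by_chrom:
        tss_by_chrom[chrom].sort()
    chosen = rng.choice(cfg.n_enhancers, size=cfg.n_true_pairs, replace=False)
    used_genes: set[str] = set()
    pairs: list[tuple[str, str]] = []
    for ei in sorted(chosen.tolist()):
        iv = enhancers[ei]
        cands = tss_by_chrom.get(iv.chrom, [])
        mid = (iv.start + iv.end) // 2
        order = sorted(cands, key=lambda t: abs(t[0] - mid))
        gene = next((g for _p, g in order if g not in used_genes), None)
        if gene is None:
            continue
        used_genes.add(gene)
        pairs.append((iv.name, gene))

    return TruthSet(
        cfg=cfg, chrom_lengths=chrom_lengths,
        enhancers=IntervalSet(enhancers, sorted=True),
        classes=classes, activity=activity, conservation=conservation,
        genes=ann, pairs=pairs, background_slots=background_slots,
    )


def simulate_sample_peaks(
    truth: TruthSet, week: int, sample_id: str, cfg: TruthConfig | None = None
) -> IntervalSet:
    """One sample's peak calls: truly active enhancers emitted with
    probability 1 - dropout and Gaussian edge jitter, plus background peaks
    placed in free slots away from true enhancers and TSS windows."""
    cfg = cfg or truth.cfg
    if week not in WEEKS:
        raise ValueError(f"week {week} outside 4..8")
    rng = _rng(cfg, 2, week, _sample_key(sample_id))
    active = truth.active_in_week(week)
    peaks: list[GenomicInterval] = []
    max_jit = cfg.enhancer_separation // 2 - 1
    for i in np.flatnonzero(active):
        if rng.random() < cfg.peak_dropout:
            continue
        iv = truth.enhancers[int(i)]
        js = int(np.clip(round(rng.normal(0, cfg.peak_jitter_sd)), -max_jit, max_jit))
        je = int(np.clip(round(rng.normal(0, cfg.peak_jitter_sd)), -max_jit, max_jit))
        start = max(0, iv.start + js)
        end = min(truth.chrom_lengths[iv.chrom], iv.end + je)
        if end <= start:  # degenerate jitter: keep at least the midpoint base
            mid = (iv.start + iv.end) // 2
            start, end = mid, mid + 1
        peaks.append(GenomicInterval(iv.chrom, start, end))
    n_bg = int(rng.poisson(cfg.background_peak_rate))
    if n_bg and truth.background_slots:
        idx = rng.choice(len(truth.background_slots),
                         size=min(n_bg, len(truth.background_slots)), replace=False)
        for i in np.sort(idx):
            peaks.append(truth.background_slots[int(i)])
    return IntervalSet(peaks).sort()


def simulate_atac_tracks(truth: TruthSet, cfg: TruthConfig | None = None) -> list[SampleTrack]:
    """ATAC peak tracks for week-7 samples whose union covers a planted
    fraction of the week-7-active enhancers."""
    cfg = cfg or truth.cfg
    rng = _rng(cfg, 6)
    wk7 = np.flatnonzero(truth.active_in_week(7))
    covered = wk7[rng.random(wk7.size) < cfg.atac_cover_fraction]
    tracks = []
    n_atac = min(2, cfg.samples_per_week.get(7, 2))
    for s in range(n_atac):
        peaks = [
            GenomicInterval(truth.enhancers[int(i)].chrom,
                            truth.enhancers[int(i)].start,
                            truth.enhancers[int(i)].end)
            for i in covered
        ]
        tracks.append(SampleTrack(
            sample_id=f"atac_wk7_s{s + 1}", carnegie_stage=_STAGE_FOR_WEEK[7],
            week=7, assay="ATAC", peaks=IntervalSet(peaks, sorted=True),
        ))
    return tracks


def simulate_snps(truth: TruthSet, cfg: TruthConfig | None = None) -> SnpCatalog:
    """Background SNPs uniform over the genome; trait-associated SNPs placed
    so the expected in-enhancer odds ratio vs background equals planted_or.
    Associated SNPs are grouped into LD blocks: one lead per block, true
    partners at r^2 in [0.8, 1], decoy partners strictly below 0.8."""
    cfg = cfg or truth.cfg
    rng = _rng(cfg, 3)
    chroms = list(truth.chrom_lengths)
    lengths = np.array([truth.chrom_lengths[c] for c in chroms], dtype=np.int64)
    genome = int(lengths.sum())
    offsets = np.concatenate([[0], np.cumsum(lengths)])

    enh_by_chrom = {c: [] for c in chroms}
    for iv in truth.enhancers:
        enh_by_chrom[iv.chrom].append((iv.start, iv.end))
    starts = {c: np.array([s for s, _ in enh_by_chrom[c]], dtype=np.int64) for c in chroms}
    ends = {c: np.array([e for _, e in enh_by_chrom[c]], dtype=np.int64) for c in chroms}

    def in_enhancer(chrom_idx: np.ndarray, pos: np.ndarray) -> np.ndarray:
        out = np.zeros(pos.size, dtype=bool)
        for ci, c in enumerate(chroms):
            m = chrom_idx == ci
            if not m.any() or starts[c].size == 0:
                continue
            p = pos[m]
            j = np.searchsorted(starts[c], p, side="right") - 1
            ok = (j >= 0) & (p < ends[c][np.clip(j, 0, None)])
            out[m] = ok
        return out

    def uniform_positions(n: int) -> tuple[np.ndarray, np.ndarray]:
        flat = rng.integers(0, genome, size=n)
        ci = np.searchsorted(offsets, flat, side="right") - 1
        return ci, flat - offsets[ci]

    # background SNPs: uniform
    n_bg = int(round(cfg.snp_density * genome))
    bg_ci, bg_pos = uniform_positions(n_bg)

    # associated SNPs: planted odds of landing in an enhancer
    enh_bp = truth.enhancer_bp()
    p0 = enh_bp / genome
    odds1 = cfg.planted_or * p0 / (1 - p0)
    p1 = odds1 / (1 + odds1)
    n_as = cfg.n_associated_snps
    inside = rng.random(n_as) < p1
    as_ci = np.empty(n_as, dtype=np.int64)
    as_pos = np.empty(n_as, dtype=np.int64)

    # inside: uniform over pooled enhancer bp
    widths = np.array([iv.width for iv in truth.enhancers], dtype=np.int64)
    wcum = np.concatenate([[0], np.cumsum(widths)])
    k_in = int(inside.sum())
    if k_in:
        flat = rng.integers(0, enh_bp, size=k_in)
        ei = np.searchsorted(wcum, flat, side="right") - 1
        local = flat - wcum[ei]
        as_ci[inside] = [chroms.index(truth.enhancers[int(i)].chrom) for i in ei]
        as_pos[inside] = np.array(
            [truth.enhancers[int(i)].start for i in ei], dtype=np.int64
        ) + local
    # outside: uniform with rejection of enhancer bases
    k_out = n_as - k_in
    got = 0
    oc = np.empty(k_out, dtype=np.int64)
    op = np.empty(k_out, dtype=np.int64)
    while got < k_out:
        ci, pos = uniform_positions(int((k_out - got) * 1.2) + 16)
        ok = ~in_enhancer(ci, pos)
        take = min(int(ok.sum()), k_out - got)
        oc[got:got + take] = ci[ok][:take]
        op[got:got + take] = pos[ok][:take]
        got += take
    as_ci[~inside] = oc
    as_pos[~inside] = op

    chrom_arr = np.array(chroms)
    snps = pd.DataFrame({
        "chrom": chrom_arr[np.concatenate([as_ci, bg_ci])],
        "pos": np.concatenate([as_pos, bg_pos]),
        "snp_id": np.concatenate([
            np.char.add("rs", np.arange(n_as).astype("U")),
            np.char.add("bg", np.arange(n_bg).astype("U")),
        ]),
        "associated": np.concatenate([
            np.ones(n_as, dtype=bool), np.zeros(n_bg, dtype=bool)
        ]),
        "trait_class": np.concatenate([
            rng.choice(["disease", "normal_variation"], size=n_as, p=[0.2, 0.8]),
            np.full(n_bg, "none"),
        ]),
    })

    # LD blocks over the associated SNPs (sorted by position within chrom)
    assoc = snps.iloc[:n_as].sort_values(["chrom", "pos"]).reset_index(drop=True)
    rows = []
    lead_id: str | None = None
    last_chrom, last_pos = None, None
    block_start = 0
    for rec in assoc.itertuples(index=False):
        new_block = (
            lead_id is None or rec.chrom != last_chrom
            or rec.pos - last_pos > cfg.ld_block_size
            or rec.pos - block_start > cfg.ld_block_size
        )
        if new_block:
            lead_id = rec.snp_id
            block_start = rec.pos
        else:
            rows.append((lead_id, rec.snp_id, float(rng.uniform(0.8, 1.0)), "EUR"))
        # decoy partner below threshold, drawn from background near the lead
        if new_block and rng.random() < 0.5 and n_bg:
            decoy = f"bg{int(rng.integers(0, n_bg))}"
            rows.append((lead_id, decoy, float(rng.uniform(0.4, 0.79)), "EUR"))
        last_chrom, last_pos = rec.chrom, rec.pos
    ld = pd.DataFrame(rows, columns=["lead_id", "partner_id", "r2", "population"])
    return SnpCatalog(snps=snps, ld_pairs=ld)


def lead_snp_ids(catalog: SnpCatalog) -> set[str]:
    """The leads of the generated LD table plus associated singletons
    (associated SNPs that head their own block)."""
    partners = set(catalog.ld_pairs["partner_id"])
    assoc = set(catalog.snps.loc[catalog.snps["associated"], "snp_id"])
    return assoc - partners


def simulate_signal_and_expression(
    truth: TruthSet, cfg: TruthConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Matched enhancer-signal and gene-expression matrices.

    True pairs share a latent per-sample activity factor with coupling
    ``pair_effect``; all other rows are independent. One library gets a
    composition bias (a subset of enhancer rows scaled up) so that TMM
    normalization has real work to do.
    """
    cfg = cfg or truth.cfg
    rng = _rng(cfg, 4)
    samples = [f"M{j + 1:02d}" for j in range(cfg.n_matched_samples)]
    enh_ids = truth.enhancer_ids
    gene_ids = sorted(truth.genes.genes)
    n_e, n_g, n_s = len(enh_ids), len(gene_ids), len(samples)

    base_e = rng.normal(6.0, 1.0, size=n_e)
    base_g = rng.normal(6.0, 1.0, size=n_g)
    z_e = rng.normal(0.0, 1.0, size=(n_e, n_s))
    z_g = rng.normal(0.0, 1.0, size=(n_g, n_s))

    e_index = {e: i for i, e in enumerate(enh_ids)}
    g_index = {g: i for i, g in enumerate(gene_ids)}
    rho = cfg.pair_effect
    for e_id, g_id in truth.pairs:
        i, j = e_index[e_id], g_index[g_id]
        u = z_e[i]  # the enhancer's per-sample activity is the shared factor
        z_g[j] = rho * u + np.sqrt(max(0.0, 1 - rho * rho)) * rng.normal(0, 1, n_s)

    signal = np.power(2.0, base_e[:, None] + cfg.signal_sd * z_e)
    expr = np.power(2.0, base_g[:, None] + cfg.signal_sd * z_g)

    # composition bias in the first library so TMM has real work to do
    biased = rng.random(n_e) < cfg.composition_bias_rows
    signal[biased, 0] *= max(cfg.composition_bias, 1e-12)

    # signal rows are keyed by the quantified region's coordinates, the way
    # a signal matrix over a peak catalog is usually shipped
    enh_keys = [f"{iv.chrom}:{iv.start}-{iv.end}" for iv in truth.enhancers]
    sig = pd.DataFrame(np.round(signal, 3), index=enh_keys, columns=samples)
    exp = pd.DataFrame(np.round(expr, 3), index=gene_ids, columns=samples)
    return sig, exp


# ---------------------------------------------------------------------------
# cross-species resources and study emission

def build_chain_and_target(
    truth: TruthSet,
) -> tuple[ChainFile, TssAnnotation, OrthologyTable, IntervalSet]:
    """Chain file, target gene annotation, orthology and target peaks.

    Each source chromosome maps to one target chromosome through a single
    forward chain whose alignment gaps (source-side) fall exactly over the
    planted non-alignable enhancers. Functionally conserved enhancers get an
    H3K27ac peak at their mapped location on the target genome.
    """
    cfg = truth.cfg
    rng = _rng(cfg, 5)
    pad = 100
    chains: list[Chain] = []
    target_tss: list[tuple[str, int, str, str]] = []
    target_genes: dict[str, tuple[GenomicInterval, str]] = {}
    orth: dict[str, str] = {}
    target_peaks: list[GenomicInterval] = []

    for cn, (chrom, length) in enumerate(truth.chrom_lengths.items(), start=1):
        tname = f"tchr{cn}"
        gaps = sorted(
            (max(1, iv.start - pad), min(length - 1, iv.end + pad))
            for i, iv in enumerate(truth.enhancers)
            if iv.chrom == chrom and truth.conservation[i] == "not_alignable"
        )
        blocks: list[tuple[int, int, int]] = []
        cursor = 0
        for gs, ge in gaps:
            blocks.append((gs - cursor, ge - gs, 0))
            cursor = ge
        blocks.append((length - cursor, 0, 0))
        total_dt = sum(b[1] for b in blocks)
        chains.append(Chain(
            score=1000.0, t_name=chrom, t_size=length, t_strand="+",
            t_start=0, t_end=length, q_name=tname, q_size=length,
            q_strand="+", q_start=0, q_end=length - total_dt,
            chain_id=str(cn), blocks=blocks,
        ))

        gap_starts = np.array([g[0] for g in gaps], dtype=np.int64)
        gap_cum = np.concatenate(
            [[0], np.cumsum([g[1] - g[0] for g in gaps])]
        )

        def q_of(t: int) -> int:
            j = int(np.searchsorted(gap_starts, t, side="right"))
            return t - int(gap_cum[j])

        for gchrom, p, gene_id, strand in truth.genes.tss:
            if gchrom != chrom:
                continue
            giv, biotype = truth.genes.genes[gene_id]
            tgt_id = f"m{gene_id}"
            tiv = GenomicInterval(tname, q_of(giv.start), q_of(giv.end), tgt_id, strand)
            target_genes[tgt_id] = (tiv, biotype)
            target_tss.append((tname, q_of(p), tgt_id, strand))
            orth[gene_id] = tgt_id

        for i, iv in enumerate(truth.enhancers):
            if iv.chrom != chrom or truth.conservation[i] != "conserved_active":
                continue
            s, e = q_of(iv.start), q_of(iv.end)
            jit = int(rng.integers(-200, 201))
            s2 = max(0, s + jit)
            target_peaks.append(GenomicInterval(tname, s2, max(s2 + 1, e + jit)))

    return (
        ChainFile(chains),
        TssAnnotation(tss=target_tss, genes=target_genes),
        OrthologyTable(orth),
        IntervalSet(target_peaks).sort(),
    )


def simulate_validated_elements(truth: TruthSet) -> pd.DataFrame:
    """VISTA-style validated elements: a planted fraction overlaps a catalog
    enhancer by >= 100 bp, the rest sit in enhancer-free background slots."""
    cfg = truth.cfg
    rng = _rng(cfg, 7)
    rows = []
    n_hit = int(round(cfg.n_validated * cfg.validated_overlap_fraction))
    hit_enh = rng.choice(len(truth.enhancers), size=n_hit, replace=False)
    for k, ei in enumerate(np.sort(hit_enh)):
        iv = truth.enhancers[int(ei)]
        start = iv.start + int(rng.integers(0, max(1, iv.width - 150)))
        rows.append((iv.chrom, start, start + 400, f"hsx{k + 1:04d}", "positive"))
    n_miss = cfg.n_validated - n_hit
    slot_idx = rng.choice(len(truth.background_slots), size=n_miss, replace=False)
    for k, si in enumerate(np.sort(slot_idx)):
        s = truth.background_slots[int(si)]
        rows.append((s.chrom, s.start, s.start + 400, f"hsy{k + 1:04d}",
                     "positive" if rng.random() < 0.5 else "negative"))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "element_id", "activity"])


def simulate_interactions(truth: TruthSet) -> pd.DataFrame:
    """Promoter-interaction fragments: one per true pair (enhancer padded
    +-500 bp, linked to its target gene) plus decoys in background slots."""
    cfg = truth.cfg
    rng = _rng(cfg, 8)
    by_id = {iv.name: iv for iv in truth.enhancers}
    gene_ids = sorted(truth.genes.genes)
    rows = []
    for e_id, g_id in truth.pairs:
        iv = by_id[e_id]
        rows.append((iv.chrom, max(0, iv.start - 500), iv.end + 500, g_id))
    n_decoy = min(cfg.n_decoy_fragments, len(truth.background_slots))
    slot_idx = rng.choice(len(truth.background_slots), size=n_decoy, replace=False)
    for si in np.sort(slot_idx):
        s = truth.background_slots[int(si)]
        rows.append((s.chrom, s.start, s.end, gene_ids[int(rng.integers(0, len(gene_ids)))]))
    return pd.DataFrame(rows, columns=["frag_chrom", "frag_start", "frag_end", "gene_id"])


def h3k27ac_tracks(truth: TruthSet) -> list[SampleTrack]:
    """All per-sample H3K27ac tracks of the study design."""
    cfg = truth.cfg
    tracks = []
    for week in WEEKS:
        for s in range(cfg.samples_per_week.get(week, 0)):
            sid = f"wk{week}_s{s + 1}"
            tracks.append(SampleTrack(
                sample_id=sid, carnegie_stage=_STAGE_FOR_WEEK[week], week=week,
                assay="H3K27ac", peaks=simulate_sample_peaks(truth, week, sid, cfg),
            ))
    return tracks


def write_study(out_dir: str | Path, truth: TruthSet) -> dict[str, Path]:
    """Emit the full study as plain-text files; returns the path map."""
    cfg = truth.cfg
    out = Path(out_dir)
    (out / "peaks").mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    cfg.to_yaml(out / "config.yaml")
    truth.to_json(out / "truth.json")
    paths["config"] = out / "config.yaml"
    paths["truth"] = out / "truth.json"

    manifest_rows = []
    for t in h3k27ac_tracks(truth) + simulate_atac_tracks(truth):
        rel = Path("peaks") / f"{t.sample_id}.bed"
        write_bed(t.peaks, out / rel, provenance=f"synthetic peaks {t.sample_id}")
        manifest_rows.append((t.sample_id, t.carnegie_stage, t.week, t.assay, str(rel)))
    manifest = pd.DataFrame(
        manifest_rows, columns=["sample_id", "stage", "week", "assay", "bed_path"]
    )
    manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    paths["manifest"] = out / "manifest.tsv"

    write_tss_table(truth.genes, out / "tss.tsv")
    paths["tss"] = out / "tss.tsv"

    chains, target_ann, orth, target_peaks = build_chain_and_target(truth)
    write_chain_file(chains, out / "study.chain")
    write_tss_table(target_ann, out / "target_tss.tsv")
    with open(out / "orthology.tsv", "wt") as fh:
        fh.write("# source_gene\ttarget_gene\n")
        for s, t in sorted(orth.pairs.items()):
            fh.write(f"{s}\t{t}\n")
    write_bed(target_peaks, out / "target_peaks.bed", provenance="synthetic target peaks")
    paths.update(chain=out / "study.chain", target_tss=out / "target_tss.tsv",
                 orthology=out / "orthology.tsv", target_peaks=out / "target_peaks.bed")

    snp_cat = simulate_snps(truth)
    snps_out = snp_cat.snps.copy()
    snps_out["pos"] = snps_out["pos"] + 1  # emit 1-based, dbSNP style
    snps_out.to_csv(out / "snps.tsv", sep="\t", index=False, header=False)
    snp_cat.ld_pairs.to_csv(out / "ld.tsv", sep="\t", index=False, header=False)
    (out / "lead_snps.txt").write_text(
        "\n".join(sorted(lead_snp_ids(snp_cat))) + "\n"
    )
    paths.update(snps=out / "snps.tsv", ld=out / "ld.tsv",
                 leads=out / "lead_snps.txt")

    sig, exp = simulate_signal_and_expression(truth)
    sig.to_csv(out / "signal.tsv", sep="\t", index_label="enhancer_id")
    exp.to_csv(out / "expression.tsv", sep="\t", index_label="gene_id")
    paths.update(signal=out / "signal.tsv", expression=out / "expression.tsv")

    simulate_interactions(truth).to_csv(
        out / "interactions.tsv", sep="\t", index=False, header=False
    )
    simulate_validated_elements(truth).to_csv(
        out / "validated.tsv", sep="\t", index=False
    )
    paths.update(interactions=out / "interactions.tsv", validated=out / "validated.tsv")
    return paths
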