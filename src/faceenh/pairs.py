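"""Enhancer-target-gene assignment and signal/expression association testing.

Enhancers are assigned to genes through promoter-interaction fragments
(promoter-capture Hi-C style segments). Enhancer H3K27ac signal is TMM
(trimmed mean of M-values) normalized across libraries, each predicted
enhancer:gene pair is scored by Spearman's rank correlation across matched
samples, and the pair correlations are compared to all other (background)
pairs with a Mann-Whitney U test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata

from .catalog import EnhancerCatalog
from .intervals import GenomicInterval, IntervalSet, count_overlaps

__all__ = [
    "InteractionMap",
    "PairTestResult",
    "read_interactions",
    "assign_targets",
    "tmm_factors",
    "normalize_tmm",
    "spearman",
    "spearman_rows",
    "pair_vs_background_test",
    "correlate_pairs",
]


@dataclass
class InteractionMap:
    """Fragment -> gene links from promoter-interaction data."""

    segments: list[tuple[GenomicInterval, str]] = field(default_factory=list)

    def fragment_set(self) -> IntervalSet:
        return IntervalSet([iv for iv, _ in self.segments])


def read_interactions(path: str | Path) -> InteractionMap:
    """Read an interaction TSV (frag_chrom, frag_start, frag_end, gene_id)."""
    segments = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        chrom, start, end, gene_id = line.split("\t")[:4]
        segments.append((GenomicInterval(chrom, int(start), int(end)), gene_id))
    return InteractionMap(segments)


def assign_targets(
    catalog: EnhancerCatalog, imap: InteractionMap
) -> list[tuple[str, str]]:
    """(enhancer_id, gene_id) pairs where the enhancer overlaps (>=1 bp) a
    fragment linked to the gene; many-to-many, deduplicated, sorted."""
    if not imap.segments:
        return []
    frags = imap.fragment_set()
    hits = count_overlaps(catalog.regions, frags, min_overlap=1)
    pairs = {
        (catalog.ids[i], imap.segments[j][1])
        for i, rec in enumerate(hits) for j, _w in rec
    }
    return sorted(pairs)


# ---------------------------------------------------------------------------
# TMM normalization (trimmed mean of M-values, edgeR-style)

def _p75_fraction(counts: np.ndarray) -> np.ndarray:
    lib = counts.sum(axis=0)
    return np.percentile(counts, 75, axis=0) / lib


def tmm_factors(
    m: pd.DataFrame | np.ndarray, trim_m: float = 0.30, trim_a: float = 0.05
) -> np.ndarray:
    """Per-library TMM scaling factors (geometric mean rescaled to 1).

    The reference library is the one whose 75th-percentile count fraction is
    closest to the mean of those fractions. For every other library the
    factor is 2^(precision-weighted mean of M = log2 fold-changes), after
    discarding the most extreme ``trim_m`` of rows by M and ``trim_a`` by
    A (two-sided each) and any row with a zero in either library.
    """
    counts = np.asarray(m, dtype=float)
    if counts.ndim != 2 or counts.shape[1] < 2:
        raise ValueError("need a rows x >=2 libraries matrix")
    if (counts < 0).any():
        raise ValueError("counts must be nonnegative")
    lib = counts.sum(axis=0)
    if (lib == 0).any():
        j = int(np.flatnonzero(lib == 0)[0])
        name = m.columns[j] if isinstance(m, pd.DataFrame) else str(j)
        raise ValueError(f"library {name!r} has all-zero counts")
    f75 = _p75_fraction(counts)
    ref = int(np.argmin(np.abs(f75 - f75.mean())))

    factors = np.empty(counts.shape[1])
    for k in range(counts.shape[1]):
        factors[k] = _tmm_pair(counts[:, k], counts[:, ref], lib[k], lib[ref],
                               trim_m, trim_a)
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


def _tmm_pair(obs, ref, n_obs, n_ref, trim_m, trim_a) -> float:
    ok = (obs > 0) & (ref > 0)
    obs, ref = obs[ok], ref[ok]
    if obs.size == 0:
        return 1.0
    p_obs, p_ref = obs / n_obs, ref / n_ref
    m_vals = np.log2(p_obs / p_ref)
    a_vals = 0.5 * np.log2(p_obs * p_ref)
    # asymptotic (delta-method) variance of M; weights are its inverse
    var = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)

    if np.allclose(m_vals, m_vals[0]):
        # identical composition (possibly a pure depth shift)
        return float(2 ** m_vals[0]) if abs(m_vals[0]) > 1e-10 else 1.0

    keep = _double_trim(m_vals, a_vals, trim_m, trim_a)
    if not keep.any():
        return 1.0
    w = 1.0 / var[keep]
    return float(2 ** (np.sum(w * m_vals[keep]) / np.sum(w)))


def _double_trim(m_vals, a_vals, trim_m, trim_a) -> np.ndarray:
    n = m_vals.size
    lo_m, hi_m = int(np.floor(n * trim_m)) + 1, n - int(np.floor(n * trim_m))
    lo_a, hi_a = int(np.floor(n * trim_a)) + 1, n - int(np.floor(n * trim_a))
    rank_m = rankdata(m_vals, method="average")
    rank_a = rankdata(a_vals, method="average")
    return (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)


def normalize_tmm(m: pd.DataFrame, trim_m: float = 0.30, trim_a: float = 0.05) -> pd.DataFrame:
    """Scale each library to counts-per-million of its TMM-effective size."""
    factors = tmm_factors(m, trim_m, trim_a)
    eff = m.sum(axis=0).to_numpy() * factors
    return m / eff * 1e6


# ---------------------------------------------------------------------------
# correlation and rank tests

def spearman(x, y) -> float:
    """Spearman rho: Pearson correlation of mid-ranks (ties averaged).

    Returns NaN when either vector has zero variance (undefined; excluded
    downstream).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length vectors of size >= 3")
    rx, ry = rankdata(x), rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return float("nan")
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(np.dot(rx, ry) / np.sqrt(np.dot(rx, rx) * np.dot(ry, ry)))


def spearman_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise Spearman rho between matching rows of two (n, k) matrices."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rx = rankdata(x, axis=1).astype(float)
    ry = rankdata(y, axis=1).astype(float)
    rx -= rx.mean(axis=1, keepdims=True)
    ry -= ry.mean(axis=1, keepdims=True)
    denom = np.sqrt((rx * rx).sum(axis=1) * (ry * ry).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return (rx * ry).sum(axis=1) / denom


@dataclass
class PairTestResult:
    pair_rhos: np.ndarray
    u_statistic: float
    p_value: float
    n_pairs: int
    n_background: int
    alternative: str
    method: str


def pair_vs_background_test(
    pair_rhos, background_rhos, alternative: str = "greater"
) -> PairTestResult:
    """Mann-Whitney U comparing pair correlations against background.

    Mid-ranks on ties. Exact enumeration when both groups have <= 8
    observations and no cross-group ties; otherwise the normal approximation
    with tie and continuity correction.
    """
    if alternative not in ("greater", "two_sided"):
        raise ValueError("alternative must be 'greater' or 'two_sided'")
    x = np.asarray(pair_rhos, dtype=float)
    y = np.asarray(background_rhos, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    small = max(x.size, y.size) <= 8
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = mannwhitneyu(
        x, y,
        alternative="greater" if alternative == "greater" else "two-sided",
        method=method,
    )
    return PairTestResult(
        pair_rhos=x, u_statistic=float(res.statistic), p_value=float(res.pvalue),
        n_pairs=int(x.size), n_background=int(y.size),
        alternative=alternative, method=method,
    )


def correlate_pairs(
    pairs: list[tuple[str, str]],
    signal: pd.DataFrame,
    expression: pd.DataFrame,
    tmm_normalize: bool = True,
    max_background: int | None = 20_000,
    rng: np.random.Generator | None = None,
    alternative: str = "greater",
) -> tuple[pd.DataFrame, PairTestResult]:
    """Score predicted pairs and test them against all other combinations.

    ``signal`` (enhancer x sample) is TMM-normalized before ranking;
    ``expression`` (gene x sample) is used as-is (rank-based statistics are
    insensitive to per-gene scaling). Background pairs are every
    enhancer x gene combination over the tested ids minus the predicted
    pairs, subsampled to ``max_background`` when larger.
    """
    if list(signal.columns) != list(expression.columns):
        raise ValueError("signal and expression must share the sample header")
    sig = normalize_tmm(signal) if tmm_normalize else signal
    pairs = [
        (e, g) for e, g in pairs if e in sig.index and g in expression.index
    ]
    if not pairs:
        raise ValueError("no testable pairs (ids missing from matrices)")
    enh_ids = sorted({e for e, _ in pairs})
    gene_ids = sorted({g for _, g in pairs})
    pair_set = set(pairs)
    background = [
        (e, g) for e in enh_ids for g in gene_ids if (e, g) not in pair_set
    ]
    if max_background is not None and len(background) > max_background:
        rng = rng or np.random.default_rng(0)
        idx = rng.choice(len(background), size=max_background, replace=False)
        background = [background[i] for i in sorted(idx)]

    def rhos(plist):
        xs = sig.loc[[e for e, _ in plist]].to_numpy()
        ys = expression.loc[[g for _, g in plist]].to_numpy()
        return spearman_rows(xs, ys)

    pair_rhos = rhos(pairs)
    back_rhos = rhos(background) if background else np.array([])
    table = pd.DataFrame(
        {"enhancer_id": [e for e, _ in pairs],
         "gene_id": [g for _, g in pairs],
         "rho": pair_rhos}
    )
    result = pair_vs_background_test(pair_rhos, back_rhos, alternative=alternative)
    return table, result
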