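"""Cross-species coordinate mapping and conservation classification.

Candidate enhancers are mapped to a target genome by walking UCSC chain
alignments (the liftOver procedure), checked for synteny against flanking
protein-coding genes via an orthology table, and classified three ways:

* ``not_alignable``     — no chain maps enough of the interval, the mapping
  is ambiguous (several chains qualify), or the flanking-gene context is lost;
* ``conserved_inactive`` — maps cleanly but no target-species peak overlaps;
* ``conserved_active``   — maps cleanly and overlaps a target-species peak.

Chain convention: the *t* (first) side of a chain is the source assembly,
the *q* (second) side the target, as in UCSC ``<src>To<Tgt>`` chain files.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

from .intervals import GenomicInterval, IntervalSet, TssAnnotation, count_overlaps

__all__ = [
    "Chain",
    "ChainFile",
    "ChainParseError",
    "OrthologyTable",
    "ConservationCall",
    "read_chain_file",
    "write_chain_file",
    "read_orthology_table",
    "liftover_interval",
    "synteny_check",
    "classify_conservation",
]

CONSERVATION_STATUSES = ("not_alignable", "conserved_inactive", "conserved_active")


class ChainParseError(ValueError):
    pass


@dataclass
class Chain:
    score: float
    t_name: str
    t_size: int
    t_strand: str
    t_start: int
    t_end: int
    q_name: str
    q_size: int
    q_strand: str
    q_start: int
    q_end: int
    chain_id: str
    # blocks: list of (size, dt, dq); the last block has dt = dq = 0
    blocks: list[tuple[int, int, int]] = field(default_factory=list)

    def validate(self) -> None:
        sizes = sum(b[0] for b in self.blocks)
        dts = sum(b[1] for b in self.blocks)
        dqs = sum(b[2] for b in self.blocks)
        if any(b[0] < 0 or b[1] < 0 or b[2] < 0 for b in self.blocks):
            raise ChainParseError(f"chain {self.chain_id}: negative block size or gap")
        if sizes + dts != self.t_end - self.t_start:
            raise ChainParseError(
                f"chain {self.chain_id}: block arithmetic does not match source range"
            )
        if sizes + dqs != self.q_end - self.q_start:
            raise ChainParseError(
                f"chain {self.chain_id}: block arithmetic does not match target range"
            )


@dataclass
class ChainFile:
    chains: list[Chain] = field(default_factory=list)

    def for_chrom(self, chrom: str) -> list[Chain]:
        return [c for c in self.chains if c.t_name == chrom]


def read_chain_file(path: str | Path | io.TextIOBase) -> ChainFile:
    """Parse a UCSC chain file; block arithmetic is validated per chain."""
    if isinstance(path, io.TextIOBase):
        lines = path.read().splitlines()
    else:
        lines = Path(path).read_text().splitlines()
    chains: list[Chain] = []
    cur: Chain | None = None
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("chain"):
            parts = line.split()
            if len(parts) != 13:
                raise ChainParseError(f"line {lineno}: chain header needs 13 fields")
            cur = Chain(
                score=float(parts[1]),
                t_name=parts[2], t_size=int(parts[3]), t_strand=parts[4],
                t_start=int(parts[5]), t_end=int(parts[6]),
                q_name=parts[7], q_size=int(parts[8]), q_strand=parts[9],
                q_start=int(parts[10]), q_end=int(parts[11]),
                chain_id=parts[12],
            )
            if cur.t_strand != "+":
                raise ChainParseError(f"line {lineno}: source strand must be '+'")
            chains.append(cur)
        else:
            if cur is None:
                raise ChainParseError(f"line {lineno}: block line before chain header")
            parts = line.split()
            try:
                if len(parts) == 3:
                    cur.blocks.append((int(parts[0]), int(parts[1]), int(parts[2])))
                elif len(parts) == 1:
                    cur.blocks.append((int(parts[0]), 0, 0))
                else:
                    raise ValueError
            except ValueError as exc:
                raise ChainParseError(f"line {lineno}: malformed block line") from exc
    for chain in chains:
        chain.validate()
    return ChainFile(chains)


def write_chain_file(cf: ChainFile, path: str | Path) -> None:
    with open(path, "wt") as fh:
        for c in cf.chains:
            fh.write(
                f"chain {c.score:g} {c.t_name} {c.t_size} {c.t_strand} {c.t_start} "
                f"{c.t_end} {c.q_name} {c.q_size} {c.q_strand} {c.q_start} "
                f"{c.q_end} {c.chain_id}\n"
            )
            for size, dt, dq in c.blocks[:-1]:
                fh.write(f"{size} {dt} {dq}\n")
            fh.write(f"{c.blocks[-1][0]}\n\n")


def _map_through_chain(iv: GenomicInterval, chain: Chain) -> tuple[int, int, int] | None:
    """Map ``iv`` through one chain.

    Returns (mapped_bases, q_min, q_max) in chain-local q coordinates
    (i.e. on the q strand as stored), or None when nothing maps.
    """
    t_pos, q_pos = chain.t_start, chain.q_start
    mapped = 0
    q_min: int | None = None
    q_max: int | None = None
    for size, dt, dq in chain.blocks:
        lo = max(iv.start, t_pos)
        hi = min(iv.end, t_pos + size)
        if hi > lo:
            mapped += hi - lo
            q_lo = q_pos + (lo - t_pos)
            q_hi = q_pos + (hi - t_pos)
            q_min = q_lo if q_min is None else min(q_min, q_lo)
            q_max = q_hi if q_max is None else max(q_max, q_hi)
        t_pos += size + dt
        q_pos += size + dq
        if t_pos >= iv.end:
            break
    if q_min is None:
        return None
    return mapped, q_min, q_max


def liftover_interval(
    iv: GenomicInterval, chains: ChainFile, min_match: float = 0.95
) -> GenomicInterval | None:
    """Map an interval to the target assembly through chain alignments.

    Succeeds iff (mapped bases / interval width) >= ``min_match`` with all
    mapped bases coming from a single chain (one target chromosome and
    strand); intervals for which several chains qualify are treated as
    ambiguous and rejected, mirroring liftOver's split/multiple rule.
    The result spans min..max mapped target positions; minus-strand chains
    are flipped to forward coordinates.
    """
    if not (0 < min_match <= 1):
        raise ValueError("min_match must be in (0, 1]")
    candidates: list[tuple[Chain, int, int]] = []
    for chain in chains.for_chrom(iv.chrom):
        res = _map_through_chain(iv, chain)
        if res is None:
            continue
        mapped, q_lo, q_hi = res
        if mapped / iv.width >= min_match:
            candidates.append((chain, q_lo, q_hi))
    if len(candidates) != 1:
        return None
    chain, q_lo, q_hi = candidates[0]
    if chain.q_strand == "-":
        q_lo, q_hi = chain.q_size - q_hi, chain.q_size - q_lo
    return GenomicInterval(chain.q_name, q_lo, q_hi, iv.name)


@dataclass
class OrthologyTable:
    """Partial mapping source gene_id -> target gene_id (one-way)."""

    pairs: dict[str, str] = field(default_factory=dict)

    def get(self, source_gene: str) -> str | None:
        return self.pairs.get(source_gene)


def read_orthology_table(path: str | Path) -> OrthologyTable:
    pairs: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        src, tgt = line.split("\t")[:2]
        pairs[src] = tgt
    return OrthologyTable(pairs)


def _flanking_genes(
    chrom: str, start: int, end: int, ann: TssAnnotation, window: int
) -> list[str]:
    """Nearest protein-coding gene upstream of ``start`` and downstream of
    ``end`` (linear scan over TSS positions), within ``window`` bp."""
    up_gene, up_pos = None, None
    down_gene, down_pos = None, None
    for c, pos, gene_id, _strand in ann.protein_coding_tss():
        if c != chrom:
            continue
        if pos <= start and start - pos <= window:
            if up_pos is None or pos > up_pos:
                up_gene, up_pos = gene_id, pos
        elif pos >= end and pos - end <= window:
            if down_pos is None or pos < down_pos:
                down_gene, down_pos = gene_id, pos
        elif start < pos < end:
            # gene TSS inside the interval counts as flanking on both sides
            if up_pos is None or pos > up_pos:
                up_gene, up_pos = gene_id, pos
            if down_pos is None or pos < down_pos:
                down_gene, down_pos = gene_id, pos
    return [g for g in (up_gene, down_gene) if g is not None]


def synteny_check(
    iv: GenomicInterval,
    mapped: GenomicInterval,
    source_genes: TssAnnotation,
    target_genes: TssAnnotation,
    orth: OrthologyTable,
    window: int = 2_000_000,
    mode: str = "any",
) -> bool:
    """Check that a mapped interval keeps its flanking-gene context.

    True iff at least one (``mode='any'``, default) or both (``mode='both'``)
    of the source interval's nearest flanking protein-coding genes has its
    ortholog among the target interval's nearest flanking protein-coding
    genes. With no flanking source gene within ``window``, returns True
    (nothing to contradict synteny).
    """
    if mode not in ("any", "both"):
        raise ValueError("mode must be 'any' or 'both'")
    src_flanks = _flanking_genes(iv.chrom, iv.start, iv.end, source_genes, window)
    if not src_flanks:
        return True
    tgt_flanks = set(
        _flanking_genes(mapped.chrom, mapped.start, mapped.end, target_genes, window)
    )
    ok = [orth.get(g) in tgt_flanks for g in src_flanks if orth.get(g) is not None]
    if not ok:
        return False
    return any(ok) if mode == "any" else all(ok) and len(ok) == len(src_flanks)


@dataclass
class ConservationCall:
    enhancer_id: str
    status: str
    mapped_interval: GenomicInterval | None
    synteny_ok: bool

    def __post_init__(self) -> None:
        if self.status not in CONSERVATION_STATUSES:
            raise ValueError(f"unknown status {self.status!r}")
        if (self.mapped_interval is None) != (self.status == "not_alignable"):
            raise ValueError("mapped_interval present iff status != not_alignable")


def classify_conservation(
    regions: IntervalSet,
    region_ids: list[str],
    chains: ChainFile,
    source_genes: TssAnnotation,
    target_genes: TssAnnotation,
    orth: OrthologyTable,
    target_peaks: IntervalSet,
    min_match: float = 0.95,
    synteny_window: int = 2_000_000,
    synteny_mode: str = "any",
) -> list[ConservationCall]:
    """Three-way conservation call for every region; statuses partition the set."""
    mapped_ivs: list[GenomicInterval | None] = []
    synteny_flags: list[bool] = []
    for iv in regions:
        mapped = liftover_interval(iv, chains, min_match=min_match)
        if mapped is not None and not synteny_check(
            iv, mapped, source_genes, target_genes, orth,
            window=synteny_window, mode=synteny_mode,
        ):
            synteny_flags.append(False)
            mapped_ivs.append(None)
        else:
            synteny_flags.append(mapped is not None)
            mapped_ivs.append(mapped)

    ok_idx = [i for i, m in enumerate(mapped_ivs) if m is not None]
    mapped_set = IntervalSet([mapped_ivs[i] for i in ok_idx])
    hits = count_overlaps(mapped_set, target_peaks, min_overlap=1) if len(mapped_set) else []
    active = {ok_idx[j] for j, rec in enumerate(hits) if rec}

    calls: list[ConservationCall] = []
    for i, rid in enumerate(region_ids):
        if mapped_ivs[i] is None:
            calls.append(ConservationCall(rid, "not_alignable", None, synteny_flags[i]))
        elif i in active:
            calls.append(ConservationCall(rid, "conserved_active", mapped_ivs[i], True))
        else:
            calls.append(ConservationCall(rid, "conserved_inactive", mapped_ivs[i], True))
    return calls


def conservation_to_rows(calls: list[ConservationCall]) -> list[dict]:
    rows = []
    for c in calls:
        rows.append({
            "enhancer_id": c.enhancer_id,
            "status": c.status,
            "mapped_chrom": c.mapped_interval.chrom if c.mapped_interval else "",
            "mapped_start": c.mapped_interval.start if c.mapped_interval else -1,
            "mapped_end": c.mapped_interval.end if c.mapped_interval else -1,
            "synteny_ok": c.synteny_ok,
        })
    return rows
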