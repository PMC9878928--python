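"""Reproducible-peak filtering, scale factors, fragment counting, annotation.

The reproducibility rule mirrors the two-tier peak-calling convention: a peak
is reproducible when it was called at high confidence (FDR <= 0.05) in at
least one replicate and overlaps a low-confidence call (FDR <= 0.5) in the
other replicates. "Other replicates" is read strictly (all of them) by
default; ``others_mode='any'`` relaxes to at least one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .core import Gene, GenomicInterval, Peak

ANNOTATION_CATEGORIES = (
    "Promoter.Up",
    "Promoter.Down",
    "Exonic",
    "Intronic",
    "genic",
    "TES",
    "distal5",
    "distal3",
    "intergenic",
)


@dataclass(frozen=True)
class ScaleFactor:
    sample_id: str
    factor: float
    basis: str  # libsize | spikein_total | spikein_ratio

    def __post_init__(self) -> None:
        if not (np.isfinite(self.factor) and self.factor > 0):
            raise ValueError(f"scale factor must be finite and positive, got {self.factor}")


@dataclass(frozen=True)
class AnnotatedPeak:
    peak: Peak
    category: str
    assigned_gene: Optional[str] = None


def _merge_intervals(ivs: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping (>=1 bp) intervals; strand collapses to '.'."""
    out: list[GenomicInterval] = []
    for iv in sorted(ivs, key=lambda x: (x.chrom, x.start, x.end)):
        if out and out[-1].chrom == iv.chrom and iv.start < out[-1].end:
            prev = out.pop()
            out.append(GenomicInterval(prev.chrom, prev.start,
                                       max(prev.end, iv.end), "."))
        else:
            out.append(GenomicInterval(iv.chrom, iv.start, iv.end, "."))
    return out


def _any_overlap(iv: GenomicInterval, others: Sequence[GenomicInterval]) -> bool:
    return any(iv.overlaps(o) for o in others)


def reproducible_peaks(
    replicate_peaksets: Mapping[str, Sequence[tuple[GenomicInterval, str]]],
    others_mode: str = "all",
) -> list[Peak]:
    """Keep high-tier peaks supported by low-tier calls in other replicates.

    ``replicate_peaksets`` maps replicate id to (interval, tier) calls with
    tier in {'high', 'low'}; a high call counts as a low call too. The output
    intervals are the qualifying high-tier intervals, merged where replicates'
    high calls overlap.
    """
    if others_mode not in ("all", "any"):
        raise ValueError("others_mode must be 'all' or 'any'")
    reps = list(replicate_peaksets)
    if len(reps) < 2:
        raise ValueError(
            "reproducible_peaks needs >= 2 replicates; with one replicate "
            "pass its high-confidence peaks through directly"
        )
    for rep, calls in replicate_peaksets.items():
        for _, tier in calls:
            if tier not in ("high", "low"):
                raise ValueError(f"{rep}: tier must be 'high' or 'low', got {tier!r}")

    # low-tier evidence per replicate includes the high calls (high subset low)
    low_by_rep = {
        rep: [iv for iv, _tier in calls] for rep, calls in replicate_peaksets.items()
    }
    kept: list[GenomicInterval] = []
    for rep, calls in replicate_peaksets.items():
        others = [r for r in reps if r != rep]
        for iv, tier in calls:
            if tier != "high":
                continue
            support = [_any_overlap(iv, low_by_rep[o]) for o in others]
            ok = all(support) if others_mode == "all" else any(support)
            if ok:
                kept.append(iv)
    merged = _merge_intervals(kept)
    return [
        Peak(f"rp_{i:05d}", iv, replicate_calls={}) for i, iv in enumerate(merged)
    ]


def merge_condition_peaks(sets: Mapping[str, Sequence[Peak]]) -> list[Peak]:
    """Merge reproducible peak sets across conditions into unified features.

    Provenance is recorded in ``replicate_calls`` as {condition: 'high'} for
    every condition contributing to the merged interval.
    """
    tagged: list[tuple[GenomicInterval, str]] = []
    for cond, peaks in sets.items():
        tagged.extend((p.interval, cond) for p in peaks)
    merged = _merge_intervals([iv for iv, _ in tagged])
    out = []
    for i, iv in enumerate(merged):
        prov = sorted({cond for src, cond in tagged if iv.overlaps(src)})
        out.append(
            Peak(f"merged_{i:05d}", iv, replicate_calls={c: "high" for c in prov})
        )
    return out


def extend_reads(
    reads: Sequence[GenomicInterval], fragment_size: int, mode: str = "to_length"
) -> list[GenomicInterval]:
    """Extend reads to fragments in strand direction.

    ``to_length``: the fragment spans ``fragment_size`` bp from the read's 5'
    end. ``slop``: the read keeps its span and grows ``fragment_size`` bp past
    its 3' end (bedtools ``slop -s -l 0 -r`` semantics).
    """
    if fragment_size < 1:
        raise ValueError("fragment_size must be >= 1")
    out = []
    for r in reads:
        if r.strand not in ("+", "-"):
            raise ValueError(f"read without strand cannot be extended: {r}")
        if mode == "to_length":
            if r.strand == "+":
                start, end = r.start, r.start + fragment_size
            else:
                start, end = r.end - fragment_size, r.end
        elif mode == "slop":
            if r.strand == "+":
                start, end = r.start, r.end + fragment_size
            else:
                start, end = r.start - fragment_size, r.end
        else:
            raise ValueError("mode must be 'to_length' or 'slop'")
        out.append(GenomicInterval(r.chrom, max(0, start), max(1, end), r.strand))
    return out


def count_fragments(
    reads: Sequence[GenomicInterval],
    peaks: Sequence[Peak],
    fragment_size: int,
    extend_mode: str = "to_length",
) -> np.ndarray:
    """Count extended fragments overlapping (>= 1 bp) each peak.

    Per chromosome, a fragment [s, e) overlaps peak [ps, pe) iff s < pe and
    e > ps; counts are computed from sorted fragment starts/ends.
    """
    frags = extend_reads(reads, fragment_size, extend_mode)
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {f.chrom for f in frags}:
        sub = [f for f in frags if f.chrom == chrom]
        by_chrom[chrom] = (
            np.sort(np.array([f.start for f in sub])),
            np.sort(np.array([f.end for f in sub])),
        )
    counts = np.zeros(len(peaks), dtype=int)
    for i, p in enumerate(peaks):
        if p.chrom not in by_chrom:
            continue
        starts, ends = by_chrom[p.chrom]
        n = len(starts)
        n_start_after = n - np.searchsorted(starts, p.interval.end, side="left")
        n_end_before = np.searchsorted(ends, p.interval.start, side="right")
        counts[i] = n - n_start_after - n_end_before
    return counts


def scale_factor_libsize(sample_id: str, lib_size: int,
                         target: float = 15e6) -> ScaleFactor:
    """Library-size scaling to a fixed depth (default 15 million reads)."""
    if lib_size <= 0:
        raise ValueError("library size must be positive")
    return ScaleFactor(sample_id, target / lib_size, "libsize")


def scale_factor_spikein(sample_id: str, spikein_reads: int,
                         target: float = 1e6) -> ScaleFactor:
    """Spike-in scaling to a fixed exogenous depth (default 1 million reads)."""
    if spikein_reads <= 0:
        raise ValueError(
            "no spike-in reads: spike-in scaling requires exogenous chromatin; "
            "use scale_factor_libsize instead"
        )
    return ScaleFactor(sample_id, target / spikein_reads, "spikein_total")


def _annotate_one(
    point: int,
    chrom: str,
    genes: Sequence[Gene],
    exons: Optional[Mapping[str, Sequence[tuple[int, int]]]],
    promoter_bp: int,
    distal_bp: int,
) -> tuple[str, Optional[str]]:
    """Return (category, gene) for one anchor point, by fixed priority."""

    def updown(g: Gene, pos: int) -> int:
        """Signed distance from TSS in the gene's 5'->3' direction."""
        return (pos - g.tss) if g.interval.strand != "-" else (g.tss - pos)

    def tes_dist(g: Gene, pos: int) -> int:
        return (pos - g.tes) if g.interval.strand != "-" else (g.tes - pos)

    cands = [g for g in genes if g.chrom == chrom]

    def nearest(matches: list[Gene]) -> Optional[str]:
        if not matches:
            return None
        return min(matches, key=lambda g: (abs(point - g.tss), g.gene_id)).gene_id

    # Promoter.Up: [TSS - promoter_bp, TSS]; Promoter.Down: (TSS, TSS + promoter_bp]
    up = [g for g in cands if -promoter_bp <= updown(g, point) <= 0]
    if up:
        return "Promoter.Up", nearest(up)
    down = [g for g in cands if 0 < updown(g, point) <= promoter_bp]
    if down:
        return "Promoter.Down", nearest(down)
    genic = [g for g in cands if g.interval.start <= point < g.interval.end]
    if genic:
        if exons is not None:
            exonic = [
                g for g in genic
                if any(s <= point < e for s, e in exons.get(g.gene_id, ()))
            ]
            if exonic:
                return "Exonic", nearest(exonic)
            return "Intronic", nearest(genic)
        return "genic", nearest(genic)
    tes = [g for g in cands if abs(tes_dist(g, point)) <= promoter_bp]
    if tes:
        return "TES", nearest(tes)
    d5 = [g for g in cands if -distal_bp <= updown(g, point) < 0]
    if d5:
        return "distal5", nearest(d5)
    d3 = [g for g in cands if 0 < tes_dist(g, point) <= distal_bp]
    if d3:
        return "distal3", nearest(d3)
    return "intergenic", None


def annotate_peaks(
    peaks: Sequence[Peak],
    genes: Sequence[Gene],
    exons: Optional[Mapping[str, Sequence[tuple[int, int]]]] = None,
    promoter_bp: int = 2000,
    distal_bp: int = 50_000,
) -> list[AnnotatedPeak]:
    """Assign each peak exactly one category by fixed priority.

    Priority: Promoter.Up > Promoter.Down > Exonic > Intronic > TES > distal5
    > distal3 > intergenic, tested at the peak summit (midpoint when absent).
    Without exon models the Exonic/Intronic pair collapses to 'genic'.
    """
    out = []
    for p in peaks:
        cat, gid = _annotate_one(p.anchor_point, p.chrom, genes, exons,
                                 promoter_bp, distal_bp)
        out.append(AnnotatedPeak(p, cat, gid))
    return out
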