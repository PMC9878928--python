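"""Aggregate peak analysis (P2LL) and loop-set / anchor classification.

APA stacks the (2w+1) x (2w+1) contact submatrix centered on each loop's
anchor-pair pixel and averages across loops; the P2LL score is the central
pixel (or central block mean) over the mean of the lower-left corner block,
the region between the anchors and the diagonal that serves as the local
background. Loops too close to the diagonal or the matrix edge are skipped
and counted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import ContactMap, GenomicInterval, Loop, Peak


@dataclass
class APAResult:
    matrix: np.ndarray  # (2w+1) x (2w+1) aggregate
    p2ll: float
    n_loops_used: int
    n_loops_skipped: int
    window_bp: int

    def __post_init__(self) -> None:
        m = self.matrix
        if m.ndim != 2 or m.shape[0] != m.shape[1] or m.shape[0] % 2 == 0:
            raise ValueError("aggregate matrix must be square with odd size")


def apa_aggregate(
    cmap: ContactMap,
    loops: Sequence[Loop],
    window: int = 10,
    corner: int = 6,
    center: int = 1,
    normed: bool = True,
) -> APAResult:
    """Aggregate loop-centered submatrices and score enrichment as P2LL.

    Each loop contributes the submatrix centered at (bin(anchor1),
    bin(anchor2)) with anchor1 < anchor2. With ``normed`` each submatrix is
    divided by its own mean before averaging (the plotting-normalized APA);
    ``corner`` and ``center`` set the background block and central block edge
    lengths in bins.
    """
    w = int(window)
    size = 2 * w + 1
    if corner < 1 or corner > size:
        raise ValueError("corner block must fit in the aggregate window")
    if center < 1 or center > size or center % 2 == 0:
        raise ValueError("center block edge must be odd and fit the window")
    agg = np.zeros((size, size))
    used = skipped = 0
    n = cmap.n_bins
    for lp in loops:
        if lp.chrom != cmap.chrom:
            skipped += 1
            continue
        b1 = cmap.bin_of(lp.anchor1.midpoint)
        b2 = cmap.bin_of(lp.anchor2.midpoint)
        if b1 > b2:
            b1, b2 = b2, b1
        if (b2 - b1) < size or b1 - w < 0 or b2 + w >= n:
            skipped += 1
            continue
        sub = cmap.matrix[b1 - w : b1 + w + 1, b2 - w : b2 + w + 1]
        if normed:
            mu = sub.mean()
            if mu <= 0:
                skipped += 1
                continue
            sub = sub / mu
        agg += sub
        used += 1
    if used == 0:
        raise ValueError("no usable loops for APA (all skipped)")
    agg /= used
    half = center // 2
    center_val = agg[w - half : w + half + 1, w - half : w + half + 1].mean()
    ll = agg[size - corner :, :corner].mean()
    p2ll = center_val / ll if ll > 0 else np.inf
    return APAResult(agg, float(p2ll), used, skipped, cmap.bin_size)


def _loop_bins(lp: Loop, bin_size: int) -> tuple[str, int, int]:
    return (lp.chrom, lp.anchor1.midpoint // bin_size, lp.anchor2.midpoint // bin_size)


def compare_loop_sets(
    loops_a: Sequence[Loop],
    loops_b: Sequence[Loop],
    bin_size: int,
    slack_bins: int = 1,
) -> dict[str, list[Loop]]:
    """Split loop sets into lost (a only), retained (both) and gained (b only).

    Two loops match when they share a chromosome and both anchor bins agree
    within ``slack_bins``. Matching is greedy over set b per a-loop.
    """
    keys_b = [_loop_bins(lp, bin_size) for lp in loops_b]
    matched_b: set[int] = set()
    lost, retained = [], []
    for la in loops_a:
        ca, a1, a2 = _loop_bins(la, bin_size)
        hit = None
        for j, (cb, b1, b2) in enumerate(keys_b):
            if j in matched_b or cb != ca:
                continue
            if abs(a1 - b1) <= slack_bins and abs(a2 - b2) <= slack_bins:
                hit = j
                break
        if hit is None:
            lost.append(la)
        else:
            matched_b.add(hit)
            retained.append(la)
    gained = [lp for j, lp in enumerate(loops_b) if j not in matched_b]
    return {"lost": lost, "retained": retained, "gained": gained}


def classify_anchor(
    anchor: GenomicInterval,
    tss_list: Sequence[tuple[str, int]],
    h3k27ac_peaks: Sequence[GenomicInterval],
    promoter_bp: int = 2000,
) -> str:
    """P / E / CTCF anchor classes from TSS proximity and H3K27ac overlap.

    P: overlaps both a TSS +/- promoter_bp window and an H3K27ac peak.
    E: overlaps H3K27ac away from any TSS. CTCF: everything else.
    """
    near_tss = any(
        chrom == anchor.chrom
        and anchor.start <= tss + promoter_bp
        and anchor.end > tss - promoter_bp
        for chrom, tss in tss_list
    )
    has_k27 = any(anchor.overlaps(pk) for pk in h3k27ac_peaks)
    if has_k27 and near_tss:
        return "P"
    if has_k27:
        return "E"
    return "CTCF"


def classify_loops(
    loops: Sequence[Loop],
    tss_list: Sequence[tuple[str, int]],
    h3k27ac_peaks: Sequence[GenomicInterval],
    promoter_bp: int = 2000,
) -> list[Loop]:
    """Return loops with both anchors classified into P/E/CTCF."""
    return [
        Loop(
            lp.anchor1,
            lp.anchor2,
            classify_anchor(lp.anchor1, tss_list, h3k27ac_peaks, promoter_bp),
            classify_anchor(lp.anchor2, tss_list, h3k27ac_peaks, promoter_bp),
        )
        for lp in loops
    ]


def loop_category(lp: Loop) -> str:
    """Unordered anchor-pair category label (P-E == E-P)."""
    if lp.category1 is None or lp.category2 is None:
        raise ValueError("loop anchors are not classified")
    a, b = sorted([lp.category1, lp.category2])
    return f"{a}-{b}"


def loop_category_table(
    loops_a: Sequence[Loop],
    loops_b: Sequence[Loop],
    label_a: str = "lost",
    label_b: str = "retained",
) -> pd.DataFrame:
    """Per-category counts in two loop sets with 2x2 enrichment tests.

    For each category the contingency table is
    [[n_a_category, n_a_other], [n_b_category, n_b_other]]; the odds ratio is
    (n_a_cat * n_b_other) / (n_a_other * n_b_cat) and the p-value a
    two-sided Fisher exact test. Degenerate categories (a zero margin) are
    flagged with NaN p.
    """
    if not loops_a or not loops_b:
        raise ValueError("both loop sets must be non-empty")
    cats_a = pd.Series([loop_category(lp) for lp in loops_a])
    cats_b = pd.Series([loop_category(lp) for lp in loops_b])
    all_cats = sorted(set(cats_a) | set(cats_b))
    rows = []
    for cat in all_cats:
        a1 = int((cats_a == cat).sum())
        a0 = len(loops_a) - a1
        b1 = int((cats_b == cat).sum())
        b0 = len(loops_b) - b1
        table = np.array([[a1, a0], [b1, b0]])
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            orx, p = np.nan, np.nan
        else:
            orx = (a1 * b0) / (a0 * b1) if a0 * b1 > 0 else np.inf
            _, p = stats.fisher_exact(table, alternative="two-sided")
        rows.append(
            {
                "category": cat,
                f"n_{label_a}": a1,
                f"n_{label_b}": b1,
                "odds_ratio": orx,
                "p_value": p,
            }
        )
    return pd.DataFrame(rows).set_index("category")


def anchor_peak_overlap(
    loops: Sequence[Loop], peaks: Sequence[Peak], mode: str = "anchors"
) -> float:
    """Fraction of loop anchors (or loops) overlapping >= 1 peak.

    ``anchors``: overlapping anchors / all anchors (the numerator counts
    anchors, not loops). ``both`` / ``either``: fraction of loops whose two /
    at least one anchor(s) overlap a peak.
    """
    if mode not in ("anchors", "both", "either"):
        raise ValueError("mode must be 'anchors', 'both' or 'either'")
    ivs = [p.interval for p in peaks]

    def over(anchor: GenomicInterval) -> bool:
        return any(anchor.overlaps(iv) for iv in ivs)

    if not loops:
        return 0.0
    flags = [(over(lp.anchor1), over(lp.anchor2)) for lp in loops]
    if mode == "anchors":
        return sum(f1 + f2 for f1, f2 in flags) / (2 * len(loops))
    if mode == "both":
        return sum(f1 and f2 for f1, f2 in flags) / len(loops)
    return sum(f1 or f2 for f1, f2 in flags) / len(loops)
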