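"""Gene-peak integration of expression and binding changes.

Each gene's expression log2FC and each peak's binding log2FC are converted
to z-scores by dividing by the standard deviation of all fold changes in
the respective table (no centering):

    z_g = log2FC(g) / sd(log2FC),   z_p = log2FC(p) / sd(log2FC)

Genes are paired with every peak in [TSS - 50 kb, TES + 50 kb]; the combined
score z_{g,p} = z_g * z_p is positive when binding and expression move
together ("correlated") and negative otherwise. Within each sign class,
pairs are ranked by non-dominated sorting on (|z_g|, |z_p|) and the top
Pareto levels are selected as the most correlated / anti-correlated pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import Gene, Peak


@dataclass(frozen=True)
class ZScoreVector:
    """Per-feature z-scores together with the sd used as denominator."""

    z: pd.Series
    sd_log2fc: float

    def reconstruct_log2fc(self) -> pd.Series:
        return self.z * self.sd_log2fc


def zscore_fold_changes(fc: pd.DataFrame) -> ZScoreVector:
    """z_i = log2fc_i / sd(all log2fc), sample sd (ddof=1), no centering."""
    vals = fc["log2fc"].to_numpy(float)
    finite = np.isfinite(vals)
    if finite.sum() < 2:
        raise ValueError("need >= 2 features with finite log2FC")
    sd = float(np.std(vals[finite], ddof=1))
    if sd == 0:
        raise ValueError("all fold changes identical: z-scores undefined")
    z = pd.Series(vals / sd, index=fc.index, name="z")
    return ZScoreVector(z, sd)


def associate_gene_peaks(
    genes: Sequence[Gene], peaks: Sequence[Peak], flank_bp: int = 50_000
) -> pd.DataFrame:
    """Pair every gene with the peaks overlapping its +/- flank neighborhood.

    The window is the strand-independent genomic span
    [min(TSS, TES) - flank, max(TSS, TES) + flank], inclusive; a peak pairs
    with a gene when its interval overlaps that window by >= 1 bp. A peak may
    pair with several genes and vice versa.
    """
    by_chrom: dict[str, list[Peak]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append(p)
    arrays = {}
    for chrom, plist in by_chrom.items():
        plist.sort(key=lambda p: p.interval.start)
        arrays[chrom] = (
            np.array([p.interval.start for p in plist]),
            np.array([p.interval.end for p in plist]),
            [p.peak_id for p in plist],
        )
    rows = []
    for g in genes:
        if g.chrom not in arrays:
            continue
        starts, ends, ids = arrays[g.chrom]
        lo = min(g.tss, g.tes) - flank_bp
        hi = max(g.tss, g.tes) + flank_bp
        # overlap with [lo, hi] (inclusive): start <= hi and end > lo
        i_hi = np.searchsorted(starts, hi, side="right")
        for i in range(i_hi):
            if ends[i] > lo:
                rows.append((g.gene_id, ids[i]))
    return pd.DataFrame(rows, columns=["gene_id", "peak_id"])


def combined_scores(
    pairs: pd.DataFrame, z_genes: ZScoreVector, z_peaks: ZScoreVector
) -> pd.DataFrame:
    """Attach z_g, z_p, z_gp = z_g * z_p and the correlation class to pairs."""
    missing_g = set(pairs["gene_id"]) - set(z_genes.z.index)
    missing_p = set(pairs["peak_id"]) - set(z_peaks.z.index)
    if missing_g or missing_p:
        raise KeyError(
            f"pairs reference features without z-scores: "
            f"{sorted(missing_g)[:3]} {sorted(missing_p)[:3]}"
        )
    out = pairs.copy()
    out["z_g"] = z_genes.z.reindex(out["gene_id"]).to_numpy()
    out["z_p"] = z_peaks.z.reindex(out["peak_id"]).to_numpy()
    out["z_gp"] = out["z_g"] * out["z_p"]
    cls = np.where(out["z_gp"] > 0, "correlated",
                   np.where(out["z_gp"] < 0, "anti_correlated", "unassigned"))
    out["correlation_class"] = cls
    return out


def nondominated_levels(points: np.ndarray) -> np.ndarray:
    """Non-dominated sorting levels for 2D maximization (1 = best front).

    A point is dominated when another is >= in both objectives and > in at
    least one; identical points share a level. O(n log n) staircase sweep:
    after sorting by (-x, -y) and grouping duplicates, the dominators of a
    group are exactly the already-processed groups with y' >= y, so the level
    is one more than the deepest such level (binary search on the
    non-increasing per-level maxima of y).
    """
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (n, 2)")
    n = len(pts)
    if n == 0:
        return np.zeros(0, dtype=int)
    order = np.lexsort((-pts[:, 1], -pts[:, 0]))
    levels = np.zeros(n, dtype=int)
    level_max_y: list[float] = []  # max y among groups at level k+1; non-increasing
    i = 0
    while i < n:
        j = i
        while j < n and pts[order[j], 0] == pts[order[i], 0] \
                and pts[order[j], 1] == pts[order[i], 1]:
            j += 1
        y = pts[order[i], 1]
        # deepest existing level whose max y >= y (level_max_y non-increasing)
        lo, hi = 0, len(level_max_y)
        while lo < hi:
            mid = (lo + hi) // 2
            if level_max_y[mid] >= y:
                lo = mid + 1
            else:
                hi = mid
        lvl = lo + 1
        if lvl > len(level_max_y):
            level_max_y.append(y)
        else:
            level_max_y[lvl - 1] = max(level_max_y[lvl - 1], y)
        levels[order[i:j]] = lvl
        i = j
    return levels


def pareto_levels(
    pairs: pd.DataFrame, objective: str = "two_sided"
) -> pd.DataFrame:
    """Assign Pareto levels within each correlation class.

    ``two_sided`` maximizes (|z_g|, |z_p|); ``abs_product`` ranks by |z_gp|
    alone (1D levels = descending distinct values). Pairs with z_gp == 0
    ('unassigned') get no level.
    """
    out = pairs.copy()
    out["pareto_level"] = 0
    for cls in ("correlated", "anti_correlated"):
        mask = out["correlation_class"] == cls
        if not mask.any():
            continue
        if objective == "two_sided":
            pts = np.abs(out.loc[mask, ["z_g", "z_p"]].to_numpy(float))
        elif objective == "abs_product":
            v = np.abs(out.loc[mask, "z_gp"].to_numpy(float))
            pts = np.column_stack([v, v])
        else:
            raise ValueError("objective must be 'two_sided' or 'abs_product'")
        out.loc[mask, "pareto_level"] = nondominated_levels(pts)
    return out


def select_top_levels(pairs: pd.DataFrame, max_level: int = 10) -> pd.DataFrame:
    """Keep pairs on the top Pareto levels (per correlation class)."""
    leveled = pairs[pairs["pareto_level"] > 0]
    return leveled[leveled["pareto_level"] <= max_level].copy()


def recover_planted_coupling(
    selected: pd.DataFrame, gene_truth: pd.DataFrame
) -> dict:
    """Recall/precision of planted gene-causal-peak pairs in a selection.

    ``gene_truth`` needs columns 'coupled', 'causal_peak' and (for the
    scatter table) 'planted_log2fc'. Returns recall, precision over planted
    pairs, counts, and the selected pairs annotated with truth status.
    """
    planted = gene_truth[gene_truth["coupled"]]
    truth_pairs = set(zip(planted.index, planted["causal_peak"]))
    unknown = set(selected["gene_id"]) - set(gene_truth.index)
    if unknown:
        raise KeyError(f"selected genes missing from truth table: {sorted(unknown)[:3]}")
    sel_pairs = set(zip(selected["gene_id"], selected["peak_id"]))
    hits = truth_pairs & sel_pairs
    recall = len(hits) / len(truth_pairs) if truth_pairs else 0.0
    precision = len(hits) / len(sel_pairs) if sel_pairs else 0.0
    scatter = selected.copy()
    scatter["is_planted_pair"] = [
        (g, p) in truth_pairs for g, p in zip(scatter["gene_id"], scatter["peak_id"])
    ]
    return {
        "recall": recall,
        "precision": precision,
        "n_planted": len(truth_pairs),
        "n_selected": len(sel_pairs),
        "n_recovered": len(hits),
        "scatter": scatter,
    }


def integrate(
    genes: Sequence[Gene],
    peaks: Sequence[Peak],
    gene_fc: pd.DataFrame,
    peak_fc: pd.DataFrame,
    flank_bp: int = 50_000,
    max_level: int = 10,
    objective: str = "two_sided",
    de_genes_only: bool = False,
    de_labels: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """End-to-end pairing -> z-scores -> combined score -> Pareto selection.

    With ``de_genes_only`` the pairing is restricted to genes labeled 'up' or
    'down' in ``de_labels`` (the stringent DE cutoff applied upstream);
    z-score denominators are still computed from the full tables.
    """
    z_g = zscore_fold_changes(gene_fc)
    z_p = zscore_fold_changes(peak_fc)
    gene_set = genes
    if de_genes_only:
        if de_labels is None:
            raise ValueError("de_genes_only requires de_labels")
        keep = set(de_labels[de_labels != "unchanged"].index)
        gene_set = [g for g in genes if g.gene_id in keep]
    pairs = associate_gene_peaks(gene_set, peaks, flank_bp)
    pairs = pairs[pairs["gene_id"].isin(gene_fc.index)
                  & pairs["peak_id"].isin(peak_fc.index)]
    scored = combined_scores(pairs, z_g, z_p)
    leveled = pareto_levels(scored, objective)
    leveled["selected"] = (leveled["pareto_level"] > 0) & (
        leveled["pareto_level"] <= max_level
    )
    return leveled
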