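"""Normalization and moderated two-group differential testing for count tables.

The same machinery is applied to peak-fragment counts (binding) and gene
counts (expression): TMM or spike-in median-of-ratios factors, log2-CPM
transform, a per-feature two-group fit with empirical-Bayes variance
shrinkage (scaled inverse-chi-square prior fitted by moment matching on
log residual variances), moderated t-statistics, and BH FDR.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .core import CountTable


# ---------------------------------------------------------------------------
# filtering and normalization


def cpm(counts: pd.DataFrame, lib_sizes: Optional[pd.Series] = None) -> pd.DataFrame:
    """Counts per million with raw library sizes (no pseudocount)."""
    libs = counts.sum(axis=0) if lib_sizes is None else lib_sizes
    return counts.div(libs, axis=1) * 1e6


def cpm_filter(table: CountTable, min_cpm: float = 1.0) -> CountTable:
    """Drop features whose CPM is <= min_cpm in every sample."""
    c = cpm(table.counts)
    keep = (c > min_cpm).any(axis=1)
    return CountTable(table.counts.loc[keep], table.spikein_counts)


@dataclass(frozen=True)
class NormFactors:
    factors: pd.Series  # per-sample, positive
    method: str  # "TMM" | "spikein_median_ratio" | "none"

    def __post_init__(self) -> None:
        f = self.factors.to_numpy(float)
        if not (np.isfinite(f).all() and (f > 0).all()):
            raise ValueError("normalization factors must be finite and positive")


def tmm_factors(
    table: CountTable, trim_m: float = 0.30, trim_a: float = 0.05
) -> NormFactors:
    """Trimmed-mean-of-M-values normalization factors (geometric mean 1).

    The reference sample is the one whose upper-quartile count fraction is
    closest to the mean across samples. For each sample, M (log ratio) and A
    (log abundance) values vs the reference are doubly trimmed (trim_m per
    tail on M, trim_a per tail on A) and averaged with inverse asymptotic
    variance weights.
    """
    counts = table.counts.to_numpy(float)
    libs = counts.sum(axis=0)
    if (libs <= 0).any():
        raise ValueError("all-zero sample in count table")
    if counts.shape[1] < 2:
        raise ValueError("TMM needs >= 2 samples")

    uq = np.array([
        np.quantile(counts[:, j][counts[:, j] > 0] / libs[j], 0.75)
        if (counts[:, j] > 0).any() else 0.0
        for j in range(counts.shape[1])
    ])
    ref = int(np.argmin(np.abs(uq - uq.mean())))

    factors = np.ones(counts.shape[1])
    xr, nr = counts[:, ref], libs[ref]
    for j in range(counts.shape[1]):
        if j == ref:
            continue
        xj, nj = counts[:, j], libs[j]
        ok = (xj > 0) & (xr > 0)
        if ok.sum() == 0:
            continue
        pj, pr = xj[ok] / nj, xr[ok] / nr
        m = np.log2(pj / pr)
        a = 0.5 * np.log2(pj * pr)
        w = (nj - xj[ok]) / (nj * xj[ok]) + (nr - xr[ok]) / (nr * xr[ok])
        n = len(m)
        lo_m = np.floor(n * trim_m) + 1
        lo_a = np.floor(n * trim_a) + 1
        rank_m = stats.rankdata(m, method="ordinal")
        rank_a = stats.rankdata(a, method="ordinal")
        keep = (
            (rank_m >= lo_m) & (rank_m <= n + 1 - lo_m)
            & (rank_a >= lo_a) & (rank_a <= n + 1 - lo_a)
        )
        if keep.any() and w[keep].sum() > 0:
            f = (m[keep] / w[keep]).sum() / (1.0 / w[keep]).sum()
            factors[j] = 2.0 ** f
    factors = factors / np.exp(np.mean(np.log(factors)))
    return NormFactors(pd.Series(factors, index=table.counts.columns), "TMM")


def spikein_size_factors(spikein: pd.DataFrame) -> NormFactors:
    """Median-of-ratios size factors from a spike-in count matrix.

    factor_j = median over spike-in features i of counts_ij / geomean_i,
    where the geometric mean runs over samples and features containing any
    zero are excluded. Factors are returned unscaled (their ratios carry the
    meaning); divide by their geometric mean if a normalized view is wanted.
    """
    x = spikein.to_numpy(float)
    usable = (x > 0).all(axis=1)
    if not usable.any():
        raise ValueError("no spike-in feature is positive in all samples")
    xu = x[usable]
    geo = np.exp(np.mean(np.log(xu), axis=1))
    ratios = xu / geo[:, None]
    factors = np.median(ratios, axis=0)
    return NormFactors(pd.Series(factors, index=spikein.columns),
                       "spikein_median_ratio")


# ---------------------------------------------------------------------------
# moderated two-group test


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with monotonicity enforcement."""
    p = np.asarray(p_values, float)
    if np.isnan(p).any():
        raise ValueError("NaN p-values are not allowed")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must be in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton iterations on 1/y scale)."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled inverse-chi-square prior to residual variances.

    Returns (d0, s0_sq): prior degrees of freedom (may be inf) and prior
    variance. Uses the log-variance moments: for s^2 ~ s0^2 F(df, d0),
    E[log s^2] and Var[log s^2] involve digamma/trigamma terms.
    """
    s2 = np.asarray(s2, float)
    pos = s2 > 0
    # an all-zero-residual feature carries no variance information
    z = np.log(s2[pos])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    n = len(e)
    if n < 2:
        return np.inf, float(np.exp(np.mean(e))) if n else 1.0
    var_e = np.var(e, ddof=1) * (n - 1) / n - special.polygamma(1, df / 2.0)
    if var_e <= 0:
        return np.inf, float(np.exp(np.mean(e)))
    d0 = 2.0 * _trigamma_inverse(var_e)
    s0_sq = float(np.exp(
        np.mean(e) + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)
    ))
    return float(d0), s0_sq


class ModeratedTTest:
    """Two-group moderated-t model on log2-CPM of a count table.

    Parameters
    ----------
    table : CountTable
        Feature x sample counts.
    design : mapping or sequence
        Sample -> condition labels; exactly two conditions, >= 2 replicates
        each. The log2 fold change is condition2 - condition1 with conditions
        in sorted label order unless ``baseline`` names the reference.
    norm : NormFactors, optional
        Per-sample normalization factors; library sizes are multiplied by
        them before the CPM transform. Defaults to library-size-only.
    """

    def __init__(
        self,
        table: CountTable,
        design: Mapping[str, str] | Sequence[str],
        norm: Optional[NormFactors] = None,
        baseline: Optional[str] = None,
        prior_df: Optional[float] = None,
    ) -> None:
        self.table = table
        if not isinstance(design, Mapping):
            design = dict(zip(table.sample_ids, design))
        missing = set(table.sample_ids) - set(design)
        if missing:
            raise ValueError(f"design is missing samples: {sorted(missing)}")
        self.design = {s: design[s] for s in table.sample_ids}
        levels = sorted(set(self.design.values()))
        if len(levels) != 2:
            raise ValueError(f"need exactly two conditions, got {levels}")
        if baseline is not None:
            if baseline not in levels:
                raise ValueError(f"baseline {baseline!r} not a design level")
            levels = [baseline] + [l for l in levels if l != baseline]
        self.baseline, self.treatment = levels
        for lvl in levels:
            if sum(v == lvl for v in self.design.values()) < 2:
                raise ValueError(f"condition {lvl!r} has < 2 replicates")
        self.norm = norm
        self.prior_df = prior_df

    def fit(self) -> "ModeratedTTestResults":
        counts = self.table.counts.to_numpy(float)
        libs = counts.sum(axis=0)
        if self.norm is not None:
            libs = libs * self.norm.factors.reindex(self.table.sample_ids).to_numpy()
        logcpm = np.log2((counts + 0.5) / (libs + 1.0)[None, :] * 1e6)

        grp = np.array([self.design[s] == self.treatment
                        for s in self.table.sample_ids])
        n1, n2 = int((~grp).sum()), int(grp.sum())
        m1 = logcpm[:, ~grp].mean(axis=1)
        m2 = logcpm[:, grp].mean(axis=1)
        df_resid = n1 + n2 - 2
        ss = (
            ((logcpm[:, ~grp] - m1[:, None]) ** 2).sum(axis=1)
            + ((logcpm[:, grp] - m2[:, None]) ** 2).sum(axis=1)
        )
        s2 = ss / df_resid

        if self.prior_df is None:
            d0, s0_sq = fit_variance_prior(s2, df_resid)
        else:
            d0 = float(self.prior_df)
            s0_sq = float(np.mean(s2)) if d0 > 0 else 0.0
        if np.isinf(d0):
            s2_post = np.full_like(s2, s0_sq)
            df_total = np.inf
        else:
            s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
            df_total = d0 + df_resid

        log2fc = m2 - m1
        se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, log2fc / se, 0.0)
        if np.isinf(df_total):
            p = 2.0 * stats.norm.sf(np.abs(t))
        else:
            p = 2.0 * stats.t.sf(np.abs(t), df_total)
        q = bh_fdr(p)

        mean_cpm = cpm(self.table.counts).mean(axis=1).to_numpy()
        res = pd.DataFrame(
            {
                "log2fc": log2fc,
                "t": t,
                "p_value": p,
                "fdr": q,
                "mean_cpm": mean_cpm,
                "residual_var": s2,
                "posterior_var": s2_post,
            },
            index=pd.Index(self.table.feature_ids, name="feature_id"),
        )
        return ModeratedTTestResults(self, res, d0, s0_sq, df_resid)


class ModeratedTTestResults:
    """Fit results: per-feature effects, moderated statistics and FDR."""

    def __init__(self, model: ModeratedTTest, table: pd.DataFrame,
                 prior_df: float, prior_var: float, residual_df: int) -> None:
        self.model = model
        self.table = table
        self.prior_df = prior_df
        self.prior_var = prior_var
        self.residual_df = residual_df

    @property
    def log2fc(self) -> pd.Series:
        return self.table["log2fc"]

    @property
    def p_values(self) -> pd.Series:
        return self.table["p_value"]

    @property
    def fdr(self) -> pd.Series:
        return self.table["fdr"]

    def fold_change_table(self) -> pd.DataFrame:
        return self.table[["log2fc", "p_value", "fdr", "mean_cpm"]].copy()

    def classify(self, **kwargs) -> pd.Series:
        return classify_db(self.table, **kwargs)

    def summary(self) -> str:
        n = len(self.table)
        up = int(((self.table.log2fc >= 1) & (self.table.fdr <= 0.05)).sum())
        dn = int(((self.table.log2fc <= -1) & (self.table.fdr <= 0.05)).sum())
        lines = [
            "Moderated two-group t-test",
            "=" * 40,
            f"features:            {n}",
            f"contrast:            {self.model.treatment} - {self.model.baseline}",
            f"residual df:         {self.residual_df}",
            f"prior df (d0):       {self.prior_df:.4g}",
            f"prior variance s0^2: {self.prior_var:.4g}",
            f"up   (log2FC >= 1, FDR <= 0.05): {up}",
            f"down (log2FC <= -1, FDR <= 0.05): {dn}",
        ]
        return "\n".join(lines)


def moderated_test(
    table: CountTable,
    design: Mapping[str, str] | Sequence[str],
    norm: Optional[NormFactors] = None,
    **kwargs,
) -> ModeratedTTestResults:
    """Convenience wrapper: build and fit a :class:`ModeratedTTest`."""
    return ModeratedTTest(table, design, norm, **kwargs).fit()


# ---------------------------------------------------------------------------
# classification rules


def classify_db(
    result: pd.DataFrame, min_abs_log2fc: float = 1.0, max_fdr: float = 0.05
) -> pd.Series:
    """Differential-binding labels: up/down/unchanged at |log2FC| >= 1, FDR <= 0.05."""
    up = (result["log2fc"] >= min_abs_log2fc) & (result["fdr"] <= max_fdr)
    down = (result["log2fc"] <= -min_abs_log2fc) & (result["fdr"] <= max_fdr)
    labels = pd.Series("unchanged", index=result.index, name="db_class")
    labels[up] = "up"
    labels[down] = "down"
    return labels


def classify_de(
    result: pd.DataFrame,
    min_abs_log2fc: float = 1.0,
    max_padj: float = 0.05,
    min_cpm: float = 1.0,
) -> pd.Series:
    """Differential-expression labels; adds the mean CPM >= min_cpm requirement."""
    base = classify_db(result, min_abs_log2fc, max_padj)
    labels = base.where(result["mean_cpm"] >= min_cpm, "unchanged")
    labels.name = "de_class"
    return labels
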