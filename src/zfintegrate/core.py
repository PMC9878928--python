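"""Shared domain types for the CTCF binding / expression integration pipeline.

All coordinates are 0-based half-open (BED convention). Inputs in other
conventions are converted at the I/O boundary, never downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

STRANDS = ("+", "-", ".")

#: replicate-level peak confidence tiers
TIERS = ("high", "low", "none")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open span on a chromosome.

    ``start`` is inclusive, ``end`` exclusive; ``strand`` is '+', '-' or '.'
    (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True when the two spans share >= 1 bp on the same chromosome."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Gene:
    """A gene model carrying its transcription start and end sites.

    On the + strand the TSS is the interval start and the TES the last base;
    on the - strand the TSS is the last base and the TES the start.
    """

    gene_id: str
    interval: GenomicInterval

    @property
    def tss(self) -> int:
        return self.interval.start if self.interval.strand != "-" else self.interval.end - 1

    @property
    def tes(self) -> int:
        return self.interval.end - 1 if self.interval.strand != "-" else self.interval.start

    @property
    def chrom(self) -> str:
        return self.interval.chrom


@dataclass(frozen=True)
class Peak:
    """A binding-site interval with optional summit and per-replicate tiers."""

    peak_id: str
    interval: GenomicInterval
    summit: Optional[int] = None
    replicate_calls: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.summit is not None and not (
            self.interval.start <= self.summit < self.interval.end
        ):
            raise ValueError(
                f"summit {self.summit} outside peak {self.peak_id} "
                f"[{self.interval.start},{self.interval.end})"
            )
        for tier in self.replicate_calls.values():
            if tier not in TIERS:
                raise ValueError(f"unknown confidence tier {tier!r}")

    @property
    def anchor_point(self) -> int:
        """Summit when present, interval midpoint otherwise."""
        return self.summit if self.summit is not None else self.interval.midpoint

    @property
    def chrom(self) -> str:
        return self.interval.chrom


class CountTable:
    """Integer feature x sample count matrix, optionally with spike-in rows.

    The spike-in matrix shares samples with the main matrix but has its own
    feature set (exogenous chromatin, e.g. Drosophila in a human ChIP).
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        spikein_counts: Optional[pd.DataFrame] = None,
    ) -> None:
        counts = counts.copy()
        self._validate(counts)
        if spikein_counts is not None:
            spikein_counts = spikein_counts.copy()
            self._validate(spikein_counts)
            if list(spikein_counts.columns) != list(counts.columns):
                raise ValueError("spike-in samples must match main table samples")
        self.counts = counts
        self.spikein_counts = spikein_counts

    @staticmethod
    def _validate(df: pd.DataFrame) -> None:
        if df.index.duplicated().any():
            raise ValueError("duplicate feature ids")
        if df.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        vals = df.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                raise ValueError("counts must be integral")
        if (vals < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def subset_features(self, keep: Sequence[str]) -> "CountTable":
        return CountTable(self.counts.loc[list(keep)], self.spikein_counts)


def fold_change_table(
    feature_ids: Sequence[str],
    log2fc: Sequence[float],
    p_value: Sequence[float],
    fdr: Sequence[float],
    mean_cpm: Sequence[float],
) -> pd.DataFrame:
    """Assemble a fold-change table (log2FC, p, FDR, mean CPM per feature)."""
    df = pd.DataFrame(
        {
            "log2fc": np.asarray(log2fc, float),
            "p_value": np.asarray(p_value, float),
            "fdr": np.asarray(fdr, float),
            "mean_cpm": np.asarray(mean_cpm, float),
        },
        index=pd.Index(feature_ids, name="feature_id"),
    )
    for col in ("p_value", "fdr"):
        bad = ~df[col].between(0.0, 1.0)
        if bad.any():
            raise ValueError(f"{col} outside [0, 1] for {int(bad.sum())} features")
    return df


@dataclass(frozen=True)
class Loop:
    """A chromatin loop: two cis anchors, anchor1 upstream of anchor2."""

    anchor1: GenomicInterval
    anchor2: GenomicInterval
    category1: Optional[str] = None
    category2: Optional[str] = None

    def __post_init__(self) -> None:
        if self.anchor1.chrom != self.anchor2.chrom:
            raise ValueError("loop anchors must be on the same chromosome")
        if self.anchor1.start > self.anchor2.start:
            raise ValueError("anchor1 must not start downstream of anchor2")

    @property
    def chrom(self) -> str:
        return self.anchor1.chrom

    @property
    def span(self) -> int:
        """Anchor midpoint separation in bp."""
        return self.anchor2.midpoint - self.anchor1.midpoint


class ContactMap:
    """A binned symmetric cis contact matrix for one chromosome."""

    SYMMETRY_TOL = 1e-9

    def __init__(self, chrom: str, bin_size: int, matrix: np.ndarray) -> None:
        matrix = np.asarray(matrix, dtype=float)
        if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
            raise ValueError("contact matrix must be square")
        if not np.allclose(matrix, matrix.T, atol=self.SYMMETRY_TOL, rtol=0):
            raise ValueError("contact matrix must be symmetric")
        if (matrix < 0).any():
            raise ValueError("contact values must be non-negative")
        if bin_size <= 0:
            raise ValueError("bin_size must be positive")
        self.chrom = chrom
        self.bin_size = int(bin_size)
        self.matrix = matrix

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]

    def bin_of(self, pos: int) -> int:
        return int(pos) // self.bin_size
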