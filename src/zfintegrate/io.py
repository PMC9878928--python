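"""Readers and writers for the plain-text formats the pipeline exchanges.

BED/BEDPE are parsed as 0-based half-open. Chromosome names are kept
verbatim: mixing ``chr1`` and ``1`` across inputs is the caller's error and
is never silently repaired.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from Bio import SeqIO

from .core import ContactMap, CountTable, Gene, GenomicInterval, Loop, Peak

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

_DNA_ALPHABET = set("ACGTN")


class ParseError(ValueError):
    """Malformed input; the message names the offending line."""


def read_bed(path: PathLike) -> list[GenomicInterval]:
    """Read a 3-6 column BED file into intervals (strand honored if present)."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 BED columns")
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                strand = fields[5] if len(fields) >= 6 else "."
                out.append(GenomicInterval(chrom, start, end, strand))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed(items: Iterable[GenomicInterval], path: PathLike) -> None:
    """Write intervals as BED6 in deterministic (chrom, start, end) order."""
    rows = sorted(items, key=lambda iv: (iv.chrom, iv.start, iv.end))
    with open(path, "w") as fh:
        for i, iv in enumerate(rows):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\tfeature_{i}\t0\t{iv.strand}\n")


def read_peaks_bed(path: PathLike) -> list[Peak]:
    """Read peaks from BED; column 4 (if present) becomes the peak id."""
    peaks = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 BED columns")
            try:
                iv = GenomicInterval(
                    fields[0], int(fields[1]), int(fields[2]),
                    fields[5] if len(fields) >= 6 else ".",
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            pid = fields[3] if len(fields) >= 4 and fields[3] else f"peak_{lineno}"
            peaks.append(Peak(pid, iv))
    return peaks


def write_peaks_bed(peaks: Iterable[Peak], path: PathLike) -> None:
    rows = sorted(peaks, key=lambda p: (p.chrom, p.interval.start, p.interval.end))
    with open(path, "w") as fh:
        for p in rows:
            fh.write(
                f"{p.chrom}\t{p.interval.start}\t{p.interval.end}\t"
                f"{p.peak_id}\t0\t{p.interval.strand}\n"
            )


def read_fasta(path: PathLike) -> dict[str, str]:
    """Read DNA FASTA; sequences upper-cased, names must be unique."""
    seqs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seqs:
            raise ParseError(f"duplicate FASTA name {record.id!r} in {path}")
        seq = str(record.seq).upper()
        bad = set(seq) - _DNA_ALPHABET
        if bad:
            raise ParseError(
                f"non-DNA characters {sorted(bad)} in sequence {record.id!r}"
            )
        seqs[record.id] = seq
    return seqs


def write_fasta(seqs: dict[str, str], path: PathLike, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_bedpe(path: PathLike) -> list[Loop]:
    """Read loops from 6+ column BEDPE, reordering anchors and skipping
    trans-chromosomal rows (skips are logged with a count)."""
    loops: list[Loop] = []
    n_trans = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ParseError(f"{path}:{lineno}: expected >= 6 BEDPE columns")
            try:
                a = GenomicInterval(f[0], int(f[1]), int(f[2]))
                b = GenomicInterval(f[3], int(f[4]), int(f[5]))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if a.chrom != b.chrom:
                n_trans += 1
                continue
            if a.start > b.start:
                a, b = b, a
            loops.append(Loop(a, b))
    if n_trans:
        logger.warning("%s: skipped %d trans-chromosomal loop rows", path, n_trans)
    return loops


def write_bedpe(loops: Iterable[Loop], path: PathLike) -> None:
    with open(path, "w") as fh:
        for lp in loops:
            fh.write(
                f"{lp.anchor1.chrom}\t{lp.anchor1.start}\t{lp.anchor1.end}\t"
                f"{lp.anchor2.chrom}\t{lp.anchor2.start}\t{lp.anchor2.end}\n"
            )


def read_count_table(
    path: PathLike, spikein_path: Optional[PathLike] = None
) -> CountTable:
    """Read a TSV count table (first column feature_id, header sample ids)."""
    counts = pd.read_csv(path, sep="\t", index_col=0)
    spike = pd.read_csv(spikein_path, sep="\t", index_col=0) if spikein_path else None
    return CountTable(counts, spike)


def write_count_table(table: CountTable, path: PathLike,
                      spikein_path: Optional[PathLike] = None) -> None:
    table.counts.to_csv(path, sep="\t", index_label="feature_id")
    if spikein_path is not None and table.spikein_counts is not None:
        table.spikein_counts.to_csv(spikein_path, sep="\t", index_label="feature_id")


def read_genes_tsv(path: PathLike) -> list[Gene]:
    """Read gene models from TSV: gene_id, chrom, start, end, strand."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    genes = []
    for row in df.itertuples(index=False):
        genes.append(
            Gene(row.gene_id, GenomicInterval(row.chrom, int(row.start),
                                              int(row.end), row.strand))
        )
    return genes


def write_genes_tsv(genes: Iterable[Gene], path: PathLike) -> None:
    rows = [
        {
            "gene_id": g.gene_id,
            "chrom": g.chrom,
            "start": g.interval.start,
            "end": g.interval.end,
            "strand": g.interval.strand,
        }
        for g in genes
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_contact_map_dense(path: PathLike, chrom: str, bin_size: int) -> ContactMap:
    """Read a dense whitespace/tab-separated matrix as a contact map."""
    matrix = np.loadtxt(path)
    return ContactMap(chrom, bin_size, matrix)


def write_contact_map_dense(cmap: ContactMap, path: PathLike) -> None:
    np.savetxt(path, cmap.matrix, fmt="%.10g", delimiter="\t")


def read_contact_map_triplet(
    path: PathLike, chrom: str, bin_size: int, n_bins: Optional[int] = None
) -> ContactMap:
    """Read (bin_i, bin_j, value) triplets; missing pixels are zero.

    Triplets may give either triangle; the matrix is symmetrized by mirroring.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=["i", "j", "value"])
    size = n_bins if n_bins is not None else int(max(df["i"].max(), df["j"].max())) + 1
    m = np.zeros((size, size))
    m[df["i"].to_numpy(int), df["j"].to_numpy(int)] = df["value"].to_numpy(float)
    upper = np.triu(m) + np.triu(m, 1).T
    lower = np.tril(m) + np.tril(m, -1).T
    merged = np.where(np.abs(upper) >= np.abs(lower), upper, lower)
    return ContactMap(chrom, bin_size, merged)


def read_meme_motif(path: PathLike) -> tuple[str, np.ndarray, np.ndarray]:
    """Read the first motif of a MEME-minimal file.

    Returns (name, probability matrix W x 4 in A/C/G/T order, background
    frequencies; uniform when the file has no background line).
    """
    name = None
    bg = np.full(4, 0.25)
    rows: list[list[float]] = []
    in_matrix = False
    with open(path) as fh:
        lines = iter(fh)
        for line in lines:
            stripped = line.strip()
            if stripped.startswith("Background letter frequencies"):
                freq_line = next(lines).split()
                bg = np.array([float(freq_line[i]) for i in (1, 3, 5, 7)])
            elif stripped.startswith("MOTIF"):
                if name is not None:
                    break  # only the first motif
                name = stripped.split()[1]
            elif stripped.startswith("letter-probability matrix"):
                in_matrix = True
            elif in_matrix:
                if not stripped or stripped.startswith("URL"):
                    in_matrix = False
                    continue
                rows.append([float(x) for x in stripped.split()])
    if name is None or not rows:
        raise ParseError(f"{path}: no MEME motif found")
    return name, np.array(rows), bg


def write_meme_motif(
    name: str, probs: np.ndarray, path: PathLike,
    background: Optional[Sequence[float]] = None,
) -> None:
    bg = np.asarray(background if background is not None else [0.25] * 4)
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(f"A {bg[0]:.5f} C {bg[1]:.5f} G {bg[2]:.5f} T {bg[3]:.5f}\n\n")
        fh.write(f"MOTIF {name}\n")
        fh.write(
            f"letter-probability matrix: alength= 4 w= {len(probs)} "
            f"nsites= 20 E= 0\n"
        )
        for row in probs:
            fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")
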