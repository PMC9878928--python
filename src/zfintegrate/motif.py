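"""PWM scanning with exact p-values and flank-signature analysis.

Scanning follows the FIMO scheme: log2 odds scores against a 0-order
background, discretized on a fixed score grid, with the exact null
distribution of the score obtained by position-wise convolution over the
background — so every reported p-value is exact for the discretized scores.
Matches are orientation-normalized and the +/- 20 bp flanks around the core
are aligned, clustered by hamming distance, summarized as information-content
logos, and tested for single-base signatures (e.g. a dominant G at position
+4 downstream of the core).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.proportion import proportion_confint

_BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _encode(seq: str) -> np.ndarray:
    """A/C/G/T -> 0..3, anything else (N) -> 4."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    out = np.full(len(arr), 4, dtype=np.int64)
    for b, i in _CODE.items():
        out[arr == ord(b)] = i
    return out


@dataclass
class PWM:
    """Position weight matrix with background and pseudocount.

    ``probs`` is W x 4 (A, C, G, T); the pseudocount is background-
    proportional: p' = (p + pc * bg) / (1 + pc), so columns matching the
    background score exactly zero.
    """

    name: str
    probs: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 0.1

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, float)
        self.background = np.asarray(self.background, float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("probs must be W x 4")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PWM columns must each sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError("background must sum to 1")
        if (self.background <= 0).any():
            raise ValueError("background probabilities must be positive")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @classmethod
    def from_consensus(cls, consensus: str, fidelity: float = 0.9,
                       background: Optional[Sequence[float]] = None,
                       name: str = "consensus") -> "PWM":
        """PWM giving ``fidelity`` to the consensus base, rest split evenly."""
        w = len(consensus)
        probs = np.full((w, 4), (1.0 - fidelity) / 3.0)
        for j, b in enumerate(consensus.upper()):
            probs[j, _CODE[b]] = fidelity
        bg = np.asarray(background if background is not None else np.full(4, 0.25))
        return cls(name, probs, bg)

    def log_odds(self) -> np.ndarray:
        """W x 4 matrix of log2((p + pc*bg) / ((1+pc) * bg)) in bits."""
        adj = (self.probs + self.pseudocount * self.background[None, :]) / (
            1.0 + self.pseudocount
        )
        return np.log2(adj / self.background[None, :])

    def reverse_complement(self) -> "PWM":
        return PWM(self.name + "_rc", self.probs[::-1, ::-1].copy(),
                   self.background, self.pseudocount)


class ScoreDistribution:
    """Exact null distribution of the discretized log-odds score.

    Scores are rounded to an integer grid of step ``resolution`` bits; the
    distribution is the position-wise convolution of the per-column score
    distributions under the 0-order background.
    """

    MAX_RESOLUTION = 0.01  # bits

    def __init__(self, pwm: PWM, resolution: float = 1e-3) -> None:
        if resolution > self.MAX_RESOLUTION:
            raise ValueError(
                f"resolution {resolution} bits too coarse (max {self.MAX_RESOLUTION})"
            )
        if pwm.width > 30:
            raise ValueError("exact score distribution limited to width <= 30")
        self.resolution = resolution
        self.int_scores = np.round(pwm.log_odds() / resolution).astype(np.int64)
        bg = pwm.background
        mins = self.int_scores.min(axis=1)
        self.min_total = int(mins.sum())
        span = int((self.int_scores.max(axis=1) - mins).sum())
        dist = np.zeros(span + 1)
        dist[0] = 1.0
        offset = 0  # current distribution starts at sum of column minima
        width_used = 0
        for j in range(pwm.width):
            col = self.int_scores[j] - self.int_scores[j].min()
            new = np.zeros(width_used + col.max() + 1)
            for b in range(4):
                new[col[b] : col[b] + width_used + 1] += bg[b] * dist[: width_used + 1]
            width_used += int(col.max())
            dist = new
        self._probs = dist
        # tail[i] = P(score_int >= min_total + i)
        self._tail = np.cumsum(dist[::-1])[::-1]

    def pvalue_int(self, int_score: np.ndarray | int) -> np.ndarray | float:
        """P(score >= s) for integer grid score(s); exact by construction."""
        idx = np.asarray(int_score) - self.min_total
        idx = np.clip(idx, 0, len(self._tail))
        tail = np.append(self._tail, 0.0)
        out = tail[idx]
        return float(out) if np.isscalar(int_score) else out

    def pvalue(self, score_bits: float) -> float:
        return float(self.pvalue_int(int(round(score_bits / self.resolution))))


def score_pvalue_table(pwm: PWM, resolution: float = 1e-3) -> pd.DataFrame:
    """Exact mapping from every achievable discretized score to its p-value.

    Rows cover the support of the null score distribution; ``p_value`` is
    P(score >= s) under the PWM's 0-order background.
    """
    dist = ScoreDistribution(pwm, resolution)
    support = np.flatnonzero(dist._probs > 0) + dist.min_total
    return pd.DataFrame(
        {
            "score": support * resolution,
            "probability": dist._probs[support - dist.min_total],
            "p_value": dist.pvalue_int(support),
        }
    )


@dataclass(frozen=True)
class MotifHit:
    seq_id: str
    offset: int  # 0-based leftmost position of the match on the forward strand
    strand: str
    score: float  # bits
    p_value: float


def estimate_background(sequences: dict[str, str]) -> np.ndarray:
    """0-order background from base counts over all scanned sequences."""
    counts = np.zeros(4)
    for seq in sequences.values():
        codes = _encode(seq)
        counts += np.bincount(codes[codes < 4], minlength=4)
    if counts.sum() == 0:
        return np.full(4, 0.25)
    return counts / counts.sum()


def _window_scores(codes: np.ndarray, int_matrix: np.ndarray) -> np.ndarray:
    """Integer score of every window; windows containing N get a sentinel low."""
    W = int_matrix.shape[0]
    nwin = len(codes) - W + 1
    if nwin <= 0:
        return np.zeros(0, dtype=np.int64)
    mat = np.hstack([int_matrix, np.full((W, 1), np.iinfo(np.int32).min // W,
                                         dtype=np.int64)])
    acc = np.zeros(nwin, dtype=np.int64)
    for j in range(W):
        acc += mat[j][codes[j : j + nwin]]
    return acc


def scan(
    sequences: dict[str, str],
    pwm: PWM,
    p_threshold: float = 1e-4,
    background: str | np.ndarray = "sequences",
    resolution: float = 1e-3,
) -> list[MotifHit]:
    """Scan both strands of each sequence; report hits with p <= threshold.

    ``background`` is 'sequences' (0-order, estimated from the input, the
    FIMO default), 'uniform', or an explicit length-4 array. Windows
    containing N are skipped.
    """
    if isinstance(background, str):
        if background == "uniform":
            bg = np.full(4, 0.25)
        elif background == "sequences":
            bg = estimate_background(sequences)
        else:
            raise ValueError("background must be 'sequences', 'uniform' or an array")
    else:
        bg = np.asarray(background, float)
    pwm = PWM(pwm.name, pwm.probs, bg, pwm.pseudocount)
    fwd = ScoreDistribution(pwm, resolution)
    rc = ScoreDistribution(pwm.reverse_complement(), resolution)

    hits: list[MotifHit] = []
    W = pwm.width
    for seq_id, seq in sequences.items():
        codes = _encode(seq.upper())
        if len(codes) < W:
            continue
        for strand, dist in (("+", fwd), ("-", rc)):
            ints = _window_scores(codes, dist.int_scores)
            pvals = dist.pvalue_int(ints)
            for off in np.flatnonzero(pvals <= p_threshold):
                hits.append(
                    MotifHit(seq_id, int(off), strand,
                             float(ints[off] * dist.resolution),
                             float(pvals[off]))
                )
    hits.sort(key=lambda h: (h.seq_id, h.offset, h.strand))
    return hits


def best_hits(hits: Sequence[MotifHit]) -> dict[str, MotifHit]:
    """One hit per sequence: lowest p, ties broken by score then position."""
    best: dict[str, MotifHit] = {}
    for h in hits:
        cur = best.get(h.seq_id)
        if cur is None or (h.p_value, -h.score, h.offset, h.strand) < (
            cur.p_value, -cur.score, cur.offset, cur.strand
        ):
            best[h.seq_id] = h
    return best


@dataclass
class FlankAlignment:
    """Orientation-normalized alignment of core matches with flanks.

    Every row is flank + core + flank long, in motif (plus-strand)
    orientation; truncated windows are padded with N.
    """

    ids: list[str]
    rows: list[str]
    core_width: int
    flank: int
    padded: list[bool]
    cluster: Optional[np.ndarray] = None

    @property
    def width(self) -> int:
        return self.core_width + 2 * self.flank

    def as_codes(self) -> np.ndarray:
        return np.vstack([_encode(r) for r in self.rows])


def extract_flanks(
    hits: dict[str, MotifHit] | Sequence[MotifHit],
    sequences: dict[str, str],
    core_width: int,
    flank: int = 20,
) -> FlankAlignment:
    """Cut the core +/- flank window around each (single) hit per sequence.

    Minus-strand matches are reverse-complemented so that alignment position
    +1..+flank is always 3' of the core in motif orientation. Windows
    running past a sequence end are padded with N and flagged.
    """
    if not isinstance(hits, dict):
        hits = best_hits(hits)
    ids, rows, padded = [], [], []
    for seq_id, hit in sorted(hits.items()):
        seq = sequences[seq_id].upper()
        lo = hit.offset - flank
        hi = hit.offset + core_width + flank
        pad_left = max(0, -lo)
        pad_right = max(0, hi - len(seq))
        window = "N" * pad_left + seq[max(0, lo) : min(len(seq), hi)] + "N" * pad_right
        if hit.strand == "-":
            window = revcomp(window)
        ids.append(seq_id)
        rows.append(window)
        padded.append(bool(pad_left or pad_right))
    return FlankAlignment(ids, rows, core_width, flank, padded)


def hamming_distance_matrix(alignment: FlankAlignment) -> np.ndarray:
    """Pairwise normalized hamming distances; N mismatches count 1/2."""
    X = alignment.as_codes()
    n, L = X.shape
    isn = X == 4
    D = np.zeros((n, n))
    for i in range(n):
        neq = X[i][None, :] != X
        either_n = isn[i][None, :] | isn
        d = (neq & ~either_n).sum(axis=1) + 0.5 * either_n.sum(axis=1)
        D[i] = d / L
    np.fill_diagonal(D, 0.0)
    return D


def hamming_cluster(
    alignment: FlankAlignment, k: int = 5
) -> tuple[np.ndarray, np.ndarray]:
    """Average-linkage clustering on hamming distances, cut to k clusters.

    Returns (labels 1..k per row, dendrogram leaf order for heatmap output).
    """
    n = len(alignment.rows)
    if k > n:
        raise ValueError(f"k={k} exceeds {n} rows")
    if n == 1:
        return np.array([1]), np.array([0])
    D = hamming_distance_matrix(alignment)
    Z = hierarchy.linkage(squareform(D, checks=False), method="average")
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    order = hierarchy.leaves_list(Z)
    return labels, order


def column_information(rows: Sequence[str]) -> pd.DataFrame:
    """Per-column information content (bits) and logo heights.

    IC_j = 2 + sum_b f_jb log2 f_jb with N excluded from the counts; logo
    height of base b is f_jb * IC_j. Columns with no A/C/G/T calls get IC 0.
    """
    X = np.vstack([_encode(r) for r in rows])
    L = X.shape[1]
    out = []
    for j in range(L):
        col = X[:, j]
        col = col[col < 4]
        rec = {"position": j, "ic": 0.0, "A": 0.0, "C": 0.0, "G": 0.0, "T": 0.0}
        if len(col):
            f = np.bincount(col, minlength=4) / len(col)
            nz = f[f > 0]
            ic = 2.0 + float((nz * np.log2(nz)).sum())
            rec["ic"] = ic
            for b, i in _CODE.items():
                rec[b] = f[i] * ic
        out.append(rec)
    return pd.DataFrame(out)


def signature_column(alignment: FlankAlignment, offset: int) -> int:
    """Alignment column of a core-relative flank offset (+1 = first 3' base)."""
    if offset == 0 or abs(offset) > alignment.flank:
        raise ValueError(f"offset must be in +/-1..{alignment.flank}, got {offset}")
    if offset > 0:
        return alignment.flank + alignment.core_width + offset - 1
    return alignment.flank + offset


def signature_fraction(
    alignment: FlankAlignment,
    offset: int,
    base: str,
    control: Optional[FlankAlignment] = None,
) -> dict:
    """Fraction of sites carrying ``base`` at a core-relative flank offset.

    Offsets are counted from the core edge in motif orientation: +4 is the
    4th base 3' of the core, -1 the base immediately 5'. Rows with N at the
    column are excluded from the denominator. Returns the fraction with its
    Wilson 95% CI, and the enrichment ratio over ``control`` when given.
    """
    col = signature_column(alignment, offset)
    X = alignment.as_codes()[:, col]
    informative = X < 4
    n = int(informative.sum())
    count = int((X[informative] == _CODE[base.upper()]).sum())
    frac = count / n if n else 0.0
    lo, hi = (proportion_confint(count, n, alpha=0.05, method="wilson")
              if n else (0.0, 1.0))
    result = {
        "fraction": frac,
        "count": count,
        "n": n,
        "ci_low": float(lo),
        "ci_high": float(hi),
        "offset": offset,
        "base": base.upper(),
    }
    if control is not None:
        ctrl = signature_fraction(control, offset, base)
        result["control_fraction"] = ctrl["fraction"]
        result["enrichment"] = (
            frac / ctrl["fraction"] if ctrl["fraction"] > 0 else np.inf
        )
    return result
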