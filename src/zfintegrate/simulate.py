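"""Synthetic data with the statistical structure the pipeline assumes.

One simulated chromosome carries gene models and binding peaks; a "mutant"
condition removes binding at a subset of peaks (negative-binomial counts with
a planted log2 fold change) and couples expression changes to genes whose
neighborhood [TSS-50kb, TES+50kb] contains an affected peak. Peak sequences
carry one core-motif instance each, with a flank signature (e.g. G at +4
downstream of the core) planted in a controlled fraction of affected sites.
Contact maps combine 1/(1+distance) decay background with multiplicative
enrichment at loop anchor pixels.

Ground-truth labels are kept alongside every output so downstream recall and
calibration can be measured without re-deriving the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import ContactMap, CountTable, Gene, GenomicInterval, Loop, Peak

# stream offsets so each generator op has an independent, reproducible stream
_STREAM_GENOME = 1
_STREAM_COUNTS = 2
_STREAM_SEQS = 3
_STREAM_LOOPS = 4
_STREAM_MAP = 5


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults describe the reference dataset: 2,000 genes and 5,000 peaks on a
    100-Mb chromosome, 20% of peaks losing binding at log2FC -2 in the mutant,
    ~100 genes coupled to a nearby affected peak at |log2FC| = 2 (direction
    random: degradation both de-represses and silences targets), 4 replicates
    per condition, NB dispersion 0.1, and a flank signature G at +4 planted in
    82% of affected sites.
    """

    seed: int = 0
    chrom: str = "chr1"
    chrom_length: int = 100_000_000
    n_genes: int = 2000
    n_peaks: int = 5000
    gene_length: int = 10_000
    peak_width: int = 400
    frac_dependent_peaks: float = 0.2
    binding_loss_log2fc: float = -2.0
    coupling_prob: float = 0.14
    expression_log2fc: float = 2.0  # magnitude; sign is random per gene
    coupling_window_bp: int = 50_000
    nb_dispersion: float = 0.1
    n_replicates: int = 4
    base_mean_peaks: float = 200.0
    base_mean_genes: float = 500.0
    spikein_n: int = 500
    spikein_base_mean: float = 100.0
    spikein_scale_per_sample: Optional[Sequence[float]] = None
    motif_core: str = "TGGCCACCAGGGGGCGCTAG"
    motif_fidelity: float = 0.9  # per-position probability of the consensus base
    flank_signature: tuple = (4, "G", 0.82)  # (offset downstream of core, base, fraction)
    sequence_length: int = 120
    loop_n: int = 50
    loop_enrichment: float = 3.0
    bin_size: int = 10_000
    map_n_bins: int = 2000
    loop_min_sep_bins: int = 200
    loop_max_sep_bins: int = 800
    contact_scale: float = 100.0
    contact_noise_sigma: float = 0.2

    def __post_init__(self) -> None:
        for name in ("frac_dependent_peaks", "coupling_prob", "motif_fidelity"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not (0.0 <= self.flank_signature[2] <= 1.0):
            raise ValueError("flank signature fraction must be in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates per condition")
        if not np.isfinite([self.binding_loss_log2fc, self.expression_log2fc]).all():
            raise ValueError("effect sizes must be finite")

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), stream])

    def to_dict(self) -> dict:
        d = asdict(self)
        d["flank_signature"] = list(d["flank_signature"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "flank_signature" in d:
            d["flank_signature"] = tuple(d["flank_signature"])
        return cls(**d)


@dataclass
class SimulatedGenome:
    """Gene and peak layout plus the planted ground truth."""

    genes: list[Gene]
    peaks: list[Peak]
    gene_truth: pd.DataFrame  # gene_id, coupled, causal_peak, planted_log2fc
    peak_truth: pd.DataFrame  # peak_id, dependent, planted_log2fc


def simulate_genome(cfg: SimulationConfig) -> SimulatedGenome:
    """Place genes and peaks, mark dependent peaks and coupled genes.

    A gene whose [TSS-window, TES+window] span contains exactly one dependent
    peak becomes coupled with probability ``coupling_prob``; that peak is its
    causal peak. Requiring a unique dependent peak keeps the planted
    gene-causal-peak association identifiable, so recall against the truth
    table measures the integration method rather than label ambiguity.
    Coupled genes carry a planted expression log2FC of random sign.
    """
    rng = cfg._rng(_STREAM_GENOME)
    slot = cfg.chrom_length / cfg.n_genes
    if cfg.gene_length >= slot:
        raise ValueError(
            f"cannot pack {cfg.n_genes} genes of {cfg.gene_length} bp "
            f"into {cfg.chrom_length} bp"
        )
    genes = []
    for i in range(cfg.n_genes):
        start = int(i * slot + rng.integers(0, int(slot - cfg.gene_length)))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            Gene(f"gene_{i:05d}",
                 GenomicInterval(cfg.chrom, start, start + cfg.gene_length, strand))
        )

    starts = np.sort(rng.integers(0, cfg.chrom_length - cfg.peak_width, cfg.n_peaks))
    peaks = [
        Peak(f"peak_{i:05d}",
             GenomicInterval(cfg.chrom, int(s), int(s) + cfg.peak_width),
             summit=int(s) + cfg.peak_width // 2)
        for i, s in enumerate(starts)
    ]

    n_dep = int(round(cfg.frac_dependent_peaks * cfg.n_peaks))
    dep_idx = rng.choice(cfg.n_peaks, size=n_dep, replace=False)
    dependent = np.zeros(cfg.n_peaks, bool)
    dependent[dep_idx] = True

    dep_mid = np.array([peaks[i].interval.midpoint for i in np.flatnonzero(dependent)])
    dep_ids = [peaks[i].peak_id for i in np.flatnonzero(dependent)]

    coupled, causal, gene_fc = [], [], []
    w = cfg.coupling_window_bp
    for g in genes:
        lo = min(g.tss, g.tes) - w
        hi = max(g.tss, g.tes) + w
        in_window = (dep_mid >= lo) & (dep_mid <= hi)
        if in_window.sum() == 1 and rng.random() < cfg.coupling_prob:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            coupled.append(True)
            causal.append(dep_ids[int(np.flatnonzero(in_window)[0])])
            gene_fc.append(sign * cfg.expression_log2fc)
        else:
            coupled.append(False)
            causal.append("")
            gene_fc.append(0.0)

    gene_truth = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "coupled": coupled,
            "causal_peak": causal,
            "planted_log2fc": gene_fc,
        }
    ).set_index("gene_id")
    peak_truth = pd.DataFrame(
        {
            "peak_id": [p.peak_id for p in peaks],
            "dependent": dependent,
            "planted_log2fc": np.where(dependent, cfg.binding_loss_log2fc, 0.0),
        }
    ).set_index("peak_id")
    return SimulatedGenome(genes, peaks, gene_truth, peak_truth)


def _nb_draws(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB in mean-dispersion form: var = mu + dispersion * mu^2."""
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_counts(
    cfg: SimulationConfig, sim: SimulatedGenome
) -> tuple[CountTable, CountTable]:
    """Draw NB peak and gene counts; planted effects apply in the mutant only.

    The peak table carries a companion spike-in matrix whose per-sample means
    follow ``spikein_scale_per_sample`` and show no condition effect.
    """
    rng = cfg._rng(_STREAM_COUNTS)
    n_rep = cfg.n_replicates
    samples = [f"ctrl_{i+1}" for i in range(n_rep)] + [f"mut_{i+1}" for i in range(n_rep)]
    is_mut = np.array([0] * n_rep + [1] * n_rep, bool)

    def draw_table(ids, base_mean, sigma, planted_fc):
        base = rng.lognormal(np.log(base_mean), sigma, size=len(ids))
        mean = base[:, None] * np.where(is_mut[None, :],
                                        2.0 ** np.asarray(planted_fc)[:, None], 1.0)
        counts = _nb_draws(rng, mean, cfg.nb_dispersion)
        return pd.DataFrame(counts, index=pd.Index(ids, name="feature_id"),
                            columns=samples)

    peak_counts = draw_table(
        list(sim.peak_truth.index), cfg.base_mean_peaks, 0.5,
        sim.peak_truth["planted_log2fc"].to_numpy(),
    )
    gene_counts = draw_table(
        list(sim.gene_truth.index), cfg.base_mean_genes, 1.0,
        sim.gene_truth["planted_log2fc"].to_numpy(),
    )

    scale = np.asarray(
        cfg.spikein_scale_per_sample
        if cfg.spikein_scale_per_sample is not None
        else np.ones(2 * n_rep),
        float,
    )
    if scale.shape != (2 * n_rep,):
        raise ValueError("spikein_scale_per_sample must have one factor per sample")
    spike_base = rng.lognormal(np.log(cfg.spikein_base_mean), 0.5, size=cfg.spikein_n)
    spike_mean = spike_base[:, None] * scale[None, :]
    spike = pd.DataFrame(
        _nb_draws(rng, spike_mean, cfg.nb_dispersion),
        index=pd.Index([f"spike_{i:04d}" for i in range(cfg.spikein_n)],
                       name="feature_id"),
        columns=samples,
    )
    return CountTable(peak_counts, spike), CountTable(gene_counts)


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def simulate_sequences(
    cfg: SimulationConfig, sim: SimulatedGenome
) -> tuple[dict[str, str], pd.DataFrame]:
    """One sequence per peak with a single planted core-motif instance.

    A fraction f of dependent-peak sequences carries the flank-signature base
    at the stated offset relative to the core (in motif orientation); the
    remaining dependent sites carry one of the other three bases there, so the
    observed base fraction among dependent sites is unbiased for f.
    Non-dependent sites keep plain background at that position. Returns
    (sequences, truth) where truth records core offset and strand in forward
    coordinates plus whether the signature was planted.
    """
    rng = cfg._rng(_STREAM_SEQS)
    core = cfg.motif_core.upper()
    W = len(core)
    if W < 8:
        raise ValueError("motif core must be >= 8 bp")
    sig_offset, sig_base, sig_frac = cfg.flank_signature
    if not (1 <= abs(int(sig_offset)) <= 20):
        raise ValueError("flank signature offset must be within +/-20 of the core")
    L = cfg.sequence_length
    margin = 25
    if L < W + 2 * margin:
        raise ValueError("sequence_length too short for core plus flanks")

    bases = np.array(list("ACGT"))
    core_idx = np.array(["ACGT".index(b) for b in core])
    dep = sim.peak_truth["dependent"].to_numpy()

    seqs: dict[str, str] = {}
    rows = []
    for i, pid in enumerate(sim.peak_truth.index):
        arr = bases[rng.integers(0, 4, L)]
        off = int(rng.integers(margin, L - W - margin + 1))
        # core instance: consensus base with prob motif_fidelity, else random other
        keep = rng.random(W) < cfg.motif_fidelity
        mut = (core_idx + rng.integers(1, 4, W)) % 4
        arr[off : off + W] = np.where(keep, bases[core_idx], bases[mut])
        planted = False
        if dep[i]:
            if sig_offset > 0:
                col = off + W + (sig_offset - 1)  # +1 is first base 3' of core
            else:
                col = off + sig_offset  # -1 is first base 5' of core
            if rng.random() < sig_frac:
                arr[col] = sig_base
                planted = True
            else:
                others = [b for b in "ACGT" if b != sig_base]
                arr[col] = others[int(rng.integers(0, 3))]
        seq = "".join(arr)
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            seq = revcomp(seq)
            fwd_off = L - (off + W)
        else:
            fwd_off = off
        seqs[pid] = seq
        rows.append((pid, fwd_off, strand, planted))
    truth = pd.DataFrame(
        rows, columns=["seq_id", "core_offset", "strand", "signature_planted"]
    ).set_index("seq_id")
    return seqs, truth


def simulate_loops(cfg: SimulationConfig) -> list[Loop]:
    """Loop anchor pairs on the contact-map bin grid, clear of edges/diagonal."""
    rng = cfg._rng(_STREAM_LOOPS)
    margin = 12  # bins clear of matrix edges (> APA window)
    loops = []
    for _ in range(cfg.loop_n):
        sep = int(rng.integers(cfg.loop_min_sep_bins, cfg.loop_max_sep_bins + 1))
        b1 = int(rng.integers(margin, cfg.map_n_bins - margin - sep))
        b2 = b1 + sep
        a1 = GenomicInterval(cfg.chrom, b1 * cfg.bin_size, (b1 + 1) * cfg.bin_size)
        a2 = GenomicInterval(cfg.chrom, b2 * cfg.bin_size, (b2 + 1) * cfg.bin_size)
        loops.append(Loop(a1, a2))
    return loops


def simulate_contact_map(cfg: SimulationConfig, loops: list[Loop]) -> ContactMap:
    """Distance-decay background with multiplicative enrichment at loop pixels.

    Background value at bins (i, j) is contact_scale / (1 + |i - j|), jittered
    by symmetric multiplicative lognormal noise; each loop's anchor-pair pixel
    is scaled by ``loop_enrichment`` before noise is applied.
    """
    rng = cfg._rng(_STREAM_MAP)
    n = cfg.map_n_bins
    idx = np.arange(n)
    dist = np.abs(idx[:, None] - idx[None, :])
    m = cfg.contact_scale / (1.0 + dist)

    for lp in loops:
        b1 = lp.anchor1.midpoint // cfg.bin_size
        b2 = lp.anchor2.midpoint // cfg.bin_size
        if not (0 <= b1 < n and 0 <= b2 < n):
            raise ValueError(f"loop anchors outside contact map: bins {b1},{b2}")
        m[b1, b2] *= cfg.loop_enrichment
        m[b2, b1] = m[b1, b2]

    if cfg.contact_noise_sigma > 0:
        s = cfg.contact_noise_sigma
        noise = rng.lognormal(-0.5 * s * s, s, size=(n, n))
        noise = np.triu(noise) + np.triu(noise, 1).T  # symmetric jitter
        m = m * noise
    return ContactMap(cfg.chrom, cfg.bin_size, m)
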