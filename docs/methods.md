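# Methods

Conventions and statistical methods implemented in `zfintegrate`. Coordinates are
0-based, half-open (`[start, end)`); the TSS of a minus-strand gene is `end − 1`
and its TES is `start`. All randomness flows through `numpy.random.default_rng`
seeded from a single configuration seed, with independent sub-streams per
simulation stage, so every output is reproducible bit-for-bit.

## Reproducible peaks and counting

A peak is *reproducible* when it was called at high confidence (FDR ≤ 0.05) in at
least one replicate and overlaps (≥ 1 bp) a low-confidence call (FDR ≤ 0.5) in the
other replicates; a high-confidence call counts as low-confidence support. With
three or more replicates the default reading is "all other replicates"
(`others_mode="all"`), with `"any"` as the relaxed alternative. Qualifying
intervals are merged where they overlap. Condition-level reproducible sets are
merged into unified features with per-condition provenance.

Single-end reads are extended to fragments from their 5′ end: on `+` the fragment
is `[start, start + fragment_size)`, on `−` it is `[end − fragment_size, end)`
(default `to_length` mode; a `slop` mode instead grows the read 3′ by
`fragment_size`, matching `bedtools slop -s -l 0 -r`). A fragment `[s, e)` counts
toward a peak `[ps, pe)` when `s < pe` and `e > ps`; counting is
O((reads + peaks) log reads) via sorted start/end arrays.

Per-sample scale factors are `15e6 / library_size` (depth normalization) or
`1e6 / spikein_reads` (spike-in normalization); with zero spike-in reads the
latter refuses with guidance to fall back to library size.

Peaks are annotated at their summit (midpoint when absent) by fixed priority:
`Promoter.Up` = `[TSS − 2 kb, TSS]` in the gene's 5′→3′ direction,
`Promoter.Down` = `(TSS, TSS + 2 kb]`, then Exonic/Intronic (collapsing to
`genic` without exon models), `TES` (± 2 kb of the TES), `distal5` / `distal3`
(up to 50 kb), else `intergenic`. Gene assignment is by nearest TSS among the
matching genes.

## Normalization

**TMM** (trimmed mean of M-values): the reference sample is the one whose
upper-quartile positive-count fraction is closest to the mean. For each other
sample, M = log2 ratio and A = mean log2 abundance of co-positive features are
doubly trimmed (30% per tail on M, 5% per tail on A, ordinal ranks), and the
trimmed M values are averaged with inverse asymptotic-variance weights
`(N − x)/(Nx)` summed over both samples. Factors are scaled to geometric mean 1.
The implementation reproduces `edgeR::calcNormFactors(method="TMM")` on a frozen
fixture to 1e-6.

**Spike-in median of ratios**: using only spike-in features positive in every
sample, `factor_j = median_i (x_ij / geomean_j(x_ij))`. Factors are reported
unscaled; their ratios carry the normalization, and a per-sample scaling of the
spike-in matrix is recovered exactly up to the overall geometric mean.

## Moderated two-group test

Counts are transformed to `log2CPM = log2((count + 0.5) / (lib · factor + 1) · 1e6)`.
For each feature the pooled two-group residual variance `s²` (df = n₁ + n₂ − 2)
is shrunk toward a scaled inverse-chi-square prior fitted by moment matching on
`log s²`: with `e = log s² − ψ(df/2) + log(df/2)`, the prior df is
`d₀ = 2·ψ′⁻¹(var(e)·(n−1)/n − ψ′(df/2))` and
`s₀² = exp(mean(e) + ψ(d₀/2) − log(d₀/2))` (digamma/trigamma inversion by
Newton iteration). The posterior variance is `(d₀·s₀² + df·s²)/(d₀ + df)`, the
moderated t has `d₀ + df` degrees of freedom (normal when `d₀ = ∞`), and p-values
are two-sided. Setting the prior df to 0 recovers the ordinary pooled t-test
exactly. Multiple testing uses Benjamini–Hochberg step-up q-values.

Under a global-null negative-binomial simulation (10,000 features, dispersion
0.1, 4 vs 4), the realized `P(p ≤ 0.05)` is within [0.04, 0.06].

Classification: differential binding = `|log2FC| ≥ 1` and `FDR ≤ 0.05` (both
inclusive); differential expression adds `mean CPM ≥ 1`.

## Gene–peak integration

Fold changes are standardized without centering: `z = log2FC / sd(log2FC)` with
the sample standard deviation (ddof = 1) over all finite fold changes in the
table, so `z · sd` reconstructs the fold change exactly and any rescaling
`log2FC → c · log2FC` leaves the z-ranks, Pareto levels and selection unchanged.

Each gene is paired with every peak overlapping
`[min(TSS, TES) − 50 kb, max(TSS, TES) + 50 kb]` (strand-independent,
inclusive). The combined score `z_gp = z_g · z_p` assigns the pair to the
correlated (`> 0`) or anti-correlated (`< 0`) class. Within each class, pairs
are ranked by non-dominated sorting on `(|z_g|, |z_p|)` (maximization; a point
is dominated when another is ≥ in both coordinates and > in one; identical
points share a level), computed by an O(n log n) staircase sweep that matches an
O(n²) peeling oracle exactly. The top 10 levels per class form the selection;
against planted ground truth the selection's recall/precision over
gene–causal-peak pairs is reported.

## Motif scanning and flank signatures

PWM scores are log2 odds against a 0-order background with a
background-proportional pseudocount: `score(b) = log2((p_b + 0.1·bg_b) /
(1.1·bg_b))`, so background-identical columns score zero. Scores are discretized
on a 1e-3-bit grid and the exact null distribution of the window score is the
position-wise convolution of per-column distributions under the background;
reported p-values are exact for the discretized score (verified against
exhaustive enumeration for widths ≤ 6). Both strands are scanned (the reverse
strand via the reverse-complement matrix); windows containing N are skipped; the
default threshold is p ≤ 1e-4 with the background estimated from the scanned
sequences.

The best hit per sequence is orientation-normalized (minus-strand matches are
reverse-complemented) and the core ± 20 bp window extracted, N-padded at
sequence boundaries. Pairwise distances are normalized Hamming distances with
either-N positions counting ½; clustering is average-linkage hierarchical
(scipy) cut to k clusters. Column summaries use information content
`IC = 2 + Σ f·log2 f` (N excluded). A flank signature at core-relative offset
+k (k-th base 3′ of the core; −k is 5′) is reported as the fraction of
informative rows carrying the base, with a Wilson 95% CI and, when a control
alignment is given, the enrichment ratio.

## Loops and APA

For each cis loop with anchor-bin pair (b₁, b₂), the (2w+1)×(2w+1) submatrix of
the contact map centered at pixel (b₁, b₂) is extracted (w = 10 bins by
default); loops closer than 2w+1 bins to the diagonal or within w of the matrix
edge are skipped and counted. Each submatrix is divided by its own mean
("normed" APA) before averaging. `P2LL` is the central pixel (or odd-sized
central block mean) divided by the mean of the corner block closest to the
diagonal (lower-left, 6×6 by default). On simulated maps P2LL is calibrated:
enrichment 3.0 scores in [2.7, 3.3] and enrichment 1.0 in [0.8, 1.2].

Loop sets are compared by greedy anchor-bin matching with ±1 bin slack into
lost / retained / gained. Anchors are classified P (TSS ± 2 kb overlap and
H3K27ac), E (H3K27ac only) or CTCF (neither); unordered category pairs (e.g.
`E-P`) are tabulated across two loop sets with odds ratios
`(a₁·b₀)/(a₀·b₁)` and two-sided Fisher exact tests.

## Synthetic data generator

Genes (10 kb) and peaks (400 bp) are placed without overlap on one chromosome
(100 Mb). A fraction (default 0.2) of peaks are *dependent*: their mutant-
condition counts carry a planted log2FC of −2. A gene whose
`[TSS − 50 kb, TES + 50 kb]` window contains **exactly one** dependent peak is
*coupled* with probability 0.14: its expression changes by |log2FC| = 2 with a
random sign (the factor acts as activator at some sites and insulator at
others), giving an identifiable gene → causal-peak truth pair. Counts are
negative binomial with variance `μ + 0.1·μ²`; spike-in features are generated
with per-sample scale multipliers. Peak sequences (120 bp) embed a 20-bp motif
core at a random offset and strand; dependent sites carry the signature base at
flank offset +4 with probability f (default 0.82) and one of the other three
bases otherwise, so the observed fraction is an unbiased estimate of f. Contact
maps follow `scale / (1 + |i − j|)` distance decay with symmetric lognormal
noise; loop pixels are multiplied by the enrichment factor (default 3.0) at
separations of 200–800 bins.
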