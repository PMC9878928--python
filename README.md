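# zfintegrate

Toolkit for asking a recurring question in degron epigenomics: **when a DNA-binding
factor is acutely depleted (or its zinc fingers mutated), which binding-site losses
actually drive expression changes, and what distinguishes the sites that are lost?**

Acute-degradation experiments (dTAG/AID-style) of architectural factors such as CTCF
produce three read-outs that must be reconciled:

1. **ChIP-seq of the factor** before/after depletion — thousands of peaks shrink, but
   global loss makes within-sample normalization misleading, so spike-in chromatin is
   required.
2. **RNA-seq** — a comparatively small set of genes responds, in both directions.
3. **Chromatin loops (HiChIP/Hi-C)** — anchors co-occupied by the factor weaken.

`zfintegrate` implements the complete desk-scale analysis chain for such experiments,
plus a synthetic-data generator with planted ground truth so every stage can be
validated quantitatively:

- **Peak processing** (`zfintegrate.peaks`): two-tier reproducible-peak filtering
  (high-confidence call in one replicate supported by low-confidence calls in the
  others), strand-aware read-to-fragment extension and fragment counting over peaks,
  library-size and spike-in scale factors, and priority-based genomic annotation
  (Promoter.Up/Down &gt; Exonic/Intronic &gt; TES &gt; distal &gt; intergenic).
- **Differential testing** (`zfintegrate.differential`): TMM and spike-in
  median-of-ratios normalization, a limma-style moderated two-group t-test on
  log2-CPM with an empirical-Bayes variance prior, BH FDR, and the standard
  differential-binding / differential-expression cutoffs. The test is exposed
  model-style: `ModeratedTTest(table, design).fit()` returns a results object with
  `.table`, `.fold_change_table()` and `.summary()`.
- **Gene–peak integration** (`zfintegrate.integration`): fold changes are converted
  to z-scores (`z = log2FC / sd(all log2FC)`, no centering), every gene is paired
  with peaks in `[TSS − 50 kb, TES + 50 kb]`, the combined score `z_g · z_p` splits
  pairs into correlated/anti-correlated classes, and within each class the top
  Pareto levels of (|z_g|, |z_p|) under non-dominated sorting are selected.
- **Motif-flank signatures** (`zfintegrate.motif`): FIMO-style PWM scanning with
  exact p-values (discretized-score convolution), orientation-normalized ±20 bp
  flank extraction, normalized-Hamming average-linkage clustering, per-column
  information content, and single-base signature fractions with Wilson CIs.
- **Loop analysis** (`zfintegrate.loops`): aggregate peak analysis (APA) with the
  P2LL score (center pixel over lower-left corner block), lost/retained/gained
  loop-set comparison, and P/E/CTCF anchor classification with per-category
  Fisher tests.
- **Synthetic data** (`zfintegrate.simulate`): negative-binomial counts with
  spike-ins, planted binding losses coupled to expression changes of ±2 log2 units
  in nearby genes, motif cores with a plantable flank signature, and contact maps
  with distance decay plus loop-pixel enrichment — all deterministic under a seed,
  with truth tables sufficient to score recall/precision.

## Worked example

The `demo` command simulates one full dataset (2,000 genes, 5,000 peaks, 4+4
replicates, ~100 coupled gene–peak pairs), runs every stage and writes a report:

```
zfintegrate demo --seed 0 --out demo_out
```

Output (seed 0):

```json
{
  "n_db_down": 987,
  "n_db_up": 56,
  "n_de": 110,
  "n_pairs": 11004,
  "n_selected_pairs": 416,
  "n_planted_pairs": 104,
  "coupling_recall": 0.875,
  "coupling_precision": 0.21875,
  "signature_fraction": 0.8205,
  "signature_control_fraction": 0.2457,
  "signature_enrichment": 3.3396,
  "n_motif_sites": 997,
  "n_flank_clusters": 5,
  "apa_p2ll": 2.9436,
  "apa_loops_used": 50
}
```

Reading the numbers: spike-in-normalized moderated testing flags 987 peaks with
binding loss (the generator plants ~1,000 dependent peaks at log2FC −2); Pareto
selection of the top 10 levels per sign class recovers 91/104 planted
gene–causal-peak pairs (recall 0.875); the planted G at flank position +4 is
estimated at 0.8205 (planted fraction 0.82, control sites sit at the 0.246
background); and APA on a contact map with 3× loop enrichment scores
P2LL = 2.94.

The same pipeline is available as a library call:

```python
from zfintegrate import run_demo
report = run_demo(seed=0, outdir="demo_out")
```

Other subcommands operate on files (`zfintegrate simulate / diff / integrate /
apa / peaks count / peaks annotate / motif scan / motif signature`); run any of
them with `--help`.

## Reproduction

- `python -m pytest tests/` runs the unit suite plus `tests/test_acceptance.py`,
  which checks each stage against independent oracles: an O(n²) non-dominated
  sorting reference, exhaustive motif-score enumeration for widths ≤ 6, scipy's
  plain t-test as the zero-prior limit of the moderated test, Wilson-CI coverage
  of planted signature fractions, APA calibration bands, and hand-built rule
  fixtures. TMM factors are additionally frozen against `edgeR::calcNormFactors`
  output on a fixed fixture.
- `python scripts/acceptance.py --seed 1 --out results/acceptance.json`
  recomputes the headline quantities (oracle mismatch counts, coupling
  recall/precision plus a null-dataset enrichment p-value, signature CI coverage,
  P2LL at enrichment 3 and 1, null type-I error rate) from fresh synthetic data
  and writes them as JSON.

All computation is deterministic given the seed; `docs/methods.md` documents the
statistical methods and conventions.
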