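# adscout

Active-learning discovery and quantification of transcriptional **activation
domains (ADs)** — the intrinsically disordered regions of transcription
factors that recruit transcriptional machinery to drive gene expression.

High-throughput reporter assays measure AD activity for libraries of
fixed-length protein *tiles* (53-residue windows, 10-residue stride), but the
space of natural proteins is astronomically larger than any library. adscout
implements the computational loop that closes that gap:

1. **Corpus → design space** — deduplicate proteins, cluster them at 90%
   sequence identity (greedy, CD-HIT-style), and slice representatives into
   53-AA / 10-stride tiles.
2. **Sequence → activity regression** — a residual convolutional network
   (conv stem → residual blocks with batch-norm/ReLU → global average pool →
   dense head) trained on z-scored activities with MSE loss, Adam, and early
   stopping (patience 5) on a stratified 80/10/10 split.
3. **Deep-ensemble uncertainty** — *K* independently seeded regressors
   (20 in production); the prediction is the member mean
   ŷ(x) = (1/K) Σₖ fₖ(x) and the epistemic uncertainty is the member spread
   σ(x) = √((1/K) Σₖ (fₖ(x) − ŷ(x))²).
4. **Acquisition** — quantile-balanced uncertainty sampling: candidates are
   cut into equal-frequency bins of predicted activity and the
   top-uncertainty tiles are taken per bin, so a labeling batch has maximum
   uncertainty while spanning the predicted-activity range. The same
   mechanics select harmonization tiles (smallest |empirical − predicted|
   per bin) and control tiles.
5. **Sort-seq scoring** — from sorted-bin barcode sequencing (8 bins, each
   10% of the population): perfect-match read extraction between conserved
   flanks, per-bin depth normalization, relative abundance pₑ per barcode,
   activity = Σₑ pₑ · medianₑ (a weighted average of bin median
   fluorescences), a <50-read filter, and barcode-mean aggregation per tile.
6. **Harmonization** — the FACS readout saturates at both extremes, so a new
   dataset is mapped onto a reference activity scale by an affine fit
   restricted to the assay's linear range, found by maximizing the Pearson
   correlation of dual-measured tiles over a quantile grid and validated on
   independent control tiles.
7. **Attribution** — sampled-Shapley per-position contributions of the
   trained ensemble (additive and complete by construction: per tile the
   attributions sum exactly to prediction − baseline).

A synthetic module generates tile libraries with a known activity law (an
acidic-exposure-style oracle: hydrophobics W/F/L/M/Y count only with D/E in a
±3 neighborhood, K/R penalize, saturating response) and simulates the full
sort-seq readout, so the entire loop runs and is tested end to end with no
experimental data.

## Worked example

`examples/` contains one short script per capability. For instance:

```bash
$ python examples/02_simulate_and_score.py
simulated 2340 (tile, barcode) rows over 8 bins
bin medians: [0.6, 2.23, 3.31, 4.12, 4.89, 5.66, 6.41, 7.15]
200 tiles scored, 0 missing, 0 barcode rows below the read filter
Spearman(recovered, true) = 0.997
```

The rank correlation of 0.997 between recovered and true activities shows the
bin-weighted scoring computation reconstructs the underlying activities from
simulated read counts almost perfectly at the default depth (~12 barcodes per
tile, 200 reads per barcode).

```bash
$ python examples/06_active_learning_round.py
round 1: acquired 200 tiles, training set 500 -> 700
OOD eval RMSE:   2.020 -> 1.656
OOD eval Pearson: 0.442 -> 0.641
```

One uncertainty-guided acquisition round on a pool rich in a composition
regime the ensemble never saw cuts evaluation error on that regime: the batch
concentrates exactly where the ensemble members disagree.

A thin CLI mirrors the library (`adscout tile`, `adscout score`,
`adscout ensemble-train`, `adscout acquire`, `adscout harmonize`,
`adscout simulate`, `adscout explain`, ...); run `adscout --help`.

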