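# Methods

This note documents the models and procedures adscout implements, the
parameters that matter, what the synthetic generator does and does not
emulate, and the numerical choices made where the design was genuinely open.

## Design space construction

Proteins are deduplicated exactly (first occurrence kept, multiplicity
recorded), then clustered greedily longest-first: a sequence joins the first
existing cluster whose representative it matches at ≥ the identity threshold
(default 0.90), otherwise it founds a new cluster. Identity is the number of
identical aligned positions in a global pairwise alignment (match 1,
mismatch 0, gap open −0.5, extend −0.1) divided by the shorter sequence's
length — CD-HIT-like semantics without CD-HIT's short-word screening, so it
is suitable for test-scale corpora, not millions of proteins. Ties in the
processing order break lexicographically by id, making clustering
deterministic and idempotent on its own representatives.

Tiling uses 0-based half-open windows of 53 residues at a 10-residue stride.
Proteins shorter than one window yield no tiles, and trailing residues not
covered by a full window are dropped (no end-anchored tile); both choices
keep every tile exactly window-length, which the fixed-shape encoder and
regressor require. Non-canonical residues (X, U, B, Z) skip the protein by
default; an opt-in mode masks them to X, which the one-hot encoder renders as
an all-zero row.

## Encodings

The default encoding is one-hot over the alphabetically ordered 20-letter
canonical alphabet (53×20 per tile). Per-residue embeddings from a pretrained
protein language model enter through a provider contract
(`embed(sequence, layer) -> positions×D`) rather than a bundled model; results
are cached by (sequence hash, provider name, layer) so upgrading a provider
can never silently mix representations. All shipped tests and defaults use
one-hot.

Composition descriptors: net charge = #K + #R − #D − #E (histidine excluded
— its protonation state is condition-dependent), non-polar set
{A,V,L,I,M,F,W,P,G}. Both sets are conventions and overridable per call.

## Activity regressor

Architecture: conv stem (kernel 5) → N residual blocks (two convs with batch
normalization and ReLU, identity skip) → global average pooling → a single
dense output. Two presets: the default (64 channels, 3 blocks) and a compact
variant (16 channels, 1 block) used throughout the simulation studies and
tests — on the synthetic task the compact network is within noise of the
default at a fraction of the cost. The network is implemented directly in
numpy (float64) with hand-written backprop, verified against central-
difference gradients.

Training: labels are z-scored with training-split statistics only (the
inverse transform is applied at prediction); MSE loss; Adam (lr 1e-3, batch
64, up to 200 epochs); early stopping when validation MSE has not improved
for 5 epochs, restoring the best-validation weights rather than the last.
Constant training labels are a hard error (z-scoring undefined). All
randomness (initialization, shuffling) flows from one seed; identical seed,
config and data reproduce the split bitwise and the metrics exactly.

Splits: 80/10/10 stratified on the above-median activity indicator —
activity is continuous, so it is binarized at the median purely to balance
active/inactive content across splits. Out-of-distribution evaluation uses
spectral clustering of mean-pooled encodings (RBF affinity, bandwidth =
median pairwise distance — a standard heuristic; the affinity definition was
an open choice) with an entire held-out cluster as the test set.

## Deep ensemble

Members differ only by seed (initialization and shuffling); all share one
train/validation split. Sharing the split keeps member disagreement a pure
function of optimization stochasticity rather than data resampling — the
standard deep-ensemble recipe; per-member resplitting was the open
alternative and is not used. Uncertainty is the population (ddof=0) standard
deviation of member predictions on the de-normalized scale. Production size
is 20 members; simulation studies use 3–5, which already separate
in-distribution from out-of-distribution uncertainty cleanly. Identical
member outputs are reported as exactly zero uncertainty (a guard absorbs the
one-ulp residue of float summation).

## Acquisition

Quantile-balanced uncertainty sampling with precisely fixed semantics so
exhaustive-search tests are well defined: candidates are ordered by
(binning value, tile id) and cut into n equal-frequency bins (default 10 —
the bin count was open); with quota = ceil(batch/bins) as a per-bin cap,
every non-empty bin first contributes its best candidate (when the batch
allows), then remaining slots fill greedily by global objective rank under
the caps, relaxing caps only if sparse bins leave a shortfall. Under a
partition-matroid cap constraint the greedy fill is optimal, so the selection
maximizes total uncertainty among quota-respecting batches. All ties break
lexicographically by tile id. Harmonization tiles minimize
|empirical − predicted| per bin of empirical activity; control tiles maximize
uncertainty per bin of empirical activity — same machinery, different
objective and binning variable.

## Sort-seq scoring

Reads are kept only on a perfect match: exact conserved flanks and an exact
library tile sequence between them (rejections are categorized: malformed,
no-flank, bad-length, no-match). Scoring per (tile, barcode) row: counts are
divided by each bin's total depth, renormalized across the 8 bins to a
relative abundance, and dotted with the bin median fluorescences — a weighted
average that is invariant to uniform depth rescaling of any single bin and
always lies within the median range. Rows under 50 raw reads are discarded.
The read filter is applied per barcode row rather than per tile aggregate:
it matches the per-barcode scoring flow, and a tile's surviving barcodes are
then averaged unweighted (barcode count and total reads are reported, and
expected tiles with no surviving barcode are listed for recovery
accounting). Bin medians are required inputs: the assay measures them, the
simulator generates them. Barcodes observed for conflicting tiles are
dropped with a warning.

## Harmonization

The FACS readout saturates at both signal extremes, so the affine map
between two activity scales is estimated inside a linear-range window: all
(lower, upper) pairs on a 5%-step quantile grid of the reference activity are
scored by the Pearson correlation of the harmonization pairs inside the
window, subject to retaining ≥ 50% of pairs; ties break toward the wider
window. Control pairs validate the chosen window (their in-window correlation
is reported) but never drive the argmax. The map itself is OLS
(new → reference) on in-window pairs with the residual standard deviation
kept as a Gaussian noise scale. Applying the map is deterministic by
default; noise injection (distribution matching) is an explicit seeded
opt-in, because fitting *with* Gaussian noise and *injecting* it are
different readings of the same description and the deterministic one is the
safer default. OLS is asymmetric: swapping the scales recovers the
reciprocal slope only in the noise-free case.

Two statistical facts shaped the synthetic-pair generator (below): windowing
on the response truncates the regression, biasing the slope toward zero, and
restricting range lowers Pearson even without saturation. Both effects
shrink as the signal spread grows relative to the measurement noise.

## Active-learning round

One round: predict the design space, acquire a quantile-balanced
maximum-uncertainty batch, label it (oracle callable or label table),
optionally push new labels through a fitted harmonization map, merge, and
retrain the ensemble *from scratch* on the merged data (not fine-tuned —
retraining avoids order-dependence on acquisition history). The evaluation
set is fixed before round 1 and can never be acquired; design/training and
design/evaluation overlaps are hard errors, as is labeling a tile twice.
Round reports carry pre/post metrics, pre/post median design-space
uncertainty, acquired ids, seeds, and SHA-256 hashes of every input table.

A caution on uncertainty trajectories: while a round reliably cuts
prediction *error* on the out-of-distribution evaluation set, the median
uncertainty over the remaining design pool is not guaranteed to fall after a
single round at desk scale — in the shipped 5-seed benchmark it rises,
because the ensemble retrained on the merged, more heterogeneous dataset
(now containing noisy labels from a new composition regime) disagrees more
across the board even where it is more accurate. Uncertainty reduction
should be read per region of sequence space, not as a global scalar.

A second desk-scale finding concerns the comparison with random
acquisition. In the shipped benchmark (700 training tiles, a 1,500-tile
pool in which the withheld Leu/Phe regime is 12%, a 500-tile batch, and
each strategy's post-round RMSE averaged over two independent retrains),
one uncertainty-guided round reduces out-of-distribution RMSE in every
seeded replicate, by a wide margin. Its advantage over a *random* batch of
equal size, however, is positive in aggregate but smaller than
replicate-to-replicate noise: some seeded replicates come out as ties or
small reversals, and the shipped 5-replicate check reflects this honestly.
The cause is structural. A 500-tile batch is a third of any desk-scale
pool, so even random sampling labels enough of the rare informative regime
to climb the steep part of the learning curve; batch enrichment by
uncertainty sampling is correspondingly mild (~1.4x). The regime where
uncertainty targeting decisively dominates is extreme selectivity — a batch
that is a vanishing fraction of a genome-scale design space — which a
desk-scale pool cannot reproduce. The benchmark therefore demonstrates the
machinery and the error-reduction effect, not a universal dominance of
uncertainty sampling over random sampling at this scale.

## Attribution

Positions (not channels) are the Shapley players: a position is "present"
with the evaluated tile's residue and "absent" with a background tile's.
Sampled permutations walk from a sampled background to the tile, recording
marginal prediction changes; permutations come in antithetic pairs (each
with its reversal) to reduce estimator variance. Because whole positions are
swapped, channel contributions are summed to residue level by construction,
and each permutation chain telescopes, so per tile the attributions sum
*exactly* to prediction − mean sampled-background prediction — additive
completeness holds for any model, and for linear models the estimate is
exact after one permutation. Backgrounds are drawn from training data only.
Ensemble attribution runs on the member-mean predictor, which equals the
mean of per-member attributions under shared permutations.

## Synthetic generator

The generator defines the study conditions for every test; all constants are
simulator inventions, none are experimental measurements.

**Oracle** (acidic-exposure-style): raw = Σᵢ h(sᵢ)·[∃ D/E within ±3 of i]
− 0.5·#(K,R), with h = {W:2.0, F:1.8, L:1.2, M:1.2, Y:1.0}; activity =
10·max(raw,0)/(8+max(raw,0)); label noise N(0, 0.2). The saturating form
mimics reporter saturation; the ±3 acidic-context rule encodes the idea that
acidic residues keep key hydrophobics solvent-exposed, and K/R suppression
mirrors their role in the acidic exposure model.

**Library regimes**: residue-frequency mixtures over a uniform base —
background (uniform), acidic (D/E-rich with elevated hydrophobics: classic
ADs), Leu/Phe-rich (L/F-loaded, D/E-depleted: non-acidic in composition, yet
a subset is active through residual D/E adjacency — this regime is the
withheld out-of-distribution condition in all OOD experiments), and basic
(K/R-rich, inactive). Default mix 55/25/10/10: most tiles inactive,
reflecting that ADs are rare in protein space.

**Sort-seq simulator**: cell fluorescence ~ Normal(tile activity, 0.75); 8
sorting gates at the pooled population's 10%–90% deciles (each bin 10% of the
population; the tails go unsampled, as in the sorted-gate design); bin
medians are pooled within-bin medians; barcodes per tile ~ max(Poisson(12),1);
each barcode gets exactly 200 reads, multinomial over the tile's bin
occupancy. Nucleotide-level read simulation reverse-translates tiles with a
fixed codon table and wraps them in the assay's conserved flanks plus a
random 14-nt barcode, with optional single-substitution corruption for
testing the perfect-match filter.

**Harmonization pairs**: new-scale activity ~ Normal(1.5, 1.25); reference =
0.8·new + 0.3 + N(0, 0.1), hard-clipped outside its central 80% (saturation),
clipped points flagged. Two generator choices matter and were made on
statistical grounds: (i) the activity distribution is Gaussian, not uniform —
with a bell-shaped score distribution the correlation leverage sits in the
tails, exactly where saturation destroys it, so excluding the clipped tails
genuinely maximizes the in-window Pearson (under a uniform design,
restriction of range dominates and the window search would rightly keep the
tails); (ii) the spread (sd 1.25) is large relative to the 0.1 noise so that
response-truncation bias of the windowed OLS fit is small (~0.01 on the
slope) and recovery accuracy is governed by the sampling distribution.

**What the generator does not emulate**: PCR amplification bias, barcode
error correction, FACS instrument noise beyond Gaussian cell spread,
epistasis or position-specific activity grammar beyond the local
acidic-context rule, and the phylogenetic correlation structure of real
protein corpora. Tests passing on this generator therefore demonstrate that
the computational machinery is correct and that the loop behaves as designed
when its assumptions hold — not that a model trained on real assay data will
match these numbers.

## Problem sizes and reproducibility

Simulation studies use deliberately modest sizes chosen as the smallest
conditions that exercise each property cleanly: 500 tiles × ~12 barcodes ×
200 reads for pipeline closure; 3,000 tiles for regressor recovery; 800-tile
libraries with 5-member compact ensembles over 5 seeds for the ensemble and
OOD studies; 700 training tiles, a 1,000-tile pool and a 500-tile batch with
3-member ensembles over 5 seeds for the active-learning comparison; 400
pairs for harmonization. Every stochastic step (library sampling, label
noise, sorting, training, acquisition, attribution) is driven by explicit
seeds, and reruns are exactly reproducible.

## Known limitations

- The greedy clusterer is quadratic in the number of unique sequences and is
  not a CD-HIT replacement at corpus scale.
- The numpy network trains on CPU only; the architecture presets are sized
  for desk-scale studies, not for tens of millions of tiles.
- The spectral OOD split materializes a dense pairwise affinity (O(n²)
  memory).
- OLS harmonization ignores errors in the new-scale variable
  (errors-in-variables and nonlinear saturation models are out of scope).
- Attribution cost grows linearly in tiles × permutations × positions;
  production-scale interpretability would batch across tiles.
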