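# Methods

## Overview

phenoscreen models a plate-based fluorescence phenotyping screen of a
cell-line panel and the analysis that turns it into an origin classifier.
The pipeline has five stages — synthetic screen generation, intensity
quantification, kinetic fold-change features, hierarchical clustering,
and stepwise linear discriminant analysis (LDA) — each usable on its own.
Real screens enter through the manifest: any directory of single-channel
TIFFs with a manifest CSV (probe, line, origin, concentration, channel,
site, time, replicate, path) flows through the identical code path as
generated screens; there are no synthetic-only branches downstream of the
manifest.

## Synthetic screen model

Each image is a field of "cells" — a union of random ellipses covering an
area fraction `a` (default 0.7) of a 128 x 128 16-bit frame — over a dim
background (level 150, optional Gaussian jitter).  Foreground intensity
follows a multiplicative model:

* a per-(probe, line) baseline mean at the first time point, lognormal
  across conditions with log-mean log(2000) and log-sd 0.2 — bright
  enough that integer quantization is negligible, far from the 16-bit
  ceiling even for the largest configured folds;
* a fluorescence **turn-on fold** reached at the last time point, with
  geometric interpolation at intermediate times: the expected fold of a
  (probe, line) pair is the product of a (series-or-family, origin)
  effect and a line-specific effect, neutral = 1.0.  The emitted ground
  truth records this product per design cell;
* an optional **batch factor**: one multiplicative lognormal draw
  (log-sd `batch_sd`) per plate, where a plate is one
  (probe, concentration) — duplicate wells and both sites sit on the
  same plate, so every image pooled into one quantification shares a
  factor.  By default the factor is also shared by all time points of
  the plate ("aligned"), the situation in which the kinetic ratio
  cancels it; a flag redraws it per time point to emulate the
  pathological case and is used by the robustness tests.  (If replicates
  lived on *different* plates, pooling them would mix foreground
  populations whose means differ by the factor ratio and Otsu could
  split between them — a scenario worth knowing about when applying the
  combine-then-threshold order to real screens);
* **pixel noise**: i.i.d. mean-corrected lognormal per foreground pixel
  (`x -> x exp(sigma z - sigma^2/2)`), sigma 0.15 by default.  The noise
  family of real screen intensities is not established; lognormal is the
  conventional choice for multiplicative fluorescence noise and is a
  config parameter, not a commitment.

Pixels are scaled, rounded and clipped to the bit depth.  All randomness
is keyed by `(seed, semantic key)` through CRC-hashed `SeedSequence`
streams, so any single condition can be re-rendered in isolation and a
whole screen regenerates byte-identically; pixel-noise streams are
independent of the batch stream, so toggling batch effects leaves the
underlying noise realization fixed (what the robustness tests rely on).

The full published layout — 557 probes x 60 lines x 2 concentrations x
2 channels x 2 sites x 3 time points x 2 replicates = 1,604,160 images —
is enumerated as metadata only; rendering that many frames is neither
feasible nor informative at desk scale.  The default demo recipe scales
to 100 probes (family split in the library's 240:317 ratio), 60 lines,
one concentration/channel/site, the two time points the fold change
uses, and 2 replicates: 24,000 images, ~1.5 minutes end to end on one
CPU.  Morphological realism is explicitly out of scope: only intensity
statistics matter downstream, so blobs, not cells, are drawn.

The demo recipe's class structure: 30 of 100 probes are informative,
split 15/15 between families; RS informative probes take their primary
origin from the first six origins, BD from the last six, so each family
covers six of nine origins and only the combined library covers all
nine.  Each informative probe gets a primary-origin fold drawn from
U(2, 4) and one secondary origin from U(1.5, 2.5) (probes respond to
multiple related lines, not single targets), and every (probe, line)
pair carries lognormal line-to-line scatter of log-sd 0.12 (~12% CV, the
biological variability within an origin).  These defaults put the
recipe at >= 2-fold effects with <= 20% coefficient of variation.

## Quantification

All images of a condition are pooled first, then thresholded — the
combine-then-threshold order.  Otsu's threshold is computed on 256
equal-width bins spanning the observed pooled range (the classic
`graythresh` route rescales to 8 bits; 256 bins keeps comparability),
maximizing between-class variance with ties broken toward the smaller
threshold.  "Positive for the threshold" is read as strictly greater
than; the returned integer threshold is chosen so the pixel-level split
reproduces the histogram split exactly.  A constant (single-bin) pooled
image is a degenerate-histogram error; `quantify_screen` maps it, and
missing image files, to flagged rows rather than dropping or guessing,
so missing-data accounting is first-class.

## Features

`Fold = I(endpoint)/I(baseline)` per probe x line x concentration x
channel.  Baselines below a floor (default background + 1 intensity
unit) raise rather than produce unstable ratios; features containing any
flagged cell are dropped whole and counted.  Two collapse policies:
`per_condition` (lossless, one feature per probe x concentration x
channel — the default, since how the original analysis merged the two
concentrations and channels is not stated) and `brightest_channel` (one
feature per probe at the top concentration, channel chosen by larger
mean baseline).  Features are log2-transformed for clustering and LDA
(config flag, default on) — standard for ratio data.  The generated
24 h time point is not used by the default feature, which is defined at
48 h over 1 h.

## Clustering

`scipy.cluster.hierarchy` average linkage on euclidean distances of the
log2 folds, both axes; metric and linkage are options since no canonical
choice exists for this assay.  Leaf order is the deterministic
left-to-right traversal (earlier-formed cluster first).  Origin purity
of a k-group cut = (sum of majority-origin counts)/n; k = 9 mirrors the
nine origins.  Purity of a singleton cut is trivially 1, so it is a
diagnostic for coarse cuts, not an objective to maximize.

## Stepwise LDA

Written from first principles (this is the analysis the package exists
for):

* Wilks' lambda by determinant ratio, `det(W)/det(T)`; exact 0 at zero
  within-class scatter, error on singular total scatter.
* Partial F with df (g-1, n-g-q+1), q the subset size after addition;
  upper-tail p from the F distribution (scipy's regularized
  incomplete-beta machinery, |p - reference| well below 1e-10).
* Forward selection with alpha-to-enter = alpha-to-remove = 0.150
  defaults; after each entry, included variables failing the removal
  test are dropped worst-first.  Determinism: ties break on smallest p,
  then largest F, then lowest feature index.  Guards: never more than
  n - g - 1 variables; candidates whose entry pushes cond(W) above 1e10
  are skipped (near-collinear additions); lambdas are floored at 1e-12
  inside the selection loop so perfect separation degrades gracefully.
* Classification functions `c_k(x) = mu_k' S^-1 x - mu_k' S^-1 mu_k / 2
  + ln pi_k` with S = W/(n-g) via Cholesky (refusing singular fits, with
  an optional ridge `eps tr(S)/q` on the diagonal).  Priors are equal
  across origins by default — the panel's class sizes (2-10) reflect
  panel construction, not prevalence — with proportional priors as an
  option.
* Jackknife: per held-out sample the means and pooled covariance are
  refitted, the feature set is not re-selected — the classical jackknifed
  classification matrix.  Re-running selection inside the loop is the
  more honest (and more pessimistic) estimate but not the conventional
  one; the package reports the conventional form.  A single-member class
  is fitted absent and its sample necessarily misclassified, logged.
* The family comparison runs selection + jackknife on each scaffold
  family alone and on the combined pool.  With the demo recipe the
  combined pool reaches 100% while either family alone plateaus near
  77% — the families' informative probes cover complementary origin
  subsets.  A note on selection size: with ~3 informative probes per
  origin the panel is redundant, and stepwise correctly stops near 15
  variables once additional informative probes no longer improve lambda
  at alpha = 0.15; selection sufficiency, not exhaustiveness, is the
  design goal of the statistic.

## Numerical and design choices

* Determinants on scatter matrices (subset sizes <= n - g - 1 <= 50 at
  panel scale) are well within double-precision comfort; the eigenvalue
  identity `Lambda = 1/prod(1+lambda_i)` over eig(W^-1 B) is used as an
  independent cross-check in tests, not as the implementation.
* Integer thresholds: for integer pixel data the Otsu bin boundary is
  converted to `ceil(edge) - 1`, making `pixel > threshold` exactly the
  histogram's upper class regardless of bin-edge rounding.
* Plate maps skip the first and last two columns of the 384-well layout
  (edge evaporation); this affects well bookkeeping only.
* Config is a flat YAML-serializable dataclass; every run writes its
  effective config, a SHA-256 config hash, the seed and stage timings
  into `run_meta.json`, and all artifacts regenerate byte-for-byte from
  (config, seed) apart from PNG encoder metadata.

## Problem sizes

Defaults were chosen to keep a full run at desk scale: the demo screen
is 24,000 images (~90 s generate + ~15 s quantify + ~3 s cluster/LDA on
one CPU); the test suite's five-replicate recovery study is ~8 minutes;
the full factorial enumeration is metadata-only and takes ~3 s.

## What passing tests do and do not show

The generator reproduces the *statistical* structure the analysis
assumes — multiplicative origin effects, line scatter, batch factors,
pixel noise — not real biology: no subcellular localization, no
morphology, no plate-position gradients, no probe spectra, and effect
assignments are independent across probes (real probe families share
structure–activity correlations).  Perfect jackknife accuracy on the
demo screen therefore validates the machinery (quantification is
unbiased, folds cancel batches, selection finds the informative probes,
the jackknife is honest), not the claim that any real screen separates
origins this cleanly; on real data, accuracy depends on effect sizes
and noise the generator can only posit.  Reproducing the original
37-probe panel or its exact 98/90/80% accuracies would require the
original images, which were never deposited.
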