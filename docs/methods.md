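# Methods

## Preprocessing

All model input passes through one chain, in this order: trim to the
450–1650 cm⁻¹ analysis window; asymmetric-least-squares (ASLS) baseline
subtraction; Savitzky–Golay smoothing; area normalization; linear
resampling onto the canonical grid (450–1650 cm⁻¹ at 1 cm⁻¹, 1201
points).  The canonical grid gives every model a fixed feature vector
and is chosen finer than the ~1.5 cm⁻¹ instrument spacing so resampling
is interpolation, never decimation across peaks.

The ASLS baseline z minimizes Σ wᵢ(yᵢ−zᵢ)² + λ Σ(Δ²z)² with λ = 1×10⁵
and asymmetry p = 0.01 (wᵢ = p above the baseline, 1−p below).  Weights
start at 1 and the banded symmetric system (W + λDᵀD) z = W y is
re-solved until the weight vector stops changing, capped at 50
iterations — in practice convergence takes well under ten.  The solver
uses a banded Cholesky factorization; the test suite checks it against a
dense direct solve of the identical reweighted system to 1e-8.

Savitzky–Golay uses window 7 / polynomial order 1, for which every
interior point equals the centered 7-point mean; the three points at
each edge are taken from the polynomial fitted over the nearest full
window (length-preserving).  Baseline subtraction can leave small
negative residuals; these are clipped to zero before normalization
(physical nonnegativity), and the unit-sum constraint is re-asserted
after the final resampling because interpolation onto a different grid
perturbs a discrete sum.  Normalization divides by the plain sum rather
than a trapezoidal integral; on the uniform canonical grid the two
differ only by a constant factor, which cosine similarity and all
classifiers ignore.  When an acquisition grid does not sample 450 or
1650 cm⁻¹ exactly, one guard point beyond each trim bound is retained
through the intermediate stages so the final interpolation at the window
edges is defined; the guard points are discarded by the resampling.

## Phase I — pathway classification

Six classifier kinds are provided with their tuned hyperparameters:
logistic regression (C = 100, L2, 500 iterations); PLS discriminant
analysis (17 latent variables, one-hot targets regressed by PLS2, argmax
decision — the standard PLS-DA convention, since only the latent-variable
count is prescribed); random forest (depth 5, min split 10, 100 trees);
gradient-boosted trees via xgboost (η = 0.05, depth 1, 500 rounds);
a feed-forward network; and cosine-similarity nearest neighbor (CSNNC).
PLSDA is the default pipeline classifier.  The latent-variable count is
capped at min(n_features, n_samples−1) with a warning when the training
matrix cannot support 17.

The Phase I training set contains pure direct dyes (nonoxidative class),
self-oxidized primaries, couplers alone, and the full primary×coupler
Cartesian product (all oxidative).  Couplers alone are included behind a
flag, on by default, since Raman detects the unreacted organics; the
resulting class imbalance (oxidative ≫ nonoxidative) mirrors the
intended deployment composition and is deliberately not rebalanced.

## Phase II — mixture identification

Both branches use a multi-label feed-forward network with per-colorant
sigmoid outputs and a strict score > 0.5 decision (an all-below-threshold
row is a legitimate "No Match").  The network is a compact NumPy
implementation — ReLU hidden layers, inverted dropout, RMSprop or plain
SGD updates, optional L1/L2 penalties — with a fixed budget of 200
epochs and no early stopping, fully deterministic given its seed.
Branch hyperparameters: nonoxidative — layers [512, 256], dropout 0.3,
RMSprop, η = 5e-4, batch 16, L2 = 1e-3, L1 = 1e-6; oxidative — layers
[1024, 512], no dropout, RMSprop, η = 1e-3, batch 32, no penalties.
RMSprop uses the conventional decay 0.9 and ε = 1e-8.

The nonoxidative branch trains on LASM spectra: equal-weight means of
preprocessed pure direct-dye profiles over all subsets up to size 3
(configurable; kept at the sizes the product catalog uses so the label
space stays tractable), each subset contributing noisy replicates.  The
oxidative branch trains on simulated dyed samples under a grouped
small-train split: 20 % of samples train, 80 % test, with no sample's
spectra crossing sides and at least one training sample per product —
the reference-limited regime of casework, where reference spectra are
scarce relative to questioned material.

## Phase III — color assignment and calibration

Each reference dye class is summarized by the centroid of its reference
spectra (centroid rather than nearest instance for noise robustness; the
nearest-instance rule is available behind a flag).  A query receives the
color of the class whose mixture equals its Phase II call iff the cosine
similarity to that centroid is ≥ θ; ties at θ count as matches, and the
convention is recorded in the calibration object.  An empty or unknown
mixture short-circuits to "No Color Match".

θ is calibrated per substrate from a shuffled null: mixture identities
are reassigned by a derangement (redrawn until no sample keeps its own
identity — a fixed point would be a true pairing, not the
misclassification the null simulates), similarities of true and false
pairings are pooled, and θ maximizes Youden's J = TPR − FPR over
candidate thresholds at the midpoints of adjacent sorted unique scores
plus outer guards, ties resolving to the smallest θ.

## Sample aggregation

Phase routing is per spectrum; spectra of one sample may take different
branches, and the summary reports the label distribution per phase.  The
sample verdict per phase is the modal label with its support fraction;
support ≤ 50 % or a modal tie yields the inconclusive (IC) verdict.
Samples with fewer than 15 spectra (5 per strand × 3 strands) are
processed but flagged.

## Scoring conventions

Phase I accuracy is at sample level with IC incorrect.  Phase II/III
metrics include only samples whose Phase I call was correct.  Subset
recall is the per-sample indicator of ≥ 1 correctly identified colorant
(IC and empty predictions score 0).  Phase II accuracy is partial
credit, |true ∩ pred| / |pred|, averaged across samples.  Phase III
scores "No Color Match" as correct exactly when the colorant prediction
was wrong and incorrect when it was exactly right; a concrete color is
right iff it equals the true color, independent of colorant exactness —
the only reading consistent, row by row, with the published summary
values the fixtures reproduce.  Truth sets exclude unmodeled pigments
(codes printed in parentheses): they are outside every model's label
space and the published per-row scores treat them that way.

Two published numbers are deliberately not reproduced: the nonoxidative
table's global F1 (0.8824; micro-averaging the printed sets gives a
nearby but different value, and one sample appears in two rows, so the
original averaging convention is ambiguous) and the photodegradation
table's per-dye Phase II accuracies (the printed 85.7 % for one dye is
inconsistent with the stated per-row rule, which gives 7/8 = 87.5 %).
Both are flagged rather than guessed.

## Synthetic data generator

Pseudo-colorants are 4–9 Gaussian peaks (widths 8–30 cm⁻¹, centers
within the window) on a smooth quadratic baseline.  A simulated
acquisition applies a slowly varying multiplicative gain (amplitude
±20 %, emulating SERS enhancement variability across spots and
batches) and additive Gaussian noise with σ = 5 % of the mean intensity;
both values chosen once as representative of replicate SER variability
on hair.  Nonoxidative dyes are the LASM of their components under this
nuisance; oxidative dyes first blend the LASM with a reaction-product
profile, α ∈ U(0.4, 0.7), where the profile is a pseudo-random peak set
keyed deterministically (CRC of the sorted component codes) so the same
mixture always reacts the same way without simulating chemistry.  This
reproduces the qualitative additivity gap (simulated nonoxidative dyes
reconstruct near-perfectly, oxidative ones poorly) but not its published
magnitudes, which depend on real colorants.

What the generator does *not* emulate: concentration-dependent band
intensities beyond a scalar gain, matrix effects of the hair substrate,
peak shifting or broadening, photodegradation, and cross-instrument
wavenumber error.  Passing the synthetic study therefore demonstrates
that the pipeline's machinery — routing, training-set construction,
multi-label decision, calibration, aggregation, abstention — is correct
under realistic noise, not that the published accuracies transfer to
real spectra.

## Synthetic study design

The default study uses 20 pseudo-colorants (5 primaries, 8 couplers, 7
direct dyes) and 30 unique products (60 % oxidative, mixtures of 1–2
primaries with 1–3 couplers; 40 % nonoxidative, 1–3 direct dyes), each
with a color from an 8-label palette.  Oxidative products contribute 5
samples of 5 spectra (one sample trains the oxidative branch, four are
held out); nonoxidative products contribute 2 test samples of 15
spectra; 3 undyed controls (baseline-only spectra) of 15 spectra ride
along.  Dedicated reference samples per product provide Phase III
centroids, and separate calibration samples per product feed the
shuffled-null threshold selection, so the gate never sees test data.
These sizes complete the full study in about a minute on one CPU while
leaving dozens of samples per metric.

## Known limitations

The oxidative branch can only predict mixtures it has seen as products;
the generator's reaction profiles make oxidative products nearly
distinct classes, so its multi-label task is easier than real coupling
chemistry.  The binary pathway model inherits the blurred cases real
formulations present (direct dyes marketed as permanent are handled by a
pathway override flag on the product record).  Phase III references key
on exact mixture equality; a near-miss Phase II call falls to "No Color
Match" rather than the nearest class — conservative by design.
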