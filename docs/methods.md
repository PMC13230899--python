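# Methods

## Setting and notation

A sample is a host–microbiome mixture with host purity *p* ∈ (0, 1] (the
fraction of sequencing material of host origin) and an unknown true host
SNV count *T*. A conventional caller applied to the mixture reports a raw
count *R* whose bias grows as *p* falls. `snvpurify` estimates *T* from
per-sample summaries of the call set; the estimate Ĉ is the *corrected
count* and the *residual* is *T* − Ĉ.

## The simulator

The simulator is the package's benchmark generator, not a fixture: it
produces call sets with strictly controlled *T* so residuals can be
computed exactly.

Per sample (all draws from one seeded generator stream, so the truth table
is a deterministic function of the config):

* *p* ~ U(purity_range), default (0.2, 1.0); *T* ~ U(true_count_range),
  default [200, 2000].
* Each true variant is a diploid heterozygous host SNV. Its latent VAF is
  Beta-distributed with mean *p*/2 and concentration ν (default 50,
  giving a VAF spread of ≈ 0.06 at *p* = 1 — comparable to binomial
  sampling noise at ~100× and loose enough to mimic mapping/allelic
  imbalance). Site depth is negative binomial with mean 100 and dispersion
  3 (variance ≈ m + m²/k, the standard overdispersed coverage model); the
  observed alt count is Binomial(depth, VAF), floored at 1 because a
  reported call has at least one supporting read.
* Caller failure modes are purity-interpolated: the false-negative rate
  fn(*p*) rises linearly from 0 at *p* = 1 to fn_max (default 0.3) at the
  low end of the purity range, and likewise fp(*p*) to fp_max (default
  0.4). Each true variant is dropped with probability fn(*p*);
  Binomial(*T*, fp(*p*)) spurious records are injected with low-VAF Beta
  draws (mean 0.05, concentration 20 — microbial mis-mappings and
  artifacts). Hence E[R − T] = T·(fp(p) − fn(p)), the closed form used as
  the Monte-Carlo oracle in tests.
* Positions are drawn uniformly without replacement on a single simulated
  chromosome (`chrS`, 1 Mb); annotation tracks (repeat 15 %, DNase 10 %,
  blacklist 5 % of the genome) are non-overlapping interval sets whose
  coverage matches the requested density.

The default noise/cohort settings are the benchmark conditions used by
the acceptance script and the end-to-end tests.

What the simulator does *not* model: read-level errors and alignment,
explicit microbial genomes (their effect is summarised as dilution plus
noise), VAF–context interactions (a variant's VAF is independent of
whether it falls in a repeat), multi-chromosome genomes, somatic subclonal
structure, and InDels/SVs. Passing tests therefore demonstrate that the
method removes the *modelled* class of purity-driven bias; they do not
certify performance on real cohorts, where the readers accept arbitrary
VCF/BED inputs but the error structure may differ.

## Features

Five groups, fixed lengths (9, 4, 5, 5, 5). Statistics over an empty
subset are encoded as 0 plus a paired "empty" indicator, keeping the model
input dense. Quantiles use linear interpolation and standard deviations
the population form (n denominator) so oracle tests can assert exact
equality. The baseline purity estimator is p̂ = clip(2·median VAF of
calls with VAF ∈ [0.02, 0.6], 0, 1) — the diploid-heterozygote argument —
with a fallback to all calls (flagged in the feature vector) when the
window is empty. The window bounds are config-exposed; 0.6 trims
homozygous-like and artifact VAFs while keeping *p* = 1 recoverable
(median VAF 0.5). Track membership uses the single base position of the
variant against merged half-open intervals (binary search over sorted
interval arrays; the brute-force double loop is kept in the tests as the
oracle). VCF positions are 1-based, BED 0-based half-open, per the
formats' conventions.

## Network

* **Group encoders.** One affine + tanh map per group to a d_model-wide
  token (default 64), plus a learned per-group position embedding. tanh
  keeps tokens bounded before gating; group identity must be injected
  explicitly because self-attention is otherwise permutation-equivariant
  (a property the tests exploit).
* **Gates.** A scalar sigmoid self-gate per token, broadcast across the
  token width: interpretable as a per-group importance in (0, 1) and
  inspectable per sample via `CorrectionModel.gate_values`. An
  elementwise variant is a config switch.
* **Decoder.** N = 2 post-norm transformer blocks over the 5-token
  sequence: multi-head self-attention (4 heads) and a 4·d_model FFN, each
  wrapped in residual + LayerNorm. No causal mask and no cross-attention —
  the sequence is an unordered set of groups, and with weights zeroed each
  block reduces to its two LayerNorms (the residual-path contract tested
  directly).
* **Head.** Mean-pool over tokens → affine → softplus, trained against
  log1p(T). softplus (not clipping) keeps gradients smooth; the log1p
  transform stabilises training across counts spanning an order of
  magnitude, and expm1 at inference guarantees non-negative outputs.

Everything runs in float64 on the package's own reverse-mode autodiff
engine (`snvpurify.autograd`), gradient-checked against central finite
differences to ~1e-8 relative error. Float64 plus a single-threaded BLAS
path makes runs bitwise reproducible from the seed.

## Training

Adam (β = 0.9/0.999) with decoupled weight decay applied to weight
matrices only (biases, LayerNorm parameters and position embeddings are
exempt, so e.g. a constant target is representable as decayed-to-zero
weights plus a head bias). Defaults: learning rate 3e-3 with cosine decay
over 300 epochs, batch 64, early stopping on validation loss with
patience 60, weight decay 1e-4, dropout 0.

These defaults were chosen by desk experiments on simulated cohorts. The
decisive observation: beating the raw counts in the *high*-purity bins
requires ~1 % relative accuracy (there the raw count is nearly unbiased,
so the bar is the caller's own small noise), and both dropout noise and a
conservative constant learning rate left the network short of that —
cosine decay lets late epochs polish the fit. These are optimiser knobs,
not benchmark conditions; the simulator's noise rates and cohort sizes
are fixed independently of them.

The train/validation split is stratified over the five evaluation purity
bins so both sides see the full gradient; singleton bins are merged into a
neighbour with a warning. The best-validation-epoch parameters are
restored on return (with `val_fraction = 0` the final parameters are kept
— used for capacity checks). The feature scaler (per-feature
standardisation) is fitted on the training split only and stored in the
checkpoint; the head bias is initialised to softplus⁻¹(mean target) so
the initial prediction is already centred.

Checkpoints are single JSON files (config echo + scaler + named parameter
arrays); loading verifies every shape against the config and refuses
silent re-shaping.

## Evaluation

MAE is the primary metric (robust, count-scale); RMSE is reported
alongside. The five purity bins are (0.2, 0.3], (0.3, 0.5], (0.5, 0.7],
(0.7, 0.8], (0.8, 1.0] — left-open/right-closed so the printed labels
partition (0.2, 1.0] without overlap; out-of-range samples are counted
separately, and empty bins keep their row with an undefined-metrics flag.
Residual summaries report mean, standard deviation (n−1), adjusted
Fisher–Pearson skewness and a histogram; normality is reported, not
hypothesis-tested. Trend curves are per-interval means of raw, corrected
and actual counts over the purity range. Intra-group Pearson correlation
matrices are symmetrised exactly, with unit diagonal; correlations
involving constant columns are NaN (flagged, never zeroed). Figures
mirror these tables (trajectories, per-bin bars, residual histogram,
trend curves, correlation heatmaps).

## Pipeline

One YAML config with nested per-stage sections; unknown keys are
collected and rejected as a batch, resolution is idempotent, and a global
seed propagates to any stage that did not set its own. Stages run into
the configured output root with per-stage config-hash sentinels, so an
unchanged rerun skips completed stages (the run timestamp lives in the
manifest rather than in the directory name — a timestamped root would
defeat resume). A seeded held-out fraction (default 25 %) never enters
training and is the set all evaluation metrics are computed on.

## Problem sizes

The end-to-end checks use the benchmark cohort of 2 000 samples (500 held
out) with default noise; the identity-recovery check (noise disabled)
uses 1 200 samples; purity-estimator recovery uses 200 noise-free samples
per purity level at 100×; capacity/determinism checks use 8 samples and
at most 500 full-batch steps. A full benchmark run (simulate, extract,
train, evaluate) takes a few minutes on one CPU core.

## Known limitations

* Trained models are specific to the feature layout and to call-set
  summary statistics; they do not transfer to per-variant classification.
* The correction is only as good as the simulator's fidelity for a given
  cohort; for real data, retraining on cohorts with matched pure-tissue
  or single-cell ground truth is the intended path.
* The purity estimator assumes a predominantly diploid heterozygous
  variant pool; copy-number alterations or inbred hosts violate it.
* With fewer than ~500 training samples the network's advantage over the
  raw counts in high-purity bins shrinks (see the worked example in the
  README, trained on 450 samples).
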