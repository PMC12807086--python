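# Methods

## The model

`methylformer` treats per-read 5mC calling as binary classification of the
centre event of a window of w consecutive translocation events. Each event
is summarized by seven features — normalized signal mean f_m, population
(ddof 0) standard deviation f_sd, raw sample count f_l, and a one-hot of the
reference base in A, C, G, T order. The window (default w = 21, centre ±10
events) is chosen so the classifier sees both the ~7 bases inside the pore
and flanking context.

Signals are normalized per read before featurization: all samples of the
read are pooled, centred on their median and scaled by 1.4826 × the median
absolute deviation (the consistent sigma estimate for Gaussian data), then
hard-clipped to [−5, 5]. Median/MAD was chosen over mean/sd because nanopore
traces carry current spikes; the clip guarantees the stated feature range. A
constant read (MAD = 0) falls back to unit scale with a warning. f_l is used
raw (no log transform); the standard deviation is population-form. These are
the package's conventions where multiple reasonable choices exist.

Self-attention is permutation-equivariant, so each window row i receives a
sinusoidal position embedding: component 2j = sin(i·w0^(2j/n)), component
2j+1 = cos(i·w0^(2j/n)), with base frequency w0 = 1/10000 and n the
embedding's own width (for odd n the last unpaired component is the sine
term). Using n — rather than the model width — in the exponent makes the
frequency ladder span exactly the emitted components. Positions are
window-relative (0..w−1): genomic coordinates would make the embedding
unbounded. Two attachment strategies are implemented because their
comparison is scientifically interesting: concatenation (d_model = n + 7;
the default, with n = 9 → d_model = 16) and summation, which requires a
learned affine 7 → d_model input projection so the widths match. The
`ablate` harness runs both on identical data and seeds.

The encoder stacks n_layers = 2 blocks, each a multi-head self-attention
sub-layer and a position-wise feed-forward sub-layer (d_ff = 4·d_model),
every sub-layer wrapped in a residual connection with layer normalization.
Pre-norm ordering is used for training stability at these tiny widths.
d_model must be even and a multiple of the head count (default 2 heads —
more heads overfit at d_model = 16). The attention key projection carries no
bias: softmax scores are invariant to a constant shift, so a key bias is an
exact null direction of the loss. The classification head reads the centre
row of the final encoder output and applies FC(d → d), ReLU, FC(d → 2),
softmax; a read-site is called methylated iff p_meth > 0.5, with exact ties
called unmethylated.

Two implementation details sit in front of the encoder. First, a fixed
per-feature standardization (location/scale of each of the 7 feature
columns, estimated on the training windows, stored in the checkpoint): the
raw dwell count f_l (~8 ± 2.6 samples) otherwise dominates the layer-norm
row statistics and measurably slows optimization in short training budgets.
Second, in concat mode the position-embedding block can be zeroed at
inference (`zero_pe`), a diagnostic that restores exact order-agnosticism
and is used to validate the attention implementation.

## Training

The loss is 2-class cross-entropy, minimized with Adam (β₁ = 0.9,
β₂ = 0.999). Defaults follow the hyper-parameter scopes the method was tuned
over: batch size 256 (scope [256, 512]), learning rate 0.001 (scope
[0.001, 0.01]), 50 epochs. For the desk-scale experiments shipped with the
package (~3–4k windows, 10 epochs ≈ 130 optimizer steps) the learning rate
is set to 0.01, the top of the scope, because 0.001 demonstrably
under-converges in that budget. Dropout (attention weights and both
sub-layer outputs) defaults to 0.05; 0.1 was tried and underfits at this
data scale. Epoch-level shuffling, dropout masks and initialization
(Glorot-uniform weights, zero biases) all derive from the seed; arithmetic
is float64 throughout, so two identically seeded runs produce bitwise
identical parameters, and tests pin BLAS to one thread to keep this true
across machines.

The train/validation split (default 20%) is **grouped by genomic site**.
This matters: per-site methylation status is shared by all reads covering
the site, so a window-level random split would let the model score
validation windows by memorizing site-specific signal baselines from their
sequence context — label leakage that a delta = 0 null control exposes
immediately. With site-disjoint validation the null control scores at
chance (AUC ≈ 0.5). Model selection keeps the epoch with the best validation
F1; the selected parameters, the resolved configuration and the input
standardization are serialized to a single `.npz` checkpoint that restores
predictions bitwise.

Undefined metric ratios (zero denominators) are reported as 0 and flagged in
`MetricReport.undefined` rather than NaN, keeping reports machine-readable.
AUC is the Mann–Whitney pairwise-concordance statistic computed from rank
sums, with ties counted 1/2.

## The simulator

`simulate()` generates the full input side of the pipeline: a uniform-random
ACGT reference (CpG sites therefore occur at ~1/16 of positions), reads as
random substrings, and per-event raw samples. Its defaults are the
conditions under which the package's claims are tested:

* **Pore model.** The clean level of each event is a deterministic function
  of the k-mer centred on it (k = 7, the approximate pore span). Levels are
  marginally N(0, level_scale²) with level_scale = 1 and decompose into an
  additive per-position/per-base component carrying 75% of the variance plus
  an i.i.d. per-k-mer Gaussian residual carrying 25%. Real pore models are
  predominantly additive in the neighbouring bases with k-mer-specific
  deviations; the additive share is what a classifier can learn from one-hot
  context and generalize to unseen sites, while the residual keeps k-mers
  idiosyncratic and bounds that generalization. Both tables are calibrated
  to their nominal variances and centred so no seed carries a spurious
  genome-wide offset. The level map is a pure function of (k-mer,
  `pore_seed`); `pore_seed` defaults to the run seed but can be pinned so
  that several runs — e.g. a training run and a high-coverage evaluation
  run — share the same chemistry, as real runs on one platform do.
* **Methylation.** Each CpG site is methylated with probability 0.5; each
  read copy agrees with its site with probability `read_meth_fidelity`
  (default 1.0). A methylated copy shifts the levels of `shift_span` = k
  events centred on the C by delta × a triangular taper (weights 1 at the
  centre falling to 1/4 at ±3), encoding the observation that neighbouring
  events also carry methylation signal. The default delta is 0.6 level
  units; the recovery experiments plant delta = 2.0.
* **Sampling.** Events draw 1 + Poisson(dwell_mean − 1) samples
  (dwell_mean = 8) with N(0, noise_sd²) sample noise, noise_sd = 0.3, and
  are emitted on an arbitrary current scale (offset 90) so the pipeline's
  own normalization is always exercised. Reads are forward-strand by
  default; `emit_minus_strand` adds reverse-complement reads anchored to
  forward coordinates with their own (independent) site statuses at the
  palindromic partner cytosines.

What the simulator does **not** emulate: stay/skip pore kinetics, current
drift, basecalling or alignment error (events arrive perfectly
reference-anchored), non-uniform genome composition, CpG-island methylation
correlation, and hemimethylation coupling between strands. Passing tests
therefore demonstrate that the architecture, training loop and aggregation
recover planted context-dependent signals under the stated noise model —
not performance on real flow-cell data.

## Experiment sizes and numerical choices

The shipped end-to-end experiments use a 32 kb genome with 64 × 1 kb reads
(~2× coverage, ~2000 CpG sites, ~3900 windows) for training and null
controls — many distinct sites keep the site-grouped validation AUC
estimate tight — and a 4 kb genome with 250 × 400 bp reads (~25× coverage)
sharing the training run's pore model for site-level frequency recovery at
coverage ≥ 20. Training runs 10 epochs at d_model 16, 2 heads, window 21,
concatenated PE. Windows whose centre lies within ⌊w/2⌋ events of a read
end are skipped, not padded (a padded row would fabricate signal); skipped
candidates are counted and reported. Window rows are indexed by event order
within the read, so alignment indels are invisible to the artifact.

Numerical details: layer-norm epsilon 1e-5; softmax computed with max
subtraction; cross-entropy via log-sum-exp; checkpoint `.npz` archives are
deterministic byte-for-byte. Gradient correctness is enforced in the test
suite by central finite differences (tolerance 1e-5 relative) over every
parameter tensor of a small model in both embedding modes, and the
parameter count is checked against a closed form.

## Known limitations

* Per-read calling only consumes fully observed windows; sites near read
  ends are never called on that read.
* The CG motif is the only supported candidate definition (no GpC/6mA
  modes), and candidate scanning assumes an uppercase reference.
* Strand-symmetric CpG pairs are reported separately, never merged.
* The NumPy implementation targets desk-scale data; it is single-threaded
  by design for reproducibility and has no GPU path.
* Site frequencies are computed from hard 0.5-threshold calls (a mean
  per-site probability is emitted alongside as an auxiliary column in the
  API); at moderate coverage a site whose sequence context the model
  mis-baselines is wrong for most of its reads, so per-site frequency error
  is bimodal rather than binomial.
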