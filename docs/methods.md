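# Methods

This note documents the models, conventions, and design choices behind
`reefclr`, in the spirit of a package reference manual. It states no
empirical result that the test suite or `scripts/acceptance.py` does
not itself compute.

## Problem setting and assumptions

Passive acoustic monitoring archives consist of short clips (here
20 s) recorded at intervals, containing recurrent but non-identical
low-frequency events — fish calls and choruses, vessel noise — embedded
in ambient noise whose energy concentrates at low frequencies. The
framework assumes: (i) events of the same source type are acoustically
similar but not identical; (ii) different clips in a batch frequently
contain distinct instances of the same source type, so treating all
other batch items as negatives is wrong; (iii) labels, when present,
are coarse (source class, not call type).

## Preprocessing conventions

* Resampling: polyphase anti-aliased decimation to 10 kHz; upsampling
  is out of contract.
* Segmentation: non-overlapping 2-s windows; trailing remainder
  dropped.
* STFT: 25 ms Hamming window (250 samples), 10 ms hop, no center
  padding, FFT size 256 (window zero-padded to the next power of two).
  The frame count is floor((N − win)/hop) + 1, so a 2-s segment yields
  exactly 198 frames. No center padding avoids edge artifacts in crops
  and makes the frame count exact.
* Mel filterbank: 128 HTK-mel triangular filters over 0–5 kHz,
  unit-area normalized. Compression is log(1+x) on mel *power*;
  z-normalization is per spectrogram (whole matrix), with an epsilon
  guard mapping all-zero input to all zeros.
* Splits are performed at the parent-recording level so no recording
  contributes segments to both partitions. Class balancing downsamples
  every class to the smallest class count, stratified over sites with
  largest-remainder allocation.

## View generation

A 2-s segment alone yields 198 frames, fewer than the 256-frame global
crop, so view sources are 320-frame context windows sliced from the
parent clip's spectrogram, centered on the segment (clipped to clip
bounds; shorter-than-context clips are zero-padded). Global crops are
256 frames at uniform random offsets; local crops are 96 frames
centered on the maximum of the 9-frame-smoothed per-frame energy with
±24-frame jitter. The smoothing width (~90 ms) stops impulsive pulse
trains from dominating the argmax through single noisy frames.
Mask and notch augmentations fill with the per-view mean (≈0 after
normalization), matching SpecAugment practice on normalized inputs;
temporal shift zero-fills; truncation zero-fills a trailing fraction;
Gaussian noise is i.i.d. Augmentation probabilities and magnitudes are
package defaults, exposed in `AugmentationPolicy`.

## Loss system

* **Multi-positive NT-Xent.** Anchors are the 2B global-view
  embeddings. The unnormalized weight row has 1 on the paired view and
  (1 + sim(t_i, t_j))/2 on the top-k in-batch teacher neighbors with
  similarity above θ (self and the paired view excluded; k applied
  after the θ filter); rows are then normalized to sum to 1. The
  normalization is defined this way round (raw weights first, then
  divide by the row sum) because it is the only reading under which
  per-anchor weight normalization is well-defined. The denominator
  runs over the other 2B−1 batch embeddings plus all bank entries,
  log-sum-exp stabilized; self-pairs are masked. Bank entries carry
  zero positive weight: the queue exists to enlarge the negative set.
* **Teacher.** An EMA copy of encoder + projection head; outputs are
  re-normalized to unit length. Teacher similarities select soft
  positives because they are more stable than the online encoder's.
* **Bank.** Fixed-capacity FIFO of past teacher embeddings; pushed
  after the loss is computed so the current batch never appears in its
  own negative queue.
* **SimSiam term.** Symmetric negative cosine between a 2-layer MLP
  predictor output and a detached (stop-gradient) target, applied
  between paired global and local views.
* **VICReg.** Invariance = mean squared difference between the two
  global projections (pre-normalization — variance/covariance are
  meaningless on unit-norm rows); variance = hinge at target 1 on the
  per-dimension standard deviation (biased variance, ε = 1e-4);
  covariance = mean squared off-diagonal covariance (n−1 denominator),
  divided by the dimension. Internal weights default to (1, 1, 0.04),
  so the composite weight γ scales the whole block.
* **Composite objective** L = α·L_ctr + β·L_siam + γ·L_vic with
  defaults α=1, β=0.5, γ=0.1, τ=0.2. Local views never enter L_ctr.
* **Loss modes.** `teacher` (full engine), `vanilla` (one-hot pairing,
  no bank/teacher/auxiliaries — exactly standard NT-Xent), `supcon`
  (uniform positive weight over same-label views).

## Training preset and optimization

The package ships a desk-scale preset designed to run the full
mechanism set in CPU minutes: a 4-block strided 3×3 convolutional
encoder over 64×64 bilinear-resized views (channels 8→16→32→64),
linear layer to a 128-d backbone feature, 3-layer projection head to a
32-d embedding, 2-layer predictor (hidden 16), batch 32, bank capacity
512. Optimization is Adam (lr 3e-3) with a cosine decay. Gradients
flow through the online branch only. A full-size ResNet-18 preset is
named in the configuration enum for interface parity but is not
provided by this build; constructing it raises with an explicit
message.

Two desk-scale adaptations matter and are deliberate design choices:

* **EMA momentum 0.99** (not the 0.996+ typical of long schedules): at
  a few hundred steps a slower teacher never leaves its random
  initialization, and its similarities are uninformative.
* **Soft-positive warmup (default 100 steps):** positives are
  paired-only until the teacher has drifted from initialization.
  A randomly initialized teacher assigns high cosine similarity to
  almost everything, so early soft positives are spurious and drag
  unrelated samples together; warmup removes that failure mode and is
  standard practice for teacher-guided objectives at short schedules.

Inference-time embeddings use a single deterministic, un-augmented,
energy-centered 256-frame crop per segment, and are the unit-norm
projection outputs (all downstream similarity computations are
cosine-based, so clustering operates in the same geometry the loss
shaped). Checkpoints round-trip the full train state (parameters,
teacher, optimizer moments, bank, RNG), reproducing the subsequent
loss trajectory exactly.

## Synthetic soundscape generator

The simulator emulates the statistical structure the framework
assumes, not the physics of any real reef:

* **Archetypes**: pulse trains (Gaussian-envelope bursts at a drawn
  rate over a noise carrier), harmonic tonals (f0 plus decaying
  harmonics, Tukey envelope), choruses (slow-AM band noise), narrowband
  vessel tones, broadband vessel noise. Every event is brick-wall
  band-passed as the final synthesis step, so at least 90 % (in
  practice ~100 %) of its periodogram energy lies in its declared band.
  Per-event parameter jitter is multiplicative log-normal, producing
  repeated-but-non-identical events with controllable spread.
* **Background** is pink (1/f power) noise, matching low-frequency-
  dominated ambient conditions.
* **SNR** is defined in the event's own band: the ratio of event to
  background mean-square after band-passing both, measured over the
  event span. Broadband SNR would be meaningless for narrowband calls
  in pink noise.
* **Placement**: onsets uniform; with probability `overlap_prob` a new
  event is instead planted inside an existing event's span. Segment
  labels come from event-log bookkeeping: the archetype contributing
  the plurality of in-segment event energy, or "noise" if no event
  overlaps the segment.
* Clips are written as 16-bit PCM WAV (per-clip peak normalization,
  which preserves all SNR ratios), with a per-segment manifest CSV.

What the simulator does *not* model: propagation, multipath, recorder
transfer functions, diel/seasonal rhythms, or mimicry of real species
calls beyond band and temporal structure. Passing tests therefore show
that the pipeline recovers planted band/temporal structure under pink
noise at the stated SNR — not that it resolves real species
repertoires.

## Study designs (scaled-down defaults)

* **Separability**: one site, three spectrally disjoint archetypes
  (harmonic tonal 60–480 Hz, pulse train 500–800 Hz, narrowband vessel
  40–120 Hz) at +20 dB SNR; 24 clips (240 segments), 300 steps; score =
  ARI of k-means (k=3) on embeddings vs generator labels.
* **Dictionary recovery**: two sites sharing the tonal archetype, with
  the pulse train exclusive to site 1 and the vessel tone to site 2;
  20 clips per site, 250 steps; joint GMM with k=8; cohesion threshold
  0.10; site presence requires ≥10 members. Success = the shared
  archetype's cluster present at both sites and each exclusive
  archetype's cluster present only at its home site.

These sizes are the package's desk-scale defaults chosen so each study
completes in a few CPU minutes; the cohesion threshold (0.10) and the
fixed-k evaluation presets (k=6 label agreement, k=60 discovery
granularity) are the framework's standard operating points. At
production scale the joint clustering uses k=60; the two-site study
uses k=8 because only a handful of distinct sources exist.

## Numerical choices and degenerate inputs

* All-zero spectrograms normalize to all zeros (ε-guard); the energy
  center of a flat spectrogram is frame 0 (smallest-index tie rule).
* Cosine similarity raises on zero rows rather than returning NaN.
* Cohesion is undefined for singletons; such clusters are excluded
  from filtering rather than silently scored.
* Hungarian accuracy solves the rectangular assignment problem
  exactly; unmatched clusters contribute zero correct.
* Silhouette and Davies–Bouldin are computed from exact pairwise
  distances (not the quadratic-expansion shortcut) so they agree with
  their definitions to ~1e-12.
* Density-method noise points (label −1) are excluded from internal
  metrics and reported as a separate noise fraction.
* GMM clustering uses full covariances, 5 restarts, best likelihood.
* Signature descriptors: frequency band = central 90 % of the
  time-averaged mel energy profile (mapped to Hz via filter center
  frequencies); harmonicity = normalized height of the strongest
  non-zero-lag autocorrelation peak of the linear-frequency resampled
  profile. Both are deliberately simple, parameter-free summaries.
* The site-presence rule (≥10 members) is a package convention,
  exposed as configuration.

## Known limitations

* The autodiff engine and conv encoder are minimal by design; the
  desk-scale preset targets correctness and reproducibility, not
  throughput, and no GPU or distributed path exists.
* Embeddings for clustering are projection outputs; backbone features
  are available but not the default.
* The generator's archetypes are spectrally stylized; studies with
  heavily overlapping bands or sub-0 dB SNR are outside the default
  study conditions and would need larger models and longer schedules.
* Expert review of discovered clusters is replaced by an optional
  spectral-flatness screen (off by default); ecological interpretation
  is out of scope.
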