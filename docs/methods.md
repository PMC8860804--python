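# Methods

This note documents the models, estimators and numerical choices behind
`dirconn`, what the synthetic generator does and does not emulate, and
the problem sizes the validation suite uses.

## Signal model and preprocessing

The pipeline assumes multichannel (or ROI-level) time series sampled
well above twice the highest analysis band. Band-limiting uses a
Butterworth band-pass designed at order 4 and applied forward-backward
(`scipy.signal.sosfiltfilt`), i.e. zero net phase shift and the squared
Butterworth magnitude as the effective response. Downsampling is
polyphase with the built-in anti-alias filter. Common-average
re-referencing subtracts the per-sample channel mean.

Instantaneous phase and amplitude come from the Hilbert analytic signal,
computed **per continuous clean segment** and never across a splice:
concatenating raw segments first would manufacture phase discontinuities
at the joins. After the transform, one cycle of the band's low edge is
trimmed from each segment end to discard filter/Hilbert edge transients;
segments shorter than three cycles of the low edge are dropped entirely.
The surviving phase/amplitude samples are pooled per channel. When two
bands feed a cross-frequency measure, both use the same trim and the
same minimum segment length so their pooled samples stay aligned.

Phase differences are always wrapped to (−π, π] before any sign test —
unwrapped differences would make the Heaviside sum meaningless.

## Source projection and ROI reduction

A precomputed linear inverse operator (3 dipole components per point
source) is applied independently to the real and imaginary parts of the
sensor analytic signal; per-source power is the squared norm of the
3-component complex vector. Computing the operator itself (head model,
regularization) is out of scope — it is consumed as a numeric matrix.

Power is z-scored across time per source to remove static activation
biases. The standardization window pools all conditions of a subject:
standardizing within the same window one then averages over would give
identically zero, so condition averages are deviations from the pooled
mean (they sum to zero across two equal-length conditions by
construction).

For connectivity, each ROI's member sources (all three orientations
stacked as rows of a time × rows matrix of **band-filtered signed
signals**, not power — coupling estimators need oscillatory sign
information) are reduced to the first SVD component. The SVD sign
indeterminacy is resolved by the majority-of-vectors rule: flip the
component so that more member rows load positively than negatively,
with exact ties left untouched. The rule is discontinuous at a tie; the
test suite therefore checks sign agreement with an independent
Gram-matrix oracle only where the majority margin is ≥ 2 and no loading
sits at numerical zero, and checks direction up to sign everywhere.

Because the atlas the analysis was designed around is not
redistributable from here, the default ROI geometry
(`synthetic_roi_table`) is a synthetic stand-in: 84 bilaterally paired
centroids with MNI-plausible coordinate ranges. It exists so adjacency
and distance computations have realistic geometry; it is labelled
synthetic in its docstring and is configuration-replaceable by any
TSV with real atlas centroids and source assignments.

## Coupling measures

* **dPLI**: mean Heaviside of wrapped phase differences. H(0) = ½, which
  keeps the complement identity dPLI_xy + dPLI_yx = 1 exact when
  finite-precision zeros occur (exact-zero differences are otherwise
  measure-zero). The diagonal is undefined and excluded (NaN).
* **nMI**: (1/√N)·|Σ a e^{iφ}| / √(Σ a²) over all ordered pairs
  including the diagonal (local coupling is meaningful and tested).
* **logit**: group statistics run on log(p/(1−p)). Finite-sample dPLI
  can saturate at 0 or 1; saturated entries are clipped to
  ε = 1/(2N) — N the sample count behind the matrix — which keeps the
  transform finite without reordering values, and clipping events are
  logged. On the logit scale dPLI matrices are anti-symmetric and the
  no-lead value is 0 (the raw scale satisfies dPLI_xy = 1 − dPLI_yx
  instead; anti-symmetry proper only holds after the transform).

## Network statistics

First-level thresholds use the t-distribution CDF (parametric first
level, as in the canonical network-based statistic); the component-level
inference is purely permutation-based:

* **Paired variant** (nMI, condition A vs B): per-link paired t across
  subjects; links with two-sided p < α_init (default 0.005) kept per
  tail; weakly connected components formed per tail; null statistic =
  maximum component link count over within-subject condition swaps
  (equivalently sign flips of the difference matrices), maximized over
  both tails.
* **One-sample variant** (logit dPLI vs 0 within one condition): only
  the leading (positive-t) direction of each pair survives; the null
  transposes each subject's matrix independently — reversing all of
  that subject's link directions — and records the maximum component
  link count.

Permutation patterns are drawn in **antithetic pairs** (each pattern
with its complement). This is a valid sampling of the same permutation
group with slightly lower Monte-Carlo variance, and it makes the
one-sample procedure exactly equivariant under global transposition of
its inputs: transposing every matrix reverses all recovered link
directions with identical p-values.

p-values use (1 + #{null ≥ observed}) / (1 + n_perm), so they live on
the grid {1/(n_perm+1), …, 1} and are never zero. Zero-variance links
are excluded (NaN t). Defaults mirror the printed analysis parameters:
α_init = 0.005 (links), 0.0005 (power clusters), final α = 0.05,
n_perm = 5000.

Cluster inference on power maps is the spatial analogue: two-sided
paired t per source, adjacency-connected suprathreshold clusters per
tail scored by summed t, sign-flip null on the maximum |mass|. Source
adjacency defaults to "within 1.5× the median nearest-neighbour
spacing", a standard neighbourhood heuristic for irregular grids.

Condition-difference handling for dPLI: since the one-sample test runs
per condition, both conditions are tested separately and the overlap of
their significant link sets is reported (`network_overlap`); no link is
automatically removed from one network based on the other.

Node typing on significant components: source = only outgoing links,
sink = only incoming, intermediate = both (a self-loop makes its node
intermediate). Link distances are Euclidean distances between ROI
centroids (mm) of the links in the group-level significant networks;
profiles across measures are compared with a one-way ANOVA and all
pairwise pooled-variance t-tests corrected by Dunn–Šidák,
p_adj = 1 − (1 − p)^m.

## Synthetic generator

The generator emulates a two-condition within-subject EEG study:
defaults are 15 subjects, 40 trials of 30 s at 500 Hz per condition,
84 ROIs, high-theta 7–10 Hz and gamma 30–80 Hz, pink (1/f) background
noise — the spectral shape the measures must tolerate. Planted structure
appears in the "memory" condition only:

* **Phase-lag links**: a narrowband carrier (band-filtered white noise,
  so its bandwidth and autocorrelation are realistic) is placed in the
  source ROI; the destination receives the carrier rotated by the lag in
  the analytic domain, with per-sample uniform phase jitter on a
  fraction (1 − strength) of samples. This gives direct analytic
  control of the ground-truth dPLI: strength 1 ⇒ dPLI = 1 for a
  positive lag; strength 0 ⇒ 0.5.
* **PAC links**: the gamma envelope of the destination is
  (1 − depth) + depth·g(φ_θ − φ_pref) with g a von-Mises-style bump
  exp(κ(cos·−1)), κ = 4, peak 1 at the preferred phase. depth = 0 is a
  constant envelope; the nMI is monotone in depth.

Planted components are normalized to unit RMS and scaled to
`noise_snr` × the background RMS *within the same band* (default 1.0,
i.e. 0 dB in-band — a strong but realistic planted effect). An optional
instantaneous mixing matrix emulates zero-lag linear leakage; an
optional artifact fraction marks one contiguous bad segment per trial.
Everything is a deterministic function of the config seed (bit-identical
reruns).

What the generator does **not** emulate: volume conduction with a real
head model, non-stationarity across trials, ocular/muscle artifacts
with realistic spectra (bad segments are marked, not shaped), inter-
subject anatomical variability, or behavioural covariates. Passing the
recovery tests therefore shows the estimators and statistics do what
they claim under controlled conditions with realistic spectra and
leakage — not that every real-data confound is handled.

## Validation suite: problem sizes and tolerances

* Oracle equivalence: 100 random small instances per primitive, against
  independently written brute-force oracles (loop Heaviside sum, direct
  nMI formula, Gram-matrix eigendecomposition, union-find, explicit
  sum-of-squares ANOVA, standalone FFT Hilbert), agreement to 1e-12
  (1e-6 relative for the eigenproblem, whose conditioning is squared).
* Leakage robustness: 50 seeded runs of two independent 7–10 Hz sources
  under zero-lag 2×2 mixing, 50 000 samples at 500 Hz. The tolerance is
  3 binomial standard errors of the mean sign indicator with the SE
  inflated by the indicator's integrated autocorrelation time — the
  standard SE for an autocorrelated Bernoulli sequence. (The naive
  binomial SE at the raw sample count would understate the sampling SD
  of any narrowband phase statistic by the autocorrelation factor.)
* Family-wise error calibration: 200 null simulations per NBS variant at
  12 subjects, 20 ROIs, 500 permutations, exchangeable Gaussian null
  matrices (anti-symmetrized for the one-sample variant). The null is
  generated at the matrix level: the NBS null hypothesis and its
  permutation distribution are defined on the matrices, and 200 full
  signal-level simulations would add tens of minutes of filtering for
  no additional coverage of the statistic. A signal-level null run of
  the whole pipeline is exercised separately. Bound: 0.05 + 2
  Monte-Carlo SE.
* Planted recovery: full signal path (pink noise, filtering, Hilbert,
  logit, NBS; ground truth planted at ROI level so recovery does not
  depend on inverse-modelling quality) at 12 subjects, 20 ROIs,
  2 × 10 s trials per condition, 3 planted links at depth/strength 0.8
  arranged as a star (so they form one weakly connected component — an
  isolated single link can never beat a max-component-size null),
  n_perm = 1000. Success criterion — all planted links inside a
  significant component — was fixed before the first run.

These sizes keep the whole suite around half a minute on one CPU while
leaving each claim statistically meaningful; they are scaled-down study
conditions, chosen once.

## Known limitations

* The first level of both NBS variants is parametric (t distribution);
  heavy-tailed link distributions would make α_init nominal rather than
  exact. The component level is exact by permutation regardless.
* dPLI says nothing about coupling strength, only lead consistency; a
  tiny but consistent lag saturates it given enough data.
* The nMI inherits the usual PAC caveats: amplitude non-stationarity and
  waveform asymmetry can masquerade as coupling; surrogate-based local
  testing (as in the examples) is advisable on real data.
* ROI reduction keeps one component per ROI; genuinely multi-modal ROI
  activity is collapsed.
* The BrainVision reader is a thin optional wrapper around MNE and is
  exercised only when MNE is importable.
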