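# Methods

This note documents the models, conventions and numerical choices behind
`phylosong`, and what the synthetic-data tests do and do not demonstrate
about real recordings.

## Acoustic measurement model

All analysis happens on a magnitude STFT of the preprocessed signal
(22 050 Hz, fft 512, hop 256, Hann window, frames centred by fft/2
zero-padding; frame count `1 + len//hop`, so the last frame is always at
least half-filled — a ceil convention would append a nearly empty frame
whose RMS distorts envelope statistics). Preprocessing is
resample → band-pass → standardize, in that order, so the unit-variance
contract holds on the filtered signal. The band-pass is a 4th-order
Butterworth (100 Hz–10 kHz) applied forward–backward for zero phase; only
the corner frequencies are scientifically meaningful, the filter family is
a convention.

The nine features and their fixed transforms:

| feature | definition |
|---|---|
| `rms_cv` | sd/mean of per-frame RMS (unit-free; 0 for a steady envelope, 1 for a two-point on/off envelope) |
| `flux_logsd` | ln(sd over frames of Σ_f (|S|_{f,t} − |S|_{f,t−1})²), floored by ε = 1e−12 |
| `entropy` | Shannon entropy (bits) of the normalized whole-vocalization mean power spectrum |
| `flatness_logmean` | ln of the time-averaged per-frame spectral flatness (geometric/arithmetic mean of power, powers floored at 1e−10) |
| `centroid_logmedian` | ln median over frames of the amplitude-weighted mean frequency; zero-magnitude frames are dropped, not imputed |
| `contrast1..4` | ln mean over frames of log10(peak/valley) within 0–500 / 500–1000 / 1000–2000 / 2000–4000 Hz, peak/valley = mean of the top/bottom 2 % of band bins (≥ 1 bin) |

Natural log is used for all "log transformed" features and log10 for the
per-frame contrast ratio (a decibel-like quantity). The bases are internal
conventions: distances are min–max normalized downstream, so rank-level
conclusions do not depend on them.

**Flatness orientation.** The geometric/arithmetic flatness ratio is 1 for
a flat (noise-like) spectrum and → 0 for a pure tone. The field sometimes
describes the same axis in the opposite "tonality" orientation (0 = white
noise, 1 = harmonic). Both are exposed (`flatness_index`,
`tonality_index = 1 − flatness_index`); the pipeline feature is
`ln(flatness_index)`. Spectral entropy is computed from the mean STFT power
spectrum rather than a separate Welch periodogram; at these frame counts
the two are practically indistinguishable for the rank statistics used.

## Distances

Acoustic distances are absolute differences of species-mean features —
species means, not per-recording pairs — min–max scaled over the
off-diagonals to [0, 1] so all nine features contribute on a common scale
before averaging (a z-score alternative is selectable; including the
structural zero diagonal in the scaling would only shift the minimum).
p-distances exclude columns with a gap or N in either sequence of the pair.
Cophenetic matrices are branch-length path sums; the ensemble genetic
distance is their element-wise mean across trees, aligned by species label
(never by position).

## Phylogenetic signal

`V` is the phylogenetic variance–covariance matrix (shared root-to-MRCA
path lengths). Blomberg's K uses the GLS phylogenetic mean and the ratio of
observed to Brownian-expected variance ratios; its p-value permutes trait
values across tips (default 1000 permutations, observed arrangement counted
in a +1 denominator, so p ≥ 1/(n_perm+1)). Pagel's λ multiplies the
off-diagonal of V and is profiled over [0, λ_max] with
λ_max = max(diag V)/max(offdiag V); on non-ultrametric (jittered) trees
that bound can exceed the positive-definite region, so the profile
likelihood returns −∞ outside it and the optimizer (25-point grid scan plus
bounded Brent, xatol 1e−6) stays inside. Significance is a likelihood-ratio
test of λ̂ against λ = 0 on χ²(1); the boundary-at-zero subtlety (which
would halve the p-value) is ignored, matching common practice. When V is
numerically singular a ridge of 1e−8 · mean(diag V) is added and logged.
Per-(feature, tree) permutation seeds are derived by stable hashing, so
ensemble results are independent of execution order.

Implementation check: K, λ̂, both log-likelihoods and the LRT p-value agree
with `phytools::phylosig` to at least 5 decimals on a 20-tip fixture (test
suite). Known behaviour: λ̂ is a boundary-constrained MLE and carries a
downward finite-sample bias at intermediate truth (mean λ̂ ≈ 0.41 for
λ = 0.5 at 64 tips) — a property of the estimator, not a defect.

## Matrix statistics

The Mantel test is one-tailed (greater), with r computed on upper-triangle
off-diagonals and p = (# permuted r ≥ observed)/n_perm — permutations only
in the denominator, so p = 0 is attainable. The closest-relative test
averages acoustic distances over genetically tied closest relatives and
excludes the closest relative from the "other species" mean, so the two
paired quantities never overlap; the t-test is two-tailed with df = n−1.
Per-species regressions z-score the response as well as the predictors, so
reported β are standardized coefficients comparable across predictors;
rank-deficient designs and zero-variance correlations are skipped and
logged, never imputed.

## Synthetic studies: what they emulate

The generator produces a complete study with known ground truth:

* **Tree:** pure-birth (Yule) with exponential waiting times, rescaled to
  unit root-to-tip depth (ultrametric). No birth–death extensions.
* **Ensemble:** each branch length multiplied by an i.i.d. log-normal
  factor (median 1, log-sd default 0.1). This emulates the *role* of a
  bootstrap ensemble — near-identical topologies with varying lengths — at
  trivial cost, not the bootstrap process itself.
* **Traits:** eight latent phenotypes drawn from MVN(0, σ²·V(λ)), mutually
  independent, plus one extra latent for log body mass
  (mass = exp(ln 50 g + scaled latent)), which couples mass differences to
  genetic distance.
* **Sequences:** Jukes–Cantor evolution, gapless, branch lengths in
  substitutions/site (a site is redrawn uniformly from {A,C,G,T} with
  probability 1 − e^(−4t/3), reproducing the JC69 transition kernel).
* **Audio:** a harmonic stack (≤ 10 harmonics below 0.45·sr) mixed with
  band-passed noise. Monotone dials, with u = sigmoid(latent): carrier
  frequency 300–8000 Hz (linear in u, so the baseline carrier sits above
  the four contrast bands); harmonic/noise mix; 6-Hz AM depth 0–1; the
  amplitude of a frequency-warbling component (a tone jumping ±0.35 octaves
  at 8 jumps/s near 1.3× the carrier) driving spectral flux; and three
  bin-centred tones per contrast band. Two of these dials deserve comment:
  spectral flux responds to how much spectral energy moves between frames,
  not how far it moves — a plain "sweep rate" dial saturates as soon as the
  per-frame movement exceeds one bin, so the flux dial scales the moving
  component's amplitude instead; and the band tones sit on STFT bin centres
  because off-bin tones leak into neighbouring bins and poison the contrast
  valleys. Within-species variation adds latent noise with sd equal to 10 %
  of the between-species Brownian sd (a free parameter; the emulated study
  design does not pin it down). Durations are uniform 0.5–3 s, written as
  16-bit mono WAV.
* **Seeding:** one master seed; per-species/per-recording/per-analysis
  seeds derived by stable BLAKE2 hashing of (master, role, id), so outputs
  are bit-reproducible and order-independent.

What passing tests show: the pipeline recovers planted phylogenetic signal
through the full audio round-trip, its test statistics are calibrated under
the null, and its estimators match independent references. What they do not
show: robustness to field-recording noise, non-stationary song syntax,
syllable structure, or perceptual realism — the synthesizer makes no
attempt at any of these.

## Problem sizes and defaults

Default analysis parameters follow the emulated study design: 100 trees in
an ensemble, 5000 Mantel permutations, 1000 K permutations, ~1000-bp
alignments, 2–6 recordings per species. The validation suite uses smaller
but statistically adequate sizes chosen once: 500 Brownian replicates for K
calibration at 32 tips, 100 replicates per λ level at 64 tips, 500 null
Mantel simulations at n = 20 with 199 permutations, and end-to-end power
studies of 40 species with 20-tree ensembles and 199 permutations (the
smallest permutation count whose minimum attainable p, ≈ 0.005, sits
comfortably below the 0.05 threshold).

## Known limitations

* Single-trait (univariate) K and λ only; no OU/EB alternatives, no
  ancestral-state reconstruction, no partial Mantel, no phylogenetic GLS
  regression, no multiple-testing correction across features (raw
  per-feature p-values are reported deliberately).
* p-distances are uncorrected; model-corrected distances (K2P/GTR) are out
  of scope, as is sequence alignment itself (pre-aligned FASTA only).
* The closest-relative test assumes the genetic matrix identifies a
  meaningful nearest neighbour; with heavily tied distances the averaging
  convention dilutes the contrast.
* Audio ingestion assumes one vocalization per WAV file and the
  `<species>__<index>.wav` naming convention.
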