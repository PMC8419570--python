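# phylosong

Quantify **phylogenetic signal in animal vocalizations**: do closely related
species sound more alike than expected by chance?

The package implements a complete comparative-bioacoustics pipeline for
researchers who have (i) vocalization recordings for a set of species,
(ii) a phylogeny (ideally a bootstrap ensemble of trees) and, optionally,
(iii) an aligned marker-gene alignment and body masses. A first-class
synthetic-data module generates all of these with known ground truth, so
every stage is testable offline.

## The method

1. **Preprocessing.** Each recording is resampled to 22 050 Hz, band-pass
   filtered 100 Hz–10 kHz (4th-order zero-phase Butterworth) and
   standardized to mean 0 / sd 1, making all downstream measures invariant
   to recording level.
2. **Nine acoustic features** from a magnitude STFT (fft 512, hop 256, Hann
   window): the coefficient of variation of the per-frame RMS envelope,
   ln sd of spectral flux, spectral entropy of the whole-vocalization mean
   power spectrum, ln mean spectral flatness, ln median spectral centroid,
   and ln mean spectral contrast in four bands (0–0.5, 0.5–1, 1–2,
   2–4 kHz). Features are averaged within species.
3. **Distance matrices.** Per-feature acoustic distances
   `D_f(i,j) = |m_f(i) − m_f(j)|` on species means, min–max normalized and
   averaged into a mean acoustic distance matrix. Genetic distances come
   from uncorrected p-distances on the alignment and from cophenetic
   (patristic) distances averaged element-wise over the tree ensemble.
4. **Matrix comparisons.** A paired t-test of the acoustic distance to each
   species' closest genetic relative versus all other species; per-species
   Pearson correlations between genetic and acoustic distances; one-tailed
   permutation **Mantel tests** (default 5000 permutations); and per-species
   multiple regressions of genetic distance on the nine feature distances
   plus |Δ log body mass|, with standardized coefficients averaged across
   species.
5. **Phylogenetic signal.** For each feature and each tree of the ensemble,
   **Blomberg's K** (with a tip-permutation p-value) and **Pagel's λ** (ML
   over the λ-scaled phylogenetic covariance V(λ), likelihood-ratio test
   against λ = 0). With x the species trait vector and V the matrix of
   shared root-to-MRCA branch lengths,

   K = (MSE₀/MSE) / E_BM[MSE₀/MSE],  MSE₀ = (x−â)ᵀ(x−â)/(n−1),
   MSE = (x−â)ᵀV⁻¹(x−â)/(n−1),  â the GLS phylogenetic mean,

   and K = 1 is the Brownian-motion expectation. Results are summarized as
   mean ± sd across the ensemble plus the proportion of trees with p < 0.05.

The implementation of K and λ is cross-validated in the test suite against
`phytools::phylosig` (agreement to ≥ 5 decimals on a 20-tip fixture).

## Worked example

Generate a synthetic study of 20 species (Brownian traits with λ = 1 on a
Yule tree, 2–3 recordings per species, a 25-tree ensemble) and run the full
pipeline:

```bash
cat > config.yaml <<'YAML'
seed: 11
synthetic:
  n_species: 20
  recordings_min: 2
  recordings_max: 3
  n_trees: 25
  lam: 1.0
  n_sites: 500
params:
  n_perm_mantel: 999
  n_perm_k: 199
YAML
phylosong run --config config.yaml --out out/
```

`out/signal_summary.csv` then contains (rounded):

```
           feature  mean_K  prop_signif_K  mean_lambda  prop_signif_lambda
            rms_cv   0.407            0.0        0.307                0.00
        flux_logsd   0.779            1.0        0.986                1.00
           entropy   1.150            1.0        0.997                1.00
  flatness_logmean   1.507            1.0        1.018                1.00
centroid_logmedian   1.076            1.0        0.993                1.00
         contrast1   0.108            0.0        0.000                0.00
         contrast2   1.528            1.0        1.013                1.00
         contrast3   0.648            1.0        1.023                0.76
         contrast4   1.241            1.0        1.015                1.00
```

Most features recover the simulated Brownian signal: mean λ̂ ≈ 1 and K
significant in 100 % of the 25 trees (features whose latent drivers are
weakly expressed in the audio, like `rms_cv` here, can stay undetected —
that is the measurement noise of the audio round-trip, not an error).
`out/mantel.csv` shows the group-level agreement (mean acoustic distance:
r = 0.495, p < 0.001) and `out/closest_relative.csv` the species-level test
(t₁₉ = 6.55, p ≈ 3 × 10⁻⁶): species are acoustically closer to their
closest genetic relative than to the rest.

The same CLI exposes the stages separately (`phylosong simulate`,
`features`, `distances`, `signal`, `mantel`, `closest`, `regress`); all of
it is importable from Python via `import phylosong`.

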