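# thzchem

Chemometric screening of structurally similar drug candidates from
terahertz (THz) absorbance spectra.

When a family of candidate compounds shares a common scaffold, their
solid-state THz spectra (20–80 cm⁻¹) encode crystal-lattice dynamics that
correlate with bulk physicochemical properties. `thzchem` implements the
full analysis chain that exploits this:

- **Preprocessing** — decadic absorbance from time-domain pulse pairs,
  `A(ν) = −2·log₁₀|S(ν)/R(ν)|`, band cropping to the informative window,
  and standard normal variate (SNV) row normalization
  `x → (x − x̄)/s_x`.
- **A priori map** — unscaled (covariance) PCA of the molecular descriptor
  table (MP, PSA, logP, HBD, HBA, Mr, ROTB, AROMS), with correlation-style
  biplot arrows `(v_{j1}√λ₁, v_{j2}√λ₂)`.
- **A posteriori map** — mean-centered PCA of the SNV spectra: scores,
  loadings, explained variance, out-of-sample projection, k-component
  reconstruction.
- **Spectral clustering** — UPGMA on pairwise Euclidean spectral distances,
  with the dendrogram axis kept in spectral-distance units, threshold cuts,
  leaf-ordered intensity-image export and Newick output.
- **Map linking** — quantified concordance between the two maps: mean k-NN
  overlap against a label-permutation null, and pairwise agreement of
  UPGMA groupings of each map.
- **Melting-point prediction** — NIPALS PLS1 of MP on the spectra under a
  randomized leave-k-out protocol: per sample, the mean absolute error ê,
  mean relative error ê_R (%), and the extreme errors e_α (max) and e_ω
  (min); plus a training-set influence ranking that flags compounds whose
  presence in training degrades everyone else's predictions.
- **Synthetic data** — a generator producing descriptor tables whose
  covariance is dominated by MP and Mr and matched spectra whose dominant
  absorption band tracks MP, with frequency-dependent multiplicative noise
  suppressed by √n coherent averaging. Measured datasets of this kind are
  rarely public, so every stage is testable end to end against known truth.

## Worked example

```python
from thzchem import (SimConfig, build_map, knn_concordance, leave_k_out,
                     normalize_matrix, simulate_dataset)

ds = simulate_dataset(SimConfig(n_samples=27, seed=1, mp_link_strength=0.9))
norm = normalize_matrix(ds.spectra_matrix(), "snv")

map_a = build_map(ds.descriptors)            # a priori
map_b = build_map(norm, normalize="none")    # a posteriori
conc = knn_concordance(map_a, map_b, k=3, permutations=2000, seed=1)
print(conc.mean_overlap, conc.null_q95, conc.p_value)

rep = leave_k_out(norm.values, ds.descriptors["MP"].to_numpy(),
                  k=4, iterations=500, seed=1)
print(rep.mean_relative_error)
```

prints

```
0.2222  0.1852  0.0105
15.2
```

A mean 3-nearest-neighbor overlap of 0.222 against a permutation-null 95th
percentile of 0.185 (p ≈ 0.01) means compounds that are physicochemical
neighbors stay spectral neighbors far more often than chance — the
computational restatement of linking the two maps. The leave-4-out PLS
mean relative error of ~15% on the melting point (vs ~24% when the
spectrum–MP link is switched off) shows the spectra carry usable predictive
signal for candidate triage.

The `examples/` directory walks each capability in a short script, and the
`thzchem` CLI exposes the stages
(`thzchem {simulate|preprocess|pca|cluster|link|predict|run}`), e.g. a full
demo run:

```sh
thzchem run --seed 1 --out-dir runs/demo
```

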