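# Methods

## Problem setting

A family of solid drug candidates sharing one scaffold is characterized two
ways: *a priori*, by eight molecular descriptors — melting point (MP, °C),
polar surface area (PSA, Å²), octanol–water partition coefficient (logP),
hydrogen-bond donors/acceptors (HBD/HBA), molecular mass (Mr, g/mol),
rotatable bonds (ROTB) and aromatic rings (AROMS) — and *a posteriori*, by
THz absorbance spectra of pellets in the 20–80 cm⁻¹ band, where
crystal-lattice vibrations absorb. The package projects both domains onto 2D
PCA maps, measures whether neighborhoods agree, and regresses MP on the
spectra.

## Preprocessing

Time-domain pulses are Fourier-transformed (no window by default — traces
are assumed fully decayed; a Hann window and zero padding are available) and
referenced against the blank diluting-medium pellet:
`A(ν) = −2 log₁₀ |S(ν)/R(ν)|`. The factor 2 is the decadic *power*
absorbance convention applied to amplitude-spectrum ratios; the amplitude
convention (factor 1) is selectable, since published absorbance
definitions differ only in this constant and all downstream statistics are
invariant to it after SNV. The wavenumber axis follows from the sampling
interval via ν[cm⁻¹] = f[GHz]/29.9792458. A vanishing reference amplitude
at any grid point is a hard error rather than a silently infinite
absorbance.

Band cropping keeps the closed interval [lo, hi]; the grid length is
whatever the transform produced (1137 points in the canonical 20–80 cm⁻¹
configuration of the generator) and is never enforced.

SNV divides by the *sample* standard deviation (n−1). Row-wise min–max and
unit-norm scaling are provided as alternatives; SNV is the pipeline default
because it equalizes each spectrum's contribution while amplifying weak
bands.

## PCA

PCA is computed by SVD of the centered (optionally autoscaled) matrix.
Descriptor tables use **unscaled** (covariance) PCA: the point of the
*a priori* map is that MP and Mr, the two descriptors with by far the
largest numeric spreads, dominate — autoscaling would erase exactly that
structure. Spectra are only mean-centered, since rows are already SNV
normalized. Explained-variance ratios are eigenvalues over the total
variance of the processed data. Sign indeterminacy is fixed by making each
loading column's largest-magnitude entry positive; every concordance metric
downstream is isometry-invariant, so orientation never matters. Biplot
arrows are correlation-style, `loading × √eigenvalue`, which equals the
covariance of each raw variable with the scores divided by √eigenvalue.

## UPGMA clustering

Spectral similarity is the plain Euclidean distance between SNV spectra.
UPGMA merges the closest pair of clusters, with inter-cluster distance the
unweighted mean over all cross-pair leaf distances. Two conventions are
deliberate:

- **merge height = the average distance itself, not halved**, so a
  dendrogram cut reads directly in spectral-distance units;
- **ties broken by the lexicographically lowest cluster-index pair**, and
  leaf order placing the subtree containing the lowest original index
  first — both arbitrary but required for bit-reproducible trees.

Newick export halves heights along root-to-leaf paths so the tree is
ultrametric and round-trips through standard parsers.

## Map concordance

The published analysis of this design linked the two maps by manually
encircling corresponding groups; that is not reproducible, so the package
replaces it with two metrics:

- **k-NN overlap**: for each sample, the fraction of its k nearest
  neighbors (Euclidean, raw score coordinates) shared between maps; the
  mean overlap is tested against a null built by permuting the sample
  labels of one map, with p = (1 + #{null ≥ observed})/(1 + permutations).
  Defaults k = 3 (appropriate for n ≈ 27) and 2000 permutations. The
  permutation p-value is exact but conservative under ties of the discrete
  overlap statistic.
- **group agreement**: each map is UPGMA-clustered into n_groups (default
  8) on its 2D coordinates; agreement is the fraction of sample pairs
  classified concordantly (Rand index), plus the fraction of samples
  following their group's majority mapping across maps.

## PLS melting-point prediction

PLS1 is implemented as NIPALS with both X- and y-deflation — the canonical
chemometrics variant — and the compact coefficients b = W(PᵀW)⁻¹q; the test
suite proves equivalence to an independent NIPALS implementation and to
ordinary least squares at full rank. The component count is the smallest
number whose *training-set* mean relative error reaches ≈10%, a stopping
rule that deliberately under-fits to protect generalization; the cap and
target are configurable.

The leave-k-out protocol draws a uniform random k-subset per iteration
(subsets may repeat across iterations), refits on the remainder and
predicts the held-out samples. Errors aggregate **per sample** over all
iterations in which the sample was held out: ê = mean |ŷ−y|,
ê_R = mean(|ŷ−y|/|y|)·100, e_α = max, e_ω = min — i.e. the error bars are
per compound, not per iteration. Relative error uses MP in °C.

Training-set influence compares, for each sample s, the mean per-iteration
test ê_R when s is in the training set against iterations where s was held
out; in the latter, s's own prediction error is excluded from the iteration
mean so the ratio isolates s's effect *as a training member* (otherwise an
outlier's large self-error masks its influence). Ratios ≫ 1 flag compounds
whose spectrum–property relation deviates from the family.

## Synthetic data generator

The generator encodes the study conditions the analysis assumes:

- **Descriptors**: MP ~ N(150, 40²) °C and Mr ~ N(420, 60²) g/mol,
  independent; PSA ~ N(108, 4²) Å² sharing a latent factor with MP to give
  Pearson ρ ≈ 0.46; logP ~ N(3.1, 0.45²); HBD/HBA/ROTB/AROMS are rounded,
  clipped normals in drug-like ranges. Only the ≥10× spread ordering
  (MP, Mr vs the rest) is load-bearing — it makes unscaled PCA concentrate
  >95% variance in two components; the marginal centers are conventions.
- **Spectra**: 1–4 Gaussian bands (σ 2–6 cm⁻¹) on a 1137-point 20–80 cm⁻¹
  grid. Gaussians were chosen over Lorentzians for bounded tails on a
  cropped band; no lineshape is canonical for disordered pellet spectra at
  this resolution. The dominant band center is affine in MP
  (ν₀ = 10.5 + 0.28·MP, mapping MP ± 2σ onto the central ~75% of the band),
  perturbed by (1 − mp_link_strength)·N(0, 20²) cm⁻¹; `mp_link_strength`
  (default 0.9) dials the recoverable spectrum→MP signal, and 0 is the
  null.
- **Noise**: multiplicative Gaussian with relative std σ(ν) constant at 5%
  up to 50 cm⁻¹, rising linearly to 30% at 80 cm⁻¹ (single acquisition),
  divided by √n_averages for n coherently averaged acquisitions. There is
  no additive floor: the modeled measurement variance is dominated by
  alignment/position irreproducibility, which scales with signal.

What the generator does **not** emulate: baseline drift between reference
measurements, etalon fringes, pellet-scattering backgrounds, correlated
(non-white) spectral noise, and polymorph pairs. Passing tests therefore
demonstrate the statistical machinery recovers planted structure under the
stated noise model, not that real spectra of any compound family carry an
MP link of this strength.

## Numerical choices and problem sizes

- Distances/overlaps are computed in raw (not variance-rescaled) score
  coordinates, matching how such maps are plotted and compared.
- Leave-k-out is validated at 500 iterations for signal-vs-null contrasts
  and 5000 iterations for protocol-fidelity (bit-reproducibility and error
  bound) checks, both at n = 27 with k ∈ {4, 8}; permutation nulls use
  2000 draws. These sizes give Monte-Carlo error well below the effect
  sizes being asserted.
- Seeded `numpy` Generators drive every random draw; dataset generation
  spawns per-sample child seeds from a SeedSequence so results are
  bit-reproducible and order-independent.

## Limitations

PCA and PLS are linear; a genuinely nonlinear spectrum–property relation
will be underfit, and the observed relative errors (≈10–50% depending on
training-set composition) bound how far a linear model can support triage.
The concordance metrics quantify neighborhood agreement but do not identify
*which* chemistry drives it. Real-data absorbance extraction here stops at
the amplitude-ratio absorbance; no phase unwrapping or refractive-index
retrieval is performed.
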