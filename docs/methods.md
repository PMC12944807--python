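# Methods

## Spectra

A compound's vibrational spectrum enters as a line list: 3N−6 harmonic
modes, each a wavenumber (cm⁻¹, > 0) and a non-negative activity (IR
intensity, Raman activity, or unit weight for the vibrational density of
states). Continuous pseudo-spectra are produced by Gaussian broadening: a
Gaussian of standard deviation σ is placed on every mode and the sum is
sampled on a uniform grid.

- **σ = 10 cm⁻¹ (default).** A 10 cm⁻¹ width is the conventional choice for
  resolving fingerprint-region structure. Width specifications in the
  literature are sometimes FWHM rather than SD; here the parameter is the
  SD, and it is configurable (`BroadeningParams(sigma=...)`) so an FWHM
  convention can be emulated with σ = FWHM/2.355.
- **Amplitude convention.** Unit-area Gaussians scaled by the line
  intensity, so the integrated broadened spectrum equals the summed line
  intensities — a conserved quantity the tests verify to 1e-3 relative. A
  peak-height convention (`amplitude="peak"`) is available; Pearson
  correlation is scale-invariant, so the choice does not affect clustering
  of a single-σ pipeline.
- **Grid 400–1800 cm⁻¹, step 1 cm⁻¹ (default).** The classic fingerprint
  region is 600–1800 cm⁻¹, but the S–S stretch of dialkyl sulfides sits at
  452 cm⁻¹ and is one of the most odor-diagnostic bands in the benchmark,
  so the default lower bound is 400. Both bounds and the step are
  CLI-configurable; `window()` restricts to any narrower range.
- **−50 cm⁻¹ shift.** Harmonic DFT frequencies overestimate experiment by
  ≈50 cm⁻¹; `shift_frequencies(line, -50)` applies the rigid correction.
  Modes shifted to ≤ 0 cm⁻¹ are dropped with a warning rather than
  reflected. Because the shift is rigid and Pearson correlation is
  location-invariant only in intensity (not frequency), shifting all
  spectra identically does not change their pairwise correlations on a
  common full-coverage grid; it matters only near window edges.
- The same Gaussian broadening is used for IR, Raman and VDOS alike
  (uniform treatment keeps the three spectroscopies comparable).

## Similarity and clustering

The similarity between two spectra is Pearson's r between their intensity
vectors on the shared grid: subtract each spectrum's mean, multiply
deviations pointwise, sum, normalize by the standard deviations. A constant
(zero-variance) spectrum makes r undefined and raises an error naming the
compound.

- **Negative correlations.** A similarity graph needs non-negative
  affinities; by default negative r is clipped to 0 (`clip_policy="clip"`).
  The alternative rescaling (1+r)/2 (`"shift"`) is provided. The diagonal is
  forced to exactly 1, which also guarantees positive degrees.
- **Laplacian.** L_sym = I − D^{−1/2} S D^{−1/2}. It is symmetric PSD with
  eigenvalues in [0, 2]; √d spans the null space per connected component,
  and the multiplicity of eigenvalue 0 equals the number of components —
  both properties are tested.
- **Embedding.** The eigenvectors of the k smallest eigenvalues
  (scipy.linalg.eigh on the dense matrix; n is small here). Sign is fixed
  per column (largest-magnitude entry positive) for determinism; rotations
  within degenerate eigenspaces remain arbitrary, which the discretization
  is designed to absorb.
- **Discretization (Yu–Shi).** Rows of U are length-normalized; a k×k
  rotation is seeded with k mutually far rows (the first chosen by the
  seed); then alternate: assign each row to the argmax column of UR (ties →
  lowest index), and update R = VW^T from the SVD X^T U = W Σ V^T of the
  indicator matrix X. The loop stops when the sum of singular values
  changes by < 1e-7 or after 100 sweeps. An empty cluster triggers a
  restart with a fresh initial row (up to 30), then a degenerate-clustering
  error. A single integer seed controls everything; identical inputs and
  seed give identical labels.
- **Choosing k.** The mean silhouette coefficient, computed on the
  correlation distance 1 − r of the *unclipped* correlations — the space
  closest to the similarity the clustering consumed. (Euclidean distance in
  the embedding is a defensible alternative; it was not made the default
  because the embedding changes dimension with k, which makes silhouettes
  across k less comparable.) The default search range is k ∈ [2, 10],
  suited to the n = 25 benchmark scale; ties go to the smallest k.

## Agreement statistics

All comparison statistics are computed from the R×C contingency table of
two labelings, in natural logarithms (nats).

- MI = Σ (n_ij/n) ln(n·n_ij/(a_i b_j)).
- EMI is the expectation of MI under the permutation model: at fixed
  marginals, n_ij is hypergeometric, so EMI sums the MI kernel over the
  support max(1, a_i+b_j−n)..min(a_i, b_j) weighted by hypergeometric
  probabilities evaluated via log-factorials (scipy.special.gammaln). The
  implementation is numerically stable to n ≈ 1e4 and is verified against
  exhaustive enumeration of all n! permutations at small n.
- AMI = (MI − EMI)/(norm(H_a, H_b) − EMI). The normalization is the
  arithmetic mean of entropies by default — the common modern convention —
  with max, min and geometric also exposed. When the denominator is 0 with
  MI = EMI (both labelings trivial) AMI is defined as 0.
- Silhouette: s(i) = (b−a)/max(a,b) with a = mean within-cluster distance
  (self excluded) and b = smallest mean distance to another cluster;
  singletons and a = b = 0 score 0; the mean over points is reported.
  Precomputed-distance form only.
- For comparison against printed two-decimal reference values, AMI is
  rounded to 2 d.p.

**Which normalization reproduces the benchmark values.** The packaged IR
clustering vs the odor descriptors gives 0.4381 under the arithmetic
normalization — it is the arithmetic variant that reproduces the reference
value 0.44 (max: 0.38, min: 0.51, geometric: 0.44). For Raman the four
variants give 0.28/0.26/0.32/0.29 and for VDOS 0.24/0.17/0.37/0.25: *no*
normalization reproduces the reference value 0.33 for either. Since the IR
value reproduces exactly from the same descriptor table, the packaged
memberships and labels are internally consistent; the Raman/VDOS reference
scores appear not to correspond to the published group memberships (e.g.
they may stem from a different clustering run). The package reports the
honestly computed values and flags the mismatch in the `reproduce` table
rather than adjusting either input.

## Benchmark data

`vibroclust/data/odorants.csv` lists the 25 aroma-active compounds of six
flower species (three Orchidaceae, three Apocynaceae) with a seven-word
odor-descriptor vocabulary (fruit ×4, wood ×3, sweet ×5, spices ×5,
flower ×2, garlic ×2, decayed ×4) and relative contents per species.
`reference_clusterings.json` holds the reported spectral-clustering
partitions: IR (6 groups), Raman (6), VDOS (5). Loaders validate that each
partition is exhaustive and disjoint over compounds 1–25. The descriptor
words are taken verbatim; no synonym re-mapping. The underlying DFT spectra
are not publicly deposited, so the reported silhouettes (0.48/0.51/0.57)
and the selected cluster counts cannot be recomputed from spectra here;
the synthetic planted-partition experiments below stand in for end-to-end
validation.

## Synthetic data generator

The generator emulates line spectra of five odorant classes via band
templates (`data/class_templates.yaml`): sulfide (452, 963, 1344,
1470 cm⁻¹), aromatic carbonyl (C=O 1750–1780, ring C–C ≈1600, out-of-plane
C–H ≈750), aliphatic aldehyde (dominant carbonyl ≈1800, weak CH bends),
terpene (=CH₂ 900–950, CH₂ twist/wag 1000–1400, scissoring 1450–1500, C=C
1650–1700) and N-heterocycle (dominant ≈750, ring stretches 1300–1550).
Ranges become midpoint centers with the half-width folded into the jitter
SD. Noise model: band presence is Bernoulli, frequency jitter Gaussian,
intensity multiplicative lognormal (positivity preserved), plus a handful
of weak background modes uniform over the grid range — the simplest
positive/symmetric choices, stated so they are testable. Intensity means
are order-of-magnitude synthetic estimates (the data file says so); no
IR-vs-Raman activity modeling is attempted — one template set serves all
kinds, with VDOS collapsing to unit weights.

Everything is driven by a single integer seed (NumPy Generator; per-compound
child seeds drawn from a master stream), so datasets are bit-reproducible.
`noiseless()` strips all stochastic elements for exact-recovery tests.

What passing the planted-partition experiments shows: the pipeline
separates classes whose band structure differs at the chosen jitter, and
recovery degrades monotonically with jitter (mean AMI over 20 seeds falls
across jitter 2 → 10 → 30 → 80 cm⁻¹). What it does not show: performance on
real DFT spectra, whose within-class variability is structured (conformers,
coupling, mode mixing) rather than independent Gaussian jitter, and whose
between-class contrasts are weaker than clean template bands.

## Problem sizes

The validation experiments use the benchmark scale throughout: 25 compounds
(5 classes × 5), grid 400–1800 cm⁻¹ at 1 cm⁻¹, k searched over [2, 10],
20 seeds per experimental condition; oracle cross-checks use 100 random
labeling pairs (n ≤ 50) and 50 planted similarity instances (n ≤ 24).

## Known limitations

- Raman/VDOS reference AMI values are not reproducible from the packaged
  memberships (see above); the discrepancy is reported, not patched.
- The discretization objective is non-convex; different seeds can yield
  different local optima on weakly structured similarity matrices. The
  seed is part of every result file.
- The silhouette-based k selection inherits silhouette's bias toward
  compact, well-separated clusters; on spectra with one diffuse class it
  can prefer merging it.
- No anharmonic corrections, no parsing of quantum-chemistry output files,
  no JCAMP-DX support.
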