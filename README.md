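# vibroclust

Spectral clustering of molecular vibrational spectra for odorant
classification.

Floral odorants — terpenes, aromatic carbonyls, sulfides, aldehydes,
N-heterocycles — carry characteristic vibrational signatures in the
mid-infrared fingerprint region. If olfaction is sensitive to molecular
vibrations, molecules whose IR/Raman spectra look alike should tend to smell
alike. `vibroclust` provides the full computational chain to test that idea
on any set of compounds with computed or measured vibrational line spectra:

1. **Broadening** — each line spectrum (3N−6 modes, frequency + activity) is
   convolved with a Gaussian of width σ = 10 cm⁻¹ and sampled on a uniform
   wavenumber grid (default 400–1800 cm⁻¹), optionally after the −50 cm⁻¹
   rigid shift that corrects harmonic DFT frequencies.
2. **Similarity graph** — pairwise Pearson correlation r between intensity
   vectors; negatives are clipped to zero so S is a non-negative affinity
   with unit diagonal.
3. **Spectral clustering** — the symmetric normalized Laplacian
   L<sub>sym</sub> = I − D<sup>−1/2</sup> S D<sup>−1/2</sup>
   (D = diag of row sums of S) is eigendecomposed; the k lowest eigenvectors
   embed the compounds in ℝ<sup>k</sup>, and hard labels come from the
   Yu–Shi discretization (alternating SVD rotation updates and per-row
   argmax / non-maximum suppression). k is chosen by the mean silhouette
   coefficient on the correlation distance 1 − r.
4. **Agreement with odor** — adjusted mutual information (AMI) between the
   cluster labels and categorical odor descriptors, with the expected MI
   under the hypergeometric permutation model removed, so chance ≈ 0 and
   identity = 1:
   AMI = (MI − E[MI]) / (mean(H(U), H(V)) − E[MI]).

All statistics (MI, EMI, AMI in four normalizations, silhouette on
precomputed distances) are implemented from first principles; scikit-learn
appears only as an independent cross-check in the test suite.

The package also ships two datasets:

- `vibroclust.datasets` — a 25-compound benchmark: the aroma-active
  compounds of three Orchidaceae and three Apocynaceae species with their
  literature odor descriptors (fruit, wood, sweet, spices, flower, garlic,
  decayed) and the literature-reported IR/Raman/VDOS cluster memberships.
- `vibroclust.synthetic` — a generator of labeled synthetic odorant line
  spectra built from functional-group band templates (e.g. the S–S stretch
  at 452 cm⁻¹ for sulfides, the dominant carbonyl near 1800 cm⁻¹ for
  aliphatic aldehydes), used for planted-partition validation of the whole
  pipeline.

## Worked example

Generate a small synthetic dataset of three odorant classes, cluster it with
automatic k selection, and score the result against the ground truth:

```sh
$ vibroclust synth --classes sulfide,aromatic_carbonyl,aliphatic_aldehyde \
      --n-per-class 4 --jitter 2 --seed 0 --out demo
INFO wrote 12 spectra + truth.csv to demo

$ vibroclust cluster demo --k auto --k-max 6 --seed 0 --out result.json
INFO loaded 12 line spectra from demo
INFO grid 400.0..1800.0 step 1.0 (1401 points)
INFO k=3 silhouette=0.9169 eigenvalues=[0.0, 0.0037, 0.0556]
INFO result written to result.json
```

The silhouette of 0.92 says the three clusters are tight and well separated
in correlation distance; the three near-zero Laplacian eigenvalues reflect
three nearly disconnected blocks in the similarity graph. Scoring the
labels in `result.json` against `demo/truth.csv`:

```sh
$ vibroclust ami labels.csv demo/truth.csv
...
"ami_by_normalization": {"arithmetic": 1.0, "geometric": 1.0, "max": 1.0, "min": 1.0}
```

AMI = 1.0: the clustering recovered the planted classes exactly.

The packaged benchmark table is printed by:

```sh
$ vibroclust reproduce
kind    k    arithmetic         max         min   geometric   reference   match
IR      6        0.4381      0.3816      0.5142      0.4411        0.44    True
...
```

For the IR clustering the arithmetic-normalized AMI of 0.44 indicates that
odor categories are partially — far from randomly — represented in the
infrared spectra of the 25 benchmark odorants.

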