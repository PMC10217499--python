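# fishspec

Chemometric analysis of single-fibre FTIR micro-spectra of fish muscle:
predicting how long a fillet has been stored on ice and identifying which
spectral bands mark freshness or aging.

## Scientific problem

During cold storage, fish muscle degrades: nucleic acids and proteins are
broken down by endogenous enzymes, proteins aggregate into antiparallel
β-sheet structures, and lipids oxidise. Each of these processes leaves a
signature in the mid-infrared fingerprint region (900–1780 cm⁻¹) of an FTIR
absorbance spectrum measured on a single muscle fibre. Two questions follow:

1. **Prediction** — can the postmortem day (0, 1, 3, 5, 7, 9 or 15 days on
   ice) be read from a single-fibre spectrum?
2. **Interpretation** — which wavenumbers carry that information, and what
   biochemistry do they correspond to?

`fishspec` answers both on synthetic but biophysically structured data. A
generator produces full measurement campaigns (multiple fish, dozens of
fibres per fish and day, realistic band structure, baseline drift,
thickness scaling, fish/fibre heterogeneity and noise), and the analysis
stack mirrors the standard chemometric workflow for such data.

## The model

The interpretive core is **principal component discriminant analysis
(PC-DA)**. Spectra are baseline-corrected (iterative modified-polynomial
fitting), cropped to the fingerprint region and vector-normalised. PCA
compresses the n×p matrix to k score vectors, and a Fisher discriminant is
fitted in score space: for groups with PC-space means *m₁, m₂* and pooled
within-group covariance *W*, the canonical axis is

> **w** = W⁻¹(m₁ − m₂)   (two groups; generalised eigenproblem for more)

Back-projecting through the PCA loadings *L* gives the **F1 contribution
vector** F1 = **w**ᵀL, a function of wavenumber whose extrema localise the
discriminating bands — positive peaks are elevated in the first group
(fresh), negative peaks in the second (aged). The identity
score(x) = F1·(x − mean) holds exactly, so the spectral-domain vector is a
faithful picture of what the classifier uses. Group membership is a
softmax over Mahalanobis distances to the group means.

For pure prediction the package uses an RBF-kernel SVM (with per-feature
standardisation) under stratified k-fold cross-validation, plus t-SNE
embeddings for visual inspection. A band-assignment table, peak/ratio
extraction, one-way ANOVA with Tukey post-hoc letters, and a correlation
routine against physicochemical measurements (pH, protein solubility,
colour, proteolysis) complete the marker-analysis side.

## Worked example

```python
import fishspec as fs

cfg = fs.default_scenario("paper_effects")   # 3 fish x 39 fibres x 7 days
cfg.seed = 42
raw = fs.generate_spectra(cfg)
print("raw:", len(raw), "spectra x", raw.grid.size, "points")
# raw: 819 spectra x 951 points

pre = fs.preprocess(raw)                     # baseline, crop, normalise
print("preprocessed:", pre.intensities.shape)
# preprocessed: (819, 441)

res = fs.fit_pcda(pre.subset_days([0, 7]), (0, 7))
print(res.summary())
```

```
PC-DA results
==============================================
groups:            D0 (n=117), D7 (n=117)
retained PCs:      1
variance captured: 0.946 of total (0.007235 leading eigenvalue)
ridge:             1e-06
canonical axes:    1
resubstitution accuracy: 100.0%
  D0: canonical score +4892.446 +/- 70.618
  D7: canonical score -4892.446 +/- 120.759
```

```python
print(res.f1_vector().extract_biomarkers().head(6).to_string(index=False))
```

```
 wavenumber         score associated_group
     1552.0  11233.770099               D0
     1670.0 -10377.478522               D7
     1634.0   7166.027241               D0
     1176.0   7004.112948               D0
     1248.0   4222.617417               D0
     1490.0  -3837.833783               D7
```

The top freshness markers sit at the α-helical amide bands (1552, 1634),
the nucleic-acid bands (1176, 1248); the aging side is dominated by
antiparallel β-sheet aggregation (1670, 1490) — see
`fs.load_band_table()` for the full assignment table.

Day prediction over all seven storage days:

```python
rep = fs.svm_cv(pre, folds=10, seed=42)
print(rep.summary())
```

```
SVM 10-fold CV (seed 42, C=1.0, gamma=scale)
==================================================
      D0   D1   D3   D5   D7   D9  D15
D0   116    1    0    0    0    0    0
D1     0  117    0    0    0    0    0
D3     0    0  102   15    0    0    0
D5     0    0    4  113    0    0    0
D7     0    0    0    0  109    8    0
D9     0    0    0    0    9  108    0
D15    0    0    0    0    0    0  117

per-class accuracy (%): D0: 99.1  D1: 100.0  D3: 87.2  D5: 96.6  D7: 93.2  D9: 92.3  D15: 100.0
overall accuracy: 95.5%
```

Misclassifications fall almost exclusively between adjacent days, as
expected for a gradual degradation process.

The same pipeline is available from the shell via the `fishspec` command
(`simulate`, `preprocess`, `pcda`, `svm-cv`, `embed`, `markers`,
`correlate`; each accepts `--help`).

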