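# Methods

What `subnucpred` computes, which conventions it fixes where several are
defensible, and where its synthetic scope ends.  The package predicts a
protein's subnuclear localization class from primary sequence alone; no
alignments, homology searches or structure are used.

## 1. Sequence handling

Sequences are restricted to the 20 standard residues (order
`ACDEFGHIKLMNPQRSTVWY` everywhere).  Two input policies:

* `strict` — any other character is an error;
* `clean` (default) — ambiguity codes are resolved conservatively
  (B→D, Z→E, U→C, J→L), while `X`, `O`, `*` and gap characters are
  dropped.  A sequence that cleans to nothing is an error.

Labels live in a sidecar TSV (`id<TAB>label[,label…]`); multi-label
records are kept for the any-match evaluation criterion but excluded from
training (`Dataset.single_label_subset`).  Class order follows first
appearance in the FASTA, so the label-file line order is irrelevant.

## 2. Feature extractors

### Reduced-alphabet extractors

Twenty residue classification schemes are shipped
(`data/classification_schemes.tsv`): hydrophobicity-based 2/5-letter
alphabets, structure- and contact-derived 4–12 letter alphabets, the
identity 20-letter alphabet, and seven 3-group physicochemical splits of
the composition/transition/distribution (CTD) tradition.  Three rows of
the printed source table were defective (two residues missing in one
scheme, one in another, a duplicated residue in a third); they were
repaired against the standard CTD groupings, and the repairs are recorded
in the data file header.

* **LAAC** — group composition over the N-terminal 60 and C-terminal 15
  residues (windows truncate on short sequences): 2k features per scheme.
* **LDC** — ordered dipeptide group composition over the same windows,
  2k² features; computed over a bounded default subset of six schemes
  (k ≤ 8) because the quadratic growth is pure noise for large k.
* **GD** — global composition (k), transitions (unordered unequal
  adjacent pairs over L−1 slots; k(k−1)/2) and distribution (relative
  position of the first, 25%, 50%, 75% and last occurrence per group,
  ceil-quartile convention, zeros for absent groups; 5k).
* **LZC** — Lempel-Ziv 1976 exhaustive-history complexity of the reduced
  string, one feature per scheme, normalized by sequence length by
  default so complexity is not confounded with length.  The classic
  worked example `0001101001000101 → 6` is pinned in the tests, and the
  implementation is checked against an independent pointer-scan oracle on
  every string up to length 10 over alphabets up to size 3.

### Physicochemical-property extractors

`data/physchem_properties.tsv` holds 29 distinct AAindex scales (30 table
slots; one accession legitimately occupies two slots of the original
30-property design).  Values were exported from the `aaindex` dataset of
the locally installed R package **seqinr 4.2-36** — a faithful snapshot
of the AAindex database — not hand-typed.  Property scales are
standardized to mean 0, sd 1 over the 20 residues (population sd,
divisor 20) before signal encoding, except where a method requires raw
values (PPDD).

* **AD** — Moreau-Broto (`(1/(N−d)) Σ x_i x_{i+d}`), Moran (variance
  divisor N) and Geary (divisor N−1) autocorrelations, lags 1–30 over all
  30 slots: 3 × 900 = 2700 features.  Constant signals return 0 by
  convention wherever a variance denominator would vanish.
* **AC** — autocovariance, same grid, 900 features.
* **SD** — sequence-order coupling numbers τ₁…τ₃₀ plus 50
  quasi-sequence-order descriptors per distance matrix (first 20 =
  weighted composition, remaining 30 = w·τ terms; shared denominator
  Σf + w Στ, w = 0.1), over two matrices: 160 features.  With w = 0 the
  first 20 descriptors reduce exactly to amino-acid composition (tested).
  The Grantham matrix is reconstructed from its published closed formula
  (spot-checked against printed values; one cell differs by 1 from some
  printed tables due to rounding).  A true Schneider-Wrede matrix was not
  available offline; the packaged `schneider_wrede_synthetic.tsv` is a
  **clearly-labeled synthetic stand-in** with the right structural
  properties (symmetric, zero diagonal, unit scale), adequate for
  exercising the code path but not for biological interpretation.
* **PPDD** — encode with the raw property, average all overlapping
  4-mers, z-score against the property's own 20-residue mean/sd, and
  histogram into 18 bins: open tail below −4, sixteen half-width bins on
  [−4, 4), open tail above.  Frequencies sum to 1.

### Signal-analytic extractors

All three operate on the standardized property signal of each scale.

* **RQA** — delay embedding m = 4, τ = 1; recurrence threshold ε = 0.2 ×
  mean pairwise point distance; 14 variables (RR, DET, meanL, Lmax, DIV,
  ENTR over diagonal lines; LAM, TT, Vmax, ENTR over vertical lines;
  RATIO, TREND, T1, T2).  Convention: diagonal-line statistics exclude
  the main diagonal (self-recurrence carries no information), vertical
  statistics include it; minimum line length 2; degenerate denominators
  yield 0.  Equivalence with an independent run-length enumeration is
  verified over **all** 65 536 binary 4×4 matrices.
* **DWT** — `bior3.1` wavelet, 5 decomposition levels, symmetric
  padding; max/mean/min/sd of the approximation and each detail band
  (24 features per property).  Signals too short for 5 levels are
  decomposed as deep as allowed and the missing scales zero-padded, so
  the dimension is invariant; signals shorter than the filter are an
  error.
* **HHT** — in-package empirical mode decomposition (cubic-spline
  envelopes anchored at the signal endpoints, Cauchy-type sifting stop
  SD < 0.2, at most 10 siftings and 10 modes).  Per property: 4
  statistics of the first 6 intrinsic mode functions (zero-padded) plus
  the Hilbert-Huang spectral entropy — normalized Shannon entropy of the
  marginal Hilbert amplitude spectrum on 64 bins over (0, 0.5]
  cycles/residue.  Reconstruction (Σ modes + residual = input) is exact
  to machine precision; monotone signals yield zero modes and a zero
  entropy slot.  A third-party EMD package was not available in the
  pinned environment, which is why the decomposition is implemented here.

## 3. Feature selection

Per binary class pair, two steps:

1. within each method block: mRMR ranking (features discretized into
   three bins at mean ± sd; greedy maximization of I(f; y) − mean
   I(f; selected), mutual information in nats) followed by incremental
   feature selection (IFS) over nested top-k subsets (k = step, 2·step, …,
   cap) scored by stratified 5-fold CV accuracy of an RBF SVM;
2. the union of the per-block winners is re-ranked and searched the same
   way.

Ties break toward the smaller subset, then the smaller C, then the
smaller gamma — a deliberate parsimony preference.  The RBF width is
chosen automatically unless a grid is given: gamma = 1/(2σ²) with σ the
mean pairwise Euclidean distance of the candidate matrix (GFO); identical
samples make σ = 0 an error rather than a silent fallback.

## 4. Ensemble

Stage 1: one probabilistic (Platt-scaled) binary RBF SVM per unordered
class pair on its own optimal subset.  The k(k−1)/2 pairwise
probabilities are coupled into a k-vector by the Wu-Lin-Weng second
method (the LIBSVM fixed-point iteration, tolerance 0.005/k); k = 2
reduces to [p, 1−p] exactly.  Stage 2: a conventional one-against-one
multiclass RBF SVM over the coupled probability vectors (C searched on
the same grid, GFO gamma; no feature selection — the input is already
k-dimensional).  Class imbalance is handled at both stages by weighting
each class by largest-class-size / class-size; the {100, 20} design
yields a minority weight of exactly 5.

For leave-one-out model aggregation (`finalize`) the per-pair subset is
the union of all turn-optimal subsets and (C, gamma) the log2-space means
of the turn optima, then the system is retrained on the full data with
those frozen choices.

## 5. Evaluation

One-vs-rest confusion counts per class; OA, sensitivity, specificity
(TN/(TN+FP)), precision and MCC (0 when the denominator vanishes — and
both specificity and precision are reported because published "Sp"
figures for this problem are consistent with either under imbalance).
ROC/AUC per binary member via the trapezoid rule; AUC is verified
against the Mann-Whitney U statistic.  Multi-localization accuracy uses
the any-match criterion: a prediction is correct if it is one of the
annotated locations.  The jackknife harness refits the entire trainer —
including ranking and selection — on every leave-one-out turn, so the
held-out sample can never leak into selection (audited by an
instrumented trainer in the tests).

Two randomization controls probe whether selected features carry real
class information, both with frozen hyperparameters: label permutation
(50 rounds) and random feature subsets of ¼, ½ and 1× the optimal size
drawn from a feature pool (50 rounds per fraction).

## 6. Synthetic data generator

Classes are generated from Dirichlet-drawn residue frequency vectors
(concentration 150/30/6 for low/medium/high separation — lower
concentration pushes compositions apart) with, at high separation, a
distinct 10-residue N-terminal motif per class inserted with probability
0.9 (a crude stand-in for targeting-signal content).  Residues are
otherwise i.i.d.; lengths uniform in 120–300 (minimum 80 enforced so the
default windows and lags are satisfiable).  The generator reproduces
composition and local-motif signal and **nothing else** — no long-range
correlation, no domain structure, no homology — so absolute accuracies on
it say nothing about real proteins; it exists to verify that the pipeline
recovers a known signal and collapses to chance when the signal is
destroyed.

Default experiment fixture: k = 4, 30 sequences per class, high
separation, seed 20130227.

## 7. Problem sizes and runtime choices

The full 11-method, cap-300 configuration is supported but expensive;
the packaged experiments fix a smaller, pre-registered condition set
chosen for a minutes-scale leave-one-out run on one CPU **before any
outcome was measured**: methods laac+gd, mRMR cap 40, IFS step 10,
C grid {0.5, 8, 128}, automatic GFO gamma, 5-fold inner CV.  Under these
conditions the 120-sequence LOOCV (with per-turn selection) takes about
4 minutes.

## 8. Known limitations

* The Schneider-Wrede matrix is synthetic (see §2); Grantham is an exact
  reconstruction up to ±1 rounding in isolated cells.
* The EMD implementation uses a simple endpoint-anchored envelope rather
  than mirror extension; adequate for feature extraction, not a general
  signal-processing tool.
* Sequences shorter than 31 residues cannot produce lag-30
  autocorrelation or sequence-order features; the generator enforces
  length ≥ 80, real data would need filtering.
* `SVC(probability=True)` is deprecated in scikit-learn 1.9; the package
  silences that specific warning at the fit site and will need migrating
  to `CalibratedClassifierCV` when support is removed.
* No redundancy filtering (CD-HIT-style identity culling) is provided;
  synthetic data has no homology to cull.
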