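# Methods

`clonerx` predicts clone-specific drug and dose options for a cancer sample
from a single scRNA-seq count matrix, then pairs the top predictions for two
malignant subclones into candidate two-drug regimens.  This note documents
the model, the assumptions behind each stage, the synthetic study conditions
used by the tests, and the design choices made where the design was open.

## 1. The prediction model

### Training corpus

The regressor learns from matched triads *(perturbation signature,
interpolated inhibition, drug fingerprint, dose)*:

* a **perturbation signature** is the log2 fold-change vector of a landmark
  gene panel after treating a cell line with a drug at a dose (the in-memory
  analogue of an L1000-style profile);
* the **inhibition label** is `100 − viability`, where viability is read off
  that (drug, cell line)'s multi-dose viability curve *at the perturbation
  dose* by linear interpolation in log10-dose, clipped to [0, 100].  Doses
  outside the measured span are skipped, never extrapolated: extrapolating
  sigmoid tails would invent data.  Raw measured points are interpolated
  directly (no 4PL refit at this stage) — the simplest faithful reading of a
  dose-matching step; 4PL fitting lives in the pharmacometrics module where
  it is actually needed;
* the **fingerprint** is a fixed-length binary vector with circular-
  fingerprint semantics (ECFP4 via RDKit in real-SMILES mode; synthetic bits
  from the generator otherwise).  Viability above 100% (growth stimulation)
  maps to 0 inhibition so the regression target stays bounded.

### Regressor

A LightGBM gradient-boosted tree ensemble maps
`signature ⊕ fingerprint ⊕ log10 dose → inhibition %`.  Hyperparameters are
chosen by randomized search (default 8 draws from the grid in
`model.DEFAULT_PARAM_GRID`) scored by grouped 3-fold CV RMSE.  All CV folds
are grouped by (drug, cell line) pair so no pair appears on both sides of a
split — the leakage mode that matters here, since the same pair contributes
several doses.  Predictions are clipped to [0, 100] (bounded percentages).
Fits are deterministic under a fixed seed (single-threaded, deterministic
histogram construction, seeded fold shuffles).

### Conformal confidence

After tuning, a repeated grouped CV (3 repeats × 10 folds) with the winning
configuration pools out-of-fold absolute errors into a split-conformal
calibration set.  The 90th-percentile residual is the interval half-width
*h*, and every prediction carries `confidence = 1 − h/100`.  This is a
single global (not locally adaptive) nonconformity scale: the simplest
construction whose marginal coverage guarantee (~q on exchangeable data) is
testable.  Predictions with confidence < 0.8 are discarded.  The published
filter description ("nonconformity score < 0.8 excluded") is ambiguous —
low nonconformity normally means *high* confidence — so the filter is
implemented and documented as "confidence < 0.8 excluded" and not silently
reinterpreted elsewhere.  A 1 µM dose cap (boundary inclusive) removes
high-dose predictions when ranking over a predefined dose grid, favouring
tolerable, selective options.

## 2. Patient pipeline

1. **QC** — drop cells with detected genes outside [200, 6000] (configurable;
   no universal published bounds exist) or mitochondrial fraction above 10%
   (20% in organoid mode).  Mitochondrial genes are recognized by the `MT-`
   symbol prefix.
2. **Normalization** — counts per 10,000, log1p.
3. **Clustering** — PCA (30 components), kNN graph, Leiden community
   detection.  Leiden is used as the modern successor of Louvain with the
   same contract (graph community detection, deterministic under seed).
4. **Cell-type annotation** — specificity-weighted marker scoring: each
   marker's standardized expression is weighted by `1 − (k−1)/(K−1)` when
   listed by *k* of *K* cell types (a marker shared by all types is inert);
   a cluster whose best score is below `n_cells/4` is "Unknown".  Built-in
   marker sets cover the leukemia path (blast markers CD33/CD34/CD38/PROM1/
   ENG/CD99/KIT vs T-cell anchors) and the ovarian path (PAX8/MUC16/EPCAM/
   WFDC2).
5. **CNV profiles** — genes ordered along the genome, expression centred on
   the normal-anchor gene means, moving-average smoothed *within each
   chromosome arm* (window 101, clamped to arm length and kept odd),
   winsorized at ±3 reference SD, summarized as per-arm segment means.  This
   is a deliberately simplified analogue of HMM-based CNV callers: it
   delivers the same contract (per-cell profiles, arm segments, clades)
   without modelling discrete copy states.  Smoothing stays inside arms
   because arm-level events are the target resolution.
6. **Malignancy ensemble** — majority vote of three classifiers:
   (i) marker-based call; (ii) cluster-level aneuploidy: the largest
   standardized arm deviation of each expression cluster,
   `max_a |mean_a|·√n / sd_a(ref)`, against a Gaussian family-wise null at
   α = 0.01; (iii) two-way grouping of cluster-level CNV deviation scores,
   near-zero group called diploid.  Votes (ii) and (iii) are computed per
   expression cluster and broadcast to member cells: single cells at
   realistic gene counts carry too little arm-level signal for individual
   calls (measured during development: normal vs clone per-cell RMS scores
   overlap almost completely), and the reference CNV tools likewise classify
   clusters.
7. **Subclones** — malignant cells' arm-level profiles are centred per cell
   (removing a global composition factor that otherwise dominates the top
   principal component), projected onto the two leading PCs, Ward-clustered,
   cut into two clades and polished by one Gaussian-mixture refinement.  The
   two largest clades (ties broken by lower mean intra-clade distance)
   become subclones A and B; clades under 5% are "minor".  Degeneracy is
   declared when the top-two eigenvalue ratio of the centred profiles is
   below 2.0 — a clonally homogeneous population has no dominant variance
   direction (ratio ≈ 1.1 in simulation) while two planted clones give ≈ 3.3
   — and the pipeline then falls back to monotherapy mode.  The emitted
   Newick tree uses clone fractions as branch lengths (dominance, not a
   molecular clock).  Automating the two-broad-clade choice replaces a
   visual-analysis step that is not reproducible programmatically.
8. **Signatures** — per clone vs patient-matched normal cells: log2 fold
   change of `mean(expm1)+1`, two-sided Wilcoxon rank-sum p, BH q.  Genes
   expressed in < 10% of both groups or with |log2FC| < 0.25 are excluded
   (the defaults of the standard single-cell DE tooling, which the published
   workflow cites without parameters).  Non-landmark genes are dropped and
   missing landmarks imputed 0 when the vector is handed to the model.

### Monotherapy fallback

When the malignant fraction is below 10%, fewer than 40 malignant cells
remain, or subclone detection is degenerate, all malignant cells are pooled
into one signature and the top-20 single agents are reported instead of
combinations — subdividing a scarce cancer population adds noise faster
than signal.

## 3. Therapy ranking and combinations

The clone's cancer-vs-normal signature is **negated** before scoring: the
model input is the desired transcriptional change (normal − cancer), so
drugs whose induced perturbation matches that reversal score high.  Every
(drug, dose) pair in the library is scored, conformal-filtered and
dose-capped; per drug the best surviving dose is kept (ties → lower dose,
then drug id) and drugs are ranked by predicted inhibition.

Combination plans pair the top-k (default 6) drugs of the two subclones,
excluding same-drug pairs (a drug is never paired with itself), ranked by
the unweighted mean of the two predicted inhibitions — no pair-scoring
formula is published, and the mean is symmetric and monotone in both
components.  Each drug carries a dose bracket one dilution step above and
below the predicted dose for experimental follow-up.  An optional
selectivity filter can drop drugs predicted ≥ 50% inhibition against a
normal-cell signature; it is off by default because that readout is an
experimental, not computational, criterion.

## 4. Pharmacometrics

* **Percent inhibition**: `100·(DMSO − raw)/(DMSO − BzCl)`; deliberately
  unclipped so over-killing (> 100%) stays visible as an assay artifact.
* **4PL fit**: least squares in log10-EC50 with multi-start initials,
  asymptotes softly bounded to [−10, 110]; on failure a monotone linear
  interpolant is substituted and flagged.  A flat response reports slope 0.
* **ZIP synergy**: 4PL fits to the two monotherapy margins; zero-interaction
  expectation at each interior cell is the Bliss surface of the fitted
  fractional effects `f1 + f2 − f1·f2`; the score is the mean observed −
  expected over interior cells (optionally a dose window around the
  predicted effective doses), × 100.  This Bliss-referenced delta form —
  not the full potency-shift refit of the original ZIP formulation — is
  exactly 0 on any surface generated under Bliss independence from its own
  margins, which is the property the validation uses.
* **DSS**: `∫ max(0, I(d) − t) dlog10(d)` over the tested range, normalized
  by `(100 − t)·range`, × 100, with activity threshold t = 10.  The
  published description ("normalized area under the dose-response curve")
  does not resolve the DSS1/2/3 variants; this threshold-integral form is
  the common core of all three.
* **ROC/AUC**: rank statistic with tie correction; **DeLong**: paired AUC
  comparison via placement-value covariance, two-sided.

## 5. Synthetic study conditions

The generator produces every input the pipeline needs; its defaults *are*
the test conditions.

**Reference corpus** — 50 drugs × 20 cell lines × 8 log10-spaced doses
(10⁻³–10 µM, mirroring 10-fold dilution practice), landmark panel of 200
genes (a fast stand-in for the ~1000-gene commercial panel), 256 fingerprint
bits, viability noise SD 5%, signature noise SD 0.1 log2 units.  Per-drug
Hill parameters: EC50 log-uniform in [0.01, 10] µM, slope in [0.7, 2.5],
maximal inhibition in [60, 100]%.  Drugs belong to one of 10 **mechanism
templates**: a template defines a 10-gene module with signed effects
(|log2FC| 1–3 at full inhibition) and a fingerprint scaffold from which
member drugs differ by 5% random bit flips.  Per (drug, cell line), EC50 is
jittered (log10 SD 0.15) and a sensitivity factor in [0.3, 1] scales the
attainable inhibition; the signature magnitude tracks the *realized*
inhibition.  These two structural choices are load-bearing: shared
scaffold/module templates encode "similar structures hit similar targets"
(the premise of fingerprint featurization), and cell-line-dependent
sensitivity makes the fingerprint genuinely informative — without them the
signature alone saturates the training signal and library ranking at
patient time would be information-free.

**Patient samples** — 1000 cells × 1500 genes; negative-binomial counts
(per-gene dispersion log-normal around 0.3 — simple and overdispersed like
real scRNA counts) over log-normal library depths (mean 4000).  Clone
fractions 40% normal / 35% clone A / 25% clone B.  Clone A carries a 1.5×
gain on 1p and 0.5× loss on 7q; clone B a 1.5× gain on 3q and 0.5× loss on
10p — arm-level copy ratios multiply the baseline gene means.  Malignant
cells overexpress blast markers and normal cells T-cell markers (8-fold).
When a reference corpus is supplied, each clone additionally carries the
transcriptional program *opposed* by one drug-class template (the most
potent templates, by median EC50, are assigned first — the planted
vulnerability should be druggable under the 1 µM cap).  Ten genes with the
`MT-` prefix receive 5% of counts (15% in a random 5% of cells) so QC is
exercisable.  Genes are placed contiguously on 44 chromosome arms in a
seeded random order.

**What the generator does not emulate** — batch effects, doublets, ambient
RNA, cell-cycle structure, realistic gene-gene correlation, dropout beyond
NB sampling, inter-patient variation in marker expression.  Passing tests
therefore demonstrate that the algorithms are correct and recover planted
structure under realistic noise levels; they do not demonstrate performance
on real patient data.

## 6. Numerical choices and degenerate inputs

* Interpolation requires ≥ 2 distinct positive doses; queries outside the
  measured span raise (and are skipped with a logged count during joins).
* All doses are µM on ingestion.
* The fit refuses < 100 training rows or fewer groups than folds; identical
  cells short-circuit clustering to a single community; QC that removes all
  cells, missing normal anchors (< 20 cells), groups of < 3 cells for DE,
  < 40 malignant cells for subclones, and degenerate plate controls all
  raise typed errors rather than producing silent output.
* The problem sizes above were chosen so a full acceptance run (two model
  fits, ten patients, 200 synergy surfaces) completes in a few minutes on a
  single core.

## 7. Known limitations

* The conformal confidence is global: every prediction from one model run
  shares the same half-width, so the 0.8 filter acts model-wise rather than
  per-drug.  Locally adaptive nonconformity would differentiate drugs but
  has no testable contract here.
* CNV calling is expression-derived and cluster-level; subclonal events
  smaller than an expression cluster, or copy-neutral events, are invisible.
* The two-subclone limit is structural; minor clades are labeled but not
  targeted.
* Real-data ingestion (GCTX perturbation archives, pharmacogenomic APIs,
  compound databases) is out of scope; the CSV/MTX schemas documented in
  the README are the ingestion surface.
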