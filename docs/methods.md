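# Methods

This note documents the models, rules and numerical choices behind
`fiamrm`, in the spirit of a statistics package's methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Identifier chain and library

A metabolite record is resolved KEGG → PubChem SID → neutral-form CID
(SMILES, formula, molecular weight) → ChEMBL → per-group predicted pKa
values. Each link may answer "absent"; everything downstream of an absent
link stays absent and is never back-filled. Transport failures are a
distinct, retryable error so that a flaky mirror is never confused with a
missing cross-reference. Funnel statistics count a record at a stage only
when every upstream link resolved, which makes the counts non-increasing by
construction. The library persists as UTF-8 TSV with a fixed column order;
floats are encoded with Python's shortest round-trip `repr`, which makes
write → read → write byte-stable.

Live REST clients are deliberately out of scope: resolution chains depend
on database versions and are not reproducible at desk scale, so the fetcher
contract is satisfied by local tabular dumps (and, in tests, by fixture
fetchers).

## Ionization classification

pKa values are per-functional-group constants, not whole-molecule
constants. The strongest group governs: a = min over acidic pKa, b = max
over basic pKa. With cuts acid_cut = 6.5 and base_cut = 8.5:

| condition                     | class       | ESI mode            |
|-------------------------------|-------------|---------------------|
| no pKa data                   | unclassified| excluded            |
| a < 6.5, b absent or ≤ 8.5    | acid        | negative            |
| b > 8.5, a absent or ≥ 6.5    | base        | positive            |
| a < 6.5 and b > 8.5           | amphoteric  | both, deferred      |
| all remaining (weak groups)   | neutral     | by weak group(s)    |

Boundary equality counts as "weak" (not beyond the cut). Neutral
metabolites with only a weak acidic group go negative, only a weak basic
group positive, both weak groups to both modes with the decision deferred.
The rule table partitions the (a, b) plane completely — asserted over a
grid straddling both cuts — and is monotone: strengthening an acidic group
never moves a molecule off the acidic side.

The strongest-group aggregation and the treatment of boundary equality are
design choices; both cuts are configurable (`ClassifierThresholds`).

## Spectrum comparison

Predicted spectra arrive as text blocks headed `energy0/1/2` (or
low/medium/high), mapping to |CE| = 10/20/40 V signed by polarity. Relative
intensities are computed per block against that block's base peak; the 5%
relative-signal threshold never removes the base peak.

Measured vs predicted peaks are paired greedily by |Δm/z| within a
tolerance (default 0.01 Th, the high-resolution QqToF context; absolute,
not ppm — configurable), ties broken toward the more intense predicted
peak, each peak used once. Greedy pairing rather than optimal bipartite
matching is a deliberate simplification: at 0.01 Th tolerance, peak
spacings make cluster conflicts vanishingly rare, and the oracle tests
bound any divergence. Scores: R = matched/measured, P = matched/predicted,
WR and WP the intensity-weighted analogues (raw intensities; the scale
cancels within a spectrum), J = matched/union. J ≤ min(R, P) always.

## Method assembly

* Mass window 30 < MW < 1500 g/mol, strict on both ends.
* Enantiomers collapse when formula, weight and the stereo-stripped
  structure string agree and stereo descriptors are present; the survivor
  is the smallest KEGG ID (deterministic; the pair is unresolvable without
  chromatography anyway).
* Candidate transitions per metabolite and allowed polarity: in-house table
  first, then literature, then predicted fragments pooled over the three
  collision energies and ranked by relative intensity (the CE travels with
  each fragment). Precursors are [M+H]⁺ / [M−H]⁻.
* Missing EP → 10 V, missing CXP → 4 V, dwell 50 ms. Missing DP comes from
  an ordinary least-squares line of known DP on precursor mass, fitted per
  polarity with a pooled fallback below 2 points per mode.
* Isobaric convolution: two metabolites collide when they share polarity
  and agree on Q1 and Q3 within `iso_tol` (default 0.5 Th — unit-resolution
  QqQ; the tolerance is a design choice). Opposite-polarity coincidences
  are not convolutions.
* Selection: the most intense convolution-free candidate wins; deferred
  (dual-mode) metabolites take whichever polarity offers a convolution-free
  candidate, ties broken by the higher relative intensity, then negative
  mode. Only when every candidate is convolved is the top-ranked one taken
  and flagged. This is verified against exhaustive enumeration on small
  instances.
* Packaging: per polarity, ceil(n / 40) packages; transitions sorted by Q1
  and dealt round-robin, so sizes differ by at most one and every package
  spans the m/z axis. Each package is one 1-minute FIA method; analysis
  time per sample equals the package count in minutes. "Equal distribution"
  (balanced sizes) rather than fill-to-40 is a design choice; the package
  count is identical under either.
* Injection sequences, one plate per polarity: blank, QC, then seeded
  shuffled samples with replicate injections back-to-back and a QC after
  every 6 sample injections plus a closing QC.

## QC and statistics pipeline

The order is fixed: S/N filter → LOESS → QC acceptance → imputation →
(scaling inside CV) → models.

* **S/N filter**: areas with S/N ≤ 5 become missing (strictly "> 5" keeps).
* **LOESS drift correction**: per metabolite, degree-1 LOESS (tricube
  weights, `statsmodels` lowess) of QC area on injection order; the span is
  chosen from the grid {0.3, 0.4, …, 1.0} by leave-one-out CV over the QC
  injections (≥ 4 required, else skipped with a warning). Corrected area =
  raw × (QC median / trend). Trends that touch ≤ 0, or corrections that
  fail to reduce the QC RSD, leave the metabolite uncorrected and flagged —
  so correction never degrades QC precision.
* **QC acceptance**: QC RSD < 20% (sample standard deviation, n − 1) and
  QC missingness < 30%, both strict.
* **Imputation** (multivariate only): within metabolite × class, partial
  missingness → class mean (missing at random); a wholly missing class →
  half the metabolite's global minimum (below detection, missing not at
  random). The MAR/MNAR diagnosis from the missingness pattern is a design
  choice. Univariate Kruskal–Wallis tests run on the *observed* values
  before imputation — class-mean imputation would artificially shrink
  within-class variance and inflate univariate significance. A metabolite
  whose observed values span fewer than two classes gets H = 0, p = 1.
* **Scaling**: range scaling (x − min)/(max − min) with train-set bounds
  applied unclipped to test data, refit inside every CV fold and every
  bootstrap resample — no leakage.
* **PLS-DA**: NIPALS PLS2 (scikit-learn's `PLSRegression`, no autoscaling)
  on one-hot class membership; class call = argmax of the predicted
  membership columns. Class-specific VIP scores weight each component's
  contribution by the explained variance of that class's membership column,
  so mean(VIP²) over variables is exactly 1 per class. Model validation is
  a stratified double 5-fold CV: the inner loop grows latent variables
  until the Q²Y gain drops below 5 percentage points; the outer loop pools
  held-out PRESS into Q²Y and accuracy. With 6 replicates per class, some
  inner training splits hold fewer than 5 members of a class; scikit-learn
  warns and proceeds, which is the correct behaviour for this design.
* **Bootstrap**: n = 1000 (100 in the reduced acceptance runs) resamples
  with replacement, stratified within class — a class can therefore never
  vanish from a resample, making the degenerate-redraw branch unreachable
  by construction. 2.5/97.5 percentile CIs for every β(i, class) and
  VIP(i, class).
* **Variable selection**: selected ⇔ Kruskal–Wallis p < 0.05 AND, for at
  least one class, the β CI excludes 0 AND the VIP point estimate is
  strictly > 1 for that class. A point-estimate β criterion and an optional
  Benjamini–Hochberg adjustment are available via `QcConfig` but off by
  default (matching the uncorrected α = 0.05 convention).
* **PCA**: component count by the same Q²-gain rule; Q²X uses K-fold
  row-held-out reconstruction with training loadings. This estimator is
  known to be optimistic compared with element-wise cross-validation; it is
  used only for choosing an overview dimensionality, never for any
  acceptance quantity.

## Synthetic data: what it emulates, what it does not

The generators state one world and keep it fixed: three classes with six
replicates (a three-product comparison), multiplicative lognormal noise at
10% CV (typical MS peak-area repeatability), a smooth 20% linear drift over
the batch, QC injections as the pooled class mean bracketing every 6
samples, 10 planted 2-fold discriminators among 100 variables, 3% random
dropouts, two whole-class knockouts, and lognormal S/N with a small forced
low-S/N fraction. Libraries plant one enantiomer pair, one isobaric pair
per polarity, mass-window stragglers and all five ionization classes;
spectra plant one sub-5% peak per energy block.

The generators do **not** model fragmentation chemistry (fragment m/z are
random), chromatographic peak shapes (FIA areas only), matrix effects,
inter-batch variation, or heteroscedastic noise. A green test therefore
establishes that the algorithms implement their contracts on data with the
stated structure — not that the instrument model is realistic.

## Known limitations

* Greedy peak matching can, in principle, differ from optimal matching in
  dense peak clusters near the tolerance.
* The DP regression is a straight line per polarity; curvature in
  DP-vs-mass is not modelled.
* Q²X for PCA is the naive row-held-out estimator (see above).
* Percentile bootstrap CIs at n = 18 samples are approximate; no BCa
  correction is applied.
* Inter-batch normalization and absolute quantification are out of scope.
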