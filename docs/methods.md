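# Methods

This note records the models, parameter choices and numerical conventions
behind `bileprof`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Mass arithmetic

Monoisotopic atomic masses are hard-coded to ≥ 8 decimals (C 12 exact,
H 1.00782503, N 14.00307401, O 15.99491462, S 31.97207117) and verified in
the tests against an independently typed hand-summation table.  The only
ion species considered is the deprotonated molecule at charge 1:
`m/z([M−H]⁻) = M − 1.00727646`.  Using the proton mass (rather than an H
atom) keeps the electron with the anion, which is the convention under
which the published sulfate-conjugate ppm errors reproduce to better than
±0.05 ppm; ppm errors are therefore computed against *theoretical* m/z.
Deuterated internal standards add `n_D × 1.00627675` Da to the unlabeled
analog's mass.  Isotope patterns, adducts other than [M−H]⁻, and positive
mode are out of scope.

Biotransformations are fixed element-count deltas: sulfation +SO₃,
glucuronidation +C₆H₈O₆, hydroxylation +O, keto formation +O−2H,
dehydrogenation −2H, dehydroxylation −O, glycine amidation +C₂H₃NO,
taurine amidation +C₂H₅NO₂S.  Applying a delta that would drive any element
count negative is an error, and mass additivity
(`mass(f+δ) = mass(f) + mass(δ)`) holds to 1e−9 Da by construction.

## The compound library

The packaged library holds the 46 bile acids and 14 deuterated internal
standards of a commercial standards kit.  Formulas were compiled from
standard references via steroid-core arithmetic (unconjugated non-keto
cores: mono-OH C24H40O3, di-OH C24H40O4, tri-OH C24H40O5; keto groups are
+O−2H on the reduced parent; nor- species lack one CH₂; amidations as
above).  Two invariants are enforced at load and abort it on failure:
every glycine/taurine conjugate whose parent is in the library equals
parent + amidation delta, and hydroxyl classes of unconjugated non-keto
species match the core formulas.  Reference retention times are **data,
not computation**: published screening tables of this kind print RTs only
for isomer and conjugate peaks, so the standards' reference RTs ship with
the synthetic scenario, assigned to follow the tri-OH < di-OH < mono-OH elution order of
a reversed-phase C18 gradient, with taurine conjugates earliest and
unconjugated species latest within each hydroxylation class.  They are
spaced ≥ 0.4 min apart within a formula so that RT jitter cannot flip an
exemplar assignment.

## Annotation

The target list is the 46 analytes plus one target per analyte × {sulfation,
glucuronidation}; conjugate targets with identical formulas are collapsed
(they are indistinguishable by exact mass) and named after the
lexicographically first parent.  Each feature takes the candidate within
`ppm_tol` that minimises (|ppm|, |ΔRT|, name) — ties on |ppm| arise exactly
for same-formula analytes, where nearest reference RT picks the exemplar.
Tier rules: analyte match within `rt_tol` → identified; analyte match
outside `rt_tol` → isomer; conjugate match → tentative conjugate (no RT
evidence exists for predicted conjugates); otherwise unassigned.

Defaults: `ppm_tol` 10 (the accuracy claim of the emulated instrument);
`rt_tol` 0.30 min — the RT window is not stated in the source workflow, so
0.30 min was chosen once as a realistic window for a 55-min UHPLC gradient
and is config-exposed.  Shrinking `ppm_tol` can only shrink the annotated
set (tested property).

## MS/MS classification

Diagnostic ions are computed from formulas, never typed as numbers:
deprotonated glycine 74.0248, deprotonated taurine 124.0074 with companions
C₂H₃SO₃⁻ 106.9808, HSO₃⁻ 80.9652, SO₃⁻• 79.9573 (radical anion = neutral +
electron), and HSO₄⁻ 96.9601.  Note HSO₃⁻ prints as 80.97 at two decimals;
the lower-precision 80.96 sometimes quoted is a display convention, and the
rule table stores the computed value.  Matching uses an absolute 0.01 Da
window (≈100 ppm at m/z 100, the low-mass accuracy of TOF MS/MS) and
ignores peaks under 1% relative intensity — the presence threshold is a
package decision, config-exposed, since source workflows rarely state one.
Precedence is taurine > sulfate > glycine; taurine may also be called from
two of its sulfur-bearing companions, because any single low-mass sulfur
ion is ambiguous with sulfate chemistry.  When the MS/MS class contradicts
the exact-mass assignment, the annotation is rewritten to an isomeric
interpretation (library analyte + class delta with the same formula) and
flagged `msms_reassigned`; with no such interpretation it is flagged
`msms_conflict` and kept.

## Quantitation and screening

Internal standards are assigned per target by a deterministic cascade:
labelled analog of the same compound → same conjugation class with nearest
reference RT → globally nearest RT.  Area ratios analyte/IS are computed
per sample; samples with a missing or non-positive IS peak are flagged and
excluded.  The screen compares the lowest and highest dose groups (75 vs
600 mg/kg by default; all-pairwise is a caller choice) with a two-sample
**Student** (equal-variance) t-test — the default of the vendor statistics
tool the workflow emulates — with Welch behind a flag.  Fold change is the
ratio of group means of the untransformed area ratios (not log-space),
matching how the published tables define it; whether the vendor tool
log-transforms is unknown, so untransformed ratios are the default and the
choice is documented here.  Significance is `p < 0.05` and `FC > 2`
(`FC < 0.5` also qualifies in direction-agnostic mode).  No
multiple-testing correction is applied by default, replicating the emulated
workflow; Benjamini–Hochberg is available by flag.  Degenerate cases: both
groups constant and equal → p = 1; zero low-group mean → fold change
undefined and flagged, never significant.

### Peak grouping across samples

Features must be pooled into per-target groups before testing.  Identified
features group by library name.  Isomer and conjugate features group by
formula and are split into RT clusters wherever consecutive sorted RTs gap
by more than 0.25 min.  This threshold interlocks with the generator's RT
jitter truncation (±2σ = ±0.1 min): the closest planted same-formula pair
is 0.5 min apart, so the worst-case between-cluster gap (0.3 min) exceeds
the threshold while the worst within-cluster gap (0.2 min) cannot reach it.
On real data with heavier RT drift the threshold is config-exposed and
cross-run alignment (a non-goal here) would be needed first.

## In-vitro metabolite calling

Oxidative incubations search {+O, +2O, +O−2H, −2H, −O}; sulfation searches
{+SO₃}.  A full-cofactor feature matching parent+delta within 10 ppm is
called a metabolite when its area is ≥ 5× the best matching peak (±0.2 min)
in the *weakest* control.  The minimum over controls matters: each control
retains the other cofactor (a no-NADP⁺ incubation still sulfates), so a
PAPS-dependent sulfate is judged against the no-PAPS control where it is
absent, not against the no-NADP⁺ control where it is not.  Which control
lacks the peak assigns the cofactor dependence (NADPH vs PAPS); if both
lack it, the delta's chemistry decides.  The 5× threshold and ±0.2 min
window are package decisions (unspecified in source workflows),
config-exposed; raising the threshold can only remove calls (tested
property).  Plasma cross-matching pairs significant isomer/conjugate
targets with calls of the identical formula within 0.3 min, one-to-one by
nearest RT.

## Peak detection (XIC path)

For raw traces (long-format TSV or centroided mzML), XICs sum per-scan
intensity within ±ppm window on the acquisition grid.  Peak detection uses
baseline = trace median and noise = 1.4826 × MAD (robust, parameter-free);
apexes are local maxima of a 5-point moving average above baseline +
3×noise; boundaries run to the nearest valley or 1% of apex height;
integration is trapezoidal **on the raw trace** so smoothing cannot bias
areas; candidates narrower than 5 points are rejected.  On a planted
Gaussian this recovers the closed-form area A·σ·√(2π) within 2% (the 1%
truncation alone costs 0.24%).  The mzML reader is a minimal
self-contained implementation (MS1 scans, base64 float arrays, optional
zlib), since the environment's MGF/mzML library supports MGF only here.

## The synthetic-data generator

The generator emulates the study design the analysis assumes: 4 doses ×
3 replicates, the 46+14 library, 33 detectable standards (13 with planted
fold changes ≥ 4, anchored at 6.0 for DCA and 6.4 for HDCA), 22 isomers
and 9 significant sulfate conjugates at published-table RTs and fold
changes, 4 further sulfates and 6 glucuronides without effects (19
phase-II conjugates in all), 15 decoys, and per-conjugate MS/MS spectra
carrying the correct diagnostic ions.  Models and defaults:

* areas: baseline × dose-multiplier × mean-1 lognormal noise, CV 10%
  (multiplicative because areas are positive and CV-scaled); per-compound
  baselines draw once per study from a lognormal with log-CV 0.5;
* dose response: log-linear in dose, equal to 1 at 75 and to the planted
  FC at 600 mg/kg;
* mass error: Gaussian, σ 3 ppm, redrawn (not clipped) beyond ±5 ppm;
* RT jitter: Gaussian, σ 0.05 min, truncated at ±0.1 min;
* decoys: uniform m/z in 350–550 excluding ±25 ppm of every target
  (analytes, all vocabulary conjugates, internal standards), hence
  unannotatable at 10 ppm by construction;
* limit of detection 500 area units; features below it are dropped;
* in-vitro: metabolites per the incubation plans of nine parents (54
  products), controls missing their blocked pathway's products (down to a
  leakage fraction, default 0) while keeping the other pathway's; four
  oxidative metabolites are planted at the RT of a same-formula significant
  plasma isomer.

Identical config + seed reproduce byte-identical outputs.  The planted
truth table records, per feature, the compound, kind, expected tier,
formula, fold change, baseline, theoretical m/z, nominal RT, drawn ppm
error and the expected MS/MS class.

**What passing tests show — and don't.**  The generator's features are
aligned across runs, peaks never co-elute closer than the clustering
threshold allows, isotopologue envelopes and matrix interference do not
exist, and noise is exactly lognormal.  Recovery of every planted compound
therefore demonstrates the *logic* of the pipeline (tier rules, clustering,
normalisation, thresholds) under its own assumptions, not robustness to
chromatographic drift, co-elution or detector saturation.  Real-data
figures such as the exact p-values of animal experiments are not
reproducible at this scale and are not targets of the test suite; the
statistical suite instead checks calibration (null type-I rate 5% ± 2
points at n = 3/group; t-test p-values equal to an independent
t-distribution CDF oracle to 1e−9; planted 6.0-fold DCA effect recovered
within ±0.15 averaged over 200 simulated studies).

## Problem sizes

The default study is 12 samples × 103 features (1236 features, 420 MS/MS
spectra) and analyses in about a second; the fold-change calibration uses
200 studies and the null calibration 1000 simulated targets — sizes chosen
so the whole suite and the acceptance script each run in well under a
minute while keeping Monte-Carlo error far below the tested tolerances.

## Known limitations

* Structure within a formula is never resolved: "X isomer" names an
  exemplar, not a stereochemistry; de novo elucidation is a non-goal.
* One annotation per feature: chimeric peaks are not split.
* No cross-run RT alignment, calibration curves or absolute quantitation.
* The abstract-level count of significant isomers in the emulated study is
  ambiguous in its source (22 vs 23); the pipeline reports what it counts
  and takes no side.
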