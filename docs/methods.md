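# Methods

## Cohort model and synthetic data

The reference design is a 36-animal rhesus macaque total-body-irradiation
cohort: six groups of six at 6.0, 6.5, 7.0, 7.5, 8.0 and 8.5 Gy, 19 males
and 17 females, serum sampled pre-irradiation and on days 1, 2 and 6 —
144 samples in all. Survival to study end ("RRiF" status) is fixed per
group: 10 of the 18 animals at ≤7.0 Gy and 6 of the 18 at ≥7.5 Gy survive
(16/36 overall, a 56% low-dose and 33% high-dose survival rate). Only the
low/high-dose aggregates are constrained by the published summary; the
per-group split (4,3,3,3,2,1) is the package's own monotone-in-dose
allocation. Within a group, which animals survive is drawn uniformly per
seed.

The count generator draws `counts[i,j] ~ NB(mean = m_i · s_j · 2^shift,
dispersion φ)` with feature means `m_i` log-normal (median `baseline_mean`,
default 50 counts; sdlog 1.5, giving a realistic spread from barely-detected
to abundant miRNAs), per-sample relative depth `s_j` uniform over
`library_size_range` scaled by its midpoint, and planted effects entering
the log2 mean of post-irradiation samples only:

* dose markers: ±`effect × dose` (default 0.6 log2/Gy),
* time markers: ±`effect × days` (default 0.3 log2/day),
* sex markers: a constant log2 shift in one sex (default 1.0),
* survival panel: a constant log2 shift in decedents (default 0.6).

log2 fold change is therefore linear in dose and days by construction.
Defaults were calibrated so that recovered statistics resemble the scale of
published NHP radiation-marker reports: planted dose/time markers realize
per-marker regression F statistics in the tens-to-hundreds (the reported
range for such markers runs from about F = 7 to F = 280), and each survival
feature alone is an imperfect classifier so that the panel, not any single
member, carries the prognostic signal. Planted features are floored at the
median expression scale — a usable biomarker is by necessity well measured.

Because samples are drawn independently, the dispersion default (0.05, a
22% biological CV) represents the within-animal, repeated-serum-sampling
component — the part of biological noise that per-animal baselining cannot
cancel. What the generator deliberately omits: persistent per-animal
expression offsets (real cohorts have them; the fold-change transform would
remove them, but they would also correlate the expression rows of one
animal), batch effects, sequencing adapter artifacts, and miRNA–miRNA
correlation structure. Passing tests therefore demonstrate correctness of
the statistical machinery under idealized independence, not robustness to
those real-data features.

The FASTA generator writes uppercase RNA (A/C/G/U, 60-column wrap) mature
sequences of 18–30 nt; a homologue pair at a requested percent identity is
produced by substituting `round(L·(1−pct/100))` distinct positions, so the
realized identity is the nearest achievable on that length and is reported
back (with a warning when rounding was needed).

## Normalization

Features with fewer than 40% non-zero samples are removed before
normalization; the boundary is inclusive (exactly 40% is kept), since the
published rule states only the removal side. TMM follows the canonical
definition: reference sample = upper-quartile count fraction closest to the
cohort mean; per-sample factor = 2 to the precision-weighted mean of log2
expression ratios (M) after trimming the extreme 30% of M and 5% of A
(rank-based, ties averaged); factors rescaled to geometric mean 1. A sample
sharing no expressed features with the reference receives factor 1.0 with a
warning. CPM divides by `lib_size × factor`, so a pure depth difference is
absorbed by the library size while the factors stay at 1 — composition,
not depth, moves TMM factors.

Fold change uses a pseudocount of 1.0 on the CPM scale in both numerator
and denominator (the source protocol does not state its zero-handling), so
a feature absent pre and post has log2FC exactly 0 and all values are
finite. Near the count floor, `E[log2(CPM+1)]` is concave-biased, which
steepens fitted slopes of strongly down-regulated markers by a few tenths
of a log2 unit; signs and monotonicity are unaffected.

## Factorial ANOVA

The differential screen fits, per miRNA, a four-factor ANOVA with the 15
terms {RD, TSI, Sex, RRiF} and all their interactions. Design choices:

* **Response: normalized log2 CPM of all 144 samples**, with TSI as a
  four-level factor including the pre-irradiation baseline (the study's
  stated TSI levels). The alternative — fold-change rows over the three
  post-irradiation timepoints — shares each animal's baseline sample across
  its rows (within-animal correlation ≈ 0.5) and inflates the type-I error
  of between-animal terms to ≈0.37 at nominal 0.05 in simulation, which
  would invalidate the raw-p screening. Fold changes remain the response
  for the marker regressions, where the printed per-marker statistics are
  defined on that scale.
* **Type II sums of squares** (order-invariant, appropriate for the
  unbalanced design: sexes differ between groups, survival is partially
  confounded with dose). Each term's SS is the RSS drop when adding it to
  the model containing all terms not containing it; the denominator is the
  full-model residual mean square. On a balanced complete design this
  reduces to the orthogonal decomposition (tested).
* **Aliasing by rank check**: sum-to-zero contrast blocks are built per
  factor and interactions as column products; a term whose columns add no
  rank is flagged `aliased` (NaN statistics), a term with reduced rank is
  reported at its realized df and flagged `partially-aliased`. With the
  reference design, high-order interactions involving RRiF are partially
  aliased because survival is constant within animal and correlated with
  dose.
* **η² = SS_term / SS_total** (classical, not partial).
* **No multiple-testing correction** — the screen uses raw p < 0.05 by
  design, and the DE union is the deduplicated union over terms.

Calibration: under null simulation the main-effect terms reject at
0.045–0.055. High-df interaction terms on weakly expressed (discrete,
zero-inflated) features run slightly liberal — about 0.055–0.067 per term
systematically — which is a property of F tests on log-transformed counts,
not of the Type II machinery (a Gaussian control is calibrated across all
15 terms). Calibration tests therefore assert the nominal band per term for
the four main effects and for the mean across all estimable terms.

Power is estimated by Monte Carlo rather than an analytic formula: Gaussian
responses are simulated on the real 144-sample design, a dose-linear effect
is scaled so the expected η² of the RD term matches a target, and power is
the rejection fraction of that term over ≥100 replicates (vectorized across
replicates, so 300 replicates take well under a second).

## Sequence conservation

Alignment is exact global dynamic programming with affine gaps via
`Bio.Align.PairwiseAligner`: match +5 / mismatch −4, gap open 10, gap
extension 0.1 (a length-k gap costs 10 + (k−1)·0.1). A nucleotide matrix is
used because the named protein-style scoring matrix has no meaning for RNA;
the scores are configurable. With at most a few thousand short mature
sequences, every query is aligned against every reference — no heuristic
k-tuple pre-screen is needed, and tests verify the optimum against
exhaustive enumeration of all alignments for short pairs. Percent identity
is matches over alignment columns (gap columns included) on one optimal
alignment; ties in `top_match` are all retained, ordered by target id.

*sc*-miRNAs are DE features whose top match reaches `min_identity`
(default 90%, a conservative threshold exposed in config; the source
protocol names only "top matches"). The *fs* pathway approximates raw-read
re-alignment to the human genome by re-assigning each quantified feature to
its best human mature match, summing counts per human identifier, and
re-running prefilter → TMM → log2 CPM → ANOVA on the aggregated matrix;
with the species-A set itself as reference this reproduces the original DE
union exactly (tested). *cnvd* = sc features whose mapped identifier is in
fs.

## Marker regression

Dose fits regress per-dose mean log2FC (pooled over post timepoints, within
the chosen sex stratum) on dose in Gy; time fits regress per-timepoint
means on days. Per-sample rows are available via `use_means=False`. The
slope F test equals the squared slope t. The day-0 baseline point (0, 0) is
included by default for time fits but not dose fits: back-computing
residual degrees of freedom from published per-marker (F, p) pairs shows
the time statistics correspond to four points (df = 2) and the dose
statistics to six dose means (df = 4); both conventions are exposed via
`include_origin` since the published pairs are not mutually consistent.
Sex classification: a marker is sex-independent if the pooled fit is
significant, X-specific if significant only in stratum X; a marker can
legitimately carry both labels. Single-marker AUC uses the midrank
Mann–Whitney formulation with a stratified percentile bootstrap CI
(default 2000 resamples).

## Panel discovery

The search wraps three stages. (1) Candidate ranking: random forests are
trained on bootstrap resamples (resampled until both outcome classes are
present); each repetition records its top features by importance; features
are ranked by cumulative selection frequency and the recorded groups,
ranked by recurrence then member frequency, become seed panels. Protocol
defaults are 2000 repetitions and 200 retained panels; tests and the demo
pipeline use 50/10 with smaller forests, trading search breadth for run
time. (2) Enumeration: all subsets of size 2–10 of each seed panel,
globally deduplicated, in deterministic (size, lexical) order.
(3) Evaluation: each subpanel is a maximum-likelihood logistic model (own
Newton–Raphson; on non-convergence or divergent coefficients — perfect
separation is common at n = 36 — the fit is repeated with a 10⁻⁴ ridge on
the coefficients and flagged). RSBMR = stratified 70:30 splits repeated 10
times, reporting mean test AUC and mean sensitivity/specificity at the
Youden-optimal threshold; k-fold = stratified k = 10, reporting the mean
per-fold AUC with single-class folds skipped and counted. Stratification is
used throughout because unstratified splits of 36 animals frequently
produce single-class test sets. Screening keeps panels with mean AUC
strictly above 0.80 and likelihood-ratio p < 0.05, sorted by AUC, ties to
the smaller then lexically earlier panel. McFadden's R² = 1 − lnL/lnL₀;
the LR p-value is χ² with one df per panel feature.

At n = 36, cross-validated AUC estimates carry a standard error of several
hundredths, so ranking among near-equivalent panels is noisy; the RSBMR
ranking (11-animal test splits) is more stable than k-fold (3–4-animal
folds) and is the list recovery tests read first. Wrapper selection bias —
noise features that correlate with the outcome in this cohort inflate
their own cross-validated score — is intrinsic to the procedure at this
sample size and is why attribution tests require only that the top panel
shares two of three planted features.

## Reports and pipeline

PCA is centered, computed on samples over features, with explained-variance
fractions relative to total variance (the pipeline stores the top five
components). Hierarchical clustering uses Euclidean distances with average
(UPGMA) linkage — the distance is prescribed by the protocol, the linkage
is the package's choice. The orchestrated pipeline writes every artifact as
TSV/JSON/FASTA and finishes with a SHA-256 manifest; a fixed configuration
and seed reproduce the manifest byte-for-byte. The bundled demo
configuration simulates 150 features and uses the reduced search
(50 forests, 10 seed panels, subpanels up to size 4), which completes in
about 15 s on one CPU.

## Known limitations

* The generator's independence assumptions (no per-animal offsets, no
  feature correlation) are idealizations; see above for what that implies
  about test evidence.
* Logistic panels at n = 36 separate easily; ridge-stabilized fits are
  flagged but their coefficients are penalty-dependent.
* The fs pathway operates on mature-sequence re-assignment, not genome
  re-alignment of raw reads; features without a provided mature sequence
  are dropped from it.
* Percent-identity of an optimal alignment is reported for one optimal
  path; co-optimal paths can differ in identity by a column or two.
* High-df ANOVA interaction terms are mildly liberal on weakly expressed
  features (see calibration above); conclusions that rest on those terms
  alone should be treated with proportionate caution.
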