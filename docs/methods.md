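# Methods

## Scope and data model

`epiquant` consumes proteins × runs matrices — integer spectral counts
(SPC) and label-free quantification (LFQ) intensities with explicit
missingness — keyed by a run-design table (bait antibody or IgG, epitope
class, tissue, genotype, age, replicate). It does not touch raw spectra;
search engines and quantification tools sit upstream. All tabular I/O is
TSV; missing intensities are empty fields and are distinct from measured
zeros; protein identifiers are opaque labels with contaminants recognized
by prefix (`contam_`, `rev_` by default) or an explicit exclusion list.

## Specificity model

Pre-processing removes contaminants and, within each bait sample group
(tissue × genotype × age × epitope pool), retains the two highest
replicate counts per prey (ties broken by lexicographic run id, for
determinism). IgG control runs are pooled across all sample groups; each
prey's virtual negative control is the ten rank-central values of its
descending-sorted pooled control counts (for 37 controls, descending
ranks 14–23). This excludes both extremes of the background
distribution; the alternative reading — the ten values immediately below
the maximum, a deliberately conservative control — is available as
`vc_mode="below-max"`.

Scoring is a transparent two-component Poisson likelihood ratio with
equal priors:

    lam0 = mean(virtual controls) + eps        (eps = 0.1)
    lam1 = max(mean retained bait counts, f_min * lam0)   (f_min = 2)
    P(x) = Pois(x; lam1) / (Pois(x; lam0) + Pois(x; lam1))

AvgP is the mean of P over the retained replicates; BFDR at rank r of
the descending-AvgP ordering is the cumulative mean of (1 − AvgP), with
tied probabilities sharing the worst BFDR of their block. Scoring and
BFDR are per sample group; the "high-confidence interactor" list is the
union of preys passing BFDR ≤ 0.01 and average bait SPC ≥ 5 in at least
one condition. Estimating `lam1` from the prey's own counts makes AvgP
an optimistic posterior; the SPC floor and the per-group BFDR are what
keep the realized false-discovery proportion controlled (measured at
≈ 0.04 under the calibration conditions below). Exact reproduction of
any external scoring binary is a non-goal; the model here is fully
specified and configurable.

## Quantitative contrasts

Prey intensities (raw LFQ) are divided by the bait intensity of the same
run, which cancels per-run capture efficiency exactly (multiplying all
intensities of a run by a constant leaves normalized values unchanged).
Group summaries are means of normalized abundances on the linear scale
and ratios are log2 of the ratio of means — matching "ratio of
abundances" semantics — while significance uses unpaired t-tests on
log2-transformed values (Student by default; Welch selectable). A group
mean requires at least `min_obs = 2` observations; a one-point "mean" is
meaningless at the 3–5 replicates typical of these designs. Missing
values are never imputed. When both groups have zero variance the
p-value is 1 for equal means and a zero-adjacent sentinel otherwise,
with a `degenerate_variance` flag.

Derived classifications:

- **Epitope preference** — per prey and tissue, the genotype-age stratum
  ratio (N-terminal over Central pools) of maximal absolute value;
  |log2| > 2.5 (strict) classifies N-term- or Central-preferential.
- **Tissue enrichment** — minimum over other tissues of
  log2(mean_target/mean_other) > log2(4); comparisons with missing
  tissues are flagged partial.
- **PolyQ/age gain** — (40wk/8wk ratio in Q140) / (40wk/8wk ratio in
  Q20) per tissue, pooled over epitope pools; a prey passes at
  gain > 5 in the target tissue and ≤ 5 in every other tissue where the
  gain is defined. Two thresholds are in circulation for this filter;
  both are kept as named presets (`main-text`: 5-fold gain with 4-fold
  tissue enrichment; `fig6-legend`: 2.5-fold gain with 2-fold
  enrichment) rather than guessing one as correct.

The priority set is the union of the striatum-enriched and polyQ-gain
sets with per-prey provenance (enriched-only / gain-only / both).

## Complex-level analysis

Overrepresentation is a one-sided Fisher's exact test (hypergeometric
upper tail, via `scipy.stats.fisher_exact`) on a 2×2 table restricted to
the quantified background, with Benjamini–Hochberg correction
(`statsmodels`). "Missing members" is judged against detected proteins:
sets with under 50% of members in the background are removed before
testing, so the multiple-testing burden reflects only testable
complexes. The background defaults to all quantified proteins (a
whole-proteome background is the caller's choice of `background`).

Stoichiometry scales each subunit intensity by its theoretical number of
fully-tryptic peptides — cleavage after K or R except before P, zero
missed cleavages, length 7–30 residues, the iBAQ-style convention and
the window used by common spectral-library tools — then expresses each
subunit relative to the mean over detected members. Cleavage uses
`pyteomics.parser.icleave` with an explicit `[KR](?!P)` rule (the
package's bundled trypsin rule adds WKP/MRP exceptions that are not part
of this convention), keeping repeated peptides as separate counts.

## Thermal profiling

Curves are normalized to the lowest (reference) temperature. The
three-parameter descending logistic is fitted by a deterministic coarse
grid over Tm (30–70 °C, step 0.5) and k (0.05–2.0, log-spaced), with the
plateau solved in closed form at each grid point (the model is linear in
p), followed by bounded least-squares refinement; the derivative-free
start is what makes 5-point fits reliable. Curves with no net decrease
(no melting) return an NA Tm with a diagnostic, and fitted Tm is
constrained to the temperature span ± 10 °C. On simulated curves,
noiseless recovery is exact to well under 0.1 °C and the median absolute
Tm error at noise sd 0.05 is ≈ 0.5–0.7 °C.

Curve distances are Euclidean distances between observed normalized
replicate vectors (not fitted curves, which would smooth away replicate
variation), over all ordered cross-replicate pairs i ≠ j — the only
pairing scheme that yields six comparisons from three replicates. The
condition shift is an unpaired t-test on the two distance sets, with the
direction reported (a decrease means increased curve similarity).

## Fractionation

log2 nucleus/cytoplasm ratios are computed cell-wise on matched
matrices, defined only where both fractions are observed, and aggregated
per protein over all condition × replicate samples (16 values for a
4 × 4 design). No between-fraction normalization is applied by default
(none is standard for this assay); per-fraction median-centering is
available via `center=True`. Marker QC requires mean linear N/C ≥ 4 for
nuclear markers and C/N ≥ 4 for cytosolic markers (strict thresholds);
missing markers give an indeterminate verdict rather than a pass.

## Synthetic data generator

The generator emulates the study design: 3 tissues × 2 genotypes
(Q20/Q140) × 2 ages (8wk/40wk) × 2 epitope pools (+ pooled IgG), 4
replicates per bait group and 37 pooled IgG runs.

- **Counts** are negative binomial (Poisson-gamma), Var = μ + d·μ² with
  dispersion d = 0.5 — spectral counts are overdispersed. The IgG
  background mean defaults to 1.0 SPC: isotype-control background is
  sparse, with most proteins at 0–2 spectra per run. True interactors
  (100 of 1000 proteins) are enriched 10-fold in bait runs.
- **Planted effects** are disjoint interactor subsets (15 each):
  N-term/Central epitope preference, striatum enrichment, and polyQ/age
  gain (applied in Q140 × 40wk × striatum cells), each 8-fold.
- **Intensities** are log-normal (CV 0.3) around a bait-capture-scaled
  mean, with a shared per-run capture factor so bait normalization can
  cancel it, and logistic intensity-dependent dropout (midpoint 2¹³,
  left-censoring MNAR) mimicking LFQ missingness. The bait is present
  in every bait run.
- **Melt curves** follow the logistic model at the five assay
  temperatures with Gaussian noise (sd 0.05), clipped at zero and
  re-normalized to the reference temperature; a subset of proteins
  carries a +2.5 °C Tm shift in the second condition.
- **Fractions** plant per-protein true log2 N/C values (sd 1.0) with
  nuclear/cytosolic markers at ±3 (eight-fold), and per-fraction
  log-normal noise so the expected log2 ratio equals the truth.

What the generator does **not** emulate: peptide-level quantification,
retention times, shared peptides between proteins, correlated background
(e.g. bead proteomes that covary between runs), batch effects, or
interactor abundance distributions with heavy tails. Passing tests
therefore demonstrate correctness of the statistical machinery and
calibration under the stated generative model, not performance on any
real dataset.

## Problem sizes and numerical choices

Simulation-based checks use 1000 proteins / 100 interactors over 20
seeds for calibration and end-to-end recovery, 204 curves for Tm
recovery, and 1000 pooled values per protein for the fractionation
Monte-Carlo check — sizes at which Monte-Carlo error is far below the
tested tolerances while the full suite runs in seconds. Determinism:
every stochastic step is driven by a single integer seed through
`numpy.random.default_rng`; ties everywhere break by lexicographic
label. Known limitations: AvgP is not a calibrated posterior (see
above); Student's t on n = 2–4 log-ratios is fragile to variance
heterogeneity (Welch is available); and the logistic melt model cannot
represent biphasic transitions.
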