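# Methods

`benthos16s` implements the post-clustering computational stack of a benthic
16S rRNA amplicon survey: consensus taxonomy from tabular similarity hits,
blank-based decontamination, compositional community statistics, constrained
ordination with forward selection, and depth-stratified richness trends. This
note records the models, the parameters that matter, the numerical choices,
and what the synthetic validation does and does not demonstrate.

## Consensus taxonomy

Input is a BLAST-style tabular hit list per OTU (query), each hit carrying a
bitscore, alignment length, percent identity, E-value, and the subject's
seven-rank lineage (domain > phylum > class > order > family > genus >
species). Four steps produce the consensus lineage:

1. **Score thresholds.** Hits with bitscore < 150 or alignment length
   < 100 bp are excluded. The `low_score_rule` flag chooses the boundary
   logic: `"or"` (default) excludes a hit when *either* score fails;
   `"and"` excludes only hits failing both. The default is the stringent
   reading — under `"and"`, a short perfect repeat with a high bitscore
   would survive, which contradicts the intent of conservative assignment.
   Both behaviours are implemented and tested.
2. **Bitscore margin.** Only hits within 2% of the best bitscore for that
   query are kept (`bitscore >= 0.98 * max`); the boundary is inclusive, so
   the top hit always survives and exact ties are retained.
3. **Lowest common ancestor.** The retained lineages are collapsed to their
   longest common prefix over the fixed rank order, by exact string match,
   stopping at the first disagreement or the first rank unnamed in any
   lineage. Fully disjoint lineages give an empty (unassigned) lineage.
4. **Identity trimming.** The LCA is truncated to the deepest rank permitted
   by the *maximum* percent identity among margin-retained hits, under the
   strict ladder species > 98%, genus > 95%, family > 90%, order > 85%,
   class > 80%, phylum > 75%. An identity of exactly 98.0 therefore stops at
   genus. At or below 75%, the assignment is wholly unassigned by default;
   `retain_domain=True` keeps a bare domain label instead. Using the maximum
   retained identity is the least destructive choice consistent with "the
   best hit justifies rank r"; the margin filter guarantees that hit is a
   near-tie of the top hit.

The cascade is order-invariant (only maxima and set operations are used) and
each assignment carries an audit trail (hits in, hits after threshold, hits
after margin, max identity, LCA rank). Hits whose subject has no lineage in
the reference map are flagged at parse time and set aside before filtering;
they never silently disappear, and they do not enter the audit counts.

## Decontamination

Negative field, extraction, and PCR controls (blanks) estimate the
contamination profile. The default `subtract_scaled` method is a transparent
constant-anchor subtraction contract:

- For each OTU, compute its mean proportional abundance across control
  libraries (empty controls are skipped), giving a contamination profile
  `p`.
- The anchor is the OTU with the largest `p` — assumed pure contaminant.
- In each true sample `s`, the amount removed from OTU `o` is
  `count[anchor, s] * p[o] / p[anchor]`: the anchor's observed count in
  that sample calibrates how much contaminant that library received.
- Counts are floored at zero and rounded down, so decontamination never
  manufactures fractional or negative reads; OTUs left all-zero are dropped,
  as are the control columns.

This is the core idea of blank-based subtraction tools, restated as an
explicit contract so it is reproducible and testable; no attempt is made to
replicate any published tool's internals or its removed-OTU counts on real
data. The three control roles are pooled by default; `pool_controls=False`
applies them sequentially (field, extraction, PCR). A `prevalence_zero`
alternative simply zeroes any OTU seen in blanks above a count threshold.
The real decision behind the profile is a trade-off: the anchor scaling
removes proportional carry-over well (the scenario the generator plants) but
will over-subtract when a genuinely abundant taxon also drifts into blanks —
the trace carry-over in the synthetic design exercises exactly this, and the
observed cost is at most one read per affected cell.

## Community statistics

- **Depth strata:** epibenthic < 200 m, mesobenthic 200-1000 m (both ends
  closed), bathybenthic > 1000 m; the three bands partition (0, inf).
- **Regions:** five latitudinal bands over the Red Sea, lower-bound
  inclusive, with configurable interior cuts (defaults 19.0, 21.5, 24.5,
  27.5 degrees N spanning 12-30 degrees N). The published banding scheme
  does not print coordinates, so the defaults are a documented stand-in and
  are never asserted numerically in tests; latitudes outside the domain get
  an explicit `outside-domain` label.
- **Prevalence filter:** OTUs present (count > 0) in fewer than 3 samples
  are discarded before any compositional analysis.
- **Aggregation:** counts sum by the named rank; OTUs unnamed at that rank
  pool into `Unassigned` (kept out of the top-k competition); with `top_k`,
  the remainder pools into `other`. A nested phylum/class view keeps the
  top-k phyla and top-2 classes within each. Aggregation conserves
  per-sample totals exactly (integer arithmetic throughout).
- **clr transform:** per sample, `clr(x)_i = ln(x_i + d) - mean_j ln(x_j +
  d)`. The zero-replacement mode is a first-class parameter because the
  upstream choice is rarely reported: `add_one` (default, d = 1 on counts),
  `add_half_min` (half the smallest nonzero count), `multiplicative_
  replacement` (simplex-aware, via scikit-bio), or `none` (requires strictly
  positive counts; exactly scale-invariant). Rows sum to zero within 1e-9
  by construction.
- **Correlation grids:** Pearson r of every clr taxon against continuous
  covariates and the one-hot indicators of derived categories, on
  pairwise-complete observations per cell (oxygen saturation is missing for
  a sample subset, mirroring surveys where only some platforms carry an
  oxygen sensor). Each cell reports its n; cells with fewer than 3 complete
  pairs or a constant column are missing (NaN), never 0. Depth enters in
  raw metres by default; callers can pass a log-depth column instead.

## Constrained ordination

Redundancy analysis: the clr response matrix `Y` (samples x taxa) is column
centred and regressed on the column-centred constraint matrix `X`; the SVD
of the fitted values gives constrained axes with eigenvalues `s^2/(n-1)`,
and the SVD of the residuals the unconstrained axes. Constrained plus
residual eigenvalues partition the total variance; with a saturated
full-rank basis the analysis reduces to PCA of `Y`. Linearly dependent
constraint columns are dropped with a warning. Scores use correlation
(type-2) scaling — species scores carry `sqrt(eigenvalue)`, site scores are
the orthonormal fitted axes — and each axis is oriented so its
largest-magnitude species loading is positive, making output deterministic.

**Permutation tests.** A candidate term's partial pseudo-F is computed after
residualising both the response and the candidate on the already-selected
terms; the null distribution permutes rows of the reduced-model residuals
(not raw data), the standard choice for partial tests in constrained
ordination. `p = (1 + #{F_perm >= F_obs}) / (1 + n_perm)`. The permutation
loop is vectorised (one einsum over the stacked permuted basis), so
calibration protocols with hundreds of thousands of permutations run in
seconds. Null p-values are uniform (KS distance ~0.02 at 1,000 replicates).

**Forward selection.** Greedy: at each step the candidate block with the
largest adjusted-R-squared gain (Ezekiel adjustment, `1 - (1-R^2)(n-1)/
(n-m-1)`) is tested by partial permutation pseudo-F and admitted if
`p <= alpha` (default 0.05, `n_perm` default 999). Categorical candidates
enter and leave as indicator blocks; ties break by candidate input order.
The full-model adjusted R-squared acts as a ceiling (the double stopping
rule). Two ceiling modes are provided because their statistics differ
sharply:

- `"pre"` (classical): a candidate whose model would exceed the ceiling is
  rejected before testing. When the candidate set contains independent
  noise covariates, the expected full-model adjusted R-squared *equals* the
  expected true-model adjusted R-squared (the in-sample gain of k noise
  covariates exactly offsets their degrees-of-freedom penalty), so this
  check blocks the last genuine driver roughly half the time.
- `"post"` (default): a significant candidate is admitted, and selection
  stops once the selected model's adjusted R-squared exceeds the ceiling.
  This keeps the overfitting guard without the ~50% power loss.

Even with the post-check, exact-set recovery is bounded by a selection
effect the ceiling cannot fix: the best-gain candidate is also the
smallest-p candidate, so after all true drivers are in, the chance that the
tested noise covariate clears alpha is roughly `1 - (1-alpha)^k` for k
remaining noise terms (~23% for k = 5 at alpha 0.05), and precisely when a
noise covariate fits well the ceiling rises with it. Measured exact-set
recovery on the 3-driver + 5-noise benchmark is therefore ~75-85% for the
post mode and ~40-50% for the classical pre mode, with essentially 100% of
replicates selecting every true driver before any noise term. Users who
need strict parsimony should lower alpha; users comparing against other
implementations should use `ceiling_mode="pre"`.

## Richness trends

Richness is the per-sample count of OTUs with nonzero reads, computed after
decontamination and prevalence filtering (the same table order as the rest
of the pipeline; richness is presence-based and thus invariant to
sequencing-depth scaling). Per depth stratum, OLS of richness on latitude
gives the slope (OTUs per degree latitude), its standard error, the
two-sided t-test p-value, and a pointwise 95% confidence band for the
conditional mean (a regression band, not a prediction band) on an even
latitude grid; strata with fewer than 3 samples are skipped with a warning.
Slope CIs attain nominal coverage (95.1% over 1,000 simulations at n = 40).

The reads-vs-OTUs saturation fit supports two asymptotic forms, selected by
flag because the functional form is rarely stated: Michaelis-Menten
`a*x/(b+x)` (default) and exponential `a*(1-exp(-x/b))`. Fitting is
nonlinear least squares with self-starting values `a0 = max(otus)`,
`b0 = median(reads)` and positivity bounds; both forms are monotone
nondecreasing with asymptote `a`.

## Synthetic survey generator

The generator provides ground truth for every stage; its defaults define
the validation conditions and mirror the scale of a basin-wide benthic
survey while staying desk-sized:

- **Design:** 5 latitudinal regions x 3 depth strata x 6 samples = 90 true
  samples, plus 6 blanks of each control role (18 total); 400 community
  OTUs in 15 phyla; library sizes log-normal around 30,000 reads.
- **Counts:** log-normal-Poisson compound — each present OTU's expected
  relative abundance combines a fixed log-normal commonness baseline, its
  phylum's planted environmental effect, and per-cell log-normal noise
  (sigma 0.5), then a Poisson draw. This gives realistic overdispersion
  that plain multinomial sampling lacks.
- **Planted composition effects:** phylum log-abundance is linear in
  standardised latitude, depth, and oxygen. The leading phyla mimic the
  headline taxa of Red Sea benthos: a Chloroflexi-like phylum loading
  negatively on oxygen and latitude, a Proteobacteria-like phylum loading
  positively on both, deep-loving Gemmatimonadota/Acidobacteriota
  analogues, and a shallow-loving Planctomycetota analogue.
- **Environment:** latitude uniform within region bands (16-29.5 N), depth
  uniform within stratum ranges (20-2415 m), temperature and salinity as
  noisy linear proxies of latitude and depth, oxygen increasing northwards
  and decreasing with depth with independent noise (sd 8% saturation), and
  15% of oxygen values missing at random (one sensor platform lacking an
  oxygen probe). Because oxygen acts on communities through its measured
  value, its independent noise is genuine signal for driver recovery.
  Temperature is deliberately a near-deterministic combination of latitude
  and depth: in a minority of replicates it wins the first selection step
  as a joint proxy — a realistic failure mode worth keeping visible rather
  than designing away.
- **Richness:** each sample's target richness is linear in latitude with a
  per-stratum slope (epibenthic -6, mesobenthic -3.5, bathybenthic 0 OTUs
  per degree, baseline 140 at 23 N, Gaussian noise sd 6); the present OTU
  set is drawn by weighted sampling without replacement (Gumbel-max on the
  commonness baseline) so common OTUs recur across samples and survive the
  prevalence filter.
- **Contamination:** 6 contaminant OTUs with per-contaminant loads appear
  in every library — full load in blanks, half load smeared uniformly
  across true samples — exactly the proportional carry-over scenario the
  subtraction contract targets; blanks also receive trace carry-over
  (Poisson, rate 0.3) of the 20 most common genuine OTUs.
- **Reference and hits:** the survey's reference taxonomy is generated over
  the planted phyla, and each community OTU's hit list has its true source
  inside its planted phylum at an identity above the phylum cutoff, with
  within-margin relatives confined to the same phylum — so the pipeline's
  own taxonomy stage provably recovers the phylum structure that the
  ordination and correlation stages then detect.

Everything is bit-reproducible under a fixed seed. What the synthetic
validation shows: the algorithms recover exactly the structure planted
under their own model assumptions (linear log-abundance effects, Gaussian
noise, proportional contamination). What it does not show: robustness to
real-survey pathologies — taxonomic misannotation in reference databases,
PCR and chimera artefacts, non-proportional (batch-borne) contamination,
spatial autocorrelation between neighbouring sites, or model misspecification
in the richness trend. Passing tests certify the implementation, not the
field performance of the methods.

## Numerical and reproducibility choices

- Validation is total at ingest: counts must be nonnegative integers,
  identities within [0, 100], depths positive; missing oxygen is NaN, never
  zero. Fractional abundances exist only downstream of ingest.
- Eigenvalue cut-off 1e-10 separates true axes from numerical zeros; clr
  closure is asserted at 1e-9; the RDA oracle agrees to ~1e-14.
- The pipeline runner derives per-stage seeds from the single global seed
  (seed * 1000 + stage index, mod 2^31 - 1) so stages can be re-run in
  isolation; two runs with identical config and seed produce byte-identical
  TSV/JSON artifacts.
- Degenerate inputs fail loudly: tables without controls (decontamination),
  samples with zero total reads (clr), rank-deficient constraints (dropped
  with warning), strata below 3 samples (skipped with warning),
  non-convergent saturation fits (error with the optimizer's message).

## Validation protocol sizes

The replicated protocols (`benthos16s.acceptance`, reported by
`scripts/acceptance.py`) use: 1,000 random hit sets for oracle agreement;
200 hit sets x 4 margins for monotonicity; the default 90-sample survey for
decontamination, clr, and slope checks; 50 random 15x6 problems for the RDA
oracle; 100 replicates at n_perm = 199 for forward-selection recovery;
1,000 null replicates for permutation calibration; and 1,000 simulations at
n = 40 for CI coverage. The vectorised permutation machinery keeps the full
set under ten seconds on one CPU.
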