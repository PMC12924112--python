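# benthos16s

Post-clustering analysis of benthic 16S rRNA amplicon surveys: consensus
taxonomy from similarity hits, blank-based decontamination, compositional
(clr) community statistics, constrained ordination with forward selection,
and depth-stratified richness trends — plus a synthetic-survey generator
with known ground truth that makes every stage testable without sequence
data.

It is written for microbial ecologists who already have an OTU table, a
tabular similarity search against a ranked reference (BLAST outfmt 6 +
SILVA-style lineages), and sample metadata, and who want the downstream
statistics reproducible and auditable rather than buried in a notebook.

## The methods

**Taxonomy.** Per OTU, hits are filtered by score (bitscore ≥ 150 and
alignment length ≥ 100 by default), reduced to those within a 2% margin of
the best bitscore, collapsed to their lowest common ancestor (LCA), and
trimmed to the rank permitted by the best retained identity under the
strict ladder

> species > 98%, genus > 95%, family > 90%, order > 85%, class > 80%,
> phylum > 75%

so e.g. identity 96.3 caps an assignment at genus, and ≤ 75% leaves the OTU
unassigned.

**Decontamination.** Field/extraction/PCR blanks define a contamination
profile; the OTU most abundant in blanks anchors a per-sample scaling, and
each control OTU's expected contribution is subtracted, floored at zero
(integer counts throughout).

**Community statistics.** Prevalence < 3 OTUs are discarded; counts are
aggregated by rank (top-k with an "other" pool); analyses run on centred
log-ratios, clr(x)_i = ln(x_i + δ) − mean_j ln(x_j + δ); Pearson
correlation grids relate clr taxa to environmental covariates on
pairwise-complete observations.

**Ordination.** Redundancy analysis (RDA) of the clr matrix constrained by
environmental variables: eigenanalysis of the fitted values of Y ~ X, with
permutation-backed forward selection of constraints (largest adjusted-R²
gain, partial pseudo-F permutation test, full-model adjusted-R² ceiling).

**Trends.** Per depth stratum (epibenthic < 200 m, mesobenthic 200–1000 m,
bathybenthic > 1000 m), OLS of OTU richness on latitude with slope t-tests
and 95% confidence bands, plus an asymptotic saturation fit of OTUs versus
reads.

## Worked example

The `analysis/` scripts run the whole stack on the default synthetic survey
(90 samples across 5 regions × 3 depth strata, 400 OTUs in 15 phyla with
planted latitude/depth/oxygen effects, 18 blanks, 6 planted contaminants):

```bash
python analysis/01_simulate.py
python analysis/02_assign_taxonomy.py
python analysis/03_decontaminate.py
python analysis/04_community.py
python analysis/05_ordination.py
python analysis/06_trends.py
```

which prints, among other things:

```
planted-phylum agreement among phylum-assigned OTUs: 400/400
OTUs removed: 4; planted contaminant reads removed: 96.2% of 70770
RDA on 76 oxygen-complete samples
  + depth_m: adjR2=0.380 p=0.0010
  + latitude: adjR2=0.654 p=0.0010
epibenthic   n= 30 slope=  -6.09 OTUs/deg (SE 0.30) p=2.327e-18
mesobenthic  n= 30 slope=  -3.71 OTUs/deg (SE 0.33) p=8.428e-12
bathybenthic n= 30 slope=   0.55 OTUs/deg (SE 0.29) p=0.06738
```

Reading the numbers: the taxonomy stage recovers the planted phylum of
every assignable OTU; decontamination removes ~96% of the planted
contaminant reads; forward selection finds depth and latitude as community
drivers (68% of clr variance constrained); and the richness regressions
recover the planted slopes — a strong negative latitudinal gradient in the
epibenthic stratum (−6.1 OTUs per degree, planted −6) and no significant
gradient in the bathybenthic stratum (planted 0). The correlation grid
(`results/correlations.tsv`) shows the planted Chloroflexi-like phylum with
r = −0.95 against latitude and r = −0.68 against oxygen.

The same stages are available as a CLI (`benthos16s synth / assign /
decontam / community / ordination / trends / pipeline`); `benthos16s
pipeline --config run.yaml` runs everything end-to-end, writing every
intermediate artifact, a run manifest with per-stage OTU counts, and a
resolved config, byte-identically reproducible under a fixed seed.

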