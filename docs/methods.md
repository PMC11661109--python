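# Methods

This note documents the statistical model behind each component, the
defaults and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical conventions.

## Differential expression model

Counts for gene *g* in sample *j* are modelled as negative binomial with
mean `μ_gj = s_j · q_g(group_j)` and variance `μ + α_g μ²`, where `s_j` is a
per-sample size factor and `α_g` the per-gene dispersion.

**Size factors.** `s_j = total_j / geomean(totals)`, i.e. plain library-total
normalization (geometric mean of the factors is exactly 1). This is simpler
than median-of-ratios normalization and is appropriate here because the
screen's contrasts compare laminae of the same tissue, where composition
shifts are modest; it is also the definition under which the FPKM gates were
set. A consequence worth knowing: if a large fraction of the transcriptome
changes in one direction, totals-based factors absorb part of the fold
change (the test suite demonstrates this stays negligible when ≲ 1–2 % of
genes are differential).

**Dispersion.** Per-gene method of moments on normalized counts
`y_j = c_j / s_j`: with the two group means removed,
`α̂ = max(α_floor, (v − m) / m²)`, where `v` is the pooled within-group
variance (unbiased, `n − 2` df) and `m` the pooled mean; `α_floor = 1e-8`.
There is deliberately no empirical-Bayes shrinkage toward a mean–dispersion
trend: the estimator is transparent and per-gene, at the cost of power at
small replicate numbers (see below). All-zero genes get the floor and are
flagged untestable.

**Wald test.** The two-group NB GLM (log link, offsets `log s_j`) is fitted
by IRLS at fixed `α̂`, vectorized across genes; convergence when the maximum
coefficient change is < 1e-8, cap 100 iterations. The reported
`log2_fc` is the group coefficient divided by ln 2, its standard error comes
from the inverse Fisher information at convergence, and the Wald statistic
is coefficient/SE.

*p-value reference.* The Wald statistic is referred to a Student-t
distribution with `n_samples − 2` degrees of freedom rather than the
standard normal. With a plain per-gene moment dispersion, the standard error
carries only the few within-group degrees of freedom, and the normal
reference is badly anticonservative at realistic replicate numbers
(empirical type-I error ≈ 0.11 at nominal 0.05 with 3 + 3 samples; the t
reference restores ≈ 0.04, and the two references coincide as n grows).
This is the package's small-sample correction for forgoing dispersion
shrinkage; pipelines that shrink dispersions across genes gain the missing
degrees of freedom there instead and can justify a normal reference.

**Zero-group convention.** Genes expressed in only one group are fitted
normally (the offset model tolerates them) but the reported |log2 FC| is
capped at 30 to avoid infinities; genes with all-zero counts in both groups
are untestable and excluded from multiplicity correction.

**Multiple testing.** Benjamini–Hochberg step-up within each contrast
(per species, per layer pair), implemented directly and cross-checked in the
tests against both statsmodels and a literal O(m²) oracle.

## The screening cascade

1. **Per-species SVZ enrichment.** A gene is SVZ-enriched in a species iff
   every SVZ-type layer of that species (ISVZ *and* OSVZ where the SVZ is
   split; the single SVZ otherwise) shows padj < 0.05 and log2 FC ≥ 1 versus
   CP. The conjunction is the strictest reading of "selectively expressed in
   SVZ". The cross-species intersection (in reference-species ids, via the
   ortholog table) is recorded as the conserved-SVZ consensus.
2. **Reference-lineage specificity** is a set difference: human SVZ-enriched
   genes whose orthologs are SVZ-enriched in *no* other species. Genes
   without any ortholog survive this step by design — specificity cannot be
   assessed for them — and are removed at step 3. (A cross-species
   SVZ-vs-SVZ DE alternative was considered and rejected: it would conflate
   normalization across genomes with the specificity question.)
3. **Orthology filter**: one-to-one ortholog required in every screened
   species.
4. –5. **FPKM gates** with strict inequalities: replicate-mean FPKM > 50
   over the human SVZ-type layers and < 1.5 in every layer of every other
   species. `gate_scope="all_layers_max"` switches the human condition to
   the maximum over layers. Replicates are summarized by the arithmetic
   mean. FPKM uses raw column totals, not size-factored totals, matching the
   standard definition.

The DE significance cutoffs (padj < 0.05, log2 FC ≥ 1) are package
conventions exposed in the config — the screen definition itself fixes only
the FPKM gates.

## Synthetic data

`simulate_laminar_counts` emulates the study design the screen assumes: four
species — human, macaque and tree shrew with CP/OSVZ/ISVZ/VZ, mouse with
CP/SVZ/VZ — and 5 replicates per layer. Baseline expression is drawn per
gene as log2 FPKM uniform on [0, 6] and renormalized so that
`Σ fpkm·length = 10⁹`; expected counts are then
`μ = fpkm · library_size · length / 10⁹` with library sizes uniform on
[8·10⁶, 1.2·10⁷] and lengths uniform on [500, 5000] bp, and counts are NB
with dispersion α = 0.1 (Poisson when α = 0). Planting on the FPKM scale
makes the FPKM recomputed downstream from realized counts agree with the
planted values to within ~1 %, so the gates hold by construction.

Planted structure: 30 conserved-SVZ genes at log2 FC 2 in the SVZ-type
layers of every species; 1 human-specific gene at 80 FPKM in human SVZ
layers, 5 FPKM in human CP/VZ (log2 FC 4) and 0.5 FPKM in every layer of
every other species; 10 % of background genes lose their one-to-one ortholog
flag in one random species. One global seed drives a spawned per-purpose
seed sequence, so enlarging one planted program does not perturb unrelated
draws.

**Parameter rationale.** The dispersion default (0.1) is a typical
biological-replicate value for bulk tissue RNA-seq; the true laminar
dispersions are not published, so this is a convention, not a measurement.
The replicate default (5) was set by a power analysis during generator
design: the study design requires at least 3 replicates, but with per-gene
moment dispersions and the t-referenced Wald test, a log2 FC = 2 effect at
α = 0.1 cannot clear BH at 0.05 among 2000 genes at n = 3 (per-gene
p ≈ 6·10⁻³ against a step-up bar near 7.5·10⁻⁴); n = 5 is the smallest
replicate number at which the planted programs are detectable. The null
calibration checks use n = 3 + 3 directly and are unaffected by this
default.

**What passing tests do and do not show.** The generator draws independent
NB counts around species-shared baselines. It does not emulate: correlated
genes or co-expression modules, GC/length biases beyond the FPKM formula,
sample-quality or batch effects, mappability differences between genomes,
or compositional shifts between layers. Recovery of the planted gene
therefore demonstrates the pipeline's logic and calibration, not robustness
to those real-data pathologies. Consensus recovery of the conserved program
is deliberately partial at the default dispersion (a conjunction over up to
7 contrasts with unshrunken per-gene dispersions is conservative); the
screen's scored property is isolation of the lineage-specific candidate with
few false positives, which is robust (~97 % of runs recover it with zero
false candidates on average).

`simulate_allelic_expression` plants a parental log2(human/chimp) ratio of
cis + trans + ε and a hybrid allelic ratio of cis + ε with independent
N(0, noise_sd) noise per measurement. `simulate_trait_trend` draws
replicate-level expression linear in a species trait with the slope
calibrated so the population correlation equals the target
(`slope = sign(r)·σ·|r| / (sd_trait·√(1−r²))`); with zero noise the points
are an exact line.

## Comparative analyses

Cis/trans decomposition follows the hybrid-cell logic: both alleles of a
hybrid share one trans environment, so the hybrid allelic log2 ratio is the
cis effect and the parental ratio minus it is the trans effect. The identity
cis + trans = parental log2 ratio holds at machine precision by
construction; zero denominators yield flagged NaNs rather than errors.

Trait correlations are computed at the replicate level (each measurement
paired with its species' trait), which matches how per-point scatter is
usually reported and gives honest degrees of freedom; a species-mean option
exists. Brain weight is log10-transformed before correlating (allometric
convention). Plain Pearson correlation is used, without phylogenetic
independent contrasts — species data points are not phylogenetically
independent, so these r values describe the trend but their p-values
overstate independent evidence. The bundled trait table
(`DEFAULT_SPECIES_TRAITS`) contains round literature-scale values and is a
simulation input, not a dataset.

## Gyrification index

`GI = inner arc length / outer outline length`. The "smoothly enclosing"
outer surface is the convex hull of the contour points: parameter-free,
reproducible, and guaranteeing GI ≥ 1 for closed contours. This is a 2D
section-based GI; for anatomically concave sections (where the hull bridges
true concavities) a morphological-closing outline would be more faithful —
that variant is a known limitation, not implemented. Contours are
dimensionless ordered point lists; unit consistency is the caller's
contract. Closed contours given with a repeated first/last point have the
duplicate removed (closure is implicit).

Local GI has no canonical window size, so `window_arc` is a required
explicit parameter: windows of that outer-outline arc length advance by
`step_arc` (wrapping around), inner segments are assigned to windows by the
nearest-point projection of their midpoints onto the hull ring, and local
GI is assigned inner length / window length. With step = window the windows
partition the outline and the mean local GI approximates the global GI.

## Numerical conventions

- IRLS: linear predictor clipped to ±30 (natural log) during iteration;
  coefficient cap equivalent to |log2 FC| = 30; non-positive normal-equation
  determinants mark a gene untestable rather than aborting the batch.
- BH: mergesort (stable) ordering; ties therefore resolve deterministically.
- PCA sign convention: the largest-magnitude gene loading of each component
  is forced positive, making embeddings deterministic.
- All tabular output is TSV (UTF-8, "." decimal mark, `%.12g` floats), so
  identical runs are byte-identical; every simulation is a pure function of
  its seed.
- Problem sizes in the test and acceptance runs (2000 genes, 20–50 seed
  replicates, 3–5 replicates per group, contours of ≤ 20 000 points) were
  chosen as the smallest sizes at which the measured quantities are stable;
  everything completes in well under a minute except the 20-dataset recovery
  sweep (~1 minute).

## Known limitations

- No multi-factor designs, continuous covariates, outlier replacement or
  independent filtering in the DE module.
- Totals-based size factors are not robust to strong compositional shifts.
- Per-gene dispersion without shrinkage costs power at small n (mitigated,
  not removed, by the t reference).
- The screen's step-2 definition ("enriched nowhere else") treats absence of
  evidence in another species as evidence of absence; underpowered
  non-reference species inflate the step-2 set (they are then caught by the
  FPKM gates only if lowly expressed).
- GI with a convex-hull outline overestimates folding for globally concave
  sections.
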