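# Methods

This note documents the models and procedures implemented in `locogwas`,
the defaults and numerical choices behind them, what the synthetic cohorts
do and do not emulate, and the known limitations.

## Genotype handling

Genotypes are held as diploid two-character calls (`"AG"`, missing =
`"NN"`) with per-marker metadata (name, chromosome label, 1-based bp
position, allele pair, anchored flag).  HapMap files are read with both
two-character and one-character IUPAC genotype encodings accepted;
two-character calls are written.  VCF input (via cyvcf2) accepts biallelic
SNP records only; multi-allelic records are skipped with a logged count.
A marker is *anchored* when its chromosome label belongs to the configured
chromosome set (default `"1"`–`"10"`) and its position is ≥ 1; scaffold
and contig labels count as unanchored.

Filtering applies three removal rules in a fixed order so the accounting
is well defined: unanchored → missingness → minor allele frequency.  Each
marker is counted once, at the first rule it fails.  Boundary semantics
are strict removal — missing fraction strictly > 0.75 and MAF strictly
< 0.05 are removed, so markers exactly on either boundary are retained.
MAF is computed on observed (non-missing) allele calls, before imputation;
a heterozygote contributes one copy of each allele.

Numeric encoding counts copies of the per-marker *minor* allele (0/1/2),
with major/minor determined from observed calls and ties broken so the
lexicographically smaller allele is major.  Missing calls are imputed
conservatively as the major-allele homozygote (dosage 0) and flagged in a
mask; this is the standard conservative choice for association scans, and
it biases imputed genotypes toward the population mode rather than
inventing minor alleles.  Monomorphic markers encode as all-zero with a
warning and are reported as null results (effect 0, p = 1) by the scan.

## Loiselle kinship and the LOCO scheme

Pairwise coancestry between individuals i and j is estimated as

    F_ij = Σ_l Σ_a [ (p_ila − p̄_la)(p_jla − p̄_la) + p̄_la(1 − p̄_la)/(n_l − 1) ]
           ───────────────────────────────────────────────────────────────────
                           Σ_l Σ_a p̄_la (1 − p̄_la)

where p_ila ∈ {0, ½, 1} is individual i's frequency of allele a at locus
l, p̄_la the mean over the n_l individuals genotyped at that locus, and
the p̄(1−p̄)/(n_l − 1) term is the small-sample bias correction.  Choices
the estimator's literature leaves open, fixed here:

- **n_l counts individuals**, not gametes, in the correction term.
- **Missing data are handled pairwise-complete**: a locus contributes to
  F_ij (numerator *and* denominator) only when both i and j are genotyped
  there.  This keeps every pair's estimate a proper ratio over its own
  informative loci.
- **Negative estimates are retained** (no truncation at zero); downstream,
  kinship eigenvalues below zero are clamped with a warning, since the
  estimator is not guaranteed positive semi-definite.
- Loci with fewer than two genotyped individuals are skipped; if every
  usable locus is monomorphic the denominator is zero and the function
  raises (`no informative loci`).

For testing markers on chromosome c, the kinship K_c is computed from all
markers *not* on c (leave one chromosome out).  This avoids proximal
contamination: a tested marker that also contributes to K competes with
itself through the random effect, which costs power.  Kinships are built
from the full filtered marker set — no subsampling.

## Mixed-model association

The per-marker model is y = Xβ + x_j β_j + u + e with u ~ N(0, σ²_g K_c)
and e ~ N(0, σ²_e I).  No compression is applied: each line is its own
random-effect level.  Fixed effects default to an intercept only;
covariate columns can be supplied but no population-structure covariates
are added automatically (structure control is the kinship's job).

Variance components are estimated by REML via a single eigendecomposition
of K per chromosome.  In the rotated basis the covariance is diagonal,
σ²_g (d_i + δ) with δ = σ²_e/σ²_g, so σ²_g is profiled analytically and
the restricted likelihood is a 1-D function of δ.  The search uses a
log₁₀ grid from −5 to 5 in 100 steps followed by bounded scalar
refinement (tolerance 1e−6 on log₁₀ δ).  The implemented criterion equals
the dense-matrix form −½[log|V| + log|XᵀV⁻¹X| − log|XᵀX| + (n−q)(log 2πσ̂²_g + 1)]
and is verified against a direct |V|-based oracle in the tests.

By default the null-model components are reused for every marker on the
chromosome (P3D); exact per-marker re-optimization is available by flag
(`MlmConfig(p3d=False)`).  Each marker test is weighted least squares in
the rotated basis, with the residual scale re-estimated per marker
(σ̂² = RSS_w/(n−q)), so with K = I and δ fixed the procedure reduces
exactly to the OLS F-test.  Reported statistics: effect, SE,
F = (β̂/SE)² with (1, n − q) degrees of freedom, and the two-sided
F-distribution p-value.  A degenerate phenotype (y in the column space of
X) yields near-zero variances without error.

Chromosome scans are pure functions; parallel execution (joblib) merges
results in (chromosome, position) order, so worker count cannot change the
output bytes.

The genomic inflation factor λ is the median of χ²₁ quantiles of 1 − p
divided by the null median (≈ 0.4549).  With m markers the sample median
gives λ a standard error of roughly 2.2/√m, which is why calibration
checks here use ≥ 2000 markers.

## Significance selection

- **Bonferroni**: threshold α/n with n the number of tests in scope.  The
  default scope is per chromosome — each chromosome is scanned as its own
  family, so n_c is that chromosome's marker count.  A global scope is
  available.  Selection is inclusive (p ≤ threshold).
- **Benjamini–Hochberg**: step-up rule — largest rank k with
  p(k) ≤ Q·k/m; reported adjusted p-values use the standard monotone
  adjustment min(1, min_{j≥i} m·p(j)/j) (delegated to statsmodels).  BH
  ranks over the full result set by default (m = all markers in the
  scan); per-chromosome ranking is available since the scan itself is
  per-chromosome and either reading is defensible.
- **Manual**: a fixed p cutoff.

For Manhattan plots a single horizontal guide is drawn at the arithmetic
mean of the per-chromosome −log₁₀ thresholds.  This averaged line is a
visual aid only; selection always uses the per-family thresholds.

## Annotation

Feature lists come from GFF3, keeping chromosome, start/stop, and the
`Name`/`ID` attribute; recognized classes are gene, tRNA, lnc_RNA/ncRNA
(and miRNA as ncRNA), with structural children (exon/CDS/mRNA/UTR) left to
the architecture track.  Malformed lines are skipped with a warning.  A
transcript→protein name map can rewrite coding feature names.

A marker's candidate features are ranked by |marker position − feature
midpoint| on the same chromosome (midpoint = ⌊(start+stop)/2⌋), found by
bisection over per-chromosome sorted midpoints; ties go to the smaller
midpoint.  Association is either the nearest n features (default n = 10)
or all features within an LD window in bp (closed interval; a zero window
keeps only exact midpoint matches — window choice matters because LD decay
differs between species and panels).  The reported distance is signed,
marker − midpoint, positive when the marker lies downstream of the
midpoint on the + coordinate axis.

Cross-proteome homology uses full Smith–Waterman local alignment with
affine gaps (BLOSUM62, gap of length L costs 11 + L; `X` scores 0 against
everything).  Every subject in the secondary proteome is scored and the
best hit reported (ties → lexicographically smaller subject name), with an
e-value from the gapped Karlin–Altschul approximation
E = K·m·n·exp(−λ_ka·S) using the published BLOSUM62/11/1 constants
λ_ka = 0.267, K = 0.041 (m = total database length, n = query length).
These e-values approximate, and do not reproduce, NCBI BLAST statistics —
BLAST's seeded heuristics, composition adjustments, and length corrections
are out of scope — so they should be read as a ranking score with a
familiar scale.  The aligner itself is exact (no seeding), which at
toy-proteome scale is both simpler and faster to verify; an external
aligner could be slotted in behind `homology_best_hit` for genome-scale
proteomes.

The final report emits one row per (significant marker × associated
feature), sorted by (chromosome, position, |distance|), carrying raw and
BH-adjusted p-values, the signed distance, feature identity and class, and
per-species best hits.  Non-coding features carry empty homology columns;
markers with no association yield a single row with empty feature fields.
Assembly is a pure function — identical inputs give byte-identical files.

## Phenotypes and the damage index

Phenotype tables are two-column (taxon, value) text, tab or comma
delimited, typically BLUPs from a field trial; non-numeric values become
missing with a warning and duplicate taxa are an error.  Taxon names can
be standardized (aliases, suffix stripping, case fold) with collisions
rejected, so genotype and phenotype naming conventions can be reconciled
deterministically.

The borer damage index discretizes holes of larval entry per cm of
internode length into bins of width 0.032 holes/cm:
index = ⌊h/0.032⌋ + 1, clipped to [1, 10].  The source scale is stated by
its anchor points rather than a closed form; this left-closed rule is the
unique binning consistent with all three anchors simultaneously
(0 → 1, 0.05 → 2, 0.15 → 5) and is monotone with uniform boundaries.
Values beyond the tenth bin clip to 10.  Trait relationships are
summarized as squared Pearson correlations over pairwise-complete values.

## Synthetic cohorts

`simdata` generates Balding–Nichols cohorts: ancestral allele frequencies
~ Uniform(0.1, 0.9), subpopulation frequencies ~ Beta(p(1−F)/F,
(1−p)(1−F)/F) (the F = 0 limit handled analytically), diploid dosages
binomial, calls masked to missing at the configured rate, positions
strictly increasing.  Defaults describe a modest diversity panel: 300
taxa, two subpopulations at F_ST = 0.2, 10 chromosomes × 200 markers, 3%
missing calls.  Phenotypes are additive, g = Σ dosage·a_j, with Gaussian
noise scaled so Var(g)/Var(y) equals the requested h².  Optional haplotype
-block copying (two draws from a 16-haplotype per-subpopulation pool per
block) induces within-chromosome LD.

What the simulator does *not* emulate: coalescent-accurate LD decay,
allele-frequency spectra of real panels, inbreeding (lines are
Hardy–Weinberg draws, not inbred), genotyping-platform error modes, or
maize demography.  Tests passing on these cohorts therefore demonstrate
the statistical machinery (calibration, structure control, recovery of a
planted signal, oracle agreement), not performance on any real panel.

`choose_common_marker` picks the highest-MAF marker (deterministically) to
carry a planted causal effect: under Balding–Nichols differentiation a
uniformly chosen locus can drift near fixation, and a causal marker that
fails the MAF filter leaves no recoverable signal, which is a property of
the draw rather than of the method under test.

The fixture bundle writes HapMap + VCF genotypes, a phenotype TSV, a toy
GFF3 (genes with exons, a tRNA, a lncRNA per chromosome), two secondary
proteomes containing designed near-duplicates of the per-gene query
proteins plus unrelated decoys, and a `manifest.json` ground truth
(causal markers, nearest features) so tests never re-derive truth from the
generator's internals.  All outputs are pure functions of (config, seed).

## Pipeline engineering

A run is driven by one `PipelineConfig` (YAML-serializable); the config is
stored with every run and suffices to reproduce it.  Every stage writes
its artifact (filter stats, per-chromosome kinship matrices, the scan
table, the significance table, the annotated report, the Manhattan SVG)
plus a JSON run log with per-stage timings, filter accounting,
per-chromosome test counts, and variance components.  A stage failure
aborts with the stage name and a partial-state manifest.  `reannotate`
replays only significance → association → homology → report from the
persisted scan; the scan artifact is read, never rewritten, so its hash is
invariant.  SVG output disables embedded dates and uses a fixed hash salt,
making figures byte-reproducible.

## Problem sizes used in the validation suite

The test suite scales simulations to what the statistical check needs:
dense-matrix oracle equivalence on 20 instances of ≤ 40 taxa × ≤ 50
markers (where the dense fit is exact and cheap); type-I calibration and
structure control at the generator's default 300 taxa × 2000 markers
(≥ 2000 tests keep the binomial and median-λ noise inside the asserted
bands); power/recovery at 300 taxa with one causal marker explaining 25%
of variance; selection and annotation engines against exhaustive oracles
at 10³–10⁴ elements.

## Known limitations

- Only biallelic SNPs; indels and multi-allelic records are skipped.
- No compression/clustered-taxa model, no GLM/FarmCPU/SUPER alternatives,
  and no multi-trait models.
- The Loiselle variant (individuals in the correction term,
  pairwise-complete denominator) is one defensible reading of an
  under-specified estimator; oracle tests pin this package's variant.
- Homology e-values are approximations (above), and the aligner reports a
  single best local alignment per subject — no HSP chaining or
  reciprocal-best-hit orthology.
- No coordinate liftover between assembly versions; inputs are assumed to
  share one coordinate system.
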