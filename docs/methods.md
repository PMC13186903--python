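# Methods

This note documents the models and procedures implemented in
`haplostrat`, the parameters that matter, the design choices made where
the design was genuinely open, and what the synthetic-data validation
does and does not demonstrate.

## Haplotype blocks

Markers are packed per chromosome into non-overlapping runs of exactly
`block_size = 4` consecutive SNPs with strict constraints
`span < max_span_bp = 150,000` and every adjacent gap
`< max_gap_bp = 50,000` (coordinates are 1-based, inclusive; chromosome
labels are opaque strings). The partition is a single greedy
left-to-right scan: a marker joins the current run iff both constraints
hold; a full run is emitted and the scan restarts at the next marker; a
marker that cannot join restarts the run at itself, and members of runs
that never reach 4 are recorded as unassigned, never merged into
undersized blocks. For fixed block size on a sorted line with runs
resetting at violations, this greedy packing maximizes the number of
emitted blocks. With the default parameters the span constraint is
implied by the gap constraint (3 gaps × < 50 kb < 150 kb) but it is
enforced anyway, because it binds for non-default parameters.

## Allele-sharing distance

The per-marker sharing between two unphased diploid genotypes is the
identity-by-state fraction `s(a,b) = 1 − |a−b|/2` on dosage codes (1 for
identical genotypes, 0.5 when exactly one allele matches, 0 for opposite
homozygotes). Block sharing averages `s` over the block's markers and is
defined only when both animals are fully observed on the block
(whole-block pairwise deletion); the distance is one minus the equally
weighted mean of defined block sharings. This is a genotype-level
statistic: array genotypes are unphased and no phasing is performed, so
blocks matter through missing-data handling and per-block averaging, not
through haplotype identity. A phased haplotype-sharing variant would be
a drop-in replacement for `pair_block_sharing`; the chosen statistic is
deliberately the simplest one consistent with unphased input and is
flagged as an approximation wherever block-level semantics are
discussed.

Pairs whose fraction of defined blocks falls below
`min_valid_fraction = 0.5` raise an error naming the offending pairs;
missing-data failure is loud, never silent. The matrix computation is
vectorized through the identity
`Σ|a−b| = Σa² + Σb² − 2Σab − 2·#{opposite homozygotes}` on
block-masked dosage matrices (all sums are integer-valued floats, so the
result is exact); symmetry is enforced explicitly against BLAS rounding
and the diagonal is exactly zero.

Dosage orientation (which allele is "B") is the lexicographically larger
allele observed at the marker. The distance is invariant to flipping the
orientation at any subset of markers — sharing counts matching alleles —
so the choice affects only reporting; it is recorded in the map's
metadata columns.

## MDS

Classical (Torgerson) scaling: eigendecomposition of
`B = −½ J D² J` with `J` the centering matrix. Coordinates use the top
`dims = 2` eigenpairs; axes whose eigenvalue is non-positive (the ASD
need not be Euclidean) are zero-filled and counted in
`n_negative_axes`, never silently clipped. The reported `stress` is the
sum of squared residuals between input and embedded distances over
unordered pairs. Sign convention: each axis is flipped so the
reference-panel-A centroid is non-negative (first animal without
panels), making plots reproducible. Metric MDS was chosen over
non-metric variants because the input is a distance matrix projected
"onto the plane" — the textbook Torgerson use; the embedding is a
diagnostic, not the classifier.

## UPGMA

Size-weighted average linkage with node height = merge distance / 2.
Ties in the closest-pair search break on the lexicographically smallest
pair of cluster representatives (each cluster represented by its
smallest leaf id), and leaf ordering at each node puts the child with
the smaller minimal leaf first, so dendrograms, Newick exports and
heatmap orderings are byte-reproducible regardless of input order. The
implementation is an explicit O(n³) agglomeration (n ≤ a few hundred
animals); correctness is checked against a brute-force reference that
recomputes all cluster-pair averages from the original matrix at each
step, and against exact reconstruction of ultrametric inputs'
cophenetic matrices.

## Breed assignment

Each experimental animal's mean distance to the two purebred panels
gives the dominance score `(d̄_B − d̄_A)/(d̄_A + d̄_B)` ∈ [−1, 1];
score > 0 labels the animal A-dominant, score < 0 B-dominant, and
|score| ≤ `tie_band` (default 0) leaves it unassigned. The nearest-mean
rule replaces the visual MDS/heatmap judgment with a reproducible,
monotone criterion; the tie band exists for genuinely intermediate
animals. The score is antisymmetric under swapping panel roles and
depends on references only through panel means.

## Statistical layer

* **Mann–Whitney U** (two-sided, midranks). Exact mode computes the
  permutation null of all C(n1+n2, n1) assignments of the pooled
  midranks via a subset-sum dynamic program on doubled midranks
  (midranks are multiples of ½), which reproduces literal enumeration
  exactly while staying fast at n1+n2 = 20; `auto` uses exact up to
  n1+n2 ≤ 20 and otherwise the normal approximation with tie and
  continuity corrections. Two-sidedness is
  `P(|U − n1·n2/2| ≥ |U_obs − n1·n2/2|)`.
* **Fisher's exact test** for 2×2 tables: two-sided p sums
  hypergeometric probabilities of margin-fixed tables with probability
  ≤ the observed one (relative tolerance 1e−7 for floating-point ties);
  degenerate margins give p = 1; the statistic is the sample odds ratio
  (∞ when one off-diagonal cell is 0).
* **Pearson correlation** with the t-transform p on n−2 degrees of
  freedom.
* **ΔΔCt**: ΔCt = Ct_gene − Ct_ACTB per sample; ΔΔCt subtracts the
  arithmetic mean control ΔCt (animals are unpaired, so no per-sample
  pairing); fold = 2^−ΔΔCt. The control-group mean ΔΔCt is zero by
  construction and folds are invariant to sample-wise Ct shifts.
* **AF endpoints**: an induced episode is strictly longer than
  `episode_min_s = 10` s; the per-animal endpoint is "any inducing
  episode", the per-stimulation endpoint the fraction of burst
  stimulations that induced one. Group contrasts use Fisher's exact
  test at both levels; the stimulation-level test pools stimulations
  across animals, ignoring within-animal clustering — a documented
  caveat, not a modeling claim.
* **Stratified report**: within-breed IHF-vs-control and cross-breed
  IHF-vs-IHF contrasts for ejection fraction, pressures, AERP/AVERP per
  cycle length (500–250 ms grid), sinus-node recovery, fibrosis mean and
  heterogeneity, fold changes per gene and tissue, AF endpoints, plus
  Pearson correlations of AF episode count against the fibrosis
  difference within each breed's IHF animals. Cells carry mean ± SEM
  and the two-sided p; empty cells become NA rows. All tests are
  two-sided at the descriptive 0.05 convention and **no multiplicity
  correction is applied** — the report header states this.

"Fibrosis difference" is defined here as the per-animal max − min of the
per-image fibrosis percentages within a region (ten images per region
expected), with the per-image SD exposed as an alternative; this is the
simplest spread statistic computable from per-image data that captures
regional heterogeneity.

## Synthetic cohort generator

The generator emulates the cohort structure the analysis assumes:

* **Breed divergence** — Balding–Nichols: ancestral frequency uniform on
  (0.1, 0.9); each breed's frequency Beta-distributed around it with a
  single divergence knob `fst` (default 0.1; realized Hudson-type F_ST
  on the default panels lands in 0.05–0.15). Real Pietrain/Landrace
  differentiation is unknown here; `fst` is a scenario knob, not an
  estimate.
* **Genotypes** — reference animals Binomial(2, breed frequency) per
  marker (49 Pietrain-like + 38 Landrace-like by default); experimental
  animals draw each of two allele copies from breed A with probability α
  (defaults α ∈ {0.8, 0.2}, 25 + 15 animals in a 10/15/8/7
  treatment-by-breed design). Admixture is modeled at the allele level
  with independent copies, so there is no linkage within blocks — 
  adequate for a genotype-level sharing statistic, inadequate for
  haplotype-identity statistics; a documented limitation.
* **Map** — 5,000 markers by default over 18 chromosomes with
  exponential inter-marker gaps (mean 30 kb), a density at which the
  4-SNP constraints assign roughly 70% of markers to blocks. Positions
  are strictly increasing by construction.
* **Phenotypes** — fibrosis per-image values Normal(baseline 5% + 6
  points for breed-A×IHF, SD 2), truncated to [0, 100]; AERP
  Normal(cycle-length baseline − 40 ms for breed-B×IHF, SD 15); EF
  reduced ~25 points under IHF in both breeds; filling pressures raised
  in both, right-atrial pressure only in breed B; AF induction Bernoulli
  per stimulation (6 burst stimulations; rates 0.32/0.30 under IHF,
  0.03/0.08 in controls) with induced episodes at a fixed 15 s
  (only the >10 s indicator feeds the endpoints); qPCR Ct values Normal
  (SD 0.5) with log2 shifts per gene/tissue/breed following the
  expected pattern (ECM and profibrotic genes up in breed-A IHF,
  down in breed-B IHF) and a common ACTB reference per sample.
* **Determinism** — everything derives from one `numpy` generator
  seeded by the mandatory `seed`; reruns are bit-identical.

What passing tests show: the pipeline recovers majority ancestry
(≥ 95% at F_ST = 0.1 with 2,000 SNPs), the statistical layer is exact
and calibrated, and breed-specific effects of realistic size are
detected with the stated group sizes. What they do not show: behavior
under real linkage disequilibrium, platform-specific missingness or
genotyping error, within-animal clustering of stimulation outcomes
(the iid Bernoulli model makes per-animal inducibility higher than a
clustered process with the same per-stimulation rate would), or any
biological claim about the breeds themselves.

## Numerical choices and degenerate inputs

* Missing genotype calls are a distinct code (−1), never imputed at I/O
  time; a marker with no observed calls is removed by the call-rate
  filter.
* Strict inequalities for block span/gap constraints and for the AF
  episode threshold (an exactly-10 s episode does not count).
* Exact Mann–Whitney deviations are compared with a 1e−9 absolute slack
  on a half-integer grid; Fisher ties with 1e−7 relative slack.
* An animal exactly equidistant from both panels is UNASSIGNED (score
  0); a zero denominator (both panel distances 0) also yields 0.
* Distance matrices are validated for symmetry, zero diagonal and
  non-negativity; ASD output additionally stays in [0, 1] by
  construction. Empty matrices are rejected at write time.
* Report cells with an empty group are NA rows, not exceptions; the
  count of UNASSIGNED animals is reported in the header.

## Problem sizes

Default analyses run on 5,000 markers × 127 animals in ~2 s. The test
suite uses 600–2,000 markers and 10–20 reference animals per panel, 200
replicates for report calibration/power and 1,000 random maps for the
partition property checks; the full suite completes in about three
minutes on one CPU.

## Known limitations

* The block-level sharing statistic is genotype IBS, not phased
  haplotype identity; with phased data the block statistic should be
  replaced, not reinterpreted.
* The informative-marker thresholds (MAF ≥ 0.01, call rate ≥ 0.90) are
  conventional array-QC defaults, configurable and recorded in the
  filter report.
* Per-stimulation AF contrasts pool stimulations across animals.
* No multiplicity correction anywhere; the report is descriptive by
  design.
* Triangle inequality is not guaranteed (nor asserted) for the ASD;
  MDS eigenvalues can be negative and are reported as such.
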