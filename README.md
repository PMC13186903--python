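# haplostrat

Genetic-background stratification for two-breed animal cohorts, built
around haplotype-block allele-sharing distances, and the downstream
genotype-stratified analysis of proarrhythmic remodeling phenotypes
(atrial fibrosis, electrophysiology, atrial-fibrillation inducibility,
qPCR fold changes).

## The problem

Experimental pig cohorts are often genetically heterogeneous mixes of
commercial breeds (e.g. Pietrain and German Landrace). In ischemic
heart-failure models of atrial fibrillation (AF), that hidden structure
can drive which remodeling route an animal takes — fibrotic versus
electrical — and blur group comparisons that ignore it. `haplostrat`
reconstructs each animal's dominant genetic background from SNP-array
genotypes and re-analyzes the phenotypes stratified by that background.

## The method

1. **Informative-SNP filter** — markers with minor-allele frequency
   ≥ 0.01 and call rate ≥ 0.90 (configurable) are retained.
2. **Haplotype blocks** — each chromosome's markers are packed greedily
   into non-overlapping blocks of 4 consecutive SNPs spanning < 150 kb
   with inter-marker gaps < 50 kb, balancing SNPs per block against
   within-block recombination probability.
3. **Allele-sharing distance (ASD)** — per marker, two unphased diploid
   genotypes with dosages *a*, *b* ∈ {0,1,2} share
   *s(a,b) = 1 − |a − b|/2* of their alleles (identity by state).
   Block sharing is the mean *s* over the block's 4 markers, defined only
   when both animals are fully observed on the block, and

   *d(i,j) = 1 − mean over defined blocks of block sharing* ∈ [0, 1].

4. **Structure views** — classical (Torgerson) MDS projects the distance
   matrix onto the plane; UPGMA (size-weighted average linkage) builds
   the ultrametric dendrogram used to order heatmaps.
5. **Breed assignment** — each experimental animal gets a dominance
   score *(d̄_B − d̄_A)/(d̄_A + d̄_B)* ∈ [−1, 1] from its mean distances
   to the two purebred reference panels; the sign gives the label.
6. **Stratified statistics** — within each breed label, heart-failure
   vs control contrasts by exact two-sided Mann–Whitney *U* (full
   enumeration of the midrank permutation null) or Fisher's exact test;
   qPCR expression as 2^−ΔΔCt fold changes normalized to *ACTB*; AF
   inducibility as episodes lasting > 10 s per animal and per burst
   stimulation; Pearson correlation of AF burden against the per-animal
   fibrosis difference (max − min of per-image fibrosis percentages).

A seeded synthetic-cohort generator (Balding–Nichols breed divergence,
allele-level admixture, breed-by-treatment phenotype interactions)
provides fully reproducible inputs with the same statistical structure,
so the entire pipeline is testable without animal data.

## Worked example

```python
from haplostrat import (CohortConfig, simulate_cohort, filter_informative,
                        partition_blocks, asd_matrix, assign_breed,
                        stratified_report)

cfg = CohortConfig(seed=7, n_snps=2000, n_ref_a=20, n_ref_b=20)
cohort = simulate_cohort(cfg)

gm, snp_map, report = filter_informative(cohort.genotypes, cohort.snp_map)
print(f"markers kept: {report['n_retained']} / {report['n_input']}")

blocks = partition_blocks(snp_map)   # 4-SNP blocks, <150 kb span, <50 kb gaps
print(f"blocks: {blocks.n_blocks} ({4 * blocks.n_blocks / len(snp_map):.0%} of markers)")

dm = asd_matrix(gm, blocks)
ba = assign_breed(dm, cohort.labels)
print(ba.frame.head(3).to_string(index=False))
```

prints

```
markers kept: 1995 / 2000
blocks: 344 (69% of markers)
    id      d_a      d_b    score      label
EXP001 0.292074 0.317902 0.042342 A_DOMINANT
EXP002 0.287472 0.310774 0.038950 A_DOMINANT
EXP003 0.296512 0.322104 0.041369 A_DOMINANT
```

`d_a`/`d_b` are each animal's mean allele-sharing distances to the
Pietrain and Landrace panels; a positive score labels the animal
Pietrain-dominant. The stratified report then recovers the simulated
interaction structure:

```python
rep = stratified_report(cohort.phenotypes, ba)
row = rep.lookup("within_breed", "Pietrain", "fibrosis_la_mean").iloc[0]
# IHF 11.1±0.1% vs control 5.0±0.2%, p=3.6e-05   (fibrosis rises in breed A)
row = rep.lookup("within_breed", "Landrace", "aerp_ms", 450).iloc[0]
# IHF 181±5 ms vs control 224±6 ms, p=0.00031    (AERP shortens in breed B)
```

The same pipeline is available from the shell:

```bash
haplostrat all --seed 7 --n-snps 2000 --out-dir run/
```

which writes the filter report, block partition, distance matrix, MDS
embedding, Newick dendrogram, breed assignment and the stratified report,
plus a manifest of content hashes (reruns with the same seed are
byte-identical).

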