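"""Synthetic two-breed cohort generator.

Generates genotype panels and phenotype tables with the statistical
structure the stratified analysis assumes, so the whole pipeline runs and
is validated without animal data:

* two founder breeds diverged under a Balding-Nichols model with a single
  F (fixation-index) knob;
* purebred reference panels drawn from each breed's allele frequencies;
* admixed experimental animals whose two allele copies are drawn
  independently from breed A's frequencies with probability alpha;
* phenotypes with a breed-by-treatment interaction: atrial fibrosis and
  profibrotic gene expression respond to heart failure only in
  breed-A-dominant animals, atrial refractory periods shorten only in
  breed-B-dominant animals, and AF inducibility rises under heart
  failure in both.

Everything is drawn from one seeded generator: a fixed seed reproduces
genotypes, map and phenotypes bit for bit.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .io import (
    EXPERIMENTAL,
    MISSING,
    REF_A,
    REF_B,
    GenotypeMatrix,
    PanelLabels,
    SnpMap,
)
from .phenostats import CONTROL, IHF, PhenotypeTable

#: default qPCR panel: target genes assayed in both atria, normalised to ACTB
GENES = ("COL1A1", "FN", "MMP2", "ACTA2", "FSP1", "CCN2", "TGFB", "JNK1", "cJUN")
TISSUES = ("LA", "RA")
REFERENCE_GENE = "ACTB"

# log2 expression shifts under IHF, keyed (gene, tissue, breed); the
# qualitative pattern: breed A (Pietrain-like) upregulates ECM/profibrotic
# genes (strongly in LA, as a trend in RA), breed B (Landrace-like)
# downregulates them.
DEFAULT_EXPRESSION_SHIFTS: dict[tuple[str, str, str], float] = {
    ("FN", "LA", "A"): 1.5,
    ("JNK1", "LA", "A"): 1.5,
    ("FN", "RA", "A"): 0.7,
    ("MMP2", "RA", "A"): 0.7,
    ("CCN2", "RA", "A"): 0.7,
    ("TGFB", "RA", "A"): 0.7,
    ("JNK1", "RA", "A"): 0.7,
    ("MMP2", "LA", "B"): -1.5,
    ("FSP1", "LA", "B"): -1.5,
    ("TGFB", "LA", "B"): -1.5,
    ("JNK1", "LA", "B"): -1.5,
    ("COL1A1", "RA", "B"): -1.5,
    ("TGFB", "RA", "B"): -1.5,
    ("JNK1", "RA", "B"): -1.5,
}

# control-arm baselines for the electrophysiology series (ms / %)
DEFAULT_AERP_BASE = {500: 228.0, 450: 224.0, 400: 212.0, 350: 208.0, 300: 195.0, 250: 187.0}
DEFAULT_AVERP_BASE = {500: 222.0, 450: 216.0, 400: 210.0, 350: 200.0, 300: 187.0, 250: 178.0}
DEFAULT_SNRT_BASE = {500: 130.0, 450: 137.0, 400: 149.0}


def default_design() -> list[tuple[float, str]]:
    """Experimental design mirroring a four-group two-breed cohort:
    10 breed-A controls, 15 breed-A IHF, 8 breed-B controls, 7 breed-B
    IHF (alpha = admixture proportion toward breed A)."""
    return (
        [(0.8, CONTROL)] * 10
        + [(0.8, IHF)] * 15
        + [(0.2, CONTROL)] * 8
        + [(0.2, IHF)] * 7
    )


@dataclasses.dataclass
class CohortConfig:
    """Scenario knobs for the synthetic cohort.

    The defaults describe the study conditions the pipeline targets: two
    breeds at F ~ 0.1 divergence, reference panels of 49 and 38, forty
    admixed experimental animals in four treatment-by-breed groups, a
    breed-A-only fibrosis response (+6 percentage points), a breed-B-only
    refractory-period shortening (-40 ms) and elevated AF inducibility
    under heart failure in both breeds.
    """

    seed: int
    n_snps: int = 5000
    n_chromosomes: int = 18
    mean_gap_bp: float = 30_000.0
    fst: float = 0.1
    n_ref_a: int = 49
    n_ref_b: int = 38
    design: list[tuple[float, str]] = dataclasses.field(default_factory=default_design)
    missing_rate: float = 0.01
    breed_a_name: str = "Pietrain"
    breed_b_name: str = "Landrace"

    # phenotype effect structure
    n_images: int = 10
    fibrosis_base_pct: float = 5.0
    fibrosis_effect_pct: float = 6.0  # breed-A x IHF only
    fibrosis_sd_pct: float = 2.0
    aerp_effect_ms: float = 40.0  # breed-B x IHF shortening, all cycle lengths
    ep_sd_ms: float = 15.0
    ef_control_pct: float = 60.0
    ef_effect_pct: float = 25.0  # IHF reduction, both breeds
    ef_sd_pct: float = 5.0
    n_burst_stims: int = 6
    induced_episode_s: float = 15.0  # fixed supra-threshold duration
    af_rates: dict[tuple[str, str], float] = dataclasses.field(
        default_factory=lambda: {
            ("A", CONTROL): 0.03,
            ("A", IHF): 0.32,
            ("B", CONTROL): 0.08,
            ("B", IHF): 0.30,
        }
    )
    expression_shifts: dict[tuple[str, str, str], float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_EXPRESSION_SHIFTS)
    )
    ct_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not (0 < self.fst < 1):
            raise ValueError("fst must be in (0, 1)")
        for n in (self.n_snps, self.n_chromosomes, self.n_ref_a, self.n_ref_b):
            if n <= 0:
                raise ValueError("counts must be positive")
        for alpha, treatment in self.design:
            if not (0 <= alpha <= 1):
                raise ValueError("admixture alpha must be in [0, 1]")
            if treatment not in (CONTROL, IHF):
                raise ValueError(f"unknown treatment {treatment!r}")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        for rate in self.af_rates.values():
            if not (0 <= rate <= 1):
                raise ValueError("AF rates must be in [0, 1]")


@dataclasses.dataclass
class Cohort:
    genotypes: GenotypeMatrix
    snp_map: SnpMap
    labels: PanelLabels
    true_alpha: dict[str, float]
    phenotypes: PhenotypeTable
    config: CohortConfig


def simulate_breed_frequencies(
    cfg: CohortConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Balding-Nichols allele frequencies for the two breeds.

    The ancestral frequency is uniform on (0.1, 0.9) per marker; each
    breed's frequency is Beta(p(1-F)/F, (1-p)(1-F)/F) independently, so
    E[freq] = p and Var = F p (1 - p).
    """
    p = rng.uniform(0.1, 0.9, size=cfg.n_snps)
    f = cfg.fst
    a = p * (1 - f) / f
    b = (1 - p) * (1 - f) / f
    freq_a = np.clip(rng.beta(a, b), 1e-9, 1 - 1e-9)
    freq_b = np.clip(rng.beta(a, b), 1e-9, 1 - 1e-9)
    return freq_a, freq_b


def _simulate_map(cfg: CohortConfig, rng: np.random.Generator) -> SnpMap:
    per_chrom = np.full(cfg.n_chromosomes, cfg.n_snps // cfg.n_chromosomes)
    per_chrom[: cfg.n_snps % cfg.n_chromosomes] += 1
    markers, chroms, positions = [], [], []
    counter = 0
    for c in range(cfg.n_chromosomes):
        gaps = np.maximum(
            1, np.rint(rng.exponential(cfg.mean_gap_bp, size=per_chrom[c]))
        ).astype(np.int64)
        pos = np.cumsum(gaps)
        for p in pos:
            counter += 1
            markers.append(f"snp{counter:06d}")
            chroms.append(f"chr{c + 1:02d}")
            positions.append(int(p))
    return SnpMap(
        np.array(markers, dtype=object),
        np.array(chroms, dtype=object),
        np.array(positions, dtype=np.int64),
    )


def simulate_genotypes(
    freqs: tuple[np.ndarray, np.ndarray],
    cfg: CohortConfig,
    rng: np.random.Generator,
) -> tuple[GenotypeMatrix, SnpMap, PanelLabels, dict[str, float]]:
    """Draw reference panels and admixed experimental animals.

    Reference animals are Binomial(2, breed frequency) per marker; an
    experimental animal with admixture ``alpha`` draws each of its two
    allele copies from breed A's frequency with probability ``alpha``,
    else from breed B's (allele-level admixture, no within-block
    linkage).
    """
    freq_a, freq_b = freqs
    smap = _simulate_map(cfg, rng)
    m = cfg.n_snps

    ids: list[str] = []
    roles: dict[str, str] = {}
    rows: list[np.ndarray] = []
    true_alpha: dict[str, float] = {}

    for i in range(cfg.n_ref_a):
        animal = f"PIE{i + 1:03d}"
        ids.append(animal)
        roles[animal] = REF_A
        rows.append(rng.binomial(2, freq_a).astype(np.int8))
    for i in range(cfg.n_ref_b):
        animal = f"LR{i + 1:03d}"
        ids.append(animal)
        roles[animal] = REF_B
        rows.append(rng.binomial(2, freq_b).astype(np.int8))
    for i, (alpha, _treatment) in enumerate(cfg.design):
        animal = f"EXP{i + 1:03d}"
        ids.append(animal)
        roles[animal] = EXPERIMENTAL
        true_alpha[animal] = alpha
        copy_from_a1 = rng.random(m) < alpha
        copy_from_a2 = rng.random(m) < alpha
        c1 = (rng.random(m) < np.where(copy_from_a1, freq_a, freq_b)).astype(np.int8)
        c2 = (rng.random(m) < np.where(copy_from_a2, freq_a, freq_b)).astype(np.int8)
        rows.append(c1 + c2)

    values = np.vstack(rows)
    if cfg.missing_rate > 0:
        mask = rng.random(values.shape) < cfg.missing_rate
        values = np.where(mask, np.int8(MISSING), values)
    gm = GenotypeMatrix(ids, values)
    labels = PanelLabels(roles, breed_a=cfg.breed_a_name, breed_b=cfg.breed_b_name)
    return gm, smap, labels, true_alpha


def simulate_phenotypes(
    labels: PanelLabels,
    true_alpha: dict[str, float],
    cfg: CohortConfig,
    rng: np.random.Generator,
) -> PhenotypeTable:
    """Phenotypes for the experimental animals with the configured
    breed-by-treatment interaction structure.

    Majority ancestry (alpha >= 0.5 -> breed A) determines which effects
    an animal receives; treatment follows the design row order.
    """
    records: list[dict] = []

    def add(animal, treatment, variable, value, **quals):
        rec = {
            "animal_id": animal,
            "treatment": treatment,
            "variable": variable,
            "value": value,
        }
        rec.update(quals)
        records.append(rec)

    for i, (alpha, treatment) in enumerate(cfg.design):
        animal = f"EXP{i + 1:03d}"
        assert abs(true_alpha[animal] - alpha) < 1e-12
        breed = "A" if alpha >= 0.5 else "B"
        is_ihf = treatment == IHF

        # hemodynamics: heart failure reduces EF and raises filling
        # pressures in both breeds; right-atrial pressure rises only in
        # breed B.
        ef = cfg.ef_control_pct - (cfg.ef_effect_pct if is_ihf else 0.0)
        add(animal, treatment, "ef_pct", float(np.clip(rng.normal(ef, cfg.ef_sd_pct), 0, 100)))
        add(animal, treatment, "lv_systolic_mmhg", float(rng.normal(110, 8)))
        add(animal, treatment, "lvedp_mmhg", float(rng.normal(8 + (10 if is_ihf else 0), 2.5)))
        add(animal, treatment, "pcwp_mmhg", float(rng.normal(8 + (8 if is_ihf else 0), 2.5)))
        add(animal, treatment, "pa_systolic_mmhg", float(rng.normal(25, 4)))
        add(animal, treatment, "rv_systolic_mmhg", float(rng.normal(28, 4)))
        ra_shift = 4.0 if (is_ihf and breed == "B") else 0.0
        add(animal, treatment, "ra_systolic_mmhg", float(rng.normal(5 + ra_shift, 1.5)))

        # electrophysiology series
        aerp_shift = cfg.aerp_effect_ms if (is_ihf and breed == "B") else 0.0
        for cl, base in DEFAULT_AERP_BASE.items():
            add(
                animal, treatment, "aerp_ms",
                float(max(rng.normal(base - aerp_shift, cfg.ep_sd_ms), 50.0)),
                cycle_ms=cl,
            )
        for cl, base in DEFAULT_AVERP_BASE.items():
            add(animal, treatment, "averp_ms",
                float(max(rng.normal(base, cfg.ep_sd_ms), 50.0)), cycle_ms=cl)
        for cl, base in DEFAULT_SNRT_BASE.items():
            add(animal, treatment, "snrt_bcl_pct",
                float(max(rng.normal(base, 12.0), 100.0)), cycle_ms=cl)

        # fibrosis: per-image percentages, ten images per region
        fib_shift = cfg.fibrosis_effect_pct if (is_ihf and breed == "A") else 0.0
        for region in ("LA", "RA"):
            images = np.clip(
                rng.normal(cfg.fibrosis_base_pct + fib_shift, cfg.fibrosis_sd_pct, cfg.n_images),
                0.0, 100.0,
            )
            for k, v in enumerate(images):
                add(animal, treatment, "fibrosis_pct", float(v), region=region, image=k)

        # AF inducibility: Bernoulli per burst stimulation; induced
        # episodes get a fixed supra-threshold duration
        rate = cfg.af_rates[(breed, treatment)]
        add(animal, treatment, "n_burst_stims", float(cfg.n_burst_stims))
        induced = rng.random(cfg.n_burst_stims) < rate
        for k in np.flatnonzero(induced):
            add(animal, treatment, "af_episode_s", cfg.induced_episode_s, stim=int(k))

        # qPCR: reference gene plus targets per tissue
        for tissue in TISSUES:
            ct_ref = float(rng.normal(18.0, cfg.ct_sd))
            add(animal, treatment, "ct", max(ct_ref, 1.0), gene=REFERENCE_GENE, tissue=tissue)
            for gene in GENES:
                shift = cfg.expression_shifts.get((gene, tissue, breed), 0.0) if is_ihf else 0.0
                # lower Ct = higher expression: subtract log2 shift
                ct = rng.normal(23.0 - shift, cfg.ct_sd) + (ct_ref - 18.0)
                add(animal, treatment, "ct", max(float(ct), 1.0), gene=gene, tissue=tissue)

    return PhenotypeTable(pd.DataFrame.from_records(records))


def simulate_cohort(cfg: CohortConfig) -> Cohort:
    """End-to-end generation: frequencies, genotypes, map, labels and
    phenotypes from a single seeded generator."""
    rng = np.random.default_rng(cfg.seed)
    freqs = simulate_breed_frequencies(cfg, rng)
    gm, smap, labels, true_alpha = simulate_genotypes(freqs, cfg, rng)
    phenotypes = simulate_phenotypes(labels, true_alpha, cfg, rng)
    return Cohort(gm, smap, labels, true_alpha, phenotypes, cfg)


def hudson_fst(g_a: np.ndarray, g_b: np.ndarray) -> float:
    """Hudson-type F_ST estimator between two genotype panels.

    Per-marker numerator (p1 - p2)^2 - p1 q1 / (n1 - 1) - p2 q2 / (n2 - 1)
    and denominator p1 q2 + p2 q1, combined as a ratio of averages over
    markers; genotype input is allele dosage with MISSING allowed.
    """
    num_list, den_list = [], []
    for j in range(g_a.shape[1]):
        ca = g_a[:, j][g_a[:, j] != MISSING]
        cb = g_b[:, j][g_b[:, j] != MISSING]
        n1, n2 = 2 * ca.size, 2 * cb.size
        if n1 < 4 or n2 < 4:
            continue
        p1, p2 = ca.sum() / n1, cb.sum() / n2
        q1, q2 = 1 - p1, 1 - p2
        num = (p1 - p2) ** 2 - p1 * q1 / (n1 - 1) - p2 * q2 / (n2 - 1)
        den = p1 * q2 + p2 * q1
        if den > 0:
            num_list.append(num)
            den_list.append(den)
    if not den_list:
        raise ValueError("no usable markers for F_ST estimation")
    return float(np.mean(num_list) / np.mean(den_list))
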