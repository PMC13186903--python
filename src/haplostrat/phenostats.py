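"""Statistical layer for the stratified remodeling analysis.

Implements the study-style statistics — exact two-sided Mann-Whitney U
(midranks, full-enumeration null), Fisher's exact test for 2x2 tables,
Pearson correlation, 2^-ddCt relative expression, per-animal fibrosis
heterogeneity summaries and atrial-fibrillation inducibility endpoints —
and assembles them into a genotype-stratified comparison report
(per-breed heart-failure vs control contrasts, cross-breed contrasts,
and fibrosis-heterogeneity / AF-burden correlations).

All tests are two-sided; no multiple-testing correction is applied, and
the report header says so.
"""

from __future__ import annotations

import dataclasses
import math
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .structure import A_DOMINANT, B_DOMINANT, UNASSIGNED, BreedAssignment

CYCLE_LENGTHS_MS = (500, 450, 400, 350, 300, 250)

CONTROL = "CONTROL"
IHF = "IHF"

#: caveat printed in every report header
NO_MULTIPLICITY_NOTE = (
    "No correction for multiple comparisons was applied; p-values are "
    "descriptive."
)


@dataclasses.dataclass
class StatResult:
    method: str
    statistic: float
    pvalue: float
    n1: int
    n2: int
    mode: str = "exact"  # or "approximate"

    def __post_init__(self) -> None:
        if not (0.0 <= self.pvalue <= 1.0 or math.isnan(self.pvalue)):
            raise ValueError(f"p-value out of range: {self.pvalue}")


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------


def _exact_mw_pvalue(ranks: np.ndarray, n1: int, u_obs: float) -> float:
    """Exact two-sided p over all C(n1+n2, n1) assignments of the pooled
    midranks, via a subset-sum count on doubled (integer) midranks.

    Equivalent to explicit enumeration: p = P(|U - n1*n2/2| >= |u_obs -
    n1*n2/2|) under random assignment of the observed midranks.
    """
    n = len(ranks)
    n2 = n - n1
    r2 = np.rint(2 * ranks).astype(np.int64)  # midranks are multiples of 1/2
    total = int(r2.sum())
    # counts[k, s] = number of size-k subsets with doubled-rank sum s
    counts = np.zeros((n1 + 1, total + 1), dtype=np.float64)
    counts[0, 0] = 1.0
    for r in r2:
        upper = min(n1, n)  # shrink loop: k from high to low for in-place DP
        for k in range(upper - 1, -1, -1):
            row = counts[k]
            nz = np.flatnonzero(row)
            if nz.size:
                counts[k + 1, nz + r] += row[nz]
    sums = np.arange(total + 1)
    u_all = sums / 2.0 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    dev_obs = abs(u_obs - mu)
    extreme = np.abs(u_all - mu) >= dev_obs - 1e-9
    n_total = math.comb(n, n1)
    return float(counts[n1, extreme].sum() / n_total)


def mann_whitney_u(x, y, mode: str = "auto") -> StatResult:
    """Two-sided Mann-Whitney U test on two independent samples.

    ``mode='exact'`` enumerates the permutation null of the pooled
    midranks (ties handled exactly); ``'approximate'`` uses the normal
    approximation with tie and continuity corrections. ``'auto'`` picks
    exact when n1 + n2 <= 20.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0

    if mode == "auto":
        mode = "exact" if n1 + n2 <= 20 else "approximate"
    if mode == "exact":
        p = _exact_mw_pvalue(ranks, n1, u1)
        return StatResult("mann_whitney_u", float(u1), min(p, 1.0), n1, n2, "exact")
    if mode != "approximate":
        raise ValueError(f"unknown mode {mode!r}")

    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (n * (n - 1)) if n > 1 else 0.0
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return StatResult("mann_whitney_u", float(u1), 1.0, n1, n2, "approximate")
    dev = u1 - mu
    z = (dev - 0.5 * np.sign(dev)) / math.sqrt(sigma2) if dev != 0 else 0.0
    p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
    return StatResult("mann_whitney_u", float(u1), float(p), n1, n2, "approximate")


def _brute_force_mw_pvalue(x, y) -> float:
    """Independent reference: literal enumeration of all assignments.

    Exposed for cross-checking; O(C(n1+n2, n1)) — tiny samples only.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    mu = n1 * n2 / 2.0
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    dev_obs = abs(u_obs - mu)
    n_extreme = 0
    n_total = 0
    for subset in combinations(range(n1 + n2), n1):
        u = ranks[list(subset)].sum() - n1 * (n1 + 1) / 2.0
        n_total += 1
        if abs(u - mu) >= dev_obs - 1e-9:
            n_extreme += 1
    return n_extreme / n_total


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------


def fisher_exact_2x2(table) -> StatResult:
    """Two-sided Fisher's exact test for a 2x2 count table.

    p sums the hypergeometric probabilities of all tables with the same
    margins whose probability does not exceed the observed table's (with
    relative tolerance 1e-7 for floating-point ties).  The statistic is
    the sample odds ratio; a zero off-diagonal cell yields ``inf``.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        t = t.astype(float)
        if np.any(t < 0) or np.any(t != np.rint(t)):
            raise ValueError("counts must be non-negative integers")
        t = t.astype(np.int64)
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    n = a + b + c + d
    if n == 0:
        raise ValueError("table has no observations")
    r1, c1 = a + b, a + c

    if a * d == 0 and b * c == 0:
        odds = float("nan")
    elif b * c == 0:
        odds = float("inf")
    else:
        odds = (a * d) / (b * c)

    if r1 == 0 or r1 == n or c1 == 0 or c1 == n:
        return StatResult("fisher_exact", odds, 1.0, r1, n - r1, "exact")

    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(support, n, r1, c1)
    p_obs = pmf[a - lo]
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    return StatResult("fisher_exact", odds, min(p, 1.0), r1, n - r1, "exact")


# ---------------------------------------------------------------------------
# Pearson correlation
# ---------------------------------------------------------------------------


def pearson_corr(x, y) -> StatResult:
    """Pearson r with the two-sided t-based p (n - 2 degrees of freedom)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("samples must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in a sample")
    res = sps.pearsonr(x, y)
    return StatResult(
        "pearson", float(res.statistic), float(res.pvalue), x.size, y.size, "exact"
    )


# ---------------------------------------------------------------------------
# fibrosis heterogeneity
# ---------------------------------------------------------------------------


def fibrosis_heterogeneity(la_values, ra_values) -> dict:
    """Per-animal fibrosis summaries from per-image percentages.

    The "fibrosis difference" — the spread (max - min) of the per-image
    values within a region — is the heterogeneity measure correlated with
    AF burden; the per-image sample SD is exposed as an alternative.
    """
    out = {}
    for region, values in (("la", la_values), ("ra", ra_values)):
        v = np.asarray(values, dtype=float)
        if v.size < 2:
            raise ValueError(f"need >= 2 images per region, got {v.size} for {region}")
        out[f"{region}_mean"] = float(v.mean())
        out[f"{region}_diff"] = float(v.max() - v.min())
        out[f"{region}_sd"] = float(v.std(ddof=1))
    return out


# ---------------------------------------------------------------------------
# ddCt fold change
# ---------------------------------------------------------------------------


def ddct_fold_change(ct, ct_ref, group, control_label) -> pd.DataFrame:
    """Relative expression by the 2^-ddCt method.

    dCt = Ct_gene - Ct_reference per sample; ddCt subtracts the mean dCt
    of the control group (unpaired design), so the control-group mean
    ddCt is 0 by construction and fold changes are invariant to adding a
    constant to every Ct of a sample.
    """
    ct = np.asarray(ct, dtype=float)
    ct_ref = np.asarray(ct_ref, dtype=float)
    group = np.asarray(group, dtype=object)
    if ct.shape != ct_ref.shape or ct.shape != group.shape:
        raise ValueError("ct, ct_ref and group must be aligned")
    if np.any(np.isnan(ct_ref)):
        raise ValueError("missing reference-gene Ct for some sample")
    dct = ct - ct_ref
    is_control = group == control_label
    if not is_control.any():
        raise ValueError(f"control group {control_label!r} is empty")
    ddct = dct - dct[is_control].mean()
    return pd.DataFrame(
        {"group": group, "dct": dct, "ddct": ddct, "fold": 2.0 ** (-ddct)}
    )


# ---------------------------------------------------------------------------
# phenotype table
# ---------------------------------------------------------------------------

_QUALIFIERS = ("cycle_ms", "gene", "tissue", "region", "image", "stim")


@dataclasses.dataclass
class PhenotypeTable:
    """Long-format per-animal phenotype records.

    Columns: ``animal_id``, ``treatment`` (CONTROL/IHF), ``variable``,
    ``value`` plus qualifier columns (cycle_ms, gene, tissue, region,
    image, stim).  Variables include ``ef_pct``, pressure series
    (``*_mmhg``), ``aerp_ms``/``averp_ms``/``snrt_bcl_pct`` per cycle
    length, ``fibrosis_pct`` per region and image, ``af_episode_s`` per
    stimulation, ``n_burst_stims`` and raw ``ct`` values per gene/tissue.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        required = {"animal_id", "treatment", "variable", "value"}
        if not required.issubset(df.columns):
            raise ValueError(f"phenotype table lacks columns {required - set(df.columns)}")
        for q in _QUALIFIERS:
            if q not in df.columns:
                df[q] = np.nan
        bad_treat = set(df["treatment"].unique()) - {CONTROL, IHF}
        if bad_treat:
            raise ValueError(f"unknown treatment labels {bad_treat}")
        pct = df.loc[df["variable"].str.endswith("_pct") & (df["variable"] != "snrt_bcl_pct"), "value"]
        if ((pct < 0) | (pct > 100)).any():
            raise ValueError("percentage outside [0, 100]")
        dur = df.loc[df["variable"] == "af_episode_s", "value"]
        if (dur < 0).any():
            raise ValueError("negative AF episode duration")
        ctv = df.loc[df["variable"] == "ct", "value"]
        if (ctv <= 0).any():
            raise ValueError("Ct values must be positive")
        cyc = df.loc[df["variable"].isin(["aerp_ms", "averp_ms"]), "cycle_ms"].dropna()
        if not set(cyc.astype(int)).issubset(set(CYCLE_LENGTHS_MS)):
            raise ValueError(f"cycle lengths must come from {CYCLE_LENGTHS_MS}")

    @property
    def animal_ids(self) -> list[str]:
        return list(dict.fromkeys(self.frame["animal_id"]))

    def treatment_of(self) -> dict[str, str]:
        sub = self.frame[["animal_id", "treatment"]].drop_duplicates()
        return dict(zip(sub["animal_id"], sub["treatment"]))

    def values_of(self, variable: str, **qualifiers) -> pd.Series:
        """Per-animal mean of a variable, optionally restricted by
        qualifier values (e.g. ``cycle_ms=450`` or ``region='LA'``)."""
        sub = self.frame[self.frame["variable"] == variable]
        for key, val in qualifiers.items():
            sub = sub[sub[key] == val]
        return sub.groupby("animal_id")["value"].mean()

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path) -> "PhenotypeTable":
        return cls(pd.read_csv(path, sep="\t"))


# ---------------------------------------------------------------------------
# AF endpoints
# ---------------------------------------------------------------------------


def af_endpoints(
    pt: PhenotypeTable, episode_min_s: float = 10.0, groups: dict[str, str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-animal and per-stimulation AF inducibility.

    An animal is inducible when any recorded episode lasts strictly longer
    than ``episode_min_s`` (induced AF is an episode with irregular RR
    intervals lasting > 10 s); the per-stimulation endpoint is the
    fraction of burst stimulations that induced such an episode.  When
    ``groups`` maps animal ids to group labels, IHF vs CONTROL contrasts
    per group are computed with Fisher's exact test at both the animal
    level and the pooled-stimulation level (pooling ignores the
    per-animal clustering of stimulations; a documented caveat).
    """
    df = pt.frame
    treat = pt.treatment_of()
    stim_counts = df[df["variable"] == "n_burst_stims"].set_index("animal_id")["value"]
    rows = []
    for animal in pt.animal_ids:
        episodes = df[
            (df["variable"] == "af_episode_s") & (df["animal_id"] == animal)
        ]["value"].to_numpy()
        n_stims = int(stim_counts.get(animal, 0))
        n_episodes = int((episodes > 0).sum())
        if n_stims < n_episodes:
            raise ValueError(
                f"{animal}: {n_episodes} episodes exceed {n_stims} stimulations"
            )
        inducing = int((episodes > episode_min_s).sum())
        rows.append(
            {
                "animal_id": animal,
                "treatment": treat[animal],
                "n_stims": n_stims,
                "n_inducing_stims": inducing,
                "inducible": inducing > 0,
                "per_stim_fraction": inducing / n_stims if n_stims else 0.0,
            }
        )
    per_animal = pd.DataFrame(rows)

    tests = []
    if groups:
        per_animal["group"] = per_animal["animal_id"].map(groups)
        for g in sorted(set(groups.values())):
            sub = per_animal[per_animal["group"] == g]
            ihf = sub[sub["treatment"] == IHF]
            ctl = sub[sub["treatment"] == CONTROL]
            if len(ihf) == 0 or len(ctl) == 0:
                continue
            animal_tab = [
                [int(ihf["inducible"].sum()), int((~ihf["inducible"]).sum())],
                [int(ctl["inducible"].sum()), int((~ctl["inducible"]).sum())],
            ]
            stim_tab = [
                [
                    int(ihf["n_inducing_stims"].sum()),
                    int(ihf["n_stims"].sum() - ihf["n_inducing_stims"].sum()),
                ],
                [
                    int(ctl["n_inducing_stims"].sum()),
                    int(ctl["n_stims"].sum() - ctl["n_inducing_stims"].sum()),
                ],
            ]
            res_a = fisher_exact_2x2(animal_tab)
            res_s = fisher_exact_2x2(stim_tab)
            tests.append(
                {
                    "group": g,
                    "level": "animal",
                    "p": res_a.pvalue,
                    "odds_ratio": res_a.statistic,
                    "ihf_rate": float(ihf["inducible"].mean()),
                    "control_rate": float(ctl["inducible"].mean()),
                }
            )
            tests.append(
                {
                    "group": g,
                    "level": "stimulation",
                    "p": res_s.pvalue,
                    "odds_ratio": res_s.statistic,
                    "ihf_rate": float(
                        ihf["n_inducing_stims"].sum() / max(ihf["n_stims"].sum(), 1)
                    ),
                    "control_rate": float(
                        ctl["n_inducing_stims"].sum() / max(ctl["n_stims"].sum(), 1)
                    ),
                }
            )
    return per_animal, pd.DataFrame(tests)


# ---------------------------------------------------------------------------
# stratified report
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class StratifiedReport:
    frame: pd.DataFrame
    header: list[str]
    n_unassigned: int

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for line in self.header:
                fh.write(f"# {line}\n")
            self.frame.to_csv(fh, sep="\t", index=False, float_format="%.6g")

    def to_text(self) -> str:
        lines = [f"# {h}" for h in self.header]
        lines.append(self.frame.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
        return "\n".join(lines)

    def lookup(self, section: str, breed: str, variable: str, qualifier=None):
        sub = self.frame[
            (self.frame["section"] == section)
            & (self.frame["breed"] == breed)
            & (self.frame["variable"] == variable)
        ]
        if qualifier is not None:
            sub = sub[sub["qualifier"].astype(str) == str(qualifier)]
        return sub


def _mean_sem(v: np.ndarray) -> tuple[float, float]:
    v = np.asarray(v, dtype=float)
    if v.size == 0:
        return float("nan"), float("nan")
    sem = float(v.std(ddof=1) / math.sqrt(v.size)) if v.size > 1 else float("nan")
    return float(v.mean()), sem


def stratified_report(
    pt: PhenotypeTable,
    ba: BreedAssignment,
    episode_min_s: float = 10.0,
    reference_gene: str = "ACTB",
) -> StratifiedReport:
    """Genotype-stratified comparison report.

    Within each breed label: heart-failure (IHF) vs control contrasts for
    ejection fraction, pressures, refractory periods per cycle length,
    sinus-node recovery, fibrosis (mean and heterogeneity), qPCR fold
    changes and AF inducibility; across breeds: the IHF vs IHF contrasts;
    plus Pearson correlations of AF episode count against the fibrosis
    difference within each breed's IHF animals.  Cells report mean +/-
    SEM and the two-sided p; empty cells become NA rows, never errors.
    """
    labels = ba.labels()
    n_unassigned = sum(1 for v in labels.values() if v == UNASSIGNED)
    breed_name = {A_DOMINANT: ba.breed_a, B_DOMINANT: ba.breed_b}
    treat = pt.treatment_of()

    def animals_in(breed_label: str, treatment: str) -> list[str]:
        return [
            a
            for a in pt.animal_ids
            if labels.get(a) == breed_label and treat.get(a) == treatment
        ]

    rows: list[dict] = []

    def add_contrast(section, breed, variable, qualifier, g1_vals, g2_vals, g1, g2):
        m1, s1 = _mean_sem(g1_vals)
        m2, s2 = _mean_sem(g2_vals)
        if len(g1_vals) == 0 or len(g2_vals) == 0:
            stat, p, method = float("nan"), float("nan"), "NA"
        else:
            res = mann_whitney_u(g1_vals, g2_vals, mode="auto")
            stat, p, method = res.statistic, res.pvalue, res.method
        rows.append(
            {
                "section": section,
                "breed": breed,
                "variable": variable,
                "qualifier": qualifier,
                "group1": g1,
                "n1": len(g1_vals),
                "mean1": m1,
                "sem1": s1,
                "group2": g2,
                "n2": len(g2_vals),
                "mean2": m2,
                "sem2": s2,
                "method": method,
                "statistic": stat,
                "p": p,
            }
        )

    # continuous variables and their qualifier grids
    continuous: list[tuple[str, dict]] = [("ef_pct", {})]
    continuous += [
        (v, {})
        for v in (
            "lv_systolic_mmhg",
            "lvedp_mmhg",
            "pcwp_mmhg",
            "pa_systolic_mmhg",
            "rv_systolic_mmhg",
            "ra_systolic_mmhg",
        )
    ]
    continuous += [("aerp_ms", {"cycle_ms": c}) for c in CYCLE_LENGTHS_MS]
    continuous += [("averp_ms", {"cycle_ms": c}) for c in CYCLE_LENGTHS_MS]
    continuous += [("snrt_bcl_pct", {"cycle_ms": c}) for c in (500, 450, 400)]

    def series(variable, qualifiers, animals):
        s = pt.values_of(variable, **qualifiers)
        return s.reindex(animals).dropna().to_numpy()

    # fibrosis summaries per animal
    fib: dict[str, dict] = {}
    for a in pt.animal_ids:
        la = pt.frame[
            (pt.frame["variable"] == "fibrosis_pct")
            & (pt.frame["animal_id"] == a)
            & (pt.frame["region"] == "LA")
        ]["value"].to_numpy()
        ra = pt.frame[
            (pt.frame["variable"] == "fibrosis_pct")
            & (pt.frame["animal_id"] == a)
            & (pt.frame["region"] == "RA")
        ]["value"].to_numpy()
        if la.size >= 2 and ra.size >= 2:
            fib[a] = fibrosis_heterogeneity(la, ra)

    fib_vars = ["la_mean", "ra_mean", "la_diff", "ra_diff", "la_sd", "ra_sd"]

    # qPCR folds per breed (baseline: that breed's control animals)
    ct_frame = pt.frame[pt.frame["variable"] == "ct"]
    genes = sorted(g for g in ct_frame["gene"].dropna().unique() if g != reference_gene)
    tissues = sorted(ct_frame["tissue"].dropna().unique())

    def folds_for(breed_label, gene, tissue):
        animals = [a for a in pt.animal_ids if labels.get(a) == breed_label]
        sub = ct_frame[ct_frame["animal_id"].isin(animals) & (ct_frame["tissue"] == tissue)]
        tgt = sub[sub["gene"] == gene].set_index("animal_id")["value"]
        ref = sub[sub["gene"] == reference_gene].set_index("animal_id")["value"]
        common = [a for a in animals if a in tgt.index and a in ref.index]
        if not common:
            return {}
        grp = np.array([treat[a] for a in common], dtype=object)
        if not (grp == CONTROL).any():
            return {}
        res = ddct_fold_change(
            tgt.reindex(common).to_numpy(), ref.reindex(common).to_numpy(), grp, CONTROL
        )
        return dict(zip(common, res["fold"]))

    # ---- per-breed IHF vs control ------------------------------------
    for breed_label in (A_DOMINANT, B_DOMINANT):
        breed = breed_name[breed_label]
        ihf_ids = animals_in(breed_label, IHF)
        ctl_ids = animals_in(breed_label, CONTROL)
        for variable, quals in continuous:
            add_contrast(
                "within_breed",
                breed,
                variable,
                quals.get("cycle_ms", ""),
                series(variable, quals, ihf_ids),
                series(variable, quals, ctl_ids),
                f"{breed}-IHF",
                f"{breed}-control",
            )
        for fv in fib_vars:
            add_contrast(
                "within_breed",
                breed,
                f"fibrosis_{fv}",
                "",
                np.array([fib[a][fv] for a in ihf_ids if a in fib]),
                np.array([fib[a][fv] for a in ctl_ids if a in fib]),
                f"{breed}-IHF",
                f"{breed}-control",
            )
        for gene in genes:
            for tissue in tissues:
                folds = folds_for(breed_label, gene, tissue)
                add_contrast(
                    "within_breed",
                    breed,
                    "fold_change",
                    f"{gene}/{tissue}",
                    np.array([folds[a] for a in ihf_ids if a in folds]),
                    np.array([folds[a] for a in ctl_ids if a in folds]),
                    f"{breed}-IHF",
                    f"{breed}-control",
                )

    # ---- cross-breed IHF vs IHF --------------------------------------
    a_ihf = animals_in(A_DOMINANT, IHF)
    b_ihf = animals_in(B_DOMINANT, IHF)
    for variable, quals in continuous:
        add_contrast(
            "cross_breed",
            f"{ba.breed_a}_vs_{ba.breed_b}",
            variable,
            quals.get("cycle_ms", ""),
            series(variable, quals, a_ihf),
            series(variable, quals, b_ihf),
            f"{ba.breed_a}-IHF",
            f"{ba.breed_b}-IHF",
        )
    for fv in fib_vars:
        add_contrast(
            "cross_breed",
            f"{ba.breed_a}_vs_{ba.breed_b}",
            f"fibrosis_{fv}",
            "",
            np.array([fib[a][fv] for a in a_ihf if a in fib]),
            np.array([fib[a][fv] for a in b_ihf if a in fib]),
            f"{ba.breed_a}-IHF",
            f"{ba.breed_b}-IHF",
        )

    # ---- AF endpoints (Fisher) ---------------------------------------
    groups = {
        a: breed_name[labels[a]]
        for a in pt.animal_ids
        if labels.get(a) in (A_DOMINANT, B_DOMINANT)
    }
    keep = pt.frame["animal_id"].isin(groups)
    pt_labeled = PhenotypeTable(pt.frame[keep].reset_index(drop=True))
    per_animal, af_tests = af_endpoints(pt_labeled, episode_min_s, groups)
    for _, r in af_tests.iterrows():
        rows.append(
            {
                "section": "af_inducibility",
                "breed": r["group"],
                "variable": f"af_{r['level']}_level",
                "qualifier": "",
                "group1": f"{r['group']}-IHF",
                "n1": np.nan,
                "mean1": 100.0 * r["ihf_rate"],
                "sem1": np.nan,
                "group2": f"{r['group']}-control",
                "n2": np.nan,
                "mean2": 100.0 * r["control_rate"],
                "sem2": np.nan,
                "method": "fisher_exact",
                "statistic": r["odds_ratio"],
                "p": r["p"],
            }
        )

    # ---- AF burden vs fibrosis heterogeneity -------------------------
    episode_counts = {
        a: int(
            (
                pt.frame[
                    (pt.frame["variable"] == "af_episode_s")
                    & (pt.frame["animal_id"] == a)
                ]["value"]
                > episode_min_s
            ).sum()
        )
        for a in pt.animal_ids
    }
    for breed_label in (A_DOMINANT, B_DOMINANT):
        breed = breed_name[breed_label]
        ihf_ids = [a for a in animals_in(breed_label, IHF) if a in fib]
        for region in ("la", "ra"):
            x = np.array([fib[a][f"{region}_diff"] for a in ihf_ids])
            y = np.array([float(episode_counts[a]) for a in ihf_ids])
            try:
                res = pearson_corr(x, y)
                stat, p, method = res.statistic, res.pvalue, "pearson"
            except ValueError:
                stat, p, method = float("nan"), float("nan"), "NA"
            rows.append(
                {
                    "section": "af_fibrosis_correlation",
                    "breed": breed,
                    "variable": f"af_episodes_vs_{region}_fibrosis_diff",
                    "qualifier": "",
                    "group1": f"{breed}-IHF",
                    "n1": len(ihf_ids),
                    "mean1": np.nan,
                    "sem1": np.nan,
                    "group2": "",
                    "n2": np.nan,
                    "mean2": np.nan,
                    "sem2": np.nan,
                    "method": method,
                    "statistic": stat,
                    "p": p,
                }
            )

    header = [
        "Genotype-stratified phenotype report",
        NO_MULTIPLICITY_NOTE,
        "All tests two-sided; significance convention p < 0.05.",
        f"Animals excluded as UNASSIGNED: {n_unassigned}",
        "Per-stimulation AF contrasts pool stimulations across animals "
        "(clustering ignored).",
    ]
    return StratifiedReport(pd.DataFrame(rows), header, n_unassigned)
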