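"""Diversity statistics, Weir–Cockerham F_ST and hierarchical AMOVA.

F_ST between population samples is the Weir–Cockerham ANOVA estimator
theta computed on haplotype frequencies (haplotypes treated as alleles at
a single locus; haploid variance components, since each sequence is one
allele copy). Multilocus theta is the ratio of summed components
(sum a / sum (a+b)), not a mean of per-locus ratios. Significance comes
from a percentile bootstrap over sequences resampled within populations:
a pair is called differentiated when the 95% CI lies entirely above 0.

AMOVA partitions squared inter-haplotype distances (count of differing
retained columns) across a nested hierarchy of up to four levels
(regions / populations / individuals / within individuals), following the
classical sums-of-squares decomposition with unequal-sample-size
coefficients; Phi-statistics are derived from the variance components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genetic_io import (
    HaplotypeTable,
    LocusAlignment,
    PopulationHierarchy,
    collapse_haplotypes,
)

__all__ = [
    "nucleotide_diversity",
    "haplotype_diversity",
    "watterson_theta",
    "wc_theta_components",
    "pairwise_fst",
    "fst_bootstrap",
    "FstResult",
    "amova",
    "amova_from_distances",
    "AmovaResult",
    "diversity_table",
]


def harmonic(n: int, power: int = 1) -> float:
    """a_n = sum_{i=1}^{n-1} 1/i**power (Watterson denominators)."""
    return float(np.sum(1.0 / np.arange(1, n, dtype=float) ** power))


def nucleotide_diversity(
    aln: LocusAlignment, complete_deletion: bool = True, per_site: bool = True
) -> float:
    """Mean pairwise proportion (or count) of differing retained columns."""
    m = aln.matrix()
    if complete_deletion:
        m = m[:, aln.complete_columns()]
    n, L = m.shape
    if n < 2:
        raise ValueError("nucleotide diversity needs at least 2 sequences")
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            total += np.sum(m[i] != m[j])
    mean_pairs = total / (n * (n - 1) / 2)
    if not per_site:
        return mean_pairs
    if L == 0:
        return 0.0
    return mean_pairs / L


def haplotype_diversity(table: HaplotypeTable, population: str) -> float:
    """H = n/(n-1) * (1 - sum p_i^2)."""
    n = table.population_n(population)
    if n < 2:
        raise ValueError(f"population {population!r} has n={n} < 2")
    p = table.frequencies(population)
    return float(n / (n - 1) * (1.0 - np.sum(p**2)))


def watterson_theta(S: int, n: int) -> float:
    """Watterson's estimator theta_W = S / a_n (per locus)."""
    if n < 2:
        raise ValueError("need n >= 2")
    return S / harmonic(n)


# ---------------------------------------------------------------------------
# Weir–Cockerham theta (haploid allele-frequency components)
# ---------------------------------------------------------------------------

def _counts_matrix(tables: list[dict[str, int]]) -> np.ndarray:
    """(r populations x k alleles) count matrix from haplotype-count dicts."""
    alleles = sorted({h for t in tables for h in t})
    out = np.zeros((len(tables), len(alleles)))
    for i, t in enumerate(tables):
        for j, a in enumerate(alleles):
            out[i, j] = t.get(a, 0)
    return out


def wc_theta_components(counts: np.ndarray) -> tuple[float, float]:
    """Summed among- (a) and within-population (b) variance components.

    ``counts`` is an (r, k) allele-count matrix for r population samples of
    haploid allele copies. Components are summed over alleles; theta is
    a/(a+b). Requires every sample size >= 2.
    """
    counts = np.asarray(counts, dtype=float)
    r, k = counts.shape
    n_i = counts.sum(axis=1)
    if np.any(n_i < 2):
        raise ValueError("every population needs n >= 2 allele copies")
    if r < 2:
        raise ValueError("need at least 2 populations")
    N = n_i.sum()
    nbar = N / r
    nc = (N - np.sum(n_i**2) / N) / (r - 1)
    p = counts / n_i[:, None]
    pbar = counts.sum(axis=0) / N  # weighted mean frequency per allele
    a_sum = 0.0
    b_sum = 0.0
    for u in range(k):
        msp = np.sum(n_i * (p[:, u] - pbar[u]) ** 2) / (r - 1)
        msg = np.sum(n_i * p[:, u] * (1.0 - p[:, u])) / (N - r)
        a_sum += (msp - msg) / nc
        b_sum += msg
    return a_sum, b_sum


def pairwise_fst(
    tables: "list[HaplotypeTable] | HaplotypeTable",
    pop_a: str,
    pop_b: str,
) -> float:
    """Weir–Cockerham theta between two populations; multilocus = ratio of sums."""
    if isinstance(tables, HaplotypeTable):
        tables = [tables]
    a_tot = 0.0
    ab_tot = 0.0
    for t in tables:
        counts = _counts_matrix([t.counts.get(pop_a, {}), t.counts.get(pop_b, {})])
        a, b = wc_theta_components(counts)
        a_tot += a
        ab_tot += a + b
    if ab_tot == 0.0:
        return 0.0  # monomorphic across both samples: no differentiation signal
    return a_tot / ab_tot


@dataclass
class FstResult:
    pop_a: str
    pop_b: str
    theta: float
    ci_low: float
    ci_high: float
    significant: bool
    n_boot: int


def fst_bootstrap(
    alignments: "list[LocusAlignment] | LocusAlignment",
    hierarchy: PopulationHierarchy,
    pop_a: str,
    pop_b: str,
    n_boot: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> FstResult:
    """Percentile bootstrap CI for pairwise theta (resampling unit: sequence
    within population). Significant iff the CI lies entirely above 0."""
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    if isinstance(alignments, LocusAlignment):
        alignments = [alignments]
    rng = np.random.default_rng(seed)
    # per locus: haplotype label vector per population (complete deletion applied)
    per_locus: list[dict[str, list[str]]] = []
    for aln in alignments:
        table = collapse_haplotypes(aln, hierarchy)
        labels: dict[str, list[str]] = {}
        for pop in (pop_a, pop_b):
            haps: list[str] = []
            for hap, cnt in table.counts.get(pop, {}).items():
                haps.extend([hap] * cnt)
            if len(haps) < 2:
                raise ValueError(f"population {pop!r} has n < 2 at {aln.locus_name}")
            labels[pop] = haps
        per_locus.append(labels)

    def theta_of(labels_list: list[dict[str, list[str]]]) -> float:
        a_tot = ab_tot = 0.0
        for labels in labels_list:
            counts_dicts = []
            for pop in (pop_a, pop_b):
                d: dict[str, int] = {}
                for h in labels[pop]:
                    d[h] = d.get(h, 0) + 1
                counts_dicts.append(d)
            counts = _counts_matrix(counts_dicts)
            if counts.shape[1] < 2:
                continue  # monomorphic replicate contributes theta=0 (skip components)
            a, b = wc_theta_components(counts)
            a_tot += a
            ab_tot += a + b
        return a_tot / ab_tot if ab_tot != 0 else 0.0

    theta_obs = theta_of(per_locus)
    reps = np.empty(n_boot)
    for b in range(n_boot):
        resampled = []
        for labels in per_locus:
            resampled.append(
                {
                    pop: [hs[i] for i in rng.integers(0, len(hs), len(hs))]
                    for pop, hs in labels.items()
                }
            )
        reps[b] = theta_of(resampled)
    lo, hi = np.quantile(reps, [alpha / 2, 1 - alpha / 2])
    return FstResult(pop_a, pop_b, theta_obs, float(lo), float(hi), bool(lo > 0), n_boot)


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

@dataclass
class AmovaResult:
    level_names: list[str]
    sums_of_squares: list[float]
    degrees_of_freedom: list[int]
    variance_components: list[float]  # raw; may be negative
    percent_variation: list[float]  # negatives clamped to 0, renormalized
    phi_statistics: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "level": self.level_names,
                "df": self.degrees_of_freedom,
                "sum_of_squares": self.sums_of_squares,
                "variance_component": self.variance_components,
                "percent": self.percent_variation,
            }
        )


def _ss_within(d2: np.ndarray, groups: np.ndarray) -> float:
    """Sum over groups of (sum of pairwise squared distances)/group size."""
    total = 0.0
    for g in np.unique(groups):
        idx = np.flatnonzero(groups == g)
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            total += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    return total


def amova_from_distances(
    d2: np.ndarray, level_labels: list[np.ndarray], level_names: list[str] | None = None
) -> AmovaResult:
    """Nested AMOVA from a matrix of squared distances.

    ``level_labels`` lists grouping vectors from the top of the hierarchy
    down (e.g. region labels then population labels), one label per unit
    (sequence); the units themselves form the bottom stratum. Groups at
    each level must nest inside the level above. Levels with a single
    group are dropped with a warning.
    """
    d2 = np.asarray(d2, dtype=float)
    N = d2.shape[0]
    labels = [np.asarray(l) for l in level_labels]
    # drop degenerate levels (single group)
    kept, kept_names = [], []
    for i, lab in enumerate(labels):
        name = level_names[i] if level_names else f"level{i}"
        if len(np.unique(lab)) < 2:
            warnings.warn(f"AMOVA level {name!r} has a single group; dropped")
        else:
            kept.append(lab)
            kept_names.append(name)
    labels = kept
    L = len(labels)
    if L == 0:
        raise ValueError("no informative grouping levels")
    # nesting: refine each level by all levels above so labels are unique paths
    paths = []
    for i in range(L):
        path = np.array(
            ["|".join(str(labels[k][u]) for k in range(i + 1)) for u in range(N)]
        )
        paths.append(path)
    units = np.arange(N).astype(str)

    # sums of squares by stratum, top to bottom
    grand = np.full(N, "all")
    strata = [grand] + paths  # level -1 (grand) then each grouping level
    ss_within = [_ss_within(d2, s) for s in strata]  # within groups at each level
    ss = []  # SS between level-i groups within level-(i-1) groups
    for i in range(L):
        ss.append(ss_within[i] - ss_within[i + 1])
    ss.append(ss_within[L])  # within the lowest grouping level (error stratum)

    dfs = []
    n_groups = [1] + [len(np.unique(p)) for p in paths] + [N]
    for i in range(L + 1):
        dfs.append(n_groups[i + 1] - n_groups[i])

    # expected-mean-square coefficients, computed numerically from the labels:
    # coefficient of variance component m (m >= b) in E[SS of stratum b] is
    #   sum_{g in level b} sum_{h in level m, h within g} N_h^2 / N_g
    # - sum_{f in level b-1} sum_{h in level m, h within f} N_h^2 / N_f
    # and the unit-level component enters stratum b with coefficient df_b.
    def coef(b: int, m: int) -> float:
        # strata index b in 0..L (0 = top grouping level), component m in b..L
        def term(parent_labels: np.ndarray, child_labels: np.ndarray) -> float:
            tot = 0.0
            for g in np.unique(parent_labels):
                sel = parent_labels == g
                Ng = sel.sum()
                _, counts = np.unique(child_labels[sel], return_counts=True)
                tot += np.sum(counts.astype(float) ** 2) / Ng
            return tot

        parent_upper = strata[b]  # groups at level b-1 (grand for b=0)
        child = strata[m + 1]  # groups at component level m
        return term(strata[b + 1], child) - term(parent_upper, child)

    # solve for components bottom-up: sigma2[L] (units) from error stratum
    sigma2 = np.zeros(L + 1)
    sigma2[L] = ss[L] / dfs[L] if dfs[L] > 0 else 0.0
    for b in range(L - 1, -1, -1):
        if dfs[b] == 0:
            sigma2[b] = 0.0
            continue
        expected_known = dfs[b] * sigma2[L]
        for m in range(b + 1, L):
            expected_known += coef(b, m) * sigma2[m]
        c_own = coef(b, b)
        sigma2[b] = (ss[b] - expected_known) / c_own

    clamped = np.clip(sigma2, 0.0, None)
    total = clamped.sum()
    percent = (clamped / total * 100.0) if total > 0 else np.zeros_like(clamped)

    names = kept_names + ["within"]
    total_raw = sigma2.sum()
    phi: dict[str, float] = {}
    # cumulative Phi (top levels vs total) and conditional Phi per level
    for i in range(L):
        denom_cond = sigma2[i:].sum()
        phi[f"Phi_{names[i]}"] = float(sigma2[i] / denom_cond) if denom_cond else np.nan
    if total_raw:
        phi["Phi_total"] = float(sigma2[:L].sum() / total_raw)
    return AmovaResult(
        names,
        [float(s) for s in ss],
        [int(d) for d in dfs],
        [float(s) for s in sigma2],
        [float(p) for p in percent],
        phi,
    )


def _pairwise_diff_matrix(m: np.ndarray) -> np.ndarray:
    n = m.shape[0]
    d2 = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = np.sum(m[i] != m[j])
            d2[i, j] = d2[j, i] = d
    return d2


def amova(
    aln: LocusAlignment,
    hierarchy: PopulationHierarchy,
    levels: tuple[str, ...] = ("region", "population"),
    complete_deletion: bool = True,
    binary_distance: bool = False,
) -> AmovaResult:
    """Hierarchical AMOVA on one locus.

    Squared distance = count of differing retained columns (or 0/1 if
    ``binary_distance``, which makes one-level Phi_ST equal the
    Weir–Cockerham haplotype theta). ``levels`` is an ordered subset of
    ``("region", "population", "individual")``; for haploid loci the
    individual level is meaningless and rejected.
    """
    allowed = ("region", "population", "individual")
    if any(l not in allowed for l in levels):
        raise ValueError(f"levels must be among {allowed}")
    if "individual" in levels and aln.ploidy == 1:
        raise ValueError("within-individual level is undefined for haploid loci")
    mat = aln.matrix()
    if complete_deletion:
        mat = mat[:, aln.complete_columns()]
    d2 = _pairwise_diff_matrix(mat)
    if binary_distance:
        d2 = (d2 > 0).astype(float)
    label_vectors = []
    for level in levels:
        if level == "region":
            lab = [
                hierarchy.region_of_population(hierarchy.population_of(r.individual_id))
                for r in aln.records
            ]
        elif level == "population":
            lab = [hierarchy.population_of(r.individual_id) for r in aln.records]
        else:
            lab = [r.individual_id for r in aln.records]
        label_vectors.append(np.array(lab))
    return amova_from_distances(d2, label_vectors, list(levels))


def diversity_table(
    alignments: list[LocusAlignment],
    hierarchy: PopulationHierarchy,
) -> pd.DataFrame:
    """Per-locus, per-population n, S, pi, H and pooled Watterson theta."""
    from .genetic_io import segregating_sites, sequences_by_population

    rows = []
    for aln in alignments:
        table = collapse_haplotypes(aln, hierarchy)
        by_pop = sequences_by_population(aln, hierarchy)
        mask = aln.complete_columns()
        for pop, seqs in by_pop.items():
            sub = LocusAlignment(
                aln.locus_name,
                aln.ploidy,
                [r for r in aln.records if hierarchy.population_of(r.individual_id) == pop],
            )
            n = len(seqs)
            S = segregating_sites(sub) if n >= 2 else 0
            rows.append(
                {
                    "locus": aln.locus_name,
                    "population": pop,
                    "n": n,
                    "S": S,
                    "pi": nucleotide_diversity(sub) if n >= 2 else np.nan,
                    "H": haplotype_diversity(table, pop) if n >= 2 else np.nan,
                    "theta_w": watterson_theta(S, n) if n >= 2 else np.nan,
                    "retained_columns": int(mask.sum()),
                }
            )
    return pd.DataFrame(rows)
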