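"""Neutrality tests: Tajima's D, normalized Fay–Wu's H, Ewens–Watterson,
the DHEW compound test, and a maximum-likelihood multilocus HKA test.

The DHEW compound test jointly uses three statistics that respond to a
selective sweep — Tajima's D (skew toward rare variants), the normalized
Fay–Wu H (excess of high-frequency derived variants, polarized against an
outgroup) and the Ewens–Watterson homozygosity F (loss of haplotype
diversity). Its null distribution is obtained by neutral panmictic
coalescent simulation conditioned on the observed sample size and number
of segregating sites; a common per-component quantile is calibrated by
binary search so that the joint rejection region has null mass at most
alpha.

The multilocus HKA test models per-locus polymorphism S_i and divergence
D_i as independent Poisson counts,

    S_i ~ Poisson(k_i * theta_i * a_{n_i} * L_i)
    D_i ~ Poisson(theta_i * L_i * (T + 1))

where a_n is the Watterson factor, T the scaled divergence time (the +1
absorbs expected coalescence in the ancestral species) and k_i a
per-locus selection parameter scaling polymorphism relative to neutral
expectation (k<1: reduced polymorphism, sweep-like; k>1: excess,
balancing-selection-like). The null fixes every k_i = 1; the alternative
frees k_i for designated loci. Parameters are fitted by seeded multistart
bounded maximization and compared by a chi-square likelihood-ratio test
(the chi-square reference ignores the k>0 boundary and is approximate).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import lgamma

import numpy as np
from scipy import optimize, stats

from .genetic_io import LocusAlignment

__all__ = [
    "tajima_constants",
    "tajimas_d",
    "PolarizedSFS",
    "polarized_sfs",
    "fay_wu_h_norm",
    "ewens_watterson",
    "NeutralityReport",
    "dhew_test",
    "dhew_null_table",
    "HkaResult",
    "hka_ml",
]

UNDEFINED = float("nan")


def _a(n: int, power: int = 1) -> float:
    return float(np.sum(1.0 / np.arange(1, n, dtype=float) ** power))


def tajima_constants(n: int) -> dict[str, float]:
    """The standard a1,a2,b1,b2,c1,c2,e1,e2 constants."""
    a1 = _a(n)
    a2 = _a(n, 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d(S: int, mean_pairwise_total: float, n: int) -> float:
    """Tajima's D from S, the mean pairwise difference count, and n.

    Returns NaN (undefined) when S == 0.
    """
    if n < 4:
        raise ValueError("Tajima's D needs n >= 4")
    if S == 0:
        return UNDEFINED
    c = tajima_constants(n)
    var = c["e1"] * S + c["e2"] * S * (S - 1)
    return (mean_pairwise_total - S / c["a1"]) / np.sqrt(var)


@dataclass
class PolarizedSFS:
    """Unfolded site-frequency spectrum: xi[i-1] = count of derived alleles
    at sample frequency i (i = 1..n-1)."""

    locus_name: str
    n: int
    xi: np.ndarray
    sites_excluded: int = 0

    @property
    def S(self) -> int:
        return int(np.sum(self.xi))


def polarized_sfs(
    aln: LocusAlignment, outgroup_seq: str, complete_deletion: bool = True
) -> PolarizedSFS:
    """Polarize segregating sites against a single outgroup sequence.

    Columns where the outgroup carries a gap, N, or a third state not seen
    in the ingroup are excluded and counted in ``sites_excluded``.
    """
    m = aln.matrix()
    if len(outgroup_seq) != aln.length:
        raise ValueError("outgroup length does not match alignment")
    out = np.array(list(outgroup_seq.upper()))
    keep = np.ones(aln.length, bool)
    if complete_deletion:
        keep = aln.complete_columns()
    n = m.shape[0]
    xi = np.zeros(n - 1, dtype=int)
    excluded = 0
    for j in np.flatnonzero(keep):
        states = set(m[:, j])
        if len(states) < 2:
            continue
        if len(states) > 2:
            excluded += 1
            continue
        og = out[j]
        if og not in states or og in "N-":
            excluded += 1
            continue
        derived = (states - {og}).pop()
        i = int(np.sum(m[:, j] == derived))
        if 1 <= i <= n - 1:
            xi[i - 1] += 1
    return PolarizedSFS(aln.locus_name, n, xi, excluded)


def fay_wu_h_norm(sfs: PolarizedSFS) -> float:
    """Normalized Fay–Wu H = (theta_pi - theta_L) / sqrt(Var).

    theta_L = (1/(n-1)) sum i*xi_i; the variance uses the Watterson-based
    estimators of theta and theta^2. Returns NaN when no polarizable
    segregating sites exist.
    """
    n = sfs.n
    if n < 4:
        raise ValueError("needs n >= 4")
    S = sfs.S
    if S == 0:
        return UNDEFINED
    i = np.arange(1, n, dtype=float)
    xi = np.asarray(sfs.xi, dtype=float)
    theta_pi = float(np.sum(xi * 2.0 * i * (n - i) / (n * (n - 1))))
    theta_l = float(np.sum(i * xi) / (n - 1))
    an = _a(n)
    bn = _a(n, 2)
    bn1 = bn + 1.0 / n**2
    theta_w = S / an
    theta_sq = S * (S - 1) / (an**2 + bn)
    var = theta_w * (n - 2) / (6.0 * (n - 1)) + theta_sq * (
        18.0 * n**2 * (3.0 * n + 2.0) * bn1 - (88.0 * n**3 + 9.0 * n**2 - 13.0 * n + 6.0)
    ) / (9.0 * n * (n - 1) ** 2)
    return (theta_pi - theta_l) / np.sqrt(var)


# ---------------------------------------------------------------------------
# Ewens–Watterson homozygosity test
# ---------------------------------------------------------------------------

def _partitions(n: int, k: int, max_part: int | None = None):
    """Yield non-increasing partitions of n into exactly k positive parts."""
    if max_part is None:
        max_part = n
    if k == 1:
        if n <= max_part:
            yield (n,)
        return
    for first in range(min(n - k + 1, max_part), 0, -1):
        for rest in _partitions(n - first, k - 1, first):
            yield (first,) + rest


def _esf_weight(partition: tuple[int, ...]) -> float:
    """Ewens sampling formula weight (theta-free, conditional on k parts):
    n! / (prod parts * prod multiplicity!)."""
    n = sum(partition)
    log_w = lgamma(n + 1)
    for p in partition:
        log_w -= np.log(p)
    mult: dict[int, int] = {}
    for p in partition:
        mult[p] = mult.get(p, 0) + 1
    for m in mult.values():
        log_w -= lgamma(m + 1)
    return float(np.exp(log_w))


def ewens_watterson(
    hap_counts, exact_max_n: int = 12, n_mc: int = 100_000, seed: int = 0
) -> tuple[float, float]:
    """Observed homozygosity F = sum p_i^2 and p = Pr(F <= F_obs) under the
    Ewens sampling formula conditioned on (n, k).

    Exact partition enumeration for n <= ``exact_max_n``; otherwise
    seeded Monte Carlo (rejection sampling from the Chinese-restaurant
    process with theta tuned so E[K] = k).
    """
    counts = np.asarray(sorted(hap_counts, reverse=True), dtype=int)
    n = int(counts.sum())
    k = len(counts)
    if n < 2 or k < 1:
        raise ValueError("need n >= 2 and k >= 1")
    f_obs = float(np.sum((counts / n) ** 2))
    if k == 1:
        return 1.0, 1.0
    if n <= exact_max_n:
        weights = []
        fs = []
        for part in _partitions(n, k):
            weights.append(_esf_weight(part))
            fs.append(np.sum((np.array(part) / n) ** 2))
        weights = np.array(weights)
        fs = np.array(fs)
        p = float(weights[fs <= f_obs + 1e-12].sum() / weights.sum())
        return f_obs, p
    # Monte Carlo: tune theta so that E[K|theta] = k, then reject on K != k
    i = np.arange(n, dtype=float)

    def mean_k(theta: float) -> float:
        return float(np.sum(theta / (theta + i)))

    theta = optimize.brentq(lambda t: mean_k(t) - k, 1e-6, 1e6)
    rng = np.random.default_rng(seed)
    accepted_f: list[float] = []
    batch = 2000
    while len(accepted_f) < n_mc:
        for _ in range(batch):
            sizes: list[int] = []
            for j in range(n):
                if rng.random() < theta / (theta + j):
                    sizes.append(1)
                else:
                    # join existing table with prob proportional to size
                    tot = j
                    r = rng.random() * tot
                    acc = 0.0
                    for t_idx, s in enumerate(sizes):
                        acc += s
                        if r < acc:
                            sizes[t_idx] += 1
                            break
            if len(sizes) == k:
                arr = np.array(sizes, dtype=float)
                accepted_f.append(float(np.sum((arr / n) ** 2)))
        if not accepted_f:
            batch *= 2
    sims = np.array(accepted_f[:n_mc])
    p = float(np.mean(sims <= f_obs + 1e-12))
    return f_obs, p


# ---------------------------------------------------------------------------
# DHEW compound test
# ---------------------------------------------------------------------------

@dataclass
class NeutralityReport:
    locus_name: str
    n: int
    S: int
    tajima_d: float
    faywu_h_norm: float
    ew_homozygosity: float
    dhew_reject: bool
    alpha: float
    n_sims: int
    seed: int
    quantile: float = UNDEFINED


def _triples_from_replicates(replicates) -> np.ndarray:
    """(n_sims, 3) array of (D, H_norm, F) from simulated site configurations."""
    out = np.empty((len(replicates), 3))
    for r, (n, derived_counts, hap_sizes) in enumerate(replicates):
        S = len(derived_counts)
        i = np.asarray(derived_counts, dtype=float)
        pi_total = float(np.sum(2.0 * i * (n - i) / (n * (n - 1))))
        d = tajimas_d(S, pi_total, n)
        xi = np.bincount(derived_counts, minlength=n)[1:n]
        h = fay_wu_h_norm(PolarizedSFS("sim", n, xi))
        sizes = np.asarray(hap_sizes, dtype=float)
        f = float(np.sum((sizes / n) ** 2))
        out[r] = (d, h, f)
    return out


def dhew_null_table(n: int, S: int, n_sims: int, seed: int) -> np.ndarray:
    """Simulate the neutral null: (n_sims, 3) triples of (D, H, F) from
    fixed-S panmictic coalescent replicates."""
    from .coalsim import panmictic_site_configs

    return _triples_from_replicates(panmictic_site_configs(n, S, n_sims, seed))


def calibrate_joint_quantile(
    triples: np.ndarray, alpha: float, iters: int = 40
) -> tuple[float, tuple[float, float, float]]:
    """Find (by binary search) the largest common one-tailed quantile q such
    that the joint region {D <= d_q, H <= h_q, F >= f_(1-q)} has empirical
    null mass <= alpha. Returns q and the thresholds."""
    d, h, f = triples[:, 0], triples[:, 1], triples[:, 2]

    def joint_mass(q: float) -> tuple[float, tuple[float, float, float]]:
        dq = np.quantile(d, q)
        hq = np.quantile(h, q)
        fq = np.quantile(f, 1.0 - q)
        mass = float(np.mean((d <= dq) & (h <= hq) & (f >= fq)))
        return mass, (float(dq), float(hq), float(fq))

    lo, hi = 0.0, 1.0
    best = (0.0, joint_mass(1e-9)[1])
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        mass, thr = joint_mass(mid)
        if mass <= alpha:
            best = (mid, thr)
            lo = mid
        else:
            hi = mid
    return best


def dhew_test(
    aln: LocusAlignment,
    outgroup_seq: str,
    alpha: float = 0.05,
    n_sims: int = 2000,
    seed: int = 0,
    null_triples: np.ndarray | None = None,
) -> NeutralityReport:
    """DHEW compound neutrality test with simulated fixed-S null.

    ``null_triples`` may supply a precomputed table from
    :func:`dhew_null_table` for the same (n, S); otherwise it is simulated
    here (deterministic given ``seed``).
    """
    from .diversity import nucleotide_diversity
    from .genetic_io import segregating_sites

    n = aln.n_sequences
    if n < 4:
        raise ValueError("DHEW needs n >= 4")
    S = segregating_sites(aln)
    if S == 0:
        return NeutralityReport(
            aln.locus_name, n, 0, UNDEFINED, UNDEFINED, UNDEFINED,
            False, alpha, n_sims, seed,
        )
    pi_total = nucleotide_diversity(aln, per_site=False)
    d_obs = tajimas_d(S, pi_total, n)
    sfs = polarized_sfs(aln, outgroup_seq)
    h_obs = fay_wu_h_norm(sfs) if sfs.S > 0 else UNDEFINED
    # homozygosity from haplotype counts (complete deletion)
    m = aln.matrix()[:, aln.complete_columns()]
    haps: dict[str, int] = {}
    for row in m:
        key = "".join(row)
        haps[key] = haps.get(key, 0) + 1
    sizes = np.array(list(haps.values()), dtype=float)
    f_obs = float(np.sum((sizes / n) ** 2))

    if null_triples is None:
        null_triples = dhew_null_table(n, S, n_sims, seed)
    q, (dq, hq, fq) = calibrate_joint_quantile(null_triples, alpha)
    reject = bool(
        np.isfinite(h_obs) and d_obs <= dq and h_obs <= hq and f_obs >= fq
    )
    return NeutralityReport(
        aln.locus_name, n, S, float(d_obs), float(h_obs), f_obs,
        reject, alpha, len(null_triples), seed, q,
    )


# ---------------------------------------------------------------------------
# Multilocus HKA (maximum likelihood)
# ---------------------------------------------------------------------------

@dataclass
class LocusSummary:
    name: str
    S: int  # segregating sites (polymorphism)
    D: int  # fixed differences to outgroup (divergence)
    n: int  # sample size (sequences)
    L: int  # analysed sites


@dataclass
class HkaResult:
    loci: list[str]
    free_k_loci: list[str]
    theta: dict[str, float]
    T: float
    k: dict[str, float]
    logL_null: float
    logL_alt: float
    lrt: float
    df: int
    p_value: float

    def interpretation(self, locus: str) -> str:
        kk = self.k.get(locus, 1.0)
        if kk < 1.0:
            return "reduced polymorphism"
        if kk > 1.0:
            return "excess polymorphism"
        return "neutral"


def _hka_loglik(
    log_params: np.ndarray,
    summaries: list[LocusSummary],
    free_idx: list[int],
) -> float:
    """Poisson log likelihood; params are log(theta_1..theta_m, T, k_free...)."""
    m = len(summaries)
    thetas = np.exp(log_params[:m])
    T = np.exp(log_params[m])
    ks = np.ones(m)
    for pos, i in enumerate(free_idx):
        ks[i] = np.exp(log_params[m + 1 + pos])
    ll = 0.0
    for i, s in enumerate(summaries):
        an = _a(s.n)
        mu_s = ks[i] * thetas[i] * an * s.L
        mu_d = thetas[i] * s.L * (T + 1.0)
        ll += s.S * np.log(mu_s) - mu_s - lgamma(s.S + 1)
        ll += s.D * np.log(mu_d) - mu_d - lgamma(s.D + 1)
    return ll


def _fit(
    summaries: list[LocusSummary], free_idx: list[int], seed: int, n_starts: int
) -> tuple[float, np.ndarray]:
    m = len(summaries)
    dim = m + 1 + len(free_idx)
    rng = np.random.default_rng(seed)
    # moment-based start: theta_i ~ S_i/(a_n L), T from pooled D
    theta0 = np.array(
        [max(s.S, 0.5) / (_a(s.n) * s.L) for s in summaries]
    )
    T0 = max(
        np.mean([s.D / (t * s.L) for s, t in zip(summaries, theta0)]) - 1.0, 0.1
    )
    base = np.concatenate([np.log(theta0), [np.log(T0)], np.zeros(len(free_idx))])
    best_ll = -np.inf
    best_x = base
    bounds = [(-25.0, 10.0)] * dim
    for start in range(n_starts):
        x0 = base if start == 0 else base + rng.normal(0, 1.0, dim)
        res = optimize.minimize(
            lambda x: -_hka_loglik(x, summaries, free_idx),
            x0,
            method="L-BFGS-B",
            bounds=bounds,
        )
        if -res.fun > best_ll:
            best_ll = -res.fun
            best_x = res.x
    if not np.isfinite(best_ll):
        raise RuntimeError(f"HKA optimization failed to converge; best x={best_x}")
    return best_ll, best_x


def hka_ml(
    loci_summaries: list[LocusSummary],
    free_k_loci: list[str],
    seed: int = 0,
    n_starts: int = 10,
) -> HkaResult:
    """Maximum-likelihood multilocus HKA with per-locus selection parameters.

    Null: all k_i = 1. Alternative: k_i free for ``free_k_loci``. LRT
    compared to chi-square with df = number of free loci.
    """
    if len(loci_summaries) < 2:
        raise ValueError("HKA needs at least 2 loci")
    names = [s.name for s in loci_summaries]
    free_idx = [names.index(nm) for nm in free_k_loci]
    m = len(loci_summaries)

    ll0, x0 = _fit(loci_summaries, [], seed, n_starts)
    ll1, x1 = _fit(loci_summaries, free_idx, seed + 1, n_starts)
    lrt = max(2.0 * (ll1 - ll0), 0.0)
    df = len(free_idx)
    p = float(stats.chi2.sf(lrt, df)) if df > 0 else 1.0
    thetas = {nm: float(np.exp(x1[i])) for i, nm in enumerate(names)}
    T = float(np.exp(x1[m]))
    ks = {nm: 1.0 for nm in names}
    for pos, i in enumerate(free_idx):
        ks[names[i]] = float(np.exp(x1[m + 1 + pos]))
    return HkaResult(
        names, list(free_k_loci), thetas, T, ks,
        float(ll0), float(ll1), float(lrt), df, p,
    )
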