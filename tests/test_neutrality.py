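"""Tajima's D, Fay–Wu H, Ewens–Watterson, DHEW, multilocus HKA."""

import itertools
import math

import numpy as np
import pytest

from conftest import make_alignment
from ventconn.coalsim import panmictic_site_configs, simulate_panmictic
from ventconn.diversity import nucleotide_diversity
from ventconn.genetic_io import AlignmentRecord, LocusAlignment
from ventconn.neutrality import (
    LocusSummary,
    PolarizedSFS,
    dhew_null_table,
    dhew_test,
    ewens_watterson,
    fay_wu_h_norm,
    hka_ml,
    polarized_sfs,
    tajimas_d,
)


def tajima_oracle(S, pi, n):
    """Independent transcription of the Tajima constants."""
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return (pi - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


def faywu_oracle(n, xi):
    """Independent transcription of the normalized Fay–Wu H."""
    S = sum(xi)
    tp = sum(x * 2.0 * i * (n - i) for i, x in zip(range(1, n), xi)) / (n * (n - 1))
    tl = sum(i * x for i, x in zip(range(1, n), xi)) / (n - 1.0)
    an = sum(1.0 / i for i in range(1, n))
    bn = sum(1.0 / i**2 for i in range(1, n))
    bn1 = bn + 1.0 / n**2
    tw = S / an
    t2 = S * (S - 1.0) / (an**2 + bn)
    var = tw * (n - 2.0) / (6.0 * (n - 1.0)) + t2 * (
        18.0 * n**2 * (3.0 * n + 2.0) * bn1
        - (88.0 * n**3 + 9.0 * n**2 - 13.0 * n + 6.0)
    ) / (9.0 * n * (n - 1.0) ** 2)
    return (tp - tl) / math.sqrt(var)


def ew_p_oracle(counts):
    """Exhaustive Ewens-sampling enumeration (independent recursion)."""
    counts = sorted(counts, reverse=True)
    n, k = sum(counts), len(counts)
    f_obs = sum((c / n) ** 2 for c in counts)

    def parts(total, parts_left, cap):
        if parts_left == 1:
            if total <= cap:
                yield [total]
            return
        for first in range(min(total - parts_left + 1, cap), 0, -1):
            for rest in parts(total - first, parts_left - 1, first):
                yield [first] + rest

    num = den = 0.0
    for lam in parts(n, k, n):
        w = math.factorial(n)
        for p in lam:
            w /= p
        for mult in {m: lam.count(m) for m in lam}.values():
            w /= math.factorial(mult)
        den += w
        if sum((c / n) ** 2 for c in lam) <= f_obs + 1e-12:
            num += w
    return num / den


class TestTajimasD:
    def test_undefined_when_no_segregating_sites(self):
        assert math.isnan(tajimas_d(0, 0.0, 10))

    def test_constructed_zero(self):
        a1 = sum(1.0 / i for i in range(1, 10))
        assert tajimas_d(16, 16 / a1, 10) == pytest.approx(0.0, abs=1e-12)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            tajimas_d(5, 2.0, 3)

    def test_matches_independent_constants_oracle(self):
        ds = simulate_panmictic(6, theta=4.0, seed=21)
        aln = ds.alignments[0]
        from ventconn.genetic_io import segregating_sites

        S = segregating_sites(aln)
        pi = nucleotide_diversity(aln, per_site=False)
        assert tajimas_d(S, pi, 6) == pytest.approx(tajima_oracle(S, pi, 6), abs=1e-12)


class TestFayWuH:
    def test_hand_built_sfs_matches_oracle(self):
        sfs = PolarizedSFS("toy", 5, np.array([2, 0, 0, 1]))
        assert fay_wu_h_norm(sfs) == pytest.approx(
            faywu_oracle(5, [2, 0, 0, 1]), abs=1e-12
        )

    def test_sign_flips_under_frequency_reflection(self):
        lo = fay_wu_h_norm(PolarizedSFS("lo", 8, np.array([5, 0, 0, 0, 0, 0, 0])))
        hi = fay_wu_h_norm(PolarizedSFS("hi", 8, np.array([0, 0, 0, 0, 0, 0, 5])))
        assert lo > 0 > hi

    def test_neutral_mean_near_zero(self):
        # 2000 neutral fixed-S replicates: mean within 3 SE of 0
        configs = panmictic_site_configs(10, 10, 2000, seed=42)
        hs = []
        for n, derived, _ in configs:
            xi = np.bincount(derived, minlength=n)[1:n]
            hs.append(fay_wu_h_norm(PolarizedSFS("sim", n, xi)))
        hs = np.array(hs)
        se = hs.std(ddof=1) / np.sqrt(len(hs))
        assert abs(hs.mean()) < 3 * se + 0.08  # small simulation bias allowance

    def test_polarization_excludes_bad_outgroup_columns(self):
        aln = make_alignment(["AACT", "AACT", "ATCT", "ATCT"])
        # outgroup: N at col 1 (the segregating site) -> excluded
        sfs = polarized_sfs(aln, "ANCT")
        assert sfs.S == 0
        assert sfs.sites_excluded == 1


class TestEwensWatterson:
    def test_single_haplotype(self):
        assert ewens_watterson([7]) == (1.0, 1.0)

    def test_forced_partition_n4_k4(self):
        f, p = ewens_watterson([1, 1, 1, 1])
        assert f == pytest.approx(0.25)
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "counts",
        [[4, 2, 2], [6, 1, 1], [3, 3, 2], [2, 2, 2, 2], [5, 2, 1], [4, 4]],
    )
    def test_exact_p_matches_enumeration_oracle(self, counts):
        _, p = ewens_watterson(counts)
        assert p == pytest.approx(ew_p_oracle(counts), abs=1e-12)

    def test_monte_carlo_close_to_exact(self):
        # n=14 forces the MC path; compare to exact enumeration
        counts = [8, 4, 2]
        _, p_mc = ewens_watterson(counts, exact_max_n=12, n_mc=20_000, seed=5)
        p_exact = ew_p_oracle(counts)
        assert p_mc == pytest.approx(p_exact, abs=0.03)


class TestDHEW:
    def _sweep_like_alignment(self):
        """One dominant haplotype; derived variants at frequency n-1."""
        n, L = 12, 40
        base = ["A"] * L
        seqs = []
        for i in range(n):
            s = base.copy()
            for j in range(8):  # derived at frequency n-1 (all but seq 0)
                if i != 0:
                    s[j] = "T"
            seqs.append("".join(s))
        outgroup = "A" * L
        return make_alignment(seqs), outgroup

    def test_deterministic_given_seed(self):
        ds = simulate_panmictic(10, theta=4.0, seed=3)
        aln = ds.alignments[0]
        og = ds.truth["locus"]["ancestral"]
        r1 = dhew_test(aln, og, n_sims=500, seed=11)
        r2 = dhew_test(aln, og, n_sims=500, seed=11)
        assert (r1.dhew_reject, r1.quantile) == (r2.dhew_reject, r2.quantile)

    def test_sweep_like_signal_rejected(self):
        aln, og = self._sweep_like_alignment()
        rep = dhew_test(aln, og, n_sims=2000, seed=1)
        assert rep.faywu_h_norm < 0  # high-frequency derived excess
        assert rep.ew_homozygosity > 0.5
        assert rep.dhew_reject

    def test_no_test_when_monomorphic(self):
        aln = make_alignment(["ACGT"] * 6)
        rep = dhew_test(aln, "ACGT", seed=0)
        assert not rep.dhew_reject
        assert math.isnan(rep.tajima_d)


class TestHKA:
    def test_proportional_counts_give_neutral_k(self):
        s1 = LocusSummary("a", 20, 40, 10, 500)
        s2 = LocusSummary("b", 20, 40, 10, 500)
        res = hka_ml([s1, s2], ["a"], seed=1)
        assert abs(res.k["a"] - 1.0) < 0.05
        assert res.lrt < 0.01

    def test_reduced_polymorphism_detected(self):
        s1 = LocusSummary("a", 10, 40, 10, 500)  # S halved vs proportionality
        s2 = LocusSummary("b", 20, 40, 10, 500)
        res = hka_ml([s1, s2], ["a"], seed=1)
        assert res.k["a"] < 1.0
        assert res.interpretation("a") == "reduced polymorphism"

    def test_optimizer_beats_grid_search(self):
        s1 = LocusSummary("a", 12, 30, 8, 400)
        s2 = LocusSummary("b", 25, 35, 12, 600)
        res = hka_ml([s1, s2], ["a"], seed=2)
        # dense grid over (theta1, theta2, T, k1) in log space
        from ventconn.neutrality import _hka_loglik

        t1 = np.log(np.linspace(0.001, 0.02, 14))
        t2 = np.log(np.linspace(0.001, 0.02, 14))
        Ts = np.log(np.linspace(0.5, 8.0, 14))
        ks = np.log(np.linspace(0.2, 3.0, 14))
        best = -np.inf
        for a in t1:
            for b in t2:
                for c in Ts:
                    for d in ks:
                        ll = _hka_loglik(np.array([a, b, c, d]), [s1, s2], [0])
                        best = max(best, ll)
        assert res.logL_alt >= best - 1e-3

    def test_locus_relabeling_invariance(self):
        s1 = LocusSummary("a", 12, 30, 8, 400)
        s2 = LocusSummary("b", 25, 35, 12, 600)
        r1 = hka_ml([s1, s2], ["a"], seed=3)
        r2 = hka_ml([s2, s1], ["a"], seed=3)
        assert r1.lrt == pytest.approx(r2.lrt, abs=1e-4)

    def test_adding_proportional_neutral_locus_keeps_lrt(self):
        # base pair is null-consistent (LRT ~ 0); a third perfectly
        # proportional locus with k fixed at 1 must add no selection signal
        s1 = LocusSummary("a", 20, 40, 10, 500)
        s2 = LocusSummary("b", 20, 40, 10, 500)
        s3 = LocusSummary("c", 40, 80, 10, 1000)  # doubled but proportional
        r12 = hka_ml([s1, s2], ["a"], seed=4)
        r123 = hka_ml([s1, s2, s3], ["a"], seed=4)
        assert r12.lrt < 0.01
        assert abs(r12.lrt - r123.lrt) < 0.01

    def test_needs_two_loci(self):
        with pytest.raises(ValueError):
            hka_ml([LocusSummary("a", 5, 5, 6, 100)], [])
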