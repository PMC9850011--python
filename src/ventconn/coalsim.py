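"""Structured-coalescent simulator with migration and infinite-sites mutation.

The generator serves three purposes: neutral nulls for the DHEW compound
test (fast fixed-S panmictic replicates), study-like multilocus
multi-population data sets (one maternally inherited haploid locus with a
quarter of the autosomal effective size plus three diploid nuclear loci,
with unequal per-population sample sizes), and parameter-recovery
fixtures for the F_ST estimators.

Time is measured in coalescent units of the reference deme: a pair of
lineages in a deme of relative size x coalesces at rate 1/x (so
E[T_MRCA] = 1 for a panmictic pair), a lineage migrates backward in time
from deme i to deme j at rate M_ij/2 where M = 4N*m, and mutations fall
on a branch at rate theta/2 per unit time, giving the Watterson
expectation E[S] = theta * sum_{i<n} 1/i. A maternally inherited haploid
locus uses inheritance scaling s = 0.25: coalescence is 1/s times faster,
so its effective diversity is s*theta. Mutations follow infinite sites:
every mutation creates a new biallelic column, so the per-locus mutation
count equals the number of segregating sites and no four-gamete
violation can occur.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genetic_io import AlignmentRecord, LocusAlignment, PopulationHierarchy

__all__ = [
    "Locus",
    "CoalescentModel",
    "SimulatedDataset",
    "simulate_panmictic",
    "simulate_structured",
    "panmictic_site_configs",
    "make_study_like",
    "STUDY_PRESETS",
]

BASES = np.array(list("ACGT"))


@dataclass
class Locus:
    name: str
    theta: float
    length: int
    inheritance_scaling: float = 1.0  # 1.0 nuclear-diploid, 0.25 maternal-haploid

    @property
    def ploidy(self) -> int:
        return 1 if self.inheritance_scaling != 1.0 else 2


@dataclass
class CoalescentModel:
    demes: list[tuple[str, float]]  # (name, relative size)
    sample_sizes: dict[str, int]  # individuals per deme (default for all loci)
    migration: np.ndarray  # backward rates, scaled 4N*m; zero diagonal
    loci: list[Locus]
    seed: int = 0
    sample_sizes_per_locus: dict[str, dict[str, int]] | None = None

    def __post_init__(self) -> None:
        self.migration = np.asarray(self.migration, dtype=float)
        d = len(self.demes)
        if self.migration.shape != (d, d):
            raise ValueError("migration matrix shape mismatch")
        if np.any(self.migration < 0):
            raise ValueError("migration rates must be non-negative")
        if np.any(np.diag(self.migration) != 0):
            raise ValueError("migration matrix diagonal must be zero")
        for loc in self.loci:
            if loc.theta <= 0:
                raise ValueError(f"theta must be positive for locus {loc.name}")
        for name, n in self.sample_sizes.items():
            if n < 0:
                raise ValueError(f"negative sample size for deme {name}")

    def locus_sample_sizes(self, locus: Locus) -> dict[str, int]:
        if self.sample_sizes_per_locus and locus.name in self.sample_sizes_per_locus:
            return self.sample_sizes_per_locus[locus.name]
        return self.sample_sizes


@dataclass
class SimulatedDataset:
    alignments: list[LocusAlignment]
    hierarchy: PopulationHierarchy
    truth: dict[str, dict]  # per locus: t_mrca, total_branch_length, S, ancestral
    provenance: dict

    def alignment(self, locus_name: str) -> LocusAlignment:
        for a in self.alignments:
            if a.locus_name == locus_name:
                return a
        raise KeyError(locus_name)

    def write(self, outdir) -> None:
        """FASTA per locus + population-map CSV + JSON provenance sidecar."""
        from pathlib import Path

        from .genetic_io import write_locus_fasta

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for aln in self.alignments:
            write_locus_fasta(aln, out / f"{aln.locus_name}.fasta")
        rows = [
            {
                "individual_id": ind,
                "population": pop,
                "region": self.hierarchy.population_to_region[pop],
            }
            for ind, pop in self.hierarchy.individual_to_population.items()
        ]
        pd.DataFrame(rows).to_csv(out / "population_map.csv", index=False)
        with open(out / "provenance.json", "w") as fh:
            json.dump(self.provenance, fh, indent=2, default=str)


# ---------------------------------------------------------------------------
# Genealogy simulation
# ---------------------------------------------------------------------------

def _panmictic_tree(n: int, rng: np.random.Generator):
    """Kingman coalescent for n lineages (pair rate 1).

    Returns (branch leaf-masks, branch lengths, T_MRCA, total length).
    """
    masks = [1 << i for i in range(n)]
    blens = [0.0] * n
    out_masks: list[int] = []
    out_lens: list[float] = []
    t = 0.0
    k = n
    while k > 1:
        rate = k * (k - 1) / 2.0
        dt = rng.exponential(1.0 / rate)
        t += dt
        for i in range(k):
            blens[i] += dt
        i, j = rng.choice(k, size=2, replace=False)
        i, j = (int(i), int(j)) if i < j else (int(j), int(i))
        out_masks.append(masks[i])
        out_lens.append(blens[i])
        out_masks.append(masks[j])
        out_lens.append(blens[j])
        masks[i] = masks[i] | masks[j]
        blens[i] = 0.0
        masks.pop(j)
        blens.pop(j)
        k -= 1
    return out_masks, np.array(out_lens), t, float(np.sum(out_lens))


def _structured_tree(
    n_per_deme: list[int],
    sizes: list[float],
    migration: np.ndarray,
    rng: np.random.Generator,
    scaling: float = 1.0,
    max_events: int = 10_000_000,
):
    """Structured coalescent: pair rate 1/(x_d*scaling) within deme d,
    per-lineage migration rate M_dj/2."""
    d = len(n_per_deme)
    masks: list[int] = []
    demes: list[int] = []
    offset = 0
    for dd, nd in enumerate(n_per_deme):
        for _ in range(nd):
            masks.append(1 << offset)
            demes.append(dd)
            offset += 1
    blens = [0.0] * len(masks)
    out_masks: list[int] = []
    out_lens: list[float] = []
    mig_out = migration.sum(axis=1) / 2.0  # per-lineage rate by deme
    t = 0.0
    events = 0
    while len(masks) > 1:
        events += 1
        if events > max_events:
            raise RuntimeError(
                "structured coalescent did not finish within the event budget "
                "(disconnected migration graph with multi-deme samples?)"
            )
        k_by = np.bincount(demes, minlength=d)
        coal_rates = k_by * (k_by - 1) / 2.0 / (np.array(sizes) * scaling)
        mig_rates = k_by * mig_out
        total = coal_rates.sum() + mig_rates.sum()
        if total <= 0:
            raise RuntimeError(
                "no possible events: isolated lineages in separate demes "
                "can never coalesce (use a small positive migration rate)"
            )
        dt = rng.exponential(1.0 / total)
        t += dt
        for i in range(len(blens)):
            blens[i] += dt
        u = rng.random() * total
        if u < coal_rates.sum():
            # coalescence: pick deme, then pair
            dd = int(rng.choice(d, p=coal_rates / coal_rates.sum()))
            members = [i for i, x in enumerate(demes) if x == dd]
            i, j = rng.choice(len(members), size=2, replace=False)
            a, b = members[int(i)], members[int(j)]
            if a > b:
                a, b = b, a
            out_masks.append(masks[a])
            out_lens.append(blens[a])
            out_masks.append(masks[b])
            out_lens.append(blens[b])
            masks[a] |= masks[b]
            blens[a] = 0.0
            for lst in (masks, blens, demes):
                lst.pop(b)
        else:
            dd = int(rng.choice(d, p=mig_rates / mig_rates.sum()))
            members = [i for i, x in enumerate(demes) if x == dd]
            lin = members[int(rng.integers(len(members)))]
            dest_rates = migration[dd] / 2.0
            dest = int(rng.choice(d, p=dest_rates / dest_rates.sum()))
            demes[lin] = dest
    return out_masks, np.array(out_lens), t, float(np.sum(out_lens))


def _place_mutations(
    out_masks, out_lens, rng, theta=None, fixed_S=None
) -> list[int]:
    """Mutation carrier masks: Poisson(theta/2 * total length) or exactly S,
    placed on branches proportionally to length."""
    total = float(np.sum(out_lens))
    if fixed_S is not None:
        S = int(fixed_S)
    else:
        S = int(rng.poisson(theta / 2.0 * total))
    if S == 0:
        return []
    p = np.asarray(out_lens) / total
    idx = rng.choice(len(out_masks), size=S, p=p)
    return [out_masks[i] for i in idx]


def _hap_signatures(mut_masks: list[int], n: int) -> tuple[np.ndarray, list[int]]:
    """Per-site derived counts and haplotype class sizes."""
    derived = np.array([m.bit_count() for m in mut_masks], dtype=int)
    sigs = [0] * n
    for s, m in enumerate(mut_masks):
        while m:
            low = m & -m
            sigs[low.bit_length() - 1] |= 1 << s
            m ^= low
    counts: dict[int, int] = {}
    for s in sigs:
        counts[s] = counts.get(s, 0) + 1
    return derived, list(counts.values())


def panmictic_site_configs(n: int, S: int, n_sims: int, seed: int):
    """Fast neutral null replicates conditioned on (n, S).

    Returns a list of (n, derived_counts, haplotype_sizes) triples, one per
    replicate — everything the DHEW component statistics need, without
    building sequence alignments.
    """
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_sims):
        masks, lens, _, _ = _panmictic_tree(n, rng)
        muts = _place_mutations(masks, lens, rng, fixed_S=S)
        derived, hap_sizes = _hap_signatures(muts, n)
        out.append((n, derived, hap_sizes))
    return out


def _alignment_from_mutations(
    mut_masks: list[int],
    n: int,
    length: int,
    rng: np.random.Generator,
    locus_name: str,
    ids: list[tuple[str, str, int]],  # (sequence_id, individual_id, allele_index)
    ploidy: int,
) -> tuple[LocusAlignment, str]:
    """Build sequences (and the ancestral sequence) from mutation masks."""
    S = len(mut_masks)
    if length < S:
        raise ValueError(
            f"locus length {length} < segregating sites {S}; use a longer locus"
        )
    ancestral_idx = rng.integers(0, 4, size=length)
    positions = rng.choice(length, size=S, replace=False)
    derived_idx = {}
    for s, pos in enumerate(positions):
        derived_idx[s] = (ancestral_idx[pos] + int(rng.integers(1, 4))) % 4
    seqs = np.tile(BASES[ancestral_idx], (n, 1))
    for s, pos in enumerate(positions):
        m = mut_masks[s]
        while m:
            low = m & -m
            seqs[low.bit_length() - 1, pos] = BASES[derived_idx[s]]
            m ^= low
    records = [
        AlignmentRecord(sid, ind, allele, "".join(row))
        for (sid, ind, allele), row in zip(ids, seqs)
    ]
    ancestral = "".join(BASES[ancestral_idx])
    return LocusAlignment(locus_name, ploidy, records), ancestral


def simulate_panmictic(
    n: int,
    theta: float | None = None,
    fixed_S: int | None = None,
    length: int = 1000,
    seed: int = 0,
    locus_name: str = "locus",
) -> SimulatedDataset:
    """Standard neutral coalescent sample from a single panmictic deme."""
    if n < 2:
        raise ValueError("need n >= 2")
    if (theta is None) == (fixed_S is None):
        raise ValueError("supply exactly one of theta or fixed_S")
    rng = np.random.default_rng(seed)
    masks, lens, t_mrca, total = _panmictic_tree(n, rng)
    muts = _place_mutations(masks, lens, rng, theta=theta, fixed_S=fixed_S)
    ids = [(f"seq{i:04d}", f"seq{i:04d}", 1) for i in range(n)]
    aln, ancestral = _alignment_from_mutations(
        muts, n, length, rng, locus_name, ids, ploidy=1
    )
    hierarchy = PopulationHierarchy(
        {f"seq{i:04d}": "pop1" for i in range(n)}, {"pop1": "region1"}
    )
    truth = {
        locus_name: {
            "t_mrca": t_mrca,
            "total_branch_length": total,
            "S": len(muts),
            "ancestral": ancestral,
        }
    }
    prov = {"model": "panmictic", "n": n, "theta": theta, "fixed_S": fixed_S, "seed": seed}
    return SimulatedDataset([aln], hierarchy, truth, prov)


def _check_connected(migration: np.ndarray, sampled: list[int]) -> bool:
    d = migration.shape[0]
    adj = (migration > 0) | (migration.T > 0)
    seen = {sampled[0]}
    stack = [sampled[0]]
    while stack:
        x = stack.pop()
        for y in range(d):
            if adj[x, y] and y not in seen:
                seen.add(y)
                stack.append(y)
    return all(s in seen for s in sampled)


def simulate_structured(model: CoalescentModel) -> SimulatedDataset:
    """Structured coalescent data set: one alignment per locus, demes as
    populations, deterministic given the model seed."""
    rng = np.random.default_rng(model.seed)
    deme_names = [d[0] for d in model.demes]
    sizes = [d[1] for d in model.demes]
    alignments: list[LocusAlignment] = []
    truth: dict[str, dict] = {}
    ind2pop: dict[str, str] = {}
    for locus in model.loci:
        ss = model.locus_sample_sizes(locus)
        sampled_idx = [i for i, nm in enumerate(deme_names) if ss.get(nm, 0) > 0]
        if len(sampled_idx) > 1 and not _check_connected(model.migration, sampled_idx):
            warnings.warn(
                "migration graph disconnects sampled demes; "
                "T_MRCA may be unbounded (event budget applies)"
            )
        n_per = [ss.get(nm, 0) * locus.ploidy for nm in deme_names]
        n = sum(n_per)
        masks, lens, t_mrca, total = _structured_tree(
            n_per, sizes, model.migration, rng, scaling=locus.inheritance_scaling
        )
        muts = _place_mutations(masks, lens, rng, theta=locus.theta)
        ids: list[tuple[str, str, int]] = []
        for nm in deme_names:
            n_ind = ss.get(nm, 0)
            for i in range(n_ind):
                ind = f"{nm}_i{i:03d}"
                ind2pop[ind] = nm
                for allele in range(1, locus.ploidy + 1):
                    suffix = f"_{allele}" if locus.ploidy > 1 else ""
                    ids.append((f"{ind}{suffix}|{locus.name}", ind, allele))
        aln, ancestral = _alignment_from_mutations(
            muts, n, locus.length, rng, locus.name, ids, ploidy=locus.ploidy
        )
        alignments.append(aln)
        truth[locus.name] = {
            "t_mrca": t_mrca,
            "total_branch_length": total,
            "S": len(muts),
            "ancestral": ancestral,
        }
    pop2region = {nm: nm for nm in deme_names}
    hierarchy = PopulationHierarchy(ind2pop, pop2region)
    prov = {
        "model": "structured",
        "demes": model.demes,
        "migration": model.migration.tolist(),
        "loci": [(l.name, l.theta, l.length, l.inheritance_scaling) for l in model.loci],
        "seed": model.seed,
    }
    return SimulatedDataset(alignments, hierarchy, truth, prov)


# ---------------------------------------------------------------------------
# Study-like presets (populations, regions, per-locus sample sizes)
# ---------------------------------------------------------------------------

# per population: (region, counts of individuals sequenced for
# mtCOI / ATPSa / ATPSb / EF1a), ordered roughly west -> east (or south -> north)
STUDY_PRESETS: dict[str, dict] = {
    "boucheti-like": {
        "populations": {
            "SW8": ("Manus", (18, 14, 13, 14)),
            "SW1": ("Manus", (25, 16, 19, 17)),
            "SS": ("Manus", (41, 19, 20, 21)),
            "NF": ("Vanuatu", (6, 5, 5, 3)),
            "WL": ("NorthFiji", (17, 5, 12, 16)),
            "MH": ("NorthFiji", (15, 6, 8, 9)),
            "WR": ("NorthFiji", (15, 14, 6, 14)),
            "NS": ("Tonga", (19, 16, 3, 9)),
            "KM": ("Lau", (29, 14, 19, 27)),
            "ABE": ("Lau", (11, 9, 0, 7)),
        },
    },
    "kojimai-like": {
        "populations": {
            "SW8": ("Manus", (1, 0, 1, 1)),
            "SW1": ("Manus", (52, 23, 36, 37)),
            "WL": ("NorthFiji", (1, 0, 1, 1)),
            "MH": ("NorthFiji", (4, 0, 0, 0)),
            "WR": ("NorthFiji", (4, 2, 1, 2)),
            "TC": ("Lau", (13, 5, 12, 13)),
            "THM": ("Lau", (4, 0, 1, 3)),
            "ABE": ("Lau", (3, 0, 0, 1)),
            "TM": ("Lau", (38, 16, 20, 34)),
        },
    },
    "strummeri-like": {
        "populations": {
            "THM": ("Lau", (22, 12, 19, 23)),
            "TM": ("Lau", (34, 22, 27, 27)),
        },
    },
    "hessleri-like": {
        "populations": {
            "FC": ("South", (10, 11, 14, 15)),
            "SN": ("South", (23, 24, 19, 27)),
            "HA": ("Mid", (18, 5, 7, 3)),
            "PS": ("Mid", (6, 0, 2, 3)),
            "AS": ("North", (23, 9, 13, 8)),
            "BU": ("North", (4, 0, 2, 0)),
            "IL": ("North", (7, 1, 3, 5)),
        },
    },
}

LOCUS_NAMES = ("mtCOI", "ATPSa", "ATPSb", "EF1a")


def make_study_like(
    preset_name: str,
    seed: int = 0,
    theta: float = 2.0,
    m_within: float = 10.0,
    m_between: float = 1.0,
    asymmetry: float = 0.0,
) -> SimulatedDataset:
    """Study-like data set: 4 loci (1 maternal-haploid + 3 nuclear-diploid),
    per-population sample sizes copied from the sampling table, and a
    stepping-stone migration chain (rate ``m_within`` between adjacent
    populations of a region, ``m_between`` across region boundaries;
    ``asymmetry`` in (-1, 1) biases forward rates by (1+a) and backward
    rates by (1-a))."""
    if preset_name not in STUDY_PRESETS:
        raise ValueError(
            f"unknown preset {preset_name!r}; available: {sorted(STUDY_PRESETS)}"
        )
    preset = STUDY_PRESETS[preset_name]
    pops = list(preset["populations"])
    regions = [preset["populations"][p][0] for p in pops]
    d = len(pops)
    M = np.zeros((d, d))
    for i in range(d - 1):
        rate = m_within if regions[i] == regions[i + 1] else m_between
        M[i, i + 1] = rate * (1.0 + asymmetry)
        M[i + 1, i] = rate * (1.0 - asymmetry)
    loci = [
        Locus("mtCOI", theta, 1000, inheritance_scaling=0.25),
        Locus("ATPSa", theta, 2000),
        Locus("ATPSb", theta, 2000),
        Locus("EF1a", theta, 2000),
    ]
    per_locus = {
        ln: {p: preset["populations"][p][1][j] for p in pops}
        for j, ln in enumerate(LOCUS_NAMES)
    }
    model = CoalescentModel(
        demes=[(p, 1.0) for p in pops],
        sample_sizes={p: max(preset["populations"][p][1]) for p in pops},
        migration=M,
        loci=loci,
        seed=seed,
        sample_sizes_per_locus=per_locus,
    )
    ds = simulate_structured(model)
    # attach regions
    pop2region = {p: preset["populations"][p][0] for p in pops}
    ds.hierarchy.population_to_region.update(pop2region)
    ds.provenance.update(
        {
            "preset": preset_name,
            "m_within": m_within,
            "m_between": m_between,
            "asymmetry": asymmetry,
        }
    )
    return ds
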