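"""Sequence-alignment I/O, haplotype collapsing and the recombination screen.

Multilocus data sets are held as one :class:`LocusAlignment` per locus
(mitochondrial loci are haploid, nuclear loci carry two phased allele
sequences per individual) together with a :class:`PopulationHierarchy`
mapping individuals to populations and populations to geographic regions.

Missing data policy: the default for every downstream statistic is
complete deletion — alignment columns containing ``N`` or ``-`` in any
sequence are dropped before haplotypes are collapsed or sites counted.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_CHARS = set("ACGTN-")

#: default header pattern: "ind123_1" -> individual "ind123", allele 1;
#: headers without the suffix are haploid (allele 1).
DEFAULT_HEADER_PATTERN = r"^(?P<individual>.+?)(?:_(?P<allele>[12]))?$"


@dataclass
class AlignmentRecord:
    sequence_id: str
    individual_id: str
    allele_index: int  # 1-based; <= ploidy
    sequence: str


@dataclass
class LocusAlignment:
    """Aligned sequences for one locus, with individual/ploidy labels."""

    locus_name: str
    ploidy: int
    records: list[AlignmentRecord]
    length: int = 0

    def __post_init__(self) -> None:
        if self.records:
            lengths = {len(r.sequence) for r in self.records}
            if len(lengths) > 1:
                bad = next(
                    r for r in self.records
                    if len(r.sequence) != len(self.records[0].sequence)
                )
                raise ValueError(
                    f"ragged alignment in locus {self.locus_name!r}: "
                    f"record {bad.sequence_id!r} has length {len(bad.sequence)}"
                )
            self.length = len(self.records[0].sequence)
        seen: set[tuple[str, int]] = set()
        for r in self.records:
            if r.allele_index > self.ploidy:
                raise ValueError(
                    f"allele_index {r.allele_index} exceeds ploidy {self.ploidy} "
                    f"for {r.sequence_id!r}"
                )
            key = (r.individual_id, r.allele_index)
            if key in seen:
                raise ValueError(f"duplicate (individual, allele): {key}")
            seen.add(key)

    @property
    def n_sequences(self) -> int:
        return len(self.records)

    def matrix(self) -> np.ndarray:
        """Sequences as a (n, L) array of single characters."""
        return np.array([list(r.sequence) for r in self.records])

    def complete_columns(self) -> np.ndarray:
        """Boolean mask of columns free of N and gaps in every sequence."""
        m = self.matrix()
        return ~np.any((m == "N") | (m == "-"), axis=0)

    def individuals(self) -> list[str]:
        out: list[str] = []
        for r in self.records:
            if r.individual_id not in out:
                out.append(r.individual_id)
        return out


@dataclass
class PopulationHierarchy:
    """individual -> population -> region partition with optional site metadata."""

    individual_to_population: dict[str, str]
    population_to_region: dict[str, str]
    population_metadata: pd.DataFrame | None = None

    @property
    def populations(self) -> list[str]:
        return list(dict.fromkeys(self.population_to_region))

    @property
    def regions(self) -> list[str]:
        return list(dict.fromkeys(self.population_to_region.values()))

    def population_of(self, individual_id: str) -> str:
        try:
            return self.individual_to_population[individual_id]
        except KeyError:
            raise KeyError(f"individual {individual_id!r} missing from population map")

    def region_of_population(self, population: str) -> str:
        return self.population_to_region[population]


@dataclass
class HaplotypeTable:
    """Per-population counts of distinct haplotype strings for one locus."""

    locus_name: str
    counts: dict[str, dict[str, int]]  # population -> haplotype string -> count
    retained_columns: int = 0

    def population_n(self, population: str) -> int:
        return sum(self.counts[population].values())

    def frequencies(self, population: str) -> np.ndarray:
        c = np.array(list(self.counts[population].values()), dtype=float)
        return c / c.sum()

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pop, haps in self.counts.items():
            for hap, k in haps.items():
                rows.append({"population": pop, "haplotype": hap, "count": k})
        return pd.DataFrame(rows)


def read_locus_fasta(
    path,
    ploidy: int,
    header_pattern: str = DEFAULT_HEADER_PATTERN,
    locus_name: str | None = None,
) -> LocusAlignment:
    """Read an aligned FASTA into a :class:`LocusAlignment`.

    The FASTA header (up to the first whitespace) is the ``sequence_id``;
    ``header_pattern`` is a regex with named groups ``individual`` and
    (optionally) ``allele`` that decomposes it. Lowercase bases are
    normalized to uppercase.
    """
    pattern = re.compile(header_pattern)
    records: list[AlignmentRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        m = pattern.match(rec.id)
        if m is None:
            raise ValueError(f"unparseable FASTA header: {rec.id!r}")
        groups = m.groupdict()
        individual = groups.get("individual") or rec.id
        allele = int(groups["allele"]) if groups.get("allele") else 1
        seq = str(rec.seq).upper()
        bad = set(seq) - VALID_CHARS
        if bad:
            raise ValueError(f"invalid characters {sorted(bad)} in {rec.id!r}")
        records.append(AlignmentRecord(rec.id, individual, allele, seq))
    if not records:
        raise ValueError(f"no sequences in {path}")
    name = locus_name if locus_name is not None else str(path)
    return LocusAlignment(name, ploidy, records)


def write_locus_fasta(aln: LocusAlignment, path) -> None:
    recs = [
        SeqRecord(Seq(r.sequence), id=r.sequence_id, description="")
        for r in aln.records
    ]
    SeqIO.write(recs, str(path), "fasta")


def load_population_map(path) -> PopulationHierarchy:
    """Load the sample metadata CSV (individual_id, population, region [, lat, lon, depth_m])."""
    df = pd.read_csv(path)
    required = {"individual_id", "population", "region"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"population map missing required columns: {sorted(missing)}")
    ind2pop: dict[str, str] = {}
    for _, row in df.iterrows():
        ind = str(row["individual_id"])
        pop = str(row["population"])
        if ind in ind2pop and ind2pop[ind] != pop:
            raise ValueError(
                f"conflicting population assignment for individual {ind!r}: "
                f"{ind2pop[ind]!r} vs {pop!r}"
            )
        ind2pop[ind] = pop
    pop2region: dict[str, str] = {}
    for _, row in df.iterrows():
        pop, region = str(row["population"]), str(row["region"])
        if pop in pop2region and pop2region[pop] != region:
            raise ValueError(
                f"population {pop!r} assigned to two regions: "
                f"{pop2region[pop]!r} vs {region!r}"
            )
        pop2region[pop] = region
    meta_cols = [c for c in ("lat", "lon", "depth_m") if c in df.columns]
    meta = None
    if meta_cols:
        meta = df.drop_duplicates("population").set_index("population")[meta_cols]
    return PopulationHierarchy(ind2pop, pop2region, meta)


def sequences_by_population(
    aln: LocusAlignment, hierarchy: PopulationHierarchy
) -> dict[str, list[str]]:
    """Group the alignment's sequences by population (order preserved)."""
    out: dict[str, list[str]] = {}
    for r in aln.records:
        pop = hierarchy.population_of(r.individual_id)
        out.setdefault(pop, []).append(r.sequence)
    return out


def collapse_haplotypes(
    aln: LocusAlignment,
    hierarchy: PopulationHierarchy,
    complete_deletion: bool = True,
) -> HaplotypeTable:
    """Collapse sequences into per-population haplotype counts.

    Under complete deletion (the default) every column containing ``N`` or a
    gap in any sequence is removed before exact string comparison.
    """
    mask = aln.complete_columns() if complete_deletion else np.ones(aln.length, bool)
    m = aln.matrix()[:, mask]
    haps = ["".join(row) for row in m]
    counts: dict[str, dict[str, int]] = {}
    for r, hap in zip(aln.records, haps):
        pop = hierarchy.population_of(r.individual_id)
        counts.setdefault(pop, {})
        counts[pop][hap] = counts[pop].get(hap, 0) + 1
    for pop in hierarchy.populations:
        if pop not in counts:
            warnings.warn(f"population {pop!r} has no sequences for {aln.locus_name}")
    return HaplotypeTable(aln.locus_name, counts, retained_columns=int(mask.sum()))


def segregating_sites(aln: LocusAlignment, complete_deletion: bool = True) -> int:
    """Number of retained columns with at least two observed states."""
    if aln.n_sequences == 0:
        raise ValueError("empty alignment")
    m = aln.matrix()
    if complete_deletion:
        m = m[:, aln.complete_columns()]
    if m.shape[1] == 0:
        return 0
    return int(np.sum([len(set(col)) > 1 for col in m.T]))


def _biallelic_columns(m: np.ndarray) -> list[int]:
    cols = []
    for j in range(m.shape[1]):
        if len(set(m[:, j])) == 2:
            cols.append(j)
    return cols


def four_gamete_scan(
    aln: LocusAlignment, complete_deletion: bool = True
) -> tuple[list[tuple[int, int]], list[int]]:
    """Scan biallelic site pairs for four-gamete violations.

    Returns ``(violations, mask)`` where ``violations`` lists pairs of
    original column indices at which all four gametic types occur, and
    ``mask`` is a greedy-minimal set of columns whose removal clears every
    violation (iteratively drop the column involved in the most violating
    pairs, ties broken leftmost). Under infinite sites without
    recombination the violation list is empty.
    """
    m = aln.matrix()
    keep = aln.complete_columns() if complete_deletion else np.ones(aln.length, bool)
    idx = np.flatnonzero(keep)
    sub = m[:, keep]
    bi = _biallelic_columns(sub)
    violations: list[tuple[int, int]] = []
    for a_pos in range(len(bi)):
        for b_pos in range(a_pos + 1, len(bi)):
            a, b = bi[a_pos], bi[b_pos]
            gametes = {(x, y) for x, y in zip(sub[:, a], sub[:, b])}
            if len(gametes) == 4:
                violations.append((int(idx[a]), int(idx[b])))
    mask: list[int] = []
    remaining = list(violations)
    while remaining:
        tally: dict[int, int] = {}
        for a, b in remaining:
            tally[a] = tally.get(a, 0) + 1
            tally[b] = tally.get(b, 0) + 1
        best = max(tally, key=lambda c: (tally[c], -c))
        mask.append(best)
        remaining = [p for p in remaining if best not in p]
    return violations, sorted(mask)
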