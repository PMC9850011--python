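"""Confronting genetic gene-flow estimates with modelled dispersal.

Gene-flow matrices are inputs (external isolation-with-migration output
via a CSV adapter, or simulator ground truth); the comparison layer is
estimator-agnostic. For every population pair the directional asymmetry
(m_fw - m_bw)/(m_fw + m_bw) of genetic migration is compared with the
same quantity computed from source-normalized joint dispersal
probabilities, pairs are classified (concordant-direction,
discordant-direction, genetic-only, dispersal-only, neither), and an
overall Spearman rank concordance over ordered pairs is reported
(midranks computed explicitly).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GeneFlowMatrix",
    "asymmetry",
    "spearman_midrank",
    "ComparisonReport",
    "compare",
]

#: |asymmetry| below this is treated as bidirectional when judging direction
DIRECTION_DEADBAND = 0.1


@dataclass
class GeneFlowMatrix:
    """Directional migration estimates m[i -> j] with significance flags."""

    populations: list
    m: np.ndarray  # (n, n), non-negative, diagonal unused
    significant: np.ndarray  # (n, n) bool
    provenance: dict | None = None

    def __post_init__(self) -> None:
        self.m = np.asarray(self.m, dtype=float)
        if np.any(self.m < 0):
            raise ValueError("migration estimates must be non-negative")
        self.significant = np.asarray(self.significant, dtype=bool)

    @classmethod
    def from_csv(cls, path, provenance: dict | None = None) -> "GeneFlowMatrix":
        """CSV adapter: long format with columns source, dest, m, significant."""
        df = pd.read_csv(path)
        req = {"source", "dest", "m", "significant"}
        if not req <= set(df.columns):
            raise ValueError(f"gene-flow CSV needs columns {sorted(req)}")
        pops = sorted(set(df["source"]) | set(df["dest"]))
        idx = {p: i for i, p in enumerate(pops)}
        m = np.zeros((len(pops), len(pops)))
        sig = np.zeros((len(pops), len(pops)), dtype=bool)
        for _, row in df.iterrows():
            i, j = idx[row["source"]], idx[row["dest"]]
            m[i, j] = row["m"]
            sig[i, j] = bool(row["significant"])
        return cls(pops, m, sig, provenance)


def asymmetry(m_fw: float, m_bw: float) -> float:
    """(m_fw - m_bw) / (m_fw + m_bw); NaN when both are zero."""
    if m_fw < 0 or m_bw < 0:
        raise ValueError("migration rates must be non-negative")
    tot = m_fw + m_bw
    if tot == 0:
        return float("nan")
    return (m_fw - m_bw) / tot


def spearman_midrank(a: np.ndarray, b: np.ndarray) -> float:
    """Spearman rank correlation with midranks for ties, by explicit formula
    (Pearson correlation of the rank vectors)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)

    def midranks(x: np.ndarray) -> np.ndarray:
        order = np.argsort(x, kind="mergesort")
        ranks = np.empty(len(x))
        i = 0
        while i < len(x):
            j = i
            while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks

    ra, rb = midranks(a), midranks(b)
    ra = ra - ra.mean()
    rb = rb - rb.mean()
    denom = np.sqrt(np.sum(ra**2) * np.sum(rb**2))
    if denom == 0:
        return float("nan")
    return float(np.sum(ra * rb) / denom)


@dataclass
class ComparisonReport:
    pairs: pd.DataFrame  # one row per unordered pair
    rank_concordance: float  # Spearman over ordered pairs (m vs N)
    threshold_dispersal: float

    def class_counts(self) -> dict[str, int]:
        return self.pairs["agreement"].value_counts().to_dict()


def compare(
    gene_flow: GeneFlowMatrix,
    dispersal_N: pd.DataFrame,
    population_to_site: dict | None = None,
    threshold_d: float = 1e-3,
    deadband: float = DIRECTION_DEADBAND,
) -> ComparisonReport:
    """Classify every population pair by agreement between genetic and
    modelled connectivity.

    ``dispersal_N`` is the source-normalized joint connectivity (rows =
    source sites). ``population_to_site`` maps population labels to
    registry site ids (identity when omitted). A dispersal connection is
    "predicted" when N[i][j] >= ``threshold_d`` (probabilities below
    10^-3 are treated as effectively no connection); a genetic connection is
    "observed" when the migration estimate is flagged significant.
    Direction is concordant when the asymmetries share a sign or both lie
    within the dead band (effectively bidirectional).
    """
    pops = gene_flow.populations
    mapping = population_to_site or {p: p for p in pops}
    gaps = [p for p in pops if mapping.get(p) not in dispersal_N.index]
    if gaps:
        raise ValueError(f"populations not mapped to dispersal sites: {gaps}")
    rows = []
    m_vals = []
    n_vals = []
    for i, pa in enumerate(pops):
        for j, pb in enumerate(pops):
            if i == j:
                continue
            m_vals.append(gene_flow.m[i, j])
            n_vals.append(float(dispersal_N.loc[mapping[pa], mapping[pb]]))
    for i, pa in enumerate(pops):
        for j in range(i + 1, len(pops)):
            pb = pops[j]
            m_fw, m_bw = gene_flow.m[i, j], gene_flow.m[j, i]
            n_fw = float(dispersal_N.loc[mapping[pa], mapping[pb]])
            n_bw = float(dispersal_N.loc[mapping[pb], mapping[pa]])
            asym_g = asymmetry(m_fw, m_bw) if (m_fw + m_bw) > 0 else np.nan
            asym_d = asymmetry(n_fw, n_bw) if (n_fw + n_bw) > 0 else np.nan
            genetic = bool(
                (gene_flow.significant[i, j] and m_fw > 0)
                or (gene_flow.significant[j, i] and m_bw > 0)
            )
            dispersal = bool(n_fw >= threshold_d or n_bw >= threshold_d)
            if genetic and dispersal:
                both_small = (
                    np.isfinite(asym_g)
                    and np.isfinite(asym_d)
                    and abs(asym_g) < deadband
                    and abs(asym_d) < deadband
                )
                same_sign = (
                    np.isfinite(asym_g)
                    and np.isfinite(asym_d)
                    and np.sign(asym_g) == np.sign(asym_d)
                )
                cls = "concordant-direction" if (both_small or same_sign) else "discordant-direction"
            elif genetic:
                cls = "genetic-only"
            elif dispersal:
                cls = "dispersal-only"
            else:
                cls = "neither"
            rows.append(
                {
                    "pop_a": pa,
                    "pop_b": pb,
                    "m_ab": m_fw,
                    "m_ba": m_bw,
                    "N_ab": n_fw,
                    "N_ba": n_bw,
                    "asymmetry_genetic": asym_g,
                    "asymmetry_dispersal": asym_d,
                    "agreement": cls,
                }
            )
    rho = spearman_midrank(np.array(m_vals), np.array(n_vals))
    return ComparisonReport(pd.DataFrame(rows), rho, threshold_d)
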