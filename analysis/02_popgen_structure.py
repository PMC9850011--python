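"""Population structure on the simulated data: diversity, F_ST, AMOVA.

Reads the hessleri-like data set written by 01_simulate_genetic.py
(regenerating it if absent), computes per-locus diversity statistics,
pairwise Weir–Cockerham F_ST with bootstrap confidence intervals
(separately for the mitochondrial and the pooled nuclear markers, the
two-triangle layout of the study's tables), and hierarchical AMOVA.
Writes diversity.csv, fst_mito.csv, fst_nuclear.csv and amova.csv under
results/popgen/ and prints the headline numbers.
"""

import sys
from itertools import combinations
from pathlib import Path

import pandas as pd

from ventconn.coalsim import make_study_like
from ventconn.diversity import amova, diversity_table, fst_bootstrap

OUT = Path("results/popgen")
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 42
PRESET = "hessleri-like"  # 7 populations, 3 latitudinal clusters


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    ds = make_study_like(PRESET, seed=SEED + 3)
    div = diversity_table(ds.alignments, ds.hierarchy)
    div.to_csv(OUT / "diversity.csv", index=False)
    print("diversity (per locus x population): written", OUT / "diversity.csv")
    print(div.groupby("locus")[["pi", "H", "S"]].mean().round(4))

    mito = [a for a in ds.alignments if a.ploidy == 1]
    nuclear = [a for a in ds.alignments if a.ploidy == 2]
    pops = [p for p in ds.hierarchy.populations]
    for marker, loci in (("mito", mito), ("nuclear", nuclear)):
        rows = []
        for pa, pb in combinations(pops, 2):
            try:
                r = fst_bootstrap(loci, ds.hierarchy, pa, pb, n_boot=200, seed=SEED)
            except ValueError:
                continue  # a population unsampled at some locus
            rows.append(
                {
                    "pop_a": pa, "pop_b": pb, "theta": r.theta,
                    "ci_low": r.ci_low, "ci_high": r.ci_high,
                    "significant": r.significant,
                }
            )
        df = pd.DataFrame(rows)
        df.to_csv(OUT / f"fst_{marker}.csv", index=False)
        sig = df["significant"].mean()
        print(
            f"{marker}: {len(df)} pairs, mean theta {df.theta.mean():.4f}, "
            f"{sig:.0%} significant"
        )

    frames = []
    for aln in ds.alignments:
        levels = ("region", "population") if aln.ploidy == 1 else (
            "region", "population", "individual")
        res = amova(aln, ds.hierarchy, levels)
        f = res.to_frame()
        f.insert(0, "locus", aln.locus_name)
        frames.append(f)
        pcts = ", ".join(
            f"{n}={p:.1f}%" for n, p in zip(res.level_names, res.percent_variation)
        )
        print(f"AMOVA {aln.locus_name}: {pcts}")
    pd.concat(frames, ignore_index=True).to_csv(OUT / "amova.csv", index=False)


if __name__ == "__main__":
    main()
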