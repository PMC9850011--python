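"""Multi-generation stepping-stone connectivity.

Loads the single-generation transition matrix written by
04_dispersal_simulation.py (which must run first), filters the registry
to sites deeper than the dispersal depth, and computes first-passage
joint transition probabilities through all stepping-stone paths (up to
100 generations) plus their source-normalized form. Writes
joint_transition.csv and joint_normalized.csv under results/dispersal/
and prints the site-to-site connectivity.
"""

import sys
from pathlib import Path

import pandas as pd

from ventconn.dispersal import TransitionMatrix, VentRegistry
from ventconn.stepping_stone import (
    eligibility_filter,
    joint_transition,
    normalize_to_source,
)

DIR = Path("results/dispersal")
DEPTH = 1500.0


def main() -> None:
    tm = TransitionMatrix.from_csv(DIR / "transition_matrix.csv")
    registry = VentRegistry(pd.read_csv(DIR / "registry.csv"))
    kept = eligibility_filter(registry, DEPTH)
    print(
        f"eligibility at {DEPTH:.0f} m: kept {kept.ids} of {registry.ids} "
        f"(sites shallower than the dispersal depth cannot be sensed)"
    )
    idx = [tm.sites.index(s) for s in kept.ids]
    import numpy as np

    sub = TransitionMatrix(kept.ids, tm.P[np.ix_(idx, idx)])
    joint = joint_transition(sub, max_steps=100, tol=1e-12)
    joint.to_csv(DIR / "joint_transition.csv")
    N = normalize_to_source(joint)
    N.to_csv(DIR / "joint_normalized.csv")
    print(
        f"\njoint transition (first passage, <= {joint.max_steps} steps, "
        f"converged={joint.converged} after {joint.steps_used} steps):"
    )
    print(joint.to_frame().round(5).to_string())
    print("\nnormalized to sources N[i][j] = J[i][j]/J[i][i]:")
    print(N.round(4).to_string())


if __name__ == "__main__":
    main()
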