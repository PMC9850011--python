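"""Multi-generation stepping-stone connectivity.

Joint transition probabilities J[i][j] give the chance that a lineage of
larvae starting at site i reaches site j within at most ``max_steps``
generations through any chain of intermediate sites, where each
generation applies the single-generation transition matrix P
independently. "Reaches" is first passage: the destination absorbs, so
mass that arrives is never recycled. The self-value J[i][i] is the first
*return* probability (one transport step away from i, then i absorbing),
which makes the source-normalized matrix N[i][j] = J[i][j] / J[i][i]
well defined; an occupancy-based self-value is available behind a switch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dispersal import TransitionMatrix, VentRegistry

__all__ = [
    "JointConnectivity",
    "joint_transition",
    "normalize_to_source",
    "eligibility_filter",
]


@dataclass
class JointConnectivity:
    sites: list
    J: np.ndarray  # first-passage probability within <= steps_used generations
    steps_used: int
    converged: bool
    tol: float
    max_steps: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.J, index=self.sites, columns=self.sites)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


def joint_transition(
    P: TransitionMatrix, max_steps: int = 100, tol: float = 1e-12
) -> JointConnectivity:
    """First-passage joint transition probabilities through all paths.

    For each destination j the chain is propagated with j absorbing,
    starting from each source's one-step distribution; J[i][j] accumulates
    the absorbed mass over at most ``max_steps`` generations, stopping
    early once the largest per-step increment falls below ``tol``.
    """
    M = np.asarray(P.P, dtype=float)
    if np.any(M.sum(axis=1) > 1 + 1e-9):
        raise ValueError("row sums of P must be <= 1")
    n = M.shape[0]
    J = np.zeros((n, n))
    steps_used = 0
    converged = True
    for j in range(n):
        # rows of V: unabsorbed distribution for each source i (j absorbing)
        V = M.copy()  # after one transport step
        absorbed = V[:, j].copy()
        V[:, j] = 0.0
        step = 1
        dest_converged = False
        while step < max_steps:
            V = V @ M
            inc = V[:, j].copy()
            absorbed += inc
            V[:, j] = 0.0
            step += 1
            if inc.max(initial=0.0) < tol:
                dest_converged = True
                break
        converged = converged and (dest_converged or max_steps == 1)
        steps_used = max(steps_used, step)
        J[:, j] = absorbed
    return JointConnectivity(P.sites, J, steps_used, converged, tol, max_steps)


def normalize_to_source(joint: JointConnectivity) -> pd.DataFrame:
    """N[i][j] = J[i][j] / J[i][i]; rows with zero self-value become NaN."""
    J = joint.J
    diag = np.diag(J).copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        N = np.where(diag[:, None] > 0, J / diag[:, None], np.nan)
    return pd.DataFrame(N, index=joint.sites, columns=joint.sites)


def eligibility_filter(
    registry: VentRegistry, dispersal_depth_m: float
) -> VentRegistry:
    """Retain stepping-stone sites deeper than (or at) the dispersal depth."""
    kept = registry.sites[registry.sites["depth_m"] >= dispersal_depth_m]
    if kept.empty:
        warnings.warn(
            f"no sites at or below dispersal depth {dispersal_depth_m} m"
        )
    return VentRegistry(kept.reset_index(drop=True))
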