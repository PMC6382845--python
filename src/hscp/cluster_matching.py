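"""Pairing of time-course clusters across two activation models.

Cluster prototypes from two models (e.g. diet-induced vs toxin-induced
activation) are matched one-to-one by maximizing the total Pearson
correlation between paired prototypes (optimal linear assignment).
Shared genes are the per-pair member intersections, and their overlap
significance is an upper-tail hypergeometric probability over the
universe of genes retained in both clusterings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.stats import hypergeom

__all__ = ["ClusterPairing", "pair_clusters", "shared_genes", "overlap_significance"]


@dataclass
class ClusterPairing:
    """One-to-one cluster pairs with prototype correlations.

    ``pairs`` columns: cluster_a, cluster_b, r, low_confidence (True if
    the best achievable r for the pair is negative).
    """

    pairs: pd.DataFrame
    unpaired_a: list
    unpaired_b: list


def _align_time_axes(pa: pd.DataFrame, pb: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Interpolate the shorter prototypes onto the longer ordinal grid.

    Time axes are treated ordinally on [0, 1]; when both models share
    the same number of time points no interpolation happens.
    """
    a, b = pa.to_numpy(dtype=float), pb.to_numpy(dtype=float)
    na, nb = a.shape[1], b.shape[1]
    if na == nb:
        return a, b
    grid_long = np.linspace(0.0, 1.0, max(na, nb))
    if na < nb:
        grid_short = np.linspace(0.0, 1.0, na)
        a = np.array([np.interp(grid_long, grid_short, row) for row in a])
    else:
        grid_short = np.linspace(0.0, 1.0, nb)
        b = np.array([np.interp(grid_long, grid_short, row) for row in b])
    return a, b


def pair_clusters(protos_a: pd.DataFrame, protos_b: pd.DataFrame) -> ClusterPairing:
    """Optimal one-to-one pairing maximizing total prototype Pearson r.

    With unequal cluster counts, min(kA, kB) pairs are formed and the
    rest left unpaired with a warning.  Pairs whose r is negative are
    flagged low-confidence but still returned.
    """
    a, b = _align_time_axes(protos_a, protos_b)
    ka, kb = a.shape[0], b.shape[0]
    az = (a - a.mean(axis=1, keepdims=True)) / a.std(axis=1, keepdims=True)
    bz = (b - b.mean(axis=1, keepdims=True)) / b.std(axis=1, keepdims=True)
    r = az @ bz.T / a.shape[1]
    ri, ci = linear_sum_assignment(-r)
    rows = []
    for i, j in zip(ri, ci):
        rows.append(
            {
                "cluster_a": protos_a.index[i],
                "cluster_b": protos_b.index[j],
                "r": float(r[i, j]),
                "low_confidence": bool(r[i, j] < 0),
            }
        )
    pairs = pd.DataFrame(rows).sort_values("cluster_a").reset_index(drop=True)
    unpaired_a = [c for c in protos_a.index if c not in set(pairs["cluster_a"])]
    unpaired_b = [c for c in protos_b.index if c not in set(pairs["cluster_b"])]
    if ka != kb:
        warnings.warn(
            f"unequal cluster counts ({ka} vs {kb}); "
            f"unpaired: {unpaired_a or unpaired_b}",
            stacklevel=2,
        )
    return ClusterPairing(pairs=pairs, unpaired_a=unpaired_a, unpaired_b=unpaired_b)


def shared_genes(
    pairing: ClusterPairing,
    members_a: dict,
    members_b: dict,
) -> pd.DataFrame:
    """Per-pair intersection of member gene sets.

    Returns one row per pair with the shared gene list (sorted), the
    shared count, and the percent of the A-side parent cluster.
    """
    rows = []
    for _, p in pairing.pairs.iterrows():
        sa = set(members_a[p["cluster_a"]])
        sb = set(members_b[p["cluster_b"]])
        inter = sorted(sa & sb)
        rows.append(
            {
                "cluster_a": p["cluster_a"],
                "cluster_b": p["cluster_b"],
                "r": p["r"],
                "n_a": len(sa),
                "n_b": len(sb),
                "shared_n": len(inter),
                "percent_of_a": 100.0 * len(inter) / len(sa) if sa else 0.0,
                "shared_genes": inter,
            }
        )
    return pd.DataFrame(rows)


def overlap_significance(n_a: int, n_b: int, overlap: int, universe_n: int) -> float:
    """Upper-tail hypergeometric P(X >= overlap) for a pair's overlap.

    X ~ Hypergeometric(universe_n, n_a, n_b): draw n_b genes from a
    universe containing n_a marked ones.
    """
    if n_a > universe_n or n_b > universe_n:
        raise ValueError("cluster sizes exceed the universe")
    if overlap > min(n_a, n_b):
        raise ValueError("overlap exceeds the smaller cluster")
    return float(hypergeom.sf(overlap - 1, universe_n, n_a, n_b))
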