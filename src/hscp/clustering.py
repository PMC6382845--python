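"""Time-course clustering of scaled expression profiles.

Profiles are variance-stabilized (log2(x+1) on average RPKM) and
per-gene z-scored, then partitioned by k-medoids (PAM) under the
Pearson-correlation distance d = 1 - r.  PAM runs the classic
deterministic BUILD phase followed by steepest-descent SWAP, so a run
is reproducible without a seed.  k can be chosen by average silhouette
width.  After clustering, the globally worst-fitting fraction of genes
(fit = Pearson r of a gene to its own cluster's mean profile) and an
undersized smallest cluster are removed, mirroring standard post-hoc
clean-up of time-course clusterings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ScaledProfileMatrix",
    "ClusterSet",
    "vst_scale",
    "correlation_distance_matrix",
    "pam_cluster",
    "choose_k",
    "fit_filter",
    "prototypes",
]


@dataclass
class ScaledProfileMatrix:
    """Gene x timepoint matrix of variance-stabilized, z-scored averages."""

    profiles: pd.DataFrame
    flagged_constant: pd.Index  # rows constant after transform, excluded

    @property
    def genes(self) -> pd.Index:
        return self.profiles.index


@dataclass
class ClusterSet:
    """A k-medoids partition of time-course profiles.

    ``labels`` maps gene -> cluster id (0..k-1, ordered by medoid row);
    ``fit`` is each gene's Pearson r to its own cluster prototype
    (the arithmetic mean member profile).
    """

    k: int
    labels: pd.Series
    medoids: list
    prototypes: pd.DataFrame
    fit: pd.Series
    profiles: pd.DataFrame
    discarded: pd.Index = field(default_factory=lambda: pd.Index([]))
    removed_clusters: list = field(default_factory=list)

    def members(self, cluster) -> pd.Index:
        return self.labels.index[self.labels == cluster]

    def member_sets(self) -> dict:
        return {c: set(self.members(c)) for c in self.prototypes.index}

    def sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()

    def mean_fit(self) -> float:
        """Average member-to-prototype Pearson r over all retained genes."""
        return float(self.fit.mean())


def vst_scale(avg_rpkm: pd.DataFrame) -> ScaledProfileMatrix:
    """log2(x+1) variance stabilization then per-gene z-scoring.

    Scaling uses the sample standard deviation (ddof=1).  Rows constant
    after the transform cannot be scaled; they are set to zero and
    flagged for exclusion from clustering.
    """
    x = avg_rpkm.astype(float)
    if (x.to_numpy() < 0).any():
        raise ValueError("average RPKM must be non-negative")
    v = np.log2(x + 1.0)
    mu = v.mean(axis=1)
    sd = v.std(axis=1, ddof=1)
    constant = sd <= 1e-12
    scaled = v.sub(mu, axis=0).div(sd.where(~constant, 1.0), axis=0)
    scaled[constant] = 0.0
    return ScaledProfileMatrix(
        profiles=scaled, flagged_constant=x.index[constant]
    )


def correlation_distance_matrix(profiles: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Pairwise Pearson-correlation distance d = 1 - r between rows."""
    x = np.asarray(profiles, dtype=float)
    sd = x.std(axis=1)
    if (sd <= 1e-12).any():
        raise ValueError("constant profiles have undefined correlation; exclude them")
    r = np.corrcoef(x)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    return np.maximum(d, 0.0)


def _pam_build(d: np.ndarray, k: int) -> list[int]:
    """Deterministic greedy BUILD initialization (ties -> lowest index)."""
    n = d.shape[0]
    medoids = [int(np.argmin(d.sum(axis=1)))]
    nearest = d[medoids[0]].copy()
    while len(medoids) < k:
        # gain of adding candidate h: sum of reductions in nearest distance
        gains = np.maximum(nearest[None, :] - d, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        h = int(np.argmax(gains))
        medoids.append(h)
        nearest = np.minimum(nearest, d[h])
    return medoids


def _pam_swap(d: np.ndarray, medoids: list[int]) -> list[int]:
    """Steepest-descent SWAP until no strictly improving swap remains.

    Swap deltas for all (medoid, candidate) pairs are computed in
    O(n^2) per iteration by splitting each point's contribution into a
    medoid-independent part (gain of moving to the candidate) and a
    correction for the points losing their own medoid.
    """
    n = d.shape[0]
    medoids = list(medoids)
    while True:
        dm = d[medoids]  # k x n
        order = np.argsort(dm, axis=0, kind="stable")
        d1 = dm[order[0], np.arange(n)]
        d2 = dm[order[1], np.arange(n)] if len(medoids) > 1 else np.full(n, np.inf)
        nearest_m = order[0]
        # gain for every candidate h if no medoid were removed
        gain = np.minimum(d - d1[None, :], 0.0).sum(axis=1)
        delta = np.empty((len(medoids), n))
        for mi in range(len(medoids)):
            j = np.nonzero(nearest_m == mi)[0]
            if len(j):
                sub = d[:, j]
                corr = (
                    np.minimum(sub, d2[j][None, :])
                    - d1[j][None, :]
                    - np.minimum(sub - d1[j][None, :], 0.0)
                ).sum(axis=1)
            else:
                corr = 0.0
            delta[mi] = gain + corr
        delta[:, medoids] = np.inf
        best_mi, best_h = np.unravel_index(np.argmin(delta), delta.shape)
        if delta[best_mi, best_h] >= -1e-12:
            break
        medoids[int(best_mi)] = int(best_h)
    return medoids


#: largest number of medoid subsets solved exactly instead of BUILD+SWAP
_EXHAUSTIVE_LIMIT = 20000


def _pam_exhaustive(d: np.ndarray, k: int) -> list[int]:
    """Globally optimal medoid set by vectorized subset enumeration.

    Used for small instances where C(n, k) is modest; single-swap
    descent can stall in local optima there, and exact search is
    cheap.  Ties resolve to the lexicographically smallest subset.
    """
    import itertools

    n = d.shape[0]
    best, best_cost = None, np.inf
    for subset in itertools.combinations(range(n), k):
        cost = d[list(subset)].min(axis=0).sum()
        if cost < best_cost - 1e-12:
            best, best_cost = subset, cost
    return list(best)


def _assign(d: np.ndarray, medoids: list[int]) -> np.ndarray:
    return np.argmin(d[medoids], axis=0)


def silhouette_width(d: np.ndarray, labels: np.ndarray) -> float:
    """Average silhouette width over a precomputed distance matrix.

    s_i = (b_i - a_i) / max(a_i, b_i) with a_i the mean distance to
    the point's own cluster (excluding itself) and b_i the smallest
    mean distance to any other cluster; singletons score 0.
    """
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette needs at least two clusters")
    n = d.shape[0]
    sums = np.stack([d[:, labels == c].sum(axis=1) for c in uniq], axis=1)
    sizes = np.array([(labels == c).sum() for c in uniq])
    own = np.searchsorted(uniq, labels)
    own_size = sizes[own]
    a = np.where(own_size > 1, sums[np.arange(n), own] / np.maximum(own_size - 1, 1), 0.0)
    mean_other = sums / sizes[None, :]
    mean_other[np.arange(n), own] = np.inf
    b = mean_other.min(axis=1)
    s = np.where(own_size > 1, (b - a) / np.maximum(a, b), 0.0)
    return float(s.mean())


def _fits_and_prototypes(
    profiles: pd.DataFrame, labels: pd.Series
) -> tuple[pd.DataFrame, pd.Series]:
    protos = {}
    fit = pd.Series(np.nan, index=profiles.index)
    for c in sorted(labels.unique()):
        members = labels.index[labels == c]
        sub = profiles.loc[members]
        proto = sub.mean(axis=0)
        protos[c] = proto
        pv = proto.to_numpy()
        if np.std(pv) <= 1e-12:
            # degenerate prototype (e.g. antipodal members): fit undefined
            fit[members] = np.nan
            continue
        x = sub.to_numpy()
        xc = x - x.mean(axis=1, keepdims=True)
        pc = pv - pv.mean()
        denom = np.sqrt((xc**2).sum(axis=1) * (pc**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (xc @ pc) / denom
        fit[members] = r
    proto_df = pd.DataFrame(protos).T
    proto_df.index.name = "cluster"
    proto_df.columns = profiles.columns
    return proto_df, fit


def pam_cluster(
    profiles: pd.DataFrame | ScaledProfileMatrix,
    k: int,
    distance: np.ndarray | None = None,
) -> ClusterSet:
    """Partition profiles into k clusters by PAM under 1 - Pearson r.

    Deterministic and seed-free: small instances are solved exactly by
    medoid-subset enumeration; larger ones run BUILD initialization
    followed by steepest-descent SWAP.  Cluster ids 0..k-1 are ordered
    by medoid row position.
    """
    if isinstance(profiles, ScaledProfileMatrix):
        prof = profiles.profiles.drop(index=profiles.flagged_constant)
    else:
        prof = profiles
    n = len(prof)
    if k < 2 or k > n:
        raise ValueError(f"k={k} outside valid range 2..{n}")
    d = correlation_distance_matrix(prof) if distance is None else distance
    from math import comb

    if comb(n, k) <= _EXHAUSTIVE_LIMIT:
        medoids = _pam_exhaustive(d, k)
    else:
        medoids = _pam_swap(d, _pam_build(d, k))
    medoids = sorted(medoids)
    assign = _assign(d, medoids)
    labels = pd.Series(assign, index=prof.index, name="cluster")
    proto_df, fit = _fits_and_prototypes(prof, labels)
    return ClusterSet(
        k=k,
        labels=labels,
        medoids=[prof.index[m] for m in medoids],
        prototypes=proto_df,
        fit=fit,
        profiles=prof,
    )


def choose_k(
    profiles: pd.DataFrame | ScaledProfileMatrix,
    k_range: range = range(2, 13),
    distance: np.ndarray | None = None,
) -> tuple[int, dict[int, float]]:
    """Pick k maximizing average silhouette width (ties -> smallest k).

    Returns (k, {k: silhouette}).  Degenerate input (all profiles
    identical) returns the smallest k in range with a warning.
    """
    if isinstance(profiles, ScaledProfileMatrix):
        prof = profiles.profiles.drop(index=profiles.flagged_constant)
    else:
        prof = profiles
    n = len(prof)
    ks = [k for k in k_range if 2 <= k <= n - 1]
    if not ks:
        raise ValueError("k_range outside 2..n-1")
    d = correlation_distance_matrix(prof) if distance is None else distance
    if np.allclose(d, 0.0):
        warnings.warn("all profiles identical; returning smallest k", stacklevel=2)
        return ks[0], {}
    scores: dict[int, float] = {}
    for k in ks:
        cs = pam_cluster(prof, k, distance=d)
        labels = cs.labels.to_numpy()
        if len(np.unique(labels)) < 2:
            scores[k] = -1.0
            continue
        scores[k] = silhouette_width(d, labels)
    best = max(ks, key=lambda k: (scores[k], -k))
    return best, scores


def fit_filter(
    clusters: ClusterSet,
    drop_frac: float = 0.10,
    min_cluster_size: int = 20,
) -> ClusterSet:
    """Post-hoc removal of ill-fitting genes and an undersized cluster.

    Drops the globally lowest ``floor(n * drop_frac)`` genes by fit
    (ties broken by gene id), then removes the single smallest cluster
    if its (post-drop) size is below ``min_cluster_size``.  Prototypes
    and fits are recomputed on the retained genes.
    """
    if not (0 <= drop_frac < 1):
        raise ValueError("drop_frac must lie in [0, 1)")
    labels = clusters.labels.copy()
    fit = clusters.fit.copy()
    n_drop = int(np.floor(len(labels) * drop_frac))
    # two-key sort: fit ascending, ties broken by gene id
    order = fit.fillna(-np.inf).reset_index()
    order.columns = ["gene_id", "fit"]
    order = order.sort_values(["fit", "gene_id"], kind="mergesort")
    dropped = pd.Index(order["gene_id"].iloc[:n_drop])
    labels = labels.drop(index=dropped)

    removed_clusters: list = []
    sizes = labels.value_counts()
    if len(sizes) > 1:
        smallest = sizes.idxmin() if sizes.min() < min_cluster_size else None
        # deterministic tie-break: smallest size, then lowest cluster id
        if smallest is not None:
            cands = sizes[sizes == sizes.min()].index
            smallest = sorted(cands)[0]
            removed_clusters.append(smallest)
            cluster_drop = labels.index[labels == smallest]
            dropped = dropped.append(cluster_drop)
            labels = labels.drop(index=cluster_drop)

    prof = clusters.profiles.loc[labels.index]
    proto_df, new_fit = _fits_and_prototypes(prof, labels)
    return ClusterSet(
        k=len(proto_df),
        labels=labels,
        medoids=[m for m in clusters.medoids if m in labels.index],
        prototypes=proto_df,
        fit=new_fit,
        profiles=prof,
        discarded=clusters.discarded.append(dropped),
        removed_clusters=clusters.removed_clusters + removed_clusters,
    )


def prototypes(clusters: ClusterSet) -> tuple[pd.DataFrame, pd.Series, float]:
    """Mean aggregate profile per cluster plus per-cluster/overall mean fit.

    Empty clusters are removed with a warning; clusters whose prototype
    is degenerate (zero variance, e.g. exactly antipodal members) get
    NaN mean fit and are flagged by the NaN.
    """
    proto_df, fit = _fits_and_prototypes(clusters.profiles, clusters.labels)
    per_cluster = fit.groupby(clusters.labels).mean()
    per_cluster.index.name = "cluster"
    overall = float(fit.mean())
    return proto_df, per_cluster, overall
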