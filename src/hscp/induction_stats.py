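"""Statistics relating promoter motif presence to gene induction.

Common genes are partitioned by presence of two motifs (e.g. an
ETS1-like family and RUNX1) into none / A-only / B-only / both; the
groups' log2 fold changes are compared by pairwise Wilcoxon rank-sum
tests (exact by full enumeration at small sizes), BH-corrected, with a
compact letter display assigned via connected components of
non-significant pairs.  Rank analysis orders genes by log2FC (rank 1 =
most induced, average ranks on ties) and reports each group's median
rank.  Cluster x motif enrichment tests how motif-bearing genes
distribute over time-course clusters, and a generic hypergeometric
over-representation analysis (ORA) against user gene sets rounds out
the module.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import hypergeom

from .diffexpr import bh_adjust
from .motifscan import MotifHitTable

__all__ = [
    "MotifGroupAssignment",
    "GroupComparisonResult",
    "assign_motif_groups",
    "ranksum_p",
    "compare_groups",
    "rank_analysis",
    "cluster_motif_enrichment",
    "read_gmt",
    "ora",
]

GROUP_LABELS = ("none", "a_only", "b_only", "both")


@dataclass
class MotifGroupAssignment:
    """Gene -> motif group; a partition of the analyzed gene set."""

    groups: pd.Series  # values in GROUP_LABELS
    motif_a: str
    motif_b: str

    def sizes(self) -> pd.Series:
        return self.groups.value_counts().reindex(GROUP_LABELS, fill_value=0)


@dataclass
class GroupComparisonResult:
    """Group medians, pairwise Wilcoxon p/FDR, and letter display."""

    summary: pd.DataFrame  # group, n, median_log2fc, median_rank, letters
    pairwise: pd.DataFrame  # group_1, group_2, p, fdr
    fdr_threshold: float


def assign_motif_groups(
    genes: list[str] | pd.Index,
    table: MotifHitTable,
    motif_a: str,
    motif_b: str,
) -> MotifGroupAssignment:
    """Four-way partition of genes by presence of two motifs."""
    genes = [str(g) for g in genes]
    missing = [g for g in genes if g not in table.presence.index]
    if missing:
        raise KeyError(f"genes missing from motif table: {missing[:10]}"
                       + ("..." if len(missing) > 10 else ""))
    pa = table.presence.loc[genes, motif_a] == 1
    pb = table.presence.loc[genes, motif_b] == 1
    lab = np.select(
        [pa & pb, pa & ~pb, ~pa & pb], ["both", "a_only", "b_only"], default="none"
    )
    return MotifGroupAssignment(
        groups=pd.Series(lab, index=pd.Index(genes, name="gene_id")),
        motif_a=motif_a,
        motif_b=motif_b,
    )


def _ranksum_exact_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided rank-sum p by enumerating all group-label assignments.

    Average ranks handle ties exactly.  Intended for combined n <= 16.
    """
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n, nx = len(pooled), len(x)
    mean_w = nx * (n + 1) / 2.0
    obs = abs(float(ranks[:nx].sum()) - mean_w)
    count = 0
    total = 0
    for idx in itertools.combinations(range(n), nx):
        w = float(ranks[list(idx)].sum())
        total += 1
        if abs(w - mean_w) >= obs - 1e-9:
            count += 1
    return count / total


def ranksum_p(x: np.ndarray, y: np.ndarray, exact_limit: int = 16) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact by full enumeration when the combined size is small (handles
    ties), scipy's exact method for moderate tie-free samples, and the
    normal approximation with continuity correction above n = 50 per
    group.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) + len(y) <= exact_limit:
        return _ranksum_exact_p(x, y)
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    if max(len(x), len(y)) <= 50 and not ties:
        return float(stats.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue)
    return float(
        stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
    )


def _letters(groups: list[str], nonsig: set[tuple[str, str]]) -> dict[str, str]:
    """Compact letter display: connected components of non-significant pairs."""
    parent = {g: g for g in groups}

    def find(g):
        while parent[g] != g:
            parent[g] = parent[parent[g]]
            g = parent[g]
        return g

    for a, b in nonsig:
        parent[find(a)] = find(b)
    roots = sorted({find(g) for g in groups}, key=lambda r: groups.index(r))
    letter = {r: chr(ord("a") + i) for i, r in enumerate(roots)}
    return {g: letter[find(g)] for g in groups}


def rank_analysis(
    log2fc: pd.Series, assignment: MotifGroupAssignment | pd.Series
) -> pd.Series:
    """Median rank per motif group (rank 1 = most induced; ties averaged)."""
    groups = assignment.groups if isinstance(assignment, MotifGroupAssignment) else assignment
    fc = log2fc.loc[groups.index]
    ranks = pd.Series(stats.rankdata(-fc.to_numpy()), index=fc.index)
    return ranks.groupby(groups).median()


def compare_groups(
    log2fc: pd.Series,
    assignment: MotifGroupAssignment | pd.Series,
    fdr_threshold: float = 0.05,
) -> GroupComparisonResult:
    """Pairwise Wilcoxon rank-sum comparison of motif-group log2FC.

    Empty groups are dropped with a warning; requires >= 2 non-empty
    groups.  Letters: groups sharing a letter are pairwise
    non-significant at the BH-FDR threshold.
    """
    import warnings

    groups = assignment.groups if isinstance(assignment, MotifGroupAssignment) else assignment
    fc = log2fc.loc[groups.index].astype(float)
    present = [g for g in dict.fromkeys(groups) if (groups == g).any()]
    order = [g for g in GROUP_LABELS if g in present] + [
        g for g in present if g not in GROUP_LABELS
    ]
    values = {g: fc[groups == g].to_numpy() for g in order}
    empty = [g for g in order if len(values[g]) == 0]
    if empty:
        warnings.warn(f"dropping empty groups: {empty}", stacklevel=2)
        order = [g for g in order if g not in empty]
    if len(order) < 2:
        raise ValueError("need at least two non-empty groups")
    rows = []
    for a, b in itertools.combinations(order, 2):
        rows.append({"group_1": a, "group_2": b, "p": ranksum_p(values[a], values[b])})
    pairwise = pd.DataFrame(rows)
    pairwise["fdr"] = bh_adjust(pairwise["p"].to_numpy())
    nonsig = {
        (r["group_1"], r["group_2"])
        for _, r in pairwise.iterrows()
        if not (r["fdr"] < fdr_threshold)
    }
    letters = _letters(order, nonsig)
    med_rank = rank_analysis(fc, groups)
    summary = pd.DataFrame(
        {
            "n": [len(values[g]) for g in order],
            "median_log2fc": [float(np.median(values[g])) for g in order],
            "median_rank": [float(med_rank.get(g, np.nan)) for g in order],
            "letters": [letters[g] for g in order],
        },
        index=pd.Index(order, name="group"),
    )
    return GroupComparisonResult(
        summary=summary, pairwise=pairwise, fdr_threshold=fdr_threshold
    )


def cluster_motif_enrichment(
    cluster_assignment: pd.Series,
    motif_sets: dict[str, set[str]],
) -> pd.DataFrame:
    """Distribution of motif-bearing genes over time-course clusters.

    ``cluster_assignment`` covers the full analyzed gene universe and
    labels fit-filtered genes "no cluster".  Per cluster x motif:
    overlap count, enrichment ratio = (count / cluster size) /
    (motif total / universe), and upper-tail hypergeometric P.
    """
    universe = cluster_assignment.index
    n_u = len(universe)
    rows = []
    for motif, genes in motif_sets.items():
        genes = set(map(str, genes)) & set(universe)
        m_tot = len(genes)
        for cluster, members in cluster_assignment.groupby(cluster_assignment):
            c_genes = set(members.index)
            k = len(c_genes & genes)
            n_c = len(c_genes)
            ratio = (k / n_c) / (m_tot / n_u) if m_tot and n_c else 0.0
            p = float(hypergeom.sf(k - 1, n_u, m_tot, n_c)) if m_tot else 1.0
            rows.append(
                {"cluster": cluster, "motif": motif, "cluster_size": n_c,
                 "motif_total": m_tot, "count": k, "ratio": ratio, "p": p}
            )
    return pd.DataFrame(rows)


def read_gmt(path: str | Path) -> dict[str, tuple[str, list[str]]]:
    """Read a GMT gene-set file: name <tab> description <tab> members..."""
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = (parts[1], [g for g in parts[2:] if g])
    return sets


def ora(
    foreground: list[str] | set[str],
    background: list[str] | set[str],
    gene_sets: dict[str, tuple[str, list[str]]],
    rpkm_max: pd.Series | None = None,
    expr_filter_rpkm: float = 10.0,
    fdr_max: float = 0.01,
    log2fc: pd.Series | None = None,
) -> pd.DataFrame:
    """Hypergeometric over-representation of gene sets in a foreground.

    Both foreground and background are first restricted to expressed
    genes (max RPKM over time points >= ``expr_filter_rpkm``, closed
    bound) when an RPKM summary is supplied.  Upper-tail p per set over
    the expressed background, BH across sets; rows with FDR <= fdr_max
    flagged ``enriched``.  If per-gene log2FC is given, each set's
    member median log2FC (over foreground members) is reported.
    """
    import warnings

    fg = {str(g) for g in foreground}
    bg = {str(g) for g in background}
    if rpkm_max is not None:
        expressed = set(rpkm_max.index[rpkm_max >= expr_filter_rpkm].astype(str))
        fg &= expressed
        bg &= expressed
    fg &= bg
    if not fg:
        warnings.warn("empty foreground after expression filter", stacklevel=2)
        return pd.DataFrame(
            columns=["set", "description", "set_n", "overlap", "fold", "p", "fdr",
                     "enriched", "median_log2fc"]
        )
    n_bg, n_fg = len(bg), len(fg)
    rows = []
    for name, (desc, members) in gene_sets.items():
        mem = set(map(str, members)) & bg
        k = len(mem & fg)
        big_k = len(mem)
        p = float(hypergeom.sf(k - 1, n_bg, big_k, n_fg)) if big_k else 1.0
        fold = (k / n_fg) / (big_k / n_bg) if big_k else np.nan
        med = float(log2fc.reindex(sorted(mem & fg)).median()) if (log2fc is not None and k) else np.nan
        rows.append(
            {"set": name, "description": desc, "set_n": big_k, "overlap": k,
             "fold": fold, "p": p, "median_log2fc": med}
        )
    out = pd.DataFrame(rows)
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    out["enriched"] = out["fdr"] <= fdr_max
    return out[["set", "description", "set_n", "overlap", "fold", "p", "fdr",
                "enriched", "median_log2fc"]]
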