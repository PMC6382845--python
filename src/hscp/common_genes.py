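"""Cross-model selection of the "common" regulated gene set.

A gene is regulated within one activation model if, between some pair
of time points (later vs earlier), it changes at least ``fc_threshold``-
fold (closed bound) at FDR strictly below ``fdr_threshold``.  The
common set is the genes regulated in the same direction in every model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffexpr import DEResult

__all__ = ["CommonGeneSet", "regulated_in_model", "intersect_common"]


@dataclass
class CommonGeneSet:
    """Genes regulated >= fc-fold (FDR < threshold) in all models, same direction."""

    table: pd.DataFrame  # index gene; columns: direction + per-model stats
    n_induced: int
    n_repressed: int
    n_conflicting: int  # directions disagreed across models -> excluded
    fc_threshold: float
    fdr_threshold: float

    @property
    def genes(self) -> pd.Index:
        return self.table.index

    def __len__(self) -> int:
        return len(self.table)


def regulated_in_model(
    de_tables: list[DEResult] | dict,
    fc_threshold: float = 4.0,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Flag induced/repressed genes over all contrasts of one model.

    ``de_tables`` holds the DEResult for every configured (later vs
    earlier) time pair of one model.  A gene is induced if ANY contrast
    has log2FC >= log2(fc_threshold) and fdr < fdr_threshold; repressed
    analogously with <= -log2(fc_threshold).  A gene may carry both
    flags (resolved by the cross-model intersection).

    Returns a DataFrame with boolean columns ``induced``/``repressed``,
    the extreme ``max_log2fc``/``min_log2fc`` over flagged contrasts,
    and the best (most significant qualifying) contrast labels.
    """
    if isinstance(de_tables, dict):
        de_tables = list(de_tables.values())
    if not de_tables:
        raise ValueError("no DE tables supplied")
    models = {t.model for t in de_tables}
    if len(models) != 1:
        raise ValueError(f"DE tables mix models: {sorted(models)}")
    lfc_min = np.log2(fc_threshold)
    genes = de_tables[0].table.index
    out = pd.DataFrame(
        {
            "induced": False,
            "repressed": False,
            "max_log2fc": np.nan,
            "min_log2fc": np.nan,
            "best_induced_contrast": "",
            "best_repressed_contrast": "",
        },
        index=genes,
    )
    best_up_fdr = pd.Series(np.inf, index=genes)
    best_dn_fdr = pd.Series(np.inf, index=genes)
    for res in de_tables:
        tab = res.table
        label = f"{res.time_b}_vs_{res.time_a}"
        sig = tab["fdr"] < fdr_threshold
        up = sig & (tab["log2FC"] >= lfc_min)
        dn = sig & (tab["log2FC"] <= -lfc_min)
        out.loc[up, "induced"] = True
        out.loc[dn, "repressed"] = True
        # fmax/fmin ignore NaN, so the first qualifying contrast seeds the extreme
        out["max_log2fc"] = np.fmax(out["max_log2fc"], tab["log2FC"].where(up))
        out["min_log2fc"] = np.fmin(out["min_log2fc"], tab["log2FC"].where(dn))
        upd = up & (tab["fdr"] < best_up_fdr)
        out.loc[upd, "best_induced_contrast"] = label
        best_up_fdr[upd] = tab["fdr"][upd]
        dnd = dn & (tab["fdr"] < best_dn_fdr)
        out.loc[dnd, "best_repressed_contrast"] = label
        best_dn_fdr[dnd] = tab["fdr"][dnd]
    return out


def intersect_common(
    flags_by_model: dict[str, pd.DataFrame],
    fc_threshold: float = 4.0,
    fdr_threshold: float = 0.05,
) -> CommonGeneSet:
    """Intersect per-model regulation flags into the common gene set.

    Included: genes induced in every model, or repressed in every model.
    Genes flagged both ways within one model, or with conflicting
    directions across models, are excluded (counted as conflicting).
    """
    import warnings

    models = sorted(flags_by_model)
    if not models:
        raise ValueError("no models supplied")
    genes = flags_by_model[models[0]].index
    for m in models[1:]:
        genes = genes.intersection(flags_by_model[m].index)
    genes = genes.sort_values()

    ind = pd.DataFrame({m: flags_by_model[m].loc[genes, "induced"] for m in models})
    rep = pd.DataFrame({m: flags_by_model[m].loc[genes, "repressed"] for m in models})
    # a gene flagged in both directions anywhere has no consistent direction
    conflicting = ind.any(axis=1) & rep.any(axis=1)
    all_ind = ind.all(axis=1) & ~conflicting
    all_rep = rep.all(axis=1) & ~conflicting

    rows = []
    for g in genes[all_ind]:
        row = {"direction": "induced"}
        for m in models:
            row[f"{m}_log2fc"] = flags_by_model[m].loc[g, "max_log2fc"]
            row[f"{m}_contrast"] = flags_by_model[m].loc[g, "best_induced_contrast"]
        rows.append((g, row))
    for g in genes[all_rep]:
        row = {"direction": "repressed"}
        for m in models:
            row[f"{m}_log2fc"] = flags_by_model[m].loc[g, "min_log2fc"]
            row[f"{m}_contrast"] = flags_by_model[m].loc[g, "best_repressed_contrast"]
        rows.append((g, row))
    if rows:
        table = pd.DataFrame({g: r for g, r in rows}).T
        table.index.name = "gene_id"
        table = table.sort_index()
    else:
        warnings.warn("common gene set is empty", stacklevel=2)
        table = pd.DataFrame(columns=["direction"])
        table.index.name = "gene_id"
    return CommonGeneSet(
        table=table,
        n_induced=int(all_ind.sum()),
        n_repressed=int(all_rep.sum()),
        n_conflicting=int(conflicting.sum()),
        fc_threshold=fc_threshold,
        fdr_threshold=fdr_threshold,
    )
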