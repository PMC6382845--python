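"""End-to-end orchestration: synthetic or file inputs through all stages.

Stage order: (synthetic data) -> normalization & per-model DE ->
cross-model common genes -> per-model time-course clustering ->
cluster pairing & shared genes -> promoter motif scanning ->
motif-conditional induction statistics & ORA.  Every stage writes
plain TSV under the run directory; ``report.json`` collects the
filter-step ledger (genes in/out at every threshold) plus the headline
statistics, and MANIFEST.json lists every file written.  With a fixed
config and seed the whole output tree is byte-identical across runs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from . import (
    cluster_matching,
    clustering,
    common_genes,
    diffexpr,
    induction_stats,
    motifscan,
    synthetic_data,
)
from .data import CountMatrix, read_annotation

logger = logging.getLogger("hscp")

__all__ = ["RunConfig", "run_all"]


@dataclass
class RunConfig:
    """All knobs for a pipeline run.

    Exactly one input mode: a ``synthetic`` block, or the file paths
    (counts/samples/lengths + annotation + genome + PWMs, optional GMT).
    Thresholds default to the analysis conventions the pipeline
    implements: >= 4-fold at FDR < 0.05 for common genes, log2CPM > 2
    expression floor for testing, RPKM >= 10 for ORA, 10% fit-filter,
    ORA FDR <= 0.01, PWM scan threshold 0.8 x max score.
    """

    outdir: str | Path = "hscp_run"
    synthetic: synthetic_data.SyntheticConfig | None = None
    counts_tsv: str | None = None
    samples_tsv: str | None = None
    lengths_tsv: str | None = None
    annotation: str | None = None
    genome: str | None = None
    pwms: str | None = None
    gmt: str | None = None
    fc_threshold: float = 4.0
    fdr_threshold: float = 0.05
    floor_log2cpm: float = 2.0
    rpkm_floor: float = 10.0
    drop_frac: float = 0.10
    min_cluster_size: int = 20
    ora_fdr: float = 0.01
    scan_threshold: float = 0.80
    prior_count: float = 0.5
    phi: float | None = None  # None -> estimated per model
    contrast_mode: str = "all-pairs"  # or "control-only"
    k_range: tuple[int, int] = (2, 12)
    cluster_models: tuple[str, str] = ("WD", "CCl4")
    ets_family: dict[str, list[str]] = field(
        default_factory=lambda: {"ETS1_like": list(synthetic_data.ETS_FAMILY)}
    )
    group_motifs: tuple[str, str] = ("ETS1_like", "RUNX1")

    def validate(self) -> None:
        file_mode = self.counts_tsv is not None
        if file_mode == (self.synthetic is not None):
            raise ValueError("configure exactly one input mode: files xor synthetic")
        for name, v, lo, hi in [
            ("fc_threshold", self.fc_threshold, 1.0, np.inf),
            ("fdr_threshold", self.fdr_threshold, 0.0, 1.0),
            ("drop_frac", self.drop_frac, 0.0, 1.0),
            ("ora_fdr", self.ora_fdr, 0.0, 1.0),
            ("scan_threshold", self.scan_threshold, 0.0, 1.0),
        ]:
            if not (lo <= v <= hi):
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if self.contrast_mode not in ("all-pairs", "control-only"):
            raise ValueError(f"unknown contrast_mode {self.contrast_mode!r}")
        if file_mode:
            needed = {
                "samples_tsv": self.samples_tsv,
                "lengths_tsv": self.lengths_tsv,
                "annotation": self.annotation,
                "genome": self.genome,
                "pwms": self.pwms,
            }
            missing = [k for k, v in needed.items() if v is None or not Path(v).exists()]
            if missing:
                raise ValueError(f"missing input files for run: {missing}")


def _contrasts(times: list, mode: str) -> list[tuple]:
    """(later, earlier) time pairs to test within one model."""
    times = sorted(times)
    if mode == "control-only":
        return [(t, times[0]) for t in times[1:]]
    return [(tb, ta) for ta, tb in combinations(times, 2)]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        return float(obj)
    return obj


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the run report dict."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}}
    manifest: list[str] = []

    def emit(df: pd.DataFrame, relpath: str, **kw) -> None:
        p = outdir / relpath
        p.parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(p, sep="\t", float_format="%.10g", **kw)
        manifest.append(relpath)

    # ---------------------------------------------------------- inputs
    if config.synthetic is not None:
        syn = config.synthetic
        report["seed"] = syn.seed
        pwms = synthetic_data.default_pwms()
        truth = synthetic_data.generate_truth(syn, pwms)
        inputs = outdir / "inputs"
        paths = synthetic_data.write_genome_and_annotation(truth, inputs, pwms)
        cm = synthetic_data.simulate_counts(truth, syn)
        for rel in cm.write(inputs).values():
            manifest.append(str(rel.relative_to(outdir)))
        gmt_path = synthetic_data.write_gene_sets(truth, inputs / "gene_sets.gmt")
        manifest += [str(p.relative_to(outdir)) for p in paths.values()]
        manifest.append(str(gmt_path.relative_to(outdir)))
        annot = read_annotation(paths["annotation"])
        genome_path = paths["genome"]
    else:
        cm = CountMatrix.read(config.counts_tsv, config.samples_tsv, config.lengths_tsv)
        annot = read_annotation(config.annotation)
        genome_path = config.genome
        pwms = motifscan.read_pwms(config.pwms)
        gmt_path = config.gmt
        truth = None
    report["n_genes"] = len(cm.genes)
    models = cm.models

    # ------------------------------------------------- normalization/DE
    norm = diffexpr.normalize(cm, prior_count=config.prior_count)
    avg_rpkm = norm.avg_rpkm_by_time()
    de_by_model: dict[str, dict[tuple, diffexpr.DEResult]] = {}
    de_report: dict = {}
    for model in models:
        sub = cm.subset_model(model)
        phi = config.phi if config.phi is not None else diffexpr.estimate_common_dispersion(sub)
        times = sub.timepoints(model)
        tables: dict[tuple, diffexpr.DEResult] = {}
        for tb, ta in _contrasts(times, config.contrast_mode):
            res = diffexpr.de_table(
                cm, model, (tb, ta), phi=phi,
                prior_count=config.prior_count, floor_log2cpm=config.floor_log2cpm,
            )
            tables[(tb, ta)] = res
            emit(res.table, f"de/{model}_{tb}_vs_{ta}.tsv", index_label="gene_id")
        de_by_model[model] = tables
        final = (times[-1], times[0])
        ftab = tables.get(final) or next(iter(tables.values()))
        sig = ftab.table["fdr"] <= 0.05
        n_ind = int((sig & (ftab.table["log2FC"] > 0)).sum())
        n_rep = int((sig & (ftab.table["log2FC"] < 0)).sum())
        # global expression-distribution shift, activated vs control
        cols_f = cm.group_columns(model, times[-1])
        cols_0 = cm.group_columns(model, times[0])
        shift_p, shift_dir = diffexpr.distribution_shift_test(
            norm.log2cpm[cols_0].mean(axis=1), norm.log2cpm[cols_f].mean(axis=1)
        )
        de_report[model] = {
            "phi": float(phi),
            "n_tested": int(ftab.table["fdr"].notna().sum()),
            "final_contrast": list(final),
            "n_induced": n_ind,
            "n_repressed": n_rep,
            "distribution_shift_p": shift_p,
            "distribution_shift_direction": shift_dir,
        }
        logger.info("DE %s: %d induced, %d repressed (final vs control)", model, n_ind, n_rep)
    report["stages"]["diffexpr"] = de_report

    # ------------------------------------------------- common gene set
    flags = {
        m: common_genes.regulated_in_model(
            list(t.values()), config.fc_threshold, config.fdr_threshold
        )
        for m, t in de_by_model.items()
    }
    common = common_genes.intersect_common(flags, config.fc_threshold, config.fdr_threshold)
    emit(common.table, "common_genes.tsv")
    report["stages"]["common_genes"] = {
        "n_common": len(common),
        "n_induced": common.n_induced,
        "n_repressed": common.n_repressed,
        "n_conflicting": common.n_conflicting,
    }
    logger.info("common genes: %d (%d induced / %d repressed)", len(common),
                common.n_induced, common.n_repressed)

    # -------------------------------------------------- clustering
    cluster_sets: dict[str, clustering.ClusterSet] = {}
    clus_report: dict = {}
    kmin, kmax = config.k_range
    for model in config.cluster_models:
        prof_raw = avg_rpkm.loc[common.genes, model]
        scaled = clustering.vst_scale(prof_raw)
        n_prof = len(scaled.profiles) - len(scaled.flagged_constant)
        k_hi = min(kmax, n_prof - 1)
        k, sils = clustering.choose_k(scaled, range(kmin, k_hi + 1))
        cs = clustering.pam_cluster(scaled, k)
        filtered = clustering.fit_filter(cs, config.drop_frac, config.min_cluster_size)
        _, per_cluster_fit, avg_fit = clustering.prototypes(filtered)
        cluster_sets[model] = filtered
        out = pd.DataFrame(
            {"cluster": filtered.labels, "fit": filtered.fit}
        ).sort_index()
        out_disc = pd.DataFrame(
            {"cluster": "no cluster", "fit": np.nan}, index=filtered.discarded
        )
        emit(pd.concat([out, out_disc]).sort_index(), f"clusters_{model}.tsv",
             index_label="gene_id")
        emit(filtered.prototypes, f"prototypes_{model}.tsv", index_label="cluster")
        clus_report[model] = {
            "k_selected": int(k),
            "silhouette": {int(kk): float(v) for kk, v in sils.items()},
            "k_after_filter": int(filtered.k),
            "n_profiled": int(n_prof),
            "n_constant_flagged": int(len(scaled.flagged_constant)),
            "n_discarded": int(len(filtered.discarded)),
            "removed_clusters": [int(c) for c in filtered.removed_clusters],
            "cluster_sizes": {int(c): int(s) for c, s in filtered.sizes().items()},
            "avg_pearson": float(avg_fit),
        }
        logger.info("clustering %s: k=%d, avg prototype Pearson %.3f", model, k, avg_fit)
    report["stages"]["clustering"] = clus_report

    # -------------------------------------------------- cluster pairing
    ma, mb = config.cluster_models
    csa, csb = cluster_sets[ma], cluster_sets[mb]
    pairing = cluster_matching.pair_clusters(csa.prototypes, csb.prototypes)
    shared = cluster_matching.shared_genes(pairing, csa.member_sets(), csb.member_sets())
    universe = sorted(set(csa.labels.index) & set(csb.labels.index))
    shared["hypergeom_p"] = [
        cluster_matching.overlap_significance(
            int(r["n_a"]), int(r["n_b"]), int(r["shared_n"]), len(universe)
        )
        for _, r in shared.iterrows()
    ]
    emit(shared.drop(columns="shared_genes"), f"pairs_{ma}_{mb}.tsv", index=False)
    for _, r in shared.iterrows():
        genes_df = pd.DataFrame({"gene_id": r["shared_genes"]})
        emit(genes_df, f"shared/pair_{r['cluster_a']}_{r['cluster_b']}.tsv", index=False)
    shared_all = sorted({g for lst in shared["shared_genes"] for g in lst})
    report["stages"]["cluster_matching"] = {
        "universe_n": len(universe),
        "n_pairs": int(len(shared)),
        "n_shared_total": len(shared_all),
        "pairs": [
            {
                "cluster_a": int(r["cluster_a"]), "cluster_b": int(r["cluster_b"]),
                "r": float(r["r"]), "shared_n": int(r["shared_n"]),
                "percent_of_a": float(r["percent_of_a"]),
                "hypergeom_p": float(r["hypergeom_p"]),
            }
            for _, r in shared.iterrows()
        ],
    }
    logger.info("cluster pairing: %d shared genes across %d pairs",
                len(shared_all), len(shared))

    # -------------------------------------------------- motif scanning
    promoters = motifscan.extract_promoters(genome_path, annot)
    hits = motifscan.scan_promoters(pwms, promoters, config.scan_threshold)
    table = motifscan.gene_motif_table(
        hits, promoters.genes, [p.id for p in pwms], config.ets_family
    )
    emit(hits, "motifs/hits.tsv", index=False)
    emit(table.presence, "motifs/presence.tsv", index_label="gene_id")
    background = promoters.genes
    # enrichment within the shared genes of the most induced pair
    best_pair = None
    if len(shared):
        amp = (csa.prototypes.iloc[:, -1] - csa.prototypes.iloc[:, 0])
        best_cluster = int(amp.idxmax())
        rows = shared[shared["cluster_a"] == best_cluster]
        if len(rows):
            best_pair = rows.iloc[0]
    enr_report = {}
    if best_pair is not None and best_pair["shared_n"] > 0:
        enr = motifscan.motif_enrichment(best_pair["shared_genes"], background, table)
        emit(enr, "motifs/enrichment_induced_pair.tsv", index=False)
        enr_report = {
            "target_pair": [int(best_pair["cluster_a"]), int(best_pair["cluster_b"])],
            "target_n": int(best_pair["shared_n"]),
            "significant_motifs": enr.loc[enr["fdr"] < 0.05, "pwm"].tolist(),
        }
    widths = {p.id: p.width for p in pwms}
    spacing_mean, spacing_dist = motifscan.motif_spacing(
        table, "ETS1", "RUNX1", widths
    ) if len(hits) else (float("nan"), pd.Series(dtype=float))
    report["stages"]["motifscan"] = {
        "n_promoters": len(promoters),
        "n_excluded": len(promoters.excluded),
        "n_hits": int(len(hits)),
        "presence_totals": {c: int(v) for c, v in table.presence.sum().items()},
        "enrichment": enr_report,
        "mean_ets1_runx1_spacing_bp": float(spacing_mean),
        "n_spacing_promoters": int(len(spacing_dist)),
    }

    # ---------------------------------------- motif-conditional stats
    stats_report: dict = {}
    common_in_table = [g for g in common.genes if g in table.presence.index]
    mo_a, mo_b = config.group_motifs
    assign = induction_stats.assign_motif_groups(common_in_table, table, mo_a, mo_b)
    emit(assign.groups.rename("group").to_frame(), "stats/groups.tsv",
         index_label="gene_id")
    group_stats = {}
    for model in config.cluster_models:
        times = cm.timepoints(model)
        de_final = de_by_model[model][(times[-1], times[0])]
        fc = de_final.table["log2FC"]
        comp = induction_stats.compare_groups(fc, assign)
        emit(comp.summary, f"stats/group_summary_{model}.tsv")
        emit(comp.pairwise, f"stats/group_pairwise_{model}.tsv", index=False)
        group_stats[model] = {
            "sizes": {g: int(v) for g, v in assign.sizes().items()},
            "median_log2fc": {
                g: float(v) for g, v in comp.summary["median_log2fc"].items()
            },
            "median_rank": {g: float(v) for g, v in comp.summary["median_rank"].items()},
            "letters": dict(comp.summary["letters"]),
            "pairwise_fdr": {
                f"{r['group_1']}|{r['group_2']}": float(r["fdr"])
                for _, r in comp.pairwise.iterrows()
            },
        }
    stats_report["groups"] = group_stats

    # motif distribution over clusters of the first cluster model
    csa_labels = cluster_sets[ma].labels
    cluster_assign = pd.Series("no cluster", index=pd.Index(common_in_table, name="gene_id"))
    in_clusters = [g for g in common_in_table if g in csa_labels.index]
    cluster_assign.loc[in_clusters] = csa_labels.loc[in_clusters].astype(str)
    motif_sets = {
        mo_a: table.genes_with(mo_a) & set(common_in_table),
        mo_b: table.genes_with(mo_b) & set(common_in_table),
        "dual": table.genes_with(mo_a) & table.genes_with(mo_b) & set(common_in_table),
    }
    cme = induction_stats.cluster_motif_enrichment(cluster_assign, motif_sets)
    emit(cme, "stats/cluster_motif_enrichment.tsv", index=False)
    dual = motif_sets["dual"]
    dual_top = 0
    top_cluster = None
    if len(cluster_sets[ma].prototypes):
        amp = cluster_sets[ma].prototypes.iloc[:, -1] - cluster_sets[ma].prototypes.iloc[:, 0]
        top_cluster = int(amp.idxmax())
        dual_top = len({g for g in dual if g in csa_labels.index
                        and csa_labels[g] == top_cluster})
    stats_report["dual_motif"] = {
        "n_dual": len(dual),
        "top_induced_cluster": top_cluster,
        "n_dual_in_top_cluster": dual_top,
    }

    # ------------------------------------------------------------- ORA
    if gmt_path is not None:
        gene_sets = induction_stats.read_gmt(gmt_path)
        rpkm_max = avg_rpkm.max(axis=1)
        times_a = cm.timepoints(ma)
        fc_a = de_by_model[ma][(times_a[-1], times_a[0])].table["log2FC"]
        ora_counts = {}
        for cluster in sorted(cluster_sets[ma].prototypes.index):
            fg = cluster_sets[ma].members(cluster)
            res = induction_stats.ora(
                fg, list(cm.genes), gene_sets,
                rpkm_max=rpkm_max, expr_filter_rpkm=config.rpkm_floor,
                fdr_max=config.ora_fdr, log2fc=fc_a,
            )
            emit(res, f"stats/ora_cluster{cluster}.tsv", index=False)
            ora_counts[int(cluster)] = int(res["enriched"].sum())
        stats_report["ora_enriched_sets_per_cluster"] = ora_counts
        stats_report["ora_enriched_total"] = int(sum(ora_counts.values()))
    report["stages"]["induction_stats"] = stats_report

    # ------------------------------------------------------ report out
    manifest.sort()
    report["manifest"] = manifest
    with open(outdir / "report.json", "w") as fh:
        json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
    with open(outdir / "MANIFEST.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return report
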