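"""Scan promoters for TF motifs and relate motif presence to induction.

Writes the synthetic genome, extracts proximal promoters (-300..+50
around each TSS), scans ETS1 / ETS1-like / RUNX1 / AP-1 matrices on
both strands, and asks whether genes whose promoters carry both an
ETS1-family and a RUNX1 site are more strongly induced than genes
without either motif.
"""

import tempfile

from hscp.diffexpr import de_table
from hscp.induction_stats import assign_motif_groups, compare_groups
from hscp.motifscan import extract_promoters, gene_motif_table, motif_spacing, scan_promoters
from hscp.synthetic_data import (
    ETS_FAMILY,
    SyntheticConfig,
    default_pwms,
    generate_truth,
    simulate_counts,
    write_genome_and_annotation,
)

cfg = SyntheticConfig(n_genes=800, seed=1)
truth = generate_truth(cfg)
cm = simulate_counts(truth, cfg)

with tempfile.TemporaryDirectory() as tmp:
    paths = write_genome_and_annotation(truth, tmp)
    promoters = extract_promoters(paths["genome"], paths["annotation"])
pwms = default_pwms()
hits = scan_promoters(pwms, promoters, threshold_frac=0.80)
table = gene_motif_table(
    hits, promoters.genes, [p.id for p in pwms], families={"ETS1_like": ETS_FAMILY}
)
totals = table.presence.sum()
print(f"{len(hits)} motif hits over {len(promoters)} promoters; genes with "
      f"ETS1-like: {totals['ETS1_like']}, RUNX1: {totals['RUNX1']}, AP-1: {totals['AP1']}")

# group the regulated genes by motif content and compare induction
res = de_table(cm, "WD", (24, 0))
expressed = res.table.dropna(subset=["fdr"]).index
assign = assign_motif_groups(list(expressed), table, "ETS1_like", "RUNX1")
comp = compare_groups(res.table.loc[expressed, "log2FC"], assign)
print(comp.summary.round(2).to_string())
# Groups not sharing a letter differ significantly (pairwise Wilcoxon
# rank-sum, BH-FDR < 0.05).  "both" carries the planted
# ETS1+RUNX1/induction coupling, so its median log2FC and rank should
# stand apart from "none".

mean_sp, dist = motif_spacing(table, "ETS1", "RUNX1", {p.id: p.width for p in pwms})
print(f"mean ETS1-RUNX1 midpoint spacing: {mean_sp:.1f} bp "
      f"over {len(dist)} dual-motif promoters")
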