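"""Simulate a small HSC-activation study and test differential expression.

Generates NB counts for three activation models with planted temporal
programs, estimates the common dispersion, and runs the conditional
exact test for the final-time vs control contrast in the Western-diet
model.
"""

from hscp.diffexpr import de_table, distribution_shift_test, normalize
from hscp.synthetic_data import SyntheticConfig, generate_truth, simulate_counts

cfg = SyntheticConfig(n_genes=800, seed=1)
truth = generate_truth(cfg)
cm = simulate_counts(truth, cfg)
print(f"simulated {len(cm.genes)} genes x {cm.counts.shape[1]} samples "
      f"({', '.join(cm.models)})")

res = de_table(cm, "WD", (24, 0))  # 24 weeks of Western diet vs chow
sig = res.table[res.table["fdr"] <= 0.05]
n_up = (sig["log2FC"] > 0).sum()
n_dn = (sig["log2FC"] < 0).sum()
print(f"WD 24w vs 0w: phi = {res.phi:.3f}; "
      f"{n_up} genes induced, {n_dn} repressed (FDR <= 0.05)")

# do planted induced-program genes rise to the top?
induced = truth.genes.index[truth.genes["cluster"] == "induced"]
print(f"median log2FC of planted induced program: "
      f"{res.table.loc[induced, 'log2FC'].median():.2f} "
      f"(null genes: "
      f"{res.table.loc[truth.genes['cluster'] == 'null', 'log2FC'].median():.2f})")

# global shift of the expression distribution upon activation
norm = normalize(cm.subset_model("WD"))
c0 = cm.group_columns("WD", 0)
c24 = cm.group_columns("WD", 24)
p, direction = distribution_shift_test(
    norm.log2cpm[c0].mean(axis=1), norm.log2cpm[c24].mean(axis=1)
)
print(f"expression distribution shift at 24w: direction={direction}, p={p:.2e}")
# The shift p-value summarizes that activated cells transcribe more overall,
# not just that single genes move.
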