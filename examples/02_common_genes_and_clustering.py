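"""Select cross-model common genes and cluster their time courses.

A gene enters the common set if it changes >= 4-fold (FDR < 0.05)
between some pair of time points in every activation model, in the
same direction.  The common genes' scaled average-RPKM profiles are
then partitioned by k-medoids under correlation distance, with k
chosen by silhouette, and cleaned by the 10% fit filter.
"""

from itertools import combinations

from hscp.clustering import choose_k, fit_filter, pam_cluster, prototypes, vst_scale
from hscp.common_genes import intersect_common, regulated_in_model
from hscp.diffexpr import de_table, normalize
from hscp.synthetic_data import SyntheticConfig, generate_truth, simulate_counts

cfg = SyntheticConfig(n_genes=800, seed=1)
truth = generate_truth(cfg)
cm = simulate_counts(truth, cfg)

flags = {}
for model in cm.models:
    times = cm.timepoints(model)
    tables = [
        de_table(cm, model, (tb, ta))
        for ta, tb in combinations(sorted(times), 2)
    ]
    flags[model] = regulated_in_model(tables, fc_threshold=4.0, fdr_threshold=0.05)

common = intersect_common(flags)
print(f"common genes: {len(common)} "
      f"({common.n_induced} induced, {common.n_repressed} repressed, "
      f"{common.n_conflicting} direction conflicts excluded)")

planted = set(truth.genes.index[truth.genes["cluster"] != "null"])
overlap = len(set(common.genes) & planted)
print(f"{overlap}/{len(common)} common genes carry a planted program "
      f"(the rest are false positives)")

# cluster the WD time courses of the common genes
avg_rpkm = normalize(cm).avg_rpkm_by_time()
scaled = vst_scale(avg_rpkm.loc[common.genes, "WD"])
k, sil = choose_k(scaled, range(2, 9))
cs = fit_filter(pam_cluster(scaled, k), drop_frac=0.10, min_cluster_size=20)
_, per_cluster, avg_fit = prototypes(cs)
sizes = {int(c): int(s) for c, s in cs.sizes().items()}
print(f"silhouette selected k={k}; after the fit filter {cs.k} clusters remain, "
      f"sizes {sizes}")
print(f"average gene-to-prototype Pearson r = {avg_fit:.3f} "
      f"(how tightly members follow their cluster's mean profile)")
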