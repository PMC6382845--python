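"""Run the whole pipeline end to end on synthetic data.

One call wires every stage together -- simulation, DE, common genes,
clustering per model, cross-model cluster pairing, motif scanning,
induction statistics, and ORA -- and writes a TSV/JSON bundle plus a
machine-readable report under the run directory.
"""

import json
import tempfile
from pathlib import Path

from hscp.pipeline import RunConfig, run_all
from hscp.synthetic_data import SyntheticConfig

with tempfile.TemporaryDirectory() as tmp:
    cfg = RunConfig(
        outdir=Path(tmp) / "run",
        synthetic=SyntheticConfig(n_genes=800, seed=1),
        k_range=(2, 9),
    )
    report = run_all(cfg)

    common = report["stages"]["common_genes"]
    clus = report["stages"]["clustering"]["WD"]
    match = report["stages"]["cluster_matching"]
    groups = report["stages"]["induction_stats"]["groups"]["WD"]
    dual = report["stages"]["induction_stats"]["dual_motif"]

    print(f"common genes: {common['n_common']}")
    print(f"WD clusters: k={clus['k_after_filter']} "
          f"(avg prototype Pearson {clus['avg_pearson']:.3f})")
    print(f"shared genes across paired WD/CCl4 clusters: {match['n_shared_total']}")
    print(f"median log2FC by motif group: "
          f"{json.dumps({k: round(v, 2) for k, v in groups['median_log2fc'].items()})}")
    print(f"dual-motif genes: {dual['n_dual']}, of which "
          f"{dual['n_dual_in_top_cluster']} fall in the most induced cluster")
    print(f"{len(report['manifest'])} files written under {cfg.outdir}")
# The dual-motif group's higher median log2FC and concentration in the
# induced cluster reproduce, on planted data, the coupling between
# promoter motif content and activation strength the pipeline is
# designed to detect.
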