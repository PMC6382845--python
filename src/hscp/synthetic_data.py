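"""Synthetic multi-model HSC-activation data with planted ground truth.

Emulates the study design the pipeline targets: three activation
models -- Western diet + fructose feeding (WD: 0/12/16/24 weeks),
carbon tetrachloride (CCl4: 0/1/4/8 weeks) and in vitro
transdifferentiation (IVT: 0/1/4/8/12 days) -- with 3-4 replicates per
time point and negative-binomial counts (gene-wise means, common
dispersion).  A configurable fraction of genes carries planted
temporal programs, including a strongly induced myofibroblast-like
program and a repressed quiescence-like program, and promoter
sequences in which ETS1/RUNX1/AP-1 motif presence is statistically
coupled to induction magnitude.  Everything needed downstream is
emitted as plain text: counts + sample sheet, genome FASTA,
annotation TSV, JASPAR PWMs, a GMT of planted gene programs, and the
truth tables that make every stage verifiable.

All randomness flows from the single config seed through fixed
per-stage substreams, so outputs are byte-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import ANNOTATION_COLUMNS, CountMatrix
from .motifscan import PWM, reverse_complement, write_pwms

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "default_pwms",
    "ETS_FAMILY",
    "generate_truth",
    "simulate_counts",
    "write_genome_and_annotation",
    "write_gene_sets",
]

_BASE_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)

#: planted temporal programs as z-shaped control points on unit time
DEFAULT_PROFILES: dict[str, list[float]] = {
    "induced": [-1.2, -0.5, 0.5, 1.2],
    "repressed": [1.2, 0.5, -0.5, -1.2],
    "early_up": [-1.5, 0.9, 0.8, 0.6],
    "transient": [-1.0, 1.3, 0.3, -0.9],
    "late_up": [-0.6, -0.7, -0.2, 1.5],
    "early_down": [1.4, -0.2, -0.7, -0.8],
}

DEFAULT_PROPORTIONS: dict[str, float] = {
    "null": 0.70,
    "induced": 0.06,
    "repressed": 0.06,
    "early_up": 0.045,
    "transient": 0.045,
    "late_up": 0.045,
    "early_down": 0.045,
}


def _informative_counts(consensus: str, strong: int = 90) -> np.ndarray:
    """Count matrix with one dominant base per column (plus noise counts)."""
    rest = (100 - strong) // 3
    counts = np.full((4, len(consensus)), rest, dtype=float)
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    for j, b in enumerate(consensus):
        counts[idx[b], j] = strong
        counts[(idx[b] + 1) % 4, j] = 100 - strong - 2 * rest
    return counts


#: members of the ETS1-like family (related GGAA-core matrices)
ETS_FAMILY = ["ETS1", "ETSL1", "ETSL2"]


def default_pwms() -> list[PWM]:
    """The default synthetic TF motif models.

    ETS1 plus two ETS1-like family variants (all with the GGAA core),
    the RUNX1 motif, and the AP-1 (TPA-response element) motif.
    Consensi echo the canonical murine motifs; matrices are informative
    enough that at the default 80%-of-max threshold only (near-)
    consensus windows score as hits.
    """
    return [
        PWM(id="ETS1", counts=_informative_counts("ACAGGAAGTG")),
        PWM(id="ETSL1", counts=_informative_counts("CCGGAAGTGA")),
        PWM(id="ETSL2", counts=_informative_counts("AGAGGAAGGC")),
        PWM(id="RUNX1", counts=_informative_counts("TGTGGTTT")),
        PWM(id="AP1", counts=_informative_counts("TGACTCA")),
    ]


@dataclass
class SyntheticConfig:
    """Study-design parameters for the synthetic data generator.

    Defaults mirror the emulated study: three models with their time
    courses, 3-4 replicates, NB counts with common dispersion 0.1,
    log-normal baseline expression (log2 mean 5, sd 2), six planted
    temporal programs at modest planted fractions, and motif placement
    coupled to the induced program.
    """

    n_genes: int = 5000
    models: dict[str, list[float]] = field(
        default_factory=lambda: {
            "WD": [0, 12, 16, 24],
            "CCl4": [0, 1, 4, 8],
            "IVT": [0, 1, 4, 8, 12],
        }
    )
    replicates: dict[str, int] = field(
        default_factory=lambda: {"WD": 4, "CCl4": 4, "IVT": 3}
    )
    dispersion: float = 0.1
    baseline_mean_log2: float = 5.0
    baseline_sd_log2: float = 2.0
    cluster_profiles: dict[str, list[float]] = field(
        default_factory=lambda: dict(DEFAULT_PROFILES)
    )
    cluster_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS)
    )
    amplitude: float = 1.5  # log2FC per unit z-range of the planted shape
    motif_coupling: float = 0.8  # P(dual ETS1+RUNX1 | induced program)
    background_motif_rate: float = 0.10  # per-motif placement elsewhere
    ap1_rate: float = 0.10
    ap1_rate_induced: float = 0.30
    dual_shift_log2fc: float = 2.0  # extra induction for planted dual-motif genes
    motif_spacing: float | None = None  # fixed ETS1-RUNX1 midpoint spacing, bp
    promoter_len: int = 350
    flank: int = 2000
    genes_per_contig: int = 100
    libsize_range: tuple[float, float] = (0.8e6, 1.2e6)
    seed: int = 0

    def validate(self, pwms: list[PWM] | None = None) -> None:
        props = self.cluster_proportions
        if abs(sum(props.values()) - 1.0) > 1e-12:
            raise ValueError("cluster_proportions must sum to 1")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        for m, r in self.replicates.items():
            if r < 2:
                raise ValueError(f"model {m}: need >= 2 replicates")
        widest = max((p.width for p in (pwms or default_pwms())), default=0)
        if self.promoter_len < widest:
            raise ValueError(
                f"promoter_len {self.promoter_len} shorter than widest PWM ({widest})"
            )
        unknown = set(props) - set(self.cluster_profiles) - {"null"}
        if unknown:
            raise ValueError(f"proportions reference unknown profiles: {sorted(unknown)}")

    def to_yaml(self, path: str | Path) -> None:
        d = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "libsize_range" in d:
            d["libsize_range"] = tuple(d["libsize_range"])
        return cls(**d)


@dataclass
class SyntheticTruth:
    """Planted ground truth: the oracle for recovery tests.

    ``genes``: per-gene cluster, baseline mean, strand/chrom/TSS/length.
    ``trajectories``: per model, gene x timepoint planted log2FC vs t0.
    ``motifs``: long table of planted instances (promoter-relative
    0-based position, strand within the promoter).
    ``promoters``: gene -> planted promoter sequence (forward promoter
    orientation, 5'->3').
    """

    genes: pd.DataFrame
    trajectories: dict[str, pd.DataFrame]
    motifs: pd.DataFrame
    promoters: dict[str, str]
    config: SyntheticConfig

    def planted_motif_genes(self, motif: str) -> set[str]:
        return set(self.motifs.loc[self.motifs["motif"] == motif, "gene_id"])

    def dual_motif_genes(self) -> set[str]:
        return self.planted_motif_genes("ETS1") & self.planted_motif_genes("RUNX1")


def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stream])


def _shape_at(control: list[float], frac: np.ndarray) -> np.ndarray:
    grid = np.linspace(0.0, 1.0, len(control))
    return np.interp(frac, grid, control)


def _random_bases(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASE_ARR[rng.integers(0, 4, size=n)]


def _place_motifs(
    rng: np.random.Generator,
    wanted: list[tuple[str, int]],
    promoter_len: int,
    spacing: float | None,
) -> list[tuple[str, int, str]]:
    """Choose non-overlapping (motif, start, strand) placements."""
    placed: list[tuple[str, int, str]] = []
    widths_placed: dict[str, tuple[int, int]] = {}  # motif -> (start, width)
    occupied: list[tuple[int, int]] = []

    def fits(s: int, w: int) -> bool:
        return all(e0 <= s or s + w <= s0 for s0, e0 in occupied)

    paired = spacing is not None and {m for m, _ in wanted} >= {"ETS1", "RUNX1"}
    for motif, w in wanted:
        if paired and motif == "RUNX1" and "ETS1" in widths_placed:
            # fixed midpoint spacing relative to the already-placed ETS1
            e_start, e_w = widths_placed["ETS1"]
            mid_e = e_start + e_w / 2.0
            for sign in rng.permutation([1, -1]):
                start = int(round(mid_e + sign * spacing - w / 2.0))
                if 0 <= start <= promoter_len - w and fits(start, w):
                    break
            else:
                continue
        else:
            cand = rng.permutation(promoter_len - w + 1)
            for start in cand:
                if fits(int(start), w):
                    start = int(start)
                    break
            else:
                continue
        strand = "+" if rng.random() < 0.5 else "-"
        placed.append((motif, start, strand))
        widths_placed[motif] = (start, w)
        occupied.append((start, start + w))
    return placed


def generate_truth(
    config: SyntheticConfig, pwms: list[PWM] | None = None
) -> SyntheticTruth:
    """Draw the planted truth tables for one synthetic study.

    Deterministic for a fixed config seed.  Genes in the induced
    program receive dual ETS1+RUNX1 placements with probability
    ``motif_coupling``; all other placements follow the background
    rates, so coupling 0 makes motif presence independent of the
    planted program.
    """
    config.validate(pwms)
    pwms = pwms or default_pwms()
    widths = {p.id: p.width for p in pwms}
    rng = _rng(config, 0)
    n = config.n_genes
    gene_ids = [f"g{i:05d}" for i in range(n)]
    names = list(config.cluster_proportions)
    probs = np.array([config.cluster_proportions[c] for c in names])
    clusters = rng.choice(names, size=n, p=probs)
    baseline = 2.0 ** rng.normal(config.baseline_mean_log2, config.baseline_sd_log2, n)
    lengths = rng.integers(500, 5001, size=n)
    strands = np.where(rng.random(n) < 0.5, "+", "-")

    # ---- motif placements (before trajectories: the dual-motif shift
    # depends on which genes carry both motifs)
    consensus = {p.id: p.consensus for p in pwms}
    motif_rows = []
    for gi, gene in enumerate(gene_ids):
        wanted: list[tuple[str, int]] = []
        induced = clusters[gi] == "induced"
        if induced and rng.random() < config.motif_coupling:
            wanted += [("ETS1", widths["ETS1"]), ("RUNX1", widths["RUNX1"])]
        else:
            if rng.random() < config.background_motif_rate:
                wanted.append(("ETS1", widths["ETS1"]))
            if rng.random() < config.background_motif_rate:
                wanted.append(("RUNX1", widths["RUNX1"]))
        ap1_rate = config.ap1_rate_induced if induced else config.ap1_rate
        if rng.random() < ap1_rate:
            wanted.append(("AP1", widths["AP1"]))
        for motif, start, strand in _place_motifs(
            rng, wanted, config.promoter_len, config.motif_spacing
        ):
            motif_rows.append(
                {"gene_id": gene, "motif": motif, "pos": start, "strand": strand}
            )
    motifs = pd.DataFrame(motif_rows, columns=["gene_id", "motif", "pos", "strand"])

    dual = set(motifs[motifs["motif"] == "ETS1"]["gene_id"]) & set(
        motifs[motifs["motif"] == "RUNX1"]["gene_id"]
    )

    # ---- planted log2FC trajectories per model
    trajectories: dict[str, pd.DataFrame] = {}
    for model, times in config.models.items():
        times = list(times)
        t = np.asarray(times, dtype=float)
        frac = (t - t[0]) / (t[-1] - t[0])
        traj = np.zeros((n, len(times)))
        for cname, control in config.cluster_profiles.items():
            sel = clusters == cname
            if not sel.any():
                continue
            z = _shape_at(control, frac)
            traj[sel] = config.amplitude * (z - z[0])
        # extra induction for dual-motif genes in a planted program,
        # ramped with normalized time (the induction-coupling analogue)
        shift_sel = np.array(
            [g in dual and c != "null" for g, c in zip(gene_ids, clusters)]
        )
        traj[shift_sel] += config.dual_shift_log2fc * frac
        trajectories[model] = pd.DataFrame(
            traj, index=pd.Index(gene_ids, name="gene_id"), columns=times
        )

    # ---- genomic layout: tiled slots, one contig per genes_per_contig
    slot = 2 * config.flank + config.promoter_len
    per_contig = config.genes_per_contig
    chroms, tsss = [], []
    for gi in range(n):
        c = gi // per_contig
        j = gi % per_contig
        slot_start = j * slot
        win_start = slot_start + config.flank
        if strands[gi] == "+":
            tss = win_start + 300  # window (-300,+50) -> [win_start, win_start+350)
        else:
            tss = win_start + config.promoter_len - 300 - 1
        chroms.append(f"chr{c + 1}")
        tsss.append(tss)

    # ---- promoter sequences with planted instances written in
    promoters: dict[str, str] = {}
    by_gene = motifs.groupby("gene_id") if len(motifs) else None
    for gi, gene in enumerate(gene_ids):
        arr = _random_bases(rng, config.promoter_len)
        if by_gene is not None and gene in by_gene.groups:
            for _, row in by_gene.get_group(gene).iterrows():
                inst = consensus[row["motif"]]
                if row["strand"] == "-":
                    inst = reverse_complement(inst)
                s = int(row["pos"])
                arr[s : s + len(inst)] = np.frombuffer(inst.encode(), dtype=np.uint8)
        promoters[gene] = arr.tobytes().decode()

    genes = pd.DataFrame(
        {
            "cluster": clusters,
            "baseline_mean": baseline,
            "length_bp": lengths,
            "chrom": chroms,
            "strand": strands,
            "tss_0based": tsss,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return SyntheticTruth(
        genes=genes,
        trajectories=trajectories,
        motifs=motifs,
        promoters=promoters,
        config=config,
    )


def simulate_counts(truth: SyntheticTruth, config: SyntheticConfig | None = None) -> CountMatrix:
    """NB counts for all models in one CountMatrix.

    Per sample, gene mean = baseline * 2^(planted log2FC at t) *
    (target libsize / 1e6); counts are gamma-Poisson draws with the
    common dispersion (Poisson in the phi = 0 limit).  The drawn
    target library sizes are attached to the CountMatrix so CPM tracks
    the planted means: with strongly asymmetric planted programs,
    realized column sums drift with the induced genes (composition
    bias), which would distort the null genes' fold changes.
    """
    config = config or truth.config
    baseline = truth.genes["baseline_mean"].to_numpy()
    blocks, sheets, libsizes = [], [], {}
    for mi, (model, times) in enumerate(config.models.items()):
        rng = _rng(config, 10 + mi)
        reps = config.replicates[model]
        traj = truth.trajectories[model]
        for time in times:
            fc = 2.0 ** traj[time].to_numpy()
            for rep in range(1, reps + 1):
                lib = rng.uniform(*config.libsize_range)
                mean = baseline * fc * (lib / 1e6)
                if config.dispersion == 0:
                    counts = rng.poisson(mean)
                else:
                    lam = rng.gamma(1.0 / config.dispersion, config.dispersion * mean)
                    counts = rng.poisson(lam)
                sid = f"{model}_t{time}_r{rep}"
                blocks.append(pd.Series(counts, index=truth.genes.index, name=sid))
                sheets.append(
                    {"sample_id": sid, "model": model, "time": time, "replicate": rep}
                )
                libsizes[sid] = lib
    counts = pd.concat(blocks, axis=1)
    samples = pd.DataFrame(sheets).set_index("sample_id")
    return CountMatrix(
        counts=counts,
        samples=samples,
        lengths=truth.genes["length_bp"].astype(float),
        libsize=pd.Series(libsizes),
    )


def _write_fasta(records: dict[str, np.ndarray], path: Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, arr in records.items():
            fh.write(f">{name}\n")
            seq = arr.tobytes().decode()
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_genome_and_annotation(
    truth: SyntheticTruth,
    outdir: str | Path,
    pwms: list[PWM] | None = None,
) -> dict[str, Path]:
    """Write genome FASTA, annotation TSV, JASPAR PWMs, and truth tables.

    The genome embeds each gene's planted promoter at its genomic
    window (reverse-complemented for minus-strand genes), so promoter
    re-extraction recovers every planted motif instance exactly.
    """
    config = truth.config
    pwms = pwms or default_pwms()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = _rng(config, 20)

    slot = 2 * config.flank + config.promoter_len
    genes = truth.genes
    contigs: dict[str, np.ndarray] = {}
    for chrom, sub in genes.groupby("chrom", sort=False):
        contigs[chrom] = _random_bases(rng, len(sub) * slot)
    order = sorted(contigs, key=lambda c: int(c[3:]))
    contigs = {c: contigs[c] for c in order}
    for gene, rec in genes.iterrows():
        if rec["strand"] == "+":
            start = rec["tss_0based"] - 300
            ins = truth.promoters[gene]
        else:
            start = rec["tss_0based"] - 49
            ins = reverse_complement(truth.promoters[gene])
        arr = contigs[rec["chrom"]]
        arr[start : start + len(ins)] = np.frombuffer(ins.encode(), dtype=np.uint8)

    paths = {
        "genome": outdir / "genome.fa",
        "annotation": outdir / "annotation.tsv",
        "pwms": outdir / "pwms.jaspar",
        "truth_genes": outdir / "truth_genes.tsv",
        "truth_motifs": outdir / "truth_motifs.tsv",
        "config": outdir / "config.yaml",
    }
    _write_fasta(contigs, paths["genome"])
    annot = genes.reset_index()[
        ["gene_id", "chrom", "strand", "tss_0based", "length_bp", "cluster"]
    ].rename(columns={"cluster": "planted_cluster"})
    annot[list(ANNOTATION_COLUMNS)].to_csv(paths["annotation"], sep="\t", index=False)
    write_pwms(pwms, paths["pwms"])
    truth.genes.to_csv(paths["truth_genes"], sep="\t")
    truth.motifs.to_csv(paths["truth_motifs"], sep="\t", index=False)
    for model, traj in truth.trajectories.items():
        p = outdir / f"truth_log2fc_{model}.tsv"
        traj.to_csv(p, sep="\t")
        paths[f"truth_log2fc_{model}"] = p
    config.to_yaml(paths["config"])
    return paths


def write_gene_sets(
    truth: SyntheticTruth, path: str | Path, n_decoys: int = 10, set_size: int = 50
) -> Path:
    """GMT of planted programs plus random decoy sets (for the ORA stage)."""
    rng = _rng(truth.config, 30)
    path = Path(path)
    gene_ids = list(truth.genes.index)
    with open(path, "w") as fh:
        for cname in truth.config.cluster_profiles:
            members = truth.genes.index[truth.genes["cluster"] == cname]
            if len(members) == 0:
                continue
            fh.write(
                "program_%s\tplanted %s temporal program\t%s\n"
                % (cname, cname, "\t".join(members))
            )
        for i in range(n_decoys):
            members = rng.choice(gene_ids, size=set_size, replace=False)
            fh.write(f"decoy_{i:02d}\trandom gene set\t" + "\t".join(sorted(members)) + "\n")
    return path
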