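"""Core containers and plain-text I/O for count data and annotation.

The pipeline's central container is :class:`CountMatrix`: an integer
gene x sample count table with a sample sheet (activation model, time
point, replicate), per-gene exonic lengths for RPKM, and per-sample
library sizes.  Everything is stored as pandas objects and written as
plain TSV so that runs are diffable and byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

SAMPLE_COLUMNS = ("model", "time", "replicate")

#: annotation table column order (strand is "+" or "-", TSS is 0-based)
ANNOTATION_COLUMNS = (
    "gene_id",
    "chrom",
    "strand",
    "tss_0based",
    "length_bp",
    "planted_cluster",
)


@dataclass
class CountMatrix:
    """Gene x sample integer counts with sample metadata.

    Parameters
    ----------
    counts
        DataFrame indexed by gene id, one column per sample id.
    samples
        DataFrame indexed by sample id with columns ``model``, ``time``
        (numeric time point within the model's own unit) and
        ``replicate``.  Column order must match ``counts.columns``.
    lengths
        Per-gene exonic length in bp (for RPKM); indexed like
        ``counts.index``.
    libsize
        Optional per-sample library sizes.  Defaults to column sums.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    lengths: pd.Series
    libsize: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.samples.index):
            raise ValueError("sample sheet does not match count matrix columns")
        if not self.lengths.index.equals(self.counts.index):
            self.lengths = self.lengths.reindex(self.counts.index)
        if self.lengths.isna().any():
            raise ValueError("missing gene lengths for some genes")
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("counts must be integers")
        if (self.lengths <= 0).any():
            raise ValueError("gene lengths must be positive")
        if self.libsize is None:
            self.libsize = self.counts.sum(axis=0).astype(float)
        else:
            self.libsize = self.libsize.reindex(self.counts.columns).astype(float)
        if (self.libsize <= 0).any():
            raise ValueError("library sizes must be positive")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def models(self) -> list[str]:
        return list(dict.fromkeys(self.samples["model"]))

    def subset_model(self, model: str) -> "CountMatrix":
        """Restrict to the samples of one activation model."""
        keep = self.samples.index[self.samples["model"] == model]
        if len(keep) == 0:
            raise KeyError(f"no samples for model {model!r}")
        return CountMatrix(
            counts=self.counts[keep].copy(),
            samples=self.samples.loc[keep].copy(),
            lengths=self.lengths.copy(),
            libsize=self.libsize.loc[keep].copy(),
        )

    def timepoints(self, model: str | None = None) -> list:
        sheet = self.samples if model is None else self.samples[self.samples["model"] == model]
        return sorted(sheet["time"].unique().tolist())

    def group_columns(self, model: str, time) -> pd.Index:
        mask = (self.samples["model"] == model) & (self.samples["time"] == time)
        return self.samples.index[mask]

    # ---------------------------------------------------------------- I/O
    def write(self, outdir: str | Path, prefix: str = "counts") -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "counts": outdir / f"{prefix}.tsv",
            "samples": outdir / f"{prefix}.samples.tsv",
            "lengths": outdir / f"{prefix}.lengths.tsv",
        }
        self.counts.to_csv(paths["counts"], sep="\t", index_label="gene_id")
        sheet = self.samples.copy()
        sheet["libsize"] = self.libsize
        sheet.to_csv(paths["samples"], sep="\t", index_label="sample_id",
                     float_format="%.10g")
        self.lengths.rename("length_bp").to_csv(paths["lengths"], sep="\t", index_label="gene_id")
        return paths

    @classmethod
    def read(cls, counts_tsv: str | Path, samples_tsv: str | Path, lengths_tsv: str | Path) -> "CountMatrix":
        counts = pd.read_csv(counts_tsv, sep="\t", index_col="gene_id")
        samples = pd.read_csv(samples_tsv, sep="\t", index_col="sample_id")
        libsize = None
        if "libsize" in samples.columns:
            libsize = samples.pop("libsize")
        lengths = pd.read_csv(lengths_tsv, sep="\t", index_col="gene_id")["length_bp"]
        return cls(counts=counts, samples=samples, lengths=lengths, libsize=libsize)


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read the 6-column gene annotation TSV (see ANNOTATION_COLUMNS)."""
    annot = pd.read_csv(path, sep="\t")
    missing = set(ANNOTATION_COLUMNS) - set(annot.columns)
    if missing:
        raise ValueError(f"annotation missing columns: {sorted(missing)}")
    return annot.set_index("gene_id")


def write_annotation(annot: pd.DataFrame, path: str | Path) -> None:
    out = annot.reset_index() if annot.index.name == "gene_id" else annot
    out[list(ANNOTATION_COLUMNS)].to_csv(path, sep="\t", index=False)
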