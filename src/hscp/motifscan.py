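"""Promoter extraction and PWM scanning for TF binding-site analysis.

Proximal promoters (default window -300..+50 around the TSS, strand
aware) are pulled from a genome FASTA.  JASPAR-style count matrices
become log2-odds position weight matrices (pseudocount split by the
background composition) and are slid over both strands of each
promoter; every window scoring at least a configurable fraction of the
PWM's maximum achievable score is a hit.  Gene-level presence is
ZOOPS (zero-or-one-occurrence: present iff >= 1 hit), optionally
collapsed over a motif family (e.g. an ETS1-like family of related
PWMs), and enrichment of presence in a target gene list versus a
background is an upper-tail hypergeometric test, BH-corrected across
PWMs.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs
from scipy.stats import hypergeom

from .data import read_annotation
from .diffexpr import bh_adjust

__all__ = [
    "PWM",
    "PromoterSet",
    "MotifHitTable",
    "read_pwms",
    "write_pwms",
    "extract_promoters",
    "reverse_complement",
    "scan",
    "scan_promoters",
    "gene_motif_table",
    "motif_enrichment",
    "motif_spacing",
    "hit_pfm",
]

_BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(_BASES)}
_COMP = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class PWM:
    """A position weight matrix in log2-odds form.

    ``counts`` is 4 x w (rows A, C, G, T).  Probabilities add a
    pseudocount distributed by the background composition; the
    log-odds matrix is log2(prob / background).
    """

    id: str
    counts: np.ndarray
    pseudocount: float = 0.8
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape[0] != 4:
            raise ValueError("PWM counts must have 4 rows (A, C, G, T)")
        if self.width < 4:
            raise ValueError("PWM width must be >= 4")
        self.background = np.asarray(self.background, dtype=float)
        col_tot = self.counts.sum(axis=0)
        self.probs = (self.counts + self.pseudocount * self.background[:, None]) / (
            col_tot + self.pseudocount
        )
        self.log_odds = np.log2(self.probs / self.background[:, None])

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.probs.argmax(axis=0))


def read_pwms(path: str | Path) -> list[PWM]:
    """Read JASPAR-format count matrices into PWMs."""
    with open(path) as fh:
        text = fh.read()
    try:
        parsed = bio_motifs.parse(io.StringIO(text), "jaspar")
        out = []
        for m in parsed:
            counts = np.array([m.counts[b] for b in _BASES], dtype=float)
            out.append(PWM(id=m.matrix_id or m.name, counts=counts))
    except Exception as exc:  # ragged/non-numeric rows
        raise ValueError(f"cannot parse JASPAR file {path}: {exc}") from exc
    if not out:
        raise ValueError(f"no motifs found in {path}")
    return out


def write_pwms(pwms: list[PWM], path: str | Path) -> None:
    """Write PWMs as JASPAR count matrices (4 bracketed rows per motif)."""
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.id} {pwm.id}\n")
            for bi, base in enumerate(_BASES):
                row = " ".join(f"{v:.0f}" if v == int(v) else f"{v:g}" for v in pwm.counts[bi])
                fh.write(f"{base} [ {row} ]\n")


@dataclass
class PromoterSet:
    """Fixed-window promoter sequences with genomic provenance."""

    sequences: dict[str, str]
    window: tuple[int, int]
    provenance: pd.DataFrame  # gene_id -> chrom, start, end, strand
    excluded: list[str] = field(default_factory=list)  # window off contig
    flagged_n: list[str] = field(default_factory=list)  # N fraction > 0.5

    @property
    def genes(self) -> list[str]:
        return list(self.sequences)

    def __len__(self) -> int:
        return len(self.sequences)


def extract_promoters(
    genome_fasta: str | Path,
    annotation: pd.DataFrame | str | Path,
    window: tuple[int, int] = (-300, 50),
) -> PromoterSet:
    """Strand-aware promoter extraction around 0-based TSS coordinates.

    "+" genes take the half-open genomic interval [tss+lo, tss+hi);
    "-" genes take [tss-hi+1, tss-lo+1) reverse-complemented, so the
    returned sequence always runs 5'->3' from -lo to +hi-1 relative to
    the TSS.  Genes whose window exceeds the contig are excluded.
    """
    from pyfaidx import Fasta

    if not isinstance(annotation, pd.DataFrame):
        annotation = read_annotation(annotation)
    lo, hi = window
    fa = Fasta(str(genome_fasta), as_raw=True, rebuild=True)
    seqs: dict[str, str] = {}
    rows = []
    excluded: list[str] = []
    flagged: list[str] = []
    for gene, rec in annotation.iterrows():
        chrom, strand, tss = rec["chrom"], rec["strand"], int(rec["tss_0based"])
        if chrom not in fa:
            raise KeyError(f"unknown contig {chrom!r} for gene {gene}")
        clen = len(fa[chrom])
        if strand == "+":
            start, end = tss + lo, tss + hi
        elif strand == "-":
            start, end = tss - hi + 1, tss - lo + 1
        else:
            raise ValueError(f"bad strand {strand!r} for gene {gene}")
        if start < 0 or end > clen:
            excluded.append(str(gene))
            continue
        seq = str(fa[chrom][start:end]).upper()
        if strand == "-":
            seq = reverse_complement(seq)
        if seq.count("N") > 0.5 * len(seq):
            flagged.append(str(gene))
        seqs[str(gene)] = seq
        rows.append(
            {"gene_id": str(gene), "chrom": chrom, "start": start, "end": end, "strand": strand}
        )
    if excluded:
        warnings.warn(
            f"{len(excluded)} genes excluded (promoter window off contig)", stacklevel=2
        )
    prov = pd.DataFrame(rows).set_index("gene_id") if rows else pd.DataFrame()
    return PromoterSet(
        sequences=seqs, window=window, provenance=prov, excluded=excluded, flagged_n=flagged
    )


def _encode(seq: str) -> np.ndarray:
    codes = np.full(len(seq), -1, dtype=np.int8)
    for b, i in _CODE.items():
        codes[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(b)] = i
    return codes


def _scan_codes(
    pwm: PWM, codes: np.ndarray, threshold_frac: float
) -> list[tuple[int, str, float]]:
    w = pwm.width
    if w > len(codes):
        raise ValueError("PWM wider than sequence")
    wins = np.lib.stride_tricks.sliding_window_view(codes, w)
    valid = (wins >= 0).all(axis=1)
    cols = np.arange(w)
    lom = pwm.log_odds
    # reverse strand: score the reverse-complemented matrix on the forward seq
    lom_rc = lom[::-1, ::-1]
    threshold = threshold_frac * pwm.max_score
    safe = np.where(wins >= 0, wins, 0)
    fwd = lom[safe, cols].sum(axis=1)
    rev = lom_rc[safe, cols].sum(axis=1)
    out: list[tuple[int, str, float]] = []
    for strand, scores in (("+", fwd), ("-", rev)):
        hit = valid & (scores >= threshold - 1e-9)
        for pos in np.nonzero(hit)[0]:
            out.append((int(pos), strand, float(scores[pos])))
    out.sort(key=lambda t: (t[0], t[1]))
    return out


def scan(pwm: PWM, seq: str, threshold_frac: float = 0.80) -> pd.DataFrame:
    """All windows on both strands scoring >= threshold_frac * max score.

    Positions are 0-based window starts on the forward promoter
    coordinate; windows containing N are skipped.
    """
    hits = _scan_codes(pwm, _encode(seq), threshold_frac)
    return pd.DataFrame(hits, columns=["pos", "strand", "score"])


def scan_promoters(
    pwms: list[PWM], promoters: PromoterSet, threshold_frac: float = 0.80
) -> pd.DataFrame:
    """Scan every promoter with every PWM; long hit table."""
    rows = []
    for gene, seq in promoters.sequences.items():
        codes = _encode(seq)
        for pwm in pwms:
            for pos, strand, score in _scan_codes(pwm, codes, threshold_frac):
                rows.append((gene, pwm.id, pos, strand, score))
    return pd.DataFrame(rows, columns=["gene_id", "pwm", "pos", "strand", "score"])


@dataclass
class MotifHitTable:
    """Gene x PWM ZOOPS presence with per-hit detail.

    ``presence`` holds 0/1 per gene for each PWM id and each configured
    motif family (OR over member PWMs); ``counts`` the hit counts;
    ``hits`` the long per-hit table (positions, strands, scores).
    """

    presence: pd.DataFrame
    counts: pd.DataFrame
    hits: pd.DataFrame
    families: dict[str, list[str]] = field(default_factory=dict)

    def genes_with(self, motif: str) -> set[str]:
        return set(self.presence.index[self.presence[motif] == 1])


def gene_motif_table(
    hits: pd.DataFrame,
    genes: list[str] | pd.Index,
    pwm_ids: list[str],
    families: dict[str, list[str]] | None = None,
) -> MotifHitTable:
    """ZOOPS binarization of a hit table, with motif-family collapsing.

    All ``genes`` are retained (all-zero rows included).  A family is
    present in a gene if any member PWM has a hit.
    """
    families = families or {}
    genes = [str(g) for g in genes]
    counts = pd.DataFrame(0, index=pd.Index(genes, name="gene_id"), columns=pwm_ids)
    if len(hits):
        tab = hits.groupby(["gene_id", "pwm"]).size().unstack(fill_value=0)
        tab = tab.reindex(index=genes, columns=pwm_ids, fill_value=0).fillna(0).astype(int)
        counts = tab
    presence = (counts > 0).astype(int)
    for fam, members in families.items():
        missing = [m for m in members if m not in presence.columns]
        if missing:
            raise KeyError(f"family {fam!r} references unknown PWMs: {missing}")
        presence[fam] = (presence[members].sum(axis=1) > 0).astype(int)
        counts[fam] = counts[members].sum(axis=1)
    return MotifHitTable(presence=presence, counts=counts, hits=hits, families=families)


def motif_enrichment(
    targets: list[str] | set[str],
    background: list[str] | set[str],
    table: MotifHitTable,
) -> pd.DataFrame:
    """ZOOPS hypergeometric enrichment of each motif in a target list.

    Universe = background genes; successes = background genes carrying
    the motif; draws = target genes.  Upper-tail p, BH across motifs,
    fold = target frequency / background frequency.
    """
    targets = sorted(set(str(g) for g in targets))
    background = sorted(set(str(g) for g in background))
    if not set(targets) <= set(background):
        raise ValueError("target genes must be a subset of the background")
    pres = table.presence.reindex(background).fillna(0).astype(int)
    n_bg, n_t = len(background), len(targets)
    rows = []
    for motif in pres.columns:
        big_k = int(pres[motif].sum())
        k = int(pres.loc[targets, motif].sum())
        p = float(hypergeom.sf(k - 1, n_bg, big_k, n_t))
        bg_freq = big_k / n_bg if n_bg else 0.0
        fold = (k / n_t) / bg_freq if (n_t and bg_freq > 0) else np.nan
        rows.append(
            {"pwm": motif, "target_n": n_t, "hits": k, "background_hits": big_k,
             "fold": fold, "p": p}
        )
    out = pd.DataFrame(rows)
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    return out


def motif_spacing(
    table: MotifHitTable,
    motif_a: str | list[str],
    motif_b: str | list[str],
    widths: dict[str, int],
) -> tuple[float, pd.Series]:
    """Mean midpoint-to-midpoint spacing of two motifs per promoter.

    For every gene carrying >= 1 hit of each motif (or motif family,
    pass the list of member PWM ids), the minimal |midpoint difference|
    over hit pairs is taken; the mean over qualifying genes and the
    per-gene distribution are returned.  With no qualifying genes the
    mean is NaN and a warning is raised.
    """
    ids_a = [motif_a] if isinstance(motif_a, str) else list(motif_a)
    ids_b = [motif_b] if isinstance(motif_b, str) else list(motif_b)
    hits = table.hits
    mid = hits["pos"] + hits["pwm"].map(widths) / 2.0
    ha = hits[hits["pwm"].isin(ids_a)].assign(mid=mid)
    hb = hits[hits["pwm"].isin(ids_b)].assign(mid=mid)
    spacings = {}
    for gene in sorted(set(ha["gene_id"]) & set(hb["gene_id"])):
        ma = ha.loc[ha["gene_id"] == gene, "mid"].to_numpy()
        mb = hb.loc[hb["gene_id"] == gene, "mid"].to_numpy()
        spacings[gene] = float(np.abs(ma[:, None] - mb[None, :]).min())
    dist = pd.Series(spacings, dtype=float)
    if dist.empty:
        warnings.warn("no promoter carries both motifs; spacing undefined", stacklevel=2)
        return float("nan"), dist
    return float(dist.mean()), dist


def hit_pfm(table: MotifHitTable, promoters: PromoterSet, pwm: PWM) -> np.ndarray:
    """Position-frequency matrix (4 x w counts) of a PWM's hit sequences.

    The text-level analogue of a motif logo: every hit window (minus-
    strand hits reverse-complemented) contributes one sequence.
    """
    w = pwm.width
    counts = np.zeros((4, w))
    sub = table.hits[table.hits["pwm"] == pwm.id]
    for _, h in sub.iterrows():
        seq = promoters.sequences[h["gene_id"]][int(h["pos"]) : int(h["pos"]) + w]
        if h["strand"] == "-":
            seq = reverse_complement(seq)
        for j, base in enumerate(seq):
            if base in _CODE:
                counts[_CODE[base], j] += 1
    return counts
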