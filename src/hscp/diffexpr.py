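"""Normalization and negative-binomial exact-test differential expression.

The test is the classic conditional exact test for overdispersed counts:
with library sizes equalized, each group's count sum is negative binomial
with size ``n_group / phi`` and a common success probability.  Conditional
on the gene's total, the probability of a split no longer depends on the
unknown mean -- it is negative hypergeometric -- so an exact two-sided
p-value can be computed by summing the probabilities of all splits at
most as likely as the observed one.  In the phi -> 0 limit the split is
binomial (the Poisson case).

Also houses CPM/RPKM normalization, common-dispersion estimation by
method of moments, Benjamini-Hochberg adjustment, and the paired
signed-rank test for global shifts of the expression distribution.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .data import CountMatrix

__all__ = [
    "NormalizedExpression",
    "DEResult",
    "normalize",
    "estimate_common_dispersion",
    "nb_exact_test",
    "bh_adjust",
    "de_table",
    "distribution_shift_test",
]


@dataclass
class NormalizedExpression:
    """CPM / RPKM tables plus per-timepoint averages.

    ``log2cpm``/``log2rpkm`` use a prior count on the CPM scale so that
    zeros map to ``log2(prior)`` under a 1e6 library.
    """

    cpm: pd.DataFrame
    log2cpm: pd.DataFrame
    rpkm: pd.DataFrame
    log2rpkm: pd.DataFrame
    prior_count: float
    samples: pd.DataFrame

    def _by_time(self, table: pd.DataFrame) -> pd.DataFrame:
        cols = pd.MultiIndex.from_frame(self.samples[["model", "time"]])
        t = table.copy()
        t.columns = cols
        return t.T.groupby(level=["model", "time"]).mean().T

    def avg_cpm_by_time(self) -> pd.DataFrame:
        return self._by_time(self.cpm)

    def avg_rpkm_by_time(self) -> pd.DataFrame:
        """Per-gene average RPKM per (model, time) -- clustering input."""
        return self._by_time(self.rpkm)

    def avg_log2cpm(self) -> pd.Series:
        return self.log2cpm.mean(axis=1)


@dataclass
class DEResult:
    """Per-gene DE statistics for one contrast within one model."""

    model: str
    time_b: object  # numerator (later) time point
    time_a: object  # denominator (earlier) time point
    table: pd.DataFrame  # columns: log2FC, log2CPM, p, fdr
    phi: float
    floor_log2cpm: float

    @property
    def contrast(self) -> tuple:
        return (self.model, self.time_b, self.time_a)

    def significant(self, fdr_max: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["fdr"] < fdr_max]


def normalize(cm: CountMatrix, prior_count: float = 0.5) -> NormalizedExpression:
    """Counts-per-million and RPKM with a CPM-scale prior for logs.

    cpm = count / (libsize / 1e6); rpkm = cpm / (length_kb);
    log2cpm = log2(cpm + prior_count).
    """
    if prior_count <= 0:
        raise ValueError("prior_count must be positive")
    lib = cm.libsize.to_numpy()
    if (lib <= 0).any():
        raise ValueError("zero library size")
    if (cm.lengths <= 0).any():
        raise ValueError("zero gene length")
    cpm = cm.counts / (lib / 1e6)
    length_kb = cm.lengths / 1000.0
    rpkm = cpm.div(length_kb, axis=0)
    log2cpm = np.log2(cpm + prior_count)
    log2rpkm = np.log2(rpkm + prior_count)
    return NormalizedExpression(
        cpm=cpm,
        log2cpm=log2cpm,
        rpkm=rpkm,
        log2rpkm=log2rpkm,
        prior_count=prior_count,
        samples=cm.samples,
    )


def estimate_common_dispersion(cm: CountMatrix, groups: pd.Series | None = None) -> float:
    """Method-of-moments common NB dispersion, pooled across genes.

    Counts are first scaled to a common library size.  For each gene
    and each group with >= 2 replicates, the sample mean ``m`` and
    variance ``v`` give a per-gene moment ratio
    (v - m) / (m^2 - v/n)  (the ``- v/n`` term unbiases the squared
    sample mean; under NB, E[v] = m + phi m^2).  The common phi is the
    10%-trimmed mean of these ratios over adequately expressed genes
    (mean >= 10 when enough qualify), floored at 0.  Trimming
    equalizes gene influence: a plain ratio of sums is dominated by
    the few highest-expressed genes and is unstable under the heavy-
    tailed mean distributions typical of RNA-seq.
    """
    if groups is None:
        groups = cm.samples["model"].astype(str) + ":" + cm.samples["time"].astype(str)
    common = float(np.exp(np.mean(np.log(cm.libsize))))
    scaled = cm.counts * (common / cm.libsize)
    ratios: list[np.ndarray] = []
    means: list[np.ndarray] = []
    any_replicated = False
    for _, cols in groups.groupby(groups):
        ids = cols.index
        n = len(ids)
        if n < 2:
            continue
        any_replicated = True
        x = scaled[ids].to_numpy()
        m = x.mean(axis=1)
        v = x.var(axis=1, ddof=1)
        den = m**2 - v / n
        ok = (m > 0) & (den > 0)
        ratios.append(((v - m) / np.where(ok, den, 1.0))[ok])
        means.append(m[ok])
    if not any_replicated:
        raise ValueError(
            "no group has >= 2 replicates; supply the dispersion phi explicitly"
        )
    r = np.concatenate(ratios) if ratios else np.array([])
    m = np.concatenate(means) if means else np.array([])
    if len(r) == 0:
        return 0.0
    expressed = m >= 10
    if expressed.sum() >= 50:
        r = r[expressed]
    lo, hi = np.quantile(r, [0.10, 0.90])
    return max(0.0, float(np.clip(r, lo, hi).mean()))


def _equalize(counts: np.ndarray, libsizes: np.ndarray, common: float) -> np.ndarray:
    """Scale counts to a common library size, rounded to integers."""
    return np.rint(counts * (common / libsizes)).astype(np.int64)


def _split_logprob(t: int, r_a: float, r_b: float) -> np.ndarray:
    """Log conditional probability of each split s in 0..t of the total.

    Negative-hypergeometric weights: the NB success probability cancels
    given the total, leaving a ratio of gamma functions.
    """
    s = np.arange(t + 1, dtype=np.float64)
    logw = (
        special.gammaln(s + r_a)
        - special.gammaln(s + 1.0)
        + special.gammaln(t - s + r_b)
        - special.gammaln(t - s + 1.0)
    )
    return logw - special.logsumexp(logw)


def _binom_split_logprob(t: int, frac_a: float) -> np.ndarray:
    s = np.arange(t + 1)
    return stats.binom.logpmf(s, t, frac_a)


def exact_split_pvalue(s_a: int, s_b: int, n_a: int, n_b: int, phi: float) -> float:
    """Two-sided exact p for one gene's split, conditioning on the total.

    All splits with conditional probability <= the observed one (with a
    1e-12 relative tolerance against float noise) contribute.
    """
    t = int(s_a + s_b)
    if t == 0:
        return 1.0
    if phi == 0.0:
        logw = _binom_split_logprob(t, n_a / (n_a + n_b))
    else:
        logw = _split_logprob(t, n_a / phi, n_b / phi)
    w = np.exp(logw)
    obs = w[int(s_a)]
    return float(min(1.0, w[w <= obs * (1.0 + 1e-12)].sum()))


def nb_exact_test(
    counts_a: np.ndarray | pd.DataFrame,
    counts_b: np.ndarray | pd.DataFrame,
    phi: float,
    libsizes_a: np.ndarray | None = None,
    libsizes_b: np.ndarray | None = None,
) -> np.ndarray:
    """Per-gene two-sided conditional exact p-values, group A vs group B.

    ``counts_*`` are genes x replicates.  Library sizes are equalized to
    their geometric mean by pseudo-count scaling (rounded) before the
    conditional test; pass ``None`` for already-equal libraries.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    if b.ndim == 1:
        b = b[:, None]
    if (a < 0).any() or (b < 0).any():
        raise ValueError("negative counts")
    if phi < 0:
        raise ValueError("dispersion must be >= 0")
    if libsizes_a is not None or libsizes_b is not None:
        la = np.asarray(libsizes_a, dtype=float)
        lb = np.asarray(libsizes_b, dtype=float)
        common = float(np.exp(np.mean(np.log(np.concatenate([la, lb])))))
        a = _equalize(a, la, common)
        b = _equalize(b, lb, common)
    n_a, n_b = a.shape[1], b.shape[1]
    s_a = np.rint(a.sum(axis=1)).astype(np.int64)
    s_b = np.rint(b.sum(axis=1)).astype(np.int64)
    return np.array(
        [exact_split_pvalue(sa, sb, n_a, n_b, phi) for sa, sb in zip(s_a, s_b)]
    )


def bh_adjust(p_values: np.ndarray | pd.Series) -> np.ndarray | pd.Series:
    """Benjamini-Hochberg step-up adjusted values, clipped to 1.

    NaN inputs propagate as NaN and are excluded from the number of
    tests m.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ok.sum() > 0:
        if ((p[ok] < 0) | (p[ok] > 1)).any():
            raise ValueError("p-values must lie in [0, 1]")
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    if isinstance(p_values, pd.Series):
        return pd.Series(out, index=p_values.index)
    return out


def de_table(
    cm: CountMatrix,
    model: str,
    contrast: tuple,
    phi: float | None = None,
    prior_count: float = 0.5,
    floor_log2cpm: float = 2.0,
) -> DEResult:
    """Full DE table for one within-model contrast (time_b vs time_a).

    log2FC comes from prior-stabilized group-mean CPM; p from the NB
    exact test; BH-FDR is computed only over genes whose mean log2CPM
    across the model's samples exceeds ``floor_log2cpm`` (others get
    NaN fdr -- they were not tested).
    """
    time_b, time_a = contrast
    sub = cm.subset_model(model)
    cols_b = sub.group_columns(model, time_b)
    cols_a = sub.group_columns(model, time_a)
    if len(cols_a) == 0 or len(cols_b) == 0:
        raise ValueError(f"contrast group missing for model {model!r}: {contrast}")
    if phi is None:
        phi = estimate_common_dispersion(sub)
    norm = normalize(sub, prior_count=prior_count)
    mean_b = norm.cpm[cols_b].mean(axis=1)
    mean_a = norm.cpm[cols_a].mean(axis=1)
    log2fc = np.log2(mean_b + prior_count) - np.log2(mean_a + prior_count)
    avg_log2cpm = norm.avg_log2cpm()
    p = nb_exact_test(
        sub.counts[cols_a].to_numpy(),
        sub.counts[cols_b].to_numpy(),
        phi,
        sub.libsize[cols_a].to_numpy(),
        sub.libsize[cols_b].to_numpy(),
    )
    p = pd.Series(p, index=sub.genes, name="p")
    expressed = avg_log2cpm > floor_log2cpm
    fdr = pd.Series(np.nan, index=sub.genes)
    fdr[expressed] = bh_adjust(p[expressed])
    table = pd.DataFrame(
        {"log2FC": log2fc, "log2CPM": avg_log2cpm, "p": p, "fdr": fdr}
    )
    return DEResult(
        model=model,
        time_b=time_b,
        time_a=time_a,
        table=table,
        phi=float(phi),
        floor_log2cpm=floor_log2cpm,
    )


def _signed_rank_exact_p(d: np.ndarray) -> float:
    """Exact two-sided signed-rank p by full sign-flip enumeration.

    Handles ties in |d| by average ranks.  Intended for n <= 15.
    """
    ranks = stats.rankdata(np.abs(d))
    obs = abs(float(np.sum(np.sign(d) * ranks)))
    n = len(d)
    count = 0
    total = 2**n
    for signs in itertools.product((1.0, -1.0), repeat=n):
        w = abs(float(np.dot(signs, ranks)))
        if w >= obs - 1e-9:
            count += 1
    return count / total


def distribution_shift_test(
    expr_a: pd.Series | np.ndarray, expr_b: pd.Series | np.ndarray
) -> tuple[float, str]:
    """Paired two-sided Wilcoxon signed-rank test on per-gene summaries.

    Tests whether the whole expression distribution shifted between two
    conditions (activated vs control), gene-paired.  Returns (p-value,
    direction) where direction is "up" if B > A on median difference,
    "down" if B < A, "none" for no nonzero differences (p = 1).
    """
    a = np.asarray(expr_a, dtype=float)
    b = np.asarray(expr_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("expression vectors must share the gene universe")
    if len(a) < 10:
        raise ValueError("need at least 10 genes")
    d = b - a
    nz = d[d != 0]
    if len(nz) == 0:
        return 1.0, "none"
    direction = "up" if np.median(nz) > 0 else "down"
    if len(nz) <= 15:
        return _signed_rank_exact_p(nz), direction
    res = stats.wilcoxon(nz, alternative="two-sided", method="approx")
    return float(res.pvalue), direction
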