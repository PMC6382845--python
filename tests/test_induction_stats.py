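"""Motif grouping, exact rank-sum comparisons, rank analysis,
cluster x motif enrichment, and hypergeometric ORA."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hscp.induction_stats import (
    assign_motif_groups,
    cluster_motif_enrichment,
    compare_groups,
    ora,
    rank_analysis,
    ranksum_p,
    read_gmt,
)
from hscp.motifscan import MotifHitTable


def _table(presence: pd.DataFrame) -> MotifHitTable:
    return MotifHitTable(
        presence=presence,
        counts=presence.copy(),
        hits=pd.DataFrame(columns=["gene_id", "pwm", "pos", "strand", "score"]),
    )


class TestAssignGroups:
    def _assignment(self):
        pres = pd.DataFrame(
            {"E": [1, 1, 0, 0], "R": [0, 1, 1, 0]},
            index=pd.Index(["g1", "g2", "g3", "g4"], name="gene_id"),
        )
        return assign_motif_groups(["g1", "g2", "g3", "g4"], _table(pres), "E", "R")

    def test_four_way_partition(self):
        a = self._assignment()
        assert a.groups["g1"] == "a_only"
        assert a.groups["g2"] == "both"
        assert a.groups["g3"] == "b_only"
        assert a.groups["g4"] == "none"

    def test_sizes_sum_to_gene_count(self):
        a = self._assignment()
        assert a.sizes().sum() == 4

    def test_missing_gene_raises(self):
        pres = pd.DataFrame({"E": [1], "R": [0]}, index=pd.Index(["g1"], name="gene_id"))
        with pytest.raises(KeyError):
            assign_motif_groups(["g1", "gX"], _table(pres), "E", "R")


def _ranksum_oracle(x, y):
    """Full enumeration of group assignments over pooled ranks."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    nx = len(x)
    mean_w = nx * (len(pooled) + 1) / 2
    obs = abs(ranks[:nx].sum() - mean_w)
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), nx):
        total += 1
        if abs(ranks[list(idx)].sum() - mean_w) >= obs - 1e-9:
            hits += 1
    return hits / total


class TestRanksum:
    def test_small_example(self):
        # {1,2} vs {3,4}: only the observed and its mirror are as extreme
        assert ranksum_p(np.array([1.0, 2.0]), np.array([3.0, 4.0])) == pytest.approx(
            2 / 6
        )

    def test_identical_groups(self):
        x = np.array([1.0, 2.0, 3.0])
        assert ranksum_p(x, x.copy()) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_enumeration_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        nx, ny = int(rng.integers(2, 7)), int(rng.integers(2, 7))
        # integer draws force ties
        x = rng.integers(0, 4, nx).astype(float)
        y = rng.integers(0, 4, ny).astype(float)
        assert ranksum_p(x, y) == pytest.approx(_ranksum_oracle(x, y), abs=1e-12)

    def test_large_groups_use_normal_approximation(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=200), rng.normal(1.0, 1, 200)
        p = ranksum_p(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided").pvalue
        assert p == pytest.approx(ref, rel=1e-9)


class TestCompareGroups:
    def test_shifted_groups_get_different_letters(self):
        rng = np.random.default_rng(2)
        fc = pd.Series(
            np.concatenate([rng.normal(0, 0.3, 40), rng.normal(3, 0.3, 40)]),
            index=[f"g{i}" for i in range(80)],
        )
        groups = pd.Series(["none"] * 40 + ["both"] * 40, index=fc.index)
        out = compare_groups(fc, groups)
        assert out.summary.loc["both", "median_log2fc"] > out.summary.loc[
            "none", "median_log2fc"
        ]
        assert out.summary.loc["both", "letters"] != out.summary.loc["none", "letters"]

    def test_identical_groups_share_letter(self):
        fc = pd.Series(np.tile([1.0, 2.0, 3.0, 4.0], 2), index=[f"g{i}" for i in range(8)])
        groups = pd.Series(["a_only"] * 4 + ["b_only"] * 4, index=fc.index)
        out = compare_groups(fc, groups)
        assert out.pairwise.loc[0, "p"] == pytest.approx(1.0)
        assert len(set(out.summary["letters"])) == 1

    def test_letter_classes_consistent_with_fdr_matrix(self):
        rng = np.random.default_rng(3)
        fc = pd.Series(rng.normal(size=120), index=[f"g{i}" for i in range(120)])
        groups = pd.Series(
            rng.choice(["none", "a_only", "b_only", "both"], 120), index=fc.index
        )
        out = compare_groups(fc, groups)
        letters = out.summary["letters"]
        # different letters always mean a significant separation exists:
        # groups in different components share no non-significant edge
        for _, r in out.pairwise.iterrows():
            if letters[r["group_1"]] != letters[r["group_2"]]:
                assert r["fdr"] < out.fdr_threshold
        # a two-member letter class must be a non-significant pair
        comp = {}
        for g, l in letters.items():
            comp.setdefault(l, []).append(g)
        for members in comp.values():
            if len(members) == 2:
                row = out.pairwise[
                    (
                        out.pairwise[["group_1", "group_2"]]
                        .apply(frozenset, axis=1)
                        == frozenset(members)
                    )
                ]
                assert not (row["fdr"] < out.fdr_threshold).any()

    def test_single_group_raises(self):
        fc = pd.Series([1.0, 2.0], index=["g1", "g2"])
        groups = pd.Series(["none", "none"], index=fc.index)
        with pytest.raises(ValueError):
            compare_groups(fc, groups)


class TestRankAnalysis:
    def test_descending_ranks(self):
        fc = pd.Series([5.0, 3.0, 1.0], index=["a", "b", "c"])
        groups = pd.Series(["x", "y", "z"], index=fc.index)
        out = rank_analysis(fc, groups)
        assert out["x"] == 1 and out["y"] == 2 and out["z"] == 3

    def test_average_tie_rule(self):
        fc = pd.Series([5.0, 3.0, 3.0], index=["a", "b", "c"])
        groups = pd.Series(["x", "y", "y"], index=fc.index)
        out = rank_analysis(fc, groups)
        assert out["y"] == pytest.approx(2.5)

    def test_top_block_closed_form(self):
        k, n = 7, 30
        fc = pd.Series(np.arange(n, 0, -1, dtype=float), index=[f"g{i}" for i in range(n)])
        groups = pd.Series(["top"] * k + ["rest"] * (n - k), index=fc.index)
        out = rank_analysis(fc, groups)
        assert out["top"] == pytest.approx((k + 1) / 2)


class TestClusterMotifEnrichment:
    def test_ratio_formula(self):
        genes = [f"g{i}" for i in range(800)]
        assign = pd.Series(
            ["c1"] * 50 + ["no cluster"] * 750, index=pd.Index(genes, name="gene_id")
        )
        motif = set(genes[:25]) | set(genes[50:225])  # 25 in c1, 200 total
        out = cluster_motif_enrichment(assign, {"M": motif})
        row = out[(out["cluster"] == "c1") & (out["motif"] == "M")].iloc[0]
        assert row["ratio"] == pytest.approx((25 / 50) / (200 / 800))
        assert row["count"] == 25

    def test_additivity_over_clusters(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(300)]
        assign = pd.Series(
            rng.choice(["c1", "c2", "c3", "no cluster"], 300),
            index=pd.Index(genes, name="gene_id"),
        )
        motif = set(rng.choice(genes, 80, replace=False))
        out = cluster_motif_enrichment(assign, {"M": motif})
        assert out["count"].sum() == len(motif)

    def test_zero_overlap(self):
        genes = [f"g{i}" for i in range(100)]
        assign = pd.Series(
            ["c1"] * 50 + ["c2"] * 50, index=pd.Index(genes, name="gene_id")
        )
        out = cluster_motif_enrichment(assign, {"M": set(genes[50:])})
        row = out[(out["cluster"] == "c1") & (out["motif"] == "M")].iloc[0]
        assert row["ratio"] == 0.0
        assert row["p"] == pytest.approx(1.0)


class TestOra:
    def _gmt(self, tmp_path, sets):
        p = tmp_path / "sets.gmt"
        with open(p, "w") as fh:
            for name, genes in sets.items():
                fh.write(f"{name}\tdesc {name}\t" + "\t".join(genes) + "\n")
        return read_gmt(p)

    def test_gmt_round_trip(self, tmp_path):
        sets = self._gmt(tmp_path, {"s1": ["a", "b"], "s2": ["c"]})
        assert sets["s1"] == ("desc s1", ["a", "b"])

    def test_fully_contained_planted_set(self, tmp_path):
        genes = [f"g{i}" for i in range(1000)]
        sets = self._gmt(tmp_path, {"planted": genes[:20]})
        out = ora(genes[:50], genes, sets)
        assert out.loc[0, "overlap"] == 20
        assert out.loc[0, "p"] < 1e-20
        assert bool(out.loc[0, "enriched"])

    def test_rpkm_filter_closed_bound(self, tmp_path):
        genes = [f"g{i}" for i in range(100)]
        sets = self._gmt(tmp_path, {"s": genes[:10]})
        rpkm = pd.Series(5.0, index=genes)
        rpkm[genes[0]] = 10.0  # exactly at the threshold -> retained
        rpkm[genes[1]] = 9.999  # just below -> filtered out
        rpkm[2:10] = 50.0
        out = ora(genes[:10], genes, sets, rpkm_max=rpkm, expr_filter_rpkm=10.0)
        assert out.loc[0, "overlap"] == 9  # g1 dropped, g0 kept

    def test_empty_foreground_warns(self, tmp_path):
        genes = [f"g{i}" for i in range(20)]
        sets = self._gmt(tmp_path, {"s": genes[:5]})
        rpkm = pd.Series(0.0, index=genes)
        with pytest.warns(UserWarning, match="empty foreground"):
            out = ora(genes[:5], genes, sets, rpkm_max=rpkm)
        assert out.empty

    def test_exact_tail_small_universe(self, tmp_path):
        genes = [f"g{i}" for i in range(15)]
        sets = self._gmt(tmp_path, {"s": genes[:6]})
        out = ora(genes[:5], genes, sets)
        # all 5 drawn genes fall in the 6-member set; P(X >= 5)
        expect = sum(math.comb(6, j) * math.comb(9, 5 - j) for j in range(5, 6))
        assert out.loc[0, "p"] == pytest.approx(expect / math.comb(15, 5), abs=1e-12)
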