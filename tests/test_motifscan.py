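"""PWM ingestion arithmetic, promoter window conventions, scanner
correctness against brute-force rescoring, ZOOPS tables, enrichment,
and motif spacing."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from hscp.motifscan import (
    PWM,
    MotifHitTable,
    extract_promoters,
    gene_motif_table,
    hit_pfm,
    motif_enrichment,
    motif_spacing,
    read_pwms,
    reverse_complement,
    scan,
    write_pwms,
)
from hscp.synthetic_data import default_pwms


class TestPWM:
    def test_pseudocount_arithmetic(self):
        counts = np.zeros((4, 4))
        counts[0, 0] = 10  # column (10, 0, 0, 0)
        counts[1, 1:] = counts[2, 1:] = counts[3, 1:] = 1
        pwm = PWM(id="x", counts=counts, pseudocount=0.8)
        assert pwm.probs[0, 0] == pytest.approx(10.2 / 10.8)
        assert pwm.log_odds[0, 0] == pytest.approx(math.log2((10.2 / 10.8) / 0.25), abs=1e-9)
        assert pwm.log_odds[0, 0] == pytest.approx(1.918, abs=1e-3)

    def test_uniform_column_zero_log_odds(self):
        counts = np.full((4, 4), 5.0)
        pwm = PWM(id="x", counts=counts)
        np.testing.assert_allclose(pwm.log_odds, 0.0, atol=1e-12)

    def test_jaspar_round_trip(self, tmp_path):
        pwms = default_pwms()
        write_pwms(pwms, tmp_path / "m.jaspar")
        back = read_pwms(tmp_path / "m.jaspar")
        assert [p.id for p in back] == [p.id for p in pwms]
        for a, b in zip(pwms, back):
            np.testing.assert_allclose(a.counts, b.counts, atol=1e-9)
            np.testing.assert_allclose(a.log_odds, b.log_odds, atol=1e-9)

    def test_too_narrow_rejected(self):
        with pytest.raises(ValueError):
            PWM(id="x", counts=np.full((4, 3), 5.0))

    def test_unparseable_file(self, tmp_path):
        p = tmp_path / "bad.jaspar"
        p.write_text(">m1 m1\nA [ 1 2\nC [ x y ]\n")
        with pytest.raises(ValueError):
            read_pwms(p)


class TestExtractPromoters:
    def _genome(self, tmp_path, seq):
        fa = tmp_path / "g.fa"
        with open(fa, "w") as fh:
            fh.write(">chr1\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
        return fa

    def _annot(self, rows):
        return pd.DataFrame(
            rows, columns=["gene_id", "chrom", "strand", "tss_0based", "length_bp",
                           "planted_cluster"]
        ).set_index("gene_id")

    def test_plus_strand_window(self, tmp_path):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), 2000))
        fa = self._genome(tmp_path, seq)
        annot = self._annot([("g1", "chr1", "+", 1000, 500, "null")])
        prom = extract_promoters(fa, annot)
        assert prom.sequences["g1"] == seq[700:1050]
        assert len(prom.sequences["g1"]) == 350

    def test_minus_strand_window_reverse_complemented(self, tmp_path):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), 2000))
        fa = self._genome(tmp_path, seq)
        annot = self._annot([("g1", "chr1", "-", 1000, 500, "null")])
        prom = extract_promoters(fa, annot)
        assert prom.sequences["g1"] == reverse_complement(seq[951:1301])

    def test_short_contig_excluded(self, tmp_path):
        rng = np.random.default_rng(2)
        seq = "".join(rng.choice(list("ACGT"), 400))
        fa = self._genome(tmp_path, seq)
        annot = self._annot([("g1", "chr1", "+", 100, 500, "null")])
        with pytest.warns(UserWarning, match="excluded"):
            prom = extract_promoters(fa, annot)
        assert prom.excluded == ["g1"]
        assert "g1" not in prom.sequences

    def test_unknown_contig_raises(self, tmp_path):
        fa = self._genome(tmp_path, "ACGT" * 200)
        annot = self._annot([("g1", "chr9", "+", 400, 500, "null")])
        with pytest.raises(KeyError):
            extract_promoters(fa, annot)


def _embed(rng, consensus, pos, length=350, revcomp=False):
    seq = rng.choice(list("ACGT"), length)
    inst = reverse_complement(consensus) if revcomp else consensus
    seq[pos : pos + len(inst)] = list(inst)
    return "".join(seq)


class TestScan:
    def test_consensus_hit_at_planted_position(self):
        pwm = default_pwms()[0]  # ETS1
        rng = np.random.default_rng(3)
        seq = _embed(rng, pwm.consensus, 120)
        hits = scan(pwm, seq, 0.80)
        planted = hits[(hits["pos"] == 120) & (hits["strand"] == "+")]
        assert len(planted) == 1
        assert planted.iloc[0]["score"] == pytest.approx(pwm.max_score)

    def test_reverse_complement_hit_minus_strand(self):
        pwm = default_pwms()[0]
        rng = np.random.default_rng(4)
        seq = _embed(rng, pwm.consensus, 200, revcomp=True)
        hits = scan(pwm, seq, 0.80)
        planted = hits[(hits["pos"] == 200) & (hits["strand"] == "-")]
        assert len(planted) == 1
        assert planted.iloc[0]["score"] == pytest.approx(pwm.max_score)

    def test_matches_bruteforce_window_rescoring(self):
        rng = np.random.default_rng(5)
        base_to_i = {b: i for i, b in enumerate("ACGT")}
        for pwm in default_pwms()[:2]:
            for _ in range(25):
                seq = "".join(rng.choice(list("ACGT"), 350))
                got = {
                    (r["pos"], r["strand"]) for _, r in scan(pwm, seq, 0.5).iterrows()
                }
                expect = set()
                thr = 0.5 * pwm.max_score
                for pos in range(len(seq) - pwm.width + 1):
                    win = seq[pos : pos + pwm.width]
                    fwd = sum(
                        pwm.log_odds[base_to_i[b], j] for j, b in enumerate(win)
                    )
                    rev = sum(
                        pwm.log_odds[base_to_i[b], j]
                        for j, b in enumerate(reverse_complement(win))
                    )
                    if fwd >= thr - 1e-9:
                        expect.add((pos, "+"))
                    if rev >= thr - 1e-9:
                        expect.add((pos, "-"))
                assert got == expect

    def test_n_windows_skipped(self):
        pwm = default_pwms()[0]
        seq = pwm.consensus + "N" * 20 + pwm.consensus
        hits = scan(pwm, seq, 0.80)
        assert set(hits["pos"]) == {0, len(pwm.consensus) + 20}

    def test_strand_symmetry_property(self):
        rng = np.random.default_rng(6)
        pwm = default_pwms()[3]  # RUNX1
        for _ in range(50):
            seq = "".join(rng.choice(list("ACGT"), 120))
            fwd = scan(pwm, seq, 0.6)
            rc = scan(pwm, reverse_complement(seq), 0.6)
            mirrored = {
                (len(seq) - pwm.width - r["pos"], {"+": "-", "-": "+"}[r["strand"]])
                for _, r in rc.iterrows()
            }
            assert {(r["pos"], r["strand"]) for _, r in fwd.iterrows()} == mirrored

    def test_pwm_wider_than_sequence(self):
        with pytest.raises(ValueError):
            scan(default_pwms()[0], "ACGT", 0.8)


class TestGeneMotifTable:
    def _table(self):
        hits = pd.DataFrame(
            {
                "gene_id": ["g1", "g1", "g1", "g2", "g3"],
                "pwm": ["ETS1", "ETS1", "ETS1", "ETSL1", "RUNX1"],
                "pos": [10, 50, 90, 30, 70],
                "strand": ["+", "-", "+", "+", "+"],
                "score": [10.0] * 5,
            }
        )
        return gene_motif_table(
            hits,
            ["g1", "g2", "g3", "g4"],
            ["ETS1", "ETSL1", "RUNX1"],
            families={"ETS1_like": ["ETS1", "ETSL1"]},
        )

    def test_counts_and_presence(self):
        t = self._table()
        assert t.counts.loc["g1", "ETS1"] == 3
        assert t.presence.loc["g1", "ETS1"] == 1

    def test_family_or_semantics(self):
        t = self._table()
        assert t.presence.loc["g2", "ETS1_like"] == 1
        assert t.presence.loc["g3", "ETS1_like"] == 0

    def test_all_zero_row_retained(self):
        t = self._table()
        assert "g4" in t.presence.index
        assert t.presence.loc["g4"].sum() == 0

    def test_unknown_family_member(self):
        with pytest.raises(KeyError):
            gene_motif_table(
                pd.DataFrame(columns=["gene_id", "pwm", "pos", "strand", "score"]),
                ["g1"],
                ["ETS1"],
                families={"fam": ["NOPE"]},
            )


def _presence_table(presence: pd.DataFrame) -> MotifHitTable:
    return MotifHitTable(
        presence=presence,
        counts=presence.copy(),
        hits=pd.DataFrame(columns=["gene_id", "pwm", "pos", "strand", "score"]),
    )


class TestMotifEnrichment:
    def test_fold_and_tail_formula(self):
        genes = [f"g{i}" for i in range(1000)]
        pres = pd.DataFrame({"M": 0}, index=pd.Index(genes, name="gene_id"))
        pres.iloc[:100, 0] = 1  # 100 background genes carry the motif
        table = _presence_table(pres)
        targets = genes[:25] + genes[100:125]  # 25 of 50 targets carry it
        out = motif_enrichment(targets, genes, table)
        assert out.loc[0, "fold"] == pytest.approx(5.0)
        assert out.loc[0, "p"] == pytest.approx(
            float(hypergeom.sf(24, 1000, 100, 50)), rel=1e-12
        )

    def test_tail_matches_comb_enumeration_small(self):
        genes = [f"g{i}" for i in range(20)]
        pres = pd.DataFrame({"M": 0}, index=pd.Index(genes, name="gene_id"))
        pres.iloc[:8, 0] = 1
        table = _presence_table(pres)
        targets = genes[:5] + genes[8:10]  # 5 carriers among 7 targets
        out = motif_enrichment(targets, genes, table)
        expect = sum(
            math.comb(8, j) * math.comb(12, 7 - j) for j in range(5, 8)
        ) / math.comb(20, 7)
        assert out.loc[0, "p"] == pytest.approx(expect, abs=1e-12)

    def test_target_equals_background(self):
        genes = [f"g{i}" for i in range(50)]
        pres = pd.DataFrame({"M": 0}, index=pd.Index(genes, name="gene_id"))
        pres.iloc[:10, 0] = 1
        out = motif_enrichment(genes, genes, _presence_table(pres))
        assert out.loc[0, "fold"] == pytest.approx(1.0)
        assert out.loc[0, "p"] == pytest.approx(1.0)

    def test_target_not_subset_raises(self):
        genes = [f"g{i}" for i in range(10)]
        pres = pd.DataFrame({"M": 0}, index=pd.Index(genes, name="gene_id"))
        with pytest.raises(ValueError):
            motif_enrichment(["nope"], genes, _presence_table(pres))


class TestMotifSpacing:
    def _hits(self, rows):
        hits = pd.DataFrame(rows, columns=["gene_id", "pwm", "pos", "strand", "score"])
        return MotifHitTable(
            presence=pd.DataFrame(), counts=pd.DataFrame(), hits=hits
        )

    def test_single_pair_spacing(self):
        # ETS1 width 10 at 95 -> midpoint 100; RUNX1 width 8 at 173 -> 177
        t = self._hits([("g1", "ETS1", 95, "+", 1.0), ("g1", "RUNX1", 173, "+", 1.0)])
        mean, dist = motif_spacing(t, "ETS1", "RUNX1", {"ETS1": 10, "RUNX1": 8})
        assert mean == pytest.approx(77.0)
        assert dist["g1"] == pytest.approx(77.0)

    def test_minimum_over_hit_pairs(self):
        t = self._hits(
            [
                ("g1", "A", 45, "+", 1.0),  # width 10 -> mid 50
                ("g1", "A", 195, "+", 1.0),  # mid 200
                ("g1", "B", 55, "+", 1.0),  # width 10 -> mid 60
            ]
        )
        mean, _ = motif_spacing(t, "A", "B", {"A": 10, "B": 10})
        assert mean == pytest.approx(10.0)

    def test_no_qualifying_genes_flagged(self):
        t = self._hits([("g1", "A", 10, "+", 1.0)])
        with pytest.warns(UserWarning, match="spacing undefined"):
            mean, dist = motif_spacing(t, "A", "B", {"A": 10, "B": 10})
        assert math.isnan(mean)
        assert dist.empty


class TestHitPfm:
    def test_consensus_hits_recover_consensus(self):
        pwm = default_pwms()[0]
        rng = np.random.default_rng(7)
        seqs = {
            "g1": _embed(rng, pwm.consensus, 40),
            "g2": _embed(rng, pwm.consensus, 200, revcomp=True),
        }
        from hscp.motifscan import PromoterSet, scan_promoters

        prom = PromoterSet(sequences=seqs, window=(-300, 50), provenance=pd.DataFrame())
        hits = scan_promoters([pwm], prom, 0.8)
        table = gene_motif_table(hits, list(seqs), [pwm.id])
        pfm = hit_pfm(table, prom, pwm)
        assert pfm.sum(axis=0)[0] == 2  # both hits contribute
        got = "".join("ACGT"[i] for i in pfm.argmax(axis=0))
        assert got == pwm.consensus
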