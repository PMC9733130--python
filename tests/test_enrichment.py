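"""Promoter extraction, FIMO loading, hypergeometric enrichment, Welch comparisons."""

import math

import numpy as np
import pandas as pd
import pytest

from rp24.enrichment import (
    MotifOccurrenceTable,
    extract_promoters,
    hypergeom_tail,
    load_fimo,
    motif_effect_tests,
    motif_enrichment,
)
from rp24.spectral import RhythmStats

MOTIF = "ACGTTAGCCGTA"


def brute_hypergeom_tail(k, M, K, n):
    """P(X >= k) by direct enumeration of the hypergeometric pmf."""
    total = math.comb(M, n)
    return sum(
        math.comb(K, j) * math.comb(M - K, n - j)
        for j in range(max(k, max(0, n - (M - K))), min(n, K) + 1)
    ) / total


def _revcomp(s):
    return s.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def write_toy_genome(tmp_path, rng, planted_plus=True, planted_minus=True):
    """Random 10-kb contig with two transcripts; optionally plant MOTIF upstream."""
    seq = list(rng.choice(list("ACGT"), size=10_000))
    # plus-strand transcript: TSS at 7001, exons 7001-7200 and 7501-7700
    if planted_plus:
        seq[4000:4000 + len(MOTIF)] = list(MOTIF)  # inside its upstream window
    # minus-strand transcript: TSS at 3000 (its end), exons 2500-2700, 2801-3000
    if planted_minus:
        # upstream of the minus transcript is genomic 3001..9000; plant the
        # reverse complement so the sense-strand promoter reads MOTIF
        seq[3500:3500 + len(MOTIF)] = list(_revcomp(MOTIF))
    fasta = tmp_path / "genome.fa"
    fasta.write_text(">chr1\n" + "".join(seq) + "\n")
    gff = tmp_path / "ann.gff3"
    gff.write_text(
        "##gff-version 3\n"
        "chr1\ttest\tgene\t7001\t7700\t.\t+\t.\tID=geneA\n"
        "chr1\ttest\tmRNA\t7001\t7700\t.\t+\t.\tID=txA;Parent=geneA\n"
        "chr1\ttest\texon\t7001\t7200\t.\t+\t.\tID=txA.e1;Parent=txA\n"
        "chr1\ttest\texon\t7501\t7700\t.\t+\t.\tID=txA.e2;Parent=txA\n"
        "chr1\ttest\tgene\t2500\t3000\t.\t-\t.\tID=geneB\n"
        "chr1\ttest\tmRNA\t2500\t3000\t.\t-\t.\tID=txB;Parent=geneB\n"
        "chr1\ttest\texon\t2801\t3000\t.\t-\t.\tID=txB.e1;Parent=txB\n"
        "chr1\ttest\texon\t2500\t2700\t.\t-\t.\tID=txB.e2;Parent=txB\n"
        "chr1\ttest\tgene\t50\t400\t.\t+\t.\tID=geneC\n"
        "chr1\ttest\tmRNA\t100\t400\t.\t+\t.\tID=txC;Parent=geneC\n"
        "chr1\ttest\texon\t100\t400\t.\t+\t.\tID=txC.e1;Parent=txC\n"
    )
    return str(gff), str(fasta), "".join(seq)


class TestExtractPromoters:
    def test_plus_strand_geometry(self, tmp_path, rng):
        gff, fasta, seq = write_toy_genome(tmp_path, rng)
        recs = {r.transcript_id: r for r in extract_promoters(gff, fasta)}
        a = recs["txA"]
        # TSS at 7001 with 6000 upstream -> genomic 1001..7000
        assert a.upstream_interval == (1001, 7000)
        assert a.intron_interval == (7201, 7500)
        want = seq[1000:7000] + "N" * 20 + seq[7200:7500]
        assert a.sequence == want

    def test_minus_strand_reverse_complemented(self, tmp_path, rng):
        gff, fasta, seq = write_toy_genome(tmp_path, rng)
        recs = {r.transcript_id: r for r in extract_promoters(gff, fasta)}
        b = recs["txB"]
        assert b.strand == "-"
        assert b.upstream_interval == (3001, 9000)
        assert b.intron_interval == (2701, 2800)
        want = _revcomp(seq[3000:9000]) + "N" * 20 + _revcomp(seq[2700:2800])
        assert b.sequence == want

    def test_chromosome_start_clipping_and_single_exon(self, tmp_path, rng):
        gff, fasta, seq = write_toy_genome(tmp_path, rng)
        recs = {r.transcript_id: r for r in extract_promoters(gff, fasta)}
        c = recs["txC"]
        # TSS at 100: upstream clipped to positions 1..99 (length 99)
        assert c.upstream_interval == (1, 99)
        assert len(c.sequence) == 99  # no intron, no linker
        assert c.sequence == seq[0:99]

    def test_planted_motif_round_trip(self, tmp_path, rng):
        gff, fasta, _ = write_toy_genome(tmp_path, rng, planted_plus=True, planted_minus=True)
        recs = extract_promoters(gff, fasta)
        presence = {r.transcript_id: MOTIF in r.sequence for r in recs}
        assert presence == {"txA": True, "txB": True, "txC": False}


class TestLoadFimo:
    def _write(self, tmp_path, rows):
        path = tmp_path / "fimo.tsv"
        df = pd.DataFrame(
            rows,
            columns=["motif_id", "sequence_name", "start", "stop", "strand", "score", "p-value"],
        )
        df.to_csv(path, sep="\t", index=False)
        return str(path)

    def test_threshold_and_presence_collapse(self, tmp_path):
        path = self._write(
            tmp_path,
            [
                ["m1", "txA", 1, 10, "+", 12.0, 1e-6],
                ["m1", "txA", 50, 59, "-", 11.0, 2e-6],  # second hit collapses
                ["m1", "txB", 5, 14, "+", 9.0, 6e-5],    # fails the 5e-5 cutoff
                ["m2", "txB", 5, 14, "+", 9.0, 4.9e-5],
            ],
        )
        table = load_fimo(path, universe=["txA", "txB", "txC"])
        assert table.hits["m1"] == frozenset({"txA"})
        assert table.hits["m2"] == frozenset({"txB"})
        assert table.universe == frozenset({"txA", "txB", "txC"})

    def test_empty_scan(self, tmp_path):
        path = self._write(tmp_path, [])
        table = load_fimo(path, universe=["txA"])
        assert table.hits == {}
        assert table.universe == frozenset({"txA"})

    def test_missing_columns_named(self, tmp_path):
        path = tmp_path / "bad.tsv"
        pd.DataFrame({"motif_id": ["m"], "sequence_name": ["s"]}).to_csv(
            path, sep="\t", index=False
        )
        with pytest.raises(ValueError, match="p-value"):
            load_fimo(str(path))


class TestHypergeometric:
    def test_matches_exhaustive_enumeration(self):
        for M in (5, 12, 20, 25):
            for K in range(M + 1):
                for n in range(M + 1):
                    for k in range(min(n, K) + 1):
                        assert hypergeom_tail(k, M, K, n) == pytest.approx(
                            brute_hypergeom_tail(k, M, K, n), rel=1e-9, abs=1e-12
                        )

    def test_degenerate_cases(self):
        assert hypergeom_tail(0, 20, 5, 8) == 1.0  # upper tail from zero
        assert hypergeom_tail(8, 20, 20, 8) == pytest.approx(1.0)  # motif everywhere

    def test_worked_example(self):
        assert hypergeom_tail(4, 20, 5, 8) == pytest.approx(
            brute_hypergeom_tail(4, 20, 5, 8), rel=1e-12
        )


class TestMotifEnrichment:
    def _table(self):
        universe = frozenset(f"t{i}" for i in range(20))
        hits = {
            "m_enriched": frozenset(f"t{i}" for i in range(5)),
            "m_everywhere": frozenset(f"t{i}" for i in range(20)),
        }
        return MotifOccurrenceTable(universe=universe, hits=hits)

    def test_enrichment_and_bh(self):
        cluster = {f"t{i}" for i in range(8)}
        results = {r.motif_id: r for r in motif_enrichment(cluster, self._table(), min_cluster_size=0)}
        r = results["m_enriched"]
        assert (r.k, r.n, r.K, r.M) == (5, 8, 5, 20)
        assert r.p == pytest.approx(brute_hypergeom_tail(5, 20, 5, 8), rel=1e-9)
        assert results["m_everywhere"].p == pytest.approx(1.0)
        assert r.q >= r.p

    def test_cluster_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            motif_enrichment({"zz"}, self._table(), min_cluster_size=0)

    def test_minimum_cluster_size_enforced(self):
        with pytest.raises(ValueError, match="size"):
            motif_enrichment({"t0", "t1"}, self._table(), min_cluster_size=10)

    def test_label_invariance_under_renaming(self):
        table = self._table()
        cluster = {f"t{i}" for i in range(8)}
        before = {r.motif_id: r.p for r in motif_enrichment(cluster, table, min_cluster_size=0)}
        rename = {f"t{i}": f"x{19 - i}" for i in range(20)}
        table2 = MotifOccurrenceTable(
            universe=frozenset(rename[t] for t in table.universe),
            hits={m: frozenset(rename[t] for t in s) for m, s in table.hits.items()},
        )
        after = {
            r.motif_id: r.p
            for r in motif_enrichment({rename[t] for t in cluster}, table2, min_cluster_size=0)
        }
        assert before == after


def welch_by_hand(a, b):
    ma, mb = np.mean(a), np.mean(b)
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    return (ma - mb) / math.sqrt(va / len(a) + vb / len(b))


class TestMotifEffectTests:
    def _setup(self, rp_present, rp_absent):
        present = [f"p{i}" for i in range(len(rp_present))]
        absent = [f"a{i}" for i in range(len(rp_absent))]
        universe = frozenset(present + absent)
        table = MotifOccurrenceTable(universe=universe, hits={"m": frozenset(present)})
        stats = {
            t: RhythmStats(t, "old", rp24=rp, median_expr=rp)
            for t, rp in zip(present + absent, list(rp_present) + list(rp_absent))
        }
        return list(universe), table, stats

    def test_matches_textbook_welch_formula(self):
        rp_a = [2.0, 3.0, 4.0, 5.5]
        rp_b = [1.0, 1.2, 0.8, 1.6, 1.1]
        cluster, table, stats = self._setup(rp_a, rp_b)
        out = motif_effect_tests(cluster, table, stats).set_index("motif_id")
        assert out.loc["m", "t_rp24"] == pytest.approx(welch_by_hand(rp_a, rp_b), rel=1e-9)

    def test_identical_subgroups_give_null_result(self):
        cluster, table, stats = self._setup([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
        out = motif_effect_tests(cluster, table, stats).set_index("motif_id")
        assert out.loc["m", "t_rp24"] == 0.0
        assert out.loc["m", "p_rp24"] == pytest.approx(1.0)

    def test_small_subgroup_untestable(self):
        cluster, table, stats = self._setup([2.0], [1.0, 1.1, 0.9])
        out = motif_effect_tests(cluster, table, stats).set_index("motif_id")
        assert not out.loc["m", "testable_rp24"]
        assert np.isnan(out.loc["m", "t_rp24"])

    def test_power_on_planted_difference(self, rng):
        rp_a = rng.normal(3.0, 0.5, 20)
        rp_b = rng.normal(1.0, 0.5, 20)
        cluster, table, stats = self._setup(rp_a, rp_b)
        out = motif_effect_tests(cluster, table, stats).set_index("motif_id")
        assert out.loc["m", "p_rp24"] < 1e-6
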