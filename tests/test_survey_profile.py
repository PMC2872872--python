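import numpy as np
import pytest

from gensurvey import survey_profile as sp
from gensurvey.micro_aligner import AlignerParams
from gensurvey.sequence_io import AlignmentRecord, SurveyRead

from conftest import make_reads, random_seq


class TestReadStats:
    def test_small_example(self):
        stats = sp.read_stats(make_reads(["ACGT", "AACC"]))
        assert stats == {"count": 2, "total_bp": 8, "mean_length_bp": 4.0,
                         "gc_fraction": 0.5}

    def test_printed_totals_give_mean_229(self):
        # 84 Mbp over 366,448 reads
        assert round(84_000_000 / 366_448) == 229

    def test_all_n_read_excluded_from_gc_but_counted_in_length(self):
        stats = sp.read_stats(make_reads(["GGCC", "NNNN"]))
        assert stats["total_bp"] == 8
        assert stats["gc_fraction"] == 1.0

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            sp.read_stats([])


class TestGenomeSize:
    def test_flow_cytometry_values_reproduce_printed_sizes(self):
        res = sp.genome_size_from_pg(sp.GenomeSizeParams([7.60, 7.95]))
        assert res["total_gbp"] == pytest.approx(7.6195)
        assert res["total_gbp_rounded"] == 7.5
        assert res["per_haploid_gbp_rounded"] == 2.5

    def test_single_pg_haploid(self):
        res = sp.genome_size_from_pg(sp.GenomeSizeParams([1.0], ploidy=1))
        assert res["total_gbp"] == pytest.approx(0.98)

    def test_linearity_in_pg(self):
        a = sp.genome_size_from_pg(sp.GenomeSizeParams([2.0, 3.0]))
        b = sp.genome_size_from_pg(sp.GenomeSizeParams([4.0, 6.0]))
        assert b["total_gbp"] == pytest.approx(2 * a["total_gbp"])
        assert b["per_haploid_gbp"] == pytest.approx(2 * a["per_haploid_gbp"])


class TestCoverage:
    def test_survey_scale(self):
        res = sp.coverage_estimate(84e6, 7.5e9)
        assert res["coverage"] == pytest.approx(0.0112)
        assert res["coverage_pct"] == pytest.approx(1.12)

    def test_full_and_zero(self):
        assert sp.coverage_estimate(7.5e9, 7.5e9)["coverage"] == 1.0
        assert sp.coverage_estimate(0, 7.5e9)["coverage"] == 0.0

    def test_zero_genome_rejected(self):
        with pytest.raises(ValueError):
            sp.coverage_estimate(1.0, 0.0)


class TestContamination:
    def test_percentage_is_truncated_not_rounded(self):
        # 901 / 366,448 = 0.24587...% -> 0.24 under truncation
        assert sp.truncate_pct(901 / 366_448) == 0.24
        assert sp.truncate_pct(2_642 / 366_448, decimals=1) == 0.7

    def test_screen_recovers_planted_organelle_reads(self, rng):
        """Truth-table oracle: organelle-derived reads are found, background
        reads are not."""
        organelle = random_seq(rng, 8_000)
        background = random_seq(rng, 8_000)
        reads = []
        for i in range(30):  # planted organelle reads
            s = int(rng.integers(0, len(organelle) - 200))
            reads.append(SurveyRead(f"org{i}", organelle[s:s + 200]))
        for i in range(70):
            s = int(rng.integers(0, len(background) - 200))
            reads.append(SurveyRead(f"bg{i}", background[s:s + 200]))
        table = sp.contamination_screen(reads, [("chloro", organelle)])
        row = table.iloc[0]
        assert row["hit_count"] >= 0.95 * 30
        assert row["hit_count"] <= 30  # no background false positives
        assert row["percent"] == sp.truncate_pct(row["hit_count"] / 100)

    def test_zero_hits_zero_percent(self, rng):
        reads = make_reads([random_seq(rng, 100)])
        table = sp.contamination_screen(reads, [("ref", random_seq(rng, 5000))])
        assert table.iloc[0]["percent"] == 0.0


def _rec(query, ident, bit=100.0, subject="s"):
    return AlignmentRecord(query, subject, ident, 100, 0, 0, 1, 100, 1, 100,
                           1e-30, bit)


class TestIdentityHistogram:
    def test_identical_reads_fill_the_top_bin(self):
        recs = [_rec(f"q{i}", 100.0) for i in range(10)]
        hist = sp.identity_histogram(recs, n_reads=10)
        top = hist[hist["bin_high"] == 100.0]["fraction"].iloc[0]
        assert top == 1.0
        assert hist["fraction"].sum() == 1.0

    def test_no_alignments_empty_histogram(self):
        hist = sp.identity_histogram([], n_reads=10)
        assert (hist["fraction"] == 0).all()

    def test_best_hit_is_max_bit_score(self):
        recs = [_rec("q", 80.0, bit=200.0), _rec("q", 99.0, bit=50.0)]
        hist = sp.identity_histogram(recs, n_reads=1)
        assert hist.loc[hist["bin_low"] == 80.0, "fraction"].iloc[0] == 1.0

    def test_mode_tracks_simulated_error_rate(self, rng):
        """Reads at a fixed 5% substitution rate peak at 95 +/- 1%."""
        from gensurvey.micro_aligner import align_many

        ref = random_seq(rng, 4_000)
        reads = []
        for i in range(60):
            s = int(rng.integers(0, 4_000 - 229))
            seq = list(ref[s:s + 229])
            for x in np.flatnonzero(rng.random(229) < 0.05):
                seq[x] = "ACGT"[(("ACGT".index(seq[x])) + 1 + int(rng.integers(3))) % 4]
            reads.append((f"q{i}", "".join(seq)))
        recs = align_many(reads, [("ref", ref)],
                          AlignerParams(min_score=20))
        hist = sp.identity_histogram(recs, n_reads=60)
        mode = hist.loc[hist["fraction"].idxmax()]
        assert 94.0 <= mode["bin_low"] <= 96.0

    def test_mass_conservation(self):
        recs = [_rec(f"q{i}", 90.0 + i) for i in range(5)]
        hist = sp.identity_histogram(recs, n_reads=20)
        assert hist["fraction"].sum() == pytest.approx(5 / 20)


class TestGeneSpace:
    def test_identity_window_boundaries_inclusive_94_99_only(self, rng):
        cds = random_seq(rng, 400)

        def mutated(rate, seed):
            r = np.random.default_rng(seed)
            seq = list(cds[:229])
            k = int(round(rate * 229))
            for x in r.choice(229, k, replace=False):
                seq[x] = "ACGT"[("ACGT".index(seq[x]) + 2) % 4]
            return "".join(seq)

        reads = [SurveyRead("exact", cds[:229]),          # 100% -> excluded
                 SurveyRead("mid", mutated(0.04, 1)),      # ~96% -> selected
                 SurveyRead("far", mutated(0.15, 2))]      # ~85% -> excluded
        selected, frac = sp.gene_space_reads(reads, [("cds1", cds)], [])
        assert [r.read_id for r in selected] == ["mid"]
        assert frac == pytest.approx(1 / 3)

    def test_repeat_flagged_cds_excluded_first(self, rng):
        repeat = random_seq(rng, 500)
        cds_clean = random_seq(rng, 400)
        reads = [SurveyRead("r_rep", repeat[:229]),
                 SurveyRead("r_gene", cds_clean[:229])]
        with pytest.raises(ValueError, match="filter"):
            # the only cds is repeat-derived -> empty filtered set is an error
            sp.gene_space_reads(reads, [("c_rep", repeat[:400])],
                                [("retrotransposon|x", repeat)])


class TestExonSpace:
    def test_printed_parameters_give_66_percent(self):
        res = sp.exon_space_fraction(sp.GeneContentParams())
        assert res["fraction"] == pytest.approx(250 / 379)
        assert res["percent_rounded"] == 66

    def test_read_equal_twice_overlap_gives_unity(self):
        res = sp.exon_space_fraction(sp.GeneContentParams(
            mean_read_bp=100, min_overlap_bp=50))
        assert res["fraction"] == 1.0

    @pytest.mark.parametrize("field,delta,direction", [
        ("mean_read_bp", +20, -1), ("min_overlap_bp", +10, +1)])
    def test_monotonicity(self, field, delta, direction):
        base = sp.exon_space_fraction(sp.GeneContentParams())["fraction"]
        kw = {field: getattr(sp.GeneContentParams(), field) + delta}
        new = sp.exon_space_fraction(sp.GeneContentParams(**kw))["fraction"]
        assert np.sign(new - base) == direction

    def test_monte_carlo_placement_oracle(self):
        """Random read placement over an exon/intron mosaic (130-bp introns,
        typical for grasses) reproduces the closed form within 2 points."""
        rng = np.random.default_rng(5)
        E, I, L, m = 250, 130, 229, 50
        period, units = E + I, 300
        G = period * units
        exonic = np.zeros(G, bool)
        for u in range(units):
            exonic[u * period:u * period + E] = True
        cum = np.concatenate([[0], np.cumsum(exonic)])
        starts = rng.integers(0, G - L, 400_000)
        total_ov = cum[starts + L] - cum[starts]
        pos = starts % period
        o_here = np.clip(np.minimum(pos + L, E) - pos, 0, None)
        o_next = np.clip(np.minimum(pos + L, period + E)
                         - np.maximum(pos, period), 0, None)
        qualifying = np.maximum(o_here, o_next) >= m
        mc = total_ov[qualifying].sum() / (qualifying.sum() * L)
        f = sp.exon_space_fraction(sp.GeneContentParams())["fraction"]
        assert abs(mc - f) <= 0.02


class TestGeneContent:
    def test_full_printed_chain(self):
        params = sp.GeneContentParams(effective_genome_bp=7.5e9)
        res = sp.gene_content_estimate(0.034, params)
        assert res["coding_fraction_pct"] == 2.2
        assert res["coding_bp"] == pytest.approx(165e6)
        assert res["loci_total"] == pytest.approx(110_000)
        assert res["loci_per_subgenome"] == 37_000

    def test_zero_fraction_gives_zeros(self):
        params = sp.GeneContentParams(effective_genome_bp=7.5e9)
        res = sp.gene_content_estimate(0.0, params)
        assert res["coding_bp"] == 0 and res["loci_total"] == 0

    def test_linear_in_genome_size(self):
        p1 = sp.GeneContentParams(effective_genome_bp=7.5e9)
        p2 = sp.GeneContentParams(effective_genome_bp=15e9)
        r1 = sp.gene_content_estimate(0.034, p1)
        r2 = sp.gene_content_estimate(0.034, p2)
        assert r2["coding_bp"] == pytest.approx(2 * r1["coding_bp"])
        assert r2["coding_fraction_pct"] == r1["coding_fraction_pct"]

    def test_unset_genome_size_rejected(self):
        with pytest.raises(ValueError, match="genome"):
            sp.gene_content_estimate(0.034, sp.GeneContentParams())
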