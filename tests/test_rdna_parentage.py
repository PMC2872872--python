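import numpy as np
import pytest

from gensurvey import rdna_parentage as rp
from gensurvey.sequence_io import SurveyRead, revcomp

from conftest import random_seq


def two_haplotypes(rng, unit_len=2000, region=(1000, 1150), n_sites=6):
    """An rDNA unit and a second haplotype differing at sites inside the
    diagnostic region."""
    hap_a = random_seq(rng, unit_len)
    hap_b = list(hap_a)
    sites = rng.choice(np.arange(*region), n_sites, replace=False)
    for s in sites:
        hap_b[s] = {"A": "C", "C": "G", "G": "T", "T": "A"}[hap_b[s]]
    return hap_a, "".join(hap_b), sorted(int(s) for s in sites)


def reads_from(rng, source, n, span=(800, 1350), length=500,
               error=0.0, label=""):
    reads = []
    for i in range(n):
        start = int(rng.integers(span[0] - length + (span[1] - span[0]),
                                 span[0] + 1)) if False else \
            int(rng.integers(750, 960))
        seq = list(source[start:start + length])
        for x in np.flatnonzero(rng.random(length) < error):
            seq[x] = "ACGT"[int(rng.integers(4))]
        seq = "".join(seq)
        if rng.random() < 0.5:
            seq = revcomp(seq)
        reads.append(SurveyRead(f"rd{label}{i:02d}", seq))
    return reads


class TestMining:
    def test_reference_substring_selected(self, rng):
        ref = random_seq(rng, 1000)
        reads = [SurveyRead("hit", ref[200:400]),
                 SurveyRead("miss", random_seq(rng, 200))]
        mined = rp.mine_rdna_reads(reads, [("ref", ref)])
        assert [r.read_id for r in mined] == ["hit"]

    def test_simulated_rdna_reads_recovered_by_truth_tags(self):
        """Truth-table oracle: reads simulated from a planted rDNA array are
        mined at >= 95% sensitivity."""
        from gensurvey.synthetic_data import (GenomeSpec, ReadProfile,
                                              RepeatFamilySpec, read_origin,
                                              simulate_genome,
                                              simulate_survey_reads)

        rng = np.random.default_rng(61)
        hap = random_seq(rng, 300)
        spec = GenomeSpec(
            genome_size_bp=300_000,
            families=[RepeatFamilySpec("rdna", "rDNA", 2000, 30,
                                       tandem=True)],
            its_haplotypes=(hap, hap[:100] + revcomp(hap[100:150]) + hap[150:]),
            rng_seed=62)
        genome, truth = simulate_genome(spec)
        reads = simulate_survey_reads(
            genome, ReadProfile(coverage_fraction=0.05), seed=63, truth=truth)
        refs = [("anchor", truth.attrs["masters"]["rdna"])]
        mined = {r.read_id for r in rp.mine_rdna_reads(reads, refs)}
        rdna_reads = {r.read_id for r in reads
                      if read_origin(r.read_id)["family_id"] == "rdna"}
        assert rdna_reads
        assert len(mined & rdna_reads) / len(rdna_reads) >= 0.95


class TestAlignmentAndTrim:
    def test_tiling_reads_give_full_coverage_no_variants(self, rng):
        anchor = random_seq(rng, 1200)
        reads = [SurveyRead("r0", anchor[0:700]),
                 SurveyRead("r1", anchor[500:1200])]
        block = rp.build_its_alignment(reads, [("anchor", anchor)])
        assert block.rows[0] == anchor          # anchor row ungapped
        assert block.row("r0")[:700] == anchor[:700]
        assert block.row("r1")[500:] == anchor[500:]

    def test_single_substitution_yields_one_variant_column(self, rng):
        anchor = random_seq(rng, 800)
        seq = list(anchor[100:600])
        seq[250] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[250]]
        block = rp.build_its_alignment([SurveyRead("r0", "".join(seq))],
                                       [("anchor", anchor)])
        diffs = [k for k, (x, y) in enumerate(zip(block.rows[0],
                                                  block.row("r0")))
                 if y not in ("-",) and x != y]
        assert diffs == [350]

    def test_gate_failures_raise_when_nothing_passes(self, rng):
        anchor = random_seq(rng, 800)
        with pytest.raises(ValueError, match="gate"):
            rp.build_its_alignment([SurveyRead("junk", random_seq(rng, 300))],
                                   [("anchor", anchor)])

    def test_gap_column_threshold_is_strict(self, rng):
        """A column gapped in 100% of rows is removed; at exactly 95% kept."""
        anchor = random_seq(rng, 100)
        n_reads = 19  # 19 reads + anchor = 20 rows
        reads = [SurveyRead(f"r{i:02d}", anchor) for i in range(n_reads)]
        block = rp.build_its_alignment(reads, [("anchor", anchor)])
        # first column gapped in 19/20 rows = 95% -> kept under strict >
        rows95 = [anchor] + ["-" + anchor[1:]] * n_reads
        blk = rp.ITSBlock(ids=block.ids, origins=block.origins, rows=rows95,
                          anchor_pos=block.anchor_pos,
                          insert_before=block.insert_before,
                          coverage=block.coverage, anchor_id="anchor")
        kept = rp.trim_block(blk, (0, 100), drop_n_reads=False)
        assert kept.n_columns == 100
        # one more gap: 20/20 = 100% > 95% -> removed
        rows100 = ["-" + anchor[1:]] * (n_reads + 1)
        blk = rp.ITSBlock(ids=block.ids, origins=block.origins, rows=rows100,
                          anchor_pos=block.anchor_pos,
                          insert_before=block.insert_before,
                          coverage=block.coverage, anchor_id="anchor")
        assert rp.trim_block(blk, (0, 100),
                             drop_n_reads=False).n_columns == 99

    def test_trim_is_idempotent_and_recovers_planted_region(self, rng):
        hap_a, hap_b, sites = two_haplotypes(rng)
        reads = reads_from(rng, hap_a, 5, label="a") + \
            reads_from(rng, hap_b, 4, label="b")
        block = rp.build_its_alignment(reads, [("hapA", hap_a),
                                               ("hapB", hap_b)],
                                       anchor_id="hapA")
        trimmed = rp.trim_block(block, (1000, 1150))
        assert trimmed.n_columns == 150
        assert len(trimmed.ids) == 11       # 2 refs + 9 spanning reads
        again = rp.trim_block(trimmed, (1000, 1150))
        assert again.rows == trimmed.rows and again.ids == trimmed.ids
        # planted variant columns are exactly the haplotype differences
        a_row, b_row = trimmed.row("hapA"), trimmed.row("hapB")
        diff_cols = [trimmed.anchor_pos[k]
                     for k, (x, y) in enumerate(zip(a_row, b_row)) if x != y]
        assert diff_cols == sites

    def test_region_longer_than_alignment_rejected(self, rng):
        anchor = random_seq(rng, 300)
        block = rp.build_its_alignment([SurveyRead("r0", anchor)],
                                       [("anchor", anchor)])
        with pytest.raises(ValueError, match="region"):
            rp.trim_block(block, (0, 500))


class TestClassify:
    def _block(self, rng, n_a=10, n_b=9, error=0.0):
        hap_a, hap_b, _ = two_haplotypes(rng)
        reads = reads_from(rng, hap_a, n_a, error=error, label="a") + \
            reads_from(rng, hap_b, n_b, error=error, label="b")
        block = rp.build_its_alignment(reads, [("hapA", hap_a),
                                               ("hapB", hap_b)],
                                       anchor_id="hapA")
        return rp.trim_block(block, (1000, 1150))

    def test_read_identical_to_haplotype_assigned_distance_zero(self, rng):
        block = self._block(rng)
        calls, tallies = rp.classify_parentage(block, ["hapA", "hapB"])
        a_calls = [c for c in calls if c.read_id.startswith("rda")]
        assert all(c.assigned_haplotype == "hapA" and c.distance_to_best == 0
                   for c in a_calls)
        assert tallies == {"hapA": 10, "hapB": 9}

    def test_equidistant_read_is_ambiguous(self, rng):
        hap_a, hap_b, sites = two_haplotypes(rng, n_sites=6)
        # chimeric read: first three variant sites from A, last three from B
        chimera = list(hap_a[750:1250])
        for s in sites[3:]:
            chimera[s - 750] = hap_b[s]
        reads = [SurveyRead("chimera", "".join(chimera))]
        block = rp.build_its_alignment(reads, [("hapA", hap_a),
                                               ("hapB", hap_b)],
                                       anchor_id="hapA")
        calls, tallies = rp.classify_parentage(
            rp.trim_block(block, (1000, 1150)), ["hapA", "hapB"])
        assert calls[0].assigned_haplotype == "ambiguous"
        assert tallies == {"ambiguous": 1}

    def test_identical_references_rejected(self, rng):
        anchor = random_seq(rng, 800)
        block = rp.build_its_alignment(
            [SurveyRead("r0", anchor)],
            [("hapA", anchor), ("hapB", anchor)], anchor_id="hapA")
        with pytest.raises(ValueError, match="discriminating"):
            rp.classify_parentage(block, ["hapA", "hapB"])

    def test_row_order_invariance(self, rng):
        block = self._block(rng)
        perm = list(range(len(block.ids)))
        np.random.default_rng(0).shuffle(perm)
        shuffled = rp.ITSBlock(
            ids=[block.ids[i] for i in perm],
            origins=[block.origins[i] for i in perm],
            rows=[block.rows[i] for i in perm],
            anchor_pos=block.anchor_pos, insert_before=block.insert_before,
            coverage=block.coverage, anchor_id=block.anchor_id)
        _, t1 = rp.classify_parentage(block, ["hapA", "hapB"])
        _, t2 = rp.classify_parentage(shuffled, ["hapA", "hapB"])
        assert t1 == t2


class TestNexus:
    def test_dimensions_and_round_trip(self, rng, tmp_path):
        hap_a, hap_b, _ = two_haplotypes(rng)
        reads = reads_from(rng, hap_a, 2, label="a") + \
            reads_from(rng, hap_b, 1, label="b")
        block = rp.trim_block(
            rp.build_its_alignment(reads, [("hapA", hap_a), ("hapB", hap_b)],
                                   anchor_id="hapA"), (1000, 1150))
        path = rp.write_nexus(block, tmp_path / "b.nex")
        text = path.read_text()
        assert f"ntax={len(block.ids)}" in text.lower().replace(" ", "")
        assert "nchar=150" in text.lower().replace(" ", "")
        back = rp.read_nexus(path)
        assert {i: r for i, r in zip(block.ids, block.rows)} == back

    def test_ids_with_spaces_round_trip(self, tmp_path):
        block = rp.ITSBlock(
            ids=["taxon one", "taxon two"], origins=["read", "read"],
            rows=["ACGT", "ACGA"], anchor_pos=[0, 1, 2, 3],
            insert_before=[None] * 4,
            coverage={"taxon one": (0, 4), "taxon two": (0, 4)},
            anchor_id="taxon one")
        path = rp.write_nexus(block, tmp_path / "s.nex")
        back = rp.read_nexus(path)
        assert back == {"taxon one": "ACGT", "taxon two": "ACGA"}
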