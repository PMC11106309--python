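"""AIRR QC rules, CDR annotation, insert extraction and splits."""

import numpy as np
import pandas as pd
import pytest

from tcrlatent.airr import (AnnotationError, CoordinateError, annotate_cdrs,
                            assemble_feature, dedup_and_split, extract_insert,
                            mean_insert_physchem, qc_filter)


def make_record(**overrides):
    rec = {
        "locus": "TRB", "productive": True, "vj_in_frame": True,
        "stop_codon": False, "junction_aa": "CASSIRSSYEQYF",
        "v_call": "TRBV19*01", "j_call": "TRBJ2-7*01",
        "cdr3": "TGTGCCAGTAGTATTCGCAGCAGCTACGAGCAGTACTTC",
        "cdr3_start": 10, "cdr3_end": 48,
        "v_sequence_end": 21, "j_sequence_start": 31,
    }
    rec.update(overrides)
    return rec


class TestQCFilter:
    def test_clean_record_retained(self):
        passed, log = qc_filter(pd.DataFrame([make_record()]))
        assert len(passed) == 1
        assert log["passed"] == 1

    @pytest.mark.parametrize("override", [
        {"junction_aa": "CSSYF"},              # length 5 < 7
        {"junction_aa": "C" + "A" * 23 + "F"},  # length 25 >= 24
        {"junction_aa": "AASSIRSSYEQYF"},       # no leading C
        {"junction_aa": "CASSIRSSYEQYA"},       # no trailing F
        {"junction_aa": "CASSXRSSYEQYF"},       # contains X
        {"junction_aa": "CASSURSSYEQYF"},       # contains U
        {"junction_aa": "CASS*RSSYEQYF"},       # contains stop
        {"productive": False},
        {"vj_in_frame": False},
        {"stop_codon": True},
        {"v_call": "TRBV6-2,TRBV6-3"},          # two genes
        {"v_sequence_end": np.nan},
        {"junction_aa": None},
    ])
    def test_bad_record_removed(self, override):
        passed, _ = qc_filter(pd.DataFrame([make_record(**override)]))
        assert len(passed) == 0

    def test_multi_allele_single_gene_collapses(self):
        passed, _ = qc_filter(pd.DataFrame(
            [make_record(v_call="TRBV19*01,TRBV19*02")]))
        assert len(passed) == 1
        assert passed["v_gene"].iloc[0] == "TRBV19"

    def test_boundary_junction_lengths(self):
        ok7 = make_record(junction_aa="CASSYQF")          # length 7 kept
        ok23 = make_record(junction_aa="C" + "A" * 21 + "F")  # length 23 kept
        passed, _ = qc_filter(pd.DataFrame([ok7, ok23]))
        assert len(passed) == 2

    def test_idempotent(self, small_repertoire):
        once, _ = qc_filter(small_repertoire)
        twice, _ = qc_filter(once)
        pd.testing.assert_frame_equal(
            once.reset_index(drop=True), twice.reset_index(drop=True))

    def test_rejection_log_counts(self):
        records = pd.DataFrame([make_record(),
                                make_record(junction_aa="CSSYF"),
                                make_record(productive=False)])
        passed, log = qc_filter(records)
        assert log["input"] == 3
        assert log["flags"] == 1
        assert log["junction_length"] == 1
        assert log["passed"] == 1


class TestAnnotateCDRs:
    GERMLINE = pd.DataFrame({"v_gene": ["TRBV19"], "cdr1_aa": ["LNH"],
                             "cdr2_aa": ["SVGAGI"]})

    def test_lookup_after_allele_collapse(self):
        rec = pd.DataFrame([make_record(v_call="TRBV19*02")])
        passed, _ = qc_filter(rec)
        out = annotate_cdrs(passed, self.GERMLINE)
        assert out["cdr2_aa"].iloc[0] == "SVGAGI"
        assert out["cdr1_aa"].iloc[0] == "LNH"

    def test_alleles_of_same_gene_get_identical_cdrs(self):
        recs = pd.DataFrame([make_record(v_call="TRBV19*01"),
                             make_record(v_call="TRBV19*03")])
        passed, _ = qc_filter(recs)
        out = annotate_cdrs(passed, self.GERMLINE)
        assert out["cdr2_aa"].nunique() == 1

    def test_unknown_gene_raises_with_name(self):
        rec = pd.DataFrame([make_record(v_call="TRBV99*01")])
        with pytest.raises(AnnotationError, match="TRBV99"):
            annotate_cdrs(rec, self.GERMLINE)


class TestExtractInsert:
    def test_interval_enumeration_example(self):
        # 6 codons at nt 10-27; germline V ends at 15, J starts at 22:
        # codons 16-18 and 19-21 are fully non-germline -> 2 residues
        nt = "TGTGCC" + "AGTATT" + "TACTTC"
        rec = make_record(cdr3=nt, cdr3_start=10, cdr3_end=27,
                          v_sequence_end=15, j_sequence_start=22)
        insert = extract_insert(rec)
        assert insert == "SI"

    def test_no_nongermline_nucleotide_gives_empty_insert(self):
        rec = make_record(cdr3="TGTGCCAGT", cdr3_start=10, cdr3_end=18,
                          v_sequence_end=13, j_sequence_start=14)
        assert extract_insert(rec) == ""

    def test_single_nongermline_nucleotide_selects_one_codon(self):
        # only nt 14 is non-germline; it lies in codon 13-15 (2nd codon)
        rec = make_record(cdr3="TGTGCCAGT", cdr3_start=10, cdr3_end=18,
                          v_sequence_end=13, j_sequence_start=15)
        assert extract_insert(rec) == "A"

    def test_brute_force_oracle_on_random_coordinates(self):
        rng = np.random.default_rng(5)
        nt_alpha = "ACGT"
        for _ in range(50):
            n_codons = int(rng.integers(3, 8))
            length = 3 * n_codons
            start = int(rng.integers(1, 20))
            end = start + length - 1
            nt = "".join(rng.choice(list(nt_alpha), size=length))
            v_end = int(rng.integers(start - 1, end + 1))
            j_start = int(rng.integers(v_end + 1, end + 2))
            rec = make_record(cdr3=nt, cdr3_start=start, cdr3_end=end,
                              v_sequence_end=v_end, j_sequence_start=j_start)
            try:
                got = extract_insert(rec)
            except CoordinateError:
                continue
            from Bio.Seq import Seq
            aa = str(Seq(nt).translate())
            expected = "".join(
                aa[k] for k in range(n_codons)
                if any(v_end < p < j_start
                       for p in range(start + 3 * k, start + 3 * k + 3)))
            assert got == expected

    def test_frame_violation_raises(self):
        rec = make_record(cdr3_start=10, cdr3_end=20)  # 11 nt, not /3
        with pytest.raises(CoordinateError):
            extract_insert(rec)

    def test_reversed_coordinates_raise(self):
        rec = make_record(cdr3_start=30, cdr3_end=20)
        with pytest.raises(CoordinateError):
            extract_insert(rec)


class TestAssembleFeature:
    REC = {"junction_aa": "CASSIRSSYEQYF", "cdr1_aa": "LNH",
           "cdr2_aa": "SVGAGI"}

    def test_cdr23_join(self):
        assert assemble_feature(self.REC, feature="CDR2+3") == \
            "SVGAGI-CASSIRSSYEQYF"

    def test_cdr123_join_order(self):
        assert assemble_feature(self.REC, feature="CDR1+2+3") == \
            "LNH-SVGAGI-CASSIRSSYEQYF"

    def test_cdr3_unchanged(self):
        assert assemble_feature(self.REC, feature="CDR3") == "CASSIRSSYEQYF"

    def test_length_cap_is_strict(self):
        # CDR2(8) + gap + CDR3(19) = 28 -> excluded; 27 -> kept
        rec28 = {"cdr2_aa": "A" * 8, "junction_aa": "C" + "A" * 17 + "F"}
        rec27 = {"cdr2_aa": "A" * 7, "junction_aa": "C" + "A" * 17 + "F"}
        assert assemble_feature(rec28, feature="CDR2+3") is None
        assert assemble_feature(rec27, feature="CDR2+3") is not None

    def test_paired_chains_joined_by_gap(self):
        tra = {"junction_aa": "CAVRF", "cdr2_aa": "SSGFQ", "cdr1_aa": "TSG"}
        out = assemble_feature(self.REC, chains="paired", feature="CDR2+3",
                               record_tra=tra)
        assert out == "SVGAGI-CASSIRSSYEQYF-SSGFQ-CAVRF"

    def test_missing_annotation_raises(self):
        with pytest.raises(AnnotationError):
            assemble_feature({"junction_aa": "CASSF"}, feature="CDR2+3")


class TestDedupAndSplit:
    def make_features(self, n):
        return pd.DataFrame({"feature_text": [f"SVGAGI-CASS{i:04d}F"
                                              for i in range(n)]})

    def test_ten_unique_split_8_1_1(self):
        train, val, test = dedup_and_split(self.make_features(10), seed=0)
        assert (len(train), len(val), len(test)) == (8, 1, 1)

    def test_duplicates_removed_before_split(self):
        df = pd.concat([self.make_features(10)] * 3, ignore_index=True)
        train, val, test = dedup_and_split(df, seed=0)
        union = pd.concat([train, val, test])
        assert union["feature_text"].is_unique
        assert len(union) == 10

    def test_same_seed_identical_membership(self):
        df = self.make_features(50)
        a = dedup_and_split(df, seed=7)
        b = dedup_and_split(df, seed=7)
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x, y)

    def test_splits_disjoint(self):
        train, val, test = dedup_and_split(self.make_features(100), seed=1)
        sets = [set(s["feature_text"]) for s in (train, val, test)]
        assert not (sets[0] & sets[1]) and not (sets[0] & sets[2]) \
            and not (sets[1] & sets[2])

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            dedup_and_split(self.make_features(0), seed=0)


class TestMeanInsertPhyschem:
    def test_single_residue_returns_its_descriptors(self, feature_table):
        vec = mean_insert_physchem("W", feature_table)
        assert np.allclose(vec, feature_table.vector("W")[:7])

    def test_empty_insert_is_missing(self, feature_table):
        assert mean_insert_physchem("", feature_table) is None

    def test_two_residue_mean_matches_hand_average(self, feature_table):
        vec = mean_insert_physchem("AW", feature_table)
        expected = (feature_table.vector("A")[:7]
                    + feature_table.vector("W")[:7]) / 2.0
        assert np.allclose(vec, expected)
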