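import dataclasses

import numpy as np
import pandas as pd
import pytest

import mrmediate as mm
from mrmediate.sumstats import (CANONICAL_HEADER, harmonized_to_sumstats,
                                is_palindromic)
from mrmediate.simulate import simulate_study

from conftest import make_sumstats


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


HEADER = "SNP\tCHR\tPOS\tEA\tOA\tEAF\tBETA\tSE\tP\tN\n"


class TestReadSumstats:
    def test_valid_rows_parsed(self, tmp_path):
        p = _write(tmp_path, "a.tsv", HEADER +
                   "rs1\t1\t100\tA\tG\t0.3\t0.1\t0.02\t1e-8\t5000\n"
                   "rs2\t2\t200\tT\tC\t0.4\t-0.2\t0.03\t1e-6\t5000\n")
        df, dropped = mm.read_sumstats(p)
        assert dropped == 0
        assert list(df["rsid"]) == ["rs1", "rs2"]
        assert df.loc[1, "beta"] == -0.2
        assert df["pos"].dtype == np.int64

    def test_invalid_rows_dropped_and_counted(self, tmp_path):
        p = _write(tmp_path, "a.tsv", HEADER +
                   "rs1\t1\t100\tA\tG\t0.3\t0.1\t0.02\t1e-8\t5000\n"
                   "rs2\t1\t200\tA\tG\t0.3\t0.1\t0\t1e-8\t5000\n"      # se=0
                   "rs3\t1\t300\tA\tA\t0.3\t0.1\t0.02\t1e-8\t5000\n"   # EA==OA
                   "rs4\t1\t400\tA\tG\t1.3\t0.1\t0.02\t1e-8\t5000\n"   # eaf>1
                   "rs5\t1\t500\tAT\tG\t0.3\t0.1\t0.02\t1e-8\t5000\n"  # indel
                   "rs6\t1\t600\tA\tG\t0.3\t0.1\t0.02\t0\t5000\n")     # p=0
        df, dropped = mm.read_sumstats(p)
        assert dropped == 5
        assert list(df["rsid"]) == ["rs1"]

    def test_missing_eaf_is_allowed(self, tmp_path):
        p = _write(tmp_path, "a.tsv", HEADER +
                   "rs1\t1\t100\tA\tG\tNA\t0.1\t0.02\t1e-8\t5000\n")
        df, dropped = mm.read_sumstats(p)
        assert dropped == 0
        assert np.isnan(df.loc[0, "eaf"])

    def test_column_map_redirects_headers(self, tmp_path):
        p = _write(tmp_path, "a.csv",
                   "variant,chromosome,bp,a1,a2,freq,effect,stderr,pv,num\n"
                   "rs1,1,100,A,G,0.3,0.1,0.02,1e-8,5000\n")
        cmap = {"rsid": "variant", "chrom": "chromosome", "pos": "bp",
                "effect_allele": "a1", "other_allele": "a2", "eaf": "freq",
                "beta": "effect", "se": "stderr", "pval": "pv", "n": "num"}
        df, dropped = mm.read_sumstats(p, column_map=cmap)
        assert dropped == 0 and df.loc[0, "beta"] == 0.1

    def test_missing_mandatory_column_is_hard_error(self, tmp_path):
        p = _write(tmp_path, "a.tsv",
                   "SNP\tCHR\tPOS\tEA\tOA\tEAF\tBETA\tSE\tP\n"
                   "rs1\t1\t100\tA\tG\t0.3\t0.1\t0.02\t1e-8\n")
        with pytest.raises(ValueError, match="missing mandatory column"):
            mm.read_sumstats(p)

    def test_empty_file_is_error(self, tmp_path):
        p = _write(tmp_path, "a.tsv", "")
        with pytest.raises(ValueError, match="empty"):
            mm.read_sumstats(p)

    def test_write_read_round_trip(self, tmp_path, clean_study):
        p = tmp_path / "x.tsv"
        mm.write_sumstats(clean_study.exposure, p)
        df, dropped = mm.read_sumstats(p)
        assert dropped == 0
        pd.testing.assert_frame_equal(
            df, clean_study.exposure.reset_index(drop=True),
            check_exact=False, rtol=1e-12)


class TestPalindromeDetection:
    def test_cases(self):
        assert is_palindromic("A", "T") and is_palindromic("G", "C")
        assert not is_palindromic("A", "G") and not is_palindromic("C", "T")


def _one_snp_pair(ea_x, oa_x, ea_y, oa_y, eaf_x=0.3, eaf_y=0.3,
                  beta_y=0.05):
    exp = make_sumstats([("rs1", "1", 100, ea_x, oa_x, eaf_x, 0.2, 0.02,
                          1e-9, 7000)])
    out = make_sumstats([("rs1", "1", 100, ea_y, oa_y, eaf_y, beta_y, 0.01,
                          0.5, 250000)])
    return exp, out


class TestHarmonize:
    def test_identical_alleles_kept(self):
        h = mm.harmonize(*_one_snp_pair("A", "G", "A", "G"))
        assert h.counts()["kept"] == 1
        assert h.table.loc[0, "beta_outcome"] == 0.05

    def test_swapped_alleles_flip_beta_and_eaf(self):
        h = mm.harmonize(*_one_snp_pair("A", "G", "G", "A", eaf_y=0.7))
        row = h.table.iloc[0]
        assert row["action_taken"] == "flipped"
        assert row["beta_outcome"] == -0.05
        assert row["eaf_outcome"] == pytest.approx(0.3)

    def test_strand_complement_resolved(self):
        # exposure A/G, outcome reported on the other strand as T/C
        h = mm.harmonize(*_one_snp_pair("A", "G", "T", "C"))
        assert h.table.loc[0, "action_taken"] == "kept"
        assert h.table.loc[0, "beta_outcome"] == 0.05

    def test_complement_swapped_flips(self):
        h = mm.harmonize(*_one_snp_pair("A", "G", "C", "T", eaf_y=0.7))
        row = h.table.iloc[0]
        assert row["action_taken"] == "flipped"
        assert row["beta_outcome"] == -0.05

    def test_irreconcilable_alleles_excluded(self):
        h = mm.harmonize(*_one_snp_pair("A", "G", "A", "C"))
        assert h.table.loc[0, "action_taken"] == "excluded_mismatch"
        assert h.n_kept == 0

    def test_palindrome_near_half_excluded(self):
        h = mm.harmonize(*_one_snp_pair("A", "T", "A", "T",
                                        eaf_x=0.5, eaf_y=0.5))
        assert h.table.loc[0, "action_taken"] == "excluded_palindromic"

    def test_palindrome_informative_eaf_kept(self):
        h = mm.harmonize(*_one_snp_pair("A", "T", "A", "T",
                                        eaf_x=0.2, eaf_y=0.22))
        assert h.table.loc[0, "action_taken"] == "kept"

    def test_palindrome_opposite_sides_excluded(self):
        h = mm.harmonize(*_one_snp_pair("A", "T", "A", "T",
                                        eaf_x=0.2, eaf_y=0.8))
        assert h.table.loc[0, "action_taken"] == "excluded_palindromic"

    def test_palindrome_window_half_excludes_all(self):
        h = mm.harmonize(*_one_snp_pair("A", "T", "A", "T",
                                        eaf_x=0.05, eaf_y=0.05),
                         palindrome_eaf_window=0.5)
        assert h.table.loc[0, "action_taken"] == "excluded_palindromic"

    def test_eaf_discrepancy_excluded(self):
        h = mm.harmonize(*_one_snp_pair("A", "G", "A", "G",
                                        eaf_x=0.1, eaf_y=0.45))
        assert h.table.loc[0, "action_taken"] == "excluded_eaf"

    def test_no_overlap_is_error(self):
        exp = make_sumstats([("rs1", "1", 100, "A", "G", 0.3, 0.2, 0.02,
                              1e-9, 7000)])
        out = make_sumstats([("rs2", "1", 200, "A", "G", 0.3, 0.1, 0.01,
                              0.5, 250000)])
        with pytest.raises(ValueError, match="no overlapping"):
            mm.harmonize(exp, out)

    def test_action_counts_partition_the_merge(self, clean_study):
        s = clean_study
        h = mm.harmonize(s.exposure, s.outcome)
        merged = set(s.exposure["rsid"]) & set(s.outcome["rsid"])
        assert sum(h.counts().values()) == len(merged) == len(h.table)

    def test_idempotent_on_already_harmonized_tables(self, clean_study):
        s = clean_study
        h1 = mm.harmonize(s.exposure, s.outcome)
        exp2, out2 = harmonized_to_sumstats(h1)
        h2 = mm.harmonize(exp2, out2)
        assert h2.counts()["flipped"] == 0
        assert h2.n_kept == h1.n_kept
        k1 = h1.kept_table.sort_values("rsid").reset_index(drop=True)
        k2 = h2.kept_table.sort_values("rsid").reset_index(drop=True)
        np.testing.assert_allclose(k1["beta_outcome"], k2["beta_outcome"])
        np.testing.assert_allclose(k1["beta_exposure"], k2["beta_exposure"])

    def test_flips_do_not_change_kept_effect_pairs(self, presets):
        """Allele bookkeeping invariance: the same study emitted with and
        without allele-swapped rows harmonizes to identical effect pairs."""
        cfg = presets["clean"]
        flipped = simulate_study(dataclasses.replace(cfg, seed=101))
        plain = simulate_study(dataclasses.replace(cfg, seed=101,
                                                   flip_fraction=0.0))
        h_f = mm.harmonize(flipped.exposure, flipped.outcome)
        h_p = mm.harmonize(plain.exposure, plain.outcome)
        kf = h_f.kept_table.set_index("rsid")
        kp = h_p.kept_table.set_index("rsid")
        shared = kf.index.intersection(kp.index)
        assert len(shared) == len(kf)
        for col in ("beta_exposure", "beta_outcome", "se_outcome"):
            np.testing.assert_allclose(kf.loc[shared, col],
                                       kp.loc[shared, col])

    def test_harmonized_set_write_read_round_trip(self, tmp_path,
                                                  clean_harmonized):
        p = tmp_path / "h.tsv"
        clean_harmonized.write(p)
        back = mm.HarmonizedSet.read(p)
        assert back.n_kept == clean_harmonized.n_kept
        np.testing.assert_allclose(back.arrays()[2],
                                   clean_harmonized.arrays()[2])
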