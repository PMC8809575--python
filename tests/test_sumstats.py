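"""Summary-statistics I/O, instrument selection, clumping, harmonization."""

import numpy as np
import pandas as pd
import pytest

from mrmediate import (LDMatrix, harmonize, instrument_strength, ld_clump,
                       read_sumstats, select_instruments, write_sumstats)
from mrmediate.sumstats import (ConfigurationError, EmptyInstrumentError,
                                cross_trait_effect_correlation)

from conftest import make_table


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

class TestReadWrite:
    def test_roundtrip_identity(self, tmp_path):
        ss = make_table(["rs1", "rs2", "rs3"], beta=[0.1, -0.2, 0.05],
                        se=[0.02, 0.03, 0.01], eaf=[0.1, 0.4, 0.25])
        path = tmp_path / "ss.tsv"
        write_sumstats(ss, path)
        back = read_sumstats(path)
        assert back.equals(ss)

    def test_dialect_mapping_and_case(self, tmp_path):
        raw = pd.DataFrame({"SNP": ["rs1"], "EA": ["a"], "OA": ["g"],
                            "FRQ": [0.2], "B": [0.1], "SE": [0.02],
                            "P": [1e-6], "N": [5000]})
        path = tmp_path / "raw.tsv"
        raw.to_csv(path, sep="\t", index=False)
        ss = read_sumstats(path, dialect={"variant_id": "SNP",
                                          "effect_allele": "EA",
                                          "other_allele": "OA", "eaf": "FRQ",
                                          "beta": "B", "se": "SE",
                                          "pval": "P", "n": "N"})
        assert list(ss.table["effect_allele"]) == ["A"]
        assert len(ss) == 1

    def test_unmapped_required_column_is_config_error(self, tmp_path):
        pd.DataFrame({"variant_id": ["rs1"]}).to_csv(tmp_path / "x.tsv",
                                                     sep="\t", index=False)
        with pytest.raises(ConfigurationError):
            read_sumstats(tmp_path / "x.tsv")

    def test_invalid_rows_dropped(self, tmp_path):
        raw = pd.DataFrame({
            "variant_id": ["rs1", "rs2", "rs3", "rs4"],
            "effect_allele": ["A", "A", "X", "A"],
            "other_allele": ["G", "G", "G", "A"],
            "eaf": [0.2] * 4,
            "beta": [0.1, np.nan, 0.1, 0.1],
            "se": [0.02, 0.02, 0.02, 0.02],
            "pval": [0.5] * 4, "n": [100] * 4,
        })
        raw.loc[0, "se"] = 0.0   # non-positive se also rejected
        path = tmp_path / "bad.tsv"
        raw.to_csv(path, sep="\t", index=False)
        ss = read_sumstats(path)
        assert len(ss) == 0      # every row violates one rule


# ---------------------------------------------------------------------------
# instrument selection
# ---------------------------------------------------------------------------

class TestSelectInstruments:
    def test_de_novo_threshold(self):
        ss = make_table(["rs1", "rs2"], beta=[0.1, 0.1], se=[0.01, 0.01],
                        pval=[1e-9, 1e-7])
        kept = select_instruments(ss, mode="de_novo", p_threshold=5e-8)
        assert list(kept.variant_ids) == ["rs1"]

    def test_external_list_ignores_pvalues(self):
        ss = make_table(["rs1", "rs2", "rs3"], beta=[0.1] * 3, se=[0.05] * 3,
                        pval=[0.5, 0.5, 0.5])
        kept = select_instruments(ss, mode="external_list",
                                  external_ids=["rs1", "rs3"])
        assert sorted(kept.variant_ids) == ["rs1", "rs3"]

    def test_external_list_absent_id(self):
        ss = make_table(["rs1"], beta=[0.1], se=[0.05])
        kept = select_instruments(ss, mode="external_list",
                                  external_ids=["rs1", "rs99"])
        assert list(kept.variant_ids) == ["rs1"]

    def test_empty_result_raises(self):
        ss = make_table(["rs1"], beta=[0.1], se=[0.05], pval=[0.9])
        with pytest.raises(EmptyInstrumentError, match="de_novo"):
            select_instruments(ss, mode="de_novo", p_threshold=5e-8)


# ---------------------------------------------------------------------------
# LD clumping
# ---------------------------------------------------------------------------

class TestClump:
    def test_greedy_trace(self):
        # rs1 (best p) removes rs2; rs3 independent -> kept
        ss = make_table(["rs1", "rs2", "rs3"], beta=[0.1] * 3, se=[0.01] * 3,
                        pval=[1e-10, 1e-9, 1e-8])
        r2 = np.eye(3)
        r2[0, 1] = r2[1, 0] = 0.5
        kept = ld_clump(ss, LDMatrix(["rs1", "rs2", "rs3"], r2), 0.001)
        assert sorted(kept.variant_ids) == ["rs1", "rs3"]

    def test_identity_matrix_keeps_all(self):
        ss = make_table(["rs1", "rs2", "rs3"], beta=[0.1] * 3, se=[0.01] * 3,
                        pval=[1e-10, 1e-9, 1e-8])
        kept = ld_clump(ss, LDMatrix.identity(["rs1", "rs2", "rs3"]), 0.001)
        assert len(kept) == 3

    def test_complete_ld_keeps_best(self):
        ss = make_table(["rs1", "rs2", "rs3"], beta=[0.1] * 3, se=[0.01] * 3,
                        pval=[1e-8, 1e-10, 1e-9])
        kept = ld_clump(ss, LDMatrix(["rs1", "rs2", "rs3"], np.ones((3, 3))), 0.001)
        assert list(kept.variant_ids) == ["rs2"]

    def test_missing_variant_raises(self):
        ss = make_table(["rs1", "rs9"], beta=[0.1] * 2, se=[0.01] * 2)
        with pytest.raises(KeyError, match="rs9"):
            ld_clump(ss, LDMatrix.identity(["rs1"]), 0.001)

    def test_tie_break_lexicographic_and_idempotence(self):
        ss = make_table(["rsB", "rsA"], beta=[0.1] * 2, se=[0.01] * 2,
                        pval=[1e-8, 1e-8])
        ld = LDMatrix(["rsA", "rsB"], np.ones((2, 2)))
        kept = ld_clump(ss, ld, 0.001)
        assert list(kept.variant_ids) == ["rsA"]
        again = ld_clump(kept, ld, 0.001)
        assert list(again.variant_ids) == ["rsA"]

    def test_output_pairwise_independent(self):
        rng = np.random.default_rng(3)
        L = 12
        ids = [f"rs{i}" for i in range(L)]
        A = rng.uniform(size=(L, L))
        r2 = np.clip((A + A.T) / 2, 0, 1) ** 2
        np.fill_diagonal(r2, 1.0)
        ss = make_table(ids, beta=rng.normal(size=L) * 0.1,
                        se=np.full(L, 0.01), pval=rng.uniform(size=L))
        ld = LDMatrix(ids, r2)
        kept = ld_clump(ss, ld, 0.1)
        kept_ids = list(kept.variant_ids)
        for i, a in enumerate(kept_ids):
            for b in kept_ids[i + 1:]:
                assert ld.lookup(a, b) <= 0.1
        # clumping a clumped table is a no-op
        assert list(ld_clump(kept, ld, 0.1).variant_ids) == kept_ids


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------

class TestHarmonize:
    def test_allele_flip(self):
        exp = make_table(["rs1"], beta=[0.10], se=[0.02], eaf=[0.3],
                         effect_allele="A", other_allele="G")
        out = make_table(["rs1"], beta=[0.05], se=[0.02], eaf=[0.7],
                         effect_allele="G", other_allele="A")
        h = harmonize(exp, out).kept()
        assert np.isclose(h.loc[0, "beta_outcome"], -0.05)
        assert np.isclose(h.loc[0, "eaf_outcome"], 0.3)

    def test_palindromic_low_maf_kept_aligned(self):
        exp = make_table(["rs1"], beta=[0.1], se=[0.02], eaf=[0.10],
                         effect_allele="A", other_allele="T")
        out = make_table(["rs1"], beta=[0.05], se=[0.02], eaf=[0.12],
                         effect_allele="A", other_allele="T")
        h = harmonize(exp, out)
        row = h.kept().iloc[0]
        assert row["beta_outcome"] == 0.05

    def test_palindromic_high_maf_excluded(self):
        out = make_table(["rs1", "rs2"], beta=[0.05, 0.02], se=[0.02, 0.02],
                         eaf=[0.45, 0.3], effect_allele=["C", "A"],
                         other_allele=["G", "G"])
        exp2 = make_table(["rs1", "rs2"], beta=[0.1, 0.1], se=[0.02, 0.02],
                          eaf=[0.45, 0.3], effect_allele=["C", "A"],
                          other_allele=["G", "G"])
        h = harmonize(exp2, out)
        flags = dict(zip(h.table["variant_id"], h.table["exclusion_flag"]))
        assert flags["rs1"] == "palindromic_ambiguous"
        assert flags["rs2"] == "kept"
        # a table that is ALL ambiguous palindromes cannot be harmonized
        exp1 = make_table(["rs1"], beta=[0.1], se=[0.02], eaf=[0.45],
                          effect_allele="C", other_allele="G")
        out1 = make_table(["rs1"], beta=[0.05], se=[0.02], eaf=[0.45],
                          effect_allele="C", other_allele="G")
        with pytest.raises(EmptyInstrumentError):
            harmonize(exp1, out1)

    def test_palindromic_discordant_frequency_flipped(self):
        exp = make_table(["rs1"], beta=[0.1], se=[0.02], eaf=[0.10],
                         effect_allele="A", other_allele="T")
        out = make_table(["rs1"], beta=[0.05], se=[0.02], eaf=[0.90],
                         effect_allele="A", other_allele="T")
        row = harmonize(exp, out).kept().iloc[0]
        assert np.isclose(row["beta_outcome"], -0.05)
        assert np.isclose(row["eaf_outcome"], 0.10)

    def test_incompatible_and_missing_flags(self):
        exp = make_table(["rs1", "rs2", "rs3"], beta=[0.1, 0.1, 0.1],
                         se=[0.02, 0.02, 0.02],
                         effect_allele=["A", "A", "A"],
                         other_allele=["G", "G", "G"])
        out = make_table(["rs1", "rs3"], beta=[0.05, 0.02], se=[0.02, 0.02],
                         effect_allele=["A", "A"], other_allele=["C", "G"])
        h = harmonize(exp, out)
        flags = dict(zip(h.table["variant_id"], h.table["exclusion_flag"]))
        assert flags["rs1"] == "incompatible_alleles"
        assert flags["rs2"] == "missing_in_outcome"
        assert flags["rs3"] == "kept"

    def test_involution_under_outcome_reflip(self):
        rng = np.random.default_rng(11)
        L = 20
        ids = [f"rs{i}" for i in range(L)]
        ea = rng.choice(["A", "C"], size=L)
        oa = np.where(ea == "A", "G", "T")
        exp = make_table(ids, beta=rng.normal(0, 0.1, L), se=np.full(L, 0.02),
                         eaf=rng.uniform(0.05, 0.95, L),
                         effect_allele=list(ea), other_allele=list(oa))
        flip = rng.random(L) < 0.5
        out_ea = np.where(flip, oa, ea)
        out_oa = np.where(flip, ea, oa)
        beta_out = np.where(flip, -1, 1) * rng.normal(0, 0.05, L)
        eaf_out = rng.uniform(0.05, 0.95, L)
        out = make_table(ids, beta=list(beta_out), se=np.full(L, 0.02),
                         eaf=list(eaf_out), effect_allele=list(out_ea),
                         other_allele=list(out_oa))
        h1 = harmonize(exp, out).kept()
        # re-flip every outcome allele pair and harmonize again
        out2 = make_table(ids, beta=list(-beta_out), se=np.full(L, 0.02),
                          eaf=list(1 - eaf_out), effect_allele=list(out_oa),
                          other_allele=list(out_ea))
        h2 = harmonize(exp, out2).kept()
        assert list(h1["variant_id"]) == list(h2["variant_id"])
        assert np.allclose(h1["beta_outcome"], h2["beta_outcome"])
        assert np.allclose(h1["eaf_outcome"], h2["eaf_outcome"])


# ---------------------------------------------------------------------------
# instrument strength
# ---------------------------------------------------------------------------

class TestInstrumentStrength:
    def test_per_snp_f(self):
        ss = make_table(["rs1"], beta=[0.02], se=[0.004],
                        trait_type="continuous_sd")
        st = instrument_strength(ss)
        assert np.isclose(st.per_snp_f[0], 25.0)

    def test_combined_r2_additive(self):
        # two SNPs each explaining 0.9% on the SD scale
        beta = np.sqrt(0.009 / (2 * 0.3 * 0.7))
        ss = make_table(["rs1", "rs2"], beta=[beta, beta], se=[0.01, 0.01],
                        eaf=[0.3, 0.3], trait_type="continuous_sd")
        st = instrument_strength(ss)
        assert np.isclose(st.combined_r2, 0.018)

    def test_regression_form_f(self):
        # k=1, r²=0.5, n=6 -> F = 0.5*4/(0.5*1) = 4
        beta = np.sqrt(0.5 / (2 * 0.5 * 0.5))
        ss = make_table(["rs1"], beta=[beta], se=[0.5], eaf=[0.5], n=6,
                        trait_type="continuous_sd")
        st = instrument_strength(ss)
        assert np.isclose(st.regression_f, 4.0)

    def test_combined_r2_invariant_to_allele_flip(self):
        ss = make_table(["rs1", "rs2"], beta=[0.1, -0.2], se=[0.02, 0.03],
                        eaf=[0.2, 0.6], trait_type="continuous_sd")
        flipped = make_table(["rs1", "rs2"], beta=[-0.1, 0.2], se=[0.02, 0.03],
                             eaf=[0.8, 0.4], trait_type="continuous_sd")
        a = instrument_strength(ss).combined_r2
        b = instrument_strength(flipped).combined_r2
        assert np.isclose(a, b)

    def test_ordinal_r2_matches_study_scale(self):
        # 190 SNPs with mean chi-square 22.75 at n=244,207 give a combined
        # r2 of about 1.8% under the z²/(z²+n) rule
        L, F, n = 190, 22.75, 244_207
        se = 0.01
        beta = np.sqrt(F) * se
        ss = make_table([f"rs{i}" for i in range(L)], beta=[beta] * L,
                        se=[se] * L, n=n, trait_type="ordinal_category")
        st = instrument_strength(ss)
        assert 0.017 < st.combined_r2 < 0.019
        assert np.isclose(st.mean_f, F)


def test_cross_trait_effect_correlation_aligns_alleles():
    rng = np.random.default_rng(5)
    L = 40
    ids = [f"rs{i}" for i in range(L)]
    beta = rng.normal(0, 0.1, L)
    a = make_table(ids, beta=list(beta), se=np.full(L, 0.02),
                   effect_allele="A", other_allele="G")
    # same effects reported on the opposite allele
    b = make_table(ids, beta=list(-beta), se=np.full(L, 0.02),
                   effect_allele="G", other_allele="A")
    assert np.isclose(cross_trait_effect_correlation(a, b), 1.0)


def test_read_snp_list(tmp_path):
    path = tmp_path / "ids.txt"
    path.write_text("# instrument list\nrs1\n\nrs2\n")
    from mrmediate import read_snp_list
    assert read_snp_list(path) == ["rs1", "rs2"]
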