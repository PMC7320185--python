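"""Ingestion, validation, harmonization and SNP-filter behaviour."""

import numpy as np
import pandas as pd
import pytest

from smrcoloc.sumstats import (
    NoOverlapError,
    SumstatsError,
    apply_snp_filters,
    harmonize_pair,
    read_association_table,
    select_top_snp,
)
from .conftest import IDENTITY_DIALECT, make_sumstats


def write_tsv(df, path):
    df.to_csv(path, sep="\t", index=False)
    return path


class TestReadAssociationTable:
    def test_well_formed_rows_all_kept(self, tmp_path):
        df = make_sumstats([{"beta": 0.1, "se": 0.05}] * 3)
        out = read_association_table(write_tsv(df, tmp_path / "a.tsv"), IDENTITY_DIALECT)
        assert len(out) == 3
        assert out.attrs["n_dropped"] == 0

    def test_zero_se_row_dropped_and_counted(self, tmp_path):
        df = make_sumstats(
            [{"beta": 0.1, "se": 0.05}, {"beta": 0.1, "se": 0.0, "z": 1.0, "pvalue": 0.5}]
        )
        out = read_association_table(write_tsv(df, tmp_path / "a.tsv"), IDENTITY_DIALECT)
        assert len(out) == 1
        assert out.attrs["n_dropped"] == 1

    def test_z_filled_from_beta_over_se(self, tmp_path):
        df = make_sumstats([{"beta": 0.1, "se": 0.05}])
        df = df.drop(columns=["z"])
        out = read_association_table(write_tsv(df, tmp_path / "a.tsv"), IDENTITY_DIALECT)
        assert out.loc[0, "z"] == pytest.approx(2.0)

    def test_p_filled_from_z(self, tmp_path):
        from scipy.stats import norm

        df = make_sumstats([{"beta": 0.1, "se": 0.05}]).drop(columns=["pvalue"])
        out = read_association_table(write_tsv(df, tmp_path / "a.tsv"), IDENTITY_DIALECT)
        assert out.loc[0, "pvalue"] == pytest.approx(2 * norm.sf(2.0))

    def test_missing_mandatory_column_names_it(self, tmp_path):
        df = make_sumstats([{"beta": 0.1, "se": 0.05}]).drop(columns=["rsid"])
        with pytest.raises(SumstatsError, match="rsid"):
            read_association_table(write_tsv(df, tmp_path / "a.tsv"), IDENTITY_DIALECT)

    def test_empty_table_is_an_error(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("rsid\tchrom\tpos\n")
        with pytest.raises(SumstatsError, match="empty"):
            read_association_table(p, IDENTITY_DIALECT)

    def test_dialect_renames_columns(self, tmp_path):
        df = make_sumstats([{"beta": 0.1, "se": 0.05}])
        df = df.rename(columns={"rsid": "SNP", "beta": "b"})
        dialect = dict(IDENTITY_DIALECT, rsid="SNP", beta="b")
        out = read_association_table(write_tsv(df, tmp_path / "a.tsv"), dialect)
        assert list(out["rsid"]) == ["rs1"]


class TestHarmonizePair:
    def gwas(self):
        return make_sumstats([{"beta": 0.2, "se": 0.05}])

    def test_same_alleles_pass_through(self):
        eqtl = make_sumstats([{"beta": 0.3, "se": 0.1}])
        out = harmonize_pair(self.gwas(), eqtl)
        assert out.loc[0, "b_eqtl"] == pytest.approx(0.3)
        assert out.loc[0, "allele_effect"] == "A"

    def test_swapped_alleles_flip_effect(self):
        eqtl = make_sumstats(
            [{"beta": 0.3, "se": 0.1, "allele_effect": "G", "allele_other": "A"}]
        )
        out = harmonize_pair(self.gwas(), eqtl)
        assert out.loc[0, "b_eqtl"] == pytest.approx(-0.3)
        assert out.loc[0, "z_eqtl"] == pytest.approx(-3.0)

    def test_incompatible_allele_pair_dropped(self):
        gwas = make_sumstats([{"beta": 0.2, "se": 0.05}] * 2)
        eqtl = make_sumstats(
            [
                {"beta": 0.3, "se": 0.1},
                {"beta": 0.3, "se": 0.1, "allele_other": "C"},
            ]
        )
        out = harmonize_pair(gwas, eqtl)
        assert list(out["rsid"]) == ["rs1"]
        assert out.attrs["n_incompatible"] == 1

    def test_zero_overlap_raises(self):
        eqtl = make_sumstats([{"beta": 0.3, "se": 0.1, "rsid": "rsX"}])
        with pytest.raises(NoOverlapError):
            harmonize_pair(self.gwas(), eqtl)

    def test_double_flip_is_identity(self):
        eqtl = make_sumstats(
            [{"beta": 0.3, "se": 0.1, "allele_effect": "G", "allele_other": "A"}]
        )
        once = harmonize_pair(self.gwas(), eqtl)
        # re-harmonizing the aligned output against the GWAS is a no-op
        realigned = once.rename(
            columns={"b_eqtl": "beta", "se_eqtl": "se", "z_eqtl": "z",
                     "p_eqtl": "pvalue", "maf_eqtl": "maf"}
        )[["rsid", "chrom", "pos", "allele_effect", "allele_other",
           "beta", "se", "z", "pvalue", "maf"]]
        twice = harmonize_pair(self.gwas(), realigned.assign(n=100.0))
        assert twice.loc[0, "b_eqtl"] == pytest.approx(once.loc[0, "b_eqtl"])

    def test_palindromic_kept_by_default_dropped_on_request(self):
        gwas = make_sumstats([{"beta": 0.2, "se": 0.05, "allele_other": "T"}])
        eqtl = make_sumstats([{"beta": 0.3, "se": 0.1, "allele_other": "T"}])
        assert len(harmonize_pair(gwas, eqtl)) == 1
        with pytest.raises(NoOverlapError):
            harmonize_pair(gwas, eqtl, drop_palindromic=True)


class TestSnpFilters:
    def harmonized(self, rows):
        df = pd.DataFrame(rows)
        df["rsid"] = [f"rs{i + 1}" for i in range(len(df))]
        df["pos"] = 100 + np.arange(len(df))
        for col, default in (
            ("maf_gwas", 0.25), ("maf_eqtl", 0.25),
            ("z_gwas", 4.0), ("p_gwas", 1e-4),
        ):
            if col not in df:
                df[col] = default
        return df

    def test_low_eqtl_maf_excluded(self):
        rec = self.harmonized([{"maf_eqtl": 0.02}, {"maf_eqtl": 0.2}])
        analysis, _ = apply_snp_filters(rec)
        assert list(analysis["rsid"]) == ["rs2"]

    def test_z2_below_threshold_stays_in_analysis_only(self):
        rec = self.harmonized([{"z_gwas": np.sqrt(9.9)}, {"z_gwas": 4.0}])
        analysis, inst = apply_snp_filters(rec)
        assert len(analysis) == 2
        assert list(inst["rsid"]) == ["rs2"]

    def test_boundaries_are_inclusive(self):
        rec = self.harmonized([{"maf_gwas": 0.03, "maf_eqtl": 0.03,
                                "z_gwas": np.sqrt(10.0)}])
        analysis, inst = apply_snp_filters(rec)
        assert len(analysis) == 1 and len(inst) == 1

    def test_monotone_in_maf_and_subset_property(self):
        rng = np.random.default_rng(7)
        rec = self.harmonized(
            [{"maf_gwas": g, "maf_eqtl": e, "z_gwas": z}
             for g, e, z in zip(rng.uniform(0, 0.5, 50),
                                rng.uniform(0, 0.5, 50),
                                rng.normal(0, 4, 50))]
        )
        sizes = []
        for maf_min in (0.01, 0.03, 0.1, 0.3):
            analysis, inst = apply_snp_filters(rec, maf_min=maf_min)
            sizes.append(len(analysis))
            assert set(inst["rsid"]) <= set(analysis["rsid"])
        assert sizes == sorted(sizes, reverse=True)

    def test_missing_maf_fails_filter_unless_panel_supplies_it(self):
        rec = self.harmonized([{"maf_eqtl": np.nan}])
        analysis, _ = apply_snp_filters(rec)
        assert analysis.empty
        analysis, _ = apply_snp_filters(rec, panel_maf={"rs1": 0.2})
        assert len(analysis) == 1


class TestSelectTopSnp:
    def candidates(self, rows):
        df = pd.DataFrame(rows)
        return df

    def test_lowest_p_wins(self):
        df = self.candidates(
            [{"rsid": "a", "pos": 10, "p_gwas": 1e-8},
             {"rsid": "b", "pos": 20, "p_gwas": 1e-9}]
        )
        assert select_top_snp(df) == "b"

    def test_tie_broken_by_position_then_rsid(self):
        df = self.candidates(
            [{"rsid": "z", "pos": 200, "p_gwas": 1e-9},
             {"rsid": "a", "pos": 100, "p_gwas": 1e-9}]
        )
        assert select_top_snp(df) == "a"
        df2 = self.candidates(
            [{"rsid": "z", "pos": 100, "p_gwas": 1e-9},
             {"rsid": "a", "pos": 100, "p_gwas": 1e-9}]
        )
        assert select_top_snp(df2) == "a"

    def test_empty_candidates_signal_no_instrument(self):
        assert select_top_snp(pd.DataFrame(columns=["rsid", "pos", "p_gwas"])) is None
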