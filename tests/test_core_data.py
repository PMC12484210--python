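import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import iggsca as ig
from iggsca.core_data import (
    DegenerateVariableError,
    EmptyDatasetError,
    GenotypeCodingError,
    SnpRecord,
    ValidationError,
    gene_to_snps,
)


@pytest.fixture
def rs25531():
    return SnpRecord("rs25531", "SLC6A4", "AA", "G")


class TestGenotypeCoding:
    @pytest.mark.parametrize(
        "genotype,expected",
        [("AA", 0), ("AG", 1), ("GA", 1), ("GG", 2), ("ag", 1)],
    )
    def test_minor_allele_count(self, rs25531, genotype, expected):
        assert ig.code_minor_alleles(genotype, rs25531) == expected

    def test_unknown_allele_names_snp(self, rs25531):
        with pytest.raises(GenotypeCodingError, match="rs25531"):
            ig.code_minor_alleles("AT", rs25531)

    def test_not_two_letters(self, rs25531):
        with pytest.raises(GenotypeCodingError):
            ig.code_minor_alleles("AGG", rs25531)

    def test_coding_is_bijection_over_genotype_classes(self, gene_map):
        """Wild/hetero/mutant genotypes map exactly onto dosages 0/1/2."""
        for snp in gene_map.values():
            w, m = snp.wild_allele, snp.minor_allele
            classes = {w + w: 0, w + m: 1, m + m: 2}
            coded = {g: ig.code_minor_alleles(g, snp) for g in classes}
            assert coded == classes

    def test_string_table_coding(self, gene_map):
        tab = pd.DataFrame({"rs25531": ["AA", "AG", "GG"]}, index=["a", "b", "c"])
        out = ig.code_genotype_strings(tab, gene_map)
        assert out["rs25531"].tolist() == [0, 1, 2]


class TestResources:
    def test_gene_map_covers_nine_genes_eighteen_snps(self, gene_map):
        genes = gene_to_snps(gene_map)
        assert len(genes) == 9
        assert len(gene_map) == 18
        assert len(genes["FKBP5"]) == 9

    def test_genotype_freqs_are_distributions(self, gene_map):
        for snp in gene_map.values():
            assert abs(sum(snp.genotype_freqs) - 1.0) < 1e-6
            assert all(f >= 0 for f in snp.genotype_freqs)

    def test_roi_map_has_sixty_constructs(self, roi_map):
        assert len(roi_map.rois) == 60
        inds = roi_map.indicator_names
        assert len(inds) == len(set(inds)) == 123
        assert len(roi_map.rois["IFG"]) == 6
        assert len(roi_map.rois["InfLatVent"]) == 1

    def test_roi_volumes_positive(self, roi_map):
        for inds in roi_map.rois.values():
            for ind in inds:
                assert ind.mean > 0 and ind.sd > 0


class TestRelativeVolumes:
    def test_scalar_ratio(self):
        vol = pd.DataFrame({"a": [3.0], "total_brain_volume": [1500.0]})
        assert ig.relative_volumes(vol)["a"].iloc[0] == pytest.approx(0.002)

    def test_boundary_volume_equal_total(self):
        vol = pd.DataFrame({"a": [100.0], "total_brain_volume": [100.0]})
        assert ig.relative_volumes(vol)["a"].iloc[0] == pytest.approx(1.0)

    def test_elementwise_against_hand_division(self):
        vol = pd.DataFrame(
            {"a": [2.0, 4.0], "b": [3.0, 6.0], "c": [5.0, 1.0],
             "total_brain_volume": [10.0, 20.0]},
            index=["s1", "s2"],
        )
        rel = ig.relative_volumes(vol)
        expected = np.array([[2 / 10, 3 / 10, 5 / 10], [4 / 20, 6 / 20, 1 / 20]])
        np.testing.assert_allclose(rel.to_numpy(), expected)

    def test_nonpositive_total_rejected(self):
        vol = pd.DataFrame({"a": [1.0], "total_brain_volume": [0.0]})
        with pytest.raises(ValidationError):
            ig.relative_volumes(vol)


class TestStandardize:
    def test_moments_by_direct_recomputation(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(5, 3, size=(10, 4)), columns=list("abcd"))
        Z = ig.standardize(X)
        np.testing.assert_allclose(Z.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(Z.to_numpy().std(axis=0), 1, atol=1e-12)

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        Z1 = ig.standardize(pd.DataFrame(rng.normal(size=(20, 3))))
        Z2 = ig.standardize(Z1)
        np.testing.assert_allclose(Z1.to_numpy(), Z2.to_numpy(), atol=1e-12)

    def test_constant_column_named_in_error(self):
        X = pd.DataFrame({"ok": [1.0, 2.0], "flat": [3.0, 3.0]})
        with pytest.raises(DegenerateVariableError, match="flat"):
            ig.standardize(X)

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(st.floats(min_value=0.2, max_value=5.0))
    def test_rescaling_invariance_of_relative_then_standardize(self, factor):
        """Scaling all of a sample's volumes (incl. total) leaves the
        standardized relative volumes unchanged."""
        rng = np.random.default_rng(7)
        vol = pd.DataFrame(
            rng.uniform(1, 10, size=(8, 3)), columns=["a", "b", "c"])
        vol["total_brain_volume"] = rng.uniform(100, 200, size=8)
        scaled = vol.copy()
        scaled.iloc[0] *= factor  # per-sample global rescale
        z1 = ig.standardize(ig.relative_volumes(vol))
        z2 = ig.standardize(ig.relative_volumes(scaled))
        np.testing.assert_allclose(z1.to_numpy(), z2.to_numpy(), atol=1e-9)


class TestListwiseExclude:
    def _tables(self, n=10, seed=0):
        rng = np.random.default_rng(seed)
        ids = [f"s{i}" for i in range(n)]
        geno = pd.DataFrame({"rs1": rng.integers(0, 3, n)}, index=ids, dtype=float)
        vol = pd.DataFrame(
            {"a": rng.uniform(1, 5, n), "total_brain_volume": rng.uniform(100, 200, n)},
            index=ids,
        )
        pheno = pd.DataFrame(
            {"pte": rng.integers(0, 17, n), "severity": rng.uniform(0, 80, n),
             "gender": rng.integers(0, 2, n), "age": rng.uniform(20, 70, n),
             "audit": rng.integers(0, 40, n)},
            index=ids, dtype=float,
        )
        return geno, vol, pheno

    def test_no_missing_is_identity(self):
        geno, vol, pheno = self._tables()
        ds = ig.listwise_exclude(geno, vol, pheno)
        assert ds.n_samples == 10 and ds.n_excluded == 0

    def test_single_missing_snp_drops_whole_sample(self):
        geno, vol, pheno = self._tables()
        geno.loc["s3", "rs1"] = np.nan
        ds = ig.listwise_exclude(geno, vol, pheno)
        assert ds.n_samples == 9 and "s3" not in ds.genotypes.index
        assert ds.n_excluded == 1

    def test_count_matches_brute_force_intersection(self):
        geno, vol, pheno = self._tables(n=30, seed=5)
        rng = np.random.default_rng(9)
        geno.loc[geno.index[rng.choice(30, 4, replace=False)], "rs1"] = np.nan
        vol2 = vol.drop(index=["s0", "s1"])
        pheno.loc["s7", "age"] = np.nan
        complete = {
            i for i in geno.index
            if i in vol2.index
            and not geno.loc[i].isna().any()
            and not vol2.loc[i].isna().any()
            and not pheno.loc[i].isna().any()
        }
        ds = ig.listwise_exclude(geno, vol2, pheno)
        assert ds.n_samples == len(complete)
        assert set(ds.genotypes.index) == complete

    def test_empty_result_raises(self):
        geno, vol, pheno = self._tables(n=3)
        geno["rs1"] = np.nan
        with pytest.raises(EmptyDatasetError):
            ig.listwise_exclude(geno, vol, pheno)
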