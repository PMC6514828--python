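"""Tag-SNP classification, haplogroup proportions, core-haplotype strings
and opposite-fixation detection."""

import numpy as np
import pandas as pd
import pytest

from fadsevo.haplogroups import (
    TABLE1_TAG_BASE_NUMBER,
    TagSnpSpec,
    classify_haplotypes,
    core_haplotypes,
    haplogroup_proportions,
    load_table1,
    opposite_fixed_sites,
)

from conftest import make_alignment


@pytest.fixture(scope="module")
def small_tag(small_tag_pos):
    return TagSnpSpec(pos=small_tag_pos)


class TestClassification:
    def test_tag_alleles_define_haplogroups(self, small_alignment, small_tag):
        labeled = classify_haplotypes(small_alignment, small_tag)
        modern = labeled[~labeled["cluster"].str.startswith("archaic")]
        assert (modern["haplogroup"] == modern["cluster"]).all()

    def test_archaic_lineages_follow_their_founder_allele(self, small_alignment, small_tag):
        labeled = classify_haplotypes(small_alignment, small_tag)
        by_cluster = labeled.groupby("cluster")["haplogroup"].unique()
        assert by_cluster["archaic_near_derived"].tolist() == ["derived"]
        assert by_cluster["archaic_near_ancestral"].tolist() == ["ancestral"]

    def test_missing_base_is_unclassified(self, small_alignment, small_tag):
        aln = small_alignment.take_haplotypes(np.arange(small_alignment.n_haplotypes))
        j = aln.site_index(small_tag.pos)
        aln.haplotypes[0, j] = "N"
        labeled = classify_haplotypes(aln, small_tag)
        assert labeled.loc[0, "haplogroup"] == "unclassified"

    def test_absent_tag_site_is_an_error_naming_position(self, small_alignment):
        with pytest.raises(KeyError, match="99"):
            classify_haplotypes(small_alignment, TagSnpSpec(pos=99))


class TestProportions:
    def _labeled(self, n, n_ancestral, group="NativeAmerican"):
        return pd.DataFrame(
            {
                "sample": [f"s{i // 2}" for i in range(n)],
                "ancestry": group,
                "haplogroup": ["ancestral"] * n_ancestral + ["derived"] * (n - n_ancestral),
            }
        )

    def test_published_rounding_of_native_american_fraction(self):
        # 215 of 216 ancestral haplotypes -> 99.54%
        table = haplogroup_proportions(self._labeled(216, 215), group_by="ancestry")
        assert table.loc[0, "pct_ancestral"] == 99.54

    def test_published_rounding_of_african_fraction(self):
        # 379 of 380 derived haplotypes -> 99.74%
        table = haplogroup_proportions(self._labeled(380, 1, group="African"), group_by="ancestry")
        assert table.loc[0, "pct_derived"] == 99.74

    def test_fractions_sum_to_one_after_exclusions(self):
        df = self._labeled(10, 4)
        df.loc[0, "haplogroup"] = "unclassified"
        table = haplogroup_proportions(df, group_by="ancestry")
        assert table.loc[0, "n_haplotypes"] == 9
        assert table.loc[0, "frac_ancestral"] + table.loc[0, "frac_derived"] == pytest.approx(1.0)

    def test_unambiguous_only_drops_mixed_ancestry_samples(self):
        df = pd.DataFrame(
            {
                "sample": ["a", "a", "b", "b"],
                "ancestry": ["African", "European", "African", "African"],
                "haplogroup": ["derived"] * 4,
            }
        )
        table = haplogroup_proportions(df, group_by="ancestry", unambiguous_only=True)
        assert table["n_haplotypes"].sum() == 2  # only sample b survives

    def test_fully_unclassified_group_omitted(self):
        df = self._labeled(4, 0)
        df["haplogroup"] = "unclassified"
        assert len(haplogroup_proportions(df, group_by="ancestry")) == 0


class TestCoreHaplotypes:
    def test_consensus_capitals_and_variable_positions(self):
        aln = make_alignment(["ACG", "ACA", "ACG", "TGG"], "ACG",
                             clusters=["x", "x", "x", "y"])
        cores = core_haplotypes(aln, ["x", "x", "x", "y"])
        assert cores["x"].sequence == "ACn"
        assert cores["y"].sequence == "TGG"

    def test_single_haplotype_category_is_all_capitals(self):
        aln = make_alignment(["ACG", "TGA"], "ACG", clusters=["x", "y"])
        cores = core_haplotypes(aln, ["x", "y"])
        assert cores["y"].sequence == "TGA"
        assert cores["y"].fixed_mask().all()

    def test_duplicating_a_haplotype_never_changes_the_string(self):
        haps = ["ACG", "ACA", "TGG"]
        cats = ["x", "x", "y"]
        aln1 = make_alignment(haps, "ACG", clusters=cats)
        aln2 = make_alignment(haps + ["ACA"], "ACG", clusters=cats + ["x"])
        c1 = core_haplotypes(aln1, cats)
        c2 = core_haplotypes(aln2, cats + ["x"])
        assert c1["x"].sequence == c2["x"].sequence

    def test_majority_missing_position_is_variable_with_warning(self, caplog):
        aln = make_alignment(["NCG", "NCG", "ACG", "TCG"], "ACG",
                             clusters=["x", "x", "x", "y"])
        with caplog.at_level("WARNING"):
            cores = core_haplotypes(aln, ["x", "x", "x", "y"])
        assert cores["x"].sequence[0] == "n"


class TestOppositeFixation:
    def test_trivial_single_difference(self):
        res = opposite_fixed_sites("AnC", "TnC")
        assert res["opposite_fixed"] == [1]

    def test_identical_capital_strings_have_no_opposite_sites(self):
        assert opposite_fixed_sites("ACGT", "ACGT")["opposite_fixed"] == []

    def test_half_fixed_positions_reported_separately(self):
        res = opposite_fixed_sites("AnCG", "AACn")
        assert res["opposite_fixed"] == []
        assert res["half_fixed"] == [2, 4]

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            opposite_fixed_sites("AAA", "AA")

    def test_planted_fixed_differences_recovered(self):
        # two synthetic categories with disjoint fixed differences at 2 and 5
        a = "CAGTTA"
        b = "CTGTGA"
        res = opposite_fixed_sites(a, b)
        assert res["opposite_fixed"] == [2, 5]


class TestPublishedCoreHaplotypes:
    def test_strings_parse_to_38_variant_positions(self):
        table = load_table1()
        assert len(table) == 8
        assert (table["sequence"].str.len() == 38).all()
        assert table["sequence"].str.fullmatch("[ACGTn]+").all()

    def test_tag_base_matches_haplogroup_of_each_category(self):
        table = load_table1()
        for _, row in table.iterrows():
            base = row["sequence"][TABLE1_TAG_BASE_NUMBER - 1]
            expected = "G" if "Derived" in row["category"] else "T"
            assert base == expected

    def test_one_additional_oppositely_fixed_variant(self):
        table = load_table1().set_index("category")["sequence"]
        res = opposite_fixed_sites(
            table["Ancestral"], table["Derived"], exclude=TABLE1_TAG_BASE_NUMBER
        )
        assert res["opposite_fixed"] == [12]  # rs102274
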