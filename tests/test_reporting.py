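"""Annotation ingestion, distributions, Venn partitions and bioassay math."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import supersage as ss
from supersage.reporting import AnnotationError, write_annotations


def make_annotations(rows):
    """rows: list of dicts; missing keys get defaults."""
    defaults = {"tag_code": "Tag_1", "contig_id": "c1",
                "protein_desc": "protein", "species": "Bombyx mori",
                "evalue": 1e-10, "go_categories": "metabolism",
                "functional_group": "", "catalytic_activity": "",
                "gene_id": "", "direction": "OE"}
    if not rows:
        return pd.DataFrame(columns=list(defaults))
    return pd.DataFrame([{**defaults, **row} for row in rows])


def serine_fixture():
    """27 serine-protease tags collapsing to 12 OE-only, 7 UE-only and 3
    shared genes (22 unique genes in total)."""
    rows = []
    for i in range(12):
        rows.append({"tag_code": f"Tag_oe{i}", "gene_id": f"SP_OE{i}",
                     "functional_group": "serine_protease_trypsin",
                     "direction": "OE"})
    for i in range(7):
        rows.append({"tag_code": f"Tag_ue{i}", "gene_id": f"SP_UE{i}",
                     "functional_group": "serine_protease_chymotrypsin",
                     "direction": "UE"})
    for i in range(3):
        for direction in ("OE", "UE"):
            rows.append({"tag_code": f"Tag_sh{i}{direction}",
                         "gene_id": f"SP_SH{i}",
                         "functional_group": "serine_protease_trypsin",
                         "direction": direction})
    # two additional tags on already-seen genes: 25 + 2 = 27 tags
    rows.append({"tag_code": "Tag_extra1", "gene_id": "SP_OE0",
                 "functional_group": "serine_protease_trypsin",
                 "direction": "OE"})
    rows.append({"tag_code": "Tag_extra2", "gene_id": "SP_UE0",
                 "functional_group": "serine_protease_chymotrypsin",
                 "direction": "UE"})
    return make_annotations(rows)


def ribosomal_fixture():
    """42 ribosomal-protein tags collapsing to 40 unique genes
    (19 OE-only + 21 UE-only, none shared)."""
    rows = []
    for i in range(19):
        rows.append({"tag_code": f"Tag_rl{i}", "gene_id": f"RpL{i}",
                     "functional_group": "ribosomal_L", "direction": "OE"})
    for i in range(21):
        rows.append({"tag_code": f"Tag_rs{i}", "gene_id": f"RpS{i}",
                     "functional_group": "ribosomal_S", "direction": "UE"})
    rows.append({"tag_code": "Tag_rl_dup", "gene_id": "RpL0",
                 "functional_group": "ribosomal_L", "direction": "OE"})
    rows.append({"tag_code": "Tag_rs_dup", "gene_id": "RpS0",
                 "functional_group": "ribosomal_S", "direction": "UE"})
    return make_annotations(rows)


class TestLoadAnnotations:
    def test_well_formed_file(self, tmp_path):
        df = make_annotations([{"tag_code": f"Tag_{i}"} for i in range(10)])
        path = write_annotations(df, tmp_path / "ann.tsv")
        loaded = ss.load_annotations(path)
        assert len(loaded) == 10
        assert loaded["evalue"].dtype == float

    def test_missing_column_named(self, tmp_path):
        df = make_annotations([{}]).drop(columns=["species"])
        path = write_annotations(df, tmp_path / "ann.tsv")
        with pytest.raises(AnnotationError, match="species"):
            ss.load_annotations(path)

    def test_negative_evalue_reported_with_line(self, tmp_path):
        df = make_annotations([{}, {"evalue": -1.0}, {}])
        path = write_annotations(df, tmp_path / "ann.tsv")
        with pytest.raises(AnnotationError, match=r"\[3\]"):
            ss.load_annotations(path)
        loaded = ss.load_annotations(path, on_invalid="skip")
        assert len(loaded) == 2

    def test_round_trip(self, tmp_path):
        df = serine_fixture()
        path = write_annotations(df, tmp_path / "ann.tsv")
        loaded = ss.load_annotations(path)
        assert list(loaded["tag_code"]) == list(df["tag_code"])
        assert list(loaded["direction"]) == list(df["direction"])


class TestCategoryDistribution:
    def _records(self, spec, total):
        """spec: {category: count}; remaining rows get no GO category."""
        rows = []
        for cat, n in spec.items():
            rows += [{"go_categories": cat}] * n
        rows += [{"go_categories": ""}] * (total - len(rows))
        return make_annotations(rows)

    def test_published_percentages(self):
        records = self._records({"metabolism": 108, "translation": 66}, 416)
        dist = ss.category_distribution(records, denominator="annotated")
        by_cat = dist.set_index("category")["percent"]
        assert by_cat["metabolism"] == 25.96
        assert by_cat["translation"] == 15.87

    def test_own_denominator_is_100(self):
        records = self._records({"metabolism": 50}, 50)
        dist = ss.category_distribution(records, denominator="go_assigned")
        assert dist.loc[0, "percent"] == 100.0

    def test_go_assigned_denominator(self):
        records = self._records({"metabolism": 30, "transport": 10}, 80)
        dist = ss.category_distribution(records, denominator="go_assigned")
        assert dist.set_index("category").loc["metabolism", "percent"] == 75.0


class TestCatalyticBreakdown:
    def test_within_category_shares(self):
        rows = ([{"catalytic_activity": "serine-type hydrolase"}] * 27
                + [{"catalytic_activity": "other hydrolase"}] * 34
                + [{"catalytic_activity": "oxidoreductase"}] * 47)
        records = make_annotations(rows)
        breakdown = ss.catalytic_breakdown(records, category="metabolism")
        shares = breakdown.set_index("catalytic_activity")["percent"]
        assert shares["serine-type hydrolase"] == 25.0
        counts = breakdown.set_index("catalytic_activity")["count"]
        # hydrolases together: 61 of 108 ~ 56%
        hydrolase_pct = 100 * (counts["serine-type hydrolase"]
                               + counts["other hydrolase"]) / len(records)
        assert hydrolase_pct == pytest.approx(56.5, abs=0.1)

    def test_empty_category(self):
        records = make_annotations([{"go_categories": "transport"}])
        breakdown = ss.catalytic_breakdown(records, category="metabolism")
        assert len(breakdown) == 0


class TestVennPartition:
    def test_serine_protease_partition(self):
        part = ss.venn_partition(serine_fixture(), group_prefix="serine_protease")
        assert (part.n_oe_only, part.n_ue_only, part.n_shared) == (12, 7, 3)
        assert part.n_unique_genes == 22
        assert part.n_tags == 27

    def test_ribosomal_partition(self):
        part = ss.venn_partition(ribosomal_fixture(), group_prefix="ribosomal")
        assert part.n_unique_genes == 40
        assert (part.n_oe_only, part.n_ue_only, part.n_shared) == (19, 21, 0)
        assert part.n_tags == 42

    def test_single_gene_both_directions(self):
        rows = [{"gene_id": "G", "direction": d, "functional_group": "x"}
                for d in ("OE", "UE", "OE", "UE")]
        part = ss.venn_partition(make_annotations(rows), group_prefix="x")
        assert (part.n_oe_only, part.n_ue_only, part.n_shared) == (0, 0, 1)
        assert part.n_unique_genes == 1 and part.n_tags == 4

    def test_fallback_to_protein_desc_when_no_gene_id(self):
        rows = [{"gene_id": "", "protein_desc": "trypsin A", "direction": "OE"},
                {"gene_id": "", "protein_desc": "trypsin A", "direction": "UE"},
                {"gene_id": "", "protein_desc": "trypsin B", "direction": "OE"}]
        part = ss.venn_partition(make_annotations(rows))
        assert (part.n_oe_only, part.n_ue_only, part.n_shared) == (1, 0, 1)

    @given(st.lists(st.tuples(st.integers(0, 5), st.sampled_from(["OE", "UE"])),
                    min_size=1, max_size=40))
    @settings(max_examples=100, derandomize=True)
    def test_partition_identity(self, assignments):
        rows = [{"gene_id": f"g{g}", "direction": d} for g, d in assignments]
        part = ss.venn_partition(make_annotations(rows))
        assert part.n_unique_genes == part.n_oe_only + part.n_ue_only + part.n_shared
        assert part.n_unique_genes == len({g for g, _ in assignments})
        assert part.n_tags == len(assignments)


class TestSpeciesDistribution:
    def test_even_split(self):
        records = make_annotations([{"species": "A"}, {"species": "B"}])
        dist = ss.species_distribution(records)
        assert (dist["percent"] == 50.0).all()

    def test_sorted_descending_and_sums_to_100(self):
        records = make_annotations(
            [{"species": "A"}] * 5 + [{"species": "B"}] * 3 + [{"species": "C"}] * 2)
        dist = ss.species_distribution(records)
        assert list(dist["species"]) == ["A", "B", "C"]
        assert dist["percent"].sum() == pytest.approx(100.0, abs=0.05)

    def test_empty(self):
        dist = ss.species_distribution(make_annotations([]))
        assert len(dist) == 0


class TestTopTable:
    def _records(self, fcs, label):
        import itertools
        suffixes = ["".join(p) for p in itertools.product("ACGT", repeat=2)]
        return [ss.DGERecord("CATG" + "ACGT" * 5 + suffixes[i], 10, 1, 10, 1,
                             10.0, 1.0, fc, np.log2(fc), 0.001, label)
                for i, fc in enumerate(fcs)]

    def test_oe_ranked_by_fc_descending(self):
        records = self._records([33.52, 74.86, 67.36], "OE")
        table = ss.top_table(records, None, 2, "OE")
        assert list(table["FC"]) == [74.86, 67.36]

    def test_ue_reports_log2(self):
        fc = 2 ** -6.15
        records = self._records([fc, 0.3], "UE")
        table = ss.top_table(records, None, 1, "UE")
        assert table.loc[0, "log2FC"] == pytest.approx(-6.15)

    def test_n_larger_than_records(self):
        records = self._records([3.0, 4.0], "OE")
        assert len(ss.top_table(records, None, 40, "OE")) == 2

    def test_ties_broken_lexicographically(self):
        records = [ss.DGERecord(tag, 10, 1, 10, 1, 10.0, 1.0, 5.0,
                                np.log2(5.0), 0.001, "OE")
                   for tag in ("CATG" + "T" * 22, "CATG" + "A" * 21 + "C")]
        table = ss.top_table(records, None, 2, "OE")
        assert list(table["tag_seq_26"]) == sorted(r.tag for r in records)

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            ss.top_table([], None, 0, "OE")

    def test_annotation_join(self):
        records = self._records([5.0], "OE")
        ann = pd.DataFrame({"tag_code": [records[0].tag],
                            "protein_desc": ["REPAT39"],
                            "species": ["Spodoptera exigua"],
                            "evalue": [7e-30]})
        table = ss.top_table(records, ann, 1, "OE")
        assert table.loc[0, "protein_desc"] == "REPAT39"


class TestBioassayUtilities:
    def test_resistance_ratio_from_lc50s(self):
        raw, rounded = ss.resistance_ratio(103, 0.44)
        assert rounded == 234
        assert raw == pytest.approx(234.09, abs=0.01)

    def test_unity_and_reciprocal(self):
        assert ss.resistance_ratio(5.0, 5.0)[1] == 1
        raw, _ = ss.resistance_ratio(0.44, 103)
        assert raw == pytest.approx(0.00427, abs=1e-5)

    def test_non_positive_error(self):
        with pytest.raises(ValueError):
            ss.resistance_ratio(0, 1)

    def test_fl_overlap_rule(self):
        # resistant (46, 226) vs susceptible (0.30, 0.64): disjoint
        assert ss.fl_overlap_significant((46, 226), (0.30, 0.64)) is True
        assert ss.fl_overlap_significant((1, 5), (4, 9)) is False
        assert ss.fl_overlap_significant((1, 5), (5, 9)) is False  # touching

    def test_malformed_interval(self):
        with pytest.raises(ValueError):
            ss.fl_overlap_significant((5, 1), (0, 1))

    def test_bioassay_result_validation(self):
        result = ss.BioassayResult(103, 46, 226, 0.89, 0.15)
        assert result.fl_low <= result.lc50 <= result.fl_high
        with pytest.raises(ValueError):
            ss.BioassayResult(103, 150, 226)
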