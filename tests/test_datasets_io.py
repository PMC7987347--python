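"""Data model invariants and lossless round-trips for every file format."""

import numpy as np
import pandas as pd
import pytest

from wilddom import io
from wilddom.datasets import (
    CountTable,
    RunConfig,
    ValidationError,
    parse_taxonomy,
    validate_dataset,
    validate_metadata,
)


def make_metadata(sample_ids, **overrides):
    frame = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "host_species": ["sp_a", "sp_a", "sp_b"][: len(sample_ids)],
            "dyad_id": ["d1"] * len(sample_ids),
            "status": ["wild", "wild", "domesticated"][: len(sample_ids)],
        }
    )
    for key, values in overrides.items():
        frame[key] = values
    return frame


class TestCountTable:
    def test_negative_counts_rejected(self):
        frame = pd.DataFrame([[1, -2]], index=["s1"], columns=["t1", "t2"])
        with pytest.raises(ValidationError, match="nonnegative"):
            CountTable(frame)

    def test_non_integer_counts_rejected(self):
        frame = pd.DataFrame([[1.5, 2.0]], index=["s1"], columns=["t1", "t2"])
        with pytest.raises(ValidationError, match="integral"):
            CountTable(frame)

    def test_duplicate_ids_rejected(self):
        frame = pd.DataFrame([[1, 2], [3, 4]], index=["s1", "s1"], columns=["t1", "t2"])
        with pytest.raises(ValidationError, match="duplicate sample"):
            CountTable(frame)

    def test_merge_outer_joins_taxa(self, small_table):
        other = CountTable(
            pd.DataFrame([[7, 1]], index=["s9"], columns=["t4", "t9"])
        )
        merged = CountTable.merge([small_table, other])
        assert merged.shape == (4, 5)
        assert merged.counts.loc["s9", "t1"] == 0
        assert merged.counts.loc["s9", "t4"] == 7

    def test_taxonomy_parsing(self):
        ranks = parse_taxonomy("k__Bacteria;p__Firm;c__;o__;f__Lacto;g__Lacto;s__casei")
        assert ranks["kingdom"] == "Bacteria"
        assert ranks["class"] == ""
        assert ranks["species"] == "casei"


class TestRoundTrips:
    def test_count_table_samples_layout(self, small_table, tmp_path):
        path = tmp_path / "counts.tsv"
        io.write_count_table(small_table, path, layout="samples")
        back = io.read_count_table(path)
        pd.testing.assert_frame_equal(back.counts, small_table.counts)

    def test_count_table_otu_layout_keeps_taxonomy(self, small_table, tmp_path):
        path = tmp_path / "otu.tsv"
        io.write_count_table(small_table, path, layout="otu")
        back = io.read_count_table(path)
        pd.testing.assert_frame_equal(back.counts, small_table.counts)
        assert back.taxonomy is not None
        assert back.taxonomy["t1"].startswith("k__Bacteria")

    def test_count_table_negative_value_read_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("#SampleID\tt1\tt2\ns1\t3\t-2\n")
        with pytest.raises(ValidationError, match="negative"):
            io.read_count_table(path)

    def test_metadata_roundtrip(self, tmp_path):
        frame = make_metadata(["s1", "s2", "s3"])
        path = tmp_path / "meta.tsv"
        io.write_metadata(frame, path)
        back = io.read_metadata(path)
        assert list(back["sample_id"]) == ["s1", "s2", "s3"]
        assert (back["category"] == "NA").all()  # optional columns filled

    def test_dyad_table_roundtrip(self, tmp_path):
        frame = pd.DataFrame(
            {"dyad_id": ["d1"], "time_since_domestication": [1e4], "time_since_divergence": [2e6]}
        )
        path = tmp_path / "dyads.tsv"
        io.write_dyad_table(frame, path)
        back = io.read_dyad_table(path)
        assert back.loc["d1", "time_since_divergence"] == 2e6

    def test_tree_roundtrip_and_total_length(self, tmp_path):
        path = tmp_path / "tree.nwk"
        path.write_text("((A:1,B:1):1,(C:1,D:1):1);\n")
        tree = io.read_tree(path)
        tips = sorted(t.name for t in tree.tips())
        assert tips == ["A", "B", "C", "D"]
        total = sum(n.length for n in tree.traverse(include_self=False))
        assert total == pytest.approx(6.0)

    def test_pathogen_list_roundtrip(self, tmp_path):
        path = tmp_path / "pathogens.txt"
        io.write_pathogen_list(["Escherichia", "streptococcus pneumoniae"], path)
        back = io.read_pathogen_list(path)
        assert back == ["escherichia", "streptococcus pneumoniae"]

    def test_config_roundtrip(self, tmp_path):
        cfg = RunConfig(rarefaction_depth=7500, n_permutations=199, random_seed=5)
        path = tmp_path / "config.json"
        io.write_config(cfg, path)
        assert io.read_config(path) == cfg

    def test_distance_matrix_roundtrip(self, tmp_path):
        from skbio import DistanceMatrix

        dm = DistanceMatrix(np.array([[0, 0.5], [0.5, 0]]), ids=["a", "b"])
        path = tmp_path / "dm.tsv"
        io.write_distance_matrix(dm, path)
        back = io.read_distance_matrix(path)
        np.testing.assert_allclose(back.data, dm.data)
        assert list(back.ids) == ["a", "b"]


class TestTreeValidation:
    def test_missing_branch_length_rejected(self, tmp_path):
        path = tmp_path / "tree.nwk"
        path.write_text("((A:1,B):1,C:1);\n")
        with pytest.raises(ValidationError, match="branch length"):
            io.read_tree(path)

    def test_duplicate_tips_rejected(self, tmp_path):
        path = tmp_path / "tree.nwk"
        path.write_text("((A:1,A:1):1,C:1);\n")
        with pytest.raises(ValidationError, match="unique"):
            io.read_tree(path)


class TestMetadataValidation:
    def test_missing_required_column(self):
        frame = make_metadata(["s1", "s2", "s3"]).drop(columns=["dyad_id"])
        with pytest.raises(ValidationError, match="dyad_id"):
            validate_metadata(frame)

    def test_bad_status_rejected(self):
        frame = make_metadata(["s1", "s2", "s3"], status=["feral", "wild", "wild"])
        with pytest.raises(ValidationError, match="status"):
            validate_metadata(frame)

    def test_duplicate_sample_id_rejected(self):
        frame = make_metadata(["s1", "s1", "s3"])
        with pytest.raises(ValidationError, match="duplicated"):
            validate_metadata(frame)


class TestValidateDataset:
    def test_consistent_inputs_no_warnings(self, small_table):
        meta = make_metadata(["s1", "s2", "s3"])
        dataset = validate_dataset(small_table, meta)
        assert dataset.warnings == []
        assert dataset.sample_ids == ["s1", "s2", "s3"]

    def test_extra_count_sample_dropped_with_warning(self, small_table):
        meta = make_metadata(["s1", "s2"])
        dataset = validate_dataset(small_table, meta)
        assert "s3" not in dataset.sample_ids
        assert any("only in counts" in w for w in dataset.warnings)

    def test_idempotent(self, small_table):
        meta = make_metadata(["s1", "s2", "s3"])
        dataset = validate_dataset(small_table, meta)
        assert validate_dataset(dataset, meta) is dataset

    def test_unifrac_without_tree_errors(self, small_table):
        meta = make_metadata(["s1", "s2", "s3"])
        dataset = validate_dataset(small_table, meta)
        with pytest.raises(ValidationError, match="phylogeny"):
            dataset.require_tree()

    def test_extra_tree_tips_pruned(self, small_table, tmp_path):
        path = tmp_path / "tree.nwk"
        path.write_text("(((t1:1,t2:1):1,(t3:1,t4:1):1):1,zzz:9);\n")
        tree = io.read_tree(path)
        meta = make_metadata(["s1", "s2", "s3"])
        dataset = validate_dataset(small_table, meta, tree=tree)
        assert sorted(t.name for t in dataset.tree.tips()) == ["t1", "t2", "t3", "t4"]

    def test_three_species_dyad_rejected(self, small_table):
        meta = make_metadata(["s1", "s2", "s3"], host_species=["a", "b", "c"])
        with pytest.raises(ValidationError, match="host species"):
            validate_dataset(small_table, meta)


def test_runconfig_invariants():
    with pytest.raises(ValidationError):
        RunConfig(rarefaction_depth=0)
    with pytest.raises(ValidationError):
        RunConfig(n_permutations=10)
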