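"""Domain-type invariants and TSV/newick/YAML round trips."""

import numpy as np
import pandas as pd
import pytest

import beeqmp as bq
from beeqmp import io
from beeqmp.datamodel import CountMatrix, CtTable, SampleTable


def _cm(rows, index=("s1", "s2"), cols=("a1", "a2")):
    return CountMatrix(pd.DataFrame(rows, index=list(index), columns=list(cols)))


class TestCountMatrix:
    def test_rejects_negative_naming_cell(self):
        with pytest.raises(ValueError, match="s2.*a1"):
            _cm([[1, 2], [-3, 4]])

    def test_rejects_duplicate_labels(self):
        with pytest.raises(ValueError, match="duplicate sample"):
            _cm([[1, 2], [3, 4]], index=("s1", "s1"))
        with pytest.raises(ValueError, match="duplicate ASV"):
            _cm([[1, 2], [3, 4]], cols=("a", "a"))

    def test_integer_flag(self):
        assert _cm([[1, 2], [3, 4]]).is_integer
        assert not _cm([[1.5, 2], [3, 4]]).is_integer

    def test_label_based_subsetting(self):
        m = _cm([[1, 2], [3, 4]])
        assert m.select_samples(["s2"]).values.tolist() == [[3.0, 4.0]]
        with pytest.raises(KeyError):
            m.select_samples(["nope"])


class TestCountTableIO:
    def test_round_trip_identity(self, tmp_path):
        m = _cm([[1, 2], [3, 4]])
        p = tmp_path / "c.tsv"
        io.write_count_table(m, p)
        back = io.read_count_table(p)
        pd.testing.assert_frame_equal(back.data, m.data)

    def test_real_valued_round_trip_tolerance(self, tmp_path):
        m = _cm([[1.123456789012, 2.0], [3.0, 4.987654321098]])
        p = tmp_path / "c.tsv"
        io.write_count_table(m, p)
        assert np.allclose(io.read_count_table(p).values, m.values, atol=1e-9)

    def test_orientation_transpose(self, tmp_path):
        m = _cm([[1, 2], [3, 4]])
        p = tmp_path / "c.tsv"
        df = m.data.T.copy()
        df.index.name = "asv_id"
        df.to_csv(p, sep="\t")
        back = io.read_count_table(p, orientation="asvs_by_samples")
        pd.testing.assert_frame_equal(back.data, m.data)

    def test_negative_cell_error_names_record(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("sample_id\ta1\ta2\ns1\t1\t2\ns2\t-3\t4\n")
        with pytest.raises(ValueError, match="s2.*a1"):
            io.read_count_table(p)

    def test_non_numeric_cell_error(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("sample_id\ta1\ns1\tx\n")
        with pytest.raises(ValueError, match="non-numeric"):
            io.read_count_table(p)

    def test_empty_file_error(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("")
        with pytest.raises(ValueError, match="no samples"):
            io.read_count_table(p)


class TestSampleTable:
    def test_study_scale_grouping(self, study):
        assert study.samples.hives.shape[0] == 23
        assert study.samples.hives["location"].nunique() == 3

    def test_hive_in_two_locations_rejected(self):
        df = pd.DataFrame(
            {
                "hive_id": ["h1", "h1"],
                "location": ["locA", "locB"],
                "condition": ["survived", "survived"],
                "role": ["bee", "bee"],
            },
            index=["s1", "s2"],
        )
        with pytest.raises(ValueError, match="more than one location"):
            SampleTable(df)

    def test_hive_in_two_conditions_rejected(self):
        df = pd.DataFrame(
            {
                "hive_id": ["h1", "h1"],
                "location": ["locA", "locA"],
                "condition": ["survived", "failed"],
                "role": ["bee", "bee"],
            },
            index=["s1", "s2"],
        )
        with pytest.raises(ValueError, match="more than one condition"):
            SampleTable(df)

    def test_unknown_condition_rejected(self):
        df = pd.DataFrame(
            {
                "hive_id": ["h1"],
                "location": ["locA"],
                "condition": ["thrived"],
                "role": ["bee"],
            },
            index=["s1"],
        )
        with pytest.raises(ValueError, match="condition"):
            SampleTable(df)

    def test_controls_accepted_with_empty_hive(self):
        df = pd.DataFrame(
            {
                "hive_id": ["h1", ""],
                "location": ["locA", ""],
                "condition": ["survived", ""],
                "role": ["bee", "negative_control"],
            },
            index=["s1", "neg1"],
        )
        t = SampleTable(df)
        assert t.control_ids == ["neg1"]
        assert t.bee_ids == ["s1"]

    def test_round_trip(self, study, tmp_path):
        p = tmp_path / "s.tsv"
        io.write_sample_table(study.samples, p)
        back = io.read_sample_table(p)
        pd.testing.assert_frame_equal(back.data, study.samples.data)


class TestCtTable:
    def _rows(self, ct=20.0):
        return pd.DataFrame(
            {
                "sample_id": ["s1"] * 3,
                "assay": ["bact16S"] * 3,
                "replicate": [1, 2, 3],
                "ct": [ct, ct + 0.1, ct - 0.1],
            }
        )

    def test_triplicates_form_one_group(self):
        t = CtTable(self._rows())
        assert t.mean_ct("bact16S").loc["s1"] == pytest.approx(20.0)
        assert t.incomplete_groups().empty

    def test_nonpositive_ct_rejected(self):
        df = self._rows()
        df.loc[0, "ct"] = 0.0
        with pytest.raises(ValueError, match="positive cycle"):
            CtTable(df)

    def test_duplicate_replicate_rejected(self):
        df = self._rows()
        df.loc[1, "replicate"] = 1
        with pytest.raises(ValueError, match="duplicate replicate"):
            CtTable(df)

    def test_unknown_assay_rejected(self):
        df = self._rows()
        df.loc[0, "assay"] = "mystery"
        with pytest.raises(ValueError, match="assay"):
            CtTable(df)

    def test_incomplete_group_reported(self):
        df = self._rows().iloc[:2]
        t = CtTable(df)
        assert t.incomplete_groups().iloc[0]["n_replicates"] == 2

    def test_round_trip(self, study, tmp_path):
        p = tmp_path / "ct.tsv"
        io.write_ct_table(study.ct, p)
        back = io.read_ct_table(p)
        assert np.allclose(back.data["ct"], study.ct.data["ct"], atol=1e-9)


class TestNewick:
    def test_two_leaf_parse(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text("(A:1,B:1);\n")
        t = io.read_newick(p)
        assert sorted(x.name for x in t.tips()) == ["A", "B"]
        assert all(x.length == 1.0 for x in t.tips())

    def test_round_trip_random_tree(self, tmp_path):
        rng = np.random.default_rng(0)
        from scipy.spatial.distance import pdist, squareform
        from skbio import DistanceMatrix

        pts = rng.normal(size=(10, 3))
        dm = DistanceMatrix(squareform(pdist(pts)), ids=[f"L{i}" for i in range(10)])
        t = bq.nj_tree(dm)
        p = tmp_path / "t.nwk"
        io.write_newick(t, p)
        back = io.read_newick(p)
        assert back.compare_rfd(t) == 0.0
        d0, d1 = t.tip_tip_distances(), back.tip_tip_distances()
        assert np.allclose(d0.filter(sorted(d0.ids)).data,
                           d1.filter(sorted(d1.ids)).data, atol=1e-9)

    def test_negative_branch_rejected_unless_clamped(self, tmp_path):
        p = tmp_path / "t.nwk"
        p.write_text("(A:1,B:-0.5);\n")
        with pytest.raises(ValueError, match="negative branch"):
            io.read_newick(p)
        t = io.read_newick(p, clamp_negative=True)
        assert min(x.length for x in t.tips()) == 0.0


class TestConfig:
    def test_yaml_round_trip(self, tmp_path):
        cfg = bq.PipelineConfig(seed=7, rarefaction_replicates=42)
        p = tmp_path / "cfg.yaml"
        io.write_config(cfg, p)
        assert io.read_config(p) == cfg

    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            bq.PipelineConfig(min_prevalence=1.5)
        with pytest.raises(ValueError):
            bq.PipelineConfig(rarefaction_replicates=0)
        with pytest.raises(ValueError):
            bq.PipelineConfig.from_dict({"not_a_key": 1})

    def test_manifest_records_seed_and_parameters(self, tmp_path):
        import json

        p = tmp_path / "m.json"
        io.write_manifest(p, stage="qmp", inputs={"counts": "x.tsv"},
                          parameters={"n_reps": 1000}, seed=5)
        m = json.loads(p.read_text())
        assert m["seed"] == 5
        assert m["parameters"]["n_reps"] == 1000
        assert "beeqmp" in m["versions"]
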