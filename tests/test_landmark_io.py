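import json

import numpy as np
import pandas as pd
import pytest

from morphodiverge.errors import ParseError, ValidationError
from morphodiverge.landmark_io import (
    PairingMap,
    assemble_dataset,
    read_fcsv,
    read_slicer_markups,
    read_tps_file,
    write_tps,
)
from morphodiverge.allometry import read_trait_table, TRAITS
from morphodiverge.synthetic_data import (
    simulate_landmarks,
    simulate_traits,
    study_landmark_params,
    study_trait_params,
)

from conftest import make_config


def _write_markups(path, points, labels=None):
    cps = []
    for i, p in enumerate(points):
        cp = {"label": (labels[i] if labels else f"F-{i + 1}"), "position": p}
        cps.append(cp)
    doc = {"markups": [{"type": "Fiducial", "controlPoints": cps}]}
    path.write_text(json.dumps(doc))


class TestSlicerMarkups:
    def test_three_point_identity(self, tmp_path):
        f = tmp_path / "spec.mrk.json"
        pts = [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]
        _write_markups(f, pts)
        cfg = read_slicer_markups(f)
        assert cfg.k == 3
        assert not cfg.missing_mask.any()
        np.testing.assert_allclose(cfg.coords, pts)

    def test_undefined_point_masked(self, tmp_path):
        f = tmp_path / "spec.mrk.json"
        doc = {
            "markups": [
                {
                    "controlPoints": [
                        {"label": "a", "position": [0, 0, 0]},
                        {"label": "b", "position": None},
                        {"label": "c", "position": [1, 1, 1]},
                    ]
                }
            ]
        }
        f.write_text(json.dumps(doc))
        cfg = read_slicer_markups(f)
        assert list(cfg.missing_mask) == [False, True, False]
        assert np.isnan(cfg.coords[1]).all()

    def test_malformed_json_names_line(self, tmp_path):
        f = tmp_path / "bad.mrk.json"
        f.write_text('{"markups": [\n  {broken}\n]}')
        with pytest.raises(ParseError, match="line"):
            read_slicer_markups(f)

    def test_duplicate_labels_rejected(self, tmp_path):
        f = tmp_path / "dup.mrk.json"
        _write_markups(f, [[0, 0, 0], [1, 0, 0], [0, 1, 0]], labels=["a", "a", "b"])
        with pytest.raises(ValidationError, match="duplicate"):
            read_slicer_markups(f)


class TestFcsv:
    def test_blank_coordinate_row_masked(self, tmp_path):
        f = tmp_path / "spec.fcsv"
        f.write_text(
            "# Markups fiducial file version = 4.11\n"
            "# columns = id,x,y,z,ow,ox,oy,oz,vis,sel,lock,label,desc,assoc\n"
            "f1,0.0,0.0,0.0,0,0,0,1,1,1,0,p1,,\n"
            "f2,,,,0,0,0,1,1,1,0,p2,,\n"
            "f3,1.0,2.0,3.0,0,0,0,1,1,1,0,p3,,\n"
        )
        cfg = read_fcsv(f)
        assert list(cfg.labels) == ["p1", "p2", "p3"]
        assert list(cfg.missing_mask) == [False, True, False]
        np.testing.assert_allclose(cfg.coords[2], [1.0, 2.0, 3.0])

    def test_non_numeric_coordinate_is_parse_error(self, tmp_path):
        f = tmp_path / "bad.fcsv"
        f.write_text("f1,x,0,0,0,0,0,1,1,1,0,p1,,\n")
        with pytest.raises(ParseError):
            read_fcsv(f)


class TestTps:
    def test_single_2d_record(self, tmp_path):
        f = tmp_path / "one.tps"
        f.write_text("LM=3\n0 0\n1 0\n0 1\nID=alpha\n")
        configs = read_tps_file(f)
        assert len(configs) == 1
        assert configs[0].ndim == 2
        assert configs[0].specimen_id == "alpha"

    def test_round_trip_identity(self, tmp_path):
        ds, _ = simulate_landmarks(study_landmark_params(seed=3, missing_rate=0.01))
        f = tmp_path / "rt.tps"
        write_tps(f, ds.configurations)
        back = read_tps_file(f)
        assert len(back) == ds.n
        for a, b in zip(ds.configurations, back):
            assert b.specimen_id == a.specimen_id
            assert list(b.missing_mask) == list(a.missing_mask)
            ok = ~a.missing_mask
            np.testing.assert_allclose(b.coords[ok], a.coords[ok], atol=1e-9)

    def test_two_record_file_matches_manual_parse(self, tmp_path):
        rng = np.random.default_rng(5)
        a, b = rng.standard_normal((4, 3)), rng.standard_normal((5, 3))
        f = tmp_path / "two.tps"
        f.write_text(
            "LM3=4\n"
            + "\n".join(" ".join(str(float(v)) for v in r) for r in a)
            + "\nID=first\nLM3=5\n"
            + "\n".join(" ".join(str(float(v)) for v in r) for r in b)
            + "\nID=second\n"
        )
        configs = read_tps_file(f)
        # independent line-by-line parse
        raw = [l for l in f.read_text().splitlines() if l and "=" not in l]
        manual = np.array([[float(v) for v in l.split()] for l in raw])
        np.testing.assert_allclose(np.vstack([c.coords for c in configs]), manual)
        assert [c.specimen_id for c in configs] == ["first", "second"]

    def test_count_mismatch_is_parse_error(self, tmp_path):
        f = tmp_path / "bad.tps"
        f.write_text("LM=3\n0 0\n1 1\nID=x\n")
        with pytest.raises(ParseError, match="3"):
            read_tps_file(f)


class TestAssemble:
    def _meta(self, ids):
        return pd.DataFrame({"specimen_id": ids, "species": "sp", "sex": "M"})

    def test_two_complete_specimens(self):
        square = [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]]
        configs = [make_config("a", square), make_config("b", square)]
        ds = assemble_dataset(configs, self._meta(["a", "b"]))
        assert ds.n == 2
        assert ds.total_missing == 0

    def test_missing_count_reported(self):
        ds, _ = simulate_landmarks(study_landmark_params(seed=1, missing_rate=0.005))
        total = ds.total_missing
        assert total == sum(ds.missing_report().values())
        assert total > 0

    def test_extra_label_error_names_label(self):
        square = [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]]
        a = make_config("a", square)
        b = make_config("b", square, labels=["LM1", "LM2", "LM3", "ODD"])
        with pytest.raises(ValidationError, match="ODD"):
            assemble_dataset([a, b], self._meta(["a", "b"]))

    def test_missing_metadata_lists_ids(self):
        square = [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]]
        configs = [make_config("a", square), make_config("b", square)]
        with pytest.raises(ValidationError, match="b"):
            assemble_dataset(configs, self._meta(["a"]))

    def test_reorders_to_template_labels(self):
        c1 = make_config("a", [[0, 0, 0], [1, 0, 0], [0, 1, 0]], labels=["p", "q", "r"])
        c2 = make_config("b", [[0, 1, 0], [0, 0, 0], [1, 0, 0]], labels=["r", "p", "q"])
        ds = assemble_dataset([c1, c2], self._meta(["a", "b"]))
        np.testing.assert_allclose(ds.configurations[1].coords, c1.coords)

    def test_cranium_template_structure(self):
        ds, _ = simulate_landmarks(study_landmark_params(seed=0))
        labels = ds.labels
        assert len(labels) == 120
        assert sum(l.startswith("L") for l in labels) == 54
        assert sum(l.startswith("R") for l in labels) == 54
        assert sum(l.startswith("M") for l in labels) == 12
        assert len(ds.pairing.pairs) == 54 and len(ds.pairing.midline) == 12


class TestTraitTable:
    def test_small_csv(self, tmp_path):
        f = tmp_path / "traits.csv"
        rows = ["specimen_id,species,region,island,sex,SVL," + ",".join(TRAITS)]
        for i in range(3):
            rows.append(f"s{i},sp,northern,isl,M,{100 + i}," + ",".join(["1.0"] * 10))
        f.write_text("\n".join(rows) + "\n")
        tab = read_trait_table(f)
        assert tab.n == 3
        assert len(tab.traits) == 10
        assert not tab.incomplete.any()

    def test_missing_measurement_flagged(self, tmp_path):
        f = tmp_path / "traits.csv"
        header = "specimen_id,species,region,island,sex,SVL," + ",".join(TRAITS)
        vals = ["1.0"] * 10
        vals[TRAITS.index("HH")] = ""
        f.write_text(header + "\ns1,sp,n,i,M,100," + ",".join(["2.0"] * 10)
                     + "\ns2,sp,n,i,F,90," + ",".join(vals) + "\n")
        tab = read_trait_table(f)
        assert list(tab.incomplete) == [False, True]
        assert tab.complete_rows().n == 1

    def test_non_numeric_cell_is_parse_error(self, tmp_path):
        f = tmp_path / "traits.csv"
        header = "specimen_id,species,region,island,sex,SVL," + ",".join(TRAITS)
        f.write_text(header + "\ns1,sp,n,i,M,abc," + ",".join(["1.0"] * 10) + "\n")
        with pytest.raises(ParseError, match="SVL"):
            read_trait_table(f)

    def test_study_sized_synthetic_table(self, tmp_path):
        tab, _ = simulate_traits(study_trait_params(seed=0))
        f = tmp_path / "study.csv"
        tab.data.to_csv(f, index=False)
        back = read_trait_table(f)
        assert back.n == 567
        assert back.species_counts() == {"sey": 246, "tac": 206, "tra": 115}
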