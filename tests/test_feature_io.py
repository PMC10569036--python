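import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from turbofp import feature_io
from turbofp.feature_io import (
    FormatError,
    blank_filter,
    match_features,
    parse_formula,
    read_feature_table,
    write_feature_table,
)
from turbofp.synthdata import simulate_panel


def _write_fixture(tmp_path, drop_sample=None, extra_col=False):
    """Three features, six samples (partition/control/blank for 2 solvents)."""
    samples = ["P_oct_r1_i1", "W_oct_r1_i1", "P_hex_r1_i1", "W_hex_r1_i1",
               "B_r1_i1", "B_r1_i2"]
    roles = ["partition", "water_control", "partition", "water_control",
             "blank", "blank"]
    solvents = ["octanol", "octanol", "hexane", "hexane", "", ""]
    features = pd.DataFrame(
        {
            "feature_id": ["F1", "F2", "F3"],
            "mz": [101.0, 202.0, 303.0],
            "rt": [1.0, 2.0, 3.0],
            **{s: [10.0 * (i + 1), 20.0, 1.0] for i, s in enumerate(samples)},
        }
    )
    if extra_col:
        features["annotation"] = ["a", "b", "c"]
    manifest = pd.DataFrame(
        {
            "sample_id": samples,
            "role": roles,
            "solvent": solvents,
            "replicate": 1,
            "injection": [1, 1, 1, 1, 1, 2],
        }
    )
    if drop_sample:
        manifest = manifest[manifest["sample_id"] != drop_sample]
    fpath, mpath = tmp_path / "features.csv", tmp_path / "manifest.csv"
    features.to_csv(fpath, index=False)
    manifest.to_csv(mpath, index=False)
    return fpath, mpath


class TestReadFeatureTable:
    def test_fixture_roundtrip(self, tmp_path):
        table = read_feature_table(*_write_fixture(tmp_path))
        assert len(table.feature_ids) == 3
        assert len(table.manifest) == 6
        assert set(table.manifest["role"]) == {"partition", "water_control", "blank"}

    def test_missing_manifest_entry_names_column(self, tmp_path):
        fpath, mpath = _write_fixture(tmp_path, drop_sample="P_hex_r1_i1")
        with pytest.raises(FormatError, match="P_hex_r1_i1"):
            read_feature_table(fpath, mpath)

    def test_non_numeric_extra_column_ignored(self, tmp_path):
        table = read_feature_table(*_write_fixture(tmp_path, extra_col=True))
        assert "annotation" not in table.features.columns

    def test_negative_area_rejected(self, tmp_path):
        fpath, mpath = _write_fixture(tmp_path)
        df = pd.read_csv(fpath)
        df.loc[0, "B_r1_i1"] = -5.0
        df.to_csv(fpath, index=False)
        with pytest.raises(ValueError, match="negative"):
            read_feature_table(fpath, mpath)

    def test_simulated_panel_roundtrip_exact(self, clean_panel, tmp_path):
        write_feature_table(
            clean_panel.table, tmp_path / "f.csv", tmp_path / "m.csv"
        )
        back = read_feature_table(tmp_path / "f.csv", tmp_path / "m.csv")
        pd.testing.assert_frame_equal(
            back.features, clean_panel.table.features, check_exact=True
        )
        pd.testing.assert_frame_equal(back.manifest, clean_panel.table.manifest)


def _single_feature_table(mz: float) -> feature_io.FeatureTable:
    features = pd.DataFrame(
        {"mz": [mz], "rt": [1.0], "W_oct_r1_i1": [100.0], "B_r1_i1": [1.0]},
        index=pd.Index(["F1"], name="feature_id"),
    )
    manifest = pd.DataFrame(
        {
            "role": ["water_control", "blank"],
            "solvent": ["octanol", ""],
            "replicate": [1, 1],
            "injection": [1, 1],
        },
        index=pd.Index(["W_oct_r1_i1", "B_r1_i1"], name="sample_id"),
    )
    return feature_io.FeatureTable(features=features, manifest=manifest)


def _single_compound_db(mass: float) -> feature_io.ReferenceDB:
    rec = pd.DataFrame(
        {
            "formula": ["C10H20"],
            "smiles": [""],
            "monoisotopic_mass": [mass],
            "logK_octanol": [1.0],
            "frag_benzene": [0],
        },
        index=pd.Index(["X1"], name="compound_id"),
    )
    return feature_io.ReferenceDB(rec, solvents=("octanol",), fragments=("benzene",))


class TestMatchFeatures:
    @pytest.mark.parametrize(
        "ppm_offset,tol,expect",
        [
            (10.0, 10.0, True),   # exactly at tolerance: inclusive
            (10.0, 5.0, False),   # tighter window excludes
            (-10.0, 10.0, True),  # sign-symmetric
            (4.9, 5.0, True),
        ],
    )
    def test_ppm_window(self, ppm_offset, tol, expect):
        mass = 300.0
        observed_neutral = mass * (1 + ppm_offset * 1e-6)
        table = _single_feature_table(observed_neutral)  # neutral mode below
        db = _single_compound_db(mass)
        hits = match_features(table, db, ppm_tol=tol, ionization="neutral")
        assert bool(hits) is expect
        if hits:
            assert hits[0].ppm_error == pytest.approx(ppm_offset, abs=1e-6)

    def test_adduct_correction(self):
        mass = 300.0
        table = _single_feature_table(mass + 1.007276)  # [M+H]+ observed m/z
        hits = match_features(
            table, _single_compound_db(mass), ppm_tol=1.0, ionization="positive"
        )
        assert len(hits) == 1
        assert hits[0].ppm_error == pytest.approx(0.0, abs=1e-6)

    def test_empty_db_warns_and_returns_empty(self):
        table = _single_feature_table(300.0)
        db = _single_compound_db(300.0)
        db.records = db.records.iloc[:0]
        assert match_features(table, db, 10.0) == []

    @given(ppm=st.floats(min_value=0.1, max_value=50.0))
    @settings(deadline=None, derandomize=True, max_examples=30)
    def test_tightening_tolerance_never_adds_matches(self, ppm):
        mass = 250.0
        table = _single_feature_table(mass * (1 + ppm * 1e-6))
        db = _single_compound_db(mass)
        loose = match_features(table, db, ppm_tol=2 * ppm, ionization="neutral")
        tight = match_features(table, db, ppm_tol=ppm / 2, ionization="neutral")
        loose_pairs = {(m.feature_id, m.compound_id) for m in loose}
        tight_pairs = {(m.feature_id, m.compound_id) for m in tight}
        assert tight_pairs <= loose_pairs


class TestBlankFilter:
    def _table(self, sample_area, blank_area):
        features = pd.DataFrame(
            {
                "mz": [100.0],
                "rt": [1.0],
                "W_oct_r1_i1": [float(sample_area)],
                "B_r1_i1": [float(blank_area)],
            },
            index=pd.Index(["F1"], name="feature_id"),
        )
        manifest = pd.DataFrame(
            {
                "role": ["water_control", "blank"],
                "solvent": ["octanol", ""],
                "replicate": [1, 1],
                "injection": [1, 1],
            },
            index=pd.Index(["W_oct_r1_i1", "B_r1_i1"], name="sample_id"),
        )
        return feature_io.FeatureTable(features=features, manifest=manifest)

    @pytest.mark.parametrize(
        "sample,blank,retained",
        [(130.0, 100.0, True), (129.0, 100.0, False), (1.0, 0.0, True)],
    )
    def test_threshold(self, sample, blank, retained):
        result = blank_filter(self._table(sample, blank), ratio=1.3)
        assert ("F1" in result) is retained

    def test_ratio_one_keeps_at_mean_blank(self):
        assert "F1" in blank_filter(self._table(100.0, 100.0), ratio=1.0)

    def test_no_blanks_is_configuration_error(self):
        t = self._table(100.0, 100.0)
        t.manifest = t.manifest[t.manifest["role"] != "blank"]
        t.features = t.features.drop(columns=["B_r1_i1"])
        with pytest.raises(ValueError, match="blank"):
            blank_filter(t)


def test_parse_formula_roundtrip():
    assert parse_formula("C6H4Cl2") == {"C": 6, "H": 4, "Cl": 2}
    with pytest.raises(FormatError):
        parse_formula("C6H4Na2")  # element outside the alphabet
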