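"""Feature-table CSV dialect, class vocabulary, and the mzML/MGF adapters."""

import base64
import struct

import pytest

from nestmark.features import (
    CLASS_WHITE,
    Feature,
    FeatureTableError,
    Run,
    Spectrum,
    known_classes,
    read_feature_table,
    read_mzml_centroids,
    read_spectra_mgf,
    write_feature_table,
    write_spectra_mgf,
)
from nestmark.simulate import GeneratorConfig, generate_cohort

HEADER = "run_id,class,batch,mz,rt_min,area,charge,amount_mg"


class TestFeatureTableCsv:
    def test_empty_file_with_header_gives_zero_runs(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text(HEADER + "\n")
        runs, features = read_feature_table(path)
        assert runs == {} and features == []

    def test_missing_mandatory_column_named(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("run_id,class,batch,mz,rt_min\nr1,white_EBN,b1,500,10\n")
        with pytest.raises(FeatureTableError, match="'area'"):
            read_feature_table(path)

    def test_negative_area_rejected_with_line_number(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text(HEADER + "\nr1,white_EBN,b1,500.1,10.0,-1,,\n")
        with pytest.raises(FeatureTableError, match="line 2"):
            read_feature_table(path)

    def test_unknown_class_rejected_by_name(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text(HEADER + "\nr1,green_EBN,b1,500.1,10.0,5,,\n")
        with pytest.raises(FeatureTableError, match="green_EBN"):
            read_feature_table(path)

    def test_class_vocabulary_extends_only_by_config(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text(HEADER + "\nr1,adulterant:konjac,b1,500.1,10.0,5,,\n")
        with pytest.raises(FeatureTableError):
            read_feature_table(path)
        runs, features = read_feature_table(path, extra_adulterants=["konjac"])
        assert len(features) == 1
        assert "adulterant:konjac" in known_classes(["konjac"])

    def test_published_screen_as_single_run_table(self, tmp_path, screen):
        # the 58 published m/z+RT pairs encoded as one white-EBN run
        path = tmp_path / "screen.csv"
        lines = [HEADER] + [
            f"w1,{CLASS_WHITE},b1,{row.mz},{row.rt},1000,," for _, row in screen.iterrows()
        ]
        path.write_text("\n".join(lines) + "\n")
        runs, features = read_feature_table(path)
        assert len(runs) == 1
        assert len(features) == 58

    def test_round_trip_identity_at_six_decimals(self, tmp_path):
        runs = {
            "r1": Run("r1", CLASS_WHITE, "b1"),
            "r2": Run("r2", "calibration", "b2", amount_mg=10.0),
        }
        features = [
            Feature(454.701812, 10.243355, 123456.654321, "r1", 2),
            Feature(447.699623, 9.811111, 98765.123456, "r2", None),
        ]
        path = tmp_path / "t.csv"
        write_feature_table(runs, features, path)
        runs2, features2 = read_feature_table(path)
        assert runs2 == runs
        assert features2 == features
        # byte-stable: writing what was read reproduces the file exactly
        path2 = tmp_path / "t2.csv"
        write_feature_table(runs2, features2, path2)
        assert path.read_text() == path2.read_text()

    def test_round_trip_preserves_run_count_on_synthetic_cohort(self, tmp_path):
        cohort = generate_cohort(GeneratorConfig(seed=3, class_sizes={CLASS_WHITE: 3}))
        path = tmp_path / "cohort.csv"
        write_feature_table(cohort.runs, cohort.features, path)
        runs, features = read_feature_table(path)
        assert len(runs) == len(cohort.runs)
        assert len(features) == len(cohort.features)

    def test_header_order_is_fixed(self, tmp_path):
        path = tmp_path / "t.csv"
        write_feature_table({}, [], path)
        assert path.read_text().splitlines()[0] == HEADER


def _b64(values):
    return base64.b64encode(struct.pack(f"<{len(values)}d", *values)).decode()


def _binary_array(values, accession, name):
    data = _b64(values)
    return (
        f'<binaryDataArray encodedLength="{len(data)}">'
        '<cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>'
        '<cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>'
        f'<cvParam cvRef="MS" accession="{accession}" name="{name}" value=""/>'
        f"<binary>{data}</binary></binaryDataArray>"
    )


def _mzml_doc(spectra_xml):
    return (
        '<?xml version="1.0" encoding="utf-8"?>'
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0"><run id="r1">'
        f'<spectrumList count="{len(spectra_xml)}">' + "".join(spectra_xml)
        + "</spectrumList></run></mzML>"
    )


def _ms1_scan(index, rt_min, mzs, intensities, mode="centroid spectrum"):
    return (
        f'<spectrum index="{index}" id="scan={index + 1}" defaultArrayLength="{len(mzs)}">'
        '<cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>'
        f'<cvParam cvRef="MS" accession="MS:1000127" name="{mode}" value=""/>'
        "<scanList count=\"1\"><scan>"
        f'<cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{rt_min}" unitName="minute"/>'
        "</scan></scanList>"
        '<binaryDataArrayList count="2">'
        + _binary_array(mzs, "MS:1000514", "m/z array")
        + _binary_array(intensities, "MS:1000515", "intensity array")
        + "</binaryDataArrayList></spectrum>"
    )


class TestMzmlAdapter:
    def test_two_ms1_scans_recover_two_features(self, tmp_path):
        doc = _mzml_doc(
            [_ms1_scan(0, 5.5, [400.2], [1000.0]), _ms1_scan(1, 6.0, [500.3], [2000.0])]
        )
        path = tmp_path / "two.mzML"
        path.write_text(doc)
        features, spectra = read_mzml_centroids(path)
        assert len(features) == 2 and spectra == []
        assert features[0].mz == pytest.approx(400.2)
        assert features[1].rt == pytest.approx(6.0)

    def test_floor_above_all_intensities_gives_zero_features(self, tmp_path):
        path = tmp_path / "f.mzML"
        path.write_text(_mzml_doc([_ms1_scan(0, 5.5, [400.2], [1000.0])]))
        features, _ = read_mzml_centroids(path, intensity_floor=1e6)
        assert features == []

    def test_profile_mode_rejected(self, tmp_path):
        path = tmp_path / "p.mzML"
        path.write_text(_mzml_doc([_ms1_scan(0, 5.5, [400.2], [1000.0], mode="profile spectrum")]))
        with pytest.raises(ValueError, match="profile-mode"):
            read_mzml_centroids(path)

    def test_no_ms2_scans_gives_empty_spectrum_list(self, tmp_path):
        path = tmp_path / "n.mzML"
        path.write_text(_mzml_doc([_ms1_scan(0, 1.0, [300.0, 301.0], [10.0, 20.0])]))
        _, spectra = read_mzml_centroids(path)
        assert spectra == []


class TestSpectrumAndMgf:
    def test_peaks_sorted_by_mz(self):
        s = Spectrum(500.0, 2, ((300.0, 5.0), (200.0, 3.0)), "r1")
        assert s.fragment_mzs == [200.0, 300.0]

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            Spectrum(500.0, 2, ((300.0, -5.0),), "r1")

    def test_mgf_round_trip(self, tmp_path):
        s = Spectrum(500.25, 2, ((175.119, 10.0), (203.066, 20.0)), "runA", 9.8)
        path = tmp_path / "s.mgf"
        write_spectra_mgf([s], path)
        (back,) = read_spectra_mgf(path)
        assert back.precursor_mz == pytest.approx(500.25)
        assert back.precursor_charge == 2
        assert back.run_id == "runA"
        assert back.rt == pytest.approx(9.8)
        assert back.peaks == s.peaks
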