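import json

import numpy as np
import pytest

from mpmkit.core_io import (
    AcquisitionMetadata,
    GridError,
    ImageVolume,
    MetadataError,
    MultiEchoSeries,
    ProvenanceRecord,
    assert_common_grid,
    load_series,
    map_output_path,
    read_volume,
    validate_provenance_dict,
    write_map,
    write_volume,
)


def _vol(shape=(5, 5, 5), value=1.0, voxel=1.0):
    return ImageVolume.from_array(np.full(shape, value), voxel_size=voxel)


class TestImageVolume:
    def test_nonfinite_voxels_are_zeroed_and_counted(self):
        data = np.ones((4, 4, 4))
        data[0, 0, 0] = np.nan
        data[1, 1, 1] = np.inf
        v = ImageVolume.from_array(data)
        assert v.n_nonfinite == 2
        assert v.data[0, 0, 0] == 0 and np.isfinite(v.data).all()

    def test_rejects_non_3d_and_bad_voxel_size(self):
        with pytest.raises(ValueError):
            ImageVolume.from_array(np.ones((4, 4)))
        with pytest.raises(ValueError):
            ImageVolume.from_array(np.ones((4, 4, 4)), voxel_size=0.0)


class TestAcquisitionMetadata:
    def test_sidecar_units_are_converted_to_ms(self):
        meta = AcquisitionMetadata.from_sidecars(
            [
                {"RepetitionTime": 0.025, "EchoTime": 0.0023, "FlipAngle": 6,
                 "ContrastLabel": "PDw"},
                {"RepetitionTime": 0.025, "EchoTime": 0.0046, "FlipAngle": 6,
                 "ContrastLabel": "PDw"},
            ]
        )
        assert meta.tr_ms == pytest.approx(25.0)
        assert meta.te_ms == pytest.approx((2.3, 4.6))
        assert meta.flip_angle_deg == 6

    def test_missing_required_field_names_the_field(self):
        with pytest.raises(MetadataError, match="RepetitionTime"):
            AcquisitionMetadata.from_sidecars([{"EchoTime": 0.002, "FlipAngle": 6}])

    @pytest.mark.parametrize(
        "kw",
        [
            dict(contrast_label="FLAIR"),
            dict(flip_angle_deg=0.0),
            dict(flip_angle_deg=95.0),
            dict(tr_ms=-1.0),
            dict(te_ms=(3.0, 2.0)),
            dict(te_ms=()),
            dict(mt_pulse=True),  # PDw with MT pulse is inconsistent
        ],
    )
    def test_invariant_violations_raise(self, kw):
        base = dict(contrast_label="PDw", flip_angle_deg=6.0, tr_ms=25.0, te_ms=(2.3, 4.6))
        base.update(kw)
        with pytest.raises(MetadataError):
            AcquisitionMetadata(**base)

    def test_mt_flag_falls_back_to_contrast_label(self):
        meta = AcquisitionMetadata.from_sidecars(
            [{"RepetitionTime": 0.025, "EchoTime": 0.002, "FlipAngle": 6, "MTState": True}]
        )
        assert meta.contrast_label == "MTw" and meta.mt_pulse


class TestVolumeIO:
    def test_write_read_round_trip_is_bit_exact_for_float32(self, tmp_path):
        rng = np.random.default_rng(0)
        data = rng.normal(size=(6, 7, 8)).astype(np.float32)
        vol = ImageVolume.from_array(data, voxel_size=1.5)
        p = write_volume(vol, tmp_path / "x.nii")
        back, meta = read_volume(p)
        assert meta is None
        np.testing.assert_array_equal(back.data.astype(np.float32), data)

    def test_read_volume_without_sidecar_returns_absent_metadata(self, tmp_path):
        p = write_volume(_vol(), tmp_path / "plain.nii")
        _, meta = read_volume(p)
        assert meta is None

    def test_read_volume_with_sidecar(self, tmp_path):
        p = write_volume(_vol(), tmp_path / "pdw_e1.nii")
        (tmp_path / "pdw_e1.json").write_text(
            json.dumps({"RepetitionTime": 0.025, "EchoTime": 0.0023, "FlipAngle": 6,
                        "ContrastLabel": "PDw"})
        )
        _, meta = read_volume(p)
        assert meta is not None and meta.tr_ms == pytest.approx(25.0)

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(IOError):
            read_volume(tmp_path / "absent.nii")

    def test_load_series_orders_echoes_by_te(self, tmp_path):
        for j, te in [(1, 0.0046), (2, 0.0023)]:
            p = write_volume(_vol(value=float(j)), tmp_path / f"e{j}.nii")
            (tmp_path / f"e{j}.json").write_text(
                json.dumps({"RepetitionTime": 0.025, "EchoTime": te, "FlipAngle": 6,
                            "ContrastLabel": "PDw"})
            )
        ser = load_series([tmp_path / "e1.nii", tmp_path / "e2.nii"])
        assert ser.meta.te_ms == pytest.approx((2.3, 4.6))
        assert ser.volumes[0].data[0, 0, 0] == 2.0  # shorter TE comes first


class TestOutputNaming:
    @pytest.mark.parametrize(
        "kind,expected",
        [
            ("PD", "Results/sub01_pdw_e1_PD.nii"),
            ("R2s_OLS", "Results/sub01_pdw_e1_R2s_OLS.nii"),
            ("R2s", "Results/Supplementary/sub01_pdw_e1_R2s.nii"),
            ("PDw_TEzero", "Results/Supplementary/sub01_pdw_e1_PDw_OLSfit_TEzero.nii"),
            ("B1map", "Results/Supplementary/sub01_pdw_e1_B1map.nii"),
        ],
    )
    def test_naming_is_pure_function_of_kind_and_basename(self, kind, expected):
        got = map_output_path(kind, "/out", "/data/sub01_pdw_e1.nii")
        assert str(got) == f"/out/{expected}"
        assert map_output_path(kind, "/out", "/data/sub01_pdw_e1.nii") == got

    def test_unknown_kind_raises(self):
        with pytest.raises(ValueError):
            map_output_path("T2", "/out", "x.nii")

    def test_write_map_emits_nii_and_provenance_json(self, tmp_path):
        prov = ProvenanceRecord()
        prov.add("fit", {"n": 3})
        p = write_map(_vol(), "PD", tmp_path, "sub01_pdw_e1.nii", prov)
        assert p.name == "sub01_pdw_e1_PD.nii" and p.exists()
        back = ProvenanceRecord.from_json(p.with_suffix(".json").read_text())
        assert back.to_dict() == prov.to_dict()

    def test_collision_creates_run_subfolder_never_overwrites(self, tmp_path):
        prov = ProvenanceRecord()
        p1 = write_map(_vol(value=1.0), "PD", tmp_path, "s_pdw_e1.nii", prov)
        p2 = write_map(_vol(value=2.0), "PD", tmp_path, "s_pdw_e1.nii", prov)
        assert p1 != p2 and "run-02" in str(p2)
        v1, _ = read_volume(p1)
        assert v1.data[0, 0, 0] == 1.0


class TestProvenance:
    def test_json_round_trip_identity(self):
        prov = ProvenanceRecord()
        prov.add("simulate", {"seed": 3, "sigma": 0.5}, inputs=["a.nii"])
        prov.add("fit", {"contrasts": ["PDw", "T1w"]})
        assert ProvenanceRecord.from_json(prov.to_json()).to_dict() == prov.to_dict()

    def test_numpy_values_are_serialisable(self):
        prov = ProvenanceRecord()
        prov.add("x", {"v": np.float64(1.5), "arr": np.arange(3)})
        json.loads(prov.to_json())

    @pytest.mark.parametrize(
        "broken",
        [
            {"software": "x", "version": "1"},  # no steps
            {"software": "x", "version": "1", "steps": [{}]},
            {"software": "x", "version": "1",
             "steps": [{"step": "s", "params": [], "inputs": [], "timestamp": "t"}]},
        ],
    )
    def test_schema_violations_are_rejected(self, broken):
        with pytest.raises(MetadataError):
            validate_provenance_dict(broken)


class TestCommonGrid:
    def test_shared_grid_returns_descriptor(self, clean_series):
        shape, affine = assert_common_grid(list(clean_series.values()))
        assert shape == (24, 24, 24)

    def test_cropped_volume_raises_grid_error(self, clean_series):
        bad = ImageVolume.from_array(np.ones((23, 24, 24)))
        with pytest.raises(GridError):
            assert_common_grid([clean_series["PDw"], bad])

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            assert_common_grid([])

    def test_series_with_mismatched_echo_grids_rejected(self):
        meta = AcquisitionMetadata("PDw", 6.0, 25.0, (2.3, 4.6))
        with pytest.raises(GridError):
            MultiEchoSeries(meta=meta, volumes=[_vol((4, 4, 4)), _vol((5, 4, 4))])
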