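import numpy as np
import pandas as pd
import pytest

from pulsefeat import (
    FAMILY_COUNTS,
    CycleContext,
    CycleLandmarks,
    SignalKind,
    build_manifest,
    compute_vitals,
    extract_cycle_features,
    manifest_to_markdown,
    write_features,
)

FS = 256.0

# crafted cycle: piecewise-linear through the landmark values of the
# published worked example (normalized SPO=0.0 SPP=1.0 DN=0.4 DPP=0.55
# DPE=0.05)
IDX = {"SPO": 0, "SPP": 50, "DN": 120, "DPP": 150, "DPE": 205}
VAL = {"SPO": 0.0, "SPP": 1.0, "DN": 0.4, "DPP": 0.55, "DPE": 0.05}


@pytest.fixture()
def crafted_ctx():
    y = np.interp(np.arange(206), list(IDX.values()), list(VAL.values()))
    lm = CycleLandmarks(spo=0, spp=50, dn=120, dpe=205, dpp=150)
    return CycleContext(norm=y, raw=80.0 + 40.0 * y, landmarks=lm, fs=FS)


class TestManifest:
    def test_total_and_family_counts(self, manifest):
        assert len(manifest) == 852
        assert manifest.family_counts() == FAMILY_COUNTS
        assert sum(FAMILY_COUNTS.values()) == 852

    def test_names_unique(self, manifest):
        assert len(set(manifest.names)) == 852

    def test_deterministic(self, manifest):
        again = build_manifest("ABP")
        assert again.names == manifest.names
        assert [e.recipe for e in again.entries] == [e.recipe for e in manifest.entries]

    def test_published_names_present(self, manifest):
        names = set(manifest.names)
        for expected in (
            "ABP/PPG_AM_SPP_wrtSPO",
            "ABP/PPG_AM_DPP_wrtDN",
            "ABP/PPG_D_DN_wrtDPE",
            "ABP/PPG_D_SPO_wrtSPP",
        ):
            assert expected in names

    def test_markdown_dump_lists_every_feature(self, manifest):
        md = manifest_to_markdown(manifest)
        assert md.count("| ") >= 852
        assert "amplitude_ratio" in md


class TestExtraction:
    def test_amplitude_worked_example(self, crafted_ctx, manifest):
        v = extract_cycle_features(crafted_ctx, manifest)
        assert v["ABP/PPG_AM_SPP_wrtSPO"] == pytest.approx(1.0)
        assert v["ABP/PPG_AM_SPP_wrtDN"] == pytest.approx(0.6)
        assert v["ABP/PPG_AM_DPP_wrtDPE"] == pytest.approx(0.5)

    def test_duration_worked_example(self, crafted_ctx, manifest):
        v = extract_cycle_features(crafted_ctx, manifest)
        assert v["ABP/PPG_D_SPO_wrtDPE"] == pytest.approx(205 / FS)
        assert v["ABP/PPG_D_SPP_wrtDN"] == pytest.approx(70 / FS)

    def test_symmetric_triangle_has_zero_skewness(self, manifest):
        n = 201
        y = 1.0 - np.abs(np.linspace(-1, 1, n))
        lm = CycleLandmarks(spo=0, spp=100, dn=150, dpe=200)
        ctx = CycleContext(norm=y, raw=80 + 40 * y, landmarks=lm, fs=FS)
        v = extract_cycle_features(ctx, manifest)
        # exact symmetry up to the discretization of the sampled triangle
        assert abs(v["ABP/PPG_SKEW"]) < 1e-2

    def test_duration_features_invariant_to_amplitude_scale(self, crafted_ctx, manifest):
        v1 = extract_cycle_features(crafted_ctx, manifest)
        scaled = CycleContext(
            norm=crafted_ctx.norm,
            raw=3.0 * crafted_ctx.raw + 7.0,
            landmarks=crafted_ctx.landmarks,
            fs=FS,
        )
        v2 = extract_cycle_features(scaled, manifest)
        for e in manifest.entries:
            if e.family == "duration":
                assert v1[e.name] == pytest.approx(v2[e.name])

    def test_missing_dpp_yields_sentinels_not_zeros(self, manifest):
        y = np.interp(np.arange(206), list(IDX.values()), list(VAL.values()))
        lm = CycleLandmarks(spo=0, spp=50, dn=120, dpe=205, dpp=None)
        ctx = CycleContext(norm=y, raw=80 + 40 * y, landmarks=lm, fs=FS)
        v = extract_cycle_features(ctx, manifest)
        assert np.isnan(v["ABP/PPG_AM_DPP_wrtDN"])
        assert np.isnan(v["ABP/PPG_D_DPP_wrtDPE"])
        assert v["ABP/PPG_AM_SPP_wrtSPO"] == pytest.approx(1.0)

    def test_all_keys_match_manifest(self, crafted_ctx, manifest):
        v = extract_cycle_features(crafted_ctx, manifest)
        assert list(v.values.keys()) == manifest.names

    def test_too_short_cycle_rejected(self, manifest):
        lm = CycleLandmarks(spo=0, spp=1, dn=2, dpe=3)
        ctx = CycleContext(norm=np.zeros(4), raw=np.zeros(4), landmarks=lm, fs=FS)
        ctx.norm = ctx.norm[:3]
        ctx.raw = ctx.raw[:3]
        with pytest.raises(ValueError):
            extract_cycle_features(ctx, manifest)


class TestVitals:
    def test_sbp_dbp_map(self, crafted_ctx):
        sbp, dbp, mean_ap = compute_vitals(crafted_ctx)
        assert sbp == pytest.approx(120.0)
        assert dbp == pytest.approx(80.0)
        assert mean_ap == pytest.approx(float(np.mean(crafted_ctx.raw)))

    def test_ppg_rejected(self, crafted_ctx):
        ctx = CycleContext(norm=crafted_ctx.norm, raw=crafted_ctx.raw,
                           landmarks=crafted_ctx.landmarks, fs=FS,
                           kind=SignalKind.PPG)
        with pytest.raises(ValueError, match="ABP"):
            compute_vitals(ctx)


class TestWriteFeatures:
    def test_rows_and_columns(self, tmp_path, crafted_ctx, manifest):
        vecs = [extract_cycle_features(crafted_ctx, manifest, cycle_id=i)
                for i in range(3)]
        path = tmp_path / "features.csv"
        write_features(vecs, manifest, path)
        df = pd.read_csv(path)
        assert df.shape[0] == 3
        assert list(df.columns[7:]) == manifest.names
        assert len(df.columns) == 7 + 852

    def test_empty_input_writes_header_only(self, tmp_path, manifest):
        path = tmp_path / "empty.csv"
        write_features([], manifest, path)
        df = pd.read_csv(path)
        assert df.shape[0] == 0 and len(df.columns) == 859

    def test_sentinels_serialize_as_empty_cells(self, tmp_path, manifest):
        y = np.interp(np.arange(206), list(IDX.values()), list(VAL.values()))
        lm = CycleLandmarks(spo=0, spp=50, dn=120, dpe=205, dpp=None)
        ctx = CycleContext(norm=y, raw=80 + 40 * y, landmarks=lm, fs=FS)
        vec = extract_cycle_features(ctx, manifest)
        path = tmp_path / "s.csv"
        write_features([vec], manifest, path)
        raw_text = path.read_text().splitlines()[1]
        df = pd.read_csv(path)
        assert np.isnan(df["ABP/PPG_AM_DPP_wrtDN"].iloc[0])
        assert ",," in raw_text  # at least one empty cell
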