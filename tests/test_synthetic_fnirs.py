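import numpy as np
import pandas as pd
import pytest

from adaptkit.fnirs import (
    FnirsPipelineConfig,
    default_montage,
    process_recording,
)
from adaptkit.synthetic import (
    FnirsNoiseConfig,
    default_block_design,
    simulate_fnirs_recording,
)


class TestDesign:
    def test_default_design_layout(self, block_design):
        assert list(block_design["timepoint"].unique()) == ["Baseline", "EarlyAdapt"]
        assert (block_design["duration"] == 30.0).all()
        assert block_design["onset"].min() == 60.0  # after the standing rest

    def test_overlapping_blocks_refused(self, small_montage):
        bad = pd.DataFrame([
            {"timepoint": "Baseline", "block": 1, "onset": 60.0, "duration": 30.0},
            {"timepoint": "Baseline", "block": 2, "onset": 70.0, "duration": 30.0},
        ])
        with pytest.raises(ValueError, match="overlap"):
            simulate_fnirs_recording(bad, {}, FnirsNoiseConfig.off(),
                                     channels=small_montage)

    def test_cardiac_above_nyquist_refused(self):
        with pytest.raises(ValueError, match="Nyquist"):
            FnirsNoiseConfig(cardiac_freq=3.5).validate(6.1)


class TestGenerator:
    def test_flat_channels_when_no_activation_no_noise(self, small_montage,
                                                       block_design):
        noise = FnirsNoiseConfig.off()
        rec = simulate_fnirs_recording(block_design, {}, noise, seed=0,
                                       channels=small_montage)
        hbo = rec.ground_truth["hbo"]
        assert np.allclose(hbo, 0.0)

    def test_drift_only_channels_are_linear(self, small_montage, block_design):
        noise = FnirsNoiseConfig.off()
        noise = FnirsNoiseConfig(drift_amp=0.05, cardiac_amp=0.0, mayer_amp=0.0,
                                 spike_rate_hz=0.0, spike_amp=0.0,
                                 scalp_weight=0.0, scalp_amp=0.0,
                                 sensor_noise_sd=0.0)
        rec = simulate_fnirs_recording(block_design, {}, noise, seed=0,
                                       channels=small_montage)
        hbo = rec.ground_truth["hbo"]
        j = int(np.flatnonzero(~rec.channels["is_short"].to_numpy())[0])
        x = hbo[:, j]
        t = np.arange(x.size)
        resid = x - np.polyval(np.polyfit(t, x, 1), t)
        assert np.max(np.abs(resid)) < 1e-10

    def test_noiseless_roundtrip_recovers_beta(self, noiseless_recording):
        cfg = FnirsPipelineConfig(detect_spikes=False, tddr=False,
                                  short_channel_regression=False,
                                  temporal_filter=False, z_normalize=False)
        res = process_recording(noiseless_recording, cfg)
        ea = res.betas.query("timepoint == 'EarlyAdapt'")["beta"]
        assert np.allclose(ea, 0.1, atol=1e-9)

    def test_short_channels_carry_no_activation(self, small_montage,
                                                block_design):
        beta_map = {c: {"EarlyAdapt": 0.5}
                    for c in small_montage.loc[~small_montage.is_short, "channel"]}
        noise = FnirsNoiseConfig(scalp_amp=0.05, scalp_weight=0.3,
                                 drift_amp=0.0, cardiac_amp=0.0, mayer_amp=0.0,
                                 spike_rate_hz=0.0, spike_amp=0.0,
                                 sensor_noise_sd=0.0)
        rec = simulate_fnirs_recording(block_design, beta_map, noise, seed=1,
                                       channels=small_montage)
        hbo = rec.ground_truth["hbo"]
        short_idx = np.flatnonzero(rec.channels["is_short"].to_numpy())
        scalp = rec.ground_truth["scalp"]
        for j in short_idx:
            assert np.allclose(hbo[:, j], scalp)

    def test_deterministic_under_seed(self, small_montage, block_design):
        kw = dict(channels=small_montage, seed=99)
        a = simulate_fnirs_recording(block_design, {}, FnirsNoiseConfig(), **kw)
        b = simulate_fnirs_recording(block_design, {}, FnirsNoiseConfig(), **kw)
        for wl in a.intensity:
            assert np.array_equal(a.intensity[wl], b.intensity[wl])

    def test_ground_truth_stored(self, small_montage, block_design):
        beta_map = {small_montage["channel"].iloc[0]: {"EarlyAdapt": 0.2}}
        rec = simulate_fnirs_recording(block_design, beta_map,
                                       FnirsNoiseConfig(), seed=0,
                                       channels=small_montage)
        assert rec.ground_truth["betas"][small_montage["channel"].iloc[0]] == \
            {"EarlyAdapt": 0.2}
        assert "scalp" in rec.ground_truth


class TestMontage:
    def test_standard_montage_counts(self):
        mont = default_montage()
        assert (~mont["is_short"]).sum() == 48
        assert mont["is_short"].sum() == 8

    def test_roi_bilateral_symmetry(self):
        mont = default_montage()
        roi_rows = mont[mont["roi"].notna()]
        for roi, grp in roi_rows.groupby("roi"):
            counts = grp["hemisphere"].value_counts()
            assert counts.get("L", 0) == counts.get("R", 0)

    def test_no_channel_in_two_rois(self):
        from adaptkit.fnirs import roi_map_from_channels

        mont = default_montage()
        roi_map = roi_map_from_channels(mont)
        all_members = [c for v in roi_map.values() for c in v]
        assert len(all_members) == len(set(all_members))
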