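import numpy as np
import pytest

from adaptkit.fnirs import (
    FnirsPipelineConfig,
    process_recording,
    short_channel_regress,
    correct_motion_tddr,
    intensity_to_od,
    od_to_haemo,
)
from adaptkit.synthetic import (
    FnirsNoiseConfig,
    default_block_design,
    simulate_fnirs_recording,
)


class TestNoiselessRoundTrip:
    def test_beta_recovered_exactly_linear_chain(self, noiseless_recording):
        """conversion -> (no spikes) -> SCR -> GLM recovers the injected beta
        to float tolerance (TDDR and z-scoring excluded: neither is an
        identity map by construction; they are tested separately)."""
        cfg = FnirsPipelineConfig(detect_spikes=True, tddr=False,
                                  short_channel_regression=True,
                                  temporal_filter=False, z_normalize=False)
        res = process_recording(noiseless_recording, cfg)
        ea = res.betas.query("timepoint == 'EarlyAdapt'")["beta"].to_numpy()
        base = res.betas.query("timepoint == 'Baseline'")["beta"].to_numpy()
        assert np.allclose(ea, 0.1, atol=1e-7)
        assert np.allclose(base, 0.0, atol=1e-7)

    def test_no_spikes_flagged_on_flat_recording(self, small_montage,
                                                 block_design):
        # zero activation + zero noise: nothing for the spike detector
        # (block onsets of a strong clean response ARE legitimate triggers,
        # so the flat recording is the right null fixture here)
        rec = simulate_fnirs_recording(block_design, {}, FnirsNoiseConfig.off(),
                                       seed=0, channels=small_montage)
        res = process_recording(rec, FnirsPipelineConfig(z_normalize=False))
        assert sum(res.qc["spike_counts"].values()) == 0


@pytest.fixture
def standard_noisy_recording(small_montage, block_design):
    beta_map = {c: {"EarlyAdapt": 0.1}
                for c in small_montage.loc[~small_montage.is_short, "channel"]}
    return simulate_fnirs_recording(block_design, beta_map, FnirsNoiseConfig(),
                                    seed=11, channels=small_montage)


class TestScalpRemoval:
    def test_removes_90pct_of_scalp_variance(self, standard_noisy_recording):
        rec = standard_noisy_recording
        scalp = rec.ground_truth["scalp"]
        w = rec.ground_truth["scalp_weight"]
        od = {wl: intensity_to_od(rec.intensity[wl]) for wl in rec.intensity}
        hbo, _ = od_to_haemo(od)
        sc = scalp - scalp.mean()
        denom = float(sc @ sc)
        removed = []
        short_idx = np.flatnonzero(rec.channels["is_short"].to_numpy())
        long_idx = np.flatnonzero(~rec.channels["is_short"].to_numpy())
        shorts = np.column_stack([
            correct_motion_tddr(hbo[:, j], rec.fs) for j in short_idx])
        injected_var = np.var(w * scalp)
        for j in long_idx:
            x = correct_motion_tddr(hbo[:, j], rec.fs)
            resid, _ = short_channel_regress(x, shorts)
            leftover = float(resid @ sc) / denom  # scalp weight remaining
            removed.append(1.0 - (leftover ** 2 * np.var(scalp)) / injected_var)
        assert np.mean(removed) >= 0.9

    def test_qc_reports_chosen_short_and_sci(self, standard_noisy_recording):
        res = process_recording(standard_noisy_recording)
        long_names = standard_noisy_recording.long_channels["channel"]
        assert set(res.qc["chosen_short"]) == set(long_names)
        assert len(res.qc["sci"]) == len(standard_noisy_recording.channels)
        # no automatic rejection by SCI: channels only flagged, never dropped
        assert res.betas["channel"].nunique() == len(long_names)


class TestContrastRecovery:
    def test_injected_activation_sign_recovered_full_chain(self,
                                                           standard_noisy_recording):
        res = process_recording(standard_noisy_recording)
        wide = res.roi_contrasts.query("roi == 'all'")["contrast"].iloc[0]
        assert wide > 0  # activation present at EarlyAdapt

    def test_z_scale_recorded_for_unscaling(self, standard_noisy_recording):
        res = process_recording(standard_noisy_recording)
        assert len(res.z_scale) == len(standard_noisy_recording.channels)
        assert all(v > 0 for v in res.z_scale.values())


class TestOrthogonalityInvariant:
    def test_glm_residuals_orthogonal_to_design(self, noiseless_recording):
        from adaptkit.fnirs.glm import build_design

        rec = noiseless_recording
        od = {wl: intensity_to_od(rec.intensity[wl]) for wl in rec.intensity}
        hbo, _ = od_to_haemo(od)
        y = hbo[:, 0]
        X, names = build_design(rec.events, y.size, rec.fs)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        assert np.allclose(X.T @ resid, 0.0, atol=1e-6)
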