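"""Respirometry chain: drift correction, window selection, rate equations."""

import numpy as np
import pandas as pd
import pytest

from metabehave import (
    SimConfig,
    compute_vco2,
    compute_vo2,
    correct_baseline_drift,
    estimate_rmr,
    generate_respirometry_session,
    mass_correct,
    select_window,
)
from metabehave.respirometry import (
    RespirometryError,
    RespirometrySession,
    read_sessions_csv,
)


def _flat_session(o2=0.2095, co2=0.0004, flow=1600.0, b1=60, animal=400, b2=60):
    n = b1 + animal + b2
    t = np.arange(n, dtype=float)
    seg = ["baseline1"] * b1 + ["animal"] * animal + ["baseline2"] * b2
    data = pd.DataFrame(
        {"time_s": t, "segment": seg, "o2_frac": o2, "co2_frac": co2}
    )
    return RespirometrySession(data=data, flow_rate_ml_min=flow)


class TestSessionValidation:
    def test_rejects_nonmonotone_time(self):
        s = _flat_session()
        data = s.data.copy()
        data.loc[5, "time_s"] = 0.0
        with pytest.raises(RespirometryError, match="increasing"):
            RespirometrySession(data=data, flow_rate_ml_min=1600.0)

    def test_rejects_out_of_range_fractions(self):
        s = _flat_session()
        data = s.data.copy()
        data.loc[3, "o2_frac"] = 1.5
        with pytest.raises(RespirometryError, match="o2_frac"):
            RespirometrySession(data=data, flow_rate_ml_min=1600.0)

    def test_rejects_segment_disorder(self):
        s = _flat_session()
        data = s.data.copy()
        data["segment"] = data["segment"].to_numpy()[::-1]
        with pytest.raises(RespirometryError, match="order"):
            RespirometrySession(data=data, flow_rate_ml_min=1600.0)

    def test_missing_baseline_named_in_error(self):
        s = _flat_session()
        data = s.data[s.data["segment"] != "baseline2"]
        sess = RespirometrySession(data=data, flow_rate_ml_min=1600.0)
        with pytest.raises(RespirometryError, match="baseline2"):
            correct_baseline_drift(sess)


class TestDriftCorrection:
    def test_identity_when_baselines_agree(self):
        s = correct_baseline_drift(_flat_session())
        assert np.allclose(s.data["o2_incurrent"], 0.2095)
        assert np.allclose(s.data["co2_incurrent"], 0.0004)

    def test_midpoint_interpolation(self):
        """Baseline means 0.20950 and 0.20900 interpolate to 0.20925 midway."""
        s = _flat_session()
        data = s.data.copy()
        o2 = np.full(len(data), 0.2095)
        b2 = data["segment"] == "baseline2"
        o2[b2.to_numpy()] = 0.2090
        data["o2_frac"] = o2
        sess = correct_baseline_drift(
            RespirometrySession(data=data, flow_rate_ml_min=1600.0)
        )
        t1 = data.loc[data["segment"] == "baseline1", "time_s"].mean()
        t2 = data.loc[b2, "time_s"].mean()
        mid = 0.5 * (t1 + t2)
        i = (data["time_s"] - mid).abs().idxmin()
        assert sess.data.loc[i, "o2_incurrent"] == pytest.approx(0.20925, abs=2e-6)


class TestRateEquations:
    def test_zero_when_excurrent_equals_incurrent(self):
        s = correct_baseline_drift(_flat_session())
        w = (s.animal_start_s + 50.0, s.animal_start_s + 350.0)
        assert compute_vo2(s, w) == pytest.approx(0.0, abs=1e-9)
        assert compute_vco2(s, w) == pytest.approx(0.0, abs=1e-9)

    def test_printed_arithmetic_oracle(self):
        """FiO2 0.2095, FeO2 0.2050, flow 1600 -> 9.108 ml/min (and the
        CO2 counterpart 0.0046 vs 0.0004 -> 6.723 ml/min)."""
        s = _flat_session()
        data = s.data.copy()
        animal = (data["segment"] == "animal").to_numpy()
        data.loc[animal, "o2_frac"] = 0.2050
        data.loc[animal, "co2_frac"] = 0.0046
        sess = correct_baseline_drift(
            RespirometrySession(data=data, flow_rate_ml_min=1600.0)
        )
        w = (sess.animal_start_s, sess.animal_start_s + 300.0)
        assert compute_vo2(sess, w) == pytest.approx(
            (0.2095 - 0.2050) / (1 - 0.2095) * 1600, abs=1e-9
        )
        assert compute_vo2(sess, w) == pytest.approx(9.108, abs=5e-4)
        assert compute_vco2(sess, w) == pytest.approx(
            (0.0046 - 0.0004) / (1 - 0.0004) * 1600, abs=1e-9
        )
        assert compute_vco2(sess, w) == pytest.approx(6.723, abs=5e-4)

    def test_flow_homogeneity(self):
        """Doubling flow while halving the concentration deficit leaves the
        rate unchanged."""
        def rate(flow, deficit):
            s = _flat_session(flow=flow)
            data = s.data.copy()
            animal = (data["segment"] == "animal").to_numpy()
            data.loc[animal, "o2_frac"] = 0.2095 - deficit
            sess = correct_baseline_drift(
                RespirometrySession(data=data, flow_rate_ml_min=flow)
            )
            w = (sess.animal_start_s, sess.animal_start_s + 300.0)
            return compute_vo2(sess, w)

        assert rate(1600.0, 0.0045) == pytest.approx(rate(3200.0, 0.00225), rel=1e-9)

    def test_mass_correction(self):
        assert mass_correct(9.108, 300.0) == pytest.approx(0.03036, abs=1e-6)
        assert mass_correct(0.0, 250.0) == 0.0
        with pytest.raises(RespirometryError):
            mass_correct(9.108, 0.0)


class TestGeneratorRoundTrip:
    def test_recovers_true_rates_zero_noise(self, clean_config):
        """Past five washout time constants the inverted equations give the
        injected rates back to 0.1%."""
        s = generate_respirometry_session(
            clean_config, 9.108, 6.723, seed=0, animal_min=70
        )
        sess = correct_baseline_drift(s)
        a0 = sess.animal_start_s
        w = (a0 + 60 * 60.0, a0 + 65 * 60.0)
        assert compute_vo2(sess, w) == pytest.approx(9.108, rel=1e-3)
        assert compute_vco2(sess, w) == pytest.approx(6.723, rel=1e-3)

    def test_linear_drift_removed(self):
        config = SimConfig(
            seed=0, noise_sd_frac=0.0, baseline_drift_frac_per_min=5e-5
        )
        s = correct_baseline_drift(
            generate_respirometry_session(config, 9.108, 6.723, seed=0, animal_min=70)
        )
        a0 = s.animal_start_s
        w = (a0 + 60 * 60.0, a0 + 65 * 60.0)
        assert compute_vo2(s, w) == pytest.approx(9.108, rel=5e-3)

    def test_vo2_vco2_correlated_across_batch(self, default_config, rng):
        """Generated with proportional true rates, estimated VO2 and VCO2
        correlate strongly, as paired gas-exchange measures should."""
        vo2s, vco2s = [], []
        for k in range(12):
            true = 6.0 + 8.0 * rng.random()
            s = generate_respirometry_session(
                default_config, true, 0.85 * true, seed=int(rng.integers(2**31))
            )
            est = estimate_rmr(s)
            vo2s.append(est.vo2_ml_min)
            vco2s.append(est.vco2_ml_min)
        assert np.corrcoef(vo2s, vco2s)[0, 1] > 0.95


class TestWindowSelection:
    def test_default_window_on_clean_trace(self, default_config):
        s = correct_baseline_drift(
            generate_respirometry_session(default_config, 9.108, 6.723, seed=3)
        )
        start, end, flag = select_window(s)
        assert flag == "default_window"
        assert start == pytest.approx(s.animal_start_s + 13 * 60.0, abs=1.5)
        assert end - start == pytest.approx(300.0)

    def test_spike_excluded(self, default_config):
        """A spike injected at minutes 14-15 pushes the window off the
        default and the chosen window avoids the spiked interval."""
        s = generate_respirometry_session(default_config, 9.108, 6.723, seed=4)
        data = s.data.copy()
        a0 = s.animal_start_s
        t = data["time_s"].to_numpy()
        spike = (t >= a0 + 14 * 60) & (t <= a0 + 15 * 60)
        data.loc[spike, "o2_frac"] += 0.003
        sess = correct_baseline_drift(
            RespirometrySession(data=data, flow_rate_ml_min=s.flow_rate_ml_min)
        )
        start, end, flag = select_window(sess)
        assert flag == "shifted_window"
        assert end < a0 + 14 * 60 or start > a0 + 15 * 60

    def test_short_animal_segment_rejected(self):
        s = _flat_session(animal=200)
        with pytest.raises(RespirometryError, match="300 s"):
            select_window(s)


def test_sessions_csv_round_trip(tmp_path, clean_config):
    from metabehave import generate_dataset, write_dataset_csvs

    config = SimConfig(seed=7, n_chicks=2, rmr_sessions_per_chick=2,
                       sample_period_s=5.0)
    dataset = generate_dataset(config)
    paths = write_dataset_csvs(dataset, tmp_path)
    sessions = read_sessions_csv(paths["sessions"])
    assert len(sessions) == 4
    original = dataset.sessions[0]
    loaded = next(s for s in sessions if s.session_id == original.session_id)
    assert np.allclose(
        loaded.data["o2_frac"].to_numpy(), original.data["o2_frac"].to_numpy()
    )
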