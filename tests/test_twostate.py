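"""Telegraph-model simulator: waveforms, stationarity, exactness, design scans."""

import math

import numpy as np
import pytest

from globtx.twostate import (
    GlobalWaveform,
    SimConfig,
    TwoStateParams,
    min_reporters_for_detection,
    regulon_design_study,
    simulate_cell,
    simulate_reporter,
    temporal_cv,
    waveform_multiplier,
)


class TestWaveform:
    def test_constant_is_identity(self):
        w = GlobalWaveform(kind="constant", amplitude=0.0)
        assert waveform_multiplier(w, 17.3) == 1.0

    def test_sine_value(self):
        # 1 + 0.7*sin(2*pi*3/12) = 1 + 0.7*sin(pi/2)
        w = GlobalWaveform(kind="sine", amplitude=0.7, period_hr=12.0, phase=0.0)
        assert waveform_multiplier(w, 3.0) == pytest.approx(1.7, abs=1e-12)

    def test_sine_mean_over_period_is_one(self):
        w = GlobalWaveform(kind="sine", amplitude=0.5, period_hr=8.0)
        t = np.linspace(0.0, 8.0, 4801)[:-1]
        assert w.series(t).mean() == pytest.approx(1.0, abs=1e-6)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="kind"):
            GlobalWaveform(kind="square")

    def test_amplitude_bounds(self):
        with pytest.raises(ValueError):
            GlobalWaveform(kind="sine", amplitude=1.0)
        with pytest.raises(ValueError):
            GlobalWaveform(kind="sine", amplitude=-0.1)

    def test_smoothed_random_normalization(self):
        w = GlobalWaveform(kind="smoothed_random", amplitude=0.6, seed=5)
        t = np.arange(0, 48, 1 / 6)
        m = w.series(t)
        assert m.min() > 0
        assert m.mean() == pytest.approx(1.0, rel=0.01)
        assert m.std() == pytest.approx(0.6 / math.sqrt(2), rel=0.15)

    def test_smoothed_random_reproducible(self):
        w = GlobalWaveform(kind="smoothed_random", amplitude=0.4, seed=9)
        t = np.arange(0, 24, 1 / 6)
        assert np.array_equal(w.series(t), w.series(t))


class TestStationarity:
    def test_on_occupancy_and_mean_nascent(self, params, flat_wave):
        # long-run ON occupancy -> k_on/(k_on+k_off) = 2/3 and
        # mean nascent -> p_on * k_m / k_s = 0.5, both within 3 SE
        cfg = SimConfig(duration_hr=600.0, dt_sample_min=10.0, burn_in_hr=5.0)
        tr = simulate_reporter(params, flat_wave, cfg, seed=42)
        keep = tr.times_hr >= cfg.burn_in_hr
        occ = tr.on_states[keep].mean()
        # ~ (duration/correlation time) independent samples
        tau_hr = 1.0 / (params.k_on_per_hr + params.k_off_per_hr)
        n_eff = (600.0 - 5.0) / (2 * tau_hr)
        se_occ = math.sqrt(params.p_on * (1 - params.p_on) / n_eff)
        assert abs(occ - 2.0 / 3.0) < 3 * se_occ

        counts = tr.nascent_counts[keep].astype(float)
        se_mean = counts.std() / math.sqrt(n_eff)
        assert abs(counts.mean() - 0.5) < 3 * se_mean

    def test_mean_nascent_under_sine(self, params):
        # <m> = 1 so the stationary mean is unchanged under sine modulation
        w = GlobalWaveform(kind="sine", amplitude=0.7, period_hr=12.0)
        cfg = SimConfig(duration_hr=600.0, dt_sample_min=10.0, burn_in_hr=5.0)
        tr = simulate_reporter(params, w, cfg, seed=7)
        counts = tr.nascent_counts[tr.times_hr >= 5.0].astype(float)
        assert counts.mean() == pytest.approx(0.5, abs=0.06)

    def test_zero_synthesis_rate_gives_empty_trace(self, flat_wave):
        p = TwoStateParams(k_m_per_min=0.0)
        tr = simulate_reporter(p, flat_wave, SimConfig(duration_hr=48.0), seed=3)
        assert np.all(tr.nascent_counts == 0)

    def test_two_step_variant_matches_one_step_mean(self, flat_wave):
        # with each elongation stage at 2*k_s the total dwell is 1/k_s, so the
        # standing nascent total has the same stationary mean as one step
        cfg = SimConfig(duration_hr=600.0, dt_sample_min=10.0, burn_in_hr=5.0)
        tr2 = simulate_reporter(TwoStateParams(elongation_steps=2), flat_wave, cfg, seed=11)
        counts = tr2.nascent_counts[tr2.times_hr >= 5.0].astype(float)
        assert counts.min() >= 0
        assert counts.mean() == pytest.approx(0.5, abs=0.06)

    def test_production_channel_accounts_for_standing_count(self, params, flat_wave):
        # standing count never exceeds cumulative initiations (conservation)
        tr = simulate_reporter(
            params, flat_wave, SimConfig(duration_hr=48.0), seed=5, stationary_init=False
        )
        cum = np.cumsum(tr.production_counts)
        assert np.all(tr.nascent_counts <= cum)


def _oracle_ssa(p, m_vals, sub_dt_hr, duration_hr, sample_dt_hr, seed):
    """Brute-force time-inhomogeneous SSA, coded independently of the package.

    Same draw protocol (one uniform for the promoter init, then per event one
    uniform for the exponential target and one for the reaction choice) but a
    naive window-scanning structure and dict-based state.
    """
    rng = np.random.default_rng(seed)
    state = {"on": rng.random() < p.k_on_per_hr / (p.k_on_per_hr + p.k_off_per_hr), "n": 0}
    km, ks = p.k_m_per_min * 60.0, p.k_s_per_min * 60.0
    n_samp = int(round(duration_hr / sample_dt_hr)) + 1
    out = np.zeros(n_samp, dtype=np.int64)
    out[0] = 0
    next_samp = 1
    t = 0.0
    while True:
        target = -math.log(rng.random())
        # naive scan: walk windows until the integrated propensity reaches target
        area = 0.0
        tt = t
        while True:
            win = int(tt / sub_dt_hr + 1e-9)  # epsilon: tt may sit on a boundary
            m = m_vals[win] if win < len(m_vals) else m_vals[-1]
            prop = (p.k_off_per_hr if state["on"] else p.k_on_per_hr) + ks * state["n"]
            if state["on"]:
                prop += km * m
            win_end = (win + 1) * sub_dt_hr
            if area + prop * (win_end - tt) >= target:
                t_fire = tt + (target - area) / prop
                break
            area += prop * (win_end - tt)
            tt = win_end
            if tt >= duration_hr - 1e-12:
                t_fire = duration_hr
                break
        while next_samp < n_samp and next_samp * sample_dt_hr <= t_fire + 1e-12:
            out[next_samp] = state["n"]
            next_samp += 1
        t = t_fire
        if t >= duration_hr - 1e-12:
            break
        u = rng.random() * prop
        a_sw = p.k_off_per_hr if state["on"] else p.k_on_per_hr
        fire_win = int(t / sub_dt_hr + 1e-9)
        a_syn = km * (m_vals[fire_win] if fire_win < len(m_vals) else m_vals[-1])
        a_syn = a_syn if state["on"] else 0.0
        if u < a_sw:
            state["on"] = not state["on"]
        elif u < a_sw + a_syn:
            state["n"] += 1
        else:
            state["n"] -= 1
    while next_samp < n_samp:
        out[next_samp] = state["n"]
        next_samp += 1
    return out


class TestExactness:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_trajectory_matches_brute_force_oracle(self, params, seed):
        # frozen random stream + piecewise-constant m(t): the package core and
        # an independently coded naive SSA must agree sample-by-sample
        cfg = SimConfig(duration_hr=24.0, dt_sample_min=10.0)
        n_sub = int(24.0 * 60.0)
        t_mid = (np.arange(n_sub) + 0.5) / 60.0
        m_vals = 1.0 + 0.5 * np.sign(np.sin(2 * np.pi * t_mid / 8.0))  # 2-level signal
        tr = simulate_reporter(
            params, None, cfg, seed=seed, m_vals=m_vals, stationary_init=False
        )
        oracle = _oracle_ssa(params, m_vals, 1 / 60.0, 24.0, 1 / 6.0, seed)
        assert np.array_equal(tr.nascent_counts, oracle)


class TestSimulateCell:
    def test_single_reporter_sum_is_trace(self, params, sine_wave):
        cfg = SimConfig(duration_hr=12.0, n_reporters=1)
        cell = simulate_cell(params, sine_wave, cfg, seed=1)
        assert np.array_equal(cell.summed, cell.traces[0].nascent_counts)

    def test_no_shared_signal_no_correlation(self, params, flat_wave):
        # summed traces of separate cells are uncorrelated when A = 0
        cfg = SimConfig(duration_hr=48.0, n_reporters=5)
        corrs = []
        for seed in range(8):
            a = simulate_cell(params, flat_wave, cfg, seed=seed).summed.astype(float)
            b = simulate_cell(params, flat_wave, cfg, seed=100 + seed).summed.astype(float)
            corrs.append(np.corrcoef(a, b)[0, 1])
        assert abs(np.mean(corrs)) < 3 * np.std(corrs) / math.sqrt(len(corrs)) + 0.1

    def test_summing_recovers_global_signal(self, params, sine_wave):
        # averaging removes gene-specific noise: the 20-reporter sum correlates
        # with m(t) better than single traces do on average
        cfg = SimConfig(duration_hr=48.0, n_reporters=20)
        cell = simulate_cell(params, sine_wave, cfg, seed=2)
        keep = cell.times_hr >= 2.0
        m = cell.multiplier[keep]
        corr_sum = np.corrcoef(cell.summed[keep].astype(float), m)[0, 1]
        corr_single = np.mean(
            [
                np.corrcoef(tr.nascent_counts[keep].astype(float), m)[0, 1]
                for tr in cell.traces
            ]
        )
        assert corr_sum > corr_single


class TestMinReporters:
    def test_sentinel_when_no_global_signal(self, params, flat_wave, sim48):
        n, table = min_reporters_for_detection(
            params, flat_wave, sim48, max_n=3, n_replicates=2, seed=0
        )
        assert n == 4  # max_n + 1 sentinel
        assert not table.satisfied.any()

    def test_deterministic_oracle_needs_one_reporter(self, params, sine_wave, sim48):
        # mean-field reporters carry m(t) exactly: one copy suffices
        n, _ = min_reporters_for_detection(
            params, sine_wave, sim48, max_n=5, mode="deterministic"
        )
        assert n == 1

    def test_monotone_in_amplitude(self, params, sim48):
        # more global signal -> fewer reporters needed (fixed seed bank)
        results = []
        for a in (0.1, 0.4, 0.7):
            w = GlobalWaveform(kind="sine", amplitude=a, period_hr=12.0)
            n, _ = min_reporters_for_detection(
                params, w, sim48, max_n=12, n_replicates=10, seed=123
            )
            results.append(n)
        assert results[0] >= results[1] >= results[2]
        assert results[2] <= 12  # the strong-modulation case is detectable


class TestRegulonDesign:
    def test_single_regulon_reduces_to_cell(self, params, sine_wave):
        cfg = SimConfig(duration_hr=24.0, n_reporters=4, regulon_assignment=("default",) * 4)
        res = regulon_design_study(params, sine_wave, cfg, seed=5)
        assert set(res["summed"]) == {"default"}
        assert res["summed"]["default"].sum() > 0

    def test_inter_regulon_correlation_below_signal_correlation(self, params, sine_wave):
        # each regulon tracks m(t) better than it tracks the other regulon
        cfg = SimConfig(
            duration_hr=48.0, n_reporters=20, regulon_assignment=("X",) * 10 + ("Y",) * 10
        )
        diffs = []
        for seed in range(4):
            res = regulon_design_study(params, sine_wave, cfg, seed=seed)
            inter = res["inter_regulon_corr"].loc["X", "Y"]
            diffs.append(min(res["corr_with_multiplier"].values()) - inter)
        assert np.mean(diffs) > 0

    def test_no_signal_no_inter_regulon_correlation(self, params, flat_wave):
        cfg = SimConfig(
            duration_hr=48.0, n_reporters=10, regulon_assignment=("X",) * 5 + ("Y",) * 5
        )
        vals = [
            regulon_design_study(params, flat_wave, cfg, seed=s)["inter_regulon_corr"].loc["X", "Y"]
            for s in range(6)
        ]
        assert abs(np.mean(vals)) < 0.15


class TestTemporalCv:
    def test_burn_in_discarded(self):
        times = np.arange(10.0)
        trace = np.array([100.0, 100.0] + [5.0] * 8)
        assert temporal_cv(trace, times, burn_in_hr=2.0) == 0.0

    def test_zero_mean_is_nan(self):
        assert math.isnan(temporal_cv(np.zeros(10), np.arange(10.0)))
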