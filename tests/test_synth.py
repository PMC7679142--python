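"""Ground-truth checks on the synthetic session generator."""

import numpy as np
import pytest
from scipy import stats

from pavnet.synth import (
    Coupling,
    EventTrain,
    Oscillation,
    SynthConfig,
    SchedulingError,
    generate_calcium,
    generate_coupled_pair,
    generate_session,
)


def _session_events_sorted(trains):
    return [tr.event_times for tr in trains]


class TestGenerateSession:
    def test_determinism_same_seed(self, small_session):
        cfg, (trains, tl, lfps, ca, mo) = small_session
        trains2, tl2, lfps2, ca2, mo2 = generate_session(cfg)
        for a, b in zip(trains, trains2):
            np.testing.assert_array_equal(a.event_times, b.event_times)
        assert tl.cs_trials == tl2.cs_trials
        assert tl.behavior_episodes == tl2.behavior_episodes
        for r in lfps:
            np.testing.assert_array_equal(lfps[r].samples, lfps2[r].samples)
        np.testing.assert_array_equal(mo.motion, mo2.motion)

    def test_rate_fidelity_within_3se(self):
        cfg = SynthConfig(
            n_neurons_per_region={"aIC": 30},
            baseline_rate={"aIC": 0.2},
            session_length=1000.0,
            n_trials_per_cs=2,
            seed=5,
        )
        trains, *_ = generate_session(cfg)
        p = 0.2
        n_bins = 1000
        se = np.sqrt(p * (1 - p) / n_bins)
        rates = np.array([tr.n_events / n_bins for tr in trains])
        # population mean within 3 SE of the pooled estimate
        assert abs(rates.mean() - p) < 3 * se / np.sqrt(len(rates))
        # individual neurons: allow the expected ~0.3% tail at 3 SE
        assert np.mean(np.abs(rates - p) < 3 * se) >= 29 / 30

    def test_no_coupling_baseline_conditional(self):
        cfg = SynthConfig(
            n_neurons_per_region={"aIC": 3, "CE_SST": 3},
            baseline_rate={"aIC": 0.2, "CE_SST": 0.2},
            coupling=[Coupling("aIC", "CE_SST", 0.0, 1)],
            session_length=2000.0,
            n_trials_per_cs=2,
            seed=7,
        )
        trains, *_ = generate_session(cfg)
        src = next(tr for tr in trains if tr.region == "aIC")
        tgt = next(tr for tr in trains if tr.region == "CE_SST")
        xb = np.zeros(2000, dtype=int)
        xb[np.floor(src.event_times).astype(int)] = 1
        yb = np.zeros(2000, dtype=int)
        yb[np.floor(tgt.event_times).astype(int)] = 1
        cond = yb[1:][xb[:-1] == 1].mean()
        p = 0.2
        n = (xb[:-1] == 1).sum()
        assert abs(cond - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_cs_modulation_raises_rate(self):
        amp = 4.0
        cfg = SynthConfig(
            n_neurons_per_region={"aIC": 20},
            baseline_rate={"aIC": 0.15},
            cs_response_amp={("aIC", "R", "recall"): amp, ("aIC", "F", "recall"): amp},
            session_length=600.0,
            n_trials_per_cs=6,
            seed=3,
        )
        trains, tl, *_ = generate_session(cfg)
        cs_bins = set()
        for on, _ in tl.cs_trials:
            cs_bins.update(range(int(on), int(on) + 10))
        counts_in = counts_out = n_in = n_out = 0
        for tr in trains:
            bins = np.floor(tr.event_times).astype(int)
            counts_in += np.isin(bins, list(cs_bins)).sum()
            counts_out += (~np.isin(bins, list(cs_bins))).sum()
        n_in = len(cs_bins) * len(trains)
        n_out = (600 - len(cs_bins)) * len(trains)
        assert counts_in / n_in > 2.5 * (counts_out / n_out)

    def test_lfp_oscillation_power(self, small_session):
        cfg, (_, _, lfps, _, _) = small_session
        from scipy.signal import periodogram

        f, p = periodogram(lfps["pIC"].samples, fs=1000.0)
        band = (f > 30) & (f < 36)
        neighbor = ((f > 40) & (f < 46)) | ((f > 20) & (f < 26))
        assert p[band].max() > 5 * p[neighbor].max()

    def test_infeasible_schedule_raises(self):
        with pytest.raises(SchedulingError):
            generate_session(
                SynthConfig(session_length=100.0, n_trials_per_cs=6, seed=0)
            )

    def test_us_follows_matching_cs_in_conditioning(self):
        cfg = SynthConfig(
            n_neurons_per_region={"aIC": 2},
            baseline_rate={"aIC": 0.1},
            stage="C_early",
            session_length=600.0,
            n_trials_per_cs=6,
            seed=1,
        )
        _, tl, *_ = generate_session(cfg)
        assert len(tl.us_events) == len(tl.cs_trials)
        for (t_us, us_type), (on, cs_type) in zip(tl.us_events, tl.cs_trials):
            assert us_type == cs_type
            assert t_us == pytest.approx(on + 10.0)


class TestCoupledPair:
    def test_zero_excess_independent(self):
        # chi-square on the lagged 2x2 table: non-significant at alpha=0.01
        # for >= 95% of 100 seeds
        n_sig = 0
        for seed in range(100):
            x, y = generate_coupled_pair(2000, 0.2, 0.0, 1, seed=seed)
            x, y = x.astype(np.int64), y.astype(np.int64)
            table = np.array(
                [
                    [(1 - x[:-1]) @ (1 - y[1:]), (1 - x[:-1]) @ y[1:]],
                    [x[:-1] @ (1 - y[1:]), x[:-1] @ y[1:]],
                ]
            )
            _, p, _, _ = stats.chi2_contingency(table)
            n_sig += p < 0.01
        assert n_sig <= 5

    def test_deterministic_copy(self):
        x, y = generate_coupled_pair(200, 0.3, 1.0, 1, seed=4, p_base_y=0.0)
        np.testing.assert_array_equal(y[1:], x[:-1])
        assert y[0] == 0

    def test_excess_probability_recovered(self):
        x, y = generate_coupled_pair(10_000, 0.2, 0.3, 1, seed=9)
        p1 = y[1:][x[:-1] == 1].mean()
        p0 = y[1:][x[:-1] == 0].mean()
        assert abs((p1 - p0) - 0.3) < 0.03

    def test_lagged_odds_ratio_matches_count_oracle(self):
        x, y = generate_coupled_pair(5000, 0.2, 0.5, 1, seed=2)
        # independent 2x2 count oracle
        a = b = c = d = 0
        for t in range(len(x) - 1):
            if x[t] and y[t + 1]:
                a += 1
            elif x[t] and not y[t + 1]:
                b += 1
            elif not x[t] and y[t + 1]:
                c += 1
            else:
                d += 1
        oracle_or = (a * d) / (b * c)
        xa = x[:-1].astype(bool)
        ya = y[1:].astype(bool)
        impl_or = ((xa & ya).sum() * (~xa & ~ya).sum()) / (
            (xa & ~ya).sum() * (~xa & ya).sum()
        )
        assert impl_or == pytest.approx(oracle_or, rel=1e-12)
        # configured parameters imply OR = (p0+e)(1-p0) / ((1-p0-e) p0)
        expected = (0.7 * 0.8) / (0.3 * 0.2)
        assert impl_or == pytest.approx(expected, rel=0.25)

    def test_invalid_probability_raises(self):
        with pytest.raises(ValueError):
            generate_coupled_pair(100, 1.5, 0.2)
        with pytest.raises(ValueError):
            generate_coupled_pair(2, 0.2, 0.2, lag=1)


class TestGenerateCalcium:
    def test_no_events_flat_zero(self):
        tr = EventTrain("n0", "CEm", "recall", np.array([]))
        ca = generate_calcium(tr, amp=1.0, tau_decay=0.2, noise_sd=0.0, fs=20, duration=5.0)
        np.testing.assert_allclose(ca.dff, 0.0)

    def test_single_event_peak_amp(self):
        tr = EventTrain("n0", "CEm", "recall", np.array([1.0]))
        ca = generate_calcium(tr, amp=2.5, tau_decay=0.2, noise_sd=0.0, fs=20, duration=3.0)
        assert ca.dff[20] == pytest.approx(2.5)
        assert ca.dff[:20].max() == 0.0

    def test_double_exponential_closed_form(self):
        amp, tau, fs = 1.3, 0.2, 50.0
        tr = EventTrain("n0", "CEm", "recall", np.array([0.5, 1.5]))
        ca = generate_calcium(tr, amp=amp, tau_decay=tau, noise_sd=0.0, fs=fs, duration=3.0)
        t = np.arange(int(3.0 * fs)) / fs
        expected = np.zeros_like(t)
        for t0 in (0.5, 1.5):
            expected += np.where(t >= t0, amp * np.exp(-(t - t0) / tau), 0.0)
        np.testing.assert_allclose(ca.dff, expected, atol=1e-12)

    def test_raw_f0_consistency(self):
        tr = EventTrain("n0", "CEm", "recall", np.array([0.2]))
        ca = generate_calcium(tr, amp=1.0, tau_decay=0.3, noise_sd=0.01, fs=20, seed=1, duration=2.0)
        np.testing.assert_allclose((ca.raw - ca.f0) / ca.f0, ca.dff, atol=1e-9)

    def test_bad_params_raise(self):
        tr = EventTrain("n0", "CEm", "recall", np.array([]))
        with pytest.raises(ValueError):
            generate_calcium(tr, amp=-1, tau_decay=0.2, noise_sd=0, fs=20)
        with pytest.raises(ValueError):
            generate_calcium(tr, amp=1, tau_decay=0.2, noise_sd=0, fs=0)
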