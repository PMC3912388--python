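"""PSTHs, permutation significance, response classification, correlograms."""

import numpy as np
import pytest

from cerecoh import simulate as sim
from cerecoh import units
from cerecoh.config import AnalysisConfig
from cerecoh.core import EpochSet, SpikeTrain


class TestPSTH:
    def test_empty_train(self, train_protocol, config):
        tr = SpikeTrain("empty", [], span=(0.0, 200.0))
        h = units.compute_psth(tr, train_protocol, config)
        assert np.all(h.rate == 0) and h.baseline_rate == 0.0

    def test_one_spike_per_trial_counting_identity(self, config):
        proto = sim.gen_stim_protocol("train", 10)
        times = proto.train_onsets + 0.55
        tr = SpikeTrain("u", times, span=(0.0, proto.pulse_times[-1] + 6))
        h = units.compute_psth(tr, proto, config)
        target = np.flatnonzero(h.rate)
        assert target.size == 1
        assert h.rate[target[0]] == pytest.approx(10.0)   # 1 spike / 0.1 s
        assert h.bin_centers[target[0]] == pytest.approx(0.55)

    def test_spike_conservation_exact(self, train_protocol, config):
        tr = sim.gen_unit_spikes(sim.UnitProfileParams(category="biphasic",
                                                       seed=3), train_protocol)
        h = units.compute_psth(tr, train_protocol, config)
        total = sum(tr.in_window(o - 2.0, o + 5.0).size
                    for o in train_protocol.train_onsets)
        assert np.sum(h.rate * h.bin_width * h.n_trials) == pytest.approx(
            total, abs=1e-9)

    def test_smoothing_conserves_area(self, train_protocol, config):
        tr = sim.gen_unit_spikes(sim.UnitProfileParams(category="increase",
                                                       seed=4), train_protocol)
        h = units.compute_psth(tr, train_protocol, config)
        assert np.sum(h.smoothed_rate) == pytest.approx(np.sum(h.rate), rel=0.01)

    def test_homogeneous_rate_within_bootstrap_interval(self, config):
        proto = sim.gen_stim_protocol("train", 33)
        tr = sim.gen_unit_spikes(sim.UnitProfileParams(category="none",
                                                       baseline_rate=5.0,
                                                       seed=5), proto)
        h = units.compute_psth(tr, proto, config)
        cover = np.mean((h.rate - 3 * h.boot_err <= 5.0)
                        & (5.0 <= h.rate + 3 * h.boot_err))
        assert cover >= 0.95


class TestPermutationSignificance:
    def test_few_permutations_guarded(self, train_protocol, config):
        tr = sim.gen_unit_spikes(sim.UnitProfileParams(seed=0), train_protocol)
        with pytest.raises(ValueError, match="10,000"):
            units.permutation_significance(tr, train_protocol, config,
                                           n_permutations=100)

    def test_too_few_trials_rejected(self, config):
        proto = sim.gen_stim_protocol("train", 3)
        tr = sim.gen_unit_spikes(sim.UnitProfileParams(seed=0), proto)
        with pytest.raises(ValueError, match="trials"):
            units.permutation_significance(tr, proto, config)

    def test_alpha_zero_nothing_significant(self, train_protocol):
        cfg = AnalysisConfig(alpha=1e-12)
        tr = sim.gen_unit_spikes(sim.UnitProfileParams(category="decrease",
                                                       seed=1), train_protocol)
        res = units.permutation_significance(tr, train_protocol, cfg,
                                             n_permutations=1000,
                                             allow_fewer=True)
        assert not res.mask.any()

    def test_decrease_bins_flagged(self, train_protocol, config):
        tr = sim.gen_unit_spikes(sim.UnitProfileParams(category="decrease",
                                                       seed=2), train_protocol)
        res = units.permutation_significance(tr, train_protocol, config,
                                             n_permutations=2000,
                                             allow_fewer=True)
        stim_bins = (res.psth.bin_centers > 0) & (res.psth.bin_centers < 1.0)
        assert np.sum(res.mask & stim_bins & (res.signs < 0)) >= 2

    def test_null_p_values_superuniform(self, config):
        # rotation null on a homogeneous train: pooled p-values should not
        # concentrate below uniform (Kolmogorov distance bound)
        ps = []
        for s in range(15):
            proto = sim.gen_stim_protocol("train", 20)
            tr = sim.gen_unit_spikes(sim.UnitProfileParams(category="none",
                                                           seed=s), proto)
            res = units.permutation_significance(tr, proto, config,
                                                 n_permutations=500,
                                                 allow_fewer=True, seed=s)
            ps.extend(res.p_values.tolist())
        ps = np.sort(ps)
        grid = np.linspace(0, 1, 21)[1:]
        ecdf = np.searchsorted(ps, grid, side="right") / len(ps)
        assert np.max(ecdf - grid) <= 0.05


class TestClassification:
    def test_empty_mask_is_none(self, train_protocol, config):
        tr = sim.gen_unit_spikes(sim.UnitProfileParams(category="none", seed=9),
                                 train_protocol)
        sig = units.permutation_significance(tr, train_protocol, config,
                                             n_permutations=1000,
                                             allow_fewer=True)
        sig.mask[:] = False
        sig.signs[:] = 0
        cls = units.classify_response(sig.psth, sig, config)
        assert cls.category == "none"
        assert cls.significant_bins.size == 0

    @pytest.mark.parametrize("category", ["increase", "decrease", "biphasic",
                                          "none"])
    def test_recovers_programmed_category(self, category, train_protocol, config):
        tr = sim.gen_unit_spikes(sim.UnitProfileParams(category=category,
                                                       seed=21), train_protocol)
        cls = units.classify_unit(tr, train_protocol, config,
                                  n_permutations=2000, allow_fewer=True, seed=3)
        assert cls.category == category

    def test_decrease_magnitude_near_programmed_depth(self, train_protocol,
                                                      config):
        mags = []
        for s in range(15):
            tr = sim.gen_unit_spikes(sim.UnitProfileParams(
                category="decrease", modulation_depth=0.7, seed=s),
                train_protocol)
            cls = units.classify_unit(tr, train_protocol, config,
                                      n_permutations=1000, allow_fewer=True,
                                      seed=s)
            if cls.magnitude_pct is not None:
                mags.append(cls.magnitude_pct)
        assert np.mean(mags) == pytest.approx(30.0, abs=5.0)

    def test_biphasic_time_to_peak_near_rebound(self, train_protocol, config):
        ttp = []
        for s in range(8):
            tr = sim.gen_unit_spikes(sim.UnitProfileParams(
                category="biphasic", rebound_lag=2.0, seed=40 + s),
                train_protocol)
            cls = units.classify_unit(tr, train_protocol, config,
                                      n_permutations=1000, allow_fewer=True,
                                      seed=s)
            if cls.category == "biphasic":
                ttp.append(cls.time_to_peak)
        assert len(ttp) >= 6
        assert abs(np.mean(ttp) - 2.0) <= 0.2

    def test_tabulate_counts(self):
        cls = [units.ResponseClassification(c, None, None, np.array([]),
                                            np.array([]), 1.0)
               for c in ("increase", "decrease", "decrease", "none")]
        t = units.tabulate_categories(cls, ["a", "a", "b", "b"])
        assert t.counts.tolist() == [[1, 1, 0, 0], [0, 1, 0, 1]]

    def test_tabulate_empty(self):
        t = units.tabulate_categories([], [])
        assert t.counts.sum() == 0

    def test_tabulate_single_group(self):
        cls = [units.ResponseClassification("none", None, None, np.array([]),
                                            np.array([]), 1.0)]
        t = units.tabulate_categories(cls, ["only"])
        assert t.counts.shape == (1, 4)


class TestCorrelograms:
    def test_independent_trains_flat(self, config):
        proto = sim.gen_stim_protocol("train", 40)
        vals = []
        for s in range(25):
            a = sim.gen_unit_spikes(sim.UnitProfileParams(category="none",
                                                          seed=2 * s), proto)
            b = sim.gen_unit_spikes(sim.UnitProfileParams(category="none",
                                                          seed=2 * s + 1), proto)
            c = units.crosscorrelogram(a, b, proto, "pre", config, seed=s)
            vals.append(c.corrected)
        vals = np.array(vals)
        mean = vals.mean(axis=0)
        se = vals.std(axis=0, ddof=1) / np.sqrt(vals.shape[0])
        assert np.all(np.abs(mean) <= 3.2 * se + 1e-12)

    def test_autocorrelogram_zero_lag_masked(self, config):
        proto = sim.gen_stim_protocol("train", 20)
        a = sim.gen_unit_spikes(sim.UnitProfileParams(category="none", seed=3),
                                proto)
        c = units.crosscorrelogram(a, a, proto, "pre", config, seed=0)
        center = np.argmin(np.abs(c.lags))
        assert np.isnan(c.corrected[center])
        rest = np.delete(c.corrected, center)
        assert np.all(np.isfinite(rest))

    def test_lags_symmetric(self, config):
        proto = sim.gen_stim_protocol("train", 10)
        a = sim.gen_unit_spikes(sim.UnitProfileParams(category="none", seed=1),
                                proto)
        b = sim.gen_unit_spikes(sim.UnitProfileParams(category="none", seed=2),
                                proto)
        c = units.crosscorrelogram(a, b, proto, "pre", config, seed=0)
        np.testing.assert_allclose(c.lags, -c.lags[::-1])

    def test_slow_wave_side_peaks(self, config):
        proto = sim.gen_stim_protocol("train", 40)
        dur = proto.pulse_times[-1] + 10
        acc = None
        for s in range(6):
            trains = sim.gen_slow_wave_spikes(2, depth=0.8, duration=dur, seed=s)
            c = units.crosscorrelogram(trains[0], trains[1], proto, "pre",
                                       config, seed=50 + s)
            acc = c.corrected if acc is None else acc + c.corrected
        acc /= 6
        lags = c.lags
        # local maxima at 0 and +-1.0 s (one-bin tolerance), minima near 0.5
        i_peak = np.argmax(np.where(np.abs(lags) <= 0.04, acc, -np.inf))
        assert abs(lags[i_peak]) <= 0.04
        for side in (+1.0, -1.0):
            wide = (np.abs(lags - side) <= 0.2)
            trough = (np.abs(np.abs(lags) - 0.5) <= 0.1)
            assert acc[wide].max() > acc[trough].mean()
            i_side = np.argmax(np.where(wide, acc, -np.inf))
            assert abs(abs(lags[i_side]) - 1.0) <= 0.08

    def test_no_spikes_rejected(self, config):
        proto = sim.gen_stim_protocol("train", 10)
        a = SpikeTrain("e1", [], span=(0.0, 100.0))
        b = SpikeTrain("e2", [], span=(0.0, 100.0))
        with pytest.raises(ValueError, match="no spikes"):
            units.crosscorrelogram(a, b, proto, "pre", config)


class TestStateCompare:
    def test_identical_correlograms_null_result(self, config):
        proto = sim.gen_stim_protocol("train", 20)
        dur = proto.pulse_times[-1] + 10
        cs = []
        for s in range(3):
            trains = sim.gen_slow_wave_spikes(2, duration=dur, seed=s)
            cs.append(units.crosscorrelogram(trains[0], trains[1], proto,
                                             "pre", config, seed=s))
        res = units.correlogram_state_compare(cs, cs)
        for t in res.tests.values():
            assert t.p_value == 1.0

    def test_modulation_loss_detected(self, config):
        proto = sim.gen_stim_protocol("train", 30)
        dur = proto.pulse_times[-1] + 10
        stim_eps = EpochSet(np.column_stack([proto.train_onsets,
                                             proto.train_onsets + 2.0]))
        pre, stim = [], []
        for s in range(20):
            t_mod = sim.gen_slow_wave_spikes(2, depth=0.8, duration=dur,
                                             seed=s, suppress_epochs=stim_eps)
            pre.append(units.crosscorrelogram(t_mod[0], t_mod[1], proto, "pre",
                                              config, seed=s))
            stim.append(units.crosscorrelogram(t_mod[0], t_mod[1], proto,
                                               "stim", config, seed=s))
        res = units.correlogram_state_compare(pre, stim)
        t = res.tests["modulation_depth"]
        d_pre = np.mean([f["modulation_depth"] for f in res.features_pre])
        d_stim = np.mean([f["modulation_depth"] for f in res.features_stim])
        assert d_pre > d_stim
        assert t.p_value < 0.05

    def test_single_pair_df_warning(self, config):
        proto = sim.gen_stim_protocol("train", 10)
        a = sim.gen_unit_spikes(sim.UnitProfileParams(category="none", seed=1),
                                proto)
        b = sim.gen_unit_spikes(sim.UnitProfileParams(category="none", seed=2),
                                proto)
        c1 = units.crosscorrelogram(a, b, proto, "pre", config, seed=0)
        c2 = units.crosscorrelogram(a, b, proto, "stim", config, seed=0)
        with pytest.warns(UserWarning, match="single pair"):
            res = units.correlogram_state_compare([c1], [c2])
        assert res.tests["modulation_depth"] is not None

    def test_mismatched_lists_rejected(self, config):
        with pytest.raises(ValueError, match="match"):
            units.correlogram_state_compare([], [None])
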