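"""Spike-cycle statistics: phases, PPC1, rate metrics, waveform classes."""

import numpy as np
import pandas as pd
import pytest

import gammacycle as gc
from gammacycle.containers import SpikeTrainSet


class TestSpikePhase:
    @pytest.mark.parametrize("t,expected", [
        (0.0, 0.0),
        (0.010, np.pi),
        (0.015, 3 * np.pi / 2),
    ])
    def test_linear_interpolation(self, t, expected):
        assert gc.spike_phase(t, 0.0, 0.020) == pytest.approx(expected)

    def test_spike_outside_cycle_rejected(self):
        with pytest.raises(ValueError):
            gc.spike_phase(0.020, 0.0, 0.020)  # end is exclusive


class TestPPC1:
    def test_identical_phases_give_one(self):
        phases = np.full(30, 1.2)
        trials = np.repeat(np.arange(3), 10)
        assert gc.ppc1(phases, trials) == pytest.approx(1.0)

    def test_two_opposed_trials_give_minus_one(self):
        assert gc.ppc1(np.array([0.0, np.pi]),
                       np.array([0, 1])) == pytest.approx(-1.0)

    def test_uniform_phases_unbiased_near_zero(self):
        rng = np.random.default_rng(0)
        vals = []
        for _ in range(1000):
            n = 40
            phases = rng.uniform(0, 2 * np.pi, n)
            trials = rng.integers(0, 5, n)
            if len(np.unique(trials)) < 2:
                continue
            vals.append(gc.ppc1(phases, trials))
        vals = np.asarray(vals)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean()) < 3 * se + 1e-3

    def test_invariant_to_within_trial_spike_duplication(self):
        rng = np.random.default_rng(1)
        phases = rng.uniform(0, 2 * np.pi, 60)
        trials = np.repeat(np.arange(6), 10)
        base = gc.ppc1(phases, trials)
        doubled = gc.ppc1(np.r_[phases, phases], np.r_[trials, trials])
        assert doubled == pytest.approx(base, abs=1e-12)

    def test_invariant_to_global_phase_rotation(self):
        rng = np.random.default_rng(2)
        phases = rng.uniform(0, 2 * np.pi, 50)
        trials = np.repeat(np.arange(5), 10)
        assert gc.ppc1(phases + 1.234, trials) == pytest.approx(
            gc.ppc1(phases, trials), abs=1e-12)

    def test_single_trial_rejected(self):
        with pytest.raises(ValueError):
            gc.ppc1(np.array([0.1, 0.2]), np.array([0, 0]))


def make_cycle_table(durations, fs=1000.0, trial=0):
    """Contiguous full-cycle rows (peak-peak) with the given durations."""
    from gammacycle.containers import CYCLE_COLUMNS, HalfCycleTable

    rows = []
    t0 = 0.0
    for k, d in enumerate(durations):
        rows.append({
            "trial": trial, "channel": 0, "epoch_id": 0, "cycle_index": k,
            "polarity": "peak-peak",
            "start_index": int(t0 * fs), "end_index": int((t0 + d) * fs),
            "start_time": t0, "end_time": t0 + d,
            "start_extremum_value": 1.0, "end_extremum_value": 1.0,
            "amplitude": 1.0, "duration": d, "frequency": 1.0 / d,
        })
        t0 += d
    return HalfCycleTable(df=pd.DataFrame(rows, columns=CYCLE_COLUMNS),
                          sampling_rate=fs)


class TestPerCycleMetrics:
    def test_homogeneous_spikes_count_negative_rate_null(self):
        rng = np.random.default_rng(3)
        tables = []
        spikes = []
        for tr in range(8):
            durs = rng.uniform(0.01, 0.04, 300)
            tab = make_cycle_table(durs, trial=tr)
            tables.append(tab.df)
            total = tab.df["end_time"].max()
            st = np.sort(rng.uniform(0, total, int(100 * total)))
            spikes.append(pd.DataFrame({
                "unit_id": 0, "trial": tr, "time_s": st}))
        from gammacycle.containers import HalfCycleTable

        table = HalfCycleTable(df=pd.concat(tables, ignore_index=True),
                               sampling_rate=1000.0)
        sts = SpikeTrainSet(df=pd.concat(spikes, ignore_index=True))
        m = gc.per_cycle_spike_metrics(sts, table, cycle_kind="half")
        assert m.correlations["count_vs_frequency"] < -0.2
        assert abs(m.correlations["rate_vs_frequency"]) < 0.1

    def test_constructed_rate_frequency_coupling_detected(self):
        rng = np.random.default_rng(4)
        durs = rng.uniform(0.01, 0.04, 500)
        table = make_cycle_table(durs)
        rows = []
        t0 = 0.0
        for d in durs:
            # rate proportional to cycle frequency
            lam = 200.0 / d * 0.02
            n = rng.poisson(lam * d)
            rows.extend({"unit_id": 0, "trial": 0,
                         "time_s": t} for t in np.sort(
                             rng.uniform(t0, t0 + d, n)))
            t0 += d
        sts = SpikeTrainSet(df=pd.DataFrame(rows,
                                            columns=["unit_id", "trial",
                                                     "time_s"]))
        m = gc.per_cycle_spike_metrics(sts, table, cycle_kind="half")
        assert m.correlations["rate_vs_frequency"] > 0.2

    def test_count_equals_rate_times_duration(self, modulated_spikes,
                                              trial_table):
        from gammacycle.spikestats import _spikes_in_cycles

        per = _spikes_in_cycles(modulated_spikes, trial_table.full_cycles())
        per = per[per["count"] > 0]
        np.testing.assert_allclose(
            per["count"], (per["count"] / per["duration"]) * per["duration"])

    def test_no_overlap_rejected(self):
        table = make_cycle_table([0.02] * 10)
        sts = SpikeTrainSet(df=pd.DataFrame(
            {"unit_id": [0], "trial": [5], "time_s": [0.01]}))
        with pytest.raises(ValueError):
            gc.per_cycle_spike_metrics(sts, table, cycle_kind="half")


class TestPhaseBinProfile:
    def test_uniform_spikes_give_flat_profile(self):
        rng = np.random.default_rng(5)
        durs = rng.uniform(0.015, 0.03, 400)
        table = make_cycle_table(durs)
        total = table.df["end_time"].max()
        st = np.sort(rng.uniform(0, total, 4000))
        sts = SpikeTrainSet(df=pd.DataFrame(
            {"unit_id": 0, "trial": 0, "time_s": st}))
        prof = gc.phase_bin_profile(sts, table, cycle_kind="half")
        pooled = 0.5 * (prof["short"] + prof["long"])
        assert pooled.std() / pooled.mean() < 0.1
        assert abs(prof["short_minus_long_at_preferred"]) < 0.15
        assert abs(prof["short_minus_long_at_nonpreferred"]) < 0.15

    def test_all_spikes_in_one_bin_give_indicator(self):
        # two duration classes so the median split is non-degenerate; every
        # spike lands at 1/16 of its cycle, i.e. phase bin 0 of 8
        durs = [0.02, 0.03] * 50
        table = make_cycle_table(durs)
        starts = table.df["start_time"].to_numpy()
        st = starts + np.asarray(durs) / 16.0
        sts = SpikeTrainSet(df=pd.DataFrame(
            {"unit_id": 0, "trial": 0, "time_s": st}))
        prof = gc.phase_bin_profile(sts, table, cycle_kind="half")
        pooled = prof["short"] + prof["long"]
        assert np.argmax(pooled) == 0
        assert pooled[1:].sum() == 0

    def test_deeper_troughs_in_long_cycles_suppress_nonpreferred(
            self, modulated_spikes, trial_table):
        prof = gc.phase_bin_profile(modulated_spikes, trial_table)
        assert (prof["short_minus_long_at_nonpreferred"]
                > prof["short_minus_long_at_preferred"])


class TestWaveformClass:
    def test_broad(self):
        assert gc.classify_waveform(0.30) == "BW"

    def test_narrow(self):
        assert gc.classify_waveform(0.20) == "NW"

    def test_boundary_ties_to_narrow_with_warning(self):
        with pytest.warns(UserWarning):
            assert gc.classify_waveform(0.235) == "NW"

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            gc.classify_waveform(float("nan"))


class TestLeadLag:
    def test_independent_rates_and_durations_uncorrelated(self, trial_table):
        rng = np.random.default_rng(6)
        # homogeneous spikes: rate in the rising half-cycle carries no
        # information about the next half-cycle's duration
        rows = []
        for tr in range(trial_table.df["trial"].nunique()):
            total = trial_table.df[trial_table.df["trial"] == tr][
                "end_time"].max()
            st = np.sort(rng.uniform(0, total, 120))
            rows.append(pd.DataFrame(
                {"unit_id": 0, "trial": tr, "time_s": st}))
        sts = SpikeTrainSet(df=pd.concat(rows, ignore_index=True))
        rho = gc.leadlag_rate_duration(sts, trial_table)
        assert abs(rho) < 0.15

    def test_constructed_predictive_rate_detected(self):
        from gammacycle.containers import CYCLE_COLUMNS, HalfCycleTable

        rng = np.random.default_rng(7)
        rows, spikes = [], []
        t0 = 0.0
        k = 0
        for _ in range(300):
            d_next = rng.uniform(0.01, 0.03)
            d_up = 0.02
            # trough->peak half-cycle whose rate encodes the next duration
            rate = 20000.0 * d_next
            n = rng.poisson(rate * d_up)
            spikes.extend(np.sort(rng.uniform(t0, t0 + d_up, n)))
            for pol, d in (("trough-peak", d_up), ("peak-trough", d_next)):
                rows.append({
                    "trial": 0, "channel": 0, "epoch_id": 0,
                    "cycle_index": k, "polarity": pol,
                    "start_index": int(t0 * 1000),
                    "end_index": int((t0 + d) * 1000),
                    "start_time": t0, "end_time": t0 + d,
                    "start_extremum_value": 0.0, "end_extremum_value": 1.0,
                    "amplitude": 1.0, "duration": d,
                    "frequency": 1 / (2 * d)})
                k += 1
                t0 += d
        table = HalfCycleTable(df=pd.DataFrame(rows, columns=CYCLE_COLUMNS),
                               sampling_rate=1000.0)
        sts = SpikeTrainSet(df=pd.DataFrame(
            {"unit_id": 0, "trial": 0, "time_s": spikes}))
        assert gc.leadlag_rate_duration(sts, table) > 0.4

    def test_no_polarity_rejected(self):
        table = make_cycle_table([0.02] * 10)  # peak-peak rows only
        sts = SpikeTrainSet(df=pd.DataFrame(
            {"unit_id": [0], "trial": [0], "time_s": [0.01]}))
        with pytest.raises(ValueError):
            gc.leadlag_rate_duration(sts, table)
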