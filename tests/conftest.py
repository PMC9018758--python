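"""Shared fixtures: synthetic recordings, cycle tables and spike trains.

All fixtures are generated programmatically with fixed seeds; the heavier
ones are session-scoped so a full test run pays for each simulation once.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import gammacycle as gc
from gammacycle.containers import SpikeTrainSet

FS = 2035.0
PEAK_HZ = 50.0


@pytest.fixture(scope="session")
def ar2_params():
    return gc.ar2_from_eigen(0.97, PEAK_HZ, FS)


@pytest.fixture(scope="session")
def ar2_recording(ar2_params):
    """Single long AR(2) trace, moderately strong oscillation."""
    return gc.simulate_ar(ar2_params, 300_000, seed=11)


@pytest.fixture(scope="session")
def ar2_table(ar2_recording):
    return gc.detect_cycles_phase(ar2_recording)


@pytest.fixture(scope="session")
def trial_recording():
    """Multi-trial AR(2) recording (30 trials of ~3 s) for across-trial stats."""
    params = gc.ar2_from_eigen(0.98, PEAK_HZ, FS)
    return gc.simulate_ar(params, 6000, seed=21, n_trials=30)


@pytest.fixture(scope="session")
def trial_table(trial_recording):
    return gc.detect_cycles_phase(trial_recording)


@pytest.fixture(scope="session")
def trial_assignment(trial_recording, trial_table):
    return gc.assign_cycles_to_timepoints(
        trial_table, trial_recording.times,
        n_trials=trial_recording.n_trials)


@pytest.fixture(scope="session")
def modulated_spikes(trial_recording):
    """E-modulated Poisson spikes over the multi-trial AR(2) recording."""
    rows = []
    for tr in range(trial_recording.n_trials):
        x = trial_recording.series(tr)
        dec = gc.decompose_signal(x)
        e = dec.E / dec.E.std()
        spec = gc.SpikeSimSpec(base_rate=40.0, gain=60.0, n_units=2,
                               seed=100 + tr)
        st = gc.simulate_modulated_spikes(e, spec, FS, trial=tr)
        rows.append(st.df)
    return SpikeTrainSet(df=pd.concat(rows, ignore_index=True))


def make_synthetic_assignment(n_times: int, n_trials: int, rng,
                              amp_fn=None, dur_fn=None,
                              one_point_per_cycle: bool = False):
    """Build a CycleAssignment from synthetic per-trial cycle sequences.

    Each trial is tiled with contiguous cycles of ~20 ms whose amplitude
    and duration are drawn by the supplied callables (defaults:
    independent positive random values), giving a null dataset for
    permutation-calibration tests without running a detector.

    With ``one_point_per_cycle`` the time grid holds one point per cycle
    (cycle midpoints), so per-timepoint values are independent across
    time; on a dense grid adjacent time points share cycles and are
    therefore strongly dependent.
    """
    from gammacycle.containers import CYCLE_COLUMNS, HalfCycleTable
    from gammacycle.cycles import assign_cycles_to_timepoints

    fs = 1000.0
    dt = 0.020
    rows = []
    cyc_idx = 0
    for tr in range(n_trials):
        n_cyc = int(np.ceil(n_times / fs / dt)) + 1
        amps = amp_fn(n_cyc, tr) if amp_fn else rng.lognormal(0, 0.5, n_cyc)
        durs = dur_fn(n_cyc, tr, amps) if dur_fn else rng.lognormal(-4, 0.3, n_cyc)
        t0 = 0.0
        for k in range(n_cyc):
            rows.append({
                "trial": tr, "channel": 0, "epoch_id": tr,
                "cycle_index": cyc_idx, "polarity":
                    "trough-peak" if k % 2 == 0 else "peak-trough",
                "start_index": int(round(t0 * fs)),
                "end_index": int(round((t0 + dt) * fs)),
                "start_time": t0, "end_time": t0 + dt,
                "start_extremum_value": 0.0, "end_extremum_value": amps[k],
                "amplitude": amps[k], "duration": durs[k],
                "frequency": 1.0 / (2 * durs[k]),
            })
            cyc_idx += 1
            t0 += dt
    table = HalfCycleTable(df=pd.DataFrame(rows, columns=CYCLE_COLUMNS),
                           sampling_rate=fs)
    if one_point_per_cycle:
        n_cyc_grid = int(np.ceil(n_times / fs / dt))
        times = np.arange(n_cyc_grid) * dt + dt / 2
    else:
        times = np.arange(n_times) / fs
    return assign_cycles_to_timepoints(table, times, n_trials=n_trials)
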