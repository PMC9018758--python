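"""Spike-train statistics relative to detected gamma cycles.

Per-cycle spike counts and firing rates and their correlation with cycle
frequency, linear-interpolated spike phases, pairwise phase consistency
(the PPC1 variant, restricted to spike pairs from different trials so
that spike-count and within-trial history biases cancel), phase-bin firing
profiles split by cycle duration, and waveform-class labelling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import HalfCycleTable, SpikeTrainSet
from .cyclestats import spearman

__all__ = [
    "CycleSpikeMetrics",
    "per_cycle_spike_metrics",
    "spike_phase",
    "ppc1",
    "phase_bin_profile",
    "classify_waveform",
    "leadlag_rate_duration",
]

#: Minimum pooled spike count for a stable PPC estimate.
MIN_SPIKES_FOR_PPC = 50


def spike_phase(spike_time: float, cycle_start: float, cycle_duration: float) -> float:
    """Linear-interpolated phase of a spike within its gamma cycle.

    phase = 2 pi (t - start) / T, in [0, 2 pi); the spike must fall inside
    the half-open cycle interval [start, start + T).
    """
    t = spike_time - cycle_start
    if not 0.0 <= t < cycle_duration:
        raise ValueError("spike lies outside the cycle")
    return 2.0 * np.pi * t / cycle_duration


def ppc1(phases: np.ndarray, trials: np.ndarray) -> float:
    """Pairwise phase consistency over spike pairs from different trials.

    Averages cos(theta_i - theta_j) over all pairs (i, j) with
    trial_i != trial_j.  Unbiased by spike count: uniform phases give
    expectation 0, identical phases give 1.  Computed from per-trial
    resultant vectors: with S_a the complex resultant of trial a,
    sum-over-cross-pairs cos = |sum_a S_a|^2 - sum_a |S_a|^2 and the pair
    count is N^2 - sum_a n_a^2.
    """
    phases = np.asarray(phases, float)
    trials = np.asarray(trials)
    if phases.shape != trials.shape:
        raise ValueError("phases and trials must align")
    z = np.exp(1j * phases)
    s_tot = 0.0 + 0.0j
    sum_abs2 = 0.0
    n_tot = 0
    sum_n2 = 0
    for tr in np.unique(trials):
        sa = z[trials == tr].sum()
        na = int((trials == tr).sum())
        s_tot += sa
        sum_abs2 += abs(sa) ** 2
        n_tot += na
        sum_n2 += na ** 2
    denom = n_tot ** 2 - sum_n2
    if denom <= 0:
        raise ValueError("PPC1 needs spikes from at least two trials")
    return float((abs(s_tot) ** 2 - sum_abs2) / denom)


@dataclass
class CycleSpikeMetrics:
    """Per-frequency-bin spike metrics plus their frequency correlations.

    ``per_bin`` columns: ``freq_bin`` (Hz, bin center), ``norm_count``,
    ``norm_rate``, ``ppc``, ``n_spikes``, ``n_cycles``.  ``correlations``
    maps metric name to the Spearman correlation of the per-cycle
    (or per-bin, for PPC) metric with cycle frequency.
    """

    per_bin: pd.DataFrame
    correlations: dict


def _spikes_in_cycles(spikes: SpikeTrainSet, cycles: pd.DataFrame
                      ) -> pd.DataFrame:
    """Per (unit, cycle) table with counts and pooled spike phases.

    Spikes on a boundary belong to the cycle whose half-open [start, end)
    interval contains them.
    """
    rows = []
    for unit in spikes.unit_ids:
        sdf = spikes.unit(unit)
        for (tr,), cyc in cycles.groupby(["trial"]):
            st = sdf[sdf["trial"] == tr]["time_s"].to_numpy()
            if len(st) == 0 and len(cyc) == 0:
                continue
            c = cyc.sort_values("start_time")
            starts = c["start_time"].to_numpy()
            ends = c["end_time"].to_numpy()
            pos = np.searchsorted(starts, st, side="right") - 1
            inside = (pos >= 0) & (st < ends[np.clip(pos, 0, None)])
            for ci in range(len(c)):
                sel = inside & (pos == ci)
                row = c.iloc[ci]
                t_rel = st[sel] - row["start_time"]
                rows.append({
                    "unit_id": unit,
                    "trial": tr,
                    "cycle_row": c.index[ci],
                    "frequency": row["frequency"],
                    "duration": row["duration"],
                    "count": int(sel.sum()),
                    "phases": 2.0 * np.pi * t_rel / row["duration"],
                })
    return pd.DataFrame(rows)


def per_cycle_spike_metrics(spikes: SpikeTrainSet, cycles: HalfCycleTable,
                            cycle_kind: str = "full", bin_width: float = 1.0
                            ) -> CycleSpikeMetrics:
    """Spike count, rate and PPC as functions of gamma-cycle frequency.

    Spikes are assigned to the cycle containing them; per cycle the count
    and the rate (count/duration) are computed and normalized within each
    unit by that unit's mean across cycles, so units enter frequency bins
    on a common scale.  Per bin, PPC1 is computed over the pooled spike
    phases where at least ``MIN_SPIKES_FOR_PPC`` spikes are available.
    The Spearman correlations of normalized count and rate with cycle
    frequency are computed over cycles (pooled across units); the PPC
    correlation is over frequency bins.
    """
    cyc = cycles.full_cycles() if cycle_kind == "full" else cycles.df
    if len(cyc) == 0:
        raise ValueError("no cycles to relate spikes to")
    per = _spikes_in_cycles(spikes, cyc)
    if per.empty or per["count"].sum() == 0:
        raise ValueError("no overlap between spikes and cycles")
    per["rate"] = per["count"] / per["duration"]
    for col in ("count", "rate"):
        means = per.groupby("unit_id")[col].transform("mean")
        per[f"norm_{col}"] = np.where(means > 0, per[col] / means, np.nan)
    per["freq_bin"] = np.round(per["frequency"] / bin_width) * bin_width

    bins = []
    for fb, grp in per.groupby("freq_bin"):
        phases = np.concatenate([p for p in grp["phases"]]) if len(grp) else np.array([])
        trials_rep = np.concatenate([
            np.full(len(p), t) for p, t in zip(grp["phases"], grp["trial"])
        ]) if len(grp) else np.array([])
        n_spk = len(phases)
        ppc_val = float("nan")
        if n_spk >= MIN_SPIKES_FOR_PPC and len(np.unique(trials_rep)) >= 2:
            ppc_val = ppc1(phases, trials_rep)
        bins.append({
            "freq_bin": fb,
            "norm_count": grp["norm_count"].mean(),
            "norm_rate": grp["norm_rate"].mean(),
            "ppc": ppc_val,
            "n_spikes": n_spk,
            "n_cycles": len(grp),
        })
    per_bin = pd.DataFrame(bins).sort_values("freq_bin").reset_index(drop=True)

    ok = np.isfinite(per["norm_count"])
    corr = {
        "count_vs_frequency": spearman(per.loc[ok, "frequency"],
                                       per.loc[ok, "norm_count"]),
        "rate_vs_frequency": spearman(per.loc[ok, "frequency"],
                                      per.loc[ok, "norm_rate"]),
    }
    okb = np.isfinite(per_bin["ppc"])
    corr["ppc_vs_frequency"] = (
        spearman(per_bin.loc[okb, "freq_bin"], per_bin.loc[okb, "ppc"])
        if okb.sum() >= 3 else float("nan")
    )
    return CycleSpikeMetrics(per_bin=per_bin, correlations=corr)


def phase_bin_profile(spikes: SpikeTrainSet, cycles: HalfCycleTable,
                      n_bins: int = 8, cycle_kind: str = "full"
                      ) -> dict:
    """Firing rate per gamma-phase bin, for short vs long cycles.

    Each cycle is divided into ``n_bins`` non-overlapping phase bins;
    cycles are split at the median duration (within each unit) into short
    and long classes.  Rates are normalized per unit by the unit's overall
    mean rate.  Returns a dict with the (class, bin) rate matrix, the
    preferred bin (argmax of the pooled profile), the non-preferred bin
    (argmin), and the short-minus-long rate difference at each.
    """
    cyc = cycles.full_cycles() if cycle_kind == "full" else cycles.df
    per = _spikes_in_cycles(spikes, cyc)
    if per.empty:
        raise ValueError("no spikes over cycles")
    edges = np.linspace(0.0, 2.0 * np.pi, n_bins + 1)
    profiles = {"short": np.zeros(n_bins), "long": np.zeros(n_bins)}
    weights = {"short": 0.0, "long": 0.0}
    for unit, grp in per.groupby("unit_id"):
        med = grp["duration"].median()
        rate_mat = {}
        for cls, sel in (("short", grp["duration"] <= med),
                         ("long", grp["duration"] > med)):
            sub = grp[sel]
            if sub.empty:
                raise ValueError(f"empty {cls}-cycle class for unit {unit}")
            counts = np.zeros(n_bins)
            for p in sub["phases"]:
                h, _ = np.histogram(p, bins=edges)
                counts += h
            # time spent per phase bin: duration / n_bins per cycle
            t_bin = sub["duration"].sum() / n_bins
            rate_mat[cls] = counts / t_bin
        unit_mean = np.mean(np.concatenate(list(rate_mat.values())))
        if unit_mean <= 0:
            continue
        for cls in ("short", "long"):
            profiles[cls] += rate_mat[cls] / unit_mean
            weights[cls] += 1.0
    for cls in ("short", "long"):
        if weights[cls] > 0:
            profiles[cls] /= weights[cls]
    pooled = 0.5 * (profiles["short"] + profiles["long"])
    pref = int(np.argmax(pooled))
    nonpref = int(np.argmin(pooled))
    diff = profiles["short"] - profiles["long"]
    return {
        "bin_edges": edges,
        "short": profiles["short"],
        "long": profiles["long"],
        "preferred_bin": pref,
        "nonpreferred_bin": nonpref,
        "short_minus_long_at_preferred": float(diff[pref]),
        "short_minus_long_at_nonpreferred": float(diff[nonpref]),
    }


def classify_waveform(peak_to_trough_ms: float) -> str:
    """Broad vs narrow waveform class at the 0.235 ms peak-to-trough cut.

    Exactly 0.235 ms is a tie and is assigned NW with a warning.
    """
    if not np.isfinite(peak_to_trough_ms):
        raise ValueError("peak-to-trough duration must be finite")
    if peak_to_trough_ms > 0.235:
        return "BW"
    if peak_to_trough_ms == 0.235:
        warnings.warn("peak-to-trough exactly at the 0.235 ms boundary; "
                      "assigning NW", stacklevel=2)
    return "NW"


def leadlag_rate_duration(spikes: SpikeTrainSet, cycles: HalfCycleTable,
                          method: str = "spearman") -> float:
    """Correlation of trough-to-peak firing rate with the next half-cycle's
    duration.

    For each trough->peak half-cycle, the firing rate inside it is
    correlated with the duration of the immediately succeeding
    peak->trough half-cycle (same epoch).  A strongly positive value would
    indicate that a bout of spiking predicts a long ensuing cycle.
    """
    df = cycles.df
    if not set(df["polarity"]) & {"trough-peak", "peak-trough"}:
        raise ValueError("table carries no half-cycle polarity information")
    per = _spikes_in_cycles(spikes, df)
    if per.empty:
        raise ValueError("no spikes over cycles")
    rate_by_row = dict(zip(per["cycle_row"], per["count"] / per["duration"]))
    rates, next_durs = [], []
    for (_, _, _), grp in df.groupby(["trial", "channel", "epoch_id"], sort=True):
        g = grp.sort_values("start_time")
        for i in range(len(g) - 1):
            a, b = g.iloc[i], g.iloc[i + 1]
            if a["polarity"] == "trough-peak" and b["polarity"] == "peak-trough":
                rates.append(rate_by_row.get(g.index[i], 0.0))
                next_durs.append(b["duration"])
    if len(rates) < 2:
        raise ValueError("not enough half-cycle successions")
    return spearman(np.asarray(rates), np.asarray(next_durs), method)
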