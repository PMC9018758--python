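"""Correlation machinery, inference, CBAS and variability estimators."""

import itertools

import numpy as np
import pytest
from scipy import stats as sst

import gammacycle as gc
from conftest import make_synthetic_assignment


def brute_force_spearman(x, y):
    """Independent oracle: average ranks (ties included), then Pearson."""
    def avg_ranks(v):
        v = np.asarray(v, float)
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v))
        i = 0
        sv = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sv[j + 1] == sv[i]:
                j += 1
            ranks[order[i:j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return ranks
    rx, ry = avg_ranks(x), avg_ranks(y)
    return np.corrcoef(rx, ry)[0, 1]


class TestSpearman:
    def test_agrees_with_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(42)
        for n in (3, 5, 8, 12, 20):
            for _ in range(20):
                x = rng.integers(0, 6, n).astype(float)  # many ties
                y = rng.integers(0, 6, n).astype(float)
                if len(set(x)) < 2 or len(set(y)) < 2:
                    continue
                assert gc.spearman(x, y) == pytest.approx(
                    brute_force_spearman(x, y), abs=1e-12)

    def test_degenerate_input_gives_nan(self):
        assert np.isnan(gc.spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))


class TestTimewiseCorrelation:
    def test_identical_values_give_rho_one(self):
        rng = np.random.default_rng(0)
        asn = make_synthetic_assignment(
            200, 10, rng,
            dur_fn=lambda n, tr, amps: amps.copy())
        lc = gc.timewise_lagged_correlation(asn, 0)
        assert lc.rho == pytest.approx(1.0)

    def test_independent_values_give_rho_near_zero(self):
        rng = np.random.default_rng(1)
        asn = make_synthetic_assignment(400, 20, rng)
        lc = gc.timewise_lagged_correlation(asn, 0)
        assert abs(lc.rho) < 0.1

    def test_requires_two_valid_trials(self):
        rng = np.random.default_rng(2)
        asn = make_synthetic_assignment(50, 1, rng)
        with pytest.raises(ValueError):
            gc.timewise_lagged_correlation(asn, 0)


class TestPermutationNull:
    def test_null_data_inside_band(self):
        # null with independent time points (one grid point per cycle),
        # matching the exchangeability the surrogate construction assumes
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            asn = make_synthetic_assignment(2000, 15, rng,
                                            one_point_per_cycle=True)
            res = gc.permutation_null(asn, 0, n_perm=300, seed=seed)
            hits += res.significant
        assert hits <= 1  # ~3-in-1000 rule: 20 null runs rarely fire

    def test_coupled_data_outside_band(self):
        rng = np.random.default_rng(3)
        asn = make_synthetic_assignment(
            150, 15, rng,
            dur_fn=lambda n, tr, amps: amps + rng.normal(0, 0.1, n))
        res = gc.permutation_null(asn, 0, n_perm=300, seed=1)
        assert res.significant
        assert res.rho > res.surrogate_mean + 3 * res.surrogate_sd

    def test_surrogate_moments_match_exhaustive_shuffles(self):
        # tiny case: 2 time points x 3 trials; enumerate all (3!)^2
        # within-timepoint shuffle combinations as the exact oracle.  This
        # also certifies that shuffles never mix values across time points.
        rng = np.random.default_rng(7)
        amps = {0: np.array([1.0, 2.0, 3.0]), 1: np.array([2.0, 1.0, 4.0])}
        durs = {0: np.array([10.0, 30.0, 20.0]), 1: np.array([5.0, 6.0, 7.0])}

        def stat(d0, d1):
            r0 = brute_force_spearman(amps[0], d0)
            r1 = brute_force_spearman(amps[1], d1)
            return (r0 + r1) / 2

        exact = [stat(np.array(p0), np.array(p1))
                 for p0 in itertools.permutations(durs[0])
                 for p1 in itertools.permutations(durs[1])]
        exact = np.asarray(exact)

        # two-timepoint assignment: time 0 carries (amps[0], durs[0])
        # across trials, time 1 the second set
        amp_fn = lambda n, tr: np.array(
            [amps[0][tr], amps[1][tr]] * ((n + 1) // 2))[:n]
        dur_fn = lambda n, tr, a: np.array(
            [durs[0][tr], durs[1][tr]] * ((n + 1) // 2))[:n]
        asn = make_synthetic_assignment(2, 3, rng, amp_fn=amp_fn,
                                        dur_fn=dur_fn)
        res = gc.permutation_null(asn, 0, n_perm=4000, seed=5)
        assert res.surrogate_mean == pytest.approx(exact.mean(), abs=0.02)
        assert res.surrogate_sd == pytest.approx(exact.std(ddof=1), rel=0.1)

    def test_small_n_perm_warns(self):
        rng = np.random.default_rng(4)
        asn = make_synthetic_assignment(50, 8, rng)
        with pytest.warns(UserWarning):
            gc.permutation_null(asn, 0, n_perm=50, seed=0)


class TestSignFlip:
    def test_symmetric_values_give_p_one(self):
        assert gc.signflip_mean_test([0.3, -0.3, 0.5, -0.5]) == 1.0

    def test_six_positive_values(self):
        p = gc.signflip_mean_test([0.1, 0.2, 0.15, 0.3, 0.25, 0.12])
        assert p == pytest.approx(2 / 2 ** 6)

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            v = rng.normal(0.1, 0.2, rng.integers(3, 9))
            k = len(v)
            means = np.array([
                np.dot(s, v) / k
                for s in itertools.product((1, -1), repeat=k)])
            emp = means[0]  # itertools.product yields all +1 first
            p_hi = np.mean(means >= emp)
            p_lo = np.mean(means <= emp)
            expected = min(1.0, 2 * min(p_hi, p_lo))
            assert gc.signflip_mean_test(v) == pytest.approx(expected)

    def test_single_dataset_rejected(self):
        with pytest.raises(ValueError):
            gc.signflip_mean_test([0.2])


class TestRegressionResiduals:
    def test_exact_linear_trend_flagged(self, ):
        # amplitudes/durations on an exact line across each epoch: the
        # neighbour regression leaves zero residuals -> undefined
        from conftest import make_synthetic_assignment

        rng = np.random.default_rng(5)
        asn = make_synthetic_assignment(
            100, 6, rng,
            amp_fn=lambda n, tr: np.arange(1.0, n + 1),
            dur_fn=lambda n, tr, a: 0.01 + 0.0001 * np.arange(n))
        with pytest.raises(ValueError):
            gc.regression_residual_correlation(asn)

    def test_white_noise_residual_close_to_raw(self):
        rng = np.random.default_rng(6)
        asn = make_synthetic_assignment(300, 25, rng)
        raw = gc.timewise_lagged_correlation(asn, 0).rho
        res = gc.regression_residual_correlation(asn).rho
        assert abs(res - raw) < 0.1

    def test_ar2_residual_correlation_stays_positive(self, ar2_table):
        res = gc.residual_cycle_correlation(ar2_table)
        raw = gc.cycle_lagged_correlation(ar2_table, 0)
        assert res.rho > 0
        assert res.rho == pytest.approx(raw.rho, abs=0.25)


class TestCycleAutocorrelation:
    def test_iid_values_uncorrelated_at_all_lags(self):
        from gammacycle.containers import CYCLE_COLUMNS, HalfCycleTable
        import pandas as pd

        rng = np.random.default_rng(8)
        n = 4000
        durs = rng.lognormal(-4, 0.2, n)
        rows = []
        t0 = 0.0
        for k in range(n):
            rows.append({
                "trial": 0, "channel": 0, "epoch_id": 0, "cycle_index": k,
                "polarity": "trough-peak" if k % 2 == 0 else "peak-trough",
                "start_index": k, "end_index": k + 1,
                "start_time": t0, "end_time": t0 + durs[k],
                "start_extremum_value": 0.0, "end_extremum_value": 1.0,
                "amplitude": rng.lognormal(0, 0.4), "duration": durs[k],
                "frequency": 1 / (2 * durs[k])})
            t0 += durs[k]
        table = HalfCycleTable(df=pd.DataFrame(rows, columns=CYCLE_COLUMNS),
                               sampling_rate=1000.0)
        for lc in gc.cycle_autocorrelation(table, "amplitude",
                                           lags=[-3, -1, 1, 3]):
            assert abs(lc.rho) < 0.06

    def test_amplitude_autocorrelation_rises_with_eigenvalue(self):
        rhos = []
        for m in (0.95, 0.99):
            p = gc.ar2_from_eigen(m, 50.0, 2035.0)
            rec = gc.simulate_ar(p, 200_000, seed=31)
            tab = gc.detect_cycles_phase(rec)
            rhos.append(gc.cycle_autocorrelation(tab, "amplitude",
                                                 lags=[1])[0].rho)
        assert rhos[0] < rhos[1]


class TestEigenSweepRegression:
    def test_exact_line_recovered(self):
        x = np.array([0.9, 0.95, 0.99])
        slope, intercept = gc.eigen_sweep_regression(x, 2 * x + 1)
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            gc.eigen_sweep_regression([1.0, 1.0, 1.0], [1, 2, 3])


@pytest.fixture(scope="module")
def averaged_cbas():
    # single-rate tables sample cycle frequencies on a discrete comb
    # (fs / 2k); averaging normalized CBAS curves across datasets with
    # different sampling rates fills the combs in, which is how the
    # curves are meant to be aggregated
    amp_curves, cnt_curves = [], []
    offsets = None
    for i, fs in enumerate((1017.0, 1300.0, 1650.0, 2035.0)):
        p = gc.ar2_from_eigen(0.987, 50.0, fs)
        rec = gc.simulate_ar(p, int(200_000 * fs / 2035), seed=19 + i)
        tab = gc.detect_cycles_phase(rec)
        sp = gc.power_spectrum(rec, taper="rect", epoch_length=1.0)
        out = gc.cbas(tab, gamma_peak=sp.band(30, 70).peak_frequency)
        amp_curves.append(out.mean_amplitude / np.nanmean(out.mean_amplitude))
        cnt_curves.append(out.count / np.nansum(out.count))
        offsets = out.offsets
    return (offsets, np.nanmean(amp_curves, axis=0),
            np.nanmean(cnt_curves, axis=0))


class TestCBAS:
    def test_identical_cycles_occupy_single_bin(self):
        from gammacycle.containers import CYCLE_COLUMNS, HalfCycleTable
        import pandas as pd

        rows = [{
            "trial": 0, "channel": 0, "epoch_id": 0, "cycle_index": k,
            "polarity": "trough-peak", "start_index": k, "end_index": k + 1,
            "start_time": 0.01 * k, "end_time": 0.01 * (k + 1),
            "start_extremum_value": 0.0, "end_extremum_value": 2.0,
            "amplitude": 2.0, "duration": 0.010, "frequency": 50.0,
        } for k in range(100)]
        table = HalfCycleTable(df=pd.DataFrame(rows, columns=CYCLE_COLUMNS),
                               sampling_rate=1000.0)
        out = gc.cbas(table, gamma_peak=50.0)
        occupied = np.isfinite(out.count) & (out.count > 0)
        assert occupied.sum() == 1
        assert out.offsets[np.flatnonzero(occupied)[0]] == 0.0

    def test_count_distribution_unimodal_near_spectral_peak(self, averaged_cbas):
        offsets, _, counts = averaged_cbas
        mode = offsets[np.nanargmax(counts)]
        assert abs(mode) <= 2.0
        # roughly symmetric and unimodal: single contiguous region above
        # half maximum
        above = counts > np.nanmax(counts) / 2
        runs = np.flatnonzero(np.diff(np.r_[0, above.astype(int), 0]))
        assert len(runs) == 2

    def test_amplitude_maximum_at_or_below_peak(self, averaged_cbas):
        offsets, amps, _ = averaged_cbas
        assert offsets[np.nanargmax(amps)] <= 0.0

    def test_empty_table_rejected(self):
        from gammacycle.containers import HalfCycleTable

        with pytest.raises(ValueError):
            gc.cbas(HalfCycleTable(), gamma_peak=50.0)


class TestFrequencyVariability:
    def test_all_estimators_consistent_on_iid_gaussian(self):
        rng = np.random.default_rng(12)
        f = rng.normal(50.0, 1.0, 300_000)
        for method in ("gaussian_fit", "pairs_bessel", "triplets_debias"):
            assert gc.frequency_variability(f, method) == pytest.approx(
                1.0, abs=0.01)

    def test_triplet_without_debias_overestimates_by_three_halves(self):
        rng = np.random.default_rng(13)
        f = rng.normal(0.0, 1.0, 300_000)
        d = f[1:-1] - 0.5 * (f[:-2] + f[2:])
        assert np.mean(d ** 2) == pytest.approx(1.5, abs=0.02)

    def test_constant_input_gives_zero(self):
        f = np.full(100, 42.0)
        assert gc.frequency_variability(f, "pairs_bessel") == 0.0
        assert gc.frequency_variability(f, "triplets_debias") == 0.0
        assert gc.frequency_variability(f, "gaussian_fit") == 0.0

    def test_pairs_and_triplets_insensitive_to_linear_drift(self):
        rng = np.random.default_rng(14)
        n = 200_000
        drift = np.linspace(0, 30, n)  # slow 30 Hz drift across the session
        f = rng.normal(50.0, 1.0, n) + drift
        assert gc.frequency_variability(f, "pairs_bessel") == pytest.approx(
            1.0, abs=0.02)
        assert gc.frequency_variability(f, "triplets_debias") == pytest.approx(
            1.0, abs=0.02)
        assert gc.frequency_variability(f, "gaussian_fit") > 5.0

    def test_adjacency_respects_epochs(self):
        # two epochs with very different means: cross-epoch pairs would
        # inflate the estimate if adjacency leaked across the boundary
        rng = np.random.default_rng(15)
        f = np.r_[rng.normal(40, 0.1, 500), rng.normal(80, 0.1, 500)]
        eid = np.r_[np.zeros(500), np.ones(500)]
        sd = gc.frequency_variability(f, "pairs_bessel", epoch_ids=eid)
        assert sd == pytest.approx(0.1, abs=0.02)

    def test_insufficient_cycles_rejected(self):
        with pytest.raises(ValueError):
            gc.frequency_variability(np.array([50.0]), "pairs_bessel")
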