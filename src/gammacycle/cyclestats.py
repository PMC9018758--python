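"""Cycle-table statistics.

Lagged amplitude-duration correlations (time-resolved across trials, or
pooled across cycles for trial-less simulations), permutation and
sign-flip inference, regression-residual de-trending, amplitude/duration
autocorrelations, eigenvalue-sweep regressions, the cycle-based amplitude
spectrum (CBAS), and three estimators of cycle-frequency variability.

Correlations use Spearman's rank coefficient throughout (Pearson is
available behind a flag for comparisons with the baseline detector).  The
time-resolved scheme correlates values *across trials separately at each
post-onset time point* and then averages over time points, which removes
the contribution of stimulus-locked trends in amplitude and duration; time
points with fewer than two valid trials are skipped, not zero-filled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize as opt
from scipy import stats as sst

from .containers import HalfCycleTable
from .cycles import CycleAssignment

__all__ = [
    "LagCorrelation",
    "CBAS",
    "spearman",
    "timewise_lagged_correlation",
    "permutation_null",
    "signflip_mean_test",
    "cycle_lagged_correlation",
    "cycle_autocorrelation",
    "regression_residual_correlation",
    "residual_cycle_correlation",
    "eigen_sweep_regression",
    "cbas",
    "frequency_variability",
]


@dataclass
class LagCorrelation:
    """One lagged correlation with (optional) surrogate inference."""

    lag: int
    rho: float
    n_effective: int
    surrogate_mean: float = float("nan")
    surrogate_sd: float = float("nan")
    significant: bool | None = None


def spearman(x, y, method: str = "spearman") -> float:
    """Rank (or plain) correlation of two 1-D samples; NaN if degenerate."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2 or np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    if method == "spearman":
        return float(sst.spearmanr(x, y).statistic)
    if method == "pearson":
        return float(sst.pearsonr(x, y).statistic)
    raise ValueError(f"unknown correlation method {method!r}")


def _zranks(v: np.ndarray) -> np.ndarray:
    """Average ranks, centered and unit-normalized (NaN vector if degenerate)."""
    r = sst.rankdata(v)
    r = r - r.mean()
    n = np.linalg.norm(r)
    if n == 0:
        return np.full_like(r, np.nan)
    return r / n


# ---------------------------------------------------------------------------
# Time-resolved across-trial scheme
# ---------------------------------------------------------------------------

def _timewise_pairs(assignment: CycleAssignment, lag: int
                    ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per-timepoint (amplitude, lagged duration) vectors across trials."""
    amp_df = assignment.table.df["amplitude"].to_numpy()
    dur_df = assignment.table.df["duration"].to_numpy()
    pairs = []
    T = assignment.cycle_row.shape[0]
    for t in range(T):
        rows = assignment.cycle_row[t]
        lagged = assignment.lagged_row(rows, lag)
        ok = (rows >= 0) & (lagged >= 0)
        if ok.sum() >= 2:
            pairs.append((amp_df[rows[ok]], dur_df[lagged[ok]]))
    return pairs


def timewise_lagged_correlation(assignment: CycleAssignment, lag: int = 0,
                                method: str = "spearman") -> LagCorrelation:
    """Across-trial correlation at each time point, averaged over time.

    At each post-onset time point, the amplitude of the half-cycle
    containing that point is correlated across trials with the duration of
    the half-cycle ``lag`` positions away (within the same epoch); the
    per-timepoint coefficients are then averaged.  Positive ``lag`` pairs
    the current amplitude with a *later* cycle's duration.
    """
    pairs = _timewise_pairs(assignment, lag)
    if not pairs:
        raise ValueError("no time point has >= 2 valid trials")
    rhos = [spearman(a, d, method) for a, d in pairs]
    rhos = [r for r in rhos if np.isfinite(r)]
    if not rhos:
        raise ValueError("all per-timepoint correlations degenerate")
    return LagCorrelation(lag=lag, rho=float(np.mean(rhos)),
                          n_effective=len(rhos))


def permutation_null(assignment: CycleAssignment, lag: int = 0,
                     n_perm: int = 1000, seed=0,
                     sd_rule: float = 3.0) -> LagCorrelation:
    """Across-trial shuffle test for the time-resolved correlation.

    Duration values are shuffled across trials independently at each time
    point (never across time points), the full statistic is recomputed
    ``n_perm`` times, and a Gaussian is moment-matched to the surrogate
    statistics.  The empirical value is significant when it lies more than
    ``sd_rule`` surrogate SDs from the surrogate mean (the 3 SD rule is a
    non-parametric two-sided test at p ~ 0.001).
    """
    if n_perm < 100:
        import warnings

        warnings.warn("n_perm < 100 gives an unstable surrogate Gaussian",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    pairs = _timewise_pairs(assignment, lag)
    if not pairs:
        raise ValueError("no time point has >= 2 valid trials")
    za_list, zd_list = [], []
    for a, d in pairs:
        za, zd = _zranks(a), _zranks(d)
        if np.all(np.isfinite(za)) and np.all(np.isfinite(zd)):
            za_list.append(za)
            zd_list.append(zd)
    if not za_list:
        raise ValueError("all per-timepoint correlations degenerate")
    emp = float(np.mean([float(za @ zd) for za, zd in zip(za_list, zd_list)]))
    surro = np.zeros(n_perm)
    for za, zd in zip(za_list, zd_list):
        n = len(zd)
        # Shuffling raw values across trials and re-ranking is equivalent
        # to permuting the rank vector.
        perm = np.argsort(rng.random((n_perm, n)), axis=1)
        surro += zd[perm] @ za
    surro /= len(za_list)
    mu, sd = float(surro.mean()), float(surro.std(ddof=1))
    sig = bool(abs(emp - mu) > sd_rule * sd) if sd > 0 else False
    return LagCorrelation(lag=lag, rho=emp, n_effective=len(za_list),
                          surrogate_mean=mu, surrogate_sd=sd, significant=sig)


def signflip_mean_test(values: np.ndarray) -> float:
    """Exact sign-permutation test for a nonzero mean across datasets.

    Enumerates all 2^k assignments of signs to the per-dataset correlation
    values, forms the surrogate distribution of means, and returns the
    two-sided p-value of the empirical mean (twice the smaller tail
    fraction, capped at 1).  Requires 2 <= k <= 20 datasets.
    """
    v = np.asarray(values, float)
    k = len(v)
    if k < 2:
        raise ValueError("need at least 2 datasets")
    if k > 20:
        raise ValueError("exact enumeration limited to 20 datasets")
    signs = np.array([[1 if (i >> b) & 1 else -1 for b in range(k)]
                      for i in range(2 ** k)])
    means = signs @ v / k
    # the empirical mean is the all-(+1) assignment's surrogate value; take
    # it from the same computation so the tie with itself is exact
    emp = float(means[-1])
    p_hi = np.mean(means >= emp)
    p_lo = np.mean(means <= emp)
    return float(min(1.0, 2.0 * min(p_hi, p_lo)))


# ---------------------------------------------------------------------------
# Pooled-across-cycles scheme (trial-less simulations)
# ---------------------------------------------------------------------------

def _cycle_frame(table: HalfCycleTable, cycle_kind: str) -> pd.DataFrame:
    if cycle_kind == "half":
        return table.df
    if cycle_kind == "full":
        return table.full_cycles()
    raise ValueError("cycle_kind must be 'half' or 'full'")


def _lagged_cycle_pairs(df: pd.DataFrame, col_x: str, col_y: str, lag: int
                        ) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    for (_, _, _), grp in df.groupby(["trial", "channel", "epoch_id"], sort=True):
        g = grp.sort_values("start_time")
        x = g[col_x].to_numpy()
        y = g[col_y].to_numpy()
        if lag >= 0:
            if len(x) > lag:
                xs.append(x[: len(x) - lag])
                ys.append(y[lag:])
        else:
            if len(x) > -lag:
                xs.append(x[-lag:])
                ys.append(y[: len(y) + lag])
    if not xs:
        return np.array([]), np.array([])
    return np.concatenate(xs), np.concatenate(ys)


def cycle_lagged_correlation(table: HalfCycleTable, lag: int = 0,
                             cycle_kind: str = "half",
                             method: str = "spearman") -> LagCorrelation:
    """Amplitude vs lagged duration, pooled over all cycles.

    This is the scheme used for trial-less synthetic signals: each cycle's
    amplitude is paired with the duration of the cycle ``lag`` positions
    later within the same epoch, and a single correlation is computed over
    all pairs.
    """
    df = _cycle_frame(table, cycle_kind)
    a, d = _lagged_cycle_pairs(df, "amplitude", "duration", lag)
    if len(a) < 2:
        raise ValueError("not enough cycle pairs at this lag")
    return LagCorrelation(lag=lag, rho=spearman(a, d, method), n_effective=len(a))


def cycle_autocorrelation(table: HalfCycleTable, quantity: str = "amplitude",
                          lags=range(-10, 11), cycle_kind: str = "half",
                          method: str = "spearman") -> list[LagCorrelation]:
    """Lagged self-correlation of a cycle quantity, pooled over cycles."""
    if quantity not in ("amplitude", "duration"):
        raise ValueError("quantity must be 'amplitude' or 'duration'")
    df = _cycle_frame(table, cycle_kind)
    out = []
    for lag in lags:
        x, y = _lagged_cycle_pairs(df, quantity, quantity, int(lag))
        rho = spearman(x, y, method) if len(x) >= 2 else float("nan")
        out.append(LagCorrelation(lag=int(lag), rho=rho, n_effective=len(x)))
    return out


def _triplet_residuals(df: pd.DataFrame, col: str) -> np.ndarray:
    """OLS residuals of each interior cycle on its two neighbours (pooled)."""
    prev, cur, nxt = [], [], []
    for (_, _, _), grp in df.groupby(["trial", "channel", "epoch_id"], sort=True):
        v = grp.sort_values("start_time")[col].to_numpy()
        if len(v) >= 3:
            prev.append(v[:-2])
            cur.append(v[1:-1])
            nxt.append(v[2:])
    if not cur:
        return np.array([])
    X = np.column_stack([
        np.ones(sum(len(c) for c in cur)),
        np.concatenate(prev),
        np.concatenate(nxt),
    ])
    y = np.concatenate(cur)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("collinear neighbour predictors")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def residual_cycle_correlation(table: HalfCycleTable, cycle_kind: str = "half",
                               method: str = "spearman") -> LagCorrelation:
    """Amplitude-duration correlation after regressing out the neighbours.

    Each cycle's amplitude (and, separately, duration) is predicted by
    least squares from the previous and next cycle's value; the residuals
    measure the departure from slow trends, and their correlation isolates
    the instantaneous amplitude-duration coupling.
    """
    df = _cycle_frame(table, cycle_kind)
    ra = _triplet_residuals(df, "amplitude")
    rd = _triplet_residuals(df, "duration")
    if len(ra) < 2:
        raise ValueError("not enough interior cycles for the regression")
    rho = spearman(ra, rd, method)
    if not np.isfinite(rho):
        raise ValueError("residuals degenerate (exact linear trend)")
    return LagCorrelation(lag=0, rho=rho, n_effective=len(ra))


def regression_residual_correlation(assignment: CycleAssignment,
                                    method: str = "spearman") -> LagCorrelation:
    """Time-resolved variant of :func:`residual_cycle_correlation`.

    At each time point, the current cycle's amplitude (duration) is
    regressed across trials on the previous and next cycle's amplitude
    (duration); residual vectors are correlated per time point and the
    coefficients averaged.
    """
    amp_df = assignment.table.df["amplitude"].to_numpy()
    dur_df = assignment.table.df["duration"].to_numpy()
    rhos = []
    T = assignment.cycle_row.shape[0]
    for t in range(T):
        rows = assignment.cycle_row[t]
        prv = assignment.lagged_row(rows, -1)
        nxt = assignment.lagged_row(rows, +1)
        ok = (rows >= 0) & (prv >= 0) & (nxt >= 0)
        if ok.sum() < 4:
            continue
        res = {}
        degenerate = False
        for name, col in (("amp", amp_df), ("dur", dur_df)):
            y = col[rows[ok]]
            X = np.column_stack([np.ones(ok.sum()), col[prv[ok]], col[nxt[ok]]])
            if np.linalg.matrix_rank(X) < 3:
                degenerate = True
                break
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            res[name] = y - X @ beta
        if degenerate:
            continue
        rho = spearman(res["amp"], res["dur"], method)
        if np.isfinite(rho):
            rhos.append(rho)
    if not rhos:
        raise ValueError("no time point admits the triplet regression")
    return LagCorrelation(lag=0, rho=float(np.mean(rhos)), n_effective=len(rhos))


def eigen_sweep_regression(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Ordinary least-squares line y = slope * x + intercept."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.std(x) == 0:
        raise ValueError("zero variance in x")
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


# ---------------------------------------------------------------------------
# CBAS
# ---------------------------------------------------------------------------

@dataclass
class CBAS:
    """Cycle-based amplitude spectrum, aligned to the Fourier gamma peak.

    ``offsets`` are frequency-bin centers relative to the gamma peak (Hz,
    0 = peak); ``mean_amplitude`` the average half-cycle amplitude per bin
    (empty interior bins linearly interpolated); ``count`` the incidence of
    each cycle frequency (interpolated likewise); ``gamma_peak`` the
    alignment frequency.
    """

    offsets: np.ndarray
    mean_amplitude: np.ndarray
    count: np.ndarray
    gamma_peak: float

    @property
    def count_mode_offset(self) -> float:
        return float(self.offsets[int(np.nanargmax(self.count))])

    @property
    def amplitude_peak_offset(self) -> float:
        return float(self.offsets[int(np.nanargmax(self.mean_amplitude))])


def _interp_nan(v: np.ndarray) -> np.ndarray:
    """Linear interpolation over interior NaNs (edges left as NaN)."""
    v = v.astype(float).copy()
    ok = np.isfinite(v)
    if ok.sum() >= 2:
        first, last = np.flatnonzero(ok)[[0, -1]]
        inner = np.arange(first, last + 1)
        v[inner] = np.interp(inner, np.flatnonzero(ok), v[ok])
    return v


def cbas(table: HalfCycleTable, gamma_peak: float, halfwidth: float = 20.0,
         bin_width: float = 1.0) -> CBAS:
    """Mean cycle amplitude and cycle count per frequency bin around the peak.

    Half-cycle durations are converted to frequencies, assigned to bins of
    ``bin_width`` Hz centered on ``gamma_peak + k * bin_width`` for
    ``|k * bin_width| <= halfwidth``, and each bin's mean amplitude and
    count are computed.  Empty interior bins (a sampling-rate artifact:
    attainable cycle frequencies form a discrete set) are filled by linear
    interpolation between neighbouring occupied bins.
    """
    if table.empty:
        raise ValueError("empty cycle table")
    f = table.frequencies()
    a = table.amplitudes()
    k = int(np.floor(halfwidth / bin_width))
    offsets = np.arange(-k, k + 1) * bin_width
    centers = gamma_peak + offsets
    amp = np.full(len(centers), np.nan)
    cnt = np.full(len(centers), np.nan)
    idx = np.round((f - gamma_peak) / bin_width).astype(int)
    for j, off in enumerate(range(-k, k + 1)):
        sel = idx == off
        if np.any(sel):
            amp[j] = a[sel].mean()
            cnt[j] = sel.sum()
    return CBAS(offsets=offsets, mean_amplitude=_interp_nan(amp),
                count=_interp_nan(cnt), gamma_peak=gamma_peak)


# ---------------------------------------------------------------------------
# Cycle-frequency variability
# ---------------------------------------------------------------------------

def _adjacent_groups(values: np.ndarray, epoch_ids) -> list[np.ndarray]:
    if epoch_ids is None:
        return [np.asarray(values, float)]
    values = np.asarray(values, float)
    epoch_ids = np.asarray(epoch_ids)
    return [values[epoch_ids == e] for e in pd.unique(epoch_ids)]


def frequency_variability(frequencies: np.ndarray, method: str = "gaussian_fit",
                          epoch_ids=None, fit: str = "mle",
                          bin_width: float = 1.0) -> float:
    """Standard deviation of the cycle-frequency distribution, in Hz.

    ``gaussian_fit``
        SD of a Gaussian fitted to the frequency distribution.  Default
        ``fit="mle"`` is the maximum-likelihood fit (sample mean/SD with
        Bessel's correction); ``fit="lsq"`` least-squares fits a scaled
        Gaussian to the binned histogram.  The MLE fit reflects the full
        distribution; the LSQ fit tracks only the central peak when the
        distribution is heavy-tailed.
    ``pairs_bessel``
        Mean of adjacent-pair variances with Bessel's correction,
        square-rooted: mean((f_i - f_{i+1})^2 / 2) over adjacent cycle
        pairs.  Insensitive to slow drift in mean frequency.
    ``triplets_debias``
        Mean squared deviation of each middle cycle from its neighbours'
        mean, multiplied by the exact debiasing factor 2/3 (for i.i.d.
        values E[(f_i - (f_{i-1}+f_{i+1})/2)^2] = 1.5 sigma^2), then
        square-rooted.  Also drift-insensitive.

    ``epoch_ids`` restricts pair/triplet adjacency to within-epoch runs.
    """
    f = np.asarray(frequencies, float)
    if method == "gaussian_fit":
        if len(f) < 3:
            raise ValueError("need at least 3 cycles")
        if fit == "mle":
            return float(f.std(ddof=1))
        if fit == "lsq":
            edges = np.arange(f.min() - bin_width, f.max() + 2 * bin_width, bin_width)
            cnt, e = np.histogram(f, bins=edges)
            ctr = 0.5 * (e[:-1] + e[1:])
            ok = cnt > 0
            def g(x, a, mu, sd):
                return a * np.exp(-0.5 * ((x - mu) / sd) ** 2)
            popt, _ = opt.curve_fit(g, ctr[ok], cnt[ok],
                                    p0=[cnt.max(), f.mean(), f.std()],
                                    maxfev=20000)
            return float(abs(popt[2]))
        raise ValueError("fit must be 'mle' or 'lsq'")
    if method == "pairs_bessel":
        sq = [np.diff(g) ** 2 / 2.0 for g in _adjacent_groups(f, epoch_ids)
              if len(g) >= 2]
        if not sq:
            raise ValueError("need at least one adjacent cycle pair")
        return float(np.sqrt(np.mean(np.concatenate(sq))))
    if method == "triplets_debias":
        sq = [(g[1:-1] - 0.5 * (g[:-2] + g[2:])) ** 2
              for g in _adjacent_groups(f, epoch_ids) if len(g) >= 3]
        if not sq:
            raise ValueError("need at least one cycle triplet")
        return float(np.sqrt(np.mean(np.concatenate(sq)) * 2.0 / 3.0))
    raise ValueError(f"unknown method {method!r}")
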