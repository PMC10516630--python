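"""Heterogeneity statistics for global-transcription-rate traces.

Two decompositions are central:

* Pairwise intrinsic/extrinsic noise from two co-measured temporal traces
  E1, E2 (expectations are temporal means over the analyzed window):

      eta_int^2 = <(E1 - E2)^2> / (2 <E1><E2>)
      eta_ext^2 = (<E1 E2> - <E1><E2>) / (<E1><E2>)
      eta_tot^2 = (<E1^2 + E2^2> - 2 <E1><E2>) / (2 <E1><E2>)

  which satisfy eta_int^2 + eta_ext^2 = eta_tot^2 identically. All C(n,2)
  locus pairs of a cell are enumerated and the root mean square over pairs
  is the cell's fluctuation strength.

* The static/dynamic decomposition of a pseudotime-aligned rate matrix
  E_{t,c}: CV_total over all (t, c); CV_dynamic of the cross-cell mean
  trajectory; CV_static of the per-cell time averages E_c; and
  CV_residual = sqrt(CV_total^2 - CV_dynamic^2 - CV_static^2), which
  absorbs the noise intrinsic to the summed pseudo-reporter.

Plus the binomial null for time-averaged rates, autocorrelation-based
periodicity, and paired-correlation tests against scrambled-identity nulls.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

__all__ = [
    "PairNoise",
    "pair_noise",
    "cell_noise",
    "CVDecomposition",
    "cv_decomposition",
    "BinomialNull",
    "binomial_null",
    "autocorr_period",
    "PairedCorrelationResult",
    "paired_correlation_vs_scrambled",
]


@dataclass
class PairNoise:
    eta_int2: float
    eta_ext2: float
    eta_tot2: float
    valid: bool = True


def pair_noise(e1: np.ndarray, e2: np.ndarray) -> PairNoise:
    """Intrinsic/extrinsic/total noise of one trace pair (temporal means)."""
    e1 = np.asarray(e1, dtype=float)
    e2 = np.asarray(e2, dtype=float)
    if e1.shape != e2.shape:
        raise ValueError("traces must have equal length")
    m1, m2 = e1.mean(), e2.mean()
    if m1 <= 0 or m2 <= 0:
        return PairNoise(float("nan"), float("nan"), float("nan"), valid=False)
    denom = m1 * m2
    eta_int2 = float(np.mean((e1 - e2) ** 2) / (2.0 * denom))
    eta_ext2 = float((np.mean(e1 * e2) - denom) / denom)
    eta_tot2 = float((np.mean(e1**2 + e2**2) - 2.0 * denom) / (2.0 * denom))
    return PairNoise(eta_int2, eta_ext2, eta_tot2)


def cell_noise(traces: list[np.ndarray] | np.ndarray) -> dict:
    """RMS over all C(n,2) pair combinations of one cell's locus traces.

    Returns the per-cell root-mean-square eta_int, eta_ext, eta_tot (RMS of
    the squared terms over pairs, square-rooted; a slightly negative mean
    extrinsic term is kept as signed sqrt), the pair table, and the number
    of valid pairs. Fewer than two valid traces yields NaNs.
    """
    traces = [np.asarray(t, dtype=float) for t in traces]
    pairs = []
    for i, j in itertools.combinations(range(len(traces)), 2):
        pn = pair_noise(traces[i], traces[j])
        pairs.append({"i": i, "j": j, **pn.__dict__})
    table = pd.DataFrame(pairs, columns=["i", "j", "eta_int2", "eta_ext2", "eta_tot2", "valid"])
    valid = table[table.valid.astype(bool)] if len(table) else table

    def _rms(col: pd.Series) -> float:
        if len(col) == 0:
            return float("nan")
        m = col.mean()
        return float(np.sign(m) * np.sqrt(abs(m)))

    return {
        "eta_int": _rms(valid.eta_int2) if len(valid) else float("nan"),
        "eta_ext": _rms(valid.eta_ext2) if len(valid) else float("nan"),
        "eta_tot": _rms(valid.eta_tot2) if len(valid) else float("nan"),
        "n_pairs": int(len(table)),
        "n_valid_pairs": int(len(valid)),
        "pairs": table,
    }


@dataclass
class CVDecomposition:
    cv_total: float
    cv_dynamic: float
    cv_static: float
    cv_residual: float
    clamped: bool = False


def cv_decomposition(rate_matrix: np.ndarray) -> CVDecomposition:
    """Decompose a pseudotime-aligned rate matrix E_{t,c} (rows t, cols c).

    Population standard deviations (ddof=0) are used throughout so that the
    degenerate cases resolve exactly (e.g. cells constant in time at
    distinct levels give cv_static = cv_total and cv_dynamic =
    cv_residual = 0). A negative residual radicand is clamped to 0 and
    flagged. The output is invariant under global rescaling of all rates.
    """
    E = np.asarray(rate_matrix, dtype=float)
    if E.ndim != 2:
        raise ValueError("rate matrix must be 2-D (pseudotime x cells)")
    mu = E.mean()
    if mu == 0:
        raise ValueError("rate matrix mean is zero")
    cv_total = E.std() / mu
    mean_by_t = E.mean(axis=1)
    cv_dynamic = mean_by_t.std() / mean_by_t.mean()
    e_c = E.mean(axis=0)
    cv_static = e_c.std() / e_c.mean() if E.shape[1] >= 2 else float("nan")
    radicand = cv_total**2 - cv_dynamic**2 - (cv_static**2 if np.isfinite(cv_static) else 0.0)
    clamped = radicand < 0
    cv_residual = float(np.sqrt(max(0.0, radicand)))
    return CVDecomposition(
        cv_total=float(cv_total),
        cv_dynamic=float(cv_dynamic),
        cv_static=float(cv_static),
        cv_residual=cv_residual,
        clamped=bool(clamped),
    )


@dataclass
class BinomialNull:
    n_loci: int
    p: float
    mean_activity: float
    null_cv: float
    samples: np.ndarray = field(default_factory=lambda: np.empty(0))
    degenerate: bool = False


def binomial_null(
    n_loci: int,
    active_site_counts: np.ndarray,
    mean_activity_per_locus: float,
    n_samples: int = 10000,
    seed: int = 0,
) -> BinomialNull:
    """Null model: random, independent locus activation.

    If each of N loci is independently active with probability p (estimated
    as the observed mean number of active sites over N), the number of
    active sites is Binomial(N, p) and the randomly expected time-averaged
    rate is that count times the mean activity per active locus. The null
    CV is sqrt((1-p)/(N p)); observed static CVs above it indicate static
    heterogeneity beyond random locus activation.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    active = np.asarray(active_site_counts, dtype=float)
    p = float(active.mean() / n_loci)
    if not (0.0 <= p <= 1.0):
        raise ValueError("mean active sites must lie in [0, N]")
    if p == 0.0:
        return BinomialNull(n_loci, p, mean_activity_per_locus, float("nan"), degenerate=True)
    null_cv = float(np.sqrt((1.0 - p) / (n_loci * p)))
    rng = np.random.default_rng(seed)
    samples = rng.binomial(n_loci, p, size=n_samples) * mean_activity_per_locus
    return BinomialNull(n_loci, p, mean_activity_per_locus, null_cv, samples=samples, degenerate=p == 1.0)


def autocorr_period(
    trace: np.ndarray,
    dt_hr: float,
    prominence: float = 0.05,
    min_lag: int = 3,
    max_lag: int | None = None,
    smooth_window: int = 7,
) -> float | None:
    """Periodicity estimate: lag (hours) of the first autocorrelation maximum.

    The unbiased sample autocorrelation of the mean-subtracted trace is
    smoothed with a ``smooth_window``-lag moving average (1 disables; the
    smoothing suppresses spurious local maxima from ACF sampling noise and
    from the fast intrinsic-noise shoulder) and scanned for the first local
    maximum at lag >= ``min_lag`` samples whose value exceeds ``prominence``.
    Returns None if no such maximum exists (e.g. white noise).
    """
    x = np.asarray(trace, dtype=float)
    n = x.size
    if n < 2 * min_lag + 2:
        return None
    x = x - x.mean()
    var = np.mean(x**2)
    if var == 0:
        return None
    if max_lag is None:
        max_lag = n // 2
    acf = np.empty(max_lag + 1)
    for k in range(max_lag + 1):
        # unbiased: sum over n-k products divided by (n-k), normalized by var
        acf[k] = np.mean(x[: n - k] * x[k:]) / var
    if smooth_window > 1:
        acf = ndimage.uniform_filter1d(acf, size=smooth_window, mode="nearest")
    for k in range(max(min_lag, 1), max_lag):
        if acf[k] > prominence and acf[k] >= acf[k - 1] and acf[k] >= acf[k + 1]:
            return float(k * dt_hr)
    return None


@dataclass
class PairedCorrelationResult:
    observed: np.ndarray  # per-pair correlations (traces) or a 1-element array (scalars)
    observed_mean: float
    null_means: np.ndarray  # scrambled-null distribution of the mean correlation
    null_mean: float
    p_value: float  # one-sided: P(null >= observed mean)
    n_pairs: int
    n_dropped: int = 0


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def paired_correlation_vs_scrambled(
    first: list[np.ndarray] | np.ndarray,
    second: list[np.ndarray] | np.ndarray,
    n_scrambles: int = 1000,
    seed: int = 0,
) -> PairedCorrelationResult:
    """Observed paired correlation versus a scrambled-identity null.

    Two modes, matching the assays this statistic serves:

    * traces (list of arrays per side, e.g. the two regulons of one cell or
      the two nuclei of one fused cell): per-pair Pearson correlations;
      the null re-pairs the second member across identities and records the
      mean correlation per scramble.
    * scalars (1-D arrays, e.g. mother and daughter time-averaged rates):
      the cross-pair Pearson correlation; the null permutes the second side.

    Constant members make a pair undefined; those pairs are dropped.
    """
    rng = np.random.default_rng(seed)
    first = [np.asarray(a, dtype=float) for a in first]
    second = [np.asarray(b, dtype=float) for b in second]
    if len(first) != len(second):
        raise ValueError("sides must have equal length")
    if len(first) < 3:
        raise ValueError("need at least 3 pairs")
    trace_mode = first[0].ndim >= 1 and first[0].size > 1

    if trace_mode:
        obs = np.array([_pearson(a, b) for a, b in zip(first, second)])
        dropped = int(np.isnan(obs).sum())
        obs = obs[~np.isnan(obs)]
        null_means = np.empty(n_scrambles)
        idx = np.arange(len(second))
        for s in range(n_scrambles):
            perm = rng.permutation(idx)
            vals = np.array(
                [_pearson(first[i], second[perm[i]]) for i in range(len(first)) if perm[i] != i]
            )
            vals = vals[~np.isnan(vals)]
            null_means[s] = vals.mean() if vals.size else np.nan
        observed_mean = float(obs.mean())
    else:
        a = np.array([float(x) for x in first])
        b = np.array([float(x) for x in second])
        obs = np.array([_pearson(a, b)])
        dropped = 0
        null_means = np.empty(n_scrambles)
        for s in range(n_scrambles):
            null_means[s] = _pearson(a, rng.permutation(b))
        observed_mean = float(obs[0])

    null_means = null_means[~np.isnan(null_means)]
    p = float((np.sum(null_means >= observed_mean) + 1) / (null_means.size + 1))
    return PairedCorrelationResult(
        observed=obs,
        observed_mean=observed_mean,
        null_means=null_means,
        null_mean=float(null_means.mean()),
        p_value=p,
        n_pairs=len(first),
        n_dropped=dropped,
    )
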