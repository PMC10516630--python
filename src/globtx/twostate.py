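"""Two-state (telegraph) transcription model with global modulation.

A promoter switches stochastically between OFF and ON states; nascent RNAs
are initiated only while ON and convert to mature RNA at a first-order rate.
Gene-nonspecific ("global") fluctuations are modelled by multiplying the
initiation rate ``k_m`` with a shared temporal signal ``m(t) = 1 + A*s(t)``.
The simulator is an exact stochastic simulation algorithm (SSA) for the
time-inhomogeneous system: ``m(t)`` is treated as piecewise-constant on a
fine subgrid and firing times are obtained by inverting the integrated
propensity, which is exact for a piecewise-constant signal and consumes a
fixed, documented pair of uniform draws per reaction event.

The module also answers the reporter-design question: how many co-integrated
reporter copies must be summed before the temporal coefficient of variation
of the summed nascent-transcript trace drops below the detection criterion
``CV_sum^2 < 2 * CV_global^2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TwoStateParams",
    "GlobalWaveform",
    "SimConfig",
    "ReporterTrace",
    "CellSim",
    "waveform_multiplier",
    "simulate_reporter",
    "simulate_cell",
    "min_reporters_for_detection",
    "regulon_design_study",
    "temporal_cv",
    "REGULON_SWITCH_FACTORS",
]

# Promoter-switching rate multipliers per regulon label: X is a slow-switching
# regulon (both k_on and k_off scaled by 1/5), Y a fast-switching one (x5).
REGULON_SWITCH_FACTORS = {"default": 1.0, "X": 0.2, "Y": 5.0}


@dataclass(frozen=True)
class TwoStateParams:
    """Kinetic rates of the telegraph model.

    Defaults correspond to a moderately induced reporter: the promoter is ON
    two-thirds of the time, bursts last ~1.3 h, and the stationary nascent
    count per locus is 0.5.
    """

    k_on_per_hr: float = 1.5
    k_off_per_hr: float = 0.75
    k_m_per_min: float = 0.15
    k_s_per_min: float = 0.2
    elongation_steps: int = 1

    def __post_init__(self) -> None:
        for name in ("k_on_per_hr", "k_off_per_hr", "k_s_per_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.k_m_per_min < 0:
            raise ValueError("k_m_per_min must be non-negative")
        if self.elongation_steps not in (1, 2):
            raise ValueError("elongation_steps must be 1 or 2")

    @property
    def p_on(self) -> float:
        """Stationary ON-state occupancy k_on / (k_on + k_off)."""
        return self.k_on_per_hr / (self.k_on_per_hr + self.k_off_per_hr)

    @property
    def stationary_mean_nascent(self) -> float:
        """Stationary mean standing nascent count at <m> = 1."""
        return self.p_on * self.k_m_per_min / self.k_s_per_min


@dataclass(frozen=True)
class GlobalWaveform:
    """Gene-nonspecific modulation signal m(t) = 1 + A*s(t).

    kinds
    -----
    constant : m(t) = 1 (amplitude ignored, must be 0)
    sine : s(t) = sin(2*pi*t/T + phase); temporal SD of m is A/sqrt(2)
    smoothed_random : seeded white noise on the evaluation grid, moving-average
        smoothed over ``smoothing_window_hr``, renormalized to mean 1 and
        scaled so its temporal SD equals A/sqrt(2) (matching the sine's).
    """

    kind: Literal["constant", "sine", "smoothed_random"] = "sine"
    amplitude: float = 0.7
    period_hr: float = 12.0
    phase: float = 0.0
    smoothing_window_hr: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "sine", "smoothed_random"):
            raise ValueError(f"unknown waveform kind {self.kind!r}")
        if not (0.0 <= self.amplitude < 1.0):
            raise ValueError("amplitude must satisfy 0 <= A < 1")
        if self.period_hr <= 0:
            raise ValueError("period_hr must be positive")

    def series(self, times_hr: np.ndarray) -> np.ndarray:
        """Realize m(t) on a uniform time grid (hours)."""
        t = np.asarray(times_hr, dtype=float)
        if self.kind == "constant":
            return np.ones_like(t)
        if self.kind == "sine":
            return 1.0 + self.amplitude * np.sin(
                2.0 * math.pi * t / self.period_hr + self.phase
            )
        # smoothed_random: white noise -> moving average -> renormalize.
        rng = np.random.default_rng(self.seed)
        noise = rng.standard_normal(t.size)
        dt = t[1] - t[0] if t.size > 1 else 1.0
        win = max(1, int(round(self.smoothing_window_hr / dt)))
        kernel = np.ones(win) / win
        smooth = np.convolve(noise, kernel, mode="same")
        sd = smooth.std()
        if sd == 0:
            return np.ones_like(t)
        target_sd = self.amplitude / math.sqrt(2.0)
        m = 1.0 + (smooth - smooth.mean()) / sd * target_sd
        # keep the multiplier positive; renormalize the mean after clipping
        m = np.clip(m, 0.05, None)
        return m / m.mean()

    def analytic_cv(self) -> float:
        """Temporal CV of m(t): 0 for constant, A/sqrt(2) otherwise."""
        if self.kind == "constant":
            return 0.0
        return self.amplitude / math.sqrt(2.0)


def waveform_multiplier(w: GlobalWaveform, t_hr: float | np.ndarray) -> float | np.ndarray:
    """Evaluate m(t) at time(s) t (hours).

    For ``smoothed_random`` the signal is realized once on a 1-min grid over
    [0, t_max] from the waveform's own seed and evaluated piecewise-constant.
    """
    t = np.asarray(t_hr, dtype=float)
    if w.kind in ("constant", "sine"):
        out = w.series(t)
    else:
        t_max = float(np.max(t)) if t.size else 0.0
        grid = np.arange(0.0, t_max + 1.0 / 60.0, 1.0 / 60.0)
        vals = w.series(grid)
        idx = np.clip((t * 60.0).astype(int), 0, vals.size - 1)
        out = vals[idx]
    if np.isscalar(t_hr):
        return float(out)
    return out


@dataclass(frozen=True)
class SimConfig:
    """Simulation horizon, sampling and reporter layout."""

    duration_hr: float = 48.0
    dt_sample_min: float = 10.0
    n_reporters: int = 1
    regulon_assignment: Sequence[str] | None = None
    seed: int = 0
    burn_in_hr: float = 2.0
    subgrid_min: float = 1.0

    def __post_init__(self) -> None:
        if self.duration_hr <= 0:
            raise ValueError("duration_hr must be positive")
        if self.dt_sample_min <= 0:
            raise ValueError("dt_sample_min must be positive")
        if self.n_reporters < 1:
            raise ValueError("n_reporters must be >= 1")
        if self.regulon_assignment is not None and len(self.regulon_assignment) != self.n_reporters:
            raise ValueError("regulon_assignment length must equal n_reporters")

    @property
    def sample_times_hr(self) -> np.ndarray:
        n = int(round(self.duration_hr * 60.0 / self.dt_sample_min)) + 1
        return np.arange(n) * self.dt_sample_min / 60.0


@dataclass
class ReporterTrace:
    """Standing nascent-transcript count of one locus on the sample grid.

    ``production_counts`` is a secondary channel: initiation events per
    sampling interval (the count in (t_{i-1}, t_i]).
    """

    times_hr: np.ndarray
    nascent_counts: np.ndarray
    reporter_id: int = 0
    regulon_label: str = "default"
    production_counts: np.ndarray | None = None
    on_states: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.times_hr) != len(self.nascent_counts):
            raise ValueError("times and counts must have equal length")


@dataclass
class CellSim:
    """Traces of all reporters of one cell plus their elementwise sum."""

    traces: list[ReporterTrace]
    summed: np.ndarray
    times_hr: np.ndarray
    multiplier: np.ndarray  # m(t) on the sample grid


def _ssa_trace(
    kon: float,
    koff: float,
    km_hr: float,
    ks_hr: float,
    two_step: bool,
    m_vals: np.ndarray,
    sub_dt_hr: float,
    duration_hr: float,
    sample_dt_hr: float,
    rng: np.random.Generator,
    stationary_init: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact SSA for one reporter; rates per hour; m piecewise-constant.

    Draw protocol per event: one uniform for the exponential target
    ``E = -ln(u)``, one uniform for reaction choice. Reaction order in the
    choice: promoter switch, initiation, stage-1 maturation, stage-2
    maturation. One extra uniform initializes the promoter state and (if
    ``stationary_init``) one Poisson draw initializes the nascent count.
    """
    n_samp = int(round(duration_hr / sample_dt_hr)) + 1
    counts = np.zeros(n_samp, dtype=np.int64)
    prod = np.zeros(n_samp, dtype=np.int64)
    ons = np.zeros(n_samp, dtype=bool)
    n_sub = m_vals.size

    on = rng.random() < kon / (kon + koff)
    ks_eff = 2.0 * ks_hr if two_step else ks_hr
    n1 = 0
    n2 = 0
    if stationary_init:
        mean0 = (kon / (kon + koff)) * km_hr * m_vals[0] / ks_hr
        tot = int(rng.poisson(mean0))
        if two_step:
            n1 = int(rng.binomial(tot, 0.5)) if tot else 0
            n2 = tot - n1
        else:
            n1 = tot

    t = 0.0
    win = 0
    counts[0] = n1 + n2
    ons[0] = on
    isamp = 1
    E = -math.log(rng.random())
    acc = 0.0
    while True:
        a_sw = koff if on else kon
        a_syn = km_hr * m_vals[win if win < n_sub else n_sub - 1] if on else 0.0
        a_deg1 = ks_eff * n1
        a_deg2 = ks_eff * n2 if two_step else 0.0
        a = a_sw + a_syn + a_deg1 + a_deg2
        w_end = (win + 1) * sub_dt_hr
        if acc + a * (w_end - t) < E:
            acc += a * (w_end - t)
            t = w_end
            win += 1
            while isamp < n_samp and isamp * sample_dt_hr <= t + 1e-12:
                counts[isamp] = n1 + n2
                ons[isamp] = on
                isamp += 1
            if t >= duration_hr - 1e-12:
                break
            continue
        t_fire = t + (E - acc) / a
        if t_fire >= duration_hr:
            t_fire = duration_hr
        while isamp < n_samp and isamp * sample_dt_hr <= t_fire + 1e-12:
            counts[isamp] = n1 + n2
            ons[isamp] = on
            isamp += 1
        t = t_fire
        if t >= duration_hr - 1e-12:
            break
        u = rng.random() * a
        if u < a_sw:
            on = not on
        elif u < a_sw + a_syn:
            n1 += 1
            if isamp < n_samp:
                prod[isamp] += 1
        elif u < a_sw + a_syn + a_deg1:
            n1 -= 1
            if two_step:
                n2 += 1
        else:
            n2 -= 1
        E = -math.log(rng.random())
        acc = 0.0
    while isamp < n_samp:
        counts[isamp] = n1 + n2
        ons[isamp] = on
        isamp += 1
    return counts, prod, ons


def _subgrid(w: GlobalWaveform, c: SimConfig) -> tuple[np.ndarray, float]:
    sub_dt_hr = c.subgrid_min / 60.0
    n_sub = int(math.ceil(c.duration_hr / sub_dt_hr))
    t_sub = (np.arange(n_sub) + 0.5) * sub_dt_hr  # window midpoints
    return w.series(t_sub), sub_dt_hr


def simulate_reporter(
    p: TwoStateParams,
    w: GlobalWaveform,
    c: SimConfig,
    seed: int | np.random.Generator | None = None,
    regulon_label: str = "default",
    reporter_id: int = 0,
    m_vals: np.ndarray | None = None,
    stationary_init: bool = True,
) -> ReporterTrace:
    """Simulate one reporter locus and sample its standing nascent count."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(
        c.seed if seed is None else seed
    )
    if m_vals is None:
        m_vals, sub_dt_hr = _subgrid(w, c)
    else:
        sub_dt_hr = c.subgrid_min / 60.0
    factor = REGULON_SWITCH_FACTORS.get(regulon_label, 1.0)
    counts, prod, ons = _ssa_trace(
        p.k_on_per_hr * factor,
        p.k_off_per_hr * factor,
        p.k_m_per_min * 60.0,
        p.k_s_per_min * 60.0,
        p.elongation_steps == 2,
        np.asarray(m_vals, dtype=float),
        sub_dt_hr,
        c.duration_hr,
        c.dt_sample_min / 60.0,
        rng,
        stationary_init=stationary_init,
    )
    return ReporterTrace(
        times_hr=c.sample_times_hr,
        nascent_counts=counts,
        reporter_id=reporter_id,
        regulon_label=regulon_label,
        production_counts=prod,
        on_states=ons,
    )


def simulate_cell(
    p: TwoStateParams,
    w: GlobalWaveform,
    c: SimConfig,
    seed: int | np.random.Generator | None = None,
    k_m_scale: float = 1.0,
    m_vals: np.ndarray | None = None,
    m_sample: np.ndarray | None = None,
) -> CellSim:
    """Simulate all reporters of one cell.

    The reporters share one realization of m(t) (gene-nonspecific signal) but
    have independent reaction randomness (gene-specific noise). ``k_m_scale``
    multiplies the initiation rate, modelling a cell-specific mean rate.
    ``m_vals`` overrides the waveform with an arbitrary modulation series on
    the 1-min subgrid (used for cell-cycle-tied modulation), with
    ``m_sample`` the matching values on the sample grid.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(
        c.seed if seed is None else seed
    )
    if m_vals is None:
        m_vals, _ = _subgrid(w, c)
        m_sample = w.series(c.sample_times_hr)
    elif m_sample is None:
        sub_dt_hr = c.subgrid_min / 60.0
        idx = np.clip((c.sample_times_hr / sub_dt_hr).astype(int), 0, len(m_vals) - 1)
        m_sample = np.asarray(m_vals)[idx]
    if k_m_scale != 1.0:
        p = replace(p, k_m_per_min=p.k_m_per_min * k_m_scale)
    labels = list(c.regulon_assignment) if c.regulon_assignment else ["default"] * c.n_reporters
    traces = [
        simulate_reporter(p, w, c, rng, regulon_label=labels[i], reporter_id=i, m_vals=m_vals)
        for i in range(c.n_reporters)
    ]
    summed = np.sum([tr.nascent_counts for tr in traces], axis=0)
    return CellSim(
        traces=traces,
        summed=summed,
        times_hr=c.sample_times_hr,
        multiplier=np.asarray(m_sample, dtype=float),
    )


def _deterministic_cell(p: TwoStateParams, w: GlobalWaveform, c: SimConfig) -> np.ndarray:
    """Mean-field ODE trace (oracle mode without reaction noise).

    dp/dt = k_on (1-p) - k_off p ; dN/dt = k_m m(t) p - k_s N, Euler on the
    1-min subgrid, started at stationarity.
    """
    m_vals, sub_dt_hr = _subgrid(w, c)
    kon, koff = p.k_on_per_hr, p.k_off_per_hr
    km, ks = p.k_m_per_min * 60.0, p.k_s_per_min * 60.0
    pon = p.p_on
    N = pon * km * m_vals[0] / ks
    n_samp = c.sample_times_hr.size
    out = np.empty(n_samp)
    out[0] = N
    isamp = 1
    sample_dt_hr = c.dt_sample_min / 60.0
    for i, m in enumerate(m_vals):
        N += (km * m * pon - ks * N) * sub_dt_hr
        t = (i + 1) * sub_dt_hr
        while isamp < n_samp and isamp * sample_dt_hr <= t + 1e-12:
            out[isamp] = N
            isamp += 1
    while isamp < n_samp:
        out[isamp] = N
        isamp += 1
    return out


def temporal_cv(trace: np.ndarray, times_hr: np.ndarray, burn_in_hr: float = 2.0) -> float:
    """Temporal CV of a sampled trace after discarding a burn-in window."""
    keep = times_hr >= burn_in_hr
    x = np.asarray(trace, dtype=float)[keep]
    mu = x.mean()
    if mu == 0:
        return float("nan")
    return float(x.std() / mu)


def min_reporters_for_detection(
    p: TwoStateParams,
    w: GlobalWaveform,
    c: SimConfig,
    max_n: int = 20,
    n_replicates: int = 50,
    seed: int = 0,
    mode: Literal["gillespie", "deterministic"] = "gillespie",
    cv_global: Literal["empirical", "analytic"] = "empirical",
) -> tuple[int, pd.DataFrame]:
    """Smallest reporter copy number satisfying CV_sum^2 < 2 * CV_global^2.

    Scans n = 1..max_n; for each n the temporal CV^2 of the n-reporter summed
    trace is averaged over ``n_replicates`` independent replicates and
    compared with twice the squared temporal CV of m(t) on the same grid
    (after the same burn-in). Returns ``max_n + 1`` as a sentinel when the
    criterion is never met (including the degenerate CV_global = 0 case).
    Also returns the scan table (n, mean CV^2, threshold, satisfied).
    """
    if max_n < 1:
        raise ValueError("max_n must be >= 1")
    times = c.sample_times_hr
    keep = times >= c.burn_in_hr
    m_grid = w.series(times)[keep]
    if cv_global == "analytic":
        cvg = w.analytic_cv()
    else:
        cvg = float(m_grid.std() / m_grid.mean())
    threshold = 2.0 * cvg**2

    rows = []
    answer = max_n + 1
    rng = np.random.default_rng(seed)
    for n in range(1, max_n + 1):
        cfg = replace(c, n_reporters=n)
        if mode == "deterministic":
            trace = n * _deterministic_cell(p, w, cfg)
            cv2 = temporal_cv(trace, times, c.burn_in_hr) ** 2
        else:
            cv2s = np.empty(n_replicates)
            for r in range(n_replicates):
                cell = simulate_cell(p, w, cfg, rng)
                cv2s[r] = temporal_cv(cell.summed, times, c.burn_in_hr) ** 2
            cv2 = float(np.nanmean(cv2s))
        ok = threshold > 0 and cv2 < threshold
        rows.append({"n": n, "mean_cv2": cv2, "threshold": threshold, "satisfied": ok})
        if ok:
            answer = n
            break
    return answer, pd.DataFrame(rows)


def regulon_design_study(
    p: TwoStateParams,
    w: GlobalWaveform,
    c: SimConfig,
    seed: int = 0,
) -> dict:
    """Per-regulon summed traces and their correlation structure.

    Reporters carry regulon labels from ``c.regulon_assignment``; label X
    scales both switching rates by 1/5, Y by 5. Returns per-regulon summed
    traces, each regulon's Pearson correlation with m(t), and the
    inter-regulon correlation matrix (computed after burn-in).
    """
    if not c.regulon_assignment:
        raise ValueError("regulon_assignment required")
    cell = simulate_cell(p, w, c, seed)
    keep = cell.times_hr >= c.burn_in_hr
    labels = sorted(set(c.regulon_assignment))
    sums = {}
    for lab in labels:
        idx = [i for i, l in enumerate(c.regulon_assignment) if l == lab]
        sums[lab] = np.sum([cell.traces[i].nascent_counts for i in idx], axis=0)
    m = cell.multiplier

    def _corr(a, b):
        a, b = np.asarray(a, float)[keep], np.asarray(b, float)[keep]
        if a.std() == 0 or b.std() == 0:
            return float("nan")
        return float(np.corrcoef(a, b)[0, 1])

    corr_with_m = {lab: _corr(s, m) for lab, s in sums.items()}
    inter = pd.DataFrame(
        [[_corr(sums[a], sums[b]) for b in labels] for a in labels],
        index=labels,
        columns=labels,
    )
    return {
        "summed": sums,
        "times_hr": cell.times_hr,
        "multiplier": m,
        "corr_with_multiplier": corr_with_m,
        "inter_regulon_corr": inter,
    }


def traces_to_frame(cells: dict[int, CellSim]) -> pd.DataFrame:
    """Tidy table of traces: cell_id, reporter_id, regulon, time_hr, nascent_count."""
    recs = []
    for cid, cell in cells.items():
        for tr in cell.traces:
            recs.append(
                pd.DataFrame(
                    {
                        "cell_id": cid,
                        "reporter_id": tr.reporter_id,
                        "regulon": tr.regulon_label,
                        "time_hr": tr.times_hr,
                        "nascent_count": tr.nascent_counts,
                    }
                )
            )
    return pd.concat(recs, ignore_index=True)
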