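"""Cell-cycle phase annotation from a PCNA reporter channel.

During S phase a PCNA fusion reporter aggregates into replication foci, so
the spatial unevenness of nuclear fluorescence rises. The statistic

    PCNA_var = (max(I) - mean(I)) / mean(I)

over the nuclear pixels is ~0 for a uniform nucleus, rises at the G1/S
transition (first replication foci), peaks at the S/G2 transition (transient
bright foci before dissipation) and M phase is flagged by the disappearance
of the nuclear mask. Rate trajectories are then mapped onto a normalized
cell-cycle pseudotime (0-100% between successive mitoses).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = ["pcna_var", "CycleCall", "CellCycleAnnotation", "call_transitions", "to_pseudotime"]


def pcna_var(nuclear_pixels: np.ndarray) -> float:
    """(max - mean)/mean of nuclear reporter intensities.

    Scale-invariant; 0 iff the nuclear signal is constant. Empty input or a
    non-positive mean (no nucleus, i.e. M phase) returns NaN.
    """
    x = np.asarray(nuclear_pixels, dtype=float).ravel()
    if x.size == 0:
        return float("nan")
    mu = x.mean()
    if mu <= 0:
        return float("nan")
    return float((x.max() - mu) / mu)


@dataclass
class CycleCall:
    """Transitions within one inter-mitosis interval (frame indices)."""

    start_frame: int
    end_frame: int  # exclusive; frame of the next M event (or trace end)
    g1s_frame: int | None
    sg2_frame: int | None
    complete: bool  # bounded by M events on both sides
    s_phase_absent: bool = False


@dataclass
class CellCycleAnnotation:
    """Per-frame annotation plus per-cycle transition calls."""

    pcna_var_trace: np.ndarray
    mask_present: np.ndarray
    cycles: list[CycleCall] = field(default_factory=list)
    phase: np.ndarray | None = None  # per-frame label in {G1, S, G2M, M, NA}
    pseudotime_pct: np.ndarray | None = None  # NaN outside complete cycles

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": np.arange(len(self.pcna_var_trace)),
                "pcna_var": self.pcna_var_trace,
                "phase": self.phase,
                "pseudotime_pct": self.pseudotime_pct,
            }
        )


def _moving_median(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x.copy()
    return ndimage.median_filter(x, size=window, mode="nearest")


def call_transitions(
    pcna_var_trace: np.ndarray,
    mask_present: np.ndarray,
    smooth_window: int = 5,
    k_mad: float = 3.0,
    min_interval: int = 5,
    mad_floor_frac: float = 0.1,
) -> CellCycleAnnotation:
    """Call G1/S, S/G2 and M from a PCNA_var trace and mask presence.

    M frames are those with an absent mask. Within each inter-mitosis
    interval the trace is smoothed with a moving median; the G1/S transition
    is the first frame where the smoothed value exceeds the early-interval
    baseline (median of the first quartile) by ``k_mad`` median absolute
    deviations (the MAD is floored at ``mad_floor_frac`` of the baseline so
    a noisy but flat G1 segment cannot trigger a spurious call), and S/G2 is
    the argmax of the smoothed value after G1/S. Intervals with no
    detectable rise are flagged ``s_phase_absent``.
    """
    v = np.asarray(pcna_var_trace, dtype=float)
    present = np.asarray(mask_present, dtype=bool)
    n = v.size
    if present.size != n:
        raise ValueError("trace and mask-presence must have equal length")

    phase = np.array(["NA"] * n, dtype=object)
    phase[~present] = "M"
    pseudo = np.full(n, np.nan)

    # inter-mitosis intervals: maximal runs of present frames
    cycles: list[CycleCall] = []
    i = 0
    while i < n:
        if not present[i]:
            i += 1
            continue
        j = i
        while j < n and present[j]:
            j += 1
        complete = i > 0 and j < n
        seg = v[i:j]
        if seg.size >= min_interval:
            sm = _moving_median(seg, smooth_window)
            q = max(3, seg.size // 4)
            base = np.median(sm[:q])
            mad = np.median(np.abs(sm[:q] - base))
            thresh = base + k_mad * max(mad, mad_floor_frac * abs(base), 1e-9)
            rising = np.nonzero(sm > thresh)[0]
            if rising.size:
                g1s = int(rising[0])
                sg2 = int(g1s + np.argmax(sm[g1s:]))
                # S/G2 requires the focus signal to dissipate after the peak;
                # a plateau (e.g. a replication block) yields no S/G2 call
                peak = sm[sg2]
                dissipated = sg2 < seg.size - 1 and np.min(sm[sg2:]) < peak - 0.2 * (peak - base)
                if not dissipated:
                    sg2 = None
                cycles.append(
                    CycleCall(i, j, i + g1s, None if sg2 is None else i + sg2, complete)
                )
                phase[i : i + g1s] = "G1"
                if sg2 is None:
                    phase[i + g1s : j] = "S"
                else:
                    phase[i + g1s : i + sg2] = "S"
                    phase[i + sg2 : j] = "G2M"
            else:
                cycles.append(CycleCall(i, j, None, None, complete, s_phase_absent=True))
                phase[i:j] = "G1"
        else:
            cycles.append(CycleCall(i, j, None, None, complete, s_phase_absent=True))
        if complete:
            span = j - i
            if span > 1:
                pseudo[i:j] = 100.0 * np.arange(span) / span
        i = j

    return CellCycleAnnotation(
        pcna_var_trace=v,
        mask_present=present,
        cycles=cycles,
        phase=phase,
        pseudotime_pct=pseudo,
    )


def to_pseudotime(
    rate_trace: np.ndarray,
    annotation: CellCycleAnnotation | None = None,
    cycle: tuple[int, int] | None = None,
    n_grid: int = 101,
) -> np.ndarray:
    """Resample a rate trace onto a fixed cell-cycle percent grid.

    The cycle is anchored M-to-M: either the first complete cycle of
    ``annotation`` or an explicit ``(start_frame, end_frame)`` half-open
    interval. Linear interpolation onto ``n_grid`` evenly spaced points from
    0 to 100%; the time-warping removes cycle-duration differences, so two
    cells with identical shape but different cycle lengths resample to the
    same vector.
    """
    x = np.asarray(rate_trace, dtype=float)
    if cycle is None:
        if annotation is None:
            raise ValueError("either annotation or cycle bounds required")
        complete = [c for c in annotation.cycles if c.complete]
        if not complete:
            raise ValueError("no complete M-to-M cycle in annotation")
        cycle = (complete[0].start_frame, complete[0].end_frame)
    start, end = cycle
    seg = x[start:end]
    if seg.size < 2:
        raise ValueError("cycle too short to resample")
    src = 100.0 * np.arange(seg.size) / (seg.size - 1)
    grid = np.linspace(0.0, 100.0, n_grid)
    return np.interp(grid, src, seg)
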