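"""Synthetic ground-truth generators for every pipeline input.

Three generators make the whole analysis chain testable without any
external data:

* ``generate_population`` — clonal cell populations whose per-cell mean
  transcription-rate multipliers are log-normal (static heterogeneity),
  heritable from mother to daughter, and modulated along the cell cycle by a
  stylized two-pulse waveform (dynamic heterogeneity); per-cell reporter
  traces come from the exact telegraph-model simulator.
* ``render_timelapse`` — multi-channel time-lapse stacks: a nuclei channel,
  a nascent-transcription spot channel (Gaussian PSFs on a second-order
  polynomial background) and a PCNA-like cell-cycle texture channel, with a
  full ground-truth record.
* ``generate_count_matrices`` — spike-in-normalized single-cell intron/exon
  count matrices with a planted per-cell global-rate factor, cell-cycle
  modulation, expression tiers and Poisson sampling.

Every generator is deterministic given its spec and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd

from .twostate import SimConfig, TwoStateParams, simulate_cell

__all__ = [
    "PopulationSpec",
    "CellRecord",
    "Population",
    "two_pulse_profile",
    "generate_population",
    "ImageSpec",
    "RenderCell",
    "TimelapseStack",
    "render_timelapse",
    "population_to_render_cells",
    "psf_window_sum",
    "expected_spot_statistic",
    "CountMatrices",
    "generate_count_matrices",
]

# Cell-cycle phase boundaries (fraction of the cycle) used by the generators:
# G1 [0, .30), S [.30, .70), G2 [.70, .95), M [.95, 1).
PHASE_G1S = 0.30
PHASE_SG2 = 0.70
PHASE_M = 0.95


def two_pulse_profile(phase: np.ndarray, amplitude: float = 0.2) -> np.ndarray:
    """Stylized cell-cycle modulation of the global transcription rate.

    Two pulses per cycle — one in G1, one at the late-S/G2 boundary — with a
    trough in mid-S. The shape is standardized so that the temporal CV of
    the returned multiplier over a uniformly traversed cycle equals
    ``amplitude`` exactly; the mean multiplier is 1.
    """
    phase = np.asarray(phase, dtype=float) % 1.0
    dense = np.linspace(0.0, 1.0, 2001)[:-1]

    def raw(x):
        return np.exp(-((x - 0.15) ** 2) / (2 * 0.08**2)) + 0.9 * np.exp(
            -((x - 0.70) ** 2) / (2 * 0.10**2)
        )

    ref = raw(dense)
    mu, sd = ref.mean(), ref.std()
    return 1.0 + amplitude * (raw(phase) - mu) / sd


@dataclass(frozen=True)
class PopulationSpec:
    """Study conditions for a synthetic clonal population."""

    n_cells: int = 200
    cv_static: float = 0.3
    heritability: float = 0.6  # mother-daughter correlation of log-multipliers
    dynamic_amplitude: float = 0.2  # planted temporal CV of the two-pulse waveform
    cell_cycle_length_hr: float = 24.0
    dt_sample_min: float = 10.0
    n_reporters: int = 10
    generations: int = 0  # 0: founders only; 1: add two daughters per founder
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv_static < 0:
            raise ValueError("cv_static must be >= 0")
        if not (-1.0 <= self.heritability <= 1.0):
            raise ValueError("heritability must lie in [-1, 1]")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")


@dataclass
class CellRecord:
    """One simulated cell: identity, planted truth, and (optionally) traces."""

    cell_id: int
    mother_id: int | None
    generation: int
    g_multiplier: float
    cycle_length_hr: float
    times_hr: np.ndarray | None = None
    summed: np.ndarray | None = None
    traces: list | None = None
    multiplier: np.ndarray | None = None  # m(t) on the sample grid
    pseudotime_pct: np.ndarray | None = None

    @property
    def phase_boundaries(self) -> dict:
        """Ground-truth phase boundaries as cycle fractions."""
        return {"G1S": PHASE_G1S, "SG2": PHASE_SG2, "M": PHASE_M}


@dataclass
class Population:
    spec: PopulationSpec
    cells: list[CellRecord]

    @property
    def multipliers(self) -> np.ndarray:
        return np.array([c.g_multiplier for c in self.cells])

    def mother_daughter_pairs(self) -> list[tuple[float, float]]:
        by_id = {c.cell_id: c for c in self.cells}
        return [
            (by_id[c.mother_id].g_multiplier, c.g_multiplier)
            for c in self.cells
            if c.mother_id is not None
        ]

    def rate_matrix(self, n_grid: int = 101) -> np.ndarray:
        """Summed-rate matrix E_{t,c} resampled onto a pseudotime grid."""
        grid = np.linspace(0.0, 100.0, n_grid)
        cols = []
        for c in self.cells:
            if c.summed is None:
                continue
            cols.append(np.interp(grid, c.pseudotime_pct, c.summed.astype(float)))
        return np.column_stack(cols)


def _lognormal_multipliers(n: int, cv: float, rng: np.random.Generator) -> np.ndarray:
    if cv == 0:
        return np.ones(n)
    sigma2 = math.log(1.0 + cv**2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=n)


def generate_population(
    spec: PopulationSpec,
    params: TwoStateParams | None = None,
    simulate_traces: bool = True,
) -> Population:
    """Draw a population with planted static/dynamic/heritable structure.

    Per-cell mean multipliers g_c are log-normal with CV ``cv_static`` and
    mean 1. Daughters inherit the mother's log-multiplier with correlation
    ``heritability`` (bivariate normal on the log scale; both daughters are
    independent draws conditioned on the mother). Each traced cell is
    simulated over exactly one cell cycle with the initiation rate scaled by
    ``g_c`` and modulated by the two-pulse waveform tied to cycle position.
    """
    params = params or TwoStateParams()
    rng = np.random.default_rng(spec.seed)
    cells: list[CellRecord] = []

    g_founders = _lognormal_multipliers(spec.n_cells, spec.cv_static, rng)
    cid = 0
    for g in g_founders:
        cells.append(CellRecord(cid, None, 0, float(g), spec.cell_cycle_length_hr))
        cid += 1
    if spec.generations >= 1 and spec.cv_static > 0:
        sigma2 = math.log(1.0 + spec.cv_static**2)
        sigma = math.sqrt(sigma2)
        mu = -sigma2 / 2.0
        rho = spec.heritability
        for mother in list(cells):
            zm = (math.log(mother.g_multiplier) - mu) / sigma
            for _ in range(2):
                zd = rho * zm + math.sqrt(max(0.0, 1.0 - rho**2)) * rng.standard_normal()
                g = math.exp(mu + sigma * zd)
                cells.append(CellRecord(cid, mother.cell_id, 1, float(g), spec.cell_cycle_length_hr))
                cid += 1
    elif spec.generations >= 1:
        for mother in list(cells):
            for _ in range(2):
                cells.append(CellRecord(cid, mother.cell_id, 1, 1.0, spec.cell_cycle_length_hr))
                cid += 1

    if simulate_traces:
        cfg = SimConfig(
            duration_hr=spec.cell_cycle_length_hr,
            dt_sample_min=spec.dt_sample_min,
            n_reporters=spec.n_reporters,
            seed=spec.seed,
        )
        sub_dt_hr = cfg.subgrid_min / 60.0
        n_sub = int(math.ceil(cfg.duration_hr / sub_dt_hr))
        t_sub = (np.arange(n_sub) + 0.5) * sub_dt_hr
        m_vals = two_pulse_profile(t_sub / spec.cell_cycle_length_hr, spec.dynamic_amplitude)
        times = cfg.sample_times_hr
        m_sample = two_pulse_profile(times / spec.cell_cycle_length_hr, spec.dynamic_amplitude)
        for cell in cells:
            sim = simulate_cell(
                params,
                None,  # waveform unused when m_vals given
                cfg,
                seed=rng,
                k_m_scale=cell.g_multiplier,
                m_vals=m_vals,
                m_sample=m_sample,
            )
            cell.times_hr = sim.times_hr
            cell.summed = sim.summed
            cell.traces = sim.traces
            cell.multiplier = sim.multiplier
            cell.pseudotime_pct = 100.0 * sim.times_hr / spec.cell_cycle_length_hr
    return Population(spec=spec, cells=cells)


# ---------------------------------------------------------------------------
# Image rendering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ImageSpec:
    """Acquisition geometry and noise model of the rendered time-lapse."""

    frame_shape: tuple[int, int] = (256, 256)
    read_noise_sd: float = 20.0
    shot_noise: bool = False
    nucleus_radius_px: tuple[float, float] = (18.0, 24.0)
    psf_sigma_px: float = 1.5
    spot_amplitude_scale: float = 200.0  # counts per nascent transcript
    background_coeffs: tuple[float, ...] = (200.0, 0.1, 0.05, 0.0, 0.0, 0.0)
    z_slices: int = 1
    dt_frame_min: float = 10.0
    nuclear_base: float = 800.0
    pcna_base: float = 600.0
    pcna_puncta_amp: float = 1200.0
    pcna_n_puncta: int = 12

    def __post_init__(self) -> None:
        if self.psf_sigma_px <= 0:
            raise ValueError("psf_sigma_px must be positive")
        if self.z_slices < 1:
            raise ValueError("z_slices must be >= 1")

    def background(self, shape: tuple[int, int] | None = None) -> np.ndarray:
        h, w = shape or self.frame_shape
        r, c = np.mgrid[0:h, 0:w].astype(float)
        a0, a1, a2, a3, a4, a5 = self.background_coeffs
        return a0 + a1 * r + a2 * c + a3 * r * c + a4 * r**2 + a5 * c**2


def psf_window_sum(sigma: float, half: int = 1, subpixel: tuple[float, float] = (0.0, 0.0)) -> float:
    """Sum of a unit-amplitude pixel-sampled Gaussian over a (2*half+1)^2 window."""
    dy, dx = subpixel
    off = np.arange(-half, half + 1, dtype=float)
    gy = np.exp(-((off - dy) ** 2) / (2 * sigma**2))
    gx = np.exp(-((off - dx) ** 2) / (2 * sigma**2))
    return float(np.outer(gy, gx).sum())


def _psf_annulus_median(sigma: float) -> float:
    """Median PSF value over the 56 pixels of the 9x9-minus-5x5 annulus."""
    off = np.arange(-4, 5)
    yy, xx = np.meshgrid(off, off, indexing="ij")
    hollow = (np.abs(yy) > 2) | (np.abs(xx) > 2)
    g = np.exp(-(yy**2 + xx**2) / (2 * sigma**2))
    return float(np.median(g[hollow]))


def expected_spot_statistic(amplitude: float, background: float, sigma: float) -> float:
    """Noise-free expectation of the sum(signal-bg)/bg spot statistic.

    For a pixel-centred Gaussian of peak ``amplitude`` on a locally flat
    ``background``: the 3x3 signal square sums amplitude x K3 over the
    background, while the measured bg (median of the 9x9-minus-5x5 annulus)
    is raised by the PSF tail, amplitude x medG. Hence

        E[intensity] = amplitude * (K3 - 9*medG) / (background + amplitude*medG)
    """
    k3 = psf_window_sum(sigma)
    medg = _psf_annulus_median(sigma)
    return amplitude * (k3 - 9.0 * medg) / (background + amplitude * medg)


@dataclass
class RenderCell:
    """Geometry and per-frame state of one rendered cell."""

    cell_id: int
    center: tuple[float, float]
    radius: float
    loci: np.ndarray  # (n_loci, 3): row, col, z
    amplitudes: np.ndarray  # (n_frames, n_loci) spot amplitudes (counts)
    phases: np.ndarray  # (n_frames,) cycle fraction in [0, 1)
    present: np.ndarray  # (n_frames,) mask visible (False in M phase)


@dataclass
class TimelapseStack:
    """Rendered channels plus the ground truth needed to score the pipeline."""

    spots: np.ndarray  # (T, Z, H, W) uint16
    nuclei: np.ndarray  # (T, H, W) uint16
    pcna: np.ndarray  # (T, H, W) uint16
    spec: ImageSpec
    truth_spots: pd.DataFrame  # frame, cell_id, locus_id, row, col, z, amplitude, true_intensity
    truth_masks: np.ndarray  # (T, H, W) int labels (cell_id + 1)
    truth_phases: pd.DataFrame  # frame, cell_id, phase_fraction, present


def _disc_mask(shape, center, radius):
    r, c = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (r - center[0]) ** 2 + (c - center[1]) ** 2 <= radius**2


def population_to_render_cells(
    pop: Population,
    spec: ImageSpec,
    rng: np.random.Generator,
    max_cells: int | None = None,
    min_separation_factor: float = 2.6,
) -> list[RenderCell]:
    """Lay out traced cells on the frame and map traces to spot amplitudes."""
    h, w = spec.frame_shape
    cells = [c for c in pop.cells if c.summed is not None]
    if max_cells is not None:
        cells = cells[:max_cells]
    out = []
    centers: list[tuple[float, float]] = []
    for cell in cells:
        radius = rng.uniform(*spec.nucleus_radius_px)
        for _ in range(200):
            center = (rng.uniform(radius + 8, h - radius - 8), rng.uniform(radius + 8, w - radius - 8))
            if all(
                math.hypot(center[0] - c0, center[1] - c1) > min_separation_factor * radius
                for c0, c1 in centers
            ):
                break
        else:
            continue  # frame full; drop remaining cells
        centers.append(center)
        n_loci = len(cell.traces)
        min_sep = 6 * spec.psf_sigma_px
        loci: list = []
        for _restart in range(50):
            loci = []
            ok = True
            for _ in range(n_loci):
                for _try in range(200):
                    ang = rng.uniform(0, 2 * math.pi)
                    rad = math.sqrt(rng.uniform(0, 1)) * (radius - 6)
                    pos = (
                        int(round(center[0] + rad * math.sin(ang))),
                        int(round(center[1] + rad * math.cos(ang))),
                    )
                    if all(
                        math.hypot(pos[0] - p[0], pos[1] - p[1]) >= min_sep
                        for p in [(l[0], l[1]) for l in loci]
                    ):
                        break
                else:
                    ok = False  # layout wedged itself in; redraw the whole cell
                    break
                loci.append((pos[0], pos[1], int(rng.integers(0, spec.z_slices))))
            if ok:
                break
        else:
            raise ValueError(
                f"cannot place {n_loci} loci at separation {min_sep:.0f}px "
                f"inside a nucleus of radius {radius:.0f}px"
            )
        amp = np.stack(
            [tr.nascent_counts.astype(float) * spec.spot_amplitude_scale for tr in cell.traces],
            axis=1,
        )
        phases = (cell.times_hr / cell.cycle_length_hr) % 1.0
        present = phases < PHASE_M
        out.append(
            RenderCell(
                cell_id=cell.cell_id,
                center=center,
                radius=radius,
                loci=np.array(loci),
                amplitudes=amp,
                phases=phases,
                present=present,
            )
        )
    return out


def render_timelapse(
    cells: list[RenderCell],
    spec: ImageSpec,
    seed: int = 0,
    n_frames: int | None = None,
) -> TimelapseStack:
    """Render nuclei, spot and PCNA channels with ground truth.

    The spot channel is a second-order polynomial background plus one
    pixel-sampled Gaussian PSF per active locus in its z slice; read noise is
    Gaussian, shot noise optionally Poisson. The PCNA channel is uniform in
    G1, gains puncta whose amplitude ramps through S, peaks at the S/G2
    transition, dissipates in G2, and the nucleus disappears entirely in M.
    Each spot's ``true_intensity`` is the noise-free analytic expectation of
    the sum(signal-bg)/bg statistic at the spot position (see
    :func:`expected_spot_statistic`).
    """
    rng = np.random.default_rng(seed)
    h, w = spec.frame_shape
    if n_frames is None:
        n_frames = min(c.amplitudes.shape[0] for c in cells) if cells else 1
    bg = spec.background()
    half = 4  # render PSF over 9x9 support (covers the bg-annulus tails)
    off = np.arange(-half, half + 1)
    gy = np.exp(-(off[:, None] ** 2 + off[None, :] ** 2) / (2 * spec.psf_sigma_px**2))

    spots = np.zeros((n_frames, spec.z_slices, h, w), dtype=float)
    nuclei = np.zeros((n_frames, h, w), dtype=float)
    pcna = np.zeros((n_frames, h, w), dtype=float)
    masks = np.zeros((n_frames, h, w), dtype=np.int32)
    spot_rows = []
    phase_rows = []

    spots += bg[None, None]
    nuclei += bg[None] * 0.25
    pcna += bg[None] * 0.25

    puncta_cache: dict[int, np.ndarray] = {}
    for cell in cells:
        mask = _disc_mask((h, w), cell.center, cell.radius)
        inner = _disc_mask((h, w), cell.center, cell.radius - 3)
        idx_inner = np.argwhere(inner)
        pk = rng.choice(idx_inner.shape[0], size=min(spec.pcna_n_puncta, idx_inner.shape[0]), replace=False)
        puncta_cache[cell.cell_id] = idx_inner[pk]

    for f in range(n_frames):
        for cell in cells:
            phase = float(cell.phases[f]) if f < len(cell.phases) else 0.0
            present = bool(cell.present[f]) if f < len(cell.present) else True
            phase_rows.append(
                {"frame": f, "cell_id": cell.cell_id, "phase_fraction": phase, "present": present}
            )
            if not present:
                continue
            mask = _disc_mask((h, w), cell.center, cell.radius)
            masks[f][mask] = cell.cell_id + 1
            nuclei[f][mask] += spec.nuclear_base
            pcna[f][mask] += spec.pcna_base
            # PCNA puncta: ramp through S, peak at S/G2, fast dissipation in G2
            if PHASE_G1S <= phase < PHASE_SG2:
                level = (phase - PHASE_G1S) / (PHASE_SG2 - PHASE_G1S)
            elif PHASE_SG2 <= phase < PHASE_SG2 + 0.06:
                level = 1.0 - (phase - PHASE_SG2) / 0.06
            else:
                level = 0.0
            if level > 0:
                for (pr, pc) in puncta_cache[cell.cell_id]:
                    pcna[f, pr, pc] += spec.pcna_puncta_amp * level
            # nascent-site spots
            for j, (lr, lc, lz) in enumerate(cell.loci):
                amp = float(cell.amplitudes[f, j])
                if amp <= 0:
                    continue
                r0, r1 = lr - half, lr + half + 1
                c0, c1 = lc - half, lc + half + 1
                if r0 < 0 or c0 < 0 or r1 > h or c1 > w:
                    continue
                spots[f, lz, r0:r1, c0:c1] += amp * gy
                spot_rows.append(
                    {
                        "frame": f,
                        "cell_id": cell.cell_id,
                        "locus_id": j,
                        "row": int(lr),
                        "col": int(lc),
                        "z": int(lz),
                        "amplitude": amp,
                        "true_intensity": expected_spot_statistic(
                            amp, bg[int(lr), int(lc)], spec.psf_sigma_px
                        ),
                    }
                )

    if spec.shot_noise:
        spots = rng.poisson(np.clip(spots, 0, None)).astype(float)
        nuclei = rng.poisson(np.clip(nuclei, 0, None)).astype(float)
        pcna = rng.poisson(np.clip(pcna, 0, None)).astype(float)
    if spec.read_noise_sd > 0:
        spots += rng.normal(0, spec.read_noise_sd, spots.shape)
        nuclei += rng.normal(0, spec.read_noise_sd, nuclei.shape)
        pcna += rng.normal(0, spec.read_noise_sd, pcna.shape)

    def _to_u16(a):
        return np.clip(np.round(a), 0, 65535).astype(np.uint16)

    truth_spots = pd.DataFrame(
        spot_rows,
        columns=["frame", "cell_id", "locus_id", "row", "col", "z", "amplitude", "true_intensity"],
    )
    return TimelapseStack(
        spots=_to_u16(spots),
        nuclei=_to_u16(nuclei),
        pcna=_to_u16(pcna),
        spec=spec,
        truth_spots=truth_spots,
        truth_masks=masks,
        truth_phases=pd.DataFrame(phase_rows),
    )


# ---------------------------------------------------------------------------
# Count matrices
# ---------------------------------------------------------------------------


@dataclass
class CountMatrices:
    """Paired intron/exon count tables (genes x cells) with spike-ins."""

    intron: pd.DataFrame
    exon: pd.DataFrame
    spikein: pd.Series  # per-cell spike-in total
    pseudotime: pd.Series | None = None  # cell-cycle position in [0, 1)
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.intron.shape != self.exon.shape:
            raise ValueError("intron and exon matrices must share shape")
        if not self.intron.columns.equals(self.exon.columns):
            raise ValueError("intron and exon matrices must share cells")


def generate_count_matrices(
    n_cells: int = 400,
    n_genes: int = 200,
    global_rate_cv: float = 0.3,
    modulation_amplitude: float = 0.2,
    spike_depth: float = 300.0,
    capture_cv: float = 0.2,
    mean_intron_depth: float = 20000.0,
    exon_over_intron: float = 5.0,
    degradation_cv: float = 0.3,
    susceptibility: str = "expression_dependent",
    exon_global_coupling: bool = True,
    planted_regulator: bool = False,
    seed: int = 0,
) -> CountMatrices:
    """Emulate a spike-in-normalized single-cell intron/exon dataset.

    Per-cell: capture factor s_c (log-normal, CV ``capture_cv``), global-rate
    factor g_c (log-normal, CV ``global_rate_cv``), cell-cycle position
    phi_c (uniform) entering through the two-pulse modulation profile.
    Per-gene: synthesis rate alpha_g (log-normal across expression tiers) and
    degradation rate delta_g. Counts are Poisson:

        intron_gc ~ Poisson(s_c * g_c * m_gc * alpha_g)
        exon_gc   ~ Poisson(s_c * g_c * m_gc * alpha_g / delta_g * scale)
        spike_c   ~ Poisson(s_c * spike_depth)

    where m_gc = 1 + w_g * (m(phi_c) - 1). With the default
    ``expression_dependent`` susceptibility low-expression genes feel the
    full modulation (w = 1) while high-expression genes are buffered
    (w = 0.3), mirroring the observation that lowly transcribing genes are
    more susceptible to global fluctuations; ``uniform`` sets w = 1 for all.

    ``exon_global_coupling=False`` removes g_c and the modulation from every
    gene's *exon* counts (introns keep them), and ``planted_regulator=True``
    replaces gene 0's exon counts by a readout proportional to g_c — the
    round-trip fixture for regulator ranking.
    """
    rng = np.random.default_rng(seed)
    s_c = _lognormal_multipliers(n_cells, capture_cv, rng)
    g_c = _lognormal_multipliers(n_cells, global_rate_cv, rng)
    phi_c = rng.uniform(0.0, 1.0, n_cells)
    m_c = (
        two_pulse_profile(phi_c, modulation_amplitude)
        if modulation_amplitude > 0
        else np.ones(n_cells)
    )

    alpha = rng.lognormal(mean=0.0, sigma=1.2, size=n_genes)
    alpha *= mean_intron_depth / alpha.sum()
    delta = _lognormal_multipliers(n_genes, degradation_cv, rng)

    order = np.argsort(alpha)
    tiers = np.empty(n_genes, dtype=object)
    lo, hi = int(0.3 * n_genes), int(0.7 * n_genes)
    tiers[order[:lo]] = "low"
    tiers[order[lo:hi]] = "medium"
    tiers[order[hi:]] = "high"
    if susceptibility == "expression_dependent":
        w_g = np.where(tiers == "low", 1.0, np.where(tiers == "medium", 0.6, 0.3))
    elif susceptibility == "uniform":
        w_g = np.ones(n_genes)
    else:
        raise ValueError("susceptibility must be 'expression_dependent' or 'uniform'")

    m_gc = 1.0 + w_g[:, None] * (m_c[None, :] - 1.0)  # genes x cells
    lam_intron = s_c[None, :] * g_c[None, :] * m_gc * alpha[:, None]
    if exon_global_coupling:
        lam_exon = lam_intron / delta[:, None] * exon_over_intron
    else:
        lam_exon = s_c[None, :] * alpha[:, None] / delta[:, None] * exon_over_intron

    intron = rng.poisson(lam_intron)
    exon = rng.poisson(lam_exon)
    if planted_regulator:
        exon[0, :] = rng.poisson(200.0 * s_c * g_c)
    spike = rng.poisson(s_c * spike_depth)

    genes = [f"gene_{i:04d}" for i in range(n_genes)]
    cols = [f"cell_{i:04d}" for i in range(n_cells)]
    return CountMatrices(
        intron=pd.DataFrame(intron, index=genes, columns=cols),
        exon=pd.DataFrame(exon, index=genes, columns=cols),
        spikein=pd.Series(spike, index=cols, name="spikein"),
        pseudotime=pd.Series(phi_c, index=cols, name="pseudotime"),
        truth={
            "s_c": pd.Series(s_c, index=cols),
            "g_c": pd.Series(g_c, index=cols),
            "phi_c": pd.Series(phi_c, index=cols),
            "alpha_g": pd.Series(alpha, index=genes),
            "delta_g": pd.Series(delta, index=genes),
            "tiers": pd.Series(tiers, index=genes),
            "susceptibility": pd.Series(w_g, index=genes),
            "planted_regulator": genes[0] if planted_regulator else None,
        },
    )
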