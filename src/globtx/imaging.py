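"""Nascent-transcription quantification from time-lapse stacks.

The chain mirrors a standard live-imaging analysis: flatten each frame with
a fitted second-order polynomial background, segment nuclei from the
Sobel edge magnitude, track nuclei by nearest-centroid linking, detect
nascent transcription sites with a Laplacian-of-Gaussian filter on the
background-eliminated maximum-intensity projection, score each site with the
dimensionless statistic sum(signal - bg)/bg (3x3 signal square; bg = median
of a 9x9 square with a 5x5 hollow), and sum sites per cell into the
instantaneous global transcription rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import sobel, threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.morphology import dilation, disk

__all__ = [
    "BackgroundFit",
    "correct_background",
    "segment_nuclei",
    "NucleusTrack",
    "track_nuclei",
    "detect_spots",
    "quantify_spot",
    "track_spots",
    "global_rate",
]


@dataclass
class BackgroundFit:
    corrected: np.ndarray
    surface: np.ndarray
    degenerate: bool = False


def _poly_basis(shape: tuple[int, int]) -> np.ndarray:
    r, c = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    r, c = r.ravel(), c.ravel()
    return np.column_stack([np.ones_like(r), r, c, r * c, r**2, c**2])


def correct_background(image: np.ndarray, mask: np.ndarray | None = None) -> BackgroundFit:
    """Flatten a frame by a least-squares 2nd-order polynomial surface.

    The full six-coefficient bivariate polynomial is fitted to the frame
    (optionally restricted to ``mask`` pixels, e.g. a background subset),
    subtracted, and the frame mean restored. A constant image is returned
    unchanged with ``degenerate=True``.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("correct_background expects a 2-D single-channel frame")
    if np.ptp(img) == 0:
        return BackgroundFit(corrected=img.copy(), surface=np.full_like(img, img.mean()), degenerate=True)
    basis = _poly_basis(img.shape)
    y = img.ravel()
    if mask is not None:
        sel = np.asarray(mask, dtype=bool).ravel()
        coeffs, *_ = np.linalg.lstsq(basis[sel], y[sel], rcond=None)
    else:
        coeffs, *_ = np.linalg.lstsq(basis, y, rcond=None)
    surface = (basis @ coeffs).reshape(img.shape)
    corrected = img - surface + img.mean()
    return BackgroundFit(corrected=corrected, surface=surface)


def segment_nuclei(
    image: np.ndarray,
    min_area: int = 200,
    dilation_radius: int = 2,
    threshold: float | None = None,
) -> np.ndarray:
    """Label nuclei: Sobel edges -> threshold -> dilate -> fill -> label.

    The edge threshold defaults to Otsu on the gradient magnitude.
    Components below ``min_area`` pixels are dropped. Zero nuclei is a valid
    result (all-zero label mask).
    """
    img = np.asarray(image, dtype=float)
    grad = sobel(img)
    if threshold is None:
        if np.ptp(grad) == 0:
            return np.zeros(img.shape, dtype=np.int32)
        threshold = threshold_otsu(grad)
    edges = grad > threshold
    if dilation_radius > 0:
        edges = dilation(edges, disk(dilation_radius))
    filled = ndimage.binary_fill_holes(edges)
    labels = cc_label(filled)
    out = np.zeros_like(labels, dtype=np.int32)
    nxt = 1
    for prop in regionprops(labels):
        if prop.area >= min_area:
            out[labels == prop.label] = nxt
            nxt += 1
    return out


@dataclass
class NucleusTrack:
    cell_id: int
    frames: list[int] = field(default_factory=list)
    labels: list[int] = field(default_factory=list)  # per-frame label in the mask
    centroids: list[tuple[float, float]] = field(default_factory=list)
    areas: list[float] = field(default_factory=list)
    mother_id: int | None = None
    daughter_ids: list[int] = field(default_factory=list)

    @property
    def last_centroid(self) -> tuple[float, float]:
        return self.centroids[-1]


def _frame_props(mask: np.ndarray):
    return [(p.label, p.centroid, p.area) for p in regionprops(mask)]


def track_nuclei(
    masks: list[np.ndarray],
    max_displacement: float = 20.0,
    division_window: int = 3,
    division_radius: float = 40.0,
) -> list[NucleusTrack]:
    """Greedy nearest-centroid linking of per-frame label masks.

    Matches are made smallest-distance-first; distances above the gate start
    new tracks. A track that ends (mask disappearance, the M-phase
    signature) followed within ``division_window`` frames by two new tracks
    starting within ``division_radius`` of its last centroid is recorded as
    a division (mother linked to two daughters).
    """
    tracks: list[NucleusTrack] = []
    active: list[NucleusTrack] = []
    recently_ended: list[NucleusTrack] = []
    for f, mask in enumerate(masks):
        props = _frame_props(mask)
        pairs = []
        for ti, tr in enumerate(active):
            cy, cx = tr.last_centroid
            for pi, (_, (py, px), _) in enumerate(props):
                d = np.hypot(cy - py, cx - px)
                if d <= max_displacement:
                    pairs.append((d, ti, pi))
        pairs.sort()
        used_t: set[int] = set()
        used_p: set[int] = set()
        survivors = []
        for d, ti, pi in pairs:
            if ti in used_t or pi in used_p:
                continue
            used_t.add(ti)
            used_p.add(pi)
            lab, cen, area = props[pi]
            tr = active[ti]
            tr.frames.append(f)
            tr.labels.append(lab)
            tr.centroids.append(cen)
            tr.areas.append(area)
            survivors.append(tr)
        new_tracks = []
        for pi, (lab, cen, area) in enumerate(props):
            if pi in used_p:
                continue
            tr = NucleusTrack(cell_id=len(tracks), frames=[f], labels=[lab], centroids=[cen], areas=[area])
            tracks.append(tr)
            new_tracks.append(tr)
        # division: a recently-ended track with two nearby just-started tracks
        ended = [tr for tr in active if tr not in survivors]
        recently_ended.extend(ended)
        recently_ended = [
            tr for tr in recently_ended if f - tr.frames[-1] <= division_window
        ]
        for mother in recently_ended:
            if mother.daughter_ids:
                continue
            close = [
                tr
                for tr in new_tracks
                if np.hypot(
                    tr.centroids[0][0] - mother.last_centroid[0],
                    tr.centroids[0][1] - mother.last_centroid[1],
                )
                <= division_radius
            ]
            if len(close) >= 2:
                for d in close[:2]:
                    d.mother_id = mother.cell_id
                    mother.daughter_ids.append(d.cell_id)
        active = survivors + new_tracks
    return tracks


def detect_spots(
    zstack: np.ndarray,
    log_sigma: float = 1.5,
    threshold_factor: float = 5.0,
    background_correct: bool = True,
    min_distance: int = 2,
) -> np.ndarray:
    """Detect nascent sites in one (Z, H, W) frame.

    Each slice is background-eliminated with the polynomial fit, the stack
    is maximum-intensity projected, filtered with a Laplacian of Gaussian
    (negated so bright spots are maxima), and 8-connected local maxima above
    ``threshold_factor`` times the robust noise level (MAD-based SD of the
    filtered image) are returned as an array of (row, col, z) with z the
    slice contributing the projected value.
    """
    stack = np.asarray(zstack, dtype=float)
    if stack.ndim == 2:
        stack = stack[None]
    if background_correct:
        stack = np.stack([correct_background(sl).corrected for sl in stack])
    proj = stack.max(axis=0)
    z_origin = stack.argmax(axis=0)
    filt = -ndimage.gaussian_laplace(proj, sigma=log_sigma)
    med = np.median(filt)
    mad = np.median(np.abs(filt - med))
    if mad > 0:
        thresh = med + threshold_factor * 1.4826 * mad
    elif np.ptp(filt) > 0:
        # noise-free frame: fall back to a fraction of the dynamic range
        thresh = med + 0.05 * (filt.max() - med)
    else:
        return np.empty((0, 3), dtype=int)
    peaks = peak_local_max(filt, min_distance=min_distance, threshold_abs=thresh, exclude_border=False)
    if peaks.size == 0:
        return np.empty((0, 3), dtype=int)
    zs = z_origin[peaks[:, 0], peaks[:, 1]]
    return np.column_stack([peaks, zs]).astype(int)


def quantify_spot(frame: np.ndarray, row: int, col: int) -> float:
    """Dimensionless spot intensity sum(signal - bg)/bg.

    signal: the 9 pixels of the 3x3 square centred on (row, col); bg: the
    median of the 56 pixels of the centred 9x9 square excluding the centred
    5x5 square. Positions closer than 4 px to the frame edge (incomplete
    9x9 window) return NaN.
    """
    img = np.asarray(frame, dtype=float)
    h, w = img.shape
    if row < 4 or col < 4 or row >= h - 4 or col >= w - 4:
        return float("nan")
    signal = img[row - 1 : row + 2, col - 1 : col + 2]
    outer = img[row - 4 : row + 5, col - 4 : col + 5].copy()
    outer[2:7, 2:7] = np.nan
    bg = float(np.nanmedian(outer))
    if bg == 0:
        return float("nan")
    return float(np.sum(signal - bg) / bg)


def track_spots(
    detections: pd.DataFrame,
    masks: np.ndarray | list[np.ndarray],
    n_frames: int | None = None,
    max_displacement: float = 4.0,
) -> pd.DataFrame:
    """Link per-frame detections into per-locus intensity traces.

    ``detections`` needs columns frame, row, col, intensity. Each detection
    is assigned to the cell whose mask contains it (label value at its
    pixel); detections on background are dropped. Within each cell, loci are
    linked frame-to-frame by greedy nearest-neighbour matching
    (smallest distance first) with a displacement gate; frames where a locus
    is undetected are filled with intensity 0.

    Returns a tidy frame: cell_id, locus_id, frame, row, col, intensity.
    """
    masks = np.asarray(masks)
    if n_frames is None:
        n_frames = len(masks)
    det = detections.copy()
    cell_ids = []
    for _, d in det.iterrows():
        lab = int(masks[int(d.frame), int(d.row), int(d.col)])
        cell_ids.append(lab - 1 if lab > 0 else -1)
    det["cell_id"] = cell_ids
    det = det[det.cell_id >= 0]

    rows = []
    for cid, sub in det.groupby("cell_id"):
        loci: list[dict] = []  # locus state: last position, per-frame record
        for f in range(n_frames):
            here = sub[sub.frame == f]
            pairs = []
            for li, locus in enumerate(loci):
                for di, (_, d) in enumerate(here.iterrows()):
                    dist = np.hypot(locus["row"] - d.row, locus["col"] - d.col)
                    if dist <= max_displacement:
                        pairs.append((dist, li, di))
            pairs.sort(key=lambda t: t[0])
            used_l: set[int] = set()
            used_d: set[int] = set()
            recs = list(here.iterrows())
            for dist, li, di in pairs:
                if li in used_l or di in used_d:
                    continue
                used_l.add(li)
                used_d.add(di)
                d = recs[di][1]
                loci[li].update(row=float(d.row), col=float(d.col))
                loci[li]["trace"][f] = float(d.intensity)
            for di, (_, d) in enumerate(recs):
                if di in used_d:
                    continue
                loci.append(
                    {"row": float(d.row), "col": float(d.col), "trace": {f: float(d.intensity)}}
                )
        for lid, locus in enumerate(loci):
            for f in range(n_frames):
                rows.append(
                    {
                        "cell_id": cid,
                        "locus_id": lid,
                        "frame": f,
                        "row": locus["row"],
                        "col": locus["col"],
                        "intensity": locus["trace"].get(f, 0.0),
                    }
                )
    return pd.DataFrame(rows, columns=["cell_id", "locus_id", "frame", "row", "col", "intensity"])


def global_rate(traces: pd.DataFrame) -> pd.DataFrame:
    """Per-cell, per-frame aggregates of tracked locus traces.

    Returns cell_id, frame, rate (summed intensity of all sites),
    mean_intensity (mean over detected sites, 0 if none) and active_sites
    (sites with intensity > 0).
    """
    def _agg(sub: pd.DataFrame) -> pd.Series:
        active = sub.intensity > 0
        return pd.Series(
            {
                "rate": sub.intensity.sum(),
                "mean_intensity": sub.intensity[active].mean() if active.any() else 0.0,
                "active_sites": int(active.sum()),
            }
        )

    if traces.empty:
        return pd.DataFrame(columns=["cell_id", "frame", "rate", "mean_intensity", "active_sites"])
    out = traces.groupby(["cell_id", "frame"]).apply(_agg, include_groups=False).reset_index()
    out["active_sites"] = out["active_sites"].astype(int)
    return out
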