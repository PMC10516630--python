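"""Readers and writers for the package's on-disk formats.

Traces and annotations travel as CSV; image stacks as multi-page TIFF (one
file per channel; page order frame-major, then z); count matrices as
MatrixMarket plus TSV row/column annotations and a TSV spike-in table;
ground truth as a JSON sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import io as spio
from scipy import sparse

from .synthetic import CountMatrices, TimelapseStack

__all__ = [
    "write_stack",
    "read_stack",
    "write_count_matrices",
    "read_count_matrices",
]


def write_stack(stack: TimelapseStack, out_dir: str | Path) -> dict[str, Path]:
    """Write a rendered time-lapse: per-channel TIFFs + ground-truth sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    t, z, h, w = stack.spots.shape
    paths["spots"] = out / "spots.tif"
    tifffile.imwrite(paths["spots"], stack.spots.reshape(t * z, h, w))
    paths["nuclei"] = out / "nuclei.tif"
    tifffile.imwrite(paths["nuclei"], stack.nuclei)
    paths["pcna"] = out / "pcna.tif"
    tifffile.imwrite(paths["pcna"], stack.pcna)
    paths["masks"] = out / "truth_masks.tif"
    tifffile.imwrite(paths["masks"], stack.truth_masks.astype(np.uint16))
    paths["truth"] = out / "truth.json"
    sidecar = {
        "z_slices": z,
        "frames": t,
        "spots": stack.truth_spots.to_dict(orient="records"),
        "phases": stack.truth_phases.to_dict(orient="records"),
    }
    paths["truth"].write_text(json.dumps(sidecar))
    return paths


def read_stack(in_dir: str | Path) -> dict:
    """Read back what :func:`write_stack` wrote (arrays + truth tables)."""
    d = Path(in_dir)
    truth = json.loads((d / "truth.json").read_text())
    t, z = truth["frames"], truth["z_slices"]
    spots = tifffile.imread(d / "spots.tif").reshape(t, z, *tifffile.imread(d / "nuclei.tif").shape[1:])
    return {
        "spots": spots,
        "nuclei": tifffile.imread(d / "nuclei.tif"),
        "pcna": tifffile.imread(d / "pcna.tif"),
        "truth_masks": tifffile.imread(d / "truth_masks.tif").astype(np.int32),
        "truth_spots": pd.DataFrame(truth["spots"]),
        "truth_phases": pd.DataFrame(truth["phases"]),
    }


def write_count_matrices(cm: CountMatrices, out_dir: str | Path) -> dict[str, Path]:
    """Write intron/exon MTX (genes x cells) + TSV annotations/spike-ins."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in (("intron", cm.intron), ("exon", cm.exon)):
        paths[name] = out / f"{name}.mtx"
        spio.mmwrite(paths[name], sparse.csr_matrix(df.to_numpy()))
    paths["genes"] = out / "genes.tsv"
    pd.Series(cm.intron.index, name="gene").to_csv(paths["genes"], sep="\t", index=False)
    cells = pd.DataFrame({"cell": cm.intron.columns})
    if cm.pseudotime is not None:
        cells["pseudotime"] = cm.pseudotime.values
    paths["cells"] = out / "cells.tsv"
    cells.to_csv(paths["cells"], sep="\t", index=False)
    paths["spikein"] = out / "spikein.tsv"
    cm.spikein.rename_axis("cell").reset_index().to_csv(paths["spikein"], sep="\t", index=False)
    return paths


def read_count_matrices(in_dir: str | Path) -> CountMatrices:
    d = Path(in_dir)
    genes = pd.read_csv(d / "genes.tsv", sep="\t")["gene"].tolist()
    cells_df = pd.read_csv(d / "cells.tsv", sep="\t")
    cells = cells_df["cell"].tolist()
    intron = pd.DataFrame(
        np.asarray(spio.mmread(d / "intron.mtx").todense()), index=genes, columns=cells
    )
    exon = pd.DataFrame(
        np.asarray(spio.mmread(d / "exon.mtx").todense()), index=genes, columns=cells
    )
    spike_df = pd.read_csv(d / "spikein.tsv", sep="\t").set_index("cell")
    pseudotime = (
        pd.Series(cells_df["pseudotime"].values, index=cells, name="pseudotime")
        if "pseudotime" in cells_df
        else None
    )
    return CountMatrices(
        intron=intron,
        exon=exon,
        spikein=spike_df["spikein"],
        pseudotime=pseudotime,
    )
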