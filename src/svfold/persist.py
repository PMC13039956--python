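"""Persistence helpers: contact maps and bin matrices to HDF5, tracks to bedGraph."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .geometry import BIN_SIZE, PredictionWindow
from .predictor import ContactMap


def save_maps_hdf5(
    maps: dict[str, dict[str, ContactMap]], path: str | Path
) -> None:
    """Write predicted maps as ``/<sv_id>/<augmentation>`` datasets.

    Window coordinates are stored as dataset attributes so maps can be
    re-anchored on the genome when loaded.
    """
    with h5py.File(path, "w") as fh:
        for sv_id, by_aug in maps.items():
            grp = fh.create_group(sv_id)
            for aug, cmap in by_aug.items():
                ds = grp.create_dataset(aug, data=cmap.values,
                                        compression="gzip", compression_opts=4)
                if cmap.window is not None:
                    ds.attrs["chrom"] = cmap.window.chrom
                    ds.attrs["input_start"] = cmap.window.input_start
                    ds.attrs["input_end"] = cmap.window.input_end


def load_maps_hdf5(path: str | Path) -> dict[str, dict[str, ContactMap]]:
    out: dict[str, dict[str, ContactMap]] = {}
    with h5py.File(path, "r") as fh:
        for sv_id, grp in fh.items():
            out[sv_id] = {}
            for aug, ds in grp.items():
                window = None
                if "chrom" in ds.attrs:
                    window = PredictionWindow(
                        str(ds.attrs["chrom"]),
                        int(ds.attrs["input_start"]),
                        int(ds.attrs["input_end"]),
                    )
                out[sv_id][aug] = ContactMap(ds[...], window=window)
    return out


def track_to_bedgraph(
    track: np.ndarray, window: PredictionWindow, path: str | Path,
    name: str = "disruption",
) -> None:
    """Write a 448-bin track as bedGraph over the window's visible bins."""
    lines = [f'track type=bedGraph name="{name}"']
    start = window.visible_start
    for i, v in enumerate(track):
        lines.append(
            f"{window.chrom}\t{start + i * BIN_SIZE}"
            f"\t{start + (i + 1) * BIN_SIZE}\t{v:.6g}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def mask_to_bed(
    mask_bins, window: PredictionWindow, path: str | Path, name: str = "sv_mask"
) -> None:
    """Export masked bins as merged 0-based BED intervals."""
    rows = []
    run_start = None
    prev = None
    for b in sorted(mask_bins) + [None]:
        if run_start is None:
            run_start = b
        elif b is None or b != prev + 1:
            s, e = window.bin_interval(run_start)[0], window.bin_interval(prev)[1]
            rows.append(f"{window.chrom}\t{s}\t{e}\t{name}")
            run_start = b
        prev = b
    Path(path).write_text("\n".join(rows) + "\n" if rows else "")


def bin_matrix_to_hdf5(matrix: pd.DataFrame, path: str | Path) -> None:
    """Persist a sample-by-bin score matrix with its labels."""
    with h5py.File(path, "w") as fh:
        fh.create_dataset("values", data=matrix.to_numpy(dtype=float),
                          compression="gzip", compression_opts=4)
        fh.create_dataset("samples",
                          data=np.array(matrix.index, dtype="S"))
        fh.create_dataset("bins", data=np.array(matrix.columns, dtype="S"))


def bin_matrix_from_hdf5(path: str | Path) -> pd.DataFrame:
    with h5py.File(path, "r") as fh:
        return pd.DataFrame(
            fh["values"][...],
            index=[s.decode() for s in fh["samples"][...]],
            columns=[b.decode() for b in fh["bins"][...]],
        )
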