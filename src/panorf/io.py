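"""HDF5 / CSV persistence for recordings, RF stacks and cell tables."""

from __future__ import annotations

from typing import Sequence

import h5py
import numpy as np
import pandas as pd

from .mapping import SpatiotemporalRF
from .simulate import (GroundTruthCell, ShiftingNoiseStimulus,
                       SimulatedRecording)

__all__ = [
    "save_recording",
    "load_recording",
    "save_rf_stack",
    "load_rf_stack",
    "cells_to_frame",
    "save_panorama_stack",
    "load_panorama_stack",
]


def cells_to_frame(cells: Sequence[GroundTruthCell]) -> pd.DataFrame:
    """Ground-truth cell table (one row per cell, kernel omitted)."""
    return pd.DataFrame([{
        "cell_id": c.cell_id,
        "x_um": c.position_um[0],
        "y_um": c.position_um[1],
        "polarity": c.polarity,
        "center_amp": c.center_amp,
        "surround_amp": c.surround_amp,
        "center_sigma_um": c.center_sigma_um,
        "surround_sigma_um": c.surround_sigma_um,
        "surround_offset_um": c.surround_offset_um,
        "noise_level": c.noise_level,
        "true_relative_surround": c.true_relative_surround(),
        "true_vertical_asymmetry": c.true_vertical_asymmetry(),
    } for c in cells])


def save_recording(path: str, rec: SimulatedRecording) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("stimulus")
        g.create_dataset("frames", data=rec.stimulus.frames, compression="gzip")
        g.create_dataset("shifts_px", data=rec.stimulus.shifts_px)
        for k in ("px_um", "checker_um", "shift_quantum_um", "update_hz", "seed"):
            g.attrs[k] = getattr(rec.stimulus, k)
        f.create_dataset("traces", data=rec.traces, compression="gzip")
        f.attrs["imaging_hz"] = rec.imaging_hz
        f.attrs["origin_um"] = rec.origin_um
        f.attrs["seed"] = rec.seed
        ct = f.create_group("cells")
        tbl = cells_to_frame(rec.cells)
        for col in tbl.columns:
            ct.create_dataset(col, data=tbl[col].to_numpy())
        ct.create_dataset("kernel", data=np.stack(
            [c.temporal_kernel for c in rec.cells]))


def load_recording(path: str) -> SimulatedRecording:
    with h5py.File(path, "r") as f:
        g = f["stimulus"]
        stim = ShiftingNoiseStimulus(
            frames=g["frames"][...], shifts_px=g["shifts_px"][...],
            px_um=float(g.attrs["px_um"]), checker_um=float(g.attrs["checker_um"]),
            shift_quantum_um=float(g.attrs["shift_quantum_um"]),
            update_hz=float(g.attrs["update_hz"]), seed=int(g.attrs["seed"]))
        ct = f["cells"]
        kernels = ct["kernel"][...]
        n = kernels.shape[0]
        cells = [GroundTruthCell(
            cell_id=int(ct["cell_id"][i]),
            position_um=(float(ct["x_um"][i]), float(ct["y_um"][i])),
            polarity=int(ct["polarity"][i]),
            center_amp=float(ct["center_amp"][i]),
            surround_amp=float(ct["surround_amp"][i]),
            center_sigma_um=float(ct["center_sigma_um"][i]),
            surround_sigma_um=float(ct["surround_sigma_um"][i]),
            surround_offset_um=float(ct["surround_offset_um"][i]),
            temporal_kernel=kernels[i],
            noise_level=float(ct["noise_level"][i]),
        ) for i in range(n)]
        return SimulatedRecording(
            stimulus=stim, traces=f["traces"][...],
            imaging_hz=float(f.attrs["imaging_hz"]), cells=cells,
            origin_um=tuple(f.attrs["origin_um"]), seed=int(f.attrs["seed"]))


def save_rf_stack(path: str, rfs: Sequence[SpatiotemporalRF]) -> None:
    with h5py.File(path, "w") as f:
        for rf in rfs:
            g = f.create_group(f"rf_{rf.cell_id}")
            g.create_dataset("values", data=rf.values, compression="gzip")
            g.create_dataset("mask", data=rf.mask)
            g.create_dataset("latencies", data=rf.latencies)
            g.attrs["px_um"] = rf.px_um
            g.attrs["cell_id"] = rf.cell_id
            g.attrs["normalized"] = rf.normalized
            if rf.p_var is not None:
                g.attrs["p_var"] = rf.p_var
            if rf.t_var is not None:
                g.attrs["t_var"] = rf.t_var
            if rf.snr_db is not None:
                g.attrs["snr_db"] = rf.snr_db


def load_rf_stack(path: str) -> list[SpatiotemporalRF]:
    out = []
    with h5py.File(path, "r") as f:
        for name in sorted(f, key=lambda s: int(s.split("_")[1])):
            g = f[name]
            rf = SpatiotemporalRF(
                values=g["values"][...], latencies=g["latencies"][...],
                px_um=float(g.attrs["px_um"]), cell_id=int(g.attrs["cell_id"]),
                mask=g["mask"][...], normalized=bool(g.attrs["normalized"]))
            if "p_var" in g.attrs:
                rf.p_var = tuple(int(v) for v in g.attrs["p_var"])
            if "t_var" in g.attrs:
                rf.t_var = int(g.attrs["t_var"])
            if "snr_db" in g.attrs:
                rf.snr_db = float(g.attrs["snr_db"])
            out.append(rf)
    return out


def save_panorama_stack(path: str, images, params=None) -> None:
    """Image stack + generator attributes (seed and scalar params)."""
    with h5py.File(path, "w") as f:
        stack = np.stack([im.intensity for im in images])
        d = f.create_dataset("images", data=stack, compression="gzip")
        d.attrs["deg_per_row"] = images[0].deg_per_row
        d.attrs["top_elevation_deg"] = images[0].top_elevation_deg
        d.attrs["channel"] = images[0].channel
        if params is not None:
            for k in ("spectral_exponent", "horizon_step", "seed"):
                d.attrs[k] = getattr(params, k)


def load_panorama_stack(path: str):
    from .scenes import PanoramicImage
    with h5py.File(path, "r") as f:
        d = f["images"]
        stack = d[...]
        return [PanoramicImage(stack[i], deg_per_row=float(d.attrs["deg_per_row"]),
                               top_elevation_deg=float(d.attrs["top_elevation_deg"]),
                               channel=str(d.attrs["channel"]))
                for i in range(stack.shape[0])]
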