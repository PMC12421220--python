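"""Standard-format I/O: CSV voxel tables, NIfTI volumes, b-value files,
run manifests.

Voxel tables are CSV with a fixed column order — ``voxel_id``, one signal
column per b-value (``signal_b<value>``), then any parameter columns with
units in the header (``Dt_um2_per_ms`` etc.). NIfTI is used only for
volumetric workflows: a 4D diffusion-weighted volume whose last axis matches
the protocol, flattened to a voxel table with an index map so parameter maps
can be written back (masked-out voxels become NaN).

b-value files follow the FSL convention: whitespace- or newline-separated
numbers in s/mm^2, converted to the package's working units (ms/um^2) on
read unless the file is already in working units.
"""

from __future__ import annotations

import datetime
import json
import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .ivim import PARAM_NAMES, AcquisitionProtocol
from .rician import NoiseSpec
from .simulate import SignalBatch

__all__ = [
    "read_bvals",
    "signal_columns",
    "write_signal_csv",
    "read_signal_csv",
    "write_params_csv",
    "read_dwi_nifti",
    "write_param_maps_nifti",
    "write_manifest",
    "PARAM_UNIT_COLUMNS",
]

logger = logging.getLogger(__name__)

#: CSV headers carry units
PARAM_UNIT_COLUMNS = {
    "Dt": "Dt_um2_per_ms",
    "Dp": "Dp_um2_per_ms",
    "f": "f_fraction",
    "S0": "S0_au",
}


def read_bvals(path, units: str = "s/mm^2") -> AcquisitionProtocol:
    """Read a one-column/whitespace-separated b-value text file.

    ``units``: 's/mm^2' (FSL convention, divided by 1000) or 'ms/um^2'
    (already in working units).
    """
    values = np.loadtxt(path).ravel()
    if units == "s/mm^2":
        return AcquisitionProtocol.from_s_per_mm2(values)
    if units == "ms/um^2":
        return AcquisitionProtocol(values)
    raise ValueError(f"unknown b-value units {units!r}")


def signal_columns(protocol: AcquisitionProtocol) -> list:
    return [f"signal_b{b:g}" for b in protocol.b_values]


def write_signal_csv(batch: SignalBatch, path) -> None:
    """Voxel table: voxel_id, signal columns, then truth columns if present."""
    df = pd.DataFrame(batch.M, columns=signal_columns(batch.protocol))
    df.insert(0, "voxel_id", np.arange(batch.n_voxels))
    if batch.truth is not None:
        for name in PARAM_NAMES:
            df[PARAM_UNIT_COLUMNS[name]] = batch.truth[name].to_numpy()
        if "combo_id" in batch.truth.columns:
            df["combo_id"] = batch.truth["combo_id"].to_numpy()
    df.to_csv(path, index=False)


def read_signal_csv(path, protocol: AcquisitionProtocol,
                    sigma: float | None = None) -> SignalBatch:
    df = pd.read_csv(path)
    cols = signal_columns(protocol)
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"signal CSV lacks columns for this protocol: {missing}")
    truth = None
    if all(PARAM_UNIT_COLUMNS[n] in df.columns for n in PARAM_NAMES):
        truth = pd.DataFrame(
            {n: df[PARAM_UNIT_COLUMNS[n]].to_numpy() for n in PARAM_NAMES}
        )
        if "combo_id" in df.columns:
            truth["combo_id"] = df["combo_id"].to_numpy()
    return SignalBatch(
        M=df[cols].to_numpy(dtype=float),
        protocol=protocol,
        truth=truth,
        sigma_true=None if sigma is None else NoiseSpec(sigma),
    )


def write_params_csv(params: pd.DataFrame, path) -> None:
    """Parameter table with units in headers; passes through extra columns."""
    out = params.rename(columns=PARAM_UNIT_COLUMNS)
    out.insert(0, "voxel_id", np.arange(len(out)))
    out.to_csv(path, index=False)


def read_dwi_nifti(path, bvals_path=None, protocol: AcquisitionProtocol = None,
                   mask_path=None, bval_units: str = "s/mm^2"):
    """Flatten a 4D diffusion-weighted NIfTI volume to a SignalBatch.

    Returns (batch, index_map) where ``index_map`` carries everything needed
    to write parameter maps back: the 3D shape, affine, and the flat indices
    of the in-mask voxels. Voxels outside the mask (or with any nonpositive
    signal) are excluded and reappear as NaN in output maps.
    """
    if (bvals_path is None) == (protocol is None):
        raise ValueError("supply exactly one of bvals_path or protocol")
    if protocol is None:
        protocol = read_bvals(bvals_path, units=bval_units)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"expected a 4D volume, got shape {data.shape}")
    if data.shape[-1] != protocol.n_measurements:
        raise ValueError(
            f"volume has {data.shape[-1]} diffusion volumes but protocol has "
            f"{protocol.n_measurements} b-values"
        )
    shape3d = data.shape[:3]
    flat = data.reshape(-1, data.shape[-1])
    keep = np.all(flat > 0, axis=1)
    if mask_path is not None:
        mask = np.asarray(nib.load(str(mask_path)).dataobj).astype(bool)
        if mask.shape != shape3d:
            raise ValueError("mask shape does not match volume")
        keep &= mask.reshape(-1)
    idx = np.flatnonzero(keep)
    if idx.size == 0:
        raise ValueError("no usable voxels after masking")
    batch = SignalBatch(M=flat[idx], protocol=protocol)
    index_map = {"shape": shape3d, "affine": np.asarray(img.affine),
                 "flat_indices": idx}
    return batch, index_map


def write_param_maps_nifti(params: pd.DataFrame, index_map: dict,
                           out_dir) -> dict:
    """One 3D NIfTI per parameter; masked voxels are NaN. Returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n = int(np.prod(index_map["shape"]))
    paths = {}
    for name in PARAM_NAMES:
        vol = np.full(n, np.nan)
        vol[index_map["flat_indices"]] = params[name].to_numpy(dtype=float)
        img = nib.Nifti1Image(vol.reshape(index_map["shape"]),
                              index_map["affine"])
        p = out_dir / f"{name}.nii"
        nib.save(img, str(p))
        paths[name] = p
    return paths


def write_manifest(out_dir, command: str, config: dict) -> Path:
    """Snapshot of the run: command, config, seeds, sigma, protocol, versions."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "config": config,
        "timestamp": datetime.datetime.now().isoformat(timespec="seconds"),
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "nibabel": nib.__version__,
        },
    }
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    logger.info("wrote manifest %s", path)
    return path
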