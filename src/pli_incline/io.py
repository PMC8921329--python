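"""Reading and writing rasters, rotation series and phantom bundles.

Rasters travel as single-page 32-bit float TIFFs or HDF5 datasets; rotation
series as multi-page TIFFs or a 3D HDF5 dataset with the angle axis first.
Phantom bundles are HDF5 files with datasets ``transmittance``,
``direction``, ``retardation``, ``alpha_truth``, ``dm_truth``,
``labels_truth`` (and optionally ``series``/``angles``), with the spec
embedded as a JSON attribute.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .phantom import Phantom, PhantomSpec
from .signal import PLIMaps, RotationSeries

__all__ = [
    "read_raster",
    "write_raster",
    "read_series",
    "write_series",
    "read_maps",
    "write_maps",
    "write_phantom",
    "read_phantom",
]

_MAP_NAMES = ("transmittance", "direction", "retardation")


def _is_hdf5(path: Path) -> bool:
    return path.suffix.lower() in {".h5", ".hdf5", ".hdf"}


def read_raster(path: str | Path, dataset: str | None = None) -> np.ndarray:
    """Read a 2D raster from a TIFF file or an HDF5 dataset."""
    path = Path(path)
    if _is_hdf5(path):
        if dataset is None:
            raise ValueError("an HDF5 raster needs a dataset name")
        with h5py.File(path, "r") as f:
            return np.asarray(f[dataset], dtype=float)
    return np.asarray(tifffile.imread(path), dtype=float)


def write_raster(path: str | Path, data: np.ndarray, dataset: str | None = None) -> None:
    """Write a 2D raster as a 32-bit float TIFF or an HDF5 dataset."""
    path = Path(path)
    if _is_hdf5(path):
        if dataset is None:
            raise ValueError("an HDF5 raster needs a dataset name")
        with h5py.File(path, "a") as f:
            if dataset in f:
                del f[dataset]
            f.create_dataset(dataset, data=np.asarray(data, dtype=np.float32))
    else:
        tifffile.imwrite(path, np.asarray(data, dtype=np.float32))


def read_series(path: str | Path, dataset: str = "series") -> RotationSeries:
    """Read a rotation series (angle axis first) from multi-page TIFF or HDF5."""
    path = Path(path)
    if _is_hdf5(path):
        with h5py.File(path, "r") as f:
            stack = np.asarray(f[dataset], dtype=float)
            angles = (
                np.asarray(f["angles"], dtype=float)
                if "angles" in f
                else np.arange(stack.shape[0]) * (180.0 / stack.shape[0])
            )
    else:
        stack = np.asarray(tifffile.imread(path), dtype=float)
        angles = np.arange(stack.shape[0]) * (180.0 / stack.shape[0])
    return RotationSeries(stack, angles)


def write_series(path: str | Path, series: RotationSeries, dataset: str = "series") -> None:
    path = Path(path)
    if _is_hdf5(path):
        with h5py.File(path, "a") as f:
            for name in (dataset, "angles"):
                if name in f:
                    del f[name]
            f.create_dataset(dataset, data=series.intensities.astype(np.float32))
            f.create_dataset("angles", data=series.angles)
    else:
        tifffile.imwrite(path, series.intensities.astype(np.float32))


def read_maps(path: str | Path) -> PLIMaps:
    """Read transmittance/direction/retardation from one HDF5 file or a
    directory of ``<name>.tif`` files."""
    path = Path(path)
    if path.is_dir():
        arrays = {}
        for name in _MAP_NAMES:
            candidates = list(path.glob(f"{name}.tif*"))
            if not candidates:
                raise FileNotFoundError(f"no {name} TIFF in {path}")
            arrays[name] = read_raster(candidates[0])
        return PLIMaps(**arrays)
    if _is_hdf5(path):
        with h5py.File(path, "r") as f:
            return PLIMaps(**{n: np.asarray(f[n], dtype=float) for n in _MAP_NAMES})
    raise ValueError(f"cannot read maps from {path}; expected a directory or HDF5 file")


def write_maps(path: str | Path, maps: PLIMaps) -> None:
    """Write the three maps to an HDF5 file or a directory of TIFFs."""
    path = Path(path)
    data = {
        "transmittance": maps.transmittance,
        "direction": maps.direction,
        "retardation": maps.retardation,
    }
    if _is_hdf5(path):
        for name, arr in data.items():
            write_raster(path, arr, dataset=name)
    else:
        path.mkdir(parents=True, exist_ok=True)
        for name, arr in data.items():
            write_raster(path / f"{name}.tif", arr)


def write_phantom(path: str | Path, phantom: Phantom) -> None:
    """Write a phantom bundle (maps + ground truth + embedded spec JSON)."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("transmittance", data=phantom.maps.transmittance)
        f.create_dataset("direction", data=phantom.maps.direction)
        f.create_dataset("retardation", data=phantom.maps.retardation)
        f.create_dataset("alpha_truth", data=phantom.alpha_truth)
        f.create_dataset("dm_truth", data=phantom.dm_truth)
        f.create_dataset("labels_truth", data=phantom.labels_truth)
        if phantom.series is not None:
            f.create_dataset("series", data=phantom.series.intensities)
            f.create_dataset("angles", data=phantom.series.angles)
        f.attrs["spec"] = json.dumps(dataclasses.asdict(phantom.spec))


def read_phantom(path: str | Path) -> Phantom:
    path = Path(path)
    with h5py.File(path, "r") as f:
        spec_dict = json.loads(f.attrs["spec"])
        spec_dict["shape"] = tuple(spec_dict["shape"])
        spec_dict["layout"] = tuple(spec_dict["layout"])
        spec = PhantomSpec(**spec_dict)
        maps = PLIMaps(
            transmittance=np.asarray(f["transmittance"], dtype=float),
            direction=np.asarray(f["direction"], dtype=float),
            retardation=np.asarray(f["retardation"], dtype=float),
        )
        series = None
        if "series" in f:
            series = RotationSeries(
                np.asarray(f["series"], dtype=float), np.asarray(f["angles"], dtype=float)
            )
        return Phantom(
            spec=spec,
            maps=maps,
            alpha_truth=np.asarray(f["alpha_truth"], dtype=float),
            dm_truth=np.asarray(f["dm_truth"], dtype=float),
            labels_truth=np.asarray(f["labels_truth"]),
            series=series,
        )
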