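"""Volume readers/writers: HDF5 (canonical), TIFF and PNG stacks.

HDF5 stores a single dataset (default name ``stack``) with an
``axis_order`` attribute; integer label volumes are written as unsigned
64-bit, intensity volumes as 32-bit float.  TIFF handles 2D images and 3D
stacks; a directory of PNG slices covers 2D/small-3D convenience cases.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["read_volume", "write_volume"]

_H5_EXT = {".h5", ".hdf5", ".hdf"}
_TIFF_EXT = {".tif", ".tiff"}
_PNG_EXT = {".png"}

LABEL_DTYPE = np.uint64
INTENSITY_DTYPE = np.float32


def _as_output_dtype(volume, labels: bool):
    volume = np.asarray(volume)
    if labels:
        if not np.issubdtype(volume.dtype, np.integer) and not np.issubdtype(
            volume.dtype, np.unsignedinteger
        ):
            raise ValueError(
                f"label volume must have integer dtype, got {volume.dtype}"
            )
        return volume.astype(LABEL_DTYPE)
    return volume.astype(INTENSITY_DTYPE)


def write_volume(
    volume,
    path,
    labels: bool = False,
    dataset: str = "stack",
    axis_order: str | None = None,
):
    """Write a volume; format chosen by file extension.

    ``labels=True`` enforces integer data and the label dtype.  For PNG,
    ``path`` may be a directory, written as one 8/16-bit slice per file.
    """
    path = Path(path)
    volume = _as_output_dtype(volume, labels)
    ext = path.suffix.lower()
    if ext in _H5_EXT:
        import h5py

        with h5py.File(path, "w") as f:
            d = f.create_dataset(dataset, data=volume)
            d.attrs["axis_order"] = axis_order or "spatial+channel"
            d.attrs["labels"] = bool(labels)
    elif ext in _TIFF_EXT:
        import tifffile

        tifffile.imwrite(path, volume)
    elif ext in _PNG_EXT or (ext == "" and labels is not None):
        _write_png(volume, path, labels)
    else:
        raise ValueError(f"unknown volume format for {path}")


def _write_png(volume, path, labels):
    import imageio.v3 as iio

    if labels:
        if volume.max() > np.iinfo(np.uint16).max:
            raise ValueError("label values exceed 16-bit PNG range")
        volume = volume.astype(np.uint16)
    else:
        volume = np.clip(volume, 0, 1)
        volume = (volume * np.iinfo(np.uint16).max).astype(np.uint16)
    if volume.ndim == 2:
        iio.imwrite(Path(path).with_suffix(".png"), volume)
    elif volume.ndim == 3:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        width = len(str(volume.shape[0] - 1))
        for i, sl in enumerate(volume):
            iio.imwrite(path / f"slice_{i:0{width}d}.png", sl)
    else:
        raise ValueError("PNG supports 2D images or 3D stacks only")


def read_volume(
    path, labels: bool = False, dataset: str = "stack"
) -> np.ndarray:
    """Read a volume written by :func:`write_volume`.

    PNG directories are read as a (k, H, W) stack in sorted slice order.
    ``labels=True`` validates integer content and returns the label
    dtype; intensities come back as float32 (PNG rescaled to [0, 1]).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    ext = path.suffix.lower()
    if path.is_dir():
        vol = _read_png_stack(path)
    elif ext in _H5_EXT:
        import h5py

        with h5py.File(path, "r") as f:
            if dataset not in f:
                raise ValueError(
                    f"dataset {dataset!r} not found in {path}; "
                    f"available: {list(f.keys())}"
                )
            vol = f[dataset][...]
    elif ext in _TIFF_EXT:
        import tifffile

        vol = tifffile.imread(path)
    elif ext in _PNG_EXT:
        import imageio.v3 as iio

        vol = iio.imread(path)
    else:
        raise ValueError(
            f"unknown volume format for {path} (tried HDF5/TIFF/PNG by extension)"
        )
    if labels:
        if not np.issubdtype(vol.dtype, np.integer):
            raise ValueError(
                f"requested labels but {path} holds {vol.dtype} data"
            )
        return vol.astype(LABEL_DTYPE)
    vol = vol.astype(INTENSITY_DTYPE)
    if ext in _PNG_EXT or path.is_dir():
        vol = vol / np.iinfo(np.uint16).max
    return vol


def _read_png_stack(path: Path) -> np.ndarray:
    import imageio.v3 as iio

    files = sorted(path.glob("*.png"))
    if not files:
        raise ValueError(f"no PNG slices found in directory {path}")
    return np.stack([iio.imread(f) for f in files])
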