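"""NIfTI-1, paradigm, and table I/O.

Images use RAS orientation with isotropic voxel size (mm) in the spatial
zooms and the volume TR (s) in the fourth zoom.  In-memory 4D arrays are
(t, x, y, z); on disk the NIfTI layout is (x, y, z, t).
"""

from __future__ import annotations

import numpy as np
import nibabel as nib

from .recon import ImageSeries

__all__ = ["write_nifti", "read_nifti", "write_onsets", "read_onsets"]

_SUPPORTED_DTYPES = (
    np.float32, np.float64, np.int16, np.int32, np.uint8, np.uint16,
)


def write_nifti(path, series: ImageSeries | np.ndarray, voxel_size: float | None = None,
                volume_tr: float | None = None) -> None:
    """Write a 3D volume or 4D series as NIfTI-1 (RAS, zooms set)."""
    if isinstance(series, ImageSeries):
        data = np.moveaxis(series.data, 0, -1)
        voxel_size = series.voxel_size
        volume_tr = series.volume_tr
    else:
        data = np.asarray(series)
        if data.ndim == 4:
            data = np.moveaxis(data, 0, -1)
        if voxel_size is None:
            raise ValueError("voxel_size is required for plain arrays")
    affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    img = nib.Nifti1Image(data.astype(np.float32), affine)
    zooms = [voxel_size] * 3
    if data.ndim == 4:
        zooms.append(volume_tr or 0.0)
        img.header.set_xyzt_units("mm", "sec")
    else:
        img.header.set_xyzt_units("mm")
    img.header.set_zooms(zooms)
    nib.save(img, str(path))


def read_nifti(path) -> ImageSeries:
    """Read a 3D/4D NIfTI-1 file into an :class:`ImageSeries`.

    3D volumes come back as a single-volume series.  Unsupported on-disk
    datatypes raise with the datatype named.
    """
    img = nib.load(str(path))
    dt = img.get_data_dtype()
    if dt.type not in _SUPPORTED_DTYPES:
        raise ValueError(f"unsupported NIfTI datatype {dt}")
    data = np.asarray(img.dataobj, dtype=float)
    zooms = img.header.get_zooms()
    if data.ndim == 3:
        data = data[None]
        tr = 0.0
    elif data.ndim == 4:
        data = np.moveaxis(data, -1, 0)
        tr = float(zooms[3]) if len(zooms) > 3 else 0.0
    else:
        raise ValueError(f"expected 3-D or 4-D image, got {data.ndim}-D")
    return ImageSeries(data=data, voxel_size=float(zooms[0]), volume_tr=tr)


def write_onsets(path, paradigm) -> None:
    """Three-column (onset, duration, amplitude) stimulation file."""
    np.savetxt(path, paradigm.to_onsets_table(), fmt="%.6g", delimiter="\t")


def read_onsets(path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path, delimiter="\t"))
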