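"""Volume readers/writers: NIfTI (.nii/.nii.gz), MetaImage (.mha), TIFF.

Label maps are stored unsigned 16-bit, images signed 16-bit HU (rounded).
On load, unsigned integer data becomes a :class:`LabelMap` and everything
else a :class:`VoxelImage`.  Anisotropic header spacing is accepted with a
warning; the carried isotropic spacing is the geometric mean so voxel
volumes in mm³ stay correct.
"""
from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np

from .grid import DEFAULT_SPACING_UM, LabelMap, VoxelImage

__all__ = ["load_volume", "save_volume"]

_MET_TYPES = {
    "MET_SHORT": np.int16,
    "MET_USHORT": np.uint16,
    "MET_UCHAR": np.uint8,
    "MET_FLOAT": np.float32,
    "MET_DOUBLE": np.float64,
}
_MET_NAMES = {np.dtype(v): k for k, v in _MET_TYPES.items()}


def _effective_spacing(zooms_um: tuple[float, ...], path) -> float:
    z = np.asarray(zooms_um, dtype=float)
    if np.any(z <= 0):
        raise ValueError(f"{path}: non-positive voxel spacing in header")
    if not np.allclose(z, z[0]):
        warnings.warn(
            f"{path}: anisotropic spacing {tuple(z)} µm; carrying the "
            "geometric mean so voxel volumes stay correct",
            stacklevel=3,
        )
        return float(np.prod(z) ** (1.0 / 3.0))
    return float(z[0])


def _wrap(arr: np.ndarray, spacing_um: float):
    if np.issubdtype(arr.dtype, np.unsignedinteger):
        return LabelMap(arr.astype(np.int64), spacing_um)
    return VoxelImage(arr, spacing_um)


def load_volume(path, spacing_um: float | None = None):
    """Load a grid as :class:`VoxelImage` or :class:`LabelMap` by dtype."""
    path = Path(path)
    suffixes = "".join(path.suffixes)
    try:
        if suffixes.endswith((".nii", ".nii.gz")):
            import nibabel as nib

            img = nib.load(str(path))
            arr = np.asanyarray(img.dataobj)
            # stored x,y,z -> (z,y,x)
            arr = np.transpose(arr, (2, 1, 0))
            zooms_mm = img.header.get_zooms()[:3]
            sp = _effective_spacing(tuple(1000.0 * z for z in zooms_mm[::-1]), path)
            return _wrap(arr, sp)
        if suffixes.endswith(".mha"):
            return _load_mha(path)
        if suffixes.endswith((".tif", ".tiff")):
            import tifffile

            with tifffile.TiffFile(str(path)) as tf:
                arr = tf.asarray()
                desc = tf.pages[0].tags.get("ImageDescription")
                sp = None
                if desc is not None:
                    try:
                        sp = float(json.loads(desc.value).get("spacing_um"))
                    except (ValueError, TypeError, json.JSONDecodeError):
                        sp = None
            if sp is None:
                if spacing_um is None:
                    raise ValueError(
                        f"{path}: TIFF carries no spacing; pass spacing_um explicitly"
                    )
                sp = spacing_um
            return _wrap(arr, sp)
    except (OSError, EOFError) as exc:
        raise ValueError(f"cannot parse volume file {path}: {exc}") from exc
    raise ValueError(f"unsupported volume extension for {path} (use .nii[.gz], .mha, .tif)")


def save_volume(obj, path) -> None:
    """Write a VoxelImage (int16 HU) or LabelMap (uint16) by extension."""
    path = Path(path)
    if isinstance(obj, LabelMap):
        if obj.values.max(initial=0) > np.iinfo(np.uint16).max:
            raise ValueError("label values exceed uint16 range")
        arr = obj.values.astype(np.uint16)
    elif isinstance(obj, VoxelImage):
        arr = np.clip(np.rint(obj.values), -32768, 32767).astype(np.int16)
    else:
        raise TypeError(f"cannot save object of type {type(obj).__name__}")
    spacing_um = obj.spacing_um
    suffixes = "".join(path.suffixes)
    if suffixes.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        zoom_mm = spacing_um / 1000.0
        affine = np.diag([zoom_mm, zoom_mm, zoom_mm, 1.0])
        # store as x,y,z
        nib.save(nib.Nifti1Image(np.transpose(arr, (2, 1, 0)), affine), str(path))
    elif suffixes.endswith(".mha"):
        _save_mha(arr, spacing_um, path)
    elif suffixes.endswith((".tif", ".tiff")):
        import tifffile

        tifffile.imwrite(
            str(path), arr, description=json.dumps({"spacing_um": spacing_um})
        )
    else:
        raise ValueError(f"unsupported volume extension for {path}")


# -- minimal uncompressed MetaImage codec (SimpleITK-free) -----------------
def _save_mha(arr: np.ndarray, spacing_um: float, path: Path) -> None:
    nz, ny, nx = arr.shape
    sp_mm = spacing_um / 1000.0
    header = (
        "ObjectType = Image\n"
        "NDims = 3\n"
        "BinaryData = True\n"
        "BinaryDataByteOrderMSB = False\n"
        f"DimSize = {nx} {ny} {nz}\n"
        f"ElementSpacing = {sp_mm:.9g} {sp_mm:.9g} {sp_mm:.9g}\n"
        f"ElementType = {_MET_NAMES[arr.dtype]}\n"
        "ElementDataFile = LOCAL\n"
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(np.ascontiguousarray(arr).tobytes())


def _load_mha(path: Path):
    with open(path, "rb") as fh:
        raw = fh.read()
    try:
        end = raw.index(b"ElementDataFile")
        end = raw.index(b"\n", end) + 1
    except ValueError:
        raise ValueError(f"cannot parse volume file {path}: missing ElementDataFile")
    fields = {}
    for line in raw[: end].decode("ascii", errors="replace").splitlines():
        if "=" in line:
            k, v = line.split("=", 1)
            fields[k.strip()] = v.strip()
    try:
        nx, ny, nz = (int(v) for v in fields["DimSize"].split())
        dtype = _MET_TYPES[fields["ElementType"]]
        sp_mm = tuple(float(v) for v in fields["ElementSpacing"].split())
    except (KeyError, ValueError) as exc:
        raise ValueError(f"cannot parse volume file {path}: {exc}") from exc
    data = np.frombuffer(raw[end:], dtype=dtype, count=nx * ny * nz)
    if data.size != nx * ny * nz:
        raise ValueError(f"cannot parse volume file {path}: truncated pixel data")
    arr = data.reshape(nz, ny, nx).copy()
    sp = _effective_spacing(tuple(1000.0 * s for s in sp_mm), path)
    return _wrap(arr, sp)
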