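"""Readers and writers: NIfTI-1 volumes, CSV tables, packaged fixtures."""
from __future__ import annotations

import hashlib
from importlib import resources

import nibabel as nib
import numpy as np
import pandas as pd

from .volume import VolumeMap

__all__ = ["read_volume", "write_volume", "load_table1_fixture", "sha256_file", "TABLE1_SHA256"]

#: Frozen checksum of the packaged cohort table (28 patients, baseline /
#: month-3 / month-9 scores for NIH, mRS, HD, PSO, TOR plus demographics).
TABLE1_SHA256 = "9aefc0263829ed8605c1e4bb68a790b71a66b05e51144a654066af4ddc7ea85d"

VolumeFormatError = type("VolumeFormatError", (ValueError,), {})


def write_volume(vmap: VolumeMap, path) -> None:
    """Write a volume as single-file NIfTI-1, 32-bit float.

    The affine is diagonal with the isotropic voxel size, translated by the
    origin offset, so geometry survives a round trip losslessly.
    """
    affine = np.diag([vmap.voxel_size_mm] * 3 + [1.0])
    affine[:3, 3] = vmap.origin_mm
    img = nib.Nifti1Image(np.asarray(vmap.data, dtype=np.float32), affine)
    img.header.set_zooms((vmap.voxel_size_mm,) * 3)
    nib.save(img, str(path))


def read_volume(path, name: str = "") -> VolumeMap:
    """Read a single-file NIfTI-1 volume written by :func:`write_volume`."""
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float32)
        zooms = img.header.get_zooms()[:3]
    except Exception as exc:
        raise VolumeFormatError(f"cannot read NIfTI volume {path}: {exc}") from exc
    if data.ndim != 3:
        raise VolumeFormatError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    if not np.allclose(zooms, zooms[0]):
        raise VolumeFormatError(f"{path}: anisotropic voxels {zooms} not supported")
    origin = tuple(np.asarray(img.affine[:3, 3], dtype=float))
    return VolumeMap(data, float(zooms[0]), origin, name=name)


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def load_table1_fixture(verify_checksum: bool = True) -> pd.DataFrame:
    """The packaged 28-patient cohort table.

    Columns: id, age, gender, side, etiology and per-visit (baseline, month
    3, month 9) scores nih_*, mrs_*, hd_*, pso_*, tor_*.  The file is frozen
    by a SHA-256 checksum; a mismatch raises.
    """
    ref = resources.files("strokecov.data") / "table1.csv"
    with resources.as_file(ref) as path:
        if verify_checksum:
            digest = sha256_file(path)
            if digest != TABLE1_SHA256:
                raise ValueError(
                    f"table1.csv checksum mismatch: {digest} != {TABLE1_SHA256}"
                )
        table = pd.read_csv(path)
    if len(table) != 28:
        raise ValueError(f"expected 28 patients, got {len(table)}")
    return table
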