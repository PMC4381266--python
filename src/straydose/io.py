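"""Volume and report I/O: NIfTI and MetaImage rasters with JSON sidecars.

World units are centimetres; the affine/spacing stored in the files is in
those same units, and every raster is written with a JSON sidecar recording
units and provenance so the convention is explicit on disk.  Array axis
order in memory is (x, y, z), matching the NIfTI on-disk layout; MetaImage
volumes are transposed on the way through SimpleITK.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import SimpleITK as sitk

from .grid import DoseGrid, StructureMask, VoxelGrid

__all__ = [
    "write_volume",
    "read_volume",
    "write_dose",
    "write_phantom",
    "read_labels",
]

_NIFTI_SUFFIXES = (".nii", ".nii.gz")
_META_SUFFIXES = (".mha", ".mhd")


def _suffix(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".nii.gz"):
        return ".nii.gz"
    return path.suffix.lower()


def _write_array(array: np.ndarray, origin, spacing, path: Path) -> None:
    suffix = _suffix(path)
    if suffix in _NIFTI_SUFFIXES:
        affine = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
        affine[:3, 3] = origin
        img = nib.Nifti1Image(np.asarray(array), affine)
        nib.save(img, str(path))
    elif suffix in _META_SUFFIXES:
        img = sitk.GetImageFromArray(np.ascontiguousarray(array.transpose(2, 1, 0)))
        img.SetSpacing(tuple(float(s) for s in spacing))
        img.SetOrigin(tuple(float(o + 0.5 * s) for o, s in zip(origin, spacing)))
        sitk.WriteImage(img, str(path))
    else:
        raise ValueError(f"unsupported volume format {suffix!r}")


def _read_array(path: Path):
    suffix = _suffix(path)
    if suffix in _NIFTI_SUFFIXES:
        img = nib.load(str(path))
        affine = img.affine
        spacing = np.sqrt((affine[:3, :3] ** 2).sum(axis=0))
        origin = affine[:3, 3]
        return np.asarray(img.dataobj), origin, spacing
    if suffix in _META_SUFFIXES:
        img = sitk.ReadImage(str(path))
        array = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
        spacing = np.asarray(img.GetSpacing())
        origin = np.asarray(img.GetOrigin()) - 0.5 * spacing
        return array, origin, spacing
    raise ValueError(f"unsupported volume format {suffix!r}")


def write_volume(grid: VoxelGrid, path, sidecar: dict | None = None) -> Path:
    """Write a voxel grid to NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    _write_array(grid.values, grid.origin, grid.spacing, path)
    meta = {"units": "cm", "value_kind": grid.value_kind}
    if sidecar:
        meta.update(sidecar)
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=2))
    return path


def read_volume(path, value_kind: str | None = None) -> VoxelGrid:
    """Read a raster written by :func:`write_volume` back into a VoxelGrid."""
    path = Path(path)
    array, origin, spacing = _read_array(path)
    if value_kind is None:
        sidecar = Path(str(path) + ".json")
        value_kind = "density"
        if sidecar.exists():
            value_kind = json.loads(sidecar.read_text()).get("value_kind", "density")
    return VoxelGrid(
        origin=origin,
        spacing=spacing,
        values=np.asarray(array, dtype=np.float64),
        value_kind=value_kind,
    )


def write_dose(dose: DoseGrid, path, sidecar: dict | None = None) -> Path:
    """Write a dose grid with a JSON sidecar recording its units."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    _write_array(dose.values, dose.grid.origin, dose.grid.spacing, path)
    meta = {"units": dose.units, "world_units": "cm"}
    if sidecar:
        meta.update(sidecar)
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=2))
    return path


def write_phantom(grid: VoxelGrid, masks, outdir, fmt: str = "nii") -> dict:
    """Write density raster + integer label volume + structure manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    density_path = write_volume(grid, outdir / f"density.{fmt}")

    if isinstance(masks, StructureMask):
        masks = {masks.name: masks}
    labels = np.zeros(grid.dims, dtype=np.float64)
    mapping = {}
    for value, (name, mask) in enumerate(masks.items(), start=1):
        labels[mask.mask] = value
        mapping[name] = value
    label_path = outdir / f"labels.{fmt}"
    _write_array(labels, grid.origin, grid.spacing, label_path)

    manifest = {
        "density": density_path.name,
        "labels": label_path.name,
        "structures": mapping,
        "units": "cm",
    }
    (outdir / "phantom_manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def read_labels(outdir, grid: VoxelGrid | None = None) -> dict[str, StructureMask]:
    """Read a label volume + manifest back into structure masks."""
    outdir = Path(outdir)
    manifest = json.loads((outdir / "phantom_manifest.json").read_text())
    if grid is None:
        grid = read_volume(outdir / manifest["density"])
    labels, _, _ = _read_array(outdir / manifest["labels"])
    return {
        name: StructureMask(name, labels == value, grid)
        for name, value in manifest["structures"].items()
    }
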