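"""Image and mask I/O: NIfTI for 3-D (and exact 2-D round trips), PNG for
2-D fixtures.

Spacing is read from the NIfTI header; PNG carries no spacing, so it must be
supplied explicitly — never silently defaulted.  PNG images are quantized to
uint16 with a fixed scale of 10000 counts per intensity unit (lossy for
arbitrary floats, documented); PNG masks are exact uint8.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np

from .grid import ImageGrid, LabelMask
from .labels import validate_labels

PNG_INTENSITY_SCALE = 10000.0


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return name.endswith(".nii") or name.endswith(".nii.gz")


def read_image(path, spacing=None) -> ImageGrid:
    """Read an image; NIfTI supplies spacing, PNG requires it explicitly."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if _is_nifti(path):
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float64)
        zooms = img.header.get_zooms()[: data.ndim]
        return ImageGrid(data, tuple(float(z) for z in zooms))
    if path.suffix.lower() == ".png":
        if spacing is None:
            raise ValueError(
                "PNG images carry no spacing; pass spacing explicitly"
            )
        data = iio.imread(path).astype(np.float64) / PNG_INTENSITY_SCALE
        return ImageGrid(data, tuple(spacing))
    raise ValueError(f"unrecognized image format: {path}")


def write_image(path, image: ImageGrid) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if _is_nifti(path):
        affine = np.diag(list(image.spacing) + [1.0] * (4 - image.ndim))
        nii = nib.Nifti1Image(image.data, affine)
        nii.header.set_zooms(image.spacing)
        nib.save(nii, str(path))
    elif path.suffix.lower() == ".png":
        if image.ndim != 2:
            raise ValueError("PNG supports 2-D images only")
        q = np.clip(np.round(image.data * PNG_INTENSITY_SCALE), 0, 65535).astype(
            np.uint16)
        iio.imwrite(path, q)
    else:
        raise ValueError(f"unrecognized image format: {path}")


def read_mask(path, spacing=None) -> LabelMask:
    """Read a label mask and validate it against the 7-class schema."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if _is_nifti(path):
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        zooms = img.header.get_zooms()[: data.ndim]
        spacing = tuple(float(z) for z in zooms)
    elif path.suffix.lower() == ".png":
        if spacing is None:
            raise ValueError("PNG masks carry no spacing; pass spacing explicitly")
        data = iio.imread(path)
    else:
        raise ValueError(f"unrecognized mask format: {path}")
    validate_labels(data)
    return LabelMask(data.astype(np.int64), tuple(spacing))


def write_mask(path, mask: LabelMask) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if _is_nifti(path):
        affine = np.diag(list(mask.spacing) + [1.0] * (4 - mask.ndim))
        nii = nib.Nifti1Image(mask.data.astype(np.int16), affine)
        nii.header.set_zooms(mask.spacing)
        nib.save(nii, str(path))
    elif path.suffix.lower() == ".png":
        if mask.ndim != 2:
            raise ValueError("PNG supports 2-D masks only")
        iio.imwrite(path, mask.data.astype(np.uint8))
    else:
        raise ValueError(f"unrecognized mask format: {path}")


def write_sample(out_dir, stem: str, sample) -> dict:
    """Write a phantom sample (image + mask + JSON sidecar); returns paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if sample.image.ndim == 3:
        img_path = out_dir / f"{stem}_image.nii.gz"
        mask_path = out_dir / f"{stem}_mask.nii.gz"
    else:
        img_path = out_dir / f"{stem}_image.png"
        mask_path = out_dir / f"{stem}_mask.png"
    write_image(img_path, sample.image)
    write_mask(mask_path, sample.mask)
    sidecar = {
        "seed": sample.spec.seed if sample.spec else None,
        "spacing_mm": list(sample.image.spacing),
        "true_volumes_ml": {str(k): v for k, v in sample.true_volumes_ml.items()},
    }
    sidecar_path = out_dir / f"{stem}.json"
    sidecar_path.write_text(json.dumps(sidecar, indent=2))
    return {"image": img_path, "mask": mask_path, "sidecar": sidecar_path}
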