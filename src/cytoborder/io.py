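"""File I/O for the pipeline's artefacts.

Sections travel as TIFF (float32) or PNG (16-bit) with a JSON ground-truth
sidecar; contours and traverses as JSON coordinate arrays; profiles and
feature matrices as CSV; cohort label volumes, probability maps and MPM as
NIfTI-1 with the voxel size in the header.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "save_section", "load_section_image",
    "save_cohort_nifti", "load_label_volume",
    "save_probability_map", "save_mpm",
    "save_contours", "load_contours",
    "save_traverses", "save_profiles_csv", "save_features_csv",
    "save_cog_table", "save_gli_map",
]


def save_section(section, path, fmt: str = "tiff"):
    """Section image (TIFF float32 or PNG uint16) + JSON ground-truth sidecar."""
    path = Path(path)
    if fmt == "tiff":
        import tifffile

        img_path = path.with_suffix(".tif")
        tifffile.imwrite(img_path, section.image.astype(np.float32))
    elif fmt == "png":
        import imageio.v3 as iio

        img_path = path.with_suffix(".png")
        iio.imwrite(img_path, (np.clip(section.image, 0, 1) * 65535).astype(np.uint16))
    else:
        raise ValueError("fmt must be 'tiff' or 'png'")
    sidecar = {
        "pixel_size_um": section.geometry.pixel_size_um,
        "truth_borders_um": np.asarray(section.truth_borders_um).tolist(),
        "areas": [a.name for a in section.areas],
        "seed": section.seed,
        "section_id": section.section_id,
        "outer_contour_um": section.geometry.outer_contour.tolist(),
        "inner_contour_um": section.geometry.inner_contour.tolist(),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return img_path


def load_section_image(path):
    path = Path(path)
    if path.suffix in (".tif", ".tiff"):
        import tifffile

        return np.asarray(tifffile.imread(path), float)
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(path), float)
    return arr / 65535.0 if arr.max() > 1 else arr


def _nifti(data, voxel_size_mm):
    import nibabel as nib

    affine = np.diag(list(voxel_size_mm) + [1.0])
    return nib.Nifti1Image(np.asarray(data), affine)


def save_cohort_nifti(cohort, out_dir):
    """One .nii.gz label volume per subject plus a JSON metadata file."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i in range(cohort.n_subjects):
        p = out_dir / f"subject_{i:02d}_labels.nii.gz"
        _nifti(cohort.labels[i].astype(np.int16), cohort.voxel_size_mm).to_filename(p)
        paths.append(p)
    meta = {
        "sex": list(cohort.sex),
        "fresh_volume_mm3": cohort.fresh_volume_mm3.tolist(),
        "processed_volume_mm3": cohort.processed_volume_mm3.tolist(),
        "voxel_size_mm": list(cohort.voxel_size_mm),
        "area_ids": list(cohort.area_ids),
    }
    (out_dir / "cohort.json").write_text(json.dumps(meta, indent=1))
    return paths


def load_label_volume(path):
    import nibabel as nib

    img = nib.load(str(path))
    vox = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.dataobj), vox


def save_probability_map(pmap, path):
    _nifti(pmap.values.astype(np.float32), pmap.voxel_size_mm).to_filename(str(path))


def save_mpm(mpm, path):
    _nifti(mpm.voxels.astype(np.int16), mpm.voxel_size_mm).to_filename(str(path))


def save_contours(geometry, path):
    """Contours as GeoJSON-style JSON with role tags."""
    obj = {"pixel_size_um": geometry.pixel_size_um, "contours": [
        {"role": "outer", "coordinates": geometry.outer_contour.tolist()},
        {"role": "inner", "coordinates": geometry.inner_contour.tolist()},
    ]}
    Path(path).write_text(json.dumps(obj))


def load_contours(path):
    from .synthetic import RibbonGeometry

    obj = json.loads(Path(path).read_text())
    by_role = {c["role"]: np.asarray(c["coordinates"], float) for c in obj["contours"]}
    return RibbonGeometry(by_role["outer"], by_role["inner"],
                          obj.get("pixel_size_um", 1.02))


def save_traverses(traverses, path):
    obj = [{"index": t.index, "seed_arclength_um": t.seed_arclength_um,
            "length_um": t.length_um, "points_um": t.points.tolist()}
           for t in traverses]
    Path(path).write_text(json.dumps(obj))


def save_profiles_csv(profiles, path):
    """One row per profile, columns = depth samples; depths in the header."""
    depths = profiles[0].depths
    df = pd.DataFrame([p.values for p in profiles],
                      columns=[f"depth_{d:g}" for d in depths])
    df.insert(0, "traverse_index", [p.traverse_index for p in profiles])
    df.insert(1, "section_id", [p.section_id for p in profiles])
    df.to_csv(path, index=False)


def save_features_csv(features, path):
    from .profiles import FEATURE_NAMES

    pd.DataFrame(np.atleast_2d(features), columns=FEATURE_NAMES).to_csv(path, index=False)


def save_cog_table(cogs, path, hemisphere=None):
    """Centre-of-gravity table (area, hemisphere, x, y, z) as CSV."""
    rows = []
    for i, c in enumerate(cogs):
        rows.append({"area": c.area_id,
                     "hemisphere": hemisphere[i] if hemisphere else "",
                     "x_mm": c.x_mm, "y_mm": c.y_mm, "z_mm": c.z_mm})
    pd.DataFrame(rows).to_csv(path, index=False)


def save_gli_map(gli, path):
    """GLI map as float32 TIFF plus JSON metadata."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(path.with_suffix(".tif"), gli.values.astype(np.float32))
    meta = {"field_size_px": gli.field_size_px, "pixel_size_um": gli.pixel_size_um,
            "units": "fraction in [0,1]"}
    path.with_suffix(".json").write_text(json.dumps(meta))
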