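"""Readers and writers for the standard neuroimaging formats.

All on-disk exchange goes through nibabel: NIfTI for volumes, GIFTI (plus
the FreeSurfer binary dialect) for surfaces, TCK/TRK for tractograms.  The
in-memory convention is world RAS millimetres with 0-based voxel indices;
format-specific conventions are applied only at these boundaries.
"""
from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .field import DiffusionField
from .mesh import CorticalMesh
from .tracking import Streamline, Tractogram, TrackingParams


# -- volumes ----------------------------------------------------------------

def write_diffusion_field(field: DiffusionField, fa_path, dirs_path) -> None:
    """Write FA as a scalar NIfTI and directions as a 4D (x,y,z,3) NIfTI."""
    nib.save(nib.Nifti1Image(field.fa.astype(np.float32), field.affine), str(fa_path))
    nib.save(nib.Nifti1Image(field.directions.astype(np.float32), field.affine),
             str(dirs_path))


def read_diffusion_field(fa_path, dirs_path, validate: bool = True) -> DiffusionField:
    fa_img = nib.load(str(fa_path))
    dir_img = nib.load(str(dirs_path))
    fa = np.asarray(fa_img.get_fdata(), float)
    dirs = np.asarray(dir_img.get_fdata(), float)
    if dirs.shape != fa.shape + (3,):
        raise ValueError(f"direction grid {dirs.shape} does not match FA grid {fa.shape}")
    if not np.allclose(fa_img.affine, dir_img.affine, atol=1e-5):
        raise ValueError("FA and direction affines disagree")
    field = DiffusionField(fa, dirs, fa_img.affine)
    if validate:
        # float32 round-trip leaves ~1e-7 norm error; renormalize then check
        norms = np.linalg.norm(dirs, axis=-1)
        if not np.allclose(norms, 1.0, atol=1e-3):
            raise ValueError("direction volume contains non-unit vectors")
        field.directions /= norms[..., None]
        field.validate(atol=1e-4)
    return field


def write_label_volume(labels_by_voxel: dict, grid_shape, affine, path) -> None:
    """Indexed label NIfTI: voxel -> CU id + 1 (0 = background)."""
    vol = np.zeros(grid_shape, dtype=np.int32)
    for vox, lab in labels_by_voxel.items():
        vol[tuple(vox)] = lab + 1
    nib.save(nib.Nifti1Image(vol, affine), str(path))


# -- surfaces ---------------------------------------------------------------

def write_mesh_gifti(mesh: CorticalMesh, path) -> None:
    img = nib.gifti.GiftiImage(darrays=[
        nib.gifti.GiftiDataArray(mesh.vertices.astype(np.float32),
                                 intent="NIFTI_INTENT_POINTSET"),
        nib.gifti.GiftiDataArray(mesh.faces.astype(np.int32),
                                 intent="NIFTI_INTENT_TRIANGLE"),
    ])
    nib.save(img, str(path))


def read_mesh(path) -> CorticalMesh:
    """Read a GIFTI surface or a FreeSurfer binary surface."""
    path = str(path)
    if path.endswith(".gii"):
        img = nib.load(path)
        verts = img.get_arrays_from_intent("NIFTI_INTENT_POINTSET")[0].data
        faces = img.get_arrays_from_intent("NIFTI_INTENT_TRIANGLE")[0].data
    else:
        verts, faces = nib.freesurfer.read_geometry(path)
    return CorticalMesh(np.asarray(verts, float), np.asarray(faces, int))


def write_scalar_map_gifti(values: np.ndarray, path) -> None:
    img = nib.gifti.GiftiImage(darrays=[
        nib.gifti.GiftiDataArray(np.asarray(values, np.float32),
                                 intent="NIFTI_INTENT_NONE"),
    ])
    nib.save(img, str(path))


def read_scalar_map_gifti(path) -> np.ndarray:
    img = nib.load(str(path))
    return np.asarray(img.darrays[0].data, float)


# -- tractograms ------------------------------------------------------------

def write_tractogram(t: Tractogram, path, dialect: str | None = None) -> None:
    """Write streamlines as TCK (world RAS mm verbatim) or TRK."""
    path = str(path)
    dialect = (dialect or Path(path).suffix.lstrip(".")).upper()
    if dialect not in {"TCK", "TRK"}:
        raise ValueError(f"dialect must be TCK or TRK, got {dialect!r}")
    streams = [s.points.astype(np.float32) for s in t.streamlines]
    tractogram = nib.streamlines.Tractogram(streams, affine_to_rasmm=np.eye(4))
    if dialect == "TCK":
        nib.streamlines.save(nib.streamlines.tck.TckFile(tractogram), path)
    else:
        # TRK needs a reference grid; an identity header keeps coordinates RAS mm
        hdr = nib.streamlines.trk.TrkFile.create_empty_header()
        hdr["voxel_to_rasmm"] = np.eye(4, dtype=np.float32)
        hdr["voxel_sizes"] = np.ones(3, dtype=np.float32)
        hdr["voxel_order"] = b"RAS"
        nib.streamlines.save(nib.streamlines.trk.TrkFile(tractogram, header=hdr), path)


def read_tractogram(path, field: DiffusionField | None = None,
                    params: TrackingParams | None = None) -> Tractogram:
    """Read TCK/TRK back into world RAS mm.

    When a field is given, per-fiber mean FA is resampled from it; otherwise
    mean FA is NaN (lengths are always recomputed from the points).
    """
    obj = nib.streamlines.load(str(path))
    lines = []
    for pts in obj.tractogram.streamlines:
        pts = np.asarray(pts, float)
        if len(pts) < 2:
            continue
        if field is not None:
            interp = params.interpolation if params else "nearest"
            lines.append(Streamline.from_points(pts, field, interp))
        else:
            seg = float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
            lines.append(Streamline(points=pts, length=seg, mean_fa=np.nan))
    return Tractogram(streamlines=lines, params=params)


# -- tables -----------------------------------------------------------------

def write_table(df: pd.DataFrame, path, config_hash: str | None = None) -> None:
    """CSV with an optional '# config: <hash>' provenance comment line."""
    with open(path, "w") as fh:
        if config_hash:
            fh.write(f"# config: {config_hash}\n")
        df.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
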