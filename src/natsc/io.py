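"""Readers/writers for every on-disk artifact the pipeline touches.

Volumes travel as NIfTI-1 (with a JSON sidecar carrying units, seeds and
provenance); ROI structure sets as JSON with run-length-encoded masks on
the reference grid; k-space as an ``.npz`` container with a JSON header;
DICOM RT-STRUCT is supported as an import (and minimal export) convenience
for clinically exported contours.

Internally everything is LPS; NIfTI affines are RAS by convention, so the
first two world axes are sign-flipped on the way in and out. The round trip
GridMeta → NIfTI affine → GridMeta is lossless to float precision.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np

from .core import GridMeta, LabelVolume, ScalarVolume

__all__ = [
    "write_volume",
    "read_volume",
    "write_structure_set",
    "read_structure_set",
    "import_rtstruct",
    "export_rtstruct",
    "write_kspace",
    "read_kspace",
    "provenance",
]

_RAS_FLIP = np.diag([-1.0, -1.0, 1.0, 1.0])


def provenance(seed: int | None = None, config: dict | None = None) -> dict:
    """Version/seed/config-hash block embedded in every sidecar."""
    from . import __version__

    block = {"tool": "natsc", "version": __version__}
    if seed is not None:
        block["seed"] = int(seed)
    if config is not None:
        block["config_sha256"] = hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]
    return block


def _meta_to_ras_affine(meta: GridMeta) -> np.ndarray:
    return _RAS_FLIP @ meta.affine


def _ras_affine_to_meta(affine: np.ndarray, shape) -> GridMeta:
    lps = _RAS_FLIP @ np.asarray(affine, dtype=float)
    lin = lps[:3, :3]
    spacing = np.linalg.norm(lin, axis=0)
    if np.any(spacing <= 0):
        raise ValueError("affine has zero-length axis")
    direction = lin / spacing
    if not np.allclose(direction @ direction.T, np.eye(3), atol=1e-4):
        raise ValueError("non-orthonormal affine: sheared grids are not supported")
    return GridMeta(
        shape=tuple(int(n) for n in shape),
        spacing=tuple(float(s) for s in spacing),
        origin=tuple(float(o) for o in lps[:3, 3]),
        direction=tuple(float(d) for d in direction.ravel()),
    )


def write_volume(
    vol: ScalarVolume | LabelVolume,
    path: str | Path,
    seed: int | None = None,
    config: dict | None = None,
) -> Path:
    """Write a volume as NIfTI-1 plus a JSON sidecar (units, provenance)."""
    path = Path(path)
    data = vol.data
    if isinstance(vol, LabelVolume):
        data = data.astype(np.int16)
    img = nib.Nifti1Image(data, _meta_to_ras_affine(vol.meta))
    img.header.set_zooms(vol.meta.spacing)
    nib.save(img, str(path))
    sidecar = {"provenance": provenance(seed, config)}
    if isinstance(vol, ScalarVolume) and vol.units:
        sidecar["units"] = vol.units
    if isinstance(vol, LabelVolume) and vol.names:
        sidecar["labels"] = {str(k): v for k, v in vol.names.items()}
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_volume(path: str | Path) -> ScalarVolume | LabelVolume:
    """Read a NIfTI volume; integer dtype yields a LabelVolume.

    Rejects 4-D inputs and non-orthonormal affines explicitly; truncated or
    unreadable files raise before any partial object is constructed.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
    except Exception as e:  # noqa: BLE001 - normalize loader errors
        raise IOError(f"cannot read NIfTI volume {path}: {e}") from e
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    elif data.ndim != 3:
        raise ValueError(
            f"{path}: expected a 3-D volume, got {data.ndim}-D; "
            "4-D series are not supported"
        )
    if img.affine is None:
        raise ValueError(f"{path}: missing affine")
    meta = _ras_affine_to_meta(img.affine, data.shape)
    sidecar_path = Path(str(path) + ".json")
    units, names = "", {}
    if sidecar_path.exists():
        sc = json.loads(sidecar_path.read_text())
        units = sc.get("units", "")
        names = {int(k): v for k, v in sc.get("labels", {}).items()}
    if np.issubdtype(data.dtype, np.integer):
        return LabelVolume(data, meta, names)
    return ScalarVolume(data.astype(float), meta, units)


# --- structure sets (native JSON, RLE masks) --------------------------------


def _rle_encode(flat: np.ndarray) -> list[list[int]]:
    flat = np.asarray(flat, bool).ravel()
    if not flat.any():
        return []
    padded = np.concatenate([[False], flat, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2]
    return [[int(s), int(e - s)] for s, e in zip(starts, ends)]


def _rle_decode(runs, size: int) -> np.ndarray:
    flat = np.zeros(size, dtype=bool)
    for start, length in runs:
        flat[start : start + length] = True
    return flat


def write_structure_set(
    rois: dict[str, LabelVolume | np.ndarray],
    meta: GridMeta,
    path: str | Path,
    seed: int | None = None,
    config: dict | None = None,
) -> Path:
    """Write named ROI masks (shared grid) as a JSON structure set."""
    path = Path(path)
    out = {
        "grid": {
            "shape": list(meta.shape),
            "spacing": list(meta.spacing),
            "origin": list(meta.origin),
            "direction": list(meta.direction),
            "space": meta.space,
        },
        "rois": {},
        "provenance": provenance(seed, config),
    }
    for name, roi in rois.items():
        arr = roi.data if isinstance(roi, LabelVolume) else np.asarray(roi)
        if tuple(arr.shape) != tuple(meta.shape):
            raise ValueError(f"ROI {name!r} not on the structure-set grid")
        out["rois"][name] = _rle_encode(arr != 0)
    path.write_text(json.dumps(out))
    return path


def read_structure_set(path: str | Path) -> tuple[dict[str, LabelVolume], GridMeta]:
    doc = json.loads(Path(path).read_text())
    g = doc["grid"]
    meta = GridMeta(
        shape=tuple(g["shape"]),
        spacing=tuple(g["spacing"]),
        origin=tuple(g["origin"]),
        direction=tuple(g["direction"]),
    )
    size = int(np.prod(meta.shape))
    rois = {}
    for name, runs in doc["rois"].items():
        mask = _rle_decode(runs, size).reshape(meta.shape)
        rois[name] = LabelVolume(mask.astype(np.int16), meta, {1: name})
    return rois, meta


# --- DICOM RT-STRUCT ---------------------------------------------------------


def import_rtstruct(path: str | Path, target_grid: GridMeta) -> dict[str, LabelVolume]:
    """Rasterize RT-STRUCT planar contours onto ``target_grid``.

    Each structure's contour stack is filled slice-wise by
    voxel-centre-in-polygon on the axial plane nearest to the contour's z.
    Assumes an axis-aligned target grid (the reference-grid convention).
    """
    import pydicom
    from skimage.draw import polygon as draw_polygon

    ds = pydicom.dcmread(str(path))
    if ds.SOPClassUID != "1.2.840.10008.5.1.4.1.1.481.3":
        raise ValueError(f"{path} is not an RT Structure Set")
    names = {
        int(r.ROINumber): str(r.ROIName) for r in ds.StructureSetROISequence
    }
    out: dict[str, LabelVolume] = {}
    for rc in ds.ROIContourSequence:
        name = names.get(int(rc.ReferencedROINumber), f"roi_{rc.ReferencedROINumber}")
        mask = np.zeros(target_grid.shape, dtype=bool)
        for contour in getattr(rc, "ContourSequence", []):
            if contour.ContourGeometricType not in ("CLOSED_PLANAR", "CLOSEDPLANAR"):
                continue
            pts = np.asarray(contour.ContourData, dtype=float).reshape(-1, 3)
            idx = target_grid.physical_to_index(pts)
            k = int(round(float(np.median(idx[:, 2]))))
            if not (0 <= k < target_grid.shape[2]):
                continue
            rr, cc = draw_polygon(
                idx[:, 0], idx[:, 1], shape=target_grid.shape[:2]
            )
            mask[rr, cc, k] = True
        if not mask.any():
            warnings.warn(f"structure {name!r} rasterized to an empty mask",
                          stacklevel=2)
        out[name] = LabelVolume(mask.astype(np.int16), target_grid, {1: name})
    return out


def export_rtstruct(
    rois: dict[str, LabelVolume | np.ndarray],
    meta: GridMeta,
    path: str | Path,
) -> Path:
    """Minimal RT-STRUCT writer (contours traced per axial slice).

    Intended for interoperability smoke tests, not clinical use: only the
    structures' planar contours and names are populated.
    """
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import generate_uid
    from skimage import measure

    file_meta = FileMetaDataset()
    file_meta.MediaStorageSOPClassUID = pydicom.uid.UID(
        "1.2.840.10008.5.1.4.1.1.481.3"
    )
    file_meta.MediaStorageSOPInstanceUID = generate_uid()
    file_meta.TransferSyntaxUID = pydicom.uid.ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = file_meta
    ds.SOPClassUID = file_meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = file_meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTSTRUCT"
    ds.StructureSetLabel = "natsc"
    ds.PatientName = "synthetic^phantom"
    ds.PatientID = "SYN000"
    ds.StructureSetROISequence = []
    ds.ROIContourSequence = []
    frame_uid = generate_uid()
    ds.FrameOfReferenceUID = frame_uid

    for num, (name, roi) in enumerate(rois.items(), start=1):
        arr = roi.data if isinstance(roi, LabelVolume) else np.asarray(roi)
        sroi = Dataset()
        sroi.ROINumber = num
        sroi.ROIName = name
        sroi.ReferencedFrameOfReferenceUID = frame_uid
        sroi.ROIGenerationAlgorithm = "AUTOMATIC"
        ds.StructureSetROISequence.append(sroi)

        rcont = Dataset()
        rcont.ReferencedROINumber = num
        rcont.ContourSequence = []
        for k in range(meta.shape[2]):
            sl = arr[:, :, k] != 0
            if not sl.any():
                continue
            for verts in measure.find_contours(sl.astype(float), 0.5):
                idx = np.column_stack([verts, np.full(len(verts), float(k))])
                phys = meta.index_to_physical(idx)
                cont = Dataset()
                cont.ContourGeometricType = "CLOSED_PLANAR"
                cont.NumberOfContourPoints = len(phys)
                cont.ContourData = [float(v) for v in phys.ravel()]
                rcont.ContourSequence.append(cont)
        ds.ROIContourSequence.append(rcont)

    ds.is_little_endian = True
    ds.is_implicit_VR = False
    pydicom.dcmwrite(str(path), ds, enforce_file_format=True)
    return Path(path)


# --- k-space container -------------------------------------------------------


def write_kspace(kspace, path: str | Path, seed: int | None = None) -> Path:
    """Save a RadialKSpace as .npz plus a JSON header (trajectory units
    cycles/mm)."""
    from dataclasses import asdict

    path = Path(path)
    np.savez_compressed(
        path,
        samples=kspace.samples if kspace.samples is not None else np.zeros(0),
        trajectory=kspace.trajectory,
        dcf=kspace.dcf,
    )
    header = {
        "params": asdict(kspace.params),
        "fov_mm": list(kspace.fov_mm) if kspace.fov_mm else None,
        "fov_center_mm": list(kspace.fov_center_mm),
        "trajectory_units": "cycles/mm",
        "provenance": provenance(seed),
    }
    Path(str(path) + ".json").write_text(json.dumps(header, indent=1))
    return path


def read_kspace(path: str | Path):
    from .recon import RadialKSpace, SequenceParams

    path = Path(path)
    npz = np.load(str(path) if str(path).endswith(".npz") else str(path) + ".npz")
    header = json.loads(Path(str(path) + ".json").read_text())
    params = SequenceParams(**header["params"])
    samples = npz["samples"]
    return RadialKSpace(
        trajectory=npz["trajectory"],
        dcf=npz["dcf"],
        params=params,
        samples=None if samples.size == 0 else samples,
        fov_mm=tuple(header["fov_mm"]) if header["fov_mm"] else None,
        fov_center_mm=tuple(header["fov_center_mm"]),
    )
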