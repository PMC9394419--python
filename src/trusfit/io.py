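"""File round-trips: NRRD/NIfTI volumes, 3D-Slicer markups JSON, transforms.

Volumes go through SimpleITK, which preserves spacing, origin and
orientation for both NRRD and NIfTI.  Point annotations use the 3D-Slicer
markups JSON schema with explicit ``coordinateSystem`` handling; the
internal frame is RAS (LPS coordinates are converted by negating x and y
on read, and back on write).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import SimpleITK as sitk

from .fitting import AnnotatedSlice
from .registration import AffineTransform3D, ImageVolume, LandmarkSet
from .volume import BinaryMask3D

__all__ = [
    "MarkupDocument",
    "read_volume",
    "write_volume",
    "read_markups",
    "write_markups",
    "markups_to_slices",
    "contours_to_markups",
    "read_landmarks",
    "write_transform",
    "read_transform",
]

VOLUME_EXTENSIONS = (".nrrd", ".nii", ".nii.gz")
MARKUPS_SCHEMA = (
    "https://raw.githubusercontent.com/slicer/slicer/master/Modules/Loadable/Markups"
    "/Resources/Schema/markups-schema-v1.0.3.json#"
)


@dataclass
class MarkupDocument:
    """Named 3D control points with an explicit coordinate frame."""

    control_points: list  # [(label, (x, y, z))]
    frame: str = "RAS"
    volume_ref: str | None = None

    def __post_init__(self):
        if self.frame not in ("RAS", "LPS"):
            raise ValueError(f"coordinate frame must be RAS or LPS, got {self.frame!r}")
        self.control_points = [
            (str(label), np.asarray(pos, dtype=float).reshape(3))
            for label, pos in self.control_points
        ]

    def in_frame(self, frame: str) -> "MarkupDocument":
        if frame == self.frame:
            return self
        flipped = [(lab, pos * np.array([-1.0, -1.0, 1.0])) for lab, pos in self.control_points]
        return MarkupDocument(control_points=flipped, frame=frame, volume_ref=self.volume_ref)


def _check_volume_path(path: Path):
    name = path.name.lower()
    if not any(name.endswith(ext) for ext in VOLUME_EXTENSIONS):
        raise ValueError(
            f"unsupported volume extension for {path} (expected one of {VOLUME_EXTENSIONS})"
        )


def read_volume(path) -> ImageVolume | BinaryMask3D:
    """Read a NRRD/NIfTI volume; {0,1}-valued integer content becomes a mask."""
    path = Path(path)
    _check_volume_path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img)
    kw = dict(spacing=tuple(img.GetSpacing()), origin=tuple(img.GetOrigin()))
    if np.issubdtype(arr.dtype, np.integer) and set(np.unique(arr)) <= {0, 1}:
        return BinaryMask3D(data=arr.astype(np.uint8), **kw)
    return ImageVolume(data=arr.astype(np.float64), **kw)


def write_volume(vol, path) -> None:
    path = Path(path)
    _check_volume_path(path)
    binary = isinstance(vol, BinaryMask3D)
    arr = vol.data.astype(np.uint8) if binary else vol.data.astype(np.float64)
    img = sitk.GetImageFromArray(arr)
    img.SetSpacing(tuple(float(s) for s in vol.spacing))
    img.SetOrigin(tuple(float(o) for o in vol.origin))
    sitk.WriteImage(img, str(path), useCompression=False)


def read_markups(path) -> MarkupDocument:
    """Read a 3D-Slicer markups JSON file into the internal RAS frame."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"markups file not found: {path}")
    with open(path) as fh:
        doc = json.load(fh)
    try:
        markup = doc["markups"][0]
        frame = markup["coordinateSystem"]
        pts = [
            (cp.get("label", str(i)), cp["position"])
            for i, cp in enumerate(markup["controlPoints"])
        ]
    except (KeyError, IndexError, TypeError) as exc:
        raise ValueError(f"{path} does not follow the Slicer markups schema: {exc}") from exc
    return MarkupDocument(control_points=pts, frame=frame).in_frame("RAS")


def write_markups(doc: MarkupDocument, path, frame: str = "RAS") -> None:
    doc = doc.in_frame(frame)
    payload = {
        "@schema": MARKUPS_SCHEMA,
        "markups": [
            {
                "type": "Fiducial",
                "coordinateSystem": doc.frame,
                "controlPoints": [
                    {
                        "id": str(i + 1),
                        "label": label,
                        "position": [float(v) for v in pos],
                        "orientation": [-1.0, 0.0, 0.0, 0.0, -1.0, 0.0, 0.0, 0.0, 1.0],
                    }
                    for i, (label, pos) in enumerate(doc.control_points)
                ],
            }
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def _infer_regions(zs: np.ndarray) -> list:
    """Assign base/mid/apex by axial order: superior extreme = base."""
    regions = ["mid"] * len(zs)
    regions[int(np.argmax(zs))] = "base"
    regions[int(np.argmin(zs))] = "apex"
    return regions


def markups_to_slices(
    doc: MarkupDocument,
    z_origin: float = 0.0,
    z_spacing: float = 1.0,
    mid_model: str = "bspline",
) -> list:
    """Group markup points into per-slice annotations by nearest axial plane.

    Point labels prefixed ``base``/``mid``/``apex`` force the region;
    otherwise the superior extreme slice is the base, the inferior the
    apex, and everything between mid-gland.
    """
    pts = np.stack([pos for _, pos in doc.control_points])
    labels = [lab for lab, _ in doc.control_points]
    idx = np.rint((pts[:, 2] - z_origin) / z_spacing).astype(int)
    groups = {}
    for i, k in enumerate(idx):
        groups.setdefault(int(k), []).append(i)
    ks = np.array(sorted(groups))
    zs = z_origin + ks * z_spacing
    regions = _infer_regions(zs)
    out = []
    for region, k, z in zip(regions, ks, zs):
        members = groups[int(k)]
        forced = {
            lab.split("-")[0].split("_")[0].lower()
            for lab in (labels[i] for i in members)
        } & {"base", "mid", "apex"}
        if len(forced) == 1:
            region = forced.pop()
        n = len(members)
        out.append(
            AnnotatedSlice(
                slice_index=int(k),
                z_mm=float(z),
                points=pts[members, :2],
                region=region,
                model=mid_model if (region == "mid" and n >= 6) else "superellipse",
            )
        )
    return out


def contours_to_markups(contours: list, frame: str = "RAS") -> MarkupDocument:
    """Package exported per-slice contour points as one markup document."""
    cps = []
    for z, pts in contours:
        for i, (x, y) in enumerate(np.atleast_2d(pts)):
            cps.append((f"slice{z:g}-{i}", (float(x), float(y), float(z))))
    return MarkupDocument(control_points=cps, frame=frame)


def read_landmarks(path) -> LandmarkSet:
    doc = read_markups(path)
    return LandmarkSet(points={lab: pos for lab, pos in doc.control_points}, frame="RAS")


def write_transform(t: AffineTransform3D, path) -> None:
    """Write the homogeneous 4x4 matrix as plain text."""
    np.savetxt(path, t.as_matrix4(), fmt="%.12g")


def read_transform(path) -> AffineTransform3D:
    m = np.loadtxt(path)
    if m.shape != (4, 4):
        raise ValueError(f"{path} does not contain a 4x4 matrix")
    return AffineTransform3D(matrix=m[:3, :3], translation=m[:3, 3], center=np.zeros(3))
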