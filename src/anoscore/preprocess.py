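"""Volume -> frontal surface render preprocessing.

A CT series (or a synthetic density volume) is turned into the 2D grayscale
image the anomaly network consumes: the volume's isosurface is viewed
front-on and encoded as an orthographic depth map.  Each pixel holds the
normalized distance from the anterior image plane to the first surface
crossing along the anterior-posterior axis; rays that miss the surface are
background and map to exactly 1.0 (white), so the surface is always darker
than the background.

Axis convention: array axis 0 is anterior-posterior (index 0 = most
anterior), axis 1 is left-right, axis 2 is cranio-caudal.  The frontal view
looks along increasing axis 0 from in front of the patient.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage import measure, transform

__all__ = [
    "VolumeGrid", "SurfaceMesh", "RenderedImage",
    "load_dicom_series", "extract_isosurface", "depth_map",
    "render_frontal", "resize_normalize", "mesh_surface_area",
]

AXIS_CONVENTION = ("anterior-posterior", "left-right", "cranio-caudal")

#: depth of the nearest surface point maps to 0, the farthest to this value;
#: background stays strictly brighter at exactly 1.0
DEPTH_MAX_GRAY = 0.95

#: default iso level for CT volumes in HU (skin/air boundary)
CT_ISO_LEVEL_HU = -300.0
#: default iso level for synthetic density phantoms in [0, 1]
PHANTOM_ISO_LEVEL = 0.5


@dataclass
class VolumeGrid:
    """3D scalar field with physical voxel spacing (mm per voxel per axis)."""

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    axis_convention: tuple[str, str, str] = AXIS_CONVENTION

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("VolumeGrid.values must be 3-dimensional")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")


@dataclass
class SurfaceMesh:
    vertices: np.ndarray  # (n_vertices, 3) in mm
    faces: np.ndarray     # (n_faces, 3) vertex indices
    iso_level: float

    def __post_init__(self):
        if len(self.faces) and self.faces.max() >= len(self.vertices):
            raise ValueError("face index out of range")


@dataclass
class RenderedImage:
    pixels: np.ndarray  # (size, size) in [0, 1]; background exactly 1.0
    render_mode: str = "depth_map"
    provenance: dict = field(default_factory=dict)

    @property
    def size(self) -> int:
        return self.pixels.shape[0]


# ---------------------------------------------------------------------------
# DICOM loading
# ---------------------------------------------------------------------------

def load_dicom_series(path: str | Path) -> VolumeGrid:
    """Load one CT series from a directory of DICOM slice files.

    Slices are sorted by their physical position along the slice axis and
    the rescale slope/intercept are applied, so values are in HU.  The axial
    slice grid (rows=anterior-posterior, cols=left-right, slices=
    cranio-caudal) is transposed to this module's (AP, LR, CC) convention.
    """
    import pydicom

    files = sorted(p for p in Path(path).iterdir() if p.is_file())
    slices = [pydicom.dcmread(str(p)) for p in files]
    if not slices:
        raise ValueError(f"no DICOM files in {path}")

    uids = {getattr(s, "SeriesInstanceUID", None) for s in slices}
    if len(uids) > 1:
        raise ValueError("mixed series: multiple SeriesInstanceUID values found")

    for attr in ("PixelSpacing", "ImagePositionPatient"):
        vals = {tuple(np.round(np.asarray(getattr(s, attr, None), dtype=float), 6))
                if getattr(s, attr, None) is not None else None for s in slices}
        if None in vals:
            raise ValueError(f"missing required DICOM attribute: {attr}")
        if attr == "PixelSpacing" and len(vals) > 1:
            raise ValueError(f"inconsistent PixelSpacing across slices: {sorted(vals)}")

    slices.sort(key=lambda s: float(s.ImagePositionPatient[2]))
    arrays = []
    for s in slices:
        slope = float(getattr(s, "RescaleSlope", 1.0))
        intercept = float(getattr(s, "RescaleIntercept", 0.0))
        arrays.append(s.pixel_array.astype(float) * slope + intercept)
    stack = np.stack(arrays, axis=0)          # (cc, ap, lr)
    volume = np.transpose(stack, (1, 2, 0))   # -> (ap, lr, cc)

    row_mm, col_mm = (float(v) for v in slices[0].PixelSpacing)
    if len(slices) > 1:
        zs = [float(s.ImagePositionPatient[2]) for s in slices]
        dz = float(np.mean(np.diff(zs)))
    else:
        dz = float(getattr(slices[0], "SliceThickness", 1.0))
    return VolumeGrid(volume, spacing=(row_mm, col_mm, abs(dz)))


# ---------------------------------------------------------------------------
# Isosurface
# ---------------------------------------------------------------------------

def extract_isosurface(volume: VolumeGrid, iso_level: float) -> SurfaceMesh:
    """Marching-cubes triangulation of ``volume`` at ``iso_level`` (mm units)."""
    vmin, vmax = float(volume.values.min()), float(volume.values.max())
    if not (vmin < iso_level < vmax):
        raise ValueError(
            f"iso_level {iso_level} outside volume value range [{vmin}, {vmax}]")
    verts, faces, _, _ = measure.marching_cubes(
        volume.values, level=iso_level, spacing=volume.spacing)
    return SurfaceMesh(vertices=verts, faces=faces, iso_level=iso_level)


def mesh_surface_area(mesh: SurfaceMesh) -> float:
    return float(measure.mesh_surface_area(mesh.vertices, mesh.faces))


# ---------------------------------------------------------------------------
# Frontal depth rendering
# ---------------------------------------------------------------------------

def depth_map(volume: VolumeGrid, iso_level: float) -> tuple[np.ndarray, np.ndarray]:
    """First-crossing depth along the anterior-posterior axis, in mm.

    Returns ``(depth, hit)`` over the (LR, CC) grid.  The crossing index is
    interpolated linearly between the bracketing voxels, giving sub-voxel
    depth accuracy on smooth fields.  ``depth`` is NaN where ``hit`` is
    False.
    """
    v = volume.values
    above = v >= iso_level
    hit = above.any(axis=0)
    # first index at/above the level along axis 0
    k = above.argmax(axis=0)
    depth = np.full(v.shape[1:], np.nan)

    kk = np.where(hit, k, 0)
    lr, cc = np.meshgrid(np.arange(v.shape[1]), np.arange(v.shape[2]), indexing="ij")
    interior = hit & (kk == 0)          # surface at (or before) the first voxel
    depth[interior] = 0.0
    crossing = hit & (kk > 0)
    if crossing.any():
        k_c = kk[crossing]
        v_hi = v[k_c, lr[crossing], cc[crossing]]
        v_lo = v[k_c - 1, lr[crossing], cc[crossing]]
        frac = np.where(v_hi > v_lo, (iso_level - v_lo) / np.where(
            v_hi > v_lo, v_hi - v_lo, 1.0), 0.0)
        depth[crossing] = (k_c - 1 + frac) * volume.spacing[0]
    return depth, hit


def _depth_from_mesh(mesh: SurfaceMesh, n_pixels: int) -> tuple[np.ndarray, np.ndarray]:
    """Orthographic front-on depth of a triangle mesh on a square grid.

    Rays run along +AP (axis 0), so each triangle is rasterized in the
    (LR, CC) plane with barycentric interpolation of its AP coordinate and
    a min-depth buffer keeps the first (most anterior) surface.
    """
    verts, faces = mesh.vertices, mesh.faces
    lo = verts.min(axis=0)
    hi = verts.max(axis=0)
    if np.any(hi[1:] - lo[1:] <= 0):
        raise ValueError("degenerate mesh bounding box")
    ys = np.linspace(lo[1], hi[1], n_pixels)
    zs = np.linspace(lo[2], hi[2], n_pixels)
    depth = np.full((n_pixels, n_pixels), np.inf)

    tri = verts[faces]                       # (F, 3, 3)
    eps = 1e-12
    for t in tri:
        (x0, y0, z0), (x1, y1, z1), (x2, y2, z2) = t
        det = (y1 - y0) * (z2 - z0) - (y2 - y0) * (z1 - z0)
        if abs(det) < eps:                   # edge-on to the view
            continue
        i0, i1 = np.searchsorted(ys, [min(y0, y1, y2), max(y0, y1, y2)])
        j0, j1 = np.searchsorted(zs, [min(z0, z1, z2), max(z0, z1, z2)])
        if i0 >= n_pixels or j0 >= n_pixels:
            continue
        i0 = max(i0 - 1, 0)
        j0 = max(j0 - 1, 0)
        py, pz = np.meshgrid(ys[i0:i1 + 1], zs[j0:j1 + 1], indexing="ij")
        w1 = ((py - y0) * (z2 - z0) - (y2 - y0) * (pz - z0)) / det
        w2 = ((y1 - y0) * (pz - z0) - (py - y0) * (z1 - z0)) / det
        w0 = 1.0 - w1 - w2
        inside = (w0 >= -1e-9) & (w1 >= -1e-9) & (w2 >= -1e-9)
        if not inside.any():
            continue
        x = w0 * x0 + w1 * x1 + w2 * x2
        block = depth[i0:i1 + 1, j0:j1 + 1]
        np.minimum(block, np.where(inside, x, np.inf), out=block)

    hit = np.isfinite(depth)
    out = np.where(hit, depth - lo[0], np.nan)
    return out, hit


def render_frontal(mesh_or_volume, image_size: int) -> RenderedImage:
    """Orthographic frontal depth-map render, normalized to [0, 1].

    Hits are min-max scaled into [0, DEPTH_MAX_GRAY]; misses (background)
    are exactly 1.0.
    """
    if image_size < 1:
        raise ValueError("image_size must be positive")
    if isinstance(mesh_or_volume, VolumeGrid):
        vol = mesh_or_volume
        if vol.values.size == 0 or min(vol.values.shape) < 2:
            raise ValueError("degenerate volume")
        iso = PHANTOM_ISO_LEVEL if vol.values.max() <= 1.0 else CT_ISO_LEVEL_HU
        depth, hit = depth_map(vol, iso)
        prov = {"source": "volume", "iso_level": iso, "shape": vol.values.shape}
    elif isinstance(mesh_or_volume, SurfaceMesh):
        depth, hit = _depth_from_mesh(mesh_or_volume, image_size)
        prov = {"source": "mesh", "iso_level": mesh_or_volume.iso_level}
    else:
        raise TypeError("expected VolumeGrid or SurfaceMesh")

    pixels = np.ones_like(depth, dtype=float)
    if hit.any():
        d = depth[hit]
        span = d.max() - d.min()
        if span > 0:
            pixels[hit] = (d - d.min()) / span * DEPTH_MAX_GRAY
        else:
            pixels[hit] = 0.0
    # image rows run cranio-caudal (vertical), columns left-right
    pixels = pixels.T
    img = RenderedImage(pixels=pixels, provenance=prov)
    if img.size != image_size or pixels.shape[0] != pixels.shape[1]:
        img = resize_normalize(img, image_size)
    return img


def resize_normalize(image: RenderedImage, out_size: int) -> RenderedImage:
    """Bilinear resize to ``out_size`` square, values clipped to [0, 1].

    Idempotent when the image is already ``out_size`` square.
    """
    if out_size < 1:
        raise ValueError("out_size must be positive")
    px = image.pixels
    if px.shape == (out_size, out_size):
        return RenderedImage(px.copy(), image.render_mode, dict(image.provenance))
    resized = transform.resize(px, (out_size, out_size), order=1,
                               mode="edge", anti_aliasing=False)
    resized = np.clip(resized, 0.0, 1.0)
    prov = dict(image.provenance)
    prov["resized_from"] = px.shape
    return RenderedImage(resized, image.render_mode, prov)
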