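"""Volume-to-radiograph preprocessing.

Turns a 10-phase 4D thoracic volume into a model-ready
:class:`PhaseSequence`: threshold-based lung segmentation, beam's-eye-view
ray-cast projection (lungs only, so bone does not obscure parenchyma), a
single lung bounding box shared by all phases (union over the cycle, keeping
inter-phase pixel correspondence), bilinear resize to the network size and
per-case min-max normalisation. Phase 0 is the end-of-inhale image that the
motion network takes as input.

Volumes are indexed ``(rows = superior-inferior, cols = lateral,
depth = anterior-posterior)``; the default projection integrates along the
depth axis (parallel AP beam).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "PhaseSequence",
    "ProjectionGeometry",
    "segment_lungs",
    "ray_cast_drr",
    "lung_bounding_box",
    "crop_and_normalize",
    "resize_bilinear",
    "preprocess_case",
    "read_volume",
    "write_phase_sequence",
]

LEFT, RIGHT = 1, 2
DEFAULT_THRESHOLD_HU = -400.0


@dataclass(frozen=True)
class ProjectionGeometry:
    """Ray-casting geometry; parallel axis-aligned beam by default."""

    mode: str = "parallel"
    direction: int = 2              # anterior-posterior axis index
    source_distance_mm: float | None = None
    step_mm: float = 1.0

    def __post_init__(self):
        if self.mode not in ("parallel", "perspective"):
            raise ValueError("mode must be 'parallel' or 'perspective'")
        if self.step_mm <= 0:
            raise ValueError("step_mm must be positive")
        if self.direction not in (0, 1, 2):
            raise ValueError("direction must be an axis index in {0, 1, 2}")
        if self.mode == "perspective" and (self.source_distance_mm is None
                                           or self.source_distance_mm <= 0):
            raise ValueError("perspective mode needs a positive source distance")


@dataclass
class PhaseSequence:
    """Preprocessed 10-phase image stack with masks and spacing."""

    phases: np.ndarray       # (10, H, W) float32 in [0, 1]
    lung_masks: np.ndarray   # (10, H, W) uint8, 0 bg / 1 left / 2 right
    spacing_mm: float        # row-direction spacing after resize
    bbox: tuple[int, int, int, int]   # (row0, col0, row1, col1), half-open
    provenance: str = "volume"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.phases.shape[0] != 10 or self.phases.shape != self.lung_masks.shape:
            raise ValueError("a phase sequence holds 10 congruent phases and masks")

    @property
    def p0(self) -> np.ndarray:
        """The end-of-inhale input image."""
        return self.phases[0]


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def segment_lungs(volume: np.ndarray, threshold_hu: float = DEFAULT_THRESHOLD_HU
                  ) -> np.ndarray:
    """Threshold-based lung segmentation of an HU volume.

    Voxels below ``threshold_hu`` are air-like; air components touching the
    volume border (the surrounding atmosphere) are discarded and the two
    largest remaining components are labeled 1 (image-left, smaller column
    centroid) and 2 (image-right). Raises if fewer than two components
    survive.
    """
    volume = np.asarray(volume)
    if not np.all(np.isfinite(volume)):
        raise ValueError("volume contains non-finite values")
    air = volume < threshold_hu
    if not air.any():
        raise ValueError("no voxels below the threshold - no lung found")
    lab, n = ndimage.label(air)
    border_labels = np.unique(np.concatenate([
        lab[0].ravel(), lab[-1].ravel(),
        lab[:, 0].ravel(), lab[:, -1].ravel(),
        lab[:, :, 0].ravel(), lab[:, :, -1].ravel(),
    ]))
    border_labels = border_labels[border_labels > 0]
    interior = air & ~np.isin(lab, border_labels)
    lab2, n2 = ndimage.label(interior)
    if n2 < 2:
        raise ValueError("fewer than two lung components after removing external air")
    sizes = ndimage.sum_labels(np.ones_like(lab2), lab2, index=np.arange(1, n2 + 1))
    keep = np.argsort(sizes)[-2:] + 1
    centroids = ndimage.center_of_mass(interior, lab2, keep)
    order = np.argsort([c[1] for c in centroids])  # column coordinate
    out = np.zeros(volume.shape, dtype=np.uint8)
    out[lab2 == keep[order[0]]] = LEFT
    out[lab2 == keep[order[1]]] = RIGHT
    return out


# ---------------------------------------------------------------------------
# ray casting
# ---------------------------------------------------------------------------

def hu_to_attenuation(volume: np.ndarray) -> np.ndarray:
    """Affine HU -> attenuation map, clamped at zero (air ~ 0, water ~ 1)."""
    return np.clip(1.0 + np.asarray(volume, dtype=np.float64) / 1000.0, 0.0, None)


def ray_cast_drr(volume: np.ndarray, mask: np.ndarray,
                 geometry: ProjectionGeometry | None = None) -> np.ndarray:
    """Beam's-eye-view DRR: per-pixel line integral of masked attenuation.

    Restricting the integral to lung-masked voxels projects the parenchyma
    without interference from bone and soft tissue. Parallel mode sums along
    the beam axis exactly; perspective mode marches rays from a point source
    through the volume with trilinear sampling.
    """
    geometry = geometry or ProjectionGeometry()
    volume = np.asarray(volume)
    mask = np.asarray(mask)
    if volume.shape != mask.shape:
        raise ValueError("volume and mask must be congruent")
    atten = hu_to_attenuation(volume) * (mask > 0)
    if geometry.mode == "parallel":
        return atten.sum(axis=geometry.direction) * geometry.step_mm
    return _perspective_drr(atten, geometry)


def _perspective_drr(atten: np.ndarray, geometry: ProjectionGeometry) -> np.ndarray:
    axis = geometry.direction
    vol = np.moveaxis(atten, axis, 2)  # beam along the last axis
    h, w, d = vol.shape
    if geometry.source_distance_mm <= d:
        raise ValueError("source distance must exceed the volume extent")
    src = np.array([(h - 1) / 2.0, (w - 1) / 2.0, -geometry.source_distance_mm + (d - 1) / 2.0])
    n_steps = int(np.ceil(d / geometry.step_mm)) + 1
    ts = np.linspace(0.0, d - 1.0, n_steps)
    rr, cc = np.meshgrid(np.arange(h, dtype=float), np.arange(w, dtype=float),
                         indexing="ij")
    out = np.zeros((h, w))
    for t in ts:
        # point on the ray from source to detector pixel (r, c, d-1)
        frac = (t - src[2]) / ((d - 1.0) - src[2])
        pr = src[0] + frac * (rr - src[0])
        pc = src[1] + frac * (cc - src[1])
        pz = np.full_like(pr, t)
        out += ndimage.map_coordinates(vol, [pr, pc, pz], order=1, mode="constant")
    return out * geometry.step_mm * (d - 1.0) / max(n_steps - 1, 1)


# ---------------------------------------------------------------------------
# bounding box, crop, resize
# ---------------------------------------------------------------------------

def lung_bounding_box(projected_masks: np.ndarray, margin_px: int = 0
                      ) -> tuple[int, int, int, int]:
    """Minimal half-open box containing the union of the projected masks,
    expanded by ``margin_px`` and clipped to the frame."""
    masks = np.asarray(projected_masks)
    if masks.ndim == 2:
        masks = masks[None]
    union = (masks > 0).any(axis=0)
    if not union.any():
        raise ValueError("empty mask union")
    rows = np.flatnonzero(union.any(axis=1))
    cols = np.flatnonzero(union.any(axis=0))
    h, w = union.shape
    return (
        max(int(rows[0]) - margin_px, 0),
        max(int(cols[0]) - margin_px, 0),
        min(int(rows[-1]) + 1 + margin_px, h),
        min(int(cols[-1]) + 1 + margin_px, w),
    )


def resize_bilinear(image: np.ndarray, out_size: tuple[int, int]) -> np.ndarray:
    """Bilinear resize with corner-aligned coordinate mapping."""
    image = np.asarray(image, dtype=np.float64)
    h, w = image.shape
    oh, ow = out_size
    rr = np.linspace(0.0, h - 1.0, oh) if oh > 1 else np.array([(h - 1) / 2.0])
    cc = np.linspace(0.0, w - 1.0, ow) if ow > 1 else np.array([(w - 1) / 2.0])
    r0 = np.minimum(np.floor(rr).astype(int), max(h - 2, 0))
    c0 = np.minimum(np.floor(cc).astype(int), max(w - 2, 0))
    ar = (rr - r0)[:, None]
    ac = (cc - c0)[None, :]
    r1 = np.minimum(r0 + 1, h - 1)
    c1 = np.minimum(c0 + 1, w - 1)
    out = ((1 - ar) * (1 - ac) * image[np.ix_(r0, c0)]
           + (1 - ar) * ac * image[np.ix_(r0, c1)]
           + ar * (1 - ac) * image[np.ix_(r1, c0)]
           + ar * ac * image[np.ix_(r1, c1)])
    return out


def _resize_nearest(mask: np.ndarray, out_size: tuple[int, int]) -> np.ndarray:
    h, w = mask.shape
    oh, ow = out_size
    rr = np.clip(np.rint(np.linspace(0.0, h - 1.0, oh) if oh > 1 else [(h - 1) / 2.0]),
                 0, h - 1).astype(int)
    cc = np.clip(np.rint(np.linspace(0.0, w - 1.0, ow) if ow > 1 else [(w - 1) / 2.0]),
                 0, w - 1).astype(int)
    return mask[np.ix_(rr, cc)]


def crop_and_normalize(image: np.ndarray, bbox: tuple[int, int, int, int],
                       out_size: tuple[int, int],
                       vrange: tuple[float, float] | None = None) -> np.ndarray:
    """Crop to ``bbox``, bilinear-resize to ``out_size`` and min-max scale to
    [0, 1]. ``vrange`` overrides the min/max (used for per-case
    normalisation); a constant image maps to all zeros."""
    r0, c0, r1, c1 = bbox
    h, w = np.asarray(image).shape
    if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
        raise ValueError(f"degenerate or out-of-frame bbox {bbox} for {h}x{w}")
    crop = np.asarray(image, dtype=np.float64)[r0:r1, c0:c1]
    out = resize_bilinear(crop, out_size)
    vmin, vmax = vrange if vrange is not None else (out.min(), out.max())
    if vmax - vmin <= 0:
        return np.zeros(out_size, dtype=np.float32)
    return (np.clip((out - vmin) / (vmax - vmin), 0.0, 1.0)).astype(np.float32)


# ---------------------------------------------------------------------------
# end-to-end
# ---------------------------------------------------------------------------

def preprocess_case(volumes, threshold_hu: float = DEFAULT_THRESHOLD_HU,
                    geometry: ProjectionGeometry | None = None,
                    out_size: tuple[int, int] = (64, 64),
                    voxel_spacing_mm: float = 1.0, margin_px: int = 2,
                    provenance: str = "volume") -> PhaseSequence:
    """Segment, project, crop and normalise a 10-phase volume sequence.

    Phases keep the order given by the caller; phase 0 must be end-of-inhale.
    One bounding box (union over phases) and one intensity range (per case)
    are shared by all phases so inter-phase correspondence survives.
    """
    volumes = [np.asarray(v) for v in volumes]
    if len(volumes) != 10:
        raise ValueError(f"expected exactly 10 phase volumes, got {len(volumes)}")
    geometry = geometry or ProjectionGeometry()
    masks3d = [segment_lungs(v, threshold_hu) for v in volumes]
    drrs = [ray_cast_drr(v, m, geometry) for v, m in zip(volumes, masks3d)]
    proj_masks = []
    for m in masks3d:
        left = (m == LEFT).sum(axis=geometry.direction) > 0
        right = (m == RIGHT).sum(axis=geometry.direction) > 0
        pm = np.zeros(left.shape, dtype=np.uint8)
        pm[left] = LEFT
        pm[right] = RIGHT
        proj_masks.append(pm)
    proj_masks = np.stack(proj_masks)
    bbox = lung_bounding_box(proj_masks, margin_px=margin_px)
    crops = [resize_bilinear(d[bbox[0]:bbox[2], bbox[1]:bbox[3]], out_size)
             for d in drrs]
    vmin = min(c.min() for c in crops)
    vmax = max(c.max() for c in crops)
    phases = np.stack([
        crop_and_normalize(d, bbox, out_size, vrange=(vmin, vmax)) for d in drrs
    ])
    masks = np.stack([
        _resize_nearest(pm[bbox[0]:bbox[2], bbox[1]:bbox[3]], out_size)
        for pm in proj_masks
    ])
    spacing = voxel_spacing_mm * (bbox[2] - bbox[0]) / out_size[0]
    return PhaseSequence(phases=phases, lung_masks=masks, spacing_mm=float(spacing),
                         bbox=bbox, provenance=provenance,
                         meta={"threshold_hu": threshold_hu,
                               "geometry": geometry.__dict__})


# ---------------------------------------------------------------------------
# volume IO
# ---------------------------------------------------------------------------

def read_volume(path) -> tuple[np.ndarray, float]:
    """Read a NIfTI file or a DICOM series directory; returns (volume,
    in-plane voxel spacing in mm)."""
    path = Path(path)
    if path.is_dir():
        import pydicom

        files = sorted(path.glob("*.dcm")) or sorted(
            p for p in path.iterdir() if p.is_file())
        if not files:
            raise FileNotFoundError(f"no DICOM files in {path}")
        slices = [pydicom.dcmread(str(f)) for f in files]
        slices.sort(key=lambda s: int(getattr(s, "InstanceNumber", 0)))
        vol = np.stack([s.pixel_array.astype(np.float64) for s in slices], axis=-1)
        first = slices[0]
        slope = float(getattr(first, "RescaleSlope", 1.0))
        inter = float(getattr(first, "RescaleIntercept", 0.0))
        spacing = float(getattr(first, "PixelSpacing", [1.0, 1.0])[0])
        return vol * slope + inter, spacing
    import nibabel as nib

    img = nib.load(str(path))
    vol = np.asanyarray(img.dataobj).astype(np.float64)
    spacing = float(img.header.get_zooms()[0])
    return vol, spacing


def write_phase_sequence(seq: PhaseSequence, out_dir, png_preview: bool = True):
    """Write a phase sequence as an array bundle plus optional 8-bit PNGs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(out / "sequence.npz", phases=seq.phases,
                        lung_masks=seq.lung_masks,
                        spacing_mm=np.float64(seq.spacing_mm),
                        bbox=np.asarray(seq.bbox, dtype=np.int64))
    if png_preview:
        from PIL import Image

        for t, ph in enumerate(seq.phases):
            Image.fromarray((np.clip(ph, 0, 1) * 255).astype(np.uint8)).save(
                out / f"phase_{t}.png")
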