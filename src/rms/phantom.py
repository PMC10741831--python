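"""Synthetic 4D thoracic phantom generator.

Produces seeded, fully deterministic breathing sequences that stand in for
cropped sequential chest DRRs: 10 phases starting at end-of-inhale (p0),
diaphragm maximally elevated near mid-cycle (end-of-exhale, p4-p5), smooth
spatially varying displacement concentrated in the lower lung, and per-case
anatomical/amplitude variability. 2D mode ships ground-truth displacement
fields; 3D mode renders small HU-valued volumes for the preprocessing path.

Phase weighting follows ``w_t = sin^2(pi * t / 10)`` — zero at p0, maximal at
mid-cycle, returning toward inhale by p9. Ground-truth fields use the
backward-warping convention of :func:`rms.model.spatial_transform` (for each
phase-t pixel, where to sample in p0), so a single warper serves generation,
prediction and evaluation.

A deliberate design point: per-case diaphragm excursion is tied to visible
anatomy (taller lungs excurse more), with only a small residual jitter. A
single projection therefore genuinely carries motion information — the
premise the motion network relies on — while the jitter keeps an irreducible
error floor so a perfect score is impossible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .model import spatial_transform, warp_labeled_mask

__all__ = [
    "PhantomSpec",
    "PhantomCase",
    "phase_weight",
    "synth_anatomy_2d",
    "synth_cycle_dvfs",
    "render_phantom_sequence",
    "synth_volume_4d",
    "build_phantom_dataset",
    "load_manifest",
    "load_case",
    "iter_split",
]

N_PHASES = 10
LEFT, RIGHT = 1, 2
_SUPERSAMPLE = 4


# ---------------------------------------------------------------------------
# spec / case containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomSpec:
    """Study-condition knobs of the synthetic cohort.

    ``diaphragm_amplitude_mm`` is the cohort-mean peak superior displacement
    of the diaphragm dome at end-of-exhale. Per case it is scaled by a
    lung-height factor (anatomy-linked, learnable from the image) and a small
    multiplicative jitter of fraction ``amplitude_jitter`` (not learnable).
    ``apex_motion_fraction`` is the residual motion at the lung apex relative
    to the diaphragm. ``noise_sigma`` is additive Gaussian sensor noise on
    the [0, 1] intensity scale, drawn independently per phase.
    """

    image_size: tuple[int, int] = (64, 64)
    pixel_spacing_mm: float = 4.0
    n_phases: int = N_PHASES
    diaphragm_amplitude_mm: float = 28.0
    amplitude_jitter: float = 0.05
    apex_motion_fraction: float = 0.1
    nodule_count: int = 0
    noise_sigma: float = 0.002
    volume_size: tuple[int, int, int] = (48, 48, 32)

    def __post_init__(self):
        h, w = self.image_size
        if h < 32 or w < 32:
            raise ValueError("image_size must be at least 32x32 (4 pooling levels)")
        if self.pixel_spacing_mm <= 0:
            raise ValueError("pixel_spacing_mm must be positive")
        if self.n_phases != N_PHASES:
            raise ValueError(f"the breathing cycle is fixed at {N_PHASES} phases")
        if self.diaphragm_amplitude_mm < 0:
            raise ValueError("diaphragm_amplitude_mm must be >= 0")
        if self.diaphragm_amplitude_mm / self.pixel_spacing_mm >= 0.25 * h:
            raise ValueError("diaphragm amplitude too large for the frame "
                             "(amplitude / spacing must stay below 0.25 * H)")
        if not 0.0 <= self.apex_motion_fraction <= 1.0:
            raise ValueError("apex_motion_fraction must lie in [0, 1]")
        if self.amplitude_jitter < 0 or self.noise_sigma < 0 or self.nodule_count < 0:
            raise ValueError("amplitude_jitter, noise_sigma, nodule_count must be >= 0")

    def spec_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PhantomCase:
    """One synthetic patient: a 10-phase sequence with ground truth."""

    images: np.ndarray       # (10, H, W) float32 in [0, 1]
    lung_masks: np.ndarray   # (10, H, W) uint8, 0 bg / 1 left / 2 right
    gt_dvfs: np.ndarray      # (9, 2, H, W) float32, pixels, backward warping
    spacing_mm: float
    seed: int
    meta: dict = field(default_factory=dict)

    @property
    def p0(self) -> np.ndarray:
        return self.images[0]

    def mask_binary(self, t: int) -> np.ndarray:
        return self.lung_masks[t] > 0


def phase_weight(t) -> np.ndarray:
    """Relative motion amplitude of phase t in a 10-phase cycle: sin^2(pi t / 10)."""
    return np.sin(np.pi * np.asarray(t, dtype=float) / N_PHASES) ** 2


# ---------------------------------------------------------------------------
# 2D anatomy
# ---------------------------------------------------------------------------

def _smoothstep(s: np.ndarray) -> np.ndarray:
    s = np.clip(s, 0.0, 1.0)
    return s * s * (3.0 - 2.0 * s)


def _sample_anatomy_params(spec: PhantomSpec, rng: np.random.Generator) -> dict:
    h, w = spec.image_size
    u = rng.uniform
    height_factor = u(0.88, 1.12)          # drives per-case excursion
    apex_row = 0.10 * h * u(0.8, 1.25)
    dome_row = apex_row + 0.62 * h * height_factor
    dome_row = min(dome_row, 0.85 * h)
    params = {
        "height_factor": height_factor,
        "apex_row": apex_row,
        "dome_row": dome_row,
        "lungs": [],
    }
    for side, sign in ((LEFT, -1.0), (RIGHT, 1.0)):
        cx = 0.5 * w + sign * 0.235 * w * u(0.9, 1.1)
        half_width = 0.165 * w * u(0.88, 1.08)
        dome_curv = u(0.12, 0.30) * h      # parabolic dome sag toward the ribs
        params["lungs"].append({
            "label": side,
            "cx": cx,
            "half_width": half_width,
            "apex_row": apex_row * u(0.9, 1.15),
            "dome_row": dome_row + u(-1.5, 1.5),
            "dome_curv": dome_curv,
        })
    return params


def _lung_coverage(params: dict, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Fractional-coverage (anti-aliased) lung interiors at supersampled grid.

    Returns ``(coverage (2, H, W) float in [0,1], labels (2,))``.
    """
    h, w = shape
    ss = _SUPERSAMPLE
    rr = (np.arange(h * ss) + 0.5) / ss - 0.5
    cc = (np.arange(w * ss) + 0.5) / ss - 0.5
    rows = rr[:, None]
    cols = cc[None, :]
    covs = []
    for lung in params["lungs"]:
        cx, a = lung["cx"], lung["half_width"]
        top, dome = lung["apex_row"], lung["dome_row"]
        cy = dome - 0.12 * (dome - top)     # ellipse centre near the base
        b = cy - top
        xn = (cols - cx) / a
        yn = (rows - cy) / b
        inside = (xn ** 2 + yn ** 2) <= 1.0
        border = dome + lung["dome_curv"] * xn ** 2   # convex inferior border
        inside &= rows < border
        cov = inside.reshape(h, ss, w, ss).mean(axis=(1, 3))
        covs.append(cov)
    return np.stack(covs), np.array([lg["label"] for lg in params["lungs"]])


def synth_anatomy_2d(spec: PhantomSpec, seed: int) -> tuple[np.ndarray, np.ndarray, dict]:
    """Render the end-of-inhale anatomy.

    Returns ``(image (H, W) float in [0,1], labeled mask (H, W) uint8 with
    1=left / 2=right, params dict)``. Appearance follows cropped-radiograph
    convention: bright soft-tissue background, darker air-filled lungs with
    smooth vascular-like texture, a bright mediastinal/spine band between the
    lungs, optional bright nodules inside a lung. Deterministic per
    ``(spec, seed)``.
    """
    h, w = spec.image_size
    rng = np.random.default_rng(seed)
    params = _sample_anatomy_params(spec, rng)
    cov, labels = _lung_coverage(params, (h, w))

    rows = np.arange(h, dtype=float)[:, None]
    cols = np.arange(w, dtype=float)[None, :]
    body = 0.82 + 0.06 * (rows / max(h - 1, 1)) + 0.02 * np.sin(np.pi * cols / max(w - 1, 1))
    spine = 0.10 * np.exp(-0.5 * ((cols - 0.5 * w) / (0.05 * w)) ** 2) * np.ones_like(body)
    image = body + spine

    texture = ndimage.gaussian_filter(rng.normal(0.0, 1.0, size=(h, w)), sigma=1.6)
    texture *= 0.06 / max(texture.std(), 1e-9)
    lung_intensity = 0.33 + 0.05 * (rows / max(h - 1, 1)) + texture
    total_cov = cov.sum(axis=0).clip(0.0, 1.0)
    image = image * (1.0 - total_cov) + lung_intensity * total_cov

    mask = np.zeros((h, w), dtype=np.uint8)
    for cvg, lab in zip(cov, labels):
        mask[cvg > 0.5] = lab

    for _ in range(spec.nodule_count):
        side = int(rng.integers(0, 2))
        lung = params["lungs"][side]
        nr = rng.uniform(lung["apex_row"] + 0.3 * (lung["dome_row"] - lung["apex_row"]),
                         lung["dome_row"] - 3.0)
        nc = rng.uniform(lung["cx"] - 0.5 * lung["half_width"],
                         lung["cx"] + 0.5 * lung["half_width"])
        rad = rng.uniform(1.6, 2.6)
        d2 = (rows - nr) ** 2 + (cols - nc) ** 2
        disc = np.clip(rad + 0.5 - np.sqrt(d2), 0.0, 1.0)  # anti-aliased disc
        image += 0.28 * disc * (mask == labels[side])

    image = np.clip(image, 0.0, 1.0).astype(np.float32)
    _require_two_lungs(mask)
    return image, mask, params


def _require_two_lungs(mask: np.ndarray):
    lab, n = ndimage.label(mask > 0)
    if n != 2 or not ((mask == LEFT).any() and (mask == RIGHT).any()):
        raise ValueError(f"expected exactly two lung components, found {n}")


def _clean_warped_mask(mask: np.ndarray) -> np.ndarray:
    """Remove speckles shed by nearest-neighbour warping of a labeled mask.

    Compression can tear off isolated pixels at the lung border; fragments
    below 1% of a lung's area (or 8 px) are dropped. A detached major
    fragment or an emptied lung raises, signalling an excessive amplitude.
    """
    out = mask.copy()
    for lab_val in (LEFT, RIGHT):
        m = mask == lab_val
        if not m.any():
            raise ValueError(f"lung label {lab_val} vanished after warping")
        lab, n = ndimage.label(m)
        if n == 1:
            continue
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        main = int(sizes.argmax()) + 1
        limit = max(8.0, 0.01 * sizes.max())
        if np.any(np.delete(sizes, main - 1) > limit):
            raise ValueError(f"lung label {lab_val} split after warping")
        out[m & (lab != main)] = 0
    return out


# ---------------------------------------------------------------------------
# breathing-cycle displacement fields
# ---------------------------------------------------------------------------

def _case_amplitude_px(spec: PhantomSpec, params: dict, rng: np.random.Generator) -> float:
    base = spec.diaphragm_amplitude_mm / spec.pixel_spacing_mm
    anatomical = params["height_factor"] ** 1.5
    residual = 1.0 + spec.amplitude_jitter * float(np.clip(rng.normal(), -2.0, 2.0))
    return base * anatomical * max(residual, 0.0)


def _motion_basis(spec: PhantomSpec, params: dict) -> tuple[np.ndarray, np.ndarray]:
    """Unit-amplitude smooth displacement basis (u_x, u_y) of the exhale motion.

    Vertical: ~0 above the apex, rising smoothly to 1 at the diaphragm dome,
    decaying below it (anchored past the inferior frame edge so slopes stay
    below 1/pixel — the field remains invertible at allowed amplitudes).
    Lateral: gentle inward squeeze at 15% of the vertical amplitude.
    """
    h, w = spec.image_size
    rows = np.arange(h, dtype=float)[:, None]
    cols = np.arange(w, dtype=float)[None, :]
    apex, dome = params["apex_row"], params["dome_row"]
    frac = spec.apex_motion_fraction

    up = _smoothstep(rows / max(apex, 1.0))           # frame top -> apex
    # convex ramp: the displacement *gradient* (local strain, i.e. the
    # ventilation signal) grows toward the lung base, as in real lungs
    mid = _smoothstep((rows - apex) / max(dome - apex, 1.0)) ** 2
    below = _smoothstep((rows - dome) / max(h + 10.0 - dome, 1.0))
    f_vert = np.where(
        rows <= apex,
        frac * up,
        frac + (1.0 - frac) * mid,
    )
    f_vert = np.where(rows > dome, 1.0 - (1.0 - 0.15) * below, f_vert)

    f_lat = 0.4 + 0.6 * np.sin(np.pi * cols / max(w - 1, 1))
    u_y = f_vert * f_lat * np.ones((h, w))
    u_x = -0.15 * np.sin(2.0 * np.pi * cols / max(w - 1, 1)) * f_vert * np.ones((h, w))
    return u_x.astype(np.float32), u_y.astype(np.float32)


def synth_cycle_dvfs(spec: PhantomSpec, params: dict, seed: int) -> np.ndarray:
    """Ground-truth backward-warping DVFs for phases t = 1..9, (9, 2, H, W), pixels.

    Phase t scales a fixed smooth per-case basis by ``amplitude *
    phase_weight(t)``: during exhalation content below the apex moves
    superiorly (positive u_y under backward warping), maximally near t=5,
    and returns toward the inhale position by t=9.
    """
    h, w = spec.image_size
    rng = np.random.default_rng(seed)
    amp_px = _case_amplitude_px(spec, params, rng)
    u_x, u_y = _motion_basis(spec, params)
    basis = np.stack([u_x, u_y])
    weights = phase_weight(np.arange(1, N_PHASES))
    out = (weights[:, None, None, None] * amp_px * basis[None]).astype(np.float32)
    return out


# ---------------------------------------------------------------------------
# sequence rendering
# ---------------------------------------------------------------------------

def render_phantom_sequence(spec: PhantomSpec, seed: int) -> PhantomCase:
    """Compose anatomy + cycle DVFs into a complete :class:`PhantomCase`.

    Phase images are the EOI render backward-warped by the ground-truth DVFs
    (bilinear); phase masks are the EOI labeled mask warped with
    nearest-neighbour sampling. Independent sensor noise (``noise_sigma``) is
    added to every phase. Raises if any warped phase loses a lung component.
    """
    image0, mask0, params = synth_anatomy_2d(spec, seed)
    dvfs = synth_cycle_dvfs(spec, params, seed)
    rng = np.random.default_rng((seed * 2654435761 + 97) % (2 ** 31))

    images = [image0]
    masks = [mask0]
    for t in range(1, N_PHASES):
        images.append(spatial_transform(image0, dvfs[t - 1], interp="bilinear"))
        try:
            mt = _clean_warped_mask(warp_labeled_mask(mask0, dvfs[t - 1]))
            _require_two_lungs(mt)
        except ValueError as exc:
            raise ValueError(f"phase {t}: {exc} (amplitude too large?)") from exc
        masks.append(mt)
    images = np.stack(images).astype(np.float32)
    if spec.noise_sigma > 0:
        images = images + rng.normal(0.0, spec.noise_sigma, size=images.shape).astype(np.float32)
        images = np.clip(images, 0.0, 1.0)
    return PhantomCase(
        images=images,
        lung_masks=np.stack(masks).astype(np.uint8),
        gt_dvfs=dvfs,
        spacing_mm=spec.pixel_spacing_mm,
        seed=int(seed),
        meta={"params": {k: v for k, v in params.items() if k != "lungs"},
              "spec_hash": spec.spec_hash()},
    )


# ---------------------------------------------------------------------------
# 3D mode (feeds the preprocessing path)
# ---------------------------------------------------------------------------

HU_AIR, HU_LUNG, HU_SOFT, HU_BONE = -1000.0, -800.0, 0.0, 400.0


def synth_volume_4d(spec: PhantomSpec, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Render 10 small HU-valued volumes plus labeled 3D lung masks.

    Returns ``(volumes (10, H, W, D), masks (10, H, W, D) uint8)`` with axes
    (rows = superior-inferior, cols = lateral, depth = anterior-posterior).
    The diaphragm dome surface rises by ``amplitude * phase_weight(t)`` per
    phase — exhalation analytically shrinks the lungs. Deterministic per seed.
    """
    h, w, d = spec.volume_size
    if min(h, w, d) < 32:
        raise ValueError("volume_size must be at least 32 in every dimension")
    rng = np.random.default_rng(seed)
    rows = np.arange(h, dtype=float)[:, None, None]
    cols = np.arange(w, dtype=float)[None, :, None]
    deps = np.arange(d, dtype=float)[None, None, :]

    body = (((cols - 0.5 * w) / (0.46 * w)) ** 2
            + ((deps - 0.5 * d) / (0.42 * d)) ** 2) <= 1.0
    body = body & (rows >= 0)  # broadcast to (h, w, d)
    body = np.broadcast_to(body, (h, w, d))

    apex = 0.10 * h * rng.uniform(0.85, 1.2)
    dome0 = apex + 0.62 * h * rng.uniform(0.9, 1.1)
    amp_px = spec.diaphragm_amplitude_mm / spec.pixel_spacing_mm * (h / spec.image_size[0])
    lungs0 = []
    for sign in (-1.0, 1.0):
        cx = 0.5 * w + sign * 0.22 * w
        ax = 0.16 * w * rng.uniform(0.9, 1.1)
        az = 0.28 * d
        lungs0.append((cx, ax, az))

    spine = (((cols - 0.5 * w) / (0.05 * w)) ** 2
             + ((deps - 0.82 * d) / (0.08 * d)) ** 2) <= 1.0
    spine = np.broadcast_to(spine, (h, w, d)) & body

    lung_noise = rng.normal(0.0, 30.0, size=(h, w, d))

    volumes = np.empty((N_PHASES, h, w, d), dtype=np.float32)
    masks = np.zeros((N_PHASES, h, w, d), dtype=np.uint8)
    for t in range(N_PHASES):
        dome_t = dome0 - amp_px * phase_weight(t)
        vol = np.full((h, w, d), HU_AIR, dtype=np.float32)
        vol[body] = HU_SOFT
        for lab, (cx, ax, az) in zip((LEFT, RIGHT), lungs0):
            cy = dome_t - 0.12 * (dome_t - apex)
            b = cy - apex
            inside = (((cols - cx) / ax) ** 2 + ((rows - cy) / b) ** 2
                      + ((deps - 0.48 * d) / az) ** 2) <= 1.0
            border = dome_t + 0.2 * h * ((cols - cx) / ax) ** 2
            inside = inside & (rows < border) & body
            masks[t][inside] = lab
            vol[inside] = np.clip(HU_LUNG + lung_noise[inside], -940.0, -660.0)
        vol[spine & (masks[t] == 0)] = HU_BONE
        volumes[t] = vol
    return volumes, masks


# ---------------------------------------------------------------------------
# on-disk dataset
# ---------------------------------------------------------------------------

def _case_seed(seed: int, index: int) -> int:
    return int((int(seed) * 1_000_003 + 7919 * index + 13) % (2 ** 31))


def build_phantom_dataset(out_dir, n_train: int = 40, n_test: int = 20,
                          spec: PhantomSpec | None = None, seed: int = 0,
                          mode: str = "2d", force: bool = False) -> dict:
    """Write a split phantom cohort to ``out_dir`` and return the manifest.

    One compressed array bundle per case plus ``manifest.json``. Case seeds
    are disjoint deterministic functions of ``seed``; re-running with the
    same arguments reproduces byte-identical manifests. Refuses to overwrite
    an existing dataset directory unless ``force``.
    """
    if n_train < 1 or n_test < 1:
        raise ValueError("n_train and n_test must be >= 1")
    if mode not in ("2d", "3d"):
        raise ValueError("mode must be '2d' or '3d'")
    spec = spec or PhantomSpec()
    out_dir = Path(out_dir)
    manifest_path = out_dir / "manifest.json"
    if manifest_path.exists() and not force:
        raise FileExistsError(f"{out_dir} already holds a dataset (use force=True)")
    out_dir.mkdir(parents=True, exist_ok=True)

    cases = []
    for i in range(n_train + n_test):
        split = "train" if i < n_train else "test"
        cseed = _case_seed(seed, i)
        cid = f"case_{i:03d}"
        fname = f"{cid}.npz"
        if mode == "2d":
            case = render_phantom_sequence(spec, cseed)
            np.savez_compressed(out_dir / fname, images=case.images,
                                lung_masks=case.lung_masks, gt_dvfs=case.gt_dvfs,
                                spacing_mm=np.float64(case.spacing_mm),
                                seed=np.int64(cseed))
        else:
            volumes, vmasks = synth_volume_4d(spec, cseed)
            np.savez_compressed(out_dir / fname, volumes=volumes, lung_masks=vmasks,
                                spacing_mm=np.float64(spec.pixel_spacing_mm),
                                seed=np.int64(cseed))
        cases.append({"case_id": cid, "split": split, "seed": cseed,
                      "file": fname, "spec_hash": spec.spec_hash()})
    manifest = {
        "mode": mode,
        "seed": int(seed),
        "n_train": n_train,
        "n_test": n_test,
        "spec": asdict(spec),
        "spec_hash": spec.spec_hash(),
        "cases": cases,
    }
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def load_manifest(dataset_dir) -> dict:
    return json.loads((Path(dataset_dir) / "manifest.json").read_text())


def load_case(dataset_dir, entry: dict, spec: PhantomSpec | None = None) -> PhantomCase:
    with np.load(Path(dataset_dir) / entry["file"]) as z:
        return PhantomCase(
            images=z["images"], lung_masks=z["lung_masks"], gt_dvfs=z["gt_dvfs"],
            spacing_mm=float(z["spacing_mm"]), seed=int(z["seed"]),
            meta={"case_id": entry["case_id"], "split": entry["split"]},
        )


def iter_split(dataset_dir, split: str):
    """Yield :class:`PhantomCase` objects of one split of a 2D dataset."""
    manifest = load_manifest(dataset_dir)
    if manifest["mode"] != "2d":
        raise ValueError("iter_split serves 2D datasets")
    for entry in manifest["cases"]:
        if entry["split"] == split:
            yield load_case(dataset_dir, entry)
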