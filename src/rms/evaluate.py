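"""Evaluation suite: Jacobian ventilation maps, Dice, diaphragm kinetics.

Quantities reported per test case and phase t = 1..9:

* **Dice** between the predicted whole-lung mask (the EOI mask warped by the
  predicted DVF, nearest-neighbour) and the ground-truth phase mask.
* **LLE / RLE** — left/right lung diaphragmatic-position errors in mm: the
  apex-to-dome length measured on the predicted mask minus the ground-truth
  length (signed; absolute values are also tabulated).
* **Ventilation maps** ``v = det J - 1`` of each predicted field, where
  ``J`` is the Jacobian of the deformation ``x -> x + u(x)``; ``det J > 1``
  marks local expansion, ``< 1`` compression.

Aggregates mirror a per-phase mean (+-std) table plus overall summary flags
(mean Dice, minimum Dice, median absolute diaphragm error).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import MotionNet, RMSCheckpoint, warp_labeled_mask
from .phantom import LEFT, RIGHT, PhantomCase, iter_split
from .train import downsample_image, upsample_dvf

__all__ = [
    "VentilationMap",
    "MetricsReport",
    "ventilation_map",
    "dice_score",
    "predict_phase_masks",
    "diaphragm_length",
    "evaluate_model",
    "evaluate_cases",
    "identity_predictor",
    "model_predictor",
    "gt_predictor",
]


# ---------------------------------------------------------------------------
# ventilation
# ---------------------------------------------------------------------------

@dataclass
class VentilationMap:
    v: np.ndarray        # det J - 1
    det_j: np.ndarray
    phase: int


def ventilation_map(dvf: np.ndarray, phase: int = 0) -> VentilationMap:
    """Jacobian-determinant ventilation of a (2, H, W) displacement field.

    Central finite differences in the interior (one-sided at the borders):
    ``det J = (1 + du_x/dx)(1 + du_y/dy) - (du_x/dy)(du_y/dx)``.
    """
    dvf = np.asarray(dvf, dtype=np.float64)
    if dvf.ndim != 3 or dvf.shape[0] != 2:
        raise ValueError(f"expected a (2, H, W) field, got {dvf.shape}")
    if not np.all(np.isfinite(dvf)):
        raise ValueError("displacement field contains non-finite values")
    u_x, u_y = dvf
    dux_dy, dux_dx = np.gradient(u_x)  # axis 0 = rows (y), axis 1 = cols (x)
    duy_dy, duy_dx = np.gradient(u_y)
    det = (1.0 + dux_dx) * (1.0 + duy_dy) - dux_dy * duy_dx
    return VentilationMap(v=det - 1.0, det_j=det, phase=phase)


# ---------------------------------------------------------------------------
# overlap and diaphragm metrics
# ---------------------------------------------------------------------------

def dice_score(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice similarity 2|A∩B| / (|A|+|B|) of two binary masks."""
    a = np.asarray(mask_a).astype(bool)
    b = np.asarray(mask_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    sa, sb = int(a.sum()), int(b.sum())
    if sa + sb == 0:
        raise ValueError("both masks are empty")
    return 2.0 * float(np.logical_and(a, b).sum()) / float(sa + sb)


def predict_phase_masks(p0_mask: np.ndarray, dvfs: np.ndarray) -> np.ndarray:
    """Warp the labeled EOI lung mask by each predicted DVF (nearest).

    Returns a (T, H, W) labeled stack. A phase whose warp empties a lung is
    left as-is; downstream reporting flags it.
    """
    out = np.stack([warp_labeled_mask(p0_mask, d) for d in dvfs])
    return out.astype(p0_mask.dtype)


def diaphragm_length(mask: np.ndarray, spacing_mm: float) -> float:
    """Apex-to-dome length of one lung in mm.

    Apex = most superior mask row. Dome = the most superior point of the
    per-column inferior boundary, restricted to the central 60% of the
    lung's column span (avoiding costophrenic angles and the mediastinal
    border). Requires a mask at least 3 columns wide.
    """
    m = np.asarray(mask).astype(bool)
    if not m.any():
        raise ValueError("empty mask")
    cols = np.flatnonzero(m.any(axis=0))
    if cols.size < 3:
        raise ValueError("mask thinner than 3 columns")
    apex_row = int(np.argmax(m.any(axis=1)))
    span = cols[-1] - cols[0] + 1
    lo = cols[0] + int(np.floor(0.2 * span))
    hi = cols[-1] - int(np.floor(0.2 * span))
    central = np.arange(lo, hi + 1)
    central = central[m[:, central].any(axis=0)]
    if central.size == 0:
        raise ValueError("no mask columns in the central band")
    h = m.shape[0]
    inferior = (h - 1) - np.argmax(m[::-1][:, central], axis=0)  # per-column max row
    dome_row = int(inferior.min())
    length = (dome_row - apex_row) * float(spacing_mm)
    if length <= 0:
        raise ValueError("degenerate lung mask (dome not below apex)")
    return length


# ---------------------------------------------------------------------------
# cohort evaluation
# ---------------------------------------------------------------------------

@dataclass
class MetricsReport:
    """Per-case table, per-phase aggregates and summary flags."""

    per_case: pd.DataFrame
    per_phase: pd.DataFrame
    summary: dict = field(default_factory=dict)

    def save(self, out_dir):
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.per_case.to_csv(out / "per_case.csv", index=False)
        self.per_phase.to_csv(out / "per_phase.csv", index=False)
        import json
        (out / "summary.json").write_text(json.dumps(self.summary, indent=1))


def identity_predictor(case: PhantomCase) -> np.ndarray:
    """Zero-motion baseline: nine zero fields at data resolution."""
    return np.zeros((9, 2) + case.images.shape[1:], dtype=np.float32)


def gt_predictor(case: PhantomCase) -> np.ndarray:
    """Oracle upper bound: the generator's ground-truth fields."""
    return case.gt_dvfs


def model_predictor(net: MotionNet):
    """Wrap a trained network as a case-level DVF predictor.

    The EOI image is block-mean downsampled to the network resolution; the
    predicted fields are bilinearly upsampled (and rescaled) back.
    """

    def predict(case: PhantomCase) -> np.ndarray:
        data_size = case.images.shape[-1]
        factor = data_size // net.image_size
        if net.image_size * factor != data_size:
            raise ValueError("data resolution must be a multiple of the model's")
        p0 = downsample_image(case.images[0], factor)
        dvfs, _ = net.forward(p0)
        return np.stack([upsample_dvf(d, factor) for d in dvfs])

    return predict


def evaluate_cases(predict_fn, cases, out_dir=None) -> MetricsReport:
    """Evaluate a DVF predictor over phantom cases.

    ``predict_fn(case) -> (9, 2, H, W)`` fields at data resolution. Dice uses
    the whole-lung (union) mask; diaphragm lengths are per lung. Ventilation
    maps of the predicted fields are written to ``out_dir`` when given.
    """
    rows = []
    cases = list(cases)
    if not cases:
        raise ValueError("no cases to evaluate")
    for case in cases:
        dvfs = predict_fn(case)
        pred_masks = predict_phase_masks(case.lung_masks[0], dvfs)
        cid = case.meta.get("case_id", f"seed_{case.seed}")
        for t in range(1, 10):
            pm = pred_masks[t - 1]
            gm = case.lung_masks[t]
            row = {"case_id": cid, "phase": t,
                   "empty_mask": bool((pm == LEFT).sum() == 0 or (pm == RIGHT).sum() == 0)}
            row["dice"] = dice_score(pm > 0, gm > 0)
            for name, lab in (("lle", LEFT), ("rle", RIGHT)):
                pred_len = diaphragm_length(pm == lab, case.spacing_mm)
                gt_len = diaphragm_length(gm == lab, case.spacing_mm)
                row[f"{name}_mm"] = pred_len - gt_len
                row[f"abs_{name}_mm"] = abs(pred_len - gt_len)
                row[f"{name}_pred_mm"] = pred_len
                row[f"{name}_gt_mm"] = gt_len
            rows.append(row)
        if out_dir is not None:
            _save_ventilation(out_dir, cid, dvfs)
    per_case = pd.DataFrame(rows)
    agg = per_case.groupby("phase").agg(
        dice_mean=("dice", "mean"), dice_std=("dice", "std"),
        lle_mean=("lle_mm", "mean"), lle_std=("lle_mm", "std"),
        rle_mean=("rle_mm", "mean"), rle_std=("rle_mm", "std"),
    ).reset_index()
    abs_err = np.concatenate([per_case["abs_lle_mm"], per_case["abs_rle_mm"]])
    summary = {
        "n_cases": len(cases),
        "dice_mean": float(per_case["dice"].mean()),
        "dice_min": float(per_case["dice"].min()),
        "median_abs_diaphragm_error_mm": float(np.median(abs_err)),
        "frac_abs_error_below_10mm_left": float((per_case["abs_lle_mm"] < 10.0).mean()),
        "frac_abs_error_below_10mm_right": float((per_case["abs_rle_mm"] < 10.0).mean()),
        "any_empty_mask": bool(per_case["empty_mask"].any()),
    }
    report = MetricsReport(per_case=per_case, per_phase=agg, summary=summary)
    if out_dir is not None:
        report.save(out_dir)
    return report


def evaluate_model(checkpoint, dataset_dir_or_cases, out_dir=None) -> MetricsReport:
    """Evaluate a trained checkpoint (or net) on the test split of a dataset
    directory, or on an explicit iterable of cases."""
    if isinstance(checkpoint, MotionNet):
        net = checkpoint
    else:
        ck = (checkpoint if isinstance(checkpoint, RMSCheckpoint)
              else RMSCheckpoint.load(checkpoint))
        net = ck.build_net()
    if isinstance(dataset_dir_or_cases, (str, Path)):
        cases = iter_split(dataset_dir_or_cases, "test")
    else:
        cases = dataset_dir_or_cases
    return evaluate_cases(model_predictor(net), cases, out_dir=out_dir)


def _save_ventilation(out_dir, case_id: str, dvfs: np.ndarray):
    out = Path(out_dir) / "ventilation" / case_id
    out.mkdir(parents=True, exist_ok=True)
    maps = np.stack([ventilation_map(d, phase=t + 1).v for t, d in enumerate(dvfs)])
    np.save(out / "ventilation.npy", maps.astype(np.float32))
    try:
        from matplotlib import cm
        from PIL import Image
        lim = max(float(np.abs(maps).max()), 1e-6)
        for t, v in enumerate(maps):
            rgba = cm.coolwarm(0.5 + 0.5 * np.clip(v / lim, -1, 1))
            Image.fromarray((rgba[..., :3] * 255).astype(np.uint8)).save(
                out / f"phase_{t + 1}.png")
    except Exception:
        pass  # previews are best-effort
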