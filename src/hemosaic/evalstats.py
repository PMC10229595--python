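"""Diagnostic statistics and mosaic-quality measures.

The diagnostic metrics on a binary confusion matrix are

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)

evaluated as exact rationals and rounded only at display time. A metric
whose denominator class is empty is reported as explicitly undefined
(``None`` plus a flag) rather than a numeric sentinel, so a degenerate
margin can never masquerade as 0%.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .core import ConfusionMatrix

__all__ = [
    "DiagnosticMetrics",
    "confusion_metrics",
    "placement_error",
    "reconstruction_error",
]


@dataclass(frozen=True)
class DiagnosticMetrics:
    accuracy: Fraction | None
    sensitivity: Fraction | None
    specificity: Fraction | None

    @property
    def undefined(self) -> tuple[str, ...]:
        return tuple(
            name for name in ("accuracy", "sensitivity", "specificity")
            if getattr(self, name) is None
        )

    def as_percent(self, digits: int = 1) -> dict[str, str]:
        out = {}
        for name in ("accuracy", "sensitivity", "specificity"):
            v = getattr(self, name)
            out[name] = "n/a" if v is None else f"{float(v) * 100:.{digits}f}%"
        return out

    def to_json(self) -> str:
        return json.dumps(
            {
                name: (None if getattr(self, name) is None else float(getattr(self, name)))
                for name in ("accuracy", "sensitivity", "specificity")
            }
        )


def confusion_metrics(cm: ConfusionMatrix) -> DiagnosticMetrics:
    """Accuracy, sensitivity and specificity of a confusion matrix."""
    acc = Fraction(cm.TP + cm.TN, cm.total) if cm.total else None
    sens = Fraction(cm.TP, cm.TP + cm.FN) if cm.TP + cm.FN >= 1 else None
    spec = Fraction(cm.TN, cm.TN + cm.FP) if cm.TN + cm.FP >= 1 else None
    return DiagnosticMetrics(acc, sens, spec)


def placement_error(
    est: dict[str, dict], truth: dict[str, dict]
) -> tuple[dict[str, float], dict[str, float]]:
    """Euclidean per-tile placement errors and their summary.

    ``est`` maps tile_id to a row with ``placed_x_px``/``placed_y_px``;
    ``truth`` to a row with ``true_x_px``/``true_y_px``. Returns
    ``(per_tile, summary)`` where summary holds mean, max and RMSE in
    pixels.
    """
    missing = sorted(set(est) ^ set(truth))
    if missing:
        raise ValueError(f"unmatched tile_ids: {missing}")
    per_tile = {}
    for tid, e in est.items():
        t = truth[tid]
        dx = e["placed_x_px"] - t["true_x_px"]
        dy = e["placed_y_px"] - t["true_y_px"]
        per_tile[tid] = math.hypot(dx, dy)
    errs = np.array(list(per_tile.values()))
    summary = {
        "mean_px": float(errs.mean()),
        "max_px": float(errs.max()),
        "rmse_px": float(np.sqrt(np.mean(errs**2))),
        "n_tiles": len(errs),
    }
    return per_tile, summary


def reconstruction_error(
    mosaic: np.ndarray,
    scene: np.ndarray,
    mask: np.ndarray | None = None,
) -> dict[str, float]:
    """RMSE between a stitched mosaic and the ground-truth scene.

    Both are cropped to the common extent; ``mask`` (2-D bool) restricts
    the comparison, e.g. to the area actually covered by tiles. Returns
    per-channel and combined RMSE in 8-bit intensity levels.
    """
    if mosaic.ndim == 2:
        mosaic = mosaic[:, :, None]
    if scene.ndim == 2:
        scene = scene[:, :, None]
    h = min(mosaic.shape[0], scene.shape[0])
    w = min(mosaic.shape[1], scene.shape[1])
    a = mosaic[:h, :w].astype(np.float64)
    b = scene[:h, :w].astype(np.float64)
    if mask is None:
        mask = np.ones((h, w), dtype=bool)
    else:
        mask = mask[:h, :w].astype(bool)
    if not mask.any():
        raise ValueError("empty valid mask")
    out = {}
    sq = (a - b) ** 2
    for c in range(a.shape[2]):
        out[f"rmse_ch{c}"] = float(np.sqrt(sq[:, :, c][mask].mean()))
    out["rmse"] = float(np.sqrt(sq[mask].mean()))
    return out
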