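"""Overlap metrics between a segmentation and a ground-truth mask.

Four quantities are reported, all derived from the voxel counts
``V_seg`` (segmented volume), ``V_ground`` (ground-truth volume) and their
overlap ``V_seg ∩ V_ground``:

* Dice similarity coefficient ``DSC = 2|A∩B| / (|A|+|B|)``, in [0, 1]
  (0 = no overlap, 1 = complete overlap);
* Sensitivity ``|A∩B| / V_ground`` — how much of the truth is recovered;
* Inclusiveness ``|A∩B| / V_seg`` — how much of the segmentation is true;
* ``ΔV = (V_seg - V_ground) / V_ground × 100%`` — signed relative volume
  error (a magnitude option is provided for reporting parity with
  conventions that print only positive values).

DSC is the harmonic mean of sensitivity and inclusiveness whenever both are
positive, and ``ΔV = (sensitivity/inclusiveness - 1)·100`` whenever the
overlap is non-empty.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import UndefinedMetricError, ValidationError

__all__ = [
    "MetricsReport",
    "evaluate_masks",
    "batch_evaluate",
    "write_report_csv",
    "write_report_json",
    "REPORT_COLUMNS",
]

REPORT_COLUMNS = [
    "label",
    "dsc",
    "sensitivity",
    "inclusiveness",
    "delta_v_percent",
    "v_seg",
    "v_ground",
]


@dataclass(frozen=True)
class MetricsReport:
    """The four overlap metrics plus the raw voxel counts behind them.

    ``inclusiveness_defined`` is False when the segmentation is empty (the
    ratio has a zero denominator; 0 is reported in its place).
    """

    dsc: float
    sensitivity: float
    inclusiveness: float
    delta_v_percent: float
    v_seg: int
    v_ground: int
    v_overlap: int
    inclusiveness_defined: bool = True

    def volumes_physical(self, spacing: Sequence[float]) -> Tuple[float, float]:
        """(V_seg, V_ground) scaled by the product of the voxel spacings."""
        factor = float(np.prod(spacing))
        return self.v_seg * factor, self.v_ground * factor


def _as_binary(mask: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(mask)
    if not np.isin(arr, (0, 1)).all():
        raise ValidationError(f"{name} mask must be binary (0/1)")
    return arr.astype(bool)


def evaluate_masks(
    seg: np.ndarray, ground: np.ndarray, *, signed_delta_v: bool = True
) -> MetricsReport:
    """Compare a segmentation against ground truth of the same shape.

    Raises :class:`UndefinedMetricError` for an empty ground truth.  An empty
    segmentation yields ``dsc = 0``, ``sensitivity = 0``, inclusiveness
    reported as 0 with ``inclusiveness_defined=False`` and ``ΔV = -100%``.
    """
    seg_b = _as_binary(seg, "seg")
    gt_b = _as_binary(ground, "ground")
    if seg_b.shape != gt_b.shape:
        raise ValidationError(
            f"shape mismatch: seg {seg_b.shape} vs ground {gt_b.shape}"
        )
    v_ground = int(gt_b.sum())
    if v_ground == 0:
        raise UndefinedMetricError("ground-truth mask is empty; metrics undefined")
    v_seg = int(seg_b.sum())
    v_overlap = int(np.logical_and(seg_b, gt_b).sum())

    dsc = 2.0 * v_overlap / (v_seg + v_ground)
    sensitivity = v_overlap / v_ground
    if v_seg > 0:
        inclusiveness = v_overlap / v_seg
        defined = True
    else:
        inclusiveness = 0.0
        defined = False
    delta_v = (v_seg - v_ground) / v_ground * 100.0
    if not signed_delta_v:
        delta_v = abs(delta_v)
    return MetricsReport(
        dsc=dsc,
        sensitivity=sensitivity,
        inclusiveness=inclusiveness,
        delta_v_percent=delta_v,
        v_seg=v_seg,
        v_ground=v_ground,
        v_overlap=v_overlap,
        inclusiveness_defined=defined,
    )


def batch_evaluate(
    cases: Iterable[Tuple[np.ndarray, np.ndarray, str]],
    *,
    signed_delta_v: bool = True,
) -> pd.DataFrame:
    """Evaluate a sequence of ``(seg, ground, label)`` cases into a table.

    Per-case errors are recorded in the ``error`` column (with ``valid``
    False and NaN metrics) rather than aborting the batch.
    """
    rows = []
    for seg, ground, label in cases:
        row = {"label": label}
        try:
            rep = evaluate_masks(seg, ground, signed_delta_v=signed_delta_v)
        except (UndefinedMetricError, ValidationError) as exc:
            row.update(
                dsc=np.nan, sensitivity=np.nan, inclusiveness=np.nan,
                delta_v_percent=np.nan, v_seg=np.nan, v_ground=np.nan,
                valid=False, error=str(exc),
            )
        else:
            row.update(
                dsc=rep.dsc, sensitivity=rep.sensitivity,
                inclusiveness=rep.inclusiveness,
                delta_v_percent=rep.delta_v_percent,
                v_seg=rep.v_seg, v_ground=rep.v_ground,
                valid=True, error="",
            )
        rows.append(row)
    return pd.DataFrame(rows, columns=REPORT_COLUMNS + ["valid", "error"])


def write_report_csv(table: pd.DataFrame, path) -> None:
    """Write a metrics table as CSV with the fixed column order."""
    table[REPORT_COLUMNS].to_csv(path, index=False)


def write_report_json(table: pd.DataFrame, path) -> None:
    """Write a metrics table as a JSON array of row objects, fixed column order."""
    table[REPORT_COLUMNS].to_json(path, orient="records", indent=2)
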