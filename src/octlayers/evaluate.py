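"""Quantitative evaluation: boundary positioning error and thickness maps.

The mean unsigned positioning error (MUE) between two curves ``L1`` and
``L2`` over ``N`` A-scans is

    MUE(L1, L2) = (1/N) * sum_j |L1(j) - L2(j)|

reported in micrometres by scaling with the axial pixel pitch. Columns
where either curve is undefined (NaN) are excluded from ``N`` and
counted separately.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core import BOUNDARY_ORDER, ValidationError
from .identify import BoundaryCurve, Segmentation
from .phantom import PhantomTruth


class MUEEntry(NamedTuple):
    mue_um: float      # mean |L1 - L2| in micrometres
    sd_um: float       # standard deviation of the unsigned error
    n_columns: int     # A-scans compared
    n_excluded: int    # A-scans dropped because a curve was undefined


@dataclass(frozen=True)
class MUEReport:
    """Per-boundary MUE entries plus their mean."""

    entries: dict[str, MUEEntry]
    axial_px_um: float

    @property
    def mean_mue_um(self) -> float:
        return float(np.mean([e.mue_um for e in self.entries.values()]))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "boundary": name,
                "mue_um": e.mue_um,
                "sd_um": e.sd_um,
                "n_columns": e.n_columns,
                "n_excluded": e.n_excluded,
            }
            for name, e in self.entries.items()
        ]
        rows.append(
            {
                "boundary": "mean",
                "mue_um": self.mean_mue_um,
                "sd_um": float("nan"),
                "n_columns": 0,
                "n_excluded": 0,
            }
        )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class ThicknessMap:
    """Layer thickness in micrometres per (slice, column)."""

    values: np.ndarray
    layer_span: tuple[str, str]  # (upper boundary, lower boundary)
    axial_px_um: float = 3.9


def _rows_of(curve) -> np.ndarray:
    if isinstance(curve, BoundaryCurve):
        return curve.rows
    return np.asarray(curve, dtype=float)


def mue(curve1, curve2, axial_px_um: float = 3.9) -> MUEEntry:
    """Mean unsigned positioning error between two curves, in um.

    Accepts plain row arrays or :class:`BoundaryCurve` objects; named
    curves must agree on the name.
    """
    if isinstance(curve1, BoundaryCurve) and isinstance(curve2, BoundaryCurve):
        if curve1.name != curve2.name:
            raise ValidationError(
                f"curve name mismatch: {curve1.name!r} vs {curve2.name!r}"
            )
    l1, l2 = _rows_of(curve1), _rows_of(curve2)
    if l1.shape != l2.shape:
        raise ValidationError(f"curve length mismatch: {l1.shape} vs {l2.shape}")
    ok = np.isfinite(l1) & np.isfinite(l2)
    n_excluded = int((~ok).sum())
    if not ok.any():
        raise ValidationError("no columns where both curves are defined")
    err = np.abs(l1[ok] - l2[ok]) * axial_px_um
    return MUEEntry(float(err.mean()), float(err.std()), int(ok.sum()), n_excluded)


def thickness(
    segmentations: Union[Segmentation, Sequence[Segmentation]],
    upper: str,
    lower: str,
    axial_px_um: Optional[float] = None,
) -> ThicknessMap:
    """Thickness between two boundaries per slice and column, in um."""
    if isinstance(segmentations, Segmentation):
        segmentations = [segmentations]
    iu, il = BOUNDARY_ORDER.index(upper), BOUNDARY_ORDER.index(lower)
    if iu > il:
        raise ValidationError(
            f"{upper!r} is anatomically below {lower!r}; swap the span"
        )
    if axial_px_um is None:
        axial_px_um = 3.9
    vals = np.stack(
        [(s.curves[lower] - s.curves[upper]) * axial_px_um for s in segmentations]
    )
    return ThicknessMap(vals, (upper, lower), axial_px_um)


def evaluate_against_truth(
    seg: Segmentation, truth: PhantomTruth, axial_px_um: Optional[float] = None
) -> MUEReport:
    """Score a segmentation against phantom truth, boundary by boundary."""
    if axial_px_um is None:
        axial_px_um = truth.config.pixel_size_axial
    entries = {}
    for name in BOUNDARY_ORDER:
        t = truth.boundaries[name]
        s = seg.curves[name]
        if t.shape != s.shape:
            raise ValidationError("segmentation width does not match the truth")
        entries[name] = mue(s, t, axial_px_um)
    return MUEReport(entries, axial_px_um)
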