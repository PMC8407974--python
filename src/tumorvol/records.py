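"""Flat per-case records joining morphometry, formula estimates and ground truth."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .estimators import VolumeEstimates
from .morphometry import TumorMorphometry

__all__ = ["CohortRecord", "COHORT_COLUMNS", "records_to_frame"]

COHORT_COLUMNS = [
    "case_id",
    "v_plan",
    "s",
    "a",
    "b",
    "h",
    "max_diameter",
    "ellipsoidity",
    "n_slices",
    "max_slice_index",
    "v_13abc",
    "v_12abc",
    "v_23abc",
    "v_13sh",
    "v_12sh",
    "v_23sh",
    "shape",
    "truth_volume",
    "truth_ax1",
    "truth_ax2",
    "truth_ax3",
]


def _nan_to_none(value):
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    return value


@dataclass(frozen=True)
class CohortRecord:
    """One tumor's morphometry and estimates, plus analytic truth for phantoms.

    ``truth_volume_ml`` and ``truth_half_axes_mm`` are populated only for
    ellipsoid phantoms, where the rasterised geometry has a closed form.
    """

    case_id: str
    morphometry: TumorMorphometry
    estimates: VolumeEstimates
    shape: str | None = None
    truth_volume_ml: float | None = None
    truth_half_axes_mm: tuple[float, float, float] | None = None

    def as_row(self) -> dict:
        m, e = self.morphometry, self.estimates
        ax = self.truth_half_axes_mm or (None, None, None)
        return {
            "case_id": self.case_id,
            "v_plan": m.v_plan,
            "s": m.s,
            "a": m.a,
            "b": m.b,
            "h": m.h,
            "max_diameter": m.max_diameter,
            "ellipsoidity": m.ellipsoidity,
            "n_slices": m.n_slices,
            "max_slice_index": m.max_slice_index,
            "v_13abc": e.v_13abc,
            "v_12abc": e.v_12abc,
            "v_23abc": e.v_23abc,
            "v_13sh": e.v_13sh,
            "v_12sh": e.v_12sh,
            "v_23sh": e.v_23sh,
            "shape": self.shape,
            "truth_volume": self.truth_volume_ml,
            "truth_ax1": ax[0],
            "truth_ax2": ax[1],
            "truth_ax3": ax[2],
        }

    @classmethod
    def from_row(cls, row: Mapping) -> "CohortRecord":
        morpho = TumorMorphometry(
            case_id=str(row["case_id"]),
            v_plan=float(row["v_plan"]),
            s=float(row["s"]),
            a=float(row["a"]),
            b=float(row["b"]),
            h=float(row["h"]),
            max_diameter=float(row["max_diameter"]),
            ellipsoidity=_nan_to_none(row["ellipsoidity"]),
            n_slices=int(row["n_slices"]),
            max_slice_index=int(row["max_slice_index"]),
        )
        est = VolumeEstimates(
            v_13abc=float(row["v_13abc"]),
            v_12abc=float(row["v_12abc"]),
            v_23abc=float(row["v_23abc"]),
            v_13sh=float(row["v_13sh"]),
            v_12sh=float(row["v_12sh"]),
            v_23sh=float(row["v_23sh"]),
        )
        axes = tuple(
            _nan_to_none(row[k]) for k in ("truth_ax1", "truth_ax2", "truth_ax3")
        )
        shape = _nan_to_none(row.get("shape"))
        return cls(
            case_id=str(row["case_id"]),
            morphometry=morpho,
            estimates=est,
            shape=None if shape is None else str(shape),
            truth_volume_ml=_nan_to_none(row["truth_volume"]),
            truth_half_axes_mm=None if axes[0] is None else axes,  # type: ignore[arg-type]
        )


def records_to_frame(records: Sequence[CohortRecord] | Iterable[CohortRecord] | pd.DataFrame) -> pd.DataFrame:
    """Normalise a record sequence (or an already-flat DataFrame) to a DataFrame."""
    if isinstance(records, pd.DataFrame):
        return records
    return pd.DataFrame([r.as_row() for r in records], columns=COHORT_COLUMNS)
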