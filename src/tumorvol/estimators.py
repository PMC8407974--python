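"""The six formula-based volume estimates.

Three ABC-derived methods (k*A*B*C) and three SH-derived methods (k*S*H) with
k in {1/3, 1/2, 2/3}. A, B are the caliper lengths of the maximum-area axial
slice (cm), S its area (cm^2), and C = H the tumor height (cm); results are in
mL (cm^3). For a perfectly ellipsoidal tumor 2/3*S*H equals the true volume and
1/2*A*B*C overestimates it by a factor 3/pi.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["VolumeEstimates", "estimate_volumes", "METHOD_NAMES", "METHOD_FIELDS"]

METHOD_NAMES = ("1/3ABC", "1/2ABC", "2/3ABC", "1/3SH", "1/2SH", "2/3SH")
METHOD_FIELDS = {
    "1/3ABC": "v_13abc",
    "1/2ABC": "v_12abc",
    "2/3ABC": "v_23abc",
    "1/3SH": "v_13sh",
    "1/2SH": "v_12sh",
    "2/3SH": "v_23sh",
}


@dataclass(frozen=True)
class VolumeEstimates:
    """Formula volumes in mL; within each family the 1/3 : 1/2 : 2/3 values
    stand in an exact 2 : 3 : 4 ratio."""

    v_13abc: float
    v_12abc: float
    v_23abc: float
    v_13sh: float
    v_12sh: float
    v_23sh: float

    def by_method(self, method: str) -> float:
        return getattr(self, METHOD_FIELDS[method])


def estimate_volumes(a: float, b: float, s: float, h: float) -> VolumeEstimates:
    """Compute all six formula volumes from A, B (cm), S (cm^2) and H (cm)."""
    if min(a, b, s, h) < 0:
        raise ValueError("morphometric inputs must be non-negative")
    abc = a * b * h
    sh = s * h
    return VolumeEstimates(
        v_13abc=abc / 3.0,
        v_12abc=abc / 2.0,
        v_23abc=2.0 * abc / 3.0,
        v_13sh=sh / 3.0,
        v_12sh=sh / 2.0,
        v_23sh=2.0 * sh / 3.0,
    )
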