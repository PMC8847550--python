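"""Physical torsional rigidity (GJ) extraction from torque-angle curves.

The biomechanical test convention: torsional rigidity is the least-squares
slope of the torque-angle loading curve restricted to the 6-10 N*m window,
multiplied by the specimen gauge length, reported in N*m**2 per degree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["RigidityMeasurement", "TORQUE_WINDOW_NM", "compute_gj"]

#: loading window (N*m) over which the slope is regressed, inclusive bounds
TORQUE_WINDOW_NM = (6.0, 10.0)


@dataclass(frozen=True)
class RigidityMeasurement:
    """GJ = regression slope x gauge length, with fit diagnostics."""

    gj: float  # N*m**2/degree
    regression_slope: float  # N*m/degree
    window: tuple[float, float]
    gauge_length: float  # mm
    r_squared_of_fit: float


def compute_gj(curve) -> RigidityMeasurement:
    """Least-squares rigidity from the 6-10 N*m window of a loading curve.

    Raises if fewer than 3 samples fall inside the window or the angle
    samples are not strictly increasing (enforced by the curve type, and
    re-checked here for externally constructed records).
    """
    angle = np.asarray(curve.angle, dtype=np.float64)
    torque = np.asarray(curve.torque, dtype=np.float64)
    if np.any(np.diff(angle) <= 0):
        raise ValueError("angle samples must be strictly increasing")
    lo, hi = TORQUE_WINDOW_NM
    sel = (torque >= lo) & (torque <= hi)
    if sel.sum() < 3:
        raise ValueError(
            f"need >= 3 samples with torque in [{lo}, {hi}] N*m, got {int(sel.sum())}"
        )
    fit = sps.linregress(angle[sel], torque[sel])
    gauge_m = curve.gauge_length / 1000.0
    return RigidityMeasurement(
        gj=float(fit.slope * gauge_m),
        regression_slope=float(fit.slope),
        window=TORQUE_WINDOW_NM,
        gauge_length=float(curve.gauge_length),
        r_squared_of_fit=float(fit.rvalue**2),
    )
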