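"""Reference margin-of-stability (MoS) computation from marker trajectories.

The MoS compares the extrapolated centre of mass (XCoM) with the base of
support (BoS).  With CoM position ``x_com``, horizontal velocity ``v_com``
and inverted-pendulum natural frequency ``omega = sqrt(g / l)`` (``l`` the
CoM height above ground), the XCoM is

    x_xcom = x_com + v_com / omega,

where on a treadmill the belt speed is added to the anterior component of
the velocity before extrapolation.  The anterior MoS is the signed
difference ``bos_y - xcom_y`` (positive = XCoM inside the anterior BoS
boundary); the mediolateral MoS is the absolute difference
``|bos_x - xcom_x|``.  Per-step labels take the minimum of each series over
the step (support-foot heel contact to opposite heel contact).

The CoM is approximated by the midpoint of the two ASIS markers; the BoS
boundary by the stance foot's forefoot (toe) marker.  ``l`` is the
trial-mean CoM height, giving one constant natural frequency per trial.
"""

from __future__ import annotations

import logging
import warnings
from typing import List, Optional, Tuple

import numpy as np
from scipy.signal import find_peaks

from .config import GRAVITY
from .errors import DataError, DetectionError
from .types import HeelContactSeries, MarkerFrameSeries, MosSeries, StepLabel

log = logging.getLogger(__name__)


def com_from_asis(markers: MarkerFrameSeries) -> np.ndarray:
    """CoM trajectory (n, 3): pointwise midpoint of the ASIS markers."""
    return 0.5 * (markers.positions["ASIS_L"] + markers.positions["ASIS_R"])


def com_velocity(com: np.ndarray, dt: float) -> np.ndarray:
    """Differentiate a trajectory: central differences in the interior,
    one-sided first-order differences at the ends (exact for quadratics
    in the interior, for straight lines everywhere)."""
    com = np.asarray(com, dtype=float)
    if com.shape[0] < 3:
        raise DataError("com_velocity: need at least 3 samples")
    if dt <= 0:
        raise DataError("com_velocity: dt must be positive")
    return np.gradient(com, dt, axis=0, edge_order=1)


def natural_frequency(l: float, g: float = GRAVITY) -> float:
    """Inverted-pendulum natural frequency omega = sqrt(g / l) [rad/s]."""
    if l <= 0:
        raise DataError(f"natural_frequency: CoM height must be > 0, got {l}")
    return float(np.sqrt(g / l))


def extrapolated_com(
    x_com: np.ndarray,
    v_com: np.ndarray,
    omega: float,
    belt_speed: float = 0.0,
) -> np.ndarray:
    """XCoM on the horizontal plane: x_com + (v_com + belt) / omega.

    ``x_com``/``v_com`` are (..., 2) arrays of [x (mediolateral),
    y (anterior)]; the belt speed (m/s, >= 0) is added to the anterior
    velocity component.
    """
    if omega <= 0:
        raise DataError("extrapolated_com: omega must be > 0")
    if belt_speed < 0:
        raise DataError("extrapolated_com: belt_speed must be >= 0")
    x_com = np.asarray(x_com, dtype=float)
    v_com = np.asarray(v_com, dtype=float)
    v = v_com.copy()
    v[..., 1] = v[..., 1] + belt_speed
    return x_com + v / omega


def anterior_mos(bos_y, xcom_y):
    """Signed anterior margin: BoS boundary minus XCoM, both anterior."""
    return np.asarray(bos_y, dtype=float) - np.asarray(xcom_y, dtype=float)


def mediolateral_mos(bos_x, xcom_x):
    """Absolute mediolateral margin |bos_x - xcom_x| (symmetric)."""
    return np.abs(np.asarray(bos_x, dtype=float) - np.asarray(xcom_x, dtype=float))


def detect_heel_contacts(
    markers: MarkerFrameSeries,
    belt_speed: float,
    refractory_s: float = 0.3,
) -> HeelContactSeries:
    """Detect heel contacts from the toe markers.

    On a treadmill the stance toe is dragged backwards by the belt, so each
    heel contact coincides with a local maximum of the toe marker's
    anterior (y) coordinate.  Peaks closer than ``refractory_s`` are
    suppressed per foot; events are then merged, sorted and checked for
    strict left/right alternation.
    """
    dt = markers.dt
    min_dist = max(1, int(round(refractory_s / dt)))
    times: List[float] = []
    feet: List[str] = []
    for foot, marker in (("left", "TOE_L"), ("right", "TOE_R")):
        y = markers.positions[marker][:, 1]
        if np.ptp(y) < 1e-12:
            raise DetectionError(
                f"detect_heel_contacts: {marker} anterior trajectory is "
                "constant; no peaks"
            )
        peaks, _ = find_peaks(y, distance=min_dist)
        if peaks.size == 0:
            raise DetectionError(
                f"detect_heel_contacts: no local maxima for {marker}"
            )
        times.extend(markers.time[peaks])
        feet.extend([foot] * peaks.size)
    order = np.argsort(times)
    times_arr = np.asarray(times)[order]
    feet_arr = np.asarray(feet, dtype=object)[order]
    for i in range(1, len(times_arr)):
        if feet_arr[i] == feet_arr[i - 1]:
            raise DetectionError(
                "detect_heel_contacts: two consecutive "
                f"{feet_arr[i]}-foot contacts at t={times_arr[i - 1]:.3f} s "
                f"and t={times_arr[i]:.3f} s (alternation violated)"
            )
    return HeelContactSeries(times=times_arr, feet=feet_arr)


def mos_series(
    markers: MarkerFrameSeries,
    belt_speed: float,
    events: HeelContactSeries,
) -> MosSeries:
    """Frame-wise anterior and mediolateral MoS.

    At each frame the support foot is the foot of the most recent heel
    contact and the BoS boundary is that foot's toe-marker horizontal
    position.  Frames before the first event are excluded.
    """
    if len(events) < 1:
        raise DataError("mos_series: need at least one heel-contact event")
    com = com_from_asis(markers)
    vel = com_velocity(com, markers.dt)
    l = float(np.mean(com[:, 2]))
    omega = natural_frequency(l)
    xcom = extrapolated_com(com[:, :2], vel[:, :2], omega, belt_speed)

    start = int(np.searchsorted(markers.time, events.times[0], side="left"))
    t = markers.time[start:]
    # support foot index: most recent event at or before each frame
    ev_idx = np.searchsorted(events.times, t, side="right") - 1
    is_left = np.asarray([events.feet[i] == "left" for i in ev_idx])
    toe_l = markers.positions["TOE_L"][start:, :2]
    toe_r = markers.positions["TOE_R"][start:, :2]
    bos = np.where(is_left[:, None], toe_l, toe_r)

    ant = anterior_mos(bos[:, 1], xcom[start:, 1])
    ml = mediolateral_mos(bos[:, 0], xcom[start:, 0])
    return MosSeries(time=t, anterior=ant, mediolateral=ml)


def min_mos_per_step(
    series: MosSeries,
    events: HeelContactSeries,
    participant: int = 0,
    speed_kmh: float = 0.0,
) -> List[StepLabel]:
    """Per-step minima of the MoS series, in millimetres.

    A step runs from one heel contact to the next (opposite-foot) contact;
    its support foot is the foot of the opening contact.  Anterior and
    mediolateral minima are taken independently within the step.
    """
    if len(events) < 2:
        raise DataError("min_mos_per_step: need at least 2 events")
    labels: List[StepLabel] = []
    for j in range(len(events) - 1):
        lo = int(np.searchsorted(series.time, events.times[j], side="left"))
        hi = int(np.searchsorted(series.time, events.times[j + 1], side="left"))
        if hi <= lo:
            warnings.warn(
                f"min_mos_per_step: step {j} contains no frames; skipped",
                stacklevel=2,
            )
            continue
        labels.append(
            StepLabel(
                participant=participant,
                speed_kmh=speed_kmh,
                support_foot=str(events.feet[j]),
                step_index=j,
                min_anterior_mm=float(np.min(series.anterior[lo:hi]) * 1000.0),
                min_mediolateral_mm=float(
                    np.min(series.mediolateral[lo:hi]) * 1000.0
                ),
            )
        )
    return labels


def reference_labels(
    markers: MarkerFrameSeries,
    belt_speed: float,
    events: Optional[HeelContactSeries] = None,
    refractory_s: float = 0.3,
    participant: int = 0,
    speed_kmh: float = 0.0,
) -> Tuple[List[StepLabel], MosSeries, HeelContactSeries]:
    """Full marker -> per-step-label path (detecting events if not given)."""
    if events is None:
        events = detect_heel_contacts(markers, belt_speed, refractory_s)
    series = mos_series(markers, belt_speed, events)
    labels = min_mos_per_step(series, events, participant, speed_kmh)
    log.info(
        "reference_labels: %d steps, belt %.3f m/s, omega from l=%.3f m",
        len(labels),
        belt_speed,
        float(np.mean(com_from_asis(markers)[:, 2])),
    )
    return labels, series, events
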