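"""Step segmentation, time normalization and predictor assembly.

Each support-foot step (support heel contact = 0 % of the gait cycle,
opposite heel contact = 50 %) is linearly interpolated onto 51 equally
spaced normalized time points per channel.  The per-site 51 x 6 arrays are
flattened channel-by-channel (ax, ay, az, gx, gy, gz, 51 points each) into
a 306-vector; with two sensors the two blocks are concatenated in declared
site order into a 612-vector.  Rows of the design matrix are predictor
vectors; the target is the step's minimum MoS (mm) in one direction.
Left- and right-support steps are never mixed.
"""

from __future__ import annotations

import logging
import warnings
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import DataError
from .types import (
    IMU_CHANNELS,
    N_GRID,
    DesignMatrix,
    HeelContactSeries,
    ImuRecording,
    StepSample,
)

log = logging.getLogger(__name__)


def segment_and_resample(
    rec: ImuRecording,
    events: HeelContactSeries,
    support: str,
    n_points: int = N_GRID,
) -> List[np.ndarray]:
    """Cut one site's recording into support-foot steps on the 51-point grid.

    Returns one (n_points, 6) array per step opened by a ``support``-foot
    heel contact and closed by the opposite contact, channels interpolated
    linearly at n_points equally spaced times spanning the step (both
    endpoints included).  Steps whose window holds fewer than two IMU
    samples, or extends outside the recording, are skipped with a warning.
    """
    if support not in ("left", "right"):
        raise DataError(f"support must be left|right, got {support!r}")
    if n_points < 2:
        raise DataError("n_points must be >= 2")
    channels = rec.channels()
    out: List[np.ndarray] = []
    for j in range(len(events) - 1):
        if events.feet[j] != support:
            continue
        t0, t1 = float(events.times[j]), float(events.times[j + 1])
        if t0 < rec.time[0] or t1 > rec.time[-1]:
            warnings.warn(
                f"step at t={t0:.3f}s extends outside recording "
                f"[{rec.site}]; skipped",
                stacklevel=2,
            )
            continue
        n_in = int(np.searchsorted(rec.time, t1, side="right")) - int(
            np.searchsorted(rec.time, t0, side="left")
        )
        if n_in < 2:
            warnings.warn(
                f"step at t={t0:.3f}s contains {n_in} IMU samples "
                f"[{rec.site}]; skipped",
                stacklevel=2,
            )
            continue
        ts = np.linspace(t0, t1, n_points)
        arr = np.empty((n_points, channels.shape[1]))
        for c in range(channels.shape[1]):
            arr[:, c] = np.interp(ts, rec.time, channels[:, c])
        out.append(arr)
    return out


def build_predictor_vector(
    arrays: Dict[str, np.ndarray], sites: Sequence[str]
) -> np.ndarray:
    """Flatten per-site step arrays into one predictor vector.

    Per site, channels are laid out ax(0..50), ay, az, gx, gy, gz; sites
    follow each other in the declared order.  Length is 306 per site.
    """
    if not 1 <= len(sites) <= 2:
        raise DataError(f"need 1 or 2 sites, got {len(sites)}")
    parts = []
    for site in sites:
        if site not in arrays:
            raise DataError(f"site {site!r} missing from step arrays")
        arr = np.asarray(arrays[site], dtype=float)
        if arr.ndim != 2 or arr.shape[1] != len(IMU_CHANNELS):
            raise DataError(
                f"site {site!r}: expected (n_points, 6) array, got {arr.shape}"
            )
        parts.append(arr.ravel(order="F"))  # column-major = channel blocks
    return np.concatenate(parts)


def unflatten_predictor_vector(
    vec: np.ndarray, sites: Sequence[str], n_points: int = N_GRID
) -> Dict[str, np.ndarray]:
    """Inverse of :func:`build_predictor_vector` (exact round trip)."""
    vec = np.asarray(vec, dtype=float)
    block = n_points * len(IMU_CHANNELS)
    if vec.shape != (block * len(sites),):
        raise DataError(
            f"vector length {vec.shape} inconsistent with {len(sites)} sites"
        )
    out = {}
    for i, site in enumerate(sites):
        out[site] = (
            vec[i * block : (i + 1) * block]
            .reshape((len(IMU_CHANNELS), n_points))
            .T.copy()
        )
    return out


def build_design_matrix(
    samples: Sequence[StepSample],
    sites: Sequence[str],
    direction: str,
) -> DesignMatrix:
    """Stack step samples into X (n x 306*S) and labels y (mm)."""
    if len(samples) == 0:
        raise DataError("build_design_matrix: no step samples")
    if direction not in ("anterior", "mediolateral"):
        raise DataError(f"unknown direction {direction!r}")
    feet = {s.support_foot for s in samples}
    if len(feet) != 1:
        raise DataError(
            "build_design_matrix: mixed support feet "
            f"{sorted(feet)}; analyze left and right steps separately"
        )
    rows = []
    y = []
    meta = []
    for s in samples:
        for site in sites:
            if site not in s.arrays:
                raise DataError(
                    f"site {site!r} missing from step sample "
                    f"(participant {s.participant}, step {s.step_index})"
                )
        rows.append(build_predictor_vector(s.arrays, sites))
        y.append(s.label(direction))
        meta.append(
            {
                "participant": s.participant,
                "speed_kmh": s.speed_kmh,
                "support_foot": s.support_foot,
                "step_index": s.step_index,
            }
        )
    dm = DesignMatrix(
        X=np.vstack(rows),
        y=np.asarray(y, dtype=float),
        meta=pd.DataFrame(meta),
        sites=tuple(sites),
        direction=direction,
        support_foot=samples[0].support_foot,
    )
    log.info(
        "design matrix: %d x %d (%s, %s support, sites %s)",
        dm.X.shape[0],
        dm.X.shape[1],
        direction,
        dm.support_foot,
        ",".join(sites),
    )
    return dm


def step_samples_from_trial(trial, n_points: int = N_GRID) -> List[StepSample]:
    """Build labelled StepSamples (all sites) from a synthetic trial.

    Pairs each truth row with the matching step window; windows skipped by
    the resampler at any site drop the whole step.
    """
    events = trial.events
    truth = trial.truth
    samples: List[StepSample] = []
    # resample every site once, indexed by step j
    per_site: Dict[str, Dict[int, np.ndarray]] = {}
    for site, rec in trial.imu.items():
        channels = rec.channels()
        per_site[site] = {}
        for j in range(len(events) - 1):
            t0, t1 = float(events.times[j]), float(events.times[j + 1])
            if t0 < rec.time[0] or t1 > rec.time[-1]:
                continue
            ts = np.linspace(t0, t1, n_points)
            arr = np.empty((n_points, channels.shape[1]))
            for c in range(channels.shape[1]):
                arr[:, c] = np.interp(ts, rec.time, channels[:, c])
            per_site[site][j] = arr
    for _, row in truth.iterrows():
        j = int(row["step_index"])
        arrays = {}
        ok = True
        for site in trial.imu:
            if j not in per_site[site]:
                ok = False
                break
            arrays[site] = per_site[site][j]
        if not ok:
            continue
        samples.append(
            StepSample(
                participant=int(row["participant"]),
                speed_kmh=float(row["speed_kmh"]),
                support_foot=str(row["support_foot"]),
                step_index=j,
                arrays=arrays,
                min_anterior_mm=float(row["min_anterior_mm"]),
                min_mediolateral_mm=float(row["min_mediolateral_mm"]),
            )
        )
    return samples
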