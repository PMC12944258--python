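"""Synthetic gait generators with known ground truth.

Two generators stand in for treadmill recordings:

``generate_latent_dataset``
    A pure latent-linear model ``X = C P^T + E``, ``y = C b + e`` matching
    the structural assumptions of principal motion analysis exactly.  Used
    for parameter-recovery and null-calibration studies.

``generate_gait_trial``
    A stylized kinematic treadmill trial: the CoM follows an
    inverted-pendulum-flavoured path (constant height, lateral sinusoid at
    the stride frequency plus slow modulators that create step-to-step MoS
    variability); toe markers land a fixed distance ahead of the pelvis and
    are dragged backwards by the belt during stance, returning smoothly
    during swing.  IMU channels are linear mixtures of a few periodic
    latent waveforms — two of which are exactly the slow modulators driving
    the MoS labels — plus Gaussian sensor noise.  Sites configured as
    uninformative get zero loading on those MoS-coupled latents.

The stored per-step minimum-MoS truth is evaluated from closed-form
expressions for the marker model; the velocity truth is the closed form of
the central/one-sided finite difference of the sinusoidal CoM components,
so the marker -> MoS reference pipeline reproduces the truth to floating
precision without the generator ever calling that pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np
import pandas as pd

from .config import GRAVITY, KMH_TO_MS, GaitSimConfig, LatentLinearSpec
from .errors import ConfigurationError
from .types import (
    DesignMatrix,
    HeelContactSeries,
    ImuRecording,
    MarkerFrameSeries,
)

log = logging.getLogger(__name__)

#: substrings marking sites that load strongly on the MoS-coupled latents
_LOWER_LIMB_TOKENS = ("knee", "thigh", "instep", "sacral")


@dataclass
class SyntheticTrial:
    """One generated participant x speed trial with ground truth."""

    participant: int
    speed_kmh: float
    markers: MarkerFrameSeries
    imu: Dict[str, ImuRecording]
    events: HeelContactSeries
    truth: pd.DataFrame  # one row per step: labels (mm) + latent scores
    config: GaitSimConfig


# ---------------------------------------------------------------------------
# latent-linear generator
# ---------------------------------------------------------------------------

def generate_latent_dataset(
    spec: LatentLinearSpec,
) -> Tuple[np.ndarray, np.ndarray, Dict[str, np.ndarray]]:
    """Draw (X, y) from the latent-linear model; truth holds C, P, b.

    Scores C are i.i.d. standard normal (columns independent); loadings P
    default to i.i.d. normal entries and coefficients b to the descending
    sequence n_latent..1, so earlier latents carry more of the signal.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.loading_matrix is not None:
        P = spec.loading_matrix
    else:
        P = rng.normal(size=(spec.dim, spec.n_latent))
    if np.linalg.matrix_rank(P) < spec.n_latent:
        raise ConfigurationError(
            "latent loading columns are linearly dependent"
        )
    b = (
        spec.coeffs
        if spec.coeffs is not None
        else np.arange(spec.n_latent, 0, -1, dtype=float)
    )
    C = rng.normal(size=(spec.n_samples, spec.n_latent))
    X = C @ P.T
    if spec.noise_sd_x > 0:
        X = X + spec.noise_sd_x * rng.normal(size=X.shape)
    y = C @ b
    if spec.noise_sd_y > 0:
        y = y + spec.noise_sd_y * rng.normal(size=y.shape)
    truth = {"C": C, "P": P, "b": b, "noise_sd_y": spec.noise_sd_y}
    return X, y, truth


def latent_design_matrix(
    spec: LatentLinearSpec,
) -> Tuple[DesignMatrix, Dict[str, np.ndarray]]:
    """Wrap a latent-linear draw as a single-stratum DesignMatrix."""
    X, y, truth = generate_latent_dataset(spec)
    meta = pd.DataFrame(
        {
            "participant": np.zeros(len(y), dtype=int),
            "speed_kmh": np.zeros(len(y)),
            "support_foot": ["left"] * len(y),
            "step_index": np.arange(len(y)),
        }
    )
    dm = DesignMatrix(
        X=X, y=y, meta=meta, sites=(), direction="anterior",
        support_foot="left",
    )
    return dm, truth


# ---------------------------------------------------------------------------
# kinematic treadmill generator
# ---------------------------------------------------------------------------

def _sin_fd_velocity(
    amp: float, w: float, phase: float, time: np.ndarray, dt: float
) -> np.ndarray:
    """Closed form of the finite-difference derivative of amp*sin(w t + p).

    Interior: central difference == amp*cos(w t + p)*sin(w dt)/dt.
    Ends: one-sided differences evaluated from the exact samples.
    """
    v = amp * np.cos(w * time + phase) * (np.sin(w * dt) / dt)
    s = lambda t: amp * np.sin(w * t + phase)  # noqa: E731
    v[0] = (s(time[1]) - s(time[0])) / dt
    v[-1] = (s(time[-1]) - s(time[-2])) / dt
    return v


def _site_coupling(site: str, uninformative: Tuple[str, ...]) -> float:
    if site in uninformative:
        return 0.0
    if any(tok in site for tok in _LOWER_LIMB_TOKENS):
        return 1.0
    return 0.4


def generate_gait_trial(
    config: GaitSimConfig, participant: int, speed_kmh: float
) -> SyntheticTrial:
    """Generate one participant x speed treadmill trial.

    Heel contacts sit on a strict grid of one step period, right foot on
    even multiples; the recording covers a warm-up segment (whose steps are
    excluded, mirroring the discard of the first minute) followed by
    exactly ``steps_per_foot_per_speed`` steps per foot.
    """
    if speed_kmh not in config.speeds_kmh:
        raise ConfigurationError(
            f"speed {speed_kmh} km/h not in configured speeds "
            f"{config.speeds_kmh}"
        )
    speed_idx = config.speeds_kmh.index(speed_kmh)
    rng = np.random.default_rng(
        [int(config.seed), int(participant), int(speed_idx)]
    )

    T = config.step_period_s(speed_kmh)  # step period (s)
    stride = 2.0 * T
    v_belt = speed_kmh * KMH_TO_MS
    t_stance = config.stance_fraction * stride  # > T: stance spans the step
    w_stride = np.pi / T  # stride angular frequency (rad/s)
    w_ml = 2.0 * np.pi * config.ml_mod_freq_hz
    w_ant = 2.0 * np.pi * config.ant_mod_freq_hz
    phi_ml = rng.uniform(0.0, 2.0 * np.pi)
    phi_ant = rng.uniform(0.0, 2.0 * np.pi)

    n_steps = 2 * config.steps_per_foot_per_speed
    i0 = int(np.ceil(config.warmup_s / T))
    event_idx = np.arange(i0, i0 + n_steps + 1)
    event_times = event_idx * T
    event_feet = np.where(event_idx % 2 == 0, "right", "left").astype(object)
    t_end = event_times[-1] + T

    dt = 1.0 / config.marker_rate_hz
    n_frames = int(np.floor(t_end / dt)) + 1
    time = np.arange(n_frames) * dt

    # --- CoM and ASIS markers -------------------------------------------
    A, A_ml, B_ant = (
        config.sway_amplitude_m,
        config.ml_mod_amplitude_m,
        config.ant_mod_amplitude_m,
    )
    x_com = A * np.sin(w_stride * time) + A_ml * np.sin(w_ml * time + phi_ml)
    y_com = B_ant * np.sin(w_ant * time + phi_ant)
    z_com = np.full(n_frames, config.com_height_m)
    hw = config.hip_half_width_m
    asis_l = np.column_stack([x_com - hw, y_com, z_com])
    asis_r = np.column_stack([x_com + hw, y_com, z_com])

    # --- toe markers -----------------------------------------------------
    def toe_track(parity: int, x_off: float) -> np.ndarray:
        u = np.mod(time - parity * T, stride)
        in_stance = u < t_stance
        y_low = config.toe_lead_m - v_belt * t_stance
        s = (u - t_stance) / (stride - t_stance)
        y = np.where(
            in_stance,
            config.toe_lead_m - v_belt * u,
            y_low + (config.toe_lead_m - y_low) * 0.5 * (1 - np.cos(np.pi * s)),
        )
        z = np.where(in_stance, 0.0, config.swing_lift_m * np.sin(np.pi * s) ** 2)
        return np.column_stack([np.full(n_frames, x_off), y, z])

    half_w = 0.5 * config.step_width_m
    toe_r = toe_track(parity=0, x_off=+half_w)
    toe_l = toe_track(parity=1, x_off=-half_w)

    markers = MarkerFrameSeries(
        time=time,
        positions={
            "ASIS_L": asis_l,
            "ASIS_R": asis_r,
            "TOE_L": toe_l,
            "TOE_R": toe_r,
        },
    )
    events = HeelContactSeries(times=event_times.astype(float), feet=event_feet)

    # --- analytic per-step minimum MoS ----------------------------------
    omega = np.sqrt(GRAVITY / config.com_height_m)
    v_x = _sin_fd_velocity(A, w_stride, 0.0, time, dt) + _sin_fd_velocity(
        A_ml, w_ml, phi_ml, time, dt
    )
    v_y = _sin_fd_velocity(B_ant, w_ant, phi_ant, time, dt)
    xcom_x = x_com + v_x / omega
    xcom_y = y_com + (v_y + v_belt) / omega

    rows = []
    for j in range(n_steps):
        e0, e1 = event_times[j], event_times[j + 1]
        lo = int(np.searchsorted(time, e0, side="left"))
        hi = int(np.searchsorted(time, e1, side="left"))
        tt = time[lo:hi]
        foot = str(event_feet[j])
        x_bos = half_w if foot == "right" else -half_w
        ant = config.toe_lead_m - v_belt * (tt - e0) - xcom_y[lo:hi]
        ml = np.abs(x_bos - xcom_x[lo:hi])
        t_mid = e0 + 0.5 * T
        rows.append(
            {
                "participant": participant,
                "speed_kmh": speed_kmh,
                "support_foot": foot,
                "step_index": j,
                "min_anterior_mm": float(np.min(ant) * 1000.0),
                "min_mediolateral_mm": float(np.min(ml) * 1000.0),
                "ml_latent": float(np.sin(w_ml * t_mid + phi_ml)),
                "ant_latent": float(np.sin(w_ant * t_mid + phi_ant)),
            }
        )
    truth = pd.DataFrame(rows)

    # --- IMU latent mixtures ---------------------------------------------
    dt_imu = 1.0 / config.imu_rate_hz
    n_imu = int(np.floor(t_end / dt_imu)) + 1
    t_imu = np.arange(n_imu) * dt_imu
    K = config.n_latent
    latents = np.empty((K, n_imu))
    extra_phases = rng.uniform(0.0, 2.0 * np.pi, size=max(0, K - 3))
    for k in range(K):
        if k == 0:
            latents[k] = np.cos(w_stride * t_imu)
        elif k == 1:
            latents[k] = np.sin(w_ml * t_imu + phi_ml)
        elif k == 2:
            latents[k] = np.sin(w_ant * t_imu + phi_ant)
        else:
            latents[k] = np.cos(
                (k - 1) * 2.0 * np.pi / T * t_imu + extra_phases[k - 3]
            )
    coupled = [k for k in (1, 2) if k < K]

    imu: Dict[str, ImuRecording] = {}
    for site in config.sites:
        M = rng.normal(size=(6, K))
        M[:3] *= 1.5  # accel channels, m/s^2 scale
        M[3:] *= 0.8  # gyro channels, rad/s scale
        factor = _site_coupling(site, config.uninformative_sites)
        for k in coupled:
            M[:, k] *= factor
        sig = (M @ latents).T  # (n_imu, 6)
        accel = sig[:, :3].copy()
        accel[:, 2] += GRAVITY  # static gravity component on the z channel
        gyro = sig[:, 3:].copy()
        if config.noise_sd_accel > 0:
            accel += config.noise_sd_accel * rng.normal(size=accel.shape)
        if config.noise_sd_gyro > 0:
            gyro += config.noise_sd_gyro * rng.normal(size=gyro.shape)
        imu[site] = ImuRecording(site=site, time=t_imu, accel=accel, gyro=gyro)

    log.info(
        "generated trial p%02d @ %.1f km/h: %d steps, %d marker frames",
        participant,
        speed_kmh,
        n_steps,
        n_frames,
    )
    return SyntheticTrial(
        participant=participant,
        speed_kmh=speed_kmh,
        markers=markers,
        imu=imu,
        events=events,
        truth=truth,
        config=config,
    )
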