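"""Configuration dataclasses for simulation and the pipeline.

Defaults mirror the study conditions the package is designed around:
eight participants, treadmill speeds 2.5/3.0/3.5 km/h, 60 left- and 60
right-stance steps per participant and speed after a one-minute warm-up,
markers at 200 Hz, ten 6-axis IMUs at 100 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import yaml

from .errors import ConfigurationError
from .types import DEFAULT_SITES

KMH_TO_MS = 1.0 / 3.6  # exact km/h -> m/s conversion
GRAVITY = 9.81  # m/s^2


@dataclass(frozen=True)
class GaitSimConfig:
    """Parameters of the kinematic treadmill-gait generator.

    Cadence defaults rise with belt speed, as in human walking; geometry
    defaults (step width, sway, CoM height) are typical young-adult values.
    """

    n_participants: int = 8
    speeds_kmh: Tuple[float, ...] = (2.5, 3.0, 3.5)
    steps_per_foot_per_speed: int = 60
    #: cadence (single steps per second) per belt speed
    step_frequency_hz: Dict[float, float] = field(
        default_factory=lambda: {2.5: 1.60, 3.0: 1.75, 3.5: 1.90}
    )
    step_width_m: float = 0.22  # lateral toe-to-toe separation
    sway_amplitude_m: float = 0.015  # CoM lateral oscillation amplitude
    com_height_m: float = 0.95  # mean CoM height above the belt
    marker_rate_hz: float = 200.0
    imu_rate_hz: float = 100.0
    sites: Tuple[str, ...] = DEFAULT_SITES
    n_latent: int = 3
    noise_sd_accel: float = 0.05  # m/s^2
    noise_sd_gyro: float = 0.02  # rad/s
    seed: int = 0

    # --- stylized-gait details (not part of the study protocol) ---
    warmup_s: float = 60.0  # steps in the first minute are discarded
    hip_half_width_m: float = 0.12  # ASIS markers sit at CoM x +/- this
    toe_lead_m: float = 0.74  # toe anterior offset from CoM at heel contact
    stance_fraction: float = 0.6  # stance duration / stride duration
    swing_lift_m: float = 0.05  # peak toe height during swing
    #: slow sinusoidal modulators creating step-to-step MoS variability
    ml_mod_amplitude_m: float = 0.008
    ml_mod_freq_hz: float = 0.11
    ant_mod_amplitude_m: float = 0.02
    ant_mod_freq_hz: float = 0.07
    #: sites whose IMU mixtures have zero loading on the MoS-coupled latents
    uninformative_sites: Tuple[str, ...] = ("left_wrist", "skull_vertex")

    def __post_init__(self) -> None:
        if self.marker_rate_hz <= 0 or self.imu_rate_hz <= 0:
            raise ConfigurationError("sampling rates must be positive")
        if self.steps_per_foot_per_speed < 1:
            raise ConfigurationError("steps_per_foot_per_speed must be >= 1")
        if self.n_latent < 1:
            raise ConfigurationError("n_latent must be >= 1")
        if any(s <= 0 for s in self.speeds_kmh):
            raise ConfigurationError("belt speeds must be strictly positive")
        for s in self.speeds_kmh:
            if s not in self.step_frequency_hz:
                raise ConfigurationError(
                    f"no cadence configured for speed {s} km/h"
                )
            f = self.step_frequency_hz[s]
            if f <= 0:
                raise ConfigurationError("cadence must be positive")
            # a step must cover at least 4 marker samples to be resolvable
            if (1.0 / f) * self.marker_rate_hz < 4:
                raise ConfigurationError(
                    f"step period at {s} km/h shorter than 4 marker samples"
                )

    def step_period_s(self, speed_kmh: float) -> float:
        return 1.0 / self.step_frequency_hz[speed_kmh]

    def with_(self, **kwargs) -> "GaitSimConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class LatentLinearSpec:
    """Spec of the pure latent-linear generator X = C P^T + E, y = C b + e.

    ``loading_matrix`` (dim x n_latent) and ``coeffs`` (n_latent,) may be
    given explicitly; when None they are drawn once from the seeded RNG
    (Gaussian loadings, coefficients n_latent..1 descending).  Defaults give
    a signal-to-noise ratio around 10 on y.
    """

    n_samples: int = 480
    dim: int = 306
    n_latent: int = 3
    loading_matrix: Optional[np.ndarray] = None
    coeffs: Optional[np.ndarray] = None
    noise_sd_x: float = 0.1
    noise_sd_y: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2 or self.dim < 1 or self.n_latent < 1:
            raise ConfigurationError("n_samples/dim/n_latent out of range")
        if self.n_latent > min(self.n_samples, self.dim):
            raise ConfigurationError("n_latent exceeds min(n_samples, dim)")
        if self.loading_matrix is not None:
            P = np.asarray(self.loading_matrix, dtype=float)
            if P.shape != (self.dim, self.n_latent):
                raise ConfigurationError(
                    f"loading_matrix must be {(self.dim, self.n_latent)}, "
                    f"got {P.shape}"
                )
            if np.linalg.matrix_rank(P) < self.n_latent:
                raise ConfigurationError(
                    "loading_matrix columns must be linearly independent"
                )
            object.__setattr__(self, "loading_matrix", P)
        if self.coeffs is not None:
            b = np.asarray(self.coeffs, dtype=float)
            if b.shape != (self.n_latent,):
                raise ConfigurationError(
                    f"coeffs must have shape {(self.n_latent,)}, got {b.shape}"
                )
            object.__setattr__(self, "coeffs", b)
        if self.noise_sd_x < 0 or self.noise_sd_y < 0:
            raise ConfigurationError("noise SDs must be >= 0")


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings (paths + analysis knobs) for the CLI."""

    markers: Optional[Path] = None
    imu_dir: Optional[Path] = None
    events: Optional[Path] = None
    out_dir: Path = Path("gaitmos_out")
    belt_speed_kmh: float = 3.0
    sites: Tuple[str, ...] = DEFAULT_SITES
    support_foot: str = "left"
    direction: str = "anterior"
    n_components: Optional[int] = None  # fixed L; None -> tune over l_range
    l_range: Tuple[int, int] = (1, 10)
    k_folds: int = 10
    repetitions: int = 5
    base_seed: int = 0
    pls_variant: str = "as_printed"
    refractory_s: float = 0.3
    n_grid: int = 51

    def __post_init__(self) -> None:
        if self.n_grid < 2:
            raise ConfigurationError("interpolation grid size must be >= 2")
        if self.k_folds < 2:
            raise ConfigurationError("k_folds must be >= 2")
        if self.support_foot not in ("left", "right"):
            raise ConfigurationError("support_foot must be left|right")
        if self.direction not in ("anterior", "mediolateral"):
            raise ConfigurationError(
                "direction must be anterior|mediolateral"
            )
        if self.pls_variant not in ("as_printed", "nipals"):
            raise ConfigurationError("pls_variant must be as_printed|nipals")


def load_pipeline_config(path: Path | str) -> PipelineConfig:
    """Read a YAML pipeline config; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    allowed = set(PipelineConfig.__dataclass_fields__)
    unknown = sorted(set(raw) - allowed)
    if unknown:
        raise ConfigurationError(f"unknown config keys: {', '.join(unknown)}")
    for key in ("markers", "imu_dir", "events", "out_dir"):
        if key in raw and raw[key] is not None:
            raw[key] = Path(raw[key])
    for key in ("sites", "l_range"):
        if key in raw and raw[key] is not None:
            raw[key] = tuple(raw[key])
    return PipelineConfig(**raw)
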