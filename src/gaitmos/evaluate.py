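"""Cross-validated evaluation, component-count tuning, placement grids.

The evaluation protocol: stratified 10-fold cross-validation where, within
each (participant, speed) stratum, samples are shuffled and dealt
round-robin to folds (fold sizes within a stratum differ by at most one);
the whole procedure is repeated (default five times) with different random
assignments, and RMSE / Pearson correlation between predicted and
reference minimum MoS are summarized as mean +/- sd over the
k x repetitions fold-level values.  The number of principal motions L is
tuned over 1..10 by the same procedure, picking the smallest mean RMSE
(ties broken toward smaller L).  The placement grid evaluates every single
site and every unordered pair of sites for one support foot and one MoS
direction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DataError
from .featurize import build_design_matrix
from .pma import PMARegressor
from .types import DesignMatrix, StepSample

log = logging.getLogger(__name__)


def rmse(y_hat, y) -> float:
    """Root mean squared error between predictions and reference."""
    y_hat = np.asarray(y_hat, dtype=float)
    y = np.asarray(y, dtype=float)
    if y_hat.shape != y.shape or y.size == 0:
        raise DataError("rmse: inputs must be equal-length and nonempty")
    return float(np.sqrt(np.mean((y_hat - y) ** 2)))


def pearson(y_hat, y) -> float:
    """Pearson correlation; NaN (with a warning) if either input is constant."""
    y_hat = np.asarray(y_hat, dtype=float)
    y = np.asarray(y, dtype=float)
    if y_hat.shape != y.shape or y.size < 3:
        raise DataError("pearson: need equal-length inputs with >= 3 samples")
    if np.ptp(y_hat) == 0 or np.ptp(y) == 0:
        warnings.warn(
            "pearson: constant input, correlation undefined", stacklevel=2
        )
        return float("nan")
    return float(stats.pearsonr(y_hat, y).statistic)


@dataclass
class FoldAssignment:
    """Per-sample fold indices for one repetition."""

    folds: np.ndarray  # (n,) ints in 0..k-1
    k: int
    seed: int

    def indices(self, fold: int) -> Tuple[np.ndarray, np.ndarray]:
        test = np.nonzero(self.folds == fold)[0]
        train = np.nonzero(self.folds != fold)[0]
        return train, test


def make_folds(meta: pd.DataFrame, k: int = 10, seed: int = 0) -> FoldAssignment:
    """Stratified fold assignment.

    Within every (participant, speed_kmh) stratum the samples are shuffled
    by the seeded RNG and dealt round-robin to the k folds, so per-stratum
    fold sizes differ by at most one.
    """
    n = len(meta)
    if k < 2:
        raise ConfigurationError("k must be >= 2")
    if k > n:
        raise ConfigurationError(f"k={k} exceeds the {n} available samples")
    rng = np.random.default_rng(seed)
    folds = np.empty(n, dtype=int)
    strata = meta.groupby(["participant", "speed_kmh"], sort=True).indices
    for key in sorted(strata):
        idx = np.asarray(strata[key])
        if idx.size == 0:
            raise ConfigurationError(f"empty stratum {key}")
        perm = rng.permutation(idx)
        folds[perm] = np.arange(perm.size) % k
    return FoldAssignment(folds=folds, k=k, seed=seed)


@dataclass
class CvResult:
    """Fold-level RMSE (mm) and correlation with mean +/- sd summaries."""

    rmse_values: np.ndarray  # (k * repetitions,)
    corr_values: np.ndarray
    k: int
    repetitions: int
    L: int

    @property
    def rmse_mean(self) -> float:
        return float(np.mean(self.rmse_values))

    @property
    def rmse_sd(self) -> float:
        return float(np.std(self.rmse_values, ddof=1))

    @property
    def corr_mean(self) -> float:
        return float(np.nanmean(self.corr_values))

    @property
    def corr_sd(self) -> float:
        return float(np.nanstd(self.corr_values, ddof=1))


def cross_validate(
    dm: DesignMatrix,
    L: int,
    k: int = 10,
    repetitions: int = 5,
    base_seed: int = 0,
    variant: str = "as_printed",
) -> CvResult:
    """Repeated stratified k-fold CV of a PMA model with fixed L.

    Centring statistics are recomputed inside every training fold; the
    repetition r uses seed ``base_seed + r``.
    """
    if len(dm) == 0:
        raise DataError("cross_validate: empty design matrix")
    if L < 1:
        raise ConfigurationError("L must be >= 1")
    rmses: List[float] = []
    corrs: List[float] = []
    for r in range(repetitions):
        fa = make_folds(dm.meta, k=k, seed=base_seed + r)
        for fold in range(k):
            train, test = fa.indices(fold)
            if train.size < 2:
                raise ConfigurationError(
                    f"fold {fold} (rep {r}) leaves {train.size} training "
                    "samples"
                )
            model = PMARegressor(n_components=L, variant=variant)
            model.fit(dm.X[train], dm.y[train])
            y_hat = model.predict(dm.X[test])
            rmses.append(rmse(y_hat, dm.y[test]))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                corrs.append(
                    pearson(y_hat, dm.y[test])
                    if test.size >= 3
                    else float("nan")
                )
    return CvResult(
        rmse_values=np.asarray(rmses),
        corr_values=np.asarray(corrs),
        k=k,
        repetitions=repetitions,
        L=L,
    )


def select_L(
    dm: DesignMatrix,
    L_range: Sequence[int] = range(1, 11),
    k: int = 10,
    repetitions: int = 5,
    base_seed: int = 0,
    variant: str = "as_printed",
) -> Tuple[int, Dict[int, float]]:
    """Tune the component count: smallest mean CV RMSE, ties to smaller L.

    One model with L_max components is fitted per fold and evaluated at
    every L on its prediction path, so the sweep costs one fit per fold.
    """
    L_values = sorted(int(L) for L in L_range)
    if not L_values or L_values[0] < 1:
        raise ConfigurationError("L_range must contain integers >= 1")
    L_max = L_values[-1]
    sums = {L: [] for L in L_values}
    for r in range(repetitions):
        fa = make_folds(dm.meta, k=k, seed=base_seed + r)
        for fold in range(k):
            train, test = fa.indices(fold)
            if train.size < 2:
                raise ConfigurationError(
                    f"fold {fold} (rep {r}) leaves {train.size} training "
                    "samples"
                )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = PMARegressor(n_components=L_max, variant=variant)
                model.fit(dm.X[train], dm.y[train])
                path = model.predict_path(dm.X[test])
            for L in L_values:
                # early-stopped models keep their last available column
                col = min(L, model.n_components_) - 1
                sums[L].append(rmse(path[:, col], dm.y[test]))
    mean_rmse = {L: float(np.mean(v)) for L, v in sums.items()}
    best = min(L_values, key=lambda L: (mean_rmse[L], L))
    log.info("select_L: best L=%d (mean RMSE %.4f)", best, mean_rmse[best])
    return best, mean_rmse


@dataclass
class PlacementGrid:
    """CV summaries for all single sites and site pairs (triangular grid)."""

    sites: Tuple[str, ...]
    support_foot: str
    direction: str
    cells: Dict[Tuple[str, str], CvResult] = field(default_factory=dict)

    def cell(self, a: str, b: Optional[str] = None) -> CvResult:
        key = (a, a) if b is None else tuple(sorted((a, b)))
        return self.cells[key]

    def to_frame(self) -> pd.DataFrame:
        """Tidy rows, deterministic order: sites sorted, pairs lexicographic."""
        rows = []
        for key in sorted(self.cells):
            res = self.cells[key]
            rows.append(
                {
                    "site_a": key[0],
                    "site_b": key[1],
                    "support_foot": self.support_foot,
                    "direction": self.direction,
                    "n_sensors": 1 if key[0] == key[1] else 2,
                    "L": res.L,
                    "rmse_mean_mm": res.rmse_mean,
                    "rmse_sd_mm": res.rmse_sd,
                    "corr_mean": res.corr_mean,
                    "corr_sd": res.corr_sd,
                }
            )
        columns = [
            "site_a",
            "site_b",
            "support_foot",
            "direction",
            "n_sensors",
            "L",
            "rmse_mean_mm",
            "rmse_sd_mm",
            "corr_mean",
            "corr_sd",
        ]
        return pd.DataFrame(rows, columns=columns)


def placement_grid(
    samples: Sequence[StepSample],
    sites: Sequence[str],
    support_foot: str,
    direction: str,
    L: int,
    k: int = 10,
    repetitions: int = 5,
    base_seed: int = 0,
    variant: str = "as_printed",
) -> PlacementGrid:
    """Evaluate every single site and unordered pair by repeated CV.

    With 10 sites this yields 10 + C(10, 2) = 55 cells per (support foot,
    direction).
    """
    sites = tuple(sites)
    if len(sites) < 2:
        raise ConfigurationError("placement_grid needs at least 2 sites")
    samples = [s for s in samples if s.support_foot == support_foot]
    if not samples:
        raise DataError(f"no {support_foot}-support step samples")
    for s in samples:
        missing = [site for site in sites if site not in s.arrays]
        if missing:
            raise DataError(
                f"site {missing[0]!r} missing from step sample "
                f"(participant {s.participant}, step {s.step_index})"
            )
    grid = PlacementGrid(
        sites=sites, support_foot=support_foot, direction=direction
    )
    combos = [(s, s) for s in sites] + list(combinations(sites, 2))
    for a, b in combos:
        site_set = (a,) if a == b else (a, b)
        dm = build_design_matrix(samples, site_set, direction)
        res = cross_validate(
            dm, L=L, k=k, repetitions=repetitions, base_seed=base_seed,
            variant=variant,
        )
        grid.cells[tuple(sorted((a, b)))] = res
        log.info(
            "grid cell %s: RMSE %.2f +/- %.2f mm",
            "+".join(site_set),
            res.rmse_mean,
            res.rmse_sd,
        )
    return grid


def categorize_mos(value: float, ref_mean: float, ref_sd: float) -> str:
    """SD-band category of a minimum-MoS value against a reference cohort.

    Only low values are risky (smaller MoS = less stable): within one sd
    below the mean is ``typical``, between one and two sd below is
    ``cautionary``, below two sd is ``high_risk``.
    """
    if ref_sd <= 0:
        raise DataError("categorize_mos: ref_sd must be > 0")
    if value >= ref_mean - ref_sd:
        return "typical"
    if value >= ref_mean - 2.0 * ref_sd:
        return "cautionary"
    return "high_risk"
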