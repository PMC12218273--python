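"""Detection-limit statistics for dilution studies.

A dilution study measures the mutant/wild-type relative intensity R over
a grid of prepared VAFs (including 0%) with several replicates each.
The detection threshold is the mean plus three sample standard
deviations of the 0%-VAF replicates; the detection limit is the smallest
prepared VAF at which every replicate exceeds the threshold, with the
additional consistency requirement that all replicates at every larger
grid VAF exceed it as well.

The map from a ratio R to a measured VAF is v = 100 R / (1 + R): the
mutant fraction of the combined mutant + wild-type signal.  It is
bounded on [0, 100), symmetric at R = 1 (v = 50%), and linear for small
R, matching the observed behaviour below 5%.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections import Counter
from typing import Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class DilutionStudy:
    """Replicate-by-VAF relative-intensity matrix for one mutation.

    ``vaf_grid`` holds prepared VAFs as fractions, sorted ascending and
    including 0; ``R_matrix`` has shape (len(vaf_grid), replicates).
    """

    mutation: str
    vaf_grid: tuple[float, ...]
    replicates: int
    R_matrix: np.ndarray

    def __post_init__(self) -> None:
        grid = tuple(float(v) for v in self.vaf_grid)
        if list(grid) != sorted(grid):
            raise ValueError("vaf_grid must be sorted ascending")
        R = np.asarray(self.R_matrix, dtype=float)
        if R.shape != (len(grid), self.replicates):
            raise ValueError(
                f"R_matrix shape {R.shape} != "
                f"({len(grid)}, {self.replicates})"
            )
        if not np.all(np.isfinite(R)):
            raise ValueError("R_matrix must be complete and finite")
        object.__setattr__(self, "vaf_grid", grid)
        object.__setattr__(self, "R_matrix", R)

    def baseline(self) -> np.ndarray:
        if 0.0 not in self.vaf_grid:
            raise ValueError("study grid lacks a 0% VAF row")
        return self.R_matrix[self.vaf_grid.index(0.0)]


@dataclass(frozen=True)
class CalibrationCurve:
    """Least-squares line of measured VAF (%) on prepared VAF (%)."""

    slope: float
    intercept: float
    residual_sd: float


@dataclass(frozen=True)
class LoDStudyResult:
    threshold: float
    detection_limit: float | None  # prepared VAF fraction; None = not reached
    pass_pattern: tuple[bool, ...]  # per positive grid VAF: all replicates > T

    @property
    def detection_limit_percent(self) -> float | None:
        return None if self.detection_limit is None else 100 * self.detection_limit


def measured_vaf(R: float) -> float:
    """Measured VAF in percent from a relative intensity R >= 0."""
    if R < 0:
        raise ValueError(f"relative intensity must be nonnegative, got {R}")
    return 100.0 * R / (1.0 + R)


def compute_threshold(baseline_R: Sequence[float]) -> float:
    """Mutation-presence threshold: mean + 3 sample SD of 0%-VAF replicates."""
    r = np.asarray(baseline_R, dtype=float)
    if r.size < 2:
        raise ValueError("need at least 2 baseline replicates")
    return float(r.mean() + 3.0 * r.std(ddof=1))


def detection_limit(
    study: DilutionStudy, threshold: float | None = None
) -> LoDStudyResult:
    """Smallest prepared VAF at which every replicate exceeds the threshold.

    Exceedance is strict; ties at the threshold fail.  The limit must
    also hold consistently: every replicate at every larger grid VAF
    must exceed the threshold too.  Returns ``detection_limit=None``
    ("not reached") when no grid VAF qualifies.
    """
    T = compute_threshold(study.baseline()) if threshold is None else threshold
    positive = [(i, v) for i, v in enumerate(study.vaf_grid) if v > 0]
    passes = tuple(
        bool(np.all(study.R_matrix[i] > T)) for i, _ in positive
    )
    limit = None
    for k, (_, v) in enumerate(positive):
        if all(passes[k:]):
            limit = v
            break
    return LoDStudyResult(threshold=T, detection_limit=limit, pass_pattern=passes)


def fit_calibration(
    study: DilutionStudy, clip_negative: bool = True
) -> CalibrationCurve:
    """OLS fit of per-replicate measured VAF (%) on prepared VAF (%).

    Baseline noise can push R slightly negative; with ``clip_negative``
    those values are clamped to 0 before the VAF map (the map itself
    rejects negatives).
    """
    if len(set(study.vaf_grid)) < 2:
        raise ValueError("calibration needs >= 2 distinct prepared VAFs")
    x, y = [], []
    for i, v in enumerate(study.vaf_grid):
        for R in study.R_matrix[i]:
            if R < 0:
                if not clip_negative:
                    raise ValueError("negative R with clip_negative=False")
                R = 0.0
            x.append(100.0 * v)
            y.append(measured_vaf(R))
    fit = stats.linregress(x, y)
    resid = np.asarray(y) - (fit.slope * np.asarray(x) + fit.intercept)
    dof = max(len(x) - 2, 1)
    return CalibrationCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        residual_sd=float(np.sqrt((resid**2).sum() / dof)),
    )


def vaf_threshold_from_R_threshold(
    threshold: float, curve: CalibrationCurve
) -> float:
    """Map an R-scale threshold to the prepared-VAF scale (percent).

    The threshold is converted to a measured VAF, then the calibration
    line ``measured = slope * prepared + intercept`` is inverted.
    """
    if curve.slope <= 0:
        raise ValueError("calibration curve not invertible (slope <= 0)")
    return (measured_vaf(threshold) - curve.intercept) / curve.slope


def simulate_dilution_study(
    mutation: str = "KRAS-G12D",
    vaf_grid: Sequence[float] = (0.0, 0.001, 0.005, 0.01, 0.05),
    replicates: int = 8,
    noise_sd: float = 0.0008,
    seed: int = 0,
) -> DilutionStudy:
    """Generate a study under the additive-noise model R = v + N(0, sigma).

    ``vaf_grid`` is in fractions; the default grid and 8 replicates match
    the control-DNA dilution protocol (0, 0.1, 0.5, 1, 5%).
    """
    rng = np.random.default_rng(seed)
    grid = tuple(float(v) for v in vaf_grid)
    R = np.array(grid)[:, None] + rng.normal(
        0.0, noise_sd, size=(len(grid), replicates)
    )
    return DilutionStudy(
        mutation=mutation, vaf_grid=grid, replicates=replicates, R_matrix=R
    )


def modal_detection_limit(
    noise_sd: float,
    n_seeds: int = 100,
    base_seed: int = 0,
    vaf_grid: Sequence[float] = (0.0, 0.001, 0.005, 0.01, 0.05),
    replicates: int = 8,
) -> float | None:
    """Most frequent detection limit over independently seeded studies.

    Returns the modal prepared-VAF fraction (or None if "not reached"
    is modal).  Seeds are ``base_seed + k`` for k in [0, n_seeds).
    """
    limits = []
    for k in range(n_seeds):
        study = simulate_dilution_study(
            vaf_grid=vaf_grid,
            replicates=replicates,
            noise_sd=noise_sd,
            seed=base_seed + k,
        )
        limits.append(detection_limit(study).detection_limit)
    counts = Counter(limits)
    return counts.most_common(1)[0][0]
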