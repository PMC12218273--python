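"""Spectral deconvolution of binned CCD signals into dye intensities.

Each dye's emission is dispersed over the 20 spectral binning regions of a
capillary, so neighbouring dyes leak into each other's bands ("pull-up").
Given a region x dye response matrix ``M`` (columns sum to one), the dye
vector ``d`` for one scan is recovered from the 20-region signal ``s`` by
ordinary least squares, ``min ||M d - s||^2``, solved through the
pseudo-inverse.  Negative solutions are kept by default so that baseline
noise statistics downstream remain unbiased.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

from .config import N_DYES, SW_REGIONS


@dataclass(frozen=True)
class SpectralMatrix:
    """Nonnegative region x dye response weights; columns sum to 1."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[1] != N_DYES:
            raise ValueError(f"expected a (n_regions, {N_DYES}) matrix")
        if np.any(w < 0):
            raise ValueError("spectral weights must be nonnegative")
        colsum = w.sum(axis=0)
        if not np.allclose(colsum, 1.0, atol=1e-8):
            raise ValueError("each dye column must sum to 1")
        if np.linalg.matrix_rank(w) < N_DYES:
            raise ValueError(
                "spectral matrix is rank deficient "
                f"(condition number {np.linalg.cond(w):.3g})"
            )
        object.__setattr__(self, "weights", w)

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]

    def condition_number(self) -> float:
        return float(np.linalg.cond(self.weights))


def make_dye_spectra(
    centers=(2.5, 7.5, 12.5, 17.5),
    widths=2.5,
    n_regions: int = SW_REGIONS,
) -> SpectralMatrix:
    """Build discretised Gaussian dye spectra, column-normalised.

    ``centers`` are spectral-region coordinates of each dye's emission
    maximum; ``widths`` a scalar or per-dye sequence of Gaussian SDs in
    region units.  Identical (center, width) pairs produce duplicate
    columns and are rejected as rank deficient.
    """
    centers = np.asarray(centers, dtype=float)
    widths = np.broadcast_to(np.asarray(widths, dtype=float), centers.shape)
    if centers.shape != (N_DYES,):
        raise ValueError(f"need exactly {N_DYES} dye centers")
    if np.any(widths <= 0):
        raise ValueError("widths must be positive")
    if np.any(centers < 0) or np.any(centers > n_regions - 1):
        raise ValueError("centers must lie within the region range")
    r = np.arange(n_regions, dtype=float)[:, None]
    w = np.exp(-((r - centers[None, :]) ** 2) / (2.0 * widths[None, :] ** 2))
    w /= w.sum(axis=0, keepdims=True)
    return SpectralMatrix(w)


def deconvolve(trace, matrix: SpectralMatrix, nonnegative: bool = False):
    """Deconvolve a :class:`~hidyce.binning.BinnedTrace` into dye signals.

    Returns a :class:`~hidyce.binning.DyeTrace` whose per-scan saturation
    flag is the OR of the source trace's region flags (a clipped region
    biases every dye estimate at that scan).
    """
    from .binning import DyeTrace  # local import to avoid a cycle

    M = matrix.weights
    signals = np.asarray(trace.signals, dtype=float)
    if signals.shape[-1] != M.shape[0]:
        raise ValueError(
            f"trace has {signals.shape[-1]} regions but matrix expects "
            f"{M.shape[0]}"
        )
    if nonnegative:
        flat = signals.reshape(-1, M.shape[0])
        out = np.empty((flat.shape[0], N_DYES))
        for i, s in enumerate(flat):
            out[i] = nnls(M, np.maximum(s, 0.0))[0]
        intensities = out.reshape(signals.shape[:-1] + (N_DYES,))
    else:
        pinv = np.linalg.pinv(M)
        intensities = signals @ pinv.T
    saturated = np.asarray(trace.saturated, dtype=bool).any(axis=-1)
    return DyeTrace(intensities=intensities, saturated=saturated)
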