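"""Synthetic CCD pixel-frame generator.

Produces the raw material every downstream stage consumes: per-scan
photoelectron counts over the 240 3x1-pixel regions of each capillary.
Alleles are Gaussian peaks in scan index whose dye-space amplitude is
spread over the spectral regions by the dye-response matrix; loading
scales linearly with injection voltage x time relative to the 1.6 kV / 9 s
reference.  Background noise has variance ``sigma_b^2`` per 3x12 region
per scan, apportioned equally (``sigma_b^2/12``) over its twelve 3x1
regions; optional Poisson shot noise acts on the expected counts.
Readout noise belongs to acquisition (:func:`hidyce.binning.acquire`),
not here, because the number of readout events differs between modes.

All values are pre-readout and unclipped; saturation is applied by the
binning stage.  Every stochastic path is driven by an explicit seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .config import (
    AlleleSpec,
    InstrumentConfig,
    SamplePlan,
    SW_GROUP,
    validate_plan,
)
from .spectral import SpectralMatrix, make_dye_spectra


@dataclass(frozen=True)
class PixelFrameSeries:
    """Pre-readout photoelectron counts, shape (scan, capillary, 240)."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "counts", np.asarray(self.counts, dtype=float)
        )
        if self.counts.ndim != 3:
            raise ValueError("counts must be (scan, capillary, region)")

    @property
    def scan_count(self) -> int:
        return self.counts.shape[0]


def voltage_scale(config: InstrumentConfig) -> float:
    """Loading factor relative to the reference injection.

    The amount of sample electrokinetically loaded is modelled as linear
    in injection voltage x time, so 4.8 kV / 9 s loads 3x the reference
    1.6 kV / 9 s.
    """
    v_ref, t_ref = config.reference_injection
    if v_ref <= 0 or t_ref <= 0:
        raise ValueError("reference injection must be positive")
    return (config.injection_voltage_kv * config.injection_time_s) / (
        v_ref * t_ref
    )


def _hw_spectrum(config: InstrumentConfig) -> np.ndarray:
    """Per-hardware-region dye weights: each software-region weight is
    split evenly over its twelve 3x1 columns, so software sums recover the
    20x4 matrix exactly."""
    if config.spectral_matrix is not None:
        M = SpectralMatrix(np.asarray(config.spectral_matrix, float))
    else:
        M = make_dye_spectra()
    return np.repeat(M.weights, SW_GROUP, axis=0) / SW_GROUP


def expected_frames(
    config: InstrumentConfig, plan: SamplePlan
) -> np.ndarray:
    """Noise-free expected counts, shape (scan, capillary, 240)."""
    validate_plan(config, plan)
    w = _hw_spectrum(config)
    n_reg = w.shape[0]
    vs = voltage_scale(config)
    t = np.arange(config.scan_count, dtype=float)
    expected = np.zeros((config.scan_count, config.n_capillaries, n_reg))
    for allele, vaf in plan.alleles:
        profile = (
            allele.amplitude_per_unit_vaf
            * vaf
            * vs
            * np.exp(
                -((t - allele.peak_position) ** 2)
                / (2.0 * allele.peak_sigma**2)
            )
        )
        expected[:, plan.capillary, :] += np.outer(
            profile, w[:, allele.dye_channel]
        )
    expected += config.background_mean / SW_GROUP
    return expected


def simulate_pixel_frames(
    config: InstrumentConfig,
    plan: SamplePlan,
    seed: int | None = None,
) -> PixelFrameSeries:
    """Simulate one run's pixel frames.

    ``seed`` overrides ``plan.seed`` when given.  Deterministic for a
    fixed seed; with both noise terms zero and shot noise off the output
    equals :func:`expected_frames` exactly.
    """
    expected = expected_frames(config, plan)
    rng = np.random.default_rng(plan.seed if seed is None else seed)
    counts = expected
    if config.shot_noise:
        counts = rng.poisson(np.maximum(expected, 0.0)).astype(float)
    if config.background_noise_sd > 0:
        counts = counts + rng.normal(
            0.0,
            config.background_noise_sd / np.sqrt(SW_GROUP),
            size=expected.shape,
        )
    return PixelFrameSeries(counts=counts)


def make_control_run(
    config: InstrumentConfig,
    panel: Sequence[AlleleSpec],
    control_vaf: float = 0.25,
    seed: int | None = None,
) -> PixelFrameSeries:
    """Simulate the control sample used for allele registration.

    Every panel allele is loaded at the same moderate VAF so that each
    produces a clear, unsaturating peak; in the noise-free case the apex
    of each peak sits exactly at its configured position.  Peaks closer
    than 3x the wider sigma on a shared dye channel make registration
    ambiguous and raise a warning.
    """
    if not 0 < control_vaf <= 1:
        raise ValueError("control_vaf must be in (0, 1]")
    specs = list(panel)
    for i, a in enumerate(specs):
        for b in specs[i + 1:]:
            if a.dye_channel == b.dye_channel and abs(
                a.peak_position - b.peak_position
            ) < 3 * max(a.peak_sigma, b.peak_sigma):
                warnings.warn(
                    f"alleles {a.name} and {b.name} are closer than 3 sigma "
                    "on the same dye channel; registration may be ambiguous",
                    stacklevel=2,
                )
    plan = SamplePlan(
        alleles=tuple((a, control_vaf) for a in specs),
        capillary=0,
        seed=0 if seed is None else seed,
    )
    return simulate_pixel_frames(config, plan, seed=seed)
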