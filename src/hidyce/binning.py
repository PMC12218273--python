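"""CCD binning modes: conventional hardware binning versus HiDy.

Conventional acquisition digitises charge in 20 hardware regions of 3x12
pixels per capillary: the twelve columns of a group are summed *on chip*,
so the group saturates at one full-well capacity ``S`` and receives one
readout-noise draw.  HiDy digitises 240 hardware regions of 3x1 pixels —
each clipping independently at the same ``S`` and each paying its own
readout-noise draw — then sums groups of twelve in software.  A HiDy
software region therefore holds up to ``12 S``, at the cost of twelve
readout events instead of one.

Defining dynamic range as capacity over baseline-noise SD per software
region, the HiDy : conventional ratio is

    12 * sqrt((sigma_r^2 + sigma_b^2) / (12 sigma_r^2 + sigma_b^2))

which ranges from sqrt(12) (readout-dominated) to 12 (background-
dominated) and equals 8.09 at the default background/readout variance
ratio of 8.163.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import InstrumentConfig, SW_GROUP, SW_REGIONS


@dataclass(frozen=True)
class BinningMode:
    """Acquisition geometry: (hardware regions, software group size)."""

    name: str
    hw_regions_per_capillary: int
    sw_group_size: int

    def __post_init__(self) -> None:
        valid = {
            "conventional": (SW_REGIONS, 1),
            "hidy": (SW_REGIONS * SW_GROUP, SW_GROUP),
        }
        if self.name not in valid:
            raise ValueError(f"unknown binning mode {self.name!r}")
        if (self.hw_regions_per_capillary, self.sw_group_size) != valid[self.name]:
            raise ValueError(
                f"{self.name} mode requires geometry {valid[self.name]}"
            )

    @classmethod
    def conventional(cls) -> "BinningMode":
        return cls("conventional", SW_REGIONS, 1)

    @classmethod
    def hidy(cls) -> "BinningMode":
        return cls("hidy", SW_REGIONS * SW_GROUP, SW_GROUP)

    @classmethod
    def from_name(cls, name: str) -> "BinningMode":
        return cls.hidy() if name == "hidy" else cls("conventional", 20, 1)

    def capacity(self, full_well: float) -> float:
        """Saturation capacity of one software region in this mode."""
        return full_well * (SW_GROUP if self.name == "hidy" else 1)


@dataclass(frozen=True)
class BinnedTrace:
    """Per-scan signals of the 20 software regions per capillary.

    ``signals`` has shape (scan, capillary, 20); ``saturated`` flags a
    region whenever at least one contributing hardware bin clipped (the
    sum is then biased low).
    """

    signals: np.ndarray
    saturated: np.ndarray
    mode: BinningMode

    def __post_init__(self) -> None:
        s = np.asarray(self.signals, dtype=float)
        f = np.asarray(self.saturated, dtype=bool)
        if s.shape != f.shape:
            raise ValueError("signals and saturation flags must align")
        object.__setattr__(self, "signals", s)
        object.__setattr__(self, "saturated", f)

    @property
    def scan_count(self) -> int:
        return self.signals.shape[0]


@dataclass(frozen=True)
class DyeTrace:
    """Electropherogram: per-scan, per-capillary intensities of the 4 dyes.

    ``intensities`` has shape (scan, capillary, 4); ``saturated`` is the
    scan-level flag (scan, capillary) carried forward from acquisition.
    """

    intensities: np.ndarray
    saturated: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.intensities, dtype=float)
        if not np.all(np.isfinite(x)):
            raise ValueError("dye intensities must be finite")
        object.__setattr__(self, "intensities", x)
        object.__setattr__(
            self, "saturated", np.asarray(self.saturated, dtype=bool)
        )

    @property
    def scan_count(self) -> int:
        return self.intensities.shape[0]


def acquire(
    frames,
    mode: BinningMode,
    config: InstrumentConfig,
    seed: int | None = 0,
) -> BinnedTrace:
    """Digitise pixel frames under one binning mode.

    Conventional: sum each contiguous group of twelve 3x1 regions before
    readout, clip the sum at ``full_well``, add one readout-noise draw.
    HiDy: clip each 3x1 region at ``full_well``, add one readout-noise
    draw per region, then sum groups of twelve in software.  Readout
    noise applies to the already-saturated charge, hence is added after
    clipping.  ``seed=None`` disables readout noise (deterministic).
    """
    counts = np.asarray(frames.counts, dtype=float)
    n_scan, n_cap, n_reg = counts.shape
    if n_reg % SW_GROUP != 0:
        raise ValueError(
            f"region count {n_reg} not divisible by group size {SW_GROUP}"
        )
    n_sw = n_reg // SW_GROUP
    S = config.full_well
    rng = np.random.default_rng(seed) if seed is not None else None
    sigma_r = config.readout_noise_sd

    def readout(shape):
        if rng is None or sigma_r == 0:
            return 0.0
        return rng.normal(0.0, sigma_r, size=shape)

    grouped = counts.reshape(n_scan, n_cap, n_sw, SW_GROUP)
    if mode.name == "conventional":
        summed = grouped.sum(axis=-1)
        clipped = summed > S
        signals = np.minimum(summed, S) + readout(summed.shape)
        flags = clipped
    else:
        hw_clipped = grouped > S
        hw = np.minimum(grouped, S) + readout(grouped.shape)
        signals = hw.sum(axis=-1)
        flags = hw_clipped.any(axis=-1)
    return BinnedTrace(signals=signals, saturated=flags, mode=mode)


def capacity_ratio(mode_a: BinningMode, mode_b: BinningMode) -> float:
    """Ratio of per-software-region saturation capacities (a over b)."""
    return mode_a.capacity(1.0) / mode_b.capacity(1.0)


def dynamic_range_ratio(
    readout_noise_sd: float, background_noise_sd: float
) -> float:
    """HiDy : conventional dynamic-range ratio from the two noise terms.

    Both modes share the same background photon noise per software region
    (variance ``sigma_b^2``); conventional pays one readout (variance
    ``sigma_r^2``), HiDy pays twelve.  Capacity differs by 12x, so

        ratio = 12 sqrt((sigma_r^2 + sigma_b^2) / (12 sigma_r^2 + sigma_b^2))
    """
    vr = readout_noise_sd**2
    vb = background_noise_sd**2
    if vr < 0 or vb < 0:
        raise ValueError("noise SDs must be nonnegative")
    if vr == 0 and vb == 0:
        raise ValueError("dynamic-range ratio undefined for zero noise")
    return SW_GROUP * math.sqrt((vr + vb) / (SW_GROUP * vr + vb))


def baseline_noise_sd(mode: BinningMode, config: InstrumentConfig) -> float:
    """Analytic per-software-region baseline SD under ``mode``."""
    vr = config.readout_noise_sd**2
    vb = config.background_noise_sd**2
    n_readouts = SW_GROUP if mode.name == "hidy" else 1
    return math.sqrt(n_readouts * vr + vb)
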