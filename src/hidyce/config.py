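"""Instrument and sample-plan configuration.

The instrument model is a four-capillary CE sequencer whose fluorescence is
dispersed onto a CCD covering 3 x 240 pixels per capillary.  Charge is
digitised in hardware-binning regions of 3 x 1 pixels (240 per capillary);
the acquisition mode (see :mod:`hidyce.binning`) decides whether those are
read out individually (HiDy) or pre-summed on chip in groups of twelve
(conventional).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

#: Default ratio of background to readout noise *variance* per software
#: region.  With this ratio the analytic HiDy/conventional dynamic-range
#: ratio equals 8.09 (see :func:`hidyce.binning.dynamic_range_ratio`).
NOISE_VARIANCE_RATIO_DEFAULT = 8.163

#: Reference injection condition (kV, s): signals are expressed relative to
#: the loading obtained at 1.6 kV for 9 s.
REFERENCE_INJECTION = (1.6, 9.0)

N_DYES = 4
HW_REGIONS = 240
SW_REGIONS = 20
SW_GROUP = 12


@dataclass(frozen=True)
class InstrumentConfig:
    """Static description of one electrophoresis run.

    Parameters
    ----------
    full_well
        Saturation capacity of a single 3x1 hardware-binning region, in
        photoelectron counts.  Identical between acquisition modes.
    readout_noise_sd
        Noise added per analog-to-digital readout event (counts).
    background_noise_sd
        SD of the summed background of one 3x12 region per scan (counts);
        apportioned equally over its twelve 3x1 regions in the simulator.
    scan_count
        Number of CCD scans in the run (one per second; 1280 s run time).
    injection_voltage_kv, injection_time_s
        Electrokinetic injection condition; loaded signal scales linearly
        with voltage x time relative to ``reference_injection``.
    background_mean
        Mean background level per 3x12 region per scan (counts).
    shot_noise
        If True, Poisson shot noise is applied to the expected photoelectron
        counts (off by default so analytic tests are exact).
    spectral_matrix
        Optional 20x4 dye-response matrix used by the simulator; defaults to
        :func:`hidyce.spectral.make_dye_spectra` defaults when None.
    """

    n_capillaries: int = 4
    pixels_per_capillary: int = HW_REGIONS
    full_well: float = 30_000.0
    readout_noise_sd: float = 3.0
    background_noise_sd: float = 3.0 * math.sqrt(NOISE_VARIANCE_RATIO_DEFAULT)
    scan_count: int = 1280
    injection_voltage_kv: float = 1.6
    injection_time_s: float = 9.0
    reference_injection: tuple[float, float] = REFERENCE_INJECTION
    background_mean: float = 0.0
    shot_noise: bool = False
    spectral_matrix: "np.ndarray | None" = None

    def __post_init__(self) -> None:
        if self.full_well <= 0:
            raise ValueError("full_well must be positive")
        if self.readout_noise_sd < 0 or self.background_noise_sd < 0:
            raise ValueError("noise SDs must be nonnegative")
        if self.scan_count < 1:
            raise ValueError("scan_count must be >= 1")
        if self.injection_voltage_kv <= 0 or self.injection_time_s <= 0:
            raise ValueError("injection voltage and time must be positive")
        if self.n_capillaries < 1:
            raise ValueError("need at least one capillary")
        if self.pixels_per_capillary % SW_GROUP != 0:
            raise ValueError(
                f"pixels_per_capillary must be divisible by {SW_GROUP}"
            )

    def replace(self, **kwargs) -> "InstrumentConfig":
        d = asdict(self)
        d.pop("spectral_matrix")
        d.update({"spectral_matrix": self.spectral_matrix})
        d.update(kwargs)
        return InstrumentConfig(**d)

    def to_dict(self) -> dict:
        d = asdict(self)
        m = d.pop("spectral_matrix")
        if m is not None:
            d["spectral_matrix"] = np.asarray(m).tolist()
        d["reference_injection"] = list(self.reference_injection)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "InstrumentConfig":
        d = dict(d)
        if d.get("spectral_matrix") is not None:
            d["spectral_matrix"] = np.asarray(d["spectral_matrix"], float)
        if "reference_injection" in d:
            d["reference_injection"] = tuple(d["reference_injection"])
        return cls(**d)


@dataclass(frozen=True)
class AlleleSpec:
    """One allele resolved as a Gaussian peak on one dye channel.

    ``amplitude_per_unit_vaf`` is the dye-space apex signal (counts) the
    allele would produce at VAF 100% under the reference injection; the
    shifted-termination chemistry places wild-type and mutant products at
    distinct ``peak_position`` values.
    """

    name: str
    dye_channel: int
    peak_position: int
    peak_sigma: float
    amplitude_per_unit_vaf: float

    def __post_init__(self) -> None:
        if not 0 <= self.dye_channel < N_DYES:
            raise ValueError(f"dye_channel must be in [0, {N_DYES})")
        if self.peak_sigma <= 0:
            raise ValueError("peak_sigma must be positive")
        if self.amplitude_per_unit_vaf < 0:
            raise ValueError("amplitude_per_unit_vaf must be >= 0")
        if self.peak_position < 0:
            raise ValueError("peak_position must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AlleleSpec":
        return cls(**d)


@dataclass(frozen=True)
class SamplePlan:
    """Alleles loaded on one capillary with their true VAFs."""

    alleles: tuple[tuple[AlleleSpec, float], ...]
    capillary: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "alleles", tuple(
            (a, float(v)) for a, v in self.alleles
        ))
        for allele, vaf in self.alleles:
            if not 0.0 <= vaf <= 1.0:
                raise ValueError(f"VAF for {allele.name} outside [0, 1]")
        if self.capillary < 0:
            raise ValueError("capillary index must be >= 0")

    def to_dict(self) -> dict:
        return {
            "alleles": [[a.to_dict(), v] for a, v in self.alleles],
            "capillary": self.capillary,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SamplePlan":
        return cls(
            alleles=tuple(
                (AlleleSpec.from_dict(a), float(v)) for a, v in d["alleles"]
            ),
            capillary=int(d.get("capillary", 0)),
            seed=int(d.get("seed", 0)),
        )


def validate_plan(config: InstrumentConfig, plan: SamplePlan) -> None:
    """Reject plans referencing hardware the config does not have."""
    if plan.capillary >= config.n_capillaries:
        raise ValueError(
            f"plan capillary {plan.capillary} outside the "
            f"{config.n_capillaries}-capillary instrument"
        )
    for allele, _ in plan.alleles:
        if allele.peak_position >= config.scan_count:
            raise ValueError(
                f"allele {allele.name}: peak_position {allele.peak_position} "
                f"outside scan range [0, {config.scan_count})"
            )
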