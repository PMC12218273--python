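"""Allele peak registration and the +/-5-position quantification rule.

A control sample containing every allele is electrophoresed first; the
apex scan of each allele on its dye channel is recorded in a registry.
In target runs, an allele's signal intensity is the maximum of its dye
trace within +/-5 scan positions of the registered apex (an 11-scan
window, truncated at trace edges).  The variant allele ratio R is the
mutant over wild-type intensity; a saturated wild-type peak makes R
unreliable because the clipped denominator is biased low.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

from .binning import DyeTrace

#: Half-width of the quantification window, in scan positions.
WINDOW_HALF_WIDTH = 5


class RegistrationError(RuntimeError):
    """Raised when a dye channel shows fewer peaks than expected alleles."""


@dataclass(frozen=True)
class RegistryEntry:
    name: str
    dye_channel: int
    position: int


@dataclass(frozen=True)
class AlleleRegistry:
    """Registered apex positions; unique per (dye, position)."""

    entries: tuple[RegistryEntry, ...]

    def __post_init__(self) -> None:
        entries = tuple(self.entries)
        keys = [(e.dye_channel, e.position) for e in entries]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (dye, position) pairs in registry")
        object.__setattr__(self, "entries", entries)

    def __getitem__(self, name: str) -> RegistryEntry:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(name)

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class PeakMeasurement:
    """Signal intensity of one allele from the window-maximum rule."""

    allele: str
    intensity: float
    window: tuple[int, int]
    saturated: bool


@dataclass(frozen=True)
class RelativeIntensity:
    """Mutant / wild-type intensity ratio with a reliability marker."""

    value: float
    unreliable: bool = False


def register_alleles(
    control: DyeTrace,
    panel: Sequence[tuple[str, int]],
    capillary: int = 0,
    min_rel_height: float = 0.2,
) -> AlleleRegistry:
    """Locate each panel allele's apex in a control-run electropherogram.

    ``panel`` lists (allele name, dye channel) in nominal migration
    order per channel.  On each channel, local maxima at least
    ``min_rel_height`` of the channel maximum are found; the k most
    prominent (k = alleles expected on that channel) are assigned to the
    alleles in scan order.  Fewer maxima than alleles is a registration
    failure naming the channel.
    """
    entries: list[RegistryEntry] = []
    by_channel: dict[int, list[str]] = {}
    for name, dye in panel:
        by_channel.setdefault(dye, []).append(name)
    for dye, names in by_channel.items():
        y = control.intensities[:, capillary, dye]
        height = min_rel_height * float(y.max()) if y.max() > 0 else None
        peaks, props = find_peaks(y, height=height, prominence=0.0)
        if len(peaks) < len(names):
            raise RegistrationError(
                f"dye channel {dye}: found {len(peaks)} peaks for "
                f"{len(names)} alleles ({', '.join(names)})"
            )
        order = np.argsort(props["prominences"])[::-1][: len(names)]
        chosen = np.sort(peaks[order])
        for name, pos in zip(names, chosen):
            entries.append(RegistryEntry(name, dye, int(pos)))
    return AlleleRegistry(tuple(entries))


def measure_allele(
    trace: DyeTrace,
    entry: RegistryEntry,
    capillary: int = 0,
) -> PeakMeasurement:
    """Apply the +/-5-position maximum rule at a registered position.

    The window is truncated at trace boundaries; the saturation flag is
    the OR of the trace's scan-level flags across the window.  A window
    whose maximum is negative (pure baseline noise after deconvolution)
    is clamped to zero intensity.
    """
    n = trace.scan_count
    lo = entry.position - WINDOW_HALF_WIDTH
    hi = entry.position + WINDOW_HALF_WIDTH
    if hi < 0 or lo >= n:
        raise ValueError(
            f"window [{lo}, {hi}] entirely outside trace of {n} scans"
        )
    lo_c, hi_c = max(lo, 0), min(hi, n - 1)
    window = trace.intensities[lo_c : hi_c + 1, capillary, entry.dye_channel]
    intensity = float(window.max())
    saturated = bool(trace.saturated[lo_c : hi_c + 1, capillary].any())
    return PeakMeasurement(
        allele=entry.name,
        intensity=max(intensity, 0.0),
        window=(lo_c, hi_c),
        saturated=saturated,
    )


def relative_intensity(
    mt: PeakMeasurement, wt: PeakMeasurement
) -> RelativeIntensity:
    """R = mutant / wild-type intensity.

    Rejected when the wild-type intensity is not positive; returned with
    the ``unreliable`` marker when the wild-type window touched
    saturation, since a clipped denominator inflates R unpredictably.
    """
    if wt.intensity <= 0:
        raise ValueError(
            f"wild-type intensity {wt.intensity} not positive; "
            "cannot form MT/WT ratio"
        )
    return RelativeIntensity(
        value=mt.intensity / wt.intensity,
        unreliable=wt.saturated,
    )
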