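"""Named acquisition scenarios for the saturation comparison study.

Each preset reproduces one arm of the wild-type-saturation experiment: a
KRAS G12R assay whose wild-type product is far more abundant than the
0.1%-VAF mutant.  The wild-type dye-space amplitude is 22x the full-well
capacity of a single hardware-binning region, so at the standard 1.6 kV
injection its apex spectral region carries ~3.9x a conventional
hardware bin's capacity (clips) but only ~0.32x a HiDy software
region's (does not clip); at 4.8 kV the HiDy software region reaches
~0.97x capacity, still unsaturated, while the mutant signal is tripled.
"""

from __future__ import annotations

from dataclasses import dataclass

from .binning import BinningMode
from .config import AlleleSpec, InstrumentConfig, SamplePlan

#: Wild-type apex amplitude as a multiple of full-well capacity.
WT_AMPLITUDE_FULL_WELLS = 22.0

MT_POSITION = 610
WT_POSITION = 640
PEAK_SIGMA = 4.0
MT_VAF = 0.001


@dataclass(frozen=True)
class Scenario:
    name: str
    config: InstrumentConfig
    plan: SamplePlan
    mode: BinningMode

    @property
    def panel(self) -> tuple[AlleleSpec, ...]:
        return tuple(a for a, _ in self.plan.alleles)


def _kras_g12r_alleles(config: InstrumentConfig):
    amp = WT_AMPLITUDE_FULL_WELLS * config.full_well
    wt = AlleleSpec(
        name="KRAS-12-WT", dye_channel=0, peak_position=WT_POSITION,
        peak_sigma=PEAK_SIGMA, amplitude_per_unit_vaf=amp,
    )
    mt = AlleleSpec(
        name="KRAS-G12R-MT", dye_channel=0, peak_position=MT_POSITION,
        peak_sigma=PEAK_SIGMA, amplitude_per_unit_vaf=amp,
    )
    return wt, mt


def _scenario(name, voltage_kv, mode_name, mt_vaf=MT_VAF, seed=0) -> Scenario:
    config = InstrumentConfig(injection_voltage_kv=voltage_kv)
    wt, mt = _kras_g12r_alleles(config)
    plan = SamplePlan(
        alleles=((wt, 1.0 - mt_vaf), (mt, mt_vaf)), capillary=0, seed=seed
    )
    return Scenario(
        name=name, config=config, plan=plan,
        mode=BinningMode.from_name(mode_name),
    )


def fig1b_conventional_1p6kv(mt_vaf: float = MT_VAF, seed: int = 0) -> Scenario:
    """Standard 1.6 kV injection on conventional hardware binning."""
    return _scenario("fig1b_conventional_1p6kv", 1.6, "conventional", mt_vaf, seed)


def fig1b_hidy_1p6kv(mt_vaf: float = MT_VAF, seed: int = 0) -> Scenario:
    """Standard 1.6 kV injection under HiDy binning."""
    return _scenario("fig1b_hidy_1p6kv", 1.6, "hidy", mt_vaf, seed)


def fig1b_hidy_4p8kv(mt_vaf: float = MT_VAF, seed: int = 0) -> Scenario:
    """Boosted 4.8 kV injection under HiDy binning (3x loading)."""
    return _scenario("fig1b_hidy_4p8kv", 4.8, "hidy", mt_vaf, seed)


PRESETS = {
    "fig1b_conventional_1p6kv": fig1b_conventional_1p6kv,
    "fig1b_hidy_1p6kv": fig1b_hidy_1p6kv,
    "fig1b_hidy_4p8kv": fig1b_hidy_4p8kv,
}


def get_preset(name: str, **kwargs) -> Scenario:
    try:
        return PRESETS[name](**kwargs)
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
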