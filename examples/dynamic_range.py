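"""Dynamic-range gain of HiDy binning, analytic and empirical.

Builds a blank (signal-free) run, acquires it under both binning modes,
and compares the measured baseline noise with the closed-form model.
"""

import math

from hidyce import (
    BinningMode,
    InstrumentConfig,
    SamplePlan,
    acquire,
    baseline_noise_sd,
    capacity_ratio,
    dynamic_range_ratio,
    simulate_pixel_frames,
)
from hidyce.config import NOISE_VARIANCE_RATIO_DEFAULT

hidy, conv = BinningMode.hidy(), BinningMode.conventional()

print("capacity ratio (hidy/conventional):", capacity_ratio(hidy, conv))
analytic = dynamic_range_ratio(1.0, math.sqrt(NOISE_VARIANCE_RATIO_DEFAULT))
print(f"analytic dynamic-range ratio: {analytic:.4f}")

config = InstrumentConfig(scan_count=10_000, n_capillaries=1)
frames = simulate_pixel_frames(config, SamplePlan(alleles=(), seed=3))
sd = {}
for mode, seed in ((conv, 31), (hidy, 32)):
    trace = acquire(frames, mode, config, seed=seed)
    sd[mode.name] = trace.signals[:, 0, 0].std(ddof=1)
    print(
        f"{mode.name}: measured baseline SD {sd[mode.name]:.2f} counts "
        f"(model {baseline_noise_sd(mode, config):.2f})"
    )

print(
    "empirical dynamic-range ratio:",
    f"{capacity_ratio(hidy, conv) * sd['conventional'] / sd['hidy']:.2f}",
)
# The 12x capacity gain costs only ~1.5x extra baseline noise, so the
# usable signal range grows roughly eightfold.
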