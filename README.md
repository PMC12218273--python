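# hidyce

Simulation and analysis of **high-dynamic-range (HiDy) CCD binning** for
capillary electrophoresis (CE) fragment analysis, aimed at quantifying
low-frequency somatic mutations — KRAS codon 12/13 hotspots in particular —
from mutant/wild-type peak-intensity ratios.

## The problem

A four-capillary CE sequencer disperses fluorescence onto a CCD region of
3 × 240 pixels per capillary. Conventionally the charge is digitised in 20
hardware-binning regions of 3 × 12 pixels, each saturating at one full-well
capacity *S*. When a shifted-termination assay separates a wild-type (WT)
and a rare mutant (MT) product into two peaks, the abundant WT peak clips at
*S* long before the 0.1–1 %-VAF mutant rises above baseline, so the ratio
R = I_MT / I_WT — and hence the variant allele frequency (VAF) — cannot be
computed.

HiDy acquisition instead digitises 240 hardware regions of 3 × 1 pixels
(each still saturating at *S*) and sums them in software in groups of 12.
A software region then holds up to 12 *S*, at the cost of twelve
readout-noise draws instead of one. With readout noise σ_r and background
noise σ_b per software region, the dynamic-range gain is

    DR ratio = 12 · sqrt( (σ_r² + σ_b²) / (12 σ_r² + σ_b²) )  ∈ [√12, 12],

which equals **8.09** at the package default σ_b²/σ_r² = 8.163.

The package simulates the whole acquisition chain (Gaussian allele peaks,
voltage-scaled injection, spectral overlap between the four dyes,
background/readout noise, per-hardware-bin clipping), deconvolves the 20
spectral signals into 4 dye traces by per-scan least squares, quantifies
each allele as the maximum intensity within ±5 scans of its registered
apex, and implements the downstream statistics: mean + 3 SD detection
thresholds at 0 % input VAF, all-replicates-exceed detection limits,
calibration curves of measured VAF (100·R/(1+R)) on prepared VAF, Pearson
concordance between assays, and the >3-mutant-droplet digital-PCR decision
rule with Poisson occupancy correction.

## Worked example

`examples/saturation_rescue.py` pushes the same 0.1 %-VAF KRAS G12R sample
through the full pipeline under three acquisition scenarios:

```
fig1b_conventional_1p6kv:
  KRAS-G12R-MT: intensity 669.3
  KRAS-12-WT: intensity 194,852.4 [SATURATED]
  R(KRAS-G12R-MT/WT) = 0.003435 [UNRELIABLE: saturated wild type]

fig1b_hidy_1p6kv:
  KRAS-G12R-MT: intensity 672.9
  KRAS-12-WT: intensity 659,330.5
  R(KRAS-G12R-MT/WT) = 0.001021

fig1b_hidy_4p8kv:
  KRAS-G12R-MT: intensity 1,982.3
  KRAS-12-WT: intensity 1,978,010.5
  R(KRAS-G12R-MT/WT) = 0.001002
```

Conventional binning clips the WT peak at its region capacity, biasing the
ratio 3.4× high and flagging it unreliable; HiDy keeps the WT peak on scale
and recovers the true ratio (0.001/0.999 ≈ 0.001001) to within ~2 % at the
standard 1.6 kV injection and within 0.1 % when 4.8 kV triples the loading.

The other examples print the dynamic-range gain (analytic 8.0895, empirical
8.03 over 10⁴ blank scans), a dilution-series detection-limit study
(modal limit 0.5 % at noise SD 8×10⁻⁴, 1 % at 1.8×10⁻³), and the clinical
concordance table (r = 0.955 between 10 ng CE and amplicon sequencing over
25 pairs; r = 0.965 between 2 ng CE and digital PCR over 36 pairs).

A thin CLI mirrors the library: `hidyce simulate|bin|deconvolve|call-peaks|
quantify|lod|concord|dpcr-call|pipeline` (see `hidyce --help`).

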