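# Methods

## Acquisition model

Each capillary's fluorescence is dispersed over 240 spectral positions of
3 pixels each. The simulator works at the 3 × 1-region level: the expected
signal of region *j* at scan *t* is

    E[s_j(t)] = Σ_alleles A · VAF · ν · exp(−(t − p)² / 2σ_p²) · w_j(dye) + b/12,

where *A* is the allele's dye-space apex amplitude at VAF 100 % under the
reference injection, ν the injection scale, *p* and σ_p the peak position
and width in scans, *w_j* the per-hardware-region dye weight, and *b* the
mean background per 3 × 12 region. Peaks are Gaussian in scan index — the
shape is an assumption; only its apex value enters the downstream
window-maximum rule, so the results are insensitive to the exact profile.
Injection is modelled as linear in voltage × time relative to 1.6 kV / 9 s
(ν = V·t / 14.4 kV·s), the simplest model consistent with higher voltage
enhancing peak signal proportionally.

Noise has three components with distinct physical origins:

* **background photon noise**, variance σ_b² per 3 × 12 region per scan,
  apportioned equally (σ_b²/12 per 3 × 1 region) so that any sum of twelve
  regions has variance σ_b² regardless of binning mode;
* **readout noise**, SD σ_r per analog-to-digital readout event, added at
  *acquisition* time because the number of readouts differs between modes
  (one per software region conventionally, twelve under HiDy);
* optional **shot noise**, Poisson on the expected counts, off by default
  so that linearity and end-to-end recovery tests are exact.

Saturation is hard clipping at the full-well capacity *S* per hardware
region (no blooming); readout noise is added after clipping since readout
digitises the already-saturated charge. A software region is flagged
saturated when at least one contributing hardware bin clipped — the sum is
then biased low and any ratio built on it is unreliable.

## Binning modes and dynamic range

Conventional mode sums each contiguous group of twelve 3 × 1 regions on
chip (clip at *S*, one readout); HiDy clips each 3 × 1 region at *S*, reads
each out, and sums groups of twelve in software (capacity 12 *S*, twelve
readouts). Defining dynamic range as capacity over baseline-noise SD per
software region gives the ratio 12·sqrt((σ_r²+σ_b²)/(12σ_r²+σ_b²)),
bounded between √12 (readout-dominated) and 12 (background-dominated).
The default variance mix σ_b²/σ_r² = 8.163 places the ratio at 8.09; it is
the root of (12+x)/(1+x) = (12/8.09)², exposed as
`NOISE_VARIANCE_RATIO_DEFAULT`. The individual scales (full well 30 000
counts, σ_r = 3 counts) are package defaults — only their ratio is
constrained by the dynamic-range figure; everything downstream is scale
free.

## Spectral deconvolution

A 20 × 4 response matrix *M* (columns sum to 1, full column rank) maps dye
amplitudes to region signals; per scan the dye vector solves
min‖M·d − s‖² via the pseudo-inverse. Unconstrained least squares was
chosen deliberately: negative baseline estimates keep the 0 %-VAF noise
statistics unbiased, which the mean + 3 SD threshold depends on. A
nonnegativity option (NNLS) exists but is off by default. Fixture spectra
are discretised Gaussians (`make_dye_spectra`, default centers
2.5/7.5/12.5/17.5 regions, width 2.5, condition number ≈ 2) — broad enough
that a bright peak spreads over several software regions, as on a real
spectrograph.

## Peak quantification

Registration runs a control sample containing all panel alleles and takes,
per dye channel, the k most prominent local maxima assigned to the alleles
in nominal migration order. Measurement is the raw maximum within ±5 scan
positions (an 11-scan window, truncated at trace edges, no baseline
subtraction; a wholly negative window clamps to 0). "Positions" are
interpreted as scan indices. R = I_MT / I_WT requires a positive,
unsaturated wild-type intensity; a saturated WT window returns R with an
`unreliable` marker rather than an error, mirroring how a clipped run is
still inspectable but not quantifiable.

## Detection-limit statistics

The threshold per mutation is mean + 3·SD (sample SD, n−1) of the
0 %-input replicates; the detection limit is the smallest prepared VAF at
which **all** replicates strictly exceed the threshold, with the
consistency requirement that every replicate at every larger grid VAF also
exceeds it (a single failure high in the series voids lower claims). Ties
at the threshold fail. The ratio-to-VAF map is v = 100·R/(1+R): bounded on
[0, 100), v(1) = 50 %, and linear for small R; the exact instrument
formula is not public, so this realisation is a documented assumption.
Calibration curves are OLS fits of per-replicate measured VAF on prepared
VAF (negative R clipped to 0 first); an R-scale threshold maps to the
prepared-VAF scale by applying v(·) and inverting the line.

The dilution-study generator draws R = v + N(0, σ) on the grid
{0, 0.1, 0.5, 1, 5} % with 8 replicates — the additive-noise abstraction
of the full pipeline, justified because R is a ratio of window maxima
whose fluctuations are approximately Gaussian and VAF-independent at
these levels. σ = 8×10⁻⁴ reproduces a 0.5 % modal limit and σ = 1.8×10⁻³ a
1 % limit over 100 seeds, bracketing the per-mutation spread reported for
control genomic DNA. What this does *not* show: real traces add PCR/STA
chemistry variability, baseline drift, and non-specific peaks, so these
simulated limits characterise the detection rule, not a clinical assay.

## Concordance

Assay pairs are coded ND ("not detected") → 0 % and N/A ("not analyzed")
→ row excluded; a double-ND contributes one (0, 0) pair and two-mutation
patients contribute one pair per mutation. Pearson r is computed with the
least-squares best-fit line. The packaged table has three typographically
ambiguous cells (patients 17 and 34, and patient 22's amplicon column),
coded ND and marked in the `ambiguous` column; `table1_report()` recodes
each as N/A and shows r moves by < 0.002 in every case. The dPCR rule
calls a mutation only above three mutant-positive droplets; VAF uses the
Poisson occupancy correction λ = −ln(1 − positives/total), an
implementation choice that reduces to the naive droplet fraction at low
occupancy.

## The saturation scenarios

The named presets realise the WT-saturation comparison: WT amplitude
22× full well, MT at VAF 0.1 % on the same dye, peaks at scans 610/640
(σ = 4). At 1.6 kV the WT apex spectral region carries 3.9× a conventional
hardware bin's capacity (clips, flagged) but 0.32× a HiDy software
region's; at 4.8 kV HiDy reaches 0.97× capacity — still unsaturated while
the mutant signal triples. These amplitudes and positions are package
choices; the source instrument's absolute signal levels are undisclosed.

## Numerical and scale choices

* Every stochastic operation takes an explicit integer seed
  (`numpy.random.default_rng`); no global RNG state.
* Simulations in the test and acceptance runs use full 1280-scan runs for
  pipeline scenarios and 10⁴ blank scans for noise calibration; dilution
  studies use 100 seeds × 5 grid points × 8 replicates.
* Floats serialise with 9 significant digits in TSV artifacts; reruns with
  the same seed are byte-identical.
* Degenerate inputs are rejected early: rank-deficient spectra (with the
  condition number in the message), non-positive WT intensities, grids
  without a 0 % row, fully-positive dPCR channels.

## Known limitations

No electrophoretic physics (mobility, temperature, polymer ageing), no
base-calling or size-standard calibration, no ABIF/.fsa binary formats,
no modelling of the extension chemistry itself. The spectral matrix is
synthetic rather than calibrated from pull-up runs. Detection limits on
clinical FFPE/biopsy material are outside what a simulator can certify.
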