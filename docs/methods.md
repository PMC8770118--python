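# Methods

This note records the models implemented in `peptidepore`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices that affect results.

## Recording model and the synthetic generator

A recording is a uniformly sampled current trace *I(t)* (pA) at a constant
applied voltage *V* (mV).  Defaults follow standard planar-bilayer practice
for these pores: 20 kHz sampling with a 4 kHz low-pass characteristic,
realized as a 4-pole Bessel filter applied forward–backward to the
generated noise.  The filter is applied to the noise only, not to the ideal
piecewise-constant signal: this keeps planted amplitudes and transition
times exact in the ground truth, at the cost of unrealistically sharp step
edges (one sample instead of the ~0.1 ms rise a real filter would impose).
The configured `noise_sd` is the post-filter RMS; the white-noise input is
rescaled after filtering so the generated trace matches it exactly.

Insertion signals come in four morphologies.  *Step*: successive upward
transitions of the unit step ΔI = g·V, final level held to the end.
*Square-top*: a rise followed by a return to baseline.  *Multi-level*: a
rise to the top level followed by downward steps, giving ≥3 distinct
above-baseline levels with both transition signs.  *Erratic*: an
Ornstein–Uhlenbeck fluctuation (correlation time 1 ms, sd one third of the
unit step) around half the unit step, clipped at baseline — raised current
with no resolvable level.  These are operational definitions chosen so that
each class is decidable from the idealization alone.

Translocation event streams use a capture/dwell kinetics model:

* arrivals are Poisson with rate k₀·C·exp(V/v₀) — linear in concentration,
  exponential in voltage;
* dwell times are log-normal with log-scale sd 0.4 and mean
  μ(V) = μ_max·(V/V_p)·exp(1 − V/V_p), a unimodal-in-voltage law whose peak
  at V_p encodes rejection of the analyte at low voltage and fast sweeping
  at high voltage;
* blockade amplitudes are Gaussian, truncated positive.

Defaults are the conditions the analysis is demonstrated under: amplitude
195 ± 20 pA and dwell scale μ_max = 1.8 ms (the dsDNA blockade scale
through the ~5.4 nm pore), dwell-peak voltage V_p = 80 mV (inside the
40–100 mV sweep), capture scale v₀ = 25 mV (a typical exponential slope
for DNA capture), and k₀ = 4·10⁻⁴ events·s⁻¹·nM⁻¹, giving ~2 events/s at
100 nM and 100 mV.  Overlapping planted events add their depths, as
concurrent pore occupancies would.

What the generator does **not** emulate: 1/f and shot noise, membrane
capacitance transients, baseline drift, gating flicker, filter-limited
rise times, and amplitude attenuation of sub-filter-width events.  Passing
recovery tests on these synthetics therefore demonstrates correctness of
the estimators under the stated model, not robustness to every artifact of
real bilayer recordings.

## Idealization and signal classification

Idealization is piecewise-constant fitting by recursive binary
segmentation on segment means (vectorized over cumulative sums).  A split
is accepted when the mean difference exceeds both the merge tolerance
(3 × noise sd) and 5 standard errors of the difference, with the standard
error inflated by √2.5 for the sample correlation a 4 kHz filter leaves at
20 kHz sampling.  The minimum splittable segment is a quarter of the
minimum resolvable dwell, so erratic fluctuation is fitted (and then
rejected as unresolvable) rather than averaged away.  Adjacent levels
closer than 3 × noise sd are merged; the residual RMS against the
idealization is reported.

Classification precedence: **erratic** (no level meets the minimum dwell
of 0.5 ms, or residual RMS > 3 × noise sd) > **multi-level** (≥3 distinct
resolvable levels with both signs of transition) > **square-top** (rose
and returned to within tolerance of the starting level) > **step** (only
upward transitions, final level persisting).  Stability is derived:
step/square-top = stable, multi-level/erratic = unstable; the stable
fraction is the mean of per-signal indicators, computed per signal (not
per recording).

## Event detection

The baseline is the mode of a current histogram (refined by the median of
samples near the modal bin); noise sd is the median of ~10 ms windowed
standard deviations — robust to the minority of windows containing steps.
Insertion steps are upward idealized transitions larger than k_σ × noise
sd (default k_σ = 5) persisting ≥0.5 ms; each carries g = ΔI/V, and the
first step taken from the starting level is flagged `initial` (the
initial-step conductance is what the pore-size histogram uses).  Blockades
are contiguous excursions below (1 − f)·I_open (default threshold fraction
f = 0.1) lasting ≥0.5 ms; amplitude is the mean depth (not the extreme,
for noise robustness), and events containing a second resolvable blocked
level are flagged `nested` rather than deconvolved.  The exact thresholds
used in the original recordings are not published; these defaults are
declared, configurable choices.

## Conductance peaks

Conductances are histogrammed on a uniform grid (default 0.25 nS).  Peak
picking is the second-derivative method with a 15% threshold, with one
structural choice: pore-conductance mixtures have component widths
proportional to their means (constant CV), so in linear bins the smallest
peak is an order of magnitude sharper than the largest and no single
curvature threshold treats them comparably.  The detector therefore
redistributes the histogram mass onto uniform log-conductance bins (width
0.06 in ln g), where equal-weight constant-CV components have equal width
and height, smooths with a 3-bin moving average, and accepts local maxima
whose negative second derivative reaches 15% of the global maximum
magnitude within the smoothing window of the apex (the curvature of a
multi-bin peak lives on its shoulders).  Detections are mapped back to the
strongest nearby linear-histogram bin and then refined by least-squares
multi-Gaussian fitting (`scipy.optimize.curve_fit`, seeded at the detected
locations; seeds are returned flagged unconverged if the optimizer fails).
Consequences: the threshold is scale-invariant in the counts, and
components with strongly unequal masses (≳7× ratio) may fall below a 15%
relative threshold by design.

## Geometry calibration and the Hille comparator

The packaged reference table is the characterized five-pore set
(conductance 1.1–14.4 nS, diameter 1.7–6.3 nm, strands 13.8–36.4); users
can supply their own β-barrel literature table as CSV.  The functional
forms are the implementer's choice: a power law d = a·g^b fitted by least
squares on log–log axes (the reference set is consistent with
d ≈ 1.63·g^0.51 to within 0.04 nm) and a line n_s = c·d + e by ordinary
least squares.  Monomers = strands/2, reported raw and rounded to nearest
integer.  Leave-one-out refitting is provided as the calibration's
internal validation.

The Hille comparator treats the pore as a solution-filled cylinder with
access resistance, σπd²/4 = g(L + πd/4), solved for its positive root.
Defaults σ = 10.5 S/m (1 M KCl near 22 °C) and L = 3.5 nm (the membrane
span of a ten-residue β-strand) are implementation choices; under them the
Hille diameter is strictly below the empirical calibration for every
reference conductance, reflecting that these barrels conduct less per unit
area than an ideal cylinder.

## Bootstrap and scatter peak

The "exact bootstrap" is fixed-count n-out-of-n Monte-Carlo resampling:
B = 65,536 resamples with replacement, each summarized by its mean
(duration, amplitude) pair.  The scatter peak is the mode of a 2D Gaussian
kernel density over those pairs, with Scott's plug-in bandwidth per axis,
evaluated as a binned KDE (2D histogram on a 128² grid padded by 3
bandwidths, Gaussian-filtered) — O(B + grid) rather than O(B·grid), and
translation-equivariant because the grid is anchored to the data.  With
fewer than 10 pairs, or a degenerate cloud, the coordinate-wise median is
returned with a warning.  Whether the original "peak top" was a KDE mode,
histogram mode or Gaussian-fit center is unstated; the KDE mode is the
choice here, and for the near-Gaussian clouds that resampled means form
the three coincide to within the grid resolution.

Frequency fits use `scipy.stats.linregress`: a line in concentration at
fixed voltage, and a line in log-frequency against voltage (equivalently
f = A·exp(V/v₀)) at fixed concentration, with non-positive frequencies
excluded from the log fit with a warning.  Dwell-versus-voltage
characterization is descriptive (condition means); no mechanistic
capture/rejection model is fitted.

Molecular volumes: dsDNA as a cylinder (radius 1.0 nm — standard B-form —
length as measured, 4 nm for the blockade-scale comparison) and the
G-quadruplex as a stack of five 3.0 × 2.7 nm² boxes.  The per-unit height
default 0.72 nm is back-derived so the default stack gives 29.2 nm³; it is
flagged as such and configurable.  Signal-to-noise is the mean blockade
amplitude over the baseline noise sd.

## Design grammar

Sequences assemble deterministically as cap + strand + turn + strand + cap
(defaults RG / 10 residues / DSDG / 10 residues / GR = 28 residues).
Strand positions alternate hydrophilic (Ser) and hydrophobic (Val)
starting hydrophilic at each strand's first residue; tyrosines replace
positions 4, 12, 18 and 26 (all hydrophobic-slot positions, preserving
amphipathicity); an optional glycine kink replaces one strand residue.
The kink position of the monodisperse redesign is not recoverable from
published text, so it is a required user parameter with no default.
Validation checks length, strand alternation (snorkel/kink positions
exempt, hydrophobicity per a fixed binary table: AVLIMFWYC hydrophobic),
≥2 anionic turn residues, cationic caps, snorkel placement, and reports
the net formal charge (R/K = +1, D/E = −1); the default sequence is
RGSYSVSVSVSYDSDGSYSVSVSVSYGR with net charge 0.  Output metadata labels
sequences "rule-derived", not "as-published".

## Problem sizes and determinism

The test suite and acceptance script run everything at desk scale, chosen
as the smallest sizes at which the statistical contracts are sharp:
1,000-signal classification ensembles at SNR ≈ 11, 2,000-draw conductance
samples, 120 s simulated translocation recordings (~250 events each),
B = 65,536 bootstrap replicates, and 600 s equivalent event lists for the
kinetics recovery study (generated as event times directly, without
synthesizing the 20 kHz trace).  Every stochastic step takes an explicit
seed; pipeline stage seeds are spawned from the run seed via
`numpy.random.SeedSequence`, and identical configs reproduce identical
outputs.

## Known limitations

* The classifier's operational definitions stand in for unpublished
  per-class criteria; boundary cases between multi-level and square-top
  are resolved by precedence, not probability.
* Binary segmentation is greedy; closely spaced opposite-sign transitions
  inside one minimum-dwell window can be merged.
* The peak detector assumes roughly comparable component masses (see
  above) and positive conductances.
* The calibration is empirical interpolation over 1–15 nS; extrapolation
  far outside the reference range inherits no physical guarantee.
* Blockade amplitudes of events near the minimum dwell are biased low by
  the mean-depth summary when the true waveform is attenuated; the
  generator does not model that attenuation, so the bias is not exercised
  by the tests.
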