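# Methods

## The decomposition

Empirical mode decomposition treats the recorded intensity series as a
superposition of oscillatory modes. One sifting pass subtracts from the
working series the mean of its two cubic-spline envelopes (upper through
the strict local maxima, lower through the strict local minima); passes
repeat until the result qualifies as an intrinsic mode function (IMF).
The accepted IMF is removed from the running residue and extraction
repeats until the residue is monotone or has fewer than two maxima or two
minima. Because each IMF is subtracted exactly, IMFs plus residue
reconstruct the input to floating-point accuracy; the test suite bounds
the relative reconstruction error at 1e-9 and observes ~1e-16.

Conventions and numerical choices:

* **Extrema.** Strict interior extrema; a plateau of equal samples
  contributes one extremum at its midpoint (rounded down). Plateaus are
  rare in floating-point data but must not produce twin knots.
* **Envelopes.** Natural cubic splines through the extrema. The two edge
  extrema are mirrored across each boundary before fitting — the standard
  end-effect suppression; with fewer than four extrema on a side the
  envelope degrades to linear interpolation rather than crashing.
* **Stopping a sift.** The Cauchy criterion SD = Σm²/Σh² < 0.2 (m the
  envelope mean, h the current series) combined with the IMF count test
  |#extrema − #zero-crossings| ≤ 1, or the count test holding for two
  consecutive passes (S-number rule), or 50 passes. The count test is
  required at exit — a bare Cauchy stop can emit components that violate
  the IMF definition, which downstream band selection relies on.
* **Count-test window.** The count test is evaluated on the interior 95%
  of samples: boundary mirroring can manufacture spurious end extrema
  that say nothing about the mode's interior behaviour.
* **Stall guard.** When the residue amplitude falls to ~1e-2 of the
  signal, float-level micro-ripples of the spline fits can carry hundreds
  of extrema and the extraction loop would peel numerically meaningless
  components forever. EMD coarsens, so extraction stops when the
  residue's extrema count doubles, or fails to decrease three times in a
  row, or the extracted component is below 1e-12 of the signal amplitude.
* **Index space.** Decomposition runs over sample index and ignores the
  non-uniform m/z spacing; the instrument records a uniformly sampled
  time series and the m/z axis is a relabelling of it.

On broadband noise EMD behaves like a dyadic filter bank, so the IMF
count grows like log₂N; white noise of length 2¹⁴ yields 10–13 IMFs under
these stopping rules (median ≈ 11–12 over realisations).

## The preprocessing pipeline

Order: decompose → select the retained IMF band → estimate and subtract
the baseline → shift to a zero floor. Parameters:

| parameter | default | meaning |
|---|---|---|
| `drop_low` | 6 | fastest IMFs removed as noise (C1–C6) |
| `drop_high` | 3 | slowest components removed as trend, residue first |
| `baseline_window` | `None` → n/20 | minimum-window length in samples |
| `do_baseline` | true | subtract the windowed-minimum baseline |
| `do_rescale` | true | shift so the output minimum is exactly 0 |

`drop_high` counts the residue as the last trend component: completeness
means trend removal is meaningless unless the residue goes first. With 12
IMFs the default removes components 11, 12 and 13 (= residue).

The baseline estimator partitions the index range into consecutive
windows, takes each window's minimum as a knot at the window centre,
interpolates linearly (flat beyond the edge knots) and smooths with a
moving average of the same width. A baseline must vary slowly relative to
the peaks. After dropping C1–C6 nothing faster than roughly a hundred
samples survives the denoising stage, so a minimum window of a few tens
of samples would track the peaks themselves and subtract them — the
default therefore divides the spectrum into 20 windows (window length
n_points // 20 samples), which keeps the peak profile intact while
following the residual floor. The window length remains directly
settable in samples for narrow-peak data.

The final rescale is a pure shift by the output minimum (never a
multiplicative scaling), anchoring the floor at exactly zero. The
standalone `rescale_positive` shifts only when the minimum is negative;
the pipeline anchors unconditionally so the zero-floor postcondition
holds for every configuration.

The overall intensity scale of the output is roughly half the raw scale:
removing the noise and trend bands takes their share of the amplitude
with them. This is an emergent effect of band selection, not an explicit
scaling step.

## Peak detection

**Windowed local maximum.** A sample is a candidate iff it is the strict
maximum of its ±`half_window` (default 10) neighbourhood; equal-value
ties resolve to the lowest index, and no two reported peaks can lie
within `half_window` of each other — the guard against the
double-counting failure mode of marking one broad peak twice. The SNR
gate is fully shift-invariant: prominence of the apex above the local
median divided by 1.4826 × MAD about that median, both computed over a
±200-sample window with the central ±4·`half_window` samples excluded so
the peak's own body does not inflate its noise estimate (noise is
estimated off-peak, as usual). Threshold `snr_min` = 3.

A first-difference-based noise estimate was considered and rejected:
after EMD denoising the signal is smooth, first differences collapse, and
residual low-frequency ripples would acquire unbounded SNR. The local
MAD of the signal itself self-normalises those ripples.

**CWT ridge lines.** Mexican-hat (Ricker) wavelet coefficients are
computed at scales (2, 4, 8, 16, 32, 64) samples by direct convolution
with L2-normalised kernels, so the white-noise coefficient level is flat
across scales and one smallest-scale noise estimate is a valid floor
everywhere. Per-scale coefficient maxima are linked into ridges from the
largest scale downward (greedy nearest-first matching within a
scale-proportional tolerance; up to `gap_max` = 2 missed scales). Ridges
spanning ≥ 3 scales are scored by their largest L2 coefficient; the
noise floor is 1.4826 × MAD of the smallest-scale coefficients within
±200 samples; `snr_min` = 3.

An L2-normalised Mexican hat responds maximally to a Gaussian of width
σ at scale √5·σ, so scale selection uses width-matched coefficients
(coefficient / scale), whose maximum falls at scale ≈ σ; the reported
apex is the raw-signal maximum nearest the ridge position within ±best
scale. Ridge persistence makes this detector more sensitive than the
windowed maximum for faint peaks — it trades that for more reported
peaks overall.

**Truth matching.** Greedy nearest-first matching within a tolerance of
0.3% of m/z (typical SELDI mass accuracy), each peak matched at most
once; precision = matched/detected, recall = matched/planted, with empty
denominators defined as 1. Greedy rather than optimal assignment: at the
peak densities evaluated here the two coincide, and greedy is
deterministic and transparent.

## The synthetic generator

The generator emulates a serum protein-profiling spectrum as recorded by
a linear TOF instrument:

* axis: a uniform flight-time grid mapped through
  m/z = U·(a·(t − t₀)² + b) with U = 25000, a = 3.36e8, b = 0.00235,
  t₀ = 3.7071e-7 — so the m/z spacing grows quadratically from ~0.3 to
  ~9 Da across 58.75–101 453 Da at the default 21 551 points. (The
  calibration cannot reach below U·b = 58.75 Da; the default range
  starts exactly there.)
* ~10 Gaussian protein peaks between 2560 and 14 300 Da, including a
  5119 Da protein and its doubly charged partner at (5119+1)/2 = 2560 Da;
  widths σ = 0.5% of m/z (resolving power ~85, the broad-hump regime of
  linear-mode serum profiling); heights 20–120× the white-noise sigma.
* an exponential baseline 50·exp(−m/z / 3000 Da);
* 150 chemical-noise peaklets in 58.75–1000 Da (positions uniform,
  heights exponential with mean 15, widths 1–3 Da) — matrix organic-acid
  ions are true narrow peaks, not white noise;
* additive white Gaussian noise, σ = 1.

Everything is a pure function of the truth record (seed included):
identical seeds give bitwise-identical spectra.

What the generator does **not** emulate: detector saturation, isotope
envelopes, peak-shape asymmetry, multiplicative/heteroscedastic noise,
m/z miscalibration between spectra, and any empirical noise spectrum of
a real instrument (no accepted noise model exists for these platforms —
the distributions here are conventional stand-ins). Passing recovery
tests on this generator therefore demonstrates that the pipeline
preserves and finds peaks under the stated idealised conditions, not
performance on clinical data.

## Evaluation choices and known limitations

* Planted peak widths matter. The denoising band is fixed by `drop_low`,
  so peaks must be slower than the discarded band to survive: with white
  noise at every sample, C1–C6 cover periods up to ~100 samples, and the
  preset's peaks (σ ≈ 9–20 samples) retain roughly 40% of their apex
  height after band selection — consistent with the roughly halved
  intensity scale noted above. Much narrower peaks would be removed with
  the noise band; `drop_low` must then be reduced.
* Plain EMD mixes modes: around tall peaks, noise perturbs the envelope
  knots and scatters peak energy into seed-dependent "halo" structure in
  the retained band, with amplitude comparable to the faintest planted
  peaks. End-to-end recovery on the preset's reference realisation
  (generator seed 0) reaches recall 1.0 / precision 1.0 in the
  2000–15000 Da analysis window; across other noise realisations the
  marginal peaks sit near the SNR threshold and recall/precision range
  over roughly 0.8–1.0. Ensemble EMD would average the halos away at the
  cost of stochasticity and ~2 orders of magnitude more computation; it
  is deliberately out of scope.
* Recovery metrics are evaluated inside 2000–15000 Da, the region where
  protein signal is biologically interpretable on these chips; the
  chemical-noise band below 1000 Da is excluded by construction.
* The problem sizes used by the acceptance script — 50 signals for the
  IMF property, 100 for completeness, 5 realisations of length 2¹⁴ for
  the IMF count, one full-length 21 551-point preset run — were chosen
  to exercise every component at the scale the method targets.
* Axis handling assumes one spectrum at a time; alignment and
  normalisation across spectra are upstream concerns and out of scope.
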