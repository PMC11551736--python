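# Methods

## The assay and its statistical model

A stepwise-photodropping nuclease assay immobilizes DNA duplexes whose
single-stranded overhang carries two Cy3 fluorophores separated by `S`
nucleotides with native scissile phosphodiester bonds.  A nuclease removes
the fluorophores one at a time; each removal drops the molecule's summed
fluorescence by one unit.  Every trace over the acquisition window falls
into one of three scenarios: no drop, one drop (dwell `T1`, from
acquisition start to the drop), or two drops (dwell `T2`, the interval
between the drops).  Spontaneous photobleaching produces the same step
signature and is the confound the analysis subtracts.

For a processive exonuclease that binds once and traverses the overhang,

```
E[T2] = tau_bond * S + tau_label
```

where `tau_bond` (s/nt) is the mean time to cleave one native bond and
`tau_label` (s) the extra time to cleave a fluorophore-conjugated bond.
Regressing the background-subtracted mean dwell `T2_av` on `S` therefore
yields `tau_bond` as the slope, `tau_label` as the intercept, and the
degradation rate as `1/slope` (nt/s).  A distributive endonuclease instead
cleaves each labeled site independently at a concentration-dependent rate
`k_site(c)`; by memorylessness its inter-drop interval is
Exponential(`k_site`), so `T2_av` falls with enzyme concentration.  That
contrast is the processive/distributive classifier: `T2_av` is regressed
on log-concentration and called distributive when the slope is negative
and exceeds twice its standard error.

The FRET branch handles two situations: a static high-efficiency duplex
population (the double-strand negative control) and duplex unwinding,
where the efficiency ramps from a low to a high level; the unwinding rate
is the number of base pairs unwound divided by the Gaussian-fitted mean of
the transition-dwell histogram.

## Synthetic-data generator

The generator is first-class, tested code: every analysis stage is
validated against traces with known ground truth.

Event model (processive): binding time ~ Exponential(rate
`k_bind_per_nM * concentration`), zero when `prebound` (the
divalent-cation-triggered wash condition); the enzyme then traverses
`lead_nt` native bonds, the first label bond, `spacing` native bonds, and
the second label bond.  Native-bond times are independent exponentials
(memoryless single-enzyme catalysis), so the `S`-bond traversal is
Gamma(`S`, `tau_bond`) — this is what makes `E[T2]` linear in `S`.

The label-bond time is Gamma(shape `label_shape` = 4, mean `tau_label`),
not exponential.  The shape is the one genuinely open distributional
choice: only means and standard deviations of dwell pools are observable.
An exponential label bond would force an exGaussian `T2` whose standard
deviation can never fall below `tau_label` and whose least-squares
Gaussian fit tracks the mode with a spacing-dependent bias; observed
dwell pools in this assay class are unimodal and peaked with sd below
`tau_label`, which requires a multi-substep (Gamma-shaped) label-bond
time.  Shape 4 (coefficient of variation 0.5) keeps the distribution
clearly skewed while preserving `E[T2]` exactly.

Photophysics: each fluorophore independently bleaches at `k_bleach`
(default 1.2e-3 s^-1, chosen so that both fluorophores survive a 100-s
window with probability exp(-2 k t) ~ 0.79, the observed no-drop control
fraction); whichever of cleavage and bleaching comes first removes that
fluorophore's intensity unit.  Because empirical control scenario splits
(78.4/15.8/5.8%) are not reproducible by two independent exponentials
(independence would force the one-drop fraction to ~20% given 78.4%
no-drop), the generator also offers a mixture mode that draws the
non-enzymatic scenario directly from a supplied 3-vector and samples
bleach times conditionally inside the window.  The mixture mode is the
default contamination model for realistic runs.

Rendering: intensity starts at `2 * unit_intensity` (default 1000 a.u.),
drops by one unit per removal, plus i.i.d. Gaussian noise (default sd
50 a.u., SNR ~ 20 by `(S - B)/sigma`); frames are 100 ms over a 100-s
window; events beyond the window are censored — logged but not rendered.

FRET: static traces hold one true efficiency; unwinding traces hold the
low level, ramp linearly to the high level over a Gamma-distributed
duration, then hold.  The ramp-duration shape is 19 — one Gamma sub-step
per unwound base pair of the 19-bp duplex — giving a peaked,
near-symmetric dwell (CV 23%) for which the Gaussian-fitted histogram
mean is a self-consistent estimator of the generator mean.  Donor and
acceptor are `total*(1-E)` and `total*E` plus channel noise.

Movies: traces can be rendered as 2-D Gaussian spots (integrated
intensity per frame equal to the trace value) on a constant background
with Poisson noise, and re-extracted by local-maximum spot detection with
local-median background subtraction — a round trip exercised in the
tests.

What the generator does *not* emulate: blinking and triplet states,
diffusing background molecules, stage drift, camera gain structure,
channel registration errors.  Passing tests therefore demonstrate
correctness of the estimators under the stated event model, not
robustness to every instrumental pathology of real recordings.

## Trace processing

Step detection fits a piecewise-constant signal by binary segmentation:
a segment is split at the point of maximal residual-sum-of-squares
reduction whenever the reduction exceeds a BIC-style penalty
`10 * ln(n) * sigma^2`, with `sigma` estimated robustly from the median
absolute deviation of first differences (floored at a tiny fraction of
the trace scale so noiseless input stays finite).  Segments shorter than
`min_dwell` = 3 frames are never created.  Accepted steps are downward
with magnitude within [0.5, 1.5] of the fluorophore unit; a larger
downward step (two fluorophores lost within one frame) or more than two
accepted steps rejects the trace, and rejected traces leave the scenario
denominator.  Binary segmentation was chosen over HMMs for determinism
and the absence of tunable state counts.  Step times are reported as
`frame_index * frame_interval` with the index of the first frame at the
new level.

The fluorophore unit is the median of candidate downward step magnitudes
across at least 20 traces (configuration fallback otherwise), and only
molecules whose initial intensity (mean of the first 5 frames) lies
within 25% of two units enter the analysis — rejecting single-fluorophore
molecules that would contaminate the one-step class.

## Dwell-time fitting

Bin width: a plain Gaussian is fitted at each candidate width in
ascending order (defaults 0.25–2 s) and the smallest width whose fitted
mean agrees with the next wider one within `stability_tol` (default
0.3 s) is kept, falling back to the Freedman–Diaconis width.

Background: the enzyme-free control `T2` histogram (same bin width) is
fitted with a quartic polynomial by least squares; predictions are
clipped at zero.

Degradation peak: the condition histogram is fitted with
`A exp(-(t-mu)^2 / 2 sigma^2) + quartic(t)` by bounded nonlinear least
squares (lmfit), `mu` initialized at the background-subtracted mode with
two fallback starts, bounds `A >= 0`, `mu` inside the histogram range,
`sigma` in (bin_width/2, range/2).  In the default `joint` mode the
quartic keeps the control's shape with a free overall scale and per-
coefficient refinements bounded to +/-50%; a fully free clipped quartic
can otherwise collapse onto the degradation peak itself (a clipped
polynomial approximates a compact bump), which is a degenerate fit, not a
background.  `fixed_shape` mode scales the control quartic by a single
factor and is retained for robustness comparisons.  Histogram fitting is
least squares on bin counts, not maximum likelihood on samples.

Decomposition: unweighted ordinary least squares of `T2_av` on `S`
(weighted fit available when per-point standard errors are supplied);
`rate = 1/slope` with its standard error by the delta method
`se_rate = se_slope / slope^2`.  Reported probabilities and dwells are
rounded to one decimal, slopes to two, rates to one, and population
deltas are computed on one-decimal-rounded percentages, matching the
printed-table conventions this package reproduces.

## FRET analysis

Efficiency is the uncorrected proximity ratio
`acceptor / (acceptor + donor)` on frames whose total emission exceeds a
floor (default 0.2 of the two-fluorophore unit); no gamma, leakage, or
direct-excitation correction is applied, so equivalence with corrected
instruments holds only at histogram-mean level.  Pooled histograms are
fitted with one Gaussian, or two when the dip contrast between the two
largest modes exceeds 0.5.

Unwinding dwells: crossing frames of the thresholds
`low + 0.1 (high-low)` and `high - 0.1 (high-low)` bracket the
transition; a least-squares line over the inter-threshold segment gives
the ramp slope, and the line's crossings of the full low and high levels
delimit the dwell.  The regression is used instead of the raw first/last
crossing frames because extreme-crossing statistics under frame noise
bias the inter-threshold interval short, while the fitted slope is
unbiased; on a noiseless linear ramp the two coincide.  A contiguous
intermediate-level plateau of at least 0.5 s flags the call as paused;
paused calls are excluded from rate aggregation.  The aggregate rate is
`bp / mu` with `mu` the Gaussian-fitted mean of the dwell histogram,
preferred over the mean of per-call `bp/T` because of the heavy right
tail of reciprocal dwells.

## Reproducibility and problem sizes

All randomness flows from one master seed through a counter-based
scheme: trace `j` of condition `i` uses `default_rng([seed, i, j])`,
recorded in the trace metadata; re-running any configuration reproduces
every output exactly.  The reproduction script works at desk scale:
260 traces per spacing (about 200 two-step events) for the processive
spacing grids, 220 per spacing for the slower-enzyme grid, 1200
mixture-mode control traces per grid, 500 unwinding traces, and 200
static FRET traces — sizes at which the recovered slope and intercept
carry the few-percent uncertainties the tests assert.

## Known limitations

- The per-bond exponential and Gamma label-bond choices are modeling
  assumptions over unobserved microscopic kinetics; only their first
  moments are constrained by the linear dwell model.
- The step finder guarantees recovery at SNR ~ 20 with dwells of a few
  frames or longer; closely spaced events (under `min_dwell` frames)
  merge into one oversized step and the trace is rejected rather than
  resolved.
- The three-point spacing grid of the slower-enzyme condition puts the
  recovered rate's seed-to-seed spread near 1 nt/s at these event
  counts; this is the statistical floor of peak localization, not fit
  instability.
- Occurrence-delta arithmetic on one-decimal-rounded percentages
  reproduces printed-table conventions; unrounded pipelines will differ
  in the last digit.
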