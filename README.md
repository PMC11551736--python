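# nisp

Single-molecule analysis of nuclease kinetics by **n**uclease-**i**nduced
**s**tepwise **p**hotodropping: a DNA overhang carrying two Cy3
fluorophores is degraded by a nuclease, each fluorophore removal drops the
molecule's fluorescence by one unit, and the dwell between the two drops
reports how long the enzyme spent traversing the nucleotides in between.

The package is for single-molecule biophysicists who record (or want to
simulate) such dual-fluorophore intensity time traces and need the whole
chain from raw traces to per-nucleotide degradation rates:

- **Simulation** — a Monte-Carlo generator of intensity traces, FRET trace
  pairs, and TIRF-like image stacks with known ground truth, covering
  processive exonucleases, distributive endonucleases, inactive-enzyme
  controls, and spontaneous photobleaching.
- **Trace processing** — spot extraction from image stacks, SNR
  (`(S−B)/σ`), two-fluorophore intensity selection, change-point step
  detection (binary segmentation with a BIC-style penalty), and scenario
  classification (no-drop / one-step / two-step) with dwell extraction.
- **Kinetics** — occurrence tables with control subtraction, dwell
  histograms with bin-width stability selection, a quartic
  photobleaching background plus Gaussian degradation peak, and the
  linear decomposition of the mean dwell:

  ```
  T2_av = tau_bond · S + tau_label        rate = 1 / tau_bond  (nt/s)
  ```

  where `S` is the number of native scissile bonds between the
  fluorophores.  A concentration-dependence test classifies enzymes as
  processive (dwell independent of concentration) or distributive
  (dwell falls with concentration).
- **FRET** — proximity-ratio efficiency, one/two-component histogram
  fits, and duplex-unwinding dwell detection with the unwinding rate
  `bp / ⟨T_unwinding⟩`.

## Worked example

Simulate a processive exonuclease on four substrates (spacings 8, 13,
18, 28 nt; per-bond time 0.16 s, label-bond time 0.40 s, realistic noise
and photobleaching contamination), run the full pipeline, and recover
the degradation rate:

```python
from nisp.workflows import recover_degradation_rate
from nisp.models import LabelType

dec, fits = recover_degradation_rate(
    [8, 13, 18, 28], tau_bond=0.16, tau_label=0.40, seed=1,
    label_type=LabelType.ICY3, concentration=10.0, n_traces=260,
)
for name, fit in fits.items():
    print(f"{name:>4}: T2_av = {fit.mu:.2f} s  (sigma {fit.sigma:.2f} s, n = {fit.n_events})")
print(f"slope      = {dec.slope:.3f} s/nt   (tau_bond)")
print(f"intercept  = {dec.intercept:.2f} s     (tau_label)")
print(f"rate       = {dec.rate:.1f} nt/s   (R^2 = {dec.r_squared:.3f})")
```

prints

```
  S8: T2_av = 1.61 s  (sigma 0.43 s, n = 260)
 S13: T2_av = 2.48 s  (sigma 0.63 s, n = 260)
 S18: T2_av = 3.11 s  (sigma 0.67 s, n = 260)
 S28: T2_av = 4.73 s  (sigma 0.84 s, n = 259)
slope      = 0.154 s/nt   (tau_bond)
intercept  = 0.40 s     (tau_label)
rate       = 6.5 nt/s   (R^2 = 0.998)
```

The fitted means grow linearly with the fluorophore spacing; the slope
recovers the generator's per-bond time within a few percent, the
intercept isolates the extra time spent on the fluorophore-conjugated
bond, and inverting the slope gives the per-nucleotide degradation rate.

The same pipeline is scriptable from the shell: `nisp simulate` writes
trace tables and a ground-truth manifest from a YAML condition grid,
`nisp analyze` runs selection → step detection → occurrence table →
histogram fits → decomposition/processivity classification, `nisp fret`
produces efficiency histograms and unwinding rates, and `nisp report`
prints a results directory.  Every output directory contains a resolved
configuration with the master seed; re-running it reproduces all outputs
exactly.

See `docs/methods.md` for the event model, the fitting choices, and the
generator's known limitations.

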