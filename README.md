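# sonasim

A simulator-backed control stack for MR-guided high-intensity focused
ultrasound (MR-HIFU), for researchers who want to develop and test
therapy-control and real-time thermometry software without scanner or
therapy hardware.

MR-HIFU systems couple a phased-array ultrasound transducer to an MR
scanner: the array heats tissue at an electronically steered focus while
the scanner streams temperature-sensitive images that close the control
loop.  `sonasim` reproduces that tool-chain end to end in software:

* **Treatment protocols** (`sonasim.protocols`) — an immutable command
  model (continuous/pulsed exposures, transducer moves with 5 degrees of
  freedom, pauses, low-level per-element "R&D" control), protocol
  assembly, real-time *modifications*, and a frozen JSON wire format.
* **Execution engine** (`sonasim.engine`, `sonasim.server`) — executes
  one protocol at a time on a deterministic simulated clock, applies
  modifications mid-run (including "go to step *n*" restarts), answers
  status queries (position, powers, ultrasound on/off, movement, time
  index), and is exposed over newline-JSON TCP sessions.
* **Physics backends** — a 256-element spherical-shell array with
  Rayleigh–Sommerfeld element fields and electronic steering
  (`sonasim.acoustics`), and a Pennes bioheat solver driven by the
  engine's exposure timeline (`sonasim.bioheat`).
* **Virtual MR scanner** (`sonasim.scanner`) — synthesizes dynamic
  magnitude/phase and two-echo images from digital phantoms plus the
  simulated temperature field, with the real stream semantics: subscribe /
  query / unsubscribe, pause/resume, real-time stack repositioning, FIFO
  queues, volumetric ordering by (type, stack, slice).
* **Thermometry** (`sonasim.thermometry`) — proton-resonance-frequency-
  shift (PRFS) temperature maps with B0-drift correction, two-echo T2
  mapping for fatty tissue (bone marrow), and maximum temperature-change
  projections.
* **Applications** (`sonasim.apps`) — three end-to-end runs: an automated
  per-element hydrophone scan, a combined therapy+imaging run that heats
  the word "HIFU" into a phantom, and a small-animal thermometry demo.

## The models in brief

PRFS thermometry: the water proton resonance falls by
α ≈ −0.01 ppm/°C, so a phase-difference image at echo time TE encodes

ΔT = wrap(φ − φ_ref) / (2π γ B₀ α TE),  γ = 42.576 MHz/T.

Fat has no water shift, so marrow temperature instead uses the linear
rise of T₂: a two-echo estimate T₂ = (TE₂ − TE₁)/ln(S₁/S₂) scaled by a
calibration slope of 20 ms/°C.

Acoustics: each element contributes a Rayleigh integral
p(r) = (iρck u₀/2π) Σ e^{−(ik+α)d}/d ΔS over its discretized surface;
steering phases φ_n = k(|r_n − r_f| − F) relocate the focus.  Heating
follows the Pennes equation ρc ∂T/∂t = k∇²T − w_b c_b (T − T_a) + Q with
Q = 2 α_abs |p|²/(2ρc), solved explicitly (FTCS) with automatic
sub-stepping.

See `docs/methods.md` for assumptions, parameter defaults and numerical
choices.

## Worked example

```python
>>> from sonasim import apps
>>> result = apps.run_element_scan()        # all 256 elements
>>> len(result.records)
256
>>> result.total_time_s
588.8000000000003
>>> round(result.records[0].summary_amplitude_pa)
211068
```

Each of the 256 channels takes exactly 2.3 s of simulated time (1.8 s of
pulsed exposure — 40 cycles at 1.2 MHz, 40 Hz repetition, 64 averaged
hydrophone readings — plus transfer/modification overhead), so the whole
scan occupies 588.8 s ≈ 589 s of device time.  The summary amplitude is
half the peak-to-peak pressure of the averaged tone burst at the focus
(~211 kPa for a single element driven at 10 W in water).

The pattern application runs the full therapy loop (move → 2-s reference
pause → 8-s, 80-W steered exposure per 18-mm segment → 60-s cooling, with
a protocol modification switching segments):

```python
>>> report = apps.run_hifu_pattern().report
>>> report["n_segments"], report["n_reference_frames"]
(10, 4)
>>> round(report["peak_delta_t_c"], 1)
4.9
```

The drift-corrected maximum temperature-change projection shows all ten
segments above half the global peak rise while the background more than
6 mm from every segment stays below a quarter of it — the word "HIFU" is
legible in the projection.

A command-line interface mirrors the library:

```bash
sonasim run element-scan --out out/        # CSV + JSON report
sonasim run hifu-pattern --out out/        # NIfTI movie + max projection
sonasim serve --port 8760                  # engine over TCP
sonasim status --port 8760
sonasim thermo --method prfs --phase p.nii.gz --reference r.nii.gz --out dt.nii.gz
```

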