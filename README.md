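# rfbreath

Contactless respiratory monitoring from UHF RFID backscatter phase.

Passive RFID tags taped to the chest and abdomen turn breathing into a phase
signal: a tag at distance *R* from the reader antenna returns the carrier
phase

    θ = 2π · 2R/λ + θ_t + θ_r + θ_tag   (mod 2π),

so the few-millimetre chest-wall excursion of quiet breathing (≈0.5 cm
peak-to-peak at 0.2–0.33 Hz) modulates θ with peak-to-peak amplitude
8π·A/λ ≈ 0.2 rad — easily resolved by a reader whose 12-bit phase field has
a step of 2π/4096 ≈ 0.0015 rad. Because each tag carries a unique,
rewritable EPC, several people can be monitored simultaneously by one
reader, something most contactless methods cannot do.

The raw phase is unusable as-is: the reader randomly offsets readings by π
(hardware ambiguity), the phase wraps at 2π, sampling is irregular, and the
signal is noisy. `rfbreath` implements the full processing chain:

1. **clean** — sequential π-disambiguation and 2π-unwrapping against a
   running corrected reference, then linear resampling onto a uniform grid
   at the stream's own mean rate;
2. **rate** — DC removal, 2nd-order Butterworth bandpass (0.1–1 Hz),
   respiratory rate = the largest FFT magnitude in the band (readout grid
   ≤ 0.01 Hz);
3. **reconstruct** — db2 wavelet approximation at a depth *n* chosen so
   Fs/2ⁿ lands in 0.6–2 Hz near twice a 0.3 Hz reference rate, extremum
   detection, amplitude filtering at α·(ē_max − ē_min) with α = 0.5,
   differencing with sign-alternation enforcement, and a natural cubic
   spline through the surviving peaks/troughs;
4. **select** — a tag is informative iff its difference sequence satisfies
   2·f_min·Δt < L (f_min = 0.05 Hz) and mean|dᵢ| > Δ; the chest tag is
   preferred, the abdomen tag is the fallback, and a subject whose tags both
   fail is flagged as apneic. Accuracy against a reference rate R is
   100·(1 − |R̂ − R|/R).

A seeded simulator (`rfbreath.synth`) generates multi-tag phase logs with
the full physical model — quantisation, π-ambiguity events, wrapping, noise,
jittered sampling, apnea intervals — plus exact ground truth, so the whole
pipeline is testable end to end without hardware.

## Worked example

```sh
$ rfbreath simulate --subjects 3 --duration 120 --seed 7 -o demo
wrote 6 streams (21584 samples) to demo

$ rfbreath monitor demo/phase_log.csv --map demo/subject_map.csv
subject  tag                         rate Hz  rate bpm  apnea
      1  E28068940000000000000011     0.1995     11.97  no
      2  E28068940000000000000021     0.2647     15.88  no
      3  E28068940000000000000031     0.3296     19.77  no
```

The three subjects were simulated breathing at 0.2, 0.265 and 0.33 Hz
(`demo/truth.json`); the recovered rates agree within 0.01 Hz (12.0, 15.9
and 19.8 breaths/min), each read from the subject's chest tag, and no one is
flagged apneic. Adding `--apnea 12:30` to a 30 s simulation makes the first
subject hold their breath for 18 s, and `rfbreath apnea demo/phase_log.csv`
then reports `subject 1: APNEA` with the offending window. The other
subcommands expose the intermediate stages: `clean` writes the unwrapped
uniform phase, `rate` a per-tag JSON rate report, `reconstruct` the spline
waveform and extremum sequence per tag.

Everything the CLI does is a thin layer over the library:

```python
import rfbreath as rb

scenario = rb.default_scenario(n_subjects=3, seed=7)
streams, truth = rb.simulate_streams(scenario, duration_s=120.0)
report = rb.monitor(streams, rb.SubjectMap.from_epcs(streams))
print(report.subjects[1].rate_hz)   # 0.1995...
```

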