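# Methods

## Signal model

A passive UHF tag at distance `R` returns carrier phase
`θ = 4πR/λ + θ_t + θ_r + θ_tag (mod 2π)`, with `λ = c/f` (≈0.326 m at
920.625 MHz) and three hardware offsets that are constant within a session
(the simulator lumps them into one). The reader quantises phase to a 12-bit
code, `φ = v·2π/4096`, so the circular quantisation error is at most
π/4096. Two artefacts corrupt the sequence: with some probability a sample
is reported offset by π (reader ambiguity), and the wrapped phase jumps by
≈2π at period boundaries.

Breathing displaces the tag sinusoidally, `R(t) = R0 + A·sin(2π·f_r·t + φ0)`,
with `A` ≈ 2.5 mm (0.5 cm peak-to-peak) and `f_r` in 0.2–0.33 Hz for quiet
adult breathing. The phase therefore swings by `8πA/λ` ≈ 0.19 rad
peak-to-peak — two orders of magnitude above the quantisation step. Doppler
utilities are provided for completeness, but the shift breathing induces
(`2v·cos(α)/λ`, below 1e-2 Hz) is far beneath the reader's 0.0625 Hz Doppler
resolution, which is why the pipeline uses phase.

## Cleaning

Both jump removers scan in time order and compare each raw sample against
the previous **corrected** value; comparing against the raw predecessor
would let one correction trigger a cascade of misfires.

* **Disambiguation**: a sample whose circular distance to the reference is
  within Δ of π is corrected by ±π, choosing the sign that lands closer to
  the reference. Default Δ = 1.8 rad. The detection uses circular distance
  so that a genuine 2π wrap (circular distance ≈ 0) can never be mistaken
  for an ambiguity event.
* **Unwrapping**: a cumulative offset (multiple of 2π) is carried forward;
  when the offset-adjusted sample sits within Δ (default 1.0 rad) of a full
  period from the reference it is shifted by ∓2π toward continuity and the
  offset updated. Carrying the offset makes the rule correct after the
  accumulated phase has drifted through several periods, where a
  single-step comparison of raw values would stop firing. On slowly varying
  signals the result coincides with the standard cumulative 2π-correction
  (numpy.unwrap) up to a global 2π multiple.

Both operations are idempotent on their own output and length-preserving.
A stream that *begins* with a flipped sample is recovered up to a global π
offset — unavoidable, since a constant offset is unobservable; all
downstream processing is offset-invariant.

Readers interrogate tags at an irregular rate (20–40 Hz typically, varying
with distance and orientation), so the cleaned phase is linearly
interpolated onto a uniform grid at the stream's own mean rate
`Fs = (N−1)/span`. Linear interpolation is adequate because the signal
varies by ≪1 rad between reads; the error is second-order in `2πf_r/Fs`.

## Rate extraction

DC (the mean, dominated by the `4πR0/λ` term) is subtracted, then a
2nd-order Butterworth bandpass over 0.1–1.0 Hz removes low-frequency drift
and high-frequency noise; the respiratory rate is the frequency of the
largest FFT magnitude inside the band. The FFT is zero-padded to the next
power of two above `max(8N, Fs/0.01)` so the readout grid is ≤ 0.01 Hz;
ties break toward the lower frequency. Filtering is zero-phase
(forward–backward) by default because the reconstruction stage depends on
extremum timing; causal mode is available by flag. No taper is applied by
default (a Hann window is available via config) — the band-limited peak of
a 120 s record does not need one.

## Waveform reconstruction

The decomposition depth is chosen from the sampling rate: admissible depths
are `Ω = {n ≥ 0 : Fs/2ⁿ ∈ [0.6, 2.0] Hz}` (the band in which the
approximation keeps breathing but sheds noise), and among members with
`f(n) = Fs/2ⁿ − 2·F_rr ≥ 0` the minimiser of `f` is taken, `F_rr = 0.3` Hz
being a common breathing rate; this puts the effective rate just above
twice `F_rr`. When no member clears the floor (possible only for
non-default bands) the depth with smallest `|f(n)|` is used — the nearest
admissible resolution. At the reference reader rate 23.1674 Hz this yields
Ω = {4, 5} and n = 5.

The level-n **db2** approximation coefficients are used directly in their
decimated convention (times `t_k = t0 + k·2ⁿ/Fs`, amplitudes scaled by
`2^{n/2}`), with symmetric boundary extension; a full-length lowpass
reconstruction is available by flag. db2 is the shortest Daubechies wavelet
with usable symmetry properties; shorter (Haar) distorts phase, longer
buys little at this signal length.

Strict local extremes of the coefficients are the candidate breath peaks
and troughs (plateaus count once, at their first sample). Two filters
follow:

* **amplitude**: extremes are kept only if they swing at least
  `α·(ē_max − ē_min)` from the last kept one, with `α = 0.5` and the means
  computed once over the input sequence. Computing the means once (not
  after each rejection) keeps the threshold anchored to the breathing-scale
  swing of the whole record — essential for apnea detection, where a hold
  period contains only noise extremes that must be judged against the
  breathing amplitude. If the sequence contains only maxima or only minima
  the threshold is undefined and the filter passes everything through.
* **alternation**: the differences `d_i = e_{i+1} − e_i` must alternate in
  sign (a peak follows a trough). While an adjacent pair shares a sign, the
  middle extremum of the offending triple with the smallest `|d|`
  contribution is removed and the differences recomputed. The literal
  condition `d_i·d_{i−1} = −1` is read as sign alternation, since real
  products rarely equal −1 exactly. Zero differences count as violations
  inside a pair.

A natural cubic spline through the surviving extremes, evaluated at 10 Hz,
is the reconstructed waveform. The knots are the (time, value) extremes
themselves: a waveform cannot be rebuilt from the difference values alone,
which carry no time axis or baseline.

## Tag selection and apnea

Each subject wears a chest and an abdomen tag (different people breathe
thoracically, abdominally, or both). A tag is **informative** iff

* `2·f_min·Δt < L` with `f_min = 0.05` Hz — an apparent rate below 3
  breaths/min is not breathing; the factor 2 counts a peak and a trough per
  breath; and
* `mean |d_i| > Δ` — the phase must actually swing on a respiration scale.
  Δ is set to 0.015 rad (ten quantisation steps), separating breathing
  (~1 rad swings in the coefficient domain) from quantisation noise.

The chest tag is preferred when both pass (it is listed first by
convention); if only one passes it is selected; if neither passes the
subject is flagged apneic. Monitoring accuracy versus a reference rate is
`100·(1 − |R̂ − R|/R)` percent (negative for gross errors).

**Apnea detection** runs the reconstruction chain once per tag over the
full recording — so the extremum-filter threshold reflects breathing-scale
swings and prunes the small noise extremes inside a hold — and then
re-evaluates both principles on the extremes falling inside each sliding
window (default 20 s, hop half a window). A subject is flagged when some
window leaves every tag uninformative. The bandpass is **off** by default
in this mode: its transient smears the onset of a breath-hold into
spurious oscillation, and detection is more faithful without it.

## Synthetic data

The simulator is the package's test bed and defines its study conditions:
per-tag jittered sampling (mean 30 Hz, inter-arrival
`(1/rate)·(1 + U(−0.2, 0.2))`, integer-millisecond, strictly increasing),
Gaussian phase noise σ = 0.02 rad (reader jitter scale), i.i.d. π-ambiguity
with probability 0.05 per sample (the reader gives no occurrence model),
12-bit quantisation, and RSSI as a constant-plus-noise placeholder (RSSI is
too noisy to carry respiration and is unused downstream). Subjects default
to 2.5 mm amplitude at distinct rates spread over 0.2–0.33 Hz, 0.8–2 m from
the antenna; apnea intervals force the displacement to zero. Each tag draws
from its own seed substream, so output is byte-identical for a given
scenario and seed regardless of iteration order.

What the simulator does **not** model: multipath and fading, body-motion
artefacts other than breathing, tag-orientation and angular effects,
reader anticollision timing, RSSI path loss, and non-sinusoidal breathing
shapes. Passing tests therefore demonstrate correctness of the processing
chain under the stated physical model, not robustness to every artefact of
real recordings.

Problem sizes used in the tests were chosen for statistical adequacy: rate
recovery uses 120 s records (FFT grid 0.01 Hz needs ≥100 s for a clean
margin) over 20 seeds per rate; apnea recall uses 30 s records with an 18 s
hold over 10 seeds; jump-injection round trips use 60 s noiseless records.

## Known limitations

* The π-disambiguation threshold admits signals whose true inter-sample
  step approaches π − Δ; at the default Δ = 1.8 this requires inter-read
  phase steps > 1.34 rad, far outside the breathing regime, but fast
  non-respiratory motion would be corrupted.
* A global π or 2π offset of a whole stream is unobservable and is not
  (and need not be) recovered.
* Rate extraction reports a single stationary rate per record/window; it
  does not track within-record rate changes.
* The Eq.-style amplitude threshold Δ (0.015 rad) is a quantisation-scale
  floor; strong environmental phase noise can exceed it, in which case the
  length principle (backed by the record-wide extremum filter) carries the
  apnea decision.
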