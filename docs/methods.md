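# Methods

This note documents the model implemented by `somsnn`, its assumptions, the
defaults and why they were chosen, what the synthetic data does and does not
emulate, and the numerical choices made where the design was open.

## Auditory front-end

The front-end is an MFCC-style chain that stops at the log mel-filterbank
energies (no cepstral/DCT step): pre-emphasis, overlapping Hamming-windowed
frames, power spectrum via FFT, 20 triangular filters spaced uniformly on
the mel scale between `fmin` and `fmax`, and `log(energy + floor)`.

Parameter defaults and rationale:

- `preemphasis_alpha = 0.97` — the standard speech-processing value.
- Environmental-sound profile (`rwcp_profile`): 100 ms frames, 50 ms shift,
  200–8000 Hz. Speech profile (`tidigits_profile`): 25 ms frames, 15 ms
  shift, 200–10000 Hz. The speech profile's shift follows
  `shift = length − overlap` with a 10 ms overlap.
- `n_fft`: next power of two at or above the frame length in samples.
- Filters have unit peak height by default (`unit_peak=False` switches to
  unit area); centers are the interior points of a uniform mel grid with
  `n_filters + 2` edges.
- `log_floor = 1e-10` keeps silence finite at `log(1e-10)`.
- The last partial frame is dropped, so the frame count is exactly
  `floor((n − frame_len)/frame_step) + 1`.

## Self-organizing map

The map is trained with the classical online Kohonen rule rather than a
batch variant: for each presented frame, every unit moves toward the input
by `η(t)·exp(−d_grid(u, b)²/(2σ(t)²))`, where `b` is the best-matching unit
under Euclidean distance (ties to the lowest index). η decays exponentially
from 0.5 to 0.01 and σ from `max(rows, cols)/2` to 1 over the epochs; an
epoch is one shuffled pass over all frames of the training set. Weights are
initialized uniformly inside the per-feature min/max box of the data, and
all randomness flows from a single seed, so training is reproducible
bit-for-bit. The online rule was chosen because it is fully specifiable and
its convergence is easy to diagnose via the mean quantization error
(mean distance of frames to their BMU weights).

Spike encoding places one spike per activated unit per frame at
`i · frame_shift_ms` (frame start, 0-based); with top-K activation the
pattern has exactly `K · n_frames` events. The spike-time convention (frame
start rather than center or end) is arbitrary but global, so it cancels out
of all comparisons.

## Spiking classifier

Output neurons are kernel leaky integrate-and-fire units: the PSP kernel is
the causal difference of exponentials normalized to a unit maximum at
`t_peak = τ_m τ_s/(τ_m − τ_s) · ln(τ_m/τ_s)`. Membrane potentials are
evaluated on a uniform grid (default `dt = 1` ms); a spike is registered at
the first grid point where `V ≥ threshold` and `V` is rising
(`V(t) > V(t − dt)`). After a spike, later input events are shunted — the
single-spike regime needs no post-spike dynamics. The simulation extends
`3·τ_m` past the last frame so that late PSPs can still cross threshold.

The trace computation factorizes each exponential sum as
`exp(−t/τ) · cumsum(w_j · exp(t_j/τ))`, which is `O(events + grid)` and
matches a naive double loop to better than 1e-9 (tested); the factored
exponents stay well inside float64 range for pattern durations up to tens
of seconds.

Training (maximum-margin Tempotron): during learning the target neuron's
effective threshold is `V_thr + Δ` and non-targets use `V_thr − Δ`
(defaults `V_thr = 1.0`, `Δ = 0.5`, λ = 0.005, 10 epochs, Gaussian
`N(0, 10⁻³)` initial weights). LTP potentiates every input unit by the
kernel-weighted sum over its spikes preceding `t_max`; LTD is the
mirror-image depression at the erroneous spike time. Updates are applied
per sample (stochastic), with a seeded shuffle per epoch. With `Δ = 0` the
rule reduces exactly to the standard Tempotron; the test suite verifies the
weight trajectories are bit-identical in that case. Weights are neither
clamped nor renormalized.

Degenerate maximum: when a target neuron's potential never rises above
rest, the earliest-maximum convention puts `t_max` before the first input
spike and the LTP sum is empty, so learning would silently stall. In that
case `t_max` is taken as the maximum over the post-onset part of the trace
instead. This only matters for freshly initialized neurons with
near-symmetric weights and leaves the standard rule untouched whenever the
maximum is properly attained.

Decision rules at test time (margin removed): (1) no neuron fires → the
class with the highest peak potential (ties: lowest index); (2) exactly one
fires → that class; (3) several fire → the earliest spike, with ties broken
by the higher peak and then the lower index. The no-fire peak is taken over
the full simulated trace. The decision time is the deciding spike time, or
the pattern duration when nothing fires.

ReSuMe variant: each class neuron has a single desired spike time, computed
by presenting the class's training patterns to the randomly initialized
neuron and averaging the times of maximum potential. Updates use an
exponential learning window over preceding input spikes (amplitude λ,
time constant τ_s, no non-Hebbian bias by default; all configurable):
potentiation at the desired time, depression at actual spikes, which cancel
exactly when the neuron fires at the desired instant. The kernel time
constants should match the pattern timescale — for sub-second patterns the
sharper speech-profile kernel (τ_m = 225 ms, τ_s = 56.25 ms) separates
classes that the slower environmental-sound kernel blurs.

## Noise model

- Environmental noise: a seeded random contiguous segment of a noise
  recording is scaled by `g = sqrt(E_s/(E_n·10^(SNR/10)))` (energies are
  whole-sample sums of squares) and added; the realized SNR is exact to
  float precision. Multi-condition sets contain the clean clips plus one
  mixed copy per clip per SNR level (default levels 20, 10, 0, −5 dB, so
  200 clean clips become 1000).
- Neuronal noise: spike-time jitter adds i.i.d. `N(0, σ²)` to every event
  time, clipping into `[0, duration]` so event counts are preserved (σ is
  usually expressed as a fraction of the frame period); spike deletion
  removes each event independently with the given probability (an
  exact-count mode is available via a flag).

## Synthetic data

The sound generator emulates short isolated events: each class is a set of
linearly swept partials with a linear attack/decay envelope, a white-noise
floor, and a seeded duration draw; clips are peak-normalized. The default
study fixture has 5 classes with well-separated spectral trajectories
(steady tones, rising and falling sweeps, a high tone cluster, crossing
sweeps), 20 training and 20 test clips per class, 0.5–1.0 s at 16 kHz. The
babble surrogate sums eight amplitude-modulated, log-spaced noise bands over
100–4000 Hz, mimicking the low-frequency-dominated, non-stationary
character of multi-talker noise.

The spike generator bypasses the acoustic stages: each class is a prototype
unit sequence (a random walk confined to a per-class band of the unit
range, giving high inter-class variability), with multiplicative duration
warping and per-frame unit substitution as the intra-class noise knobs.

What passing tests show — and do not show: the fixture classes are cleanly
separable by design, so perfect accuracy on them demonstrates that the
pipeline's mechanics (encoding, margin training, decision rules, robustness
trends) work as specified, not that the architecture reaches any particular
accuracy on real corpora, whose class overlap, recording variability and
silence structure the generator does not model. Relative effects (margin ≥
no-margin, robustness to moderate deletion, early decisions) are the
meaningful read-outs.

## Pipeline and problem sizes

`run_train` trains the map on all training frames, encodes the clips, and
trains the classifier; `run_eval` applies one test-time transformation
(noise mixing per SNR, pattern truncation, jitter, or deletion) before
classification, and writes CSV decisions plus a JSON report carrying the
configuration hash and seeds. For the synthetic fixture the pipeline
default is 50 SOM epochs on an 8×8 map: the quantization error plateaus
well before that on these smooth, well-separated spectra, so the larger
epoch counts appropriate for real corpora (hundreds of passes) buy nothing
here. All other defaults are the standard settings listed above.

## Known limitations

- Single-layer, single-spike classification only; no multi-spike or
  multi-layer training.
- The online SOM is sequential by nature; very large maps or corpora would
  need a batch or accelerated implementation.
- ReSuMe's desired-time heuristic depends on the random probe weights; with
  few input units its potential maximum can sit near pattern onset, which
  weakens the learned discrimination (see the kernel-timescale remark
  above).
- WAV input is limited to mono integer-PCM or float files.
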