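# Methods

This note documents the models and procedures the engine implements, the
defaults and why they were chosen, what the synthetic fixtures do and do
not emulate, and the numerical conventions that make the behaviour exact
and reproducible.

## Signal conventions

All audio is mono, real-valued, full scale ±1.0. Levels are RMS in dB FS
(a constant full-scale signal is 0 dB FS; a full-scale sine −3.01 dB FS).
Test material is calibrated to a common **−25 dB FS** RMS so a single
comfort-level setting holds across a session. Calibration is exact (the
gain is computed in closed form, error < 1e−9 dB) and refuses to clip: a
target that would push the peak past full scale raises an error naming
the required reduction, rather than limiting silently — the level
contract is bit-exact. Durations round half-up to integer samples;
sample indexing is 0-based. Silence prepending (default 200 ms) pads
exact digital zeros and leaves the original samples bit-identical.

SNR mixing scales the **noise** and holds the speech fixed, keeping the
calibrated presentation level of the target constant. Noise longer than
the speech is cropped from a seeded random offset; shorter noise is
rejected rather than looped (looping introduces periodicity artifacts).

## Adaptive staircases

The transformed up–down engine makes the task harder after `n_up`
consecutive correct responses and easier after `n_down` consecutive
incorrect ones; both counters reset after any level change. Procedure
parameters:

| parameter | DIN | sweep density |
|---|---|---|
| rule | 1-up-1-down | 2-up-1-down |
| tracked variable | SNR (dB) | density (dimensionless) |
| start | 0 dB | 1.1 |
| rails | −20 … +20 dB | 1.0 … 20 |
| steps | 2 dB | 0.5, then 0.2 after reversal 4 |
| stop | 24 trials | 8 reversals |
| threshold | mean SNR of trials 9–24 | mean of last 4 reversal densities |
| convergence point | 50% correct | 70.7% correct |

The density floor is 1.0 (fewer than one sweep cannot be presented); the
ceiling of 20 is configurable. Both procedures are exposed as plain
configs (`din_config()`, `stripes_config()`), not hard-coded.

Two semantic choices the classical literature leaves open are fixed and
oracle-tested here:

* **Reversals at the rails.** A step clamped by a rail still counts as a
  move in its *intended* direction; a reversal is logged only when the
  intended direction flips. A track pinned at a rail for many trials
  therefore logs nothing until the response pattern actually turns.
* **Step schedule timing.** Each move uses the step size associated with
  the number of reversals logged at that moment, *including* a reversal
  logged by the move itself: with schedule `[(0, 0.5), (4, 0.2)]` the
  move that creates the fourth reversal already steps by 0.2.

A reversal-stopped track driven by a responder that never errs would
never finish, so configs accept an optional `max_trials` safety cap;
capped runs are flagged unconverged and excluded from threshold
estimation (the simulations use a cap of 1000 trials, which a plausible
listener never approaches).

## Simulated listeners

Responses are Bernoulli draws from a cumulative-Gaussian psychometric
function P(correct | x) = γ + (1 − γ − λ)·Φ(±(x − μ)/σ), with the sign
set by whether the task gets easier at high levels (DIN: easier at high
SNR) or low levels (density: easier at low density). The digit-triple
listener responds at the triplet level — one draw per trial — matching
the all-or-nothing scoring rule; per-digit simulation would need a
digit-confusion model the engine does not claim.

Validation targets are the classical transformed up–down convergence
points: 50% correct for 1-up-1-down, and for 2-up-1-down the level where
the probability of two consecutive correct responses is ½, i.e.
P(correct) = √½ ≈ 0.707. The Monte-Carlo checks use a DIN listener with
μ = −8 dB, σ = 2 dB (a plausible speech-in-noise slope) and a density
listener with μ = 4.0, σ = 0.8, γ = ½ (the target interval is one of two
positions, so chance is one half). Measured biases (500 runs/sessions)
are ≈ −0.01 dB for DIN and ≈ −0.15 density for the 2-up-1-down track —
the small negative density bias is the familiar mean-of-reversals
underestimate for a track approaching its convergence level from below
with large initial steps, and sits well inside the ±0.3 validation band.

## Task structures

*Ordered* tasks step through a manifest in fixed order, in a seeded
permutation (each stimulus exactly once per run), or adaptively by
looking up the row whose difficulty level equals the staircase level.
*Paired* tasks enumerate the cross product A×B of two stimulus sets —
the natural reading for comparing two processing conditions item by
item; a within-set mode (all C(n,2) pairs of one set) is available
behind a flag. *Ranked* tasks insert each new stimulus into the ranked
list by binary search, probing the midpoint of the remaining interval
(even intervals round toward the better-ranked end — deterministic
tie-breaking); any judgment sequence yields a total order, and a
transitive comparator yields the true order in at most
Σ_{k=2..n} ceil(log₂ k) comparisons.

The session state machine issues a warning once the inactivity clock
passes `warn_after_s` and terminates past `terminate_after_s`; responses
reset the clock, and recorded trials survive warning and termination.
Practice-phase trials are flagged and excluded from scoring by default.

## Connection check

Metrics: (a) the peak absolute normalized cross-correlation between
playback and recording over lags 0…`max_lag_ms` (default 250 ms,
generous for acoustic-plus-buffering delay), normalized per lag by the
energies of the playback and the aligned recording window so the
statistic is invariant to recording level and polarity; (b) the Pearson
correlation of moving-average-smoothed amplitude spectra (default 9
bins) computed on matched-length segments **after best-lag alignment**,
so a pure delay does not depress the spectral metric. Either metric at
or above its threshold ⇒ the recording matches the playback ⇒ the sound
came from the loudspeakers ⇒ the check fails. A zero-energy recording is
inconclusive (not a pass) with a silent-microphone advisory. The verdict
is advisory by design: it never blocks a session.

The thresholds (cross-correlation 0.3, spectral 0.6) were calibrated on
the synthetic scene grid — delayed, low-pass-filtered, attenuated
playback plus stationary Gaussian noise — to give ≥95% detection at
leak-to-noise ratios of 10 dB and above with ≤5% false alarms on
independent noise; measured rates on the seeded grid are 100% and 0%.
Real rooms add reverberation, nonstationary interference, and device
nonlinearities that the grid does not model; field false-alarm behaviour
under heavy background noise is documented but not reproducible here.

## Synthetic stimuli

The fixture generators make the engine testable offline; none claims
perceptual fidelity to recorded corpora.

* **Digit tokens** are harmonic complexes with digit-specific
  fundamentals (96–324 Hz), alternating spectral tilt, and digit-indexed
  syllabic amplitude modulation; all 45 digit pairs stay below 0.9 peak
  normalized cross-correlation, and tokens are bit-reproducible per
  (digit, seed). They stand in for a recorded male-talker digit corpus.
* **Speech-shaped noise** filters white Gaussian noise by the square
  root of the reference's Welch power spectrum and matches its RMS;
  250 ms windows stay within ±3 dB of the global RMS (stationarity).
* **Sweep stimuli** sum `n_components` (default 4) exponential glides
  traversing [f_low, f_high] `density` times per stimulus, staggered
  evenly in sweep phase; up and down differ only in sweep sign. This
  geometry is a documented surrogate: it makes density monotonically
  control sweep repetitions and keeps up/down machine-discriminable
  (the quadrant-energy orientation statistic of the log-spectrogram's
  2-D spectrum separates the two perfectly at density 1.1), which is
  what exercising the adaptive procedure requires. It is *not* a
  perceptually validated reconstruction of the published test stimuli.

## Persistence

Manifests are UTF-8 CSV with a mandatory header
(`filename,difficulty_level,response_options,correct_answer,condition`);
XLSX is accepted read-only. Validation is total: every malformed input
produces a row-addressed error (header = row 1), never a crash. Results
are a versioned JSON document (schema version 1; any other version
raises an explicit migration error) whose export → import round trip is
the identity, plus a flat per-trial CSV for analysis software.
Timestamps are UTC ISO-8601. Participant tokens are 128-bit random
identifiers carrying no personal data, unique per project by
construction. WAV I/O covers mono PCM16/24 and float32; integer export
is undithered so round trips are deterministic.

## Problem sizes used in validation

The shipped checks use 1 000 random response sequences per staircase
config for oracle equivalence, 500 Monte-Carlo runs/sessions for
convergence, 100 seeded scenes per operating point of the connection
check, 1 000 random waveform pairs for calibration/mixing exactness, all
720 permutations at n = 6 (plus seeded n = 50 trials) for ranking, and a
16 kHz sample rate for synthesis checks — sizes at which the binomial
and Monte-Carlo error of each estimate is comfortably inside its
validation band.

## Known limitations

* No real-time audio, capture, or transport (Bluetooth latency and
  dropouts are out of scope); recordings enter as WAV files.
* No absolute SPL calibration — levels are digital (dB FS) only, so
  absolute detection thresholds are out of reach by design.
* Keyword scoring is exact token matching after lower-casing and
  punctuation stripping; morphological leniency (plurals, tense) is off
  by default and available as a documented flag, since human scorers'
  leniency rules vary. No automatic speech recognition.
* The noise-reduction processing condition of speech-perception studies
  is represented only as an intelligibility parameter in simulations,
  not as a signal-processing stage.
* Inferential statistics on exported results (ANOVA, mixed models,
  reliability coefficients) are left to standard statistics tooling.
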