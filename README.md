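# auditest

An offline, scriptable engine for adaptive listening tests in hearing
research — the computational core of a remote listening-test platform for
cochlear-implant and hearing-aid users, rebuilt as a Python library that
runs entirely without a browser, audio hardware, or human participants.

It is aimed at auditory-psychophysics researchers who want to prototype,
validate, and regression-test listening procedures (speech-in-noise tests,
adaptive discrimination tracks, paired-comparison rankings, technical
device checks) before deploying them to real participants.

## What it implements

**Stimulus calibration and synthesis** (`auditest.audio`, `auditest.synth`)
— mono waveforms at full scale ±1.0; exact RMS calibration in dB FS
(default −25 dB FS across all test material); SNR mixing that scales the
noise and holds the speech level fixed; silence prepending (default
200 ms) to protect stimulus onsets from wireless wake-up delays; and
deterministic synthetic stimuli: digit-like harmonic-complex tokens,
speech-shaped stationary noise matched to a reference spectrum, and
"stripes" stimuli built from concurrent exponential frequency sweeps
whose repetition *density* is the tracked difficulty variable.

**Adaptive staircases** (`auditest.staircase`) — a generic transformed
up–down engine with two preconfigured procedures:

* *Digits-in-noise (DIN)*: 1-up-1-down on SNR, 2 dB steps, start 0 dB,
  rails ±20 dB, 24 trials; the speech reception threshold (SRT) is the
  mean SNR of the final 16 trials after discarding the first 8.
* *Sweep-density (STRIPES-style)*: 2-up-1-down on density, start 1.1,
  steps 0.5 then 0.2 after the fourth of eight reversals; the threshold
  is the mean of the final four reversal densities, and the final score
  the mean of two runs.

A 1-up-1-down track converges near the 50%-correct level, a 2-up-1-down
track near the 70.7%-correct level (where P(two consecutive correct) = ½).

**Task structures and sessions** (`auditest.tasks`) — ordered
(fixed/random/adaptive) stimulus sequencing from a manifest; paired
comparisons over two stimulus sets; full rank ordering by binary
insertion with midpoint probes (never more than Σ ceil(log₂ k)
comparisons); and a session state machine with inactivity warning and
termination timers.

**Technical checks** (`auditest.checks`) — the connection check compares
a concurrent microphone recording with the playback by peak normalized
cross-correlation in time and by correlation of smoothed amplitude
spectra; a high correlation in either domain means the sound leaked from
the loudspeakers rather than streaming directly, so a *match fails* the
check. Plus the loudness (comfort-level, locked per session) and
microphone checks, and a synthetic acoustic-scene generator for testing
the detector without hardware.

**Scoring and I/O** (`auditest.scoring`, `auditest.session_io`) —
three-keyword sentence scoring (0–3 per trial, percent correct per
list), all-or-nothing ordered digit-triple scoring, CSV stimulus
manifests with row-addressed validation, anonymous participant tokens,
and versioned, losslessly round-tripping result export.

**Simulated listeners** (`auditest.simulate`) — cumulative-Gaussian
responders P(correct) = γ + (1 − γ − λ)·Φ(±(x − μ)/σ) that drive every
procedure end to end and report estimator bias against the theoretical
convergence points.

## Worked example

Validate the digits-in-noise procedure against a simulated listener with
a 50%-correct SNR of −8 dB and slope 2 dB:

```sh
$ auditest simulate din --runs 500 --seed 1
{
  "procedure": "din",
  "mean": -8.0115,
  "sd": 0.6999804964359947,
  "target": -8.0,
  "bias": -0.011499999999999844,
  "n_runs": 500,
  "n_unconverged": 0,
  "seed": 1
}
```

Across 500 simulated 24-trial tracks the mean estimated SRT is −8.01 dB
against the listener's true −8.00 dB 50% point — a bias of −0.01 dB with
a run-to-run SD of 0.70 dB, i.e. the adaptive procedure and its
final-16-trials estimator recover the listener's threshold essentially
unbiased. The same harness is available from Python:

```python
from auditest import PsychometricListener, run_din_simulation

listener = PsychometricListener(threshold_mu=-8.0, slope_sigma=2.0)
report = run_din_simulation(listener, n_runs=500, seed=1)
print(report.mean, report.bias)   # -8.0115 -0.0115
```

Other entry points: `auditest simulate stripes|keywords`,
`auditest connection-check --playback a.wav --recording b.wav`,
`auditest validate-manifest stimuli.csv`, `auditest make-token`,
`auditest run-task task.json --manifest m.csv --listener l.json --out out/`.

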