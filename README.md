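# sleepwvd

Automatic wake / deep-sleep (N3) staging from a single EEG channel, built
the way a sleep technician scores: absolute, interpretable rules on band
energies rather than a black-box classifier.

Sleep labs score overnight polysomnography by eye, 30 seconds at a time —
slow, costly and subjective. `sleepwvd` reproduces the technician's
decisions for the two stages with the clearest EEG signatures: **wake**
(alpha rhythm, 8–13 Hz, for more than 15 s of an epoch) and **N3 /
slow-wave sleep** (0.5–2 Hz waves over 75 µV covering ≥ 20 % of an epoch),
with everything else grouped as "other". It is aimed at sleep researchers
and engineers who need reproducible wake/N3 hypnograms or a transparent
baseline against which to compare heavier models.

## Method

For each one-second block of the referenced EEG trace (e.g. C3−M2), the
discrete **Wigner–Ville distribution** (WVD) of the analytic signal

&nbsp;&nbsp;&nbsp;&nbsp;W(t, f) = ∫ z(t + τ/2) z*(t − τ/2) e^(−j2πfτ) dτ

is integrated over time to give a cross-term-free marginal spectrum on a
0.5 Hz grid, from which per-second band energies are read off: E_δs
(0.5–4 Hz), E_θs (4–8 Hz), E_αs (8–13 Hz), E_Ts (0.3–35 Hz), plus their
all-night totals. Three normalized, amplitude-invariant features drive the
rules:

| feature | definition | used for |
|---|---|---|
| P_M | E_Ts / E_Tall | major body movement (P_M > T_M, or P_M = 0 for electrode loss, > 15 s of an epoch) |
| P_W | (E_αs − E_θs) / E_θall | wake (P_W > T1 for > 15 s of an epoch) |
| P_N3 | E_δs / E_δall | N3 (within-epoch 80th percentile of P_N3 > T2, rank n = ⌈P/100 · 30⌉ = 24) |

Movement epochs are resolved the AASM way: any alpha activity → wake
(even if brief); a wake neighbour → wake; otherwise the epoch inherits the
following epoch's stage. The two free thresholds (T1, T2) are tuned by
**particle swarm optimization** (200 particles, 40 iterations, c1 = c2 = 1,
random inertia weight) maximizing pooled epoch accuracy against technician
hypnograms; agreement is reported as confusion matrices with sensitivity,
accuracy and Cohen's κ = (p_o − p_c)/(1 − p_c).

A seeded synthetic-night generator (alpha-laden wake epochs, ≥ 75 µV slow
waves, mixed-frequency light sleep, movement bursts and electrode dropouts)
makes the whole train/score/evaluate loop runnable without clinical data.

## Worked example

```sh
python examples/03_train_and_score.py
```

trains thresholds on four synthetic nights and scores four held-out ones:

```
optimized thresholds: t1 = 7.740e-05, t2 = 4.389e-04
training accuracy:    100.00 %
held-out epochs:      400
wake: sensitivity 100.0 %, accuracy 100.0 %, kappa 1.0
n3:   sensitivity 100.0 %, accuracy 100.0 %, kappa 1.0
global accuracy:      100.0 %
```

The thresholds are the learned baselines on the night-normalized features
(dimensionless); kappa 1.0 means perfect chance-corrected agreement with
the generator's truth — expected here because the synthetic stages are
well separated, and a ceiling for what the rules can do on real EEG. The
other examples show the WVD cross-term cancellation (`01`), the feature
separation per stage (`02`), and the metric computations on a published-
style 8207-epoch confusion table (`04`).

The same loop is available from a shell:

```sh
sleepwvd simulate --nights 4 --epochs 100 --out nights/
sleepwvd train --nights nights/manifest.csv --out thresholds.json
sleepwvd score --edf nights/night00.edf --thresholds thresholds.json --out pred.csv
sleepwvd evaluate --pred pred.csv --truth nights/night00.csv --out report.json
```

## Layout

- `src/sleepwvd/signal_io.py` — EDF/CSV I/O, µV conversion, 30-s epoching
- `src/sleepwvd/wvd.py` — discrete WVD, marginal spectrum, band energies
- `src/sleepwvd/features.py` — P_M, P_W, P_N3, percentile, thresholds
- `src/sleepwvd/staging.py` — rule engine and movement resolution
- `src/sleepwvd/pso.py` — particle swarm threshold optimization
- `src/sleepwvd/metrics.py` — confusion matrices, sensitivity, κ
- `src/sleepwvd/synthetic.py` — seeded synthetic PSG nights
- `src/sleepwvd/pipeline.py`, `cli.py` — disk-level orchestration + CLI

See `docs/methods.md` for modelling assumptions, numerical choices and
limitations.
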