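# Methods

## Model and scope

`sleepwvd` classifies each 30-second epoch of a single referenced EEG
derivation into WAKE, N3 or OTHER, mimicking technician scoring under the
AASM definitions. The pipeline is: per-second time–frequency energy
extraction → night-normalized features → threshold rules with AASM
movement resolution → threshold optimization against technician labels →
chance-corrected agreement reporting. N1/N2/REM discrimination, artifact
rejection beyond the movement rule, and smoothing of the stage sequence
are out of scope.

## Discrete Wigner–Ville distribution

Each one-second block of `N = fs` samples is analysed independently. The
block is made analytic (FFT-based Hilbert transform), which removes
negative frequencies and with them the aliasing above fs/4 and the
positive/negative-frequency cross-terms of the discrete WVD. The kernel
`K[n, m] = z[n+m] · conj(z[n−m])` (zero-extended outside the block) is
transformed over the lag `m` with a length-2N FFT; the even-indexed bins
give an N-bin frequency axis with spacing `fs / (2N)` = 0.5 Hz, which puts
the band edges 0.5, 4, 8 and 13 Hz exactly on bin centres. Per-second
blocks keep the cost at O(N² log N) per second and make the marginal
cross-term-free, instead of an infeasible whole-night N² transform.

**Marginal condition at finite length.** The time sum of the matrix obeys
the exact identity

    sum_n W[n, k] = (|Z[k]|² + |Z[k+N]|²) / (2N),

where `Z` is the 2N-point DFT of the zero-padded block — the squared DFT
magnitude with the upper half folded back. The folded term is the alias
inherent to the half-sample-lag discretization; for analytic inputs it is
small except immediately below fs/2 and it is part of the module's defined
scaling. `marginal_spectrum` is computed from this identity directly (and
equals the explicit matrix sum to machine precision); the grand total
equals the block energy exactly. Band energies divide by `2 fs` to convert
analytic-signal energy per sample to real-signal energy in µV²·s, so a
30 µV tone reads ~450 µV²·s per second.

**What cancels and what does not.** The oscillatory cross-term of a
two-tone signal is order-1 in the raw matrix and collapses in the marginal:
for 6 + 11 Hz tones the residual at the 8.5 Hz midpoint bin is the
rectangular-window edge term, analytically `|2|²/(2N)` ≈ 1.2·10⁻⁴ of the
peak at fs = 256; for tones an even number of Hz apart it cancels exactly.
Separately, an on-bin tone leaks a deterministic few percent of its energy
into half-integer bins (Dirichlet sidelobes of the 1-s rectangular window;
no taper is applied, deliberately — tapering is exactly the
resolution-for-cross-term trade this construction avoids). In-band shares
are therefore ~0.965 (alpha at 10 Hz) and ~0.984 (delta at 1 Hz) rather
than 1.0; all such levels are fixed numbers, not noise. Circular time
shifts leave the marginal exactly invariant for circularly-consistent
content (integer-Hz components); for arbitrary content the shift moves the
window-edge discontinuity and the padded spectrum itself changes.

## Features and thresholds

P_M = E_Ts/E_Tall, P_W = (E_αs − E_θs)/E_θall and P_N3 = E_δs/E_δall are
dimensionless and invariant to overall amplitude scaling, absorbing
inter-subject and inter-montage gain differences. Normalization totals
include movement and wake seconds; P_W is computed for every second,
including inside movement epochs, because the alpha-presence check needs
it there. The N3 statistic is the within-epoch 80th percentile of P_N3
with the rank-order definition n = ⌈P/100 · M⌉ (n = 24 for M = 30; exact
for the used case, ceiling for non-integer products). The within-epoch
percentile uses all 30 seconds, movement-flagged or not.

Defaults: T_M = 5·10⁻⁴ (movement), T1 and T2 learned. All "more than
15 s" rules are strict (> 15), and `P_M = 0` is tested as ≤ 10⁻¹² so that
near-zero float residue still counts as electrode loss.

**The movement threshold encodes a night length.** Because P_M sums to 1
over the night, its per-second mean is 1/n_seconds, and a fixed T_M is
really "a second holding more than T_M · n_seconds times the mean energy
share" — about 12× for a typical ~820-epoch night. For nights of other
lengths `Thresholds.tm_for_night(n_seconds)` returns the equivalent
threshold `T_M · 24600 / n_seconds` (24 600 s being the reference night).
Short experimental nights (e.g. 100 epochs) must use it: with the raw
default, ordinary slow-wave seconds of a 100-epoch night would exceed the
cut for arithmetic reasons alone. The staging engine itself stays literal
(`P_M > tm` with `tm` as configured).

## Rule engine

Non-movement epochs: WAKE if > 15 seconds have P_W > T1; else N3 if the
P_N3 percentile exceeds T2; else OTHER. WAKE takes full precedence — a
wake-positive epoch is never tested for N3. Movement epochs (> 15 flagged
seconds) are resolved afterwards: (a) alpha at any point → WAKE, with
alpha-presence operationalised as *any* second with P_W > T1 (one alpha
definition for the whole system); (b) a WAKE immediately before or after →
WAKE; (c) otherwise the stage of the following epoch, applied right-to-left
so a run of movement epochs inherits the first stage after the run; a run
ending the night inherits the preceding stage (the following epoch does
not exist). All-movement nights are rejected as unresolvable.

## Threshold optimization

Global-best PSO over a 2-D box, defaults t1 ∈ [0, 10⁻⁴], t2 ∈ [0, 10⁻³]
(spanning the plausible range of the night-normalized features;
configurable). Swarm 200, 40 iterations, c1 = c2 = 1, inertia weight drawn
uniformly in (0, 1) each iteration and shared across the swarm (a fixed
float is accepted for degenerate-case testing). Velocities are clamped to
20 % of each dimension's range and positions to the box; personal/global
bests update on strict improvement only, so ties keep the first find and
the best-fitness history is non-decreasing. Fitness is pooled 3-class
epoch accuracy over all training nights (joint 2-D optimization); a single
seeded generator drives everything and the seed is recorded in the result.

## Synthetic nights

The generator emulates the statistical signatures the classifier senses,
not physiological EEG (no spindles, K-complexes or sawtooth waves):

- background: Gaussian noise band-limited to 0.3–35 Hz, 10 µV rms;
- WAKE: 10 Hz, 30 µV alpha in 22 randomly placed seconds (> 15);
- N3: 1 Hz slow wave, 150 µV peak-to-peak (AASM floor 75 µV), over a
  contiguous 80 % of the epoch;
- LIGHT/REM: background plus 5 Hz, 20 µV theta;
- MOVEMENT: a contiguous 20-s burst of 500 µV-scale noise low-passed to
  0.3–5 Hz, or (probability 0.3) a flat electrode-loss segment. Bursts are
  low-frequency dominated — as electrode/movement artifact is — rather
  than broadband; a broadband burst would carry more alpha- than
  theta-band energy and spuriously trigger the alpha branch of the
  movement resolution. Per-second burst power is held constant at the
  uniform-noise level (amp²/3): sustained artifact, not a flickering one.
  Optional alpha seconds inside movement epochs (`movement_alpha_prob`)
  exercise the alpha branch deliberately.

Stage sequences come from an explicit script, a first-order Markov chain,
or i.i.d. draws from WAKE .20 / N3 .22 / LIGHT .43 / REM .13 /
MOVEMENT .02 — movement epochs are rare in technician-scored nights, and
because low-frequency artifact energy enters the all-night delta
normalizer, an unrealistically high movement rate would also make the N3
feature scale vary strongly across short nights. The truth hypnogram
labels MOVEMENT epochs the way a scorer would, using the same neighbour
rule as the classifier (alpha → W, else the following epoch's stage).
Everything is reproducible from the seed; presets exist for the three
recording rates 200/256/512 Hz.

What passing synthetic tests shows — and does not. They verify the
machinery end to end: feature separation, rule logic, threshold recovery
and generalization across independently generated nights. They do not
certify performance on real EEG, where alpha is intermittent and
reactive, slow waves are non-sinusoidal, stages are autocorrelated, and
electrode quality varies; published technician-agreement levels on real
recordings (κ ≈ 0.8 for wake) are the realistic expectation, not the
near-perfect synthetic numbers.

## Numerical choices

- Band intervals are half-open [f_lo, f_hi): 4 Hz belongs to theta, 8 Hz
  to alpha, 13 Hz to neither.
- The marginal is clipped at zero after the (exact) folded-DFT evaluation.
- Percentile ranks guard against float excess with a 10⁻⁹ backoff before
  the ceiling.
- Trailing partial epochs are discarded at segmentation with a logged
  warning; epoch indices are 0-based everywhere.
- EDF is written 16-bit with symmetric physical range padded 0.1 % above
  the extreme and rounded to an 8-character header field; round-trip error
  is below one quantization step. Physical values are converted to µV at
  read time (the 75 µV criterion is absolute).
- Technician labels collapse to {WAKE, N3, OTHER} exactly once, in
  `metrics` (W → WAKE; N1/N2/REM → OTHER).
- Display rounding is 2 decimals for percentages and kappa; comparisons in
  code use full precision.

## Problem sizes

The synthetic recovery experiment uses 4 training + 4 held-out nights of
100 epochs at 256 Hz — ample for the threshold plateau to be located, and
a size at which the whole experiment (generation, extraction, PSO,
scoring) completes in well under a minute. The movement threshold for
these nights comes from `tm_for_night(3000)`.

## Known limitations

- The C3−M2 vs C3−M4 derivation choice is configuration, not detection;
  recordings with pervasive alpha contamination (poor electrode placement)
  will defeat the wake rule, as they defeat the method on real data.
- A fixed T2 assumes the night's delta normalizer is dominated by genuine
  slow-wave sleep; nights with little N3 or heavy low-frequency artifact
  shift the P_N3 scale.
- The rule engine has no notion of stage context (no smoothing/HMM), so
  isolated misclassified epochs are not corrected.
- Only EDF/EDF+ signals and CSV hypnograms are supported; EDF+ annotation
  channels are not parsed.
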