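"""Seeded synthetic PSG nights with the structure the classifier senses.

Real overnight recordings are rarely shareable, so the pipeline is exercised
on generated nights that reproduce the *statistical* signatures the staging
rules key on, not physiological EEG:

* WAKE epochs carry a 10 Hz alpha sinusoid in more than 15 of the 30
  seconds (default 22), riding on band-limited background noise.
* N3 epochs carry a 1 Hz slow wave with >= 75 uV peak-to-peak amplitude
  (default 150 uV) over a contiguous block covering 80% of the epoch.
* LIGHT / REM epochs are background plus a modest 5 Hz theta component,
  mimicking mixed-frequency light sleep.
* MOVEMENT epochs contain a contiguous high-amplitude low-frequency burst
  over more than 15 seconds, or (with probability ``dropout_prob``) a flat
  electrode-loss segment instead.

Background noise is Gaussian, band-limited to the 0.3-35 Hz recording band.
Stage sequences come from an explicit script or a first-order Markov chain;
everything is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .signal_io import (EPOCH_LEN_S, EpochedRecording, Hypnogram,
                        TECHNICIAN_STAGES)
from .staging import resolve_movement_epochs

__all__ = [
    "SyntheticNightConfig",
    "STAGES",
    "generate_stage_sequence",
    "synthesize_epoch_waveform",
    "generate_night",
    "hospital_profile",
]

#: generator stage alphabet (truth side; MOVEMENT is resolved in the
#: technician hypnogram the way a scorer would)
STAGES = ("WAKE", "N3", "LIGHT", "REM", "MOVEMENT")

#: default stationary mix of a plausible night: mostly light/REM sleep,
#: a fifth wake, a fifth N3, and the rare movement epoch (major body
#: movements cover only a percent or two of a technician-scored night)
DEFAULT_STAGE_PROBS = {
    "WAKE": 0.20, "N3": 0.22, "LIGHT": 0.43, "REM": 0.13, "MOVEMENT": 0.02,
}

#: mapping of generator stages to technician tokens (MOVEMENT handled
#: separately by neighbour resolution)
_TECH_TOKEN = {"WAKE": "W", "N3": "N3", "LIGHT": "N2", "REM": "REM"}


@dataclass(frozen=True)
class SyntheticNightConfig:
    fs: int = 256
    #: explicit per-epoch stage script; None draws i.i.d. from stage_probs
    stage_script: tuple[str, ...] | None = None
    #: per-stage probabilities (i.i.d. draw) when no script is given
    stage_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STAGE_PROBS))
    #: optional Markov transition spec {stage: {stage: prob}}
    markov: dict[str, dict[str, float]] | None = None
    alpha_freq: float = 10.0
    alpha_amp: float = 30.0          # uV
    alpha_seconds_wake: int = 22     # seconds of alpha per WAKE epoch (> 15)
    delta_freq: float = 1.0
    delta_p2p: float = 150.0         # uV peak-to-peak (AASM floor is 75)
    delta_fraction_n3: float = 0.8   # fraction of the epoch with slow waves
    theta_freq: float = 5.0
    theta_amp: float = 20.0          # uV, light/REM mixed-frequency content
    background_rms: float = 10.0     # uV, band-limited 0.3-35 Hz noise
    movement_amp: float = 500.0      # uV, artifact burst amplitude
    movement_seconds: int = 20       # burst length (> 15 s)
    dropout_prob: float = 0.3        # movement epoch is flat-zero instead
    movement_alpha_prob: float = 0.0 # movement epoch also carries alpha seconds
    seed: int = 0

    def __post_init__(self) -> None:
        if self.delta_p2p < 75:
            raise ValueError("delta_p2p below the 75 uV slow-wave floor")
        if not 0 < self.delta_fraction_n3 <= 1:
            raise ValueError("delta_fraction_n3 must be in (0, 1]")
        if self.alpha_seconds_wake <= 15:
            raise ValueError("alpha_seconds_wake must exceed 15 s")
        if self.movement_seconds <= 15:
            raise ValueError("movement_seconds must exceed 15 s")


def hospital_profile(fs: int) -> SyntheticNightConfig:
    """Preset mirroring one of the three recording sites (200/256/512 Hz)."""
    if fs not in (200, 256, 512):
        raise ValueError("site sampling rates are 200, 256 or 512 Hz")
    return SyntheticNightConfig(fs=fs)


def generate_stage_sequence(cfg: SyntheticNightConfig, n_epochs: int) -> tuple[str, ...]:
    """Truth stage sequence: explicit script, Markov chain, or i.i.d. mix."""
    if n_epochs < 1:
        raise ValueError("n_epochs must be >= 1")
    if cfg.stage_script is not None:
        script = tuple(cfg.stage_script)
        bad = sorted(set(script) - set(STAGES))
        if bad:
            raise ValueError(f"unknown stages in script: {bad}")
        if len(script) != n_epochs:
            raise ValueError(f"script length {len(script)} != n_epochs {n_epochs}")
        return script
    rng = np.random.default_rng(cfg.seed)
    if cfg.markov is not None:
        states = list(cfg.markov)
        rows = {}
        for s, row in cfg.markov.items():
            p = np.array([row.get(t, 0.0) for t in states], dtype=float)
            if abs(p.sum() - 1.0) > 1e-9:
                raise ValueError(f"Markov row for {s!r} sums to {p.sum()}, not 1")
            rows[s] = p
        seq = [states[rng.choice(len(states))]]
        for _ in range(n_epochs - 1):
            seq.append(states[rng.choice(len(states), p=rows[seq[-1]])])
        return tuple(seq)
    states = list(cfg.stage_probs)
    p = np.array([cfg.stage_probs[s] for s in states], dtype=float)
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"stage_probs sum to {p.sum()}, not 1")
    draws = rng.choice(len(states), size=n_epochs, p=p)
    return tuple(states[i] for i in draws)


def _background(n: int, cfg: SyntheticNightConfig, rng: np.random.Generator) -> np.ndarray:
    sos = butter(4, [0.3, 35.0], btype="bandpass", fs=cfg.fs, output="sos")
    x = sosfiltfilt(sos, rng.standard_normal(n))
    rms = np.sqrt(np.mean(x**2))
    return cfg.background_rms / rms * x if rms > 0 else x


def _burst(n: int, cfg: SyntheticNightConfig, rng: np.random.Generator) -> np.ndarray:
    # movement/electrode artifact: high-amplitude, low-frequency dominated,
    # with per-second power held at that of uniform +-amp noise (sustained
    # artifact, not a flickering one)
    sos = butter(4, [0.3, 5.0], btype="bandpass", fs=cfg.fs, output="sos")
    x = sosfiltfilt(sos, rng.uniform(-1, 1, size=n))
    x = x.reshape(-1, cfg.fs)
    rms = np.sqrt(np.mean(x**2, axis=1, keepdims=True))
    target = cfg.movement_amp / np.sqrt(3.0)
    return (target / rms * x).ravel()


def synthesize_epoch_waveform(
    stage: str, cfg: SyntheticNightConfig, rng: np.random.Generator,
    alpha_in_movement: bool = False,
) -> np.ndarray:
    """One 30-s microvolt waveform with the energy signature of ``stage``."""
    fs = cfg.fs
    n = EPOCH_LEN_S * fs
    t = np.arange(n) / fs
    x = _background(n, cfg, rng)
    if stage == "WAKE":
        secs = rng.choice(EPOCH_LEN_S, size=cfg.alpha_seconds_wake, replace=False)
        mask = np.zeros(EPOCH_LEN_S, dtype=bool)
        mask[secs] = True
        gate = np.repeat(mask, fs)
        x = x + gate * cfg.alpha_amp * np.sin(
            2 * np.pi * cfg.alpha_freq * t + rng.uniform(0, 2 * np.pi))
    elif stage == "N3":
        n_active = int(round(cfg.delta_fraction_n3 * EPOCH_LEN_S))
        start = rng.integers(0, EPOCH_LEN_S - n_active + 1)
        mask = np.zeros(EPOCH_LEN_S, dtype=bool)
        mask[start:start + n_active] = True
        gate = np.repeat(mask, fs)
        x = x + gate * (cfg.delta_p2p / 2) * np.sin(
            2 * np.pi * cfg.delta_freq * t + rng.uniform(0, 2 * np.pi))
    elif stage in ("LIGHT", "REM"):
        x = x + cfg.theta_amp * np.sin(
            2 * np.pi * cfg.theta_freq * t + rng.uniform(0, 2 * np.pi))
    elif stage == "MOVEMENT":
        start = rng.integers(0, EPOCH_LEN_S - cfg.movement_seconds + 1)
        sl = slice(start * fs, (start + cfg.movement_seconds) * fs)
        if rng.uniform() < cfg.dropout_prob:
            x[sl] = 0.0                                   # electrode loss
        else:
            x[sl] = _burst(cfg.movement_seconds * fs, cfg, rng)
        if alpha_in_movement:
            free = [s for s in range(EPOCH_LEN_S)
                    if s < start or s >= start + cfg.movement_seconds]
            take = free[: max(1, len(free) // 2)]
            mask = np.zeros(EPOCH_LEN_S, dtype=bool)
            mask[take] = True
            gate = np.repeat(mask, fs)
            x = x + gate * cfg.alpha_amp * np.sin(
                2 * np.pi * cfg.alpha_freq * t + rng.uniform(0, 2 * np.pi))
    else:
        raise ValueError(f"unknown stage {stage!r}")
    return x


def _resolve_truth(script: tuple[str, ...], alpha_flags: np.ndarray) -> tuple[str, ...]:
    """Technician truth labels, resolving MOVEMENT epochs the AASM way."""
    movement = np.array([s == "MOVEMENT" for s in script])
    base = [None if m else _TECH_TOKEN[s] for m, s in zip(movement, script)]
    # reuse the staging neighbour rule on technician tokens ('W' plays WAKE)
    resolved = resolve_movement_epochs(
        movement, alpha_flags,
        ["WAKE" if b == "W" else b for b in base],
    )
    return tuple("W" if s == "WAKE" else s for s in resolved)


def generate_night(
    cfg: SyntheticNightConfig, n_epochs: int
) -> tuple[EpochedRecording, Hypnogram]:
    """One synthetic night: epoched microvolt trace plus technician truth.

    MOVEMENT epochs appear in the waveform but are resolved to a technician
    stage in the truth hypnogram (alpha content -> W, else the following
    epoch's stage), matching how a scorer labels movement-obscured epochs.
    """
    script = generate_stage_sequence(cfg, n_epochs)
    if all(s == "MOVEMENT" for s in script):
        raise ValueError("unresolvable night: every epoch is a movement epoch")
    rng = np.random.default_rng(cfg.seed + 1)   # independent of the sequence draw
    alpha_flags = np.array([
        s == "MOVEMENT" and cfg.movement_alpha_prob > 0
        and rng.uniform() < cfg.movement_alpha_prob
        for s in script
    ])
    chunks = [
        synthesize_epoch_waveform(s, cfg, rng, alpha_in_movement=bool(alpha_flags[e]))
        for e, s in enumerate(script)
    ]
    rec = EpochedRecording(np.concatenate(chunks), cfg.fs, channel_label="C3-M2")
    truth = Hypnogram(_resolve_truth(script, alpha_flags), TECHNICIAN_STAGES)
    return rec, truth
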