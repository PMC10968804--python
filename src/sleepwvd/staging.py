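"""Technician-mimicking rule engine for wake / N3 / other staging.

The decision logic per 30-s epoch, in AASM order:

1. *Movement*: a second is movement-flagged when its normalized total energy
   P_M exceeds the movement threshold (high-amplitude artifact) or is zero
   (electrode loss).  An epoch with more than 15 flagged seconds is a major
   body movement epoch.
2. *Wake*: a non-movement epoch with more than 15 seconds of P_W above the
   wake threshold t1 is scored WAKE.
3. *N3*: otherwise, if the 80th percentile of the epoch's P_N3 exceeds t2,
   the epoch is scored N3; else OTHER (N1/N2/REM, not discriminated here).
4. Movement epochs are then resolved: alpha activity at any point makes the
   epoch WAKE (even under 15 s); else a WAKE neighbour makes it WAKE; else
   it inherits the stage of the following epoch (runs resolve right-to-left,
   a trailing run inherits the preceding stage).

All "more than 15 s" rules are strict (> 15), matching the more-than-half-
the-epoch wording of the standard, and WAKE takes precedence over N3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal_io import EPOCH_LEN_S, PREDICTED_STAGES, Hypnogram
from .features import FeatureSeries, Thresholds

__all__ = [
    "EpochDecision",
    "movement_flags",
    "detect_movement_epochs",
    "score_wake",
    "score_n3",
    "resolve_movement_epochs",
    "stage_night",
    "decision_trace",
]

WAKE, N3, OTHER = "WAKE", "N3", "OTHER"

#: P_M at or below this counts as "no signal" (electrode loss)
FLAT_EPS = 1e-12

#: strict lower bound of seconds for the movement / wake majority rules
HALF_EPOCH_S = 15


@dataclass(frozen=True)
class EpochDecision:
    """Audit record of the per-epoch rule evaluation."""

    index: int
    movement: bool
    movement_seconds: int
    wake_seconds: int
    pn3_p80: float
    stage: str


def _per_epoch(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x)
    if x.size == 0 or x.size % EPOCH_LEN_S:
        raise ValueError("per-second vector length must be a nonzero multiple of 30")
    return x.reshape(-1, EPOCH_LEN_S)


def movement_flags(pm: np.ndarray, tm: float) -> np.ndarray:
    """Seconds that are movement (P_M > tm) or flat (P_M ~ 0)."""
    pm = np.asarray(pm, dtype=float)
    return (pm > tm) | (pm <= FLAT_EPS)


def detect_movement_epochs(flags: np.ndarray) -> np.ndarray:
    """Epochs with strictly more than 15 flagged seconds."""
    return _per_epoch(flags).sum(axis=1) > HALF_EPOCH_S


def score_wake(pw: np.ndarray, t1: float) -> np.ndarray:
    """Epochs with strictly more than 15 seconds of P_W above t1."""
    return (_per_epoch(pw) > t1).sum(axis=1) > HALF_EPOCH_S


def epoch_pn3_percentile(pn3: np.ndarray, p: float = 80.0) -> np.ndarray:
    """Within-epoch Pth percentile of P_N3 (rank n = ceil(P/100 * 30))."""
    ep = _per_epoch(pn3)
    n = int(np.ceil(p * ep.shape[1] / 100 - 1e-9))  # same rank as percentile_value
    return np.sort(ep, axis=1)[:, n - 1]


def score_n3(pn3: np.ndarray, t2: float) -> np.ndarray:
    """Epochs whose 80th-percentile P_N3 strictly exceeds t2."""
    return epoch_pn3_percentile(pn3) > t2


def resolve_movement_epochs(
    movement: np.ndarray,
    alpha_present: np.ndarray,
    base_stages: list[str | None],
) -> list[str]:
    """Assign stages to movement epochs per the AASM neighbour rules.

    For each movement epoch, in order of precedence: alpha activity at any
    point scores it WAKE; a WAKE epoch immediately preceding or following
    scores it WAKE; otherwise it takes the stage of the following epoch.
    Runs of movement epochs are resolved right-to-left so the whole run
    inherits the first stage after it; a run ending the night inherits the
    stage before it.
    """
    movement = np.asarray(movement, dtype=bool)
    alpha_present = np.asarray(alpha_present, dtype=bool)
    n = movement.size
    if movement.all():
        raise ValueError("unresolvable night: every epoch is a movement epoch")
    resolved: list[str | None] = [
        WAKE if movement[e] and alpha_present[e] else
        (None if movement[e] else base_stages[e])
        for e in range(n)
    ]
    pending: list[int] = []
    for e in range(n - 1, -1, -1):
        if resolved[e] is not None:
            continue
        prev_stage = resolved[e - 1] if e > 0 else None   # None if still unresolved
        next_stage = resolved[e + 1] if e < n - 1 else None
        if prev_stage == WAKE or next_stage == WAKE:
            resolved[e] = WAKE
        elif next_stage is not None:
            resolved[e] = next_stage
        else:
            pending.append(e)          # trailing run: no following epoch
    for e in pending:                  # inherit the preceding resolved stage
        k = e - 1
        while resolved[k] is None:
            k -= 1
        resolved[e] = resolved[k]
    assert all(s is not None for s in resolved)
    return resolved  # type: ignore[return-value]


def stage_night(features: FeatureSeries, th: Thresholds) -> Hypnogram:
    """Score a whole night into {WAKE, N3, OTHER}.

    Non-movement epochs: WAKE if wake-positive, else N3 if N3-positive,
    else OTHER.  Movement epochs are resolved by neighbour rules, with
    alpha presence operationalised as any second with P_W above t1.
    """
    if features.n_seconds == 0:
        raise ValueError("empty feature series")
    flags = movement_flags(features.pm, th.tm)
    movement = detect_movement_epochs(flags)
    wake = score_wake(features.pw, th.t1)
    n3 = score_n3(features.pn3, th.t2)
    alpha_present = (features.by_epoch("pw") > th.t1).any(axis=1)
    base: list[str | None] = [
        None if movement[e] else (WAKE if wake[e] else (N3 if n3[e] else OTHER))
        for e in range(features.n_epochs)
    ]
    if movement.any():
        stages = resolve_movement_epochs(movement, alpha_present, base)
    else:
        stages = base  # type: ignore[assignment]
    return Hypnogram(tuple(stages), PREDICTED_STAGES)


def decision_trace(features: FeatureSeries, th: Thresholds) -> list[EpochDecision]:
    """Per-epoch audit trail of the rule evaluation (one row per epoch)."""
    stages = stage_night(features, th).labels
    flags = _per_epoch(movement_flags(features.pm, th.tm))
    movement = flags.sum(axis=1) > HALF_EPOCH_S
    wake_sec = (_per_epoch(features.pw) > th.t1).sum(axis=1)
    p80 = epoch_pn3_percentile(features.pn3)
    return [
        EpochDecision(e, bool(movement[e]), int(flags[e].sum()),
                      int(wake_sec[e]), float(p80[e]), stages[e])
        for e in range(features.n_epochs)
    ]
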