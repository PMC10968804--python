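"""Normalized per-second staging features and the percentile statistic.

Night-level normalization makes the features amplitude-invariant, absorbing
inter-subject and inter-montage gain differences:

    P_M[s]  = E_T[s]  / E_T_all      (movement; sums to 1 over the night)
    P_W[s]  = (E_alpha[s] - E_theta[s]) / E_theta_all   (wake; may be < 0)
    P_N3[s] = E_delta[s] / E_delta_all                  (slow-wave sleep)

The N3 rule uses the 80th percentile of P_N3 within each 30-s epoch, with
the percentile rank defined as n = ceil(P/100 * M) on the ascending sort
(for P = 80, M = 30 this is exactly the 24th smallest value).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .signal_io import EPOCH_LEN_S
from .wvd import BandEnergyTable

__all__ = [
    "FeatureSeries",
    "Thresholds",
    "compute_pm",
    "compute_pw",
    "compute_pn3",
    "compute_features",
    "percentile_value",
]

#: movement threshold on P_M; an absolute setting on the normalized total
#: energy, calibrated on full-length overnight recordings
DEFAULT_TM = 5e-4

#: night length (seconds) the default movement threshold is calibrated for:
#: ~820 epochs, the mean overnight recording the threshold was set on
REFERENCE_NIGHT_SECONDS = 24_600


class DegenerateRecordingError(ValueError):
    """All-night energy of a normalizing band is zero."""


@dataclass(frozen=True)
class Thresholds:
    """Decision thresholds: tm (movement, fixed), t1 (wake), t2 (N3)."""

    t1: float
    t2: float
    tm: float = DEFAULT_TM

    def __post_init__(self) -> None:
        if not (self.tm > 0):
            raise ValueError("tm must be positive")
        for name in ("t1", "t2"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be finite and >= 0")

    @staticmethod
    def tm_for_night(n_seconds: int, tm: float = DEFAULT_TM) -> float:
        """Movement threshold equivalent to ``tm`` for a night of given length.

        P_M is normalized by the all-night total, so its per-second mean is
        1/n_seconds and a fixed threshold encodes a night duration: ``tm``
        at the reference ~820-epoch night means "a second holding more than
        ``tm * 24600`` (~12x) the mean energy share".  For nights of a
        different length the same physical criterion is
        ``tm * REFERENCE_NIGHT_SECONDS / n_seconds``.
        """
        if n_seconds <= 0:
            raise ValueError("n_seconds must be positive")
        return tm * REFERENCE_NIGHT_SECONDS / n_seconds


@dataclass(frozen=True)
class FeatureSeries:
    """Per-second P_M, P_W, P_N3 for one night."""

    pm: np.ndarray
    pw: np.ndarray
    pn3: np.ndarray

    def __post_init__(self) -> None:
        for name in ("pm", "pw", "pn3"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (self.pm.shape == self.pw.shape == self.pn3.shape) or self.pm.ndim != 1:
            raise ValueError("pm, pw, pn3 must be 1-D and share one length")
        if self.pm.size % EPOCH_LEN_S:
            raise ValueError("feature length must be a whole number of 30-s epochs")

    @property
    def n_seconds(self) -> int:
        return self.pm.size

    @property
    def n_epochs(self) -> int:
        return self.pm.size // EPOCH_LEN_S

    def by_epoch(self, which: str) -> np.ndarray:
        """One feature reshaped to (n_epochs, 30)."""
        return getattr(self, which).reshape(self.n_epochs, EPOCH_LEN_S)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "second": np.arange(self.n_seconds),
            "pm": self.pm, "pw": self.pw, "pn3": self.pn3,
        })


def _total(energies: BandEnergyTable, band: str) -> float:
    tot = energies.total(band)
    if tot <= 0:
        raise DegenerateRecordingError(
            f"degenerate recording: all-night {band} energy is zero"
        )
    return tot


def compute_pm(energies: BandEnergyTable) -> np.ndarray:
    """Total-band energy per second, normalized by the all-night total."""
    return energies.column("total") / _total(energies, "total")


def compute_pw(energies: BandEnergyTable) -> np.ndarray:
    """Alpha-minus-theta energy per second over the all-night theta energy."""
    diff = energies.column("alpha") - energies.column("theta")
    return diff / _total(energies, "theta")


def compute_pn3(energies: BandEnergyTable) -> np.ndarray:
    """Delta energy per second, normalized by the all-night delta energy."""
    return energies.column("delta") / _total(energies, "delta")


def compute_features(energies: BandEnergyTable) -> FeatureSeries:
    return FeatureSeries(compute_pm(energies), compute_pw(energies),
                         compute_pn3(energies))


def percentile_value(values: np.ndarray, p: float) -> float:
    """Pth percentile as the n-th smallest value, n = ceil(P/100 * M).

    This is the rank-order definition used in visual scoring arithmetic:
    sort ascending and take the value below P% of the observations; for
    P = 80 over the 30 seconds of an epoch, n = 24 exactly.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty vector")
    if not 0 < p <= 100:
        raise ValueError("percentile P must be in (0, 100]")
    # guard against float excess pushing an exact integer rank up by one
    n = int(math.ceil(p * values.size / 100 - 1e-9))
    return float(np.sort(values)[n - 1])
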