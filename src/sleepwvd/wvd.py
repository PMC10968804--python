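"""Discrete Wigner-Ville distribution and per-second band energies.

The staging features all derive from the energy of the EEG in the delta,
theta, alpha and total bands, computed second by second.  Each one-second
block of ``N = fs`` samples is analysed with a discrete Wigner-Ville
distribution (WVD)

    W[n, k] ~ sum_m  z[n+m] conj(z[n-m]) exp(-2j pi k m / N),

where ``z`` is the analytic signal of the block (zero-extended outside it)
and the frequency axis carries ``N`` bins spaced ``fs / (2N)`` = 0.5 Hz
apart, so the clinical band edges (0.5, 4, 8, 13 Hz) fall exactly on bin
centres.  The WVD has optimal joint time-frequency resolution but produces
oscillatory cross-terms for multi-component signals; integrating over the
one-second time axis cancels them, and the resulting *marginal spectrum*
obeys an exact discrete analogue of the continuous marginal condition:

    sum_n W[n, k]  =  (|Z[k]|^2 + |Z[k+N]|^2) / (2N),

with ``Z`` the 2N-point DFT of the zero-padded block.  The second (folded)
term is the alias inherent to the half-sample-lag discretization; for an
analytic input it is negligible except immediately below fs/2.  The matrix
is normalised so its grand total equals the block energy ``sum |z|^2``.

Band energies are in uV^2 * s: energies of the real signal, i.e. half the
analytic-signal energy, times the 1/fs sample spacing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .signal_io import EpochedRecording

__all__ = [
    "BandDefinition",
    "BandEnergyTable",
    "DEFAULT_BANDS",
    "analytic_signal",
    "wvd_matrix",
    "marginal_spectrum",
    "band_energies_per_second",
]


@dataclass(frozen=True)
class BandDefinition:
    """Half-open frequency band [f_lo, f_hi) in Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not 0 <= self.f_lo < self.f_hi:
            raise ValueError(f"band {self.name}: need 0 <= f_lo < f_hi")


#: AASM-style bands: slow waves (N3), theta and alpha (wake), and the full
#: recorded band (movement detection).
DEFAULT_BANDS = (
    BandDefinition("delta", 0.5, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("total", 0.3, 35.0),
)


@dataclass(frozen=True)
class BandEnergyTable:
    """Per-second band energies and their all-night totals (uV^2 * s).

    ``per_second`` has shape (n_seconds, n_bands), columns ordered as
    ``band_names``; ``totals`` are the exact column sums.
    """

    per_second: np.ndarray
    band_names: tuple[str, ...]
    fs: int

    def __post_init__(self) -> None:
        ps = np.asarray(self.per_second, dtype=float)
        object.__setattr__(self, "per_second", ps)
        if ps.ndim != 2 or ps.shape[1] != len(self.band_names):
            raise ValueError("per_second must be (n_seconds, n_bands)")
        if np.any(ps < 0):
            raise ValueError("band energies must be non-negative")

    @property
    def n_seconds(self) -> int:
        return self.per_second.shape[0]

    @property
    def totals(self) -> np.ndarray:
        return self.per_second.sum(axis=0)

    def column(self, name: str) -> np.ndarray:
        return self.per_second[:, self.band_names.index(name)]

    def total(self, name: str) -> float:
        return float(self.totals[self.band_names.index(name)])

    def to_frame(self):
        """Per-second energies as a DataFrame (`second,E_delta,...`)."""
        import pandas as pd

        df = pd.DataFrame(self.per_second,
                          columns=[f"E_{n}" for n in self.band_names])
        df.insert(0, "second", np.arange(self.n_seconds))
        return df


def analytic_signal(segment: np.ndarray) -> np.ndarray:
    """Analytic (one-sided-spectrum) version of a real segment.

    The real part equals the input; negative-frequency DFT bins are zero.
    Removing the negative frequencies before the WVD avoids aliasing above
    fs/4 and the positive/negative-frequency cross-terms.
    """
    segment = np.asarray(segment, dtype=float)
    if segment.size == 0:
        raise ValueError("empty segment")
    if not np.all(np.isfinite(segment)):
        raise ValueError("segment contains non-finite values")
    return hilbert(segment)


def wvd_matrix(segment: np.ndarray) -> np.ndarray:
    """Discrete WVD of a one-second complex segment (N = fs samples).

    Returns a real (N, N) array: rows are time samples, columns frequency
    bins ``k * fs / (2N)`` (0.5 Hz apart for N = fs).  The grand total
    equals the segment energy ``sum |z|^2``.
    """
    z = np.asarray(segment, dtype=complex)
    N = z.size
    if N == 0:
        raise ValueError("empty segment")
    # instantaneous autocorrelation K[n, m] = z[n+m] conj(z[n-m]),
    # lag m in (-N, N), laid out mod 2N for the lag FFT
    K = np.zeros((N, 2 * N), dtype=complex)
    n = np.arange(N)
    mmax = np.minimum(n, N - 1 - n)
    for m in range(int(mmax.max()) + 1):
        rows = n[(n >= m) & (n <= N - 1 - m)]
        prod = z[rows + m] * np.conj(z[rows - m])
        K[rows, m] = prod
        if m:
            K[rows, 2 * N - m] = np.conj(prod)
    # even bins of the 2N-point lag transform give the 0.5 Hz grid on [0, fs/2)
    W = np.fft.fft(K, axis=1)[:, ::2].real / N
    return W


def _marginal_from_fft(z: np.ndarray) -> np.ndarray:
    """Exact marginal of :func:`wvd_matrix` via the folded 2N-point DFT."""
    N = z.size
    P = np.abs(np.fft.fft(z, 2 * N)) ** 2
    return 0.5 * (P[:N] + P[N:]) / N


def marginal_spectrum(segment: np.ndarray) -> np.ndarray:
    """Energy per 0.5 Hz frequency bin: the time-integral of the WVD.

    Equals the squared magnitude of the zero-padded DFT of the segment
    (upper half folded back) under the module scaling; total equals the
    segment energy.  Tiny negative excursions are clipped to zero.
    """
    z = np.asarray(segment, dtype=complex)
    if z.size == 0:
        raise ValueError("empty segment")
    m = _marginal_from_fft(z)
    return np.clip(m, 0.0, None)


def band_bins(band: BandDefinition, fs: int) -> np.ndarray:
    """Indices of 0.5 Hz-spaced bins with centre in [f_lo, f_hi)."""
    if band.f_hi > fs / 2:
        raise ValueError(
            f"band {band.name} [{band.f_lo}, {band.f_hi}) exceeds Nyquist {fs / 2} Hz"
        )
    freqs = np.arange(fs) * fs / (2 * fs)  # = 0.5 Hz spacing for N = fs
    return np.nonzero((freqs >= band.f_lo) & (freqs < band.f_hi))[0]


def band_energies_per_second(
    rec: EpochedRecording,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
) -> BandEnergyTable:
    """Per-second WVD band energies for a whole night.

    For each second, the marginal spectrum of that second's analytic signal
    is summed over the bins of each band.  The factor 1/(2 fs) converts
    analytic-signal energy per sample to real-signal energy in uV^2 * s.
    """
    fs = rec.fs
    seconds = rec.seconds()                       # (n_seconds, fs)
    z = hilbert(seconds, axis=1)
    P = np.abs(np.fft.fft(z, 2 * fs, axis=1)) ** 2
    marg = 0.5 * (P[:, :fs] + P[:, fs:]) / fs      # marginal per second
    marg = np.clip(marg, 0.0, None)
    cols = []
    for band in bands:
        idx = band_bins(band, fs)
        cols.append(marg[:, idx].sum(axis=1))
    per_second = np.column_stack(cols) / (2.0 * fs)
    return BandEnergyTable(per_second, tuple(b.name for b in bands), fs)
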