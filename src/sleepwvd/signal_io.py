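"""PSG signal and hypnogram input/output.

Reads one referenced EEG derivation (e.g. C3-M2) from EDF/EDF+, converts it
to microvolts, and segments it into the 30-second epochs that are the atomic
unit of sleep staging.  Hypnograms travel as plain ``epoch,stage`` CSV files.

EDF writing is implemented here directly (16-bit EDF, one channel group per
file) so that synthetic nights can be materialised on disk; reading goes
through MNE, which also serves as an independent check of the writer.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from datetime import datetime
from pathlib import Path
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

EPOCH_LEN_S = 30

#: stage tokens a technician file may contain
TECHNICIAN_STAGES = ("W", "N1", "N2", "N3", "REM")
#: stage tokens a predicted (3-class) file may contain
PREDICTED_STAGES = ("WAKE", "N3", "OTHER")


class ChannelNotFoundError(KeyError):
    """Requested EDF channel is absent from the file."""


class RateMismatchError(ValueError):
    """Active and reference channels are stored at different sampling rates."""


class TooShortError(ValueError):
    """Recording shorter than one 30-s epoch."""


@dataclass(frozen=True)
class EpochedRecording:
    """One night of a single referenced EEG trace on a whole-epoch grid.

    Parameters
    ----------
    samples
        Amplitude in microvolts; length is exactly ``n_epochs * 30 * fs``.
    fs
        Sampling rate in Hz (integer, >= 100).
    channel_label
        Derivation name, e.g. ``"C3-M2"``.
    """

    samples: np.ndarray
    fs: int
    channel_label: str = "EEG"
    epoch_len_s: int = EPOCH_LEN_S

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if int(self.fs) != self.fs or self.fs < 100:
            raise ValueError(f"sampling rate must be an integer >= 100 Hz, got {self.fs}")
        object.__setattr__(self, "fs", int(self.fs))
        spe = self.epoch_len_s * self.fs
        if samples.size < spe:
            raise TooShortError(
                f"recording of {samples.size / self.fs:.1f} s is shorter than one "
                f"{self.epoch_len_s}-s epoch"
            )
        if samples.size % spe:
            raise ValueError(
                "samples must hold a whole number of epochs; use segment_into_epochs"
            )

    @property
    def n_epochs(self) -> int:
        return self.samples.size // (self.epoch_len_s * self.fs)

    @property
    def n_seconds(self) -> int:
        return self.n_epochs * self.epoch_len_s

    def seconds(self) -> np.ndarray:
        """View of the trace as (n_seconds, fs)."""
        return self.samples.reshape(self.n_seconds, self.fs)

    def epochs(self) -> np.ndarray:
        """View of the trace as (n_epochs, 30 * fs)."""
        return self.samples.reshape(self.n_epochs, self.epoch_len_s * self.fs)


@dataclass(frozen=True)
class Hypnogram:
    """Per-epoch stage labels, either technician 5-class or predicted 3-class."""

    labels: tuple[str, ...]
    label_set: tuple[str, ...] = TECHNICIAN_STAGES
    epoch_len_s: int = EPOCH_LEN_S

    def __post_init__(self) -> None:
        labels = tuple(self.labels)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "label_set", tuple(self.label_set))
        bad = sorted({l for l in labels if l not in self.label_set})
        if bad:
            raise ValueError(
                f"unknown stage token(s) {bad}; accepted tokens: {list(self.label_set)}"
            )

    def __len__(self) -> int:
        return len(self.labels)


def _infer_label_set(labels: Sequence[str]) -> tuple[str, ...]:
    if all(l in TECHNICIAN_STAGES for l in labels):
        return TECHNICIAN_STAGES
    if all(l in PREDICTED_STAGES for l in labels):
        return PREDICTED_STAGES
    bad = sorted({l for l in labels} - set(TECHNICIAN_STAGES) - set(PREDICTED_STAGES))
    raise ValueError(
        f"unknown stage token(s) {bad}; accepted tokens: "
        f"{list(TECHNICIAN_STAGES)} or {list(PREDICTED_STAGES)}"
    )


def segment_into_epochs(trace: np.ndarray, fs: int, channel_label: str = "EEG") -> EpochedRecording:
    """Cut a microvolt trace into whole 30-s epochs, discarding the tail.

    A trailing partial epoch is dropped with a logged warning: staging scores
    whole 30-s epochs only.
    """
    trace = np.asarray(trace, dtype=float)
    spe = EPOCH_LEN_S * int(fs)
    n_epochs = trace.size // spe
    if n_epochs < 1:
        raise TooShortError(
            f"trace of {trace.size} samples (< {spe}) is shorter than one 30-s epoch"
        )
    discarded = trace.size - n_epochs * spe
    if discarded:
        logger.warning(
            "discarding %d trailing samples (%.2f s) not filling a 30-s epoch",
            discarded, discarded / fs,
        )
    return EpochedRecording(trace[: n_epochs * spe], int(fs), channel_label)


def derive_reference(active: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Referenced derivation: element-wise active minus reference."""
    active = np.asarray(active, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if active.shape != reference.shape:
        raise ValueError("active and reference traces differ in length")
    return active - reference


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _edf_header_rates(path: Path) -> dict[str, float]:
    """Per-channel sampling rates straight from the EDF header.

    MNE resamples mixed-rate files transparently, so the rate-mismatch
    contract is enforced against the raw header instead.
    """
    with open(path, "rb") as fh:
        hdr = fh.read(256)
        if len(hdr) < 256:
            raise ValueError(f"{path} is not a valid EDF file (truncated header)")
        record_dur = float(hdr[244:252].decode("ascii").strip() or 1)
        ns = int(hdr[252:256].decode("ascii").strip())
        sig_hdr = fh.read(ns * 256)
    labels = [sig_hdr[i * 16:(i + 1) * 16].decode("ascii").strip() for i in range(ns)]
    nsamp_off = ns * 216
    rates = {}
    for i, lab in enumerate(labels):
        nsamp = int(sig_hdr[nsamp_off + i * 8: nsamp_off + (i + 1) * 8].decode("ascii").strip())
        rates[lab] = nsamp / record_dur
    return rates


def read_psg_edf(path: str | Path, active: str, reference: str | None = None) -> EpochedRecording:
    """Read a referenced EEG derivation from an EDF/EDF+ file, in microvolts.

    Returns ``active - reference`` when a reference channel is named, else the
    active channel as-is (use this for pre-referenced channels like "C3-M2").
    """
    import mne  # deferred: heavy import

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rates = _edf_header_rates(path)
    wanted = [active] + ([reference] if reference else [])
    for ch in wanted:
        if ch not in rates:
            raise ChannelNotFoundError(
                f"channel {ch!r} not found; available channels: {sorted(rates)}"
            )
    if reference and rates[active] != rates[reference]:
        raise RateMismatchError(
            f"rate mismatch: {active!r} at {rates[active]:g} Hz but "
            f"{reference!r} at {rates[reference]:g} Hz"
        )
    raw = mne.io.read_raw_edf(path, include=wanted, preload=True, verbose="error")
    data = raw.get_data(units="uV")
    idx = {name: i for i, name in enumerate(raw.ch_names)}
    trace = data[idx[active]]
    label = active
    if reference:
        trace = derive_reference(trace, data[idx[reference]])
        label = f"{active}-{reference}"
    fs = int(round(rates[active]))
    return segment_into_epochs(trace, fs, channel_label=label)


def write_edf(path: str | Path, signals: dict[str, np.ndarray], fs: int) -> None:
    """Write a minimal 16-bit EDF file with physical dimension microvolts.

    One-second data records; all channels share one sampling rate.  The
    digital range is the full 16-bit span, so the quantization step is
    (phys_max - phys_min) / 65535.
    """
    path = Path(path)
    names = list(signals)
    arrs = [np.asarray(signals[n], dtype=float) for n in names]
    n = arrs[0].size
    if any(a.size != n for a in arrs):
        raise ValueError("all channels must share one length")
    if n % fs:
        raise ValueError("signal length must be a whole number of seconds")
    n_records = n // fs
    ns = len(names)

    def pad(s: str, width: int) -> bytes:
        b = s.encode("ascii")
        if len(b) > width:
            raise ValueError(f"field {s!r} longer than {width} bytes")
        return b.ljust(width)

    now = datetime(2000, 1, 1)
    header = b"".join([
        pad("0", 8),
        pad("X X X X", 80),
        pad("Startdate X X X X", 80),
        pad(now.strftime("%d.%m.%y"), 8),
        pad(now.strftime("%H.%M.%S"), 8),
        pad(str(256 * (1 + ns)), 8),
        pad("", 44),
        pad(str(n_records), 8),
        pad("1", 8),           # record duration, seconds
        pad(str(ns), 4),
    ])
    def fmt8(v: float) -> str:
        # EDF numeric fields are 8 ASCII chars; use the widest precision that fits
        for p in range(7, 0, -1):
            s = f"{v:.{p}g}"
            if len(s) <= 8:
                return s
        raise ValueError(f"cannot format {v} in 8 chars")

    phys_min, phys_max, digital = [], [], []
    for a in arrs:
        amax = float(np.max(np.abs(a))) if a.size else 1.0
        amax = max(amax, 1.0) * 1.001  # keep extremes inside the digital span
        amax = float(fmt8(amax))       # scale with the header-representable value
        phys_min.append(-amax)
        phys_max.append(amax)
        scale = 65535 / (2 * amax)
        digital.append(np.clip(np.round((a + amax) * scale) - 32768, -32768, 32767)
                       .astype("<i2"))
    sig_hdr = b"".join([
        b"".join(pad(nm, 16) for nm in names),
        b"".join(pad("", 80) for _ in names),                       # transducer
        b"".join(pad("uV", 8) for _ in names),
        b"".join(pad(fmt8(lo), 8) for lo in phys_min),
        b"".join(pad(fmt8(hi), 8) for hi in phys_max),
        b"".join(pad("-32768", 8) for _ in names),
        b"".join(pad("32767", 8) for _ in names),
        b"".join(pad("", 80) for _ in names),                       # prefiltering
        b"".join(pad(str(fs), 8) for _ in names),
        b"".join(pad("", 32) for _ in names),                       # reserved
    ])
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_hdr)
        for r in range(n_records):
            for d in digital:
                fh.write(d[r * fs:(r + 1) * fs].tobytes())


def write_night_edf(path: str | Path, rec: EpochedRecording) -> None:
    """Write one epoched night as a single-channel EDF file."""
    write_edf(path, {rec.channel_label: rec.samples}, rec.fs)


def edf_quantization_step(samples: np.ndarray) -> float:
    """Amplitude resolution of ``write_edf`` for this trace (microvolts)."""
    amax = max(float(np.max(np.abs(samples))), 1.0) * 1.001
    return 2 * amax / 65535


# ---------------------------------------------------------------------------
# Hypnogram CSV
# ---------------------------------------------------------------------------

def read_hypnogram(path: str | Path) -> Hypnogram:
    """Read an ``epoch,stage`` CSV with contiguous 0-based epoch indices."""
    path = Path(path)
    labels: list[str] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header[:2]] != ["epoch", "stage"]:
            raise ValueError(f"{path}: expected header 'epoch,stage', got {header}")
        for i, row in enumerate(reader):
            if not row:
                continue
            if int(row[0]) != i:
                raise ValueError(
                    f"{path}: epoch indices must be contiguous from 0; "
                    f"row {i} has index {row[0]}"
                )
            labels.append(row[1].strip())
    if not labels:
        raise ValueError(f"{path}: no epochs")
    return Hypnogram(tuple(labels), _infer_label_set(labels))


def write_hypnogram(h: Hypnogram, path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("epoch,stage\n")
        for i, label in enumerate(h.labels):
            fh.write(f"{i},{label}\n")
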