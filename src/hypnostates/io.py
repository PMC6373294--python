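"""Recording container and on-disk formats.

Recordings travel as EDF (16-bit, one 1-s data record per second, channel
labels equal to the montage labels, physical units µV).  Writing uses a
small self-contained EDF encoder; reading goes through MNE's EDF reader, so
the round trip is checked against an independent implementation.

Event tables are plain CSV with columns ``stim_time_s``, ``category``,
``response_time_s`` (empty field = no response); times are seconds from
recording onset and ``response_time_s`` is absolute (not a latency).
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .montage import Montage, MontageError, make_montage

__all__ = [
    "Recording",
    "write_edf",
    "read_recording",
    "read_events",
    "write_events",
]

EVENT_COLUMNS = ("stim_time_s", "category", "response_time_s")


@dataclass
class Recording:
    """Multichannel scalp EEG in µV.

    Attributes
    ----------
    data : ndarray, shape (n_channels, n_samples)
    sfreq : float
        Sampling rate in Hz.
    labels : tuple of str
    montage : Montage
    reference : str
        ``"recorded"`` or ``"common_average"``.
    history : list of dict
        Ordered record of the operations applied so far; each entry holds
        the operation name and its parameters, enough to reconstruct the
        preprocessing chain.
    """

    data: np.ndarray
    sfreq: float
    labels: tuple[str, ...]
    montage: Montage
    reference: str = "recorded"
    history: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        self.labels = tuple(self.labels)
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("labels length must equal channel count")
        if not self.sfreq > 0:
            raise ValueError("sample_rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains NaN/Inf")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sfreq

    def copy(self) -> "Recording":
        return Recording(
            data=self.data.copy(),
            sfreq=self.sfreq,
            labels=self.labels,
            montage=self.montage,
            reference=self.reference,
            history=list(self.history),
        )

    def log(self, op: str, **params) -> None:
        self.history.append({"op": op, **params})


def _pad_ascii(text: str, width: int) -> bytes:
    b = text.encode("ascii", errors="replace")[:width]
    return b + b" " * (width - len(b))


def write_edf(path, data_uv: np.ndarray, sfreq: float, labels) -> None:
    """Write a minimal EDF file (16-bit integers, 1-s records).

    The physical range is chosen symmetric per channel set so quantisation
    error is bounded by one step of (2 * phys_max) / 65534.  The sampling
    rate must be a positive integer and the signal is zero-padded to a whole
    number of records.
    """
    data_uv = np.asarray(data_uv, dtype=float)
    n_ch, n_samp = data_uv.shape
    fs = int(round(sfreq))
    if fs != sfreq or fs <= 0:
        raise ValueError("EDF writer requires an integer sampling rate")
    n_rec = int(np.ceil(n_samp / fs))
    padded = np.zeros((n_ch, n_rec * fs))
    padded[:, :n_samp] = data_uv

    phys_max = float(np.max(np.abs(padded)))
    phys_max = max(np.ceil(phys_max * 1.01), 1.0)
    scale = 32767.0 / phys_max
    digital = np.clip(np.round(padded * scale), -32767, 32767).astype("<i2")

    header = b"".join([
        _pad_ascii("0", 8),
        _pad_ascii("X X X X", 80),
        _pad_ascii("Startdate X X X X", 80),
        _pad_ascii("01.01.00", 8),
        _pad_ascii("00.00.00", 8),
        _pad_ascii(str(256 * (1 + n_ch)), 8),
        _pad_ascii("", 44),
        _pad_ascii(str(n_rec), 8),
        _pad_ascii("1", 8),
        _pad_ascii(str(n_ch), 4),
    ])
    fields = [
        ("%s", 16, list(labels)),
        ("%s", 80, [""] * n_ch),
        ("%s", 8, ["uV"] * n_ch),
        ("%s", 8, [f"{-phys_max:g}"] * n_ch),
        ("%s", 8, [f"{phys_max:g}"] * n_ch),
        ("%s", 8, ["-32767"] * n_ch),
        ("%s", 8, ["32767"] * n_ch),
        ("%s", 80, [""] * n_ch),
        ("%s", 8, [str(fs)] * n_ch),
        ("%s", 32, [""] * n_ch),
    ]
    sig_header = b"".join(
        b"".join(_pad_ascii(fmt % v, width) for v in values)
        for fmt, width, values in fields
    )
    body = digital.reshape(n_ch, n_rec, fs).transpose(1, 0, 2).tobytes()
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        fh.write(body)


def read_events(path) -> pd.DataFrame:
    """Read an event CSV, returning rows sorted by stimulus time.

    Raises
    ------
    ValueError
        If a required column is missing (named in the message).
    """
    try:
        ev = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - propagated with location
        raise ValueError(f"could not parse events CSV {path}: {exc}") from exc
    for col in ("stim_time_s", "response_time_s"):
        if col not in ev.columns:
            raise ValueError(f"events CSV {path} is missing column '{col}'")
    if "category" not in ev.columns:
        ev["category"] = ""
    ev = ev.sort_values("stim_time_s", kind="stable").reset_index(drop=True)
    ev["rt_s"] = ev["response_time_s"] - ev["stim_time_s"]
    return ev


def write_events(path, events: pd.DataFrame) -> None:
    events[list(EVENT_COLUMNS)].to_csv(path, index=False)


def read_recording(edf_path, events_path=None, montage: Montage | None = None):
    """Load an EDF recording (and optionally its event table).

    Channel labels in the file must map onto the montage labels (the native
    63-channel montage by default); the recording is returned with channels
    in file order and data in µV.

    Returns
    -------
    (Recording, DataFrame) if ``events_path`` is given, else Recording.
    """
    import mne

    edf_path = Path(edf_path)
    if not edf_path.exists():
        raise FileNotFoundError(edf_path)
    raw = mne.io.read_raw_edf(edf_path, preload=True, verbose="error")
    labels = list(raw.ch_names)
    if montage is None:
        montage = make_montage(63)
    unknown = [l for l in labels if l not in montage.labels]
    if unknown:
        raise MontageError(
            f"EDF channel labels not present in montage: {unknown}"
        )
    rec = Recording(
        data=raw.get_data() * 1e6,  # volts -> µV
        sfreq=float(raw.info["sfreq"]),
        labels=labels,
        montage=montage.subset(labels),
        reference="recorded",
    )
    rec.log("read_recording", path=str(edf_path))
    if events_path is None:
        return rec
    return rec, read_events(events_path)
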