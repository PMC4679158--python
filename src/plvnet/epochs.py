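"""Core containers for epoched EEG data.

The package operates on fixed-length epochs cut around a task cue: a
``trials x channels x samples`` array on a uniform time grid expressed in
seconds relative to the cue.  All time windows in the package follow a single
half-open convention ``[t0, t0 + L)``: an epoch spanning (-4, 6) s at
``rate`` Hz holds ``round(10 * rate)`` samples, the first at t = -4 and the
last one sample short of t = 6.  Sample lookup is
``index = round((t - tmin) * rate)``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

#: 64-channel Biosemi ActiveTwo cap, 10-10 labels (A1..B32 in standard order).
BIOSEMI64: tuple[str, ...] = (
    "Fp1", "AF7", "AF3", "F1", "F3", "F5", "F7", "FT7",
    "FC5", "FC3", "FC1", "C1", "C3", "C5", "T7", "TP7",
    "CP5", "CP3", "CP1", "P1", "P3", "P5", "P7", "P9",
    "PO7", "PO3", "O1", "Iz", "Oz", "POz", "Pz", "CPz",
    "Fpz", "Fp2", "AF8", "AF4", "AFz", "Fz", "F2", "F4",
    "F6", "F8", "FT8", "FC6", "FC4", "FC2", "FCz", "Cz",
    "C2", "C4", "C6", "T8", "TP8", "CP6", "CP4", "CP2",
    "P2", "P4", "P6", "P8", "P10", "PO8", "PO4", "O2",
)

TASKS = ("active", "mi", "passive")


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band with edges in Hz (0 < low < high)."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not 0.0 < self.low < self.high:
            raise ValueError(f"invalid band edges: {self.low}-{self.high} Hz")

    @property
    def center(self) -> float:
        return 0.5 * (self.low + self.high)


#: The four sensorimotor-rhythm bands the analysis is run in.
BANDS: tuple[BandSpec, ...] = (
    BandSpec("mu", 8.0, 12.0),
    BandSpec("low_beta", 13.0, 20.0),
    BandSpec("high_beta", 21.0, 30.0),
    BandSpec("gamma", 31.0, 50.0),
)

BAND_BY_NAME = {b.name: b for b in BANDS}


def n_samples(tmin: float, tmax: float, rate: float) -> int:
    """Sample count of the half-open span ``[tmin, tmax)`` at ``rate`` Hz."""
    return int(np.rint((tmax - tmin) * rate))


def time_to_index(t: float, tmin: float, rate: float) -> int:
    """Index of time ``t`` on the grid starting at ``tmin``."""
    return int(np.rint((t - tmin) * rate))


@dataclass
class EpochsSet:
    """Multi-trial, multi-channel epoched EEG.

    Parameters
    ----------
    data : ndarray, shape (n_trials, n_channels, n_samples)
        Signal in microvolts.
    rate : float
        Sampling rate in Hz.
    tmin : float
        Time of the first sample in seconds relative to the cue.
    channel_names : sequence of str
        10-10 montage labels, one per channel row.
    task : str
        One of ``active``, ``mi``, ``passive``.
    subject : str
        Subject identifier.
    """

    data: np.ndarray
    rate: float
    tmin: float
    channel_names: tuple[str, ...]
    task: str = "active"
    subject: str = "S00"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.channel_names = tuple(self.channel_names)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        if self.data.shape[1] != len(self.channel_names):
            raise ValueError(
                f"{self.data.shape[1]} channel rows but "
                f"{len(self.channel_names)} channel names"
            )
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if np.isnan(self.data).any():
            raise ValueError("data contains NaN")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def tmax(self) -> float:
        """End of the half-open epoch span (exclusive)."""
        return self.tmin + self.n_samples / self.rate

    @property
    def times(self) -> np.ndarray:
        return self.tmin + np.arange(self.n_samples) / self.rate

    def copy_with(self, **changes) -> "EpochsSet":
        return replace(self, **changes)

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_names.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in montage") from None
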