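"""Epoch preprocessing: downsampling, filtering, cropping, CAR, rejection.

The fixed stage order is: downsample -> broadband band-pass (1-80 Hz) ->
amplitude-based trial rejection -> common average reference -> per-band
band-pass.  All filters are order-4 Butterworth applied forward-backward
(zero phase), which is mandatory upstream of phase estimation; band filtering
runs on the full epoch and the analysis crop (-1..3 s by default) leaves
>= 3 s of edge padding on each side.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import gcd

import numpy as np
from scipy import signal

from .epochs import BANDS, BandSpec, EpochsSet, n_samples, time_to_index

BROADBAND = BandSpec("broadband", 1.0, 80.0)
DEFAULT_PTP_THRESHOLD_UV = 150.0
FILTER_ORDER = 4
#: steeper order for the band split: adjacent bands share an edge, and
#: narrowband activity just inside one band must not phase-contaminate its
#: neighbor's Hilbert phase
BAND_SPLIT_ORDER = 8


def downsample(epochs: EpochsSet, target_rate: float) -> EpochsSet:
    """Resample to ``target_rate`` Hz with anti-alias (polyphase) filtering."""
    if target_rate > epochs.rate:
        raise ValueError(
            f"target rate {target_rate} Hz exceeds current rate {epochs.rate} Hz")
    if target_rate == epochs.rate:
        return epochs.copy_with()
    up = int(round(target_rate))
    down = int(round(epochs.rate))
    if not (np.isclose(up, target_rate) and np.isclose(down, epochs.rate)):
        raise ValueError("rates must be (near-)integer Hz for polyphase resampling")
    g = gcd(up, down)
    data = signal.resample_poly(epochs.data, up // g, down // g, axis=-1)
    return epochs.copy_with(data=data, rate=float(target_rate))


def bandpass(epochs: EpochsSet, band: BandSpec,
             order: int = FILTER_ORDER) -> EpochsSet:
    """Zero-phase Butterworth band-pass; attenuation >= 20 dB one octave out."""
    nyq = epochs.rate / 2.0
    if band.high >= nyq:
        raise ValueError(f"band edge {band.high} Hz at or above Nyquist {nyq} Hz")
    sos = signal.butter(order, [band.low, band.high],
                        btype="bandpass", fs=epochs.rate, output="sos")
    data = signal.sosfiltfilt(sos, epochs.data, axis=-1)
    return epochs.copy_with(data=data)


def crop(epochs: EpochsSet, tmin: float, tmax: float) -> EpochsSet:
    """Restrict to the half-open span ``[tmin, tmax)``."""
    eps = 0.5 / epochs.rate
    if tmin < epochs.tmin - eps or tmax > epochs.tmax + eps:
        raise ValueError(
            f"crop [{tmin}, {tmax}) outside epoch span "
            f"[{epochs.tmin}, {epochs.tmax})")
    i0 = time_to_index(tmin, epochs.tmin, epochs.rate)
    n = n_samples(tmin, tmax, epochs.rate)
    if i0 == 0 and n == epochs.n_samples:
        return epochs.copy_with()
    return epochs.copy_with(data=epochs.data[:, :, i0:i0 + n], tmin=float(tmin))


def common_average_reference(epochs: EpochsSet) -> EpochsSet:
    """Subtract the instantaneous mean across channels (CAR).  Idempotent."""
    if epochs.n_channels < 2:
        raise ValueError("CAR requires at least 2 channels")
    data = epochs.data - epochs.data.mean(axis=1, keepdims=True)
    return epochs.copy_with(data=data)


@dataclass(frozen=True)
class RejectionRecord:
    trial: int
    channels: tuple[str, ...]
    max_ptp_uv: float


def reject_trials(
    epochs: EpochsSet, ptp_threshold: float = DEFAULT_PTP_THRESHOLD_UV
) -> tuple[EpochsSet, list[RejectionRecord]]:
    """Drop trials whose peak-to-peak amplitude exceeds the threshold.

    A deterministic stand-in for manual artifact screening: any trial with a
    peak-to-peak excursion above ``ptp_threshold`` (microvolts) on any channel
    is removed.  Returns the surviving epochs and a log of dropped trials
    with the offending channels.
    """
    if ptp_threshold <= 0:
        raise ValueError("peak-to-peak threshold must be positive")
    ptp = epochs.data.max(axis=-1) - epochs.data.min(axis=-1)  # trials x channels
    bad = ptp > ptp_threshold
    log = []
    for trial in np.flatnonzero(bad.any(axis=1)):
        chans = tuple(epochs.channel_names[c] for c in np.flatnonzero(bad[trial]))
        log.append(RejectionRecord(int(trial), chans, float(ptp[trial].max())))
    keep = ~bad.any(axis=1)
    if not keep.any():
        raise ValueError(
            f"all {epochs.n_trials} trials exceed the {ptp_threshold} uV "
            "peak-to-peak threshold")
    return epochs.copy_with(data=epochs.data[keep]), log


def preprocess_epochs(
    epochs: EpochsSet,
    target_rate: float = 256.0,
    broadband: BandSpec = BROADBAND,
    ptp_threshold: float = DEFAULT_PTP_THRESHOLD_UV,
    bands: tuple[BandSpec, ...] = BANDS,
) -> tuple[dict, list[RejectionRecord]]:
    """Run the fixed preprocessing chain; returns band name -> EpochsSet."""
    out = downsample(epochs, target_rate)
    out = bandpass(out, broadband)
    out, log = reject_trials(out, ptp_threshold)
    out = common_average_reference(out)
    return {band.name: bandpass(out, band, order=BAND_SPLIT_ORDER)
            for band in bands}, log
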