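"""Seedable synthetic EEG cohorts with implanted phase coupling.

The generator emulates a 64-channel grasping-task study: per subject and task
it produces fixed-length epochs (default -4..6 s around the cue, 2048 Hz)
containing band-limited oscillations over a pink (1/f) background, and a
clinical upper-limb motor score (FMA-UL, 0-66) per subject.

Phase coupling is the implanted ground truth.  Each channel carries one
oscillator per analysis band at the band's center frequency with an
independent uniform phase per trial.  A :class:`CouplingSpec` makes a target
channel's oscillator inherit the source channel's phase plus a von Mises
jitter, restricted to one band and one time interval.  The jitter
concentration is the exact inverse of the von Mises mean resultant length
``A(c) = I1(c)/I0(c)``, so that across many trials the expected PLV of the
pair equals the requested strength ``kappa`` (before noise dilution):
kappa = 0 means independent phases, kappa = 1 zero jitter.

Randomness is split into named substreams with ``np.random.SeedSequence``:
epochs for subject ``s`` / task index ``t`` use ``spawn_key=(s, t)`` and the
FMA draw for subject ``s`` uses ``spawn_key=(s, 10000)``, so adding subjects
or tasks never reshuffles existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import i0e, i1e

from .epochs import BANDS, BAND_BY_NAME, BIOSEMI64, TASKS, BandSpec, EpochsSet, n_samples

FMA_STREAM_KEY = 10_000  # spawn-key slot reserved for the per-subject FMA draw
_RAMP_S = 0.1  # raised-cosine crossfade at coupling-interval edges, seconds


def vonmises_mean_resultant(concentration: float) -> float:
    """Mean resultant length A(c) = I1(c)/I0(c) of a von Mises distribution."""
    if concentration <= 0:
        return 0.0
    # exponentially scaled Bessels: the e^c factors cancel in the ratio
    return float(i1e(concentration) / i0e(concentration))


def kappa_to_concentration(kappa: float) -> float:
    """Invert A(c) so that E[PLV] of a coupled pair equals ``kappa``.

    Returns ``inf`` for kappa ~ 1 (zero jitter) and 0 for kappa ~ 0
    (independent phases).
    """
    if not 0.0 <= kappa <= 1.0:
        raise ValueError(f"coupling strength must be in [0, 1], got {kappa}")
    if kappa < 1e-9:
        return 0.0
    if kappa > 1.0 - 1e-6:
        return np.inf
    return float(brentq(lambda c: vonmises_mean_resultant(c) - kappa, 1e-9, 1e6))


@dataclass(frozen=True)
class CouplingSpec:
    """Time- and band-localized phase coupling between two channels.

    ``channel_pair`` is (source, target): the target's oscillator in ``band``
    follows the source's phase during ``interval`` with strength ``kappa``.

    ``lag`` is a static phase offset (radians) added to the target; PLV is
    invariant to it.  The default (``None``) draws one lag per subject/task
    uniformly on the circle.  Non-zero lags matter: if many channels locked
    to one source all sat at zero lag, their shared oscillation would build
    up in the common average and be subtracted away again by CAR,
    erasing the very coupling that was implanted.
    """

    channel_pair: tuple[str, str]
    band: str
    interval: tuple[float, float]
    kappa: float
    lag: float | None = None

    def __post_init__(self) -> None:
        if self.band not in BAND_BY_NAME:
            raise ValueError(f"unknown band {self.band!r}")
        if not 0.0 <= self.kappa <= 1.0:
            raise ValueError(f"kappa must be in [0, 1], got {self.kappa}")
        t0, t1 = self.interval
        if not t0 < t1:
            raise ValueError(f"empty coupling interval {self.interval}")


@dataclass
class NoiseSpec:
    """Pink-noise background and per-band oscillator SNR.

    ``exponent`` is the 1/f^a slope of the background PSD.  ``snr_db`` is the
    oscillator power relative to the background power *within the
    oscillator's own band* (scalar, or a per-band-name mapping).  ``rms_uv``
    sets the broadband background RMS in microvolts.
    """

    exponent: float = 1.0
    snr_db: float | Mapping[str, float] = 0.0
    rms_uv: float = 10.0

    def band_snr_db(self, band: str) -> float:
        if isinstance(self.snr_db, Mapping):
            return float(self.snr_db.get(band, 0.0))
        return float(self.snr_db)


@dataclass
class FmaSpec:
    """FMA-UL score model: Normal(mean, sd) clipped to the 0-66 scale.

    ``linkage='monotone'`` additionally maps the within-cohort FMA rank to a
    per-subject coupling-strength multiplier in ``multiplier_range`` (highest
    score -> largest multiplier), for correlation-recovery experiments.
    """

    mean: float = 46.7
    sd: float = 8.0
    linkage: str = "independent"  # or "monotone"
    multiplier_range: tuple[float, float] = (0.3, 1.0)

    def __post_init__(self) -> None:
        if self.linkage not in ("independent", "monotone"):
            raise ValueError(f"unknown FMA linkage {self.linkage!r}")


@dataclass
class SyntheticCohortConfig:
    n_subjects: int = 9
    n_trials: int = 42
    channels: tuple[str, ...] = BIOSEMI64
    rate: float = 2048.0
    epoch_span: tuple[float, float] = (-4.0, 6.0)
    tasks: tuple[str, ...] = TASKS
    couplings: Mapping[str, Sequence[CouplingSpec]] = field(default_factory=dict)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    fma: FmaSpec = field(default_factory=FmaSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        self.channels = tuple(self.channels)
        self.tasks = tuple(self.tasks)
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        unknown = set(self.tasks) - set(TASKS)
        if unknown:
            raise ValueError(f"unknown tasks {sorted(unknown)}")
        for task, specs in self.couplings.items():
            if task not in self.tasks:
                raise ValueError(f"couplings given for absent task {task!r}")
            seen: set[tuple[str, str]] = set()
            for cs in specs:
                for label in cs.channel_pair:
                    if label not in self.channels:
                        raise ValueError(f"coupling channel {label!r} not in montage")
                band = BAND_BY_NAME[cs.band]
                if self.rate <= 2.0 * band.high:
                    raise ValueError(
                        f"rate {self.rate} Hz below Nyquist for band {cs.band}"
                    )
                key = (cs.channel_pair[1], cs.band)
                if key in seen:
                    raise ValueError(
                        f"channel {key[0]!r} is coupling target twice in band {key[1]!r}"
                    )
                seen.add(key)
                t0, t1 = cs.interval
                if t0 < self.epoch_span[0] or t1 > self.epoch_span[1]:
                    raise ValueError(f"coupling interval {cs.interval} outside epoch span")
        highest = max(b.high for b in BANDS)
        if self.rate <= 2.0 * highest:
            raise ValueError(f"rate {self.rate} Hz below Nyquist for {highest} Hz band edge")


@dataclass
class SubjectRecord:
    id: str
    fma_ul: float
    epochs: dict  # task -> EpochsSet
    coupling_multiplier: float = 1.0


# ---------------------------------------------------------------------------
# noise model


def _pink_spectrum_template(n: int, rate: float, exponent: float):
    """rFFT amplitude template of 1/f^a noise plus per-bin variance weights."""
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    # weight 2 for bins with a conjugate partner, 1 for DC / Nyquist
    weights = np.full(freqs.shape, 2.0)
    weights[0] = 1.0
    if n % 2 == 0:
        weights[-1] = 1.0
    return freqs, amp, weights


def band_noise_fraction(band: BandSpec, n: int, rate: float, exponent: float) -> float:
    """Fraction of the background noise variance inside ``band``."""
    freqs, amp, w = _pink_spectrum_template(n, rate, exponent)
    total = float(np.sum(w * amp**2))
    mask = (freqs >= band.low) & (freqs <= band.high)
    return float(np.sum(w[mask] * amp[mask] ** 2) / total)


def pink_noise(rng: np.random.Generator, shape: tuple[int, ...], n: int,
               rate: float, exponent: float, rms: float) -> np.ndarray:
    """Pink noise of broadband RMS ``rms``, shape ``shape + (n,)``."""
    _, amp, w = _pink_spectrum_template(n, rate, exponent)
    nf = amp.size
    # one interleaved draw viewed as complex (re, im) pairs
    coef = rng.standard_normal(shape + (nf, 2)).view(np.complex128)[..., 0]
    coef *= amp / np.sqrt(2.0)
    coef[..., 0] = 0.0
    if n % 2 == 0:
        coef[..., -1] = coef[..., -1].real
    x = np.fft.irfft(coef, n=n, axis=-1)
    # expected variance: each conjugate-paired bin contributes amp^2, DC is
    # zeroed; the realified Nyquist bin is off by a factor 2 but negligible
    var = float(np.sum(w[1:] * amp[1:] ** 2)) / n**2
    x *= rms / np.sqrt(var)
    return x


# ---------------------------------------------------------------------------
# epoch synthesis


def _coupling_mix(times: np.ndarray, interval: tuple[float, float]) -> np.ndarray:
    """Raised-cosine 0->1->0 mixing envelope for a coupling interval."""
    t0, t1 = interval
    ramp = min(_RAMP_S, 0.25 * (t1 - t0))
    m = np.zeros_like(times)
    inside = (times >= t0 + ramp) & (times < t1 - ramp)
    m[inside] = 1.0
    if ramp > 0:
        up = (times >= t0) & (times < t0 + ramp)
        m[up] = 0.5 * (1.0 - np.cos(np.pi * (times[up] - t0) / ramp))
        down = (times >= t1 - ramp) & (times < t1)
        m[down] = 0.5 * (1.0 + np.cos(np.pi * (times[down] - (t1 - ramp)) / ramp))
    return m


def generate_subject_epochs(
    config: SyntheticCohortConfig,
    task: str,
    rng: np.random.Generator,
    coupling_multiplier: float = 1.0,
    subject: str = "S00",
) -> EpochsSet:
    """Synthesize one subject/task block of epochs.

    Per trial and channel the signal is the sum over analysis bands of a
    center-frequency oscillator with a per-trial random phase, plus pink
    noise.  Coupled targets blend in a phase-locked copy of the source's
    oscillator over the coupling interval (amplitude crossfade, so no phase
    discontinuities enter the band filters).
    """
    tmin, tmax = config.epoch_span
    n = n_samples(tmin, tmax, config.rate)
    times = tmin + np.arange(n) / config.rate
    T, C = config.n_trials, len(config.channels)
    B = len(BANDS)
    ch_index = {c: i for i, c in enumerate(config.channels)}

    data = pink_noise(rng, (T, C), n, config.rate, config.noise.exponent,
                      config.noise.rms_uv)

    amps = np.empty(B)
    for b, band in enumerate(BANDS):
        frac = band_noise_fraction(band, n, config.rate, config.noise.exponent)
        snr = 10.0 ** (config.noise.band_snr_db(band.name) / 10.0)
        amps[b] = np.sqrt(2.0 * snr * frac) * config.noise.rms_uv

    # cos(w t + phi) = cos(phi) cos(w t) - sin(phi) sin(w t); summing over
    # bands is a pair of small real GEMMs, avoiding complex intermediates
    omegas = 2.0 * np.pi * np.array([band.center for band in BANDS])
    carrier_cos = np.cos(omegas[:, None] * times[None, :])  # B x n
    carrier_sin = np.sin(omegas[:, None] * times[None, :])
    phases = rng.uniform(-np.pi, np.pi, size=(B, T, C))
    p_cos = (amps[:, None, None] * np.cos(phases)).transpose(1, 2, 0).reshape(T * C, B)
    p_sin = (amps[:, None, None] * np.sin(phases)).transpose(1, 2, 0).reshape(T * C, B)
    data2d = data.reshape(T * C, n)
    tmp = p_cos @ carrier_cos
    data2d += tmp
    np.matmul(p_sin, carrier_sin, out=tmp)
    data2d -= tmp
    del tmp
    carriers = carrier_cos + 1j * carrier_sin  # used only for coupled targets

    band_idx = {band.name: b for b, band in enumerate(BANDS)}
    for spec in config.couplings.get(task, ()):
        kappa = spec.kappa * coupling_multiplier
        conc = kappa_to_concentration(kappa)
        lag = (rng.uniform(-np.pi, np.pi) if spec.lag is None
               else float(spec.lag))
        jitter = (np.zeros(T) if np.isinf(conc)
                  else rng.vonmises(0.0, conc, size=T))
        if conc == 0.0:
            continue  # independent: the base tone already is (draws kept)
        b = band_idx[spec.band]
        src = ch_index[spec.channel_pair[0]]
        tgt = ch_index[spec.channel_pair[1]]
        locked = phases[b, :, src] + lag + jitter
        mix = _coupling_mix(times, spec.interval)
        indep_tone = (np.exp(1j * phases[b, :, tgt])[:, None]
                      * carriers[b][None, :]).real
        locked_tone = (np.exp(1j * locked)[:, None] * carriers[b][None, :]).real
        data[:, tgt, :] += amps[b] * mix * (locked_tone - indep_tone)

    return EpochsSet(data=data, rate=config.rate, tmin=tmin,
                     channel_names=config.channels, task=task, subject=subject)


def cohort_scores(config: SyntheticCohortConfig) -> tuple[np.ndarray, np.ndarray]:
    """FMA-UL scores and coupling-strength multipliers for the cohort.

    Scores are Normal(mean, sd) clipped to [0, 66], one independent
    substream per subject.  Under monotone linkage the within-cohort FMA
    rank maps linearly onto ``multiplier_range`` (best score -> strongest
    coupling); otherwise all multipliers are 1.
    """
    fma_scores = np.empty(config.n_subjects)
    for s in range(config.n_subjects):
        rng = np.random.default_rng(
            np.random.SeedSequence(config.seed, spawn_key=(s, FMA_STREAM_KEY)))
        fma_scores[s] = np.clip(rng.normal(config.fma.mean, config.fma.sd), 0.0, 66.0)
    if config.fma.linkage == "monotone":
        lo, hi = config.fma.multiplier_range
        order = np.argsort(np.argsort(fma_scores))  # rank 0..n-1, ties broken by index
        multipliers = lo + (hi - lo) * order / max(config.n_subjects - 1, 1)
    else:
        multipliers = np.ones(config.n_subjects)
    return fma_scores, multipliers


def generate_cohort(config: SyntheticCohortConfig) -> list[SubjectRecord]:
    """Generate the full cohort: FMA scores plus epochs per subject and task.

    Deterministic for a fixed ``(config, config.seed)``.
    """
    fma_scores, multipliers = cohort_scores(config)
    cohort = []
    for s in range(config.n_subjects):
        sid = f"S{s + 1:02d}"
        epochs = {}
        for t, task in enumerate(config.tasks):
            rng = np.random.default_rng(
                np.random.SeedSequence(config.seed, spawn_key=(s, t)))
            epochs[task] = generate_subject_epochs(
                config, task, rng,
                coupling_multiplier=float(multipliers[s]), subject=sid)
        cohort.append(SubjectRecord(id=sid, fma_ul=float(fma_scores[s]),
                                    epochs=epochs,
                                    coupling_multiplier=float(multipliers[s])))
    return cohort
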