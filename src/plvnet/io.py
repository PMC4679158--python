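"""File I/O: EDF read/write, cohort manifests, config (de)serialization.

Synthetic cohorts are persisted as one EDF file per subject/task (one data
record per trial) plus a TSV manifest carrying subject id, task, FMA-UL
score, trial layout and file path.  Reading goes through ``mne`` (EDF and
BDF); the writer here emits plain 16-bit EDF, so a round trip is exact up to
the 16-bit amplitude quantization.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .epochs import EpochsSet
from .synthetic import (CouplingSpec, FmaSpec, NoiseSpec, SubjectRecord,
                        SyntheticCohortConfig)

_EDF_HEADER = 256
_EDF_PER_SIGNAL = 256


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")[:width]
    return b + b" " * (width - len(b))


def write_edf(epochs: EpochsSet, path: str | Path) -> Path:
    """Write epochs as a plain EDF file, one data record per trial."""
    path = Path(path)
    T, C, S = epochs.data.shape
    record_dur = S / epochs.rate
    pmin = epochs.data.min(axis=(0, 2))
    pmax = epochs.data.max(axis=(0, 2))
    flat = pmax - pmin == 0
    pmax = np.where(flat, pmin + 1.0, pmax)
    dmin, dmax = -32768, 32767

    with open(path, "wb") as fh:
        fh.write(_pad("0", 8))
        fh.write(_pad(f"subject {epochs.subject}", 80))
        fh.write(_pad(f"task {epochs.task} synthetic", 80))
        fh.write(_pad("01.01.00", 8))
        fh.write(_pad("00.00.00", 8))
        fh.write(_pad(str(_EDF_HEADER + _EDF_PER_SIGNAL * C), 8))
        fh.write(_pad("", 44))
        fh.write(_pad(str(T), 8))
        fh.write(_pad(f"{record_dur:g}", 8))
        fh.write(_pad(str(C), 4))
        for name in epochs.channel_names:
            fh.write(_pad(name, 16))
        for _ in range(C):
            fh.write(_pad("synthetic EEG", 80))
        for _ in range(C):
            fh.write(_pad("uV", 8))
        for v in pmin:
            fh.write(_pad(f"{v:.8g}"[:8], 8))
        for v in pmax:
            fh.write(_pad(f"{v:.8g}"[:8], 8))
        for _ in range(C):
            fh.write(_pad(str(dmin), 8))
        for _ in range(C):
            fh.write(_pad(str(dmax), 8))
        for _ in range(C):
            fh.write(_pad("", 80))
        for _ in range(C):
            fh.write(_pad(str(S), 8))
        for _ in range(C):
            fh.write(_pad("", 32))
        # re-read the 8-char physical bounds so scaling matches what a reader sees
        p0 = np.array([float(f"{v:.8g}"[:8]) for v in pmin])
        p1 = np.array([float(f"{v:.8g}"[:8]) for v in pmax])
        scale = (dmax - dmin) / (p1 - p0)
        for trial in range(T):
            dig = np.rint((epochs.data[trial] - p0[:, None]) * scale[:, None] + dmin)
            dig = np.clip(dig, dmin, dmax).astype("<i2")
            fh.write(dig.tobytes())
    return path


def check_edf_integrity(path: str | Path) -> None:
    """Verify the file length matches the header; raise naming the offset."""
    path = Path(path)
    size = path.stat().st_size
    with open(path, "rb") as fh:
        head = fh.read(_EDF_HEADER)
        if len(head) < _EDF_HEADER:
            raise ValueError(f"{path}: truncated EDF header at byte {len(head)}")
        header_bytes = int(head[184:192].decode("ascii", "replace"))
        n_records = int(head[236:244].decode("ascii", "replace"))
        n_signals = int(head[252:256].decode("ascii", "replace"))
        sig_head = fh.read(header_bytes - _EDF_HEADER)
        off = 216 * n_signals  # samples-per-record field block
        spr = [int(sig_head[off + 8 * i: off + 8 * (i + 1)]) for i in range(n_signals)]
    bytes_per_rec = 2 * sum(spr)
    expected = header_bytes + n_records * bytes_per_rec
    if size < expected:
        raise ValueError(
            f"{path}: truncated EDF file, {size} bytes on disk but header "
            f"declares {expected}; data ends at byte offset {size}")


def read_eeg(path: str | Path, fmt: str | None = None,
             expected_channels: int | None = None):
    """Read an EDF/BDF file; returns ``(data_uv, rate, channel_names)``.

    ``data_uv`` is channels x samples (continuous concatenation of the
    file's data records) in microvolts.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    if fmt == "edf":
        check_edf_integrity(path)
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    elif fmt == "bdf":
        raw = mne.io.read_raw_bdf(path, preload=True, verbose="error")
    else:
        raise ValueError(f"unknown EEG format {fmt!r} (expected edf or bdf)")
    names = tuple(raw.ch_names)
    if expected_channels is not None and len(names) != expected_channels:
        raise ValueError(
            f"{path}: expected {expected_channels} channels, found {len(names)}")
    data_uv = raw.get_data() * 1e6  # mne returns SI volts
    return data_uv, float(raw.info["sfreq"]), names


def write_cohort(cohort: list[SubjectRecord], outdir: str | Path,
                 tmin: float) -> Path:
    """Write one EDF per subject/task plus a TSV manifest; returns manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in cohort:
        for task, ep in rec.epochs.items():
            fname = f"{rec.id}_{task}.edf"
            write_edf(ep, outdir / fname)
            rows.append(dict(subject_id=rec.id, task=task,
                             fma_ul=round(rec.fma_ul, 4), file=fname,
                             n_trials=ep.n_trials, n_samples=ep.n_samples,
                             rate=ep.rate, tmin=tmin))
    manifest = outdir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest


def read_cohort(manifest_path: str | Path) -> list[SubjectRecord]:
    """Reconstruct a cohort from a manifest written by :func:`write_cohort`."""
    manifest_path = Path(manifest_path)
    table = pd.read_csv(manifest_path, sep="\t")
    root = manifest_path.parent
    subjects: dict[str, SubjectRecord] = {}
    for row in table.itertuples():
        data, rate, names = read_eeg(root / row.file, expected_channels=None)
        n_trials, n_samp = int(row.n_trials), int(row.n_samples)
        epochs = EpochsSet(
            data=data.reshape(len(names), n_trials, n_samp).transpose(1, 0, 2),
            rate=float(row.rate), tmin=float(row.tmin),
            channel_names=names, task=row.task, subject=row.subject_id)
        rec = subjects.setdefault(
            row.subject_id,
            SubjectRecord(id=row.subject_id, fma_ul=float(row.fma_ul), epochs={}))
        rec.epochs[row.task] = epochs
    return list(subjects.values())


# ---------------------------------------------------------------------------
# cohort-config serialization (YAML-friendly plain dicts)


def cohort_config_to_dict(config: SyntheticCohortConfig) -> dict:
    return dict(
        n_subjects=config.n_subjects,
        n_trials=config.n_trials,
        channels=list(config.channels),
        rate=config.rate,
        epoch_span=list(config.epoch_span),
        tasks=list(config.tasks),
        couplings={
            task: [dict(pair=list(cs.channel_pair), band=cs.band,
                        interval=list(cs.interval), kappa=cs.kappa,
                        lag=cs.lag)
                   for cs in specs]
            for task, specs in config.couplings.items()},
        noise=dict(exponent=config.noise.exponent,
                   snr_db=(dict(config.noise.snr_db)
                           if isinstance(config.noise.snr_db, dict)
                           else config.noise.snr_db),
                   rms_uv=config.noise.rms_uv),
        fma=dict(mean=config.fma.mean, sd=config.fma.sd,
                 linkage=config.fma.linkage,
                 multiplier_range=list(config.fma.multiplier_range)),
        seed=config.seed,
    )


def cohort_config_from_dict(d: dict) -> SyntheticCohortConfig:
    kwargs = dict(d)
    if "couplings" in kwargs:
        kwargs["couplings"] = {
            task: [CouplingSpec(channel_pair=tuple(cs["pair"]), band=cs["band"],
                                interval=tuple(cs["interval"]), kappa=cs["kappa"],
                                lag=cs.get("lag"))
                   for cs in specs]
            for task, specs in kwargs["couplings"].items()}
    if "noise" in kwargs:
        kwargs["noise"] = NoiseSpec(**kwargs["noise"])
    if "fma" in kwargs:
        fma = dict(kwargs["fma"])
        if "multiplier_range" in fma:
            fma["multiplier_range"] = tuple(fma["multiplier_range"])
        kwargs["fma"] = FmaSpec(**fma)
    for key in ("epoch_span",):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    for key in ("channels", "tasks"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    return SyntheticCohortConfig(**kwargs)
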