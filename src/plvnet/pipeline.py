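"""End-to-end orchestration: cohort -> preprocessing -> PLV -> graph metrics
-> baseline statistics -> motor-function correlation.

Metrics are always computed on the full montage and only afterwards filtered
to regions of interest for reporting.  The default configuration fixes the
analysis parameters: 256 Hz analysis rate, 1-80 Hz broadband,
-1..3 s analysis span, 1 s windows stepped by 250 ms (13 windows), baseline
[-1, 0) s, link density 0.2783, four sensorimotor bands.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .connectivity import TimeWindow, instantaneous_phase, plv_tensor, sliding_windows
from .epochs import BANDS, BAND_BY_NAME, BIOSEMI64
from .netmetrics import DEFAULT_DENSITY, metric_time_series
from .preprocess import DEFAULT_PTP_THRESHOLD_UV, preprocess_epochs
from .stats import ALPHAS, correlate_with_motor, window_vs_baseline_test
from .synthetic import (CouplingSpec, SyntheticCohortConfig, cohort_scores,
                        generate_subject_epochs)

METRICS = ("degree_centrality", "local_efficiency")

#: Electrode-level ROI proxies, left hemisphere = lesioned (contralateral).
DEFAULT_ROI_MAP: dict[str, str] = {
    "contralateral_m1": "C3",
    "ipsilateral_m1": "C4",
    "contralateral_pmc": "FC3",
    "ipsilateral_pmc": "FC4",
    "sma": "Fz",
    "contralateral_smc": "CP3",
    "ipsilateral_smc": "CP4",
    "contralateral_parietal": "P3",
    "ipsilateral_parietal": "P4",
}


def flip_roi_map(roi_map: Mapping[str, str]) -> dict[str, str]:
    """Mirror a left-lesion ROI map for right-lesioned subjects (3 <-> 4)."""
    trans = str.maketrans("34", "43")
    return {role: label.translate(trans) for role, label in roi_map.items()}


@dataclass
class PipelineConfig:
    target_rate: float = 256.0
    analysis_span: tuple[float, float] = (-1.0, 3.0)
    window_length: float = 1.0
    step: float = 0.25
    baseline_start: float = -1.0
    density: float = DEFAULT_DENSITY
    ptp_threshold: float = DEFAULT_PTP_THRESHOLD_UV
    band_names: tuple[str, ...] = tuple(b.name for b in BANDS)
    plv_mode: str = "across_trials"
    test_mode: str = "signed_rank"
    correlation: str = "spearman"
    normalize_mode: str = "difference"
    alphas: tuple[float, float] = ALPHAS
    fdr: bool = False
    roi_map: dict = field(default_factory=lambda: dict(DEFAULT_ROI_MAP))

    @property
    def bands(self):
        return tuple(BAND_BY_NAME[name] for name in self.band_names)

    @property
    def windows(self) -> list[TimeWindow]:
        return sliding_windows(*self.analysis_span, self.window_length, self.step)

    @property
    def baseline(self) -> TimeWindow:
        return TimeWindow(self.baseline_start, self.window_length)

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("analysis_span", "band_names", "alphas"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kwargs = dict(d)
        for key in ("analysis_span", "band_names", "alphas"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def default_cohort_config(seed: int = 0, **overrides) -> SyntheticCohortConfig:
    """The default simulated study: 9 subjects, 3 tasks, 42 trials, 64
    channels at 2048 Hz, with a contralateral-M1 (C3) high-beta hub during
    movement execution in the active task, a milder contralateral-SMC (CP3)
    hub in the MI task, and no implanted effects in the passive task."""
    c3_partners = ("C1", "C5", "FC3", "FC1", "CP3", "CP1", "Cz", "C4")
    cp3_partners = ("CP1", "CP5", "P3", "P1", "C3", "CPz")
    couplings = {
        "active": [CouplingSpec(("C3", p), "high_beta", (0.0, 2.0), 0.8)
                   for p in c3_partners],
        "mi": [CouplingSpec(("CP3", p), "high_beta", (0.0, 2.0), 0.6)
               for p in cp3_partners],
    }
    kwargs = dict(n_subjects=9, n_trials=42, channels=BIOSEMI64, rate=2048.0,
                  couplings=couplings, seed=seed)
    kwargs.update(overrides)
    return SyntheticCohortConfig(**kwargs)


# ---------------------------------------------------------------------------
# result bundle


@dataclass
class PipelineResult:
    config: PipelineConfig
    metrics: pd.DataFrame           # long: subject, task, band, metric, window_start, channel, value
    stacks: dict                    # (task, band, metric) -> subjects x windows x channels
    stats: dict                     # (task, band, metric) -> StatResult
    correlations: dict              # (task, band, metric) -> CorrelationResult
    fma: dict                       # subject -> score
    subjects: list
    channel_names: tuple
    window_starts: np.ndarray
    rejections: pd.DataFrame
    manifest: dict

    def stats_table(self) -> pd.DataFrame:
        rows = []
        for (task, band, metric), res in self.stats.items():
            for wdx, start in enumerate(res.window_starts):
                for c, ch in enumerate(res.channel_names):
                    rows.append((task, band, metric, start, ch,
                                 res.statistic[wdx, c], res.p[wdx, c],
                                 int(res.direction[wdx, c]),
                                 bool(res.p[wdx, c] < self.config.alphas[0]),
                                 bool(res.p[wdx, c] < self.config.alphas[1])))
        return pd.DataFrame(rows, columns=[
            "task", "band", "metric", "window_start", "channel",
            "statistic", "p", "direction", "sig_05", "sig_01"])

    def correlation_table(self) -> pd.DataFrame:
        rows = []
        for (task, band, metric), res in self.correlations.items():
            for wdx, start in enumerate(res.window_starts):
                for c, ch in enumerate(res.channel_names):
                    rows.append((task, band, metric, start, ch,
                                 res.coefficient[wdx, c], res.p[wdx, c]))
        return pd.DataFrame(rows, columns=[
            "task", "band", "metric", "window_start", "channel", "rho", "p"])


def _iter_subject_tasks(cohort) -> Iterable[tuple[str, float, str, object]]:
    """Yield (subject_id, fma, task, epochs_or_callable) lazily.

    Accepts either a realized cohort (list of SubjectRecord) or a
    SyntheticCohortConfig, in which case each subject/task block is
    generated on demand and can be freed after use.
    """
    if isinstance(cohort, SyntheticCohortConfig):
        config = cohort
        # scores/multipliers are cheap; the signal arrays are generated lazily
        fma_scores, mult = cohort_scores(config)
        for s in range(config.n_subjects):
            sid = f"S{s + 1:02d}"
            for t, task in enumerate(config.tasks):
                def make(s=s, t=t, task=task):
                    rng = np.random.default_rng(
                        np.random.SeedSequence(config.seed, spawn_key=(s, t)))
                    return generate_subject_epochs(
                        config, task, rng, coupling_multiplier=float(mult[s]),
                        subject=sid)
                yield sid, float(fma_scores[s]), task, make
    else:
        for rec in cohort:
            for task, ep in rec.epochs.items():
                yield rec.id, rec.fma_ul, task, (lambda ep=ep: ep)


def run_pipeline(cohort, config: PipelineConfig | None = None,
                 outdir: str | Path | None = None) -> PipelineResult:
    """Run the full analysis chain over a cohort.

    ``cohort`` is a list of SubjectRecord (in-memory or from
    :func:`plvnet.io.read_cohort`) or a SyntheticCohortConfig to be
    generated subject-by-subject on the fly.  Deterministic for fixed
    inputs; writes all result tables as TSV when ``outdir`` is given.
    """
    config = config or PipelineConfig()
    windows = config.windows
    starts = np.array([w.start for w in windows])
    base_match = np.flatnonzero(np.isclose(starts, config.baseline_start))
    if base_match.size == 0:
        raise ValueError(
            f"baseline start {config.baseline_start} s not on the window grid")
    baseline_index = int(base_match[0])

    metric_rows = []
    reject_rows = []
    stacks: dict[tuple, dict[str, np.ndarray]] = {}
    fma: dict[str, float] = {}
    channel_names: tuple[str, ...] | None = None
    subjects: list[str] = []

    for sid, score, task, make_epochs in _iter_subject_tasks(cohort):
        fma[sid] = score
        if sid not in subjects:
            subjects.append(sid)
        try:
            epochs = make_epochs()
            band_epochs, rej_log = preprocess_epochs(
                epochs, target_rate=config.target_rate,
                ptp_threshold=config.ptp_threshold, bands=config.bands)
            del epochs
            band_phases = {
                name: instantaneous_phase(ep, BAND_BY_NAME[name])
                for name, ep in band_epochs.items()}
            del band_epochs
            tensor = plv_tensor(band_phases, windows, mode=config.plv_mode)
            del band_phases
            series = metric_time_series(tensor, config.density,
                                        task=task, subject=sid)
            del tensor
        except Exception as exc:
            raise RuntimeError(
                f"pipeline failed for subject {sid}, task {task}: {exc}") from exc
        for rec in rej_log:
            reject_rows.append((sid, task, rec.trial, ";".join(rec.channels),
                                rec.max_ptp_uv))
        for (band, metric), ser in series.items():
            channel_names = ser.channel_names
            stacks.setdefault((task, band, metric), {})[sid] = ser.values
            for wdx, start in enumerate(ser.window_starts):
                for c, ch in enumerate(ser.channel_names):
                    metric_rows.append((sid, task, band, metric, start, ch,
                                        ser.values[wdx, c]))

    stack_arrays = {}
    stats_grids = {}
    corr_grids = {}
    skipped = []
    for key, per_subject in stacks.items():
        arr = np.stack([per_subject[sid] for sid in subjects])
        stack_arrays[key] = arr
        # across-subject stages need their minimum cohort sizes
        if len(subjects) >= 5:
            stats_grids[key] = window_vs_baseline_test(
                arr, starts, baseline_index, channel_names,
                mode=config.test_mode, fdr=config.fdr)
        elif "stats" not in skipped:
            skipped.append("stats")
        base = arr[:, baseline_index:baseline_index + 1, :]
        if config.normalize_mode == "ratio":
            with np.errstate(divide="ignore", invalid="ignore"):
                normalized = np.where(base != 0, arr / base, np.nan)
        else:
            normalized = arr - base
        if len(subjects) >= 4:
            corr_grids[key] = correlate_with_motor(
                normalized, np.array([fma[sid] for sid in subjects]),
                starts, channel_names, method=config.correlation)
        elif "correlations" not in skipped:
            skipped.append("correlations")

    metrics = pd.DataFrame(metric_rows, columns=[
        "subject", "task", "band", "metric", "window_start", "channel", "value"])
    rejections = pd.DataFrame(reject_rows, columns=[
        "subject", "task", "trial", "channels", "max_ptp_uv"])
    manifest = dict(
        package="plvnet", version=__version__,
        config_hash=config.config_hash(), config=config.to_dict(),
        n_subjects=len(subjects), subjects=subjects,
        n_windows=len(windows), baseline_index=baseline_index,
        skipped_stages=skipped,
        cohort_seed=(cohort.seed if isinstance(cohort, SyntheticCohortConfig)
                     else None),
    )
    result = PipelineResult(
        config=config, metrics=metrics, stacks=stack_arrays, stats=stats_grids,
        correlations=corr_grids, fma=fma, subjects=subjects,
        channel_names=channel_names, window_starts=starts,
        rejections=rejections, manifest=manifest)
    if outdir is not None:
        write_result(result, outdir)
    return result


def write_result(result: PipelineResult, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.metrics.to_csv(outdir / "metrics.tsv", sep="\t", index=False)
    result.stats_table().to_csv(outdir / "stats.tsv", sep="\t", index=False)
    result.correlation_table().to_csv(outdir / "correlations.tsv", sep="\t",
                                      index=False)
    result.rejections.to_csv(outdir / "rejections.tsv", sep="\t", index=False)
    pd.DataFrame(sorted(result.fma.items()),
                 columns=["subject", "fma_ul"]).to_csv(
        outdir / "fma.tsv", sep="\t", index=False)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
    return outdir


def extract_roi_table(table: pd.DataFrame,
                      roi_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Restrict a long results table to ROI channels (pure selection).

    Adds a ``role`` column; values are untouched.  Raises if an ROI label is
    absent from the table's channels.
    """
    roi_map = dict(roi_map or DEFAULT_ROI_MAP)
    if table.empty:
        out = table.copy()
        out.insert(0, "role", pd.Series(dtype=str))
        return out
    present = set(table["channel"].unique())
    missing = [lb for lb in roi_map.values() if lb not in present]
    if missing:
        raise ValueError(f"ROI channels missing from results: {missing}")
    label_to_role = {label: role for role, label in roi_map.items()}
    out = table[table["channel"].isin(label_to_role)].copy()
    out.insert(0, "role", out["channel"].map(label_to_role))
    return out.reset_index(drop=True)
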