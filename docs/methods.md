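# Methods

`plvnet` implements a time-resolved analysis of EEG functional brain
networks during cued motor tasks, together with a synthetic cohort
generator that provides ground truth for every stage. This note documents
the models, the parameters that matter, the numerical choices, and what the
synthetic validation does and does not establish.

## Analysis pipeline

### Preprocessing

Epochs (trials x channels x samples, microvolts, cut around the task cue)
pass through a fixed chain:

1. **Downsampling** to 256 Hz (anti-aliased polyphase resampling).
2. **Broadband band-pass** 1–80 Hz, Butterworth order 4, applied
   forward–backward (`sosfiltfilt`), so the net filter has zero phase.
   Zero-phase filtering is mandatory here: any group delay would bias the
   instantaneous phase estimates that all downstream statistics rest on.
3. **Trial rejection** by peak-to-peak amplitude: any trial exceeding a
   threshold (default 150 µV) on any channel is dropped and logged. This is
   a deterministic, testable stand-in for manual/ICA artifact screening of
   real recordings; an ICA hook is deliberately out of scope.
4. **Common average reference (CAR)**: each sample is re-referenced to the
   instantaneous mean across channels. Idempotent by construction.
5. **Band split** into mu (8–12 Hz), low beta (13–20 Hz), high beta
   (21–30 Hz) and gamma (31–50 Hz). The band filters are Butterworth
   **order 8**, zero-phase. Order 8 rather than 4 is a measured choice:
   adjacent analysis bands share an edge (30/31 Hz), and with order 4 a
   narrowband source near 25 Hz leaks through the gamma filter edge at
   ~0.17 amplitude (after forward–backward application), enough to carry
   phase structure across bands and bias gamma-band PLV upward by ~0.045.
   With order 8 the cross-band PLV bias falls below ~0.01, the estimation
   noise level.

All time windows use one half-open convention `[t0, t0 + L)` with sample
index `round((t - t_start) * rate)`; an epoch spanning (-4, 6) s at 2048 Hz
has 20480 samples. Band filtering runs on the full epoch and the analysis
is confined to -1..3 s, leaving seconds of edge padding on each side, so
filter and Hilbert edge transients never reach the analyzed samples.

### Connectivity

Instantaneous phase is the argument of the Hilbert analytic signal of each
band-limited epoch. Phase-locking value for channels (i, j) in a window is

    PLV_ij = (1/S) * sum_s | (1/T) * sum_t exp(i (phi_i,ts - phi_j,ts)) |

— locking **across the T trials** at each sample, averaged over the S
window samples. This across-trials estimator is the default; a
within-trial-over-time variant (`mode="within_trials"`) is provided because
either reading is defensible, and which one a given study used is often
unstated. For T independent trials the null expectation is the Rayleigh
mean resultant `sqrt(pi)/(2 sqrt(T))` (0.0886 at T = 100), which the tests
pin down.

Windows are 1 s long, stepped by 250 ms over -1..3 s: 13 windows, the first
of which, [-1, 0) s, is the pre-cue baseline. Windowing slices phase
samples only — there is no per-window re-filtering, which would reintroduce
edge transients. Matrices are symmetric with zero diagonal, so a 64-channel
matrix has 64 x 64 - 64 informative entries (2016 undirected links).

### Graph metrics

Each (band, window) PLV matrix is proportionally thresholded: the strongest
`round(density * n(n-1)/2)` undirected links keep their weights (round half
to even; ties broken by a stable (weight, i, j) sort so results are
deterministic). The default density 0.2783 retains 561 of 2016 links at 64
channels. Density is applied per window; comparable link counts across
windows and subjects is the point of proportional thresholding.

Two per-channel indices are computed:

* **Degree centrality** `k_i = sum_j a_ij` on the binarized matrix.
* **Weighted local efficiency**

      E^w_loc,i = sum_{j != h in N_i} (w_ij w_ih [d^w_jh(N_i)]^-1)^(1/3)
                  / (k_i (k_i - 1))

  where `d^w_jh(N_i)` is the shortest path from j to h running only
  through neighbors of i, with link length 1/w. The sum runs over ordered
  neighbor pairs and the `k_i (k_i - 1)` normalization makes a complete
  unit-weight graph score exactly 1 at every node — the anchor property the
  tests enforce. Unreachable pairs contribute zero; `k_i < 2` scores zero.
  Shortest paths use Floyd–Warshall on the (small) neighbor subgraph; an
  exhaustive simple-path enumerator, written independently, serves as the
  test oracle on all graphs up to 6 nodes.

### Statistics

Per subject, each metric series is referenced to the subject's own baseline
window by subtraction (`window - baseline`); subtraction rather than ratio
because the quantities of interest are small signed changes (a ratio mode
exists behind a flag). Across subjects, every (channel, window) cell is
tested against baseline with an **exact paired Wilcoxon signed-rank test**:
zero differences are dropped, midranks handle ties, and for n <= 12 the
two-sided p-value `P(|W - mu| >= |w_obs - mu|)` is computed by enumerating
all 2^n sign assignments (normal approximation with tie correction beyond).
The enumeration is implemented here rather than delegated because library
exact modes silently fall back to approximations under ties, and tied
integer degree differences are the *common* case for this statistic. An
unpaired rank-sum mode is selectable; the paired test is the default
because the analysis is explicitly baseline-referenced within subject.
Normality is screened (one-sample Kolmogorov–Smirnov of the standardized
sample against N(0,1)) but the nonparametric path is always available; with
nine subjects per group, normality cannot be assumed.

No multiple-comparison correction is applied by default — cells are
reported at per-cell alpha = 0.05 and 0.01, mirroring common practice in
this literature — and a Benjamini–Hochberg flag exists for stricter reuse.

Metric–motor-function association is Spearman rank correlation across
subjects between each cell of the baseline-normalized series and the
FMA-UL score (Pearson selectable). With n = 9 and no distributional
grounds, rank correlation is the defensible default.

ROIs (C3/C4 primary motor, FC3/FC4 premotor, Fz supplementary motor,
CP3/CP4 somatosensory, P3/P4 parietal; left hemisphere = lesioned by
convention, with a flip helper) are applied **after** computation: metrics
are always computed on the full montage and only filtered for reporting.

## Synthetic cohort generator

The generator emulates a 64-channel (Biosemi 10-10) grasping-task study:
9 subjects, three task conditions (active, motor imagery, passive), 42
trials per task, epochs -4..6 s at 2048 Hz, and a per-subject upper-limb
motor score (FMA-UL, 0–66, Normal(46.7, 8) clipped).

Signal model per trial and channel: one oscillator per analysis band at the
band's center frequency with an independent uniform phase per trial, plus
1/f (pink) background noise. Oscillator amplitude is set per band from the
in-band SNR: `A^2/2 = snr * P_band`, where `P_band` is the pink-noise power
inside the band; the default 0 dB makes oscillator and in-band noise power
equal — realistic for sensorimotor rhythms and deliberately unflattering to
the estimator (at 0 dB the noise-induced phase jitter dilutes an implanted
PLV of kappa to roughly 0.5–0.6 kappa after the full pipeline; the
zero-noise limit recovers kappa itself).

**Implanted coupling** is the ground truth: a `CouplingSpec` makes a target
channel's band oscillator follow a source channel's phase during a stated
interval, with von Mises jitter whose concentration is the exact inverse of
the mean resultant length `A(c) = I1(c)/I0(c)` evaluated at kappa — so the
expected PLV of the pair equals kappa (before noise dilution) with no
free calibration constants. kappa = 1 means zero jitter; kappa = 0 means
independent phases. Interval restriction uses a 100 ms raised-cosine
amplitude crossfade between the independent and the locked oscillator, so
no phase discontinuities enter the filters. Each coupling also carries a
static phase lag (default: drawn uniformly per subject/task). The lag is
invisible to PLV but matters physically: if several channels locked to one
source all sat at zero lag, their common oscillation would accumulate in
the channel average and CAR would subtract it straight back out of every
cluster member, erasing the implanted effect. Nonzero lags — the
physiologically ordinary case — keep the common average incoherent.

FMA linkage: by default scores are independent of the implanted structure.
In `monotone` mode, the within-cohort FMA rank maps linearly onto a
coupling-strength multiplier (default range 0.3–1.0, best score =
strongest coupling), giving correlation-recovery experiments a known
monotone ground truth.

Randomness is split into named substreams (`SeedSequence(seed,
spawn_key=(subject, task))`; FMA uses slot 10000), so cohorts are bitwise
reproducible and adding a subject or task never reshuffles existing data.

Default implanted effects in the simulated study: a contralateral-M1 (C3)
high-beta hub coupled to eight sensorimotor neighbors at kappa = 0.8 during
movement execution (0–2 s) in the active task, a milder contralateral-SMC
(CP3) hub (kappa = 0.6) in the MI task, and nothing in the passive task.

### What the generator does *not* model

No volume conduction or leadfield mixing (beyond what CAR induces), no
EOG/EMG artifacts, no event-related (de)synchronization amplitude dynamics,
no baseline connectivity structure (the pre-cue period is the independent-
phase null — an assumption, since baseline coupling levels in real data
are unknown). Passing tests therefore demonstrate that the pipeline
recovers known phase-coupling structure under realistic noise, not that it
is robust to artifacts or source mixing in real recordings.

## Validation design and problem sizes

Validation is property-based. The graph metrics are checked against
exhaustive brute-force enumeration on 200 random graphs of up to 6 nodes
(max deviation < 1e-12) plus closed-form anchors; PLV against circular
statistics (exact 1 for constant lag, Rayleigh floor for independence);
the exact test against full sign-flip enumeration; and the whole chain
against two cohort-level experiments:

* **Type-I calibration**: 200 null cohorts (9 subjects, no coupling) — the
  fraction of significant local-efficiency cells at alpha = 0.05 must sit
  in 0.05 ± 0.02. The continuous metric is the right calibration probe: on
  integer degree cells the exact test is conservative by construction
  (ties and zero differences shrink the effective sample).
* **Parameter recovery**: 50 cohorts with the C3 high-beta hub
  (kappa = 0.8, 0–2 s) and FMA-linked multipliers — the hub's degree
  increase must reach p < 0.05 in at least one execution window in >= 90%
  of replicates, other bands must flag it in <= 10%, and the hub's
  local-efficiency series must rank-correlate with FMA at median rho > 0.8.
  Local efficiency is the correlation readout because it is continuous in
  the link weights; thresholded binary degree saturates (a link is either
  retained or not) and is information-limited for rank recovery at n = 9.

The cohort-level experiments run on scaled problem sizes chosen for suite
runtime: a 16-channel sensorimotor montage, 256 Hz native rate, and
-2..4 s epochs (still 1 s of filter padding around the analysis span);
subject count (9), trials (42 for recovery), coupling strength, alphas and
all pass thresholds keep the emulated study's values. The full-scale default study
(9 subjects x 3 tasks x 42 trials x 64 channels at 2048 Hz) runs end to end
in the acceptance suite, twice, to establish the runtime envelope and
byte-identical reproducibility at a fixed seed.

## Known limitations

* The exact signed-rank test's discreteness at n = 9 caps per-cell type-I
  error at 24/512 ≈ 0.047 and makes heavily tied cells conservative.
* Band specificity is as good as the band filters: extremely strong
  narrowband sources just inside a neighboring band can still contribute
  a small cross-band PLV bias (< ~0.01 at order 8).
* CAR couples channels weakly (each channel inherits -1/n of every other);
  with small montages this raises the PLV floor slightly above the
  Rayleigh value. The effect is window-independent and cancels in
  baseline-referenced statistics.
* Proportional thresholding conserves total link count, so strong focal
  coupling necessarily *displaces* links elsewhere in the same window —
  degree changes at uncoupled channels can be (weakly) negative without
  any implanted effect there.
* EDF export quantizes to 16 bits of the per-channel dynamic range.
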