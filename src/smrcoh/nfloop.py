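"""Closed-loop neurofeedback protocol simulation.

One training session is one 3-min baseline run followed by six 3-min
feedback runs.  The trainee watches three bars updated once per second:
the middle bar shows SMR-band (12-15 Hz) coherence between Cz and CPz
over a trailing window of 1-s epochs, the outer bars show theta (4-7 Hz)
and beta (21-35 Hz) power on Cz, which act as artifact-control bars.

Thresholds come from the baseline run: mean coherence for the feedback
bar, mean + 1 SD for each control bar.  After every feedback run the
coherence threshold is re-set to that run's mean while the control
thresholds stay fixed for the whole session.  The display is "green"
when both control bars are below threshold and the coherence bar is on
the desired side of its threshold (above for the up-regulation group,
below for down-regulation); a reward counter increments on every entry
into the green state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numpy.typing import NDArray

from .eegsim import BETA_BAND, SMR_BAND, THETA_BAND, BandSpec, LearnerParams, Recording, simulate_run
from .preproc import RejectionCriteria, epoch, reject_epochs
from .spectral import complex_demod_power, run_summary

__all__ = [
    "ProtocolConfig",
    "Thresholds",
    "BarSeries",
    "SessionRecord",
    "compute_thresholds",
    "adapt_threshold",
    "online_bars",
    "score_rewards",
    "run_training",
]


@dataclass(frozen=True)
class ProtocolConfig:
    """Training protocol geometry and online-estimator settings."""

    n_sessions: int = 10
    runs_per_session: int = 7  # 1 baseline + 6 feedback
    run_s: float = 180.0
    fs: float = 256.0
    feedback_band: BandSpec = SMR_BAND
    theta_band: BandSpec = THETA_BAND
    beta_band: BandSpec = BETA_BAND
    direction: str = "up"
    online_window_epochs: int = 8
    reward_mode: str = "entry"  # 'entry': count green entries; 'second': green seconds
    adaptation: str = "last-run"  # or 'running-mean' over baseline + prior feedback runs
    criteria: RejectionCriteria = field(default_factory=RejectionCriteria)

    def __post_init__(self) -> None:
        if self.runs_per_session < 2:
            raise ValueError(
                "runs_per_session must be >= 2 (baseline + at least one feedback run)"
            )
        if self.online_window_epochs < 2:
            raise ValueError("online_window_epochs must be >= 2")
        if self.direction not in ("up", "down"):
            raise ValueError("direction must be 'up' or 'down'")
        if self.reward_mode not in ("entry", "second"):
            raise ValueError("reward_mode must be 'entry' or 'second'")
        if self.adaptation not in ("last-run", "running-mean"):
            raise ValueError("adaptation must be 'last-run' or 'running-mean'")


@dataclass(frozen=True)
class Thresholds:
    """Bar thresholds: coherence (feedback) and theta/beta power (control)."""

    coh_thr: float
    theta_thr: float
    beta_thr: float

    def __post_init__(self) -> None:
        if self.theta_thr <= 0 or self.beta_thr <= 0:
            raise ValueError("control-band power thresholds must be positive")


@dataclass
class BarSeries:
    """Per-second bar values for one run (NaN before the first estimable update)."""

    coh: NDArray[np.float64]
    theta: NDArray[np.float64]
    beta: NDArray[np.float64]

    @property
    def n_updates(self) -> int:
        return self.coh.size


@dataclass
class SessionRecord:
    session_idx: int
    group: str
    thresholds: list[Thresholds]       # one per run (baseline's = thresholds it produced)
    run_summaries: list[dict]          # 7 dicts: offline per-run summaries
    reward_count: int

    def __post_init__(self) -> None:
        if self.reward_count < 0:
            raise ValueError("reward_count must be non-negative")

    def to_dict(self) -> dict:
        return {
            "session": self.session_idx,
            "group": self.group,
            "reward_count": self.reward_count,
            "thresholds": [vars(t) for t in self.thresholds],
            "runs": self.run_summaries,
        }


def online_bars(recording: Recording, config: ProtocolConfig = ProtocolConfig()) -> BarSeries:
    """Simulated once-per-second feedback display values.

    At second t the coherence bar is the band MSC over the trailing
    ``online_window_epochs`` 1-s epochs (all epochs so far while the window
    is filling; NaN at t=1, where a single epoch would give MSC=1 trivially).
    The control bars are the current epoch's complex-demodulation theta and
    beta power on Cz.
    """
    fs = recording.fs
    samples_per = int(round(fs))
    n_sec = recording.n_samples // samples_per
    if n_sec < config.online_window_epochs:
        raise ValueError("recording shorter than the online coherence window")
    x = recording.channel("Cz")[: n_sec * samples_per].reshape(n_sec, samples_per)
    y = recording.channel("CPz")[: n_sec * samples_per].reshape(n_sec, samples_per)

    # sliding-window band MSC via cumulative sums of per-epoch (cross-)spectra
    from .spectral import band_bins, taper

    window = taper(samples_per, 0.10)
    sel = band_bins(np.fft.rfftfreq(samples_per, d=1.0 / fs), config.feedback_band)
    X = np.fft.rfft((x - x.mean(axis=1, keepdims=True)) * window, axis=1)[:, sel]
    Y = np.fft.rfft((y - y.mean(axis=1, keepdims=True)) * window, axis=1)[:, sel]

    def _cum(a):
        return np.concatenate([np.zeros((1, a.shape[1]), dtype=a.dtype), np.cumsum(a, axis=0)])

    cxx, cyy, cxy = _cum(np.abs(X) ** 2), _cum(np.abs(Y) ** 2), _cum(X * np.conj(Y))
    coh = np.full(n_sec, np.nan)
    w = config.online_window_epochs
    for t in range(2, n_sec + 1):
        lo = max(0, t - w)
        sxx, syy, sxy = cxx[t] - cxx[lo], cyy[t] - cyy[lo], cxy[t] - cxy[lo]
        denom = sxx * syy
        msc = np.zeros(denom.shape)
        ok = denom > 0
        msc[ok] = np.abs(sxy[ok]) ** 2 / denom[ok]
        coh[t - 1] = float(np.clip(msc, 0.0, 1.0).mean())

    cz = recording.channel("Cz")
    theta = complex_demod_power(cz, config.theta_band, fs)[:n_sec]
    beta = complex_demod_power(cz, config.beta_band, fs)[:n_sec]
    return BarSeries(coh=coh, theta=theta, beta=beta)


def compute_thresholds(baseline_bars: BarSeries) -> Thresholds:
    """Baseline-derived thresholds: mean coherence; mean + 1 SD control power.

    The SD is the sample standard deviation (n-1 denominator).
    """
    coh = baseline_bars.coh[np.isfinite(baseline_bars.coh)]
    if coh.size < 2:
        raise ValueError("baseline has fewer than 2 estimable coherence updates")
    return Thresholds(
        coh_thr=float(coh.mean()),
        theta_thr=float(baseline_bars.theta.mean() + baseline_bars.theta.std(ddof=1)),
        beta_thr=float(baseline_bars.beta.mean() + baseline_bars.beta.std(ddof=1)),
    )


def adapt_threshold(previous_bars: BarSeries, thresholds: Thresholds,
                    prior_means: list[float] | None = None) -> Thresholds:
    """After a feedback run: coherence threshold <- that run's mean coherence;
    control thresholds unchanged.

    With ``prior_means`` (the mean coherence of the baseline and earlier
    feedback runs) the new threshold is instead the running mean over all
    runs so far -- the smoother alternative adaptation rule.
    """
    coh = previous_bars.coh[np.isfinite(previous_bars.coh)]
    if coh.size == 0:
        return thresholds
    run_mean = float(coh.mean())
    if prior_means:
        run_mean = float(np.mean([*prior_means, run_mean]))
    return replace(thresholds, coh_thr=run_mean)


def green_states(bars: BarSeries, thresholds: Thresholds, direction: str) -> NDArray[np.bool_]:
    """Per-update green/non-green state of the display."""
    controls_ok = (bars.theta < thresholds.theta_thr) & (bars.beta < thresholds.beta_thr)
    with np.errstate(invalid="ignore"):
        if direction == "up":
            coh_ok = bars.coh > thresholds.coh_thr
        else:
            coh_ok = bars.coh < thresholds.coh_thr
    return controls_ok & np.nan_to_num(coh_ok, nan=False).astype(bool)


def score_rewards(bars: BarSeries, thresholds: Thresholds, direction: str = "up",
                  mode: str = "entry") -> int:
    """Reward count: entries into the green state (or green seconds)."""
    green = green_states(bars, thresholds, direction)
    if mode == "second":
        return int(green.sum())
    entries = green & ~np.concatenate(([False], green[:-1]))
    return int(entries.sum())


def run_training(
    cohort: list[LearnerParams],
    config: ProtocolConfig = ProtocolConfig(),
    seed: int = 0,
    group: str | None = None,
    subject_offset: int = 0,
) -> tuple[pd.DataFrame, list[SessionRecord]]:
    """Full training for a cohort: baseline thresholds, adaptation, rewards,
    and the offline pipeline on every run.

    Returns the long-format dataset (one row per subject x session x run with
    band coherence, band powers and the rejection rate) and the per-session
    records.  Deterministic given ``seed``: subject s uses stream (seed, s).
    """
    if not cohort:
        raise ValueError("cohort must not be empty")
    group = group or config.direction
    rows = []
    records: list[SessionRecord] = []
    for si, learner in enumerate(cohort):
        subject = subject_offset + si + 1
        subj_seed = [int(seed), 1000 + subject]
        for session_idx in range(1, config.n_sessions + 1):
            thresholds: Thresholds | None = None
            session_thresholds: list[Thresholds] = []
            summaries: list[dict] = []
            run_means: list[float] = []
            reward_total = 0
            for run_idx in range(1, config.runs_per_session + 1):
                rec = simulate_run(
                    learner, session_idx, run_idx, config.run_s, config.fs,
                    seed=np.random.SeedSequence(subj_seed).generate_state(1)[0] % (2**31),
                )
                try:
                    bars = online_bars(rec, config)
                    es = reject_epochs(epoch(rec), config.criteria)
                    summary = run_summary(es)
                except Exception as err:  # annotate with protocol context
                    raise RuntimeError(
                        f"subject {subject}, session {session_idx}, run {run_idx}: {err}"
                    ) from err
                if run_idx == 1:
                    thresholds = compute_thresholds(bars)
                else:
                    assert thresholds is not None
                    reward_total += score_rewards(
                        bars, thresholds, config.direction, config.reward_mode
                    )
                    prior = run_means if config.adaptation == "running-mean" else None
                    thresholds = adapt_threshold(bars, thresholds, prior)
                run_means.append(float(np.nanmean(bars.coh)))
                session_thresholds.append(thresholds)
                summary.update(
                    group=group, subject=subject, session=session_idx, run=run_idx,
                    true_coupling=rec.meta["coupling"], reward_count=reward_total,
                )
                summaries.append(summary)
                rows.append(summary)
            records.append(
                SessionRecord(
                    session_idx=session_idx, group=group,
                    thresholds=session_thresholds, run_summaries=summaries,
                    reward_count=reward_total,
                )
            )
    dataset = pd.DataFrame(rows)
    return dataset, records


def records_to_json(records: list[SessionRecord], path) -> None:
    """Serialize SessionRecords (thresholds, summaries, rewards) to JSON."""
    import json
    from pathlib import Path

    Path(path).write_text(json.dumps([r.to_dict() for r in records], indent=1))
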