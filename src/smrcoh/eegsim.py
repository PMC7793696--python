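"""Synthetic two-channel EEG with known band-limited coupling.

Generates Cz/CPz/EOG recordings whose ground truth is fully known:
a 1/f background, a shared 12-15 Hz (SMR) component with configurable
lag and coupling strength, independent theta and beta components, ocular
and muscle artifacts, and subject-level linear learning trends in the
coupling across runs and sessions.  Every downstream stage (epoching,
rejection, coherence estimation, the closed-loop protocol, the trend
statistics) is testable against this ground truth.

Coupling model
--------------
For a coupling parameter ``c`` in [0, 1] the two channels carry

    x1 = sqrt(c) * s(t)       + sqrt(1 - c) * n1(t)
    x2 = sqrt(c) * s(t - tau) + sqrt(1 - c) * n2(t)

where ``s``, ``n1``, ``n2`` are independent band-limited Gaussian signals
of equal power.  The cross-spectral correlation coefficient inside the
band then equals ``c`` and the magnitude-squared coherence equals ``c**2``
(closed form), while the imaginary part of coherency is ``c * sin(2*pi*f*tau)``
-- zero for an instantaneous (volume-conducted) mixture, maximal when the
lag is a quarter period of the band centre.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numpy.typing import NDArray

__all__ = [
    "BandSpec",
    "Recording",
    "LearnerParams",
    "SMR_BAND",
    "THETA_BAND",
    "BETA_BAND",
    "make_background",
    "make_bandlimited_noise",
    "make_coupled_pair",
    "make_volume_conduction_pair",
    "inject_artifacts",
    "simulate_run",
    "simulate_outcomes",
]


@dataclass(frozen=True)
class BandSpec:
    """A frequency band [f_lo, f_hi] in Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not 0 < self.f_lo < self.f_hi:
            raise ValueError(f"need 0 < f_lo < f_hi, got [{self.f_lo}, {self.f_hi}]")

    @property
    def center(self) -> float:
        return 0.5 * (self.f_lo + self.f_hi)

    @property
    def width(self) -> float:
        return self.f_hi - self.f_lo


SMR_BAND = BandSpec("smr", 12.0, 15.0)
THETA_BAND = BandSpec("theta", 4.0, 7.0)
BETA_BAND = BandSpec("beta", 21.0, 35.0)


@dataclass
class Recording:
    """Multichannel time series in microvolts.

    ``artifact_truth`` maps an artifact class name ('blink', 'muscle') to a
    per-sample boolean mask marking affected samples; ``meta`` carries
    simulation ground truth (coupling used, seed, event times).
    """

    data: NDArray[np.float64]  # channels x samples, microvolts
    fs: float = 256.0
    labels: tuple[str, ...] = ("Cz", "CPz", "EOG")
    artifact_truth: dict[str, NDArray[np.bool_]] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("one label per channel required")
        if self.artifact_truth is not None:
            for name, mask in self.artifact_truth.items():
                if mask.shape != (self.data.shape[1],):
                    raise ValueError(f"artifact mask {name!r} length mismatch")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, label: str) -> NDArray[np.float64]:
        try:
            return self.data[self.labels.index(label)]
        except ValueError:
            raise KeyError(f"channel {label!r} not in {self.labels}") from None

    def any_artifact(self) -> NDArray[np.bool_]:
        """Union of all ground-truth artifact masks (all-False if none)."""
        out = np.zeros(self.n_samples, dtype=bool)
        if self.artifact_truth:
            for mask in self.artifact_truth.values():
                out |= mask
        return out


@dataclass(frozen=True)
class LearnerParams:
    """Generative parameters of one simulated trainee.

    The coupling used in session s, run r is

        c(s, r) = clip(c0 + beta_session*(s-1) + beta_run*(r-1) + eps, 0, 0.95)

    with eps ~ N(0, noise_sd^2) drawn once per run.  ``power_trends`` maps a
    band name to (session_slope, run_slope) multiplicative amplitude trends
    (fraction per session / per run).  Artifact rates are events per minute.
    """

    c0: float = 0.3
    beta_session: float = 0.0
    beta_run: float = 0.0
    lag_ms: float = 18.0
    power_trends: dict[str, tuple[float, float]] = field(default_factory=dict)
    noise_sd: float = 0.02
    blink_rate: float = 4.0  # with muscle_rate=1 this lands the pooled rejection rate near 9%
    muscle_rate: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.c0 <= 1.0:
            raise ValueError("c0 must lie in [0, 1]")
        if self.lag_ms < 0:
            raise ValueError("lag_ms must be non-negative")

    def coupling(self, session_idx: int, run_idx: int, eps: float = 0.0) -> float:
        c = self.c0 + self.beta_session * (session_idx - 1) + self.beta_run * (run_idx - 1) + eps
        return float(np.clip(c, 0.0, 0.95))


def _check_duration(duration_s: float, fs: float) -> int:
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if fs <= 0:
        raise ValueError("fs must be positive")
    n = int(round(duration_s * fs))
    if n < 2:
        raise ValueError("duration too short for the given sampling rate")
    return n


def make_background(
    duration_s: float,
    fs: float = 256.0,
    alpha: float = 1.0,
    sd: float = 10.0,
    seed: int | np.random.Generator | None = None,
) -> NDArray[np.float64]:
    """1/f^alpha Gaussian background, exactly zero-mean with sample SD = ``sd``.

    Spectral shaping is done in the frequency domain: white Gaussian noise is
    multiplied by f^(-alpha/2) (alpha=0 gives white noise, alpha=1 the pink
    1/f spectrum typical of resting EEG), transformed back, then demeaned and
    rescaled so the realized SD matches ``sd`` exactly.
    """
    if not 0.0 <= alpha <= 2.0:
        raise ValueError("alpha must lie in [0, 2]")
    n = _check_duration(duration_s, fs)
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = freqs[nz] ** (-alpha / 2.0)
    shaping[0] = 0.0  # no DC
    x = np.fft.irfft(spec * shaping, n=n)
    x -= x.mean()
    s = x.std()
    if s > 0:
        x *= sd / s
    return x


def make_bandlimited_noise(
    band: BandSpec,
    duration_s: float,
    fs: float = 256.0,
    rms: float = 1.0,
    rng: np.random.Generator | int | None = None,
) -> NDArray[np.float64]:
    """Gaussian noise brick-wall filtered to ``band``, scaled to the given RMS."""
    if band.f_hi >= fs / 2:
        raise ValueError("band must lie below Nyquist")
    n = _check_duration(duration_s, fs)
    rng = np.random.default_rng(rng)
    spec = np.fft.rfft(rng.standard_normal(n))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec[(freqs < band.f_lo) | (freqs > band.f_hi)] = 0.0
    x = np.fft.irfft(spec, n=n)
    s = x.std()
    if s > 0:
        x *= rms / s
    return x


def _delay(x: NDArray[np.float64], lag_s: float, fs: float) -> NDArray[np.float64]:
    """Circular fractional delay via a frequency-domain phase ramp."""
    if lag_s == 0:
        return x.copy()
    n = x.size
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return np.fft.irfft(np.fft.rfft(x) * np.exp(-2j * np.pi * freqs * lag_s), n=n)


def make_coupled_pair(
    band: BandSpec = SMR_BAND,
    coupling: float = 0.5,
    lag_ms: float = 18.0,
    duration_s: float = 180.0,
    fs: float = 256.0,
    rms: float = 1.0,
    seed: int | np.random.Generator | None = None,
) -> tuple[NDArray[np.float64], NDArray[np.float64], float]:
    """Two band-limited signals sharing a lagged common source.

    Returns ``(x1, x2, true_msc)`` where ``true_msc = coupling**2`` is the
    closed-form magnitude-squared coherence inside the band.  Channel 2's
    shared component is delayed by ``lag_ms``; with ``lag_ms = 0`` the pair
    is a pure volume-conduction surrogate (real-valued coherency).
    """
    if not 0.0 <= coupling <= 1.0:
        raise ValueError("coupling must lie in [0, 1]")
    if lag_ms / 1000.0 >= duration_s:
        raise ValueError("lag must be shorter than the signal")
    rng = np.random.default_rng(seed)
    n = _check_duration(duration_s, fs)
    shared = make_bandlimited_noise(band, duration_s, fs, rms=1.0, rng=rng)
    n1 = make_bandlimited_noise(band, duration_s, fs, rms=1.0, rng=rng)
    n2 = make_bandlimited_noise(band, duration_s, fs, rms=1.0, rng=rng)
    a = np.sqrt(coupling)
    b = np.sqrt(1.0 - coupling)
    x1 = a * shared + b * n1
    x2 = a * _delay(shared, lag_ms / 1000.0, fs) + b * n2
    # rms of each mixture is ~1 by construction (independent unit-RMS parts)
    return rms * x1, rms * x2, coupling**2


def make_volume_conduction_pair(
    band: BandSpec = SMR_BAND,
    mixing: NDArray[np.float64] | None = None,
    noise_rms: float = 0.3,
    duration_s: float = 180.0,
    fs: float = 256.0,
    seed: int | np.random.Generator | None = None,
) -> tuple[NDArray[np.float64], NDArray[np.float64]]:
    """Zero-lag mixtures of k shared band-limited sources plus independent noise.

    ``mixing`` is a 2 x k real weight matrix (default one source, weights
    (1, 0.8)).  Because the mixing is instantaneous, the cross-spectrum is
    real: magnitude-squared coherence can be large while the imaginary part
    of coherency is zero in expectation -- the textbook volume-conduction
    confound.
    """
    if mixing is None:
        mixing = np.array([[1.0], [0.8]])
    mixing = np.atleast_2d(np.asarray(mixing, dtype=float))
    if mixing.shape[0] != 2 or mixing.shape[1] < 1:
        raise ValueError("mixing must be a 2 x k matrix with k >= 1")
    if not np.any(mixing):
        raise ValueError("mixing matrix must not be all zero")
    rng = np.random.default_rng(seed)
    k = mixing.shape[1]
    sources = np.stack(
        [make_bandlimited_noise(band, duration_s, fs, rms=1.0, rng=rng) for _ in range(k)]
    )
    chans = mixing @ sources
    for i in range(2):
        chans[i] += make_bandlimited_noise(band, duration_s, fs, rms=noise_rms, rng=rng)
    return chans[0], chans[1]


def _raised_cosine(n: int) -> NDArray[np.float64]:
    t = np.arange(n)
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * t / max(n - 1, 1)))


def inject_artifacts(
    recording: Recording,
    blink_rate: float = 4.0,
    muscle_rate: float = 1.0,
    blink_amp_uV: float = 300.0,
    muscle_amp_uV: float = 40.0,
    blink_ratio: tuple[float, float] = (0.4, 0.2),
    seed: int | np.random.Generator | None = None,
) -> Recording:
    """Add eye blinks and muscle bursts; record a ground-truth mask.

    Blinks are 400 ms raised-cosine transients, dominant on the EOG channel
    with attenuated copies on Cz and CPz (amplitude ratios ``blink_ratio``).
    Muscle events are ~300-500 ms bursts of 30-100 Hz noise on the EEG
    channels.  Event onsets are Poisson with the given per-minute rates.

    The ground-truth mask marks the FWHM core of each event (samples where
    the transient's envelope exceeds half its peak), i.e. the span where the
    artifact dominates the underlying EEG, not the near-zero cosine tails.
    """
    if blink_rate < 0 or muscle_rate < 0:
        raise ValueError("artifact rates must be non-negative")
    rng = np.random.default_rng(seed)
    n = recording.n_samples
    fs = recording.fs
    data = recording.data.copy()
    truth = {
        "blink": np.zeros(n, dtype=bool),
        "muscle": np.zeros(n, dtype=bool),
    }
    meta = dict(recording.meta)

    def _poisson_onsets(rate_per_min: float) -> NDArray[np.int_]:
        expected = rate_per_min * recording.duration_s / 60.0
        count = rng.poisson(expected)
        return np.sort(rng.integers(0, n, size=count))

    blink_len = int(round(0.4 * fs))
    template = _raised_cosine(blink_len)
    eog_idx = recording.labels.index("EOG") if "EOG" in recording.labels else None
    eeg_idx = [i for i, lab in enumerate(recording.labels) if lab != "EOG"]
    blink_onsets = _poisson_onsets(blink_rate)
    for onset in blink_onsets:
        stop = min(onset + blink_len, n)
        seg = template[: stop - onset]
        sign = 1.0 if rng.random() < 0.9 else -1.0  # blinks are mostly positive at the eye
        if eog_idx is not None:
            data[eog_idx, onset:stop] += sign * blink_amp_uV * seg
        for j, idx in enumerate(eeg_idx[:2]):
            data[idx, onset:stop] += sign * blink_amp_uV * blink_ratio[j] * seg
        truth["blink"][onset:stop] |= seg >= 0.5

    muscle_onsets = _poisson_onsets(muscle_rate)
    for onset in muscle_onsets:
        length = int(round(rng.uniform(0.3, 0.5) * fs))
        stop = min(onset + length, n)
        burst = make_bandlimited_noise(
            BandSpec("emg", 30.0, min(100.0, fs / 2 - 1)), length / fs, fs,
            rms=muscle_amp_uV, rng=rng,
        )[: stop - onset]
        envelope = _raised_cosine(stop - onset)
        for idx in eeg_idx[:2]:
            data[idx, onset:stop] += burst * envelope
        truth["muscle"][onset:stop] |= envelope >= 0.5

    meta["blink_onsets"] = blink_onsets.tolist()
    meta["muscle_onsets"] = muscle_onsets.tolist()
    return replace(recording, data=data, artifact_truth=truth, meta=meta)


# default component amplitudes (uV RMS), calibrated once so Cz band powers
# land near the scalp-EEG scale typical of this paradigm (SMR ~3 uV^2,
# theta ~10 uV^2, beta ~3.5 uV^2 including the 1/f background's share)
_DEFAULT_RMS = {"background": 6.0, "smr": 1.6, "theta": 3.1, "beta": 1.4}


def simulate_run(
    learner: LearnerParams,
    session_idx: int,
    run_idx: int,
    duration_s: float = 180.0,
    fs: float = 256.0,
    seed: int = 0,
    with_artifacts: bool = True,
) -> Recording:
    """One 3-min neurofeedback run for one simulated trainee.

    Composes 1/f background, the coupled SMR pair (coupling follows the
    learner's linear trend in session and run), independent theta and beta
    components with optional amplitude trends, an EOG channel, and injected
    artifacts.  Deterministic for a fixed ``seed``: the per-run RNG stream is
    derived from (seed, session_idx, run_idx).
    """
    if not 1 <= session_idx <= 10:
        raise ValueError("session_idx must lie in 1..10")
    if not 1 <= run_idx <= 7:
        raise ValueError("run_idx must lie in 1..7")
    rng = np.random.default_rng([int(seed), session_idx, run_idx])
    eps = float(rng.normal(0.0, learner.noise_sd)) if learner.noise_sd > 0 else 0.0
    c = learner.coupling(session_idx, run_idx, eps)

    def _trend(band_name: str) -> float:
        s_slope, r_slope = learner.power_trends.get(band_name, (0.0, 0.0))
        return max(0.0, 1.0 + s_slope * (session_idx - 1) + r_slope * (run_idx - 1))

    smr1, smr2, true_msc = make_coupled_pair(
        SMR_BAND, c, learner.lag_ms, duration_s, fs,
        rms=_DEFAULT_RMS["smr"] * _trend("smr"), seed=rng,
    )
    cz = make_background(duration_s, fs, alpha=1.0, sd=_DEFAULT_RMS["background"], seed=rng)
    cpz = make_background(duration_s, fs, alpha=1.0, sd=_DEFAULT_RMS["background"], seed=rng)
    theta_rms = _DEFAULT_RMS["theta"] * _trend("theta")
    beta_rms = _DEFAULT_RMS["beta"] * _trend("beta")
    cz = cz + smr1 + make_bandlimited_noise(THETA_BAND, duration_s, fs, theta_rms, rng) \
        + make_bandlimited_noise(BETA_BAND, duration_s, fs, beta_rms, rng)
    cpz = cpz + smr2 + make_bandlimited_noise(THETA_BAND, duration_s, fs, theta_rms, rng) \
        + make_bandlimited_noise(BETA_BAND, duration_s, fs, beta_rms, rng)
    eog = make_background(duration_s, fs, alpha=1.5, sd=15.0, seed=rng)

    rec = Recording(
        data=np.vstack([cz, cpz, eog]),
        fs=fs,
        labels=("Cz", "CPz", "EOG"),
        meta={
            "coupling": c,
            "true_msc": true_msc,
            "session": session_idx,
            "run": run_idx,
            "seed": int(seed),
        },
    )
    if with_artifacts and (learner.blink_rate > 0 or learner.muscle_rate > 0):
        rec = inject_artifacts(
            rec, blink_rate=learner.blink_rate, muscle_rate=learner.muscle_rate, seed=rng
        )
    else:
        rec.artifact_truth = {
            "blink": np.zeros(rec.n_samples, dtype=bool),
            "muscle": np.zeros(rec.n_samples, dtype=bool),
        }
    return rec


def simulate_outcomes(
    n_subjects: int,
    c0: float = 0.3,
    beta_session: float = 0.0,
    beta_run: float = 0.0,
    subject_sd: float = 0.05,
    slope_sd: tuple[float, float] = (0.005, 0.005),
    noise_sd: float = 0.05,
    n_sessions: int = 10,
    n_runs: int = 7,
    group: str = "up",
    seed: int | np.random.Generator | None = None,
):
    """Outcome-level cohort simulator (no signal synthesis).

    Draws, per subject, a random baseline offset and random session/run
    slopes around the population values, then emits the long-format table
    (group, subject, session, run, value) with i.i.d. measurement noise.
    This is the lightweight counterpart of the full closed-loop simulation,
    used for statistical calibration studies where only the outcome
    trajectories matter.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    rows = []
    sessions = np.arange(1, n_sessions + 1)
    runs = np.arange(1, n_runs + 1)
    for subj in range(1, n_subjects + 1):
        b0 = c0 + rng.normal(0.0, subject_sd)
        bs = beta_session + rng.normal(0.0, slope_sd[0])
        br = beta_run + rng.normal(0.0, slope_sd[1])
        for s in sessions:
            for r in runs:
                value = b0 + bs * (s - 1) + br * (r - 1) + rng.normal(0.0, noise_sd)
                rows.append((group, subj, int(s), int(r), value))
    return pd.DataFrame(rows, columns=["group", "subject", "session", "run", "value"])
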