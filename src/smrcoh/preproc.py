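"""Epoching and artifact rejection.

Continuous recordings are cut into non-overlapping 1-s epochs and screened
with standard amplitude-based rejection rules: a maximum sample-to-sample
voltage step (50 uV), an absolute amplitude bound (+/-120 uV), a minimum
peak-to-peak activity inside any 100 ms window (0.5 uV, the flatline
criterion), plus an EOG amplitude threshold standing in for manual ocular
rejection.  Rejection is epoch-level and all-channel: an artifact on either
EEG channel removes the epoch from the channel-pair analysis, because
coherence needs paired epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.typing import NDArray
from scipy.ndimage import maximum_filter1d, minimum_filter1d

from .eegsim import Recording

__all__ = ["EpochSet", "RejectionCriteria", "epoch", "reject_epochs", "rejection_rate"]


@dataclass(frozen=True)
class RejectionCriteria:
    """Amplitude-based epoch rejection thresholds (all in microvolts)."""

    max_step_uV: float = 50.0
    max_abs_uV: float = 120.0
    min_activity_uV: float = 0.5
    activity_window_ms: float = 100.0
    eog_abs_uV: float = 100.0

    def __post_init__(self) -> None:
        for name in ("max_step_uV", "max_abs_uV", "min_activity_uV",
                     "activity_window_ms", "eog_abs_uV"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class EpochSet:
    """Epoched data plus the per-epoch keep mask and rejection reasons."""

    epochs: NDArray[np.float64]  # n_epochs x channels x samples_per_epoch
    fs: float
    labels: tuple[str, ...]
    keep_mask: NDArray[np.bool_]
    reject_reasons: list[set[str]]
    artifact_truth: NDArray[np.bool_] | None = None  # per-epoch ground truth
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = self.epochs.shape[0]
        if self.keep_mask.shape != (n,):
            raise ValueError("keep_mask length must equal n_epochs")
        if len(self.reject_reasons) != n:
            raise ValueError("one reason set per epoch required")
        for kept, reasons in zip(self.keep_mask, self.reject_reasons):
            if not kept and not reasons:
                raise ValueError("rejected epoch lacks a reason")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_kept(self) -> int:
        return int(self.keep_mask.sum())

    def kept(self, label: str) -> NDArray[np.float64]:
        """Kept epochs for one channel: n_kept x samples."""
        idx = self.labels.index(label)
        return self.epochs[self.keep_mask, idx, :]

    def mask_frame(self):
        """Keep mask and reasons as a table (epoch_index, kept, reasons)."""
        import pandas as pd

        return pd.DataFrame({
            "epoch_index": np.arange(self.n_epochs),
            "kept": self.keep_mask,
            "reasons": ["|".join(sorted(r)) for r in self.reject_reasons],
        })


def epoch(recording: Recording, epoch_s: float = 1.0) -> EpochSet:
    """Cut a recording into consecutive non-overlapping epochs.

    The trailing partial epoch is discarded; all epochs start out kept.
    """
    if epoch_s <= 0:
        raise ValueError("epoch_s must be positive")
    samples_per = int(round(epoch_s * recording.fs))
    n_epochs = recording.n_samples // samples_per
    if n_epochs < 1:
        raise ValueError(
            f"recording of {recording.duration_s:.2f} s is shorter than one "
            f"{epoch_s:.2f} s epoch"
        )
    usable = n_epochs * samples_per
    cut = recording.data[:, :usable]
    epochs = cut.reshape(cut.shape[0], n_epochs, samples_per).transpose(1, 0, 2)
    truth = None
    if recording.artifact_truth is not None:
        union = recording.any_artifact()[:usable].reshape(n_epochs, samples_per)
        truth = union.any(axis=1)
    return EpochSet(
        epochs=epochs.copy(),
        fs=recording.fs,
        labels=recording.labels,
        keep_mask=np.ones(n_epochs, dtype=bool),
        reject_reasons=[set() for _ in range(n_epochs)],
        artifact_truth=truth,
        meta=dict(recording.meta),
    )


def _sliding_ptp_min(x: NDArray[np.float64], window: int) -> NDArray[np.float64]:
    """Minimum peak-to-peak range over all full sliding windows, per epoch/channel.

    ``x`` is n_epochs x channels x samples; windows slide with stride 1 and
    stay inside the epoch.
    """
    hi = maximum_filter1d(x, size=window, axis=-1, mode="nearest")
    lo = minimum_filter1d(x, size=window, axis=-1, mode="nearest")
    ptp = hi - lo
    # centered filters: full windows correspond to positions where the window
    # fits entirely; trim half-window margins at both ends
    left = window // 2
    right = window - 1 - left
    valid = ptp[..., left: ptp.shape[-1] - right] if right > 0 else ptp[..., left:]
    return valid.min(axis=-1)


def reject_epochs(epoch_set: EpochSet, criteria: RejectionCriteria | None = None) -> EpochSet:
    """Apply the rejection criteria; returns a new EpochSet with updated mask.

    Reasons per epoch: 'step' (voltage step between consecutive samples on an
    EEG channel exceeds max_step_uV), 'amplitude' (absolute value exceeds
    max_abs_uV), 'flatline' (some 100 ms window has peak-to-peak range below
    min_activity_uV), 'eog' (EOG amplitude exceeds eog_abs_uV).
    """
    if criteria is None:
        criteria = RejectionCriteria()
    if epoch_set.n_epochs == 0:
        raise ValueError("no epochs to screen")
    eeg_idx = [i for i, lab in enumerate(epoch_set.labels) if lab.upper() != "EOG"]
    eog_idx = [i for i, lab in enumerate(epoch_set.labels) if lab.upper() == "EOG"]
    eeg = epoch_set.epochs[:, eeg_idx, :]

    step = np.abs(np.diff(eeg, axis=-1)).max(axis=(1, 2)) > criteria.max_step_uV
    amplitude = np.abs(eeg).max(axis=(1, 2)) > criteria.max_abs_uV
    window = max(2, int(round(criteria.activity_window_ms / 1000.0 * epoch_set.fs)))
    flat = _sliding_ptp_min(eeg, window).min(axis=-1) < criteria.min_activity_uV
    if eog_idx:
        eog = epoch_set.epochs[:, eog_idx, :]
        ocular = np.abs(eog).max(axis=(1, 2)) > criteria.eog_abs_uV
    else:
        ocular = np.zeros(epoch_set.n_epochs, dtype=bool)

    reasons: list[set[str]] = []
    for i in range(epoch_set.n_epochs):
        r = set()
        if step[i]:
            r.add("step")
        if amplitude[i]:
            r.add("amplitude")
        if flat[i]:
            r.add("flatline")
        if ocular[i]:
            r.add("eog")
        reasons.append(r)
    keep = ~(step | amplitude | flat | ocular)
    return EpochSet(
        epochs=epoch_set.epochs,
        fs=epoch_set.fs,
        labels=epoch_set.labels,
        keep_mask=keep,
        reject_reasons=reasons,
        artifact_truth=epoch_set.artifact_truth,
        meta=epoch_set.meta,
    )


def rejection_rate(epoch_sets) -> float:
    """Fraction of rejected epochs pooled over a collection of EpochSets."""
    if isinstance(epoch_sets, EpochSet):
        epoch_sets = [epoch_sets]
    epoch_sets = list(epoch_sets)
    total = sum(es.n_epochs for es in epoch_sets)
    if total == 0:
        raise ValueError("no epochs supplied")
    rejected = sum(es.n_epochs - es.n_kept for es in epoch_sets)
    return rejected / total
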