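"""Epoch-averaged cross-spectra, coherence, and band power.

The coherency between two channels is

    C(f) = Sxy(f) / sqrt(Sxx(f) * Syy(f))

with Sxy the cross-spectrum averaged over 1-s epochs (average-then-normalize).
Magnitude-squared coherence |C|^2 measures linear dependence in [0, 1] but is
inflated by zero-lag volume conduction; the imaginary part Im(C) is blind to
instantaneous mixing and therefore isolates genuinely time-lagged coupling.
Band power is computed two ways: summing the epoch-averaged auto-spectrum
over band bins, and by complex demodulation (shift the band centre to
baseband, low-pass at half the bandwidth, square the envelope) -- the two
agree on stationary narrowband signals and cross-check each other.

Windowing uses a split-cosine-bell (Tukey) taper whose tapered fraction
defaults to 10% of the epoch, with the full Hann window as the limiting
case.  Spectra are normalized so that a pure amplitude-A sinusoid carries
power A^2/2 in its bin and white noise satisfies Parseval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import NDArray
from scipy import signal as sps

from .eegsim import BandSpec
from .preproc import EpochSet

__all__ = [
    "SpectralEstimate",
    "CoherenceResult",
    "taper",
    "epoch_spectra",
    "coherence",
    "band_power_fft",
    "complex_demod_power",
    "band_bins",
]


class InsufficientDataError(ValueError):
    """Fewer epochs than the estimator can use (single-epoch MSC is always 1)."""


class DegenerateSignalError(ValueError):
    """Zero auto-spectral power at a bin needed for normalization."""


@dataclass
class SpectralEstimate:
    """Epoch-averaged auto- and cross-spectra for one channel pair."""

    freqs: NDArray[np.float64]
    Sxx: NDArray[np.float64]
    Syy: NDArray[np.float64]
    Sxy: NDArray[np.complex128]
    n_epochs: int

    def __post_init__(self) -> None:
        if self.n_epochs < 2:
            raise InsufficientDataError("need at least 2 epochs")
        if np.any(self.Sxx < -1e-12) or np.any(self.Syy < -1e-12):
            raise ValueError("auto-spectra must be non-negative")


@dataclass
class CoherenceResult:
    freqs: NDArray[np.float64]
    msc: NDArray[np.float64]
    imcoh: NDArray[np.float64]
    band: BandSpec
    band_msc: float
    band_imcoh: float


def taper(n_samples: int, taper_fraction: float = 0.10) -> NDArray[np.float64]:
    """Split-cosine-bell window: raised-cosine ramps over ``taper_fraction``
    of the epoch (half at each end), flat 1.0 elsewhere.

    ``taper_fraction=0`` is rectangular, ``taper_fraction=1`` the full Hann
    window.  This is scipy's Tukey window with ``alpha = taper_fraction``.
    """
    if n_samples < 4:
        raise ValueError("n_samples must be at least 4")
    if not 0.0 <= taper_fraction <= 1.0:
        raise ValueError("taper_fraction must lie in [0, 1]")
    return sps.windows.tukey(n_samples, alpha=taper_fraction, sym=False)


def _epoch_ffts(epochs: NDArray[np.float64], window: NDArray[np.float64],
                fs: float) -> tuple[NDArray[np.float64], NDArray[np.complex128], float]:
    """Demean, window and FFT each epoch; return (freqs, spectra, norm).

    ``norm`` scales |X|^2 products so that the one-sided spectrum of an
    amplitude-A sinusoid integrates to A^2/2 and white noise satisfies
    Parseval for the unwindowed variance (window power normalization).
    """
    n = epochs.shape[-1]
    demeaned = epochs - epochs.mean(axis=-1, keepdims=True)
    spectra = np.fft.rfft(demeaned * window, axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    norm = 2.0 / (n * np.sum(window**2))
    return freqs, spectra, norm


def epoch_spectra(
    x_epochs: NDArray[np.float64],
    y_epochs: NDArray[np.float64],
    fs: float = 256.0,
    taper_fraction: float = 0.10,
) -> SpectralEstimate:
    """Average per-epoch auto- and cross-spectra of two epoch-aligned channels.

    ``x_epochs`` and ``y_epochs`` are n_epochs x samples arrays of the kept
    epochs.  Fewer than two epochs is refused: the epoch-averaged MSC of a
    single epoch is identically 1 regardless of the data.
    """
    x_epochs = np.atleast_2d(np.asarray(x_epochs, dtype=float))
    y_epochs = np.atleast_2d(np.asarray(y_epochs, dtype=float))
    if x_epochs.shape != y_epochs.shape:
        raise ValueError("channel epoch arrays must be aligned (equal shape)")
    n_ep = x_epochs.shape[0]
    if n_ep < 2:
        raise InsufficientDataError(
            f"{n_ep} epoch(s): epoch-averaged coherence needs at least 2"
        )
    window = taper(x_epochs.shape[-1], taper_fraction)
    freqs, X, norm = _epoch_ffts(x_epochs, window, fs)
    _, Y, _ = _epoch_ffts(y_epochs, window, fs)
    # one-sided doubling except DC (and Nyquist for even n)
    scale = np.full(freqs.shape, norm)
    scale[0] = norm / 2.0
    if x_epochs.shape[-1] % 2 == 0:
        scale[-1] = norm / 2.0
    Sxx = (np.abs(X) ** 2).mean(axis=0) * scale
    Syy = (np.abs(Y) ** 2).mean(axis=0) * scale
    Sxy = (X * np.conj(Y)).mean(axis=0) * scale
    return SpectralEstimate(freqs=freqs, Sxx=Sxx, Syy=Syy, Sxy=Sxy, n_epochs=n_ep)


def spectra_from_epochset(epoch_set: EpochSet, ch_x: str = "Cz", ch_y: str = "CPz",
                          taper_fraction: float = 0.10) -> SpectralEstimate:
    """Convenience: epoch_spectra on the kept epochs of two named channels."""
    return epoch_spectra(
        epoch_set.kept(ch_x), epoch_set.kept(ch_y), epoch_set.fs, taper_fraction
    )


def band_bins(freqs: NDArray[np.float64], band: BandSpec) -> NDArray[np.bool_]:
    """Bins whose centre frequency lies in [f_lo, f_hi] inclusive."""
    sel = (freqs >= band.f_lo - 1e-9) & (freqs <= band.f_hi + 1e-9)
    if not sel.any():
        raise ValueError(f"band {band.name} [{band.f_lo}, {band.f_hi}] Hz has no bins")
    return sel


def coherence(estimate: SpectralEstimate, band: BandSpec) -> CoherenceResult:
    """Coherency, MSC and signed imaginary coherence, with band averages.

    Band values are arithmetic means over the included bins (at 1 Hz
    resolution the 12-15 Hz band averages the 12, 13, 14 and 15 Hz bins).
    The imaginary part is kept signed; its sign flips under channel swap.
    """
    sel = band_bins(estimate.freqs, band)
    denom_sq = estimate.Sxx * estimate.Syy
    if np.any(denom_sq[sel] <= 0):
        raise DegenerateSignalError("zero auto-spectral power inside the band")
    valid = denom_sq > 0
    C = np.zeros(estimate.freqs.shape, dtype=complex)
    C[valid] = estimate.Sxy[valid] / np.sqrt(denom_sq[valid])
    msc = np.clip(np.abs(C) ** 2, 0.0, 1.0)
    imcoh = np.clip(np.imag(C), -1.0, 1.0)
    return CoherenceResult(
        freqs=estimate.freqs,
        msc=msc,
        imcoh=imcoh,
        band=band,
        band_msc=float(msc[sel].mean()),
        band_imcoh=float(imcoh[sel].mean()),
    )


def coherency_normalize_then_average(
    x_epochs: NDArray[np.float64],
    y_epochs: NDArray[np.float64],
    fs: float = 256.0,
    taper_fraction: float = 0.10,
) -> NDArray[np.complex128]:
    """Sensitivity-analysis variant: per-epoch normalized coherency, averaged.

    The standard estimator normalizes the epoch-averaged cross-spectrum
    (see :func:`coherence`); this variant normalizes within each epoch first
    and then averages the unit-modulus phase factors, which weights epochs
    equally regardless of power.  Provided for sensitivity checks only.
    """
    x_epochs = np.atleast_2d(np.asarray(x_epochs, dtype=float))
    y_epochs = np.atleast_2d(np.asarray(y_epochs, dtype=float))
    if x_epochs.shape[0] < 2:
        raise InsufficientDataError("need at least 2 epochs")
    window = taper(x_epochs.shape[-1], taper_fraction)
    _, X, _ = _epoch_ffts(x_epochs, window, fs)
    _, Y, _ = _epoch_ffts(y_epochs, window, fs)
    num = X * np.conj(Y)
    denom = np.abs(X) * np.abs(Y)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_epoch = np.where(denom > 0, num / denom, 0.0)
    return per_epoch.mean(axis=0)


def band_power_fft(estimate: SpectralEstimate, band: BandSpec,
                   channel: str = "x") -> float:
    """Band power (uV^2) as the sum of the epoch-averaged auto-spectrum."""
    sel = band_bins(estimate.freqs, band)
    S = estimate.Sxx if channel == "x" else estimate.Syy
    return float(S[sel].sum())


def complex_demod_power(
    x: NDArray[np.float64],
    band: BandSpec,
    fs: float = 256.0,
    epoch_s: float = 1.0,
    order: int = 4,
) -> NDArray[np.float64]:
    """Per-epoch band power (uV^2) via complex demodulation.

    The signal is shifted by the band centre frequency, low-pass filtered at
    half the bandwidth (zero-phase Butterworth), and the squared envelope is
    scaled so a pure amplitude-A sinusoid at the band centre yields A^2/2.
    Epoch means of the instantaneous power are returned, one value per full
    ``epoch_s`` segment.
    """
    x = np.asarray(x, dtype=float)
    if band.f_hi - band.f_lo >= fs / 2 or band.f_hi >= fs / 2:
        raise ValueError("band must fit below Nyquist")
    if x.size < 2 * fs * epoch_s:
        raise ValueError("signal must span at least two epochs")
    t = np.arange(x.size) / fs
    baseband = x * np.exp(-2j * np.pi * band.center * t)
    cutoff = band.width / 2.0
    sos = sps.butter(order, cutoff, btype="low", fs=fs, output="sos")
    envelope = sps.sosfiltfilt(sos, baseband.real) + 1j * sps.sosfiltfilt(sos, baseband.imag)
    # demodulated sinusoid of amplitude A has |envelope| = A/2; power A^2/2
    inst_power = 2.0 * np.abs(envelope) ** 2
    samples_per = int(round(epoch_s * fs))
    n_epochs = x.size // samples_per
    return inst_power[: n_epochs * samples_per].reshape(n_epochs, samples_per).mean(axis=1)


def run_summary(epoch_set: EpochSet, bands: dict[str, BandSpec] | None = None,
                taper_fraction: float = 0.10) -> dict[str, float]:
    """Offline per-run summary: band coherence, band powers, rejection rate.

    Returns the flat mapping serialized to the per-run CSV: n_epochs_kept,
    band_msc, band_imcoh, and per-band FFT powers on both channels, with
    complex-demodulation powers averaged over kept epochs.
    """
    from .eegsim import BETA_BAND, SMR_BAND, THETA_BAND

    if bands is None:
        bands = {"smr": SMR_BAND, "theta": THETA_BAND, "beta": BETA_BAND}
    est = spectra_from_epochset(epoch_set, taper_fraction=taper_fraction)
    coh = coherence(est, bands["smr"])
    out = {
        "n_epochs_kept": float(epoch_set.n_kept),
        "rejection_rate": float(1.0 - epoch_set.n_kept / epoch_set.n_epochs),
        "band_msc": coh.band_msc,
        "band_imcoh": coh.band_imcoh,
    }
    keep = epoch_set.keep_mask
    for name, band in bands.items():
        for ch in ("Cz", "CPz"):
            full = epoch_set.epochs[:, epoch_set.labels.index(ch), :].reshape(-1)
            per_epoch = complex_demod_power(full, band, epoch_set.fs)
            out[f"power_{name}_{ch.lower()}"] = float(per_epoch[keep].mean())
    return out
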