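"""Epoching, FFT band-pass filtering, relative band power and the tau rule.

Filtering is a per-epoch brick-wall FFT filter: the epoch is transformed
with a discrete Fourier transform, bins outside the band zeroed (DC always
zeroed) and the signal inverse-transformed.  No taper or padding is applied;
the ringing this introduces at band edges is accepted as part of the
procedure.  Band edges are half-open ``[f_low, f_high)`` so adjacent
canonical bands never share a bin (8 Hz belongs to alpha, not theta).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "BandDefinition",
    "EpochedRecording",
    "DEFAULT_BANDS",
    "extract_epochs",
    "bandpass",
    "bandpass_recording",
    "relative_power",
    "tau_from_band",
    "per_subject_aggregate",
]


@dataclass(frozen=True)
class BandDefinition:
    """A frequency band ``[f_low, f_high)`` in Hz."""

    name: str
    f_low: float
    f_high: float

    def __post_init__(self) -> None:
        if not (0 < self.f_low < self.f_high):
            raise ValueError(
                f"band {self.name!r}: need 0 < f_low < f_high, got [{self.f_low}, {self.f_high})"
            )

    def validate_for(self, fs: float) -> None:
        if self.f_high >= fs / 2:
            raise ValueError(
                f"band {self.name!r} upper edge {self.f_high} Hz reaches the "
                f"Nyquist frequency {fs / 2} Hz"
            )


#: Canonical analysis bands: theta, alpha, beta and the broad reference band.
DEFAULT_BANDS = (
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
    BandDefinition("broadband", 0.5, 45.0),
)

BROADBAND = DEFAULT_BANDS[3]


@dataclass(frozen=True)
class EpochedRecording:
    """A ``channels x epochs x samples`` recording with sampling rate and labels."""

    data: np.ndarray
    fs: float
    channel_labels: tuple[str, ...]
    band: str = "raw"

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 3:
            raise ValueError(f"data must be channels x epochs x samples, got shape {data.shape}")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "channel_labels", tuple(self.channel_labels))
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if len(self.channel_labels) != data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {data.shape[0]} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_epochs(self) -> int:
        return self.data.shape[1]

    @property
    def epoch_len(self) -> int:
        return self.data.shape[2]

    @property
    def epoch_duration(self) -> float:
        """Duration of one epoch in seconds (e.g. 4096 samples at 1250 Hz
        = 3.2768 s)."""
        return self.epoch_len / self.fs


def default_labels(n_channels: int) -> tuple[str, ...]:
    return tuple(f"ROI_{i + 1:03d}" for i in range(n_channels))


def extract_epochs(
    raw,
    fs: float,
    n_epochs: int = 20,
    epoch_len: int = 4096,
    channel_labels=None,
) -> EpochedRecording:
    """Cut the first ``n_epochs`` consecutive non-overlapping epochs of
    ``epoch_len`` samples from a ``channels x samples`` matrix, starting at
    sample 0."""
    raw = np.atleast_2d(np.asarray(raw, dtype=float))
    needed = n_epochs * epoch_len
    if raw.shape[1] < needed:
        raise ValueError(
            f"recording has {raw.shape[1]} samples but {n_epochs} epochs of "
            f"{epoch_len} samples need {needed} (short by {needed - raw.shape[1]})"
        )
    data = raw[:, :needed].reshape(raw.shape[0], n_epochs, epoch_len)
    labels = channel_labels if channel_labels is not None else default_labels(raw.shape[0])
    return EpochedRecording(data=data.copy(), fs=fs, channel_labels=labels)


def _band_bins(n_samples: int, fs: float, band: BandDefinition) -> np.ndarray:
    """Boolean mask over rfft bins with ``f_low <= f < f_high`` (DC excluded)."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    return (freqs >= band.f_low) & (freqs < band.f_high) & (freqs > 0)


def bandpass(epoch, fs: float, band: BandDefinition):
    """Brick-wall FFT band-pass along the last axis.

    Zeroes every Fourier bin with frequency outside ``[f_low, f_high)``
    (DC always zeroed) and inverse-transforms; idempotent by construction.
    """
    band.validate_for(fs)
    x = np.asarray(epoch, dtype=float)
    spec = np.fft.rfft(x, axis=-1)
    keep = _band_bins(x.shape[-1], fs, band)
    spec[..., ~keep] = 0.0
    return np.fft.irfft(spec, n=x.shape[-1], axis=-1)


def bandpass_recording(rec: EpochedRecording, band: BandDefinition) -> EpochedRecording:
    """Band-pass every epoch of a recording; the result carries the band label."""
    return replace(rec, data=bandpass(rec.data, rec.fs, band), band=band.name)


def relative_power(epoch, fs: float, band: BandDefinition, total_band: BandDefinition = BROADBAND):
    """Fraction of spectral power in ``band`` relative to ``total_band``.

    Power is the sum of squared FFT magnitudes over the bins of each
    half-open band; computed along the last axis.  The reference band
    defaults to the 0.5–45 Hz broad band.
    """
    if band.f_low < total_band.f_low or band.f_high > total_band.f_high:
        raise ValueError(
            f"band {band.name!r} [{band.f_low}, {band.f_high}) not contained in "
            f"reference band {total_band.name!r} [{total_band.f_low}, {total_band.f_high})"
        )
    band.validate_for(fs)
    total_band.validate_for(fs)
    x = np.asarray(epoch, dtype=float)
    power = np.abs(np.fft.rfft(x, axis=-1)) ** 2
    num = power[..., _band_bins(x.shape[-1], fs, band)].sum(axis=-1)
    den = power[..., _band_bins(x.shape[-1], fs, total_band)].sum(axis=-1)
    if np.any(den == 0):
        raise ValueError("zero power in the reference band")
    return num / den


def tau_from_band(fs: float, band: BandDefinition) -> int:
    """Band-adapted time delay: ``round(fs / (3 * f_high))`` with a floor of 1.

    Chosen so that tau is small enough to resolve the fastest oscillations
    left after filtering; rounding is half-up to the nearest integer.
    """
    band.validate_for(fs)
    return max(1, int(np.floor(fs / (3.0 * band.f_high) + 0.5)))


def per_subject_aggregate(values) -> np.ndarray:
    """Mean over epochs of an ``epochs x ...`` per-epoch feature array.

    Features are estimated per epoch and averaged per subject before any
    group statistics.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim < 1 or values.shape[0] == 0:
        raise ValueError("need at least one epoch to aggregate")
    return values.mean(axis=0)
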