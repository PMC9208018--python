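"""Synthetic two-group multichannel cohorts with known spectral, coupling
and leakage structure.

Each channel is a weighted sum of unit-variance components:

* a dominant AR(2) resonator tuned to ``osc_freq`` (alpha-like by default),
* an AR(2) resonator tuned to 6 Hz mixed in with weight ``theta_fraction``
  (pathological theta is emulated with a broad resonance, ``theta_bandwidth``),
* 1/f (pink) background noise of amplitude ``noise_sd``.

Genuine interregional coupling is a lagged common drive: one shared
band-limited signal is blended into every channel with weight ``coupling``,
channel ``i`` receiving it delayed by ``i * coupling_lag`` samples, so every
channel pair is coupled at a non-zero lag (a multiple of ``coupling_lag``)
and survives the identical/mirrored-pattern exclusion.  Volume conduction /
source leakage is emulated afterwards as instantaneous mixing with the
nearest-neighbour channels, ``x_i <- (1 - leakage) * x_i +
leakage * mean(x_{i-1}, x_{i+1})`` — exactly the zero-lag structure the
JPE_inv correction is meant to absorb.

The two default group templates mimic an early-Alzheimer contrast:
``scd_like()`` (control-like: 10 Hz peak, little theta, stronger coupling)
and ``mci_like()`` (oscillatory slowing: more and broader theta, weaker
coupling).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import lfilter

from .spectral import EpochedRecording, default_labels

__all__ = [
    "SubjectSpec",
    "CohortSpec",
    "Cohort",
    "scd_like",
    "mci_like",
    "default_cohort_spec",
    "generate_subject",
    "generate_cohort",
]


@dataclass(frozen=True)
class SubjectSpec:
    """Parameters of one simulated subject recording."""

    n_rois: int = 80
    fs: float = 1250.0
    n_epochs: int = 20
    epoch_len: int = 4096
    osc_freq: float = 10.0        # Hz, peak of the dominant oscillation
    osc_bandwidth: float = 1.5    # Hz, -pi*bw/fs pole-radius mapping
    theta_fraction: float = 0.15  # weight of the theta component
    theta_freq: float = 6.0       # Hz, center of the theta component
    theta_bandwidth: float = 3.0  # Hz, broad (irregular) theta resonance
    coupling: float = 0.4         # kappa, lagged common-drive blend weight
    coupling_lag: int = 10        # samples (8 ms at 1250 Hz)
    leakage: float = 0.0          # lambda, zero-lag neighbour mixing
    noise_sd: float = 1.0         # amplitude of the 1/f background
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rois < 1:
            raise ValueError("n_rois must be >= 1")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.n_epochs < 1 or self.epoch_len < 2:
            raise ValueError("need at least 1 epoch of >= 2 samples")
        if not 0 <= self.theta_fraction <= 1:
            raise ValueError("theta_fraction must lie in [0, 1]")
        if not 0 <= self.coupling <= 1:
            raise ValueError("coupling must lie in [0, 1]")
        if not 0 <= self.leakage < 1:
            raise ValueError("leakage must lie in [0, 1)")
        if self.coupling_lag < 1:
            raise ValueError("coupling_lag must be >= 1 (zero-lag drive would be "
                             "removed by the mirror/identity exclusion)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for f in (self.osc_freq, self.theta_freq):
            if f >= self.fs / 2:
                raise ValueError("oscillator frequency must be below Nyquist")


@dataclass(frozen=True)
class CohortSpec:
    """Two groups of subjects drawn from jittered templates."""

    group_a: SubjectSpec = field(default_factory=lambda: scd_like())
    group_b: SubjectSpec = field(default_factory=lambda: mci_like())
    n_subjects_a: int = 18
    n_subjects_b: int = 18
    label_a: str = "SCD"
    label_b: str = "MCI"
    seed: int = 0
    jitter: float = 0.10  # relative jitter on coupling and theta_fraction

    def __post_init__(self) -> None:
        if self.n_subjects_a < 2 or self.n_subjects_b < 2:
            raise ValueError("each group needs at least 2 subjects")


@dataclass(frozen=True)
class Cohort:
    """Generated recordings with subject IDs, group labels and specs."""

    recordings: tuple[EpochedRecording, ...]
    labels: tuple[str, ...]
    subject_ids: tuple[str, ...]
    specs: tuple[SubjectSpec, ...]
    spec: CohortSpec


def scd_like(**overrides) -> SubjectSpec:
    """Control-like template: 10 Hz dominant peak, little theta, stronger
    lagged coupling."""
    base = dict(osc_freq=10.0, theta_fraction=0.15, theta_freq=7.0,
                theta_bandwidth=2.0, coupling=0.45, noise_sd=1.0)
    base.update(overrides)
    return SubjectSpec(**base)


def mci_like(**overrides) -> SubjectSpec:
    """Early-AD-like template: oscillatory slowing (peak shifted toward
    theta, more and broader theta content) and weaker lagged coupling."""
    base = dict(osc_freq=9.0, theta_fraction=0.35, theta_freq=7.0,
                theta_bandwidth=2.0, coupling=0.25, noise_sd=1.0)
    base.update(overrides)
    return SubjectSpec(**base)


def default_cohort_spec(seed: int = 0, **overrides) -> CohortSpec:
    return CohortSpec(seed=seed, **overrides)


def _ar2(rng: np.random.Generator, n: int, f0: float, bw: float, fs: float) -> np.ndarray:
    """Unit-variance AR(2) resonator: poles at radius exp(-pi*bw/fs), angle
    2*pi*f0/fs, driven by white noise."""
    rho = np.exp(-np.pi * bw / fs)
    theta = 2 * np.pi * f0 / fs
    a1, a2 = 2 * rho * np.cos(theta), -rho**2
    x = lfilter([1.0], [1.0, -a1, -a2], rng.standard_normal(n))
    return x / x.std()


def _pink(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-variance 1/f noise via spectral shaping of white noise."""
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n)
    scale = np.zeros_like(f)
    scale[1:] = 1.0 / np.sqrt(f[1:])
    x = np.fft.irfft(spec * scale, n=n)
    return x / x.std()


_BURN_IN = 2000  # samples discarded to let the AR filters reach steady state


def generate_subject(spec: SubjectSpec) -> EpochedRecording:
    """Generate one subject's ``n_rois x n_epochs x epoch_len`` recording.

    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    total = spec.n_epochs * spec.epoch_len
    max_shift = (spec.n_rois - 1) * spec.coupling_lag

    # shared lagged drive, same spectral recipe as a private channel
    drive_len = total + max_shift + _BURN_IN
    drive = (
        (1 - spec.theta_fraction) * _ar2(rng, drive_len, spec.osc_freq, spec.osc_bandwidth, spec.fs)
        + spec.theta_fraction * _ar2(rng, drive_len, spec.theta_freq, spec.theta_bandwidth, spec.fs)
    )[_BURN_IN:]
    drive = drive / drive.std()

    data = np.empty((spec.n_rois, total))
    for i in range(spec.n_rois):
        private = (
            (1 - spec.theta_fraction)
            * _ar2(rng, total + _BURN_IN, spec.osc_freq, spec.osc_bandwidth, spec.fs)[_BURN_IN:]
            + spec.theta_fraction
            * _ar2(rng, total + _BURN_IN, spec.theta_freq, spec.theta_bandwidth, spec.fs)[_BURN_IN:]
            + spec.noise_sd * _pink(rng, total)
        )
        # channel i receives the drive delayed by i * coupling_lag samples,
        # so pair (i, j) shares it at lag |i - j| * coupling_lag
        shift = max_shift - i * spec.coupling_lag
        lagged = drive[shift : shift + total]
        data[i] = (1 - spec.coupling) * private + spec.coupling * lagged

    if spec.leakage > 0 and spec.n_rois > 1:
        neighbours = np.empty_like(data)
        neighbours[0] = data[1]
        neighbours[-1] = data[-2]
        if spec.n_rois > 2:
            neighbours[1:-1] = 0.5 * (data[:-2] + data[2:])
        data = (1 - spec.leakage) * data + spec.leakage * neighbours

    epochs = data.reshape(spec.n_rois, spec.n_epochs, spec.epoch_len)
    return EpochedRecording(
        data=epochs, fs=spec.fs, channel_labels=default_labels(spec.n_rois)
    )


def _jittered(template: SubjectSpec, rng: np.random.Generator, jitter: float, seed: int) -> SubjectSpec:
    """Per-subject template with +-jitter relative perturbation of coupling
    and theta_fraction (clipped to their valid ranges)."""
    factor_k = 1.0 + jitter * rng.uniform(-1, 1)
    factor_t = 1.0 + jitter * rng.uniform(-1, 1)
    return replace(
        template,
        coupling=float(np.clip(template.coupling * factor_k, 0.0, 1.0)),
        theta_fraction=float(np.clip(template.theta_fraction * factor_t, 0.0, 1.0)),
        seed=seed,
    )


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate the full two-group cohort; per-subject seeds and parameter
    jitter are derived deterministically from the master seed."""
    rng = np.random.default_rng(spec.seed)
    n_total = spec.n_subjects_a + spec.n_subjects_b
    seeds = rng.integers(0, 2**31 - 1, size=n_total)

    recordings, labels, ids, specs = [], [], [], []
    for k in range(n_total):
        in_a = k < spec.n_subjects_a
        template = spec.group_a if in_a else spec.group_b
        label = spec.label_a if in_a else spec.label_b
        s = _jittered(template, rng, spec.jitter, int(seeds[k]))
        recordings.append(generate_subject(s))
        labels.append(label)
        ids.append(f"sub-{k + 1:03d}")
        specs.append(s)
    return Cohort(
        recordings=tuple(recordings),
        labels=tuple(labels),
        subject_ids=tuple(ids),
        specs=tuple(specs),
        spec=spec,
    )
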