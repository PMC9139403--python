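"""Synthetic resting-EEG cohorts.

Generates cohorts with the statistical structure the downstream pipeline
assumes: per-subject band-limited oscillations (θ 4–8, α 8–13, β 13–30 Hz)
with smoothly varying scalp topography on top of a 1/f background, a
posterior α gradient, and a class effect that multiplies band power over a
named scalp region for the depressed group.  Optional artifacts (frontal
biphasic blinks, mains-frequency line noise) provide inputs for the
cleaning stage.

Everything is deterministic given the spec's seed.  Signals are in µV.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .io import Montage, RawRecording, load_montage

logger = logging.getLogger("topogru")

#: canonical band edges (Hz), half-open [lo, hi)
BAND_EDGES = {"theta": (4.0, 8.0), "alpha": (8.0, 13.0), "beta": (13.0, 30.0)}

# baseline per-band RMS amplitude (µV) of the oscillatory components; the
# α value is further scaled by the posterior gradient below.  Chosen to
# mimic resting eyes-closed scalp EEG where α dominates posteriorly.
_BASE_RMS = {"theta": 4.0, "alpha": 6.0, "beta": 3.0}
_BACKGROUND_RMS = 5.0          # 1/f background, µV
_TOPOGRAPHY_SD = 0.25          # log-amplitude SD of per-subject spatial field
_TOPOGRAPHY_SCALE = 0.6        # correlation length (chord distance) of field
_ALPHA_POSTERIOR_GAIN = 0.5    # posterior α amplitude boost factor


@dataclass
class BandEffect:
    """Multiplicative band-power elevation for the depressed class.

    1.0 everywhere is the null effect: the two classes are then identical
    in distribution.  The elevation applies only to electrodes in
    ``region``.
    """

    theta: float = 1.0
    alpha: float = 1.0
    beta: float = 1.0
    region: str = "parietal-occipital"

    def __post_init__(self) -> None:
        for b in ("theta", "alpha", "beta"):
            if getattr(self, b) < 1.0:
                raise ValueError(f"{b} elevation must be ≥ 1")

    def elevation(self, band: str) -> float:
        return float(getattr(self, band))


@dataclass
class ArtifactSpec:
    """Blink and line-noise contamination levels; zeros = artifact-free."""

    blink_rate: float = 0.0           # events / minute
    blink_amplitude: float = 0.0      # µV at the most frontal electrode
    line_noise_amplitude: float = 0.0  # µV
    mains_freq: float = 50.0          # Hz

    def __post_init__(self) -> None:
        for f in ("blink_rate", "blink_amplitude", "line_noise_amplitude",
                  "mains_freq"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be ≥ 0")

    @property
    def is_null(self) -> bool:
        return (self.blink_rate * self.blink_amplitude == 0
                and self.line_noise_amplitude == 0)


@dataclass
class CohortSpec:
    """Shape and effect structure of a simulated cohort.

    Defaults emulate a 53-subject resting study with 24 depressed cases at
    250 Hz; the packaged 16-channel 10-20 montage keeps the default cohort
    tractable on a laptop while preserving the spatial structure the
    pipeline exploits.
    """

    n_subjects: int = 53
    depressed_fraction: float = 24 / 53
    fs: float = 250.0
    duration: float = 12.0
    montage_name: str = "standard-1020-16"
    effect: BandEffect = field(default_factory=BandEffect)
    artifact_cfg: ArtifactSpec = field(default_factory=ArtifactSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if self.duration < 1.0:
            raise ValueError("duration must be at least 1 s")
        if self.duration < 10.0:
            raise ValueError("duration must be ≥ 10 s (10 one-second segments)")
        if not self.fs > 60:
            raise ValueError("sampling rate must exceed 60 Hz")
        if not 0.0 <= self.depressed_fraction <= 1.0:
            raise ValueError("depressed_fraction must lie in [0, 1]")

    @property
    def n_depressed(self) -> int:
        # rounding toward the control class
        return int(math.floor(self.n_subjects * self.depressed_fraction + 1e-12))


def region_channels(montage: Montage, region: str = "parietal-occipital") -> list[int]:
    """Indices of montage electrodes in a named scalp region.

    For 10-20-style labels the parietal-occipital region is label-driven
    (names starting with P or O); montages without such labels (the dense
    simulated net) fall back to the posterior hemisphere, y < 0 under the
    +y=nasion convention.
    """
    if region != "parietal-occipital":
        raise ValueError(f"unknown region {region!r}")
    idx = [i for i, n in enumerate(montage.channel_names)
           if n[:1] in ("P", "O")]
    if not idx:
        idx = [i for i in range(len(montage)) if montage.coords[i, 1] < 0]
    return idx


def _smooth_field(coords: np.ndarray, rng: np.random.Generator,
                  sd: float, scale: float) -> np.ndarray:
    """Sample a smooth zero-mean Gaussian field over electrode positions."""
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
    cov = np.exp(-d2 / (2.0 * scale**2)) + 1e-9 * np.eye(len(coords))
    chol = np.linalg.cholesky(cov)
    return sd * (chol @ rng.standard_normal(len(coords)))


def _bandpassed_noise(rng: np.random.Generator, n_ch: int, n_samp: int,
                      fs: float, lo: float, hi: float) -> np.ndarray:
    """Unit-RMS noise band-limited to [lo, hi] Hz, per channel."""
    hi = min(hi, 0.45 * fs)
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    # pad to wash out filter transients
    pad = int(fs)
    x = rng.standard_normal((n_ch, n_samp + 2 * pad))
    y = sps.sosfiltfilt(sos, x, axis=1)[:, pad:pad + n_samp]
    rms = np.sqrt((y**2).mean(axis=1, keepdims=True))
    return y / np.maximum(rms, 1e-12)


def _pink_noise(rng: np.random.Generator, n_ch: int, n_samp: int,
                fs: float) -> np.ndarray:
    """1/f-amplitude background, unit RMS per channel."""
    freqs = np.fft.rfftfreq(n_samp, 1.0 / fs)
    shaping = np.zeros_like(freqs)
    nz = freqs >= 0.5
    shaping[nz] = 1.0 / np.sqrt(freqs[nz])
    spec = (rng.standard_normal((n_ch, freqs.size))
            + 1j * rng.standard_normal((n_ch, freqs.size))) * shaping
    y = np.fft.irfft(spec, n=n_samp, axis=1)
    rms = np.sqrt((y**2).mean(axis=1, keepdims=True))
    return y / np.maximum(rms, 1e-12)


def _subject_signal(rng: np.random.Generator, montage: Montage, fs: float,
                    n_samp: int, depressed: bool, effect: BandEffect) -> np.ndarray:
    coords = montage.coords
    n_ch = len(montage)
    data = _BACKGROUND_RMS * _pink_noise(rng, n_ch, n_samp, fs)
    posterior = np.clip(-coords[:, 1], 0.0, 1.0)  # 0 anterior → 1 posterior rim
    region = region_channels(montage, effect.region)
    for band, (lo, hi) in BAND_EDGES.items():
        amp = _BASE_RMS[band] * np.exp(_smooth_field(
            coords, rng, _TOPOGRAPHY_SD, _TOPOGRAPHY_SCALE))
        if band == "alpha":
            amp = amp * (1.0 + _ALPHA_POSTERIOR_GAIN * posterior)
        if depressed:
            gain = np.ones(n_ch)
            gain[region] = math.sqrt(effect.elevation(band))
            amp = amp * gain
        data += amp[:, None] * _bandpassed_noise(rng, n_ch, n_samp, fs, lo, hi)
    return data


def generate_cohort(spec: CohortSpec) -> list[tuple[RawRecording, int]]:
    """Simulate a labelled cohort; label 1 = depressed.

    Deterministic given ``spec`` (including its seed): the class
    assignment, every subject's signal, and any injected artifacts all
    derive from ``spec.seed``.
    """
    montage = load_montage(spec.montage_name)
    n = spec.n_subjects
    n_samp = int(round(spec.duration * spec.fs))
    labels = np.zeros(n, dtype=int)
    labels[:spec.n_depressed] = 1
    rng_assign = np.random.default_rng(np.random.SeedSequence([spec.seed, 0]))
    labels = labels[rng_assign.permutation(n)]

    cohort: list[tuple[RawRecording, int]] = []
    for i in range(n):
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1, i]))
        data = _subject_signal(rng, montage, spec.fs, n_samp,
                               depressed=bool(labels[i]), effect=spec.effect)
        rec = RawRecording(data, spec.fs, list(montage.channel_names),
                           subject_id=f"sub-{i + 1:03d}")
        if not spec.artifact_cfg.is_null:
            rec = inject_artifacts(rec, spec.artifact_cfg,
                                   seed=int(np.random.SeedSequence(
                                       [spec.seed, 2, i]).generate_state(1)[0]
                                       % (2**31)),
                                   montage=montage)
        cohort.append((rec, int(labels[i])))
    return cohort


def _blink_template(fs: float, width_s: float = 0.35) -> np.ndarray:
    """Biphasic low-frequency transient (derivative-of-Gaussian), peak 1."""
    n = int(round(width_s * fs))
    t = np.linspace(-1.0, 1.0, n)
    sigma = 0.35
    w = -t * np.exp(-(t**2) / (2 * sigma**2))
    return w / np.abs(w).max()


def inject_artifacts(rec: RawRecording, spec: ArtifactSpec, seed: int,
                     montage: Montage | None = None) -> RawRecording:
    """Add blink transients and mains line noise to a recording.

    Blinks are frontal-weighted biphasic transients; the event count is
    exactly ``round(blink_rate × duration/60)`` with seeded random onsets.
    Line noise is a common-mode sinusoid at the mains frequency.  With all
    amplitudes zero the input is returned untouched.
    """
    if spec.mains_freq >= rec.fs / 2:
        raise ValueError(
            f"mains frequency {spec.mains_freq} Hz is at/above Nyquist "
            f"({rec.fs / 2} Hz)")
    if spec.is_null:
        return rec
    rng = np.random.default_rng(seed)
    data = rec.data.copy()
    n_ch, n_samp = data.shape

    if montage is not None:
        y = montage.get_positions(rec.channel_names)[:, 1]
        frontal_w = np.clip(y, 0.0, None) ** 2
        frontal_w = frontal_w / max(frontal_w.max(), 1e-12)
    else:
        frontal_w = np.array(
            [1.0 if n.startswith(("Fp", "AF")) else
             0.4 if n[:1] == "F" else 0.0 for n in rec.channel_names])
        if frontal_w.max() == 0:
            frontal_w[:] = 1.0

    if spec.blink_rate > 0 and spec.blink_amplitude > 0:
        template = _blink_template(rec.fs) * spec.blink_amplitude
        n_events = int(round(spec.blink_rate * rec.duration / 60.0))
        width = template.size
        starts = rng.integers(0, max(1, n_samp - width), size=n_events)
        for s in np.sort(starts):
            data[:, s:s + width] += frontal_w[:, None] * template[None, :width]

    if spec.line_noise_amplitude > 0:
        t = np.arange(n_samp) / rec.fs
        phase = rng.uniform(0, 2 * np.pi)
        data += spec.line_noise_amplitude * np.sin(
            2 * np.pi * spec.mains_freq * t + phase)[None, :]

    return rec.copy_with(data)
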