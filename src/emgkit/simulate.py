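"""Synthetic EMG generator: superposed motor-unit action-potential trains.

A needle-EMG interference pattern is emulated as the sum of per-motor-unit
MUAP trains plus additive Gaussian instrumentation noise, band-limited with
a zero-phase Butterworth filter.  Class structure follows the textbook
clinical contrasts:

* **Normal** — intermediate amplitude/duration, 2–4 phases, many units.
* **Myopathy** — small, short, polyphasic MUAPs (fibre loss within units).
* **Neuropathy** — large, long MUAPs from few surviving (reinnervated) units.

The MUAP waveform itself is a sum of ``n_phases`` alternating-sign Gaussian
lobes spread across the duration; lobe magnitudes are balanced so that for
two or more phases the waveform returns to baseline (≈ zero mean).  A
monophasic template (n_phases = 1) is a single one-signed lobe and cannot
have zero mean.

Motor-unit firing is a renewal process: inter-pulse intervals are Gaussian
with mean 1/rate and standard deviation ``jitter``/rate, truncated to stay
positive.  Everything is a pure function of the configuration seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from ._util import CLASSES, rng_from, seed_sequence
from .errors import ConfigurationError, ParameterError
from .io import EmgRecording

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MuapShapeParams:
    """Morphology of one motor-unit action potential."""

    amplitude_mv: float
    duration_ms: float
    n_phases: int = 2

    def __post_init__(self) -> None:
        if not self.amplitude_mv > 0:
            raise ParameterError("amplitude_mv must be positive")
        if not self.duration_ms > 0:
            raise ParameterError("duration_ms must be positive")
        if not 1 <= int(self.n_phases) <= 8:
            raise ParameterError("n_phases must be in 1..8")


@dataclass(frozen=True)
class ClassProfile:
    """Population statistics of one diagnostic class's motor units.

    ``amplitude_dist`` / ``duration_dist`` are (mean, sd) of truncated
    normals (truncated at zero); ``phases_dist`` maps phase count to
    probability; ``firing_jitter`` is the coefficient of variation of the
    inter-pulse intervals.
    """

    class_label: str
    amplitude_dist: tuple[float, float]
    duration_dist: tuple[float, float]
    phases_dist: dict[int, float]
    n_motor_units: int
    firing_rate_hz: float
    firing_jitter: float = 0.15
    noise_sd_mv: float = 0.05

    def __post_init__(self) -> None:
        if self.n_motor_units < 1:
            raise ParameterError("n_motor_units must be >= 1")
        if self.firing_rate_hz < 0:
            raise ParameterError("firing_rate_hz must be >= 0")
        if not 0 <= self.firing_jitter < 1:
            raise ParameterError("firing_jitter must be in [0, 1)")
        if self.noise_sd_mv < 0:
            raise ParameterError("noise_sd_mv must be >= 0")
        for dist, name in ((self.amplitude_dist, "amplitude"), (self.duration_dist, "duration")):
            if not dist[0] > 0 or dist[1] < 0:
                raise ParameterError(f"{name}_dist must have positive mean, sd >= 0")
        probs = np.array(list(self.phases_dist.values()), dtype=float)
        if len(probs) == 0 or np.any(probs < 0) or not np.isclose(probs.sum(), 1.0):
            raise ParameterError("phases_dist must be a probability distribution")
        for p in self.phases_dist:
            if not 1 <= int(p) <= 8:
                raise ParameterError("phase counts must be in 1..8")


@dataclass(frozen=True)
class SimulationConfig:
    """Acquisition settings: 20 kHz, 5 s, 5 Hz–10 kHz band by default."""

    sampling_rate_hz: float = 20_000.0
    duration_s: float = 5.0
    bandpass_hz: tuple[float, float] = (5.0, 10_000.0)
    seed: int = 0
    quantize_bits: int | None = None  # 12-bit ADC emulation, off by default

    def __post_init__(self) -> None:
        low, high = self.bandpass_hz
        nyquist = self.sampling_rate_hz / 2.0
        if not (0 < low < high <= nyquist):
            raise ParameterError(
                "bandpass must satisfy 0 < low < high <= sampling_rate/2"
            )
        if not self.duration_s > 0:
            raise ParameterError("duration_s must be positive")


#: Default class profiles: simulator defaults encoding the clinical contrast,
#: not measurements of any particular dataset.
DEFAULT_PROFILES: dict[str, ClassProfile] = {
    "Normal": ClassProfile(
        class_label="Normal",
        amplitude_dist=(1.0, 0.3),
        duration_dist=(9.0, 2.0),
        phases_dist={2: 1 / 3, 3: 1 / 3, 4: 1 / 3},
        n_motor_units=12,
        firing_rate_hz=15.0,
    ),
    "Myopathy": ClassProfile(
        class_label="Myopathy",
        amplitude_dist=(0.4, 0.15),
        duration_dist=(5.0, 1.5),
        phases_dist={4: 1 / 3, 5: 1 / 3, 6: 1 / 3},
        n_motor_units=12,
        firing_rate_hz=20.0,
    ),
    "Neuropathy": ClassProfile(
        class_label="Neuropathy",
        amplitude_dist=(1.6, 0.5),
        duration_dist=(14.0, 3.0),
        phases_dist={2: 1 / 3, 3: 1 / 3, 4: 1 / 3},
        n_motor_units=5,
        firing_rate_hz=12.0,
    ),
}


def make_muap_template(shape: MuapShapeParams, sampling_rate_hz: float) -> np.ndarray:
    """Build one MUAP waveform sampled at ``sampling_rate_hz``.

    Returns round(duration_ms * fs / 1000) samples.  The waveform has
    exactly ``n_phases - 1`` sign changes, peak absolute value equal to
    ``amplitude_mv``, and (for n_phases >= 2) near-zero mean.
    """
    n = round(shape.duration_ms * sampling_rate_hz / 1000.0)
    if n < 4:
        raise ParameterError(
            f"duration {shape.duration_ms} ms spans only {n} samples at "
            f"{sampling_rate_hz} Hz; need >= 4"
        )
    p = int(shape.n_phases)
    t = np.arange(n, dtype=float)
    centers = (np.arange(1, p + 1) / (p + 1)) * n
    width = n / (4.0 * (p + 1))
    if p == 1:
        mags = np.array([1.0])
    elif p % 2 == 0:
        mags = np.ones(p)
    else:
        # Half-magnitude end lobes make the alternating areas cancel.
        mags = np.ones(p)
        mags[0] = mags[-1] = 0.5
    signs = (-1.0) ** np.arange(p)
    x = np.zeros(n)
    for c, w_, m, s in zip(centers, [width] * p, mags, signs):
        x += s * m * np.exp(-0.5 * ((t - c) / w_) ** 2)
    x *= shape.amplitude_mv / np.max(np.abs(x))
    return x


def count_sign_changes(x: np.ndarray, rel_tol: float = 1e-9) -> int:
    """Sign changes of a waveform, ignoring numerically-zero samples."""
    s = np.sign(x)
    s[np.abs(x) < rel_tol * np.max(np.abs(x))] = 0
    s = s[s != 0]
    return int(np.count_nonzero(np.diff(s)))


def _draw_shape(profile: ClassProfile, rng: np.random.Generator) -> MuapShapeParams:
    def trunc_normal(mean: float, sd: float) -> float:
        for _ in range(100):
            v = rng.normal(mean, sd)
            if v > 0:
                return v
        return mean  # pathological sd; fall back to the mean
    phases = np.array(sorted(profile.phases_dist), dtype=int)
    probs = np.array([profile.phases_dist[p] for p in phases], dtype=float)
    probs = probs / probs.sum()
    return MuapShapeParams(
        amplitude_mv=trunc_normal(*profile.amplitude_dist),
        duration_ms=trunc_normal(*profile.duration_dist),
        n_phases=int(rng.choice(phases, p=probs)),
    )


def _firing_times(
    rate_hz: float, jitter: float, duration_s: float, rng: np.random.Generator
) -> np.ndarray:
    """Renewal-process discharge times over [0, duration_s)."""
    if rate_hz <= 0:
        return np.empty(0)
    mean_ipi = 1.0 / rate_hz
    times = [rng.uniform(0.0, mean_ipi)]
    while times[-1] < duration_s:
        ipi = rng.normal(mean_ipi, jitter * mean_ipi)
        ipi = max(ipi, 0.05 * mean_ipi)  # truncate positive
        times.append(times[-1] + ipi)
    return np.array(times[:-1])


def _band_limit(x: np.ndarray, config: SimulationConfig) -> np.ndarray:
    low, high = config.bandpass_hz
    nyquist = config.sampling_rate_hz / 2.0
    if high >= nyquist * (1 - 1e-9):
        # Upper edge at Nyquist: the band-pass degenerates to a high-pass.
        sos = sps.butter(4, low, btype="highpass", fs=config.sampling_rate_hz, output="sos")
    else:
        sos = sps.butter(
            4, [low, high], btype="bandpass", fs=config.sampling_rate_hz, output="sos"
        )
    return sps.sosfiltfilt(sos, x)


def simulate_recording(
    profile: ClassProfile,
    config: SimulationConfig,
    recording_id: str | None = None,
) -> EmgRecording:
    """Simulate one labelled recording; deterministic for a fixed seed."""
    rng = rng_from(config.seed, "recording")
    fs = config.sampling_rate_hz
    n = round(config.duration_s * fs)
    x = np.zeros(n)
    for _unit in range(profile.n_motor_units):
        template = make_muap_template(_draw_shape(profile, rng), fs)
        half = len(template) // 2
        for t_fire in _firing_times(
            profile.firing_rate_hz, profile.firing_jitter, config.duration_s, rng
        ):
            start = round(t_fire * fs) - half
            lo, hi = max(start, 0), min(start + len(template), n)
            if lo < hi:
                x[lo:hi] += template[lo - start : hi - start]
    if profile.noise_sd_mv > 0:
        x += rng.normal(0.0, profile.noise_sd_mv, n)
    x = _band_limit(x, config)
    if config.quantize_bits is not None:
        full_scale = max(np.max(np.abs(x)), 1e-12)
        levels = 2 ** (config.quantize_bits - 1)
        x = np.round(x / full_scale * levels) / levels * full_scale
    return EmgRecording(
        samples=x,
        sampling_rate_hz=fs,
        label=profile.class_label,
        recording_id=recording_id or f"{profile.class_label}-{config.seed}",
        meta={"seed": config.seed, "sampling_rate_hz": fs},
    )


def simulate_dataset(
    profiles: list[ClassProfile],
    n_recordings_per_class: int,
    config: SimulationConfig,
) -> list[EmgRecording]:
    """Simulate ``n_recordings_per_class`` recordings for every profile.

    Per-recording seeds are derived deterministically from ``config.seed``.
    """
    if n_recordings_per_class < 1:
        raise ParameterError("n_recordings_per_class must be >= 1")
    labels = [p.class_label for p in profiles]
    if len(set(labels)) != len(labels):
        raise ConfigurationError(f"duplicate class labels in profiles: {labels}")
    recordings = []
    for ci, profile in enumerate(profiles):
        for j in range(n_recordings_per_class):
            child = seed_sequence(config.seed, "dataset", ci, j)
            child_seed = int(child.generate_state(1)[0] % (2**31))
            rec_config = SimulationConfig(
                sampling_rate_hz=config.sampling_rate_hz,
                duration_s=config.duration_s,
                bandpass_hz=config.bandpass_hz,
                seed=child_seed,
                quantize_bits=config.quantize_bits,
            )
            recordings.append(
                simulate_recording(
                    profile, rec_config, recording_id=f"{profile.class_label}-{j:03d}"
                )
            )
    logger.info(
        "simulated %d recordings (%d per class, classes: %s)",
        len(recordings), n_recordings_per_class, ", ".join(labels),
    )
    return recordings


def default_profiles(order: tuple[str, ...] = CLASSES) -> list[ClassProfile]:
    """The built-in three-class profiles in canonical class order."""
    return [DEFAULT_PROFILES[name] for name in order]
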