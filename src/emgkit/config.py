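"""Run configuration: one YAML file drives simulate → extract → evaluate.

Validation is strict — unknown keys raise :class:`ConfigurationError`
naming the key path, so typos in experiment grids fail fast.  One global
seed fans out to per-stage seeds by fixed derivation tags.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from ._util import CLASSES
from .ensembles import EnsembleSpec
from .errors import ConfigurationError
from .evaluation import CvConfig
from .simulate import ClassProfile, DEFAULT_PROFILES, SimulationConfig
from .wpd import STAT_NAMES, WpdConfig

_SIMULATE_KEYS = {
    "n_recordings_per_class", "sampling_rate_hz", "duration_s",
    "bandpass_low_hz", "bandpass_high_hz", "quantize_bits", "profiles",
}
_PROFILE_KEYS = {
    "amplitude_mean", "amplitude_sd", "duration_mean", "duration_sd",
    "phases", "n_motor_units", "firing_rate_hz", "firing_jitter", "noise_sd_mv",
}
_WPD_KEYS = {
    "wavelet_name", "level", "extension_mode", "subband_set", "ordering",
    "statistics", "include_ratios",
}
_FRAMING_KEYS = {"frame_length", "overlap"}
_ENSEMBLE_KEYS = {"method", "T", "n_subcommittees", "noise_model", "noise_scale", "samme"}
_CV_KEYS = {"k_folds", "grouping"}
_TOP_KEYS = {
    "seed", "output_dir", "log_level", "simulate", "wpd", "framing",
    "learners", "ensembles", "cv",
}


def _check_keys(section: dict, allowed: set[str], path: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigurationError(
            f"unknown config key(s) under {path!r}: {sorted(unknown)}"
        )


def _profile_from(name: str, overrides: dict) -> ClassProfile:
    _check_keys(overrides, _PROFILE_KEYS, f"simulate.profiles.{name}")
    base = DEFAULT_PROFILES.get(name)
    if base is None:
        raise ConfigurationError(
            f"profile {name!r} is not one of {sorted(DEFAULT_PROFILES)}"
        )
    phases = overrides.get("phases")
    phases_dist = (
        {int(p): 1.0 / len(phases) for p in phases} if phases else base.phases_dist
    )
    return ClassProfile(
        class_label=name,
        amplitude_dist=(
            overrides.get("amplitude_mean", base.amplitude_dist[0]),
            overrides.get("amplitude_sd", base.amplitude_dist[1]),
        ),
        duration_dist=(
            overrides.get("duration_mean", base.duration_dist[0]),
            overrides.get("duration_sd", base.duration_dist[1]),
        ),
        phases_dist=phases_dist,
        n_motor_units=overrides.get("n_motor_units", base.n_motor_units),
        firing_rate_hz=overrides.get("firing_rate_hz", base.firing_rate_hz),
        firing_jitter=overrides.get("firing_jitter", base.firing_jitter),
        noise_sd_mv=overrides.get("noise_sd_mv", base.noise_sd_mv),
    )


@dataclass
class RunConfig:
    seed: int = 0
    output_dir: Path = Path("emgkit-out")
    log_level: str = "INFO"
    n_recordings_per_class: int = 17
    profiles: list[ClassProfile] = field(
        default_factory=lambda: [DEFAULT_PROFILES[c] for c in CLASSES]
    )
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    wpd: WpdConfig = field(default_factory=WpdConfig)
    frame_length: int = 2048
    overlap: int = 0
    learners: list[dict] = field(default_factory=lambda: [{"name": "random_forest"}])
    ensembles: list[EnsembleSpec] = field(default_factory=lambda: [EnsembleSpec()])
    cv: CvConfig = field(default_factory=CvConfig)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError(f"{path}: top level must be a mapping")
        _check_keys(raw, _TOP_KEYS, "<top>")
        seed = int(raw.get("seed", 0))

        sim_raw = raw.get("simulate", {}) or {}
        _check_keys(sim_raw, _SIMULATE_KEYS, "simulate")
        simulation = SimulationConfig(
            sampling_rate_hz=sim_raw.get("sampling_rate_hz", 20_000.0),
            duration_s=sim_raw.get("duration_s", 5.0),
            bandpass_hz=(
                sim_raw.get("bandpass_low_hz", 5.0),
                sim_raw.get("bandpass_high_hz", 10_000.0),
            ),
            seed=seed,
            quantize_bits=sim_raw.get("quantize_bits"),
        )
        profile_over = sim_raw.get("profiles", {}) or {}
        if not isinstance(profile_over, dict):
            raise ConfigurationError("simulate.profiles must be a mapping")
        profiles = [_profile_from(c, profile_over.get(c, {})) for c in CLASSES]

        wpd_raw = raw.get("wpd", {}) or {}
        _check_keys(wpd_raw, _WPD_KEYS, "wpd")
        wpd = WpdConfig(
            wavelet_name=wpd_raw.get("wavelet_name", "db4"),
            level=wpd_raw.get("level", 4),
            extension_mode=wpd_raw.get("extension_mode", "periodic"),
            subband_set=wpd_raw.get("subband_set", "terminal"),
            ordering=wpd_raw.get("ordering", "frequency"),
            statistics=tuple(wpd_raw.get("statistics", STAT_NAMES)),
            include_ratios=wpd_raw.get("include_ratios", True),
        )

        framing_raw = raw.get("framing", {}) or {}
        _check_keys(framing_raw, _FRAMING_KEYS, "framing")

        learners = raw.get("learners", [{"name": "random_forest"}])
        if not isinstance(learners, list) or not all(
            isinstance(e, dict) and "name" in e for e in learners
        ):
            raise ConfigurationError("learners must be a list of mappings with a 'name'")

        ens_raw = raw.get("ensembles", [{}])
        ensembles = []
        for i, e in enumerate(ens_raw):
            _check_keys(e, _ENSEMBLE_KEYS, f"ensembles[{i}]")
            ensembles.append(
                EnsembleSpec(
                    method=e.get("method", "adaboost"),
                    T=e.get("T", 10),
                    n_subcommittees=e.get("n_subcommittees"),
                    noise_model=e.get("noise_model", "continuous_poisson"),
                    noise_scale=e.get("noise_scale", 2.0),
                    samme=e.get("samme", False),
                )
            )

        cv_raw = raw.get("cv", {}) or {}
        _check_keys(cv_raw, _CV_KEYS, "cv")
        cv = CvConfig(
            k_folds=cv_raw.get("k_folds", 10),
            seed=seed,
            grouping=cv_raw.get("grouping", "frame"),
        )

        return cls(
            seed=seed,
            output_dir=Path(raw.get("output_dir", "emgkit-out")),
            log_level=str(raw.get("log_level", "INFO")),
            n_recordings_per_class=int(sim_raw.get("n_recordings_per_class", 17)),
            profiles=profiles,
            simulation=simulation,
            wpd=wpd,
            frame_length=int(framing_raw.get("frame_length", 2048)),
            overlap=int(framing_raw.get("overlap", 0)),
            learners=list(learners),
            ensembles=ensembles,
            cv=cv,
        )
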