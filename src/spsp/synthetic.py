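"""Synthetic multichannel datasets with class-conditional radial structure.

The generator emulates the shape of a preprocessed multichannel EEG corpus
(by default 32 channels, 8064 samples at 128 Hz per trial) while planting
the class signal exactly where the spherical-partitioning pipeline looks
for it: in the distribution over time of the trajectory's distance from its
center.  Channel m of a trial from class c is

    x_m(n) = a_c(n) * g_m(n) + noise_sd * eps_m(n)

where g_m is a smooth subject-seeded base waveform (a common component plus
a subject-specific component scaled by ``subject_variability``), eps is
white Gaussian noise, and a_c(n) = 1 + separation * c_index * w(n) is a
class-specific radial envelope driven by a fixed slow modulation w.  With
``separation`` = 0 the label carries no information at all.

Everything is reproducible from the spec's seed alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .dataset_io import DatasetManifest, ManifestEntry, Recording
from .errors import ConfigError, DomainError
from .phase_space import DistanceSeries

#: relative amplitude of the slow class modulation w(n)
_W_AMPLITUDE = 0.25
#: cycles of the slow modulation across one trial
_W_CYCLES = 2
#: smoothing scale of the base waveforms, as a fraction of trial length
_SMOOTH_FRAC = 1.0 / 256.0


@dataclass
class SyntheticSpec:
    """Parameters of a generated dataset."""

    n_subjects: int = 8
    class_labels: tuple[str, ...] = ("calm", "excited")
    trials_per_class: int = 1
    M: int = 32
    N: int = 8064
    sample_rate_hz: float = 128.0
    separation: float = 1.0
    subject_variability: float = 0.5
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        self.class_labels = tuple(str(c) for c in self.class_labels)
        if self.n_subjects < 2:
            raise ConfigError(f"n_subjects must be >= 2, got {self.n_subjects}")
        if len(self.class_labels) < 1:
            raise ConfigError("class_labels must be non-empty")
        if len(set(self.class_labels)) != len(self.class_labels):
            raise ConfigError("class_labels must be distinct")
        if self.trials_per_class < 1:
            raise ConfigError(
                f"trials_per_class must be >= 1, got {self.trials_per_class}"
            )
        if self.M < 1 or self.N < 2:
            raise ConfigError(f"need M >= 1 and N >= 2, got M={self.M}, N={self.N}")
        if self.sample_rate_hz <= 0:
            raise ConfigError("sample_rate_hz must be positive")
        if self.separation < 0:
            raise ConfigError(f"separation must be >= 0, got {self.separation}")
        if self.subject_variability < 0:
            raise ConfigError("subject_variability must be >= 0")
        if self.noise_sd <= 0:
            raise ConfigError(f"noise_sd must be positive, got {self.noise_sd}")

    @classmethod
    def from_dict(cls, doc: dict) -> "SyntheticSpec":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ConfigError(f"unknown synthetic-spec fields: {sorted(unknown)}")
        if "class_labels" in doc:
            doc = dict(doc)
            doc["class_labels"] = tuple(doc["class_labels"])
        return cls(**doc)


def _smooth_waveforms(rng: np.random.Generator, m: int, n: int) -> np.ndarray:
    """M smooth unit-variance waveforms: low-pass filtered white noise."""
    white = rng.standard_normal((m, n))
    sigma = max(2.0, n * _SMOOTH_FRAC)
    smooth = gaussian_filter1d(white, sigma=sigma, axis=1, mode="wrap")
    sd = smooth.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return smooth / sd


def _slow_modulation(n: int) -> np.ndarray:
    t = np.arange(n) / n
    return _W_AMPLITUDE * np.sin(2.0 * np.pi * _W_CYCLES * t)


def generate_dataset(spec: SyntheticSpec) -> tuple[list[Recording], DatasetManifest]:
    """Generate every trial of the spec, plus an in-memory manifest.

    The manifest's file paths follow the naming the CLI uses when the
    dataset is written to disk (``<subject>_<trial>.csv``).
    """
    w = _slow_modulation(spec.N)
    rng_common = np.random.default_rng(
        np.random.SeedSequence([spec.seed, 0xC0117017])
    )
    common = _smooth_waveforms(rng_common, spec.M, spec.N)
    channel_names = [f"ch{i + 1:02d}" for i in range(spec.M)]

    recordings: list[Recording] = []
    entries: list[ManifestEntry] = []
    for s_idx in range(spec.n_subjects):
        subject_id = f"s{s_idx + 1:02d}"
        rng_subject = np.random.default_rng(
            np.random.SeedSequence([spec.seed, 1, s_idx])
        )
        base = common + spec.subject_variability * _smooth_waveforms(
            rng_subject, spec.M, spec.N
        )
        for c_idx, label in enumerate(spec.class_labels):
            envelope = 1.0 + spec.separation * c_idx * w
            for t_idx in range(spec.trials_per_class):
                rng_trial = np.random.default_rng(
                    np.random.SeedSequence([spec.seed, 2, s_idx, c_idx, t_idx])
                )
                data = envelope[None, :] * base + spec.noise_sd * (
                    rng_trial.standard_normal((spec.M, spec.N))
                )
                trial_id = f"{label}{t_idx + 1:02d}"
                recordings.append(
                    Recording(
                        subject_id=subject_id,
                        trial_id=trial_id,
                        label=label,
                        sample_rate_hz=spec.sample_rate_hz,
                        channel_names=list(channel_names),
                        data=data,
                    )
                )
                entries.append(
                    ManifestEntry(
                        file_path=f"{subject_id}_{trial_id}.csv",
                        subject_id=subject_id,
                        trial_id=trial_id,
                        label=label,
                    )
                )
    manifest = DatasetManifest(
        entries=entries,
        channel_count=spec.M,
        sample_rate_hz=spec.sample_rate_hz,
    )
    return recordings, manifest


def generate_distance_series(n: int, seed: int) -> DistanceSeries:
    """Tie-free i.i.d. uniform(0, 1) distance series, for symbolizer tests."""
    if n < 2:
        raise DomainError(f"need n >= 2, got {n}")
    rng = np.random.default_rng(seed)
    return DistanceSeries(
        values=rng.uniform(0.0, 1.0, size=n),
        source=("synthetic", f"seed{seed}"),
    )
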