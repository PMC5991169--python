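"""Multi-subject synthetic recordings with embedded cross-individual structure.

Each subject carries two latent traits: a background magnitude scale (drives
band RMS and, through the intercept coefficients, the amplitude-on-rating
intercept d) and an alpha-2 center frequency f in [11, 13] Hz (drives
narrowband temporal variability and, through the slope coefficients, the
amplitude-on-rating slope c).  Evoked responses are inserted on one
designated channel with peak-to-peak amplitude c*rating + d (+ trial noise)
for fast-pain trials only (rating > 4); low-pain trials get no deflection.

All randomness flows through one seeded numpy Generator passed explicitly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import Recording
from .preprocessing import BANDS

ALPHA2_BAND = BANDS["alpha-2"]

DEFAULT_BAND_MAGNITUDES = {
    "delta": 2.0,
    "theta": 1.5,
    "alpha-1": 2.0,
    "alpha-2": 2.0,
    "beta": 1.0,
}


class ConfigurationError(ValueError):
    pass


@dataclass
class GeneratorConfig:
    n_subjects: int = 30
    sampling_rate: float = 1000.0
    channels: tuple[str, ...] = ("Cz",)
    lep_channel: str = "Cz"
    isi_range: tuple[float, float] = (10.0, 15.0)
    energy_min: float = 1.0
    energy_step: float = 0.25
    max_energy_range: tuple[float, float] = (3.75, 4.5)
    pulses_per_level: int = 10
    band_magnitude_means: dict = field(
        default_factory=lambda: dict(DEFAULT_BAND_MAGNITUDES))  # uV RMS
    magnitude_scale_range: tuple[float, float] = (0.5, 1.5)
    intercept_coeffs: tuple[float, float] = (5.0, 4.0)    # beta0 uV, beta1 uV/uV
    slope_coeffs: tuple[float, float] = (6.0, 2.0)        # gamma0 uV/NRS, gamma1 uV/NRS/Hz
    subject_noise_sds: dict = field(
        default_factory=lambda: {"intercept": 1.5, "slope": 0.3})
    trial_noise_sd: float = 1.0       # uV on inserted peak-to-peak amplitude
    rating_noise_sd: float = 0.5      # NRS units before rounding
    first_onset: float = 5.0
    post_stimulus_window: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.isi_range[0] <= 2.0 + self.post_stimulus_window:
            raise ConfigurationError(
                "isi_range lower bound must exceed 2 s + the post-stimulus window")
        if self.sampling_rate <= 2 * 30.0:
            raise ConfigurationError("sampling_rate must exceed twice 30 Hz")
        if self.lep_channel not in self.channels:
            raise ConfigurationError(
                f"lep_channel {self.lep_channel!r} not in channels")
        for bound in self.max_energy_range:
            if bound < self.energy_min:
                raise ConfigurationError("energy_min must not exceed max energies")
            steps = (bound - self.energy_min) / self.energy_step
            if abs(steps - round(steps)) > 1e-9:
                raise ConfigurationError(
                    f"energy step {self.energy_step} J does not divide "
                    f"{bound} - {self.energy_min} J")
        if self.slope_coeffs[0] <= 0:
            raise ConfigurationError(
                "slope baseline (gamma0) must be positive: most subjects would "
                "have non-positive amplitude-per-rating slopes")

    def max_energy_grid(self) -> np.ndarray:
        lo, hi = self.max_energy_range
        n = int(round((hi - lo) / self.energy_step))
        return lo + self.energy_step * np.arange(n + 1)

    @classmethod
    def from_json(cls, path: str | Path) -> "GeneratorConfig":
        raw = json.loads(Path(path).read_text())
        for key in ("channels", "isi_range", "max_energy_range",
                    "magnitude_scale_range", "intercept_coeffs", "slope_coeffs"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))


@dataclass
class SubjectProfile:
    subject_id: str
    magnitude_scale: dict          # band -> background RMS target, uV
    alpha2_center_freq: float      # f_s, Hz in [11, 13]
    true_slope: float              # c_s, uV per NRS unit, > 0
    true_intercept: float          # d_s, uV
    max_energy: float              # J

    @property
    def overall_magnitude(self) -> float:
        """Root-sum-square background RMS across bands (uV)."""
        return float(np.sqrt(sum(v ** 2 for v in self.magnitude_scale.values())))


@dataclass
class StimulusSchedule:
    onsets: np.ndarray     # s, strictly increasing
    energies: np.ndarray   # J per trial
    level_count: int


def draw_subject_profiles(config: GeneratorConfig,
                          rng: np.random.Generator) -> list[SubjectProfile]:
    """Draw latent traits; by construction corr(M, d) > 0 and corr(f, c) < 0
    in expectation when the coupling coefficients are positive."""
    beta0, beta1 = config.intercept_coeffs
    gamma0, gamma1 = config.slope_coeffs
    sd_d = config.subject_noise_sds.get("intercept", 0.0)
    sd_c = config.subject_noise_sds.get("slope", 0.0)
    grid = config.max_energy_grid()

    profiles = []
    for i in range(config.n_subjects):
        scale = rng.uniform(*config.magnitude_scale_range)
        mags = {b: m * scale for b, m in config.band_magnitude_means.items()}
        f_s = rng.uniform(ALPHA2_BAND[0], ALPHA2_BAND[1])
        overall = float(np.sqrt(sum(v ** 2 for v in mags.values())))
        d_s = beta0 + beta1 * overall + rng.normal(0.0, sd_d)
        c_s = 0.0
        for _ in range(100):
            c_s = gamma0 - gamma1 * (f_s - 12.0) + rng.normal(0.0, sd_c)
            if c_s > 0:
                break
        else:
            raise ConfigurationError(
                "could not draw a positive slope in 100 attempts; "
                "check slope_coeffs / subject_noise_sds")
        profiles.append(SubjectProfile(
            subject_id=f"S{i:03d}",
            magnitude_scale=mags,
            alpha2_center_freq=float(f_s),
            true_slope=float(c_s),
            true_intercept=float(d_s),
            max_energy=float(rng.choice(grid)),
        ))
    return profiles


def generate_schedule(profile: SubjectProfile, config: GeneratorConfig,
                      rng: np.random.Generator) -> StimulusSchedule:
    """Pseudorandomized energy order, ISIs i.i.d. uniform on isi_range."""
    n_levels = int(round((profile.max_energy - config.energy_min)
                         / config.energy_step)) + 1
    if n_levels < 2:
        raise ConfigurationError("schedule needs at least 2 energy levels")
    levels = config.energy_min + config.energy_step * np.arange(n_levels)
    energies = rng.permutation(np.repeat(levels, config.pulses_per_level))
    isis = rng.uniform(*config.isi_range, size=len(energies) - 1)
    onsets = config.first_onset + np.concatenate([[0.0], np.cumsum(isis)])
    return StimulusSchedule(onsets=onsets, energies=energies,
                            level_count=n_levels)


def rating_from_energy(energy: float | np.ndarray, profile: SubjectProfile,
                       config: GeneratorConfig,
                       rng: np.random.Generator | None = None) -> np.ndarray:
    """Affine energy->NRS map calibrated to energy_min -> 1 and max_energy -> 8,
    plus optional noise, rounded and clipped to the 0-10 scale."""
    energy = np.asarray(energy, dtype=float)
    base = 1.0 + 7.0 * (energy - config.energy_min) / (
        profile.max_energy - config.energy_min)
    if rng is not None and config.rating_noise_sd > 0:
        base = base + rng.normal(0.0, config.rating_noise_sd, size=energy.shape)
    return np.clip(np.rint(base), 0, 10).astype(int)


def lep_template(times_s: np.ndarray) -> np.ndarray:
    """Unit biphasic vertex waveform: negative extremum near 200 ms, positive
    near 350 ms, zero outside [0, 800] ms, peak-to-peak exactly 1 on the
    evaluated samples."""
    t = np.asarray(times_s, dtype=float)
    neg = np.exp(-0.5 * ((t - 0.20) / 0.030) ** 2)
    pos = np.exp(-0.5 * ((t - 0.35) / 0.055) ** 2)
    w = 1.1 * pos - 1.0 * neg
    w = np.where((t >= 0.0) & (t <= 0.8), w, 0.0)
    ptp = w.max() - w.min()
    if ptp > 0:
        w = w / ptp
    return w


def _background(n: int, fs: float, magnitudes: dict, alpha2_center: float,
                rng: np.random.Generator) -> np.ndarray:
    """Sum over bands of band-limited Gaussian noise, synthesized in the
    frequency domain (one inverse FFT per channel); each band's RMS is scaled
    exactly to its target, and the alpha-2 component is a 1-Hz-wide narrowband
    process centered on the subject's alpha-2 trait frequency."""
    from scipy.fft import irfft, next_fast_len
    nfft = next_fast_len(n, real=True)
    freqs = np.fft.rfftfreq(nfft, 1.0 / fs)
    coef = rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs))
    out = np.zeros(len(freqs), dtype=complex)
    for band, target in magnitudes.items():
        if target <= 0:
            continue
        if band == "alpha-2":
            low, high = alpha2_center - 0.5, alpha2_center + 0.5
        else:
            low, high = BANDS[band]
        mask = (freqs >= low) & (freqs < high)
        power = np.sum(np.abs(coef[mask]) ** 2)
        if power == 0:
            continue
        # Parseval: rms(irfft(C)) = sqrt(2 * sum|C_k|^2) / n for interior bins
        out[mask] = coef[mask] * (target * nfft / np.sqrt(2.0 * power))
    return irfft(out, nfft)[:n]


def synthesize_recording(profile: SubjectProfile, schedule: StimulusSchedule,
                         config: GeneratorConfig, rng: np.random.Generator
                         ) -> tuple[Recording, pd.DataFrame]:
    """Background oscillations on every channel plus rating-scaled evoked
    responses on the designated channel; returns the recording and the
    per-trial event table."""
    fs = config.sampling_rate
    duration = schedule.onsets[-1] + 2.0
    n = int(round(duration * fs))

    ratings = np.array([
        int(rating_from_energy(e, profile, config, rng)) for e in schedule.energies
    ])

    data = np.zeros((n, len(config.channels)))
    if any(v > 0 for v in profile.magnitude_scale.values()):
        for ch in range(len(config.channels)):
            data[:, ch] = _background(n, fs, profile.magnitude_scale,
                                      profile.alpha2_center_freq, rng)

    lep_idx = config.channels.index(config.lep_channel)
    template_times = np.arange(int(round(0.8 * fs))) / fs
    template = lep_template(template_times)
    for onset, rating in zip(schedule.onsets, ratings):
        if rating <= 4:
            continue  # low-pain trials carry no evoked deflection
        target = -1.0
        for _ in range(20):
            target = (profile.true_slope * rating + profile.true_intercept
                      + rng.normal(0.0, config.trial_noise_sd))
            if target > 0:
                break
        if target <= 0:
            raise ConfigurationError(
                f"could not draw a positive evoked amplitude for rating {rating}")
        i0 = int(np.floor(onset * fs))
        data[i0:i0 + len(template), lep_idx] += template * target

    events = pd.DataFrame({
        "trial_index": np.arange(len(schedule.onsets)),
        "onset_s": schedule.onsets,
        "energy_J": schedule.energies,
        "rating": ratings,
    })
    recording = Recording(
        data=data, sampling_rate=fs, channel_labels=list(config.channels),
        metadata={"subject_id": profile.subject_id, "seed": config.seed,
                  "true_slope": profile.true_slope,
                  "true_intercept": profile.true_intercept},
    )
    return recording, events


def generate_subject(profile: SubjectProfile, config: GeneratorConfig,
                     rng: np.random.Generator
                     ) -> tuple[Recording, pd.DataFrame]:
    schedule = generate_schedule(profile, config, rng)
    return synthesize_recording(profile, schedule, config, rng)
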