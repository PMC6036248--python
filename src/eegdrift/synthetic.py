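"""Synthetic multi-day, multi-subject EEG generator.

Features follow a log-linear band-power model: for epoch *e* of class *l* on
day *d*, channel *c*, band *b*,

    log10 power = baseline[c, b] + class_effect[l, c, b]
                  + day_effect[d, c, b] + drift(e) + noise

with the day effect drawn ``Normal(0, day_effect_sd^2)`` once per generated
study (or fixed, for regression tests), i.i.d. Gaussian per-epoch noise, and
an optional slow linear within-day drift.  Class effects are nonzero only on
a sparse informative set and sum to zero over classes, so marginal class
priors carry no signal.

The signal-level generator realises the same target powers as band-limited
Gaussian noise (white noise masked in the frequency domain, which confines
power exactly to each band), so the feature-extraction path can be exercised
end to end on raw epochs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from eegdrift.features import BandScheme, EpochArray, feature_names
from eegdrift.protocols import SubjectStudy

DEFAULT_CLASSES = ("positive", "neutral", "negative")


@dataclass(frozen=True)
class SyntheticModel:
    """Parameters of the multi-day band-power generator.

    ``baseline`` has shape ``(n_channels, n_bands)``; ``class_effect`` has
    shape ``(n_classes, n_channels, n_bands)`` and must average to zero over
    classes.  ``epochs_per_day_per_class`` gives, per day, how many epochs
    of *each* class to generate (days may differ).  ``day_effect`` pins the
    per-day offsets for regression tests; when ``None`` they are drawn
    ``Normal(0, day_effect_sd^2)`` afresh for every generated study.
    """

    baseline: np.ndarray
    class_effect: np.ndarray
    epochs_per_day_per_class: tuple[int, ...] = (20, 20, 20, 20, 20)
    classes: tuple[str, ...] = DEFAULT_CLASSES
    n_days: int = 5
    fs: float = 500.0
    epoch_seconds: float = 5.0
    bands: BandScheme = field(default_factory=BandScheme)
    day_effect_sd: float = 0.0
    day_effect: np.ndarray | None = None
    noise_sd: float = 0.1
    within_day_drift_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        baseline = np.asarray(self.baseline, dtype=float)
        gamma = np.asarray(self.class_effect, dtype=float)
        object.__setattr__(self, "baseline", baseline)
        object.__setattr__(self, "class_effect", gamma)
        object.__setattr__(
            self, "epochs_per_day_per_class", tuple(int(m) for m in self.epochs_per_day_per_class)
        )
        if baseline.ndim != 2:
            raise ValueError("baseline must be (n_channels, n_bands)")
        n_ch, n_b = baseline.shape
        if n_b != len(self.bands):
            raise ValueError(f"baseline has {n_b} bands but the scheme defines {len(self.bands)}")
        if gamma.shape != (len(self.classes), n_ch, n_b):
            raise ValueError(
                f"class_effect must be (n_classes, n_channels, n_bands) = "
                f"({len(self.classes)}, {n_ch}, {n_b}), got {gamma.shape}"
            )
        if len(self.epochs_per_day_per_class) != self.n_days:
            raise ValueError("epochs_per_day_per_class must have one entry per day")
        if any(m < 1 for m in self.epochs_per_day_per_class):
            raise ValueError("epochs per day per class must be >= 1")
        for name, arr in (("baseline", baseline), ("class_effect", gamma)):
            if not np.isfinite(arr).all():
                raise ValueError(f"{name} contains non-finite values")
        for name, v in (
            ("noise_sd", self.noise_sd),
            ("day_effect_sd", self.day_effect_sd),
            ("within_day_drift_sd", self.within_day_drift_sd),
        ):
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative")
        if np.abs(gamma.mean(axis=0)).max() > 1e-9:
            raise ValueError("class effects must average to zero over classes")
        if self.day_effect is not None:
            delta = np.asarray(self.day_effect, dtype=float)
            if delta.shape != (self.n_days, n_ch, n_b):
                raise ValueError("fixed day_effect must be (n_days, n_channels, n_bands)")
            if not np.isfinite(delta).all():
                raise ValueError("day_effect contains non-finite values")
            object.__setattr__(self, "day_effect", delta)
        if self.fs <= 2 * self.bands.max_edge:
            raise ValueError(
                f"fs = {self.fs} Hz must exceed twice the highest band edge "
                f"({self.bands.max_edge} Hz)"
            )

    @property
    def n_channels(self) -> int:
        return self.baseline.shape[0]

    @property
    def n_bands(self) -> int:
        return self.baseline.shape[1]

    @property
    def n_features(self) -> int:
        return self.n_channels * self.n_bands

    @property
    def feature_names(self) -> list[str]:
        return feature_names(self.n_channels, self.bands)


def balanced_class_effect(
    n_classes: int,
    n_channels: int,
    n_bands: int,
    informative: Sequence[tuple[int, int]],
    scale: float,
    diversify: bool = True,
) -> np.ndarray:
    """Zero-mean class-effect tensor, nonzero only on ``informative`` pairs.

    With ``diversify`` (default) the informative pairs cycle through
    orthogonal zero-mean class contrasts (for 3 classes, a linear ramp and a
    quadratic bump, with sign flips), so no single feature separates all
    classes and the informative set is not mutually redundant.  With
    ``diversify=False`` every informative pair carries the same linear ramp.
    """
    ramp = np.linspace(1.0, -1.0, n_classes)
    gamma = np.zeros((n_classes, n_channels, n_bands))
    if diversify and n_classes >= 3:
        bump = np.full(n_classes, -1.0)
        bump[n_classes // 2] = n_classes - 1.0
        bump *= np.linalg.norm(ramp) / np.linalg.norm(bump)
        patterns = [ramp, bump, -ramp, -bump]
    else:
        patterns = [ramp]
    for i, (c, b) in enumerate(informative):
        gamma[:, c, b] = patterns[i % len(patterns)] * scale
    return gamma


def make_model(
    n_channels: int = 60,
    informative: Sequence[tuple[int, int]] = (),
    class_effect_scale: float = 0.5,
    day_effect_sd: float = 0.0,
    noise_sd: float = 0.1,
    epochs_per_day_per_class: Sequence[int] = (20, 20, 20, 20, 20),
    within_day_drift_sd: float = 0.0,
    seed: int = 0,
    bands: BandScheme | None = None,
    fs: float = 500.0,
    epoch_seconds: float = 5.0,
    baseline_by_band: Sequence[float] | None = None,
) -> SyntheticModel:
    """Convenience factory with a band-typical baseline (log10 power per band)."""
    bands = bands or BandScheme()
    n_bands = len(bands)
    if baseline_by_band is None:
        # typical 1/f-like log10 band-power profile, padded/truncated to n_bands
        profile = [1.5, 1.2, 1.0, 0.7, 0.3, 0.0]
        baseline_by_band = (profile * ((n_bands // 6) + 1))[:n_bands]
    baseline = np.tile(np.asarray(baseline_by_band, dtype=float), (n_channels, 1))
    gamma = balanced_class_effect(3, n_channels, n_bands, informative, class_effect_scale)
    return SyntheticModel(
        baseline=baseline,
        class_effect=gamma,
        epochs_per_day_per_class=tuple(epochs_per_day_per_class),
        day_effect_sd=day_effect_sd,
        noise_sd=noise_sd,
        within_day_drift_sd=within_day_drift_sd,
        seed=seed,
        bands=bands,
        fs=fs,
        epoch_seconds=epoch_seconds,
    )


def _subject_key(subject_id: object) -> int:
    return zlib.crc32(str(subject_id).encode("utf-8"))


def _study_streams(model: SyntheticModel, subject_id: object):
    """Deterministic per-subject random streams, shared by both generators."""
    ss = np.random.SeedSequence([model.seed & 0xFFFFFFFF, _subject_key(subject_id)])
    day_ss, drift_ss, noise_ss, signal_ss = ss.spawn(4)
    return (
        np.random.default_rng(day_ss),
        np.random.default_rng(drift_ss),
        np.random.default_rng(noise_ss),
        np.random.default_rng(signal_ss),
    )


def _draw_day_effect(model: SyntheticModel, rng: np.random.Generator) -> np.ndarray:
    if model.day_effect is not None:
        return model.day_effect
    return rng.normal(0.0, model.day_effect_sd, (model.n_days, model.n_channels, model.n_bands))


def _log_power_table(model: SyntheticModel, subject_id: object, noise_rng, delta, drift_slopes):
    """Per-day arrays of (log10 power, class label) in within-day temporal order."""
    n_cls = len(model.classes)
    days = {}
    for d in range(model.n_days):
        m = model.epochs_per_day_per_class[d]
        n_rows = m * n_cls
        logp = np.empty((n_rows, model.n_channels, model.n_bands))
        labels = []
        pos = 0
        for li, cls in enumerate(model.classes):
            for _ in range(m):
                drift = drift_slopes[d] * ((pos / max(n_rows - 1, 1)) - 0.5)
                eps = noise_rng.normal(0.0, model.noise_sd, (model.n_channels, model.n_bands))
                logp[pos] = model.baseline + model.class_effect[li] + delta[d] + drift + eps
                labels.append(cls)
                pos += 1
        days[d + 1] = (logp, labels)
    return days


def generate_feature_study(model: SyntheticModel, subject_id: object = 0) -> SubjectStudy:
    """Generate one subject's multi-day feature study directly at feature level.

    Band powers are returned on the linear scale (``10 ** log10power``).
    Regeneration with the same model seed and subject id is bit-identical.
    """
    day_rng, drift_rng, noise_rng, _ = _study_streams(model, subject_id)
    delta = _draw_day_effect(model, day_rng)
    slopes = drift_rng.normal(
        0.0, model.within_day_drift_sd, (model.n_days, model.n_channels, model.n_bands)
    )
    cols = model.feature_names
    tables = {}
    for day, (logp, labels) in _log_power_table(model, subject_id, noise_rng, delta, slopes).items():
        meta = pd.DataFrame({"subject": subject_id, "day": day, "class": labels})
        values = pd.DataFrame(10.0 ** logp.reshape(len(labels), -1), columns=cols)
        tables[day] = pd.concat([meta, values], axis=1)
    return SubjectStudy(tables, subject=subject_id)


def band_limited_noise(
    rng: np.random.Generator,
    n_samples: int,
    fs: float,
    f_low: float,
    f_high: float,
    power: float,
) -> np.ndarray:
    """Gaussian noise confined to ``[f_low, f_high)`` with expected band power ``power``.

    White noise is masked in the frequency domain (exact band confinement)
    and scaled so the expected variance — hence the expected integrated
    spectral power — equals the target.
    """
    if f_high > fs / 2:
        raise ValueError(f"band edge {f_high} Hz is above Nyquist ({fs / 2} Hz)")
    if power < 0:
        raise ValueError("band power must be non-negative")
    if power == 0:
        return np.zeros(n_samples)
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    mask = (freqs >= f_low) & (freqs < f_high)
    if not mask.any():
        raise ValueError(f"band [{f_low}, {f_high}) Hz contains no DFT bins")
    spectrum = np.fft.rfft(rng.standard_normal(n_samples))
    spectrum[~mask] = 0.0
    x = np.fft.irfft(spectrum, n_samples)
    # expected variance of the masked reconstruction: each interior one-sided
    # bin contributes 2/n of the white-noise unit variance, DC/Nyquist 1/n
    weights = np.full(mask.sum(), 2.0)
    edge = (freqs[mask] == 0) | np.isclose(freqs[mask], fs / 2)
    weights[edge] = 1.0
    expected_var = weights.sum() / n_samples
    return x * np.sqrt(power / expected_var)


def synthesize_epoch(
    rng: np.random.Generator,
    target_powers: np.ndarray,
    fs: float,
    n_samples: int,
    bands: BandScheme,
) -> np.ndarray:
    """Multichannel epoch whose expected band powers match ``target_powers``.

    ``target_powers`` has shape ``(n_channels, n_bands)``; each channel is an
    independent sum of band-limited noise components.
    """
    target_powers = np.asarray(target_powers, dtype=float)
    n_channels = target_powers.shape[0]
    data = np.zeros((n_channels, n_samples))
    for c in range(n_channels):
        for j, band in enumerate(bands):
            data[c] += band_limited_noise(
                rng, n_samples, fs, band.f_low, band.f_high, target_powers[c, j]
            )
    return data


def generate_signal_study(
    model: SyntheticModel,
    subject_id: object = 0,
    include_reference_channels: bool = False,
    common_mode_sd: float = 1.0,
) -> list[EpochArray]:
    """Generate raw signal epochs realising the same log-linear power model.

    Target band powers per epoch are drawn exactly as in
    :func:`generate_feature_study` (shared day-effect stream, so the two
    paths agree in expectation); each epoch is then synthesised as
    band-limited Gaussian noise.  With ``include_reference_channels`` two
    mastoid channels (``M1``, ``M2``) carrying a shared common-mode signal —
    also added to every data channel — are appended, so re-referencing can
    be exercised.
    """
    day_rng, drift_rng, noise_rng, signal_rng = _study_streams(model, subject_id)
    delta = _draw_day_effect(model, day_rng)
    slopes = drift_rng.normal(
        0.0, model.within_day_drift_sd, (model.n_days, model.n_channels, model.n_bands)
    )
    n_samples = int(round(model.fs * model.epoch_seconds))
    ch_names = tuple(f"CH{c + 1}" for c in range(model.n_channels))
    epochs = []
    for day, (logp, labels) in _log_power_table(model, subject_id, noise_rng, delta, slopes).items():
        for row, cls in enumerate(labels):
            data = synthesize_epoch(signal_rng, 10.0 ** logp[row], model.fs, n_samples, model.bands)
            names = ch_names
            if include_reference_channels:
                common = common_mode_sd * signal_rng.standard_normal(n_samples)
                data = np.vstack([data + common, common, common])
                names = ch_names + ("M1", "M2")
            epochs.append(
                EpochArray(
                    data=data,
                    fs=model.fs,
                    channel_names=names,
                    metadata={"subject": subject_id, "day": day, "class": cls},
                )
            )
    return epochs


__all__ = [
    "DEFAULT_CLASSES",
    "SyntheticModel",
    "balanced_class_effect",
    "band_limited_noise",
    "generate_feature_study",
    "generate_signal_study",
    "make_model",
    "synthesize_epoch",
]
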