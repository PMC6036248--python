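"""Band-power feature extraction from multichannel EEG epochs.

Epochs are turned into per-channel, per-band spectral power features using
Welch's averaged-periodogram method (Hamming-tapered 500 ms segments, 50 %
overlap by default).  Band power is the integral of the spectral density
over each band's half-open ``[f_low, f_high)`` interval, so the six
canonical bands tile ``[0.5, 100)`` Hz and their sum approximates the total
spectral power.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

#: Metadata columns carried by every feature table, in this order.
METADATA_COLUMNS = ("subject", "day", "class")


class Band(NamedTuple):
    """A named frequency band with half-open edges ``[f_low, f_high)`` in Hz."""

    name: str
    f_low: float
    f_high: float


#: The six canonical bands used throughout the pipeline.
DEFAULT_BANDS: tuple[Band, ...] = (
    Band("delta", 0.5, 4.0),
    Band("theta", 4.0, 8.0),
    Band("alpha", 8.0, 13.0),
    Band("beta", 13.0, 30.0),
    Band("low_gamma", 30.0, 44.0),
    Band("high_gamma", 44.0, 100.0),
)


@dataclass(frozen=True)
class BandScheme:
    """An ordered collection of frequency bands.

    Parameters
    ----------
    bands
        Bands ordered by ``f_low``; each band must have ``f_low < f_high``.
    """

    bands: tuple[Band, ...] = DEFAULT_BANDS

    def __post_init__(self) -> None:
        bands = tuple(Band(*b) for b in self.bands)
        object.__setattr__(self, "bands", bands)
        if not bands:
            raise ValueError("band scheme must contain at least one band")
        for b in bands:
            if not b.f_low < b.f_high:
                raise ValueError(f"band {b.name!r}: edges must be strictly increasing")
        lows = [b.f_low for b in bands]
        if lows != sorted(lows):
            raise ValueError("bands must be ordered by f_low")

    def __len__(self) -> int:
        return len(self.bands)

    def __iter__(self):
        return iter(self.bands)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(b.name for b in self.bands)

    @property
    def max_edge(self) -> float:
        return max(b.f_high for b in self.bands)

    def check_nyquist(self, fs: float) -> None:
        if self.max_edge > fs / 2:
            raise ValueError(
                f"band edge {self.max_edge} Hz exceeds Nyquist frequency {fs / 2} Hz"
            )


@dataclass(frozen=True)
class WelchConfig:
    """Welch spectral-estimation settings.

    Defaults: 500 ms Hamming segments at 50 % overlap, mean-detrended.
    """

    window_seconds: float = 0.5
    overlap_fraction: float = 0.5
    taper: str = "hamming"

    def __post_init__(self) -> None:
        if self.window_seconds <= 0:
            raise ValueError("window_seconds must be positive")
        if not 0 <= self.overlap_fraction < 1:
            raise ValueError("overlap_fraction must be in [0, 1)")

    def nperseg(self, fs: float) -> int:
        return int(round(self.window_seconds * fs))

    def noverlap(self, fs: float) -> int:
        return int(round(self.nperseg(fs) * self.overlap_fraction))


@dataclass
class EpochArray:
    """One multichannel epoch: ``channels x time-samples`` at a sampling rate.

    ``metadata`` carries at least ``subject``, ``day`` and ``class``.
    """

    data: np.ndarray
    fs: float
    channel_names: tuple[str, ...]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.channel_names = tuple(self.channel_names)
        if self.data.ndim != 2:
            raise ValueError("epoch data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError(
                f"{self.data.shape[0]} data rows but {len(self.channel_names)} channel names"
            )
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


def feature_names(n_channels: int, bands: BandScheme | None = None) -> list[str]:
    """Channel-major feature column names: ``CH{i}_{band}``, 1-based channels."""
    bands = bands or BandScheme()
    return [f"CH{c + 1}_{b.name}" for c in range(n_channels) for b in bands]


def rereference(epoch: EpochArray, reference_channels: Sequence[str]) -> EpochArray:
    """Subtract the mean of the reference channels from every other channel.

    The reference channels are dropped from the output.
    """
    if not reference_channels:
        raise ValueError("at least one reference channel is required")
    missing = [c for c in reference_channels if c not in epoch.channel_names]
    if missing:
        raise ValueError(f"unknown reference channel(s): {missing}")
    ref_set = set(reference_channels)
    ref_idx = [i for i, c in enumerate(epoch.channel_names) if c in ref_set]
    keep_idx = [i for i, c in enumerate(epoch.channel_names) if c not in ref_set]
    if not keep_idx:
        raise ValueError("re-referencing would drop every channel")
    ref_mean = epoch.data[ref_idx].mean(axis=0)
    return EpochArray(
        data=epoch.data[keep_idx] - ref_mean,
        fs=epoch.fs,
        channel_names=tuple(epoch.channel_names[i] for i in keep_idx),
        metadata=dict(epoch.metadata),
    )


def decimate(epoch: EpochArray, target_fs: float) -> EpochArray:
    """Anti-alias filter and down-sample an epoch to ``target_fs``.

    ``target_fs`` must divide the epoch's sampling rate exactly.
    """
    if target_fs <= 0:
        raise ValueError("target sampling rate must be positive")
    ratio = epoch.fs / target_fs
    factor = int(round(ratio))
    if abs(ratio - factor) > 1e-9:
        raise ValueError(
            f"target_fs {target_fs} must divide fs {epoch.fs} (ratio {ratio} is not an integer)"
        )
    if factor == 1:
        return EpochArray(epoch.data.copy(), epoch.fs, epoch.channel_names, dict(epoch.metadata))
    # zero-phase FIR keeps passband amplitude and alignment intact
    data = sps.decimate(epoch.data, factor, axis=1, ftype="fir", zero_phase=True)
    return EpochArray(data, target_fs, epoch.channel_names, dict(epoch.metadata))


def welch_band_powers(
    epoch: EpochArray,
    cfg: WelchConfig | None = None,
    bands: BandScheme | None = None,
) -> np.ndarray:
    """Per-channel, per-band Welch band powers, shape ``(n_channels, n_bands)``.

    Spectral density is estimated with Welch's method and integrated
    (density times bin width, summed) over each band's half-open interval,
    left edge inclusive.
    """
    cfg = cfg or WelchConfig()
    bands = bands or BandScheme()
    bands.check_nyquist(epoch.fs)
    nperseg = cfg.nperseg(epoch.fs)
    if nperseg > epoch.n_samples:
        raise ValueError(
            f"Welch window ({nperseg} samples) exceeds epoch length ({epoch.n_samples})"
        )
    freqs, psd = sps.welch(
        epoch.data,
        fs=epoch.fs,
        window=cfg.taper,
        nperseg=nperseg,
        noverlap=cfg.noverlap(epoch.fs),
        detrend="constant",
        scaling="density",
        axis=1,
    )
    df = freqs[1] - freqs[0]
    out = np.empty((epoch.n_channels, len(bands)))
    for j, band in enumerate(bands):
        mask = (freqs >= band.f_low) & (freqs < band.f_high)
        out[:, j] = psd[:, mask].sum(axis=1) * df
    return out


def total_power(epoch: EpochArray, cfg: WelchConfig | None = None) -> np.ndarray:
    """Per-channel total Welch spectral power (integral over the full spectrum)."""
    cfg = cfg or WelchConfig()
    freqs, psd = sps.welch(
        epoch.data,
        fs=epoch.fs,
        window=cfg.taper,
        nperseg=cfg.nperseg(epoch.fs),
        noverlap=cfg.noverlap(epoch.fs),
        detrend="constant",
        scaling="density",
        axis=1,
    )
    return psd.sum(axis=1) * (freqs[1] - freqs[0])


def extract_features(
    epochs: Iterable[EpochArray],
    cfg: WelchConfig | None = None,
    bands: BandScheme | None = None,
) -> pd.DataFrame:
    """Build a feature table: one row per epoch, channel-major band-power columns.

    All epochs must share a common channel set; channel order is normalised
    to the first epoch's order before extraction, so tables are invariant to
    input channel permutations.
    """
    cfg = cfg or WelchConfig()
    bands = bands or BandScheme()
    epochs = list(epochs)
    if not epochs:
        raise ValueError("no epochs supplied")
    canonical = epochs[0].channel_names
    canonical_set = set(canonical)
    rows = []
    meta_rows = []
    for ep in epochs:
        if set(ep.channel_names) != canonical_set:
            raise ValueError(
                f"inconsistent channel names: expected {sorted(canonical_set)}, "
                f"got {sorted(ep.channel_names)}"
            )
        if ep.channel_names != canonical:
            order = [ep.channel_names.index(c) for c in canonical]
            ep = EpochArray(ep.data[order], ep.fs, canonical, dict(ep.metadata))
        rows.append(welch_band_powers(ep, cfg, bands).ravel())
        meta_rows.append({k: ep.metadata.get(k) for k in METADATA_COLUMNS})
    cols = feature_names(len(canonical), bands)
    return pd.concat(
        [pd.DataFrame(meta_rows), pd.DataFrame(np.asarray(rows), columns=cols)], axis=1
    )


#: Bookkeeping columns that are never features (row identity, temporal order).
AUXILIARY_COLUMNS = ("row_id", "epoch")


def feature_columns(table: pd.DataFrame) -> list[str]:
    """The feature columns of a table (everything except metadata/bookkeeping)."""
    non_features = set(METADATA_COLUMNS) | set(AUXILIARY_COLUMNS)
    return [c for c in table.columns if c not in non_features]


def passthrough_artifact_removal(epoch: EpochArray) -> EpochArray:
    """Artifact-removal hook; the default implementation is a no-op."""
    return epoch


__all__ = [
    "Band",
    "BandScheme",
    "DEFAULT_BANDS",
    "EpochArray",
    "METADATA_COLUMNS",
    "WelchConfig",
    "decimate",
    "extract_features",
    "feature_columns",
    "feature_names",
    "passthrough_artifact_removal",
    "rereference",
    "total_power",
    "welch_band_powers",
]
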