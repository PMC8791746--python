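"""Spectral feature extraction at 1 Hz resolution.

One instance's feature vector is the concatenation, over the selected
scalp channels, of its max-normalized magnitude spectrum resampled onto
an integer-frequency grid.  The 1 Hz resampling decouples the feature
length from sampling rate and window duration, and the per-channel max
normalization makes features invariant to overall signal gain — both
chosen so the classifier sees spectral *shape*, not amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .preprocess import InstanceSegment
from .synthetic import REFERENCE_CHANNELS, SCALP_CHANNELS_1020

__all__ = [
    "FeatureConfig",
    "FeatureVector",
    "FeatureStore",
    "select_channels",
    "select_time_window",
    "magnitude_spectrum",
    "resample_to_1hz",
    "normalize_and_band_select",
    "build_feature_vector",
    "featurize_segments",
]

#: Highest integer frequency with valid content after the 32 Hz LPF.
MAX_FREQ_HZ = 32


@dataclass(frozen=True)
class FeatureConfig:
    """Feature-extraction parameters.

    ``t_w_s`` skips the cue + rest portion at the head of each instance
    (must cover excitation + rest time); ``t_s_s`` is the analysed
    duration.  ``freq_lo_hz``..``freq_hi_hz`` is the retained integer
    band; with ``exclude_dc`` the 0 Hz value is dropped even if
    ``freq_lo_hz`` is 0.  A1/A2 are reference electrodes, not scalp EEG,
    and are rejected from ``channels`` unless
    ``allow_reference_channels`` is set.
    """

    channels: tuple[str, ...] = SCALP_CHANNELS_1020
    t_w_s: float = 1.0
    t_s_s: float = 2.5
    freq_lo_hz: int = 1
    freq_hi_hz: int = 31
    exclude_dc: bool = True
    resample_method: str = "mean"
    allow_reference_channels: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.freq_lo_hz <= self.freq_hi_hz <= MAX_FREQ_HZ:
            raise ValueError(
                f"need 0 <= freq_lo <= freq_hi <= {MAX_FREQ_HZ}, got "
                f"[{self.freq_lo_hz}, {self.freq_hi_hz}]")
        if self.t_w_s < 0 or self.t_s_s <= 0:
            raise ValueError("t_w_s must be >= 0 and t_s_s > 0")
        if self.resample_method not in ("mean", "interp"):
            raise ValueError("resample_method must be 'mean' or 'interp'")
        if not self.allow_reference_channels:
            bad = [c for c in self.channels if c in REFERENCE_CHANNELS]
            if bad:
                raise ValueError(
                    f"reference channels {bad} are not scalp EEG; set "
                    "allow_reference_channels=True to use them anyway")

    @property
    def retained_freqs(self) -> np.ndarray:
        """Integer frequencies kept in each channel block."""
        lo = self.freq_lo_hz
        if self.exclude_dc and lo == 0:
            lo = 1
        return np.arange(lo, self.freq_hi_hz + 1)

    @property
    def n_freqs(self) -> int:
        return len(self.retained_freqs)


@dataclass(frozen=True)
class FeatureVector:
    """One instance's features: Lf = n_channels * n_freqs values in [0,1]."""

    values: np.ndarray
    class_code: int
    subject_id: int
    record_id: int
    n_channels: int
    n_freqs: int

    def __post_init__(self) -> None:
        if self.values.shape != (self.n_channels * self.n_freqs,):
            raise ValueError("feature length must equal n_channels * n_freqs")


@dataclass
class FeatureStore:
    """Columnar feature database for one or more subjects.

    ``X`` is [n_instances x Lf]; ``word``, ``record`` and ``subject``
    are parallel label arrays (single-digit word code, part number,
    subject id).
    """

    X: np.ndarray
    word: np.ndarray
    record: np.ndarray
    subject: np.ndarray
    feature_names: tuple[str, ...] = field(default=())

    def __len__(self) -> int:
        return self.X.shape[0]

    def select(self, word: int | None = None, record: int | None = None,
               subject: int | None = None) -> np.ndarray:
        """Boolean mask of instances matching the given labels."""
        mask = np.ones(len(self), dtype=bool)
        if word is not None:
            mask &= self.word == word
        if record is not None:
            mask &= self.record == record
        if subject is not None:
            mask &= self.subject == subject
        return mask


def select_channels(segment: InstanceSegment, channels: Sequence[str]
                    ) -> InstanceSegment:
    """Reduce a segment to the requested channels, in the given order."""
    unknown = [c for c in channels if c not in segment.channel_names]
    if unknown:
        raise ValueError(f"unknown channel name(s) {unknown}; "
                         f"segment has {segment.channel_names}")
    rows = [segment.channel_names.index(c) for c in channels]
    from dataclasses import replace
    return replace(segment, data=segment.data[rows],
                   channel_names=tuple(channels))


def select_time_window(data: np.ndarray, fs_hz: float, t_w_s: float,
                       t_s_s: float) -> np.ndarray:
    """Samples of the processed interval: t_s seconds starting at t_w."""
    start = int(round(t_w_s * fs_hz))
    n = int(round(t_s_s * fs_hz))
    if n < 2:
        raise ValueError("window must contain at least 2 samples")
    if start + n > data.shape[-1]:
        raise ValueError(
            f"window [{t_w_s}, {t_w_s + t_s_s}] s exceeds the "
            f"{data.shape[-1] / fs_hz:.3g} s segment")
    return data[..., start:start + n]


def magnitude_spectrum(window: np.ndarray, fs_hz: float
                       ) -> tuple[np.ndarray, np.ndarray]:
    """One-sided FFT magnitude along the last axis.

    Native frequency resolution is 1/t_s Hz (0.4 Hz for the default
    2.5 s window).  No taper is applied: instances are cut well inside
    the epoch, so a rectangular window suffices.
    """
    window = np.asarray(window, dtype=float)
    n = window.shape[-1]
    if n < 2:
        raise ValueError("need at least 2 samples")
    mags = np.abs(np.fft.rfft(window, axis=-1))
    freqs = np.fft.rfftfreq(n, 1.0 / fs_hz)
    return freqs, mags


def resample_to_1hz(freqs: np.ndarray, mags: np.ndarray,
                    method: str = "mean") -> np.ndarray:
    """Resample a native-resolution spectrum onto integers 0..32 Hz.

    ``mean`` averages the native magnitudes whose bin centers fall in
    [f - 0.5, f + 0.5) for each integer f — robust to spectral leakage;
    ``interp`` evaluates by linear interpolation instead.  Values above
    32 Hz are discarded (nothing valid survives the 32 Hz LPF).
    """
    freqs = np.asarray(freqs, dtype=float)
    mags = np.asarray(mags, dtype=float)
    if len(freqs) > 1:
        res = freqs[1] - freqs[0]
        if res > 1.0 + 1e-9:
            raise ValueError(
                f"native resolution {res:.3g} Hz is coarser than 1 Hz; "
                "lengthen the analysis window")
    grid = np.arange(MAX_FREQ_HZ + 1)
    if method == "interp":
        flat = mags.reshape(-1, mags.shape[-1])
        out = np.stack([np.interp(grid, freqs, row) for row in flat])
        return out.reshape(*mags.shape[:-1], len(grid))
    if method != "mean":
        raise ValueError("method must be 'mean' or 'interp'")
    out = np.zeros((*mags.shape[:-1], len(grid)))
    for f in grid:
        sel = (freqs >= f - 0.5) & (freqs < f + 0.5)
        if sel.any():
            out[..., f] = mags[..., sel].mean(axis=-1)
    return out


def normalize_and_band_select(values: np.ndarray, cfg: FeatureConfig
                              ) -> np.ndarray:
    """Per-channel max normalization, then band selection.

    ``values`` holds the 0..32 Hz grid along the last axis.  Each channel
    is divided by its own maximum (an all-zero channel passes through
    unchanged), then the DC value is dropped and the configured integer
    band retained, leaving ``cfg.n_freqs`` values per channel in [0, 1].
    """
    values = np.asarray(values, dtype=float)
    peak = values.max(axis=-1, keepdims=True)
    safe = np.where(peak > 0, peak, 1.0)
    normed = values / safe
    return normed[..., cfg.retained_freqs]


def build_feature_vector(segment: InstanceSegment,
                         cfg: FeatureConfig = FeatureConfig()) -> FeatureVector:
    """Full per-instance chain: channels -> window -> FFT -> 1 Hz -> band.

    Channel blocks are concatenated in config order; the result has
    Lf = n_channels * n_freqs values, every one in [0, 1].
    """
    reduced = select_channels(segment, cfg.channels)
    window = select_time_window(reduced.data, reduced.fs_hz,
                                cfg.t_w_s, cfg.t_s_s)
    freqs, mags = magnitude_spectrum(window, reduced.fs_hz)
    grid = resample_to_1hz(freqs, mags, cfg.resample_method)
    feats = normalize_and_band_select(grid, cfg)
    return FeatureVector(
        values=feats.reshape(-1),
        class_code=segment.class_code,
        subject_id=segment.subject_id,
        record_id=segment.record_id,
        n_channels=len(cfg.channels),
        n_freqs=cfg.n_freqs,
    )


def feature_names(cfg: FeatureConfig) -> tuple[str, ...]:
    """Column labels like ``Cz_10Hz`` in concatenation order."""
    return tuple(f"{ch}_{f}Hz" for ch in cfg.channels
                 for f in cfg.retained_freqs)


def featurize_segments(segments: Sequence[InstanceSegment],
                       cfg: FeatureConfig = FeatureConfig()) -> FeatureStore:
    """Extract features for a batch of segments into a FeatureStore."""
    if not segments:
        raise ValueError("no segments to featurize")
    vecs = [build_feature_vector(s, cfg) for s in segments]
    return FeatureStore(
        X=np.stack([v.values for v in vecs]),
        word=np.array([v.class_code // 10 for v in vecs]),
        record=np.array([v.record_id for v in vecs]),
        subject=np.array([v.subject_id for v in vecs]),
        feature_names=feature_names(cfg),
    )
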