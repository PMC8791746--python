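"""Preprocessing chain: low-pass filter, block-average downsampling,
sync-driven segmentation, and energy-based artifact rejection.

The order is fixed — filter at the acquisition rate, then downsample,
then cut instances, then reject outliers — because block averaging is
itself a (crude) low-pass stage and swapping the first two steps changes
the aliasing behaviour.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .synthetic import EEGRecord, SYNC_CHANNELS

__all__ = [
    "PreprocessConfig",
    "InstanceSegment",
    "lowpass_filter",
    "block_downsample",
    "segment_record",
    "reject_artifacts",
    "preprocess_record",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PreprocessConfig:
    """Knobs of the preprocessing chain.

    ``lpf_cutoff_hz`` (32 Hz) keeps everything up to low gamma and kills
    50 Hz mains noise; ``downsample_factor`` 5 takes 500 Hz to 100 Hz;
    ``energy_reject_factor`` k flags instances whose mean energy falls
    outside [E/k, E*k] of the batch average; ``target_instance_samples``
    is the exact post-crop/pad segment length (None = Ti * fs_out).
    """

    lpf_cutoff_hz: float = 32.0
    filter_order: int = 4
    downsample_factor: int = 5
    energy_reject_factor: float = 3.0
    target_instance_samples: int | None = None

    def __post_init__(self) -> None:
        if self.downsample_factor < 1:
            raise ValueError("downsample_factor must be >= 1")
        if self.energy_reject_factor <= 1:
            raise ValueError("energy_reject_factor must exceed 1")


@dataclass(frozen=True)
class InstanceSegment:
    """EEG of one word instance, cut from a preprocessed record.

    ``class_code`` is the two-digit code: word digit (1..7) * 10 + part
    number (0..9), e.g. word 4 in part 1 -> 41.  ``data`` is
    [n_eeg_channels x n_samples] at the post-downsample rate.
    """

    class_code: int
    subject_id: int
    record_id: int
    data: np.ndarray
    fs_hz: float
    channel_names: tuple[str, ...]

    @property
    def word_code(self) -> int:
        return self.class_code // 10

    def __post_init__(self) -> None:
        if not 1 <= self.word_code <= 7:
            raise ValueError(f"word digit out of 1..7 in class_code {self.class_code}")
        if not 0 <= self.record_id <= 9:
            raise ValueError(f"record_id must be in 0..9, got {self.record_id}")


def lowpass_filter(x: np.ndarray, fs_hz: float, cutoff_hz: float = 32.0,
                   order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth low-pass along the last axis.

    Applied forward and backward (``sosfiltfilt``) so there is no group
    delay and sync onsets stay aligned with the filtered signal.
    """
    if cutoff_hz >= fs_hz / 2:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz must be below Nyquist {fs_hz / 2} Hz")
    sos = sps.butter(order, cutoff_hz, btype="low", fs=fs_hz, output="sos")
    return sps.sosfiltfilt(sos, x, axis=-1)


def block_downsample(x: np.ndarray, factor: int = 5) -> np.ndarray:
    """Replace every ``factor`` consecutive samples with their average.

    Works along the last axis; trailing samples that do not fill a block
    are dropped, so the output length is floor(n / factor).
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    x = np.asarray(x)
    n_out = x.shape[-1] // factor
    trimmed = x[..., : n_out * factor]
    return trimmed.reshape(*x.shape[:-1], n_out, factor).mean(axis=-1)


def _crop_or_pad(x: np.ndarray, n: int) -> np.ndarray:
    """Crop from the end, or zero-pad at the end, to exactly n samples."""
    if x.shape[-1] >= n:
        return x[..., :n]
    pad = np.zeros((*x.shape[:-1], n - x.shape[-1]), dtype=x.dtype)
    return np.concatenate([x, pad], axis=-1)


def segment_record(record: EEGRecord, cfg: PreprocessConfig = PreprocessConfig()
                   ) -> list[InstanceSegment]:
    """Cut a preprocessed record into per-instance segments via sync data.

    Expects ``record.data`` already filtered and downsampled, with
    ``sync_events`` onsets on the same (downsampled) sample grid.  Each
    segment is cropped or zero-padded to ``target_instance_samples`` and
    labeled word-digit * 10 + part number.
    """
    names = record.channel_names
    eeg_rows = [i for i, c in enumerate(names) if c not in SYNC_CHANNELS]
    eeg_names = tuple(names[i] for i in eeg_rows)
    fs = record.fs_hz
    if cfg.target_instance_samples is not None:
        target = cfg.target_instance_samples
    elif len(record.sync_events) > 1:
        target = record.sync_events[1][1] - record.sync_events[0][1]
    else:
        target = record.n_samples
    segments: list[InstanceSegment] = []
    for word, onset in record.sync_events:
        if onset >= record.n_samples:
            warnings.warn(
                f"sync onset {onset} beyond record end {record.n_samples}; "
                "instance skipped", stacklevel=2)
            continue
        window = record.data[eeg_rows, onset:onset + target]
        segments.append(InstanceSegment(
            class_code=word * 10 + record.record_id,
            subject_id=record.subject_id,
            record_id=record.record_id,
            data=_crop_or_pad(window, target),
            fs_hz=fs,
            channel_names=eeg_names,
        ))
    return segments


def segment_energy(segment: InstanceSegment) -> float:
    """Mean squared sample amplitude, pooled over channels."""
    return float(np.mean(segment.data ** 2))


def reject_artifacts(segments: Sequence[InstanceSegment], k: float = 3.0
                     ) -> tuple[list[InstanceSegment], list[InstanceSegment]]:
    """Partition segments into (kept, rejected) by mean energy.

    A segment is rejected iff its energy falls outside [E/k, E*k], where
    E is the average energy over all input segments — catching both
    high-energy movement artifacts and low-energy dropouts.
    """
    if k <= 1:
        raise ValueError("k must exceed 1")
    if not segments:
        raise ValueError("need at least one segment")
    energies = np.array([segment_energy(s) for s in segments])
    e_bar = float(energies.mean())
    kept: list[InstanceSegment] = []
    rejected: list[InstanceSegment] = []
    for seg, e in zip(segments, energies):
        if e_bar / k <= e <= e_bar * k:
            kept.append(seg)
        else:
            reason = "high" if e > e_bar * k else "low"
            logger.info(
                "rejected instance class=%d record=%d: %s energy %.3g "
                "(batch mean %.3g, k=%.2g)",
                seg.class_code, seg.record_id, reason, e, e_bar, k)
            rejected.append(seg)
    return kept, rejected


def preprocess_record(record: EEGRecord,
                      cfg: PreprocessConfig = PreprocessConfig()
                      ) -> list[InstanceSegment]:
    """Full per-record chain: filter -> downsample -> segment.

    Filters the EEG rows at the acquisition rate, block-averages them
    down, rescales the sync onsets by the downsample factor, and cuts the
    instances.  Artifact rejection is a separate batch step
    (:func:`reject_artifacts`), usually applied across a whole dataset.
    """
    names = record.channel_names
    eeg_rows = [i for i, c in enumerate(names) if c not in SYNC_CHANNELS]
    filtered = lowpass_filter(record.data[eeg_rows], record.fs_hz,
                              cfg.lpf_cutoff_hz, cfg.filter_order)
    down = block_downsample(filtered, cfg.downsample_factor)
    fs_out = record.fs_hz / cfg.downsample_factor
    events = tuple((c, o // cfg.downsample_factor) for c, o in record.sync_events)
    target = cfg.target_instance_samples
    if target is None and len(events) > 1:
        target = events[1][1] - events[0][1]
    from dataclasses import replace
    reduced = replace(
        record,
        data=down,
        fs_hz=fs_out,
        sync_events=events,
        channel_names=tuple(names[i] for i in eeg_rows),
    )
    return segment_record(reduced, PreprocessConfig(
        lpf_cutoff_hz=cfg.lpf_cutoff_hz, filter_order=cfg.filter_order,
        downsample_factor=cfg.downsample_factor,
        energy_reject_factor=cfg.energy_reject_factor,
        target_instance_samples=target))
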