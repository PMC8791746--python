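"""Synthetic imagined-speech EEG acquisition.

Emulates a silent-talk recording campaign: a test-schedule generator (the
role the original stimulus software plays), and a multichannel EEG
synthesizer that plants class-dependent spectral signatures on a 1/f
background, with per-record drift to mimic session-to-session
nonstationarity, plus sync channels that encode instance type and onset.

The default acquisition design is 5 sessions x 2 parts x 3 tests per
subject; each test presents 20 trials of 2 words + Silence at a 4 s
instance time, so one subject yields 30 records, 200 instances per word
and 600 Silence instances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "SCALP_CHANNELS_1020",
    "REFERENCE_CHANNELS",
    "SYNC_CHANNELS",
    "SILENCE_CODE",
    "WORD_NAMES",
    "DEFAULT_WORD_ORDER",
    "AcquisitionConfig",
    "TestSchedule",
    "ClassSignature",
    "EEGRecord",
    "default_signatures",
    "generate_schedule",
    "synthesize_record",
    "generate_subject_dataset",
    "inject_artifact",
    "generate_label_independent_features",
]

#: The 19 scalp electrodes of the international 10-20 montage.
SCALP_CHANNELS_1020: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6", "O1", "O2",
)

#: Earlobe reference electrodes; recorded but never carry class signal.
REFERENCE_CHANNELS: tuple[str, ...] = ("A1", "A2")

#: Names of the two synchronization rows appended to every record.
SYNC_CHANNELS: tuple[str, ...] = ("SyncClass", "SyncOnset")

#: Class code reserved for the rest / idle state.
SILENCE_CODE: int = 7

#: Single-digit class codes for the six command words plus Silence.
WORD_NAMES: dict[int, str] = {
    1: "Up", 2: "Yes", 3: "Left", 4: "No", 5: "Down", 6: "Right",
    7: "Silence",
}

#: Word codes in test order: (Up, Down), (Left, Right), (Yes, No).
#: Consecutive pairs form the word sets of tests T1, T2, T3.
DEFAULT_WORD_ORDER: tuple[int, ...] = (1, 5, 3, 6, 2, 4)


@dataclass(frozen=True)
class AcquisitionConfig:
    """Timing and layout of one recording campaign.

    Attributes
    ----------
    fs_hz : sampling rate of the amplifier in Hz.
    instance_time_s : Ti, seconds allotted to one word instance.
    display_time_s : Td, stimulus display time; metadata only in the
        vocal-stimulation protocol emulated here.
    excitation_time_s : Te, seconds the subject spends hearing the cue.
    rest_time_s : Tr, pause between cue and silent repetition.
    n_classes_per_test : Nc, classes per test (2 words + Silence).
    n_trials : Nt, trials per test; each trial presents every class once.
    n_sessions, n_parts_per_session, n_tests_per_part : campaign layout.
    channel_names : the 21 recorded 10-20 electrodes (19 scalp + A1/A2).
    max_test_time_s : soft cap on a single test's duration; schedules
        exceeding it trigger a warning (subjects tire on long tests).
    """

    fs_hz: float = 500.0
    instance_time_s: float = 4.0
    display_time_s: float = 1.0
    excitation_time_s: float = 0.5
    rest_time_s: float = 0.25
    n_classes_per_test: int = 3
    n_trials: int = 20
    n_sessions: int = 5
    n_parts_per_session: int = 2
    n_tests_per_part: int = 3
    channel_names: tuple[str, ...] = SCALP_CHANNELS_1020 + REFERENCE_CHANNELS
    max_test_time_s: float = 240.0

    def __post_init__(self) -> None:
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if self.instance_time_s <= self.excitation_time_s + self.rest_time_s:
            raise ValueError("instance_time_s must exceed excitation + rest time")
        if self.n_classes_per_test < 2:
            raise ValueError("need at least 2 classes per test")
        if self.n_trials < 1:
            raise ValueError("need at least 1 trial")
        missing = [c for c in REFERENCE_CHANNELS + SCALP_CHANNELS_1020
                   if c not in self.channel_names]
        if missing:
            raise ValueError(f"channel_names missing 10-20 electrodes: {missing}")

    @property
    def samples_per_instance(self) -> int:
        return int(round(self.instance_time_s * self.fs_hz))

    @property
    def n_records(self) -> int:
        return self.n_sessions * self.n_parts_per_session * self.n_tests_per_part


@dataclass(frozen=True)
class TestSchedule:
    """Ordered presentation plan of one test.

    ``entries`` is the flattened trial sequence: ``(class_code,
    onset_sample)`` per instance, onsets strictly increasing at Ti
    spacing.  Every contiguous block of ``len(word_set)`` entries is a
    permutation of ``word_set``.
    """

    entries: tuple[tuple[int, int], ...]
    word_set: tuple[int, ...]

    @property
    def n_instances(self) -> int:
        return len(self.entries)

    @property
    def classes(self) -> np.ndarray:
        return np.array([c for c, _ in self.entries], dtype=int)

    @property
    def onsets(self) -> np.ndarray:
        return np.array([o for _, o in self.entries], dtype=int)


@dataclass(frozen=True)
class ClassSignature:
    """Spectral fingerprint a class imprints on the scalp channels.

    A stand-in for real imagined-speech EEG (which is available only on
    request from the original authors): each class is a set of narrowband
    peaks riding on 1/f^alpha background noise.  ``drift_per_record`` and
    ``freq_drift_hz_per_record`` scale linearly with the record id and
    model slow nonstationarity (electrode placement, subject state); when
    they are shared across the classes of a record they act as a
    record-common shift, which is what makes train/test time separation
    matter downstream.
    """

    class_code: int
    peak_freqs_hz: tuple[float, ...] = ()
    peak_amplitudes: tuple[float, ...] = ()
    background_exponent: float = 1.0
    drift_per_record: float = 0.0
    freq_drift_hz_per_record: float = 0.0

    def __post_init__(self) -> None:
        if len(self.peak_freqs_hz) != len(self.peak_amplitudes):
            raise ValueError("peak_freqs_hz and peak_amplitudes must align")
        if any(not 1.0 <= f <= 31.0 for f in self.peak_freqs_hz):
            raise ValueError("peak frequencies must lie in 1-31 Hz")
        if any(a < 0 for a in self.peak_amplitudes):
            raise ValueError("peak amplitudes must be non-negative")


@dataclass(frozen=True)
class EEGRecord:
    """One continuous test recording.

    ``data`` is [n_channels x n_samples] in microvolts: the 21 EEG rows
    of ``channel_names`` followed by the two sync rows.  ``sync_events``
    lists ``(class_code, onset_sample)`` per instance, mirroring what the
    sync rows encode.
    """

    subject_id: int
    session: int
    part: int
    test_index: int
    data: np.ndarray
    fs_hz: float
    sync_events: tuple[tuple[int, int], ...]
    channel_names: tuple[str, ...]

    @property
    def record_id(self) -> int:
        """Chronological part number 0..9 (2 parts per session)."""
        return self.session * 2 + self.part

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def eeg_channel_names(self) -> tuple[str, ...]:
        return tuple(c for c in self.channel_names if c not in SYNC_CHANNELS)


def as_seed_sequence(seed) -> np.random.SeedSequence:
    """Wrap an int (or None) into a SeedSequence; pass one through."""
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def default_signatures(
    peak_amplitude_uv: float = 2.5,
    drift_per_record: float = 0.05,
    freq_drift_hz_per_record: float = 0.25,
    background_exponent: float = 1.0,
) -> dict[int, ClassSignature]:
    """Default class signatures for the six words plus Silence.

    Words paired within a test sit 2 Hz apart (separable in the 1 Hz
    feature grid but close enough that record drift mixes them when
    records are pooled); Silence carries background only.
    """
    pair_freqs = {1: 10.0, 5: 12.0, 3: 15.0, 6: 17.0, 2: 20.0, 4: 22.0}
    sigs = {
        code: ClassSignature(
            class_code=code,
            peak_freqs_hz=(f,),
            peak_amplitudes=(peak_amplitude_uv,),
            background_exponent=background_exponent,
            drift_per_record=drift_per_record,
            freq_drift_hz_per_record=freq_drift_hz_per_record,
        )
        for code, f in pair_freqs.items()
    }
    sigs[SILENCE_CODE] = ClassSignature(
        class_code=SILENCE_CODE,
        background_exponent=background_exponent,
        drift_per_record=drift_per_record,
        freq_drift_hz_per_record=freq_drift_hz_per_record,
    )
    return sigs


def generate_schedule(
    word_set: Sequence[int],
    n_trials: int,
    ti_s: float = 4.0,
    fs_hz: float = 500.0,
    seed=None,
    max_test_time_s: float = 240.0,
) -> TestSchedule:
    """Draw the pseudorandom presentation order of one test.

    Each trial is an independent uniform permutation of ``word_set``;
    the test concatenates ``n_trials`` trials, so every class appears
    exactly ``n_trials`` times.  Onsets advance by Ti per instance.
    """
    word_set = tuple(int(w) for w in word_set)
    if len(set(word_set)) != len(word_set):
        raise ValueError(f"word_set codes must be distinct, got {word_set}")
    if len(word_set) < 2:
        raise ValueError("need at least 2 classes")
    if n_trials < 1:
        raise ValueError("need at least 1 trial")
    total_s = len(word_set) * n_trials * ti_s
    if total_s > max_test_time_s:
        warnings.warn(
            f"test duration {total_s:.0f} s exceeds the {max_test_time_s:.0f} s "
            "cap; subjects tire on long tests", stacklevel=2)
    rng = np.random.default_rng(seed)
    spi = int(round(ti_s * fs_hz))
    entries = []
    idx = 0
    for _ in range(n_trials):
        for code in rng.permutation(word_set):
            entries.append((int(code), idx * spi))
            idx += 1
    return TestSchedule(entries=tuple(entries), word_set=word_set)


def _pink_noise(rng: np.random.Generator, n: int, fs: float,
                exponent: float, amplitude: float) -> np.ndarray:
    """1/f^exponent Gaussian noise, scaled to the given RMS amplitude."""
    if amplitude == 0.0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    shape = np.empty_like(f)
    shape[1:] = f[1:] ** (-exponent / 2.0)
    shape[0] = 0.0  # no DC drift
    x = np.fft.irfft(spec * shape, n)
    rms = np.sqrt(np.mean(x ** 2))
    return x * (amplitude / rms) if rms > 0 else x


def synthesize_record(
    schedule: TestSchedule,
    signatures: Mapping[int, ClassSignature],
    cfg: AcquisitionConfig,
    record_id: int,
    seed=None,
    *,
    subject_id: int = 1,
    test_index: int = 0,
    noise_amplitude_uv: float = 10.0,
) -> EEGRecord:
    """Render one test schedule into a continuous multichannel recording.

    Every instance window gets 1/f^alpha background noise on all 21 EEG
    rows; the 19 scalp rows of a word instance additionally carry that
    class's sinusoidal peaks (random phase per instance and channel),
    amplitude-scaled by ``1 + drift_per_record * record_id`` and
    frequency-shifted by ``freq_drift_hz_per_record * record_id``.
    A1/A2 never carry class signal.  One sync row holds the class code as
    a constant level over the instance, the other a short pulse at onset.
    """
    missing = sorted({c for c, _ in schedule.entries} - set(signatures))
    if missing:
        raise ValueError(f"no signature for class(es) {missing}")
    if not 0 <= record_id <= 9:
        raise ValueError(f"record_id must be in 0..9, got {record_id}")

    rng = np.random.default_rng(seed)
    fs = cfg.fs_hz
    spi = cfg.samples_per_instance
    n_samples = max(o for _, o in schedule.entries) + spi
    eeg_names = cfg.channel_names
    n_eeg = len(eeg_names)
    scalp_rows = [i for i, c in enumerate(eeg_names) if c not in REFERENCE_CHANNELS]

    data = np.zeros((n_eeg + 2, n_samples))
    t_win = np.arange(spi) / fs
    pulse = max(1, int(round(0.05 * fs)))  # 50 ms onset marker

    for code, onset in schedule.entries:
        sig = signatures[code]
        sl = slice(onset, onset + spi)
        for row in range(n_eeg):
            data[row, sl] += _pink_noise(
                rng, spi, fs, sig.background_exponent, noise_amplitude_uv)
        gain = 1.0 + sig.drift_per_record * record_id
        df = sig.freq_drift_hz_per_record * record_id
        for f0, a in zip(sig.peak_freqs_hz, sig.peak_amplitudes):
            f = f0 + df
            phases = rng.uniform(0, 2 * np.pi, size=len(scalp_rows))
            wave = np.sin(2 * np.pi * f * t_win[None, :] + phases[:, None])
            data[scalp_rows, sl] += a * gain * wave
        data[n_eeg, sl] = float(code)
        data[n_eeg + 1, onset:onset + pulse] = 1.0

    return EEGRecord(
        subject_id=subject_id,
        session=record_id // 2,
        part=record_id % 2,
        test_index=test_index,
        data=data,
        fs_hz=fs,
        sync_events=tuple(schedule.entries),
        channel_names=eeg_names + SYNC_CHANNELS,
    )


def generate_subject_dataset(
    cfg: AcquisitionConfig = AcquisitionConfig(),
    word_codes: Sequence[int] = DEFAULT_WORD_ORDER,
    signatures: Mapping[int, ClassSignature] | None = None,
    seed=None,
    *,
    subject_id: int = 1,
    noise_amplitude_uv: float = 10.0,
) -> list[EEGRecord]:
    """Synthesize one subject's complete recording campaign.

    The six words are split into three fixed pairs — tests T1, T2, T3 —
    each recorded with Silence in every part, so each word appears in
    exactly 10 records (one per part) and Silence in all 30.
    """
    word_codes = tuple(int(w) for w in word_codes)
    if len(word_codes) != 6 or len(set(word_codes)) != 6:
        raise ValueError(f"exactly 6 distinct word codes required, got {word_codes}")
    if signatures is None:
        signatures = default_signatures()
    pairs = [word_codes[0:2], word_codes[2:4], word_codes[4:6]]
    ss = as_seed_sequence(seed)
    records: list[EEGRecord] = []
    for session in range(cfg.n_sessions):
        for part in range(cfg.n_parts_per_session):
            record_id = session * cfg.n_parts_per_session + part
            for test_index in range(cfg.n_tests_per_part):
                pair = pairs[test_index % len(pairs)]
                sched_seed, rec_seed = ss.spawn(2)
                schedule = generate_schedule(
                    (*pair, SILENCE_CODE), cfg.n_trials,
                    ti_s=cfg.instance_time_s, fs_hz=cfg.fs_hz,
                    seed=sched_seed, max_test_time_s=cfg.max_test_time_s)
                records.append(synthesize_record(
                    schedule, signatures, cfg, record_id, seed=rec_seed,
                    subject_id=subject_id, test_index=test_index,
                    noise_amplitude_uv=noise_amplitude_uv))
    return records


def inject_artifact(record: EEGRecord, instance_index: int,
                    energy_gain: float) -> EEGRecord:
    """Scale one instance's EEG samples, changing its energy by gain^2.

    Emulates a movement/contact artifact (gain > 1) or an electrode
    dropout (gain < 1).  Sync rows and all other instances are untouched;
    a new record is returned.
    """
    if energy_gain <= 0:
        raise ValueError("energy_gain must be positive")
    if not 0 <= instance_index < len(record.sync_events):
        raise ValueError(
            f"instance_index {instance_index} out of range "
            f"0..{len(record.sync_events) - 1}")
    _, onset = record.sync_events[instance_index]
    spi = int(round((record.sync_events[1][1] - record.sync_events[0][1])
                    )) if len(record.sync_events) > 1 else record.n_samples
    n_eeg = len(record.eeg_channel_names)
    data = record.data.copy()
    data[:n_eeg, onset:onset + spi] *= energy_gain
    return replace(record, data=data)


def generate_label_independent_features(
    class_codes: Sequence[int],
    n_per_class: int,
    n_features: int = 589,
    seed=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Feature vectors statistically independent of their labels.

    Draws uniform [0, 1] vectors shaped like real feature vectors
    (default length 19 channels x 31 frequencies) and assigns labels in a
    balanced round-robin.  Any classifier evaluated on this data should
    recover the 1/n chance level.
    """
    class_codes = tuple(int(c) for c in class_codes)
    rng = np.random.default_rng(seed)
    n = len(class_codes) * n_per_class
    X = rng.uniform(0.0, 1.0, size=(n, n_features))
    y = np.repeat(class_codes, n_per_class)
    return X, y
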