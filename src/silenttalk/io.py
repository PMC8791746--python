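"""On-disk stores: HDF5 for records / segments / features, CSV for
schedules, and an EDF reader for externally supplied recordings."""

from __future__ import annotations

import csv
from typing import Sequence

import h5py
import numpy as np

from .features import FeatureStore
from .preprocess import InstanceSegment
from .synthetic import EEGRecord, SYNC_CHANNELS, TestSchedule

__all__ = [
    "save_records", "load_records",
    "save_segments", "load_segments",
    "save_features", "load_features",
    "schedule_to_csv",
    "read_edf_record",
]


def save_records(path, records: Sequence[EEGRecord]) -> None:
    with h5py.File(path, "w") as fh:
        for k, rec in enumerate(records):
            g = fh.create_group(f"record_{k:03d}")
            g.create_dataset("data", data=rec.data, compression="gzip")
            g.create_dataset("sync_events", data=np.asarray(rec.sync_events))
            g.attrs.update({
                "subject_id": rec.subject_id, "session": rec.session,
                "part": rec.part, "test_index": rec.test_index,
                "fs_hz": rec.fs_hz,
                "channel_names": ",".join(rec.channel_names),
            })


def load_records(path) -> list[EEGRecord]:
    records = []
    with h5py.File(path, "r") as fh:
        for key in sorted(fh):
            g = fh[key]
            records.append(EEGRecord(
                subject_id=int(g.attrs["subject_id"]),
                session=int(g.attrs["session"]),
                part=int(g.attrs["part"]),
                test_index=int(g.attrs["test_index"]),
                data=g["data"][()],
                fs_hz=float(g.attrs["fs_hz"]),
                sync_events=tuple(map(tuple, g["sync_events"][()].tolist())),
                channel_names=tuple(str(g.attrs["channel_names"]).split(",")),
            ))
    return records


def save_segments(path, segments: Sequence[InstanceSegment]) -> None:
    if not segments:
        raise ValueError("nothing to save")
    data = np.stack([s.data for s in segments])
    with h5py.File(path, "w") as fh:
        fh.create_dataset("data", data=data, compression="gzip")
        fh.create_dataset("class_code",
                          data=[s.class_code for s in segments])
        fh.create_dataset("subject_id",
                          data=[s.subject_id for s in segments])
        fh.create_dataset("record_id",
                          data=[s.record_id for s in segments])
        fh.attrs["fs_hz"] = segments[0].fs_hz
        fh.attrs["channel_names"] = ",".join(segments[0].channel_names)


def load_segments(path) -> list[InstanceSegment]:
    with h5py.File(path, "r") as fh:
        data = fh["data"][()]
        codes = fh["class_code"][()]
        subjects = fh["subject_id"][()]
        records = fh["record_id"][()]
        fs = float(fh.attrs["fs_hz"])
        names = tuple(str(fh.attrs["channel_names"]).split(","))
    return [InstanceSegment(class_code=int(c), subject_id=int(s),
                            record_id=int(r), data=d, fs_hz=fs,
                            channel_names=names)
            for c, s, r, d in zip(codes, subjects, records, data)]


def save_features(path, store: FeatureStore) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("X", data=store.X, compression="gzip")
        fh.create_dataset("word", data=store.word)
        fh.create_dataset("record", data=store.record)
        fh.create_dataset("subject", data=store.subject)
        fh.attrs["feature_names"] = ",".join(store.feature_names)


def load_features(path) -> FeatureStore:
    with h5py.File(path, "r") as fh:
        return FeatureStore(
            X=fh["X"][()], word=fh["word"][()], record=fh["record"][()],
            subject=fh["subject"][()],
            feature_names=tuple(str(fh.attrs["feature_names"]).split(",")),
        )


def features_to_csv(path, store: FeatureStore) -> None:
    """Feature matrix as CSV: label columns then one column per
    channel-frequency feature (``Cz_10Hz`` style)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["subject", "word", "record", *store.feature_names])
        for s, wd, r, row in zip(store.subject, store.word, store.record,
                                 store.X):
            w.writerow([s, wd, r, *row])


def schedule_to_csv(path, schedule: TestSchedule, fs_hz: float) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["class_code", "onset_sample", "onset_seconds"])
        for code, onset in schedule.entries:
            w.writerow([code, onset, onset / fs_hz])


def read_edf_record(path, *, subject_id: int = 1, session: int = 0,
                    part: int = 0, test_index: int = 0,
                    sync_class_channel: str = SYNC_CHANNELS[0],
                    sync_onset_channel: str = SYNC_CHANNELS[1]) -> EEGRecord:
    """Read a continuous EDF recording with two sync data channels.

    Instance type and onsets are decoded from the sync-class channel:
    each run of a constant positive level is one instance whose class is
    that level.  Requires ``mne`` (optional dependency).
    """
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    names = tuple(raw.ch_names)
    if sync_class_channel not in names:
        raise ValueError(
            f"sync channel {sync_class_channel!r} not found in {names}")
    data = raw.get_data() * 1e6  # mne uses volts; records are in microvolts
    sync = np.rint(data[names.index(sync_class_channel)]).astype(int)
    events = []
    prev = 0
    for idx in range(len(sync)):
        if sync[idx] != prev and sync[idx] > 0:
            events.append((int(sync[idx]), idx))
        prev = sync[idx]
    order = [n for n in names if n not in (sync_class_channel,
                                           sync_onset_channel)]
    rows = [names.index(n) for n in order] + \
        [names.index(sync_class_channel), names.index(sync_onset_channel)]
    return EEGRecord(
        subject_id=subject_id, session=session, part=part,
        test_index=test_index, data=data[rows], fs_hz=float(raw.info["sfreq"]),
        sync_events=tuple(events),
        channel_names=tuple(order) + SYNC_CHANNELS,
    )
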