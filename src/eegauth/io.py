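"""Reading and writing recordings, trial sets and feature matrices.

Recordings travel as EDF (one file per subject/session/protocol) with a
sidecar CSV of stimulus events (columns ``onset_sample, onset_s,
stimulus_index``).  Writing uses a self-contained 16-bit EDF encoder
(header layout per the EDF standard, 1 s data records); reading goes
through :mod:`mne`, which also serves as an independent check that the
files we write are standard-conformant.

Trial sets are stored as ``.npz`` arrays with a JSON metadata sidecar;
feature matrices as CSV with a JSON header describing the channel-pair map
and column order.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from eegauth.features import FeatureMatrix
from eegauth.preprocess import TrialSet
from eegauth.simulate import Recording

_DIG_MIN, _DIG_MAX = -32768, 32767


def _field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} chars")
    return s.ljust(width).encode("ascii")


def write_edf(recording: Recording, path: str | Path) -> Path:
    """Write a recording as a 16-bit EDF file (1 s data records).

    Per-channel physical ranges are chosen to cover the signal, so the
    16-bit quantization error is below ``phys_range / 65535`` microvolts.
    Signals are zero-padded to a whole number of 1 s records; the pipeline's
    recordings have whole-second durations, so this is normally a no-op.
    """
    path = Path(path)
    fs = recording.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    spr = int(round(fs))  # samples per 1 s record
    n_ch, n = recording.signal.shape
    n_records = int(np.ceil(n / spr))
    padded = np.zeros((n_ch, n_records * spr))
    padded[:, :n] = recording.signal
    if n_records * spr != n:
        warnings.warn(
            f"zero-padded {n_records * spr - n} samples to complete the "
            "final 1 s EDF record", stacklevel=2,
        )

    phys_max = np.maximum(1.0, np.ceil(np.abs(padded).max(axis=1)))
    phys_min = -phys_max

    # single token: EDF+ readers treat spaces in this field as sub-field
    # separators, so metadata is packed with underscores instead
    patient = f"{recording.subject_id}_{recording.session_id}_{recording.protocol}"
    header = b"".join([
        _field(0, 8),                       # version
        _field(patient, 80),                # local patient id (carries metadata)
        _field("eegauth synthetic", 80),    # local recording id
        _field("01.01.00", 8),              # start date (fixed: synthetic data)
        _field("00.00.00", 8),              # start time
        _field(256 * (n_ch + 1), 8),        # header byte count
        _field("", 44),                     # reserved
        _field(n_records, 8),
        _field(1, 8),                       # record duration, seconds
        _field(n_ch, 4),
    ])
    header += b"".join(_field(lbl, 16) for lbl in recording.channel_labels)
    header += b"".join(_field("", 80) for _ in range(n_ch))          # transducer
    header += b"".join(_field("uV", 8) for _ in range(n_ch))         # phys dim
    header += b"".join(_field(int(v), 8) for v in phys_min)
    header += b"".join(_field(int(v), 8) for v in phys_max)
    header += b"".join(_field(_DIG_MIN, 8) for _ in range(n_ch))
    header += b"".join(_field(_DIG_MAX, 8) for _ in range(n_ch))
    header += b"".join(_field("", 80) for _ in range(n_ch))          # prefilter
    header += b"".join(_field(spr, 8) for _ in range(n_ch))
    header += b"".join(_field("", 32) for _ in range(n_ch))          # reserved

    scale = (_DIG_MAX - _DIG_MIN) / (2.0 * phys_max)
    digital = np.round((padded - phys_min[:, None]) * scale[:, None]) + _DIG_MIN
    digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")
    # record-major layout: for each 1 s record, all channels' samples in turn
    records = digital.reshape(n_ch, n_records, spr).transpose(1, 0, 2)

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(records.tobytes())
    return path


def write_events_csv(recording: Recording, path: str | Path) -> Path:
    """Sidecar stimulus-event table: onset_sample, onset_s, stimulus_index."""
    path = Path(path)
    pd.DataFrame({
        "onset_sample": recording.events,
        "onset_s": recording.events / recording.fs,
        "stimulus_index": np.arange(recording.events.size),
    }).to_csv(path, index=False)
    return path


def read_recording(
    edf_path: str | Path, events_path: str | Path | None = None
) -> Recording:
    """Load an EDF recording (and optional events CSV) back into memory."""
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(str(edf_path), preload=True, verbose="error")
    signal_uv = raw.get_data() * 1e6  # mne returns volts
    fs = float(raw.info["sfreq"])

    subject_id, session_id, protocol = "unknown", "unknown", "EC"
    subj_info = (raw.info.get("subject_info") or {}).get("his_id", "")
    parts = str(subj_info).rsplit("_", 2)
    if len(parts) == 3 and parts[2] in ("EC", "VS"):
        subject_id, session_id, protocol = parts

    events = np.array([], dtype=int)
    if events_path is not None:
        table = pd.read_csv(events_path)
        events = table["onset_sample"].to_numpy(dtype=int)
        if events.size:
            protocol = "VS"
    return Recording(
        signal=signal_uv,
        fs=fs,
        channel_labels=tuple(raw.ch_names),
        protocol=protocol,
        events=events,
        subject_id=subject_id,
        session_id=session_id,
    )


def recording_basename(recording: Recording) -> str:
    return f"{recording.subject_id}_{recording.session_id}_{recording.protocol}"


def save_recording(recording: Recording, out_dir: str | Path) -> list[Path]:
    """Write an EDF (plus an events CSV for VS) into ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    base = recording_basename(recording)
    written = [write_edf(recording, out_dir / f"{base}.edf")]
    if recording.protocol == "VS":
        written.append(
            write_events_csv(recording, out_dir / f"{base}_events.csv")
        )
    return written


def save_trialset(trialset: TrialSet, path: str | Path) -> Path:
    """Store trials as .npz with a JSON metadata sidecar."""
    path = Path(path)
    np.savez_compressed(
        path, trials=trialset.trials, kept_indices=trialset.kept_indices
    )
    meta = {
        "fs": trialset.fs,
        "protocol": trialset.protocol,
        "subject_id": trialset.subject_id,
        "session_id": trialset.session_id,
        "channel_labels": list(trialset.channel_labels),
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
    return path


def load_trialset(path: str | Path) -> TrialSet:
    path = Path(path)
    arrays = np.load(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    return TrialSet(
        trials=arrays["trials"],
        kept_indices=arrays["kept_indices"],
        fs=meta["fs"],
        protocol=meta["protocol"],
        subject_id=meta["subject_id"],
        session_id=meta["session_id"],
        channel_labels=tuple(meta["channel_labels"]),
    )


def save_features(matrix: FeatureMatrix, path: str | Path) -> Path:
    """Feature matrix as CSV (label + feature columns) with a JSON header."""
    path = Path(path)
    columns = [matrix.column_name(k) for k in range(matrix.X.shape[1])]
    frame = pd.DataFrame(matrix.X, columns=columns)
    frame.insert(0, "label", matrix.labels)
    frame.to_csv(path, index=False)
    header = {
        "pair_map": [list(p) for p in matrix.pair_map],
        "column_order": "pair-major, (max, mean, var)-minor",
        "columns": columns,
    }
    path.with_suffix(".json").write_text(json.dumps(header, indent=2))
    return path


def load_features(path: str | Path) -> FeatureMatrix:
    path = Path(path)
    frame = pd.read_csv(path)
    header = json.loads(path.with_suffix(".json").read_text())
    return FeatureMatrix(
        X=frame.drop(columns="label").to_numpy(dtype=float),
        labels=frame["label"].to_numpy(),
        pair_map=[tuple(p) for p in header["pair_map"]],
    )
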