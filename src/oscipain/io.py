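"""Reading and writing of EDF recordings, metadata tables and feature matrices.

Recordings travel as plain EDF (16-bit, one-second data records): the open
interchange format virtually every EEG tool reads.  Metadata is UTF-8 CSV
with a fixed header, feature matrices are CSV with a two-row header
(electrode, frequency in Hz).

The EDF layer here is deliberately minimal: fixed-layout ASCII header plus
little-endian int16 data records, physical units scaled to µV on read.  The
subject id is carried in the EDF patient field and the reference scheme in
the recording field, so a write/read round trip reconstructs the Recording.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import CohortFeatures, Recording, SubjectMeta, group_from_nrs
from .errors import (
    FormatError,
    LabeledChannelError,
    ParameterError,
    ValidationError,
)
from .montage import MASTOIDS

_DIG_MIN, _DIG_MAX = -32768, 32767

#: Physical (µV) range declared in the EDF header; samples must fit inside it.
DEFAULT_PHYS_RANGE = (-1000.0, 1000.0)

_UNIT_TO_UV = {"uV": 1.0, "µV": 1.0, "mV": 1e3, "V": 1e6, "": 1.0}


def _ascii(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def write_edf(
    recording: Recording,
    path: str | Path,
    phys_range: tuple[float, float] = DEFAULT_PHYS_RANGE,
) -> None:
    """Write a Recording as a standard EDF file.

    The record duration is one second, so the recording must span a whole
    number of seconds at an integer sampling rate.  Samples outside
    ``phys_range`` (µV) raise a ValueError: the 16-bit quantization grid is
    only defined inside the declared physical range.
    """
    data = recording.data
    if not np.all(np.isfinite(data)):
        raise ValueError("cannot write non-finite samples to EDF")
    pmin, pmax = float(phys_range[0]), float(phys_range[1])
    if data.size and (data.min() < pmin or data.max() > pmax):
        raise ValueError(
            f"sample amplitude outside the declared physical range [{pmin}, {pmax}] µV"
        )
    fs = recording.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ParameterError(f"EDF writer requires an integer sampling rate, got {fs}")
    fs = int(round(fs))
    n_samples = recording.n_samples
    if n_samples % fs != 0:
        raise ParameterError(
            "EDF writer requires a whole number of 1-s records: "
            f"{n_samples} samples at {fs} Hz"
        )
    n_records = n_samples // fs
    ns = len(recording.channels)

    scale = (pmax - pmin) / (_DIG_MAX - _DIG_MIN)
    digital = np.round((data - pmin) / scale).astype(np.int64) + _DIG_MIN
    digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")

    header = b"".join(
        [
            _ascii("0", 8),
            _ascii(recording.subject_id, 80),
            _ascii(f"ref={recording.reference}", 80),
            _ascii("01.01.00", 8),
            _ascii("00.00.00", 8),
            _ascii(256 * (ns + 1), 8),
            _ascii("", 44),
            _ascii(n_records, 8),
            _ascii(1, 8),
            _ascii(ns, 4),
        ]
    )
    fields = [
        [_ascii(c, 16) for c in recording.channels],
        [_ascii("", 80)] * ns,
        [_ascii("uV", 8)] * ns,
        [_ascii(f"{pmin:g}", 8)] * ns,
        [_ascii(f"{pmax:g}", 8)] * ns,
        [_ascii(_DIG_MIN, 8)] * ns,
        [_ascii(_DIG_MAX, 8)] * ns,
        [_ascii("", 80)] * ns,
        [_ascii(fs, 8)] * ns,
        [_ascii("", 32)] * ns,
    ]
    with open(path, "wb") as fh:
        fh.write(header)
        for group in fields:
            fh.write(b"".join(group))
        # data records: per record, all channels sequentially
        for r in range(n_records):
            block = digital[:, r * fs : (r + 1) * fs]
            fh.write(block.tobytes())


def _read_field(raw: bytes, offset: int, width: int, name: str, kind=str):
    chunk = raw[offset : offset + width]
    if len(chunk) < width:
        raise FormatError(f"EDF header truncated while reading field {name!r}")
    text = chunk.decode("ascii", errors="replace").strip()
    if kind is str:
        return text
    try:
        return kind(text)
    except ValueError:
        raise FormatError(f"EDF header field {name!r} is not numeric: {text!r}") from None


def read_edf(path: str | Path, require_mastoids: bool = True) -> Recording:
    """Read an EDF file into a Recording with µV-scaled data.

    ``require_mastoids`` enforces the presence of the M1/M2 labels needed by
    the linked-mastoid re-reference; disable it to read already re-referenced
    30-channel files.
    """
    raw = Path(path).read_bytes()
    if len(raw) < 256:
        raise FormatError("EDF header truncated: file shorter than 256 bytes")
    subject_id = _read_field(raw, 8, 80, "patient")
    rec_field = _read_field(raw, 88, 80, "recording")
    header_bytes = _read_field(raw, 184, 8, "header_bytes", int)
    n_records = _read_field(raw, 236, 8, "n_records", int)
    record_dur = _read_field(raw, 244, 8, "record_duration", float)
    ns = _read_field(raw, 252, 4, "n_signals", int)
    if ns <= 0:
        raise FormatError(f"EDF header field 'n_signals' must be positive, got {ns}")
    if header_bytes != 256 * (ns + 1):
        raise FormatError(
            f"EDF header field 'header_bytes' is {header_bytes}, expected {256 * (ns + 1)}"
        )
    if n_records < 0:
        raise FormatError("EDF header field 'n_records' is negative")
    if record_dur <= 0:
        raise FormatError("EDF header field 'record_duration' must be positive")

    def sig_field(block: int, width: int, i: int, name: str, kind=str):
        offset = 256 + block + i * width
        return _read_field(raw, offset, width, f"{name}[{i}]", kind)

    # per-signal blocks are laid out field-major
    widths = [16, 80, 8, 8, 8, 8, 8, 80, 8, 32]
    starts = np.concatenate([[0], np.cumsum(np.array(widths) * ns)])[:-1]
    labels = [sig_field(starts[0], 16, i, "label") for i in range(ns)]
    units = [sig_field(starts[2], 8, i, "physical_dimension") for i in range(ns)]
    pmins = [sig_field(starts[3], 8, i, "physical_min", float) for i in range(ns)]
    pmaxs = [sig_field(starts[4], 8, i, "physical_max", float) for i in range(ns)]
    dmins = [sig_field(starts[5], 8, i, "digital_min", float) for i in range(ns)]
    dmaxs = [sig_field(starts[6], 8, i, "digital_max", float) for i in range(ns)]
    spr = [sig_field(starts[8], 8, i, "samples_per_record", int) for i in range(ns)]

    for i in range(ns):
        if units[i] not in _UNIT_TO_UV:
            raise FormatError(
                f"EDF field 'physical_dimension[{i}]' has unsupported unit {units[i]!r}"
            )
        if dmaxs[i] == dmins[i]:
            raise FormatError(f"EDF field 'digital_min/max[{i}]' span is zero")
        if spr[i] <= 0:
            raise FormatError(f"EDF field 'samples_per_record[{i}]' must be positive")

    body = raw[header_bytes:]
    rec_len_words = sum(spr)
    expected = n_records * rec_len_words * 2
    if len(body) < expected:
        raise FormatError(
            f"EDF data truncated: {len(body)} bytes, header promises {expected}"
        )
    words = np.frombuffer(body[:expected], dtype="<i2").reshape(n_records, rec_len_words)
    bounds = np.concatenate([[0], np.cumsum(spr)])
    channels_data = []
    for i in range(ns):
        sig = words[:, bounds[i] : bounds[i + 1]].reshape(-1).astype(float)
        scale = (pmaxs[i] - pmins[i]) / (dmaxs[i] - dmins[i])
        phys = (sig - dmins[i]) * scale + pmins[i]
        channels_data.append(phys * _UNIT_TO_UV[units[i]])
    if len({len(c) for c in channels_data}) != 1:
        raise FormatError("EDF signals have differing sampling rates; not supported")
    data = np.vstack(channels_data)
    fs = spr[0] / record_dur

    if require_mastoids:
        missing = [m for m in MASTOIDS if m not in labels]
        if missing:
            raise LabeledChannelError(
                f"EDF file lacks required mastoid channel(s): {', '.join(missing)}"
            )

    reference = rec_field.removeprefix("ref=") if rec_field.startswith("ref=") else "unknown"
    return Recording(
        subject_id=subject_id, channels=labels, fs=fs, data=data, reference=reference
    )


META_COLUMNS = [
    "subject_id",
    "age",
    "gender",
    "education",
    "asa",
    "operation",
    "nrs_day1",
    "nrs_day2",
    "nrs_day3",
    "group",
]


def read_meta(path: str | Path) -> list[SubjectMeta]:
    """Read the per-subject metadata CSV; the group label is derived from
    nrs_day3 when the column is absent."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    required = {"subject_id", "age", "nrs_day1", "nrs_day2", "nrs_day3"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"metadata table lacks columns: {sorted(missing)}")
    if df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValidationError(f"duplicate subject_id values: {dupes}")
    out = []
    for _, row in df.iterrows():
        group = row.get("group")
        if isinstance(group, float) and np.isnan(group):
            group = None
        out.append(
            SubjectMeta(
                subject_id=str(row["subject_id"]),
                age=float(row["age"]),
                nrs_day1=int(row["nrs_day1"]),
                nrs_day2=int(row["nrs_day2"]),
                nrs_day3=int(row["nrs_day3"]),
                group=group,
                gender=str(row.get("gender", "") or ""),
                education=str(row.get("education", "") or ""),
                asa=str(row.get("asa", "") or ""),
                operation=str(row.get("operation", "") or ""),
            )
        )
    return out


def write_meta(metas: list[SubjectMeta], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "subject_id": m.subject_id,
                "age": m.age,
                "gender": m.gender,
                "education": m.education,
                "asa": m.asa,
                "operation": m.operation,
                "nrs_day1": m.nrs_day1,
                "nrs_day2": m.nrs_day2,
                "nrs_day3": m.nrs_day3,
                "group": m.group,
            }
        for m in metas],
        columns=META_COLUMNS,
    )
    df.to_csv(path, index=False)


def write_features(features: CohortFeatures, path: str | Path) -> None:
    """Feature matrix as CSV with a two-row header: electrode, frequency."""
    cols = pd.MultiIndex.from_tuples(features.feature_index, names=["electrode", "freq_hz"])
    df = pd.DataFrame(features.X, index=pd.Index(features.subject_ids, name="subject_id"),
                      columns=cols)
    df.to_csv(path)


def read_features(path: str | Path) -> CohortFeatures:
    df = pd.read_csv(path, header=[0, 1], index_col=0)
    index = [(str(e), float(f)) for e, f in df.columns]
    return CohortFeatures(
        subject_ids=[str(s) for s in df.index],
        feature_index=index,
        X=df.to_numpy(dtype=float),
    )


__all__ = [
    "read_edf",
    "write_edf",
    "read_meta",
    "write_meta",
    "read_features",
    "write_features",
    "group_from_nrs",
    "DEFAULT_PHYS_RANGE",
]
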