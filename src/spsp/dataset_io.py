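"""Reading and writing recordings, manifests, symbol sequences and reports.

On-disk formats are deliberately plain: delimited-text matrices (channels in
rows, samples in columns), a JSON manifest describing a dataset, and
JSON/CSV evaluation reports.  All floating point output uses 17 significant
digits so write/read round-trips are bit-faithful.
"""

from __future__ import annotations

import csv
import json
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import (
    ConsistencyError,
    DataIOError,
    FormatError,
    ManifestError,
    ParseError,
)

#: printf-style format giving round-trip-exact decimal text for float64
FLOAT_FMT = ".17g"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class Recording:
    """One trial: a channels-by-samples matrix plus identifying metadata.

    Attributes
    ----------
    subject_id, trial_id : str
        Identify the trial within a dataset; the pair must be unique.
    label : str or None
        Class label, absent for unlabeled data.
    sample_rate_hz : float
        Sampling rate, strictly positive.
    channel_names : list of str
        One name per channel, no duplicates.
    data : ndarray, shape (M, N)
        Finite float matrix; M >= 1 channels, N >= 2 samples.
    """

    subject_id: str
    trial_id: str
    label: Optional[str]
    sample_rate_hz: float
    channel_names: list[str]
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise FormatError(
                f"recording data must be 2-D, got shape {self.data.shape}"
            )
        m, n = self.data.shape
        if m < 1 or n < 2:
            raise FormatError(
                f"recording must have M >= 1 channels and N >= 2 samples, "
                f"got M={m}, N={n}"
            )
        if not np.all(np.isfinite(self.data)):
            bad = np.argwhere(~np.isfinite(self.data))[0]
            raise FormatError(
                f"non-finite value at channel {bad[0]}, sample {bad[1]}"
            )
        if self.sample_rate_hz <= 0:
            raise FormatError(
                f"sample_rate_hz must be positive, got {self.sample_rate_hz}"
            )
        if len(self.channel_names) != m:
            raise FormatError(
                f"{len(self.channel_names)} channel names for {m} channels"
            )
        if len(set(self.channel_names)) != m:
            raise FormatError("duplicate channel names")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class ManifestEntry:
    file_path: str
    subject_id: str
    trial_id: str
    label: Optional[str] = None


@dataclass
class DatasetManifest:
    """Maps matrix files to subject / trial / label metadata."""

    entries: list[ManifestEntry]
    channel_count: int
    sample_rate_hz: float
    delimiter: str = ","
    has_header: bool = False
    has_rownames: bool = False
    transpose: bool = False

    def __post_init__(self) -> None:
        keys = [(e.subject_id, e.trial_id) for e in self.entries]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise ManifestError(
                f"duplicate (subject, trial) pairs in manifest: {dupes}"
            )
        if self.channel_count < 1:
            raise ManifestError(
                f"channel_count must be >= 1, got {self.channel_count}"
            )
        if self.sample_rate_hz <= 0:
            raise ManifestError(
                f"sample_rate_hz must be positive, got {self.sample_rate_hz}"
            )


# ---------------------------------------------------------------------------
# matrix files
# ---------------------------------------------------------------------------


def _parse_matrix(
    path: str,
    delimiter: str,
    has_header: bool,
    has_rownames: bool,
) -> tuple[np.ndarray, Optional[list[str]]]:
    """Parse a delimited numeric matrix, reporting the exact offending cell."""
    rows: list[list[float]] = []
    names: list[str] = []
    width: Optional[int] = None
    try:
        fh = open(path, newline="")
    except OSError as exc:
        raise DataIOError(f"cannot read {path}: {exc}") from exc
    with fh:
        reader = csv.reader(fh, delimiter=delimiter)
        for r, raw in enumerate(reader):
            if not raw or (len(raw) == 1 and raw[0].strip() == ""):
                continue  # blank line
            if has_header and not rows and not names and r == 0:
                continue
            if has_rownames:
                names.append(raw[0].strip())
                raw = raw[1:]
            if width is None:
                width = len(raw)
            elif len(raw) != width:
                raise FormatError(
                    f"{path}: ragged rows (row {r} has {len(raw)} columns, "
                    f"expected {width})"
                )
            parsed = []
            for c, cell in enumerate(raw):
                try:
                    parsed.append(float(cell))
                except ValueError:
                    raise ParseError(
                        f"{path}: non-numeric value {cell.strip()!r} at "
                        f"row {r}, column {c}"
                    ) from None
            rows.append(parsed)
    if not rows:
        raise FormatError(f"{path}: no data rows")
    return np.asarray(rows, dtype=float), (names if has_rownames else None)


def read_recording(path: str, entry: ManifestEntry, manifest: DatasetManifest) -> Recording:
    """Read one trial's matrix file as described by a manifest entry.

    Rows are channels and columns are samples unless ``manifest.transpose``
    is set.  Raises :class:`ConsistencyError` when the parsed channel count
    disagrees with the manifest.
    """
    data, names = _parse_matrix(
        path, manifest.delimiter, manifest.has_header, manifest.has_rownames
    )
    if manifest.transpose:
        data = data.T
    if data.shape[0] != manifest.channel_count:
        raise ConsistencyError(
            f"{path}: {data.shape[0]} channels parsed but manifest declares "
            f"{manifest.channel_count}"
        )
    if names is None:
        names = [f"ch{i + 1:02d}" for i in range(data.shape[0])]
    return Recording(
        subject_id=entry.subject_id,
        trial_id=entry.trial_id,
        label=entry.label,
        sample_rate_hz=manifest.sample_rate_hz,
        channel_names=names,
        data=data,
    )


def write_recording(
    recording: Recording,
    path: str,
    delimiter: str = ",",
    write_rownames: bool = False,
) -> None:
    """Write a recording matrix with full (17 significant digit) precision."""
    with open(path, "w", newline="") as fh:
        for name, row in zip(recording.channel_names, recording.data):
            cells = [format(v, FLOAT_FMT) for v in row]
            if write_rownames:
                cells = [name] + cells
            fh.write(delimiter.join(cells) + "\n")


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------


def read_manifest(manifest_path: str) -> DatasetManifest:
    try:
        with open(manifest_path) as fh:
            raw = json.load(fh)
    except OSError as exc:
        raise DataIOError(f"cannot read manifest {manifest_path}: {exc}") from exc
    except json.JSONDecodeError as exc:
        raise ManifestError(f"{manifest_path}: invalid JSON: {exc}") from exc
    for key in ("entries", "channel_count", "sample_rate_hz"):
        if key not in raw:
            raise ManifestError(f"{manifest_path}: missing key {key!r}")
    entries = []
    for i, e in enumerate(raw["entries"]):
        for key in ("file_path", "subject_id", "trial_id"):
            if key not in e:
                raise ManifestError(
                    f"{manifest_path}: entry {i} missing key {key!r}"
                )
        entries.append(
            ManifestEntry(
                file_path=e["file_path"],
                subject_id=str(e["subject_id"]),
                trial_id=str(e["trial_id"]),
                label=e.get("label"),
            )
        )
    return DatasetManifest(
        entries=entries,
        channel_count=int(raw["channel_count"]),
        sample_rate_hz=float(raw["sample_rate_hz"]),
        delimiter=raw.get("delimiter", ","),
        has_header=bool(raw.get("has_header", False)),
        has_rownames=bool(raw.get("has_rownames", False)),
        transpose=bool(raw.get("transpose", False)),
    )


def write_manifest(manifest: DatasetManifest, manifest_path: str, extra: Optional[dict] = None) -> None:
    doc = {
        "channel_count": manifest.channel_count,
        "sample_rate_hz": manifest.sample_rate_hz,
        "delimiter": manifest.delimiter,
        "has_header": manifest.has_header,
        "has_rownames": manifest.has_rownames,
        "transpose": manifest.transpose,
        "entries": [
            {
                "file_path": e.file_path,
                "subject_id": e.subject_id,
                "trial_id": e.trial_id,
                "label": e.label,
            }
            for e in manifest.entries
        ],
    }
    if extra:
        doc.update(extra)
    with open(manifest_path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_dataset(manifest_path: str) -> list[Recording]:
    """Load every recording referenced by a JSON manifest, in manifest order.

    Relative file paths are resolved against the manifest's directory.
    """
    manifest = read_manifest(manifest_path)
    base = os.path.dirname(os.path.abspath(manifest_path))
    recordings = []
    for entry in manifest.entries:
        path = entry.file_path
        if not os.path.isabs(path):
            path = os.path.join(base, path)
        if not os.path.exists(path):
            raise DataIOError(f"manifest references missing file: {path}")
        recordings.append(read_recording(path, entry, manifest))
    return recordings


# ---------------------------------------------------------------------------
# symbol sequences and evaluation reports
# ---------------------------------------------------------------------------


def write_symbols(symbols: Sequence[int], path: str) -> None:
    """Write a symbol sequence as a single CSV line of integers."""
    with open(path, "w") as fh:
        fh.write(",".join(str(int(s)) for s in symbols) + "\n")


def read_symbols(path: str) -> np.ndarray:
    with open(path) as fh:
        line = fh.readline().strip()
    if not line:
        raise FormatError(f"{path}: empty symbol file")
    try:
        return np.array([int(tok) for tok in line.split(",")], dtype=int)
    except ValueError as exc:
        raise ParseError(f"{path}: non-integer symbol: {exc}") from None


def write_report(report, path: str) -> None:
    """Serialize an EvaluationReport to JSON, with the confusion matrix
    additionally rendered as CSV alongside (same stem, ``.confusion.csv``).
    """
    doc = report.to_dict()
    try:
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2, sort_keys=True)
            fh.write("\n")
    except OSError as exc:
        raise DataIOError(f"cannot write report {path}: {exc}") from exc
    csv_path = os.path.splitext(path)[0] + ".confusion.csv"
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["target\\predicted"] + list(report.labels))
        for label, row in zip(report.labels, report.confusion):
            writer.writerow([label] + [int(v) for v in row])


def read_report(path: str):
    from .classify import EvaluationReport

    try:
        with open(path) as fh:
            doc = json.load(fh)
    except OSError as exc:
        raise DataIOError(f"cannot read report {path}: {exc}") from exc
    return EvaluationReport.from_dict(doc)


# ---------------------------------------------------------------------------
# optional adapter for trials x channels x samples per-subject arrays
# ---------------------------------------------------------------------------


def recordings_from_subject_array(
    array: np.ndarray,
    subject_id: str,
    trial_labels: dict[int, str],
    sample_rate_hz: float = 128.0,
    n_channels: int = 32,
) -> list[Recording]:
    """Adapt one subject's trials-by-channels-by-samples array to Recordings.

    Only the first ``n_channels`` rows of the channel axis are used; only the
    trial indices present in ``trial_labels`` (0-based) are returned, since
    the label-to-trial mapping must be supplied by the caller.
    """
    array = np.asarray(array, dtype=float)
    if array.ndim != 3:
        raise FormatError(
            f"subject array must be 3-D (trials, channels, samples), "
            f"got shape {array.shape}"
        )
    if array.shape[1] < n_channels:
        raise FormatError(
            f"subject array has {array.shape[1]} channels, need {n_channels}"
        )
    recordings = []
    for trial_idx, label in sorted(trial_labels.items()):
        if not 0 <= trial_idx < array.shape[0]:
            raise ManifestError(
                f"trial index {trial_idx} out of range for subject "
                f"{subject_id} with {array.shape[0]} trials"
            )
        recordings.append(
            Recording(
                subject_id=subject_id,
                trial_id=f"trial{trial_idx:02d}",
                label=label,
                sample_rate_hz=sample_rate_hz,
                channel_names=[f"ch{i + 1:02d}" for i in range(n_channels)],
                data=array[trial_idx, :n_channels, :],
            )
        )
    return recordings
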