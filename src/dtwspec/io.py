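"""Domain containers and plain-text readers/writers.

The on-disk interchange formats are deliberately simple: an EEG recording is a
delimited numeric matrix (rows = channels, columns = samples) with a JSON
sidecar holding the sample rate, channel labels and subject id; trial markers
and per-trial measures are tab-separated tables.  All writes are atomic
(temp file in the target directory, then rename).

Sample indices are 0-based throughout the package, and the pre-trial window of
a trial at sample ``t`` is the half-open slice ``[t - W, t)``.
"""

from __future__ import annotations

import json
import os
import tempfile
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EEGRecording",
    "TrialTable",
    "TrialMeasures",
    "MEASURE_NAMES",
    "read_eeg",
    "write_eeg",
    "read_trials",
    "write_trials",
    "read_measures",
    "write_measures",
]

#: canonical column order of the six trial-wise measures
MEASURE_NAMES = ("dtw_sd", "dft_sd", "sse", "ms_length", "mean_gfp", "ava_length")

BLOCK_TYPES = ("task", "rest")


class FormatError(ValueError):
    """Raised when an input file violates the expected layout."""


@dataclass
class EEGRecording:
    """A multichannel recording: ``data`` is channels x samples.

    Units are whatever the source provides (typically microvolts); every
    measure in this package is either scale-free or standardized internally,
    so no unit is enforced.
    """

    data: np.ndarray
    rate: float
    channel_labels: list[str] = field(default_factory=list)
    subject_id: str = "s0"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise FormatError("EEG data must be a 2-D channels x samples matrix")
        if self.data.shape[0] < 1 or self.data.shape[1] < 2:
            raise FormatError("EEG data needs >= 1 channel and >= 2 samples")
        if not np.all(np.isfinite(self.data)):
            raise FormatError("EEG data contains non-finite values")
        if not (self.rate > 0):
            raise FormatError("sample rate must be positive")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i}" for i in range(self.data.shape[0])]
        if len(self.channel_labels) != self.data.shape[0]:
            raise FormatError("channel_labels length must equal channel count")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def channel(self, name: str | int) -> np.ndarray:
        """Return one channel as a 1-D array, by label or integer index."""
        if isinstance(name, str):
            try:
                idx = self.channel_labels.index(name)
            except ValueError:
                raise KeyError(f"unknown channel label {name!r}") from None
        else:
            idx = int(name)
        return self.data[idx]


@dataclass
class TrialTable:
    """Ordered trial markers with block membership and task/rest type."""

    trial_sample: np.ndarray
    block_id: np.ndarray
    block_type: list[str]

    def __post_init__(self) -> None:
        self.trial_sample = np.asarray(self.trial_sample, dtype=int)
        self.block_id = np.asarray(self.block_id, dtype=int)
        self.block_type = list(self.block_type)
        n = len(self.trial_sample)
        if len(self.block_id) != n or len(self.block_type) != n:
            raise FormatError("trial table columns must have equal length")
        if n > 1 and not np.all(np.diff(self.trial_sample) > 0):
            raise FormatError("trial_sample must be strictly increasing")
        for bt in self.block_type:
            if bt not in BLOCK_TYPES:
                raise FormatError(f"unknown block_type {bt!r}")
        # block_type must be constant within a block
        for b in np.unique(self.block_id):
            types = {t for t, bid in zip(self.block_type, self.block_id) if bid == b}
            if len(types) > 1:
                raise FormatError(f"block {b} mixes task and rest trials")

    def __len__(self) -> int:
        return len(self.trial_sample)

    def check_bounds(self, n_samples: int) -> None:
        if len(self) and (self.trial_sample[0] < 0 or self.trial_sample[-1] >= n_samples):
            raise IndexError("trial sample outside recording bounds")

    def condition_mask(self, block_type: str) -> np.ndarray:
        return np.array([t == block_type for t in self.block_type])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial_sample": self.trial_sample,
                "block_id": self.block_id,
                "block_type": self.block_type,
            }
        )


@dataclass
class TrialMeasures:
    """Per-trial table of the six scalar measures.

    Columns follow :data:`MEASURE_NAMES`; ``ms_length`` is in samples and
    ``ava_length`` in bins, both nonnegative integers.
    """

    table: pd.DataFrame
    subject_id: str = "s0"

    def __post_init__(self) -> None:
        missing = [c for c in MEASURE_NAMES if c not in self.table.columns]
        if missing:
            raise FormatError(f"measures table missing columns: {missing}")
        self.table = self.table.loc[:, list(MEASURE_NAMES)].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def is_complete(self) -> bool:
        return bool(len(self.table)) and not self.table.isna().any().any()

    def values(self) -> np.ndarray:
        return self.table.to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# file I/O


def _atomic_write(path: str, text: str) -> None:
    d = os.path.dirname(os.path.abspath(path))
    fd, tmp = tempfile.mkstemp(dir=d, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _sniff_delim(line: str) -> str:
    return "\t" if line.count("\t") >= line.count(",") else ","


def read_eeg(path: str, meta_path: str) -> EEGRecording:
    """Read a delimited channels x samples matrix plus its JSON sidecar."""
    with open(path) as fh:
        first = fh.readline()
        if not first.strip():
            raise FormatError(f"{path}: empty matrix file")
        delim = _sniff_delim(first)
    rows: list[list[float]] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            cells = line.strip().split(delim)
            try:
                row = [float(c) for c in cells]
            except ValueError as e:
                raise FormatError(f"{path}:{ln}: non-numeric cell ({e})") from None
            if not all(np.isfinite(row)):
                raise FormatError(f"{path}:{ln}: non-finite value")
            if rows and len(row) != len(rows[0]):
                raise FormatError(f"{path}:{ln}: ragged row")
            rows.append(row)
    with open(meta_path) as fh:
        meta = json.load(fh)
    if "rate" not in meta:
        raise FormatError(f"{meta_path}: sidecar missing 'rate'")
    return EEGRecording(
        data=np.array(rows, dtype=float),
        rate=float(meta["rate"]),
        channel_labels=list(meta.get("channel_labels", [])),
        subject_id=str(meta.get("subject_id", "s0")),
    )


def write_eeg(rec: EEGRecording, path: str, meta_path: str) -> None:
    lines = ["\t".join(repr(float(v)) for v in row) for row in rec.data]
    _atomic_write(path, "\n".join(lines) + "\n")
    meta = {
        "rate": rec.rate,
        "channel_labels": rec.channel_labels,
        "subject_id": rec.subject_id,
    }
    _atomic_write(meta_path, json.dumps(meta, indent=1) + "\n")


def read_trials(path: str) -> TrialTable:
    df = pd.read_csv(path, sep="\t")
    for col in ("trial_sample", "block_id", "block_type"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    return TrialTable(
        trial_sample=df["trial_sample"].to_numpy(),
        block_id=df["block_id"].to_numpy(),
        block_type=[str(t) for t in df["block_type"]],
    )


def write_trials(trials: TrialTable, path: str) -> None:
    _atomic_write(path, trials.to_frame().to_csv(sep="\t", index=False))


def write_measures(measures: TrialMeasures, path: str) -> None:
    """Write the six-measure table as TSV: trial index + fixed column order."""
    if len(measures) and not measures.is_complete():
        raise FormatError("measures table has missing values")
    df = measures.table.copy()
    df.insert(0, "trial", np.arange(len(df)))
    _atomic_write(path, df.to_csv(sep="\t", index=False))


def read_measures(path: str, subject_id: str = "s0") -> TrialMeasures:
    df = pd.read_csv(path, sep="\t")
    return TrialMeasures(table=df, subject_id=subject_id)
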