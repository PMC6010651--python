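"""Reading and writing single-channel EEG records in the Bonn plain-text dialect.

The Bonn epilepsy corpus stores each record as an ASCII file with one integer
sample per line, sampled at 173.61 Hz for 23.6 s (~4096 samples).  The reader
is length-agnostic: real Bonn files carry 4097 lines, the synthetic generator
in :mod:`hoseeg.synth` writes 4096.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

#: Nominal sampling rate of the Bonn recordings, Hz.
BONN_FS = 173.61

#: Nominal record duration, seconds.
BONN_DURATION_S = 23.6


@dataclass
class EEGRecord:
    """A single-channel EEG record with sampling metadata.

    Parameters
    ----------
    samples : ndarray
        Amplitude values (arbitrary µV-scaled units).
    fs : float
        Sampling rate in Hz.
    set_id : str
        Bonn set letter (A–E) or a synthetic label.
    record_id : str
        Identifier of the record within its set.
    """

    samples: np.ndarray
    fs: float = BONN_FS
    set_id: str = ""
    record_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("EEGRecord requires a non-empty 1-D sample array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("EEGRecord samples must all be finite")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        """Record duration in seconds."""
        return self.n_samples / self.fs


def read_bonn_record(
    path: str | Path,
    fs: float = BONN_FS,
    set_id: str | None = None,
    record_id: str | None = None,
) -> EEGRecord:
    """Read a one-column ASCII record file (one numeric sample per line).

    Raises
    ------
    ValueError
        If the file is empty or a line cannot be parsed (the error names the
        offending 1-based line number).
    """
    path = Path(path)
    values: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            token = line.strip()
            if not token:
                continue
            try:
                values.append(float(token))
            except ValueError:
                raise ValueError(
                    f"{path}: cannot parse line {lineno}: {token!r}"
                ) from None
    if not values:
        raise ValueError(f"{path}: file contains no samples")
    return EEGRecord(
        samples=np.asarray(values),
        fs=fs,
        set_id=set_id if set_id is not None else path.parent.name,
        record_id=record_id if record_id is not None else path.stem,
    )


def write_bonn_record(path: str | Path, record: EEGRecord) -> None:
    """Write a record in the Bonn dialect: one rounded integer per line."""
    path = Path(path)
    ints = np.round(record.samples).astype(int)
    with open(path, "w") as fh:
        fh.write("\n".join(str(v) for v in ints))
        fh.write("\n")


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a dataset manifest CSV with columns ``file``, ``set``, ``class``."""
    manifest = pd.read_csv(path)
    required = {"file", "set", "class"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest {path} lacks columns: {sorted(missing)}")
    return manifest


def load_dataset(
    data_dir: str | Path, manifest_name: str = "manifest.csv"
) -> list[tuple[EEGRecord, str]]:
    """Load all records named in ``data_dir/manifest.csv``.

    Returns a list of ``(record, class_label)`` pairs in manifest order.
    """
    data_dir = Path(data_dir)
    manifest_path = data_dir / manifest_name
    if not manifest_path.exists():
        raise FileNotFoundError(
            f"expected a manifest at {manifest_path}; directories must contain "
            f"one-column ASCII records plus a (file,set,class) manifest CSV"
        )
    manifest = read_manifest(manifest_path)
    out = []
    for row in manifest.to_dict("records"):
        rec = read_bonn_record(data_dir / row["file"], set_id=str(row["set"]))
        out.append((rec, str(row["class"])))
    return out
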