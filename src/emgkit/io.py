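"""Reading, writing and framing of labelled single-channel EMG recordings.

Storage format is deliberately plain: one sample per line (text, mV) per
recording, plus a CSV manifest with columns
``recording_id,path,sampling_rate_hz,label``.  An unlabelled recording is
stored with the explicit token ``unlabelled``.

Classification operates on fixed-length rectangular frames cut from each
recording (default 2048 samples, non-overlapping, starting at sample 0,
trailing remainder discarded); each frame inherits its recording's label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FramingError, ManifestError, SampleParseError

logger = logging.getLogger(__name__)

UNLABELLED = "unlabelled"
MANIFEST_COLUMNS = ["recording_id", "path", "sampling_rate_hz", "label"]


@dataclass
class EmgRecording:
    """One labelled single-channel EMG signal.

    samples are in millivolts; ``meta`` carries in-memory provenance
    (e.g. the simulation seed) and is not serialized.
    """

    samples: np.ndarray
    sampling_rate_hz: float
    label: str | None = None
    recording_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ManifestError("recording samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ManifestError("recording samples must be finite")
        if not self.sampling_rate_hz > 0:
            raise ManifestError("sampling_rate_hz must be positive")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sampling_rate_hz


@dataclass
class Frame:
    """A fixed-length window of a recording; the classification instance."""

    samples: np.ndarray
    label: str | None
    source_id: str
    frame_index: int

    def __len__(self) -> int:
        return len(self.samples)


def write_recordings(recordings: list[EmgRecording], out_dir) -> Path:
    """Write recordings as one-sample-per-line text plus a CSV manifest.

    Returns the manifest path.  Samples are written with 17 significant
    digits so that the read/write round trip is exact for float64.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, rec in enumerate(recordings):
        rec_id = rec.recording_id or f"rec{i:04d}"
        fname = f"{rec_id}.txt"
        np.savetxt(out_dir / fname, rec.samples, fmt="%.17g")
        rows.append(
            {
                "recording_id": rec_id,
                "path": fname,
                "sampling_rate_hz": repr(float(rec.sampling_rate_hz)),
                "label": rec.label if rec.label is not None else UNLABELLED,
            }
        )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(manifest, index=False)
    return manifest


def _read_samples(path: Path) -> np.ndarray:
    try:
        data = np.loadtxt(path, dtype=float, ndmin=1)
    except ValueError:
        # Slow path only to produce a diagnostic naming the offending line.
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                token = line.strip()
                if not token:
                    continue
                try:
                    float(token)
                except ValueError:
                    raise SampleParseError(
                        f"{path}: non-numeric sample {token!r} on line {lineno}"
                    ) from None
        raise
    return data


def read_recordings(manifest_path) -> list[EmgRecording]:
    """Load all recordings listed in a manifest CSV."""
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(f"manifest not found: {manifest_path}")
    table = pd.read_csv(manifest_path, dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in table.columns]
    if missing:
        raise ManifestError(f"manifest missing column(s): {', '.join(missing)}")
    if len(table) == 0:
        logger.warning("empty manifest: %s", manifest_path)
        return []
    base = manifest_path.parent
    recordings = []
    for row in table.itertuples(index=False):
        if pd.isna(row.sampling_rate_hz):
            raise ManifestError(
                f"manifest row {row.recording_id!r}: missing sampling rate"
            )
        path = Path(row.path)
        if not path.is_absolute():
            path = base / path
        if not path.exists():
            raise FileNotFoundError(f"recording file not found: {path}")
        label = None if pd.isna(row.label) or row.label == UNLABELLED else row.label
        recordings.append(
            EmgRecording(
                samples=_read_samples(path),
                sampling_rate_hz=float(row.sampling_rate_hz),
                label=label,
                recording_id=str(row.recording_id),
            )
        )
    return recordings


def frame_signal(
    recording: EmgRecording,
    frame_length: int = 2048,
    overlap: int = 0,
    offset: int = 0,
) -> list[Frame]:
    """Cut a recording into fixed-length rectangular frames.

    Frames start at ``offset`` (default 0) and advance by
    ``frame_length - overlap``; a trailing remainder shorter than one frame
    is discarded.  Raises :class:`FramingError` if no full frame fits.
    """
    if frame_length < 2:
        raise FramingError("frame_length must be >= 2")
    if not 0 <= overlap < frame_length:
        raise FramingError("overlap must satisfy 0 <= overlap < frame_length")
    if offset < 0:
        raise FramingError("offset must be >= 0")
    n = len(recording.samples) - offset
    if n < frame_length:
        raise FramingError(
            f"recording {recording.recording_id!r}: {n} samples available, "
            f"need at least one frame of {frame_length}"
        )
    stride = frame_length - overlap
    count = (n - frame_length) // stride + 1
    frames = []
    for i in range(count):
        start = offset + i * stride
        frames.append(
            Frame(
                samples=recording.samples[start : start + frame_length],
                label=recording.label,
                source_id=recording.recording_id,
                frame_index=i,
            )
        )
    return frames
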