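"""In-memory recording container and EDF-based disk format.

A :class:`Recording` is a channels x samples matrix in microvolts plus the
metadata the pipeline needs (sampling rate, channel names, annotations,
bad-channel/segment bookkeeping).

Recordings are persisted as plain EDF (16-bit, one data record per second)
with a JSON sidecar for annotations and QC state.  The EDF writer here is a
minimal single-purpose implementation of the published header layout;
reading goes through MNE's EDF reader, which also serves as an independent
check that the files we emit are well-formed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import InputError

__all__ = ["Recording", "write_edf", "save_recording", "load_recording"]


@dataclass
class Recording:
    """One continuous multichannel EEG block.

    Attributes
    ----------
    data
        ``(n_channels, n_samples)`` float array, microvolts.
    sampling_rate
        Samples per second.
    channel_names
        Ordered, unique channel labels; one per data row.
    annotations
        ``(onset_s, duration_s, label)`` event markers.
    bad_channels
        Labels flagged by flatline detection (or set by the user).
    bad_segments
        ``(onset_s, duration_s)`` intervals flagged as unusable.
    """

    data: np.ndarray
    sampling_rate: float
    channel_names: list[str]
    annotations: list[tuple[float, float, str]] = field(default_factory=list)
    bad_channels: set[str] = field(default_factory=set)
    bad_segments: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise InputError("data must be a 2-D channels x samples array")
        if len(self.channel_names) != len(set(self.channel_names)):
            raise InputError("channel names must be unique")
        if self.data.shape[0] != len(self.channel_names):
            raise InputError(
                f"data has {self.data.shape[0]} rows but "
                f"{len(self.channel_names)} channel names"
            )
        if self.sampling_rate <= 0:
            raise InputError("sampling_rate must be positive")
        dur = self.duration
        for onset, d, _label in self.annotations:
            if onset < 0 or onset + d > dur + 1e-9:
                raise InputError("annotation outside the recording")
        for onset, d in self.bad_segments:
            if onset < 0 or onset + d > dur + 1e-9:
                raise InputError("bad segment outside the recording")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sampling_rate

    def index_of(self, name: str) -> int:
        return self.channel_names.index(name)

    def copy(self, data: np.ndarray | None = None) -> "Recording":
        return replace(
            self,
            data=self.data.copy() if data is None else data,
            channel_names=list(self.channel_names),
            annotations=list(self.annotations),
            bad_channels=set(self.bad_channels),
            bad_segments=list(self.bad_segments),
        )


# --------------------------------------------------------------------------
# EDF output

def _ascii(value, width: int) -> bytes:
    s = f"{value}"
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def write_edf(rec: Recording, path: str | Path, *, patient_id: str = "X") -> Path:
    """Write a recording as plain EDF (16-bit, 1-second data records).

    The last record is zero-padded when the recording length is not a whole
    number of seconds; ``save_recording`` stores the exact sample count in
    the sidecar so a round trip is lossless in length.
    """
    path = Path(path)
    fs = rec.sampling_rate
    spr = int(round(fs))
    if abs(spr - fs) > 1e-9:
        raise InputError("EDF writer requires an integer sampling rate")
    n_ch = rec.n_channels
    n_rec = max(1, math.ceil(rec.n_samples / spr))

    phys_max = np.maximum(np.abs(rec.data).max(axis=1), 1e-3)
    phys_max = np.ceil(phys_max * 1000) / 1000  # keep 3 decimals in 8 chars
    dig_max = 32767

    header = b"".join(
        [
            _ascii("0", 8),
            _ascii(patient_id, 80),
            _ascii("fceeg", 80),
            _ascii("01.01.00", 8),
            _ascii("00.00.00", 8),
            _ascii(256 * (n_ch + 1), 8),
            _ascii("", 44),
            _ascii(n_rec, 8),
            _ascii(1, 8),
            _ascii(n_ch, 4),
        ]
    )
    per_signal = b"".join(
        [
            b"".join(_ascii(name, 16) for name in rec.channel_names),
            b"".join(_ascii("AgAgCl electrode", 80) for _ in range(n_ch)),
            b"".join(_ascii("uV", 8) for _ in range(n_ch)),
            b"".join(_ascii(f"{-m:.3f}"[:8], 8) for m in phys_max),
            b"".join(_ascii(f"{m:.3f}"[:8], 8) for m in phys_max),
            b"".join(_ascii(-dig_max, 8) for _ in range(n_ch)),
            b"".join(_ascii(dig_max, 8) for _ in range(n_ch)),
            b"".join(_ascii("BP:0.5-45Hz", 80) for _ in range(n_ch)),
            b"".join(_ascii(spr, 8) for _ in range(n_ch)),
            b"".join(_ascii("", 32) for _ in range(n_ch)),
        ]
    )

    padded = np.zeros((n_ch, n_rec * spr))
    padded[:, : rec.n_samples] = rec.data
    scale = dig_max / phys_max
    digital = np.clip(
        np.rint(padded * scale[:, None]), -dig_max, dig_max
    ).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(per_signal)
        for r in range(n_rec):
            fh.write(digital[:, r * spr : (r + 1) * spr].tobytes())
    return path


def save_recording(rec: Recording, path: str | Path) -> Path:
    """Write ``<path>.edf`` plus a ``<path>.json`` sidecar; return the EDF path."""
    path = Path(path)
    edf = path.with_suffix(".edf")
    write_edf(rec, edf)
    sidecar = {
        "n_samples": rec.n_samples,
        "sampling_rate": rec.sampling_rate,
        "annotations": [list(a) for a in rec.annotations],
        "bad_channels": sorted(rec.bad_channels),
        "bad_segments": [list(s) for s in rec.bad_segments],
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return edf


def load_recording(path: str | Path) -> Recording:
    """Read an EDF written by :func:`save_recording` (sidecar optional)."""
    import mne

    path = Path(path)
    raw = mne.io.read_raw_edf(path.with_suffix(".edf"), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # MNE returns volts
    names = list(raw.ch_names)
    fs = float(raw.info["sfreq"])

    annotations: list[tuple[float, float, str]] = []
    bad_channels: set[str] = set()
    bad_segments: list[tuple[float, float]] = []
    sidecar_path = path.with_suffix(".json")
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        data = data[:, : int(sidecar["n_samples"])]
        annotations = [tuple(a) for a in sidecar["annotations"]]
        bad_channels = set(sidecar["bad_channels"])
        bad_segments = [tuple(s) for s in sidecar["bad_segments"]]
    return Recording(
        data=data,
        sampling_rate=fs,
        channel_names=names,
        annotations=annotations,
        bad_channels=bad_channels,
        bad_segments=bad_segments,
    )
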