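"""ECG record container and I/O: CSV columns and native WFDB (format 212/16).

The CSV surface is the primary, dependency-free path used by the test suite
and the CLI. WFDB support reads standard ``.hea``/``.dat`` pairs directly so
annotated Holter records can be used when available; it never fetches
anything.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "ECGRecord",
    "read_csv_record",
    "write_csv_record",
    "read_wfdb_record",
    "write_wfdb_record",
    "extract_event_window",
]


@dataclass(frozen=True)
class ECGRecord:
    """Single-channel ECG segment in physical units (mV).

    Parameters
    ----------
    samples
        1-D array of voltage samples.
    sampling_rate
        Samples per second; must be positive.
    record_id
        Free-form identifier (file stem, synthesis tag, ...).
    event_index
        Optional 0-based sample index of an annotated event (e.g. VF onset).
    """

    samples: np.ndarray
    sampling_rate: float
    record_id: str = "record"
    event_index: Optional[int] = None

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1:
            raise ValueError("samples must be a 1-D array")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if samples.size and not np.all(np.isfinite(samples)):
            bad = int(np.flatnonzero(~np.isfinite(samples))[0])
            raise ValueError(f"non-finite sample at index {bad}")
        if self.event_index is not None:
            if not 0 <= self.event_index < samples.size:
                raise ValueError(
                    f"event_index {self.event_index} outside [0, {samples.size})"
                )

    def __len__(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate

    def with_samples(self, samples: np.ndarray, **changes) -> "ECGRecord":
        """Copy with new samples (event annotation dropped unless re-given)."""
        kwargs = dict(
            samples=samples,
            sampling_rate=self.sampling_rate,
            record_id=self.record_id,
            event_index=None,
        )
        kwargs.update(changes)
        return ECGRecord(**kwargs)


def read_csv_record(
    path: str | os.PathLike,
    sampling_rate: float,
    record_id: Optional[str] = None,
) -> ECGRecord:
    """Read one sample column from a CSV/text file.

    Accepts either a single numeric column or the two-column
    ``sample_index,mV`` layout written by :func:`write_csv_record`; a header
    line is optional. Errors name the offending line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    values: list[float] = []
    with open(path, "r") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            cells = [c.strip() for c in line.split(",")]
            if lineno == 1 and any(_not_numeric(c) for c in cells):
                continue  # header
            try:
                values.append(float(cells[-1]))
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric value {cells[-1]!r} at line {lineno}"
                ) from None
    if not values:
        raise ValueError(f"{path}: no samples found")
    return ECGRecord(
        samples=np.asarray(values),
        sampling_rate=sampling_rate,
        record_id=record_id or path.stem,
    )


def _not_numeric(cell: str) -> bool:
    try:
        float(cell)
        return False
    except ValueError:
        return True


def write_csv_record(record: ECGRecord, path: str | os.PathLike) -> None:
    """Write ``sample_index,mV`` rows with a header line."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("sample_index,mV\n")
        for i, v in enumerate(record.samples):
            fh.write(f"{i},{float(v)!r}\n")


# ---------------------------------------------------------------------------
# Native WFDB (.hea + .dat) support, formats 212 and 16.
# ---------------------------------------------------------------------------

_FMT_RE = re.compile(r"^(\d+)")


def read_wfdb_record(path_or_name: str | os.PathLike, channel: int = 0) -> ECGRecord:
    """Read one channel of a local WFDB record in physical units (mV).

    ``path_or_name`` is the header path with or without the ``.hea``
    extension. Supports signal formats 212 (packed 12-bit pairs) and 16
    (little-endian int16). If a ``.atr``-style annotation is absent the
    returned record has no event annotation.
    """
    base = Path(str(path_or_name))
    hea = base if base.suffix == ".hea" else base.with_suffix(".hea")
    if not hea.exists():
        raise FileNotFoundError(f"missing WFDB header: {hea}")
    lines = [
        ln.strip()
        for ln in hea.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    head = lines[0].split()
    name = head[0].split("/")[0]
    n_sig = int(head[1])
    fs = float(head[2]) if len(head) > 2 else 250.0
    n_samp = int(head[3]) if len(head) > 3 else 0
    if not 0 <= channel < n_sig:
        raise IndexError(f"channel {channel} out of range for {n_sig} signals")
    sig_specs = [ln.split() for ln in lines[1 : 1 + n_sig]]
    dat_name = sig_specs[channel][0]
    fmt = _FMT_RE.match(sig_specs[channel][1]).group(1)
    gains = []
    baselines = []
    for spec in sig_specs:
        gain_field = spec[2] if len(spec) > 2 else "200"
        m = re.match(r"([-\d.eE+]+)(?:\(([-\d]+)\))?", gain_field)
        gain = float(m.group(1)) if m else 200.0
        baseline = int(m.group(2)) if m and m.group(2) else 0
        gains.append(gain if gain != 0 else 200.0)
        baselines.append(baseline)
    dat_path = hea.parent / dat_name
    if not dat_path.exists():
        raise FileNotFoundError(f"missing WFDB signal file: {dat_path}")
    raw = dat_path.read_bytes()
    if fmt == "212":
        digital = _decode_212(raw, n_sig, n_samp)
    elif fmt == "16":
        arr = np.frombuffer(raw, dtype="<i2")
        usable = arr.size - arr.size % n_sig
        digital = arr[:usable].reshape(-1, n_sig)
    else:
        raise ValueError(f"unsupported WFDB signal format: {fmt}")
    if n_samp:
        digital = digital[:n_samp]
    phys = (digital[:, channel].astype(np.float64) - baselines[channel]) / gains[channel]
    return ECGRecord(samples=phys, sampling_rate=fs, record_id=name)


def _decode_212(raw: bytes, n_sig: int, n_samp: int) -> np.ndarray:
    buf = np.frombuffer(raw, dtype=np.uint8)
    usable = buf.size - buf.size % 3
    b = buf[:usable].reshape(-1, 3).astype(np.int32)
    first = b[:, 0] | ((b[:, 1] & 0x0F) << 8)
    second = b[:, 2] | ((b[:, 1] & 0xF0) << 4)
    first = np.where(first > 2047, first - 4096, first)
    second = np.where(second > 2047, second - 4096, second)
    flat = np.empty(first.size * 2, dtype=np.int32)
    flat[0::2] = first
    flat[1::2] = second
    usable = flat.size - flat.size % n_sig
    return flat[:usable].reshape(-1, n_sig)


def write_wfdb_record(
    records: Sequence[ECGRecord],
    directory: str | os.PathLike,
    name: str,
    fmt: str = "212",
    gain: float = 200.0,
) -> Path:
    """Write channels to a WFDB header/signal pair (formats 212 or 16).

    Used by tests as the round-trip oracle for :func:`read_wfdb_record`;
    values are quantized to ``1/gain`` mV (ADC resolution).
    """
    directory = Path(directory)
    fs = records[0].sampling_rate
    n = len(records[0])
    if any(len(r) != n or r.sampling_rate != fs for r in records):
        raise ValueError("all channels need equal length and sampling rate")
    digital = np.column_stack(
        [np.round(r.samples * gain).astype(np.int32) for r in records]
    )
    if fmt == "212":
        if np.any(np.abs(digital) > 2047):
            raise ValueError("format 212 range exceeded; lower the gain")
        flat = digital.ravel()
        if flat.size % 2:
            flat = np.append(flat, 0)
        lo = flat[0::2] & 0xFFF
        hi = flat[1::2] & 0xFFF
        packed = np.empty((lo.size, 3), dtype=np.uint8)
        packed[:, 0] = lo & 0xFF
        packed[:, 1] = ((lo >> 8) & 0x0F) | (((hi >> 8) & 0x0F) << 4)
        packed[:, 2] = hi & 0xFF
        payload = packed.tobytes()
    elif fmt == "16":
        payload = digital.astype("<i2").tobytes()
    else:
        raise ValueError(f"unsupported WFDB signal format: {fmt}")
    (directory / f"{name}.dat").write_bytes(payload)
    fs_text = f"{fs:g}"
    header = [f"{name} {digital.shape[1]} {fs_text} {n}"]
    for ch in range(digital.shape[1]):
        header.append(f"{name}.dat {fmt} {gain:g}(0)/mV 12 0 0 0 0 ch{ch}")
    hea = directory / f"{name}.hea"
    hea.write_text("\n".join(header) + "\n")
    return hea


def extract_event_window(
    record: ECGRecord, pre_seconds: float, post_seconds: float
) -> ECGRecord:
    """Slice the window ending ``post_seconds`` after the annotated event.

    The window covers ``pre_seconds`` before through ``post_seconds`` after
    the event and has exactly ``round((pre + post) * rate)`` samples
    (half-open slice in 0-based coordinates). The event index is remapped
    into window coordinates.
    """
    if record.event_index is None:
        raise ValueError("record has no event annotation")
    if pre_seconds < 0 or post_seconds < 0:
        raise ValueError("window extents must be non-negative")
    fs = record.sampling_rate
    total = int(round((pre_seconds + post_seconds) * fs))
    if total <= 0:
        raise ValueError("empty window: pre + post must span at least one sample")
    end = record.event_index + int(round(post_seconds * fs))
    start = end - total
    if start < 0 or end > len(record):
        raise ValueError(
            f"window [{start}, {end}) exceeds record bounds [0, {len(record)})"
        )
    return ECGRecord(
        samples=record.samples[start:end].copy(),
        sampling_rate=fs,
        record_id=f"{record.record_id}[{start}:{end}]",
        event_index=record.event_index - start,
    )
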