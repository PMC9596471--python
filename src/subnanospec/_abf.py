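"""Minimal Axon Binary Format (ABF) version 1 reader/writer.

Supports the subset produced by this package and common gap-free
single-channel acquisitions saved as float32: the classic 2048-byte ABF1
header with the standard field offsets (file signature, acquisition
length, data section pointer, data format, channel count, per-channel
sample interval).  Integer-encoded (int16) data and multi-channel files
are out of scope and rejected with a clear error.
"""

from __future__ import annotations

import struct

import numpy as np

__all__ = ["read_abf1", "write_abf1"]

_HEADER_BYTES = 2048
_BLOCK = 512

# Classic ABF1 header offsets (bytes).
_OFF_SIGNATURE = 0          # 4s   'ABF '
_OFF_VERSION = 4            # f    e.g. 1.83
_OFF_OPERATION_MODE = 8     # h    3 = gap-free
_OFF_ACQ_LENGTH = 10        # i    total number of samples
_OFF_DATA_SECTION_PTR = 40  # i    data offset in 512-byte blocks
_OFF_DATA_FORMAT = 100      # h    0 = int16, 1 = float32
_OFF_NUM_CHANNELS = 120     # h
_OFF_SAMPLE_INTERVAL = 122  # f    microseconds per sample per channel


def write_abf1(path, samples, sampling_rate: float) -> None:
    """Write a single-channel gap-free float32 ABF1 file."""
    data = np.asarray(samples, dtype=np.float32)
    if data.ndim != 1 or data.size == 0:
        raise ValueError("samples must be a non-empty 1-D array")
    if sampling_rate <= 0:
        raise ValueError("sampling_rate must be positive")
    header = bytearray(_HEADER_BYTES)
    struct.pack_into("<4s", header, _OFF_SIGNATURE, b"ABF ")
    struct.pack_into("<f", header, _OFF_VERSION, 1.83)
    struct.pack_into("<h", header, _OFF_OPERATION_MODE, 3)
    struct.pack_into("<i", header, _OFF_ACQ_LENGTH, data.size)
    struct.pack_into("<i", header, _OFF_DATA_SECTION_PTR, _HEADER_BYTES // _BLOCK)
    struct.pack_into("<h", header, _OFF_DATA_FORMAT, 1)
    struct.pack_into("<h", header, _OFF_NUM_CHANNELS, 1)
    struct.pack_into("<f", header, _OFF_SAMPLE_INTERVAL, 1e6 / sampling_rate)
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(data.astype("<f4").tobytes())


def read_abf1(path):
    """Read a single-channel float32 ABF1 file -> (samples, sampling_rate)."""
    with open(path, "rb") as fh:
        header = fh.read(_HEADER_BYTES)
        if len(header) < _HEADER_BYTES:
            raise ValueError(
                f"{path}: truncated ABF header ({len(header)} of "
                f"{_HEADER_BYTES} bytes)"
            )
        sig = struct.unpack_from("<4s", header, _OFF_SIGNATURE)[0]
        if sig != b"ABF ":
            raise ValueError(
                f"{path}: not an ABF1 file (bad signature at byte 0: {sig!r})"
            )
        n = struct.unpack_from("<i", header, _OFF_ACQ_LENGTH)[0]
        data_ptr = struct.unpack_from("<i", header, _OFF_DATA_SECTION_PTR)[0]
        data_format = struct.unpack_from("<h", header, _OFF_DATA_FORMAT)[0]
        n_channels = struct.unpack_from("<h", header, _OFF_NUM_CHANNELS)[0]
        interval_us = struct.unpack_from("<f", header, _OFF_SAMPLE_INTERVAL)[0]
        if data_format != 1:
            raise ValueError(
                f"{path}: only float32 ABF1 data is supported "
                f"(nDataFormat={data_format})"
            )
        if n_channels != 1:
            raise ValueError(f"{path}: multi-channel ABF not supported")
        if n <= 0 or interval_us <= 0:
            raise ValueError(f"{path}: invalid header (n={n}, dt={interval_us} us)")
        fh.seek(data_ptr * _BLOCK)
        raw = fh.read(4 * n)
        if len(raw) < 4 * n:
            raise ValueError(
                f"{path}: truncated data section at byte "
                f"{data_ptr * _BLOCK + len(raw)} (expected {4 * n} data bytes)"
            )
    samples = np.frombuffer(raw, dtype="<f4").astype(float)
    return samples, 1e6 / interval_us
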