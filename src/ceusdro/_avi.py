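"""Minimal uncompressed RIFF/AVI reader and writer for 8-bit greyscale video.

Frames are stored as uncompressed 8-bit palettized device-independent bitmaps
(BI_RGB with a 256-entry grey palette, bottom-up rows padded to 4 bytes) in
'00db' chunks, with a standard idx1 index.  The format is lossless by
construction and readable by common players and ffmpeg-based tools.
"""
from __future__ import annotations

import struct

import numpy as np

from .errors import InputError

__all__ = ["write_avi", "read_avi"]

_AVIF_HASINDEX = 0x00000010
_AVIIF_KEYFRAME = 0x00000010


def _chunk(fourcc: bytes, payload: bytes) -> bytes:
    data = fourcc + struct.pack("<I", len(payload)) + payload
    if len(payload) % 2:
        data += b"\x00"
    return data


def _list(fourcc: bytes, payload: bytes) -> bytes:
    return _chunk(b"LIST", fourcc + payload)


def write_avi(path, frames: np.ndarray, fps: float) -> None:
    """Write a (T, H, W) uint8 array as an uncompressed greyscale AVI."""
    frames = np.asarray(frames)
    if frames.ndim != 3 or frames.dtype != np.uint8:
        raise InputError("frames must be a (T, H, W) uint8 array")
    if fps <= 0:
        raise InputError("fps must be > 0")
    n, h, w = frames.shape
    pad = (-w) % 4
    row_bytes = w + pad
    frame_bytes = row_bytes * h

    avih = struct.pack(
        "<14I",
        int(round(1e6 / fps)),  # dwMicroSecPerFrame
        frame_bytes * int(np.ceil(fps)),  # dwMaxBytesPerSec
        0,  # dwPaddingGranularity
        _AVIF_HASINDEX,
        n, 0, 1,  # totalframes, initialframes, streams
        frame_bytes,  # suggested buffer size
        w, h, 0, 0, 0, 0,
    )
    # fps as a rational: scale/rate with 1e6 resolution
    scale, rate = 1_000_000, int(round(fps * 1_000_000))
    strh = b"vids" + b"DIB " + struct.pack(
        "<10I4h", 0, 0, 0, scale, rate, 0, n, frame_bytes, 0xFFFFFFFF, 0, 0, 0, w, h
    )
    bmih = struct.pack("<IiiHHIIiiII", 40, w, h, 1, 8, 0, frame_bytes, 0, 0, 256, 256)
    palette = b"".join(struct.pack("<BBBB", g, g, g, 0) for g in range(256))
    strf = bmih + palette

    hdrl = _list(
        b"hdrl",
        _chunk(b"avih", avih) + _list(b"strl", _chunk(b"strh", strh) + _chunk(b"strf", strf)),
    )

    movi_payload = b"movi"
    index = b""
    offset = 4  # relative to start of 'movi' fourcc
    for frame in frames:
        dib = np.zeros((h, row_bytes), dtype=np.uint8)
        dib[:, :w] = frame[::-1]  # bottom-up rows
        data = dib.tobytes()
        movi_payload += _chunk(b"00db", data)
        index += b"00db" + struct.pack("<III", _AVIIF_KEYFRAME, offset, len(data))
        offset += 8 + len(data) + (len(data) % 2)
    movi = _chunk(b"LIST", movi_payload)
    idx1 = _chunk(b"idx1", index)

    riff_payload = b"AVI " + hdrl + movi + idx1
    with open(path, "wb") as fh:
        fh.write(b"RIFF" + struct.pack("<I", len(riff_payload)) + riff_payload)


def _iter_chunks(buf: bytes, start: int, end: int):
    pos = start
    while pos + 8 <= end:
        fourcc = buf[pos : pos + 4]
        (size,) = struct.unpack_from("<I", buf, pos + 4)
        yield fourcc, pos + 8, size
        pos += 8 + size + (size % 2)


def read_avi(path) -> tuple[np.ndarray, float]:
    """Read an uncompressed 8-bit greyscale AVI; returns (frames, fps)."""
    with open(path, "rb") as fh:
        buf = fh.read()
    if len(buf) < 12 or buf[:4] != b"RIFF" or buf[8:12] != b"AVI ":
        raise InputError(f"{path}: not a RIFF/AVI file")

    width = height = None
    bitcount = None
    micro_per_frame = None
    scale = rate = None
    frame_data: list[bytes] = []

    def walk(start: int, end: int):
        nonlocal width, height, bitcount, micro_per_frame, scale, rate
        for fourcc, data_pos, size in _iter_chunks(buf, start, end):
            if fourcc == b"LIST":
                walk(data_pos + 4, data_pos + size)
            elif fourcc == b"avih":
                micro_per_frame = struct.unpack_from("<I", buf, data_pos)[0]
            elif fourcc == b"strh" and buf[data_pos : data_pos + 4] == b"vids":
                scale, rate = struct.unpack_from("<II", buf, data_pos + 20)
            elif fourcc == b"strf" and width is None:
                _, width, height, _, bitcount = struct.unpack_from("<IiiHH", buf, data_pos)
            elif fourcc in (b"00db", b"00dc") and size > 0:
                frame_data.append(buf[data_pos : data_pos + size])

    walk(12, 8 + struct.unpack_from("<I", buf, 4)[0])

    if not frame_data:
        raise InputError(f"{path}: AVI contains no video frames")
    if width is None or height is None:
        raise InputError(f"{path}: missing stream format header")
    if bitcount != 8:
        raise InputError(f"{path}: only 8-bit greyscale AVI is supported (got {bitcount}-bit)")
    h, w = abs(height), width
    row_bytes = w + ((-w) % 4)
    frames = np.empty((len(frame_data), h, w), dtype=np.uint8)
    for i, data in enumerate(frame_data):
        if len(data) < row_bytes * h:
            raise InputError(f"{path}: frame {i} is truncated")
        arr = np.frombuffer(data[: row_bytes * h], dtype=np.uint8).reshape(h, row_bytes)[:, :w]
        frames[i] = arr[::-1] if height > 0 else arr  # bottom-up unless negative height
    if rate and scale:
        fps = rate / scale
    elif micro_per_frame:
        fps = 1e6 / micro_per_frame
    else:
        fps = 25.0
    return frames, float(fps)
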