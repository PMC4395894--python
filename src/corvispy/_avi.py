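"""Minimal uncompressed RIFF/AVI reader and writer.

Only the subset of the AVI container needed for grayscale Scheimpflug
sequences is supported: a single 'vids' stream of uncompressed 24-bit
DIB frames ('00db' chunks, bottom-up rows, BGR byte order). This is the
plain-vanilla AVI layout that any media tool can open.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

__all__ = ["write_avi", "read_avi"]


def _pad_width(width: int) -> int:
    # DIB rows are padded to 4-byte boundaries
    return (width * 3 + 3) & ~3


def write_avi(path: str | Path, frames: np.ndarray, frame_interval_us: float = 231.0) -> None:
    """Write a (T, H, W) uint8 grayscale stack as an uncompressed AVI."""
    frames = np.asarray(frames)
    if frames.ndim != 3:
        raise ValueError("frames must be a (T, H, W) array")
    t, h, w = frames.shape
    frames = np.clip(frames, 0, 255).astype(np.uint8)
    row_bytes = _pad_width(w)
    frame_bytes = row_bytes * h

    def chunk(fourcc: bytes, payload: bytes) -> bytes:
        pad = b"\x00" if len(payload) % 2 else b""
        return fourcc + struct.pack("<I", len(payload)) + payload + pad

    def lst(fourcc: bytes, payload: bytes) -> bytes:
        return chunk(b"LIST", fourcc + payload)

    avih = struct.pack(
        "<14I",
        int(frame_interval_us),  # dwMicroSecPerFrame
        frame_bytes * 1_000_000 // max(int(frame_interval_us), 1),
        0,
        0x10,  # AVIF_HASINDEX
        t, 0, 1, frame_bytes, w, h, 0, 0, 0, 0,
    )
    strh = struct.pack(
        "<4s4sIHHIIIIIIiI4h",
        b"vids", b"DIB ", 0, 0, 0, 0,
        int(frame_interval_us), 1_000_000,  # scale / rate -> fps
        0, t, frame_bytes, -1, 0,
        0, 0, w, h,
    )
    strf = struct.pack("<IiiHHIIiiII", 40, w, h, 1, 24, 0, frame_bytes, 0, 0, 0, 0)
    hdrl = lst(b"hdrl", chunk(b"avih", avih) + lst(b"strl", chunk(b"strh", strh) + chunk(b"strf", strf)))

    movi_parts = []
    idx_parts = []
    offset = 4  # relative to start of 'movi' fourcc
    for i in range(t):
        rows = frames[i][::-1]  # bottom-up
        bgr = np.repeat(rows[:, :, None], 3, axis=2)
        if row_bytes != w * 3:
            padded = np.zeros((h, row_bytes), dtype=np.uint8)
            padded[:, : w * 3] = bgr.reshape(h, w * 3)
            payload = padded.tobytes()
        else:
            payload = bgr.tobytes()
        movi_parts.append(chunk(b"00db", payload))
        idx_parts.append(struct.pack("<4sIII", b"00db", 0x10, offset, len(payload)))
        offset += 8 + len(payload) + (len(payload) % 2)
    movi = lst(b"movi", b"".join(movi_parts))
    idx1 = chunk(b"idx1", b"".join(idx_parts))

    body = b"AVI " + hdrl + movi + idx1
    with open(path, "wb") as fh:
        fh.write(b"RIFF" + struct.pack("<I", len(body)) + body)


def read_avi(path: str | Path) -> tuple[np.ndarray, float]:
    """Read an uncompressed 24-bit AVI into a (T, H, W, 3) uint8 array.

    Returns (frames, frame_interval_us). Raises ValueError for compressed
    or otherwise unsupported streams.
    """
    data = Path(path).read_bytes()
    if data[:4] != b"RIFF" or data[8:12] != b"AVI ":
        raise ValueError(f"not an AVI file: {path}")

    width = height = None
    bitcount = None
    interval_us = 0.0
    frames: list[np.ndarray] = []

    def walk(buf: bytes, pos: int, end: int) -> None:
        nonlocal width, height, bitcount, interval_us
        while pos + 8 <= end:
            fourcc = buf[pos : pos + 4]
            (size,) = struct.unpack_from("<I", buf, pos + 4)
            payload_start = pos + 8
            if fourcc == b"LIST":
                walk(buf, payload_start + 4, payload_start + size)
            elif fourcc == b"avih":
                interval_us = struct.unpack_from("<I", buf, payload_start)[0]
            elif fourcc == b"strf":
                (_, w, h, _, bc) = struct.unpack_from("<IiiHH", buf, payload_start)
                compression = struct.unpack_from("<I", buf, payload_start + 16)[0]
                if compression != 0:
                    raise ValueError("only uncompressed (DIB) AVI streams are supported")
                width, height, bitcount = w, abs(h), bc
            elif fourcc in (b"00db", b"00dc") and size > 0:
                frames.append(np.frombuffer(buf, dtype=np.uint8, count=size, offset=payload_start))
            pos = payload_start + size + (size % 2)

    walk(data, 12, len(data))
    if width is None or not frames:
        raise ValueError(f"no video frames found in {path}")
    if bitcount != 24:
        raise ValueError(f"unsupported AVI bit depth: {bitcount}")
    row_bytes = _pad_width(width)
    out = np.empty((len(frames), height, width, 3), dtype=np.uint8)
    for i, raw in enumerate(frames):
        rows = raw[: row_bytes * height].reshape(height, row_bytes)[:, : width * 3]
        bgr = rows.reshape(height, width, 3)[::-1]
        out[i] = bgr[:, :, ::-1]  # BGR -> RGB
    return out, float(interval_us)
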