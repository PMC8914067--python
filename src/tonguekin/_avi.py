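"""Minimal uncompressed AVI (RIFF) reader and writer.

Lossless fixture clips need a container that round-trips frames
byte-exactly.  This module writes and reads the plain RIFF/AVI layout
with uncompressed DIB video: 24-bit BGR, bottom-up rows padded to four
bytes, one ``00db`` chunk per frame.  Only what the package itself
produces is supported -- a single video stream, no audio, no index
requirement (an idx1 is written for player compatibility and ignored on
read).
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

_FPS_SCALE = 1000  # frame rate stored as a rational dwRate/dwScale


def _pad_row(width: int) -> int:
    return (width * 3 + 3) & ~3


def write_avi(path: str | Path, frames: np.ndarray, fps: float) -> None:
    """Write ``frames`` (n, h, w, 3) uint8 RGB to an uncompressed AVI."""
    frames = np.asarray(frames)
    if frames.ndim != 4 or frames.shape[-1] != 3 or frames.dtype != np.uint8:
        raise ValueError("frames must be (n, h, w, 3) uint8")
    n, h, w, _ = frames.shape
    row_bytes = _pad_row(w)
    frame_bytes = row_bytes * h

    def chunk(fourcc: bytes, payload: bytes) -> bytes:
        pad = b"\x00" if len(payload) % 2 else b""
        return fourcc + struct.pack("<I", len(payload)) + payload + pad

    def list_chunk(list_type: bytes, payload: bytes) -> bytes:
        return chunk(b"LIST", list_type + payload)

    avih = struct.pack(
        "<14I",
        int(round(1e6 / fps)),  # microseconds per frame
        frame_bytes * int(round(fps)),  # max bytes per second (approx)
        0,  # padding granularity
        0x10,  # flags: AVIF_HASINDEX
        n, 0, 1, frame_bytes, w, h, 0, 0, 0, 0,
    )
    strh = struct.pack(
        "<4s4sIHHIIIIIIIIhhhh",
        b"vids", b"DIB ", 0, 0, 0, 0,
        _FPS_SCALE, int(round(fps * _FPS_SCALE)),
        0, n, frame_bytes, 0xFFFFFFFF, 0, 0, 0, w, h,
    )
    strf = struct.pack("<IiiHHIIiiII", 40, w, h, 1, 24, 0, frame_bytes, 0, 0, 0, 0)
    hdrl = list_chunk(
        b"hdrl",
        chunk(b"avih", avih)
        + list_chunk(b"strl", chunk(b"strh", strh) + chunk(b"strf", strf)),
    )

    movi_payload = bytearray(b"movi")
    index = bytearray()
    offset = 4  # relative to start of 'movi' fourcc
    for f in frames:
        bgr = f[::-1, :, ::-1]  # bottom-up rows, BGR channel order
        rows = np.zeros((h, row_bytes), dtype=np.uint8)
        rows[:, : w * 3] = bgr.reshape(h, w * 3)
        payload = rows.tobytes()
        movi_payload += chunk(b"00db", payload)
        index += b"00db" + struct.pack("<III", 0x10, offset, len(payload))
        offset += 8 + len(payload) + (len(payload) % 2)
    movi = chunk(b"LIST", bytes(movi_payload))
    idx1 = chunk(b"idx1", bytes(index))

    riff_payload = b"AVI " + hdrl + movi + idx1
    with open(path, "wb") as fh:
        fh.write(b"RIFF" + struct.pack("<I", len(riff_payload)) + riff_payload)


def read_avi(path: str | Path) -> tuple[np.ndarray, float]:
    """Read an uncompressed AVI; returns ((n, h, w, 3) uint8 RGB, fps)."""
    data = Path(path).read_bytes()
    if data[:4] != b"RIFF" or data[8:12] != b"AVI ":
        raise IOError(f"not an AVI file: {path}")

    fps: float | None = None
    width = height = None
    frames: list[np.ndarray] = []

    def walk(buf: bytes, pos: int, end: int) -> None:
        nonlocal fps, width, height
        while pos + 8 <= end:
            fourcc = buf[pos : pos + 4]
            size = struct.unpack("<I", buf[pos + 4 : pos + 8])[0]
            body = pos + 8
            if fourcc == b"LIST":
                walk(buf, body + 4, body + size)
            elif fourcc == b"strh" and buf[body : body + 4] == b"vids":
                scale, rate = struct.unpack("<II", buf[body + 20 : body + 28])
                if scale:
                    fps = rate / scale
            elif fourcc == b"strf":
                w_, h_, _, bpp = struct.unpack("<iiHH", buf[body + 4 : body + 16])
                if bpp != 24:
                    raise IOError(f"unsupported AVI bit depth {bpp}: {path}")
                width, height = w_, abs(h_)
            elif fourcc in (b"00db", b"00dc") and size > 0:
                if width is None or height is None:
                    raise IOError(f"AVI frame before stream format: {path}")
                row_bytes = _pad_row(width)
                raw = np.frombuffer(buf, np.uint8, row_bytes * height, body)
                rows = raw.reshape(height, row_bytes)[:, : width * 3]
                bgr = rows.reshape(height, width, 3)
                frames.append(bgr[::-1, :, ::-1].copy())
            pos = body + size + (size % 2)

    walk(data, 12, len(data))
    if not frames:
        raise IOError(f"no video frames found in {path}")
    if fps is None:
        raise IOError(f"no video stream header found in {path}")
    return np.stack(frames), fps
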