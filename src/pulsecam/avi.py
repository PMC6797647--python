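"""Minimal uncompressed RGB AVI container I/O.

Supports exactly the container that consumer webcams produce when asked for
uncompressed output: a RIFF/AVI file with a single ``vids`` stream of
BI_RGB device-independent bitmaps (24-bit BGR, rows bottom-up, 4-byte row
alignment).  Compressed streams are rejected with a clear error; transcode
to uncompressed AVI first.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

__all__ = ["read_rgb_avi", "write_rgb_avi", "AviFormatError"]


class AviFormatError(ValueError):
    """Raised when a file is not an AVI this package can decode."""


def _pad4(n: int) -> int:
    return (n + 3) & ~3


def write_rgb_avi(path: str | Path, frames: np.ndarray, fps: float) -> None:
    """Write ``frames`` (n, H, W, 3) uint8 RGB as an uncompressed AVI.

    The stream is stored as standard BI_RGB DIBs (BGR channel order,
    bottom-up rows, rows padded to 4 bytes), so the output opens in any
    stock video player.
    """
    frames = np.asarray(frames)
    if frames.ndim != 4 or frames.shape[-1] != 3 or frames.dtype != np.uint8:
        raise ValueError("frames must be an (n, H, W, 3) uint8 array")
    if not np.isfinite(fps) or fps <= 0:
        raise ValueError(f"fps must be finite and > 0, got {fps}")
    n, h, w, _ = frames.shape
    row_bytes = _pad4(w * 3)
    frame_bytes = row_bytes * h

    # RGB -> BGR, flip vertically, pad rows to 4-byte boundaries
    dib = np.zeros((n, h, row_bytes), dtype=np.uint8)
    dib[:, :, : w * 3] = frames[:, ::-1, :, ::-1].reshape(n, h, w * 3)

    scale = 1000
    rate = int(round(fps * scale))

    avih = struct.pack(
        "<IIIIIIIIIIIIII",
        int(round(1e6 / fps)),  # microseconds per frame
        frame_bytes * int(np.ceil(fps)),  # max bytes/sec (advisory)
        0,  # padding granularity
        0x10,  # AVIF_HASINDEX
        n, 0, 1, frame_bytes, w, h, 0, 0, 0, 0,
    )
    strh = struct.pack(
        "<4s4sIHHIIIIIIIIhhhh",
        b"vids", b"DIB ", 0, 0, 0, 0,
        scale, rate, 0, n, frame_bytes, 0xFFFFFFFF, 0,
        0, 0, w, h,
    )
    strf = struct.pack(
        "<IiiHHIIiiII", 40, w, h, 1, 24, 0, frame_bytes, 0, 0, 0, 0
    )

    def chunk(fourcc: bytes, payload: bytes) -> bytes:
        pad = b"\x00" if len(payload) % 2 else b""
        return fourcc + struct.pack("<I", len(payload)) + payload + pad

    def list_chunk(kind: bytes, payload: bytes) -> bytes:
        return chunk(b"LIST", kind + payload)

    strl = list_chunk(b"strl", chunk(b"strh", strh) + chunk(b"strf", strf))
    hdrl = list_chunk(b"hdrl", chunk(b"avih", avih) + strl)

    movi_payload = b"".join(chunk(b"00db", d.tobytes()) for d in dib)
    movi = list_chunk(b"movi", movi_payload)

    # idx1: offsets relative to the start of the 'movi' fourcc payload
    idx_entries = []
    off = 4  # past the 'movi' fourcc
    for _ in range(n):
        idx_entries.append(struct.pack("<4sIII", b"00db", 0x10, off, frame_bytes))
        off += 8 + frame_bytes + (frame_bytes % 2)
    idx1 = chunk(b"idx1", b"".join(idx_entries))

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


def read_rgb_avi(path: str | Path) -> tuple[np.ndarray, float]:
    """Read an uncompressed 24-bit AVI; return ((n, H, W, 3) RGB uint8, fps)."""
    buf = Path(path).read_bytes()
    if len(buf) < 12 or buf[:4] != b"RIFF" or buf[8:12] != b"AVI ":
        raise AviFormatError(f"{path}: not a RIFF/AVI file")

    width = height = None
    fps = None
    compression = None
    bit_count = None
    frames_raw: list[bytes] = []

    def walk(start: int, end: int) -> None:
        nonlocal width, height, fps, compression, bit_count
        for fourcc, data_off, size in _iter_chunks(buf, start, end):
            data_end = min(data_off + size, len(buf))
            if fourcc == b"LIST":
                walk(data_off + 4, data_end)
            elif fourcc == b"strh" and size >= 40:
                fcc_type = buf[data_off : data_off + 4]
                if fcc_type == b"vids" and fps is None:
                    scale, rate = struct.unpack_from("<II", buf, data_off + 20)
                    if scale > 0 and rate > 0:
                        fps = rate / scale
            elif fourcc == b"strf" and size >= 40 and width is None:
                (_, w, h, _, bits, comp) = struct.unpack_from(
                    "<IiiHHI", buf, data_off
                )
                width, height, bit_count, compression = w, abs(h), bits, comp
            elif fourcc in (b"00db", b"00dc") and size > 0:
                frames_raw.append(buf[data_off:data_end])

    walk(12, len(buf))

    if width is None or height is None:
        raise AviFormatError(f"{path}: no video stream header found")
    if compression not in (0,) or bit_count != 24:
        raise AviFormatError(
            f"{path}: only uncompressed 24-bit (BI_RGB) AVI is supported "
            f"(biCompression={compression}, biBitCount={bit_count})"
        )
    if not frames_raw:
        raise AviFormatError(f"{path}: AVI contains no frames")

    row_bytes = _pad4(width * 3)
    expected = row_bytes * height
    out = np.empty((len(frames_raw), height, width, 3), dtype=np.uint8)
    for i, raw in enumerate(frames_raw):
        if len(raw) < expected:
            raise AviFormatError(f"{path}: frame {i} truncated")
        rows = np.frombuffer(raw[:expected], dtype=np.uint8).reshape(height, row_bytes)
        bgr = rows[:, : width * 3].reshape(height, width, 3)
        out[i] = bgr[::-1, :, ::-1]  # bottom-up BGR -> top-down RGB
    return out, float(fps) if fps else 0.0
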