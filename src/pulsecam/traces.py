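"""Mean-color pulse traces and low-frequency detrending.

Averaging the selected skin pixels per frame and color channel collapses a
video into three time series.  The cardiac signal is a sub-1% intensity
modulation riding on slow drifts from illumination and movement; a
zero-phase low-pass Butterworth filter estimates that drift, which is then
subtracted, leaving traces that fluctuate around zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .skin import SkinMask
from .video import FrameSequence

__all__ = ["ChannelTraces", "channel_means", "detrend"]


@dataclass(frozen=True)
class ChannelTraces:
    """Aligned mean-intensity time series for the R, G, B channels."""

    r: np.ndarray = field(repr=False)
    g: np.ndarray = field(repr=False)
    b: np.ndarray = field(repr=False)
    fps: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        n = len(self.r)
        if not (len(self.g) == len(self.b) == n):
            raise ValueError("channel traces must have equal length")
        if n < 2:
            raise ValueError("traces need at least 2 samples")
        for name in ("r", "g", "b"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"non-finite values in channel {name}")
        if not (np.isfinite(self.fps) and self.fps > 0):
            raise ValueError(f"fps must be finite and > 0, got {self.fps}")

    @property
    def n(self) -> int:
        return len(self.r)

    @property
    def t(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.fps

    def as_matrix(self) -> np.ndarray:
        """(n, 3) array with columns R, G, B."""
        return np.column_stack([self.r, self.g, self.b])

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"t": self.t, "r": self.r, "g": self.g, "b": self.b}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "ChannelTraces":
        df = pd.read_csv(path)
        t = df["t"].to_numpy(float)
        if len(t) < 2:
            raise ValueError(f"{path}: need at least 2 samples")
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=1e-6):
            raise ValueError(f"{path}: time column is not uniformly sampled")
        return cls(
            r=df["r"].to_numpy(float),
            g=df["g"].to_numpy(float),
            b=df["b"].to_numpy(float),
            fps=1.0 / dt[0],
            t0=float(t[0]),
        )


def channel_means(seq: FrameSequence, masks: list[SkinMask]) -> ChannelTraces:
    """Arithmetic mean of the selected pixels, per frame and channel."""
    if len(masks) != seq.n_frames:
        raise ValueError(
            f"need one mask per frame: {len(masks)} masks for {seq.n_frames} frames"
        )
    out = np.empty((seq.n_frames, 3), dtype=np.float64)
    for i, m in enumerate(masks):
        if m.n_selected == 0:
            raise ValueError(f"empty skin mask at frame {i}")
        sel = seq.frames[i][m.mask]  # (n_selected, 3)
        out[i] = sel.mean(axis=0)
    return ChannelTraces(r=out[:, 0], g=out[:, 1], b=out[:, 2], fps=seq.fps, t0=seq.t0)


def detrend(
    traces: ChannelTraces, cutoff_hz: float = 0.04, order: int = 6
) -> ChannelTraces:
    """Remove low-frequency drift by subtracting a zero-phase low-pass.

    Per channel, a Butterworth low-pass (cutoff_hz is the -3 dB point of
    the single-pass design) is applied forward and backward (zero phase;
    attenuation order effectively doubled) to estimate the drift, which is
    subtracted from the raw trace.  Edge transients are controlled by
    even-reflection (zero-slope) padding spanning a stretch comparable to
    the filter's impulse-response length.
    """
    if traces.fps <= 2 * cutoff_hz:
        raise ValueError(
            f"fps {traces.fps} must exceed twice the cutoff {cutoff_hz} Hz"
        )
    sos = sps.butter(order, cutoff_hz, btype="low", fs=traces.fps, output="sos")
    min_len = 3 * (2 * order + 1)
    if traces.n <= min_len:
        raise ValueError(
            f"trace of {traces.n} samples too short to detrend; need more than "
            f"{min_len} samples for the filter's startup padding"
        )
    # The drift filter's impulse response spans seconds (~1/cutoff); pad by
    # a comparable stretch (capped at n-1) or edge transients leak inward.
    padlen = min(traces.n - 1, int(np.ceil(1.5 * traces.fps / cutoff_hz)))

    def one(x: np.ndarray) -> np.ndarray:
        low = sps.sosfiltfilt(sos, x, padtype="even", padlen=padlen)
        return x - low

    return replace(traces, r=one(traces.r), g=one(traces.g), b=one(traces.b))
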