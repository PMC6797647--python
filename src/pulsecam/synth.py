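"""Ground-truthed synthetic pulse traces and videos.

The generator emulates the statistical structure a webcam sees when
pointed at illuminated skin: a mean skin color around RGB (208, 150, 136),
modulated by a small cardiac sinusoid (strongest in the green channel,
where hemoglobin absorption peaks), optionally a larger respiration
component and a slow illumination drift, plus per-pixel Gaussian sensor
noise, surrounded by a non-skin background.  Every parameter of the truth
is known, so each pipeline stage — and the pipeline end to end — can be
verified by parameter recovery without any recorded human data.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .avi import write_rgb_avi
from .traces import ChannelTraces
from .video import BBox, FrameSequence

__all__ = ["SynthSpec", "synth_traces", "synth_video", "write_synth_dataset"]

#: Relative cardiac modulation strength per color channel (R, G, B).  The
#: green channel carries the strongest pulsatile signal; the exact ratios
#: are a modelling choice, configurable per spec.
CARDIAC_WEIGHTS = (0.5, 1.0, 0.3)


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of a synthetic recording; defaults give a clean resting
    face-like recording at webcam settings (30 fps, 30 s).

    Amplitudes are in 8-bit intensity units.  ``resp_weights`` defaults to
    the cardiac channel weights: respiration-induced blood-volume
    variation modulates the same color direction as the pulse, which is
    why both peaks appear in a single component spectrum after source
    separation (the situation the respiration-rejection rule addresses).
    Set ``resp_weights=(1, 1, 1)`` for an achromatic movement-like
    confound instead.
    """

    hr_bpm: float = 75.0
    hr_amp: float = 2.0
    resp_bpm: float | None = None
    resp_amp: float = 0.0
    drift_amp: float = 0.0
    drift_period_s: float = 30.0
    noise_sd: float = 1.0
    skin_rgb: tuple[float, float, float] = (208.0, 150.0, 136.0)
    bg_rgb: tuple[float, float, float] = (50.0, 80.0, 200.0)
    fps: float = 30.0
    duration_s: float = 30.0
    frame_hw: tuple[int, int] = (60, 60)
    skin_box: BBox = field(default_factory=lambda: BBox(10, 10, 40, 40))
    seed: int = 0
    channel_weights: tuple[float, float, float] = CARDIAC_WEIGHTS
    resp_weights: tuple[float, float, float] | None = None

    def validate(self) -> None:
        problems = []
        if not 40 <= self.hr_bpm <= 200:
            problems.append(f"hr_bpm {self.hr_bpm} outside the in-band range [40, 200]")
        if self.resp_bpm is not None and not 0 < self.resp_bpm < 90:
            problems.append(f"resp_bpm {self.resp_bpm} must be in (0, 90)")
        for name in ("hr_amp", "resp_amp", "drift_amp", "noise_sd"):
            if getattr(self, name) < 0:
                problems.append(f"{name} must be >= 0")
        if self.duration_s <= 6:
            problems.append("duration_s must exceed 6 s to survive temporal cropping")
        if self.fps <= 0:
            problems.append("fps must be > 0")
        if self.drift_period_s <= 0:
            problems.append("drift_period_s must be > 0")
        h, w = self.frame_hw
        if not self.skin_box.fits(h, w):
            problems.append(f"skin_box {self.skin_box} does not fit in frame {h}x{w}")
        if problems:
            raise ValueError("invalid SynthSpec: " + "; ".join(problems))

    def truth(self) -> dict:
        d = asdict(self)
        d["skin_box"] = [self.skin_box.x, self.skin_box.y, self.skin_box.w, self.skin_box.h]
        return d


def _clean_signal(spec: SynthSpec) -> np.ndarray:
    """Noise-free per-channel signal, shape (n, 3)."""
    n = int(round(spec.duration_s * spec.fps))
    t = np.arange(n) / spec.fps
    w = np.asarray(spec.channel_weights, dtype=float)
    rw = np.asarray(
        spec.resp_weights if spec.resp_weights is not None else spec.channel_weights,
        dtype=float,
    )
    x = np.tile(np.asarray(spec.skin_rgb, dtype=float), (n, 1))
    x += spec.hr_amp * np.outer(np.sin(2 * np.pi * spec.hr_bpm / 60.0 * t), w)
    if spec.resp_bpm is not None and spec.resp_amp > 0:
        x += spec.resp_amp * np.outer(np.sin(2 * np.pi * spec.resp_bpm / 60.0 * t), rw)
    if spec.drift_amp > 0:
        x += spec.drift_amp * np.sin(2 * np.pi * t / spec.drift_period_s)[:, None]
    return x


def synth_traces(spec: SynthSpec) -> tuple[ChannelTraces, dict]:
    """Mean-color traces with additive Gaussian channel noise, plus truth."""
    spec.validate()
    x = _clean_signal(spec)
    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd > 0:
        x = x + rng.normal(0.0, spec.noise_sd, size=x.shape)
    tr = ChannelTraces(r=x[:, 0], g=x[:, 1], b=x[:, 2], fps=spec.fps)
    return tr, spec.truth()


def synth_video(spec: SynthSpec, path: str | Path | None = None) -> tuple[FrameSequence, dict]:
    """8-bit RGB frame stream: noisy background, skin box carrying the
    pulse signal plus independent per-pixel sensor noise.

    Per-pixel noise doubles as dither: when the cardiac amplitude is below
    one intensity quantum, averaging many noisy pixels still recovers the
    sub-quantum modulation, which plain 8-bit rounding would destroy.
    Hence the warning when ``hr_amp < 1`` with ``noise_sd < 0.5``.
    """
    spec.validate()
    if spec.hr_amp < 1.0 and spec.noise_sd < 0.5:
        warnings.warn(
            "hr_amp < 1 intensity quantum with noise_sd < 0.5: the cardiac "
            "modulation may be lost to 8-bit quantization (noise dithering "
            "is needed to preserve it)",
            stacklevel=2,
        )
    x = _clean_signal(spec)  # (n, 3)
    n = x.shape[0]
    h, w = spec.frame_hw
    box = spec.skin_box
    rng = np.random.default_rng(spec.seed)

    frames = np.empty((n, h, w, 3), dtype=np.uint8)
    bg = np.asarray(spec.bg_rgb, dtype=float)
    for i in range(n):
        frame = np.tile(bg, (h, w, 1))
        frame[box.y : box.y + box.h, box.x : box.x + box.w, :] = x[i]
        if spec.noise_sd > 0:
            frame = frame + rng.normal(0.0, spec.noise_sd, size=frame.shape)
        frames[i] = np.clip(np.rint(frame), 0, 255).astype(np.uint8)

    seq = FrameSequence(frames=frames, fps=spec.fps)
    if path is not None:
        write_rgb_avi(path, frames, spec.fps)
    return seq, spec.truth()


def write_synth_dataset(
    out_dir: str | Path, specs: list[SynthSpec], ids: list[str] | None = None
) -> pd.DataFrame:
    """Write AVI + truth JSON per spec, plus a manifest with reference HR.

    The reference column mimics the pulse-oximeter reference file used for
    benchmarking; here the reference is the generator's ground truth.
    Returns the manifest (video_id, video_path, hr_reference).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if ids is None:
        ids = [f"synth{i:03d}" for i in range(len(specs))]
    rows = []
    for vid, spec in zip(ids, specs):
        avi_path = out_dir / f"{vid}.avi"
        _, truth = synth_video(spec, path=avi_path)
        (out_dir / f"{vid}.truth.json").write_text(json.dumps(truth, indent=2))
        rows.append(
            {"video_id": vid, "video_path": str(avi_path), "hr_reference": spec.hr_bpm}
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
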