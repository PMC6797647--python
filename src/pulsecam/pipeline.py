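"""End-to-end orchestration of the seven processing steps.

(i) spatiotemporal cropping, (ii) skin selection, (iii) averaging and
detrending, (iv) independent component analysis, (v) FFT power spectra,
(vi) spectral smoothing, (vii) respiration/movement rejection.  Every
constant of the method lives in :class:`PipelineConfig` with its published
default; ablation flags switch off ICA (the detrended green trace is then
analyzed directly), spectral smoothing, or the respiration rule, mirroring
the method-comparison columns of the original validation study.
"""

from __future__ import annotations

import dataclasses
import logging
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import spectrum as hrspec
from .ica import ComponentSet, run_ica
from .skin import WedgeSpec, mask_per_frame
from .spectrum import EstimationError, HRResult, estimate_hr
from .traces import ChannelTraces, channel_means, detrend
from .video import BBox, FrameSequence, crop_roi, crop_time, load_frames, locate_face

__all__ = ["PipelineConfig", "StageError", "run_pipeline", "run_from_traces", "run_batch"]

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}': {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable parameters of the estimation pipeline.

    Defaults are the published method constants: 3 s head/tail crops,
    k-means with 4 clusters / 100 iterations, 0.04 Hz sixth-order
    detrending, 3 ICA components / 2000 iterations, third-order spectral
    smoothing at a 0.2 normalized cutoff, and the 90 BPM / 70% respiration
    rule.
    """

    head_s: float = 3.0
    tail_s: float = 3.0
    skin_method: str = "auto"  # "auto" (k-means) or "wedge"
    kmeans_k: int = 4
    kmeans_max_iter: int = 100
    wedge_hue_center: float = 15.0
    wedge_hue_halfwidth: float = 25.0
    wedge_sat_min: float = 0.15
    wedge_sat_max: float = 0.80
    detrend_cutoff_hz: float = 0.04
    detrend_order: int = 6
    ica_components: int = 3
    ica_max_iter: int = 2000
    seed: int = 0
    smooth_order: int = 3
    smooth_cutoff: float = 0.2
    peak_band_lo_bpm: float = hrspec.DEFAULT_PEAK_BAND[0]
    peak_band_hi_bpm: float = hrspec.DEFAULT_PEAK_BAND[1]
    hr_band_lo_bpm: float = hrspec.DEFAULT_HR_BAND[0]
    hr_band_hi_bpm: float = hrspec.DEFAULT_HR_BAND[1]
    resp_cutoff_bpm: float = 90.0
    resp_ratio: float = 0.70
    use_ica: bool = True
    use_lff: bool = True
    use_resp: bool = True

    def __post_init__(self) -> None:
        if self.skin_method not in ("auto", "wedge"):
            raise ValueError(f"skin_method must be 'auto' or 'wedge', got {self.skin_method!r}")
        if self.head_s < 0 or self.tail_s < 0:
            raise ValueError("crop durations must be >= 0")
        if not 0 < self.resp_ratio <= 1:
            raise ValueError("resp_ratio must be in (0, 1]")
        if self.peak_band_lo_bpm >= self.peak_band_hi_bpm:
            raise ValueError("peak band must be nonempty")
        if self.hr_band_lo_bpm >= self.hr_band_hi_bpm:
            raise ValueError("HR band must be nonempty")

    @property
    def wedge(self) -> WedgeSpec:
        return WedgeSpec(
            hue_center=self.wedge_hue_center,
            hue_halfwidth=self.wedge_hue_halfwidth,
            sat_min=self.wedge_sat_min,
            sat_max=self.wedge_sat_max,
        )

    def save(self, path: str | Path) -> None:
        """Write the config as flat TOML."""
        lines = []
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, bool):
                lines.append(f"{f.name} = {'true' if v else 'false'}")
            elif isinstance(v, str):
                lines.append(f'{f.name} = "{v}"')
            else:
                lines.append(f"{f.name} = {v!r}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            self.start = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.start
            if exc is None:
                logger.info("stage %-18s %.3fs", name, dt)
                return False
            if isinstance(exc, StageError):
                return False
            raise StageError(name, exc) from exc

    return _Ctx()


def run_from_traces(traces: ChannelTraces, config: PipelineConfig | None = None) -> HRResult:
    """Steps iii (detrend) through vii from saved channel traces."""
    config = config or PipelineConfig()
    with _stage("detrend"):
        det = detrend(traces, cutoff_hz=config.detrend_cutoff_hz, order=config.detrend_order)
    with _stage("ica"):
        if config.use_ica:
            comps = run_ica(
                det,
                n_components=config.ica_components,
                max_iter=config.ica_max_iter,
                seed=config.seed,
            )
        else:
            g = det.g
            comps = ComponentSet(
                components=(g / (g.std() or 1.0))[None, :],
                fps=det.fps,
                mixing=np.array([[0.0], [1.0], [0.0]]),
                seed=config.seed,
            )
    with _stage("spectrum"):
        return estimate_hr(
            comps,
            smooth=config.use_lff,
            smooth_order=config.smooth_order,
            smooth_cutoff=config.smooth_cutoff,
            peak_band_bpm=(config.peak_band_lo_bpm, config.peak_band_hi_bpm),
            hr_band_bpm=(config.hr_band_lo_bpm, config.hr_band_hi_bpm),
            respiration_rejection=config.use_resp,
            resp_cutoff_bpm=config.resp_cutoff_bpm,
            resp_ratio=config.resp_ratio,
        )


def run_pipeline(
    video: str | Path | FrameSequence,
    config: PipelineConfig | None = None,
    roi: BBox | None = None,
    detector=None,
) -> HRResult:
    """Steps i-vii on a video file or in-memory frame sequence.

    ``roi`` is the manual region of interest; without it an injected face
    ``detector`` is consulted, and failing both, the full frame is used.
    Deterministic given ``config.seed``.
    """
    config = config or PipelineConfig()
    with _stage("load"):
        seq = video if isinstance(video, FrameSequence) else load_frames(video)
    with _stage("crop_time"):
        seq = crop_time(seq, head_s=config.head_s, tail_s=config.tail_s)
    with _stage("crop_roi"):
        if roi is None and detector is not None:
            roi = locate_face(seq, detector=detector)
        if roi is not None:
            seq = crop_roi(seq, roi)
        h, w = seq.frame_shape
        box = BBox(0, 0, w, h)
    with _stage("skin_mask"):
        masks = mask_per_frame(
            seq,
            box,
            method="auto" if config.skin_method == "auto" else "wedge",
            wedge=config.wedge,
            k=config.kmeans_k,
            max_iter=config.kmeans_max_iter,
            seed=config.seed,
        )
        logger.info(
            "skin masks: %d frames, median %d px selected",
            len(masks),
            int(np.median([m.n_selected for m in masks])),
        )
    with _stage("channel_means"):
        traces = channel_means(seq, masks)
    return run_from_traces(traces, config)


def run_batch(
    manifest: str | Path | pd.DataFrame,
    config: PipelineConfig | None = None,
    out_csv: str | Path | None = None,
) -> pd.DataFrame:
    """Run the pipeline over a manifest of videos; failures become rows,
    not crashes.

    The manifest needs a ``video_path`` column; ``video_id``, condition
    columns and an optional ``hr_reference`` column are carried through.
    Optional ``roi`` column format: "x,y,w,h".
    """
    config = config or PipelineConfig()
    if not isinstance(manifest, pd.DataFrame):
        path = Path(manifest)
        if not path.exists():
            raise IOError(f"manifest not found: {path}")
        manifest = pd.read_csv(path)
    if manifest.empty:
        logger.warning("empty manifest: no videos to process")
        return pd.DataFrame(columns=["video_id", "video_path", "hr_rppg", "error"])

    rows = []
    for _, rec in manifest.iterrows():
        row = rec.to_dict()
        roi = None
        if isinstance(row.get("roi"), str):
            x, y, w, h = (int(v) for v in row["roi"].split(","))
            roi = BBox(x, y, w, h)
        try:
            result = run_pipeline(row["video_path"], config, roi=roi)
            row.update(
                hr_rppg=result.hr_bpm,
                component_index=result.component_index,
                respiration_rule_fired=result.respiration_rule_fired,
                error="",
            )
        except (StageError, EstimationError, IOError, ValueError) as exc:
            logger.error("video %s failed: %s", row.get("video_id", row["video_path"]), exc)
            row.update(hr_rppg=np.nan, error=str(exc))
        rows.append(row)
    out = pd.DataFrame(rows)
    if out_csv is not None:
        out.to_csv(out_csv, index=False)
    return out
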