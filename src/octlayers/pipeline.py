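"""End-to-end segmentation of B-scans and volumes."""
from __future__ import annotations

import dataclasses
import time
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence, Union

import numpy as np

from .core import BOUNDARY_ORDER, BScan, Polarity, ValidationError, Volume
from .enhance import (
    EnhancedImage,
    PeakMap,
    axial_gradient,
    boundary_enhance,
    denoise,
    large_scale_smooth,
    nonmax_suppress_axial,
)
from .identify import Segmentation, extract_components, identify_boundaries, smooth_curves
from .trace import SearchConfig, TraceResult, trace_channel


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable of the segmentation pipeline in one place."""

    denoise: bool = True
    smooth_window: tuple[int, int] = (9, 9)
    min_response_frac: float = 0.05  # NMS floor as a fraction of the enhanced max
    search: SearchConfig = field(default_factory=SearchConfig)
    trace_signal: str = "enhanced"   # trace on the enhanced or the raw gradient image
    smooth_sigma: float = 3.0        # final curve smoothing, in columns
    min_span_frac: float = 0.9       # minimum candidate width fraction
    pixel_size_axial: float = 3.9    # um / px
    pixel_size_lateral: float = 6.0  # um / px
    volume_stride: int = 1           # segment every k-th slice, interpolate the rest

    def __post_init__(self) -> None:
        if isinstance(self.search, dict):
            object.__setattr__(self, "search", SearchConfig(**self.search))
        object.__setattr__(self, "smooth_window", tuple(self.smooth_window))
        if self.trace_signal not in ("enhanced", "gradient"):
            raise ValidationError("trace_signal: must be 'enhanced' or 'gradient'")
        if self.volume_stride < 1:
            raise ValidationError("volume_stride: must be >= 1")
        if not 0 <= self.min_response_frac <= 1:
            raise ValidationError("min_response_frac: must lie in [0, 1]")
        if not 0 < self.min_span_frac <= 1:
            raise ValidationError("min_span_frac: must lie in (0, 1]")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["smooth_window"] = list(self.smooth_window)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)


class ChannelArtifacts(NamedTuple):
    gradient: EnhancedImage
    enhanced: EnhancedImage
    peaks: PeakMap
    trace: TraceResult
    candidates: list[np.ndarray]


class SegmentationResult(NamedTuple):
    segmentation: Segmentation
    channels: dict[Polarity, ChannelArtifacts]
    timings: dict[str, float]


def segment_bscan(
    bscan: BScan, config: Optional[PipelineConfig] = None, source: str = ""
) -> SegmentationResult:
    """Run the full segmentation pipeline on one B-scan.

    Stages: denoise -> per-polarity (axial gradient, large-scale smooth,
    boundary enhance, axial NMS, seed-band tracing, path
    superposition, dual-threshold selection, component extraction) ->
    boundary identification -> curve smoothing.
    """
    config = config or PipelineConfig()
    timings: dict[str, float] = {}
    t0 = time.perf_counter()
    den = denoise(bscan) if config.denoise else bscan
    timings["denoise"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    smooth = large_scale_smooth(den, config.smooth_window)
    timings["large_scale_smooth"] = time.perf_counter() - t0

    channels: dict[Polarity, ChannelArtifacts] = {}
    for pol in (Polarity.DARK_TO_BRIGHT, Polarity.BRIGHT_TO_DARK):
        t0 = time.perf_counter()
        grad = axial_gradient(den, pol)
        enh = boundary_enhance(grad, smooth)
        m = float(enh.pixels.max()) if enh.pixels.size else 0.0
        peaks = nonmax_suppress_axial(enh, config.min_response_frac * m)
        trace_on = enh if config.trace_signal == "enhanced" else grad
        result = trace_channel(trace_on, peaks, config.search, full=True)
        cands = extract_components(
            result.mask,
            weights=result.probability,
            min_span_frac=config.min_span_frac,
            signal=enh,
            lost_fraction=result.lost_fraction,
        )
        channels[pol] = ChannelArtifacts(grad, enh, peaks, result, cands)
        timings[f"channel_{pol.value}"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    seg = identify_boundaries(
        channels[Polarity.DARK_TO_BRIGHT].candidates,
        channels[Polarity.BRIGHT_TO_DARK].candidates,
        channels[Polarity.DARK_TO_BRIGHT].enhanced,
        channels[Polarity.BRIGHT_TO_DARK].enhanced,
        shape=bscan.shape,
        source=source,
    )
    seg = smooth_curves(seg, config.smooth_sigma)
    timings["identify"] = time.perf_counter() - t0
    return SegmentationResult(seg, channels, timings)


class VolumeResult(NamedTuple):
    segmentations: list[Segmentation]
    segmented_indices: list[int]


def segment_volume(
    volume: Union[Volume, np.ndarray, Sequence[np.ndarray]],
    config: Optional[PipelineConfig] = None,
    stride: Optional[int] = None,
    source: str = "",
) -> VolumeResult:
    """Segment a volume, optionally only every ``stride``-th slice.

    Skipped slices receive boundary surfaces linearly interpolated
    between the nearest segmented slices (the last slice is always
    segmented so no extrapolation is needed).
    """
    config = config or PipelineConfig()
    stride = stride if stride is not None else config.volume_stride
    if stride < 1:
        raise ValidationError("stride: must be >= 1")
    if isinstance(volume, Volume):
        stack = volume.pixels
    else:
        arrs = [np.asarray(s, float) for s in volume] if not isinstance(
            volume, np.ndarray
        ) else list(np.asarray(volume, float))
        shapes = {a.shape for a in arrs}
        if len(shapes) != 1:
            raise ValidationError(f"mixed slice shapes in the volume: {sorted(shapes)}")
        stack = np.stack(arrs)
    n = stack.shape[0]
    if n < 1:
        raise ValidationError("volume must contain at least one slice")

    indices = sorted(set(range(0, n, stride)) | {n - 1})
    segmented: dict[int, Segmentation] = {}
    for i in indices:
        b = BScan(stack[i], config.pixel_size_axial, config.pixel_size_lateral)
        segmented[i] = segment_bscan(b, config, source=f"{source}[{i}]").segmentation

    segs: list[Segmentation] = []
    idx = np.asarray(indices)
    rows_by_index = {i: segmented[i].rows_array() for i in indices}
    for i in range(n):
        if i in segmented:
            segs.append(segmented[i])
            continue
        i0 = int(idx[idx <= i].max())
        i1 = int(idx[idx >= i].min())
        w = (i - i0) / (i1 - i0)
        rows = (1 - w) * rows_by_index[i0] + w * rows_by_index[i1]
        seg = Segmentation(
            curves={n_: rows[k] for k, n_ in enumerate(BOUNDARY_ORDER)},
            shape=segmented[i0].shape,
            source=f"{source}[{i}]",
            meta={"interpolated": True, "between": (i0, i1)},
        )
        seg.validate()
        segs.append(seg)
    return VolumeResult(segs, indices)
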