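"""Cluster detection with an SD-based intensity threshold.

The detector follows the parameter contract of spot-counting plugins used
for cluster quantification (approximate particle size, intensity threshold
in SD units, include/segment larger particles, minimum spot size) but is an
independent implementation:

1. band-pass the channel with a difference of Gaussians
   (``σ_small = particle_size_px / 4`` floored at 0.5,
   ``σ_large = 2 × particle_size_px``);
2. estimate background statistics of the filtered image inside the ROI mask
   with the median and the MAD-derived robust SD (moment estimators are
   contaminated by the spots themselves at high density);
3. keep pixels above ``median + threshold_sd × SD``;
4. 8-connected components; discard components below ``min_pixels``;
5. components larger than ``π × particle_size_px²`` are dropped
   (``include_larger=False``, which also rejects large round granules), kept
   whole (``include_larger=True``), or watershed-split on local maxima
   (``segment_larger=True``);
6. per spot: intensity-weighted centroid on the raw image, pixel area,
   local background as the median of a 2-px-wide annulus around the
   component, and the background-corrected integrated intensity.

Spots are ordered by (y, x); detections closer than 1 px are merged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import pi
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.segmentation import watershed

from .io import ImageScene

__all__ = [
    "DetectionParams",
    "Spot",
    "SpotTable",
    "SnrSummary",
    "detect_spots",
    "detect_spots_sweep",
    "spot_snr_summary",
    "bandpass_filter",
    "robust_background",
]

_EIGHT = np.ones((3, 3), bool)
_MAD_TO_SD = 1.4826  # consistency factor for Gaussian noise


@dataclass(frozen=True)
class DetectionParams:
    """Detection parameter set (SD-threshold spot-counting dialect)."""

    particle_size_px: float = 3.0
    threshold_sd: float = 5.0
    include_larger: bool = True
    segment_larger: bool = False
    min_pixels: int = 3

    def __post_init__(self) -> None:
        if self.particle_size_px <= 0:
            raise ValueError("particle_size_px must be > 0")
        if self.threshold_sd <= 0:
            raise ValueError("threshold_sd must be > 0")
        if self.min_pixels < 1:
            raise ValueError("min_pixels must be >= 1")

    @property
    def sigma_small(self) -> float:
        return max(self.particle_size_px / 4.0, 0.5)

    @property
    def sigma_large(self) -> float:
        return 2.0 * self.particle_size_px

    @property
    def max_area_px(self) -> float:
        """Component-area cutoff separating 'larger particles'."""
        return pi * self.particle_size_px**2


@dataclass(frozen=True)
class Spot:
    y: float
    x: float
    n_area: int
    integrated_intensity: float
    peak_value: float
    channel: str
    threshold_sd_used: float
    roi_label: str | None = None


@dataclass
class SpotTable:
    """Detected spots for one channel / ROI plus detection provenance."""

    spots: list[Spot]
    channel: str
    threshold_sd: float
    params: DetectionParams
    roi_label: str | None = None
    provenance: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    labels: np.ndarray | None = None  # label image (0 = background), optional

    def __len__(self) -> int:
        return len(self.spots)

    @property
    def centers(self) -> np.ndarray:
        return np.asarray([(s.y, s.x) for s in self.spots], float).reshape(-1, 2)

    @property
    def areas(self) -> np.ndarray:
        return np.asarray([s.n_area for s in self.spots], int)

    @property
    def intensities(self) -> np.ndarray:
        return np.asarray([s.integrated_intensity for s in self.spots], float)

    def to_dataframe(self) -> pd.DataFrame:
        # column names mirror the provenance of the quantification columns
        return pd.DataFrame(
            [
                dict(
                    roi_label=s.roi_label,
                    channel=s.channel,
                    y=s.y,
                    x=s.x,
                    n_area=s.n_area,
                    integrated_intensity=s.integrated_intensity,
                    peak_value=s.peak_value,
                    threshold_sd_used=s.threshold_sd_used,
                )
                for s in self.spots
            ],
            columns=[
                "roi_label",
                "channel",
                "y",
                "x",
                "n_area",
                "integrated_intensity",
                "peak_value",
                "threshold_sd_used",
            ],
        )

    @classmethod
    def from_dataframe(
        cls, frame: pd.DataFrame, params: DetectionParams | None = None
    ) -> "SpotTable":
        params = params or DetectionParams()
        spots = [
            Spot(
                y=float(r.y),
                x=float(r.x),
                n_area=int(r.n_area),
                integrated_intensity=float(r.integrated_intensity),
                peak_value=float(r.peak_value),
                channel=str(r.channel),
                threshold_sd_used=float(r.threshold_sd_used),
                roi_label=None if pd.isna(r.roi_label) else str(r.roi_label),
            )
            for r in frame.itertuples()
        ]
        channel = spots[0].channel if spots else ""
        thr = spots[0].threshold_sd_used if spots else params.threshold_sd
        return cls(spots=spots, channel=channel, threshold_sd=thr, params=params)


def bandpass_filter(image: np.ndarray, particle_size_px: float) -> np.ndarray:
    """Difference-of-Gaussians band-pass tuned to the particle size."""
    img = np.asarray(image, float)
    s_small = max(particle_size_px / 4.0, 0.5)
    s_large = 2.0 * particle_size_px
    return ndi.gaussian_filter(img, s_small) - ndi.gaussian_filter(img, s_large)


def robust_background(values: np.ndarray) -> tuple[float, float]:
    """Median and MAD-derived SD of background intensities."""
    values = np.asarray(values, float)
    med = float(np.median(values))
    sd = _MAD_TO_SD * float(np.median(np.abs(values - med)))
    return med, sd


def _check_mask_support(mask: np.ndarray, params: DetectionParams) -> None:
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    need = int(np.ceil(2 * params.sigma_large)) + 1
    if rows[-1] - rows[0] + 1 < need or cols[-1] - cols[0] + 1 < need:
        raise ValueError(
            f"mask extent smaller than filter support ({need} px needed)"
        )


def _split_large(
    labels: np.ndarray,
    filtered: np.ndarray,
    large_ids: np.ndarray,
    params: DetectionParams,
) -> np.ndarray:
    """Watershed-split oversized components on their local maxima."""
    out = labels.copy()
    next_id = int(labels.max()) + 1
    min_dist = max(1, int(round(params.particle_size_px / 2)))
    for lid in large_ids:
        region = labels == lid
        # peaks come back ordered by decreasing filtered intensity, so the
        # brightest marker keeps the original id (deterministic tie-break)
        peaks = peak_local_max(
            filtered,
            min_distance=min_dist,
            exclude_border=False,
            labels=region.astype(np.int32),
        )
        if len(peaks) <= 1:
            continue
        markers = np.zeros_like(labels)
        markers[region] = 0
        ids = [lid] + list(range(next_id, next_id + len(peaks) - 1))
        next_id += len(peaks) - 1
        for (py, px), mid in zip(peaks, ids):
            markers[py, px] = mid
        ws = watershed(-filtered, markers=markers, mask=region)
        out[region] = ws[region]
    return out


def _measure(
    raw: np.ndarray,
    labels: np.ndarray,
    channel: str,
    threshold_sd: float,
    roi_label: str | None,
    global_bg: float,
    min_pixels: int,
) -> list[Spot]:
    spots: list[Spot] = []
    occupied = labels > 0
    objects = ndi.find_objects(labels)
    h, w = raw.shape
    for lid, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        pad = 3  # component + 2-px annulus + 1 px slack
        y0 = max(0, sl[0].start - pad)
        y1 = min(h, sl[0].stop + pad)
        x0 = max(0, sl[1].start - pad)
        x1 = min(w, sl[1].stop + pad)
        sub = labels[y0:y1, x0:x1] == lid
        n_area = int(sub.sum())
        if n_area < min_pixels:
            continue
        raw_sub = raw[y0:y1, x0:x1]
        ring = (
            ndi.binary_dilation(sub, structure=_EIGHT, iterations=2)
            & ~occupied[y0:y1, x0:x1]
        )
        bg = float(np.median(raw_sub[ring])) if ring.any() else global_bg
        weights = np.where(sub, raw_sub, 0.0)
        total = float(weights.sum())
        ys, xs = np.nonzero(sub)
        cy = float((ys * weights[ys, xs]).sum() / total) + y0
        cx = float((xs * weights[ys, xs]).sum() / total) + x0
        spots.append(
            Spot(
                y=cy,
                x=cx,
                n_area=n_area,
                integrated_intensity=total - bg * n_area,
                peak_value=float(raw_sub[sub].max()),
                channel=channel,
                threshold_sd_used=threshold_sd,
                roi_label=roi_label,
            )
        )
    spots.sort(key=lambda s: (s.y, s.x))
    # merge detections closer than 1 px (can arise from watershed splits)
    kept: list[Spot] = []
    for s in spots:
        if any((s.y - k.y) ** 2 + (s.x - k.x) ** 2 < 1.0 for k in kept):
            continue
        kept.append(s)
    return kept


def detect_spots_sweep(
    scene: ImageScene,
    channel: str,
    mask: np.ndarray,
    params: DetectionParams,
    thresholds: Sequence[float],
    roi_label: str | None = None,
    keep_labels: bool = False,
) -> list[SpotTable]:
    """Detect spots at several SD thresholds, filtering the image only once.

    Returns one :class:`SpotTable` per threshold, in the given order.
    """
    raw = np.asarray(scene.channel(channel), float)
    mask = np.asarray(mask, bool)
    if mask.shape != raw.shape:
        raise ValueError("mask shape does not match image shape")
    if not mask.any():
        raise ValueError("mask is empty")
    _check_mask_support(mask, params)

    filtered = bandpass_filter(raw, params.particle_size_px)
    med, sd = robust_background(filtered[mask])
    global_bg = float(np.median(raw[mask]))
    provenance = {
        "channel": channel,
        "background_median": med,
        "background_sd": sd,
        "sd_estimator": "median/MAD",
        "filter": "difference-of-gaussians",
    }

    tables: list[SpotTable] = []
    for thr in thresholds:
        if sd == 0.0:
            tables.append(
                SpotTable(
                    spots=[],
                    channel=channel,
                    threshold_sd=float(thr),
                    params=params,
                    roi_label=roi_label,
                    provenance=dict(provenance),
                    warnings=["zero-variance background; no detection possible"],
                )
            )
            continue
        candidates = mask & (filtered > med + thr * sd)
        labels, n_comp = ndi.label(candidates, structure=_EIGHT)
        if n_comp:
            sizes = np.bincount(labels.ravel())
            sizes[0] = 0
            drop = sizes < params.min_pixels
            large = sizes > params.max_area_px
            if not params.include_larger:
                drop |= large
            if drop.any():
                labels[drop[labels]] = 0
            if params.include_larger and params.segment_larger:
                large_ids = np.flatnonzero(large & ~drop)
                if large_ids.size:
                    labels = _split_large(labels, filtered, large_ids, params)
        spots = _measure(
            raw, labels, channel, float(thr), roi_label, global_bg, params.min_pixels
        )
        tables.append(
            SpotTable(
                spots=spots,
                channel=channel,
                threshold_sd=float(thr),
                params=params,
                roi_label=roi_label,
                provenance=dict(provenance),
                labels=labels if keep_labels else None,
            )
        )
    return tables


def detect_spots(
    scene: ImageScene,
    channel: str,
    mask: np.ndarray,
    params: DetectionParams | None = None,
    roi_label: str | None = None,
) -> SpotTable:
    """Detect spots at ``params.threshold_sd`` (see module docstring)."""
    params = params or DetectionParams()
    return detect_spots_sweep(
        scene,
        channel,
        mask,
        params,
        [params.threshold_sd],
        roi_label=roi_label,
        keep_labels=True,
    )[0]


@dataclass(frozen=True)
class SnrSummary:
    n: int
    mean_peak: float | None
    mean_in_spot: float | None
    mean_out_spot: float | None
    fold_enrichment: float | None


def spot_snr_summary(
    table: SpotTable, scene: ImageScene, mask: np.ndarray
) -> SnrSummary:
    """In-spot vs out-of-spot intensity statistics within the ROI.

    ``fold_enrichment`` is the mean intensity over all spot pixels divided by
    the mean masked intensity outside every spot; absent when the table is
    empty.
    """
    if len(table) == 0:
        return SnrSummary(0, None, None, None, None)
    if table.labels is None:
        raise ValueError("table lacks a label image (detect with keep_labels)")
    raw = np.asarray(scene.channel(table.channel), float)
    mask = np.asarray(mask, bool)
    in_spot = (table.labels > 0) & mask
    out_spot = mask & ~in_spot
    mean_in = float(raw[in_spot].mean()) if in_spot.any() else None
    mean_out = float(raw[out_spot].mean()) if out_spot.any() else None
    fold = (
        mean_in / mean_out
        if mean_in is not None and mean_out not in (None, 0.0)
        else None
    )
    return SnrSummary(
        n=len(table),
        mean_peak=float(np.mean([s.peak_value for s in table.spots])),
        mean_in_spot=mean_in,
        mean_out_spot=mean_out,
        fold_enrichment=fold,
    )
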