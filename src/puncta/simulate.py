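"""Synthetic two-channel cluster scenes and decay series with ground truth.

The generator emulates the statistical structure the coclustering analysis
assumes: a diffuse cytoplasmic background with Gaussian read noise, compact
bright clusters in the bait channel whose number and amplitude scale with a
per-cell expression level, prey clusters placed on bait clusters with a
controllable (optionally intensity-dependent) probability, free prey
clusters, large round autofluorescent granules present in both channels, and
exponential post-illumination decay of cluster counts.

Everything is driven by a single seeded generator: identical configs give
bit-identical scenes and ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.special import expit, logit

from .io import ImageScene, ROIMask, rasterize_roi

__all__ = [
    "CellSpec",
    "SceneConfig",
    "BaitSpot",
    "PreySpot",
    "GroundTruth",
    "DecaySimConfig",
    "SimulatedDecay",
    "simulate_scene",
    "simulate_zstack",
    "simulate_decay_counts",
    "default_cells",
    "ground_truth_frame",
]

BAIT = "bait"
PREY = "prey"


def _as_pair(value) -> tuple[float, float]:
    if np.isscalar(value):
        return (float(value), float(value))
    a, b = value
    return (float(a), float(b))


@dataclass(frozen=True)
class CellSpec:
    """One cell: an ROI polygon plus a relative expression level.

    ``expression_level`` scales both the expected cluster count and the
    cluster amplitudes inside the cell.
    """

    polygon: tuple[tuple[float, float], ...]
    expression_level: float = 1.0
    label: str = "cell"

    def __post_init__(self) -> None:
        if self.expression_level < 0:
            raise ValueError("expression_level must be >= 0")
        if len(self.polygon) < 3:
            raise ValueError("cell polygon needs >= 3 vertices")

    def roi(self) -> ROIMask:
        return ROIMask(label=self.label, polygon=np.asarray(self.polygon, float))


def default_cells(
    image_shape: tuple[int, int], margin: int = 8
) -> tuple[CellSpec, ...]:
    """A single rectangular cell covering the frame minus a margin."""
    h, w = image_shape
    poly = (
        (margin - 0.5, margin - 0.5),
        (margin - 0.5, w - margin - 0.5),
        (h - margin - 0.5, w - margin - 0.5),
        (h - margin - 0.5, margin - 0.5),
    )
    return (CellSpec(polygon=poly, label="cell0"),)


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of one simulated two-channel scene.

    Densities are expressed per 100 μm² (the unit used for reporting cluster
    densities).  ``cocluster_prob`` is the baseline probability ρ that a bait
    cluster carries prey signal; with ``intensity_coupling`` c > 0 the
    per-spot probability becomes ``expit(logit(ρ) + c·z)`` where ``z`` is the
    bait amplitude standardized over the scene, so brighter bait clusters are
    more likely to cocluster.
    """

    image_shape: tuple[int, int] = (256, 256)
    pixel_size: float = 0.1
    rng_seed: int = 0
    background_level: tuple[float, float] | float = 100.0
    noise_sigma: tuple[float, float] | float = 2.0
    cluster_density: float = 8.0
    cluster_sigma_px: float = 1.2
    cluster_amplitude_dist: tuple[float, float] = (60.0, 20.0)
    cocluster_prob: float = 0.0
    intensity_coupling: float = 0.0
    prey_free_density: float = 0.0
    prey_free_amplitude_scale: float = 1.0
    prey_jitter_px: float = 0.5
    prey_amplitude_gain: float = 1.0
    prey_amplitude_sigma: float = 0.15
    granule_density: float = 0.0
    granule_radius_px: float = 4.0
    granule_amplitude: float = 60.0
    min_separation_px: float = 6.0
    cells: tuple[CellSpec, ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 <= self.cocluster_prob <= 1.0:
            raise ValueError("cocluster_prob must be in [0, 1]")
        for name in ("cluster_density", "prey_free_density", "granule_density"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.intensity_coupling < 0:
            raise ValueError("intensity_coupling must be >= 0")
        if min(_as_pair(self.noise_sigma)) <= 0:
            raise ValueError("noise_sigma must be > 0")
        if min(_as_pair(self.background_level)) < 0:
            raise ValueError("background_level must be >= 0")
        if self.cluster_sigma_px <= 0 or self.granule_radius_px <= 0:
            raise ValueError("spot sizes must be > 0")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")

    def with_cells(self) -> "SceneConfig":
        if self.cells:
            return self
        return replace(self, cells=default_cells(self.image_shape))


@dataclass(frozen=True)
class BaitSpot:
    y: float
    x: float
    amplitude: float
    cell_index: int
    is_granule: bool = False


@dataclass(frozen=True)
class PreySpot:
    y: float
    x: float
    amplitude: float
    coclustered_with: int | None = None  # index into GroundTruth.bait_spots


@dataclass
class GroundTruth:
    """Every placed spot, with the bait/prey pairing that generated it."""

    bait_spots: list[BaitSpot] = field(default_factory=list)
    prey_spots: list[PreySpot] = field(default_factory=list)
    per_cell_counts: list[int] = field(default_factory=list)

    def bait_centers(self, include_granules: bool = False) -> np.ndarray:
        pts = [
            (s.y, s.x)
            for s in self.bait_spots
            if include_granules or not s.is_granule
        ]
        return np.asarray(pts, float).reshape(-1, 2)

    def prey_centers(self) -> np.ndarray:
        return np.asarray(
            [(s.y, s.x) for s in self.prey_spots], float
        ).reshape(-1, 2)

    @property
    def n_coclustered(self) -> int:
        return sum(1 for s in self.prey_spots if s.coclustered_with is not None)

    def coclustered_fraction(self) -> float | None:
        """Fraction of non-granule bait spots that carry a prey spot."""
        paired = {
            s.coclustered_with
            for s in self.prey_spots
            if s.coclustered_with is not None
        }
        n_bait = sum(1 for s in self.bait_spots if not s.is_granule)
        if n_bait == 0:
            return None
        return len(paired) / n_bait


def ground_truth_frame(truth: GroundTruth):
    """Ground truth as a tidy :class:`pandas.DataFrame` (one row per spot)."""
    import pandas as pd

    rows = []
    for i, s in enumerate(truth.bait_spots):
        rows.append(
            dict(
                channel=BAIT,
                index=i,
                y=s.y,
                x=s.x,
                amplitude=s.amplitude,
                cocluster_partner=-1,
                is_granule=s.is_granule,
                cell_index=s.cell_index,
            )
        )
    for i, s in enumerate(truth.prey_spots):
        rows.append(
            dict(
                channel=PREY,
                index=i,
                y=s.y,
                x=s.x,
                amplitude=s.amplitude,
                cocluster_partner=-1 if s.coclustered_with is None else s.coclustered_with,
                is_granule=False,
                cell_index=-1,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "channel",
            "index",
            "y",
            "x",
            "amplitude",
            "cocluster_partner",
            "is_granule",
            "cell_index",
        ],
    )


def _add_gaussian(img: np.ndarray, y: float, x: float, amp: float, sigma: float) -> None:
    h, w = img.shape
    r = int(np.ceil(4 * sigma)) + 1
    y0, y1 = max(0, int(y) - r), min(h, int(y) + r + 1)
    x0, x1 = max(0, int(x) - r), min(w, int(x) + r + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy = np.arange(y0, y1)[:, None] - y
    xx = np.arange(x0, x1)[None, :] - x
    img[y0:y1, x0:x1] += amp * np.exp(-(yy**2 + xx**2) / (2 * sigma**2))


def _add_disk(img: np.ndarray, y: float, x: float, amp: float, radius: float) -> None:
    h, w = img.shape
    r = int(np.ceil(radius)) + 1
    y0, y1 = max(0, int(y) - r), min(h, int(y) + r + 1)
    x0, x1 = max(0, int(x) - r), min(w, int(x) + r + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy = np.arange(y0, y1)[:, None] - y
    xx = np.arange(x0, x1)[None, :] - x
    img[y0:y1, x0:x1] += amp * (yy**2 + xx**2 <= radius**2)


def _sample_positions(
    rng: np.random.Generator,
    mask: np.ndarray,
    n: int,
    min_sep: float,
    existing: list[tuple[float, float]],
    max_attempts_per_spot: int = 60,
) -> list[tuple[float, float]]:
    """Dart-throwing placement inside ``mask`` with a minimum separation.

    Clusters in the images the analysis targets are regularly sized and
    spaced; the separation constraint also keeps detection well-posed.
    Placement gives up on a spot after a bounded number of rejections, so
    dense configs degrade gracefully instead of hanging.
    """
    idx = np.flatnonzero(mask.ravel())
    h, w = mask.shape
    placed: list[tuple[float, float]] = []
    pts = list(existing)
    for _ in range(n):
        for _attempt in range(max_attempts_per_spot):
            flat = idx[rng.integers(0, idx.size)]
            y = flat // w + rng.uniform(-0.5, 0.5)
            x = flat % w + rng.uniform(-0.5, 0.5)
            if min_sep > 0 and pts:
                d2 = min((y - p)**2 + (x - q)**2 for p, q in pts)
                if d2 < min_sep**2:
                    continue
            placed.append((y, x))
            pts.append((y, x))
            break
    return placed


def _render_clean(config: SceneConfig) -> tuple[dict[str, np.ndarray], GroundTruth]:
    config = config.with_cells()
    rng = np.random.default_rng(config.rng_seed)
    h, w = config.image_shape
    bg = _as_pair(config.background_level)
    bait_img = np.full((h, w), bg[0], dtype=float)
    prey_img = np.full((h, w), bg[1], dtype=float)
    px_area_um2 = config.pixel_size**2

    truth = GroundTruth()
    amp_mean, amp_sd = config.cluster_amplitude_dist

    cell_masks = []
    for cell in config.cells:
        mask = rasterize_roi(cell.roi(), (h, w))  # raises on oob / zero area
        cell_masks.append(mask)

    # --- bait clusters, cell by cell ---
    all_bait_pts: list[tuple[float, float]] = []
    for ci, (cell, mask) in enumerate(zip(config.cells, cell_masks)):
        area_um2 = mask.sum() * px_area_um2
        lam = config.cluster_density / 100.0 * area_um2 * cell.expression_level
        n = int(rng.poisson(lam))
        pts = _sample_positions(
            rng, mask, n, config.min_separation_px, all_bait_pts
        )
        all_bait_pts.extend(pts)
        amps = rng.normal(amp_mean, amp_sd, size=len(pts))
        amps = np.maximum(amps, 0.05 * amp_mean) * cell.expression_level
        for (y, x), amp in zip(pts, amps):
            truth.bait_spots.append(BaitSpot(y, x, float(amp), ci))
            _add_gaussian(bait_img, y, x, amp, config.cluster_sigma_px)
        truth.per_cell_counts.append(len(pts))

    # --- coclustered prey on bait centers ---
    cluster_spots = [s for s in truth.bait_spots]  # granules added later
    prey_pts: list[tuple[float, float]] = []
    if cluster_spots and config.cocluster_prob > 0:
        amps = np.array([s.amplitude for s in cluster_spots])
        sd = amps.std()
        z = (amps - amps.mean()) / sd if sd > 0 else np.zeros_like(amps)
        if config.cocluster_prob >= 1.0:
            p = np.ones_like(amps)
        else:
            p = expit(logit(config.cocluster_prob) + config.intensity_coupling * z)
        draws = rng.random(len(cluster_spots))
        for bi, (spot, p_i, u) in enumerate(zip(cluster_spots, p, draws)):
            if u >= p_i:
                continue
            jy, jx = rng.normal(0.0, config.prey_jitter_px, size=2)
            y, x = spot.y + jy, spot.x + jx
            y = float(np.clip(y, 0, h - 1))
            x = float(np.clip(x, 0, w - 1))
            amp = (
                spot.amplitude
                * config.prey_amplitude_gain
                * float(np.exp(rng.normal(0.0, config.prey_amplitude_sigma)))
            )
            truth.prey_spots.append(PreySpot(y, x, amp, coclustered_with=bi))
            prey_pts.append((y, x))
            _add_gaussian(prey_img, y, x, amp, config.cluster_sigma_px)

    # --- free (non-coclustered) prey clusters ---
    for cell, mask in zip(config.cells, cell_masks):
        area_um2 = mask.sum() * px_area_um2
        lam = config.prey_free_density / 100.0 * area_um2 * cell.expression_level
        n = int(rng.poisson(lam))
        pts = _sample_positions(rng, mask, n, config.min_separation_px, prey_pts)
        prey_pts.extend(pts)
        # free prey puncta are not amplified by clustering; the scale knob
        # lets them sit dimmer than coclusters, as in real prey channels
        scale = config.prey_free_amplitude_scale
        amps = rng.normal(amp_mean, amp_sd, size=len(pts)) * scale
        amps = np.maximum(amps, 0.05 * amp_mean * scale) * cell.expression_level
        for (y, x), amp in zip(pts, amps):
            truth.prey_spots.append(PreySpot(y, x, float(amp), None))
            _add_gaussian(prey_img, y, x, amp, config.cluster_sigma_px)

    # --- autofluorescent granules: disks, identical in both channels ---
    lam = config.granule_density / 100.0 * (h * w * px_area_um2)
    n_gran = int(rng.poisson(lam))
    r = config.granule_radius_px
    gran_pts = []
    for _ in range(n_gran):
        for _attempt in range(60):
            y = rng.uniform(r, h - 1 - r)
            x = rng.uniform(r, w - 1 - r)
            near = all_bait_pts + prey_pts + gran_pts
            sep = max(config.min_separation_px, 2 * r)
            if near and min((y - p)**2 + (x - q)**2 for p, q in near) < sep**2:
                continue
            gran_pts.append((y, x))
            truth.bait_spots.append(
                BaitSpot(y, x, config.granule_amplitude, -1, is_granule=True)
            )
            _add_disk(bait_img, y, x, config.granule_amplitude, r)
            _add_disk(prey_img, y, x, config.granule_amplitude, r)
            break

    return {BAIT: bait_img, PREY: prey_img}, truth


def simulate_scene(config: SceneConfig) -> tuple[ImageScene, GroundTruth]:
    """Render one two-channel scene and its ground truth.

    The bait channel is background + Gaussian read noise + one isotropic
    Gaussian per cluster (count per cell ~ Poisson(density × area ×
    expression)) + granule disks; the prey channel holds coclustered prey at
    jittered bait centers, free prey, and the same granules.
    """
    clean, truth = _render_clean(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 1]))
    ns = _as_pair(config.noise_sigma)
    channels = {}
    for (name, img), sigma in zip(clean.items(), ns):
        noisy = img + rng.normal(0.0, sigma, size=img.shape)
        channels[name] = np.clip(noisy, 0.0, None)
    scene = ImageScene(
        channels=channels,
        pixel_size=config.pixel_size,
        provenance={"simulated": True, "rng_seed": config.rng_seed},
    )
    return scene, truth


def simulate_zstack(
    config: SceneConfig, n_slices: int = 5
) -> tuple[np.ndarray, GroundTruth]:
    """Thin z-stack wrapper: the 2-D scene replicated with per-slice noise.

    Intended for I/O round-trip testing only; analysis operates on maximum
    projections.
    """
    clean, truth = _render_clean(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 2]))
    ns = _as_pair(config.noise_sigma)
    h, w = config.image_shape
    stack = np.empty((n_slices, 2, h, w), dtype=float)
    for z in range(n_slices):
        for c, (name, img) in enumerate(clean.items()):
            stack[z, c] = np.clip(
                img + rng.normal(0.0, ns[c], size=(h, w)), 0.0, None
            )
    return stack, truth


@dataclass(frozen=True)
class DecaySimConfig:
    """Cluster-count kinetics: baseline, linear rise, exponential decay.

    Illumination happens at t = 0; counts rise linearly to ``peak_count`` at
    ``peak_time`` and then decay exponentially toward ``baseline_count`` with
    half-life ``t_half`` (minutes).  ``count_noise`` is ``"poisson"``, a
    Gaussian standard deviation, or 0 for noiseless series.
    """

    t_half: float = 34.0
    baseline_count: float = 10.0
    peak_count: float = 110.0
    peak_time: float = 6.0
    sample_times: tuple[float, ...] = (-1.0, 0.0, 1.0, 6.0, 11.0, 16.0, 21.0, 26.0)
    count_noise: str | float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.t_half > 0:
            raise ValueError("t_half must be > 0")
        if not self.peak_count > self.baseline_count >= 0:
            raise ValueError("need peak_count > baseline_count >= 0")
        if not self.peak_time > 0:
            raise ValueError("peak_time must be > 0")
        times = np.asarray(self.sample_times, float)
        if times.size < 2 or np.any(np.diff(times) <= 0):
            raise ValueError("sample_times must be strictly increasing")
        if isinstance(self.count_noise, str):
            if self.count_noise != "poisson":
                raise ValueError("count_noise must be 'poisson' or a Gaussian sd")
        elif self.count_noise < 0:
            raise ValueError("count_noise sd must be >= 0")


@dataclass
class SimulatedDecay:
    times: np.ndarray
    counts: np.ndarray
    expected: np.ndarray
    config: DecaySimConfig

    @property
    def t_half_true(self) -> float:
        return self.config.t_half


def expected_decay_count(config: DecaySimConfig, t: np.ndarray) -> np.ndarray:
    """Noise-free expected count at time(s) ``t`` (minutes)."""
    t = np.asarray(t, float)
    base, peak = config.baseline_count, config.peak_count
    rise = base + (peak - base) * np.clip(t, 0.0, config.peak_time) / config.peak_time
    decay = base + (peak - base) * 0.5 ** ((t - config.peak_time) / config.t_half)
    return np.where(t <= config.peak_time, rise, np.where(t < 0, base, decay))


def simulate_decay_counts(config: DecaySimConfig) -> SimulatedDecay:
    """Sample a cluster-count time series from the decay model."""
    times = np.asarray(config.sample_times, float)
    expected = expected_decay_count(config, times)
    rng = np.random.default_rng(config.rng_seed)
    if config.count_noise == "poisson":
        counts = rng.poisson(expected).astype(float)
    elif config.count_noise:
        counts = np.clip(
            expected + rng.normal(0.0, float(config.count_noise), times.size),
            0.0,
            None,
        )
    else:
        counts = expected.copy()
    return SimulatedDecay(times=times, counts=counts, expected=expected, config=config)
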