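"""Shared independent oracles and simulation-experiment builders for tests."""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

import puncta


def point_in_polygon(y: float, x: float, poly: np.ndarray) -> bool:
    """Even-odd ray-casting point-in-polygon test (independent oracle)."""
    inside = False
    n = len(poly)
    for i in range(n):
        y1, x1 = poly[i]
        y2, x2 = poly[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            x_cross = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < x_cross:
                inside = not inside
    return inside


def brute_force_mask(poly: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    mask = np.zeros(shape, bool)
    for yy in range(shape[0]):
        for xx in range(shape[1]):
            mask[yy, xx] = point_in_polygon(yy, xx, poly)
    return mask


def match_spots(
    detected: np.ndarray, truth: np.ndarray, max_dist: float
) -> tuple[int, int, int]:
    """Hungarian assignment match; returns (n_matched, n_detected, n_truth)."""
    if len(detected) == 0 or len(truth) == 0:
        return 0, len(detected), len(truth)
    d = cdist(detected, truth)
    rows, cols = linear_sum_assignment(d)
    n_match = int((d[rows, cols] <= max_dist).sum())
    return n_match, len(detected), len(truth)


def classifier_scene_config(rho, coupling, free, seed) -> puncta.SceneConfig:
    """Scene parameterization used for classifier-discrimination experiments.

    Broad amplitude distribution and moderate read noise so the 1-25 SD sweep
    actually spans the spot brightness range; free prey sit dimmer than
    clusters (they are not amplified by clustering).
    """
    return puncta.SceneConfig(
        rng_seed=seed,
        cocluster_prob=rho,
        intensity_coupling=coupling,
        prey_free_density=free,
        prey_free_amplitude_scale=0.6,
        noise_sigma=6.0,
        cluster_amplitude_dist=(60.0, 30.0),
    )


def run_classifier_experiment(rho, coupling, free, seed, n_rep=4):
    """Simulate ``n_rep`` replicate animals and run the default sweep."""
    rng = np.random.default_rng(seed)
    replicates = []
    truths = []
    for _ in range(n_rep):
        cfg = classifier_scene_config(rho, coupling, free, int(rng.integers(0, 2**31)))
        scene, truth = puncta.simulate_scene(cfg)
        replicates.append((scene, [c.roi() for c in cfg.with_cells().cells]))
        truths.append(truth)
    curve = puncta.run_sweep(
        replicates, "bait", "prey", puncta.DetectionParams(), puncta.SweepConfig()
    )
    return curve, puncta.call_interaction(curve), truths
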