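"""Object-based bait/prey colocalization within a pairing distance.

A bait spot is colocalized iff at least one prey center lies within
``max_distance_px`` (center-to-center Euclidean, boundary inclusive) of its
center, and symmetrically for prey.  The two directional fractions —
fraction of bait spots with a prey partner and fraction of prey spots with a
bait partner — are both reported; the pairs list (for per-pair intensity
analyses) uses mutual nearest neighbors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .detect import SpotTable

__all__ = ["ColocResult", "colocalize"]


def _centers(table) -> np.ndarray:
    if isinstance(table, SpotTable):
        return table.centers
    arr = np.asarray(table, float)
    return arr.reshape(-1, 2)


@dataclass
class ColocResult:
    n_bait: int
    n_prey: int
    n_bait_coloc: int
    n_prey_coloc: int
    frac_bait_with_prey: float | None
    frac_prey_with_bait: float | None
    max_distance_px: float
    pairs: list[tuple[int, int, float]] = field(default_factory=list)
    bait_has_prey: np.ndarray = field(default_factory=lambda: np.zeros(0, bool))
    prey_has_bait: np.ndarray = field(default_factory=lambda: np.zeros(0, bool))

    def to_dict(self, pixel_size: float | None = None) -> dict:
        d = dict(
            n_bait=self.n_bait,
            n_prey=self.n_prey,
            n_bait_coloc=self.n_bait_coloc,
            n_prey_coloc=self.n_prey_coloc,
            frac_bait_with_prey=self.frac_bait_with_prey,
            frac_prey_with_bait=self.frac_prey_with_bait,
            max_distance_px=self.max_distance_px,
            distance_convention="center-to-center Euclidean, boundary inclusive",
            pairs=[
                dict(bait=i, prey=j, distance_px=d_)
                for i, j, d_ in self.pairs
            ],
        )
        if pixel_size is not None:
            d["max_distance_um"] = self.max_distance_px * pixel_size
            for p, (_, _, dist) in zip(d["pairs"], self.pairs):
                p["distance_um"] = dist * pixel_size
        return d


def colocalize(bait, prey, max_distance_px: float = 3.0) -> ColocResult:
    """Pair bait and prey spots within ``max_distance_px``.

    ``bait``/``prey`` are :class:`SpotTable` objects or ``(N, 2)`` center
    arrays.  Colocalization is presence-within-radius (any partner counts);
    fractions are absent (``None``) when their denominator is zero.
    """
    if max_distance_px < 0:
        raise ValueError("max_distance_px must be >= 0")
    b = _centers(bait)
    p = _centers(prey)
    n_bait, n_prey = len(b), len(p)
    bait_has = np.zeros(n_bait, bool)
    prey_has = np.zeros(n_prey, bool)
    pairs: list[tuple[int, int, float]] = []
    if n_bait and n_prey:
        bait_tree = cKDTree(b)
        prey_tree = cKDTree(p)
        d_bp, j_bp = prey_tree.query(b)  # nearest prey per bait
        d_pb, j_pb = bait_tree.query(p)  # nearest bait per prey
        bait_has = d_bp <= max_distance_px
        prey_has = d_pb <= max_distance_px
        for i in range(n_bait):
            if not bait_has[i]:
                continue
            j = int(j_bp[i])
            if int(j_pb[j]) == i:  # mutual nearest neighbors
                pairs.append((i, j, float(d_bp[i])))
    return ColocResult(
        n_bait=n_bait,
        n_prey=n_prey,
        n_bait_coloc=int(bait_has.sum()),
        n_prey_coloc=int(prey_has.sum()),
        frac_bait_with_prey=float(bait_has.mean()) if n_bait else None,
        frac_prey_with_bait=float(prey_has.mean()) if n_prey else None,
        max_distance_px=float(max_distance_px),
        pairs=pairs,
        bait_has_prey=bait_has,
        prey_has_bait=prey_has,
    )
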