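"""Distance to the sexual/apomict borderline and the Hexp-distance
regression pair (naive vs coverage-residual-corrected)."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .diversity import IndividualDiversity
from .model import PopulationMap, RadtraceError

EARTH_RADIUS_KM = 6371.0


@dataclass
class RegressionResult:
    slope: float      # per km
    intercept: float
    r: float
    p: float
    n: int


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in km (haversine, R = 6371 km)."""
    for lat in (lat1, lat2):
        if not -90.0 <= lat <= 90.0:
            raise ValueError(f"latitude {lat} outside [-90, 90]")
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dp = p2 - p1
    dl = np.radians(lon2 - lon1)
    a = np.sin(dp / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dl / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a)))


def distance_to_borderline(
    samples: Sequence[Tuple[str, float, float]],
    borderline: Sequence[Tuple[float, float]],
    method: str = "nearest_vertex",
) -> Dict[str, float]:
    """Per-individual distance (km) to the borderline.

    Default semantics are nearest-vertex ("distance to nearest hub"):
    the minimum haversine distance over the borderline's points.
    ``method='segment'`` projects onto segments in an equirectangular
    approximation instead.
    """
    if not borderline:
        raise ValueError("borderline needs >=1 point")
    if method not in ("nearest_vertex", "segment"):
        raise ValueError(f"unknown method {method!r}")
    out: Dict[str, float] = {}
    for ind, lat, lon in samples:
        if method == "nearest_vertex" or len(borderline) == 1:
            out[ind] = min(haversine_km(lat, lon, blat, blon) for blat, blon in borderline)
        else:
            best = np.inf
            for (alat, alon), (blat, blon) in zip(borderline[:-1], borderline[1:]):
                best = min(best, _point_segment_km(lat, lon, alat, alon, blat, blon))
            out[ind] = float(best)
    return out


def _point_segment_km(plat, plon, alat, alon, blat, blon) -> float:
    # local equirectangular projection around the segment midpoint
    lat0 = np.radians((alat + blat) / 2)
    def xy(lat, lon):
        return (np.radians(lon) * np.cos(lat0) * EARTH_RADIUS_KM,
                np.radians(lat) * EARTH_RADIUS_KM)
    px, py = xy(plat, plon)
    ax, ay = xy(alat, alon)
    bx, by = xy(blat, blon)
    dx, dy = bx - ax, by - ay
    denom = dx * dx + dy * dy
    t = 0.0 if denom == 0 else np.clip(((px - ax) * dx + (py - ay) * dy) / denom, 0, 1)
    qx, qy = ax + t * dx, ay + t * dy
    return float(np.hypot(px - qx, py - qy))


def hexp_distance_regression(
    div: Sequence[IndividualDiversity],
    distances: Dict[str, float],
    mode: str = "naive",
    min_sites: int = 6000,
    exclude: Sequence[str] = (),
    pops: Optional[PopulationMap] = None,
) -> RegressionResult:
    """OLS of per-individual Hexp (or its coverage residuals) on distance.

    Individuals with ``n_variant_sites <= min_sites`` or belonging to an
    excluded population are dropped before fitting. ``mode='residual'``
    first regresses Hexp on the number of recovered variant sites and fits
    the residuals on distance.
    """
    if mode not in ("naive", "residual"):
        raise ValueError(f"unknown mode {mode!r}")
    excluded = set(exclude)
    kept: List[IndividualDiversity] = []
    n_excluded_pop = n_low_sites = n_no_distance = 0
    for d in div:
        if pops is not None and excluded and pops.population(d.individual) in excluded:
            n_excluded_pop += 1
            continue
        if d.n_variant_sites <= min_sites or np.isnan(d.hexp_ind):
            n_low_sites += 1
            continue
        if d.individual not in distances:
            n_no_distance += 1
            continue
        kept.append(d)
    if len(kept) < 3:
        raise RadtraceError(
            f"regression needs >=3 individuals, got {len(kept)} "
            f"(excluded by population: {n_excluded_pop}, below min_sites: {n_low_sites}, "
            f"no distance: {n_no_distance})"
        )
    x_dist = np.array([distances[d.individual] for d in kept])
    hexp = np.array([d.hexp_ind for d in kept])
    if mode == "residual":
        n_sites = np.array([d.n_variant_sites for d in kept], dtype=float)
        stage1 = stats.linregress(n_sites, hexp)
        y = hexp - (stage1.intercept + stage1.slope * n_sites)
    else:
        y = hexp
    if np.allclose(y, y[0]) or np.allclose(x_dist, x_dist[0]):
        return RegressionResult(0.0, float(np.mean(y)), 0.0, 1.0, len(kept))
    fit = stats.linregress(x_dist, y)
    return RegressionResult(float(fit.slope), float(fit.intercept),
                            float(fit.rvalue), float(fit.pvalue), len(kept))
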