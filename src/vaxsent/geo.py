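"""Geospatial analysis: geocoding, the Average Nearest Neighbor statistic,
buffering, and sentiment-aware vaccination-center recommendation.

The ANN statistic follows the Clark–Evans construction used by standard
GIS tooling: with n points over study area A,

    DO  = mean nearest-neighbor distance,
    DE  = 0.5 / sqrt(n / A)          (expectation under CSR),
    ANN = DO / DE,
    z   = (DO − DE) / SE,  SE = 0.26136 / sqrt(n² / A),
    p   = 2 · (1 − Φ(|z|))           (two-sided).

ANN < 1 indicates clustering and ANN > 1 dispersion; the call is only made
at ≥ 90% joint p/z confidence (see :func:`confidence_level`).  Coordinates
may be geographic (WGS84 lat/lon; geodesic distances in km on a sphere of
radius 6371.0088 km, study area in km²) or planar (Euclidean distances,
area in squared planar units).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import norm

__all__ = [
    "ANNResult",
    "BufferQuery",
    "EARTH_RADIUS_KM",
    "GeoPoint",
    "PointPattern",
    "Recommendation",
    "VaccineCenter",
    "ann_statistic",
    "buffer_centers",
    "confidence_level",
    "geocode",
    "haversine_km",
    "read_points_geojson",
    "recommend_centers",
    "write_points_geojson",
    "z_critical",
]

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0088

#: Printed joint confidence thresholds: (p below, |z| above, confidence %).
CONFIDENCE_TABLE = ((0.01, 2.58, 99), (0.05, 1.96, 95), (0.10, 1.65, 90))


@dataclass(frozen=True)
class GeoPoint:
    """WGS84 point; equality is tolerant to 1e-9 degrees."""

    lat: float
    lon: float

    def __post_init__(self) -> None:
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude out of range: {self.lat}")
        if not -180.0 < self.lon <= 180.0:
            raise ValueError(f"longitude out of range: {self.lon}")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeoPoint):
            return NotImplemented
        return abs(self.lat - other.lat) <= 1e-9 and abs(self.lon - other.lon) <= 1e-9

    __hash__ = None  # tolerant equality is incompatible with hashing


@dataclass(frozen=True)
class VaccineCenter:
    """A vaccination center with the vaccine brands it administers."""

    name: str
    location: GeoPoint
    brands: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.brands:
            raise ValueError(f"center {self.name!r} has no brands")


def _normalize_place(text: str) -> str:
    return " ".join(text.split()).casefold()


def geocode(location_text: str, gazetteer: Mapping[str, GeoPoint]) -> GeoPoint | None:
    """Offline gazetteer lookup after trim/case-fold/whitespace-collapse.

    A miss returns ``None`` (absence is a value, not an error).
    """
    normalized = {_normalize_place(k): v for k, v in gazetteer.items()}
    return normalized.get(_normalize_place(location_text))


def haversine_km(a: GeoPoint, b: GeoPoint) -> float:
    """Great-circle distance in km on a sphere of radius 6371.0088 km."""
    phi1, phi2 = math.radians(a.lat), math.radians(b.lat)
    dphi = phi2 - phi1
    dlam = math.radians(b.lon - a.lon)
    s = math.sin(dphi / 2) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(s)))


@dataclass(frozen=True)
class PointPattern:
    """A point set for ANN analysis.

    ``coords`` is an (n, 2) array: columns (lat, lon) when ``planar`` is
    False, arbitrary (x, y) planar units (km by convention) otherwise.
    ``study_area`` overrides the bounding-rectangle default (km² for
    geographic input, squared planar units otherwise).
    """

    coords: np.ndarray
    planar: bool = False
    study_area: float | None = None
    area_convention: str = field(default="bounding_rectangle")

    def __post_init__(self) -> None:
        coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise ValueError("coords must be an (n, 2) array")
        object.__setattr__(self, "coords", coords)
        if self.study_area is not None and self.study_area <= 0:
            raise ValueError("study_area must be positive")
        convention = "user_supplied" if self.study_area is not None else "bounding_rectangle"
        object.__setattr__(self, "area_convention", convention)

    @property
    def n(self) -> int:
        return len(self.coords)

    def resolved_area(self) -> float:
        """Study area: user-supplied, else the bounding rectangle.

        For geographic input the bounding rectangle is evaluated on the
        sphere: A = R²·Δλ·(sin φ_max − sin φ_min), in km².
        """
        if self.study_area is not None:
            return float(self.study_area)
        if self.planar:
            dx = float(np.ptp(self.coords[:, 0]))
            dy = float(np.ptp(self.coords[:, 1]))
            area = dx * dy
        else:
            lat, lon = self.coords[:, 0], self.coords[:, 1]
            dlam = math.radians(float(np.ptp(lon)))
            area = (
                EARTH_RADIUS_KM**2
                * dlam
                * (math.sin(math.radians(lat.max())) - math.sin(math.radians(lat.min())))
            )
        if area <= 0:
            raise ValueError(
                "degenerate bounding rectangle; supply study_area explicitly"
            )
        return float(area)


def _nearest_neighbor_distances(pattern: PointPattern) -> np.ndarray:
    coords = pattern.coords
    if pattern.planar:
        tree = cKDTree(coords)
        dists, _ = tree.query(coords, k=2)
        return dists[:, 1]
    # embed on the unit sphere; chord length converts back to arc length
    lat = np.radians(coords[:, 0])
    lon = np.radians(coords[:, 1])
    xyz = np.column_stack(
        [np.cos(lat) * np.cos(lon), np.cos(lat) * np.sin(lon), np.sin(lat)]
    )
    tree = cKDTree(xyz)
    chords, _ = tree.query(xyz, k=2)
    chord = np.clip(chords[:, 1], 0.0, 2.0)
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(chord / 2.0)


def z_critical(confidence_pct: float) -> float:
    """Two-sided standard-normal critical value for a confidence level."""
    if not 0 < confidence_pct < 100:
        raise ValueError("confidence_pct must lie in (0, 100)")
    return float(norm.isf((1.0 - confidence_pct / 100.0) / 2.0))


def confidence_level(p: float, z: float) -> int:
    """Joint p/|z| confidence bucket: 99, 95, 90 or 0 (none).

    Both conditions of a row must hold (p below its bound and |z| beyond
    its printed critical value); rows are tried from 99% down.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must lie in [0, 1], got {p}")
    for p_max, z_min, level in CONFIDENCE_TABLE:
        if p < p_max and abs(z) > z_min:
            return level
    return 0


@dataclass(frozen=True)
class ANNResult:
    """Average-nearest-neighbor analysis of one point pattern."""

    do: float
    de: float
    ann: float
    z: float
    p: float
    confidence_pct: int
    pattern_call: str
    n: int
    study_area: float
    pz_agree: bool

    def summary(self) -> str:
        lines = [
            "Average Nearest Neighbor analysis",
            f"  n points        : {self.n}",
            f"  study area      : {self.study_area:.6g}",
            f"  observed DO     : {self.do:.6g}",
            f"  expected DE     : {self.de:.6g}",
            f"  ANN = DO/DE     : {self.ann:.6f}",
            f"  z-score         : {self.z:.6f}",
            f"  p-value (2-sided): {self.p:.6g}",
            f"  confidence      : {self.confidence_pct or 'none'}",
            f"  pattern         : {self.pattern_call}",
        ]
        if not self.pz_agree:
            lines.append("  note: p-value and z-score imply different confidence rows")
        return "\n".join(lines)


def ann_statistic(pattern: PointPattern) -> ANNResult:
    """Compute DO, DE, ANN = DO/DE, z, two-sided p and the pattern call.

    The pattern is called clustered (ANN < 1) or dispersed (ANN > 1) only
    when the joint p/z confidence reaches at least 90%; otherwise random.
    """
    if pattern.n < 2:
        raise ValueError("ANN requires at least 2 points")
    area = pattern.resolved_area()
    nn = _nearest_neighbor_distances(pattern)
    do = float(nn.mean())
    n = pattern.n
    de = 0.5 / math.sqrt(n / area)
    se = 0.26136 / math.sqrt(n * n / area)
    ann = do / de
    z = (do - de) / se
    p = float(2.0 * norm.sf(abs(z)))
    conf = confidence_level(p, z)
    # flag the (rare) reading where p and |z| land in different rows
    p_only = next((lvl for pm, _, lvl in CONFIDENCE_TABLE if p < pm), 0)
    z_only = next((lvl for _, zm, lvl in CONFIDENCE_TABLE if abs(z) > zm), 0)
    if p_only != z_only:
        logger.warning(
            "p-value (%g) and z-score (%g) imply different confidence rows", p, z
        )
    if ann < 1 and conf >= 90:
        call = "clustered"
    elif ann > 1 and conf >= 90:
        call = "dispersed"
    else:
        call = "random"
    return ANNResult(
        do=do,
        de=de,
        ann=ann,
        z=z,
        p=p,
        confidence_pct=conf,
        pattern_call=call,
        n=n,
        study_area=area,
        pz_agree=p_only == z_only,
    )


@dataclass(frozen=True)
class BufferQuery:
    """A user location, a geodesic radius (default 10 km) and the centers."""

    user: GeoPoint
    centers: tuple[VaccineCenter, ...]
    radius_km: float = 10.0

    def __post_init__(self) -> None:
        if self.radius_km <= 0:
            raise ValueError(f"radius_km must be positive, got {self.radius_km}")
        object.__setattr__(self, "centers", tuple(self.centers))


def buffer_centers(query: BufferQuery) -> list[tuple[VaccineCenter, float]]:
    """Centers within the closed geodesic ball, sorted by distance then name."""
    hits = []
    for center in query.centers:
        d = haversine_km(query.user, center.location)
        if d <= query.radius_km:
            hits.append((center, d))
    hits.sort(key=lambda cd: (cd[1], cd[0].name))
    return hits


@dataclass(frozen=True)
class Recommendation:
    center: VaccineCenter
    distance_km: float
    score: float
    best_brand: str
    score_source: str


def recommend_centers(
    query: BufferQuery,
    regional_sentiment: Mapping,
    region: str | None = None,
) -> list[Recommendation]:
    """Rank in-radius centers by regional brand sentiment.

    ``regional_sentiment`` maps a brand (or ``(region, brand)`` pair) to the
    positive-share of tweets about that brand in [0, 1]; missing entries
    default to 0.5 (no information).  A center scores the maximum share
    over its brands; ties break by distance, then name.  An empty result is
    valid and logged as an advisory.
    """

    def share(brand: str) -> tuple[float, str]:
        if region is not None and (region, brand) in regional_sentiment:
            return float(regional_sentiment[(region, brand)]), f"({region}, {brand})"
        if brand in regional_sentiment:
            return float(regional_sentiment[brand]), brand
        return 0.5, f"default (no data for {brand})"

    ranked = []
    for center, dist in buffer_centers(query):
        scored = [(share(b), b) for b in center.brands]
        (best_score, source), best_brand = max(scored, key=lambda t: t[0][0])
        ranked.append(
            Recommendation(
                center=center,
                distance_km=dist,
                score=best_score,
                best_brand=best_brand,
                score_source=source,
            )
        )
    ranked.sort(key=lambda r: (-r.score, r.distance_km, r.center.name))
    if not ranked:
        logger.warning(
            "no vaccination center within %.1f km of (%.4f, %.4f)",
            query.radius_km,
            query.user.lat,
            query.user.lon,
        )
    return ranked


# -- GeoJSON (RFC 7946) helpers -------------------------------------------

def read_points_geojson(path) -> PointPattern:
    """Read a FeatureCollection of Points into a geographic PointPattern."""
    with open(path, encoding="utf-8") as handle:
        doc = json.load(handle)
    coords = []
    for feature in doc.get("features", []):
        geom = feature.get("geometry") or {}
        if geom.get("type") != "Point":
            continue
        lon, lat = geom["coordinates"][:2]
        coords.append((lat, lon))
    if not coords:
        raise ValueError(f"no Point features found in {path}")
    return PointPattern(coords=np.asarray(coords), planar=False)


def write_points_geojson(path, points: Sequence[GeoPoint], properties=None) -> int:
    """Write points (with optional per-point property dicts); returns count."""
    features = []
    for i, pt in enumerate(points):
        props = dict(properties[i]) if properties else {}
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [pt.lon, pt.lat]},
                "properties": props,
            }
        )
    with open(path, "w", encoding="utf-8") as handle:
        json.dump({"type": "FeatureCollection", "features": features}, handle, indent=1)
    return len(features)
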