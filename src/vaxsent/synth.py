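"""Synthetic study-condition generators: labeled tweet corpora, spatial
point patterns, and gazetteer/center fixtures.

Corpora are built from three pairwise-disjoint word lists (positive,
negative, neutral filler) drawn from the dominant word-cloud vocabulary of
vaccine chatter, so a noise-free corpus is linearly separable by
construction: positive tweets contain at least one positive-lexicon word
and no negative ones (and symmetrically), neutral tweets contain filler
only.  Point patterns cover the three spatial regimes the ANN statistic
distinguishes: CSR (uniform), clustered (a Thomas-process analogue:
uniform parents with isotropic Gaussian offspring), and a regular grid.

Every generator is a pure function of its spec, seed included; no global
RNG state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .geo import GeoPoint, PointPattern, VaccineCenter

__all__ = [
    "BRANDS",
    "CorpusSpec",
    "PatternSpec",
    "SynthTweet",
    "gen_fixtures",
    "gen_point_pattern",
    "gen_tweets",
]

#: The seven vaccine brands recognized in center tables.
BRANDS = (
    "Pfizer/BioNTech",
    "Sinopharm",
    "Sinovac",
    "Moderna",
    "Oxford/AstraZeneca",
    "Covaxin",
    "Sputnik V",
)

_DEFAULT_POSITIVE = ("great", "good", "safe", "thank", "happy", "love")
_DEFAULT_NEGATIVE = ("sick", "fever", "risk", "hard", "bad", "serious")
_DEFAULT_FILLER = ("covid", "shot", "dose", "second", "people", "country")


@dataclass(frozen=True)
class CorpusSpec:
    """Conditions for a synthetic ternary-labeled tweet corpus."""

    n_per_class: int = 100
    positive_lexicon: tuple[str, ...] = _DEFAULT_POSITIVE
    negative_lexicon: tuple[str, ...] = _DEFAULT_NEGATIVE
    neutral_filler: tuple[str, ...] = _DEFAULT_FILLER
    tweet_length: tuple[int, int] = (3, 8)
    label_noise: float = 0.0
    decoration_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        pos, neg, fil = (
            set(self.positive_lexicon),
            set(self.negative_lexicon),
            set(self.neutral_filler),
        )
        if pos & neg or pos & fil or neg & fil:
            raise ValueError("lexicons must be pairwise disjoint")
        if not 0.0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must lie in [0, 0.5)")
        if self.n_per_class < 0:
            raise ValueError("n_per_class must be non-negative")
        lo, hi = self.tweet_length
        if not 1 <= lo <= hi:
            raise ValueError("tweet_length must be a range with 1 <= lo <= hi")


@dataclass(frozen=True)
class SynthTweet:
    text: str
    label: str                  # class3 label (after noise)
    decorated_text: str         # text plus hashtag/URL decorations
    true_label: str             # label before noise flips


def gen_tweets(spec: CorpusSpec) -> list[SynthTweet]:
    """Generate ``n_per_class`` tweets per ternary class.

    Decorated texts carry a hashtag and/or a synthetic URL on a fraction of
    tweets to exercise the cleaning stages; ``label_noise`` flips that
    fraction of labels to a different class.  Identical specs (seed
    included) generate identical corpora.
    """
    rng = np.random.default_rng(spec.seed)
    classes = ("positive", "negative", "neutral")
    signal = {
        "positive": spec.positive_lexicon,
        "negative": spec.negative_lexicon,
        "neutral": (),
    }
    tweets: list[SynthTweet] = []
    lo, hi = spec.tweet_length
    for label in classes:
        for _ in range(spec.n_per_class):
            length = int(rng.integers(lo, hi + 1))
            words: list[str]
            if label == "neutral":
                words = list(rng.choice(spec.neutral_filler, size=length))
            else:
                n_signal = max(1, int(rng.integers(1, max(2, length // 2 + 1))))
                n_signal = min(n_signal, length)
                words = list(rng.choice(signal[label], size=n_signal))
                words += list(
                    rng.choice(spec.neutral_filler, size=length - n_signal)
                )
                perm = rng.permutation(len(words))
                words = [words[i] for i in perm]
            text = " ".join(words)
            decorated = text
            if rng.random() < spec.decoration_rate:
                decorated = f"{decorated} #{rng.choice(spec.neutral_filler)}"
            if rng.random() < spec.decoration_rate:
                suffix = "".join(rng.choice(list("abcdefgh"), size=8))
                decorated = f"{decorated} https://t.co/{suffix}"
            tweets.append(
                SynthTweet(
                    text=text, label=label, decorated_text=decorated, true_label=label
                )
            )
    if spec.label_noise > 0 and tweets:
        n_flip = int(round(spec.label_noise * len(tweets)))
        flip_idx = rng.choice(len(tweets), size=n_flip, replace=False)
        for i in flip_idx:
            current = tweets[i].label
            other = [c for c in classes if c != current]
            new_label = str(rng.choice(other))
            tweets[i] = SynthTweet(
                text=tweets[i].text,
                label=new_label,
                decorated_text=tweets[i].decorated_text,
                true_label=tweets[i].true_label,
            )
    return tweets


@dataclass(frozen=True)
class PatternSpec:
    """Conditions for a synthetic planar point pattern (units: km)."""

    kind: str                               # csr | clustered | grid
    bbox: tuple[float, float, float, float] = (0.0, 0.0, 100.0, 100.0)
    n: int | None = None                    # csr and grid (perfect square)
    n_parents: int = 20
    offspring_per_parent: int = 10
    sigma_km: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        x0, y0, x1, y1 = self.bbox
        if x1 <= x0 or y1 <= y0:
            raise ValueError("bbox is degenerate")
        if self.kind not in ("csr", "clustered", "grid"):
            raise ValueError(f"unknown pattern kind {self.kind!r}")
        if self.kind in ("csr", "grid") and (self.n is None or self.n < 2):
            raise ValueError(f"{self.kind} requires n >= 2")
        if self.kind == "clustered":
            if self.sigma_km <= 0:
                raise ValueError("sigma_km must be positive for clustered patterns")
            if self.n_parents < 1 or self.offspring_per_parent < 1:
                raise ValueError("cluster counts must be positive")


def gen_point_pattern(spec: PatternSpec) -> PointPattern:
    """Simulate a planar point pattern; study area is the bbox area.

    csr: independent uniforms over the box.  clustered: Thomas-process
    analogue — uniform parents, isotropic Gaussian offspring (sd
    ``sigma_km``) clipped to the box.  grid: a regular lattice of cell
    centers (n must be a perfect square), whose ANN against the bbox area
    is exactly 2 for a square box.
    """
    rng = np.random.default_rng(spec.seed)
    x0, y0, x1, y1 = spec.bbox
    area = (x1 - x0) * (y1 - y0)
    if spec.kind == "csr":
        xs = rng.uniform(x0, x1, size=spec.n)
        ys = rng.uniform(y0, y1, size=spec.n)
        coords = np.column_stack([xs, ys])
    elif spec.kind == "clustered":
        px = rng.uniform(x0, x1, size=spec.n_parents)
        py = rng.uniform(y0, y1, size=spec.n_parents)
        xs = np.repeat(px, spec.offspring_per_parent) + rng.normal(
            0.0, spec.sigma_km, size=spec.n_parents * spec.offspring_per_parent
        )
        ys = np.repeat(py, spec.offspring_per_parent) + rng.normal(
            0.0, spec.sigma_km, size=spec.n_parents * spec.offspring_per_parent
        )
        coords = np.column_stack(
            [np.clip(xs, x0, x1), np.clip(ys, y0, y1)]
        )
    else:  # grid
        m = int(round(np.sqrt(spec.n)))
        if m * m != spec.n:
            raise ValueError(f"grid n must be a perfect square, got {spec.n}")
        sx = (x1 - x0) / m
        sy = (y1 - y0) / m
        gx = x0 + sx * (np.arange(m) + 0.5)
        gy = y0 + sy * (np.arange(m) + 0.5)
        xx, yy = np.meshgrid(gx, gy)
        coords = np.column_stack([xx.ravel(), yy.ravel()])
    return PointPattern(coords=coords, planar=True, study_area=area)


# -- deterministic gazetteer and center fixtures ---------------------------

_CITIES: tuple[tuple[str, float, float], ...] = (
    ("Naples, Italy", 40.8518, 14.2681),
    ("Rome, Italy", 41.9028, 12.4964),
    ("Milan, Italy", 45.4642, 9.1900),
    ("London, United Kingdom", 51.5074, -0.1278),
    ("Manchester, United Kingdom", 53.4808, -2.2426),
    ("Paris, France", 48.8566, 2.3522),
    ("Berlin, Germany", 52.5200, 13.4050),
    ("Madrid, Spain", 40.4168, -3.7038),
    ("Lisbon, Portugal", 38.7223, -9.1393),
    ("New York, USA", 40.7128, -74.0060),
    ("Los Angeles, USA", 34.0522, -118.2437),
    ("Chicago, USA", 41.8781, -87.6298),
    ("Toronto, Canada", 43.6532, -79.3832),
    ("Mexico City, Mexico", 19.4326, -99.1332),
    ("Sao Paulo, Brazil", -23.5505, -46.6333),
    ("Buenos Aires, Argentina", -34.6037, -58.3816),
    ("Cairo, Egypt", 30.0444, 31.2357),
    ("Lagos, Nigeria", 6.5244, 3.3792),
    ("Nairobi, Kenya", -1.2921, 36.8219),
    ("New Delhi, India", 28.6139, 77.2090),
    ("Mumbai, India", 19.0760, 72.8777),
    ("Beijing, China", 39.9042, 116.4074),
    ("Tokyo, Japan", 35.6762, 139.6503),
    ("Sydney, Australia", -33.8688, 151.2093),
    ("Moscow, Russia", 55.7558, 37.6173),
)

# (name, anchor city index, lat offset, lon offset, brand indices into BRANDS)
_CENTER_TABLE: tuple[tuple[str, int, float, float, tuple[int, ...]], ...] = (
    ("Naples Central Hub", 0, 0.010, 0.015, (0, 3)),
    ("Naples Harbour Clinic", 0, -0.020, 0.005, (4,)),
    ("Rome Vaccination Point", 1, 0.005, -0.010, (0, 4)),
    ("London Riverside Centre", 3, -0.008, 0.012, (0, 4, 3)),
    ("Paris Nord Vaccinodrome", 5, 0.015, 0.000, (0, 3)),
    ("Berlin Mitte Impfzentrum", 6, 0.000, 0.020, (0, 3, 4)),
    ("New York Midtown Site", 9, 0.012, -0.006, (0, 3)),
    ("Mexico City Arena Module", 13, -0.010, 0.010, (2, 5)),
    ("Sao Paulo Drive-Thru", 14, 0.008, 0.008, (2, 4)),
    ("Cairo District Center", 16, 0.004, -0.012, (1, 6)),
    ("New Delhi Seva Kendra", 19, -0.006, 0.006, (5, 4)),
    ("Beijing Chaoyang Station", 21, 0.010, 0.010, (1, 2)),
    ("Moscow Gostiny Dvor", 24, -0.004, 0.008, (6,)),
)


def gen_fixtures() -> tuple[dict[str, GeoPoint], list[VaccineCenter]]:
    """Deterministic gazetteer (25 cities) and center table (13 centers).

    The centers jointly cover all seven recognized brands; repeated calls
    return equal objects.
    """
    gazetteer = {name: GeoPoint(lat, lon) for name, lat, lon in _CITIES}
    centers = []
    for name, city_idx, dlat, dlon, brand_idx in _CENTER_TABLE:
        _, lat, lon = _CITIES[city_idx]
        centers.append(
            VaccineCenter(
                name=name,
                location=GeoPoint(lat + dlat, lon + dlon),
                brands=tuple(BRANDS[i] for i in brand_idx),
            )
        )
    return gazetteer, centers
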