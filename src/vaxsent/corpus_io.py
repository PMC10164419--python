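"""Tweet/center table I/O and run configuration.

CSV dialect: UTF-8, comma-separated, RFC-4180 quoting.  The tweet schema
mirrors the common vaccination-tweets export: ``id`` and ``text`` are
mandatory; the remaining attributes (user_name, user_location,
user_description, user_created, user_followers, user_friends,
user_favourites, user_verified, date, hashtags, source, retweets,
favorites, is_retweet) are optional typed fields.  Hashtag cells are the
bracketed list convention (``['a', 'b']``) with a plain comma-separated
fallback; dates parse as ISO-8601, then ``YYYY-MM-DD HH:MM:SS``.  Parsing
is lenient by default (malformed optional fields become absent with a
logged warning); strict mode raises row errors instead.
"""

from __future__ import annotations

import csv
import json
import logging
import re
from dataclasses import dataclass, field, fields as dataclass_fields
from datetime import datetime
from pathlib import Path
from typing import Mapping, Optional, Sequence

import yaml

from .geo import GeoPoint, VaccineCenter
from .polarity import PolarityResult

__all__ = [
    "RowError",
    "RunConfig",
    "SchemaError",
    "Tweet",
    "load_config",
    "read_centers",
    "read_tweets",
    "write_sentiment_table",
]

logger = logging.getLogger(__name__)


class SchemaError(ValueError):
    """A mandatory column is missing from an input table."""


class RowError(ValueError):
    """A row failed to parse in strict mode (carries the 1-based row number)."""

    def __init__(self, row: int, message: str):
        super().__init__(f"row {row}: {message}")
        self.row = row


@dataclass(frozen=True)
class Tweet:
    """One tweet record; only ``id`` and ``text`` are guaranteed present."""

    id: str
    text: str
    user_name: Optional[str] = None
    user_location: Optional[str] = None
    user_description: Optional[str] = None
    user_created: Optional[datetime] = None
    user_followers: Optional[int] = None
    user_friends: Optional[int] = None
    user_favourites: Optional[int] = None
    user_verified: Optional[bool] = None
    date: Optional[datetime] = None
    hashtags: tuple[str, ...] = ()
    source: Optional[str] = None
    retweets: Optional[int] = None
    favorites: Optional[int] = None
    is_retweet: Optional[bool] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("tweet id must be non-empty")
        for name in ("user_followers", "user_friends", "user_favourites",
                     "retweets", "favorites"):
            value = getattr(self, name)
            if value is not None and value < 0:
                raise ValueError(f"{name} must be non-negative, got {value}")


_BRACKET_LIST_RE = re.compile(r"^\s*\[(.*)\]\s*$", flags=re.S)


def _parse_hashtags(cell: str) -> tuple[str, ...]:
    match = _BRACKET_LIST_RE.match(cell)
    inner = match.group(1) if match else cell
    tags = []
    for part in inner.split(","):
        tag = part.strip().strip("'\"").lstrip("#").strip()
        if tag:
            tags.append(tag)
    return tuple(tags)


def _parse_date(cell: str) -> datetime:
    try:
        return datetime.fromisoformat(cell)
    except ValueError:
        return datetime.strptime(cell, "%Y-%m-%d %H:%M:%S")


def _parse_bool(cell: str) -> bool:
    lowered = cell.strip().lower()
    if lowered in ("true", "false"):
        return lowered == "true"
    raise ValueError(f"expected 'True' or 'False', got {cell!r}")


def _parse_count(cell: str) -> int:
    value = int(float(cell))
    if value < 0:
        raise ValueError(f"negative count {cell!r}")
    return value


_OPTIONAL_PARSERS = {
    "user_name": str,
    "user_location": str,
    "user_description": str,
    "user_created": _parse_date,
    "user_followers": _parse_count,
    "user_friends": _parse_count,
    "user_favourites": _parse_count,
    "user_verified": _parse_bool,
    "date": _parse_date,
    "hashtags": _parse_hashtags,
    "source": str,
    "retweets": _parse_count,
    "favorites": _parse_count,
    "is_retweet": _parse_bool,
}


def read_tweets(path, strict: bool = False) -> list[Tweet]:
    """Read a tweet CSV into Tweet records, preserving row order.

    Missing optional columns become absent fields.  A missing ``id`` or
    ``text`` column raises :class:`SchemaError` naming the column; a
    malformed optional cell raises :class:`RowError` in strict mode and is
    set absent with a logged warning otherwise.
    """
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file (no CSV header)")
        for mandatory in ("id", "text"):
            if mandatory not in reader.fieldnames:
                raise SchemaError(f"{path}: missing mandatory column {mandatory!r}")
        tweets: list[Tweet] = []
        seen_ids: set[str] = set()
        for row_no, row in enumerate(reader, start=2):   # 1 is the header
            kwargs: dict = {"id": row["id"], "text": row["text"] or ""}
            if kwargs["id"] in seen_ids:
                message = f"duplicate tweet id {kwargs['id']!r}"
                if strict:
                    raise RowError(row_no, message)
                logger.warning("%s: row %d: %s", path, row_no, message)
            seen_ids.add(kwargs["id"])
            for name, parser in _OPTIONAL_PARSERS.items():
                cell = row.get(name)
                if cell is None or cell == "":
                    continue
                try:
                    kwargs[name] = parser(cell)
                except ValueError as exc:
                    if strict:
                        raise RowError(row_no, f"column {name!r}: {exc}") from exc
                    logger.warning(
                        "%s: row %d: column %r unparseable (%s); field set absent",
                        path, row_no, name, exc,
                    )
            tweets.append(Tweet(**kwargs))
    return tweets


def write_sentiment_table(
    records: Sequence[tuple[str, PolarityResult, Optional[tuple[float, float]]]],
    path,
) -> int:
    """Write (tweet id, polarity result[, class scores]) rows to CSV.

    Columns: ``id,polarity,class7,class3[,score_pos,score_neg]`` — the
    score columns appear when any record carries them.  Polarity is written
    at 6 decimals; returns the number of data rows written.
    """
    records = list(records)
    with_scores = any(len(r) > 2 and r[2] is not None for r in records)
    header = ["id", "polarity", "class7", "class3"]
    if with_scores:
        header += ["score_pos", "score_neg"]
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(header)
        for record in records:
            tweet_id, result = record[0], record[1]
            row = [tweet_id, f"{result.polarity:.6f}", result.class7, result.class3]
            if with_scores:
                scores = record[2] if len(record) > 2 else None
                row += (
                    [f"{scores[0]:.6f}", f"{scores[1]:.6f}"]
                    if scores is not None
                    else ["", ""]
                )
            writer.writerow(row)
    return len(records)


def read_sentiment_table(path) -> list[tuple[str, PolarityResult]]:
    """Read back a sentiment table written by :func:`write_sentiment_table`."""
    out = []
    with open(path, newline="", encoding="utf-8") as handle:
        for row in csv.DictReader(handle):
            out.append(
                (
                    row["id"],
                    PolarityResult(
                        polarity=float(row["polarity"]),
                        class7=row["class7"],
                        class3=row["class3"],
                    ),
                )
            )
    return out


def read_centers(path) -> list[VaccineCenter]:
    """Read a center CSV (``name,lat,lon,brands``; brands ';'-separated)."""
    centers = []
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        for mandatory in ("name", "lat", "lon", "brands"):
            if reader.fieldnames is None or mandatory not in reader.fieldnames:
                raise SchemaError(f"{path}: missing mandatory column {mandatory!r}")
        for row in reader:
            centers.append(
                VaccineCenter(
                    name=row["name"],
                    location=GeoPoint(float(row["lat"]), float(row["lon"])),
                    brands=tuple(
                        b.strip() for b in row["brands"].split(";") if b.strip()
                    ),
                )
            )
    return centers


@dataclass(frozen=True)
class RunConfig:
    """Flat run configuration; every key has a documented default."""

    stopwords_path: Optional[str] = None     # packaged list when None
    lexicon_path: Optional[str] = None       # packaged lexicon when None
    bucket_weak: float = 0.3                 # seven-class |polarity| cutoffs
    bucket_strong: float = 0.6
    score_on: str = "clean"                  # polarity input: clean | raw
    drop_retweets: bool = False
    drop_mentions: bool = True
    alpha: float = 1.0                       # NB smoothing pseudo-count
    regularization: float = 1.0              # linear-margin C
    min_df: int = 1
    binarize: bool = True
    w_bert: float = 0.87                     # fusion weights
    w_nbsvm: float = 0.08
    normalize_weights: bool = True
    grid_step: float = 0.1
    epochs: int = 5
    batch_size: int = 8
    learning_rate: float = 0.05
    val_fraction: float = 0.2
    buffer_radius_km: float = 10.0           # geodesic buffer radius
    area_convention: str = "bounding_rectangle"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.buffer_radius_km <= 0:
            raise ValueError(
                f"buffer_radius_km must be positive, got {self.buffer_radius_km}"
            )
        if not 0.0 < self.bucket_weak < self.bucket_strong <= 1.0:
            raise ValueError("need 0 < bucket_weak < bucket_strong <= 1")
        if self.score_on not in ("clean", "raw"):
            raise ValueError("score_on must be 'clean' or 'raw'")
        if self.area_convention not in ("bounding_rectangle", "user_supplied"):
            raise ValueError(
                "area_convention must be 'bounding_rectangle' or 'user_supplied'"
            )
        if not 0.0 < self.grid_step <= 1.0:
            raise ValueError("grid_step must lie in (0, 1]")
        if self.epochs < 0 or self.batch_size < 1:
            raise ValueError("epochs must be >= 0 and batch_size >= 1")
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must lie in (0, 1)")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")


_VALID_KEYS = tuple(f.name for f in dataclass_fields(RunConfig))


def load_config(source: Mapping | str | Path | None = None) -> RunConfig:
    """Resolve a RunConfig from a mapping or a JSON/YAML file.

    Unknown keys are rejected with the list of valid keys; absent keys take
    their defaults; resolution is idempotent and the resolved config is
    logged.
    """
    if source is None:
        data: dict = {}
    elif isinstance(source, Mapping):
        data = dict(source)
    else:
        path = Path(source)
        text = path.read_text(encoding="utf-8")
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        data = dict(data or {})
    unknown = sorted(set(data) - set(_VALID_KEYS))
    if unknown:
        raise ValueError(
            f"unknown config key(s) {unknown}; valid keys: {', '.join(_VALID_KEYS)}"
        )
    config = RunConfig(**data)
    logger.info("resolved config: %s", config)
    return config
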