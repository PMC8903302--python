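"""Tweet-level input handling and account-week aggregation.

The unit of analysis is the account-week: one organization's topic tweets
pooled over one Sunday-to-Saturday week, with text-mining covariates
(NT, LT, MF, NI, HF), epidemic covariates (CC, ND) joined by region, the
organization-type indicator OG, and per-tweet response rates (RP, FV, RT).
"""

from __future__ import annotations

import datetime as dt
import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import DataError

#: Default topic filter: COVID-19 names and synonyms.
COVID_KEYWORDS: tuple[str, ...] = (
    "Coronavirus disease 2019",
    "COVID-19",
    "Coronavirus",
    "Corona",
    "COVID",
    "2019-nCoV acute respiratory disease",
    "Novel coronavirus pneumonia",
    "Severe pneumonia with novel pathogens",
    "Wuhan Acute Respiratory Syndrome (WARS)",
    "SARS-CoV-2",
)

#: Column order of the weekly table (one row per account-week).
WEEKLY_COLUMNS = [
    "account", "week_index", "OG",
    "NT", "LT", "MF", "NI", "HF", "CC", "ND",
    "SS", "SP", "RP", "FV", "RT",
]

#: Marker used in the SP column for account-weeks with zero sentiment score.
EXCLUDED = "excluded"


@dataclass(frozen=True)
class TweetRecord:
    """One raw tweet with its engagement counts."""

    account: str
    timestamp: dt.datetime
    text: str
    replies: int
    favorites: int
    retweets: int

    def __post_init__(self) -> None:
        if not self.account:
            raise DataError("TweetRecord.account must be nonempty")
        if self.timestamp.tzinfo is None:
            object.__setattr__(
                self, "timestamp", self.timestamp.replace(tzinfo=dt.timezone.utc)
            )
        for field in ("replies", "favorites", "retweets"):
            if getattr(self, field) < 0:
                raise DataError(f"TweetRecord.{field} must be >= 0")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_tweets(path: str | Path) -> list[TweetRecord]:
    """Read tweets from CSV or JSON-lines.

    Both dialects carry the columns/keys
    ``account,timestamp,text,replies,favorites,retweets``; timestamps are
    parsed as UTC.
    """
    path = Path(path)
    if path.suffix.lower() in {".jsonl", ".json", ".ndjson"}:
        rows = [json.loads(line) for line in path.read_text().splitlines() if line.strip()]
        frame = pd.DataFrame(rows)
    else:
        frame = pd.read_csv(path)
    missing = {"account", "timestamp", "text", "replies", "favorites", "retweets"} - set(frame.columns)
    if missing:
        raise DataError(f"tweet file {path} lacks columns: {sorted(missing)}")
    stamps = pd.to_datetime(frame["timestamp"], utc=True)
    return [
        TweetRecord(
            account=str(row.account),
            timestamp=stamp.to_pydatetime(),
            text="" if pd.isna(row.text) else str(row.text),
            replies=int(row.replies),
            favorites=int(row.favorites),
            retweets=int(row.retweets),
        )
        for row, stamp in zip(frame.itertuples(index=False), stamps)
    ]


def write_tweets(tweets: Iterable[TweetRecord], path: str | Path) -> None:
    """Write tweets as JSON-lines (UTF-8, ISO-8601 timestamps)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for t in tweets:
            fh.write(json.dumps({
                "account": t.account,
                "timestamp": t.timestamp.isoformat(),
                "text": t.text,
                "replies": t.replies,
                "favorites": t.favorites,
                "retweets": t.retweets,
            }, ensure_ascii=False) + "\n")


def read_epi(path: str | Path) -> pd.DataFrame:
    """Read the epidemic table: columns ``region,week_index,confirmed,deaths``.

    A long-format daily file (``region,date,confirmed,deaths`` plus a study
    start date column is not supported; use ``daily_to_weekly``) is detected
    by the presence of a ``date`` column and rejected with guidance.
    """
    frame = pd.read_csv(path)
    if "date" in frame.columns:
        raise DataError(
            "daily epidemic file detected; convert with corpus.daily_to_weekly first"
        )
    missing = {"region", "week_index", "confirmed", "deaths"} - set(frame.columns)
    if missing:
        raise DataError(f"epidemic file lacks columns: {sorted(missing)}")
    if (frame[["confirmed", "deaths"]] < 0).any().any():
        raise DataError("epidemic counts must be >= 0")
    if frame.duplicated(["region", "week_index"]).any():
        raise DataError("epidemic table has duplicate (region, week) rows")
    return frame


def daily_to_weekly(daily: pd.DataFrame, study_start: dt.date) -> pd.DataFrame:
    """Sum a daily long-format table (region,date,confirmed,deaths) to weeks."""
    frame = daily.copy()
    dates = pd.to_datetime(frame["date"], utc=True)
    frame["week_index"] = [assign_week(d.to_pydatetime(), study_start) for d in dates]
    out = (
        frame.groupby(["region", "week_index"], as_index=False)[["confirmed", "deaths"]]
        .sum()
    )
    return out


def read_account_meta(path: str | Path) -> dict[str, dict]:
    """Read account metadata CSV: columns ``account,og,region``."""
    frame = pd.read_csv(path)
    missing = {"account", "og", "region"} - set(frame.columns)
    if missing:
        raise DataError(f"account metadata lacks columns: {sorted(missing)}")
    return {
        str(r.account): {"og": int(r.og), "region": str(r.region)}
        for r in frame.itertuples(index=False)
    }


def write_weekly(weekly: pd.DataFrame, path: str | Path) -> None:
    weekly.to_csv(path, index=False, columns=WEEKLY_COLUMNS)


# ---------------------------------------------------------------------------
# Filtering, calendar, tokenization
# ---------------------------------------------------------------------------

def filter_topic(
    tweets: Sequence[TweetRecord],
    keywords: Sequence[str] = COVID_KEYWORDS,
) -> list[TweetRecord]:
    """Keep tweets whose text contains any keyword, case-insensitively.

    Substring matching is deliberate: it mirrors the use of both short
    ("COVID") and long ("Coronavirus disease 2019") filter terms, at the
    cost of known false positives such as "corona beer".
    """
    if not keywords:
        raise ValueError("keyword list must be nonempty")
    lowered = [k.lower() for k in keywords]
    return [t for t in tweets if any(k in t.text.lower() for k in lowered)]


def assign_week(timestamp: dt.datetime, study_start: dt.date) -> int:
    """Map a UTC timestamp to a 0-based study week.

    Weeks are half-open [Sunday 00:00 UTC, next Sunday 00:00 UTC);
    ``study_start`` must be a Sunday.
    """
    if study_start.weekday() != 6:  # Monday=0 ... Sunday=6
        raise ValueError(f"study_start {study_start} is not a Sunday")
    if timestamp.tzinfo is None:
        timestamp = timestamp.replace(tzinfo=dt.timezone.utc)
    start = dt.datetime.combine(study_start, dt.time(0, 0), tzinfo=dt.timezone.utc)
    delta = timestamp.astimezone(dt.timezone.utc) - start
    if delta.total_seconds() < 0:
        raise ValueError(f"timestamp {timestamp} precedes study start {study_start}")
    return delta.days // 7


_URL_RE = re.compile(r"https?://\S+|www\.\S+")
_MENTION_RE = re.compile(r"@\w+")
_SPLIT_RE = re.compile(r"[^0-9a-z]+")


def tokenize(text: str) -> list[str]:
    """Lowercase; strip URLs, @-mentions and '#'; split on non-alphanumerics."""
    text = text.lower()
    text = _URL_RE.sub(" ", text)
    text = _MENTION_RE.sub(" ", text)
    text = text.replace("#", "")
    return [tok for tok in _SPLIT_RE.split(text) if tok]


# ---------------------------------------------------------------------------
# Covariates and aggregation
# ---------------------------------------------------------------------------

def extract_covariates(week_tweets: Sequence[TweetRecord]) -> tuple[int, int, float, int, int]:
    """Text-mining covariates (NT, LT, MF, NI, HF) for one account-week.

    The term-frequency table is pooled over the whole week's tokens; MF and
    HF are the median and maximum of the distinct terms' counts.
    """
    if not week_tweets:
        return (0, 0, 0.0, 0, 0)
    texts = [t.text for t in week_tweets]
    nt = len(texts)
    lt = sum(len(s) for s in texts)
    counts: dict[str, int] = {}
    for s in texts:
        for tok in tokenize(s):
            counts[tok] = counts.get(tok, 0) + 1
    ni = sum(counts.values())
    if counts:
        freqs = np.fromiter(counts.values(), dtype=float)
        hf = int(freqs.max())
        mf = float(np.median(freqs))
    else:
        hf, mf = 0, 0.0
    return (nt, lt, mf, ni, hf)


def aggregate_weekly(
    tweets: Sequence[TweetRecord],
    epi: pd.DataFrame,
    account_meta: Mapping[str, Mapping],
    study_start: dt.date,
    n_weeks: int,
    fill_missing_epi: bool = False,
) -> pd.DataFrame:
    """Aggregate tweets to the full account x week grid.

    Returns one row per account-week over ``n_weeks`` study weeks; weeks
    without tweets are zero-filled. Response rates RP/FV/RT are the week's
    total replies/favorites/retweets divided by NT (0 when NT = 0). CC/ND
    are joined from ``epi`` by the account's region. Sentiment columns are
    initialized to SS = 0 / SP = "excluded" and filled by the sentiment
    stage.

    Tweets falling after the study range are dropped; tweets before it
    raise (see ``assign_week``).
    """
    accounts = sorted(account_meta)
    for t in tweets:
        if t.account not in account_meta:
            raise DataError(f"no metadata for account {t.account!r}")

    buckets: dict[tuple[str, int], list[TweetRecord]] = {}
    for t in tweets:
        w = assign_week(t.timestamp, study_start)
        if w >= n_weeks:
            continue
        buckets.setdefault((t.account, w), []).append(t)

    epi_idx = epi.set_index(["region", "week_index"])[["confirmed", "deaths"]]

    rows = []
    for account in accounts:
        meta = account_meta[account]
        region = meta["region"]
        for week in range(n_weeks):
            group = buckets.get((account, week), [])
            nt, lt, mf, ni, hf = extract_covariates(group)
            if nt:
                rp = sum(t.replies for t in group) / nt
                fv = sum(t.favorites for t in group) / nt
                rt = sum(t.retweets for t in group) / nt
            else:
                rp = fv = rt = 0.0
            try:
                cc, nd = epi_idx.loc[(region, week)]
            except KeyError:
                if not fill_missing_epi:
                    raise DataError(
                        f"epidemic table lacks (region={region!r}, week={week})"
                    ) from None
                cc, nd = 0, 0
            rows.append({
                "account": account, "week_index": week, "OG": int(meta["og"]),
                "NT": nt, "LT": lt, "MF": mf, "NI": ni, "HF": hf,
                "CC": float(cc), "ND": float(nd),
                "SS": 0.0, "SP": EXCLUDED,
                "RP": rp, "FV": fv, "RT": rt,
            })
    return pd.DataFrame(rows, columns=WEEKLY_COLUMNS)
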