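"""End-to-end orchestration: read -> filter -> aggregate -> score -> estimate.

Every stage logs its unit counts; the run manifest records the configuration,
seed, library versions and per-stage counts so a run can be reproduced
exactly.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .causal import PolarityEffectModel, PolarityEffectResults
from .corpus import (
    COVID_KEYWORDS, EXCLUDED, aggregate_weekly, filter_topic,
    read_account_meta, read_epi, read_tweets, tokenize, write_weekly,
)
from .exceptions import ConfigError, TweetfxError
from .sentiment import (
    Lexicon, build_term_stats, lexicon_score, seed_polarity, weekly_sentiment,
    write_term_scores,
)

log = logging.getLogger("tweetfx")

SLICES = ("pooled", "government", "news")


@dataclass
class RunConfig:
    """Configuration of one pipeline run (YAML-loadable)."""

    tweets: Path
    epi: Path
    lexicon: Path
    accounts: Path
    out_dir: Path
    study_start: dt.date = dt.date(2019, 12, 1)
    n_weeks: int = 24
    keywords: tuple[str, ...] = COVID_KEYWORDS
    sentiment_mode: str = "log_odds"  # or "lexicon_only"
    alpha: float = 0.5
    trim_lo: float = 0.3
    trim_hi: float = 0.7
    trim_mode: str = "exclude"
    bootstrap_reps: int = 500
    slices: tuple[str, ...] = SLICES
    seed: int = 0
    plots: bool = False

    def __post_init__(self) -> None:
        for name in ("tweets", "epi", "lexicon", "accounts", "out_dir"):
            setattr(self, name, Path(getattr(self, name)))
        if isinstance(self.study_start, str):
            self.study_start = dt.date.fromisoformat(self.study_start)

    def validate(self) -> None:
        for name in ("tweets", "epi", "lexicon", "accounts"):
            if not Path(getattr(self, name)).exists():
                raise ConfigError(f"input path {name!r} does not exist: "
                                  f"{getattr(self, name)}")
        if self.sentiment_mode not in {"log_odds", "lexicon_only"}:
            raise ConfigError(f"unknown sentiment_mode {self.sentiment_mode!r}")
        unknown = set(self.slices) - set(SLICES)
        if unknown:
            raise ConfigError(f"unknown slices: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} is not a mapping")
        for key in ("keywords", "slices"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_jsonable(self) -> dict:
        out = dataclasses.asdict(self)
        for k, v in out.items():
            if isinstance(v, Path):
                out[k] = str(v)
            elif isinstance(v, dt.date):
                out[k] = v.isoformat()
            elif isinstance(v, tuple):
                out[k] = list(v)
        return out


def score_weeks(
    weekly: pd.DataFrame,
    week_tokens: dict[tuple[str, int], list[str]],
    lexicon: Lexicon,
    mode: str = "log_odds",
    alpha: float = 0.5,
):
    """Fill the SS/SP columns of the weekly table in place.

    ``log_odds`` bootstraps reference corpora from lexicon seed labels at
    the account-week level and scores every token by its log2 odds ratio;
    ``lexicon_only`` sums raw lexicon scores instead. Returns the TermStats
    (None in lexicon-only mode).
    """
    keys = sorted(week_tokens)
    stats = None
    if mode == "log_odds":
        labeled = [(seed_polarity(week_tokens[k], lexicon), week_tokens[k])
                   for k in keys]
        stats = build_term_stats(labeled, alpha=alpha)
    idx = weekly.set_index(["account", "week_index"]).index
    ss_col = weekly["SS"].copy().astype(float)
    sp_col = weekly["SP"].copy().astype(object)
    for key in keys:
        tokens = week_tokens[key]
        if mode == "log_odds":
            ss, sp = weekly_sentiment(tokens, stats)
        else:
            raw = lexicon_score(tokens, lexicon)
            ss = float(raw)
            sp = 1 if raw > 0 else (0 if raw < 0 else EXCLUDED)
        loc = idx.get_loc(key)
        ss_col.iloc[loc] = ss
        sp_col.iloc[loc] = sp
    weekly["SS"] = ss_col
    weekly["SP"] = sp_col
    return stats


def _slice_frame(weekly: pd.DataFrame, name: str) -> pd.DataFrame:
    if name == "pooled":
        return weekly
    if name == "government":
        return weekly.loc[weekly["OG"] == 0]
    if name == "news":
        return weekly.loc[weekly["OG"] == 1]
    raise ConfigError(f"unknown slice {name!r}")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns results and written paths.

    Output bundle: ``weekly.csv`` (account-week table), ``term_scores.csv``
    (sentiment audit table), ``det_results.csv``/``.json`` (estimates per
    outcome x estimator x slice), ``balance.csv``, ``summary.txt`` and
    ``manifest.json``.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    stage = "read"
    try:
        tweets = read_tweets(config.tweets)
        epi = read_epi(config.epi)
        lexicon = Lexicon.from_tsv(config.lexicon)
        meta = read_account_meta(config.accounts)
        counts["tweets_read"] = len(tweets)
        log.info("read: %d tweets, %d accounts", len(tweets), len(meta))

        stage = "filter"
        topic = filter_topic(tweets, config.keywords)
        counts["tweets_topic"] = len(topic)
        counts["tweets_dropped_offtopic"] = len(tweets) - len(topic)
        log.info("filter: %d in, %d kept", len(tweets), len(topic))

        stage = "aggregate"
        weekly = aggregate_weekly(topic, epi, meta, config.study_start,
                                  config.n_weeks)
        counts["weekly_rows"] = len(weekly)
        log.info("aggregate: %d account-weeks", len(weekly))

        stage = "sentiment"
        from .corpus import assign_week
        week_tokens: dict[tuple[str, int], list[str]] = {}
        for t in topic:
            w = assign_week(t.timestamp, config.study_start)
            if w >= config.n_weeks:
                continue
            week_tokens.setdefault((t.account, w), []).extend(tokenize(t.text))
        stats = score_weeks(weekly, week_tokens, lexicon,
                            config.sentiment_mode, config.alpha)
        counts["weeks_excluded_zero_score"] = int((weekly["SP"] == EXCLUDED).sum())
        counts["weeks_analyzed"] = len(weekly) - counts["weeks_excluded_zero_score"]
        log.info("sentiment: %d weeks analyzed, %d excluded",
                 counts["weeks_analyzed"], counts["weeks_excluded_zero_score"])

        write_weekly(weekly, out / "weekly.csv")
        if stats is not None:
            write_term_scores(stats, out / "term_scores.csv")

        stage = "estimate"
        results: dict[str, PolarityEffectResults] = {}
        frames = []
        balances = []
        for i, name in enumerate(config.slices):
            part = _slice_frame(weekly, name)
            model = PolarityEffectModel(part)
            res = model.fit(
                trim_bounds=(config.trim_lo, config.trim_hi),
                trim_mode=config.trim_mode,
                bootstrap_reps=config.bootstrap_reps,
                seed=np.random.SeedSequence([config.seed, i]),
            )
            results[name] = res
            counts[f"units_{name}"] = len(model.data)
            frame = res.to_frame()
            frame.insert(0, "slice", name)
            frames.append(frame)
            bal = res.balance.reset_index()
            bal.insert(0, "slice", name)
            balances.append(bal)
            if config.plots:
                res.plot_scores(out / f"scores_{name}.png")
            log.info("estimate[%s]: %d units (%d trimmed)", name,
                     len(model.data), int(res.units["trimmed"].sum()))

        stage = "report"
        det = pd.concat(frames, ignore_index=True)
        det.to_csv(out / "det_results.csv", index=False)
        (out / "det_results.json").write_text(
            json.dumps(det.to_dict(orient="records"), indent=1, sort_keys=True)
        )
        pd.concat(balances, ignore_index=True).to_csv(out / "balance.csv",
                                                      index=False)
        (out / "summary.txt").write_text(
            "\n\n".join(f"=== slice: {name} ===\n{res.summary()}"
                        for name, res in results.items()) + "\n"
        )
        manifest = {
            "config": config.to_jsonable(),
            "seed": config.seed,
            "counts": counts,
            "versions": {
                "tweetfx": __version__,
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                      sort_keys=True))
    except TweetfxError as err:
        raise type(err)(
            f"pipeline stage {stage!r} failed (counts so far: {counts}): {err}"
        ) from err
    return {"weekly": weekly, "results": results, "det": det,
            "manifest": manifest, "out_dir": out}
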