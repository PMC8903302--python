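"""Synthetic tweet corpora and weekly tables with known ground truth.

The generator emulates the statistical shape of the study dataset: 9
accounts (5 government, 4 news) observed over 24 Sunday-to-Saturday weeks,
overdispersed weekly tweet counts with an activity ramp (most accounts post
no topic tweets in the first two weeks, so those account-weeks end up with
zero sentiment score and are excluded downstream), logistic-growth epidemic
covariates per region, covariate-dependent (confounded) polarity
assignment, and negative-binomial engagement with a known additive
treatment effect per outcome. Ground truth (true assignment probabilities,
realized polarity, true effects) is returned separately and written to a
sidecar file so estimator code cannot accidentally consume it.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .corpus import EXCLUDED, TweetRecord, WEEKLY_COLUMNS, write_tweets
from .exceptions import ConfigError
from .sentiment import Lexicon

STUDY_START = dt.date(2019, 12, 1)  # a Sunday

#: Region cycle for account assignment; "worldwide" rows sum the others.
REGIONS = ("us", "china", "australia", "uk", "worldwide")

#: Logistic-curve parameters per region: (peak weekly cases, onset week, rate).
_EPI_PARAMS = {
    "us": (6.0e5, 17.0, 0.9),
    "uk": (1.2e5, 17.0, 0.9),
    "china": (3.5e4, 9.0, 1.1),
    "australia": (2.5e3, 15.0, 0.8),
}

_COVARIATES = ("NT", "LT", "MF", "NI", "HF", "CC", "ND", "OG")

#: Weeks with reduced posting activity at the study start (pre-outbreak).
_RAMP_WEEKS = 2
_RAMP_FACTOR = 0.005


def _default_gamma() -> tuple[float, ...]:
    # confounding: high-activity, high-caseload account-weeks lean positive
    return (1.0, 0.0, 0.0, 0.0, 0.8, 0.8, 0.5, -0.5)


def _default_baseline() -> dict[str, tuple[float, tuple[float, ...]]]:
    # (intercept, covariate loadings) per outcome, on standardized covariates;
    # signs aligned with gamma so the unadjusted contrast is attenuated
    return {
        "RP": (150.0, (15.0, 0.0, 0.0, 0.0, 8.0, 8.0, 5.0, -5.0)),
        "FV": (1500.0, (150.0, 0.0, 0.0, 0.0, 80.0, 80.0, 50.0, -50.0)),
        "RT": (800.0, (70.0, 0.0, 0.0, 0.0, 40.0, 40.0, 25.0, -25.0)),
    }


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-shaped generator settings; defaults are the study conditions."""

    n_accounts: int = 9
    n_weeks: int = 24
    frac_news: float = 4.0 / 9.0
    tau_rp: float = -70.0
    tau_fv: float = -690.0
    tau_rt: float = -325.0
    gamma: tuple[float, ...] = field(default_factory=_default_gamma)
    baseline: Mapping[str, tuple[float, tuple[float, ...]]] = field(
        default_factory=_default_baseline
    )
    dispersion: float = 5.0
    mean_tweets: float = 70.0
    lexicon_size: int = 40
    seed: int = 0

    @property
    def tau(self) -> dict[str, float]:
        return {"RP": self.tau_rp, "FV": self.tau_fv, "RT": self.tau_rt}

    def validate(self) -> None:
        if self.n_accounts < 2:
            raise ConfigError("n_accounts must be >= 2")
        if self.n_weeks < 2:
            raise ConfigError("n_weeks must be >= 2")
        if not 0.0 <= self.frac_news <= 1.0:
            raise ConfigError("frac_news must be in [0, 1]")
        if self.dispersion <= 0:
            raise ConfigError("dispersion must be > 0")
        if self.mean_tweets <= 0:
            raise ConfigError("mean_tweets must be > 0")
        if len(tuple(self.gamma)) != 8:
            raise ConfigError("gamma must have 8 entries (one per covariate)")
        for outcome in ("RP", "FV", "RT"):
            if outcome not in self.baseline:
                raise ConfigError(f"baseline lacks outcome {outcome!r}")
            _, coefs = self.baseline[outcome]
            if len(tuple(coefs)) != 8:
                raise ConfigError(f"baseline[{outcome!r}] must have 8 coefficients")
        if self.lexicon_size < 2:
            raise ConfigError("lexicon_size must be >= 2")


@dataclass
class GroundTruth:
    """Generator-side truth, kept out of the estimators' reach.

    ``p_true`` is NaN and ``sp`` carries the excluded marker for
    account-weeks without topic tweets.
    """

    p_true: np.ndarray
    sp: list
    tau: dict[str, float]
    gamma: tuple[float, ...]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "tau": self.tau,
            "gamma": list(self.gamma),
            "p_true": [None if math.isnan(v) else v for v in self.p_true],
            "sp": list(self.sp),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def _rnb(rng: np.random.Generator, mean: float, k: float) -> int:
    """Negative-binomial draw with the given mean and dispersion size k."""
    if mean <= 0:
        return 0
    return int(rng.negative_binomial(k, k / (k + mean)))


def epidemic_table(n_weeks: int) -> pd.DataFrame:
    """Deterministic weekly confirmed cases and deaths per region.

    Weekly cases follow a logistic growth curve with region-specific onset;
    deaths lag one week at a 6% ratio; "worldwide" sums the named regions.
    """
    rows = []
    totals: dict[int, list[float]] = {w: [0.0, 0.0] for w in range(n_weeks)}
    for region, (peak, onset, rate) in _EPI_PARAMS.items():
        for w in range(n_weeks):
            cc = peak / (1.0 + math.exp(-rate * (w - onset)))
            nd = 0.06 * peak / (1.0 + math.exp(-rate * (w - 1 - onset)))
            cc, nd = round(cc), round(nd)
            rows.append({"region": region, "week_index": w,
                         "confirmed": cc, "deaths": nd})
            totals[w][0] += cc
            totals[w][1] += nd
    for w in range(n_weeks):
        rows.append({"region": "worldwide", "week_index": w,
                     "confirmed": int(totals[w][0]), "deaths": int(totals[w][1])})
    return pd.DataFrame(rows)


def account_table(config: SyntheticConfig) -> dict[str, dict]:
    """Account metadata: OG indicator and epidemic region per account."""
    n_news = int(round(config.frac_news * config.n_accounts))
    n_gov = config.n_accounts - n_news
    meta: dict[str, dict] = {}
    for i in range(n_gov):
        meta[f"gov{i:02d}"] = {"og": 0, "region": REGIONS[i % len(REGIONS)]}
    for i in range(n_news):
        # news agencies report national figures, never the worldwide tally
        meta[f"news{i:02d}"] = {"og": 1, "region": REGIONS[i % 4]}
    return meta


def generate_weekly(config: SyntheticConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate the account x week table plus its ground truth.

    Covariates: NT overdispersed counts with a low-activity ramp in the
    first two weeks; LT and NI proportional to NT with noise; MF and HF
    small term-frequency statistics; CC/ND from the deterministic epidemic
    curves; OG fixed per account. Polarity SP ~ Bernoulli(logistic(gamma'Xs))
    on standardized covariates of the active (NT > 0) rows; each outcome is
    max(0, baseline'Xs + tau * SP) plus negative-binomial noise. Inactive
    rows get zero covariates/outcomes and the excluded polarity marker.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    meta = account_table(config)
    accounts = sorted(meta)
    epi = epidemic_table(config.n_weeks).set_index(["region", "week_index"])

    activity = {a: float(rng.lognormal(0.0, 0.6)) for a in accounts}

    rows = []
    for account in accounts:
        region = meta[account]["region"]
        og = meta[account]["og"]
        for week in range(config.n_weeks):
            ramp = _RAMP_FACTOR if week < _RAMP_WEEKS else 1.0
            nt = _rnb(rng, config.mean_tweets * activity[account] * ramp,
                      config.dispersion)
            if nt > 0:
                lt = int(round(nt * max(20.0, rng.normal(80.0, 10.0))))
                ni = int(round(nt * max(4.0, rng.normal(12.0, 2.0))))
                mf = float(1 + rng.poisson(0.05))
                hf = int(min(ni, max(mf, round(nt * 0.85 * rng.lognormal(0.0, 0.25)))))
            else:
                lt = ni = hf = 0
                mf = 0.0
            cc, nd = epi.loc[(region, week)]
            rows.append({
                "account": account, "week_index": week, "OG": og,
                "NT": nt, "LT": lt, "MF": mf, "NI": ni, "HF": hf,
                "CC": float(cc), "ND": float(nd),
            })
    frame = pd.DataFrame(rows)

    active = (frame["NT"] > 0).to_numpy()
    X = frame[list(_COVARIATES)].to_numpy(dtype=float)
    Xa = X[active]
    mu = Xa.mean(axis=0)
    sd = Xa.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (Xa - mu) / sd

    gamma = np.asarray(config.gamma, dtype=float)
    p_active = 1.0 / (1.0 + np.exp(-(Xs @ gamma)))
    sp_active = (rng.random(len(p_active)) < p_active).astype(int)

    p_true = np.full(len(frame), np.nan)
    p_true[active] = p_active
    sp_col: list = [EXCLUDED] * len(frame)
    ss = np.zeros(len(frame))
    for pos, idx in enumerate(np.flatnonzero(active)):
        sp_col[idx] = int(sp_active[pos])
        sign = 1.0 if sp_active[pos] == 1 else -1.0
        ss[idx] = sign * (abs(rng.normal(30.0, 20.0)) + 0.1)

    outcomes = {o: np.zeros(len(frame)) for o in ("RP", "FV", "RT")}
    for o in ("RP", "FV", "RT"):
        intercept, coefs = config.baseline[o]
        mu_active = intercept + Xs @ np.asarray(coefs, dtype=float) \
            + config.tau[o] * sp_active
        draws = np.array([
            _rnb(rng, m, config.dispersion) for m in mu_active
        ], dtype=float)
        outcomes[o][active] = draws

    frame["SS"] = ss
    frame["SP"] = sp_col
    frame["RP"] = outcomes["RP"]
    frame["FV"] = outcomes["FV"]
    frame["RT"] = outcomes["RT"]
    frame = frame[WEEKLY_COLUMNS]
    truth = GroundTruth(p_true=p_true, sp=sp_col, tau=dict(config.tau),
                        gamma=tuple(config.gamma))
    return frame, truth


# ---------------------------------------------------------------------------
# Tweet-level corpus
# ---------------------------------------------------------------------------

def make_lexicon(size: int) -> Lexicon:
    """Synthetic signed lexicon: half positive, half negative terms."""
    scores: dict[str, int] = {}
    half = size // 2
    for i in range(half):
        scores[f"pos{i:03d}"] = 2 + (i % 2)
    for i in range(size - half):
        scores[f"neg{i:03d}"] = -(2 + (i % 2))
    return Lexicon(scores)


@dataclass
class SyntheticCorpus:
    """A complete synthetic study input bundle plus its ground truth."""

    tweets: list[TweetRecord]
    lexicon: Lexicon
    epi: pd.DataFrame
    account_meta: dict[str, dict]
    weekly: pd.DataFrame
    truth: GroundTruth
    study_start: dt.date
    config: SyntheticConfig


def generate_corpus(config: SyntheticConfig) -> SyntheticCorpus:
    """Generate tweets realizing the weekly table's polarity and engagement.

    Each active account-week emits NT topic tweets whose tokens are drawn
    mostly (85%) from the vocabulary matching the week's polarity, so the
    sentiment module can recover the intended label; weekly engagement
    totals are split across the week's tweets. A few off-topic decoy tweets
    exercise the keyword filter.
    """
    config.validate()
    if config.lexicon_size < 10:
        raise ConfigError("lexicon_size must be >= 10 to generate tweets")
    weekly, truth = generate_weekly(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    lexicon = make_lexicon(config.lexicon_size)
    pos_vocab = sorted(t for t in lexicon.scores if lexicon.scores[t] > 0)
    neg_vocab = sorted(t for t in lexicon.scores if lexicon.scores[t] < 0)
    meta = account_table(config)
    epi = epidemic_table(config.n_weeks)
    start = dt.datetime.combine(STUDY_START, dt.time(0, 0), tzinfo=dt.timezone.utc)
    week_seconds = 7 * 24 * 3600

    tweets: list[TweetRecord] = []
    for row in weekly.itertuples(index=False):
        nt = int(row.NT)
        base = start + dt.timedelta(weeks=int(row.week_index))
        if nt > 0:
            totals = {
                o: int(round(getattr(row, o) * nt)) for o in ("RP", "FV", "RT")
            }
            split = {
                o: rng.multinomial(totals[o], np.full(nt, 1.0 / nt))
                for o in totals
            }
            offsets = np.sort(rng.integers(0, week_seconds, nt))
            intended = pos_vocab if row.SP == 1 else neg_vocab
            other = neg_vocab if row.SP == 1 else pos_vocab
            for j in range(nt):
                n_tok = max(4, int(rng.poisson(10)))
                toks = [
                    intended[rng.integers(len(intended))]
                    if rng.random() < 0.85
                    else other[rng.integers(len(other))]
                    for _ in range(n_tok)
                ]
                tweets.append(TweetRecord(
                    account=row.account,
                    timestamp=base + dt.timedelta(seconds=int(offsets[j])),
                    text="COVID update: " + " ".join(toks),
                    replies=int(split["RP"][j]),
                    favorites=int(split["FV"][j]),
                    retweets=int(split["RT"][j]),
                ))
        for _ in range(int(rng.poisson(0.5))):
            tweets.append(TweetRecord(
                account=row.account,
                timestamp=base + dt.timedelta(seconds=int(rng.integers(0, week_seconds))),
                text="weekly schedule and staffing update",
                replies=int(rng.poisson(1.0)),
                favorites=int(rng.poisson(2.0)),
                retweets=int(rng.poisson(1.0)),
            ))
    tweets.sort(key=lambda t: (t.timestamp, t.account, t.text))
    return SyntheticCorpus(
        tweets=tweets, lexicon=lexicon, epi=epi, account_meta=meta,
        weekly=weekly, truth=truth, study_start=STUDY_START, config=config,
    )


def generate_tweets(config: SyntheticConfig) -> list[TweetRecord]:
    """Tweet records only (see ``generate_corpus`` for the full bundle)."""
    return generate_corpus(config).tweets


def write_corpus(corpus: SyntheticCorpus, out_dir: str | Path) -> dict[str, Path]:
    """Serialize a corpus bundle; ground truth goes to a separate sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "tweets": out / "tweets.jsonl",
        "epi": out / "epi.csv",
        "accounts": out / "accounts.csv",
        "lexicon": out / "lexicon.tsv",
        "weekly_true": out / "weekly_true.csv",
        "ground_truth": out / "ground_truth.json",
        "config": out / "sim_config.json",
    }
    write_tweets(corpus.tweets, paths["tweets"])
    corpus.epi.to_csv(paths["epi"], index=False)
    pd.DataFrame(
        [{"account": a, "og": m["og"], "region": m["region"]}
         for a, m in sorted(corpus.account_meta.items())]
    ).to_csv(paths["accounts"], index=False)
    corpus.lexicon.to_tsv(paths["lexicon"])
    corpus.weekly.to_csv(paths["weekly_true"], index=False)
    corpus.truth.to_json(paths["ground_truth"])
    cfg = dataclasses.asdict(corpus.config)
    cfg["gamma"] = list(cfg["gamma"])
    cfg["baseline"] = {k: [v[0], list(v[1])] for k, v in cfg["baseline"].items()}
    paths["config"].write_text(json.dumps(cfg, indent=1, sort_keys=True))
    return paths
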