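"""Trimmed inverse-probability-weighted estimation of the polarity effect.

The treatment is the account-week's sentiment polarity SP (1 positive,
0 negative); outcomes are the weekly response rates RP, FV, RT. A logistic
regression of SP on the eight covariates (NT, LT, MF, NI, HF, CC, ND, OG)
yields each unit's balancing score p_i; treated units are weighted 1/p_i
and controls 1/(1-p_i). The differential effect of treatment (DET) is
reported three ways:

* ``unadjusted`` — difference of group means,
* ``ipw_ht``     — Horvitz-Thompson form, (1/n) sum_i Y_i T_i / p_i
                   - (1/n) sum_i Y_i (1-T_i) / (1-p_i) over untrimmed units,
* ``ipw_hajek``  — the same weights normalized within each group.

Units with extreme scores are trimmed (excluded outside [0.3, 0.7] by
default, or weight-capped to [1/hi, 1/lo]); uncertainty comes from a
nonparametric bootstrap that re-runs the whole chain per replicate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats
import statsmodels.api as sm

from .exceptions import DataError, EstimationError

COVARIATES = ["NT", "LT", "MF", "NI", "HF", "CC", "ND", "OG"]
OUTCOMES = ["RP", "FV", "RT"]
ESTIMATORS = ["unadjusted", "ipw_ht", "ipw_hajek"]

#: |standardized coefficient| beyond this is treated as quasi-separation.
_COEF_BOUND = 15.0
#: Ridge penalty used by the separation fallback (on standardized covariates).
_RIDGE = 1e-4
#: Balancing scores are clipped strictly inside (0, 1).
_P_EPS = 1e-12


# ---------------------------------------------------------------------------
# Balancing-score fit
# ---------------------------------------------------------------------------

@dataclass
class BalancingFit:
    """Fitted balancing-score model and per-unit scores.

    ``params`` holds the intercept and one coefficient per covariate on the
    original covariate scale (coefficients of covariates that were constant
    in the data are 0). Scores are probabilities strictly inside (0, 1).
    """

    params: pd.Series
    scores: np.ndarray
    converged: bool
    separation: bool
    dropped: tuple[str, ...] = ()


def _ridge_logit(X: np.ndarray, y: np.ndarray, lam: float = _RIDGE) -> np.ndarray:
    """Penalized logistic MLE: -loglik + lam * ||slopes||^2 (intercept free)."""

    def nll(beta: np.ndarray) -> tuple[float, np.ndarray]:
        eta = X @ beta
        # log(1+exp(eta)) computed stably
        ll = y @ eta - np.logaddexp(0.0, eta).sum()
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
        pen = np.r_[0.0, beta[1:]]
        grad = X.T @ (p - y) + 2.0 * lam * pen
        return -ll + lam * (beta[1:] @ beta[1:]), grad

    res = scipy.optimize.minimize(
        nll, np.zeros(X.shape[1]), jac=True, method="L-BFGS-B",
        options={"maxiter": 500},
    )
    return res.x


def _fit_logit_std(Xs: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, bool, bool]:
    """Fit logistic regression on standardized design (with intercept column).

    Returns (beta, converged, separation). On non-convergence or
    quasi-separation the fit is redone with a small ridge penalty.
    """
    converged = False
    beta = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, Xs).fit(disp=0, maxiter=100)
            beta = np.asarray(res.params, dtype=float)
            converged = bool(res.mle_retvals.get("converged", False))
        except Exception:
            beta = None
    separation = (
        beta is None
        or not converged
        or not np.all(np.isfinite(beta))
        or np.max(np.abs(beta)) > _COEF_BOUND
    )
    if separation:
        beta = _ridge_logit(Xs, y)
        converged = True
    return beta, converged, separation


def fit_balancing_score(
    records: pd.DataFrame,
    covariates: Sequence[str] = COVARIATES,
) -> BalancingFit:
    """Logistic fit of SP on the covariates; returns scores on (0, 1).

    Covariates are standardized internally for numerical stability; constant
    covariates are dropped from the fit (their coefficient is reported as 0).
    Quasi-separation triggers a ridge-penalized refit and sets the
    ``separation`` flag.
    """
    sp = records["SP"].to_numpy()
    if not set(np.unique(sp)) <= {0, 1}:
        raise DataError("SP must be 0/1 (drop excluded units first)")
    y = sp.astype(float)
    if y.sum() == 0 or y.sum() == len(y):
        raise EstimationError("both treatment groups must be nonempty")

    X = records[list(covariates)].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        i, j = np.argwhere(~np.isfinite(X))[0]
        raise DataError(
            f"non-finite covariate {covariates[j]!r} at unit index {records.index[i]}"
        )

    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    keep = sd > 0
    Xs = np.column_stack([np.ones(len(y)), (X[:, keep] - mu[keep]) / sd[keep]])

    beta_std, converged, separation = _fit_logit_std(Xs, y)
    scores = 1.0 / (1.0 + np.exp(-np.clip(Xs @ beta_std, -700, 700)))
    scores = np.clip(scores, _P_EPS, 1.0 - _P_EPS)

    # map standardized coefficients back to the original covariate scale
    params = pd.Series(0.0, index=["const", *covariates])
    slopes = np.zeros(len(covariates))
    slopes[keep] = beta_std[1:] / sd[keep]
    params.iloc[1:] = slopes
    params.iloc[0] = beta_std[0] - float((mu[keep] / sd[keep]) @ beta_std[1:])

    dropped = tuple(c for c, k in zip(covariates, keep) if not k)
    return BalancingFit(params, scores, converged, separation, dropped)


# ---------------------------------------------------------------------------
# Weights, trimming, estimators
# ---------------------------------------------------------------------------

def ipw_weight(p: float, group: int) -> float:
    """Inverse-probability weight: 1/p for treated, 1/(1-p) for controls."""
    if not 0.0 < p < 1.0:
        raise ValueError(f"balancing score {p} outside (0, 1)")
    return 1.0 / p if group == 1 else 1.0 / (1.0 - p)


def make_units(records: pd.DataFrame, fit: BalancingFit) -> pd.DataFrame:
    """Attach balancing scores and IPW weights to the analyzed records."""
    units = records.copy().reset_index(drop=True)
    p = np.asarray(fit.scores, dtype=float)
    if len(p) != len(units):
        raise DataError("number of scores does not match number of units")
    sp = units["SP"].to_numpy().astype(int)
    units["p"] = p
    units["weight"] = np.where(sp == 1, 1.0 / p, 1.0 / (1.0 - p))
    units["trimmed"] = False
    return units


def trim(
    units: pd.DataFrame,
    lo: float = 0.3,
    hi: float = 0.7,
    mode: str = "exclude",
) -> pd.DataFrame:
    """Trim extreme balancing scores.

    ``exclude`` marks units with p < lo or p > hi as trimmed; ``cap``
    truncates weights to the implied closed interval [1/hi, 1/lo]
    (1.43 and 3.33 at the default 0.3/0.7 band). Boundary scores are kept
    untouched in both modes.
    """
    if not (0.0 < lo < hi < 1.0):
        raise ValueError(f"need 0 < lo < hi < 1, got lo={lo}, hi={hi}")
    if mode not in {"exclude", "cap"}:
        raise ValueError(f"unknown trim mode {mode!r}")
    out = units.copy()
    if mode == "exclude":
        out["trimmed"] = (out["p"] < lo) | (out["p"] > hi)
    else:
        out["weight"] = out["weight"].clip(lower=1.0 / hi, upper=1.0 / lo)
        out["trimmed"] = False
    return out


def det_unadjusted(records: pd.DataFrame, outcome: str) -> float:
    """Difference of mean outcome, treated minus control."""
    sp = records["SP"].to_numpy().astype(int)
    y = records[outcome].to_numpy(dtype=float)
    if (sp == 1).sum() == 0 or (sp == 0).sum() == 0:
        raise EstimationError("both groups must be nonempty")
    return float(y[sp == 1].mean() - y[sp == 0].mean())


def det_ipw(units: pd.DataFrame, outcome: str, variant: str = "ht") -> float:
    """IPW estimate of the DET over untrimmed units.

    ``ht`` (default) is the printed 1/n form; ``hajek`` normalizes the
    weights within each group, making the estimate invariant to adding a
    constant to the outcome.
    """
    kept = units.loc[~units["trimmed"]]
    sp = kept["SP"].to_numpy().astype(int)
    if (sp == 1).sum() == 0 or (sp == 0).sum() == 0:
        raise EstimationError(
            "a group is empty after trimming; consider wider trimming bounds"
        )
    y = kept[outcome].to_numpy(dtype=float)
    w = kept["weight"].to_numpy(dtype=float)
    t, c = sp == 1, sp == 0
    if variant == "ht":
        n = len(kept)
        return float((y[t] * w[t]).sum() / n - (y[c] * w[c]).sum() / n)
    if variant == "hajek":
        return float(
            (y[t] * w[t]).sum() / w[t].sum() - (y[c] * w[c]).sum() / w[c].sum()
        )
    raise ValueError(f"unknown IPW variant {variant!r}")


def group_t_test(records: pd.DataFrame, outcome: str) -> tuple[float, float]:
    """Welch two-sample t-test of the outcome between the SP groups."""
    sp = records["SP"].to_numpy().astype(int)
    y = records[outcome].to_numpy(dtype=float)
    a, b = y[sp == 1], y[sp == 0]
    if len(a) < 2 or len(b) < 2:
        raise EstimationError("each group needs at least 2 units for the t-test")
    res = scipy.stats.ttest_ind(a, b, equal_var=False)
    t, p = float(res.statistic), float(res.pvalue)
    if np.isnan(t):  # both groups constant and equal
        t, p = 0.0, 1.0
    return t, p


def balance_diagnostics(
    units: pd.DataFrame,
    covariates: Sequence[str] = COVARIATES,
    lo: float = 0.3,
    hi: float = 0.7,
) -> pd.DataFrame:
    """Standardized mean differences per covariate, unweighted and weighted.

    SMD = |mean_t - mean_c| / pooled SD, with the pooled (unweighted) SD as
    the common denominator. Weighted means use the IPW weights of untrimmed
    units. The returned frame carries ``n_outside_band`` in ``.attrs``.
    """
    sp = units["SP"].to_numpy().astype(int)
    if (sp == 1).sum() == 0 or (sp == 0).sum() == 0:
        raise EstimationError("both groups must be nonempty")
    kept = ~units["trimmed"].to_numpy()
    w = units["weight"].to_numpy(dtype=float)
    rows = []
    for cov in covariates:
        x = units[cov].to_numpy(dtype=float)
        t, c = sp == 1, sp == 0
        pooled = np.sqrt((x[t].var(ddof=1) + x[c].var(ddof=1)) / 2.0) if (
            t.sum() > 1 and c.sum() > 1
        ) else 0.0
        degenerate = pooled == 0.0
        if degenerate:
            smd_u = smd_w = 0.0
        else:
            smd_u = abs(x[t].mean() - x[c].mean()) / pooled
            tk, ck = t & kept, c & kept
            if tk.sum() == 0 or ck.sum() == 0:
                smd_w = np.nan
            else:
                mt = (x[tk] * w[tk]).sum() / w[tk].sum()
                mc = (x[ck] * w[ck]).sum() / w[ck].sum()
                smd_w = abs(mt - mc) / pooled
        rows.append({
            "covariate": cov, "smd_unweighted": smd_u,
            "smd_weighted": smd_w, "degenerate": degenerate,
        })
    out = pd.DataFrame(rows).set_index("covariate")
    p = units["p"].to_numpy(dtype=float)
    out.attrs["n_outside_band"] = int(((p < lo) | (p > hi)).sum())
    return out


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

@dataclass
class BootstrapResult:
    """Replicate summary for one (outcome, estimator) cell."""

    sd: float
    ci: tuple[float, float]
    estimates: np.ndarray
    n_redrawn: int
    reps: int


def _chain_estimates(
    X: np.ndarray,
    y_mat: np.ndarray,
    sp: np.ndarray,
    lo: float,
    hi: float,
    mode: str,
) -> np.ndarray | None:
    """Full estimation chain on raw arrays.

    Returns a (n_outcomes, 3) array of [unadjusted, ipw_ht, ipw_hajek]
    estimates, or None when a group is empty (caller redraws).
    """
    t, c = sp == 1, sp == 0
    nt, nc = int(t.sum()), int(c.sum())
    if nt == 0 or nc == 0:
        return None
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    keep = sd > 0
    Xs = np.column_stack([np.ones(len(sp)), (X[:, keep] - mu[keep]) / sd[keep]])
    beta, _, _ = _fit_logit_std(Xs, sp.astype(float))
    p = np.clip(1.0 / (1.0 + np.exp(-np.clip(Xs @ beta, -700, 700))),
                _P_EPS, 1.0 - _P_EPS)
    w = np.where(t, 1.0 / p, 1.0 / (1.0 - p))
    if mode == "exclude":
        kept = (p >= lo) & (p <= hi)
    else:
        w = np.clip(w, 1.0 / hi, 1.0 / lo)
        kept = np.ones(len(sp), dtype=bool)
    tk, ck = t & kept, c & kept
    if tk.sum() == 0 or ck.sum() == 0:
        return None
    n = int(kept.sum())
    out = np.empty((y_mat.shape[1], 3))
    for j in range(y_mat.shape[1]):
        y = y_mat[:, j]
        out[j, 0] = y[t].mean() - y[c].mean()
        out[j, 1] = (y[tk] * w[tk]).sum() / n - (y[ck] * w[ck]).sum() / n
        out[j, 2] = (y[tk] * w[tk]).sum() / w[tk].sum() - (y[ck] * w[ck]).sum() / w[ck].sum()
    return out


def _bootstrap_all(
    records: pd.DataFrame,
    outcomes: Sequence[str],
    covariates: Sequence[str],
    reps: int,
    seed: int | None,
    lo: float,
    hi: float,
    mode: str,
    max_attempt_factor: int = 50,
) -> tuple[np.ndarray, int]:
    """Bootstrap the full chain; returns (reps, n_outcomes, 3) estimates.

    Account-week units are resampled i.i.d. with replacement; replicates
    where a group empties (before or after trimming) are redrawn, up to
    ``max_attempt_factor * reps`` total draws.
    """
    if reps < 2:
        raise ValueError("bootstrap needs at least 2 replicates")
    rng = np.random.default_rng(seed)
    X = records[list(covariates)].to_numpy(dtype=float)
    y_mat = records[list(outcomes)].to_numpy(dtype=float)
    sp = records["SP"].to_numpy().astype(int)
    n = len(records)
    out = np.empty((reps, len(outcomes), 3))
    done = 0
    redrawn = 0
    attempts = 0
    while done < reps:
        attempts += 1
        if attempts > max_attempt_factor * reps:
            raise EstimationError(
                "bootstrap failed: estimator not computable in most replicates"
            )
        idx = rng.integers(0, n, n)
        est = _chain_estimates(X[idx], y_mat[idx], sp[idx], lo, hi, mode)
        if est is None:
            redrawn += 1
            continue
        out[done] = est
        done += 1
    return out, redrawn


def bootstrap_det(
    records: pd.DataFrame,
    outcome: str,
    estimator: str = "ipw_ht",
    reps: int = 500,
    seed: int | None = None,
    lo: float = 0.3,
    hi: float = 0.7,
    trim_mode: str = "exclude",
    covariates: Sequence[str] = COVARIATES,
) -> BootstrapResult:
    """Bootstrap SD and 2.5/97.5 percentile CI for one DET estimate.

    Each replicate resamples the account-week records with replacement and
    re-runs balancing fit -> weights -> trimming -> estimation.
    """
    if estimator not in ESTIMATORS:
        raise ValueError(f"unknown estimator {estimator!r}")
    ests, redrawn = _bootstrap_all(
        records, [outcome], covariates, reps, seed, lo, hi, trim_mode
    )
    col = ESTIMATORS.index(estimator)
    vals = ests[:, 0, col]
    return BootstrapResult(
        sd=float(vals.std(ddof=1)),
        ci=(float(np.percentile(vals, 2.5)), float(np.percentile(vals, 97.5))),
        estimates=vals,
        n_redrawn=redrawn,
        reps=reps,
    )


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class PolarityEffectModel:
    """Polarity-effect model on a weekly account table.

    Parameters
    ----------
    data : DataFrame
        One row per account-week with columns SP (0, 1, or the "excluded"
        marker), the outcomes and the covariates. Excluded units are dropped
        at construction and counted in ``n_excluded``.
    outcomes, covariates : sequences of column names
        Default to the study's RP/FV/RT and eight covariates.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        outcomes: Sequence[str] = OUTCOMES,
        covariates: Sequence[str] = COVARIATES,
    ) -> None:
        needed = {"SP", *outcomes, *covariates}
        missing = needed - set(data.columns)
        if missing:
            raise DataError(f"data lacks columns: {sorted(missing)}")
        self.outcomes = list(outcomes)
        self.covariates = list(covariates)
        mask = data["SP"].isin([0, 1])
        analyzed = data.loc[mask].copy()
        analyzed["SP"] = analyzed["SP"].astype(int)
        self.data = analyzed.reset_index(drop=True)
        self.n_excluded = int(len(data) - len(analyzed))
        if self.data.empty:
            raise EstimationError("no analyzable units (all excluded)")

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kwargs) -> "PolarityEffectModel":
        return cls(data, **kwargs)

    def fit(
        self,
        trim_bounds: tuple[float, float] = (0.3, 0.7),
        trim_mode: str = "exclude",
        bootstrap_reps: int = 500,
        seed: int | None = None,
    ) -> "PolarityEffectResults":
        """Run the full chain and return a results object.

        Set ``bootstrap_reps=0`` to skip the bootstrap (SDs and CIs NaN).
        """
        lo, hi = trim_bounds
        bfit = fit_balancing_score(self.data, self.covariates)
        units = trim(make_units(self.data, bfit), lo, hi, trim_mode)
        balance = balance_diagnostics(units, self.covariates, lo, hi)

        if bootstrap_reps:
            boot, redrawn = _bootstrap_all(
                self.data, self.outcomes, self.covariates,
                bootstrap_reps, seed, lo, hi, trim_mode,
            )
        else:
            boot, redrawn = None, 0

        kept = units.loc[~units["trimmed"]]
        n_t_trim = int((kept["SP"] == 1).sum())
        n_c_trim = int((kept["SP"] == 0).sum())
        n_t_all = int((self.data["SP"] == 1).sum())
        n_c_all = int((self.data["SP"] == 0).sum())

        rows = []
        for j, outcome in enumerate(self.outcomes):
            t_stat, p_val = group_t_test(self.data, outcome)
            for k, est_name in enumerate(ESTIMATORS):
                if est_name == "unadjusted":
                    point = det_unadjusted(self.data, outcome)
                    n_t, n_c = n_t_all, n_c_all
                else:
                    point = det_ipw(units, outcome, est_name.removeprefix("ipw_"))
                    n_t, n_c = n_t_trim, n_c_trim
                if boot is not None:
                    vals = boot[:, j, k]
                    bsd = float(vals.std(ddof=1))
                    ci = (float(np.percentile(vals, 2.5)),
                          float(np.percentile(vals, 97.5)))
                else:
                    bsd, ci = float("nan"), (float("nan"), float("nan"))
                rows.append({
                    "outcome": outcome, "estimator": est_name,
                    "estimate": point, "boot_sd": bsd,
                    "ci_lo": ci[0], "ci_hi": ci[1],
                    "t": t_stat, "p_value": p_val,
                    "n_treated": n_t, "n_control": n_c,
                })
        estimates = pd.DataFrame(rows).set_index(["outcome", "estimator"])
        return PolarityEffectResults(
            model=self, balancing_fit=bfit, units=units, balance=balance,
            estimates=estimates, trim_bounds=trim_bounds, trim_mode=trim_mode,
            bootstrap_reps=bootstrap_reps, bootstrap_redrawn=redrawn, seed=seed,
        )


@dataclass
class PolarityEffectResults:
    """Fitted polarity-effect estimates with bootstrap uncertainty."""

    model: PolarityEffectModel
    balancing_fit: BalancingFit
    units: pd.DataFrame
    balance: pd.DataFrame
    estimates: pd.DataFrame
    trim_bounds: tuple[float, float]
    trim_mode: str
    bootstrap_reps: int
    bootstrap_redrawn: int
    seed: int | None = None

    def det(self, outcome: str, estimator: str = "ipw_ht") -> float:
        return float(self.estimates.loc[(outcome, estimator), "estimate"])

    def summary(self) -> str:
        """Plain-text summary table of all estimates and diagnostics."""
        n = len(self.model.data)
        kept = int((~self.units["trimmed"]).sum())
        lines = [
            "Polarity effect on engagement (DET = mean Y[SP=1] - mean Y[SP=0])",
            "=" * 72,
            f"units analyzed: {n}   excluded (zero sentiment): {self.model.n_excluded}",
            f"trimming: {self.trim_mode} at p in [{self.trim_bounds[0]}, "
            f"{self.trim_bounds[1]}]   untrimmed: {kept}",
            f"balancing fit: converged={self.balancing_fit.converged} "
            f"separation={self.balancing_fit.separation}",
            f"bootstrap: {self.bootstrap_reps} replicates "
            f"({self.bootstrap_redrawn} redrawn)",
            "-" * 72,
            self.estimates.round(4).to_string(),
            "-" * 72,
            "covariate balance (|SMD|):",
            self.balance.round(4).to_string(),
        ]
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        return self.estimates.reset_index()

    def plot_scores(self, path: str) -> None:
        """Histogram of balancing scores by treatment group (diagnostic)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        p = self.units["p"]
        sp = self.units["SP"]
        bins = np.linspace(0, 1, 41)
        ax.hist(p[sp == 1], bins=bins, alpha=0.6, label="SP=1 (positive)")
        ax.hist(p[sp == 0], bins=bins, alpha=0.6, label="SP=0 (negative)")
        for b in self.trim_bounds:
            ax.axvline(b, color="k", ls="--", lw=0.8)
        ax.set_xlabel("balancing score")
        ax.set_ylabel("units")
        ax.legend()
        fig.tight_layout()
        fig.savefig(path, dpi=100)
        plt.close(fig)
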