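"""Survival analysis: Kaplan-Meier, log-rank, collinearity screening,
and Cox proportional-hazards fitting.

Cox models use the partial likelihood with Efron tie handling (monthly
survival times are rounded and tie-heavy).  Before multivariate fitting,
strongly associated covariates are removed by a greedy collinearity
screen so that, e.g., chromosome-7 loss, complex karyotype, and somatic
TP53 status do not enter alongside the chromosome-5 deletion flag they
travel with.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

log = logging.getLogger(__name__)


@dataclass
class KMEstimate:
    """Product-limit survival estimate with a risk table."""

    times: np.ndarray  # event/censor times in ascending order (0 first)
    survival: np.ndarray  # S(t) at those times, right-continuous
    at_risk: np.ndarray
    events: np.ndarray

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return float(self.survival[max(idx, 0)])

    def risk_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "at_risk": self.at_risk,
                "events": self.events,
                "survival": self.survival,
            }
        )


def km_estimate(times: Sequence[float], events: Sequence[bool]) -> KMEstimate:
    """Kaplan-Meier product-limit estimator; S(0) = 1."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if (t < 0).any():
        raise ValueError("negative survival time")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    sf = kmf.survival_function_["KM_estimate"]
    grid = sf.index.to_numpy(dtype=float)
    at_risk = np.array([(t >= u).sum() for u in grid])
    n_events = np.array([((t == u) & e).sum() for u in grid])
    return KMEstimate(
        times=grid, survival=sf.to_numpy(dtype=float), at_risk=at_risk, events=n_events
    )


def logrank_test(
    times_a: Sequence[float],
    events_a: Sequence[bool],
    times_b: Sequence[float],
    events_b: Sequence[bool],
) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p)."""
    ea, eb = np.asarray(events_a, dtype=bool), np.asarray(events_b, dtype=bool)
    if len(ea) == 0 or len(eb) == 0:
        raise ValueError("both groups must be non-empty")
    if not ea.any() and not eb.any():
        raise ValueError("log-rank undefined: no events in either group")
    res = _ll_logrank(times_a, times_b, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


@dataclass
class SurvivalFit:
    """A fitted Cox proportional-hazards model (forest-plot table)."""

    covariates: list[str]
    coefficients: np.ndarray
    hazard_ratios: np.ndarray
    ci_95: list[tuple[float, float]]
    p_values: np.ndarray
    log_likelihood: float
    dropped_collinear: list[tuple[str, str]] = field(default_factory=list)

    def as_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "covariate": self.covariates,
                "coef": self.coefficients,
                "hazard_ratio": self.hazard_ratios,
                "ci_lower": [lo for lo, _ in self.ci_95],
                "ci_upper": [hi for _, hi in self.ci_95],
                "p": self.p_values,
            }
        )

    def to_json_dict(self) -> dict:
        return {
            "log_likelihood": self.log_likelihood,
            "dropped_collinear": [list(d) for d in self.dropped_collinear],
            "covariates": {
                name: {
                    "coef": float(c),
                    "hazard_ratio": float(hr),
                    "ci_95": [float(lo), float(hi)],
                    "p": float(p),
                }
                for name, c, hr, (lo, hi), p in zip(
                    self.covariates,
                    self.coefficients,
                    self.hazard_ratios,
                    self.ci_95,
                    self.p_values,
                )
            },
        }


def cox_fit(
    times: Sequence[float],
    events: Sequence[bool],
    covariates: pd.DataFrame,
    tie_method: str = "efron",
) -> SurvivalFit:
    """Fit a Cox proportional-hazards model by partial likelihood.

    Wald 95% CIs and p-values; raises on zero-variance covariates, on
    datasets without events, and on non-convergence (naming the
    offending covariate when lifelines identifies one).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if not e.any():
        raise ValueError("Cox fit requires at least one event")
    for col in covariates.columns:
        if covariates[col].std(ddof=0) == 0:
            raise ValueError(f"zero-variance covariate {col!r}")
    df = covariates.copy()
    df["_time"] = t
    df["_event"] = e.astype(int)
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="_time", event_col="_event")
    except ConvergenceError as exc:
        raise RuntimeError(f"Cox model failed to converge: {exc}") from exc
    s = cph.summary
    return SurvivalFit(
        covariates=list(s.index),
        coefficients=s["coef"].to_numpy(),
        hazard_ratios=np.exp(s["coef"].to_numpy()),
        ci_95=list(
            zip(
                np.exp(s["coef lower 95%"].to_numpy()),
                np.exp(s["coef upper 95%"].to_numpy()),
            )
        ),
        p_values=s["p"].to_numpy(),
        log_likelihood=float(cph.log_likelihood_),
    )


def _univariate_significance(
    feature: pd.Series, times: np.ndarray, events: np.ndarray
) -> float:
    """Univariate log-rank p for a binary feature (Cox Wald p otherwise);
    non-informative features return p = 1."""
    x = feature.to_numpy(dtype=float)
    values = np.unique(x)
    try:
        if len(values) == 2:
            mask = x == values.max()
            if events[mask].sum() + events[~mask].sum() == 0:
                return 1.0
            _, p = logrank_test(times[mask], events[mask], times[~mask], events[~mask])
        else:
            fit = cox_fit(times, events, feature.to_frame())
            p = float(fit.p_values[0])
    except (ValueError, RuntimeError):
        return 1.0
    return p


def collinearity_screen(
    features: pd.DataFrame,
    times: Sequence[float],
    events: Sequence[bool],
    threshold: float = 0.7,
    anchor: Optional[str] = None,
) -> tuple[list[str], list[tuple[str, str]]]:
    """Greedy removal of collinear covariates before multivariate Cox.

    Pairs with |Pearson/phi association| >= threshold are resolved by
    keeping the designated anchor when involved, otherwise the variable
    with the stronger (smaller-p) univariate log-rank significance;
    alphabetical order breaks exact ties, so the screen is deterministic.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    cols = list(features.columns)
    assoc = features.astype(float).corr()
    sig = {c: _univariate_significance(features[c], t, e) for c in cols}
    pairs = [
        (abs(assoc.loc[a, b]), a, b)
        for i, a in enumerate(cols)
        for b in cols[i + 1 :]
        if not np.isnan(assoc.loc[a, b]) and abs(assoc.loc[a, b]) >= threshold
    ]
    pairs.sort(key=lambda x: (-x[0], x[1], x[2]))
    retained = set(cols)
    dropped: list[tuple[str, str]] = []
    for strength, a, b in pairs:
        if a not in retained or b not in retained:
            continue
        if anchor == a:
            loser, winner = b, a
        elif anchor == b:
            loser, winner = a, b
        elif (sig[a], a) <= (sig[b], b):
            loser, winner = b, a
        else:
            loser, winner = a, b
        retained.discard(loser)
        dropped.append(
            (loser, f"|association| {strength:.3f} with {winner} >= {threshold}")
        )
    return [c for c in cols if c in retained], dropped


def dichotomize(
    values: Sequence[float], cut_point: float
) -> pd.Series:
    """Binary indicator for values strictly greater than the cut point.

    Missing values are excluded from the output with a logged notice.
    """
    s = pd.Series(values, dtype=float)
    n_missing = int(s.isna().sum())
    if n_missing:
        log.info("dichotomize: excluding %d missing values", n_missing)
    s = s.dropna()
    return (s > cut_point).astype(int)


def screened_cox_fit(
    times: Sequence[float],
    events: Sequence[bool],
    features: pd.DataFrame,
    threshold: float = 0.7,
    anchor: Optional[str] = None,
) -> SurvivalFit:
    """Collinearity screen followed by the multivariate Cox fit."""
    retained, dropped = collinearity_screen(
        features, times, events, threshold=threshold, anchor=anchor
    )
    fit = cox_fit(times, events, features[retained])
    fit.dropped_collinear = dropped
    return fit
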