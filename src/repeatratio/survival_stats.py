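"""Kaplan-Meier estimation, log-rank comparison and Cox proportional hazards.

Survival records are rows of a DataFrame with a positive ``time`` column
(days), an ``event`` column (1 = relapse/progression/death, 0 = censored) and
covariate columns.  Estimation is delegated to lifelines; this module wraps it
behind the package's data contracts (declared reference levels for categorical
covariates, Efron tie handling by default with Breslow available, dropped-row
logging) and adds a partial-likelihood score test evaluated at zero, which for
a single binary covariate without ties coincides with the log-rank statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

logger = logging.getLogger(__name__)

Z_95 = 1.96  # conventional two-sided 95% multiplier: CI = exp(coef +/- 1.96*se)


@dataclass
class KMCurve:
    """Product-limit survival curve evaluated at the distinct event times."""

    times: np.ndarray  # ascending distinct event times
    survival: np.ndarray  # S(t) at each event time, right-continuous
    at_risk: np.ndarray  # risk-set size just before each event time

    def __post_init__(self) -> None:
        if (np.diff(self.times) <= 0).any():
            raise ValueError("event times must be strictly ascending")
        if ((self.survival < 0) | (self.survival > 1)).any():
            raise ValueError("survival probabilities must lie in [0, 1]")
        if (np.diff(self.survival) > 1e-12).any():
            raise ValueError("survival must be non-increasing")


@dataclass
class CoxFit:
    """A fitted proportional-hazards model.

    ``summary`` has one row per non-reference covariate level with columns
    ``coef``, ``se``, ``hr``, ``ci_low``, ``ci_high``, ``p``.
    """

    summary: pd.DataFrame
    log_likelihood: float
    converged: bool
    n: int
    n_events: int
    ties: str
    reference_levels: dict[str, str] = field(default_factory=dict)


def _check_times(time: np.ndarray) -> None:
    if (time <= 0).any():
        raise ValueError("survival times must be positive")


def km_estimate(time: Sequence[float], event: Sequence[int]) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    Censored observations reduce the risk set without producing steps; a
    fully censored cohort yields S identically 1 (empty step set).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0:
        raise ValueError("no records")
    _check_times(time)
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    tbl = kmf.event_table
    steps = tbl[tbl["observed"] > 0]
    event_times = steps.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(event_times).to_numpy()
    at_risk = steps["at_risk"].to_numpy(dtype=float)
    return KMCurve(times=event_times, survival=surv, at_risk=at_risk)


def km_table(time: Sequence[float], event: Sequence[int]) -> pd.DataFrame:
    curve = km_estimate(time, event)
    return pd.DataFrame(
        {"time": curve.times, "survival": curve.survival, "at_risk": curve.at_risk}
    )


def logrank_test(
    time_a: Sequence[float],
    event_a: Sequence[int],
    time_b: Sequence[float],
    event_b: Sequence[int],
) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square, p) with 1 df."""
    ta, tb = np.asarray(time_a, float), np.asarray(time_b, float)
    ea, eb = np.asarray(event_a, int), np.asarray(event_b, int)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be nonempty")
    _check_times(ta)
    _check_times(tb)
    if ea.sum() + eb.sum() == 0:
        raise ValueError("log-rank test requires at least one event")
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


def _build_design(
    records: pd.DataFrame,
    covariates: Sequence[str],
    reference_levels: dict[str, str],
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Dummy-code categorical covariates against declared reference levels."""
    design = pd.DataFrame(index=records.index)
    refs_used: dict[str, str] = {}
    for cov in covariates:
        if cov not in records.columns:
            raise ValueError(f"covariate {cov!r} missing from records")
        col = records[cov]
        if pd.api.types.is_numeric_dtype(col):
            if col.nunique() < 2:
                raise ValueError(f"covariate {cov!r} is constant")
            design[cov] = col.astype(float)
        else:
            levels = sorted(col.astype(str).unique())
            if len(levels) < 2:
                raise ValueError(f"covariate {cov!r} is constant")
            ref = reference_levels.get(cov, levels[0])
            if ref not in levels:
                raise ValueError(
                    f"reference level {ref!r} absent from covariate {cov!r}"
                )
            refs_used[cov] = ref
            for lev in levels:
                if lev != ref:
                    design[f"{cov}[{lev}]"] = (col.astype(str) == lev).astype(float)
    return design, refs_used


def cox_fit(
    records: pd.DataFrame,
    covariates: Sequence[str],
    *,
    reference_levels: Optional[dict[str, str]] = None,
    ties: str = "efron",
) -> CoxFit:
    """Multivariate Cox proportional-hazards fit.

    Rows with missing time, event or covariate values are dropped with a
    logged count.  Categorical covariates are dummy-coded against their
    declared reference level (first level alphabetically when undeclared).
    95% CIs are ``exp(coef +/- 1.96*se)``.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown tie-handling method {ties!r}")
    reference_levels = reference_levels or {}
    needed = ["time", "event", *covariates]
    missing_cols = [c for c in needed if c not in records.columns]
    if missing_cols:
        raise ValueError(f"records missing columns: {missing_cols}")
    data = records[needed].copy()
    complete = data.notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.warning("dropping %d record(s) with missing survival covariates",
                       n_dropped)
    data = data.loc[complete]
    _check_times(data["time"].to_numpy(float))

    design, refs_used = _build_design(data, covariates, reference_levels)
    n_events = int(data["event"].sum())
    if n_events < design.shape[1]:
        raise ValueError(
            f"{n_events} events < {design.shape[1]} parameters; fit is "
            "unidentifiable"
        )
    frame = design.copy()
    frame["time"] = data["time"].astype(float)
    frame["event"] = data["event"].astype(int)

    cph = CoxPHFitter()
    try:
        cph.fit(frame, duration_col="time", event_col="event",
                fit_options={"step_size": 0.95})
    except Exception as exc:  # convergence / separation surfaced by lifelines
        raise RuntimeError(f"Cox fit failed: {exc}") from exc

    coefs = cph.params_
    ses = cph.standard_errors_
    summary = pd.DataFrame(
        {
            "coef": coefs,
            "se": ses,
            "hr": np.exp(coefs),
            "ci_low": np.exp(coefs - Z_95 * ses),
            "ci_high": np.exp(coefs + Z_95 * ses),
            "p": cph.summary["p"],
        }
    )
    summary.index.name = "covariate"
    return CoxFit(
        summary=summary,
        log_likelihood=float(cph.log_likelihood_),
        converged=True,
        n=int(frame.shape[0]),
        n_events=n_events,
        ties="efron",
        reference_levels=refs_used,
    )


def cox_score_test(
    time: Sequence[float], event: Sequence[int], x: Sequence[float]
) -> tuple[float, float]:
    """Partial-likelihood score test of a single covariate at coefficient 0.

    Uses the Efron tie correction (identical to Breslow when event times are
    distinct).  For a binary covariate without ties this statistic equals the
    log-rank chi-square — the classical equivalence, used here as a
    cross-check between the Cox and log-rank machinery.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    x = np.asarray(x, float)
    _check_times(time)
    u = 0.0
    info = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        dead = (time == t) & (event == 1)
        d = int(dead.sum())
        s_r, s_r2 = x[at_risk].sum(), (x[at_risk] ** 2).sum()
        s_d, s_d2 = x[dead].sum(), (x[dead] ** 2).sum()
        n_r = int(at_risk.sum())
        for ell in range(d):
            frac = ell / d
            denom = n_r - ell  # at beta=0 all weights are 1
            m1 = (s_r - frac * s_d) / denom
            m2 = (s_r2 - frac * s_d2) / denom
            u_contrib = m1
            info += m2 - m1**2
            u -= u_contrib
        u += s_d
    if info <= 0:
        raise ValueError("zero information: covariate constant within risk sets")
    from scipy import stats as _st

    chi2 = u**2 / info
    return float(chi2), float(_st.chi2.sf(chi2, df=1))


def forest_table(fit: CoxFit) -> pd.DataFrame:
    """Hazard-ratio table with reference levels listed at HR exactly 1."""
    rows = []
    for cov, ref in fit.reference_levels.items():
        rows.append(
            {
                "covariate": f"{cov}[{ref}] (reference)",
                "hr": 1.0,
                "ci_low": np.nan,
                "ci_high": np.nan,
                "p": np.nan,
            }
        )
    for name, row in fit.summary.iterrows():
        rows.append(
            {
                "covariate": name,
                "hr": row["hr"],
                "ci_low": row["ci_low"],
                "ci_high": row["ci_high"],
                "p": row["p"],
            }
        )
    return pd.DataFrame(rows).set_index("covariate")
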