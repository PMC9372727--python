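"""Outcome analyses: Cox proportional hazards, Kaplan-Meier estimation,
log-rank statistics and maximally selected rank statistics.

Time-to-next-treatment style endpoints are modelled with the Cox partial
likelihood (Efron handling of tied event times).  Continuous markers are
dichotomised by maximally selected rank statistics: scan candidate cutpoints
within a quantile window of the marker, compute the standardized two-group
log-rank statistic at each, and take the cutpoint with the largest absolute
statistic; significance comes from a permutation null of the marker.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy import stats

logger = logging.getLogger("stimscreen")


def fit_cox(
    records: pd.DataFrame,
    covariates: list[str],
    duration_col: str = "time_days",
    event_col: str = "event",
    reference: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Cox proportional-hazards fit (Efron ties).

    Categorical covariates are expanded to indicators against the given
    reference level (``reference`` maps column -> level; default: the
    lexicographically first level).  Returns one row per model term with
    columns coef (log hazard ratio), se, p.
    """
    df = records[[duration_col, event_col] + covariates].dropna().copy()
    if df[event_col].sum() < 2:
        raise ValueError("need >= 2 observed events")
    reference = reference or {}
    model_cols = []
    for cov in covariates:
        col = df[cov]
        if col.dtype.kind in "OUS" or isinstance(col.dtype, pd.CategoricalDtype):
            levels = sorted(col.astype(str).unique())
            ref = str(reference.get(cov, levels[0]))
            if ref not in levels:
                raise ValueError(f"reference level {ref!r} not found in {cov!r}")
            for lev in levels:
                if lev == ref:
                    continue
                name = f"{cov}[{lev}]"
                df[name] = (col.astype(str) == lev).astype(float)
                model_cols.append(name)
            df = df.drop(columns=[cov])
        else:
            if col.nunique() < 2:
                raise ValueError(f"covariate {cov!r} is constant")
            model_cols.append(cov)
    fitter = CoxPHFitter()
    fitter.fit(
        df[[duration_col, event_col] + model_cols],
        duration_col=duration_col,
        event_col=event_col,
        # full Newton steps + tight tolerances: the damped default stops
        # short of the partial-likelihood maximum on small datasets
        fit_options={"step_size": 1.0, "precision": 1e-10, "r_precision": 1e-15},
    )
    out = fitter.summary[["coef", "se(coef)", "p"]].rename(
        columns={"se(coef)": "se"}
    )
    out.index.name = "term"
    return out


def kaplan_meier(
    records: pd.DataFrame,
    group_col: str | None = None,
    duration_col: str = "time_days",
    event_col: str = "event",
) -> dict[str, pd.DataFrame]:
    """Product-limit survival curves per group: columns time, survival, at_risk."""
    groups = (
        {"all": records}
        if group_col is None
        else {str(g): grp for g, grp in records.groupby(group_col)}
    )
    curves = {}
    for name, grp in groups.items():
        if grp.empty:
            raise ValueError(f"group {name!r} has no records")
        kmf = KaplanMeierFitter()
        kmf.fit(grp[duration_col], grp[event_col])
        surv = kmf.survival_function_.iloc[:, 0]
        at_risk = kmf.event_table["at_risk"].reindex(surv.index)
        curves[name] = pd.DataFrame(
            {"time": surv.index.to_numpy(), "survival": surv.to_numpy(),
             "at_risk": at_risk.to_numpy()}
        )
    return curves


def standardized_logrank(time, event, group) -> tuple[float, float, float]:
    """Two-group log-rank statistic.

    Returns (z, U, V) where U is the observed-minus-expected events in group 1,
    V the hypergeometric variance and z = U / sqrt(V).  The sign of z says
    which group fails faster.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group, dtype=int)
    order = np.argsort(time, kind="mergesort")
    time, event, group = time[order], event[order], group[order]
    u = 0.0
    v = 0.0
    n = len(time)
    i = 0
    at_risk = n
    at_risk1 = int(group.sum())
    while i < n:
        j = i
        d = d1 = 0
        while j < n and time[j] == time[i]:
            if event[j]:
                d += 1
                d1 += group[j]
            j += 1
        if d > 0 and at_risk > 1:
            frac = at_risk1 / at_risk
            u += d1 - d * frac
            v += d * frac * (1 - frac) * (at_risk - d) / (at_risk - 1)
        removed = j - i
        at_risk1 -= int(group[i:j].sum())
        at_risk -= removed
        i = j
    z = u / np.sqrt(v) if v > 0 else 0.0
    return float(z), float(u), float(v)


@dataclass
class MaxstatResult:
    cutpoint: float
    statistic: float  # max |standardized log-rank|
    p_value: float  # permutation p
    scan: pd.DataFrame  # cutpoint, z for every candidate


def _scan_max(marker, time, event, candidates):
    best_cut, best_abs, best_z = np.nan, -np.inf, np.nan
    zs = []
    for cut in candidates:
        grp = (marker > cut).astype(int)
        z, _, _ = standardized_logrank(time, event, grp)
        zs.append(z)
        if abs(z) > best_abs:
            best_cut, best_abs, best_z = cut, abs(z), z
    return best_cut, best_z, np.asarray(zs)


def maxstat_cutpoint(
    marker,
    records: pd.DataFrame,
    window: tuple[float, float] = (0.1, 0.9),
    n_perm: int = 1000,
    seed: int = 0,
    duration_col: str = "time_days",
    event_col: str = "event",
) -> MaxstatResult:
    """Maximally selected rank statistic for dichotomising a continuous marker.

    Candidate cutpoints are the observed marker values within the
    [low, high] marker quantiles (a cutpoint splits at marker > cut).  The
    permutation p-value shuffles the marker against the survival records.
    """
    marker = pd.Series(np.asarray(marker, dtype=float), index=records.index)
    if len(marker) < 10:
        raise ValueError("maxstat needs >= 10 samples")
    if marker.nunique() < 2:
        raise ValueError("marker is constant")
    low, high = window
    if not 0 < low < high < 1:
        raise ValueError("window quantiles must satisfy 0 < low < high < 1")
    qlo, qhi = marker.quantile([low, high])
    values = np.sort(marker.unique())
    candidates = [v for v in values if qlo <= v <= qhi and v < values[-1]]
    if len(candidates) < 2:
        raise ValueError("fewer than 2 candidate cutpoints inside the window")

    time = records[duration_col].to_numpy(dtype=float)
    event = records[event_col].to_numpy(dtype=int)
    mk = marker.to_numpy()
    cut, z, zs = _scan_max(mk, time, event, candidates)
    observed = abs(z)

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(mk)
        pvals = np.sort(np.unique(perm))
        plo, phi = np.quantile(perm, [low, high])
        pcand = [v for v in pvals if plo <= v <= phi and v < pvals[-1]]
        if not pcand:
            continue
        _, pz, _ = _scan_max(perm, time, event, pcand)
        if abs(pz) >= observed:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    scan = pd.DataFrame({"cutpoint": candidates, "z": zs})
    return MaxstatResult(cutpoint=float(cut), statistic=float(observed), p_value=float(p), scan=scan)


class TTestResult(NamedTuple):
    t: float
    p: float
    df: float
    degenerate: bool = False


def two_sample_t_test(x, y, paired: bool = False) -> TTestResult:
    """Student's t-test, two-sided.

    Unpaired uses the pooled (equal-variance) statistic; paired tests the mean
    difference.  Zero variance yields a missing p with the degenerate flag,
    except the exactly-null paired case (all differences zero) which is t=0,
    p=1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need >= 2 observations per group")
    if paired:
        if len(x) != len(y):
            raise ValueError("paired test needs equal-length samples")
        d = x - y
        if d.std(ddof=1) == 0:
            if np.allclose(d, 0):
                return TTestResult(0.0, 1.0, len(d) - 1)
            return TTestResult(np.nan, np.nan, len(d) - 1, degenerate=True)
        t, p = stats.ttest_rel(x, y)
        return TTestResult(float(t), float(p), len(d) - 1)
    df = len(x) + len(y) - 2
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
        if x.mean() == y.mean():
            return TTestResult(0.0, 1.0, df)
        return TTestResult(np.nan, np.nan, df, degenerate=True)
    t, p = stats.ttest_ind(x, y, equal_var=True)
    return TTestResult(float(t), float(p), df)
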