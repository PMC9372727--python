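"""Drug-stimulus interaction model and synergy/antagonism categorisation.

The model for the log relative viability of a treated condition is the
no-intercept linear model

    logV = bd*Xd + bs*Xs + bint*Xd*Xs + eps

where Xd and Xs indicate the presence of the drug and the stimulus.  Because
logV is normalized within plate, the DMSO condition is 0 by construction and
(0,0) rows carry no information under this parameterisation; the pooled fit
uses drug-only, stimulus-only and combination observations.  bint (the
interaction factor) measures how far the combination departs from additivity
of the single-treatment effects on the log scale.

Significant interactions are classified into four categories from the signs
and relative magnitudes of the coefficients:

I   bint > 0, antagonistic: the stimulus offsets a toxic drug
    (bd < 0 and bint <= |bd|).
II  bint < 0, antagonistic: the drug offsets a pro-survival stimulus
    (bs > 0 and |bint| <= bs).
III bint > 0, synergistic pro-survival effect (everything else positive).
IV  bint < 0, synergistic toxicity (everything else negative).

Boundary ties (bint exactly cancelling the offset) classify as antagonistic.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import preprocess

logger = logging.getLogger("stimscreen")

CATEGORIES = ("I", "II", "III", "IV")


@dataclass
class InteractionFit:
    drug: str
    stimulus: str
    beta_d: float
    beta_s: float
    beta_int: float
    se_int: float
    p_int: float
    sigma: float  # residual standard deviation
    df: int
    n_obs: int
    category: str = "none"


def fit_interaction_pooled(obs: pd.DataFrame) -> InteractionFit:
    """Least-squares fit of the no-intercept interaction model for one pair.

    ``obs`` holds one row per observation with columns logV, Xd, Xs (and
    optionally drug/stimulus labels).  All three treated conditions must be
    present.  With balanced data the estimates equal condition means and
    ``beta_int = mean(combo) - mean(drug) - mean(stim)``; with unbalanced data
    the least-squares solution is authoritative.
    """
    logv = obs["logV"].to_numpy(dtype=float)
    xd = obs["Xd"].to_numpy(dtype=float)
    xs = obs["Xs"].to_numpy(dtype=float)
    if not np.all(np.isfinite(logv)):
        raise ValueError("logV contains non-finite values")
    for name, mask in (
        ("drug-only", (xd == 1) & (xs == 0)),
        ("stimulus-only", (xd == 0) & (xs == 1)),
        ("combination", (xd == 1) & (xs == 1)),
    ):
        if not mask.any():
            raise ValueError(f"no {name} observations for this pair")

    X = np.column_stack([xd, xs, xd * xs])
    beta, *_ = np.linalg.lstsq(X, logv, rcond=None)
    resid = logv - X @ beta
    n = len(logv)
    df = n - 3
    if df > 0:
        sigma2 = float(resid @ resid) / df
        xtx_inv = np.linalg.inv(X.T @ X)
        se_int = float(np.sqrt(sigma2 * xtx_inv[2, 2]))
        t = beta[2] / se_int if se_int > 0 else np.nan
        p = float(2 * stats.t.sf(abs(t), df)) if np.isfinite(t) else np.nan
        sigma = float(np.sqrt(sigma2))
    else:
        se_int, p, sigma = np.nan, np.nan, np.nan
    drug = str(obs["drug"].iloc[0]) if "drug" in obs else ""
    stim = str(obs["stimulus"].iloc[0]) if "stimulus" in obs else ""
    return InteractionFit(
        drug=drug,
        stimulus=stim,
        beta_d=float(beta[0]),
        beta_s=float(beta[1]),
        beta_int=float(beta[2]),
        se_int=se_int,
        p_int=p,
        sigma=sigma,
        df=df,
        n_obs=n,
    )


def fit_interaction_per_sample(logv_drug, logv_stim, logv_combo) -> float:
    """Saturated single-sample identity: bint = logV_combo - logV_drug - logV_stim."""
    vals = (logv_drug, logv_stim, logv_combo)
    if any(v is None or not np.isfinite(v) for v in vals):
        return np.nan
    return float(logv_combo - logv_drug - logv_stim)


def categorize_interaction(
    beta_d: float, beta_s: float, beta_int: float, p_int: float, alpha: float = 0.05
) -> str:
    """Assign one of categories I-IV, or ``"none"`` when not significant."""
    if not np.isfinite(p_int) or p_int >= alpha or beta_int == 0:
        return "none"
    if beta_int > 0:
        if beta_d < 0 and beta_int <= abs(beta_d):
            return "I"
        return "III"
    if beta_s > 0 and abs(beta_int) <= beta_s:
        return "II"
    return "IV"


# ---------------------------------------------------------------------------
# screen-level drivers


def _drug_condition_map(matrix: pd.DataFrame, concentration: str = "low"):
    """Map each drug to the drug-only column selected by the concentration policy.

    Policies: ``low`` / ``high`` pick that concentration; ``average`` averages
    the log viabilities of both concentrations into a virtual condition.
    """
    if concentration not in ("low", "high", "average"):
        raise ValueError(f"unknown concentration policy {concentration!r}")
    by_drug: dict[str, list[float]] = {}
    for col in preprocess.drug_only_columns(matrix):
        drug, conc, _ = preprocess.split_condition(col)
        by_drug.setdefault(drug, []).append(conc)
    chosen = {}
    for drug, concs in by_drug.items():
        if concentration == "average":
            chosen[drug] = sorted(concs)
        else:
            pick = min(concs) if concentration == "low" else max(concs)
            chosen[drug] = [pick]
    return chosen


def _pair_series(matrix, drug, concs, stim):
    """(drug-only, stim-only, combo) per-sample series under a concentration choice."""
    dcols = [f"{drug}@{c:g}" for c in concs]
    ccols = [f"{drug}@{c:g}+{stim}" for c in concs]
    dcols = [c for c in dcols if c in matrix.columns]
    ccols = [c for c in ccols if c in matrix.columns]
    if not dcols or not ccols or stim not in matrix.columns:
        return None
    d = matrix[dcols].mean(axis=1)
    s = matrix[stim]
    c = matrix[ccols].mean(axis=1)
    return d, s, c


def pair_observations(
    matrix: pd.DataFrame, drug: str, stimulus: str, concentration: str = "low"
) -> pd.DataFrame:
    """Long observation table (logV, Xd, Xs) for one drug-stimulus pair."""
    concs = _drug_condition_map(matrix, concentration).get(drug)
    if concs is None:
        raise KeyError(f"no drug-only condition for {drug!r}")
    triple = _pair_series(matrix, drug, concs, stimulus)
    if triple is None:
        raise KeyError(f"conditions missing for pair ({drug}, {stimulus})")
    d, s, c = triple
    ok = d.notna() & s.notna() & c.notna()
    frames = []
    for vals, xd, xs in ((d[ok], 1, 0), (s[ok], 0, 1), (c[ok], 1, 1)):
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": vals.index,
                    "logV": vals.to_numpy(),
                    "Xd": xd,
                    "Xs": xs,
                    "drug": drug,
                    "stimulus": stimulus,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def interaction_screen(
    matrix: pd.DataFrame,
    alpha: float = 0.05,
    concentration: str = "low",
    min_samples: int = 2,
) -> pd.DataFrame:
    """Fit the pooled interaction model for every drug-stimulus pair.

    Returns one row per pair with estimates, the unadjusted interaction
    p-value and the category.  Per-pair failures are reported as flagged rows
    (NaN estimates) rather than aborting the screen.
    """
    drugs = _drug_condition_map(matrix, concentration)
    stimuli = preprocess.stimulus_only_columns(matrix)
    rows = []
    for drug, stim in itertools.product(sorted(drugs), stimuli):
        try:
            obs = pair_observations(matrix, drug, stim, concentration)
            if obs[(obs.Xd == 1) & (obs.Xs == 1)].shape[0] < min_samples:
                raise ValueError("too few complete samples")
            fit = fit_interaction_pooled(obs)
            fit.category = categorize_interaction(
                fit.beta_d, fit.beta_s, fit.beta_int, fit.p_int, alpha
            )
            rows.append(vars(fit))
        except (KeyError, ValueError) as exc:
            logger.warning("pair (%s, %s) skipped: %s", drug, stim, exc)
            rows.append(
                dict(
                    drug=drug,
                    stimulus=stim,
                    beta_d=np.nan,
                    beta_s=np.nan,
                    beta_int=np.nan,
                    se_int=np.nan,
                    p_int=np.nan,
                    sigma=np.nan,
                    df=0,
                    n_obs=0,
                    category="none",
                )
            )
    out = pd.DataFrame(rows)
    counts = out["category"].value_counts()
    logger.info(
        "interaction screen: %d/%d pairs significant at alpha=%g (%s)",
        int((out["p_int"] < alpha).sum()),
        len(out),
        alpha,
        ", ".join(f"{c}={int(counts.get(c, 0))}" for c in CATEGORIES),
    )
    return out


def per_sample_beta_int(
    matrix: pd.DataFrame, concentration: str = "low"
) -> pd.DataFrame:
    """Sample-specific interaction factors for every pair (long format).

    Samples missing any of the three conditions of a pair get a missing value.
    """
    drugs = _drug_condition_map(matrix, concentration)
    stimuli = preprocess.stimulus_only_columns(matrix)
    frames = []
    for drug, stim in itertools.product(sorted(drugs), stimuli):
        triple = _pair_series(matrix, drug, drugs[drug], stim)
        if triple is None:
            continue
        d, s, c = triple
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": matrix.index,
                    "drug": drug,
                    "stimulus": stim,
                    "beta_int": (c - d - s).to_numpy(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
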