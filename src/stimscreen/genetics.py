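"""Genetic determinants of stimulus responses and of drug-stimulus interactions.

Covers the feature encoding used throughout (IGHV M=1/U=0, methylation class
LP=0/IP=0.5/HP=1, KRAS/BRAF/NRAS collapsed into one RAS/RAF predictor,
features with > 20% missingness dropped, complete-case samples), univariate
equal-variance t-tests with BH correction, bootstrap stability-selection
lasso in three flavours (gaussian response, multinomial cluster membership,
and sample-specific interaction-factor modulators), and the read-ratio
trisomy-12 caller for ATAC peak counts.

Stability selection keeps a predictor only if an L1-penalised model selects
it in a sufficiently large fraction of bootstrap refits; the reported
coefficient is the mean over the bootstraps in which it was selected, on the
standardized-predictor scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import Lasso, LassoCV, LogisticRegression, LogisticRegressionCV

from .preprocess import bh_adjust

logger = logging.getLogger("stimscreen")

RAS_RAF_GENES = ("KRAS", "BRAF", "NRAS")
METHYLATION_ENCODING = {"LP": 0.0, "IP": 0.5, "HP": 1.0}
IGHV_ENCODING = {"M": 1.0, "U": 0.0}


# ---------------------------------------------------------------------------
# feature encoding


@dataclass
class EncodedFeatureMatrix:
    values: pd.DataFrame  # complete-case samples x predictors
    provenance: dict[str, str]  # encoded predictor -> raw source description
    dropped_features: list[str]
    dropped_samples: list[str]


def encode_features(
    genetic: pd.DataFrame,
    annotation: pd.DataFrame,
    max_missing: float = 0.2,
) -> EncodedFeatureMatrix:
    """Build the regression feature matrix from the raw genetic matrix and
    the sample annotation (IGHV status and methylation class)."""
    ann = annotation.set_index("sample_id")
    X = genetic.copy().astype(float)
    provenance = {c: f"genetic:{c}" for c in X.columns}

    present = [g for g in RAS_RAF_GENES if g in X.columns]
    if present:
        sub = X[present]
        rasraf = (sub == 1).any(axis=1).astype(float)
        rasraf[(sub != 1).all(axis=1) & sub.isna().any(axis=1)] = np.nan
        X = X.drop(columns=present)
        X["RAS_RAF"] = rasraf
        provenance["RAS_RAF"] = "any of " + "/".join(present)

    if "IGHV" in ann.columns:
        X["IGHV"] = ann["IGHV"].map(IGHV_ENCODING).reindex(X.index)
        provenance["IGHV"] = "annotation:IGHV (M=1, U=0)"
    if "methylation" in ann.columns:
        X["methylation"] = ann["methylation"].map(METHYLATION_ENCODING).reindex(X.index)
        provenance["methylation"] = "annotation:methylation (LP=0, IP=0.5, HP=1)"

    frac_missing = X.isna().mean()
    dropped_features = sorted(frac_missing[frac_missing > max_missing].index)
    X = X.drop(columns=dropped_features)
    complete = X.notna().all(axis=1)
    dropped_samples = sorted(X.index[~complete])
    X = X[complete]
    if X.empty:
        raise ValueError("no complete-case samples remain after feature encoding")
    logger.info(
        "encode_features: %d predictors x %d samples (dropped %d features, %d samples)",
        X.shape[1],
        X.shape[0],
        len(dropped_features),
        len(dropped_samples),
    )
    provenance = {k: v for k, v in provenance.items() if k in X.columns}
    return EncodedFeatureMatrix(
        values=X,
        provenance=provenance,
        dropped_features=dropped_features,
        dropped_samples=dropped_samples,
    )


# ---------------------------------------------------------------------------
# univariate carrier tests


def univariate_response_tests(
    responses: pd.DataFrame,
    features: pd.DataFrame,
    min_positive: int = 3,
    fdr: float = 0.10,
) -> pd.DataFrame:
    """Equal-variance two-sided t-tests of carriers vs non-carriers for every
    (feature, stimulus) pair, BH-adjusted across all performed tests.

    Features with fewer than ``min_positive`` carriers are excluded; missing
    genotypes are dropped pairwise per test.  Pairs with zero pooled variance
    yield a missing p-value excluded from the adjustment.
    """
    rows = []
    common = responses.index.intersection(features.index)
    responses = responses.loc[common]
    features = features.loc[common]
    for feat in features.columns:
        geno = features[feat]
        for stim in responses.columns:
            resp = responses[stim]
            ok = geno.notna() & resp.notna()
            carriers = resp[ok & (geno == 1)]
            others = resp[ok & (geno != 1)]
            if len(carriers) < min_positive or len(others) < 2:
                continue
            if carriers.std(ddof=1) == 0 and others.std(ddof=1) == 0:
                t, p = np.nan, np.nan
            else:
                t, p = stats.ttest_ind(carriers, others, equal_var=True)
            rows.append(
                dict(
                    feature=feat,
                    stimulus=stim,
                    n_pos=len(carriers),
                    n_neg=len(others),
                    t=float(t),
                    p=float(p) if np.isfinite(p) else np.nan,
                )
            )
    out = pd.DataFrame(rows)
    if out.empty:
        return out.assign(p_adj=[], significant=[])
    out["p_adj"] = np.nan
    done = out["p"].notna()
    out.loc[done, "p_adj"] = bh_adjust(out.loc[done, "p"].to_numpy())
    out["significant"] = out["p_adj"] < fdr
    return out


# ---------------------------------------------------------------------------
# bootstrap stability-selection lasso


@dataclass
class StabilitySelection:
    table: pd.DataFrame  # feature, frequency, mean_coef, sd_coef, kept
    n_boot: int
    freq_threshold: float
    coef_threshold: float | None
    seed: int

    @property
    def kept(self) -> list[str]:
        return list(self.table.loc[self.table["kept"], "feature"])


def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def _summarize(
    features, coefs: np.ndarray, selected: np.ndarray, n_boot, freq_threshold,
    coef_threshold, seed, strict: bool,
) -> StabilitySelection:
    freq = selected.mean(axis=0)
    with np.errstate(invalid="ignore"):
        counts = selected.sum(axis=0)
        mean_coef = np.where(
            counts > 0, np.where(selected, coefs, 0.0).sum(axis=0) / np.maximum(counts, 1), 0.0
        )
        sd_coef = np.zeros_like(mean_coef)
        for j in range(coefs.shape[1]):
            sel = selected[:, j]
            sd_coef[j] = coefs[sel, j].std(ddof=0) if sel.sum() > 1 else 0.0
    kept = freq > freq_threshold if strict else freq >= freq_threshold
    if coef_threshold is not None:
        kept &= np.abs(mean_coef) >= coef_threshold
    table = pd.DataFrame(
        {
            "feature": list(features),
            "frequency": freq,
            "mean_coef": mean_coef,
            "sd_coef": sd_coef,
            "kept": kept,
        }
    )
    return StabilitySelection(
        table=table,
        n_boot=n_boot,
        freq_threshold=freq_threshold,
        coef_threshold=coef_threshold,
        seed=seed,
    )


def _cv_lasso(Xb: np.ndarray, yb: np.ndarray, cv: int, penalty_rule: str):
    """L1 fit with the penalty chosen by cv-fold cross-validation.

    ``penalty_rule="1se"`` takes the sparsest model within one standard error
    of the minimum CV error (the glmnet ``lambda.1se`` convention);
    ``"min"`` takes the minimiser itself.
    """
    model = LassoCV(cv=cv, alphas=60, max_iter=5000).fit(Xb, yb)
    if penalty_rule == "min":
        return model
    if penalty_rule != "1se":
        raise ValueError(f"unknown penalty_rule {penalty_rule!r}")
    mse = model.mse_path_  # (n_alphas, n_folds), alphas descending
    mean = mse.mean(axis=1)
    se = mse.std(axis=1, ddof=1) / np.sqrt(mse.shape[1])
    i = int(np.argmin(mean))
    j = int(np.nonzero(mean <= mean[i] + se[i])[0][0])  # largest alpha within 1 SE
    return Lasso(alpha=model.alphas_[j], max_iter=5000).fit(Xb, yb)


def lasso_stability_gaussian(
    X: pd.DataFrame,
    y: pd.Series,
    n_boot: int = 30,
    freq_threshold: float = 0.75,
    seed: int = 0,
    cv: int = 10,
    penalty_rule: str = "1se",
) -> StabilitySelection:
    """Gaussian stability-selection lasso.

    Per bootstrap (samples resampled with replacement): standardize the
    predictors, fit an L1-penalised least-squares model with the penalty
    chosen by ``cv``-fold cross-validation under ``penalty_rule``, and record
    the nonzero predictors.  The one-standard-error rule is the default
    because choosing the exact CV minimiser inside a bootstrap (where
    duplicated samples leak between folds) systematically under-penalises and
    lets noise predictors through.  Predictors selected in strictly more than
    ``freq_threshold`` of the bootstraps are kept.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    common = X.index.intersection(y.dropna().index)
    Xv = X.loc[common].to_numpy(dtype=float)
    yv = y.loc[common].to_numpy(dtype=float)
    n, p = Xv.shape
    coefs = np.zeros((n_boot, p))
    selected = np.zeros((n_boot, p), dtype=bool)
    if np.std(yv) == 0:
        logger.warning("lasso_stability_gaussian: constant response, empty selection")
        return _summarize(
            X.columns, coefs, selected, n_boot, freq_threshold, None, seed, strict=True
        )
    rng = np.random.default_rng(seed)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        Xb = _standardize(Xv[idx])
        yb = yv[idx]
        model = _cv_lasso(Xb, yb, cv, penalty_rule)
        coefs[b] = model.coef_
        selected[b] = model.coef_ != 0
    return _summarize(
        X.columns, coefs, selected, n_boot, freq_threshold, None, seed, strict=True
    )


def lasso_stability_multinomial(
    X: pd.DataFrame,
    labels: pd.Series,
    n_boot: int = 50,
    freq_threshold: float = 0.60,
    coef_threshold: float = 0.35,
    seed: int = 0,
    cv: int = 10,
    max_redraws: int = 100,
) -> dict[str, StabilitySelection]:
    """Multinomial stability-selection lasso for cluster membership.

    The L1 penalty is chosen once by ``cv``-fold cross-validation on the full
    data (strongest penalty within one standard error of the best mean
    log-loss) and held fixed across bootstraps.  A bootstrap resample missing any
    cluster is redrawn (up to ``max_redraws`` attempts).  Per cluster, a
    predictor is kept iff its selection frequency is >= ``freq_threshold``
    and the absolute mean coefficient is >= ``coef_threshold``.
    """
    common = X.index.intersection(labels.dropna().index)
    Xv = X.loc[common].to_numpy(dtype=float)
    yv = labels.loc[common].to_numpy()
    classes, counts = np.unique(yv, return_counts=True)
    if len(classes) < 2 or counts.min() < 5:
        raise ValueError("need >= 2 clusters each with >= 5 samples")
    n, p = Xv.shape

    Cs = np.logspace(-2, 2, 10)
    cvfit = LogisticRegressionCV(
        Cs=Cs,
        cv=cv,
        l1_ratios=(1.0,),
        solver="saga",
        scoring="neg_log_loss",
        max_iter=5000,
        tol=1e-3,
        random_state=0,
    ).fit(_standardize(Xv), yv)
    scores = next(iter(cvfit.scores_.values()))  # (folds, Cs[, l1_ratios])
    if scores.ndim == 3:
        scores = scores[..., 0]
    mean = scores.mean(axis=0)
    se = scores.std(axis=0, ddof=1) / np.sqrt(scores.shape[0])
    best = int(np.argmax(mean))
    # strongest penalty (smallest C) within one SE of the best mean score
    C = float(Cs[np.nonzero(mean >= mean[best] - se[best])[0][0]])

    rng = np.random.default_rng(seed)
    coefs = {c: np.zeros((n_boot, p)) for c in classes}
    selected = {c: np.zeros((n_boot, p), dtype=bool) for c in classes}
    for b in range(n_boot):
        for attempt in range(max_redraws):
            idx = rng.integers(0, n, size=n)
            if len(np.unique(yv[idx])) == len(classes):
                break
        else:
            raise RuntimeError(
                f"bootstrap {b}: a cluster was absent from {max_redraws} resamples"
            )
        model = LogisticRegression(
            l1_ratio=1.0, C=C, solver="saga", max_iter=5000, tol=1e-3, random_state=0
        ).fit(_standardize(Xv[idx]), yv[idx])
        coef = model.coef_
        if coef.shape[0] == 1:  # binary: expand to one row per class
            coef = np.vstack([-coef[0], coef[0]])
        for ci, c in enumerate(model.classes_):
            coefs[c][b] = coef[ci]
            selected[c][b] = np.abs(coef[ci]) > 1e-10
    return {
        c: _summarize(
            X.columns,
            coefs[c],
            selected[c],
            n_boot,
            freq_threshold,
            coef_threshold,
            seed,
            strict=False,
        )
        for c in classes
    }


def interaction_modulators(
    beta_int: pd.DataFrame,
    X: pd.DataFrame,
    n_boot: int = 30,
    freq_threshold: float = 0.90,
    seed: int = 0,
    min_samples: int = 10,
    cv: int = 10,
) -> dict[tuple[str, str], StabilitySelection]:
    """Genetic modulators of sample-specific interaction factors.

    ``beta_int`` is the long per-sample table (sample_id, drug, stimulus,
    beta_int).  For every pair with >= ``min_samples`` complete cases a
    gaussian stability selection is run with the pair's sample-specific
    interaction factors as the response; a pair "has genetic modulators" iff
    its kept set is non-empty.
    """
    results: dict[tuple[str, str], StabilitySelection] = {}
    rng = np.random.default_rng(seed)
    grouped = beta_int.groupby(["drug", "stimulus"], sort=True)
    for (drug, stim), grp in grouped:
        y = grp.set_index("sample_id")["beta_int"].dropna()
        common = X.index.intersection(y.index)
        if len(common) < min_samples:
            logger.warning(
                "pair (%s, %s): only %d complete-case samples, skipped",
                drug,
                stim,
                len(common),
            )
            continue
        pair_seed = int(rng.integers(0, 2**31 - 1))
        results[(drug, stim)] = lasso_stability_gaussian(
            X.loc[common],
            y.loc[common],
            n_boot=n_boot,
            freq_threshold=freq_threshold,
            seed=pair_seed,
            cv=cv,
        )
    return results


# ---------------------------------------------------------------------------
# trisomy-12 calling from ATAC peak counts


def call_trisomy12_from_atac(
    peaks: pd.DataFrame, chrom: str = "chr12", threshold: float = 1.4
) -> tuple[bool, float]:
    """Call trisomy 12 when the mean reads per peak on chromosome 12 exceed
    ``threshold`` times the mean over peaks on all other chromosomes
    (strict inequality).  Returns (call, ratio)."""
    on = peaks.loc[peaks["chrom"] == chrom, "count"]
    off = peaks.loc[peaks["chrom"] != chrom, "count"]
    if on.empty:
        raise ValueError(f"no peaks on {chrom}")
    if off.empty:
        raise ValueError("no peaks outside the target chromosome")
    ratio = float(on.mean() / off.mean())
    return ratio > threshold, ratio
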