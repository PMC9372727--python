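"""From raw luminescence to log relative viability, robust z-scores and
correlation structure.

Log relative viability of a treated well is the natural log of its
luminescence divided by the median luminescence of the DMSO control wells on
the same plate, excluding controls on the outer plate edge (rows 1/16,
columns 1/24 of the 384-well grid).  Values near 0 mean no effect; negative
values indicate toxicity and positive values a pro-survival effect.  Because
the plate median is taken within plate, any multiplicative per-plate factor
cancels exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import DMSO, NO_STIMULUS

logger = logging.getLogger("stimscreen")


def is_edge(row, col, n_rows: int = 16, n_cols: int = 24):
    """True for wells on the outer ring of the plate grid."""
    row = np.asarray(row)
    col = np.asarray(col)
    return (row == 1) | (row == n_rows) | (col == 1) | (col == n_cols)


def condition_label(drug, conc, stimulus) -> str:
    """Condition naming: ``drug@conc``, ``stimulus``, or ``drug@conc+stimulus``."""
    if drug == DMSO and stimulus != NO_STIMULUS:
        return str(stimulus)
    if stimulus == NO_STIMULUS:
        return f"{drug}@{conc:g}"
    return f"{drug}@{conc:g}+{stimulus}"


def split_condition(label: str):
    """Inverse of :func:`condition_label` -> (drug, conc, stimulus); absent parts are None."""
    if "+" in label:
        left, stim = label.split("+", 1)
        drug, conc = left.split("@")
        return drug, float(conc), stim
    if "@" in label:
        drug, conc = label.split("@")
        return drug, float(conc), None
    return None, None, label


def log_relative_viability(wells: pd.DataFrame) -> pd.DataFrame:
    """Normalize every treated well against its plate's interior DMSO median.

    Returns a long table (sample_id, plate_id, condition, drug, drug_conc_nM,
    stimulus, logv) with one row per treated well.  Raises if any plate lacks
    interior DMSO controls or contains non-positive readouts.
    """
    if (wells["luminescence"] <= 0).any():
        raise ValueError("luminescence readouts must be positive")
    edge = is_edge(wells["well_row"], wells["well_col"])
    is_dmso = (wells["drug"] == DMSO) & (wells["stimulus"] == NO_STIMULUS)
    interior_dmso = wells[is_dmso & ~edge]
    medians = interior_dmso.groupby("plate_id")["luminescence"].median()
    missing = set(wells["plate_id"].unique()) - set(medians.index)
    if missing:
        raise ValueError(
            f"plate(s) without interior DMSO controls, cannot normalize: {sorted(missing)}"
        )
    treated = wells[~is_dmso].copy()
    treated["logv"] = np.log(
        treated["luminescence"].to_numpy()
        / treated["plate_id"].map(medians).to_numpy()
    )
    treated["condition"] = [
        condition_label(d, c, s)
        for d, c, s in zip(
            treated["drug"], treated["drug_conc_nM"], treated["stimulus"]
        )
    ]
    return treated[
        ["sample_id", "plate_id", "condition", "drug", "drug_conc_nM", "stimulus", "logv"]
    ].reset_index(drop=True)


def normalize_plate(wells: pd.DataFrame) -> pd.DataFrame:
    """Single-plate wrapper of :func:`log_relative_viability`."""
    if wells["plate_id"].nunique() != 1:
        raise ValueError("normalize_plate expects wells from exactly one plate")
    return log_relative_viability(wells)


def response_matrix(long: pd.DataFrame) -> pd.DataFrame:
    """Pivot normalized wells to samples x conditions, averaging replicate wells
    of the same condition after the log transform."""
    return long.pivot_table(
        index="sample_id", columns="condition", values="logv", aggfunc="mean"
    ).rename_axis(columns=None)


def stimulus_only_columns(matrix: pd.DataFrame) -> list[str]:
    return [c for c in matrix.columns if "@" not in c]


def drug_only_columns(matrix: pd.DataFrame) -> list[str]:
    return [c for c in matrix.columns if "@" in c and "+" not in c]


def combination_columns(matrix: pd.DataFrame) -> list[str]:
    return [c for c in matrix.columns if "+" in c]


@dataclass
class RobustZ:
    values: pd.DataFrame  # uncapped z-scores
    display: pd.DataFrame  # copy clipped to +/- cap for visualisation
    cap: float
    mad_floor: float


def robust_z(matrix: pd.DataFrame, cap: float = 4.0, mad_floor: float = 1e-8) -> RobustZ:
    """Row-wise robust z: (x - row median) / max(row MAD, mad_floor).

    The MAD carries no consistency constant.  The stored values are uncapped;
    ``display`` is clipped to +/- cap.  A constant row yields all zeros via the
    MAD floor.
    """
    if matrix.shape[1] < 2:
        raise ValueError("robust_z needs >= 2 conditions per row")
    if matrix.isna().all(axis=1).any():
        raise ValueError("robust_z: empty row(s) in input")
    med = matrix.median(axis=1, skipna=True)
    centered = matrix.sub(med, axis=0)
    mad = centered.abs().median(axis=1, skipna=True)
    scale = mad.clip(lower=mad_floor)
    z = centered.div(scale, axis=0)
    return RobustZ(values=z, display=z.clip(-cap, cap), cap=cap, mad_floor=mad_floor)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("bh_adjust expects a 1-D array")
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if len(p) == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class CorrelationResult:
    r: pd.DataFrame
    p: pd.DataFrame
    p_adj: pd.DataFrame
    significant: pd.DataFrame  # adjusted p < fdr (diagonal False)
    fdr: float


def pairwise_correlations(
    matrix: pd.DataFrame, fdr: float = 0.05, min_pairs: int = 3
) -> CorrelationResult:
    """Pearson correlations across samples between single-treatment columns.

    Two-sided p-values are BH-adjusted across the performed tests of this
    block (call once per drug block and once per stimulus block).  Constant
    columns or pairs with < ``min_pairs`` complete observations yield missing
    correlations excluded from the adjustment.
    """
    cols = list(matrix.columns)
    k = len(cols)
    r = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    p = pd.DataFrame(np.nan, index=cols, columns=cols)
    pairs = []
    for i in range(k):
        for j in range(i + 1, k):
            x = matrix[cols[i]]
            y = matrix[cols[j]]
            ok = x.notna() & y.notna()
            if ok.sum() < min_pairs:
                r.iloc[i, j] = r.iloc[j, i] = np.nan
                continue
            xs, ys = x[ok], y[ok]
            if xs.std() == 0 or ys.std() == 0:
                logger.warning(
                    "correlation undefined for constant column pair (%s, %s)",
                    cols[i],
                    cols[j],
                )
                r.iloc[i, j] = r.iloc[j, i] = np.nan
                continue
            rij, pij = stats.pearsonr(xs, ys)
            r.iloc[i, j] = r.iloc[j, i] = rij
            p.iloc[i, j] = p.iloc[j, i] = pij
            pairs.append((i, j, pij))
    p_adj = pd.DataFrame(np.nan, index=cols, columns=cols)
    if pairs:
        adj = bh_adjust([pij for _, _, pij in pairs])
        for (i, j, _), a in zip(pairs, adj):
            p_adj.iloc[i, j] = p_adj.iloc[j, i] = a
    significant = p_adj < fdr
    return CorrelationResult(r=r, p=p, p_adj=p_adj, significant=significant, fdr=fdr)
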