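"""Synthetic combinatorial drug-stimulus viability screens with known ground truth.

The generator emulates the statistical structure of an ex vivo 384-well
luminescence screen on primary CLL samples: each sample is cultured on two
384-well plates carrying 12 drugs (two concentrations), 17 soluble
microenvironmental stimuli, all 204 drug-stimulus combinations and DMSO
control wells (including controls on the outer plate edge, which downstream
normalization must exclude).

The generative model for a well is

    luminescence = base * exp(plate_effect + bd*Xd + bs*Xs + bint*Xd*Xs + eps)

with eps ~ Normal(0, noise_sd^2) on the log scale, a per-plate Normal
intercept shared by all wells of the plate (it cancels under within-plate
DMSO normalization), planted drug/stimulus/interaction effects that may be
restricted to genetic subgroups, four latent response clusters shifting
stimulus effects, and cluster-linked exponential event-time hazards.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import DMSO, NO_STIMULUS

# Drug panel with (low, high) concentrations in nM and the stimulus panel of
# the screen this package models.
DEFAULT_DRUGS: dict[str, tuple[float, ...]] = {
    "ibrutinib": (50.0, 500.0),
    "idelalisib": (50.0, 500.0),
    "PRT062607": (50.0, 500.0),
    "selumetinib": (100.0, 1000.0),
    "everolimus": (50.0, 500.0),
    "fludarabine": (200.0, 2000.0),
    "nutlin-3a": (1000.0, 10000.0),
    "BAY-11-7085": (200.0, 2000.0),
    "pyridone-6": (50.0, 500.0),
    "ralimetinib": (150.0, 1500.0),
    "luminespib": (20.0, 200.0),
    "I-BET-762": (100.0, 1000.0),
}

DEFAULT_STIMULI: tuple[str, ...] = (
    "IL4",
    "IL10",
    "IL2",
    "IL6",
    "IL15",
    "IL21",
    "IL1beta",
    "resiquimod",
    "CpG-ODN",
    "sCD40L",
    "sCD40L_IL4",
    "anti-IgM",
    "TGFbeta1",
    "BAFF",
    "SDF1alpha",
    "IFNgamma",
    "HS5-CM",
)

CLUSTERS = ("C1", "C2", "C3", "C4")


class DesignError(ValueError):
    """Raised for screen designs that cannot be laid out or normalized."""


@dataclass(frozen=True)
class ScreenDesign:
    """Layout of one screen: panels, cohort size and the 384-well grid.

    Each sample occupies exactly two culture plates; plate 0 carries the lower
    drug concentration and plate 1 the higher (drugs with a single
    concentration repeat it).  Stimulus-only and DMSO wells are present on
    both plates, so they enter the response matrix as replicates.
    """

    drugs: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_DRUGS)
    )
    stimuli: Sequence[str] = DEFAULT_STIMULI
    n_samples: int = 192
    n_interior_dmso: int = 16
    n_edge_dmso: int = 4
    plate_rows: int = 16
    plate_cols: int = 24

    def __post_init__(self):
        for drug, concs in self.drugs.items():
            if not 1 <= len(concs) <= 2:
                raise DesignError(f"{drug}: drugs take 1-2 concentrations")
        if self.n_interior_dmso < 8:
            raise DesignError("every plate needs >= 8 interior DMSO control wells")
        if self.n_edge_dmso < 1:
            raise DesignError("every plate needs >= 1 edge DMSO control well")
        interior = (self.plate_rows - 2) * (self.plate_cols - 2)
        per_plate = (
            len(self.drugs)
            + len(self.stimuli)
            + len(self.drugs) * len(self.stimuli)
            + self.n_interior_dmso
        )
        if per_plate > interior:
            raise DesignError(
                f"layout needs {per_plate} interior wells but the plate has {interior}"
            )

    @property
    def n_combinations(self) -> int:
        return len(self.drugs) * len(self.stimuli)

    def concentration(self, drug: str, plate_index: int) -> float:
        concs = self.drugs[drug]
        return concs[min(plate_index, len(concs) - 1)]


def plate_template(design: ScreenDesign, plate_index: int) -> pd.DataFrame:
    """Well assignment for one plate: columns well_row, well_col, drug, drug_conc_nM, stimulus."""
    interior = [
        (r, c)
        for r in range(2, design.plate_rows)
        for c in range(2, design.plate_cols)
    ]
    edge = [
        (r, c)
        for r in range(1, design.plate_rows + 1)
        for c in range(1, design.plate_cols + 1)
        if r in (1, design.plate_rows) or c in (1, design.plate_cols)
    ]
    rows: list[tuple] = []
    # interior DMSO controls spread over the interior grid
    step = max(1, len(interior) // design.n_interior_dmso)
    dmso_wells = interior[::step][: design.n_interior_dmso]
    remaining = [w for w in interior if w not in set(dmso_wells)]
    for r, c in dmso_wells:
        rows.append((r, c, DMSO, np.nan, NO_STIMULUS))
    it = iter(remaining)
    for drug in design.drugs:
        r, c = next(it)
        rows.append((r, c, drug, design.concentration(drug, plate_index), NO_STIMULUS))
    for stim in design.stimuli:
        r, c = next(it)
        rows.append((r, c, DMSO, np.nan, stim))
    for drug in design.drugs:
        for stim in design.stimuli:
            r, c = next(it)
            rows.append((r, c, drug, design.concentration(drug, plate_index), stim))
    # edge DMSO controls on the outer ring, spread along it
    estep = max(1, len(edge) // design.n_edge_dmso)
    for r, c in edge[::estep][: design.n_edge_dmso]:
        rows.append((r, c, DMSO, np.nan, NO_STIMULUS))
    return pd.DataFrame(
        rows, columns=["well_row", "well_col", "drug", "drug_conc_nM", "stimulus"]
    )


# ---------------------------------------------------------------------------
# ground truth


@dataclass
class GroundTruth:
    """Planted generative parameters for one synthetic screen.

    ``beta_int`` maps (drug, stimulus, subgroup) to an interaction effect
    where subgroup is ``"all"`` (every sample), a genetic feature name (true
    carriers only), or ``"IGHV-M"`` / ``"IGHV-U"``.  ``cluster_stimulus_shift``
    adds a per-cluster offset to a stimulus effect wherever that stimulus is
    present, which is what makes the latent clusters recoverable from the
    stimulus-response profiles.
    """

    beta_d: dict[str, float] = field(default_factory=dict)
    beta_s: dict[str, float] = field(default_factory=dict)
    beta_int: dict[tuple[str, str, str], float] = field(default_factory=dict)
    cluster_proportions: dict[str, float] = field(
        default_factory=lambda: {"C1": 0.30, "C2": 0.15, "C3": 0.25, "C4": 0.30}
    )
    cluster_stimulus_shift: dict[tuple[str, str], float] = field(default_factory=dict)
    #: (stimulus, subgroup) -> extra stimulus effect for carriers, e.g. the
    #: amplified IL4/TLR responses of trisomy-12 samples
    subgroup_stimulus_shift: dict[tuple[str, str], float] = field(default_factory=dict)
    #: feature -> prevalence, either a single probability or per-cluster map
    feature_prevalence: dict[str, float | dict[str, float]] = field(default_factory=dict)
    ighv_m_prob_by_cluster: dict[str, float] = field(
        default_factory=lambda: {"C1": 0.2, "C2": 0.3, "C3": 0.8, "C4": 0.85}
    )
    hazard_scale: dict[str, float] = field(
        default_factory=lambda: {"C1": 2.0, "C2": 2.5, "C3": 2.2, "C4": 1.0}
    )
    baseline_hazard_per_day: float = 1.0 / 900.0
    censoring_rate_per_day: float = 1.0 / 1500.0
    noise_sd: float = 0.1
    plate_effect_sd: float = 0.1
    base_luminescence: float = 1e5
    missing_rate: float = 0.05

    def interaction_effect(self, drug: str, stimulus: str, subgroup: str = "all") -> float:
        return self.beta_int.get((drug, stimulus, subgroup), 0.0)

    def with_(self, **kwargs) -> "GroundTruth":
        return replace(self, **kwargs)


def default_truth(design: ScreenDesign | None = None) -> GroundTruth:
    """Study-scale ground truth: drug toxicities, mostly pro-survival stimuli,
    four response clusters, genetic subgroup structure and planted interactions
    covering all four interaction categories."""
    design = design or ScreenDesign()
    beta_d = {
        "ibrutinib": -0.60,
        "idelalisib": -0.55,
        "PRT062607": -0.45,
        "selumetinib": -0.35,
        "everolimus": -0.25,
        "fludarabine": -0.70,
        "nutlin-3a": -0.50,
        "BAY-11-7085": -0.65,
        "pyridone-6": -0.10,
        "ralimetinib": -0.10,
        "luminespib": -0.75,
        "I-BET-762": -0.30,
    }
    beta_s = {
        "IL4": 0.45,
        "IL10": 0.10,
        "IL2": 0.08,
        "IL6": -0.08,
        "IL15": 0.10,
        "IL21": 0.12,
        "IL1beta": 0.20,
        "resiquimod": 0.40,
        "CpG-ODN": 0.35,
        "sCD40L": 0.15,
        "sCD40L_IL4": 0.50,
        "anti-IgM": 0.20,
        "TGFbeta1": -0.12,
        "BAFF": 0.15,
        "SDF1alpha": 0.05,
        "IFNgamma": 0.10,
        "HS5-CM": 0.20,
    }
    beta_d = {d: beta_d.get(d, -0.3) for d in design.drugs}
    beta_s = {s: beta_s.get(s, 0.1) for s in design.stimuli}
    # 45 planted interactions spanning the four categories:
    # 22 positive antagonistic (stimulus rescues a toxic drug, mostly IL4 and
    # IFNg over BCR inhibitors and chemotherapeutics), 6 negative antagonistic
    # (drug blocks a pro-survival stimulus), 1 positive synergistic, 16
    # negative synergistic (TLR agonists sensitising to BCR inhibition,
    # HSP90-inhibitor synergies).
    category_i = {
        ("ibrutinib", "IL4"): 0.50,
        ("idelalisib", "IL4"): 0.45,
        ("PRT062607", "IL4"): 0.40,
        ("selumetinib", "IL4"): 0.30,
        ("fludarabine", "IL4"): 0.45,
        ("nutlin-3a", "IL4"): 0.40,
        ("everolimus", "IL4"): 0.20,
        ("I-BET-762", "IL4"): 0.25,
        ("ibrutinib", "IFNgamma"): 0.35,
        ("idelalisib", "IFNgamma"): 0.35,
        ("PRT062607", "IFNgamma"): 0.30,
        ("selumetinib", "IFNgamma"): 0.25,
        ("fludarabine", "IFNgamma"): 0.40,
        ("nutlin-3a", "IFNgamma"): 0.35,
        ("BAY-11-7085", "IFNgamma"): 0.40,
        ("luminespib", "IFNgamma"): 0.45,
        ("fludarabine", "IL10"): 0.35,
        ("nutlin-3a", "IL10"): 0.30,
        ("fludarabine", "sCD40L_IL4"): 0.45,
        ("nutlin-3a", "sCD40L_IL4"): 0.35,
        ("ibrutinib", "sCD40L_IL4"): 0.40,
        ("idelalisib", "sCD40L_IL4"): 0.40,
    }
    category_ii = {
        ("pyridone-6", "sCD40L_IL4"): -0.30,
        ("pyridone-6", "IL4"): -0.30,
        ("pyridone-6", "BAFF"): -0.10,
        ("ralimetinib", "sCD40L_IL4"): -0.35,
        ("BAY-11-7085", "IL1beta"): -0.15,
        ("ibrutinib", "anti-IgM"): -0.15,
    }
    category_iii = {("ralimetinib", "IFNgamma"): 0.40}
    category_iv = {
        ("ibrutinib", "CpG-ODN"): -0.55,
        ("ibrutinib", "resiquimod"): -0.70,
        ("idelalisib", "CpG-ODN"): -0.55,
        ("idelalisib", "resiquimod"): -0.70,
        ("PRT062607", "CpG-ODN"): -0.55,
        ("PRT062607", "resiquimod"): -0.60,
        ("luminespib", "anti-IgM"): -0.40,
        ("luminespib", "IL6"): -0.30,
        ("luminespib", "TGFbeta1"): -0.30,
        ("luminespib", "SDF1alpha"): -0.25,
        ("luminespib", "IL15"): -0.35,
        ("luminespib", "IL21"): -0.40,
        ("fludarabine", "TGFbeta1"): -0.35,
        ("nutlin-3a", "TGFbeta1"): -0.30,
        ("BAY-11-7085", "IL6"): -0.25,
        ("everolimus", "IL6"): -0.25,
    }
    beta_int: dict[tuple[str, str, str], float] = {
        (d, s, "all"): v
        for block in (category_i, category_ii, category_iii, category_iv)
        for (d, s), v in block.items()
    }
    # genetic modulators of interactions (12 pairs): trisomy 12 and IGHV
    # status modulate the most, del(11q) contributes to the fludarabine-TLR
    # interaction.
    beta_int.update(
        {
            ("fludarabine", "CpG-ODN", "trisomy12"): 0.45,
            ("fludarabine", "CpG-ODN", "IGHV-U"): 0.30,
            ("fludarabine", "CpG-ODN", "del11q"): 0.25,
            ("ibrutinib", "resiquimod", "trisomy12"): 0.40,
            ("idelalisib", "resiquimod", "trisomy12"): 0.35,
            ("nutlin-3a", "IL4", "IGHV-M"): 0.30,
            ("ibrutinib", "IL4", "trisomy12"): 0.25,
            ("selumetinib", "IFNgamma", "trisomy12"): 0.30,
            ("luminespib", "anti-IgM", "IGHV-U"): -0.25,
            ("everolimus", "TGFbeta1", "trisomy12"): -0.30,
            ("PRT062607", "IL10", "IGHV-M"): 0.30,
            ("BAY-11-7085", "BAFF", "IGHV-U"): -0.20,
        }
    )
    shifts = {}
    for stim in ("IL4", "resiquimod", "CpG-ODN"):
        shifts[("C1", stim)] = 0.35
        shifts[("C2", stim)] = 0.45
        shifts[("C3", stim)] = -0.05
    for stim in ("resiquimod", "CpG-ODN"):
        shifts[("C4", stim)] = -0.35
    for stim in ("IL1beta", "anti-IgM", "sCD40L", "BAFF"):
        shifts[("C2", stim)] = 0.40
        shifts[("C3", stim)] = -0.10
    # recurrent CLL aberrations; trisomy 12 and SF3B1 are enriched in the
    # strong-responder cluster C2, POT1 in the aggressive IGHV-M cluster C3,
    # and TP53/ATM/gain(8q) are depleted in the indolent cluster C4
    feature_prevalence = {
        "trisomy12": {"C1": 0.12, "C2": 0.45, "C3": 0.12, "C4": 0.12},
        "TP53": {"C1": 0.12, "C2": 0.12, "C3": 0.12, "C4": 0.03},
        "del17p": 0.08,
        "del11q": 0.15,
        "del13q": 0.45,
        "ATM": {"C1": 0.12, "C2": 0.12, "C3": 0.12, "C4": 0.04},
        "SF3B1": {"C1": 0.08, "C2": 0.30, "C3": 0.10, "C4": 0.08},
        "POT1": {"C1": 0.05, "C2": 0.05, "C3": 0.20, "C4": 0.03},
        "NOTCH1": 0.10,
        "gain8q": {"C1": 0.06, "C2": 0.08, "C3": 0.06, "C4": 0.01},
        "KRAS": 0.04,
        "BRAF": 0.03,
        "NRAS": 0.03,
    }
    # trisomy-12 samples respond more strongly to IL4, TLR agonists and
    # sCD40L+IL4 and more negatively to TGFb (stimulus-only and combinations)
    subgroup_shifts = {
        ("IL4", "trisomy12"): 0.15,
        ("resiquimod", "trisomy12"): 0.20,
        ("CpG-ODN", "trisomy12"): 0.15,
        ("sCD40L_IL4", "trisomy12"): 0.15,
        ("TGFbeta1", "trisomy12"): -0.10,
    }
    return GroundTruth(
        beta_d=beta_d,
        beta_s=beta_s,
        beta_int=beta_int,
        cluster_stimulus_shift=shifts,
        subgroup_stimulus_shift=subgroup_shifts,
        feature_prevalence=feature_prevalence,
    )


def null_truth(design: ScreenDesign | None = None, noise_sd: float = 0.1) -> GroundTruth:
    """Truth with single-treatment effects but every interaction zero."""
    truth = default_truth(design)
    return truth.with_(
        beta_int={},
        cluster_stimulus_shift={},
        subgroup_stimulus_shift={},
        noise_sd=noise_sd,
    )


# ---------------------------------------------------------------------------
# cohort


@dataclass
class Cohort:
    annotation: pd.DataFrame  # sample_id, cluster, IGHV, methylation, sex, pretreated
    genetic: pd.DataFrame  # masked 0/1/NaN, indexed by sample_id
    genetic_true: pd.DataFrame  # unmasked 0/1, indexed by sample_id

    @property
    def sample_ids(self) -> list[str]:
        return list(self.annotation["sample_id"])


_METHYLATION_PROBS = {
    "M": (("LP", 0.10), ("IP", 0.25), ("HP", 0.65)),
    "U": (("LP", 0.65), ("IP", 0.25), ("HP", 0.10)),
}


def _stratified_clusters(n: int, proportions: Mapping[str, float], rng) -> np.ndarray:
    """Largest-remainder allocation so every cluster is non-empty even at tiny n."""
    names = sorted(proportions)
    props = np.array([proportions[c] for c in names], dtype=float)
    props = props / props.sum()
    counts = np.maximum(1, np.floor(props * n).astype(int))
    while counts.sum() > n:
        counts[np.argmax(counts)] -= 1
    rema = props * n - counts
    while counts.sum() < n:
        i = int(np.argmax(rema))
        counts[i] += 1
        rema[i] = -1
    labels = np.repeat(names, counts)
    return labels[rng.permutation(n)]


def generate_cohort(design: ScreenDesign, truth: GroundTruth, seed: int) -> Cohort:
    """Sample the cohort: cluster labels (stratified by the planted proportions),
    IGHV status, methylation class and the binary genetic matrix with
    missing-completely-at-random masking.  Deterministic given the seed."""
    n = design.n_samples
    clusters = sorted(truth.cluster_proportions)
    if n < len(clusters):
        raise ValueError(
            f"n_samples={n} is smaller than the number of clusters ({len(clusters)})"
        )
    rng = np.random.default_rng(seed)
    sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    labels = _stratified_clusters(n, truth.cluster_proportions, rng)

    m_prob = np.array([truth.ighv_m_prob_by_cluster.get(c, 0.5) for c in labels])
    ighv = np.where(rng.random(n) < m_prob, "M", "U")
    meth = np.empty(n, dtype=object)
    for status, probs in _METHYLATION_PROBS.items():
        idx = np.nonzero(ighv == status)[0]
        cats = [c for c, _ in probs]
        p = [w for _, w in probs]
        meth[idx] = rng.choice(cats, size=len(idx), p=p)
    sex = rng.choice(["m", "f"], size=n, p=[0.6, 0.4])
    pretreated = (rng.random(n) < 0.4).astype(int)

    features = sorted(truth.feature_prevalence)
    true_mat = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"))
    for feat in features:
        prev = truth.feature_prevalence[feat]
        if isinstance(prev, Mapping):
            p = np.array([prev.get(c, 0.0) for c in labels])
        else:
            p = np.full(n, float(prev))
        true_mat[feat] = (rng.random(n) < p).astype(float)
    masked = true_mat.copy()
    if truth.missing_rate > 0 and features:
        mask = rng.random(masked.shape) < truth.missing_rate
        masked = masked.mask(mask)

    annotation = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "cluster": labels,
            "IGHV": ighv,
            "methylation": meth,
            "sex": sex,
            "pretreated": pretreated,
        }
    )
    return Cohort(annotation=annotation, genetic=masked, genetic_true=true_mat)


# ---------------------------------------------------------------------------
# plates


def _subgroup_mask(subgroup: str, cohort: Cohort) -> pd.Series:
    ann = cohort.annotation.set_index("sample_id")
    if subgroup == "all":
        return pd.Series(True, index=ann.index)
    if subgroup in ("IGHV-M", "IGHV-U"):
        return ann["IGHV"] == subgroup[-1]
    if subgroup in cohort.genetic_true.columns:
        return cohort.genetic_true[subgroup] == 1
    raise KeyError(f"unknown interaction subgroup {subgroup!r}")


def generate_plates(
    design: ScreenDesign, cohort: Cohort, truth: GroundTruth, seed: int
) -> pd.DataFrame:
    """Simulate the raw well table for the whole cohort (two plates per sample)."""
    if truth.noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    templates = [plate_template(design, p) for p in range(2)]
    frames = []
    for p, tmpl in enumerate(templates):
        block = pd.concat([tmpl] * design.n_samples, ignore_index=True)
        block.insert(0, "sample_id", np.repeat(cohort.sample_ids, len(tmpl)))
        block.insert(1, "plate_id", block["sample_id"] + f"_P{p}")
        frames.append(block)
    wells = pd.concat(frames, ignore_index=True)

    mu = np.zeros(len(wells))
    mu += wells["drug"].map(truth.beta_d).fillna(0.0).to_numpy()  # DMSO -> 0
    mu += wells["stimulus"].map(truth.beta_s).fillna(0.0).to_numpy()  # none -> 0
    ann = cohort.annotation.set_index("sample_id")
    well_cluster = wells["sample_id"].map(ann["cluster"])
    for (cluster, stim), shift in truth.cluster_stimulus_shift.items():
        mask = (well_cluster == cluster) & (wells["stimulus"] == stim)
        mu[mask.to_numpy()] += shift
    for (stim, subgroup), shift in truth.subgroup_stimulus_shift.items():
        in_group = _subgroup_mask(subgroup, cohort)
        mask = (wells["stimulus"] == stim) & wells["sample_id"].map(in_group).fillna(
            False
        ).astype(bool)
        mu[mask.to_numpy()] += shift
    for (drug, stim, subgroup), effect in truth.beta_int.items():
        in_group = _subgroup_mask(subgroup, cohort)
        mask = (
            (wells["drug"] == drug)
            & (wells["stimulus"] == stim)
            & wells["sample_id"].map(in_group).fillna(False).astype(bool)
        )
        mu[mask.to_numpy()] += effect

    plate_ids = wells["plate_id"].unique()
    plate_eff = pd.Series(
        rng.normal(0.0, truth.plate_effect_sd, size=len(plate_ids)), index=plate_ids
    )
    log_lum = (
        np.log(truth.base_luminescence)
        + mu
        + wells["plate_id"].map(plate_eff).to_numpy()
        + rng.normal(0.0, truth.noise_sd, size=len(wells))
    )
    wells["luminescence"] = np.exp(log_lum)
    wells = wells.sort_values(
        ["sample_id", "plate_id", "well_row", "well_col"], kind="mergesort"
    ).reset_index(drop=True)
    return wells[
        [
            "sample_id",
            "plate_id",
            "well_row",
            "well_col",
            "drug",
            "drug_conc_nM",
            "stimulus",
            "luminescence",
        ]
    ]


# ---------------------------------------------------------------------------
# survival


def generate_survival(cohort: Cohort, truth: GroundTruth, seed: int) -> pd.DataFrame:
    """Exponential event times with cluster-specific hazards and independent
    uniform censoring on (0, 2/censoring_rate); rate 0 disables censoring."""
    clusters = cohort.annotation["cluster"]
    for c in clusters.unique():
        scale = truth.hazard_scale.get(c)
        if scale is None:
            raise ValueError(f"hazard_scale missing for cluster {c}")
        if scale <= 0:
            raise ValueError(f"hazard multiplier for {c} must be > 0")
    rng = np.random.default_rng(seed)
    rate = truth.baseline_hazard_per_day * clusters.map(truth.hazard_scale).to_numpy()
    event_time = rng.exponential(1.0 / rate)
    if truth.censoring_rate_per_day > 0:
        cens = rng.uniform(0.0, 2.0 / truth.censoring_rate_per_day, size=len(clusters))
    else:
        cens = np.full(len(clusters), np.inf)
    time = np.minimum(event_time, cens)
    event = (event_time <= cens).astype(int)
    return pd.DataFrame(
        {
            "sample_id": cohort.annotation["sample_id"],
            "time_days": np.maximum(time, 1e-9),
            "event": event,
        }
    )


def write_ground_truth(truth: GroundTruth, path) -> None:
    payload = {
        "beta_d": truth.beta_d,
        "beta_s": truth.beta_s,
        "beta_int": {"|".join(k): v for k, v in truth.beta_int.items()},
        "cluster_proportions": truth.cluster_proportions,
        "cluster_stimulus_shift": {"|".join(k): v for k, v in truth.cluster_stimulus_shift.items()},
        "subgroup_stimulus_shift": {"|".join(k): v for k, v in truth.subgroup_stimulus_shift.items()},
        "feature_prevalence": truth.feature_prevalence,
        "ighv_m_prob_by_cluster": truth.ighv_m_prob_by_cluster,
        "hazard_scale": truth.hazard_scale,
        "baseline_hazard_per_day": truth.baseline_hazard_per_day,
        "censoring_rate_per_day": truth.censoring_rate_per_day,
        "noise_sd": truth.noise_sd,
        "plate_effect_sd": truth.plate_effect_sd,
        "base_luminescence": truth.base_luminescence,
        "missing_rate": truth.missing_rate,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
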