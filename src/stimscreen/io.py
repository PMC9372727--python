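"""Readers, writers and configuration for the tabular artifacts of the pipeline.

All tables are tab-separated UTF-8 text with ``NA`` as the missing-value
marker.  Readers validate on ingest and report the first offending data row
(1-based, excluding the header) rather than silently coercing.  Every writer
emits a file its paired reader parses back to equal in-memory values.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

logger = logging.getLogger("stimscreen")

NA_MARKER = "NA"
_NA_VALUES = ["NA", ""]

WELL_COLUMNS = [
    "sample_id",
    "plate_id",
    "well_row",
    "well_col",
    "drug",
    "drug_conc_nM",
    "stimulus",
    "luminescence",
]

#: label used for control wells / absent treatments
DMSO = "DMSO"
NO_STIMULUS = "none"


def _read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", na_values=_NA_VALUES, keep_default_na=False, **kwargs
    )


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")


def _first_bad_row(mask: pd.Series) -> int:
    """1-based data-row number of the first True entry of a boolean mask."""
    return int(mask.to_numpy().nonzero()[0][0]) + 1


def read_wells(path) -> pd.DataFrame:
    """Read a well-level luminescence table.

    Expected columns: sample_id, plate_id, well_row (1-16), well_col (1-24),
    drug (or ``DMSO``), drug_conc_nM (NA for controls and stimulus-only wells),
    stimulus (or ``none``), luminescence (> 0, arbitrary units).
    """
    df = _read_tsv(path)
    _require_columns(df, WELL_COLUMNS, path)
    df = df[WELL_COLUMNS].copy()

    for col in ("sample_id", "plate_id", "drug", "stimulus"):
        bad = df[col].isna()
        if bad.any():
            raise ValueError(f"{path}: row {_first_bad_row(bad)}: missing {col}")

    lum = pd.to_numeric(df["luminescence"], errors="coerce")
    bad = lum.isna() | (lum <= 0)
    if bad.any():
        raise ValueError(
            f"{path}: row {_first_bad_row(bad)}: luminescence must be a positive number"
        )
    df["luminescence"] = lum.astype(float)

    for col, lo, hi in (("well_row", 1, 16), ("well_col", 1, 24)):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals != vals.round()) | (vals < lo) | (vals > hi)
        if bad.any():
            raise ValueError(
                f"{path}: row {_first_bad_row(bad)}: {col} must be an integer in [{lo}, {hi}]"
            )
        df[col] = vals.astype(int)

    # control wells (vehicle only, no stimulus) must not carry a concentration
    control = (df["drug"] == DMSO) & (df["stimulus"] == NO_STIMULUS)
    df["drug_conc_nM"] = pd.to_numeric(df["drug_conc_nM"], errors="coerce")
    bad = control & df["drug_conc_nM"].notna()
    if bad.any():
        raise ValueError(
            f"{path}: row {_first_bad_row(bad)}: DMSO control wells must not have a drug concentration"
        )
    return df


def write_wells(df: pd.DataFrame, path) -> None:
    df[WELL_COLUMNS].to_csv(path, sep="\t", index=False, na_rep=NA_MARKER)


def read_genetic_matrix(path) -> pd.DataFrame:
    """Read a samples x features binary matrix (values 0/1/NA), indexed by sample_id."""
    df = _read_tsv(path)
    if df.columns[0] != "sample_id":
        raise ValueError(f"{path}: first column must be sample_id")
    dup = df["sample_id"].duplicated()
    if dup.any():
        raise ValueError(f"{path}: row {_first_bad_row(dup)}: duplicate sample_id")
    df = df.set_index("sample_id")
    mat = df.apply(pd.to_numeric, errors="coerce")
    bad = mat.isna() & df.notna()
    bad |= mat.notna() & ~mat.isin([0, 1])
    if bad.any().any():
        rows = bad.any(axis=1)
        raise ValueError(
            f"{path}: row {_first_bad_row(rows.reset_index(drop=True))}: "
            "genetic-matrix values must be 0, 1 or NA"
        )
    return mat.astype(float)


def write_genetic_matrix(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", na_rep=NA_MARKER)


ANNOTATION_COLUMNS = ["sample_id", "cluster", "IGHV", "methylation", "sex", "pretreated"]


def read_annotation(path) -> pd.DataFrame:
    df = _read_tsv(path)
    _require_columns(df, ["sample_id"], path)
    dup = df["sample_id"].duplicated()
    if dup.any():
        raise ValueError(f"{path}: row {_first_bad_row(dup)}: duplicate sample_id")
    if "IGHV" in df.columns:
        bad = df["IGHV"].notna() & ~df["IGHV"].isin(["M", "U"])
        if bad.any():
            raise ValueError(f"{path}: row {_first_bad_row(bad)}: IGHV must be M, U or NA")
    if "methylation" in df.columns:
        bad = df["methylation"].notna() & ~df["methylation"].isin(["LP", "IP", "HP"])
        if bad.any():
            raise ValueError(
                f"{path}: row {_first_bad_row(bad)}: methylation must be LP, IP, HP or NA"
            )
    return df


def write_annotation(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep=NA_MARKER)


def read_survival(path) -> pd.DataFrame:
    """Read right-censored time-to-event records (sample_id, time_days, event)."""
    df = _read_tsv(path)
    _require_columns(df, ["sample_id", "time_days", "event"], path)
    time = pd.to_numeric(df["time_days"], errors="coerce")
    bad = time.isna() | (time <= 0)
    if bad.any():
        raise ValueError(f"{path}: row {_first_bad_row(bad)}: time_days must be > 0")
    df["time_days"] = time.astype(float)
    ev = pd.to_numeric(df["event"], errors="coerce")
    bad = ev.isna() | ~ev.isin([0, 1])
    if bad.any():
        raise ValueError(f"{path}: row {_first_bad_row(bad)}: event must be 0 or 1")
    df["event"] = ev.astype(int)
    return df


def write_survival(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep=NA_MARKER)


def read_matrix(path) -> pd.DataFrame:
    """Generic samples x conditions numeric matrix indexed by the first column."""
    df = _read_tsv(path, index_col=0)
    return df.apply(pd.to_numeric, errors="coerce")


def write_matrix(df: pd.DataFrame, path, index_name: str = "sample_id") -> None:
    out = df.copy()
    out.index.name = index_name
    out.to_csv(path, sep="\t", na_rep=NA_MARKER)


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep=NA_MARKER)


def read_table(path) -> pd.DataFrame:
    return _read_tsv(path)


# ---------------------------------------------------------------------------
# configuration and run metadata


def load_config(path) -> dict:
    """Load the YAML run configuration (nested key-value mapping)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def apply_column_mapping(df: pd.DataFrame, config: Mapping | None) -> pd.DataFrame:
    """Rename externally-named columns to the package schema.

    ``config["columns"]`` maps external name -> schema name, so deposited tables
    with unknown headers can be consumed without editing the files.
    """
    mapping = (config or {}).get("columns") or {}
    return df.rename(columns=dict(mapping))


def write_run_metadata(path, *, command: str, seed=None, params: Mapping | None = None) -> None:
    """JSON sidecar recording package version, seed and effective parameters."""
    from stimscreen import __version__

    payload = {
        "package": "stimscreen",
        "version": __version__,
        "command": command,
        "seed": seed,
        "params": dict(params or {}),
    }
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
    )
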