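"""Tabular readers and writers for the pipeline's external interfaces.

All tables are UTF-8 CSV with documented headers and are carried in memory as
plain :class:`pandas.DataFrame` objects:

* phenotypes: ``trial_id,genotype_id,year,irrigated,region,lat,lon,yield_blue``
  — one trial-level standardized yield BLUE per (trial, genotype);
* pedigree: ``genotype_id,dam_id,sire_id`` — unknown parents are empty cells
  or the token ``UNKNOWN``;
* covariates: ``location_id,lat,lon,<covariate...>`` — wide numeric table of
  environmental covariates for trials or grid bins, where the column-name
  prefix before the first underscore is the data-source tag.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

UNKNOWN_PARENT = "UNKNOWN"
MISSING_TOKEN = "NA"

PHENOTYPE_COLUMNS = [
    "trial_id",
    "genotype_id",
    "year",
    "irrigated",
    "region",
    "lat",
    "lon",
    "yield_blue",
]
PEDIGREE_COLUMNS = ["genotype_id", "dam_id", "sire_id"]


class SchemaError(ValueError):
    """A table violates its documented schema or invariants."""


class LinkageError(KeyError):
    """A table refers to ids absent from its companion table."""


def _require_columns(df: pd.DataFrame, required, what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table is missing column(s): {', '.join(missing)}")


def validate_phenotypes(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a phenotype table in place and return it.

    Enforces: unique (trial_id, genotype_id); one (lat, lon, year, irrigated,
    region) tuple per trial; finite yield values.
    """
    _require_columns(df, PHENOTYPE_COLUMNS, "phenotype")
    dup = df.duplicated(subset=["trial_id", "genotype_id"])
    if dup.any():
        rows = df.loc[dup, ["trial_id", "genotype_id"]].head(3).to_records(index=False)
        raise SchemaError(f"duplicated (trial_id, genotype_id) rows, e.g. {list(rows)}")
    y = pd.to_numeric(df["yield_blue"], errors="coerce")
    bad = ~np.isfinite(y.to_numpy(dtype=float))
    if bad.any():
        raise SchemaError(
            f"non-numeric or non-finite yield_blue at row index {int(np.flatnonzero(bad)[0])}"
        )
    df = df.copy()
    df["yield_blue"] = y.astype(float)
    df["year"] = pd.to_numeric(df["year"], errors="raise").astype(int)
    df["irrigated"] = df["irrigated"].astype(bool)
    meta = df.groupby("trial_id")[["lat", "lon", "year", "irrigated", "region"]].nunique()
    inconsistent = meta[(meta > 1).any(axis=1)]
    if len(inconsistent):
        raise SchemaError(
            f"trial(s) with inconsistent metadata: {list(inconsistent.index[:3])}"
        )
    return df


def read_phenotypes(path) -> pd.DataFrame:
    """Read and validate a phenotype CSV (trial-level standardized BLUEs)."""
    return validate_phenotypes(pd.read_csv(path, dtype={"trial_id": str, "genotype_id": str}))


def write_phenotypes(df: pd.DataFrame, path) -> None:
    validate_phenotypes(df)[PHENOTYPE_COLUMNS].to_csv(path, index=False)


def validate_pedigree(df: pd.DataFrame) -> pd.DataFrame:
    """Validate pedigree records: unique ids, known parents, acyclic."""
    _require_columns(df, PEDIGREE_COLUMNS, "pedigree")
    df = df.copy()
    for c in PEDIGREE_COLUMNS:
        df[c] = df[c].fillna(UNKNOWN_PARENT).astype(str).str.strip()
        df.loc[df[c].isin({"", "-", "nan"}), c] = UNKNOWN_PARENT
    if df["genotype_id"].duplicated().any():
        dup = df.loc[df["genotype_id"].duplicated(), "genotype_id"].iloc[0]
        raise SchemaError(f"duplicate genotype_id in pedigree: {dup}")
    known = set(df["genotype_id"])
    for c in ("dam_id", "sire_id"):
        orphan = set(df[c]) - known - {UNKNOWN_PARENT}
        if orphan:
            raise SchemaError(f"{c} refers to unlisted genotype(s): {sorted(orphan)[:3]}")
    _check_acyclic(df)
    return df


def _check_acyclic(df: pd.DataFrame) -> None:
    parents = {
        r.genotype_id: [p for p in (r.dam_id, r.sire_id) if p != UNKNOWN_PARENT]
        for r in df.itertuples()
    }
    state: dict[str, int] = {}  # 0 in-progress, 1 done

    def visit(node: str, stack: list) -> None:
        if state.get(node) == 1:
            return
        if state.get(node) == 0:
            cycle = stack[stack.index(node):] + [node]
            raise SchemaError(f"pedigree cycle detected: {' -> '.join(cycle)}")
        state[node] = 0
        stack.append(node)
        for p in parents.get(node, []):
            visit(p, stack)
        stack.pop()
        state[node] = 1

    for g in parents:
        visit(g, [])


def read_pedigree(path) -> pd.DataFrame:
    return validate_pedigree(pd.read_csv(path, dtype=str, keep_default_na=False))


def write_pedigree(df: pd.DataFrame, path) -> None:
    validate_pedigree(df)[PEDIGREE_COLUMNS].to_csv(path, index=False)


def validate_covariates(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, ["location_id", "lat", "lon"], "covariate")
    if df.columns.duplicated().any():
        raise SchemaError("duplicate covariate column names")
    cov_cols = covariate_columns(df)
    if not cov_cols:
        raise SchemaError("covariate table needs at least one covariate column")
    if df["location_id"].duplicated().any():
        raise SchemaError("duplicate location_id in covariate table")
    return df


def covariate_columns(df: pd.DataFrame) -> list:
    return [c for c in df.columns if c not in ("location_id", "lat", "lon")]


def impute_covariates(df: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Fill missing covariate cells with the column median.

    Returns the completed table and the number of imputed cells. Columns that
    are entirely missing are filled with zero.
    """
    df = df.copy()
    cols = covariate_columns(df)
    n_imputed = int(df[cols].isna().to_numpy().sum())
    if n_imputed:
        med = df[cols].median()
        df[cols] = df[cols].fillna(med).fillna(0.0)
    return df, n_imputed


def read_covariates(path, impute: bool = True) -> pd.DataFrame:
    df = validate_covariates(pd.read_csv(path, dtype={"location_id": str}))
    if impute:
        df, _ = impute_covariates(df)
    return df


def write_covariates(df: pd.DataFrame, path) -> None:
    validate_covariates(df).to_csv(path, index=False)


def covariate_source(column: str) -> str:
    """Data-source tag of a covariate column (prefix before first underscore)."""
    return column.split("_", 1)[0] if "_" in column else "other"


def write_grid_layer(grid, values, path) -> pd.DataFrame:
    """Write one per-bin value layer as long-format CSV (bin_id, lat, lon, value).

    NaN values are written as an explicit missing token and round-trip.
    """
    values = np.asarray(values, dtype=float)
    if values.shape != (grid.n_bins,):
        raise ValueError(f"expected {grid.n_bins} values, got shape {values.shape}")
    out = grid.bins[["bin_id", "lat", "lon"]].copy()
    out["value"] = values
    out.to_csv(path, index=False, na_rep=MISSING_TOKEN)
    return out


def read_grid_layer(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"bin_id": str}, na_values=[MISSING_TOKEN])
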