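"""Sample-sheet and trait-table CSV readers with schema validation.

Sample sheet columns: sample_id, genotype_id, sex, latitude, longitude,
source. Sex labels are normalized to {F, M, U}. Trait tables are long
format: genotype_id, ramet, site, year, trait, value (plus optional
planting_year, sex, latitude, longitude, PC1, PC2).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ParseError

_SEX_TOKENS = {
    "f": "F", "female": "F", "fem": "F",
    "m": "M", "male": "M",
    "u": "U", "unknown": "U", "na": "U", "none": "U", "": "U", "nan": "U",
}


def normalize_sex(values: pd.Series) -> pd.Series:
    """Map free-text sex labels onto {F, M, U}; unknown tokens raise."""
    tokens = values.astype(str).str.strip().str.lower()
    bad = sorted(set(tokens[~tokens.isin(_SEX_TOKENS)]))
    if bad:
        raise ParseError(f"unrecognized sex token(s): {bad}")
    return tokens.map(_SEX_TOKENS)


def read_sample_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"sample_id", "genotype_id", "sex", "latitude", "longitude"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: sample sheet lacks columns {sorted(missing)}")
    dup = df["sample_id"][df["sample_id"].duplicated()].unique()
    if len(dup):
        raise ParseError(f"{path}: duplicate sample_id(s): {sorted(dup)}")
    df["sex"] = normalize_sex(df["sex"])
    for col, lo, hi in (("latitude", -90, 90), ("longitude", -180, 180)):
        v = pd.to_numeric(df[col], errors="coerce")
        bad = df.loc[v.notna() & ((v < lo) | (v > hi)), "sample_id"]
        if len(bad):
            raise ParseError(
                f"{path}: {col} out of [{lo}, {hi}] for sample(s): "
                f"{bad.tolist()}")
        df[col] = v
    if "source" not in df.columns:
        df["source"] = "unknown"
    return df


def read_trait_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"genotype_id", "trait", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: trait table lacks columns {sorted(missing)}")
    df["value"] = pd.to_numeric(df["value"], errors="coerce")
    if "sex" in df.columns:
        df["sex"] = normalize_sex(df["sex"])
    for col in ("ramet", "year"):
        if col not in df.columns:
            df[col] = 1
    if "site" not in df.columns:
        df["site"] = "site1"
    return df


def read_tables(sample_path: str, trait_path: str):
    """Load and validate a sample sheet and a trait table together; trait
    rows inherit sex/latitude/longitude from the sample sheet when absent."""
    samples = read_sample_table(sample_path)
    traits = read_trait_table(trait_path)
    meta_cols = [c for c in ("sex", "latitude", "longitude")
                 if c not in traits.columns]
    if meta_cols:
        meta = samples.drop_duplicates("genotype_id").set_index("genotype_id")
        for c in meta_cols:
            traits[c] = traits["genotype_id"].map(meta[c])
    return samples, traits


def write_sample_table(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, index=False, float_format="%.6f")


def write_trait_table(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, index=False, float_format="%.6f")
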