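"""Packaged fixtures, config files, and tabular I/O helpers.

Two small reference tables ship with the package:

* ``table2_traits.csv`` — the 30-accession wild-hop trait table (per-
  accession means and standard errors for the cone and leaf traits), the
  verifiable surface for the trait statistics and chemotype rules.
* ``table3_flavonol_ions.csv`` — the leaf flavonol catalogue: retention
  time, UV lambda-max, and observed ESI+/- ions with relative abundances.

All tabular output uses one CSV dialect: header row, '.' decimal
separator, UTF-8.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Optional, Union

import pandas as pd
import yaml

from .errors import ConfigurationError, FixtureIntegrityError

__all__ = [
    "packaged_data_path",
    "load_table2_fixture",
    "load_table3_fixture",
    "parse_plus_minus",
    "load_config",
    "TRAIT_COLUMNS",
]

TRAIT_COLUMNS = (
    "total_prenylchalcones", "xga", "mxh", "total_alpha", "prop_coh",
    "total_beta", "alpha_ratio", "malonyl_proportion",
)
_PROPORTION_COLUMNS = ("prop_coh", "alpha_ratio", "malonyl_proportion")
_EXPECTED_COUNTS = {"lupuloides": 19, "lupulus": 11}


def packaged_data_path(name: str) -> Path:
    return Path(resources.files("hopchem").joinpath("data", name))


def parse_plus_minus(cell: Union[str, float]) -> tuple[float, Optional[float]]:
    """Parse a '1.15 ± 0.07' style cell into (mean, SE)."""
    if isinstance(cell, (int, float)):
        return float(cell), None
    text = str(cell).replace("+/-", "±").strip()
    if "±" in text:
        mean_s, se_s = (part.strip() for part in text.split("±", 1))
        return float(mean_s), float(se_s)
    return float(text), None


def load_table2_fixture(path: Optional[Union[str, Path]] = None) -> pd.DataFrame:
    """Load and integrity-check the packaged 30-accession trait table.

    Accepts either the packaged dialect (separate ``*_se`` columns) or
    cells written as ``mean ± SE``.  Raises
    :class:`~hopchem.errors.FixtureIntegrityError` naming the offending
    row when a structural invariant fails.
    """
    if path is None:
        path = packaged_data_path("table2_traits.csv")
    df = pd.read_csv(path, dtype=str).apply(lambda s: s.str.strip())
    for col in df.columns:
        if col in ("site_code", "subspecies", "habitat"):
            continue
        parsed = df[col].map(parse_plus_minus)
        df[col] = [m for m, _ in parsed]
        if any(se is not None for _, se in parsed) and f"{col}_se" not in df.columns:
            df[f"{col}_se"] = [se for _, se in parsed]
    for col in df.columns:
        if col not in ("site_code", "subspecies", "habitat"):
            df[col] = df[col].astype(float)

    missing = [c for c in TRAIT_COLUMNS if c not in df.columns]
    if missing:
        raise FixtureIntegrityError(f"fixture missing trait columns: {missing}")
    counts = df["subspecies"].value_counts().to_dict()
    if counts != _EXPECTED_COUNTS:
        raise FixtureIntegrityError(
            f"expected {_EXPECTED_COUNTS} accessions per subspecies, got {counts}"
        )
    for _, row in df.iterrows():
        site = row["site_code"]
        if row["subspecies"] == "lupulus" and (row["xga"] != 0 or row["mxh"] != 0):
            raise FixtureIntegrityError(f"row {site}: lupulus must have XGA = MXH = 0")
        for col in _PROPORTION_COLUMNS:
            if not 0.0 <= row[col] <= 1.0:
                raise FixtureIntegrityError(f"row {site}: {col} outside [0, 1]")
        if any(row[c] < 0 for c in TRAIT_COLUMNS):
            raise FixtureIntegrityError(f"row {site}: negative trait value")
    return df


def load_table3_fixture(path: Optional[Union[str, Path]] = None) -> pd.DataFrame:
    """Load the flavonol ion catalogue (long format, one observed ion/row)."""
    if path is None:
        path = packaged_data_path("table3_flavonol_ions.csv")
    df = pd.read_csv(path)
    required = {"compound_id", "rt_min", "lambda_max_nm", "mode", "mz",
                "rel_abundance", "assignment"}
    missing = required - set(df.columns)
    if missing:
        raise FixtureIntegrityError(f"ion fixture missing columns: {sorted(missing)}")
    if df["compound_id"].nunique() != 6:
        raise FixtureIntegrityError("ion fixture must list exactly 6 compounds")
    return df


def load_config(path: Union[str, Path]) -> dict:
    """Flat key-value run configuration (YAML mapping of scalars)."""
    data = yaml.safe_load(Path(path).read_text())
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigurationError("config file must be a flat key: value mapping")
    return data
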