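"""Reading and writing concentration tables and reference configuration.

Canonical concentration format: wide CSV (UTF-8, ``.`` decimal separator)
with a site-id column first and one column per metal symbol. A long format
(columns ``site, metal, value``) is accepted via ``long_format=True``.

Configuration is YAML or TOML with optional blocks ``background:``,
``preindustrial:``, ``normalizers:`` and ``zones:``; user values are merged
over the packaged pre-industrial defaults.
"""

from __future__ import annotations

import tomllib
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .datamodel import (
    PREINDUSTRIAL_REFERENCE,
    ConcentrationMatrix,
    ReferenceSet,
    ValidationError,
)

__all__ = [
    "read_concentrations",
    "write_concentrations",
    "read_reference_config",
    "read_zone_map",
]


def read_concentrations(
    path: str | Path,
    zone_map: Mapping[str, str] | None = None,
    long_format: bool = False,
) -> ConcentrationMatrix:
    """Read a delimited concentration table into a validated matrix.

    Row and column order are preserved from the file. Missing, non-numeric
    or non-positive cells raise :class:`ValidationError` naming the site and
    metal. ``zone_map`` overrides the site-id-prefix zone inference.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if long_format:
        long = pd.read_csv(path)
        required = {"site", "metal", "value"}
        if not required.issubset(long.columns):
            raise ValidationError(
                f"long format needs columns {sorted(required)}, got {list(long.columns)}"
            )
        sites = long["site"].astype(str).drop_duplicates().tolist()
        metals = long["metal"].astype(str).drop_duplicates().tolist()
        df = long.pivot_table(
            index="site", columns="metal", values="value", aggfunc="first", sort=False
        ).reindex(index=sites, columns=metals)
    else:
        df = pd.read_csv(path, index_col=0)
    df.index = df.index.map(str)
    df.columns = df.columns.map(str)
    missing = df.isna()
    if missing.to_numpy().any():
        s = missing.index[missing.any(axis=1)][0]
        m = missing.columns[missing.loc[s]][0]
        raise ValidationError(f"missing concentration for site {s!r}, metal {m!r}")
    return ConcentrationMatrix(df, dict(zone_map or {}))


def write_concentrations(conc: ConcentrationMatrix, path: str | Path) -> None:
    """Write the wide CSV representation (round-trips decimal values exactly)."""
    conc.data.to_csv(path, index_label="site")


def _load_config(path: str | Path) -> dict:
    path = Path(path)
    if path.suffix.lower() == ".toml":
        with open(path, "rb") as fh:
            return tomllib.load(fh)
    with open(path, "r", encoding="utf-8") as fh:
        return yaml.safe_load(fh) or {}


def read_reference_config(path: str | Path) -> ReferenceSet:
    """Read reference levels from YAML/TOML, merging over packaged defaults.

    An empty config yields the seven packaged pre-industrial values and no
    backgrounds. Zero or negative reference values are rejected.
    """
    raw = _load_config(path)
    preindustrial = dict(PREINDUSTRIAL_REFERENCE)
    preindustrial.update({str(k): float(v) for k, v in (raw.get("preindustrial") or {}).items()})
    background = {str(k): float(v) for k, v in (raw.get("background") or {}).items()}
    normalizers = tuple(str(m) for m in (raw.get("normalizers") or ("Mn", "Fe")))
    return ReferenceSet(background, preindustrial, normalizers)


def read_zone_map(path: str | Path) -> dict[str, str]:
    """Read the optional ``zones:`` block (site id -> zone label) of a config."""
    raw = _load_config(path)
    return {str(k): str(v) for k, v in (raw.get("zones") or {}).items()}
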