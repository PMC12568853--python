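"""Composite pollution indices built from PI and CF tables.

Per site (from a PI table over a metal subset):

* PLI     — geometric mean of PI (pollution load index),
* PI_Nem  — Nemerow index, sqrt((mean(PI)^2 + max(PI)^2) / 2), weighting the
  worst pollutant,
* CPI     — arithmetic mean of PI.

Per zone (from a CF table):

* CD      — degree of contamination, the sum of contamination factors,
* mCD     — modified degree, the mean of contamination factors.

CD class boundaries are the CF boundaries multiplied by the number of
metals; mCD keeps the raw CF boundaries.

A sensitivity helper recomputes any per-site composite with one metal
removed (used to gauge how much a single dominant metal, typically Cd,
drives the verdicts).
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .classification import SCHEMES, classify, classify_pli
from .datamodel import CompositeTable, IndexTable, ValidationError

__all__ = [
    "pli",
    "nemerow",
    "cpi",
    "contamination_degree",
    "modified_contamination_degree",
    "sensitivity_without",
]


def _pi_values(pi_table: IndexTable, metal_subset) -> pd.DataFrame:
    if pi_table.index_name != "PI":
        raise ValidationError(f"expected a PI table, got {pi_table.index_name!r}")
    subset = list(metal_subset) if metal_subset is not None else list(pi_table.values.columns)
    if not subset:
        raise ValidationError("composite index needs a non-empty metal subset")
    unknown = [m for m in subset if m not in pi_table.values.columns]
    if unknown:
        raise KeyError(f"metal {unknown[0]!r} not in the PI table")
    return pi_table.values[subset]


def pli(pi_table: IndexTable, metal_subset: Sequence[str] | None = None) -> CompositeTable:
    """Pollution load index: per-site geometric mean of PI over the subset."""
    vals = _pi_values(pi_table, metal_subset)
    per_site = np.exp(np.log(vals).mean(axis=1))
    per_site.name = "PLI"
    return CompositeTable("PLI", tuple(vals.columns), per_site=per_site,
                          classes=classify_pli(per_site))


def nemerow(pi_table: IndexTable, metal_subset: Sequence[str] | None = None) -> CompositeTable:
    """Nemerow index: quadratic mean of mean-PI and max-PI per site."""
    vals = _pi_values(pi_table, metal_subset)
    per_site = np.sqrt((vals.mean(axis=1) ** 2 + vals.max(axis=1) ** 2) / 2.0)
    per_site.name = "PI_Nem"
    return CompositeTable("PI_Nem", tuple(vals.columns), per_site=per_site,
                          classes=classify("PI_Nem", per_site))


def cpi(pi_table: IndexTable, metal_subset: Sequence[str] | None = None) -> CompositeTable:
    """Combined pollution index: per-site arithmetic mean of PI; >1 flags high contamination."""
    vals = _pi_values(pi_table, metal_subset)
    per_site = vals.mean(axis=1)
    per_site.name = "CPI"
    return CompositeTable("CPI", tuple(vals.columns), per_site=per_site,
                          classes=classify("CPI", per_site))


def _cf_values(cf_table: IndexTable) -> pd.DataFrame:
    if cf_table.index_name != "CF":
        raise ValidationError(f"expected a CF table, got {cf_table.index_name!r}")
    return cf_table.values


def contamination_degree(cf_table: IndexTable) -> CompositeTable:
    """Degree of contamination per zone: sum of CF over the assessed metals."""
    vals = _cf_values(cf_table)
    per_zone = vals.sum(axis=1)
    per_zone.name = "CD"
    scheme = SCHEMES["CF"].scaled(len(vals.columns), "CD")
    return CompositeTable("CD", tuple(vals.columns), per_zone=per_zone,
                          classes=scheme.classify(per_zone))


def modified_contamination_degree(cf_table: IndexTable) -> CompositeTable:
    """Modified degree of contamination per zone: mean of CF (classified on CF intervals)."""
    vals = _cf_values(cf_table)
    per_zone = vals.mean(axis=1)
    per_zone.name = "mCD"
    return CompositeTable("mCD", tuple(vals.columns), per_zone=per_zone,
                          classes=classify("mCD", per_zone))


def sensitivity_without(
    composite_op: Callable[..., CompositeTable],
    pi_table: IndexTable,
    exclude: str,
    metal_subset: Sequence[str] | None = None,
) -> tuple[CompositeTable, CompositeTable]:
    """Recompute a per-site composite with one metal removed.

    Returns ``(full, without)`` so reports can carry both variants side by
    side. Excluding a metal not in the subset is an error.
    """
    subset = list(metal_subset) if metal_subset is not None else list(pi_table.values.columns)
    if exclude not in subset:
        raise KeyError(f"metal {exclude!r} not in the composite's metal subset")
    reduced = [m for m in subset if m != exclude]
    if not reduced:
        raise ValidationError("removing the metal would empty the subset")
    return composite_op(pi_table, subset), composite_op(pi_table, reduced)
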