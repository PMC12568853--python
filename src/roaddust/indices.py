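"""Individual pollution indices: Igeo, PI, EF and CF, with class labels.

* Geo-accumulation index  Igeo_i = log2( C_i / (1.5 · CB_i) ) — the factor
  1.5 buffers natural lithological variation of the background.
* Pollution index         PI_i   = C_i / CB_i.
* Enrichment factor       EF_i   = (C_i / C_norm)_sample / (CB_i / CB_norm),
  the double ratio against a crustal normalizer element (Mn or Fe here),
  separating anthropogenic enrichment from natural dilution.
* Contamination factor    CF_j   = mean_zone(C_j) / C_pj against Håkanson
  pre-industrial reference levels; defined for zone means of at least five
  samples.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .classification import classify
from .datamodel import ConcentrationMatrix, IndexTable, ReferenceSet, ValidationError

__all__ = [
    "igeo",
    "pollution_index",
    "enrichment_factor",
    "contamination_factor",
    "cf_from_zone_means",
]

logger = logging.getLogger(__name__)


def _select_metals(conc: ConcentrationMatrix, metals) -> list[str]:
    if metals is None:
        return conc.metals
    unknown = [m for m in metals if m not in conc.metals]
    if unknown:
        raise KeyError(f"metal {unknown[0]!r} not in concentration matrix")
    return list(metals)


def _background_series(ref: ReferenceSet, metals: list[str]) -> pd.Series:
    ref.require_background(metals)
    return pd.Series({m: ref.background[m] for m in metals}, dtype=float)


def igeo(
    conc: ConcentrationMatrix, ref: ReferenceSet, metals: list[str] | None = None
) -> IndexTable:
    """Geo-accumulation index per site and metal with its seven-class verdicts."""
    metals = _select_metals(conc, metals)
    cb = _background_series(ref, metals)
    values = np.log2(conc.data[metals] / (1.5 * cb))
    return IndexTable("Igeo", values, classify("Igeo", values))


def pollution_index(
    conc: ConcentrationMatrix, ref: ReferenceSet, metals: list[str] | None = None
) -> IndexTable:
    """Pollution index (concentration / background) per site and metal."""
    metals = _select_metals(conc, metals)
    cb = _background_series(ref, metals)
    values = conc.data[metals] / cb
    return IndexTable("PI", values, classify("PI", values))


def enrichment_factor(
    conc: ConcentrationMatrix,
    ref: ReferenceSet,
    normalizer: str = "Mn",
    metals: list[str] | None = None,
) -> IndexTable:
    """Enrichment factor against a crustal normalizer element.

    ``EF[s, i] = (C_i / C_norm)_s / (CB_i / CB_norm)``. The normalizer metal
    itself gets EF = 1 by construction.
    """
    metals = _select_metals(conc, metals)
    if normalizer not in conc.metals:
        raise KeyError(f"normalizer {normalizer!r} not in concentration matrix")
    cb = _background_series(ref, sorted(set(metals) | {normalizer}))
    sample_ratio = conc.data[metals].div(conc.data[normalizer], axis=0)
    background_ratio = cb[metals] / cb[normalizer]
    values = sample_ratio / background_ratio
    return IndexTable("EF", values, classify("EF", values), normalizer=normalizer)


def cf_from_zone_means(
    zone_means: pd.Series, ref: ReferenceSet, zone: str = "zone"
) -> IndexTable:
    """Contamination factors from an already-averaged zone summary.

    Accepts a per-metal Series of zone-mean concentrations (e.g. a published
    summary row); metals without a pre-industrial reference are excluded with
    a logged warning. Result is a 1-row (zone) × metals table.
    """
    zone_means = zone_means.astype(float)
    usable = [m for m in zone_means.index if m in ref.preindustrial]
    skipped = [m for m in zone_means.index if m not in usable]
    if skipped:
        logger.warning(
            "no pre-industrial reference for %s; excluded from CF for zone %s",
            ", ".join(map(str, skipped)), zone,
        )
    if not usable:
        raise ValidationError("no metal with a pre-industrial reference value")
    cp = pd.Series({m: ref.preindustrial[m] for m in usable}, dtype=float)
    values = pd.DataFrame([zone_means[usable] / cp], index=[zone])
    return IndexTable("CF", values, classify("CF", values))


def contamination_factor(
    conc: ConcentrationMatrix,
    ref: ReferenceSet,
    zone: str,
    metals: list[str] | None = None,
) -> IndexTable:
    """Contamination factors for one zone of a measured site matrix.

    Requires at least five samples in the zone (the Håkanson definition uses
    the mean concentration of at least five samples).
    """
    sites = conc.zone_sites(zone)
    if len(sites) < 5:
        raise ValidationError(
            f"zone {zone!r} has {len(sites)} sites; the contamination factor "
            "requires the mean of at least five samples"
        )
    metals = _select_metals(conc, metals)
    means = conc.data.loc[sites, metals].mean(axis=0)
    return cf_from_zone_means(means, ref, zone=zone)
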