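"""Core data containers for road-dust / soil heavy-metal assessment.

The whole package operates on a single measured input — a sites × metals
concentration matrix in mg/kg dry weight — plus a set of per-metal reference
levels: geochemical *background* concentrations (used by the geo-accumulation
index, the pollution index and the enrichment factor) and *pre-industrial*
reference concentrations in the Håkanson sense (used by the contamination
factor and the degree-of-contamination composites).

µg/g and mg/kg are numerically identical (both 1e-6 mass fractions) and are
treated as the same unit throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "PREINDUSTRIAL_REFERENCE",
    "ConcentrationMatrix",
    "ReferenceSet",
    "IndexTable",
    "CompositeTable",
]


class ValidationError(ValueError):
    """An input table or configuration violates a data-model invariant."""


#: Håkanson pre-industrial reference levels (µg/g ≡ mg/kg). These are the
#: packaged defaults; the contamination factor is only defined for metals
#: with a pre-industrial reference.
PREINDUSTRIAL_REFERENCE: dict[str, float] = {
    "Cd": 1.0,
    "Cr": 90.0,
    "Cu": 50.0,
    "Ni": 68.0,
    "Pb": 70.0,
    "Zn": 175.0,
    "Mn": 850.0,
}


def _infer_zone(site_id: str) -> str:
    """Zone from the leading alphabetic prefix of a site id ('KF3' -> 'KF')."""
    prefix = ""
    for ch in str(site_id):
        if ch.isalpha():
            prefix += ch
        else:
            break
    return prefix or str(site_id)


@dataclass
class ConcentrationMatrix:
    """Sites × metals concentration matrix (mg/kg dry weight).

    Parameters
    ----------
    data
        DataFrame indexed by site id with one column per metal symbol.
        Every cell must be a strictly positive, finite concentration.
    zone_of_site
        Mapping site id -> zone label. If omitted, zones are inferred from
        the leading alphabetic prefix of each site id (``KF1 -> KF``,
        ``D7 -> D``); an explicit mapping always wins.
    """

    data: pd.DataFrame
    zone_of_site: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        if self.data.shape[0] < 1 or self.data.shape[1] < 1:
            raise ValidationError("concentration matrix needs at least 1 site and 1 metal")
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValidationError(f"duplicate site id {dup!r}")
        if self.data.columns.duplicated().any():
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise ValidationError(f"duplicate metal symbol {dup!r}")
        values = self.data.to_numpy(dtype=float)
        bad = ~np.isfinite(values) | (values <= 0)
        if bad.any():
            s, m = np.argwhere(bad)[0]
            raise ValidationError(
                f"concentration for site {self.data.index[s]!r}, metal "
                f"{self.data.columns[m]!r} must be a positive finite number, "
                f"got {self.data.iat[s, m]!r}"
            )
        self.data = self.data.astype(float)
        zones = {str(s): _infer_zone(s) for s in self.data.index}
        zones.update({str(k): str(v) for k, v in self.zone_of_site.items()})
        missing = [s for s in map(str, self.data.index) if s not in zones]
        if missing:
            raise ValidationError(f"site {missing[0]!r} has no zone assignment")
        self.zone_of_site = {str(s): zones[str(s)] for s in self.data.index}

    # -- convenience accessors -------------------------------------------------

    @property
    def site_ids(self) -> list[str]:
        return [str(s) for s in self.data.index]

    @property
    def metals(self) -> list[str]:
        return [str(m) for m in self.data.columns]

    @property
    def zones(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.site_ids:
            seen.setdefault(self.zone_of_site[s], None)
        return list(seen)

    def zone_sites(self, zone: str) -> list[str]:
        return [s for s in self.site_ids if self.zone_of_site[s] == zone]

    def zone_data(self, zone: str | None = None) -> pd.DataFrame:
        if zone is None:
            return self.data
        sites = self.zone_sites(zone)
        if not sites:
            raise KeyError(f"unknown zone {zone!r}")
        return self.data.loc[sites]


@dataclass
class ReferenceSet:
    """Per-metal reference levels.

    ``background`` holds geochemical background concentrations CB_i (mg/kg)
    for Igeo/PI/EF; no defaults are shipped — they are survey-specific and
    must come from configuration. ``preindustrial`` holds Håkanson
    pre-industrial reference levels C_pj for the contamination factor;
    packaged defaults cover Cd, Cr, Cu, Ni, Pb, Zn and Mn.
    """

    background: dict[str, float] = field(default_factory=dict)
    preindustrial: dict[str, float] = field(
        default_factory=lambda: dict(PREINDUSTRIAL_REFERENCE)
    )
    normalizer_candidates: tuple[str, ...] = ("Mn", "Fe")

    def __post_init__(self) -> None:
        for name, table in (("background", self.background),
                            ("preindustrial", self.preindustrial)):
            for metal, value in table.items():
                if not np.isfinite(value) or value <= 0:
                    raise ValidationError(
                        f"{name} reference for {metal!r} must be positive, got {value!r}"
                    )

    def require_background(self, metals) -> None:
        missing = [m for m in metals if m not in self.background]
        if missing:
            raise ValidationError(
                f"no background concentration configured for metal {missing[0]!r}"
            )


@dataclass
class IndexTable:
    """One individual pollution index evaluated on a matrix of samples.

    ``values`` and ``classes`` share the same shape: sites × metals for
    Igeo/PI/EF, zones × metals for the contamination factor. EF tables carry
    the crustal normalizer they were computed against; other indices carry
    ``None``.
    """

    index_name: str
    values: pd.DataFrame
    classes: pd.DataFrame
    normalizer: str | None = None

    def __post_init__(self) -> None:
        if self.index_name == "EF" and self.normalizer is None:
            raise ValidationError("EF tables must carry their normalizer")
        if self.index_name != "EF" and self.normalizer is not None:
            raise ValidationError(f"{self.index_name} tables carry no normalizer")


@dataclass
class CompositeTable:
    """A composite pollution index (PLI, PI_Nem, CPI, CD or mCD).

    Per-site composites populate ``per_site``; the zone-level degree of
    contamination (CD) and its modified form (mCD) populate ``per_zone``.
    """

    index_name: str
    metal_subset: tuple[str, ...]
    per_site: pd.Series | None = None
    per_zone: pd.Series | None = None
    classes: pd.Series | None = None

    def __post_init__(self) -> None:
        if not self.metal_subset:
            raise ValidationError("composite index needs a non-empty metal subset")

    @property
    def values(self) -> pd.Series:
        out = self.per_zone if self.per_site is None else self.per_site
        assert out is not None
        return out
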