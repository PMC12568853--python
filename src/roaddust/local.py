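"""Local representative-enrichment levels.

Condenses a zone's per-metal index series (EF by default; PI or Igeo work
the same way) into one representative level per metal:

1. per metal, span [min, max] of the zone's index values;
2. split the span into ``m`` equal-width sub-intervals (left-closed,
   right-open, last interval closed so the maximum is binned);
3. count the values in each sub-interval;
4. the representative sub-interval is the most frequent one; frequency ties
   go to the sub-interval whose internal mean is closest to the mean of the
   whole series (remaining ties to the leftmost).

``m`` defaults to 3. If a sub-interval is empty, ``m`` is decremented until
none is (``m >= 2``); with at least two distinct values, m = 2 always has
both bins occupied. The reported representative value is the mean of the
values inside the chosen sub-interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import ConcentrationMatrix, ReferenceSet
from .indices import enrichment_factor

__all__ = ["RepresentativeLevel", "representative_level", "ef_local_report"]


@dataclass(frozen=True)
class RepresentativeLevel:
    metal: str
    lo: float
    hi: float
    frequency: int
    representative_value: float
    m_used: int


def _representative_for_row(values: np.ndarray, m: int) -> tuple[float, float, int, float, int]:
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        raise ValueError(
            "constant series: sub-intervals between min and max are undefined"
        )
    if m < 2:
        raise ValueError("m must be at least 2")
    row_mean = float(values.mean())
    for m_used in range(int(m), 1, -1):
        edges = np.linspace(lo, hi, m_used + 1)
        # left-closed bins, last bin right-closed (max is binned)
        bin_idx = np.minimum(np.searchsorted(edges, values, side="right") - 1, m_used - 1)
        freq = np.bincount(bin_idx, minlength=m_used)
        if freq.min() == 0:
            continue
        best = int(freq.argmax())
        top = np.flatnonzero(freq == freq[best])
        if len(top) > 1:
            # tie: bin whose internal mean is closest to the series mean;
            # gaps within 1e-9 count as equal and resolve to the leftmost bin
            gaps = np.array([abs(values[bin_idx == b].mean() - row_mean) for b in top])
            tol = 1e-9 * max(1.0, float(np.abs(gaps).max()))
            best = int(top[np.flatnonzero(gaps <= gaps.min() + tol)[0]])
        rep = float(values[bin_idx == best].mean())
        return float(edges[best]), float(edges[best + 1]), int(freq[best]), rep, m_used
    raise AssertionError("unreachable: m = 2 cannot produce an empty bin")


def representative_level(index_values: pd.DataFrame, m: int = 3) -> list[RepresentativeLevel]:
    """Representative level per metal of a sites × metals index matrix.

    Each metal column needs at least two distinct values; a constant column
    raises ``ValueError``.
    """
    out = []
    for metal in index_values.columns:
        vals = index_values[metal].to_numpy(dtype=float)
        try:
            lo, hi, freq, rep, m_used = _representative_for_row(vals, m)
        except ValueError as exc:
            raise ValueError(f"metal {metal!r}: {exc}") from None
        out.append(RepresentativeLevel(str(metal), lo, hi, freq, rep, m_used))
    return out


def ef_local_report(
    conc: ConcentrationMatrix,
    ref: ReferenceSet,
    zone: str,
    normalizer: str = "Mn",
    m: int = 3,
) -> pd.DataFrame:
    """Representative EF level per metal for one zone (EF_local).

    Chains the enrichment factor with the representative-sub-interval
    condensation; rows follow the metal order of the input matrix. The
    normalizer metal is omitted (its EF is identically 1, so its series has
    no sub-interval structure).
    """
    sites = conc.zone_sites(zone)
    if not sites:
        raise KeyError(f"unknown zone {zone!r}")
    sub = ConcentrationMatrix(conc.data.loc[sites],
                              {s: conc.zone_of_site[s] for s in sites})
    ef = enrichment_factor(sub, ref, normalizer=normalizer)
    levels = representative_level(ef.values.drop(columns=[normalizer]), m=m)
    return pd.DataFrame(
        {
            "metal": [r.metal for r in levels],
            "lo": [r.lo for r in levels],
            "hi": [r.hi for r in levels],
            "frequency": [r.frequency for r in levels],
            "representative_value": [r.representative_value for r in levels],
            "m_used": [r.m_used for r in levels],
        }
    ).set_index("metal")
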