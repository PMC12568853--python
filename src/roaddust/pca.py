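"""Correlation-matrix PCA for source attribution, plus zone comparison.

Metals are z-score standardized per column, the correlation matrix is
eigendecomposed, and the usual factor-analysis summaries are derived:

* loadings        — eigenvector × sqrt(eigenvalue) (variable–component
  correlations),
* contributions   — 100 · loading² / eigenvalue per component (sums to
  100 % per component),
* cos2            — squared loading, the quality of representation of a
  metal on a component (sums to 1 per metal over all components),
* site scores     — standardized data projected on the eigenvectors.

Component signs are fixed so each component's largest-magnitude loading is
positive. Component counts are reported under both the Kaiser rule
(eigenvalue > 1) and a cumulative-explained-variance rule (default 80 %).

Zone comparison uses the Kruskal–Wallis rank test on index series (the
nonparametric analogue of a one-way ANOVA), applied to pollution-indicator
series rather than raw concentrations so that values of different metals
are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import ConcentrationMatrix, IndexTable, ValidationError

__all__ = [
    "PcaResult",
    "ComponentSelection",
    "pca",
    "select_components",
    "contributions",
    "compare_zones",
]


@dataclass
class PcaResult:
    eigenvalues: np.ndarray
    explained_pct: np.ndarray
    cumulative_pct: np.ndarray
    loadings: pd.DataFrame          # metal × component correlations
    contributions_pct: pd.DataFrame
    cos2: pd.DataFrame
    site_scores: pd.DataFrame
    eigenvectors: pd.DataFrame      # unit-norm directions in z-space

    @property
    def n_metals(self) -> int:
        return self.loadings.shape[0]

    @property
    def expected_average_contribution(self) -> float:
        """Reference line for contribution plots: 100 / number of metals."""
        return 100.0 / self.n_metals


def pca(data, zone: str | None = None) -> PcaResult:
    """Correlation PCA of a concentration matrix (optionally one zone of it)."""
    if isinstance(data, ConcentrationMatrix):
        df = data.zone_data(zone)
    else:
        df = pd.DataFrame(data)
    if df.shape[0] < 3:
        raise ValidationError("PCA needs at least 3 sites")
    sd = df.std(axis=0, ddof=1)
    constant = sd.index[sd == 0]
    if len(constant):
        raise ValidationError(f"metal {constant[0]!r} is constant; correlation undefined")
    Z = (df - df.mean(axis=0)) / sd
    R = np.corrcoef(df.to_numpy(dtype=float), rowvar=False)
    R = np.atleast_2d(R)
    w, V = np.linalg.eigh(R)
    order = np.argsort(w)[::-1]
    w, V = np.clip(w[order], 0.0, None), V[:, order]
    # sign convention: largest-|loading| entry of each component is positive
    for c in range(V.shape[1]):
        i = int(np.argmax(np.abs(V[:, c])))
        if V[i, c] < 0:
            V[:, c] = -V[:, c]
    comp = [f"PC{i + 1}" for i in range(len(w))]
    metals = df.columns
    loadings = pd.DataFrame(V * np.sqrt(w), index=metals, columns=comp)
    with np.errstate(invalid="ignore", divide="ignore"):
        contrib = pd.DataFrame(100.0 * V**2, index=metals, columns=comp)
    cos2 = loadings**2
    scores = pd.DataFrame(Z.to_numpy(dtype=float) @ V, index=df.index, columns=comp)
    explained = 100.0 * w / len(w)
    return PcaResult(
        eigenvalues=w,
        explained_pct=explained,
        cumulative_pct=np.cumsum(explained),
        loadings=loadings,
        contributions_pct=contrib,
        cos2=cos2,
        site_scores=scores,
        eigenvectors=pd.DataFrame(V, index=metals, columns=comp),
    )


@dataclass
class ComponentSelection:
    kaiser_count: int
    variance_count: int
    chosen: int
    variance_threshold: float


def select_components(result: PcaResult, variance_threshold: float = 0.8) -> ComponentSelection:
    """Component counts under the Kaiser and cumulative-variance rules.

    The operative choice is the Kaiser count, extended until the cumulative
    explained variance reaches the threshold; if no eigenvalue exceeds 1,
    the variance rule alone applies.
    """
    kaiser = int((result.eigenvalues > 1.0).sum())
    cum = result.cumulative_pct / 100.0
    variance_count = int(np.searchsorted(cum, variance_threshold - 1e-12) + 1)
    variance_count = min(variance_count, len(cum))
    chosen = variance_count if kaiser == 0 else max(kaiser, variance_count)
    return ComponentSelection(kaiser, variance_count, chosen, variance_threshold)


def contributions(result: PcaResult, dims: Sequence[int]) -> pd.Series:
    """Eigenvalue-weighted average contribution (%) of each metal to a set
    of components (``dims`` are 1-based component numbers)."""
    cols = [f"PC{d}" for d in dims]
    lam = np.array([result.eigenvalues[d - 1] for d in dims])
    weighted = (result.contributions_pct[cols] * lam).sum(axis=1) / lam.sum()
    weighted.name = "contribution_pct"
    return weighted


def compare_zones(
    index_tables: Mapping[str, Mapping[str, IndexTable]],
) -> pd.DataFrame:
    """Kruskal–Wallis comparison of pollution-indicator series between zones.

    ``index_tables`` maps an indicator label (e.g. ``"Igeo"``, ``"EF_Mn"``)
    to one IndexTable per zone; each table's values are pooled into one
    sample per zone and compared by rank. Returns a per-indicator table of
    the H statistic and p-value; fully tied data yield H = 0, p = 1 by
    convention.
    """
    rows = {}
    for name, by_zone in index_tables.items():
        groups = []
        for tab in by_zone.values():
            vals = tab.values.to_numpy(dtype=float).ravel()
            vals = vals[np.isfinite(vals)]
            if len(vals) < 2:
                raise ValidationError(
                    f"indicator {name!r}: every zone needs at least 2 values"
                )
            groups.append(vals)
        if len(groups) < 2:
            raise ValidationError(f"indicator {name!r}: need at least 2 zones")
        pooled = np.concatenate(groups)
        if np.all(pooled == pooled[0]):
            rows[name] = {"H": 0.0, "p": 1.0}
        else:
            h, p = stats.kruskal(*groups)
            rows[name] = {"H": float(h), "p": float(p)}
    return pd.DataFrame.from_dict(rows, orient="index")
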