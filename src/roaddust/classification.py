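"""Ordinal pollution-class schemes for the individual and composite indices.

Every scheme is a partition of the real line into left-closed, right-open
intervals ``[b_i, b_{i+1})`` with the topmost class closed below only
(value >= last breakpoint), so classification is exhaustive and exclusive
for every finite value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ClassificationScheme", "SCHEMES", "classify", "classify_pli"]


@dataclass(frozen=True)
class ClassificationScheme:
    index_name: str
    breakpoints: tuple[float, ...]  # strictly increasing interior breakpoints
    labels: tuple[str, ...]         # len(labels) == len(breakpoints) + 1

    def __post_init__(self) -> None:
        if any(nxt <= prev for prev, nxt in zip(self.breakpoints, self.breakpoints[1:])):
            raise ValueError("breakpoints must be strictly increasing")
        if len(self.labels) != len(self.breakpoints) + 1:
            raise ValueError("need one label per interval")

    def classify(self, values):
        """Map finite values to class labels (vectorised)."""
        arr = np.asarray(values, dtype=float)
        idx = np.digitize(arr, self.breakpoints, right=False)
        labels = np.asarray(self.labels, dtype=object)
        out = labels[idx]
        if isinstance(values, pd.DataFrame):
            return pd.DataFrame(out, index=values.index, columns=values.columns)
        if isinstance(values, pd.Series):
            return pd.Series(out, index=values.index)
        return out

    def scaled(self, factor: float, index_name: str | None = None) -> "ClassificationScheme":
        """Same labels with all breakpoints multiplied by ``factor``.

        Used for the degree of contamination, whose class boundaries are the
        contamination-factor boundaries multiplied by the number of metals.
        """
        return ClassificationScheme(
            index_name or self.index_name,
            tuple(b * factor for b in self.breakpoints),
            self.labels,
        )


SCHEMES: dict[str, ClassificationScheme] = {
    # Geo-accumulation index: seven classes.
    "Igeo": ClassificationScheme(
        "Igeo",
        (0.0, 1.0, 2.0, 3.0, 4.0, 5.0),
        (
            "unpolluted",
            "unpolluted to moderately polluted",
            "moderately polluted",
            "moderately to strongly polluted",
            "strongly polluted",
            "strongly to extremely polluted",
            "extremely polluted",
        ),
    ),
    # Pollution index: <1 none; [1,2) low; [2,3) moderate; [3,5) strong; >=5 very accentuated.
    "PI": ClassificationScheme(
        "PI",
        (1.0, 2.0, 3.0, 5.0),
        ("none", "low", "moderate", "strong", "very accentuated"),
    ),
    # Enrichment factor.
    "EF": ClassificationScheme(
        "EF",
        (2.0, 5.0, 20.0, 40.0),
        ("deficient to minimal", "moderate", "significant", "very high", "extremely high"),
    ),
    # Håkanson contamination factor; the same breakpoints classify mCD, and
    # scaled by the number of metals they classify CD.
    "CF": ClassificationScheme(
        "CF",
        (1.0, 3.0, 6.0),
        ("low", "moderate", "high", "very high"),
    ),
    # Nemerow index; CPI reuses these intervals.
    "PI_Nem": ClassificationScheme(
        "PI_Nem",
        (0.7, 1.0, 2.0, 3.0),
        ("no pollution", "warning", "slight pollution", "moderate pollution", "heavy pollution"),
    ),
}
SCHEMES["mCD"] = SCHEMES["CF"].scaled(1.0, "mCD")
SCHEMES["CPI"] = ClassificationScheme("CPI", SCHEMES["PI_Nem"].breakpoints, SCHEMES["PI_Nem"].labels)


def classify(index_name: str, values):
    return SCHEMES[index_name].classify(values)


def classify_pli(values: pd.Series, tol: float = 1e-9) -> pd.Series:
    """PLI verdicts: <1 'perfection', =1 (within ``tol``) 'baseline', >1 'contamination'."""
    arr = np.asarray(values, dtype=float)
    out = np.where(
        np.abs(arr - 1.0) <= tol, "baseline",
        np.where(arr < 1.0, "perfection", "contamination"),
    )
    return pd.Series(out, index=values.index, dtype=object)
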