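"""Published per-zone summary concentrations used as reference inputs.

Zone-mean metal concentrations (mg/kg) of a 29-site UAE road-dust survey:
15 sites in mountainous-coastal Khor Fakkan ("KF") and 14 in urban-coastal
Dubai ("D"). Only the means are carried here; they are sufficient inputs for
the zone-level contamination-factor path (CF, CD, mCD) and for worked
examples. Per-site raw data for that survey are not public, so site-level
workflows are demonstrated on synthetic matrices instead.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["KHOR_FAKKAN_MEAN", "DUBAI_MEAN", "survey_zone_means"]

#: Zone-mean concentrations, mg/kg, Khor Fakkan (15 sites).
KHOR_FAKKAN_MEAN: dict[str, float] = {
    "Cd": 33.219, "Cr": 104.14, "Cu": 59.970, "Ni": 1325.4, "Pb": 103.9,
    "Co": 33.192, "Ba": 57.679, "Fe": 17051.0, "Mn": 233.667, "Zn": 712.86,
}

#: Zone-mean concentrations, mg/kg, Dubai (14 sites).
DUBAI_MEAN: dict[str, float] = {
    "Cd": 25.885, "Cr": 89.152, "Cu": 62.682, "Ni": 201.34, "Pb": 33.748,
    "Co": 28.767, "Ba": 94.57, "Fe": 10915.0, "Mn": 197.313, "Zn": 313.39,
}


def survey_zone_means() -> pd.DataFrame:
    """Zone × metal table of the published survey means (mg/kg)."""
    return pd.DataFrame(
        [KHOR_FAKKAN_MEAN, DUBAI_MEAN], index=["Khor Fakkan", "Dubai"]
    )
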