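"""Published cohort composition of the three trio ASD cohorts.

Counts of probands, unaffected siblings, and parents per cohort and
sequencing platform, together with disruptive-DNV carrier counts among
probands (dnPTV: LOEUF < 0.37; dnMIS: MPC >= 2; non-carrier: neither).
These counts are inputs for composition arithmetic — carrier percentages
and participant conservation — not outputs of this package.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

_ROWS = [
    # cohort, platform, probands, siblings, parents, families, dnptv, dnmis, noncarrier
    ("Korean", "WES", 61, 67, 122, 61, 2, 4, 55),
    ("Korean", "WGS", 693, 216, 1346, 673, 26, 26, 641),
    ("Korean", "WES+WGS", 754, 283, 1468, 734, 28, 30, 696),
    ("SPARK", "WES", 17420, 6757, 30534, 15267, 606, 457, 16357),
    ("SPARK", "WGS", 3496, 2187, 6704, 3352, 156, 154, 3186),
    ("SPARK", "WES+WGS", 20916, 8944, 37238, 18619, 762, 611, 19543),
    ("SSC", "WGS", 2380, 1938, 4764, 2382, 141, 110, 2129),
    ("Total", "All", 24050, 11165, 43470, 21735, 931, 751, 22368),
]

COHORT_COMPOSITION = pd.DataFrame(
    _ROWS, columns=["cohort", "platform", "probands", "siblings", "parents",
                    "families", "dnptv", "dnmis", "noncarrier"])


def carrier_percentages(composition: pd.DataFrame | None = None) -> pd.DataFrame:
    """Carrier composition percentages recomputed from the raw counts."""
    comp = (composition if composition is not None else COHORT_COMPOSITION).copy()
    for col in ["dnptv", "dnmis", "noncarrier"]:
        comp[f"{col}_pct"] = 100.0 * comp[col] / comp["probands"]
    comp["dndis_pct"] = 100.0 * (comp["dnptv"] + comp["dnmis"]) / comp["probands"]
    return comp


def participant_total(composition: pd.DataFrame | None = None,
                      row: str = "Total") -> int:
    """Sum of proband, sibling, and parent counts for one composition row."""
    comp = composition if composition is not None else COHORT_COMPOSITION
    sel = comp[comp["cohort"] == row].iloc[0]
    return int(sel["probands"] + sel["siblings"] + sel["parents"])


def round_half_up(x: float, decimals: int = 2) -> float:
    """Display rounding used in composition tables (half away from zero)."""
    factor = 10.0 ** decimals
    return float(np.floor(np.abs(x) * factor + 0.5) / factor * np.sign(x))
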