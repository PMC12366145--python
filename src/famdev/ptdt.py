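"""Polygenic transmission disequilibrium test (pTDT).

Each proband's polygenic score is compared with the mid-parental mean; the
distribution of deviations is tested against zero with a one-sample t-test,
and carrier groups are compared with Welch two-sample t-tests.  Deviations
are reported both raw and standardized by the SD of the mid-parental score
distribution (the field-standard pTDT normalization).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st

from .cohort import FamilyCohort

PTDT_COLUMNS = ["family_id", "proband_id", "score_name", "proband_ps",
                "midparent_ps", "deviation", "deviation_std"]


def compute_ptdt(cohort: FamilyCohort, score_name: str) -> pd.DataFrame:
    """One pTDT record per proband whose parents both have the score.

    Probands with an unscored parent are excluded (logged implicitly by
    their absence).  ``deviation_std`` divides by the sample SD of the
    mid-parental distribution over the included families.
    """
    ps = cohort.polygenic_scores
    sel = ps[ps["score_name"] == score_name]
    values = dict(zip(sel["individual_id"], sel["value"].astype(float)))
    rows = []
    for fam in cohort.families.values():
        if fam.proband_id is None or fam.proband_id not in values:
            continue
        members = cohort.members(fam.family_id)
        parents = members[members["role"].isin(["mother", "father"])]
        pvals = [values[i] for i in parents["individual_id"] if i in values]
        if len(pvals) != 2:
            continue
        mid = float(np.mean(pvals))
        rows.append((fam.family_id, fam.proband_id, score_name,
                     values[fam.proband_id], mid, values[fam.proband_id] - mid))
    df = pd.DataFrame(rows, columns=PTDT_COLUMNS[:-1])
    if len(df) > 1 and df["midparent_ps"].std(ddof=1) > 0:
        df["deviation_std"] = df["deviation"] / df["midparent_ps"].std(ddof=1)
    else:
        df["deviation_std"] = np.nan
    return df


@dataclass
class PtdtTestResult:
    group: str
    n: int
    mean_deviation: float
    mean_deviation_std: float
    t_statistic: float
    p_value: float
    test: str  # 'one_sample_vs_zero' | 'two_sample_between_groups'
    degenerate: bool = False


def test_ptdt(records: pd.DataFrame,
              grouping: pd.Series | None = None,
              use_standardized: bool = True,
              compare: tuple[str, str] | None = None) -> list[PtdtTestResult]:
    """One-sample t vs zero per group, plus an optional Welch comparison.

    ``grouping`` maps proband_id -> group label (None tests everyone as one
    group 'all').  ``compare`` names two groups for a Welch two-sample test
    on the deviations.  ``use_standardized`` selects which deviation column
    the t statistics are computed on; means for both are always reported.
    """
    df = records.copy()
    if grouping is not None:
        df["group"] = df["proband_id"].map(grouping)
        df = df.dropna(subset=["group"])
    else:
        df["group"] = "all"
    col = "deviation_std" if use_standardized else "deviation"
    results: list[PtdtTestResult] = []
    for g, grp in df.groupby("group", sort=False):
        x = grp[col].to_numpy(dtype=float)
        if len(x) < 2:
            raise ValueError(f"group {g!r} needs n >= 2 for a t-test, has {len(x)}")
        degenerate = float(np.std(x, ddof=1)) == 0.0
        if degenerate:
            t, p = (0.0, 1.0) if np.allclose(x, 0) else (np.nan, np.nan)
        else:
            t, p = st.ttest_1samp(x, 0.0)
        results.append(PtdtTestResult(str(g), len(x),
                                      float(grp["deviation"].mean()),
                                      float(grp["deviation_std"].mean()),
                                      float(t), float(p),
                                      "one_sample_vs_zero", degenerate))
    if compare is not None:
        g1, g2 = compare
        x1 = df.loc[df["group"] == g1, col].to_numpy(dtype=float)
        x2 = df.loc[df["group"] == g2, col].to_numpy(dtype=float)
        if len(x1) < 2 or len(x2) < 2:
            raise ValueError(f"both groups in {compare} need n >= 2")
        t, p = st.ttest_ind(x1, x2, equal_var=False)
        results.append(PtdtTestResult(f"{g1} vs {g2}", len(x1) + len(x2),
                                      float(np.mean(x1) - np.mean(x2)),
                                      float(np.mean(x1) - np.mean(x2)),
                                      float(t), float(p),
                                      "two_sample_between_groups"))
    return results
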