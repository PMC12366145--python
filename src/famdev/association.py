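"""Severe-phenotype classification and disruptive-DNV association.

Two interchangeable definitions of a severe social-impairment profile are
supported: raw SRS T-score >= 76 (2.6 population SDs above the T-score mean
of 50) and within-family deviation >= 2.6 WFSD.  Association of disruptive
DNV carriage with severity uses Fisher's exact test; gene discovery lists
genes whose disruptive DNVs occur in severe probands under each definition;
gene-set overlap enrichment replaces database-backed pathway lookups with a
one-sided Fisher test on user-supplied sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class ThresholdConfig:
    """Severity and intellectual-functioning cutoffs.

    ``severe_raw_srs`` and ``severe_wfsd`` are two expressions of the same
    2.6-SD criterion (50 + 2.6 x 10 = 76); :meth:`check_consistency`
    verifies the arithmetic against a supplied population mean/SD.
    """
    severe_raw_srs: float = 76.0
    severe_wfsd: float = 2.6
    better_than_expected_wfsd: float = 2.0
    id_cut: float = 70.0
    high_cut: float = 100.0

    def check_consistency(self, population_mean: float, population_sd: float) -> bool:
        return np.isclose(population_mean + self.severe_wfsd * population_sd,
                          self.severe_raw_srs)


def classify_srs_severity(srs_t: float) -> str:
    """SRS T-score bands: <60 normative, 60-75 mild/moderate, >75 severe."""
    if not np.isfinite(srs_t):
        raise ValueError("SRS T-score must be finite")
    if srs_t < 60:
        return "normative"
    if srs_t <= 75:
        return "mild_moderate"
    return "severe"


def classify_intellectual_functioning(fsiq: float | None, nviq: float | None,
                                      vabs_total: float | None,
                                      config: ThresholdConfig = ThresholdConfig()
                                      ) -> tuple[str, str]:
    """Hierarchical ID call: FSIQ, else non-verbal IQ, else VABS total.

    The first available measure decides: < 70 is ID, >= 100 is
    higher-than-average, otherwise neither.  Returns (class, basis).
    """
    for val, basis in ((fsiq, "FSIQ"), (nviq, "NVIQ"), (vabs_total, "VABS_total")):
        if val is not None and np.isfinite(val):
            if val < config.id_cut:
                return "ID", basis
            if val >= config.high_cut:
                return "higher_than_average", basis
            return "neither", basis
    return "unclassifiable", "none"


def flag_severe(score: float, score_type: str,
                config: ThresholdConfig = ThresholdConfig()) -> bool:
    """Severe-profile flag under the raw or WFSD definition (inclusive >=)."""
    if score_type == "raw":
        return bool(score >= config.severe_raw_srs)
    if score_type == "wfsd":
        return bool(score >= config.severe_wfsd)
    raise ValueError(f"score_type must be 'raw' or 'wfsd', got {score_type!r}")


def flag_better_than_expected(wfsd: float,
                              config: ThresholdConfig = ThresholdConfig()) -> bool:
    return bool(wfsd < config.better_than_expected_wfsd)


@dataclass
class AssociationResult:
    definition: str
    table: np.ndarray  # [[severe&carrier, severe&non], [nonsevere&carrier, nonsevere&non]]
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    degenerate: bool = False


def fisher_association(severe: pd.Series | np.ndarray,
                       carrier: pd.Series | np.ndarray,
                       definition: str = "wfsd") -> AssociationResult:
    """Fisher's exact association between severity and dnDIS carriage.

    The odds ratio is the sample cross-product ad/bc with a Haldane 0.5
    continuity correction when any cell is zero; the 95% CI uses the Woolf
    normal approximation on the log odds ratio.  The p-value is the
    two-sided Fisher exact probability.
    """
    s = np.asarray(severe, dtype=bool)
    c = np.asarray(carrier, dtype=bool)
    if s.shape != c.shape:
        raise ValueError("flag vectors must align")
    a = int(np.sum(s & c))
    b = int(np.sum(s & ~c))
    cc = int(np.sum(~s & c))
    d = int(np.sum(~s & ~c))
    table = np.array([[a, b], [cc, d]])
    degenerate = (a + b == 0) or (cc + d == 0) or (a + cc == 0) or (b + d == 0)
    _, p = st.fisher_exact(table, alternative="two-sided")
    if min(a, b, cc, d) == 0:
        ah, bh, ch, dh = a + 0.5, b + 0.5, cc + 0.5, d + 0.5
    else:
        ah, bh, ch, dh = a, b, cc, d
    or_ = (ah * dh) / (bh * ch)
    se_log = np.sqrt(1 / ah + 1 / bh + 1 / ch + 1 / dh)
    ci_low = float(np.exp(np.log(or_) - 1.959963984540054 * se_log))
    ci_high = float(np.exp(np.log(or_) + 1.959963984540054 * se_log))
    return AssociationResult(definition, table, float(or_), ci_low, ci_high,
                             float(p), degenerate)


@dataclass
class GeneDiscoverySet:
    definition: str
    genes: dict[str, int]  # gene -> carrier count among severe probands
    unique_to_this: set[str] = field(default_factory=set)
    shared: set[str] = field(default_factory=set)


def discover_severe_genes(carrier_genes: pd.DataFrame,
                          severe_flags: pd.Series,
                          definition: str = "wfsd",
                          min_carriers: int = 1) -> GeneDiscoverySet:
    """Genes with >= ``min_carriers`` disruptive DNVs among severe probands.

    ``carrier_genes`` has one row per qualifying (proband, gene) pair;
    ``severe_flags`` is indexed by proband id.  A proband carrying
    qualifying variants in several genes counts once for each.
    """
    severe_ids = set(severe_flags.index[severe_flags.astype(bool)])
    hits = carrier_genes[carrier_genes["individual_id"].isin(severe_ids)]
    counts = (hits.drop_duplicates(["individual_id", "gene"])
              .groupby("gene").size())
    genes = {g: int(n) for g, n in counts.items() if n >= min_carriers}
    return GeneDiscoverySet(definition, genes)


def compare_discovery(a: GeneDiscoverySet, b: GeneDiscoverySet) -> None:
    """Fill the unique/shared partition of two discovery sets in place."""
    ga, gb = set(a.genes), set(b.genes)
    a.shared = b.shared = ga & gb
    a.unique_to_this = ga - gb
    b.unique_to_this = gb - ga


def expressivity_profile(carrier_classes: pd.DataFrame) -> pd.DataFrame:
    """Proportions of ID / higher-than-average and SRS bands among carriers.

    ``carrier_classes`` has columns ``id_class`` and ``srs_class``; rows
    with ``id_class == 'unclassifiable'`` are dropped from the ID
    denominator, rows with missing ``srs_class`` from the severity
    denominator.
    """
    out = []
    idc = carrier_classes["id_class"]
    denom = int((idc != "unclassifiable").sum())
    for cls in ["ID", "higher_than_average", "neither"]:
        out.append({"axis": "intellectual", "class": cls,
                    "n": int((idc == cls).sum()), "denominator": denom,
                    "proportion": (idc == cls).sum() / denom if denom else np.nan})
    src = carrier_classes["srs_class"].dropna()
    denom_s = int(len(src))
    for cls in ["normative", "mild_moderate", "severe"]:
        out.append({"axis": "srs_severity", "class": cls,
                    "n": int((src == cls).sum()), "denominator": denom_s,
                    "proportion": (src == cls).sum() / denom_s if denom_s else np.nan})
    table = pd.DataFrame(out)
    return table[table["denominator"] > 0].reset_index(drop=True)


@dataclass
class OverlapEnrichment:
    query_name: str
    target_name: str
    universe_size: int
    query_size: int
    target_size: int
    overlap: int
    log_odds_ratio: float
    p_value: float
    fdr: float = float("nan")


def geneset_overlap(query: set[str], targets: dict[str, set[str]],
                    universe: set[str],
                    query_name: str = "query") -> list[OverlapEnrichment]:
    """One-sided Fisher overlap enrichment of a query set against targets.

    All sets are intersected with the universe.  The log odds ratio uses a
    Haldane 0.5 correction on zero cells; FDR is Benjamini-Hochberg across
    the supplied target collection.
    """
    if not universe:
        raise ValueError("universe must be nonempty")
    q = query & universe
    results = []
    for name, tset in targets.items():
        t = tset & universe
        a = len(q & t)
        b = len(q - t)
        c = len(t - q)
        d = len(universe) - a - b - c
        _, p = st.fisher_exact([[a, b], [c, d]], alternative="greater")
        if min(a, b, c, d) == 0:
            lor = np.log(((a + .5) * (d + .5)) / ((b + .5) * (c + .5)))
            if a == 0:
                # zero observed overlap is never evidence of enrichment;
                # the Haldane estimate can spuriously exceed 0 for large d
                lor = min(lor, 0.0)
        else:
            lor = np.log((a * d) / (b * c))
        results.append(OverlapEnrichment(query_name, name, len(universe),
                                         len(q), len(t), a, float(lor), float(p)))
    if results:
        _, fdrs, _, _ = multipletests([r.p_value for r in results], method="fdr_bh")
        for r, f in zip(results, fdrs):
            r.fdr = float(f)
    return results
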