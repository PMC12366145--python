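"""De novo variant QC, consequence classification, and disruptiveness calls.

The QC engine applies per-cohort, per-variant-class threshold rules (the
rule sets used by the Korean WGS/WES, SSC, and SPARK call sets are shipped
as built-ins), a population allele-frequency filter, an internal
allele-count cap, and a per-sample DNV-count outlier exclusion.  Downstream,
protein-truncating variants in constrained genes (LOEUF < 0.37) and missense
variants with MPC >= 2 are called "disruptive" (dnPTV / dnMIS), and each
proband is assigned to exactly one genetic subgroup.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PTV_TERMS = frozenset({"frameshift_variant", "splice_acceptor_variant",
                       "splice_donor_variant", "stop_gained"})
MIS_TERMS = frozenset({"missense_variant", "inframe_deletion", "inframe_insertion",
                       "protein_altering_variant", "start_lost", "stop_lost"})
SYN_TERMS = frozenset({"synonymous_variant", "stop_retained_variant",
                       "start_retained_variant"})

#: gnomAD non-neuro AF ceiling: 0.01%
DEFAULT_AF_MAX = 1e-4


class QcConfigError(ValueError):
    """Unknown metric or malformed rule set."""


@dataclass(frozen=True)
class DisruptivenessThresholds:
    """Constraint cutoffs for disruptive DNV calls.

    ``loeuf_max`` is strict (<); ``mpc_min`` is inclusive (>=).
    """
    loeuf_max: float = 0.37
    mpc_min: float = 2.0

    def __post_init__(self):
        if self.loeuf_max <= 0 or self.mpc_min <= 0:
            raise QcConfigError("disruptiveness thresholds must be positive")


# comparators: (op, value) with op in {'ge','le','lt','gt','within'}
_OPS = {
    "ge": lambda x, v: x >= v,
    "le": lambda x, v: x <= v,
    "lt": lambda x, v: x < v,
    "gt": lambda x, v: x > v,
    "within": lambda x, v: (x >= v[0]) & (x <= v[1]),
}


@dataclass
class QcRuleSet:
    """Per-variant-class QC thresholds for one cohort's call set.

    ``rules`` maps variant class ('SNV'/'indel') to an ordered mapping of
    metric name -> (comparator, value).  ``max_internal_ac`` caps the
    internal allele count; ``sample_count_outlier_k`` is the multiplier on
    the robust SD (1.4826 x MAD) of per-sample DNV counts beyond which a
    sample's variants are excluded (None disables the step).
    """
    name: str
    rules: dict[str, dict[str, tuple[str, object]]] = field(default_factory=dict)
    max_internal_ac: int | None = None
    sample_count_outlier_k: float | None = None
    mad_scale: float = 1.4826  # normal-consistency constant for the robust SD
    strict_missing: bool = False  # True: missing metric fails the rule

    def __post_init__(self):
        for cls_rules in self.rules.values():
            for metric, (op, _) in cls_rules.items():
                if op not in _OPS:
                    raise QcConfigError(f"unknown comparator {op!r} for {metric}")


BUILTIN_RULE_SETS: dict[str, QcRuleSet] = {
    "korean_wgs": QcRuleSet(
        name="korean_wgs",
        rules={
            "SNV": {"QUAL": ("ge", 7.5), "GQmean": ("ge", 36.0),
                    "DPmean": ("ge", 34.0), "AB": ("within", (0.275, 0.725))},
            "indel": {"QUAL": ("ge", 10.51), "gDP": ("ge", 3.0),
                      "AB": ("within", (0.214, 0.786))},
        },
        max_internal_ac=4,  # retained when present in fewer than five individuals
    ),
    "korean_wes": QcRuleSet(
        name="korean_wes",
        rules={
            "SNV": {"QUAL": ("ge", 135.58), "GQmean": ("ge", 76.0),
                    "AB": ("within", (0.23, 0.77)), "gDP": ("ge", 10.0)},
            "indel": {"QUAL": ("ge", 115.8), "QD": ("ge", 6.64),
                      "MQ": ("ge", 32.15), "SOR": ("le", 2.35),
                      "gDP": ("ge", 13.0), "AB": ("within", (0.17, 0.83))},
        },
        max_internal_ac=1,  # retained when present in fewer than two individuals
    ),
    "ssc_wgs": QcRuleSet(
        name="ssc_wgs",
        rules={"SNV": {}, "indel": {}},  # upstream confidence flags assumed applied
        max_internal_ac=1,
        sample_count_outlier_k=9.0,
    ),
    "spark": QcRuleSet(
        name="spark",
        rules={"SNV": {"AB": ("lt", 0.8)}, "indel": {"AB": ("lt", 0.8)}},
        max_internal_ac=1,
        sample_count_outlier_k=9.0,
    ),
}


def _apply_rule(values: pd.Series, op: str, threshold) -> pd.Series:
    return _OPS[op](values, threshold)


def apply_qc(variants: pd.DataFrame, rules: QcRuleSet,
             af_max: float = DEFAULT_AF_MAX) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Filter a variant table through one QC rule set.

    Returns ``(passed, audit)``.  The audit trail has one row per input
    variant with the first failed rule (or 'pass') and notes for rules
    skipped because the metric was missing.  Order of application: AF
    filter, per-class metric rules, internal AC cap, then per-sample
    DNV-count outlier exclusion (which removes the sample's variants, not
    its phenotypes).
    """
    v = variants.reset_index(drop=True)
    n = len(v)
    first_fail = np.array(["pass"] * n, dtype=object)
    notes = np.array([""] * n, dtype=object)
    alive = np.ones(n, dtype=bool)

    known_metrics = set(v.columns)
    for cls_rules in rules.rules.values():
        unknown = set(cls_rules) - known_metrics
        if unknown:
            raise QcConfigError(f"rule metrics absent from variant table: {sorted(unknown)}")

    # population allele frequency; absent AF is treated as novel (passes)
    if "gnomad_af" in v.columns:
        af = v["gnomad_af"]
        fail_af = (af.notna() & (af >= af_max)).to_numpy()
        first_fail[alive & fail_af] = "gnomad_af"
        alive &= ~fail_af

    vclass = v.get("variant_class", pd.Series(["SNV"] * n)).fillna("SNV")
    for cls, cls_rules in rules.rules.items():
        in_cls = (vclass == cls).to_numpy()
        for metric, (op, threshold) in cls_rules.items():
            vals = v[metric]
            missing = vals.isna().to_numpy() & in_cls
            if missing.any():
                if rules.strict_missing:
                    sel = alive & missing
                    first_fail[sel] = f"{metric}:missing"
                    alive &= ~missing
                else:
                    for i in np.nonzero(missing & alive)[0]:
                        notes[i] += f"skipped {metric} (missing);"
            ok = _apply_rule(vals, op, threshold).fillna(not rules.strict_missing)
            fail = (~ok).to_numpy() & in_cls & ~missing
            sel = alive & fail
            first_fail[sel] = metric
            alive &= ~fail

    if rules.max_internal_ac is not None and "internal_ac" in v.columns:
        ac = v["internal_ac"]
        fail_ac = (ac.notna() & (ac > rules.max_internal_ac)).to_numpy()
        sel = alive & fail_ac
        first_fail[sel] = "internal_ac"
        alive &= ~fail_ac

    # per-sample DNV-count outlier exclusion, applied last on surviving calls
    if rules.sample_count_outlier_k is not None and alive.any():
        counts = v.loc[alive, "individual_id"].value_counts()
        med = float(counts.median())
        mad = float((counts - med).abs().median())
        cutoff = med + rules.sample_count_outlier_k * rules.mad_scale * mad
        outlier_samples = set(counts.index[counts > cutoff])
        if outlier_samples:
            is_out = v["individual_id"].isin(outlier_samples).to_numpy()
            sel = alive & is_out
            first_fail[sel] = "sample_dnv_count_outlier"
            for i in np.nonzero(sel)[0]:
                notes[i] += f"sample count cutoff {cutoff:.3g};"
            alive &= ~is_out

    audit = pd.DataFrame({
        "individual_id": v["individual_id"],
        "gene": v.get("gene", pd.Series([""] * n)),
        "first_failed_rule": first_fail,
        "notes": notes,
    })
    return v[alive].reset_index(drop=True), audit


def classify_consequence(variants: pd.DataFrame,
                         loftee_waiver: bool = True) -> pd.DataFrame:
    """Derive the PTV/MIS/SYN/other consequence class from raw VEP terms.

    Truncating terms require LOFTEE high-confidence support; a missing
    LOFTEE flag is accepted with a waiver by default (``loftee_waiver``),
    while an explicit low-confidence flag demotes the call to ``other``.
    """
    v = variants.copy()
    term = v["raw_consequence_term"].fillna("")
    cons = np.full(len(v), "other", dtype=object)
    is_ptv_term = term.isin(PTV_TERMS).to_numpy()
    hc = v.get("loftee_hc", pd.Series([np.nan] * len(v)))
    hc_ok = (hc == True).to_numpy() | (hc.isna().to_numpy() if loftee_waiver  # noqa: E712
             else np.zeros(len(v), dtype=bool))
    cons[is_ptv_term & hc_ok] = "PTV"
    cons[term.isin(MIS_TERMS).to_numpy()] = "MIS"
    cons[term.isin(SYN_TERMS).to_numpy()] = "SYN"
    v["consequence"] = cons
    return v


def is_disruptive(variants: pd.DataFrame,
                  thresholds: DisruptivenessThresholds = DisruptivenessThresholds()
                  ) -> pd.Series:
    """Tag each classified variant as 'dnPTV', 'dnMIS', or 'none'.

    PTVs qualify with LOEUF strictly below ``loeuf_max``; missense variants
    with MPC at or above ``mpc_min``.  A missing constraint score never
    qualifies.
    """
    tag = pd.Series(["none"] * len(variants), index=variants.index, dtype=object)
    loeuf = variants["loeuf"]
    mpc = variants["mpc"]
    tag[(variants["consequence"] == "PTV") & loeuf.notna()
        & (loeuf < thresholds.loeuf_max)] = "dnPTV"
    tag[(variants["consequence"] == "MIS") & mpc.notna()
        & (mpc >= thresholds.mpc_min)] = "dnMIS"
    return tag


@dataclass
class SubgroupCall:
    individual_id: str
    subgroup: str  # 'dnPTV_carrier' | 'dnMIS_carrier' | 'non_carrier'
    qualifying_variants: pd.DataFrame


def assign_subgroup(proband_id: str, variants: pd.DataFrame,
                    thresholds: DisruptivenessThresholds = DisruptivenessThresholds()
                    ) -> SubgroupCall:
    """Assign one proband to its genetic subgroup from its own DNVs.

    Precedence: any qualifying dnPTV makes the proband a dnPTV carrier even
    if a qualifying dnMIS is also present (strongest-class assignment); the
    three subgroups are mutually exclusive and exhaustive.
    """
    own = variants[variants["individual_id"] == proband_id]
    tags = is_disruptive(own, thresholds)
    qualifying = own[tags != "none"]
    if (tags == "dnPTV").any():
        sub = "dnPTV_carrier"
    elif (tags == "dnMIS").any():
        sub = "dnMIS_carrier"
    else:
        sub = "non_carrier"
    return SubgroupCall(proband_id, sub, qualifying)


def assign_subgroups(proband_ids, variants: pd.DataFrame,
                     thresholds: DisruptivenessThresholds = DisruptivenessThresholds()
                     ) -> pd.DataFrame:
    """Vectorized subgroup assignment for many probands.

    Returns a DataFrame with columns individual_id, subgroup.
    """
    tags = is_disruptive(variants, thresholds)
    ptv_carriers = set(variants.loc[tags == "dnPTV", "individual_id"])
    mis_carriers = set(variants.loc[tags == "dnMIS", "individual_id"])
    rows = []
    for pid in proband_ids:
        if pid in ptv_carriers:
            sub = "dnPTV_carrier"
        elif pid in mis_carriers:
            sub = "dnMIS_carrier"
        else:
            sub = "non_carrier"
        rows.append((pid, sub))
    return pd.DataFrame(rows, columns=["individual_id", "subgroup"])


def subgroup_percentages(subgroups: pd.DataFrame) -> pd.DataFrame:
    """Carrier composition report: count and percentage per subgroup."""
    total = len(subgroups)
    counts = (subgroups["subgroup"].value_counts()
              .reindex(["dnPTV_carrier", "dnMIS_carrier", "non_carrier"],
                       fill_value=0))
    out = pd.DataFrame({"subgroup": counts.index, "count": counts.to_numpy()})
    out["percent"] = 100.0 * out["count"] / total if total else np.nan
    return out
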