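"""Within-family standardized deviation (WFSD) of proband phenotypes.

WFSD = (proband score - mean score of unaffected reference relatives) /
population SD of the instrument.  Parents or unaffected siblings serve as
the reference class.  The module also provides dataset-derived SD
estimation for instruments without published norms, covariate-adjusted
subgroup contrasts, distribution diagnostics, and the two-dimensional
SRS x VABS neurodevelopmental shift profile.

Sign convention: WFSD keeps the raw direction (proband minus reference);
instruments where lower scores mean worse functioning (VABS, IQ) therefore
yield negative shifts for more affected probands, and downstream severity
logic is direction-aware.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
from statsmodels.stats.diagnostic import normal_ad

from .cohort import Family, FamilyCohort

#: Published population SDs where norms exist; dataset-derived values
#: (SCQ, ADOS) reproduce the scale of the study cohorts.
DEFAULT_NORMS: dict[str, tuple[float | None, float, str]] = {
    # instrument: (population mean or None, population SD, source)
    "SRS_T": (50.0, 10.0, "published_norm"),
    "VABS_total": (100.0, 15.0, "published_norm"),
    "VABS_comm": (100.0, 15.0, "published_norm"),
    "VABS_daily": (100.0, 15.0, "published_norm"),
    "VABS_social": (100.0, 15.0, "published_norm"),
    "VABS_motor": (100.0, 15.0, "published_norm"),
    "FSIQ": (100.0, 15.0, "published_norm"),
    "NVIQ": (100.0, 15.0, "published_norm"),
    "SCQ_lifetime": (None, 10.45, "dataset_derived"),
    "ADOS_total": (None, 2.17, "dataset_derived"),
    "ADOS_SA": (None, 2.13, "dataset_derived"),
    "ADOS_RRB": (None, 2.61, "dataset_derived"),
}


class NormsError(ValueError):
    pass


@dataclass
class PopulationNorms:
    """Instrument -> (population mean, SD, provenance) mapping."""

    norms: dict[str, tuple[float | None, float, str]] = field(
        default_factory=lambda: dict(DEFAULT_NORMS))

    def sd(self, instrument: str) -> float:
        if instrument not in self.norms:
            raise NormsError(f"no population SD configured for {instrument!r}")
        sd = self.norms[instrument][1]
        if not sd > 0:
            raise NormsError(f"population SD for {instrument!r} must be > 0")
        return float(sd)

    def mean(self, instrument: str) -> float | None:
        if instrument not in self.norms:
            return None
        return self.norms[instrument][0]

    def set(self, instrument: str, mean: float | None, sd: float,
            source: str = "dataset_derived") -> None:
        if not sd > 0:
            raise NormsError("population SD must be > 0")
        self.norms[instrument] = (mean, float(sd), source)


WFSD_COLUMNS = ["family_id", "proband_id", "instrument", "reference_class",
                "reference_n", "reference_mean", "wfsd", "pseudo_proband"]


def _scores_for(cohort: FamilyCohort, instrument: str) -> dict[str, float]:
    ph = cohort.phenotypes
    sel = ph[ph["instrument"] == instrument]
    return dict(zip(sel["individual_id"], sel["score"].astype(float)))


def resolve_reference(family: Family, individuals: pd.DataFrame,
                      scores: dict[str, float],
                      reference_class: str) -> tuple[float, int]:
    """Mean score and count of the unaffected reference members of one family.

    Parents mode averages the available unaffected parents with a score;
    siblings mode the unaffected siblings.  ``(nan, 0)`` means the family is
    excluded for this instrument (no scored reference member).
    """
    if reference_class not in ("parents", "siblings"):
        raise ValueError(f"reference_class must be 'parents' or 'siblings', "
                         f"got {reference_class!r}")
    members = individuals[individuals["family_id"] == family.family_id]
    if reference_class == "parents":
        ref = members[members["role"].isin(["mother", "father"]) & ~members["affected"]]
    else:
        ref = members[(members["role"] == "sibling") & ~members["affected"]]
    vals = [scores[i] for i in ref["individual_id"]
            if i in scores and math.isfinite(scores[i])]
    if not vals:
        return float("nan"), 0
    return float(np.mean(vals)), len(vals)


def compute_wfsd(cohort: FamilyCohort, instrument: str,
                 reference_class: str = "parents",
                 norms: PopulationNorms | None = None,
                 pseudo_probands: bool = False) -> pd.DataFrame:
    """One WFSD record per proband with a score and a nonempty reference.

    With ``pseudo_probands=True``, unaffected siblings are additionally
    scored against the parental reference (never against other siblings)
    and flagged; their deviations form the within-family null distribution.
    """
    norms = norms or PopulationNorms()
    sd = norms.sd(instrument)
    scores = _scores_for(cohort, instrument)
    rows = []
    for fam in cohort.families.values():
        ref_mean, ref_n = resolve_reference(
            fam, cohort.individuals, scores, reference_class)
        if ref_n == 0:
            continue
        targets: list[tuple[str, bool]] = []
        if fam.proband_id is not None:
            targets.append((fam.proband_id, False))
        if pseudo_probands and reference_class == "parents":
            members = cohort.members(fam.family_id)
            sibs = members[(members["role"] == "sibling") & ~members["affected"]]
            targets.extend((s, True) for s in sibs["individual_id"])
        for iid, pseudo in targets:
            if iid not in scores or not math.isfinite(scores[iid]):
                continue
            rows.append((fam.family_id, iid, instrument, reference_class,
                         ref_n, ref_mean, (scores[iid] - ref_mean) / sd, pseudo))
    return pd.DataFrame(rows, columns=WFSD_COLUMNS)


def estimate_dataset_sd(cohort: FamilyCohort, instrument: str,
                        pool: str = "all") -> float:
    """Sample SD (n-1 denominator) of an instrument over the cohort.

    Used where no published population norm exists.  ``pool`` selects the
    individuals entering the estimate: 'all' scored individuals (default),
    'probands', or 'relatives'.
    """
    ph = cohort.phenotypes
    sel = ph[ph["instrument"] == instrument].merge(
        cohort.individuals[["individual_id", "role"]], on="individual_id")
    if pool == "probands":
        sel = sel[sel["role"] == "proband"]
    elif pool == "relatives":
        sel = sel[sel["role"] != "proband"]
    elif pool != "all":
        raise ValueError(f"unknown pool {pool!r}")
    vals = sel["score"].dropna().to_numpy(dtype=float)
    if len(vals) < 2:
        raise NormsError(f"need >= 2 scored individuals to estimate SD for "
                         f"{instrument!r}, have {len(vals)}")
    sd = float(np.std(vals, ddof=1))
    if not sd > 0:
        raise NormsError(f"dataset SD for {instrument!r} is 0; not a valid norm")
    return sd


def subgroup_summary(wfsd_records: pd.DataFrame, subgroups: pd.DataFrame,
                     gene_set: set[str] | None = None,
                     carrier_genes: pd.DataFrame | None = None) -> pd.DataFrame:
    """Mean/SD/n of WFSD per genetic subgroup.

    With ``gene_set`` supplied, carriers are restricted to those whose
    qualifying variant falls in the set (``carrier_genes``: columns
    individual_id, gene); non-carriers are unaffected by the restriction.
    """
    rec = wfsd_records[~wfsd_records["pseudo_proband"]] if "pseudo_proband" in wfsd_records \
        else wfsd_records
    merged = rec.merge(subgroups, left_on="proband_id", right_on="individual_id")
    if gene_set is not None:
        if carrier_genes is None:
            raise ValueError("gene_set restriction requires carrier_genes")
        in_set = set(carrier_genes.loc[carrier_genes["gene"].isin(gene_set),
                                       "individual_id"])
        is_carrier = merged["subgroup"] != "non_carrier"
        merged = merged[~is_carrier | merged["proband_id"].isin(in_set)]
    out = []
    for sub in ["dnPTV_carrier", "dnMIS_carrier", "non_carrier"]:
        vals = merged.loc[merged["subgroup"] == sub, "wfsd"].to_numpy(dtype=float)
        out.append({
            "subgroup": sub,
            "n": len(vals),
            "mean_wfsd": float(np.mean(vals)) if len(vals) else np.nan,
            "sd_wfsd": float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan,
        })
    return pd.DataFrame(out)


@dataclass
class ContrastResult:
    phenotype: str
    score_type: str
    coefficients: pd.DataFrame  # term, estimate, se, p
    covariates: list[str]
    n_per_group: dict[str, int]


def adjusted_contrast(outcomes: pd.DataFrame, phenotype: str = "",
                      score_type: str = "wfsd",
                      covariates: tuple[str, ...] = ("age_years", "sex", "cohort")
                      ) -> ContrastResult:
    """Least-squares subgroup contrast with covariate adjustment.

    ``outcomes`` needs columns ``value``, ``subgroup``, and the requested
    covariates; rows with a missing covariate are dropped (complete-case).
    The model is identity-link least squares on subgroup indicators with
    non-carriers as baseline.  Perfectly collinear covariates are dropped
    with a warning by the underlying fit (pinv solver).
    """
    df = outcomes.dropna(subset=["value", "subgroup", *covariates]).copy()
    X = pd.DataFrame(index=df.index)
    for sub in ["dnPTV_carrier", "dnMIS_carrier"]:
        if (df["subgroup"] == sub).any():
            X[sub] = (df["subgroup"] == sub).astype(float)
    for cov in covariates:
        col = df[cov]
        if col.dtype.kind in "if":
            X[cov] = col.astype(float)
        else:
            dummies = pd.get_dummies(col, prefix=cov, drop_first=True, dtype=float)
            X = pd.concat([X, dummies], axis=1)
    X = sm.add_constant(X, has_constant="add")
    fit = sm.OLS(df["value"].astype(float), X).fit()
    coef = pd.DataFrame({
        "term": fit.params.index,
        "estimate": fit.params.to_numpy(),
        "se": fit.bse.to_numpy(),
        "p": fit.pvalues.to_numpy(),
    })
    n_per = df["subgroup"].value_counts().to_dict()
    return ContrastResult(phenotype, score_type, coef, list(covariates),
                          {k: int(v) for k, v in n_per.items()})


@dataclass
class NormalityReport:
    phenotype: str
    score_type: str
    n: int
    shapiro_w: float
    shapiro_p: float
    anderson_ad: float
    anderson_p: float
    ks: float
    ks_p: float


def normality_report(values, phenotype: str = "", score_type: str = "raw",
                     min_n: int = 8) -> NormalityReport:
    """Shapiro-Wilk, Anderson-Darling, and Kolmogorov-Smirnov diagnostics.

    The KS statistic is Lilliefors-style: the sample is standardized by its
    own mean/SD and compared against the standard normal.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < min_n:
        raise ValueError(f"normality tests need n >= {min_n}, have {len(x)}")
    if np.std(x) == 0:
        raise ValueError("degenerate (constant) sample")
    w, w_p = st.shapiro(x)
    ad, ad_p = normal_ad(x)
    z = (x - x.mean()) / x.std(ddof=1)
    ks, ks_p = st.kstest(z, "norm")
    return NormalityReport(phenotype, score_type, len(x),
                           float(w), float(w_p), float(ad), float(ad_p),
                           float(ks), float(ks_p))


@dataclass
class ProfileShift2D:
    label: str
    n_families: int
    mean_srs: float
    mean_vabs: float
    magnitude: float
    direction_deg: float


def _drop_pseudo(df: pd.DataFrame) -> pd.DataFrame:
    if "pseudo_proband" in df.columns:
        return df[~df["pseudo_proband"]]
    return df


def _joint_plane(wfsd_srs: pd.DataFrame, wfsd_vabs: pd.DataFrame) -> pd.DataFrame:
    a = _drop_pseudo(wfsd_srs)[["family_id", "wfsd"]].rename(columns={"wfsd": "srs"})
    b = _drop_pseudo(wfsd_vabs)[["family_id", "wfsd"]].rename(columns={"wfsd": "vabs"})
    return a.merge(b, on="family_id")


def profile_shift_2d(wfsd_srs: pd.DataFrame, wfsd_vabs: pd.DataFrame,
                     label: str = "all",
                     family_ids: set[str] | None = None) -> ProfileShift2D:
    """Mean shift of families in the SRS x VABS WFSD plane.

    Only families with both instruments' WFSD enter.  The magnitude is the
    Euclidean norm of the vector of per-axis means (norm-of-means); the
    direction is reported in degrees with +x = higher behavioral severity
    (SRS) and -y = lower adaptive ability (VABS).
    """
    joint = _joint_plane(wfsd_srs, wfsd_vabs)
    if family_ids is not None:
        joint = joint[joint["family_id"].isin(family_ids)]
    if joint.empty:
        return ProfileShift2D(label, 0, np.nan, np.nan, np.nan, np.nan)
    mx = float(joint["srs"].mean())
    my = float(joint["vabs"].mean())
    mag = float(math.hypot(mx, my))
    direction = float(math.degrees(math.atan2(my, mx)) % 360.0)
    return ProfileShift2D(label, len(joint), mx, my, mag, direction)


def profile_shift_mean_of_norms(wfsd_srs: pd.DataFrame, wfsd_vabs: pd.DataFrame,
                                family_ids: set[str] | None = None) -> float:
    """Companion aggregation: mean of per-family Euclidean norms.

    Reported alongside the norm-of-means magnitude because the two answer
    different questions (displacement of the centroid vs average
    displacement size) and diverge for dispersed clouds.
    """
    joint = _joint_plane(wfsd_srs, wfsd_vabs)
    if family_ids is not None:
        joint = joint[joint["family_id"].isin(family_ids)]
    if joint.empty:
        return float("nan")
    return float(np.hypot(joint["srs"], joint["vabs"]).mean())
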