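"""Family cohort model: pedigrees, phenotypes, variant annotations, polygenic scores.

Tables are tab-separated UTF-8 with a header row; missing values are encoded
as empty string or ``NA`` on read and written back as ``NA``.  A cohort is a
bundle of pandas DataFrames with enforced referential integrity plus a
per-family record of the designated analysis proband.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

ROLES = ("proband", "sibling", "mother", "father")
SEXES = ("male", "female", "unknown")

#: Instruments with first-class support.  Unknown instrument labels are
#: preserved on read (pass-through) so site-specific measures survive a
#: round-trip.
KNOWN_INSTRUMENTS = (
    "SRS_T", "SCQ_lifetime", "SCQ_current",
    "VABS_total", "VABS_comm", "VABS_daily", "VABS_social", "VABS_motor",
    "ADOS_total", "ADOS_SA", "ADOS_RRB",
    "FSIQ", "NVIQ", "DCDQ",
    "ADIR_A", "ADIR_B", "ADIR_C", "RBSR",
)

INDIVIDUAL_COLUMNS = ["individual_id", "family_id", "role", "sex", "affected",
                      "age_years", "cohort"]
PHENOTYPE_COLUMNS = ["individual_id", "instrument", "score"]
VARIANT_QC_METRICS = ["QUAL", "GQmean", "DPmean", "gDP", "AB", "QD", "MQ", "SOR"]
VARIANT_COLUMNS = (["individual_id", "gene", "raw_consequence_term", "consequence",
                    "loftee_hc", "loeuf", "mpc"] + VARIANT_QC_METRICS +
                   ["internal_ac", "gnomad_af", "aa_position", "variant_class"])
SCORE_COLUMNS = ["individual_id", "score_name", "value"]

_NA_STRINGS = ["", "NA"]


class CohortError(ValueError):
    """Raised for structural problems in cohort tables."""


@dataclass
class Family:
    """One family and its designated analysis proband.

    ``proband_id`` is the single affected child used in proband analyses.
    Multiplex families (more than one affected child) keep only the first
    affected child in file order; the rest are listed in
    ``excluded_affected`` and take part in no analysis, neither as probands
    nor as reference members.
    """

    family_id: str
    member_ids: list[str] = field(default_factory=list)
    proband_id: str | None = None
    excluded_affected: list[str] = field(default_factory=list)


@dataclass
class FamilyCohort:
    """Assembled cohort: individuals, families, phenotypes, variants, scores."""

    individuals: pd.DataFrame
    families: dict[str, Family]
    phenotypes: pd.DataFrame
    variants: pd.DataFrame
    polygenic_scores: pd.DataFrame
    gene_sets: dict[str, set[str]] = field(default_factory=dict)

    def counts(self) -> dict[str, int]:
        """Role counts plus total; probands here are designated analysis probands."""
        ind = self.individuals
        n_prob = sum(1 for f in self.families.values() if f.proband_id is not None)
        n_sib = int(((ind["role"] == "sibling") & (~ind["affected"])).sum())
        n_par = int(ind["role"].isin(["mother", "father"]).sum())
        return {
            "probands": n_prob,
            "siblings": n_sib,
            "parents": n_par,
            "individuals": int(len(ind)),
        }

    def members(self, family_id: str) -> pd.DataFrame:
        return self.individuals[self.individuals["family_id"] == family_id]

    def phenotype_of(self, individual_id: str, instrument: str) -> float:
        """Score for one individual/instrument, NaN when absent."""
        ph = self.phenotypes
        hit = ph[(ph["individual_id"] == individual_id) & (ph["instrument"] == instrument)]
        return float(hit["score"].iloc[0]) if len(hit) else float("nan")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _read_tsv(path, dtype=None) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", dtype=dtype, na_values=_NA_STRINGS,
                           keep_default_na=False, comment=None,
                           float_precision="round_trip")
    except pd.errors.EmptyDataError:
        return pd.DataFrame()


def read_pedigree(path, dialect: str = "extended_tsv") -> tuple[pd.DataFrame, dict[str, Family]]:
    """Read a pedigree as 6-column PED or extended TSV.

    Returns the individuals table and the family map.  Roles are inferred
    from parent pointers and affected flags when the dialect does not carry
    an explicit role column: an individual referenced as someone's father or
    mother takes that parental role; remaining individuals are children, and
    an affected child is a proband candidate.
    """
    if dialect not in ("ped6", "extended_tsv"):
        raise CohortError(f"unknown pedigree dialect: {dialect!r}")

    if dialect == "ped6":
        try:
            raw = pd.read_csv(path, sep=r"\s+", header=None, comment="#",
                              names=["family_id", "individual_id", "father_id",
                                     "mother_id", "sex", "phenotype"],
                              dtype=str)
        except pd.errors.EmptyDataError:
            raw = pd.DataFrame()
        if raw.empty:
            return _empty_individuals(), {}
        raw["affected"] = raw["phenotype"].astype(str) == "2"
        raw["sex"] = raw["sex"].map({"1": "male", "2": "female"}).fillna("unknown")
        raw["age_years"] = np.nan
        raw["cohort"] = "unknown"
        raw["role"] = pd.NA
    else:
        raw = _read_tsv(path, dtype=str)
        if raw.empty:
            return _empty_individuals(), {}
        required = {"family_id", "individual_id", "father_id", "mother_id",
                    "sex", "affected"}
        missing = required - set(raw.columns)
        if missing:
            raise CohortError(f"pedigree missing columns: {sorted(missing)}")
        raw["affected"] = raw["affected"].astype(str).str.lower().isin(
            ["1", "2", "true", "yes"])
        raw["sex"] = raw["sex"].replace({"1": "male", "2": "female"})
        raw.loc[~raw["sex"].isin(SEXES), "sex"] = "unknown"
        if "age_years" not in raw.columns:
            raw["age_years"] = np.nan
        if "cohort" not in raw.columns:
            raw["cohort"] = "unknown"
        if "role" not in raw.columns:
            raw["role"] = pd.NA

    dup = raw["individual_id"][raw["individual_id"].duplicated()]
    if len(dup):
        raise CohortError(f"duplicate individual_id: {sorted(set(dup))}")

    raw["father_id"] = raw["father_id"].replace({"0": None, "": None})
    raw["mother_id"] = raw["mother_id"].replace({"0": None, "": None})
    known = set(raw["individual_id"])
    fathers = set(raw["father_id"].dropna())
    mothers = set(raw["mother_id"].dropna())
    for ref, kind in [(fathers, "father"), (mothers, "mother")]:
        absent = ref - known
        if absent:
            warnings.warn(f"pedigree references absent {kind}(s): {sorted(absent)}; "
                          "recorded as absent", stacklevel=2)

    def infer_role(row):
        if pd.notna(row["role"]) and row["role"] in ROLES:
            return row["role"]
        iid = row["individual_id"]
        if iid in fathers:
            return "father"
        if iid in mothers:
            return "mother"
        return "proband" if row["affected"] else "sibling"

    raw["role"] = raw.apply(infer_role, axis=1)
    raw["age_years"] = pd.to_numeric(raw["age_years"], errors="coerce")

    individuals = raw[INDIVIDUAL_COLUMNS].reset_index(drop=True)
    families = _build_families(individuals)
    return individuals, families


def _empty_individuals() -> pd.DataFrame:
    df = pd.DataFrame(columns=INDIVIDUAL_COLUMNS)
    df["affected"] = df["affected"].astype(bool)
    df["age_years"] = df["age_years"].astype(float)
    return df


def _build_families(individuals: pd.DataFrame) -> dict[str, Family]:
    families: dict[str, Family] = {}
    for fid, grp in individuals.groupby("family_id", sort=False):
        fam = Family(family_id=str(fid), member_ids=list(grp["individual_id"]))
        affected_children = grp[(grp["role"] == "proband") & grp["affected"]]
        # affected individuals tagged sibling are still affected children
        affected_children = pd.concat(
            [affected_children, grp[(grp["role"] == "sibling") & grp["affected"]]])
        ids = list(affected_children["individual_id"])
        if ids:
            fam.proband_id = ids[0]
            fam.excluded_affected = ids[1:]
            if fam.excluded_affected:
                warnings.warn(
                    f"family {fid}: multiple affected children; designated "
                    f"{fam.proband_id} as analysis proband, excluded "
                    f"{fam.excluded_affected}", stacklevel=3)
        n_mo = int((grp["role"] == "mother").sum())
        n_fa = int((grp["role"] == "father").sum())
        if n_mo > 1 or n_fa > 1:
            raise CohortError(f"family {fid}: more than one mother or father")
        families[str(fid)] = fam
    return families


def read_phenotypes(path) -> pd.DataFrame:
    """Long-format phenotype table: individual_id, instrument, score."""
    df = _read_tsv(path, dtype={"individual_id": str, "instrument": str})
    if df.empty:
        return pd.DataFrame(columns=PHENOTYPE_COLUMNS)
    missing = set(PHENOTYPE_COLUMNS) - set(df.columns)
    if missing:
        raise CohortError(f"phenotype table missing columns: {sorted(missing)}")
    score = pd.to_numeric(df["score"], errors="coerce")
    bad = df.index[score.isna() & df["score"].notna()]
    if len(bad):
        lines = [int(i) + 2 for i in bad]  # +2: header + 1-based
        raise CohortError(f"non-numeric score at line(s) {lines}")
    df["score"] = score
    dup = df.duplicated(subset=["individual_id", "instrument"])
    if dup.any():
        lines = [int(i) + 2 for i in df.index[dup]]
        raise CohortError(f"duplicate (individual, instrument) at line(s) {lines}")
    unknown = set(df["instrument"]) - set(KNOWN_INSTRUMENTS)
    if unknown:
        warnings.warn(f"unknown instruments preserved: {sorted(unknown)}",
                      stacklevel=2)
    return df[PHENOTYPE_COLUMNS].reset_index(drop=True)


def read_variants(path) -> pd.DataFrame:
    """DNV annotation table; optional columns are filled with missing values."""
    df = _read_tsv(path, dtype={"individual_id": str, "gene": str,
                                "raw_consequence_term": str,
                                "variant_class": str})
    if df.empty:
        return _empty_variants()
    required = {"individual_id", "gene", "raw_consequence_term"}
    missing = required - set(df.columns)
    if missing:
        raise CohortError(f"variant table missing columns: {sorted(missing)}")
    for col in VARIANT_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    for col in ["loeuf", "mpc", "gnomad_af"] + VARIANT_QC_METRICS:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ["aa_position", "internal_ac"]:
        df[col] = pd.to_numeric(df[col], errors="coerce").astype("Int64")
    if "loftee_hc" in df.columns:
        df["loftee_hc"] = df["loftee_hc"].map(
            lambda v: v if pd.isna(v) else str(v).lower() in ("true", "1", "hc"))
    ab = df["AB"]
    bad = df.index[ab.notna() & ((ab < 0) | (ab > 1))]
    if len(bad):
        lines = [int(i) + 2 for i in bad]
        raise CohortError(f"allele balance outside [0,1] at line(s) {lines}")
    if "variant_class" in df.columns:
        df["variant_class"] = df["variant_class"].fillna("SNV")
    return df[VARIANT_COLUMNS].reset_index(drop=True)


def _empty_variants() -> pd.DataFrame:
    return pd.DataFrame(columns=VARIANT_COLUMNS)


def read_polygenic_scores(path) -> pd.DataFrame:
    df = _read_tsv(path, dtype={"individual_id": str, "score_name": str})
    if df.empty:
        return pd.DataFrame(columns=SCORE_COLUMNS)
    missing = set(SCORE_COLUMNS) - set(df.columns)
    if missing:
        raise CohortError(f"score table missing columns: {sorted(missing)}")
    df["value"] = pd.to_numeric(df["value"], errors="raise")
    if df.duplicated(subset=["individual_id", "score_name"]).any():
        raise CohortError("duplicate (individual, score_name) rows")
    return df[SCORE_COLUMNS].reset_index(drop=True)


def read_gene_set(path) -> set[str]:
    """One gene symbol per line; '#' starts a comment."""
    out: set[str] = set()
    for line in Path(path).read_text().splitlines():
        sym = line.split("#", 1)[0].strip()
        if sym:
            out.add(sym)
    return out


# ---------------------------------------------------------------------------
# writers (round-trip partners of the readers)
# ---------------------------------------------------------------------------

def _write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def write_individuals(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["affected"] = out["affected"].map({True: "true", False: "false"})
    _write_tsv(out[INDIVIDUAL_COLUMNS], path)


def write_phenotypes(df: pd.DataFrame, path) -> None:
    _write_tsv(df[PHENOTYPE_COLUMNS], path)


def write_variants(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["loftee_hc"] = out["loftee_hc"].map(
        lambda v: "NA" if pd.isna(v) else ("true" if v else "false"))
    for col in ["aa_position", "internal_ac"]:  # avoid float-formatted ints
        out[col] = pd.to_numeric(out[col], errors="coerce").astype("Int64")
    _write_tsv(out[VARIANT_COLUMNS], path)


def write_polygenic_scores(df: pd.DataFrame, path) -> None:
    _write_tsv(df[SCORE_COLUMNS], path)


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def assemble_cohort(individuals: pd.DataFrame,
                    families: dict[str, Family],
                    phenotypes: pd.DataFrame,
                    variants: pd.DataFrame,
                    polygenic_scores: pd.DataFrame,
                    gene_sets: Mapping[str, Iterable[str]] | None = None,
                    on_unknown: str = "warn") -> FamilyCohort:
    """Bundle parsed tables into a :class:`FamilyCohort` with integrity checks.

    Phenotype, variant, or score rows referencing an individual absent from
    the pedigree are dropped with a warning under the default policy
    (``on_unknown='warn'``) or rejected outright (``'error'``).
    """
    if on_unknown not in ("warn", "error"):
        raise CohortError(f"on_unknown must be 'warn' or 'error', got {on_unknown!r}")
    known = set(individuals["individual_id"])

    def _check(df: pd.DataFrame, label: str) -> pd.DataFrame:
        if df.empty:
            return df
        orphan = ~df["individual_id"].isin(known)
        if orphan.any():
            ids = sorted(set(df.loc[orphan, "individual_id"]))
            if on_unknown == "error":
                raise CohortError(f"{label} rows reference unknown individuals: {ids}")
            warnings.warn(f"dropping {int(orphan.sum())} {label} row(s) for "
                          f"unknown individuals: {ids}", stacklevel=3)
            df = df[~orphan].reset_index(drop=True)
        return df

    mismatch = individuals[~individuals["family_id"].astype(str).isin(families)]
    if len(mismatch):
        raise CohortError("individuals reference families absent from the family map")

    cohort = FamilyCohort(
        individuals=individuals.reset_index(drop=True),
        families=dict(families),
        phenotypes=_check(phenotypes, "phenotype"),
        variants=_check(variants, "variant"),
        polygenic_scores=_check(polygenic_scores, "polygenic score"),
        gene_sets={k: set(v) for k, v in (gene_sets or {}).items()},
    )
    return cohort
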