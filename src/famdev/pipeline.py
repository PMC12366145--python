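"""End-to-end orchestration of the family-relative DNV analysis.

Stage order: QC -> consequence classification -> subgroup assignment ->
WFSD -> subgroup summaries and adjusted contrasts -> severity, association,
gene discovery -> 2D profile -> outlier grid -> pTDT.  Every output TSV
carries a provenance header (config hash, seed, package version); a
machine-readable ``summary.json`` collects the headline numbers.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import (ThresholdConfig, classify_intellectual_functioning,
                          classify_srs_severity, compare_discovery,
                          discover_severe_genes, fisher_association)
from .cohort import (FamilyCohort, assemble_cohort, read_gene_set,
                     read_pedigree, read_phenotypes, read_polygenic_scores,
                     read_variants)
from .outliers import GridConfig, run_outlier_grid
from .ptdt import compute_ptdt, test_ptdt
from .qc import (BUILTIN_RULE_SETS, DEFAULT_AF_MAX, DisruptivenessThresholds,
                 apply_qc, assign_subgroups, classify_consequence,
                 is_disruptive, subgroup_percentages)
from .wfsd import (PopulationNorms, compute_wfsd, profile_shift_2d,
                   profile_shift_mean_of_norms, subgroup_summary)


class ConfigError(ValueError):
    pass


_KNOWN_KEYS = {
    "inputs", "qc", "thresholds", "norms", "reference_class", "outlier",
    "output_dir", "seed", "score_name", "instruments",
}
_KNOWN_INPUT_KEYS = {"pedigree", "pedigree_dialect", "phenotypes", "variants",
                     "polygenic_scores", "gene_sets"}
_KNOWN_THRESHOLD_KEYS = {"loeuf_max", "mpc_min", "severe_raw_srs", "severe_wfsd",
                         "better_than_expected_wfsd", "id_cut", "high_cut"}


@dataclass
class PipelineConfig:
    inputs: dict = field(default_factory=dict)
    cohort_rules: dict = field(default_factory=dict)  # cohort label -> rule set name
    af_max: float = DEFAULT_AF_MAX
    disruptiveness: DisruptivenessThresholds = field(default_factory=DisruptivenessThresholds)
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    norms: PopulationNorms = field(default_factory=PopulationNorms)
    reference_class: str = "parents"
    grid: GridConfig = field(default_factory=GridConfig)
    output_dir: Path = Path("famdev_out")
    seed: int = 0
    score_name: str = "ASD_PS"
    instruments: list[str] = field(default_factory=lambda: ["SRS_T", "VABS_total",
                                                            "SCQ_lifetime", "FSIQ"])
    raw_config: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(raw_config=raw)
        inputs = raw.get("inputs", {})
        bad = set(inputs) - _KNOWN_INPUT_KEYS
        if bad:
            raise ConfigError(f"unknown input keys: {sorted(bad)}")
        cfg.inputs = inputs
        qc = raw.get("qc", {})
        cfg.cohort_rules = qc.get("cohort_rules", {})
        for name in cfg.cohort_rules.values():
            if name not in BUILTIN_RULE_SETS:
                raise ConfigError(f"unknown QC rule set {name!r}")
        cfg.af_max = float(qc.get("af_max", DEFAULT_AF_MAX))
        thr = raw.get("thresholds", {})
        bad = set(thr) - _KNOWN_THRESHOLD_KEYS
        if bad:
            raise ConfigError(f"unknown threshold keys: {sorted(bad)}")
        cfg.disruptiveness = DisruptivenessThresholds(
            loeuf_max=float(thr.get("loeuf_max", 0.37)),
            mpc_min=float(thr.get("mpc_min", 2.0)))
        cfg.thresholds = ThresholdConfig(
            severe_raw_srs=float(thr.get("severe_raw_srs", 76.0)),
            severe_wfsd=float(thr.get("severe_wfsd", 2.6)),
            better_than_expected_wfsd=float(thr.get("better_than_expected_wfsd", 2.0)),
            id_cut=float(thr.get("id_cut", 70.0)),
            high_cut=float(thr.get("high_cut", 100.0)))
        for inst, spec in raw.get("norms", {}).items():
            cfg.norms.set(inst, spec.get("mean"), float(spec["sd"]),
                          spec.get("source", "dataset_derived"))
        cfg.reference_class = raw.get("reference_class", "parents")
        if cfg.reference_class not in ("parents", "siblings"):
            raise ConfigError(f"reference_class must be parents|siblings, "
                              f"got {cfg.reference_class!r}")
        grid = raw.get("outlier", {})
        cfg.grid = GridConfig(
            mad_sd_multiplier=float(grid.get("mad_sd_multiplier", 2.0)),
            min_carriers=int(grid.get("min_carriers", 3)),
            percentile=float(grid.get("percentile", 95.0)))
        cfg.output_dir = Path(raw.get("output_dir", "famdev_out"))
        cfg.seed = int(raw.get("seed", 0))
        cfg.score_name = raw.get("score_name", "ASD_PS")
        cfg.instruments = list(raw.get("instruments", cfg.instruments))
        return cfg

    def config_hash(self) -> str:
        # output_dir is excluded: it does not affect analytic content
        blob = json.dumps({k: v for k, v in self.raw_config.items()
                           if k != "output_dir"},
                          sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def load_cohort(cfg: PipelineConfig) -> FamilyCohort:
    inputs = cfg.inputs
    individuals, families = read_pedigree(
        inputs["pedigree"], inputs.get("pedigree_dialect", "extended_tsv"))
    phenotypes = read_phenotypes(inputs["phenotypes"]) if "phenotypes" in inputs \
        else pd.DataFrame(columns=["individual_id", "instrument", "score"])
    variants = read_variants(inputs["variants"]) if "variants" in inputs \
        else pd.DataFrame()
    scores = read_polygenic_scores(inputs["polygenic_scores"]) \
        if "polygenic_scores" in inputs \
        else pd.DataFrame(columns=["individual_id", "score_name", "value"])
    gene_sets = {name: read_gene_set(p)
                 for name, p in inputs.get("gene_sets", {}).items()}
    return assemble_cohort(individuals, families, phenotypes, variants,
                           scores, gene_sets)


def _write_with_provenance(df: pd.DataFrame, path: Path, cfg: PipelineConfig) -> None:
    header = (f"# famdev {__version__} config={cfg.config_hash()} "
              f"seed={cfg.seed}\n")
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=False, na_rep="NA", float_format="%.10g")


def run_pipeline(cfg: PipelineConfig, cohort: FamilyCohort | None = None) -> dict:
    """Execute every stage and write the report bundle.

    Returns the machine-readable summary (also written as summary.json).
    """
    out = cfg.output_dir
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"version": __version__, "config": cfg.config_hash(),
                     "seed": cfg.seed}

    if cohort is None:
        cohort = load_cohort(cfg)
    summary["counts"] = cohort.counts()

    # --- QC per cohort label ------------------------------------------------
    variants = cohort.variants
    if len(variants):
        label_of = dict(zip(cohort.individuals["individual_id"],
                            cohort.individuals["cohort"]))
        kept, audits = [], []
        labels = variants["individual_id"].map(label_of).fillna("unknown")
        for label in labels.unique():
            sub = variants[labels == label]
            rules = BUILTIN_RULE_SETS.get(cfg.cohort_rules.get(label, ""), None)
            if rules is None:
                kept.append(sub)
                continue
            passed, audit = apply_qc(sub, rules, cfg.af_max)
            kept.append(passed)
            audits.append(audit.assign(cohort=label))
        variants = pd.concat(kept, ignore_index=True) if kept else variants
        if audits:
            _write_with_provenance(pd.concat(audits, ignore_index=True),
                                   out / "qc_audit.tsv", cfg)

    # --- classification & subgroups ----------------------------------------
    variants = classify_consequence(variants) if len(variants) else variants
    proband_ids = [f.proband_id for f in cohort.families.values()
                   if f.proband_id is not None]
    subgroups = assign_subgroups(proband_ids, variants, cfg.disruptiveness)
    _write_with_provenance(subgroups, out / "subgroups.tsv", cfg)
    pct = subgroup_percentages(subgroups)
    summary["subgroup_percent"] = dict(zip(pct["subgroup"], pct["percent"]))

    tags = is_disruptive(variants, cfg.disruptiveness) if len(variants) \
        else pd.Series(dtype=object)
    carrier_genes = variants.loc[tags != "none", ["individual_id", "gene"]] \
        if len(variants) else pd.DataFrame(columns=["individual_id", "gene"])
    carrier_tables = {
        "dnPTV": variants.loc[tags == "dnPTV", ["individual_id", "gene"]]
        if len(variants) else pd.DataFrame(columns=["individual_id", "gene"]),
        "dnMIS": variants.loc[tags == "dnMIS", ["individual_id", "gene"]]
        if len(variants) else pd.DataFrame(columns=["individual_id", "gene"]),
    }

    # --- WFSD ---------------------------------------------------------------
    wfsd_tables: dict[str, pd.DataFrame] = {}
    for inst in cfg.instruments:
        try:
            rec = compute_wfsd(cohort, inst, cfg.reference_class, cfg.norms,
                               pseudo_probands=True)
        except Exception:
            continue
        if len(rec):
            wfsd_tables[inst] = rec
            _write_with_provenance(rec, out / f"wfsd_{inst}.tsv", cfg)

    summary["wfsd"] = {}
    for inst, rec in wfsd_tables.items():
        summ = subgroup_summary(rec, subgroups)
        _write_with_provenance(summ, out / f"wfsd_summary_{inst}.tsv", cfg)
        probands = rec[~rec["pseudo_proband"]]
        pseudo = rec[rec["pseudo_proband"]]
        summary["wfsd"][inst] = {
            "mean_proband": float(probands["wfsd"].mean()) if len(probands) else None,
            "mean_sibling": float(pseudo["wfsd"].mean()) if len(pseudo) else None,
            "n_families": int(probands["family_id"].nunique()),
        }

    # --- severity / association / discovery --------------------------------
    if "SRS_T" in wfsd_tables:
        srs_raw = cohort.phenotypes.query("instrument == 'SRS_T'") \
            .set_index("individual_id")["score"]
        srs_wfsd = wfsd_tables["SRS_T"]
        srs_wfsd = srs_wfsd[~srs_wfsd["pseudo_proband"]] \
            .set_index("proband_id")["wfsd"]
        sub_idx = subgroups.set_index("individual_id")["subgroup"]
        carrier_flag = sub_idx != "non_carrier"

        assoc = {}
        for definition, score in (("raw", srs_raw), ("wfsd", srs_wfsd)):
            ids = [p for p in proband_ids if p in score.index
                   and np.isfinite(score.get(p, np.nan))]
            if not ids:
                continue
            thr = cfg.thresholds.severe_raw_srs if definition == "raw" \
                else cfg.thresholds.severe_wfsd
            severe = pd.Series([score[p] >= thr for p in ids], index=ids)
            res = fisher_association(severe.values,
                                     carrier_flag.reindex(ids).fillna(False).values,
                                     definition)
            assoc[definition] = {"odds_ratio": res.odds_ratio,
                                 "ci": [res.ci_low, res.ci_high],
                                 "p": res.p_value, "n": len(ids)}
            disc = discover_severe_genes(carrier_genes, severe, definition)
            assoc[definition]["n_genes"] = len(disc.genes)
            if definition == "raw":
                disc_raw = disc
            else:
                disc_wfsd = disc
        if "raw" in assoc and "wfsd" in assoc:
            compare_discovery(disc_wfsd, disc_raw)
            assoc["wfsd"]["unique_genes"] = len(disc_wfsd.unique_to_this)
            assoc["raw"]["unique_genes"] = len(disc_raw.unique_to_this)
            assoc["shared_genes"] = len(disc_wfsd.shared)
        summary["association"] = assoc

    # --- 2D profile ---------------------------------------------------------
    if "SRS_T" in wfsd_tables and "VABS_total" in wfsd_tables:
        profiles = []
        sub_idx = subgroups.set_index("individual_id")["subgroup"]
        for label in ["dnPTV_carrier", "dnMIS_carrier", "non_carrier"]:
            fams = {f.family_id for f in cohort.families.values()
                    if f.proband_id is not None
                    and sub_idx.get(f.proband_id) == label}
            shift = profile_shift_2d(wfsd_tables["SRS_T"],
                                     wfsd_tables["VABS_total"], label, fams)
            mean_norm = profile_shift_mean_of_norms(
                wfsd_tables["SRS_T"], wfsd_tables["VABS_total"], fams)
            profiles.append({"label": label, "n_families": shift.n_families,
                             "mean_srs": shift.mean_srs, "mean_vabs": shift.mean_vabs,
                             "magnitude": shift.magnitude,
                             "direction_deg": shift.direction_deg,
                             "mean_of_norms": mean_norm})
        prof_df = pd.DataFrame(profiles)
        _write_with_provenance(prof_df, out / "profile2d.tsv", cfg)
        summary["profile2d"] = profiles

    # --- outlier grid -------------------------------------------------------
    raw_scores, wfsd_scores = {}, {}
    for ph, inst in (("SRS", "SRS_T"), ("VABS", "VABS_total")):
        raw = cohort.phenotypes.query(f"instrument == '{inst}'")
        raw = raw[raw["individual_id"].isin(proband_ids)]
        raw_scores[ph] = raw.set_index("individual_id")["score"]
        if inst in wfsd_tables:
            rec = wfsd_tables[inst]
            wfsd_scores[ph] = rec[~rec["pseudo_proband"]] \
                .set_index("proband_id")["wfsd"]
    grid = run_outlier_grid(carrier_tables, raw_scores, wfsd_scores, cfg.grid)
    grid_df = grid.to_frame()
    _write_with_provenance(grid_df, out / "outlier_grid.tsv", cfg)
    summary["outliers"] = {"n_tested": int(len(grid_df)),
                           "n_outliers": int(grid_df["is_outlier"].sum())
                           if len(grid_df) else 0}

    # --- pTDT ---------------------------------------------------------------
    if len(cohort.polygenic_scores):
        records = compute_ptdt(cohort, cfg.score_name)
        if len(records) >= 2:
            _write_with_provenance(records, out / "ptdt.tsv", cfg)
            grouping = subgroups.set_index("individual_id")["subgroup"]
            try:
                tests = test_ptdt(records, grouping)
            except ValueError:
                tests = test_ptdt(records)
            summary["ptdt"] = [
                {"group": t.group, "n": t.n, "mean_std": t.mean_deviation_std,
                 "t": t.t_statistic, "p": t.p_value} for t in tests]

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
    return summary
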