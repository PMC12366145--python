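"""Synthetic ascertained family-cohort generator with ground truth.

Families are drawn from a quantitative-trait model with parent-offspring
transmission: each child's latent score is

    population mean + b * (midparent - population mean)
    + shared family residual + individual residual,

with ``b`` the parent-offspring regression coefficient.  Proband-only DNV
effects are planted in population-SD units with optional per-carrier site
heterogeneity (a normal draw added to the gene's mean effect — the minimal
mechanism that makes dispersion-outlier genes recoverable).  Proband
ascertainment rejection-samples whole families until the proband crosses a
severity threshold, which induces the parental enrollment shift seen in
ascertained cohorts.  Polygenic scores follow parental draws with child =
midparent + Mendelian noise, plus optional proband over-transmission.
Missingness is applied last, completely at random per (role, instrument).

Effects and thresholds are orientation-aware: severity increases SRS-like
scores and decreases VABS/IQ-like scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import (FamilyCohort, Family, INDIVIDUAL_COLUMNS,
                     PHENOTYPE_COLUMNS, SCORE_COLUMNS, VARIANT_COLUMNS,
                     assemble_cohort)

#: +1: higher score = more severe; -1: lower score = worse functioning
ORIENTATION = {"SRS_T": 1.0, "SCQ_lifetime": 1.0, "SCQ_current": 1.0,
               "ADOS_total": 1.0, "ADOS_SA": 1.0, "ADOS_RRB": 1.0,
               "VABS_total": -1.0, "VABS_comm": -1.0, "VABS_daily": -1.0,
               "VABS_social": -1.0, "VABS_motor": -1.0,
               "FSIQ": -1.0, "NVIQ": -1.0, "DCDQ": -1.0}


@dataclass(frozen=True)
class InstrumentModel:
    population_mean: float
    population_sd: float
    between_family_sd: float
    within_family_sd: float


def default_instruments(parent_offspring_regression: float = 0.5
                        ) -> dict[str, InstrumentModel]:
    """Instrument models whose child marginal SD equals the population SD.

    Residual variance is split so that the shared family component carries a
    quarter of the population variance; with b = 0.5 the implied
    child-midparent correlation is b/sqrt(2) ~ 0.35, matching the familial
    correlation scale seen in unaffected siblings of ASD cohorts.
    """
    b = parent_offspring_regression
    out = {}
    for inst, (mean, sd) in {"SRS_T": (50.0, 10.0), "VABS_total": (100.0, 15.0),
                             "SCQ_lifetime": (10.0, 10.45), "FSIQ": (100.0, 15.0)}.items():
        resid_var = sd * sd * (1.0 - b * b / 2.0)
        if resid_var <= 0:
            raise ValueError("parent_offspring_regression too large for unit "
                             "marginal variance")
        between = min(0.5 * sd, np.sqrt(resid_var) * 0.99)
        within = float(np.sqrt(resid_var - between * between))
        out[inst] = InstrumentModel(mean, sd, float(between), within)
    return out


@dataclass(frozen=True)
class GeneEffect:
    gene: str
    #: mean planted effect per instrument, in population-SD units toward severity
    effect: dict
    site_heterogeneity_sd: float = 0.0
    loeuf: float = 0.1
    mpc: float = 2.5


def default_gene_model(n_genes: int = 20, effect: float = 1.0,
                       site_heterogeneity_sd: float = 0.0) -> list[GeneEffect]:
    eff = {"SRS_T": effect, "VABS_total": effect, "SCQ_lifetime": effect,
           "FSIQ": effect}
    return [GeneEffect(f"GENE{i + 1:03d}", dict(eff), site_heterogeneity_sd)
            for i in range(n_genes)]


@dataclass
class GeneratorParams:
    """Study conditions of the simulated cohort.

    Defaults mirror the composition of large trio ASD cohorts: ~3.9% of
    probands carry a disruptive de novo PTV, ~3.1% a disruptive de novo
    missense variant; enrollment requires a proband above the SRS clinical
    band (T >= 60); parent-offspring regression 0.5.
    """
    n_families: int = 500
    seed: int = 0
    parent_offspring_regression: float = 0.5
    instruments: dict[str, InstrumentModel] | None = None
    carrier_rate_ptv: float = 0.039
    carrier_rate_mis: float = 0.031
    gene_model: list[GeneEffect] = field(default_factory=default_gene_model)
    ascertainment: dict[str, float] | None = field(
        default_factory=lambda: {"SRS_T": 60.0})
    max_ascertainment_retries: int = 1000
    parental_screening_shift: float = 0.0  # population-SD units, severity-lowering
    sibling_count_probs: tuple[float, ...] = (0.3, 0.6, 0.1)  # P(0), P(1), P(2)
    missingness: dict[str, float] = field(default_factory=lambda: {
        "proband": 0.05, "sibling": 0.2, "mother": 0.2, "father": 0.2})
    ps_overtransmission: float = 0.2  # proband PS shift, mid-parental-SD units
    background_syn_rate: float = 0.5   # Poisson mean synonymous DNVs per proband
    background_mis_rate: float = 0.3   # Poisson mean low-MPC missense per proband
    cohort_label: str = "sim_wgs"

    def __post_init__(self):
        if not (0 <= self.parent_offspring_regression < 1):
            raise ValueError("parent_offspring_regression must be in [0, 1)")
        for r in (self.carrier_rate_ptv, self.carrier_rate_mis):
            if not (0 <= r <= 1):
                raise ValueError("carrier rates must lie in [0, 1]")
        if self.instruments is None:
            self.instruments = default_instruments(self.parent_offspring_regression)


TRUTH_COLUMNS = ["family_id", "proband_id", "carrier_class", "gene",
                 "site_effect_draw", "planted_effect_srs",
                 "familial_component_srs", "ps_overtransmission"]


class AscertainmentError(RuntimeError):
    pass


def _passes(scores: dict[str, float], thresholds: dict[str, float]) -> bool:
    for inst, t in thresholds.items():
        val = scores.get(inst)
        if val is None:
            return False
        if ORIENTATION.get(inst, 1.0) >= 0:
            if val < t:
                return False
        elif val > t:
            return False
    return True


def simulate_cohort(params: GeneratorParams) -> tuple[FamilyCohort, pd.DataFrame]:
    """Generate a cohort plus a per-proband ground-truth table.

    Deterministic for fixed params: each family owns an RNG substream
    derived from (seed, family index), so enlarging the cohort leaves
    earlier families unchanged.
    """
    instruments = params.instruments
    inst_names = list(instruments)
    b = params.parent_offspring_regression
    p_ptv, p_mis = params.carrier_rate_ptv, params.carrier_rate_mis
    sib_probs = np.asarray(params.sibling_count_probs, dtype=float)
    sib_probs = sib_probs / sib_probs.sum()
    genes = params.gene_model

    ind_rows, phen_rows, var_rows, ps_rows, truth_rows = [], [], [], [], []
    families: dict[str, Family] = {}

    for i in range(params.n_families):
        rng = np.random.default_rng([params.seed, i])
        fid = f"F{i + 1:05d}"
        n_sib = int(rng.choice(len(sib_probs), p=sib_probs))

        # Carrier status is fixed before ascertainment so observed carrier
        # frequencies in the enrolled cohort match the configured rates
        # (the rates describe the ascertained probands, as in real cohorts).
        carrier = _draw_carrier(rng, p_ptv, p_mis, genes)

        for attempt in range(params.max_ascertainment_retries):
            draw = _draw_family(rng, params, instruments, inst_names, b,
                                n_sib, carrier)
            if params.ascertainment is None or _passes(draw["proband_scores"],
                                                       params.ascertainment):
                break
        else:
            raise AscertainmentError(
                f"family {fid}: proband never passed ascertainment in "
                f"{params.max_ascertainment_retries} draws")

        pid, faid, moid = f"{fid}.p1", f"{fid}.fa", f"{fid}.mo"
        sib_ids = [f"{fid}.s{j + 1}" for j in range(n_sib)]
        sexes = draw["sexes"]
        ind_rows.append((pid, fid, "proband", sexes[0], True,
                         float(draw["ages"][0]), params.cohort_label))
        ind_rows.append((faid, fid, "father", "male", False,
                         float(draw["ages"][1]), params.cohort_label))
        ind_rows.append((moid, fid, "mother", "female", False,
                         float(draw["ages"][2]), params.cohort_label))
        for j, sid in enumerate(sib_ids):
            ind_rows.append((sid, fid, "sibling", sexes[1 + j], False,
                             float(draw["ages"][3 + j]), params.cohort_label))
        families[fid] = Family(fid, [pid, faid, moid] + sib_ids, proband_id=pid)

        roles = ([("proband", pid), ("father", faid), ("mother", moid)]
                 + [("sibling", s) for s in sib_ids])
        miss = params.missingness
        miss_draws = rng.random((len(roles), len(inst_names)))
        for k, inst in enumerate(inst_names):
            member_scores = [draw["proband_scores"][inst],
                             draw["father_scores"][inst],
                             draw["mother_scores"][inst],
                             *draw["sibling_scores"][inst]]
            for r, (role, iid) in enumerate(roles):
                if miss_draws[r, k] < miss.get(role, 0.0):
                    continue
                phen_rows.append((iid, inst, float(member_scores[r])))

        for v in draw["variants"]:
            var_rows.append((pid, *v))

        ps_rows.append((faid, "ASD_PS", draw["ps"][0]))
        ps_rows.append((moid, "ASD_PS", draw["ps"][1]))
        ps_rows.append((pid, "ASD_PS", draw["ps"][2]))
        for j, sid in enumerate(sib_ids):
            ps_rows.append((sid, "ASD_PS", draw["ps"][3 + j]))

        truth_rows.append((fid, pid, draw["carrier_class"], draw["gene"],
                           draw["site_draw"], draw["planted_srs"],
                           draw["familial_srs"], params.ps_overtransmission))

    individuals = pd.DataFrame(ind_rows, columns=INDIVIDUAL_COLUMNS)
    phenotypes = pd.DataFrame(phen_rows, columns=PHENOTYPE_COLUMNS)
    variants = pd.DataFrame(var_rows, columns=["individual_id"] + VARIANT_COLUMNS[1:])
    scores = pd.DataFrame(ps_rows, columns=SCORE_COLUMNS)
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    cohort = assemble_cohort(individuals, families, phenotypes, variants, scores)
    return cohort, truth


def _draw_carrier(rng, p_ptv, p_mis, genes):
    u = rng.random()
    if u < p_ptv and genes:
        carrier_class = "dnPTV"
    elif u < p_ptv + p_mis and genes:
        carrier_class = "dnMIS"
    else:
        carrier_class = "none"
    gene = None
    if carrier_class != "none":
        gene = genes[int(rng.integers(len(genes)))]
    return {"carrier_class": carrier_class, "gene": gene}


def _draw_family(rng, params, instruments, inst_names, b, n_sib, carrier):
    n_children = 1 + n_sib
    screening = params.parental_screening_shift
    carrier_class = carrier["carrier_class"]
    gene = carrier["gene"]
    # The site-level draw is refreshed on every ascertainment attempt:
    # resampling stands for enrolling a different carrier family, whose
    # variant hits a different site.  Under ascertainment this correctly
    # under-represents protective sites among enrolled carriers.
    site_draw = 0.0
    if gene is not None and gene.site_heterogeneity_sd > 0:
        site_draw = float(rng.normal(0.0, gene.site_heterogeneity_sd))

    father_scores, mother_scores = {}, {}
    proband_scores = {}
    sibling_scores = {inst: [] for inst in inst_names}
    familial_srs = 0.0
    planted_srs = 0.0

    for inst in inst_names:
        m = instruments[inst]
        orient = ORIENTATION.get(inst, 1.0)
        mu_parent = m.population_mean - screening * m.population_sd * orient
        fa = float(rng.normal(mu_parent, m.population_sd))
        mo = float(rng.normal(mu_parent, m.population_sd))
        mid = 0.5 * (fa + mo)
        fam_res = float(rng.normal(0.0, m.between_family_sd))
        child_ind = rng.normal(0.0, m.within_family_sd, size=n_children)
        base = m.population_mean + b * (mid - m.population_mean) + fam_res
        children = base + child_ind
        planted = 0.0
        if carrier_class != "none" and inst in gene.effect:
            planted = (gene.effect[inst] + site_draw) * m.population_sd * orient
        proband_scores[inst] = float(children[0] + planted)
        sibling_scores[inst] = [float(c) for c in children[1:]]
        father_scores[inst] = fa
        mother_scores[inst] = mo
        if inst == "SRS_T":
            familial_srs = float(base - m.population_mean)
            planted_srs = planted / m.population_sd

    # polygenic scores: parents ~ N(0,1); child = midparent + Mendelian noise
    ps_fa, ps_mo = rng.normal(0.0, 1.0, size=2)
    ps_mid = 0.5 * (ps_fa + ps_mo)
    sd_mid = np.sqrt(0.5)  # theoretical SD of the mid-parental distribution
    ps_children = ps_mid + rng.normal(0.0, sd_mid, size=n_children)
    ps_children[0] += params.ps_overtransmission * sd_mid
    ps = [float(ps_fa), float(ps_mo)] + [float(c) for c in ps_children]

    variants = []
    if carrier_class == "dnPTV":
        variants.append(_variant_row(gene.gene, "stop_gained", True,
                                     gene.loeuf, np.nan, rng))
    elif carrier_class == "dnMIS":
        variants.append(_variant_row(gene.gene, "missense_variant", np.nan,
                                     np.nan, gene.mpc, rng))
    for _ in range(rng.poisson(params.background_syn_rate)):
        variants.append(_variant_row(f"BG{int(rng.integers(500)):03d}",
                                     "synonymous_variant", np.nan, np.nan,
                                     np.nan, rng))
    for _ in range(rng.poisson(params.background_mis_rate)):
        variants.append(_variant_row(f"BG{int(rng.integers(500)):03d}",
                                     "missense_variant", np.nan, np.nan,
                                     float(rng.uniform(0.0, 1.5)), rng))

    sexes = ["male" if rng.random() < 0.8 else "female"]  # ~4:1 proband ratio
    sexes += ["male" if rng.random() < 0.5 else "female" for _ in range(n_sib)]
    ages = [float(rng.uniform(4, 17)), float(rng.uniform(30, 55)),
            float(rng.uniform(28, 53))] + \
           [float(rng.uniform(4, 17)) for _ in range(n_sib)]

    return {"proband_scores": proband_scores, "father_scores": father_scores,
            "mother_scores": mother_scores, "sibling_scores": sibling_scores,
            "variants": variants, "ps": ps, "carrier_class": carrier_class,
            "gene": gene.gene if gene is not None else "",
            "site_draw": site_draw, "planted_srs": planted_srs,
            "familial_srs": familial_srs, "sexes": sexes, "ages": ages}


def _variant_row(gene: str, term: str, loftee_hc, loeuf, mpc, rng):
    """One variant row matching the cohort variant schema (minus individual_id).

    QC metrics are drawn inside the strictest built-in passing region so
    simulated variants survive every rule set unless deliberately degraded.
    """
    return (gene, term, None, loftee_hc, loeuf, mpc,
            float(rng.uniform(150, 500)),   # QUAL
            float(rng.uniform(80, 99)),     # GQmean
            float(rng.uniform(34, 60)),     # DPmean
            float(rng.uniform(15, 40)),     # gDP
            float(rng.uniform(0.4, 0.6)),   # AB
            float(rng.uniform(10, 30)),     # QD
            float(rng.uniform(40, 60)),     # MQ
            float(rng.uniform(0.5, 1.5)),   # SOR
            1,                               # internal_ac
            np.nan,                          # gnomad_af (novel)
            int(rng.integers(1, 1000)),      # aa_position
            "SNV")


def truth_table(truth: pd.DataFrame, path) -> None:
    """Write the ground-truth table for recovery scoring."""
    truth.to_csv(path, sep="\t", index=False, na_rep="NA")


def implied_child_midparent_correlation(params: GeneratorParams,
                                        instrument: str = "SRS_T") -> float:
    """Model-implied correlation between a child and the mid-parental mean."""
    m = params.instruments[instrument]
    b = params.parent_offspring_regression
    var_mid = m.population_sd ** 2 / 2.0
    var_child = (b * b * var_mid + m.between_family_sd ** 2
                 + m.within_family_sd ** 2)
    return float(b * np.sqrt(var_mid) / np.sqrt(var_child))


def regression_for_correlation(rho: float, instrument_sd_ratio: float = 1.0
                               ) -> float:
    """Parent-offspring regression that yields child-midparent correlation rho.

    Assumes the default variance budget where the child marginal SD equals
    the population SD: rho = b / sqrt(2), so b = rho * sqrt(2).
    """
    b = rho * np.sqrt(2.0)
    if not (0 <= b < 1):
        raise ValueError(f"requested correlation {rho} is infeasible")
    return float(b)
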