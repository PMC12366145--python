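"""Recovery and calibration experiments on synthetic cohorts.

Each experiment generates data under known conditions, runs the analysis
under study, and returns the measured quantity together with its
Monte-Carlo uncertainty.  These drive both the validation suite and the
reproduction script; problem sizes are parameters so callers can trade
precision for runtime.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st

from .outliers import GridConfig, call_outliers
from .ptdt import compute_ptdt, test_ptdt
from .simulate import GeneratorParams, default_gene_model, simulate_cohort
from .wfsd import compute_wfsd


@dataclass
class RecoveryResult:
    estimate: float
    se: float
    truth: float
    n: int

    @property
    def ci95(self) -> tuple[float, float]:
        return (self.estimate - 1.96 * self.se, self.estimate + 1.96 * self.se)

    def covers_truth(self) -> bool:
        lo, hi = self.ci95
        return lo <= self.truth <= hi


def recover_carrier_effect(seed: int, n_families: int = 2000,
                           delta: float = 1.0, ascertained: bool = False,
                           n_replicates: int = 1) -> RecoveryResult:
    """Carrier-vs-non-carrier mean WFSD contrast against a planted effect.

    The planted effect is ``delta`` population SDs on every instrument;
    without ascertainment the contrast is an unbiased estimate of delta.
    Replicates (distinct derived seeds) are pooled.
    """
    diffs, variances, n_tot = [], [], 0
    for r in range(n_replicates):
        params = GeneratorParams(
            n_families=n_families, seed=(seed * 1009 + r) % (2 ** 31),
            gene_model=default_gene_model(effect=delta),
            ascertainment={"SRS_T": 60.0} if ascertained else None,
            missingness={})
        cohort, truth = simulate_cohort(params)
        rec = compute_wfsd(cohort, "SRS_T", "parents")
        m = rec.merge(truth[["proband_id", "carrier_class"]], on="proband_id")
        car = m.loc[m["carrier_class"] != "none", "wfsd"]
        non = m.loc[m["carrier_class"] == "none", "wfsd"]
        diffs.append(car.mean() - non.mean())
        variances.append(car.var(ddof=1) / len(car) + non.var(ddof=1) / len(non))
        n_tot += len(m)
    est = float(np.mean(diffs))
    se = float(np.sqrt(np.sum(variances)) / len(diffs))
    return RecoveryResult(est, se, delta, n_tot)


def sibling_null_center(seed: int, n_families: int = 2000) -> RecoveryResult:
    """Mean pseudo-proband (unaffected sibling) WFSD under the null.

    With no sibling-specific effects and no ascertainment the sibling
    deviation from parents is centered at zero.
    """
    params = GeneratorParams(n_families=n_families, seed=seed,
                             ascertainment=None, missingness={})
    cohort, _ = simulate_cohort(params)
    rec = compute_wfsd(cohort, "SRS_T", "parents", pseudo_probands=True)
    sib = rec.loc[rec["pseudo_proband"], "wfsd"]
    return RecoveryResult(float(sib.mean()),
                          float(sib.std(ddof=1) / np.sqrt(len(sib))),
                          0.0, int(len(sib)))


def wfsd_efficiency(seed: int, n_replicates: int = 200, n_families: int = 300,
                    regression: float = 0.9, delta: float = 1.0) -> dict:
    """Share of replicates where the WFSD contrast beats the raw-score contrast.

    Under strong familial correlation the within-family comparison removes
    between-family variance, so the standard error of the carrier contrast
    on WFSD should undercut the raw-score contrast in most replicates.
    Per replicate both contrasts are estimated on the same families and
    their analytic two-sample SEs compared.
    """
    wins = 0
    se_w, se_r = [], []
    for r in range(n_replicates):
        params = GeneratorParams(
            n_families=n_families, seed=(seed * 2003 + r) % (2 ** 31),
            parent_offspring_regression=regression,
            gene_model=default_gene_model(effect=delta),
            ascertainment=None, missingness={})
        cohort, truth = simulate_cohort(params)
        rec = compute_wfsd(cohort, "SRS_T", "parents")
        raw = cohort.phenotypes.query("instrument == 'SRS_T'") \
            .set_index("individual_id")["score"]
        m = rec.merge(truth[["proband_id", "carrier_class"]], on="proband_id")
        m["raw"] = raw.reindex(m["proband_id"]).to_numpy()
        car = m["carrier_class"] != "none"
        if car.sum() < 2 or (~car).sum() < 2:
            continue

        def contrast_se(values: pd.Series) -> float:
            a, b = values[car], values[~car]
            return float(np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b)))

        sw = contrast_se(m["wfsd"])
        sr = contrast_se(m["raw"] / 10.0)  # population-SD units, same scale
        se_w.append(sw)
        se_r.append(sr)
        wins += sw < sr
    n = len(se_w)
    return {"win_rate": wins / n if n else float("nan"), "n_replicates": n,
            "median_se_wfsd": float(np.median(se_w)),
            "median_se_raw": float(np.median(se_r))}


def outlier_recovery(seed: int, n_replicates: int = 200, n_background: int = 30,
                     n_carriers: int = 4, spread: float = 4.0,
                     config: GridConfig = GridConfig()) -> dict:
    """Sensitivity for one planted high-dispersion gene per replicate cell.

    Each replicate builds one WFSD grid cell: ``n_background`` genes whose
    carrier outcomes are standard normal and one planted gene with
    ``spread``-fold the background SD, all with ``n_carriers`` carriers.
    The planted-null false-call rate is measured on matching cells with no
    planted gene (raw score type, so only the MAD and sample-count rules
    apply).
    """
    rng = np.random.default_rng([seed, 77])
    hits = 0
    false_calls = 0
    genes_tested = 0
    for _ in range(n_replicates):
        groups = {f"BG{i}": rng.normal(0, 1, n_carriers)
                  for i in range(n_background)}
        groups["PLANTED"] = rng.normal(0, spread, n_carriers)
        calls, _ = call_outliers(groups, "wfsd", config)
        called = {c.gene for c in calls if c.is_outlier}
        hits += "PLANTED" in called

        null_groups = {f"BG{i}": rng.normal(0, 1, n_carriers)
                       for i in range(n_background + 1)}
        null_calls, _ = call_outliers(null_groups, "raw", config)
        false_calls += sum(c.is_outlier for c in null_calls)
        genes_tested += len(null_calls)
    return {"sensitivity": hits / n_replicates,
            "null_false_call_rate": false_calls / genes_tested,
            "n_replicates": n_replicates}


def ptdt_type_one_error(seed: int, n_replicates: int = 1000,
                        n_families: int = 200, alpha: float = 0.05) -> dict:
    """Rejection rate of the one-sample pTDT test under the null.

    Proband scores are midparent plus symmetric Mendelian noise; the
    one-sample t-test against zero should reject at the nominal rate.
    Families are drawn directly from the transmission model (parents
    standard normal, child = midparent + noise with half the variance).
    """
    rng = np.random.default_rng([seed, 991])
    rejections = 0
    for _ in range(n_replicates):
        pa = rng.normal(0, 1, (n_families, 2))
        mid = pa.mean(axis=1)
        child = mid + rng.normal(0, np.sqrt(0.5), n_families)
        dev = child - mid
        _, p = st.ttest_1samp(dev, 0.0)
        rejections += p < alpha
    return {"type_one_error": rejections / n_replicates,
            "n_replicates": n_replicates, "alpha": alpha}


def ptdt_overtransmission_recovery(seed: int, n_families: int = 2000,
                                   shift: float = 0.3) -> RecoveryResult:
    """Recover a planted polygenic over-transmission via the full pipeline.

    ``shift`` is in mid-parental-SD units; the mean standardized pTDT
    deviation estimates it.
    """
    params = GeneratorParams(n_families=n_families, seed=seed,
                             ps_overtransmission=shift, ascertainment=None,
                             missingness={})
    cohort, _ = simulate_cohort(params)
    records = compute_ptdt(cohort, "ASD_PS")
    tests = test_ptdt(records)
    dev = records["deviation_std"]
    return RecoveryResult(float(tests[0].mean_deviation_std),
                          float(dev.std(ddof=1) / np.sqrt(len(dev))),
                          shift, int(len(records)))
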