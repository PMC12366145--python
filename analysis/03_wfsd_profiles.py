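"""Within-family deviations, subgroup summaries, diagnostics, 2D profile.

Computes WFSD against parents for every instrument, summarizes by genetic
subgroup, contrasts carriers vs non-carriers with age/sex/cohort
adjustment, reports distribution diagnostics for raw vs WFSD SRS, and
places each subgroup in the SRS x VABS plane.
"""

import importlib
from pathlib import Path

import pandas as pd

from famdev.wfsd import (adjusted_contrast, compute_wfsd, normality_report,
                         profile_shift_2d, profile_shift_mean_of_norms,
                         subgroup_summary)

load_cohort = importlib.import_module("02_filter_and_classify").load_cohort

OUT = Path("results")


def main() -> None:
    cohort = load_cohort()
    subgroups = pd.read_csv(OUT / "subgroups.tsv", sep="\t")

    wfsd_tables = {}
    for inst in ("SRS_T", "VABS_total", "SCQ_lifetime", "FSIQ"):
        rec = compute_wfsd(cohort, inst, "parents", pseudo_probands=True)
        wfsd_tables[inst] = rec
        rec.to_csv(OUT / f"wfsd_{inst}.tsv", sep="\t", index=False)
        pro = rec[~rec["pseudo_proband"]]
        sib = rec[rec["pseudo_proband"]]
        print(f"{inst}: {len(pro)} proband records, mean WFSD "
              f"{pro['wfsd'].mean():+.2f}; {len(sib)} sibling records, "
              f"mean {sib['wfsd'].mean():+.2f}")
        summ = subgroup_summary(rec, subgroups)
        summ.to_csv(OUT / f"wfsd_summary_{inst}.tsv", sep="\t", index=False)

    # covariate-adjusted carrier contrasts on SRS WFSD
    rec = wfsd_tables["SRS_T"]
    pro = rec[~rec["pseudo_proband"]].merge(
        cohort.individuals[["individual_id", "age_years", "sex", "cohort"]],
        left_on="proband_id", right_on="individual_id")
    pro = pro.merge(subgroups, on="individual_id")
    pro["value"] = pro["wfsd"]
    res = adjusted_contrast(pro, phenotype="SRS_T")
    coef = res.coefficients.set_index("term")
    for term in ("dnPTV_carrier", "dnMIS_carrier"):
        if term in coef.index:
            print(f"adjusted {term} contrast: "
                  f"{coef.loc[term, 'estimate']:+.3f} "
                  f"(SE {coef.loc[term, 'se']:.3f}, p {coef.loc[term, 'p']:.2g})")

    # distribution diagnostics: raw vs within-family SRS
    raw = cohort.phenotypes.query("instrument == 'SRS_T'")
    probands = {f.proband_id for f in cohort.families.values()}
    raw_scores = raw[raw["individual_id"].isin(probands)]["score"]
    for label, values in (("raw", raw_scores),
                          ("wfsd", rec[~rec["pseudo_proband"]]["wfsd"])):
        rep = normality_report(values, "SRS_T", label)
        print(f"normality ({label}): W={rep.shapiro_w:.4f} "
              f"AD={rep.anderson_ad:.2f} KS={rep.ks:.4f}")

    # 2D neurodevelopmental shift per subgroup
    rows = []
    sub_idx = subgroups.set_index("individual_id")["subgroup"]
    for label in ("dnPTV_carrier", "dnMIS_carrier", "non_carrier"):
        fams = {f.family_id for f in cohort.families.values()
                if sub_idx.get(f.proband_id) == label}
        s = profile_shift_2d(wfsd_tables["SRS_T"], wfsd_tables["VABS_total"],
                             label, fams)
        mon = profile_shift_mean_of_norms(wfsd_tables["SRS_T"],
                                          wfsd_tables["VABS_total"], fams)
        rows.append({"label": label, "n_families": s.n_families,
                     "mean_srs": s.mean_srs, "mean_vabs": s.mean_vabs,
                     "magnitude": s.magnitude, "direction_deg": s.direction_deg,
                     "mean_of_norms": mon})
        print(f"2D shift [{label}]: n={s.n_families} "
              f"({s.mean_srs:+.2f}, {s.mean_vabs:+.2f}) "
              f"magnitude {s.magnitude:.2f} at {s.direction_deg:.0f} deg")
    pd.DataFrame(rows).to_csv(OUT / "profile2d.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
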