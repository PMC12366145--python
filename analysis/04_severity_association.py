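"""Severe-phenotype association and gene discovery, raw vs WFSD definitions.

Flags severe probands by raw SRS T >= 76 and by SRS WFSD >= 2.6, tests
disruptive-DNV enrichment with Fisher's exact test under both definitions,
and compares the gene lists each definition discovers.
"""

import importlib
from pathlib import Path

import numpy as np
import pandas as pd

from famdev.association import (compare_discovery, discover_severe_genes,
                                fisher_association)
from famdev.qc import classify_consequence, is_disruptive

load_cohort = importlib.import_module("02_filter_and_classify").load_cohort

OUT = Path("results")


def main() -> None:
    cohort = load_cohort()
    subgroups = pd.read_csv(OUT / "subgroups.tsv", sep="\t")
    wfsd = pd.read_csv(OUT / "wfsd_SRS_T.tsv", sep="\t")
    wfsd = wfsd[~wfsd["pseudo_proband"]].set_index("proband_id")["wfsd"]

    probands = [f.proband_id for f in cohort.families.values()]
    raw = cohort.phenotypes.query("instrument == 'SRS_T'") \
        .set_index("individual_id")["score"].reindex(probands)
    carrier = (subgroups.set_index("individual_id")["subgroup"]
               != "non_carrier")

    variants = classify_consequence(cohort.variants)
    tags = is_disruptive(variants)
    carrier_genes = variants.loc[tags != "none", ["individual_id", "gene"]]

    discoveries = {}
    rows = []
    for definition, score, threshold in (("raw", raw, 76.0),
                                         ("wfsd", wfsd, 2.6)):
        ids = [p for p in probands
               if p in score.index and np.isfinite(score.get(p, np.nan))]
        severe = pd.Series([score[p] >= threshold for p in ids], index=ids)
        res = fisher_association(severe.to_numpy(),
                                 carrier.reindex(ids).fillna(False).to_numpy(),
                                 definition)
        disc = discover_severe_genes(carrier_genes, severe, definition)
        discoveries[definition] = disc
        rows.append({"definition": definition, "n": len(ids),
                     "n_severe": int(severe.sum()),
                     "odds_ratio": res.odds_ratio, "ci_low": res.ci_low,
                     "ci_high": res.ci_high, "p": res.p_value,
                     "n_genes": len(disc.genes)})
        print(f"{definition}: n={len(ids)}, severe={int(severe.sum())}, "
              f"OR={res.odds_ratio:.2f} "
              f"[{res.ci_low:.2f}, {res.ci_high:.2f}], p={res.p_value:.3g}, "
              f"genes={len(disc.genes)}")

    compare_discovery(discoveries["wfsd"], discoveries["raw"])
    print(f"gene discovery: {len(discoveries['wfsd'].unique_to_this)} "
          f"WFSD-only, {len(discoveries['raw'].unique_to_this)} raw-only, "
          f"{len(discoveries['wfsd'].shared)} shared")
    pd.DataFrame(rows).to_csv(OUT / "severity_association.tsv", sep="\t",
                              index=False)


if __name__ == "__main__":
    main()
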