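"""Per-gene dispersion of phenotype outcomes among DNV carriers.

For each cell of the (variant type x phenotype x score type) grid — dnMIS
and dnPTV crossed with SRS and VABS, each on raw scores and on WFSD, eight
analyses in all — the median absolute deviation (MAD) of carrier outcomes
is computed per gene.  A gene is an outlier when its MAD exceeds the cell's
mean MAD by more than two sample SDs, it has more than two carriers, and
(for WFSD cells only) at least one of its carriers' |WFSD| lies above the
95th percentile of |WFSD| pooled over all carriers in the cell.

The MAD here is unscaled (no 1.4826 normal-consistency constant): the
threshold rule calibrates against the cell's own MAD distribution, so a
scale factor would cancel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VARIANT_TYPES = ("dnPTV", "dnMIS")
PHENOTYPES = ("SRS", "VABS")
SCORE_TYPES = ("raw", "wfsd")

#: instrument used for each grid phenotype
GRID_INSTRUMENTS = {"SRS": "SRS_T", "VABS": "VABS_total"}


def gene_mad(values) -> float:
    """Unscaled median absolute deviation; midpoint median for even n."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("MAD of an empty sample is undefined")
    med = np.median(x)
    return float(np.median(np.abs(x - med)))


@dataclass
class GridConfig:
    mad_sd_multiplier: float = 2.0
    min_carriers: int = 3          # "more than two samples"
    percentile: float = 95.0       # gate on pooled |wfsd|
    pool_min_carriers: int = 2     # singleton genes have MAD 0; kept out of the pool


@dataclass
class GeneDispersion:
    gene: str
    variant_type: str
    phenotype: str
    score_type: str
    n_carriers: int
    mad: float
    mad_threshold_flag: bool
    min_samples_flag: bool
    percentile_flag: bool
    is_outlier: bool


@dataclass
class CellSummary:
    n_genes: int
    mean_mad: float
    sd_mad: float
    percentile_gate: float


def call_outliers(groups: dict[str, np.ndarray], score_type: str,
                  config: GridConfig = GridConfig(),
                  variant_type: str = "", phenotype: str = ""
                  ) -> tuple[list[GeneDispersion], CellSummary | None]:
    """Apply the three outlier criteria to one grid cell.

    ``groups`` maps gene -> carrier outcome values (one per carrier).
    Genes with fewer than ``pool_min_carriers`` carriers enter neither the
    mean/SD pool nor the calling.  Cells with fewer than two pooled genes
    cannot define a threshold and are skipped with a warning.
    """
    pooled = {g: np.asarray(v, dtype=float) for g, v in groups.items()
              if len(v) >= config.pool_min_carriers}
    if len(pooled) < 2:
        warnings.warn(f"cell ({variant_type},{phenotype},{score_type}): "
                      f"fewer than 2 genes with >= {config.pool_min_carriers} "
                      "carriers; skipped", stacklevel=2)
        return [], None
    mads = {g: gene_mad(v) for g, v in pooled.items()}
    vals = np.array(list(mads.values()))
    mean_mad = float(vals.mean())
    sd_mad = float(vals.std(ddof=1))
    threshold = mean_mad + config.mad_sd_multiplier * sd_mad

    gate = float("nan")
    if score_type == "wfsd":
        all_obs = np.abs(np.concatenate(list(pooled.values())))
        gate = float(np.percentile(all_obs, config.percentile))

    calls = []
    for g in sorted(pooled):
        v = pooled[g]
        f_mad = bool(mads[g] > threshold)
        f_n = bool(len(v) >= config.min_carriers)
        f_pct = True
        if score_type == "wfsd":
            f_pct = bool(np.any(np.abs(v) > gate))
        calls.append(GeneDispersion(g, variant_type, phenotype, score_type,
                                    len(v), mads[g], f_mad, f_n, f_pct,
                                    f_mad and f_n and f_pct))
    return calls, CellSummary(len(pooled), mean_mad, sd_mad, gate)


@dataclass
class OutlierGridResult:
    cells: dict[tuple[str, str, str], list[GeneDispersion]] = field(default_factory=dict)
    summaries: dict[tuple[str, str, str], CellSummary | None] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for calls in self.cells.values():
            for c in calls:
                rows.append(vars(c))
        cols = ["gene", "variant_type", "phenotype", "score_type", "n_carriers",
                "mad", "mad_threshold_flag", "min_samples_flag",
                "percentile_flag", "is_outlier"]
        return pd.DataFrame(rows, columns=cols)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "OutlierGridResult":
        out = cls()
        for (vt, ph, sc), grp in df.groupby(["variant_type", "phenotype",
                                             "score_type"], sort=False):
            out.cells[(vt, ph, sc)] = [
                GeneDispersion(r.gene, vt, ph, sc, int(r.n_carriers),
                               float(r.mad), bool(r.mad_threshold_flag),
                               bool(r.min_samples_flag), bool(r.percentile_flag),
                               bool(r.is_outlier))
                for r in grp.itertuples()]
        return out


def _carrier_values(carrier_genes: pd.DataFrame, outcome: pd.Series
                    ) -> dict[str, np.ndarray]:
    """gene -> one outcome value per carrier.

    A carrier with several qualifying variants in the same gene contributes
    once; carriers hitting multiple genes contribute to each.
    """
    pairs = carrier_genes.drop_duplicates(["individual_id", "gene"])
    pairs = pairs[pairs["individual_id"].isin(outcome.index)]
    groups: dict[str, list[float]] = {}
    for r in pairs.itertuples():
        val = outcome.get(r.individual_id)
        if val is not None and np.isfinite(val):
            groups.setdefault(r.gene, []).append(float(val))
    return {g: np.array(v) for g, v in groups.items() if v}


def run_outlier_grid(carrier_gene_tables: dict[str, pd.DataFrame],
                     raw_scores: dict[str, pd.Series],
                     wfsd_scores: dict[str, pd.Series],
                     config: GridConfig = GridConfig()) -> OutlierGridResult:
    """Populate the eight-cell outlier grid.

    ``carrier_gene_tables`` maps 'dnPTV'/'dnMIS' to (individual_id, gene)
    tables of qualifying variants; ``raw_scores`` and ``wfsd_scores`` map
    'SRS'/'VABS' to proband-indexed outcome Series.
    """
    result = OutlierGridResult()
    for vt in VARIANT_TYPES:
        table = carrier_gene_tables.get(vt, pd.DataFrame(columns=["individual_id", "gene"]))
        for ph in PHENOTYPES:
            for sc, scores in (("raw", raw_scores), ("wfsd", wfsd_scores)):
                outcome = scores.get(ph, pd.Series(dtype=float))
                groups = _carrier_values(table, outcome)
                calls, summary = ([], None)
                if groups:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        calls, summary = call_outliers(groups, sc, config, vt, ph)
                result.cells[(vt, ph, sc)] = calls
                result.summaries[(vt, ph, sc)] = summary
    return result
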