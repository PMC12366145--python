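"""WFSD computation, dataset SDs, contrasts, diagnostics, 2D profile."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st_h

from famdev.cohort import Family, FamilyCohort, assemble_cohort
from famdev.wfsd import (NormsError, PopulationNorms, adjusted_contrast,
                         compute_wfsd, estimate_dataset_sd, normality_report,
                         profile_shift_2d, profile_shift_mean_of_norms,
                         resolve_reference, subgroup_summary)


def build_cohort(individual_rows, phenotype_rows):
    ind = pd.DataFrame(individual_rows, columns=[
        "individual_id", "family_id", "role", "sex", "affected", "age_years",
        "cohort"])
    fams = {}
    for fid, grp in ind.groupby("family_id"):
        proband = grp.loc[grp["role"] == "proband", "individual_id"]
        fams[fid] = Family(fid, list(grp["individual_id"]),
                           proband_id=proband.iloc[0] if len(proband) else None)
    ph = pd.DataFrame(phenotype_rows,
                      columns=["individual_id", "instrument", "score"])
    empty_v = pd.DataFrame(columns=["individual_id", "gene"])
    empty_s = pd.DataFrame(columns=["individual_id", "score_name", "value"])
    return assemble_cohort(ind, fams, ph, empty_v, empty_s)


@pytest.fixture
def simple_family():
    return build_cohort(
        [("p", "F", "proband", "male", True, 8.0, "x"),
         ("s", "F", "sibling", "female", False, 10.0, "x"),
         ("fa", "F", "father", "male", False, 40.0, "x"),
         ("mo", "F", "mother", "female", False, 38.0, "x")],
        [("p", "SRS_T", 80.0), ("s", "SRS_T", 52.0),
         ("fa", "SRS_T", 49.0), ("mo", "SRS_T", 45.0)])


class TestReference:
    def test_two_parent_mean(self, simple_family):
        c = simple_family
        scores = {"fa": 49.0, "mo": 45.0, "p": 80.0}
        mean, n = resolve_reference(c.families["F"], c.individuals, scores,
                                    "parents")
        assert (mean, n) == (47.0, 2)

    def test_single_scored_parent(self, simple_family):
        c = simple_family
        mean, n = resolve_reference(c.families["F"], c.individuals,
                                    {"mo": 45.0}, "parents")
        assert (mean, n) == (45.0, 1)

    def test_unscored_families_are_excluded(self):
        rows_i, rows_p = [], []
        for i in range(20):
            fid = f"F{i}"
            rows_i += [(f"{fid}.p", fid, "proband", "male", True, 8.0, "x"),
                       (f"{fid}.fa", fid, "father", "male", False, 40.0, "x"),
                       (f"{fid}.mo", fid, "mother", "female", False, 40.0, "x")]
            rows_p.append((f"{fid}.p", "SRS_T", 75.0))
            if i < 13:  # only 13 families have any scored parent
                rows_p.append((f"{fid}.fa", "SRS_T", 50.0))
        cohort = build_cohort(rows_i, rows_p)
        rec = compute_wfsd(cohort, "SRS_T", "parents")
        assert len(rec) == 13


class TestComputeWfsd:
    def test_worked_example(self, simple_family):
        rec = compute_wfsd(simple_family, "SRS_T", "parents")
        assert len(rec) == 1
        r = rec.iloc[0]
        assert (r["reference_mean"], r["reference_n"]) == (47.0, 2)
        assert r["wfsd"] == pytest.approx((80.0 - 47.0) / 10.0)  # 3.3

    def test_proband_at_reference_mean_is_zero(self):
        c = build_cohort(
            [("p", "F", "proband", "male", True, 8.0, "x"),
             ("fa", "F", "father", "male", False, 40.0, "x")],
            [("p", "SRS_T", 47.0), ("fa", "SRS_T", 47.0)])
        assert compute_wfsd(c, "SRS_T", "parents")["wfsd"].iloc[0] == 0.0

    def test_population_standardized_severity_equivalence(self):
        # Raw T of 76 sits 2.6 population SDs above the T-score mean of 50.
        norms = PopulationNorms()
        mean, sd = norms.mean("SRS_T"), norms.sd("SRS_T")
        assert (76.0 - mean) / sd == pytest.approx(2.6)

    def test_sibling_pseudo_probands_flagged(self, simple_family):
        rec = compute_wfsd(simple_family, "SRS_T", "parents",
                           pseudo_probands=True)
        assert set(rec["proband_id"]) == {"p", "s"}
        assert rec.set_index("proband_id").loc["s", "pseudo_proband"]

    def test_affected_parent_excluded_from_reference(self):
        c = build_cohort(
            [("p", "F", "proband", "male", True, 8.0, "x"),
             ("fa", "F", "father", "male", True, 40.0, "x"),
             ("mo", "F", "mother", "female", False, 38.0, "x")],
            [("p", "SRS_T", 80.0), ("fa", "SRS_T", 90.0),
             ("mo", "SRS_T", 44.0)])
        r = compute_wfsd(c, "SRS_T", "parents").iloc[0]
        assert (r["reference_mean"], r["reference_n"]) == (44.0, 1)

    @given(st_h.floats(-20, 20))
    def test_linearity_in_proband_score(self, c_shift):
        base = build_cohort(
            [("p", "F", "proband", "male", True, 8.0, "x"),
             ("fa", "F", "father", "male", False, 40.0, "x")],
            [("p", "SRS_T", 70.0 + c_shift), ("fa", "SRS_T", 50.0)])
        rec = compute_wfsd(base, "SRS_T", "parents")
        assert rec["wfsd"].iloc[0] == pytest.approx(2.0 + c_shift / 10.0)

    def test_scale_invariance(self):
        norms_a, norms_b = PopulationNorms(), PopulationNorms()
        norms_b.set("SRS_T", 50.0, 30.0)
        c_a = build_cohort(
            [("p", "F", "proband", "male", True, 8.0, "x"),
             ("fa", "F", "father", "male", False, 40.0, "x")],
            [("p", "SRS_T", 80.0), ("fa", "SRS_T", 50.0)])
        c_b = build_cohort(
            [("p", "F", "proband", "male", True, 8.0, "x"),
             ("fa", "F", "father", "male", False, 40.0, "x")],
            [("p", "SRS_T", 240.0), ("fa", "SRS_T", 150.0)])
        a = compute_wfsd(c_a, "SRS_T", "parents", norms_a)["wfsd"].iloc[0]
        b = compute_wfsd(c_b, "SRS_T", "parents", norms_b)["wfsd"].iloc[0]
        assert a == pytest.approx(b)


class TestDatasetSd:
    def test_two_point_closed_form(self):
        c = build_cohort(
            [("a", "F", "proband", "male", True, 8.0, "x"),
             ("b", "F", "father", "male", False, 40.0, "x")],
            [("a", "SCQ_lifetime", 1.0), ("b", "SCQ_lifetime", 3.0)])
        assert estimate_dataset_sd(c, "SCQ_lifetime") == pytest.approx(np.sqrt(2))

    def test_constant_scores_rejected(self):
        c = build_cohort(
            [("a", "F", "proband", "male", True, 8.0, "x"),
             ("b", "F", "father", "male", False, 40.0, "x"),
             ("c", "F", "mother", "female", False, 40.0, "x")],
            [("a", "SCQ_lifetime", 10.0), ("b", "SCQ_lifetime", 10.0),
             ("c", "SCQ_lifetime", 10.0)])
        with pytest.raises(NormsError, match="0"):
            estimate_dataset_sd(c, "SCQ_lifetime")

    def test_monte_carlo_estimate_close_to_truth(self):
        rng = np.random.default_rng(42)
        rows_i = [(f"I{i}", f"F{i}", "proband", "male", True, 8.0, "x")
                  for i in range(5000)]
        rows_p = [(f"I{i}", "SCQ_lifetime", float(s))
                  for i, s in enumerate(rng.normal(12, 10.45, 5000))]
        c = build_cohort(rows_i, rows_p)
        assert estimate_dataset_sd(c, "SCQ_lifetime") == pytest.approx(
            10.45, rel=0.03)


class TestSubgroupSummary:
    def test_fixture_means(self):
        rec = pd.DataFrame({
            "family_id": ["F1", "F2", "F3", "F4"],
            "proband_id": ["p1", "p2", "p3", "p4"],
            "instrument": "SRS_T", "reference_class": "parents",
            "reference_n": 2, "reference_mean": 50.0,
            "wfsd": [4.0, 4.0, 3.0, 3.0], "pseudo_proband": False})
        sub = pd.DataFrame({"individual_id": ["p1", "p2", "p3", "p4"],
                            "subgroup": ["dnPTV_carrier", "dnPTV_carrier",
                                         "non_carrier", "non_carrier"]})
        out = subgroup_summary(rec, sub).set_index("subgroup")
        assert out.loc["dnPTV_carrier", "mean_wfsd"] == 4.0
        assert out.loc["non_carrier", "mean_wfsd"] == 3.0
        assert out.loc["dnMIS_carrier", "n"] == 0

    def test_gene_set_restriction_can_empty_a_subgroup(self):
        rec = pd.DataFrame({
            "family_id": ["F1"], "proband_id": ["p1"], "instrument": "SRS_T",
            "reference_class": "parents", "reference_n": 2,
            "reference_mean": 50.0, "wfsd": [4.0], "pseudo_proband": False})
        sub = pd.DataFrame({"individual_id": ["p1"],
                            "subgroup": ["dnPTV_carrier"]})
        genes = pd.DataFrame({"individual_id": ["p1"], "gene": ["CHD8"]})
        out = subgroup_summary(rec, sub, gene_set={"SCN2A"},
                               carrier_genes=genes).set_index("subgroup")
        assert out.loc["dnPTV_carrier", "n"] == 0


class TestAdjustedContrast:
    def test_exact_group_difference(self):
        df = pd.DataFrame({
            "value": [1.0] * 10 + [2.0] * 10,
            "subgroup": ["non_carrier"] * 10 + ["dnPTV_carrier"] * 10,
            "age_years": 8.0, "sex": "male", "cohort": "x"})
        res = adjusted_contrast(df)
        coef = res.coefficients.set_index("term")
        assert coef.loc["dnPTV_carrier", "estimate"] == pytest.approx(1.0)

    def test_identical_groups_give_null_coefficient(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(0, 1, 40)
        df = pd.DataFrame({
            "value": np.concatenate([vals, vals]),
            "subgroup": ["non_carrier"] * 40 + ["dnPTV_carrier"] * 40,
            "age_years": 8.0, "sex": "male", "cohort": "x"})
        coef = adjusted_contrast(df).coefficients.set_index("term")
        assert coef.loc["dnPTV_carrier", "estimate"] == pytest.approx(0.0, abs=1e-10)
        assert coef.loc["dnPTV_carrier", "p"] > 0.99

    def test_confounded_cohort_matches_normal_equations_oracle(self):
        # Cohort label shifts the outcome; adjustment recovers the truth.
        rng = np.random.default_rng(5)
        n = 200
        carrier = rng.random(n) < 0.5
        cohort_b = rng.random(n) < (0.2 + 0.6 * carrier)  # confounding
        y = 1.0 * carrier + 2.0 * cohort_b + rng.normal(0, 0.5, n)
        df = pd.DataFrame({
            "value": y,
            "subgroup": np.where(carrier, "dnPTV_carrier", "non_carrier"),
            "age_years": 8.0, "sex": "male",
            "cohort": np.where(cohort_b, "B", "A")})
        res = adjusted_contrast(df, covariates=("cohort",))
        est = res.coefficients.set_index("term").loc["dnPTV_carrier", "estimate"]
        # independent normal-equations solve
        X = np.column_stack([np.ones(n), carrier.astype(float),
                             cohort_b.astype(float)])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert est == pytest.approx(beta[1], abs=1e-8)
        naive = y[carrier].mean() - y[~carrier].mean()
        assert abs(est - 1.0) < abs(naive - 1.0)


class TestNormality:
    def test_normal_sample_scores_high(self):
        rng = np.random.default_rng(8)
        rep = normality_report(rng.normal(0, 1, 5000))
        assert rep.shapiro_w > 0.99

    def test_bimodal_sample_rejected_by_all_three(self):
        rng = np.random.default_rng(9)
        x = np.concatenate([rng.normal(-3, 0.5, 1000), rng.normal(3, 0.5, 1000)])
        rep = normality_report(x)
        assert rep.shapiro_p < 0.05
        assert rep.anderson_p < 0.05
        assert rep.ks_p < 0.05

    def test_constant_vector_is_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            normality_report(np.ones(100))

    def test_small_sample_names_the_minimum(self):
        with pytest.raises(ValueError, match="8"):
            normality_report([1.0, 2.0, 3.0])


class TestProfile2D:
    @staticmethod
    def records(values, instrument):
        return pd.DataFrame({
            "family_id": [f"F{i}" for i in range(len(values))],
            "proband_id": [f"p{i}" for i in range(len(values))],
            "instrument": instrument, "reference_class": "parents",
            "reference_n": 2, "reference_mean": 0.0, "wfsd": values,
            "pseudo_proband": False})

    def test_three_four_five_triangle(self):
        shift = profile_shift_2d(self.records([3.0, 3.0], "SRS_T"),
                                 self.records([-4.0, -4.0], "VABS_total"))
        assert shift.magnitude == pytest.approx(5.0)
        assert shift.n_families == 2

    def test_zero_vector(self):
        shift = profile_shift_2d(self.records([0.0], "SRS_T"),
                                 self.records([0.0], "VABS_total"))
        assert shift.magnitude == 0.0

    def test_joint_availability_only(self):
        srs = self.records([3.0, 1.0], "SRS_T")
        vabs = self.records([-4.0], "VABS_total")  # only F0 has both
        shift = profile_shift_2d(srs, vabs)
        assert shift.n_families == 1
        assert shift.magnitude == pytest.approx(5.0)

    def test_magnitude_matches_column_mean_norm_oracle(self):
        rng = np.random.default_rng(12)
        srs_vals = rng.normal(3, 1, 200)
        vabs_vals = rng.normal(-2, 1, 200)
        shift = profile_shift_2d(self.records(srs_vals, "SRS_T"),
                                 self.records(vabs_vals, "VABS_total"))
        oracle = float(np.sqrt(srs_vals.mean() ** 2 + vabs_vals.mean() ** 2))
        assert shift.magnitude == pytest.approx(oracle)
        # ordering invariance
        perm = rng.permutation(200)
        shuffled = profile_shift_2d(
            self.records(srs_vals, "SRS_T").iloc[perm].reset_index(drop=True),
            self.records(vabs_vals, "VABS_total"))
        assert shuffled.magnitude == pytest.approx(shift.magnitude)
        # mean of norms is the companion aggregation, >= norm of means
        mon = profile_shift_mean_of_norms(self.records(srs_vals, "SRS_T"),
                                          self.records(vabs_vals, "VABS_total"))
        assert mon >= shift.magnitude
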