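"""Agreement statistics, interpretation bands and age-adjusted odds ratios."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import cohen_kappa_score

from jemkit import (
    JEM,
    assign_exposure,
    auc,
    cohen_kappa,
    interpret_auc,
    interpret_kappa,
    logistic_or,
    validity_report,
)
from jemkit.errors import DataError, DegenerateStatisticError
from jemkit.validate import agreement_report

from conftest import SYSTEM, make_cell


def brute_force_auc(scores, labels):
    """O(n^2) pairwise concordance with ties counted 1/2."""
    scores, labels = np.asarray(scores, float), np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def brute_force_kappa(x, y):
    x, y = np.asarray(x), np.asarray(y)
    p_o = np.mean(x == y)
    p_e = sum(np.mean(x == v) * np.mean(y == v)
              for v in set(x.tolist()) | set(y.tolist()))
    return (p_o - p_e) / (1 - p_e)


class TestCohenKappa:
    def test_identical_nonconstant_vectors(self):
        x = np.array([0, 1, 0, 1, 1])
        assert cohen_kappa(x, x) == pytest.approx(1.0)

    def test_hand_built_paired_table(self):
        # both-exposed 40, both-unexposed 40, discordant 10 + 10
        x = np.array([1] * 40 + [0] * 40 + [1] * 10 + [0] * 10)
        y = np.array([1] * 40 + [0] * 40 + [0] * 10 + [1] * 10)
        assert cohen_kappa(x, y) == pytest.approx(0.6)  # p_o=.8, p_e=.5

    def test_perfect_disagreement_on_balanced_vectors(self):
        x = np.array([0, 1] * 10)
        assert cohen_kappa(x, 1 - x) == pytest.approx(-1.0)

    def test_symmetry_and_label_swap_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.integers(0, 2, 50)
        y = rng.integers(0, 2, 50)
        assert cohen_kappa(x, y) == pytest.approx(cohen_kappa(y, x))
        assert cohen_kappa(1 - x, 1 - y) == pytest.approx(cohen_kappa(x, y))

    def test_degenerate_when_expected_agreement_is_one(self):
        with pytest.raises(DegenerateStatisticError, match="p_e = 1"):
            cohen_kappa(np.ones(10), np.ones(10))

    def test_matches_library_on_random_instances(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            n = int(rng.integers(2, 200))
            x = rng.integers(0, 2, n)
            y = rng.integers(0, 2, n)
            if (x == x[0]).all() and (y == x[0]).all():
                continue
            expected = cohen_kappa_score(x, y)
            if np.isnan(expected):
                continue
            assert cohen_kappa(x, y) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("value, band", [
    (0.39, "fair"), (0.74, "good"), (1.0, "excellent"),
    (0.19, "poor"), (0.20, "poor"), (0.21, "fair"),
    (0.40, "fair"), (0.41, "moderate"), (0.60, "moderate"), (0.61, "good"),
    (0.80, "good"), (0.81, "excellent"), (-0.3, "poor"),
    (0.204, "poor"), (0.205, "fair"),  # half-up rounding at the gap
])
def test_kappa_interpretation_bands(value, band):
    assert interpret_kappa(value) == band


class TestAuc:
    def test_perfect_separation_and_all_ties(self):
        labels = np.array([0, 0, 1, 1])
        assert auc([1, 2, 3, 4], labels) == pytest.approx(1.0)
        assert auc([2, 2, 2, 2], labels) == pytest.approx(0.5)

    def test_enumerated_example(self):
        labels = np.array([1, 1, 0, 0])
        scores = np.array([0.9, 0.4, 0.6, 0.2])
        assert auc(scores, labels) == pytest.approx(0.75)  # 3 of 4 pairs concordant

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(21)
        for _ in range(30):
            n = int(rng.integers(4, 120))
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            scores = rng.integers(0, 5, n).astype(float)
            assert auc(scores, labels) == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-12)

    def test_score_negation_complements(self):
        rng = np.random.default_rng(22)
        labels = rng.integers(0, 2, 80)
        scores = rng.normal(size=80)
        assert auc(scores, labels) + auc(-scores, labels) == pytest.approx(1.0)

    def test_single_class_labels_rejected(self):
        with pytest.raises(DataError, match="single class"):
            auc([1.0, 2.0], [1, 1])


@pytest.mark.parametrize("value, band", [
    (0.55, "failed"), (0.59, "failed"), (0.62, "poor"), (0.69, "poor"),
    (0.70, "fair"), (0.76, "fair"), (0.79, "fair"), (0.80, "good"),
    (0.89, "good"), (0.90, "excellent"), (1.0, "excellent"),
])
def test_auc_interpretation_bands(value, band):
    assert interpret_auc(value) == band


class TestLogisticOr:
    def test_matches_two_by_two_cross_product_without_age(self):
        # grouped data: a=30 exposed cases, b=70, c=20, d=180
        outcome = np.array([1] * 30 + [0] * 70 + [1] * 20 + [0] * 180)
        exposure = np.array([1] * 100 + [0] * 200)
        res = logistic_or(outcome, exposure, age=None)
        assert res.converged
        assert res.oddsratio == pytest.approx((30 * 180) / (70 * 20), abs=1e-6)

    def test_null_association_ci_contains_one(self):
        rng = np.random.default_rng(42)
        n = 50_000
        exposure = rng.integers(0, 2, n)
        age = rng.uniform(25, 60, n)
        outcome = (rng.random(n) < 0.2).astype(int)
        res = logistic_or(outcome, exposure, age)
        assert res.ci_low < 1.0 < res.ci_high
        assert res.oddsratio == pytest.approx(1.0, abs=0.1)

    def test_separation_is_flagged_not_silent(self):
        outcome = np.array([1] * 30 + [0] * 30)
        exposure = outcome.copy()
        res = logistic_or(outcome, exposure)
        assert not res.converged and np.isnan(res.oddsratio)
        assert res.note

    def test_preconditions(self):
        with pytest.raises(DataError, match="too small"):
            logistic_or([1, 0] * 5, [0, 1] * 5, age=list(range(10)))
        with pytest.raises(DataError, match="single class"):
            logistic_or([1, 0] * 10, [1] * 20)

    def test_age_bands_option_runs(self):
        rng = np.random.default_rng(9)
        n = 2000
        exposure = rng.integers(0, 2, n)
        age = rng.uniform(25, 60, n)
        logit = -1.5 + 0.5 * exposure + 0.02 * (age - 40)
        outcome = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
        res = logistic_or(outcome, exposure, age, age_bands=[35, 45, 55])
        assert res.converged and res.ci_low < res.oddsratio < res.ci_high


class TestAssignExposure:
    def test_category_lookup_and_dichotomization(self, tiny_jem, tiny_population):
        res = assign_exposure(tiny_population, tiny_jem, "heavy_lifting")
        frame = res.frame
        men_7210 = frame[(frame.occupation_code == "7210") & (frame.gender == "M")]
        assert (men_7210.category == 3).all() and (men_7210.exposed == 1).all()
        assert res.n_unmatched == 0

    def test_gender_specific_assignment_differs(self, tiny_jem, tiny_population):
        res = assign_exposure(tiny_population, tiny_jem, "heavy_lifting")
        frame = res.frame
        sub = frame[frame.occupation_code == "5120"]
        assert set(sub[sub.gender == "M"].exposed) == {1.0}  # 30% -> exposed
        assert set(sub[sub.gender == "F"].exposed) == {1.0}
        sub = frame[frame.occupation_code == "7210"]
        assert set(sub[sub.gender == "M"].category) == {3}
        assert set(sub[sub.gender == "F"].category) == {2}

    def test_unmatched_marked_missing_and_counted(self, tiny_jem):
        pop = pd.DataFrame({"person_id": ["a", "b"],
                            "occupation_code": ["0110", "8888"],
                            "gender": ["M", "M"], "age": [30, 40]})
        res = assign_exposure(pop, tiny_jem, "heavy_lifting")
        assert res.n_unmatched == 1 and res.unmatched_codes == {"8888": 1}
        assert np.isnan(res.frame.loc[res.frame.person_id == "b", "exposed"]).all()

    def test_fully_unmatched_escalates_to_error(self, tiny_jem):
        pop = pd.DataFrame({"person_id": ["a"], "occupation_code": ["8888"],
                            "gender": ["M"], "age": [30]})
        with pytest.raises(DataError, match="all 1 unmatched"):
            assign_exposure(pop, tiny_jem, "heavy_lifting")


def planted_cohort(seed=0, n=3000):
    """Cohort over the tiny matrix codes with a planted exposure effect."""
    rng = np.random.default_rng(seed)
    codes = np.array(["0110", "2110", "5120", "7210", "9310"])
    rows = {"person_id": [f"p{i}" for i in range(n)],
            "occupation_code": rng.choice(codes, n),
            "gender": rng.choice(["M", "F"], n),
            "age": rng.uniform(25, 60, n)}
    df = pd.DataFrame(rows)
    exposed_codes = {"5120", "7210", "9310"}
    exposed = df.occupation_code.isin(exposed_codes).astype(int)
    logit = -1.4 + np.log(1.8) * exposed + 0.02 * (df.age - 40)
    df["low_back_pain"] = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
    df["knee_pain"] = (rng.random(n) < 0.15).astype(int)
    return df


class TestValidityReport:
    def test_full_grid_populated(self, tiny_jem):
        cohort = planted_cohort()
        report = validity_report(cohort, tiny_jem,
                                 [("heavy_lifting", "low_back_pain"),
                                  ("heavy_lifting", "knee_pain")])
        assert len(report) == 4  # 2 pairs x 2 genders
        lbp = report[report.outcome_id == "low_back_pain"]
        assert (lbp.value > 1).all() and (lbp.flag == "").all()
        for _, row in lbp.iterrows():
            assert row.ci_low <= row.value <= row.ci_high

    def test_gender_relabelling_permutes_rows(self, tiny_jem):
        cohort = planted_cohort(seed=5)
        flipped = cohort.assign(gender=cohort.gender.map({"M": "F", "F": "M"}))
        # the tiny matrix differs by gender, so compare on a gender-symmetric one
        sym = JEM("sym", SYSTEM,
                  [make_cell(c, g, "heavy_lifting", prevalence=p)
                   for c, p in [("0110", 2.0), ("2110", 10.0), ("5120", 30.0),
                                ("7210", 60.0), ("9310", 80.0)]
                   for g in ("M", "F")])
        a = validity_report(cohort, sym, [("heavy_lifting", "low_back_pain")])
        b = validity_report(flipped, sym, [("heavy_lifting", "low_back_pain")])
        a_m = a[a.gender == "M"].iloc[0]
        b_f = b[b.gender == "F"].iloc[0]
        assert a_m.value == pytest.approx(b_f.value)
        assert a_m.n == b_f.n

    def test_empty_stratum_flagged_not_dropped(self, tiny_jem):
        cohort = planted_cohort(seed=2, n=500)
        cohort = cohort[cohort.gender == "M"]
        report = validity_report(cohort, tiny_jem,
                                 [("heavy_lifting", "low_back_pain")])
        f_row = report[report.gender == "F"]
        assert len(f_row) == 1 and f_row.iloc[0].flag == "empty stratum"

    def test_unknown_pair_ids_rejected(self, tiny_jem):
        cohort = planted_cohort(n=200)
        with pytest.raises(DataError, match="unknown exposure"):
            validity_report(cohort, tiny_jem, [("nope", "low_back_pain")])
        with pytest.raises(DataError, match="unknown outcome"):
            validity_report(cohort, tiny_jem, [("heavy_lifting", "nope")])


def test_agreement_report_shape_and_bands(tiny_jem, tiny_population):
    other = JEM("other", SYSTEM,
                [make_cell(c.occupation.code, c.gender, c.exposure_id,
                           prevalence=c.prevalence_pct)
                 for c in tiny_jem])
    report = agreement_report(tiny_population, tiny_jem, other,
                              ["heavy_lifting"])
    assert set(report.gender) == {"M", "F"}
    row = report.iloc[0]
    assert row.kappa == pytest.approx(1.0)
    assert row.kappa_band == "excellent"
    assert row.auc_a_vs_b == pytest.approx(1.0)
    assert row.pct_exposed_a == row.pct_exposed_b
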