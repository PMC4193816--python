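"""Cohort statistics: TAC derivation, groups, prevalence, distributions, risk, tests."""

import numpy as np
import pandas as pd
import pytest

from aortacalc.cohort import (
    add_framingham_risk,
    age_tertile_prevalence,
    classify_group,
    derive_tac,
    group_comparisons,
    lesion_distribution,
    prevalence_by_segment,
    round_pct,
)
from aortacalc.framingham import MissingCovariateError, framingham_risk
from aortacalc.synthcohort import SEGMENT_COLUMNS, CohortSpec, generate_cohort


def _subject(scores, cac=0.0, **kw):
    row = {"id": 0, "cac": cac, "age": 55.0, "male": True, "sbp_mmhg": 130.0,
           "total_chol_mmol": 5.5, "hdl_mmol": 1.3, "hypertension": False,
           "hypercholesterolemia": False, "smoker": False, "diabetes": False}
    row.update({c: s for c, s in zip(SEGMENT_COLUMNS, scores)})
    row.update(kw)
    return pd.DataFrame([row])


class TestDeriveAndClassify:
    @pytest.mark.parametrize(
        "scores,expected",
        [
            ((0, 0, 10, 20, 0), (0, 30)),
            ((5, 0, 0, 0, 7), (12, 12)),
            ((0, 0, 0, 0, 0), (0, 0)),
        ],
    )
    def test_standard_and_extended_tac(self, scores, expected):
        df = derive_tac(_subject(scores))
        assert (df["standard_tac"].iloc[0], df["extended_tac"].iloc[0]) == expected

    def test_missing_segment_column_raises(self):
        df = _subject((0, 0, 0, 0, 0)).drop(columns=["tac_s3"])
        with pytest.raises(KeyError, match="tac_s3"):
            derive_tac(df)

    @pytest.mark.parametrize(
        "scores,cac,group",
        [
            ((0, 0, 0, 0, 0), 0.0, 1),     # free of calcium
            ((0, 0, 40, 0, 0), 0.0, 3),    # arch only, no CAC: reclassification candidate
            ((0, 0, 0, 0, 0), 12.0, 2),    # CAC detected by the standard scan
            ((3, 0, 0, 0, 0), 0.0, 2),     # standard TAC positive
        ],
    )
    def test_group_labels(self, scores, cac, group):
        df = derive_tac(_subject(scores, cac=cac))
        assert classify_group(df).iloc[0] == group

    def test_standard_never_exceeds_extended(self):
        df = derive_tac(generate_cohort(CohortSpec(n=200, mode="stochastic", seed=4)))
        assert (df["standard_tac"] <= df["extended_tac"]).all()


class TestPrevalence:
    def test_single_subject_all_positive(self):
        df = _subject((1, 1, 1, 1, 1))
        assert prevalence_by_segment(df)["pct"].tolist() == [100] * 5

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            prevalence_by_segment(_subject((0,) * 5).iloc[:0])

    def test_rounding_half_away_from_zero(self):
        assert round_pct(0.5) == 1
        assert round_pct(1.5) == 2
        assert round_pct(2.5) == 3
        assert round_pct(-0.5) == -1
        assert round_pct(np.array([41.5, 41.49])).tolist() == [42, 41]


class TestLesionDistribution:
    def test_printed_count_split_shares(self):
        counts = np.array([412, 371, 2803, 3824, 3421])
        dist = lesion_distribution(counts, np.ones(5))
        assert dist["share_pct"].tolist() == [4, 3, 26, 35, 32]
        ascending = counts[0] + counts[1]
        assert round_pct(100.0 * ascending / counts.sum()) == 7

    def test_single_lesion_cohort(self):
        dist = lesion_distribution([0, 0, 1, 0, 0], np.ones(5))
        assert dist["share_pct"].tolist() == [0, 0, 100, 0, 0]

    def test_per_cm_density_scaling_identity(self):
        counts = np.array([10, 20, 30, 40, 50])
        lengths = np.array([5.0, 6.0, 4.0, 9.0, 5.0])
        d1 = lesion_distribution(counts, lengths)["per_cm"].to_numpy()
        d2 = lesion_distribution(counts, 2 * lengths)["per_cm"].to_numpy()
        np.testing.assert_allclose(d2, d1 / 2)

    def test_zero_lesions_flagged(self):
        with pytest.warns(UserWarning, match="no lesions"):
            dist = lesion_distribution(np.zeros(5), np.ones(5))
        assert dist["share_pct"].tolist() == [0] * 5


class TestAgeTertiles:
    def test_constant_age_still_partitions_evenly(self):
        df = generate_cohort(CohortSpec(n=970, mode="stochastic", seed=5))
        df["age"] = 57.0
        tert = age_tertile_prevalence(df)
        assert sorted(tert["n"].tolist()) == [323, 323, 324]

    def test_age_independent_positivity_gives_flat_tertiles(self):
        spec = CohortSpec(n=970, mode="stochastic", seed=6)
        df = generate_cohort(spec)
        tert = age_tertile_prevalence(df)
        p = 1 - np.prod([1 - q for q in spec.segment_prevalence])
        se = 100 * np.sqrt(p * (1 - p) / 323)
        assert np.all(np.abs(tert["any_pct"] - 100 * p) < 3.5 * se)

    def test_too_small_cohort_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            age_tertile_prevalence(_subject((0,) * 5))


class TestFramingham:
    def test_deterministic_for_identical_subjects(self):
        a = framingham_risk(58, True, 5.9, 1.2, 135, True, False)
        b = framingham_risk(58, True, 5.9, 1.2, 135, True, False)
        assert a == b

    def test_strictly_increasing_in_age(self):
        risks = [framingham_risk(a, False, 5.5, 1.4, 125, False, False)
                 for a in range(30, 75)]
        assert np.all(np.diff(risks) > 0)

    def test_frozen_reference_values(self):
        # computed once with an independent hand implementation of the
        # published coefficient table and frozen here
        assert framingham_risk(55, True, 6.2, 1.3, 140, True, False) == pytest.approx(
            27.239620395240994, rel=1e-12
        )
        assert framingham_risk(62, False, 5.1, 1.6, 128, False, True) == pytest.approx(
            12.700646126767213, rel=1e-12
        )

    def test_missing_covariate_named(self):
        with pytest.raises(MissingCovariateError, match="hdl_mmol"):
            framingham_risk(55, True, 6.2, float("nan"), 140, True, False)

    def test_risk_column_added(self):
        df = add_framingham_risk(_subject((0,) * 5))
        assert 0 <= df["frs"].iloc[0] <= 100


class TestGroupComparisons:
    def test_sex_difference_on_exact_cohort_is_significant(self):
        df = generate_cohort(CohortSpec(seed=3))
        report = group_comparisons(df)
        assert report["group_n"] == {1: 211, 2: 648, 3: 111}
        assert report["categorical"]["male"]["n_pos"] == {1: 167, 2: 527, 3: 60}
        assert report["categorical"]["male"]["chi2_p"] < 0.001
        # age differs between groups by construction (calcium tracks age)
        assert report["continuous"]["age"]["anova_p"] < 0.001

    def test_identical_groups_show_no_tukey_difference(self):
        rng = np.random.default_rng(7)
        rows = []
        for g, (cac, s3) in enumerate([(0.0, 0.0), (5.0, 0.0), (0.0, 5.0)]):
            for i in range(40):
                rows.append(_subject((0, 0, s3, 0, 0), cac=cac,
                                     age=float(rng.normal(55, 8))).iloc[0])
        df = pd.DataFrame(rows).reset_index(drop=True)
        df["id"] = np.arange(len(df))
        report = group_comparisons(df)
        # all groups drawn from one age distribution: no pairwise rejection
        assert not any(v["reject"] for v in report["continuous"]["age"]["tukey"].values())

    def test_small_group_skipped_with_warning(self):
        df = pd.concat([_subject((0,) * 5, cac=0.0),
                        _subject((0, 0, 5, 0, 0), cac=0.0)], ignore_index=True)
        df["id"] = np.arange(len(df))
        with pytest.warns(UserWarning, match="skipped"):
            report = group_comparisons(df)
        assert report["group_n"][2] == 0
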