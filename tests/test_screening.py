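import numpy as np
import pandas as pd
import pytest
from scipy import stats

from jointplay.screening import (
    ContingencyTable,
    DiagnosticScreen,
    dichotomize,
    evaluate_criterion,
    fisher_exact,
    recover_table,
    screening_values,
    tabulate,
)

from _oracles import fisher_exact_oracle


def random_tables(rng, count, n_max=40):
    for _ in range(count):
        n = int(rng.integers(4, n_max + 1))
        cells = rng.multinomial(n, [0.25, 0.25, 0.25, 0.25])
        if cells.sum() == 0:
            continue
        yield ContingencyTable(*map(int, cells))


class TestDichotomize:
    def test_strictly_beyond_threshold(self):
        out = dichotomize([1.0, 2.0, 3.0], 2.0, "greater")
        assert list(out) == [False, False, True]  # tie is test-negative

    def test_all_below(self):
        assert not dichotomize([0.1, 0.5], 2.0, "greater").any()

    def test_less_direction(self):
        assert list(dichotomize([1.0, 2.0, 3.0], 2.0, "less")) == [True, False, False]

    def test_pivot_shift_positivity_cut(self):
        grades = [0, 1, 2, 3, 0]
        out = dichotomize(grades, 0.5, "greater")  # grade >= 1 is positive
        assert list(out) == [False, True, True, True, False]

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            dichotomize([1.0, np.nan], 0.5)


class TestScreeningValues:
    def test_published_jpe_row_table(self):
        r = screening_values(ContingencyTable(tp=5, fn=1, fp=1, tn=23))
        assert (r.sensitivity_rounded, r.specificity_rounded,
                r.ppv_rounded, r.npv_rounded) == (83, 96, 83, 96)
        assert r.sensitivity == pytest.approx(100 * 5 / 6)
        assert r.npv == pytest.approx(100 * 23 / 24)

    def test_perfect_test(self):
        r = screening_values(ContingencyTable(10, 0, 0, 10))
        assert (r.sensitivity, r.specificity, r.ppv, r.npv) == (100, 100, 100, 100)

    def test_empty_diseased_class_undefined_not_zero(self):
        r = screening_values(ContingencyTable(tp=0, fn=0, fp=2, tn=8))
        assert r.sensitivity is None
        assert r.specificity == pytest.approx(80.0)
        assert r.npv == pytest.approx(100.0)  # tn/(tn+fn) with fn = 0
        assert r.ppv == pytest.approx(0.0)

    def test_invalid_cells_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 0, 0, 5)
        with pytest.raises(ValueError):
            ContingencyTable(0, 0, 0, 0)


class TestFisherExact:
    def test_exchangeable_rows_give_p_one(self):
        assert fisher_exact(ContingencyTable(1, 1, 1, 1)) == pytest.approx(1.0)

    def test_jpe_table_hand_enumeration(self):
        # margins 6/6 in n=30: P(5)=144/593775, P(6)=1/593775, no other
        # table is as extreme, so p = 145/593775
        p = fisher_exact(ContingencyTable(5, 1, 1, 23))
        assert p == pytest.approx(145 / 593775, rel=1e-9)

    def test_zero_margin_single_table(self):
        assert fisher_exact(ContingencyTable(0, 0, 2, 8)) == 1.0

    def test_doubling_method(self):
        p = fisher_exact(ContingencyTable(5, 1, 1, 23), method="doubling")
        assert p == pytest.approx(2 * 145 / 593775, rel=1e-9)

    def test_matches_exact_rational_oracle_on_random_tables(self, rng):
        for t in random_tables(rng, 150):
            expected = fisher_exact_oracle(t.tp, t.fp, t.fn, t.tn)
            assert fisher_exact(t) == pytest.approx(expected, rel=1e-10), t

    def test_matches_scipy_on_untied_tables(self):
        for cells in [(5, 1, 1, 23), (4, 2, 2, 22), (3, 7, 5, 11), (8, 2, 1, 9)]:
            t = ContingencyTable(*cells)
            p_scipy = stats.fisher_exact(
                [[t.tp, t.fp], [t.fn, t.tn]]
            ).pvalue
            assert fisher_exact(t) == pytest.approx(p_scipy, rel=1e-7)

    def test_transposition_and_swap_invariance(self, rng):
        for t in random_tables(rng, 60):
            p = fisher_exact(t)
            assert fisher_exact(t.transpose()) == pytest.approx(p, rel=1e-10)
            swapped = ContingencyTable(tp=t.tn, fp=t.fn, fn=t.fp, tn=t.tp)
            assert fisher_exact(swapped) == pytest.approx(p, rel=1e-10)

    def test_chi_square_ordering_sanity(self, rng):
        # on well-filled tables the exact p and the chi-square approximation
        # should order tables almost identically
        logs_f, logs_c = [], []
        while len(logs_f) < 60:
            cells = rng.integers(5, 30, size=4)
            t = ContingencyTable(*map(int, cells))
            chi = stats.chi2_contingency(
                [[t.tp, t.fp], [t.fn, t.tn]], correction=False
            ).pvalue
            logs_f.append(-np.log(fisher_exact(t)))
            logs_c.append(-np.log(max(chi, 1e-300)))
        rho = stats.spearmanr(logs_f, logs_c).statistic
        assert rho > 0.95


class TestRecoverTable:
    def test_published_jpe_row_unique_recovery(self):
        matches = recover_table((83, 96, 83, 96), n_max=30, diseased=[6],
                                n_total=30)
        assert matches == [ContingencyTable(tp=5, fp=1, fn=1, tn=23)]

    def test_perfect_row(self):
        matches = recover_table((100, 100, 100, 100), n_max=4, diseased=[2],
                                n_total=4)
        assert matches == [ContingencyTable(tp=2, fp=0, fn=0, tn=2)]

    def test_published_total_rotation_row_recovers_no_table(self):
        # the printed 29/92/83/59 row is internally inconsistent: a
        # sensitivity of 29 with ppv 83 and specificity 92 forces an npv
        # near 48 at any table size, so the audit correctly finds nothing
        assert recover_table((29, 92, 83, 59), n_max=30, diseased=[6],
                             n_total=30) == []
        assert recover_table((29, 92, 83, 59), n_max=60) == []

    def test_published_kt_row_recovers_nine_positive_table(self):
        # the KT manual-max row 56/95/83/83 admits no 6-positive table but a
        # unique 30-limb table with 9 positives
        assert recover_table((56, 95, 83, 83), n_max=30, diseased=[6],
                             n_total=30) == []
        matches = recover_table((56, 95, 83, 83), n_max=30, n_total=30)
        assert ContingencyTable(tp=5, fp=1, fn=4, tn=20) in matches

    def test_roundtrip_identity_on_recovered_tables(self, rng):
        for _ in range(20):
            t = next(iter(random_tables(rng, 1, n_max=30)))
            r = screening_values(t)
            if None in (r.sensitivity, r.specificity, r.ppv, r.npv):
                continue
            rounded = (r.sensitivity_rounded, r.specificity_rounded,
                       r.ppv_rounded, r.npv_rounded)
            matches = recover_table(rounded, n_max=t.n, n_total=t.n,
                                    diseased=[t.n_diseased])
            assert t in matches
            for m in matches:
                rm = screening_values(m)
                assert (rm.sensitivity_rounded, rm.specificity_rounded,
                        rm.ppv_rounded, rm.npv_rounded) == rounded


class TestEvaluateCriterion:
    def test_jpe_screens_study_cohort(self, study_analysis):
        res = evaluate_criterion(study_analysis, "jpe_mmdeg", threshold="search")
        assert res.p_value < 0.001
        assert res.specificity > 90
        # condition split: 6 positives, 24 negatives
        assert res.table.n_diseased == 6
        assert res.table.n == 30

    def test_strongly_separated_jpe_screens_above_90(self):
        # study-shaped cohort with tightened dispersions: the JPE separation
        # between Group-2 reconstructed limbs and all others is then large
        # relative to noise and both screening rates clear 90 %
        from jointplay.curves import extract_features, features_frame
        from jointplay.generator import CohortSpec, generate_cohort
        from jointplay.metrics import build_analysis_table

        cohort = generate_cohort(
            CohortSpec(seed=77, sd_rotation=4.0, sd_slope=0.02,
                       sd_kt=0.75, sd_play=1.0)
        )
        feats = {
            (r.subject_id, r.limb_status): extract_features(r)
            for r in cohort.recordings()
        }
        analysis = build_analysis_table(cohort.cohort_frame(),
                                        features_frame(feats))
        res = evaluate_criterion(analysis, "jpe_mmdeg", threshold="search")
        assert res.sensitivity > 90
        assert res.specificity > 90

    def test_constant_criterion_p_one_at_fixed_threshold(self, study_analysis):
        df = study_analysis.copy()
        df["constant"] = 5.0
        res = evaluate_criterion(df, "constant", threshold=7.0)
        assert res.p_value == 1.0
        with pytest.raises(ValueError, match="constant"):
            evaluate_criterion(df, "constant", threshold="search")

    def test_missing_condition_class_rejected(self, study_analysis):
        only_g1 = study_analysis[study_analysis.group == 1]
        with pytest.raises(ValueError, match="condition"):
            evaluate_criterion(only_g1, "jpe_mmdeg")

    def test_threshold_search_tiebreak_smaller_positive_count(self):
        # two thresholds give the same table-free p (p=1); the smaller
        # positive count must win
        df = pd.DataFrame(
            {
                "subject_id": [f"S{i}" for i in range(8)],
                "limb": ["reconstructed", "healthy"] * 4,
                "vas": [60, 60, 60, 60, 90, 90, 90, 90],
                "group": [2, 2, 2, 2, 1, 1, 1, 1],
                "crit": [1.0, 2.0, 3.0, 4.0, 1.5, 2.5, 3.5, 4.5],
            }
        )
        res = evaluate_criterion(df, "crit", threshold="search")
        n_pos = res.table.tp + res.table.fp
        for thr in np.unique(df["crit"])[:-1] + 0.25:
            t = tabulate(dichotomize(df[df.group.isin([1, 2])]["crit"], thr),
                         (df["group"] == 2) & (df["limb"] == "reconstructed"))
            from jointplay.screening import fisher_exact as fe

            if fe(t) == pytest.approx(res.p_value):
                assert n_pos <= t.tp + t.fp


class TestDiagnosticScreenModel:
    def test_fit_and_summary(self, study_analysis):
        res = DiagnosticScreen(study_analysis, "jpe_mmdeg").fit()
        text = res.summary()
        assert "sensitivity" in text and "Fisher exact p" in text
        frame = res.to_frame()
        assert set(["criterion", "sensitivity", "p_value", "tp"]).issubset(
            frame.columns
        )
        assert res.p_value == res.result.p_value

    def test_fixed_threshold_fit(self, study_analysis):
        thr = float(study_analysis["jpe_mmdeg"].median())
        res = DiagnosticScreen(study_analysis, "jpe_mmdeg").fit(threshold=thr)
        assert res.threshold == thr
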