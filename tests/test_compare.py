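import csv
import json
import math

import numpy as np
import pytest
from scipy import stats

from dentage import (
    DentageError,
    GroupStats,
    TableStandard,
    ToothStageRating,
    compare_methods,
    estimate_cohort,
    group_summary,
    load_builtin,
    oneway_anova,
    paired_t,
    scheffe_pairwise,
    scheffe_subsets,
    t_from_moments,
    weighted_mean,
    weighted_total,
    write_report_csv,
    write_report_json,
)
from dentage.reference import load_reference_summaries
from dentage.staging import TEETH


def rating(subject_id, sex, ca, stage):
    return ToothStageRating(
        subject_id=subject_id, sex=sex, stages={t: stage for t in TEETH}, ca_years=ca
    )


class TestEstimateCohort:
    def test_single_subject_composition(self, demo_weights, saudi_tables):
        # All-G male demo stages: score 83, inside the Saudi male grid span.
        r = rating("s1", "male", 8.0, "G")
        (res,) = estimate_cohort([r], demo_weights, [saudi_tables["male"]])
        expected = saudi_tables["male"].score_to_age(83.0)
        assert res.maturity_score == pytest.approx(83.0)
        assert res.dental_age["saudi_male"] == pytest.approx(expected)
        assert res.difference["saudi_male"] == pytest.approx(expected - 8.0)
        assert res.age_group == "8.00-8.99"

    def test_age_coverage_exclusion_leaves_fields_absent(self, demo_weights):
        std = TableStandard(
            name="older_only", sex="male", scores=(0.0, 100.0), ages=(4.0, 14.0),
            age_limits=(7.5, 17.0),
        )
        young = rating("y", "male", 5.2, "D")
        old = rating("o", "male", 9.3, "D")
        res = estimate_cohort([young, old], demo_weights, [std])
        assert "older_only" not in res[0].dental_age
        assert "older_only" not in res[0].difference
        assert "older_only" in res[1].dental_age

    def test_score_coverage_exclusion(self, demo_weights, saudi_tables):
        r = rating("s1", "male", 5.0, "0")  # score 0 < grid start 25.8
        (res,) = estimate_cohort([r], demo_weights, [saudi_tables["male"]])
        assert res.dental_age == {}

    def test_sex_routing(self, demo_weights, saudi_tables):
        r = rating("f1", "female", 8.0, "G")
        (res,) = estimate_cohort(
            [r], demo_weights, [saudi_tables["male"], saudi_tables["female"]]
        )
        assert set(res.dental_age) == {"saudi_female"}

    def test_no_standards_rejected(self, demo_weights):
        with pytest.raises(DentageError, match="standard"):
            estimate_cohort([rating("s", "male", 8.0, "D")], demo_weights, [])


class TestPairedT:
    def test_all_zero(self):
        res = paired_t([0.0] * 6)
        assert res.t == 0.0
        assert res.p == 1.0

    def test_formula_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            d = rng.normal(0.3, 1.0, size=5)
            res = paired_t(d)
            t_direct = d.mean() / (d.std(ddof=1) / math.sqrt(5))
            assert res.t == pytest.approx(t_direct, rel=1e-12)
            ref = stats.ttest_1samp(d, 0.0)
            assert res.p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_degenerate_variance_flagged(self):
        res = paired_t([0.5, 0.5, 0.5])
        assert res.degenerate
        assert res.p == 0.0
        assert math.isinf(res.t)

    def test_from_moments_matches_sample(self):
        rng = np.random.default_rng(9)
        d = rng.normal(0.2, 0.7, size=15)
        res = paired_t(d)
        res_m = t_from_moments(float(d.mean()), float(d.std(ddof=1)), 15)
        assert res_m.p == pytest.approx(res.p, rel=1e-12)
        assert res_m.ci95 == pytest.approx(res.ci95, rel=1e-12)


class TestGroupSummary:
    def test_printed_row_reconstruction(self, moments_sampler):
        # 13-year male row: n 12, mean -0.12, sd 0.69 -> CI (-0.56, 0.32),
        # p ~ 0.557.
        rng = np.random.default_rng(1)
        d = moments_sampler(rng, -0.12, 0.69, 12)
        res = paired_t(d)
        assert round(res.ci95[0], 2) == -0.56
        assert round(res.ci95[1], 2) == 0.32
        assert res.p == pytest.approx(0.557, abs=0.01)

    def test_groups_and_total(self, demo_weights, saudi_tables):
        ratings = [
            rating("a", "male", 6.2, "F"),
            rating("b", "male", 6.7, "F"),
            rating("c", "male", 9.1, "G"),
            rating("d", "male", 9.8, "G"),
        ]
        results = estimate_cohort(ratings, demo_weights, [saudi_tables["male"]])
        summary = group_summary(results, "saudi_male", "male")
        assert [g.label for g in summary.groups] == ["6.00-6.99", "9.00-9.99"]
        assert summary.total.n == 4
        assert weighted_total(summary.groups) == pytest.approx(summary.total.mean)

    def test_singleton_group_mean_only(self, demo_weights, saudi_tables):
        results = estimate_cohort(
            [rating("a", "male", 6.2, "F")], demo_weights, [saudi_tables["male"]]
        )
        summary = group_summary(results, "saudi_male", "male")
        (g,) = summary.groups
        assert g.n == 1
        assert g.sd is None and g.ci95 is None and g.p_value is None

    def test_missing_standard_rejected(self, demo_weights, saudi_tables):
        results = estimate_cohort(
            [rating("a", "male", 6.2, "F")], demo_weights, [saudi_tables["male"]]
        )
        with pytest.raises(DentageError, match="no results"):
            group_summary(results, "nope", "male")


class TestWeightedTotal:
    def test_pooled_identity(self):
        rng = np.random.default_rng(2)
        samples = [rng.normal(size=n) for n in (3, 8, 5)]
        groups = [
            GroupStats(label=str(i), n=len(s), mean=float(s.mean()))
            for i, s in enumerate(samples)
        ]
        pooled = np.concatenate(samples)
        assert weighted_total(groups) == pytest.approx(pooled.mean(), rel=1e-12)

    def test_single_group(self):
        assert weighted_total([GroupStats(label="g", n=4, mean=1.5)]) == 1.5

    def test_equal_n_is_mean_of_means(self):
        groups = [GroupStats(label=str(i), n=5, mean=m) for i, m in enumerate([1.0, 2.0, 6.0])]
        assert weighted_total(groups) == pytest.approx(3.0)

    def test_empty_rejected(self):
        with pytest.raises(DentageError):
            weighted_total([])

    def test_printed_rows_reproduce_totals(self):
        ref = load_reference_summaries()["table1"]
        rows_m = ref["male"]["groups"]
        rows_f = ref["female"]["groups"]
        wm = weighted_mean([r["n"] for r in rows_m], [r["diff_mean"] for r in rows_m])
        wf = weighted_mean([r["n"] for r in rows_f], [r["diff_mean"] for r in rows_f])
        wall = weighted_mean(
            [r["n"] for r in rows_m + rows_f],
            [r["diff_mean"] for r in rows_m + rows_f],
        )
        # The printed male total row says 0.76, but the running text (and
        # the weighted mean of the printed rows) give 0.77.
        assert round(wm, 2) == 0.77
        assert round(wf, 2) == 0.83
        assert round(wall, 2) == 0.80


class TestAnova:
    def test_identical_group_means_give_zero_f(self):
        g = [1.0, 2.0, 3.0]
        res = oneway_anova({"a": g, "b": g, "c": g})
        assert res.f == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_two_groups_equals_t_squared(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=12), rng.normal(0.5, 1.0, size=9)
        res = oneway_anova({"a": a, "b": b})
        t = stats.ttest_ind(a, b, equal_var=True)
        assert res.f == pytest.approx(t.statistic**2, rel=1e-10)
        assert res.p == pytest.approx(t.pvalue, rel=1e-10)

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            samples = {f"g{i}": rng.normal(i * 0.2, 1.0, size=10) for i in range(3)}
            res = oneway_anova(samples)
            ref = stats.f_oneway(*samples.values())
            assert res.f == pytest.approx(ref.statistic, rel=1e-10)
            assert res.p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_invariances(self):
        rng = np.random.default_rng(8)
        samples = {f"g{i}": rng.normal(i * 0.3, 1.0, size=8) for i in range(4)}
        base = oneway_anova(samples)
        relabeled = {f"x{i}": samples[f"g{3 - i}"] for i in range(4)}
        shifted = {k: v + 5.0 for k, v in samples.items()}
        assert oneway_anova(relabeled).f == pytest.approx(base.f, rel=1e-12)
        assert oneway_anova(shifted).f == pytest.approx(base.f, rel=1e-9)

    def test_zero_within_variance_rejected(self):
        with pytest.raises(DentageError, match="within"):
            oneway_anova({"a": [1.0, 1.0], "b": [2.0, 2.0]})

    def test_too_few_groups_rejected(self):
        with pytest.raises(DentageError, match="2 standards"):
            oneway_anova({"a": [1.0, 2.0]})


def _scheffe_oracle(samples, alpha=0.05):
    """Independent recomputation with explicit sums-of-squares loops."""
    names = list(samples)
    k = len(names)
    all_vals = [v for s in samples.values() for v in s]
    n_total = len(all_vals)
    ssw = 0.0
    for s in samples.values():
        m = sum(s) / len(s)
        ssw += sum((v - m) ** 2 for v in s)
    msw = ssw / (n_total - k)
    fcrit = stats.f.ppf(1 - alpha, k - 1, n_total - k)
    out = {}
    for i in names:
        for j in names:
            if i == j:
                continue
            mi = sum(samples[i]) / len(samples[i])
            mj = sum(samples[j]) / len(samples[j])
            se = math.sqrt(msw * (1 / len(samples[i]) + 1 / len(samples[j])))
            diff = mi - mj
            p = stats.f.sf((diff / se) ** 2 / (k - 1), k - 1, n_total - k)
            half = math.sqrt((k - 1) * fcrit) * se
            out[(i, j)] = (diff, se, p, (diff - half, diff + half))
    return out


class TestScheffe:
    def test_antisymmetry(self):
        rng = np.random.default_rng(10)
        samples = {f"g{i}": rng.normal(i * 0.4, 1.0, size=7 + i) for i in range(4)}
        table = {(c.standard_i, c.standard_j): c for c in scheffe_pairwise(samples)}
        for (i, j), c in table.items():
            back = table[(j, i)]
            assert c.mean_difference == -back.mean_difference
            assert c.std_error == back.std_error
            assert c.adjusted_p == back.adjusted_p

    def test_identical_groups_p_near_one(self):
        g = [1.0, 2.0, 3.0, 2.5]
        for c in scheffe_pairwise({"a": g, "b": g, "c": g}):
            assert c.adjusted_p == pytest.approx(1.0)

    def test_matches_direct_formula_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(5):
            samples = {
                f"g{i}": list(rng.normal(i * 0.5, 1.0, size=int(rng.integers(4, 9))))
                for i in range(4)
            }
            oracle = _scheffe_oracle(samples)
            for c in scheffe_pairwise(samples):
                diff, se, p, ci = oracle[(c.standard_i, c.standard_j)]
                assert c.mean_difference == pytest.approx(diff, rel=1e-10)
                assert c.std_error == pytest.approx(se, rel=1e-10)
                assert c.adjusted_p == pytest.approx(p, rel=1e-8, abs=1e-12)
                assert c.ci95 == pytest.approx(ci, rel=1e-8)

    def test_conservatism_vs_pairwise_t(self):
        # Scheffe adjusted p >= uncorrected (LSD) pairwise-t p, always.
        rng = np.random.default_rng(13)
        for _ in range(50):
            samples = {f"g{i}": rng.normal(0.0, 1.0, size=6) for i in range(4)}
            anova = oneway_anova(samples)
            for c in scheffe_pairwise(samples):
                t = c.mean_difference / c.std_error
                p_lsd = 2 * stats.t.sf(abs(t), anova.df_within)
                assert c.adjusted_p >= p_lsd - 1e-12


class TestScheffeSubsets:
    def test_identical_distributions_single_subset(self):
        rng = np.random.default_rng(14)
        samples = {f"g{i}": rng.normal(0.0, 1.0, size=30) for i in range(4)}
        res = scheffe_subsets(samples)
        assert len(res.subsets) == 1
        assert set(res.subsets[0].members) == set(samples)
        assert res.subsets[0].significance > 0.05

    def test_separated_means_singletons(self):
        rng = np.random.default_rng(15)
        samples = {f"g{i}": rng.normal(i * 50.0, 0.5, size=10) for i in range(4)}
        res = scheffe_subsets(samples)
        assert len(res.subsets) == 4
        assert all(len(s.members) == 1 for s in res.subsets)
        assert all(s.significance == 1.0 for s in res.subsets)

    def test_subsets_ordered_and_cover_all(self):
        rng = np.random.default_rng(16)
        samples = {f"g{i}": rng.normal(i * 0.35, 1.0, size=12) for i in range(5)}
        res = scheffe_subsets(samples)
        covered = {m for s in res.subsets for m in s.members}
        assert covered == set(samples)
        subset_means = [np.mean(s.means) for s in res.subsets]
        assert subset_means == sorted(subset_means)

    def test_harmonic_mean_n(self):
        rng = np.random.default_rng(17)
        samples = {"a": rng.normal(size=10), "b": rng.normal(size=40)}
        res = scheffe_subsets(samples)
        assert res.harmonic_n == pytest.approx(2 / (1 / 10 + 1 / 40))

    def test_moment_matched_boys_pattern(self, moments_sampler):
        # Printed per-standard totals for boys; expected homogeneous
        # subsets: {kuwaiti, saudi} < {french_canadian} < {belgian}.
        ref = load_reference_summaries()["by_standard"]["male"]
        rng = np.random.default_rng(18)
        samples = {}
        for name, tot in ref["totals"].items():
            mean = ref["subset_means"][name]
            samples[name] = moments_sampler(rng, mean, tot["sd"], tot["n"])
        res = scheffe_subsets(samples)
        members = [set(s.members) for s in res.subsets]
        assert members == [
            {"kuwaiti", "saudi"},
            {"french_canadian"},
            {"belgian"},
        ]

    def test_moment_matched_girls_pattern(self, moments_sampler):
        ref = load_reference_summaries()["by_standard"]["female"]
        rng = np.random.default_rng(19)
        samples = {}
        for name, tot in ref["totals"].items():
            samples[name] = moments_sampler(rng, tot["mean"], tot["sd"], tot["n"])
        res = scheffe_subsets(samples)
        members = [set(s.members) for s in res.subsets]
        assert members == [
            {"kuwaiti", "french_canadian", "saudi"},
            {"belgian"},
        ]


class TestReportWriters:
    @pytest.fixture()
    def report(self, demo_weights, saudi_tables):
        rng = np.random.default_rng(20)
        ratings = []
        for i in range(12):
            stage = "FG"[i % 2]
            ratings.append(rating(f"m{i}", "male", float(rng.uniform(6, 10)), stage))
        standards = [
            saudi_tables["male"],
            load_builtin("demo_kuwaiti_male"),
            load_builtin("demo_belgian_male"),
        ]
        results = estimate_cohort(ratings, demo_weights, standards)
        return compare_methods(results)

    def test_csv_columns(self, report, tmp_path):
        path = tmp_path / "report.csv"
        write_report_csv(report, path)
        with open(path, newline="") as fh:
            rows = list(csv.reader(fh))
        assert rows[0] == [
            "sex", "standard", "group", "n", "mean", "sd", "ci_lo", "ci_hi", "p_value",
        ]
        assert any(r[2] == "TOTAL" for r in rows[1:])

    def test_json_mirror(self, report, tmp_path):
        path = tmp_path / "report.json"
        write_report_json(report, path)
        doc = json.loads(path.read_text())
        male = doc["per_sex"]["male"]
        assert male["anova"]["df_between"] == 2
        assert len(male["pairwise"]) == 6
        for p in male["pairwise"]:
            mirror = next(
                q for q in male["pairwise"] if q["i"] == p["j"] and q["j"] == p["i"]
            )
            assert p["mean_difference"] == -mirror["mean_difference"]
        covered = {m for s in male["subsets"]["subsets"] for m in s["members"]}
        assert covered == {"saudi_male", "demo_kuwaiti_male", "demo_belgian_male"}

    def test_single_standard_no_anova(self, demo_weights, saudi_tables):
        ratings = [rating(f"m{i}", "male", 8.0 + 0.1 * i, "G") for i in range(5)]
        results = estimate_cohort(ratings, demo_weights, [saudi_tables["male"]])
        rep = compare_methods(results)
        assert rep.per_sex["male"].anova is None
        assert rep.per_sex["male"].subsets is None
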