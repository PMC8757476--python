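import numpy as np
import pandas as pd
import pytest

from fmtengraft import filter_otus
from fmtengraft.engraftment import (EngraftmentResult, average_engraftment,
                                    compare_engraftment_by_arm,
                                    compare_engraftment_by_response,
                                    compute_engraftment, engrafted_otus,
                                    engraftment_percent, results_to_frame)
from fmtengraft.stats import kruskal_wallis


class TestEngraftedSet:
    def test_definition(self):
        assert engrafted_otus({"A", "B", "C"}, {"C", "D"}, {"A", "C", "D"}) \
            == {"A"}

    def test_no_change_post_equals_pre(self):
        pre = {"A", "B"}
        assert engrafted_otus({"A", "B", "C"}, pre, pre) == frozenset()

    def test_matches_per_element_oracle_on_random_triples(self):
        rng = np.random.default_rng(13)
        universe = [f"otu{i}" for i in range(30)]
        for _ in range(200):
            donor, pre, post = (
                {o for o in universe if rng.random() < 0.4} for _ in range(3))
            result = engrafted_otus(donor, pre, post)
            expected = {o for o in universe
                        if o in donor and o in post and o not in pre}
            assert result == expected


class TestEngraftmentPercent:
    @pytest.fixture()
    def post(self):
        return pd.Series({"A": 30, "C": 50, "D": 20})

    def test_abundance_share(self, post):
        assert engraftment_percent({"A"}, {"A", "B", "C"}, post) == 30.0

    def test_empty_set_zero_in_every_mode(self, post):
        for mode in ("abundance", "donor_richness", "post_richness"):
            assert engraftment_percent(set(), {"A", "B"}, post, mode) == 0.0

    def test_donor_richness(self, post):
        p = engraftment_percent({"A"}, {"A", "B", "C"}, post, "donor_richness")
        assert p == pytest.approx(100 / 3)

    def test_post_richness(self, post):
        p = engraftment_percent({"A"}, {"A", "B", "C"}, post, "post_richness")
        assert p == pytest.approx(100 / 3)  # 1 of 3 present post-FMT

    def test_empty_donor_undefined_in_richness_mode(self, post):
        with pytest.warns(UserWarning, match="donor_richness"):
            assert engraftment_percent(set(), set(), post,
                                       "donor_richness") is None

    def test_engrafted_must_be_donor_subset(self, post):
        with pytest.raises(ValueError, match="subset"):
            engraftment_percent({"Z"}, {"A"}, post)


class TestAverageEngraftment:
    def test_both_timepoints(self):
        assert average_engraftment(20.0, 11.0) == (15.5, False)

    def test_single_timepoint_flagged(self):
        assert average_engraftment(8.0, None) == (8.0, True)
        assert average_engraftment(None, 8.0) == (8.0, True)

    def test_both_missing(self):
        assert average_engraftment(None, None) == (None, False)


class TestComputeEngraftment:
    def test_invariants_on_synthetic_trial(self, trial):
        table, meta, truth, _ = trial
        filtered = filter_otus(table)
        results = compute_engraftment(filtered, meta)
        by_subject = {r.subject: r for r in results}
        assert set(by_subject) == set(truth.transfer_fraction)
        for r in results:
            base_sid = f"{r.subject}_baseline"
            baseline_present = filtered.presence(base_sid)
            for eng in (r.engrafted_otus_w1, r.engrafted_otus_w10):
                assert not (eng & baseline_present)
            for tp, eng in (("week1", r.engrafted_otus_w1),
                            ("week10", r.engrafted_otus_w10)):
                post_present = filtered.presence(f"{r.subject}_{tp}")
                assert eng <= post_present
            assert 0 <= r.percent_avg <= 100

    def test_recovers_transfer_fraction(self, trial):
        table, meta, truth, _ = trial
        results = compute_engraftment(filter_otus(table), meta)
        for arm, f in (("FMT", 0.15), ("R-FMT", 0.05),
                       ("CM-FMT", 0.02), ("placebo", 0.0)):
            vals = [r.percent_avg for r in results if r.arm == arm]
            assert np.median(vals) == pytest.approx(100 * f, abs=2.0)

    def test_missing_week10_gives_flagged_single_timepoint(self, trial):
        table, meta, _, _ = trial
        subject = "S001"
        meta2 = meta[~((meta["subject_id"] == subject)
                       & (meta["timepoint"] == "week10"))]
        results = compute_engraftment(filter_otus(table), meta2)
        r = {x.subject: x for x in results}[subject]
        assert r.single_timepoint
        assert r.percent_w10 is None
        assert r.percent_avg == r.percent_w1
        assert "no_week10_sample" in r.exclusions

    def test_subject_without_baseline_excluded(self, trial):
        table, meta, _, _ = trial
        meta2 = meta[~((meta["subject_id"] == "S001")
                       & (meta["timepoint"] == "baseline"))]
        results = compute_engraftment(filter_otus(table), meta2)
        r = {x.subject: x for x in results}["S001"]
        assert r.percent_avg is None
        assert "no_baseline_sample" in r.exclusions

    def test_frame_output_columns(self, trial):
        table, meta, _, _ = trial
        frame = results_to_frame(compute_engraftment(filter_otus(table), meta))
        assert {"subject", "arm", "percent_w1", "percent_w10", "percent_avg",
                "n_engrafted_w1", "n_engrafted_w10", "mode"} <= set(frame.columns)


def _results(values_by_arm):
    out = []
    i = 0
    for arm, vals in values_by_arm.items():
        for v in vals:
            i += 1
            out.append(EngraftmentResult(subject=f"S{i}", arm=arm,
                                         percent_avg=v))
    return out


class TestCompareByArm:
    def test_identical_value_multisets_are_null(self):
        res = _results({a: [1.0, 5.0, 9.0] for a in ("FMT", "R-FMT", "CM-FMT")})
        rep = compare_engraftment_by_arm(res)
        assert rep["kruskal_H"] == pytest.approx(0.0, abs=1e-12)
        assert rep["kruskal_p"] == pytest.approx(1.0)
        for d in rep["dunn"].values():
            assert d["p"] == pytest.approx(1.0)

    def test_omnibus_p_consistent_with_exact_enumeration(self):
        groups = {"FMT": [21.0, 22.0, 23.0], "R-FMT": [11.0, 12.0, 13.0],
                  "CM-FMT": [1.0, 2.0, 3.0]}
        rep = compare_engraftment_by_arm(_results(groups))
        _, p_exact = kruskal_wallis(list(groups.values()), exact_max_n=9)
        # separated groups sit in the extreme tail under both computations
        assert p_exact == pytest.approx(6 / 1680)
        assert rep["kruskal_p"] < 0.05

    def test_synthetic_medians_ordered_by_transfer_fraction(self, trial):
        table, meta, _, _ = trial
        results = compute_engraftment(filter_otus(table), meta)
        rep = compare_engraftment_by_arm(results)
        med = rep["median"]
        assert med["FMT"] > med["R-FMT"] > med["CM-FMT"]
        assert rep["kruskal_p"] < 0.05

    def test_small_arm_excluded_with_warning(self):
        res = _results({"FMT": [1.0, 2.0, 3.0], "R-FMT": [4.0, 5.0, 6.0],
                        "CM-FMT": [7.0]})
        with pytest.warns(UserWarning, match="CM-FMT"):
            rep = compare_engraftment_by_arm(res)
        assert rep["arms"] == ["FMT", "R-FMT"]


class TestCompareByResponse:
    def test_identical_distributions_near_one(self):
        res = _results({"FMT": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]})
        flags = {f"S{i}": i % 2 == 0 for i in range(1, 7)}
        rep = compare_engraftment_by_response(res, flags)
        assert rep["mannwhitney_p"] > 0.9

    def test_exact_u_distribution_value(self):
        res = _results({"FMT": [1.0, 2.0, 3.0, 10.0, 11.0, 12.0]})
        flags = {"S1": True, "S2": True, "S3": True,
                 "S4": False, "S5": False, "S6": False}
        rep = compare_engraftment_by_response(res, flags)
        assert rep["mannwhitney_p"] == pytest.approx(0.1)  # 2/20 per tail

    def test_label_shuffles_do_not_systematically_reject(self):
        rng = np.random.default_rng(21)
        values = list(rng.normal(10, 3, 12))
        res = _results({"FMT": values})
        pvals = []
        for _ in range(50):
            labels = rng.permutation([True] * 6 + [False] * 6)
            flags = {f"S{i + 1}": bool(labels[i]) for i in range(12)}
            pvals.append(compare_engraftment_by_response(res, flags)
                         ["mannwhitney_p"])
        assert np.mean(np.asarray(pvals) < 0.05) < 0.2

    def test_empty_class_returns_none_with_warning(self):
        res = _results({"FMT": [1.0, 2.0, 3.0]})
        with pytest.warns(UserWarning):
            assert compare_engraftment_by_response(
                res, {"S1": True, "S2": True, "S3": True}) is None
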