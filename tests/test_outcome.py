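import math

import numpy as np
import pandas as pd
import pytest

from declina.outcome import (
    OutcomeError,
    assign_stratum,
    classify_cohort,
    flag_by_stratum_p90,
    proportional_increase,
    stratum_p90,
)


class TestProportionalIncrease:
    def test_printed_formula(self):
        assert proportional_increase(30, 34) == pytest.approx(4 / 42)

    @pytest.mark.parametrize("g", [18, 30, 55, 71])
    def test_no_change_is_zero(self, g):
        assert proportional_increase(g, g) == 0.0

    def test_maximal_decline(self):
        assert proportional_increase(18, 72) == 1.0

    def test_both_at_ceiling(self):
        assert proportional_increase(72, 72) == 0.0

    def test_improvement_from_ceiling_is_nan(self):
        assert math.isnan(proportional_increase(72, 50))

    def test_bounds_checked(self):
        with pytest.raises(OutcomeError):
            proportional_increase(17, 30)
        with pytest.raises(OutcomeError):
            proportional_increase(30, 73)

    def test_never_exceeds_one(self, rng):
        for _ in range(200):
            g0 = int(rng.integers(18, 72))
            g12 = int(rng.integers(18, 73))
            assert proportional_increase(g0, g12) <= 1.0


class TestAssignStratum:
    @pytest.mark.parametrize(
        "g0, k",
        [(18, 1), (26, 1), (27, 2), (35, 2), (36, 3), (44, 3), (45, 4),
         (53, 4), (54, 5), (62, 5), (63, 6), (72, 6)],
    )
    def test_closed_interval_edges(self, g0, k):
        assert assign_stratum(g0) == k

    def test_out_of_range(self):
        with pytest.raises(OutcomeError):
            assign_stratum(73)


class TestStratumPercentile:
    def test_nearest_rank_enumerated(self):
        """10 values 0.0..0.9: the ceil(0.9*10)=9th order statistic is 0.8,
        and exactly one value (0.9) lies strictly above it."""
        vals = [i / 10 for i in range(10)]
        cut = stratum_p90(vals)
        assert cut == 0.8
        flags, report = flag_by_stratum_p90([1] * 10, vals)
        assert flags.sum() == 1
        assert vals[int(np.flatnonzero(flags)[0])] == 0.9
        assert report.p90[0] == 0.8

    def test_all_identical_none_flagged(self):
        flags, _ = flag_by_stratum_p90([2] * 8, [0.3] * 8)
        assert flags.sum() == 0

    def test_weak_inequality_flags_the_cutoff(self):
        vals = [i / 10 for i in range(10)]
        flags, _ = flag_by_stratum_p90([1] * 10, vals, inequality="weak")
        assert flags.sum() == 2  # 0.8 and 0.9

    def test_flagged_fraction_at_most_ten_percent(self, rng):
        """Tie-free values + nearest-rank: strictly-above count <= 0.1 n."""
        for _ in range(20):
            n = int(rng.integers(5, 400))
            vals = rng.uniform(size=n)
            strata = rng.integers(1, 7, size=n)
            flags, _ = flag_by_stratum_p90(strata, vals)
            for k in range(1, 7):
                m = strata == k
                if m.sum():
                    assert flags[m].sum() <= 0.1 * m.sum()

    def test_threshold_rule(self, rng):
        """Every flagged value strictly exceeds every unflagged value in the
        same stratum that ties or sits below the cut-off."""
        vals = rng.uniform(size=200)
        strata = rng.integers(1, 4, size=200)
        flags, report = flag_by_stratum_p90(strata, vals)
        for k in range(1, 4):
            m = strata == k
            cut = report.p90[k - 1]
            assert all(v > cut for v in vals[m & flags])
            assert all(v <= cut for v in vals[m & ~flags])


def _scored(rows):
    df = pd.DataFrame(rows)
    df["gars_t12"] = df["gars_t12"].astype("Int64")
    return df


def _row(i, g0=30, g12=None, event="followed_up"):
    return {
        "id": f"p{i}", "age": 80.0, "sex": "female", "polypharmacy": False,
        "multimorbidity": False, "living": "independent",
        "gp_opinion": "not_vulnerable", "iscope_score": 0,
        "gars_t0": g0, "gars_t12": g12, "event": event,
    }


class TestClassifyCohort:
    def test_death_and_nursing_home_always_decline(self):
        rows = [_row(i, g12=30) for i in range(10)]
        rows.append(_row(10, event="died"))
        rows.append(_row(11, event="nursing_home"))
        labelled, _ = classify_cohort(_scored(rows))
        by = labelled.set_index("id")
        assert bool(by.loc["p10", "declined"]) and by.loc["p10", "reason"] == "died"
        assert by.loc["p11", "reason"] == "nursing_home"
        assert pd.isna(by.loc["p10", "prop_increase"])

    def test_lost_excluded_everywhere(self):
        rows = [_row(i, g12=31 + i) for i in range(10)]
        rows.append(_row(99, event="lost"))
        labelled, _ = classify_cohort(_scored(rows))
        assert "p99" not in set(labelled["id"])

    def test_reasons_partition_declines(self, scored_cohort):
        labelled, _ = classify_cohort(scored_cohort)
        declined = labelled[labelled["declined"]]
        counts = declined["reason"].value_counts()
        assert set(counts.index) <= {"died", "nursing_home", "gars_p90"}
        assert counts.sum() == len(declined)
        assert (labelled.loc[~labelled["declined"], "reason"] == "none").all()

    def test_order_invariance(self, scored_cohort):
        labelled, _ = classify_cohort(scored_cohort)
        shuffled = scored_cohort.sample(frac=1, random_state=5)
        labelled2, _ = classify_cohort(shuffled)
        a = labelled.sort_values("id").reset_index(drop=True)
        b = labelled2.sort_values("id").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_cutoffs_computed_within_stratum_only(self, scored_cohort):
        """Restricting the cohort to one stratum reproduces that stratum's
        labels: pooled labelling is stratum-local."""
        labelled, _ = classify_cohort(scored_cohort)
        k = int(labelled["stratum"].mode()[0])
        sub_ids = labelled.loc[labelled["stratum"] == k, "id"]
        sub = scored_cohort[scored_cohort["id"].isin(sub_ids)]
        sub_labelled, _ = classify_cohort(sub)
        merged = labelled.merge(sub_labelled, on="id", suffixes=("_all", "_sub"))
        assert (merged["declined_all"] == merged["declined_sub"]).all()

    def test_exclude_ceiling_drops_double_72(self):
        rows = [_row(i, g12=31 + i % 5) for i in range(10)]
        rows.append(_row(50, g0=72, g12=72))
        full, _ = classify_cohort(_scored(rows))
        assert "p50" in set(full["id"])
        assert not full.set_index("id").loc["p50", "declined"]
        trimmed, _ = classify_cohort(_scored(rows), exclude_ceiling=True)
        assert "p50" not in set(trimmed["id"])

    def test_all_lost_is_an_error(self):
        rows = [_row(i, event="lost") for i in range(3)]
        with pytest.raises(OutcomeError, match="no evaluable"):
            classify_cohort(_scored(rows))
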