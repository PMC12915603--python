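"""Estimation pipeline: running popularity, binning, M-hat, d-hat, classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lockin.errors import EstimationError
from lockin.estimation import (ChoiceTable, ItemEstimate,
                               attach_running_popularity, bin_influence_curve,
                               classify_items, estimate_M,
                               estimate_d_and_option_A, party_estimates)


def make_table(choices, init=(1, 1), item="q1", world="w1"):
    df = pd.DataFrame({
        "item_id": item, "world_id": world,
        "t": np.arange(1, len(choices) + 1),
        "choice": list(choices), "condition": "social",
    })
    return ChoiceTable(df=df, world_init={(item, world): init})


class TestRunningPopularity:
    def test_artificial_seed_counts(self):
        table = make_table("AB", init=(110, 10))
        soc = attach_running_popularity(table)
        assert soc["x"].iloc[0] == pytest.approx(110 / 120)

    def test_zero_init_first_record_flagged(self):
        table = make_table("AAB", init=(0, 0))
        soc = attach_running_popularity(table)
        assert not soc["x_defined"].iloc[0]
        assert soc["x"].iloc[1] == pytest.approx(1.0)  # one prior A of one

    def test_simple_counting(self):
        table = make_table("AB", init=(1, 1))
        soc = attach_running_popularity(table)
        assert list(soc["x"]) == pytest.approx([0.5, 2 / 3])

    def test_worlds_are_independent(self):
        df = pd.concat([make_table("AAAA", world="w1").df,
                        make_table("BBBB", world="w2").df])
        table = ChoiceTable(df=df, world_init={("q1", "w1"): (1, 1),
                                               ("q1", "w2"): (1, 1)})
        soc = attach_running_popularity(table)
        assert soc[soc["world_id"] == "w2"]["x"].iloc[0] == pytest.approx(0.5)


class TestBinning:
    def test_share_within_single_bin(self):
        binned = bin_influence_curve([0.32, 0.33, 0.34, 0.36], [1, 1, 1, 0])
        i = 3  # bin (0.3, 0.4)
        assert binned.counts[i] == 4
        assert binned.estimates[i] == pytest.approx(0.75)

    def test_edge_record_gets_half_weight_each_side(self):
        binned = bin_influence_curve([0.4], [1])
        assert binned.counts[3] == pytest.approx(0.5)
        assert binned.counts[4] == pytest.approx(0.5)

    def test_half_is_excluded_by_default_but_not_otherwise(self):
        binned = bin_influence_curve([0.5, 0.3], [1, 0])
        assert binned.n_excluded_half == 1
        binned2 = bin_influence_curve([0.5], [1], exclude_half=False)
        assert binned2.counts[4] == pytest.approx(0.5)
        assert binned2.counts[5] == pytest.approx(0.5)

    def test_empty_bin_estimate_undefined(self):
        binned = bin_influence_curve([0.05], [1])
        assert np.isnan(binned.estimates[7])
        assert binned.counts[7] == 0

    def test_extremes_fall_in_terminal_bins(self):
        binned = bin_influence_curve([0.0, 1.0], [0, 1])
        assert binned.counts[0] == 1 and binned.counts[9] == 1

    @given(st.lists(st.tuples(st.floats(0, 1), st.booleans()),
                    min_size=1, max_size=60))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_weight_conservation_is_exact(self, records):
        xs = [x for x, _ in records]
        cs = [c for _, c in records]
        binned = bin_influence_curve(xs, cs, exclude_half=False)
        assert binned.counts.sum() == pytest.approx(len(records), abs=1e-12)
        binned2 = bin_influence_curve(xs, cs, exclude_half=True)
        assert binned2.counts.sum() + binned2.n_excluded_half == \
            pytest.approx(len(records), abs=1e-12)


class TestEstimateM:
    def test_central_bin_difference(self):
        x = [0.45] * 20 + [0.55] * 20
        c = [1] * 8 + [0] * 12 + [1] * 11 + [0] * 9
        binned = bin_influence_curve(x, c)
        m, se = estimate_M(binned)
        assert m == pytest.approx(0.55 - 0.40)
        assert se == pytest.approx(np.hypot(np.sqrt(0.4 * 0.6 / 20),
                                            np.sqrt(0.55 * 0.45 / 20)))

    def test_empty_central_bin_raises(self):
        binned = bin_influence_curve([0.45] * 5, [1] * 5)
        with pytest.raises(EstimationError):
            estimate_M(binned)

    def test_logistic_slope_artifact_matches_bin_average_oracle(self, rng):
        # continuous curve: M-hat targets the difference of bin-averaged values
        from lockin.curves import LogisticCurve
        curve = LogisticCurve(d=0.0, b=2)
        n = 200_000
        x = rng.uniform(0.4, 0.6, size=n)
        x = x[np.abs(x - 0.5) > 1e-9]
        chose = rng.random(x.size) < curve(x)
        m, se = estimate_M(bin_influence_curve(x, chose))
        grid_lo = np.linspace(0.4, 0.5, 20_001)
        grid_hi = np.linspace(0.5, 0.6, 20_001)
        expected = curve(grid_hi).mean() - curve(grid_lo).mean()
        assert m == pytest.approx(expected, abs=3 * se)


class TestEstimateD:
    def test_counts_identify_option_a(self):
        a, d, _ = estimate_d_and_option_A(["A"] * 30 + ["B"] * 70)
        assert a == "A" and d == pytest.approx(0.4)

    def test_labels_are_not_assumed(self):
        a, d, _ = estimate_d_and_option_A(["B"] * 30 + ["A"] * 70)
        assert a == "B" and d == pytest.approx(0.4)

    def test_exact_tie_breaks_lexicographically(self):
        a, d, _ = estimate_d_and_option_A(["B"] * 50 + ["A"] * 50)
        assert a == "A" and d == pytest.approx(0.0)

    def test_consistent_for_1_minus_2g(self, rng):
        g_half = 0.38  # d = 1 - 2 g(1/2) = 0.24
        draws = np.where(rng.random(10_000) < g_half, "A", "B")
        _, d, _ = estimate_d_and_option_A(draws)
        assert abs(d - 0.24) < 0.01

    def test_empty_control_raises(self):
        with pytest.raises(EstimationError):
            estimate_d_and_option_A([])


class TestPartyEstimates:
    @staticmethod
    def _frame(rows):
        return pd.DataFrame(rows, columns=["world_id", "t", "party", "support"])

    def test_running_x_and_methods_formula(self):
        # alternating parties; the first A opposes and the first B supports,
        # pushing x = x_A - x_B negative before it recovers, so both sign
        # groups are populated.  Expected group shares worked out by hand:
        #   x < 0: A records {t3: 1} -> 1;  B records {t4: 0} -> 0
        #   x = 0: t5 ignored
        #   x > 0: A records {t7: 1, t9: 0} -> 1/2;  B {t6: 0, t8: 0, t10: 1} -> 1/3
        pattern = [("A", 0), ("B", 1), ("A", 1), ("B", 0), ("A", 1), ("B", 0),
                   ("A", 1), ("B", 0), ("A", 0), ("B", 1)]
        rows = [("w1", t, pty, s) for t, (pty, s) in enumerate(pattern, start=1)]
        social = self._frame(rows)
        control = self._frame([("c", 1, "A", 0), ("c", 2, "A", 0), ("c", 3, "A", 1),
                               ("c", 4, "B", 1), ("c", 5, "B", 1), ("c", 6, "B", 0)])
        curve, (m, _), (d, _), party_a = party_estimates(social, control)
        assert party_a == "A"
        assert d == pytest.approx(2 / 3 - 1 / 3)
        assert curve.y_minus == pytest.approx(1.0)
        assert curve.y_plus == pytest.approx(1 / 2 - 1 / 3)
        assert curve.n_ignored == 3  # t1, t2 undefined + t5 at x = 0
        # M_A = 1/2 - 1 = -1/2, M_B = 1/3 - 0; M = (M_A - M_B) / 2
        assert m == pytest.approx((-0.5 - 1 / 3) / 2)

    def test_methods_arithmetic(self):
        # direct check of M = (M_A - M_B)/2 with M_A = 0.4, M_B = -0.2
        assert (0.4 - (-0.2)) / 2 == pytest.approx(0.3)

    def test_symmetric_parties_give_near_zero_d(self, rng):
        from lockin.dynamics import party_spec_from_md, simulate_party_trial
        rows = []
        for w in range(6):
            spec = party_spec_from_md(0.3, 0.0, horizon=200, assignment="random",
                                      seed=int(rng.integers(2 ** 31)))
            traj = simulate_party_trial(spec)
            for t in range(200):
                rows.append((f"w{w}", t + 1, traj.party[t], int(traj.support[t])))
        social = self._frame(rows)
        ctrl_rows = [("c", t + 1, ["A", "B"][t % 2], int(rng.random() < 0.5))
                     for t in range(400)]
        control = self._frame(ctrl_rows)
        _, (m, m_se), (d, d_se), _ = party_estimates(social, control)
        assert abs(d) < 3 * d_se + 1e-9

    def test_empty_sign_group_raises(self):
        social = self._frame([("w1", 1, "A", 1), ("w1", 2, "B", 0),
                              ("w1", 3, "A", 1)])  # x>0 side only after priors
        control = self._frame([("c", 1, "A", 0), ("c", 2, "B", 1)])
        with pytest.raises(EstimationError):
            party_estimates(social, control)


class TestClassification:
    @staticmethod
    def _item(item_id, m, d, lock):
        return ItemEstimate(item_id=item_id, option_a="A", m_hat=m,
                            m_se=0.02 if m is not None else None, d_hat=d,
                            d_se=0.02, lock_in_observed=lock, n_trials=10,
                            enters_lock_in=None)

    def test_two_by_two_counts(self):
        tab = classify_items([self._item("a", 0.3, 0.1, True),
                              self._item("b", 0.0, 0.4, False)])
        assert tab.counts[(True, True)] == 1
        assert tab.counts[(False, False)] == 1
        assert tab.counts[(True, False)] == tab.counts[(False, True)] == 0
        assert tab.accuracy == 1.0

    def test_missing_m_goes_to_no_estimate_bucket(self):
        tab = classify_items([self._item("a", None, 0.2, False),
                              self._item("b", 0.4, 0.1, True)])
        assert tab.no_estimate == ("a",)
        assert tab.n_items == 1

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            classify_items([])
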