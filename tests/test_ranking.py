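"""Hierarchical channel ranking, endpoint prediction, mutant classification."""

import numpy as np
import pytest

from conftest import brute_force_channel_ranking, random_score_table
from terpchannel.channels import downstream
from terpchannel.datasets import SHC_WILD_TYPE, load_shc_mutant_scores
from terpchannel.ranking import (
    compare_mutant,
    evaluate_predictions,
    predict_channel,
    predict_endpoint,
    rank_channels,
    rank_intermediates,
)
from terpchannel.scores import NO_POSE, ScoreStatus, table_from_entries


def reps_table(lib, values, enzyme="E"):
    """Table from {channel: (I1 score, I2 score)}; None = NO_POSE."""
    entries = []
    for cid, (s1, s2) in values.items():
        chan = lib.channel(cid)
        entries.append((enzyme, chan.representative(1).id, s1))
        entries.append((enzyme, chan.representative(2).id, s2))
    return table_from_entries(entries)


class TestRankChannels:
    def test_two_round_example(self, lib):
        """A1 and B1 similar (<1 kcal/mol), both better than C1; A2 beats B2:
        round 1 gives A = B > C and round 2 resolves the final order A>B>C."""
        table = reps_table(lib, {"A": (-60.0, -50.0), "B": (-59.5, -47.0),
                                 "C": (-55.0, -52.0)})
        cp = rank_channels(table, "E", lib)
        assert cp.ranked_channels == ["A", "B", "C"]
        assert cp.best_channel == "A"
        assert cp.tie_group == ["A", "B"]
        assert not cp.ambiguous

    def test_round2_can_overturn_round1_order_within_tie(self, lib):
        table = reps_table(lib, {"A": (-60.0, -47.0), "B": (-59.5, -50.0),
                                 "C": (-55.0, -52.0)})
        cp = rank_channels(table, "E", lib)
        assert cp.best_channel == "B"

    def test_only_one_enabled_channel(self, lib):
        solo = lib.with_channel_enabled("B", False).with_channel_enabled("C", False)
        table = reps_table(solo, {"A": (10.0, 20.0)})
        assert predict_channel(table, "E", solo) == "A"

    def test_fully_symmetric_input_is_ambiguous(self, lib):
        table = reps_table(lib, {"A": (-50.0, -40.0), "B": (-50.0, -40.0),
                                 "C": (-50.0, -40.0)})
        cp = rank_channels(table, "E", lib)
        assert cp.ambiguous
        assert cp.best_channel == "A"  # deterministic label tie-break

    def test_all_representatives_no_pose(self, lib):
        table = reps_table(lib, {c: (None, None) for c in "ABC"})
        cp = rank_channels(table, "E", lib)
        assert cp.ambiguous
        assert cp.best_channel is None

    def test_missing_representative_errors(self, lib):
        table = reps_table(lib, {"A": (-60.0, -50.0), "B": (-59.0, -49.0)})
        with pytest.raises(KeyError):
            rank_channels(table, "E", lib)

    def test_planted_gap_recovered(self, lib):
        rng = np.random.default_rng(42)
        hits = 0
        for _ in range(200):
            planted = ("A", "B", "C")[rng.integers(3)]
            values = {}
            for cid in "ABC":
                base1 = -60.0 if cid == planted else -55.0
                base2 = -45.0 if cid == planted else -40.0
                values[cid] = (base1 + rng.normal(0, 0.3), base2 + rng.normal(0, 0.3))
            table = reps_table(lib, values)
            hits += predict_channel(table, "E", lib) == planted
        assert hits == 200

    def test_matches_brute_force_oracle_on_random_tables(self, lib):
        rng = np.random.default_rng(7)
        for _ in range(2000):
            table = random_score_table(rng, lib)
            cp = rank_channels(table, "E", lib)
            assert cp.ranked_channels == brute_force_channel_ranking(table, "E", lib)

    def test_invariant_under_uniform_shift(self, lib):
        rng = np.random.default_rng(11)
        for _ in range(200):
            table = random_score_table(rng, lib)
            shift = float(rng.normal(0, 30))
            shifted = table_from_entries(
                [
                    (e, i, None if s.is_no_pose else s.value + shift)
                    for (e, i), s in table.entries.items()
                ]
            )
            assert (
                rank_channels(table, "E", lib).ranked_channels
                == rank_channels(shifted, "E", lib).ranked_channels
            )

    def test_relative_mode_table_rejected(self, lib):
        table = reps_table(lib, {c: (-50.0, -40.0) for c in "ABC"})
        table.metadata["mode"] = "relative"
        with pytest.raises(ValueError, match="absolute"):
            rank_channels(table, "E", lib)


class TestRankIntermediates:
    def profile(self, lib, values, enzyme="E"):
        chan = lib.channel("C")
        return table_from_entries(
            [(enzyme, i.id, v) for i, v in zip(chan.intermediates, values)]
        )

    def test_downstream_minimum_first_after_i1(self, lib):
        table = self.profile(
            lib, [-62.0, -45.0, -47.0, -49.0, -51.0, -55.0, -50.0, None, -40.0]
        )
        ranked = rank_intermediates(table, "E", "C", lib)
        assert ranked[0].id == "C-I1"
        assert ranked[1].id == "C-I6"
        assert ranked[-1].id == "C-I8"  # NO_POSE strictly last

    def test_all_equal_keeps_library_order(self, lib):
        table = self.profile(lib, [-50.0] * 9)
        assert [i.id for i in rank_intermediates(table, "E", "C", lib)] == [
            f"C-I{k}" for k in range(1, 10)
        ]

    def test_matches_naive_sort_oracle(self, lib):
        rng = np.random.default_rng(5)
        chan = lib.channel("C")
        for _ in range(300):
            vals = [
                None if rng.random() < 0.2 else float(rng.normal(-50, 10))
                for _ in range(9)
            ]
            table = self.profile(lib, vals)
            got = [i.id for i in rank_intermediates(table, "E", "C", lib)]
            naive = sorted(
                range(9),
                key=lambda k: ((1, 0.0) if vals[k] is None else (0, vals[k]), k),
            )
            assert got == [chan.intermediates[k].id for k in naive]


class TestPredictEndpoint:
    def full_profile(self, lib, values, enzyme="E"):
        chan = lib.channel("C")
        return table_from_entries(
            [(enzyme, i.id, v) for i, v in zip(chan.intermediates, values)]
        )

    def test_no_pose_at_i8_terminates_at_i7_and_rules_out_downstream(self, lib):
        table = self.full_profile(
            lib, [-62.0, -45.0, -47.0, -49.0, -51.0, -55.0, -50.0, None, -40.0]
        )
        ep = predict_endpoint(table, "E", "C", lib)
        assert ep.best_intermediate == "C-I6"
        assert ep.terminate_after == 7
        assert ep.ruled_out_products == ["cycloartenol", "cucurbitadienol"]
        assert ep.rise_check_passed

    def test_monotonically_improving_profile_has_no_endpoint_signal(self, lib):
        table = self.full_profile(
            lib, [-62.0, -45.0, -46.0, -47.0, -48.0, -49.0, -50.0, -51.0, -52.0]
        )
        ep = predict_endpoint(table, "E", "C", lib)
        assert ep.terminate_after == 9
        assert ep.ruled_out_products == []
        assert not ep.rise_check_passed

    def test_ruled_out_set_matches_first_non_binder_scan_oracle(self, lib):
        rng = np.random.default_rng(17)
        chan = lib.channel("C")
        for _ in range(500):
            vals = [
                None if rng.random() < 0.25 else float(rng.normal(-30, 25))
                for _ in range(9)
            ]
            if all(v is None for v in vals[1:]):
                continue
            table = self.full_profile(lib, vals)
            ep = predict_endpoint(table, "E", "C", lib, binder_threshold=0.0)
            # oracle: best numeric index >= 2, then first downstream non-binder
            numeric = [(v, k + 1) for k, v in enumerate(vals) if k >= 1 and v is not None]
            if not numeric:
                continue
            _, best = min(numeric)
            stop = 9
            for j in range(best + 1, 10):
                v = vals[j - 1]
                if v is None or v > 0.0:
                    stop = j - 1
                    break
            expected = {
                name
                for inter in downstream(lib, chan.intermediates[stop - 1])
                for name, _ in inter.products
            } if stop < 9 else set()
            assert set(ep.ruled_out_products) == expected
            assert ep.terminate_after == stop

    def test_all_downstream_no_pose_terminates_at_i1(self, lib):
        table = self.full_profile(lib, [-62.0] + [None] * 8)
        ep = predict_endpoint(table, "E", "C", lib)
        assert ep.best_intermediate is None
        assert ep.terminate_after == 1
        assert "lanosterol" in ep.ruled_out_products


class TestCompareMutant:
    def test_y609c_pattern(self, lib):
        mut = load_shc_mutant_scores(lib)
        wt = table_from_entries(
            [(SHC_WILD_TYPE, f"A-I{k}", 0.0) for k in range(1, 5)]
        )
        rows = compare_mutant(wt, mut, SHC_WILD_TYPE, "1SQC-Y609C", "A", lib)
        cls = {r.intermediate: r.classification for r in rows}
        assert cls == {
            "A-I1": "unaffected",
            "A-I2": "unaffected",
            "A-I3": "destabilized",
            "A-I4": "unaffected",
        }
        assert {r.intermediate: r.delta for r in rows}["A-I3"] == pytest.approx(32.1)

    def test_l607k_pattern(self, lib):
        mut = load_shc_mutant_scores(lib)
        wt = table_from_entries(
            [(SHC_WILD_TYPE, f"A-I{k}", 0.0) for k in range(1, 5)]
        )
        rows = compare_mutant(wt, mut, SHC_WILD_TYPE, "1SQC-L607K", "A", lib)
        cls = {r.intermediate: r.classification for r in rows}
        assert cls == {
            "A-I1": "destabilized",
            "A-I2": "abolished",
            "A-I3": "abolished",
            "A-I4": "abolished",
        }

    def test_identical_tables_all_unaffected(self, lib):
        wt = table_from_entries([("WT", f"A-I{k}", -50.0 - k) for k in range(1, 5)])
        mut = table_from_entries([("WT", f"A-I{k}", -50.0 - k) for k in range(1, 5)])
        rows = compare_mutant(wt, mut, "WT", "WT", "A", lib)
        assert all(r.classification == "unaffected" for r in rows)
        assert all(r.delta == 0.0 for r in rows)

    def test_one_sided_intermediate_errors(self, lib):
        wt = table_from_entries([("WT", "A-I1", -50.0)])
        mut = table_from_entries([("M", "A-I1", -48.0), ("M", "A-I2", -40.0)])
        with pytest.raises(ValueError, match="only one"):
            compare_mutant(wt, mut, "WT", "M", "A", lib)

    def test_relative_wild_type_table_rejected(self, lib):
        wt = table_from_entries([("WT", "A-I1", 0.0)], mode="relative")
        mut = table_from_entries([("M", "A-I1", 1.0)], mode="relative")
        with pytest.raises(ValueError, match="wild-type"):
            compare_mutant(wt, mut, "WT", "M", "A", lib)


class TestEvaluatePredictions:
    def test_perfect_predictions(self):
        preds = {f"e{k}": "C" for k in range(5)}
        truth = dict(preds)
        clusters = {e: "1W6K" for e in preds}
        report = evaluate_predictions(preds, truth, clusters)
        assert report["total"] == {"n": 5, "correct": 5, "success_rate": 1.0}

    def test_counts_match_brute_force_tally(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            enzymes = [f"e{k}" for k in range(rng.integers(2, 30))]
            preds = {e: rng.choice(list("ABC")) for e in enzymes}
            truth = {e: rng.choice(list("ABC")) for e in enzymes}
            clusters = {e: rng.choice(["1SQC", "1W6K"]) for e in enzymes}
            report = evaluate_predictions(preds, truth, clusters)
            for cluster in set(clusters.values()):
                n = sum(clusters[e] == cluster for e in enzymes)
                correct = sum(
                    clusters[e] == cluster and preds[e] == truth[e] for e in enzymes
                )
                assert report["clusters"][cluster]["n"] == n
                assert report["clusters"][cluster]["correct"] == correct
            assert report["total"]["n"] == len(enzymes)

    def test_missing_truth_label_errors(self):
        with pytest.raises(KeyError):
            evaluate_predictions({"e1": "A"}, {}, {"e1": "x"})

    def test_precursor_statistics(self):
        report = evaluate_predictions(
            {"e1": "C", "e2": "C"},
            {"e1": "C", "e2": "C"},
            {"e1": "x", "e2": "x"},
            endpoint_best={"e1": "C-I6", "e2": "C-I9"},
            precursor_sets={"e1": ["C-I6", "C-I7"], "e2": ["C-I7", "C-I8"]},
        )
        assert report["precursor"] == {"n": 2, "hits": 1, "rate": 0.5}
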