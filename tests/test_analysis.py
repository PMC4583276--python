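"""Trial pipeline: filtering, accuracy coding, deviation scores, summaries,
strength-difference coding, and the fast/slow median split."""

import numpy as np
import pandas as pd
import pytest

from mcia import analysis as ba
from mcia.design import HalfSpec, TestFaceSpec


def make_trial(
    participant=1,
    block=1,
    trial_index=0,
    format="together",
    top=("A", "weak"),
    bottom=("A", "strong"),
    response="A",
    rt_ms=900.0,
    confidence=80,
):
    """Hand-build one tidy trial row."""
    return {
        "participant": participant,
        "block": block,
        "trial_index": trial_index,
        "format": format,
        "top_family": top[0] if top else None,
        "top_strength": top[1] if top else None,
        "top_morph": 70.0 if top else None,
        "bottom_family": bottom[0] if bottom else None,
        "bottom_strength": bottom[1] if bottom else None,
        "bottom_morph": 70.0 if bottom else None,
        "screen_x": 0,
        "screen_y": 0,
        "response": response,
        "rt_ms": rt_ms,
        "confidence": confidence,
    }


def frame(rows):
    return pd.DataFrame(rows, columns=ba.TRIAL_COLUMNS)


class TestFilterTrials:
    def test_removal_rules_and_boundaries(self):
        rows = [
            make_trial(trial_index=0, rt_ms=100.0),            # fast guess
            make_trial(trial_index=1, rt_ms=150.0),            # boundary kept
            make_trial(trial_index=2, rt_ms=5000.0),           # boundary kept
            make_trial(trial_index=3, rt_ms=5000.1),           # slow outlier
            make_trial(trial_index=4, confidence=50),          # guess rating
            make_trial(trial_index=5),                         # clean
        ]
        kept, report = ba.filter_trials(frame(rows))
        assert sorted(kept["trial_index"]) == [1, 2, 5]
        assert report["n_removed"] == 3
        assert report["by_reason"] == {
            "confidence_50": 1,
            "rt_below_150ms": 1,
            "rt_above_5s": 1,
        }

    def test_partition_preserves_every_record(self):
        rows = [make_trial(trial_index=i, rt_ms=100.0 + 100 * i) for i in range(20)]
        trials = frame(rows)
        kept, report = ba.filter_trials(trials)
        assert len(kept) + report["n_removed"] == len(trials)
        assert not kept["trial_index"].duplicated().any()


class TestCodeAccuracy:
    def test_same_family_response(self):
        t = ba.code_accuracy(frame([make_trial(response="A")]))
        assert t["correct"].iloc[0] == 1

    def test_opposite_face_keyed_to_medium_half(self):
        row = make_trial(top=("A", "medium"), bottom=("B", "weak"), response="B")
        t = ba.code_accuracy(frame([row]))
        assert t["correct_family"].iloc[0] == "A"
        assert t["correct"].iloc[0] == 0

    def test_half_face(self):
        row = make_trial(format="half", top=None, bottom=("B", "medium"), response="B")
        t = ba.code_accuracy(frame([row]))
        assert t["correct"].iloc[0] == 1


class TestStrongerHalf:
    FACE = TestFaceSpec(
        top=HalfSpec("top", "A", "weak"),
        bottom=HalfSpec("bottom", "A", "strong"),
        format="together",
    )

    def test_higher_empirical_mean_wins(self):
        means = {("top", "weak"): 0.6, ("bottom", "strong"): 0.8}
        assert ba.stronger_half(means, self.FACE) == "bottom"

    def test_empirical_rule_overrides_strength_labels(self):
        means = {("top", "weak"): 0.9, ("bottom", "strong"): 0.7}
        assert ba.stronger_half(means, self.FACE) == "top"

    def test_exact_tie_breaks_by_strength_label(self):
        means = {("top", "weak"): 0.8, ("bottom", "strong"): 0.8}
        assert ba.stronger_half(means, self.FACE) == "bottom"

    def test_equal_strength_tie_breaks_to_top(self):
        face = TestFaceSpec(
            top=HalfSpec("top", "A", "medium"),
            bottom=HalfSpec("bottom", "A", "medium"),
            format="split",
        )
        means = {("top", "medium"): 0.7, ("bottom", "medium"): 0.7}
        assert ba.stronger_half(means, face) == "top"

    def test_opposite_face_uses_medium_half_by_definition(self):
        face = TestFaceSpec(
            top=HalfSpec("top", "B", "weak"),
            bottom=HalfSpec("bottom", "A", "medium"),
            format="together",
        )
        assert ba.stronger_half({}, face) == "bottom"

    def test_missing_half_cell_rejected(self):
        with pytest.raises(KeyError, match="bottom"):
            ba.stronger_half({("top", "weak"): 0.6}, self.FACE)


class TestDeviationScores:
    def _trials(self):
        rows = []
        # participant's half-face data: top-weak 60%, bottom-strong 80%
        for i, ok in enumerate([1, 1, 1, 0, 0]):
            rows.append(
                make_trial(
                    trial_index=i, format="half", top=("A", "weak"), bottom=None,
                    response="A" if ok else "B",
                )
            )
        for i, ok in enumerate([1, 1, 1, 1, 0]):
            rows.append(
                make_trial(
                    trial_index=10 + i, format="half", top=None,
                    bottom=("A", "strong"), response="A" if ok else "B",
                )
            )
        rows.append(make_trial(trial_index=20, response="A"))   # correct w/s
        rows.append(make_trial(trial_index=21, response="B"))   # error w/s
        return ba.code_accuracy(frame(rows))

    def test_worked_example_and_error_counterpart(self):
        devs = ba.deviation_scores(self._trials())
        by_idx = devs.set_index("trial_index")["deviation"]
        assert by_idx[20] == pytest.approx(1.0 - 0.8)
        assert by_idx[21] == pytest.approx(0.0 - 0.8)

    def test_ceiling_stronger_half_gives_zero_deviation(self):
        rows = [
            make_trial(trial_index=i, format="half", top=None,
                       bottom=("A", "strong"), response="A")
            for i in range(4)
        ]
        rows += [
            make_trial(trial_index=10 + i, format="half", top=("A", "weak"),
                       bottom=None, response="A" if i % 2 else "B")
            for i in range(4)
        ]
        rows.append(make_trial(trial_index=20, response="A"))
        devs = ba.deviation_scores(ba.code_accuracy(frame(rows)))
        assert devs.set_index("trial_index")["deviation"][20] == pytest.approx(0.0)


class TestSummaries:
    def test_two_participant_hand_arithmetic(self):
        rows = []
        for pid, accs in ((1, [1, 1, 1, 1, 0]), (2, [1, 1, 1, 1, 1, 1, 1, 1, 1, 0])):
            for i, ok in enumerate(accs):
                rows.append(
                    make_trial(
                        participant=pid, trial_index=i, format="half",
                        top=("A", "medium"), bottom=None,
                        response="A" if ok else "B",
                    )
                )
        t = ba.code_accuracy(frame(rows))
        per_p = t.groupby("participant")["correct"].mean()
        mean, sem = ba._between_subject(per_p)
        assert mean == pytest.approx(0.85)
        assert sem == pytest.approx(0.05)

    def test_location_collapsing_merges_ws_and_sw(self, small_summary):
        summary, kept, _ = small_summary
        coded = ba.code_accuracy(kept)
        ws = coded[(coded["condition"] == "ws") & (coded["format"] == "together")]
        assert (ws["top_strength"] == "weak").any()
        assert (ws["top_strength"] == "strong").any()

    def test_summary_consistency_identity(self, small_summary):
        # condition deviation mean == condition accuracy mean minus the
        # participant-mean stronger-half accuracy entering those trials
        summary, kept, _ = small_summary
        devs = ba.deviation_scores(ba.code_accuracy(kept))
        for (cond, fmt), grp in devs.groupby(["condition", "format"]):
            gap = grp["correct"].mean() - grp["deviation"].mean()
            assert 0.0 <= gap <= 1.0  # the implied stronger-half accuracy

    def test_single_participant_sem_flagged_nan(self):
        rows = [make_trial(trial_index=i) for i in range(3)]
        rows += [
            make_trial(trial_index=10 + i, format="half", top=(fam_loc), bottom=None)
            for i, fam_loc in enumerate([("A", "weak")] * 2)
        ]
        rows += [
            make_trial(trial_index=20 + i, format="half", top=None, bottom=("A", "strong"))
            for i in range(2)
        ]
        t = ba.code_accuracy(frame(rows))
        per_p = t.groupby("participant")["correct"].mean()
        mean, sem = ba._between_subject(per_p)
        assert mean == 1.0 and np.isnan(sem)

    def test_pipeline_invariant_to_trial_order(self, small_summary):
        _, kept, _ = small_summary
        shuffled = kept.sample(frac=1.0, random_state=0)
        s1 = ba.summarize_conditions(ba.code_accuracy(kept))
        s2 = ba.summarize_conditions(ba.code_accuracy(shuffled))
        pd.testing.assert_frame_equal(
            s1.table.reset_index(drop=True), s2.table.reset_index(drop=True)
        )

    def test_summary_csv_roundtrip(self, small_summary, tmp_path):
        summary, _, _ = small_summary
        path = tmp_path / "summary.csv"
        summary.to_csv(path)
        again = ba.ObservedSummary.from_csv(path)
        assert again.n_participants == summary.n_participants
        pd.testing.assert_frame_equal(again.table, summary.table)


class TestStrengthDifference:
    def test_condition_coding(self, small_summary):
        _, kept, _ = small_summary
        devs = ba.deviation_scores(ba.code_accuracy(kept))
        table = ba.strength_difference_table(devs)
        merged = devs[devs["condition"].isin(ba.STRENGTH_DIFF_CODE)]
        assert set(table["strength_diff"]) <= {-1, 0, 1}
        # ws trials must code +1, equal-strength -1
        assert ba.STRENGTH_DIFF_CODE["ws"] == 1
        assert ba.STRENGTH_DIFF_CODE["mm"] == -1
        assert table["deviation"].notna().all()
        assert "wom" not in set(merged["condition"])

    def test_empty_input_gives_empty_table(self):
        out = ba.strength_difference_table(pd.DataFrame(columns=["condition"]))
        assert len(out) == 0


class TestMedianSplit:
    def test_identical_rts_put_everything_in_slow(self):
        rows = [make_trial(trial_index=i, rt_ms=800.0) for i in range(6)]
        devs = ba.deviation_scores(
            ba.code_accuracy(
                frame(
                    rows
                    + [
                        make_trial(trial_index=10 + i, format="half",
                                   top=("A", "weak"), bottom=None)
                        for i in range(2)
                    ]
                    + [
                        make_trial(trial_index=20 + i, format="half", top=None,
                                   bottom=("A", "strong"))
                        for i in range(2)
                    ]
                )
            )
        )
        split = ba.median_split(devs)
        fast_all = split[(split["format"] == "all") & (split["speed"] == "fast")]
        slow_all = split[(split["format"] == "all") & (split["speed"] == "slow")]
        assert int(fast_all["n"].iloc[0]) == 0 and np.isnan(fast_all["deviation"].iloc[0])
        assert int(slow_all["n"].iloc[0]) == 6

    def test_split_is_per_participant_not_pooled(self):
        def participant_rows(pid, rt):
            rows = [
                make_trial(participant=pid, trial_index=i, rt_ms=rt + 200 * i)
                for i in range(4)
            ]
            rows += [
                make_trial(participant=pid, trial_index=10 + i, format="half",
                           top=("A", "weak"), bottom=None)
                for i in range(2)
            ]
            rows += [
                make_trial(participant=pid, trial_index=20 + i, format="half",
                           top=None, bottom=("A", "strong"))
                for i in range(2)
            ]
            return rows

        # participant 2 is uniformly slower; a pooled split would call all of
        # participant 1's trials fast
        trials = frame(participant_rows(1, 500.0) + participant_rows(2, 3000.0))
        devs = ba.deviation_scores(ba.code_accuracy(trials))
        split = ba.median_split(devs)
        for pid in (1, 2):
            cell = split[
                (split["participant"] == pid)
                & (split["format"] == "all")
                & (split["speed"] == "fast")
            ]
            assert int(cell["n"].iloc[0]) == 2
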