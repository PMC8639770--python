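"""Splits, metrics, ROC/AUC, trial summaries, and the promotion rule.

The pairwise Mann-Whitney concordance computed here by brute force is the
independent oracle for the trapezoidal AUC.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from focusscore import evalstat as ev
from focusscore import synthgen as sg


def concordance_auc(scores, labels):
    """Brute-force Mann-Whitney probability (ties count 1/2)."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    pos, neg = s[y == 1], s[y == 0]
    diff = pos[:, None] - neg[None, :]
    return (np.sum(diff > 0) + 0.5 * np.sum(diff == 0)) / diff.size


def _manifest(n_pos, n_neg):
    import pandas as pd
    rows = [{"id": f"i{i}", "path": "", "label": 1 if i < n_pos else 0,
             "chemical": "TPA-like", "split": ""} for i in range(n_pos + n_neg)]
    return sg.DatasetManifest(pd.DataFrame(rows))


class TestStratifiedSplit:
    def test_exactly_divisible_fractions(self):
        man = ev.stratified_split(_manifest(100, 100), ev.SplitSpec(seed=0))
        counts = man.records.groupby(["split", "label"]).size()
        assert counts["train"].tolist() == [70, 70]
        assert counts["val"].tolist() == [10, 10]
        assert counts["test"].tolist() == [20, 20]

    def test_small_unbalanced_class_ratio_within_one_sample(self):
        man = ev.stratified_split(_manifest(7, 3), ev.SplitSpec(seed=1))
        df = man.records
        overall = 7 / 10
        for name in ("train", "val", "test"):
            part = df[df["split"] == name]
            n, npos = len(part), int((part["label"] == 1).sum())
            assert abs(npos - overall * n) <= 1.0

    def test_same_seed_identical_assignment(self):
        a = ev.stratified_split(_manifest(13, 7), ev.SplitSpec(seed=5))
        b = ev.stratified_split(_manifest(13, 7), ev.SplitSpec(seed=5))
        assert a.records["split"].tolist() == b.records["split"].tolist()

    def test_infeasible_tiny_class_rejected(self):
        with pytest.raises(ValueError):
            ev.stratified_split(_manifest(5, 2), ev.SplitSpec(seed=0))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(3, 60), st.integers(3, 60), st.integers(0, 10_000))
    def test_every_split_preserves_class_ratio(self, n_pos, n_neg, seed):
        man = ev.stratified_split(_manifest(n_pos, n_neg), ev.SplitSpec(seed=seed))
        df = man.records
        ratio = n_pos / (n_pos + n_neg)
        for name in ("train", "val", "test"):
            part = df[df["split"] == name]
            assert abs(int((part["label"] == 1).sum()) - ratio * len(part)) <= 1.0 + 1e-9


class TestConfusion:
    def test_basic_counts(self):
        c = ev.confusion_at_threshold([0.9, 0.1], [1, 0], 0.5)
        assert c == {"TP": 1, "FP": 0, "FN": 0, "TN": 1}

    def test_all_positive_scores(self):
        c = ev.confusion_at_threshold([1.0] * 10, [1] * 5 + [0] * 5, 0.5)
        assert c["FP"] == 5 and c["FN"] == 0

    def test_threshold_zero_predicts_everything_positive(self):
        c = ev.confusion_at_threshold([0.0, 0.3, 0.9], [0, 1, 1], 0.0)
        assert c["TP"] + c["FP"] == 3

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ev.confusion_at_threshold([], [], 0.5)


class TestRocAuc:
    def test_perfect_separator_is_one(self):
        _, auc = ev.roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0

    def test_pure_ties_give_half(self):
        _, auc = ev.roc_auc([0.5] * 8, [1, 0] * 4)
        assert auc == pytest.approx(0.5)

    def test_three_point_example(self):
        # one concordant of two pos/neg pairs
        _, auc = ev.roc_auc([0.8, 0.6, 0.4], [1, 0, 1])
        assert auc == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ev.roc_auc([0.1, 0.9], [1, 1])

    def test_roc_anchored_and_monotone(self):
        rng = np.random.default_rng(3)
        roc, _ = ev.roc_auc(rng.uniform(size=200),
                            rng.integers(0, 2, size=200))
        assert tuple(roc[0]) == (0.0, 0.0) and tuple(roc[-1]) == (1.0, 1.0)
        assert np.all(np.diff(roc[:, 0]) >= 0) and np.all(np.diff(roc[:, 1]) >= 0)

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_trapezoid_equals_pairwise_concordance(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 60))
        scores = np.round(rng.uniform(size=n), 2)   # coarse grid forces ties
        labels = rng.integers(0, 2, size=n)
        if len(np.unique(labels)) < 2:
            labels[:2] = [0, 1]
        _, auc = ev.roc_auc(scores, labels)
        assert auc == pytest.approx(concordance_auc(scores, labels), abs=1e-9)


class TestSummaries:
    def _report(self, acc, rec, auc):
        return ev.EvalReport(confusion={"TP": 1, "FP": 0, "FN": 0, "TN": 1},
                             accuracy=acc, recall=rec,
                             roc=np.array([[0, 0], [1, 1]]), auc=auc, n=2)

    def test_identical_reports_zero_sd(self):
        s = ev.summarize_trials([self._report(0.9, 0.91, 0.95)] * 3)
        assert s["auc"]["mean"] == pytest.approx(0.95)
        assert s["auc"]["sd"] == pytest.approx(0.0, abs=1e-12)

    def test_two_point_closed_form(self):
        s = ev.summarize_trials([self._report(0.8, 0.8, 0.9),
                                 self._report(0.8, 0.8, 1.0)])
        assert s["auc"]["mean"] == pytest.approx(0.95)
        assert s["auc"]["sd"] == pytest.approx(np.std([0.9, 1.0], ddof=1))

    def test_single_report_flagged(self):
        s = ev.summarize_trials([self._report(0.7, 0.7, 0.8)])
        assert s["auc"]["mean"] == 0.8 and s["auc"]["sd"] == 0.0
        assert s["auc"]["n1_flag"] is True


class TestPromotionCall:
    def test_clear_dose_response_is_positive(self):
        data = ev.PromotionInput(counts={
            0.0: [0, 0, 0, 0, 0, 1],
            5.0: [2, 3, 1, 4, 2, 2],
            10.0: [2, 3, 1, 4, 2, 2],
            20.0: [2, 3, 1, 4, 2, 2],
        })
        res = ev.promotion_call(data)
        assert res.positive
        assert all(p < 0.05 for p in res.dunnett_p.values())
        assert res.anova_p < 0.05

    def test_flat_plate_is_negative(self):
        data = ev.PromotionInput(counts={c: [1, 1, 2, 1] for c in (0.0, 5.0, 10.0)})
        res = ev.promotion_call(data)
        assert not res.positive

    def test_single_elevated_concentration_is_negative(self):
        # only the top concentration responds: no consecutive pair
        data = ev.PromotionInput(counts={
            0.0: [0, 1, 0, 1, 0, 1],
            5.0: [1, 0, 1, 0, 1, 0],
            10.0: [0, 1, 1, 0, 0, 1],
            20.0: [6, 7, 5, 8, 6, 7],
        })
        res = ev.promotion_call(data)
        assert res.significant[20.0]
        assert not res.significant[5.0] and not res.significant[10.0]
        assert not res.positive

    def test_dunnett_p_monotone_in_effect_size(self):
        control = [3, 4, 3, 4, 3, 4]
        res = ev.promotion_call(ev.PromotionInput(counts={
            0.0: control,
            1.0: [4, 5, 4, 5, 4, 5],
            2.0: [5, 6, 5, 6, 5, 6],
            3.0: [7, 8, 7, 8, 7, 8],
        }))
        ps = [res.dunnett_p[c] for c in (1.0, 2.0, 3.0)]
        assert ps[0] > ps[1] > ps[2]

    def test_degenerate_zero_variance_flagged(self):
        data = ev.PromotionInput(counts={0.0: [1, 1], 5.0: [3, 3], 10.0: [3, 3]})
        res = ev.promotion_call(data)
        assert res.degenerate and res.positive

    def test_too_few_wells_rejected(self):
        with pytest.raises(ValueError, match="2 wells"):
            ev.PromotionInput(counts={0.0: [1], 5.0: [2, 3]})

    def test_anova_gate_blocks_weak_calls(self):
        data = ev.PromotionInput(counts={
            0.0: [0, 0, 0, 0, 0, 1],
            5.0: [2, 3, 1, 4, 2, 2],
            10.0: [2, 3, 1, 4, 2, 2],
        })
        gated = ev.promotion_call(data, anova_gate=True)
        assert gated.anova_gated
        assert gated.positive == (gated.anova_p < data.alpha and bool(gated.flagged_pairs))

    def test_one_sided_mode_on_reconstructed_promoter_plate(self):
        # integer well counts matching the published mean +/- SD of expert
        # focus counts on the reference promoter plate (synthetic
        # reconstruction, 6 wells per concentration); the one-sided test
        # flags the two consecutive mid concentrations (p-values verified
        # against R multcomp's Dunnett to 4 decimals)
        plate = ev.PromotionInput(counts={
            0.0: [0, 0, 0, 0, 0, 1],
            5.0: [0, 0, 1, 1, 0, 1],
            10.0: [0, 1, 2, 2, 2, 6],
            20.0: [1, 1, 2, 2, 2, 5],
            50.0: [1, 1, 2, 3, 3, 6],
        })
        res = ev.promotion_call(plate, alternative="greater")
        assert res.positive
        assert res.significant[10.0] and res.significant[20.0]
        assert not res.significant[5.0]
        assert res.dunnett_p[10.0] == pytest.approx(0.0373, abs=0.002)
        # the two-sided default is more conservative on the same plate
        assert not ev.promotion_call(plate).significant[10.0]

    def test_random_scores_auc_near_half(self):
        # threshold-free null behavior of the ROC machinery at scale
        inside = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            scores = rng.uniform(size=2000)
            labels = np.repeat([0, 1], 1000)
            _, auc = ev.roc_auc(scores, labels)
            inside += 0.47 <= auc <= 0.53
        assert inside >= 9
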