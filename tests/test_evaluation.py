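import random

import pytest

from metallomine.classifiers import ChelatorProfile, ClassificationResult
from metallomine.evaluation import (
    CensusSummary,
    ConfusionCounts,
    census,
    census_percent,
    combination_counts,
    compute_metrics,
    confusion,
    f1_score,
    format_percent,
    round_half_up,
)


class TestConfusion:
    def test_perfect_all_positive(self):
        preds = {i: True for i in range(5)}
        c = confusion(preds, preds)
        assert (c.tp, c.fp, c.fn, c.tn) == (5, 0, 0, 0)

    def test_all_negative_predictions(self):
        truth = {i: i < 3 for i in range(10)}
        preds = {i: False for i in range(10)}
        c = confusion(preds, truth)
        assert (c.tp, c.fp, c.fn, c.tn) == (0, 0, 3, 7)

    def test_random_instance_matches_per_region_tally(self):
        rng = random.Random(9)
        for _ in range(25):
            keys = [f"r{i}" for i in range(12)]
            preds = {k: rng.random() < 0.5 for k in keys}
            truth = {k: rng.random() < 0.5 for k in keys}
            c = confusion(preds, truth)
            # brute-force per-region tally
            tp = sum(preds[k] and truth[k] for k in keys)
            fp = sum(preds[k] and not truth[k] for k in keys)
            fn = sum(not preds[k] and truth[k] for k in keys)
            tn = sum(not preds[k] and not truth[k] for k in keys)
            assert (c.tp, c.fp, c.fn, c.tn) == (tp, fp, fn, tn)
            assert c.total == len(keys)

    def test_cross_check_against_sklearn(self):
        sklearn = pytest.importorskip("sklearn.metrics")
        rng = random.Random(4)
        keys = list(range(60))
        preds = {k: rng.random() < 0.4 for k in keys}
        truth = {k: rng.random() < 0.5 for k in keys}
        m = compute_metrics(confusion(preds, truth))
        y_true = [truth[k] for k in keys]
        y_pred = [preds[k] for k in keys]
        assert m.precision == pytest.approx(
            sklearn.precision_score(y_true, y_pred)
        )
        assert m.recall == pytest.approx(sklearn.recall_score(y_true, y_pred))
        assert m.f1 == pytest.approx(sklearn.f1_score(y_true, y_pred))

    def test_key_mismatch_raises_with_difference(self):
        with pytest.raises(ValueError, match="r2"):
            confusion({"r1": True}, {"r1": True, "r2": False})


class TestComputeMetrics:
    def test_chelator_rule_benchmark_counts(self):
        # 145 detected of which 5 false positives, 180 curated positives
        m = compute_metrics(ConfusionCounts(tp=140, fp=5, fn=40, tn=573))
        assert m.precision == pytest.approx(140 / 145)
        assert (m.precision_str, m.precision_pct) == ("0.97", "97%")
        assert (m.recall_str, m.recall_pct) == ("0.78", "78%")
        assert m.f1_str == "0.86"

    def test_transporter_benchmark_counts(self):
        m = compute_metrics(ConfusionCounts(tp=100, fp=8, fn=80, tn=570))
        assert (m.precision_str, m.recall_str, m.f1_str) == ("0.93", "0.56", "0.69")

    def test_perfect_classifier(self):
        m = compute_metrics(ConfusionCounts(tp=7, fp=0, fn=0, tn=3))
        assert (m.precision, m.recall, m.f1) == (1.0, 1.0, 1.0)
        assert not m.degenerate

    def test_f1_from_reported_precision_recall(self):
        assert round_half_up(f1_score(0.92, 0.88), 2) == 0.90

    def test_harmonic_mean_identity(self):
        rng = random.Random(12)
        for _ in range(100):
            c = ConfusionCounts(
                tp=rng.randint(1, 50), fp=rng.randint(0, 50),
                fn=rng.randint(0, 50), tn=rng.randint(0, 50),
            )
            m = compute_metrics(c)
            assert 0 <= m.precision <= 1 and 0 <= m.recall <= 1 and 0 <= m.f1 <= 1
            if m.precision + m.recall > 0:
                assert m.f1 == pytest.approx(
                    2 * m.precision * m.recall / (m.precision + m.recall)
                )

    def test_degenerate_zero_denominators(self):
        m = compute_metrics(ConfusionCounts(tp=0, fp=0, fn=0, tn=10))
        assert m.degenerate
        assert (m.precision, m.recall, m.f1) == (0.0, 0.0, 0.0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, fp=0, fn=0, tn=0)


class TestRounding:
    @pytest.mark.parametrize(
        "x,nd,expected",
        [(0.8616, 2, 0.86), (0.8996, 2, 0.90), (0.9259, 2, 0.93),
         (0.775, 2, 0.78), (92.5, 0, 93.0), (8.62, 1, 8.6)],
    )
    def test_half_up(self, x, nd, expected):
        assert round_half_up(x, nd) == expected

    def test_format_percent(self):
        assert format_percent(140 / 145) == "97%"
        assert format_percent(0.5551) == "56%"


def _result(i, chelator, transporter=False, complete=True, groups=()):
    return ClassificationResult(
        region_id=f"r{i}", chelator_rule=chelator, transporter_rule=transporter,
        ensemble=chelator or transporter,
        profile=ChelatorProfile(frozenset(groups), {}), complete=complete,
    )


class TestCensus:
    @pytest.mark.parametrize(
        "pos,total,expected",
        [(3210, 20107, 16.0), (2485, 11704, 21.0), (725, 8403, 8.6),
         (176, 758, 23.0)],
    )
    def test_percentage_reporting_precision(self, pos, total, expected):
        assert census_percent(pos, total) == expected

    def test_counts_and_self_consistency(self):
        results = (
            [_result(i, True, False, True, ["catechol"]) for i in range(4)]
            + [_result(10 + i, False, True, True) for i in range(2)]
            + [_result(20 + i, False, False, False) for i in range(3)]
            + [_result(30, True, True, False, ["hydroxamate"])]
        )
        s = census(results)
        assert s.totals == {"complete": 6, "partial": 4, "total": 10}
        assert s.positives["chelator"] == {"complete": 4, "partial": 1, "total": 5}
        assert s.positives["ensemble"]["total"] == 7
        for method in CensusSummary.METHODS:
            for stratum in CensusSummary.STRATA:
                pos = s.positives[method][stratum]
                tot = s.totals[stratum]
                assert s.percentages[method][stratum] == census_percent(pos, tot)
        # combination counts draw only from complete chelator-positive regions
        assert s.combination_counts == {("catechol",): 4}

    def test_empty_input_flagged_undefined(self):
        s = census([])
        assert s.totals["total"] == 0
        assert all(
            s.percentages[m][st] is None
            for m in CensusSummary.METHODS
            for st in CensusSummary.STRATA
        )


class TestCombinationCounts:
    def test_each_profile_contributes_one_key(self):
        profiles = [
            ChelatorProfile(frozenset({"hydroxamate"})),
            ChelatorProfile(frozenset({"catechol"})),
            ChelatorProfile(frozenset({"hydroxamate", "catechol"})),
        ]
        counts = combination_counts(profiles)
        assert counts == {
            ("hydroxamate",): 1,
            ("catechol",): 1,
            ("catechol", "hydroxamate"): 1,
        }

    def test_empty_list(self):
        assert combination_counts([]) == {}

    def test_marker_only_class_is_its_own_key(self):
        profiles = [ChelatorProfile(frozenset({"NRPS-domain-marker"}))] * 3
        assert combination_counts(profiles) == {("NRPS-domain-marker",): 3}

    def test_random_instance_matches_brute_force_tally(self):
        rng = random.Random(31)
        groups = ["catechol", "hydroxamate", "beta-OHAsp", "salicylate"]
        profiles = []
        for _ in range(50):
            g = frozenset(x for x in groups if rng.random() < 0.4)
            profiles.append(ChelatorProfile(g))
        counts = combination_counts(profiles)
        expected: dict = {}
        for p in profiles:
            if p.groups:
                key = tuple(sorted(p.groups))
                expected[key] = expected.get(key, 0) + 1
        assert counts == expected
        assert sum(counts.values()) == sum(1 for p in profiles if p.groups)
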