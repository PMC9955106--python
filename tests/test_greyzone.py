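import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import WORKED_NEG, WORKED_POS, random_overlap_dataset
from oracles import grey_zone_oracle

from grayzone import (
    BayesSpec,
    GrayZone,
    MarkerDataset,
    empirical_roc,
    grey_zone_bounds,
    lr_targets,
    pretest_from_counts,
    zone_report,
)


class TestPretest:
    def test_sample_prevalence(self):
        spec = pretest_from_counts(110, 400)
        assert round(spec.pretest_prob, 3) == 0.216
        assert spec.ppv_target == 0.6 and spec.npv_target == 0.95

    @pytest.mark.parametrize(
        "n_pos, n_neg, prob", [(1, 1, 0.5), (78, 431, 78 / 509)]
    )
    def test_direct_division(self, n_pos, n_neg, prob):
        assert pretest_from_counts(n_pos, n_neg).pretest_prob == pytest.approx(prob)

    @pytest.mark.parametrize("n_pos, n_neg", [(0, 10), (10, 0), (0, 0)])
    def test_zero_counts_rejected(self, n_pos, n_neg):
        with pytest.raises(ValueError):
            pretest_from_counts(n_pos, n_neg)


class TestLrTargets:
    def test_published_settings(self):
        t = lr_targets(BayesSpec(pretest_prob=110 / 510))
        assert round(t.lr_pos_target, 3) == 5.455
        assert round(t.lr_neg_target, 3) == 0.191

    def test_no_update_case(self):
        t = lr_targets(BayesSpec(0.5, ppv_target=0.5, npv_target=0.5))
        assert t.lr_pos_target == pytest.approx(1.0)
        assert t.lr_neg_target == pytest.approx(1.0)

    def test_hand_odds_arithmetic(self):
        t = lr_targets(BayesSpec(0.2, ppv_target=0.8, npv_target=0.9))
        assert t.lr_pos_target == pytest.approx(16.0)
        assert t.lr_neg_target == pytest.approx(4 / 9)

    @given(
        p=st.floats(0.01, 0.99),
        ppv=st.floats(0.01, 0.99),
        npv=st.floats(0.01, 0.99),
    )
    @settings(max_examples=100, derandomize=True)
    def test_targets_invert_back_through_bayes(self, p, ppv, npv):
        """Plugging the targets back into the odds relation recovers PPV/NPV."""
        t = lr_targets(BayesSpec(p, ppv_target=ppv, npv_target=npv))
        assert t.lr_pos_target > 0 and t.lr_neg_target > 0
        post_odds_pos = (p / (1 - p)) * t.lr_pos_target
        assert post_odds_pos / (1 + post_odds_pos) == pytest.approx(ppv, rel=1e-9)
        post_odds_neg = ((1 - p) / p) / t.lr_neg_target
        assert post_odds_neg / (1 + post_odds_neg) == pytest.approx(npv, rel=1e-9)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 1.5])
    def test_boundary_probabilities_rejected(self, bad):
        with pytest.raises(ValueError):
            BayesSpec(pretest_prob=bad)


class TestGreyZoneBounds:
    def test_worked_example(self, worked_dataset):
        from grayzone.greyzone import LrTargets

        zone = grey_zone_bounds(
            empirical_roc(worked_dataset), LrTargets(3.0, 2 / 19)
        )
        assert (zone.lower, zone.upper) == (5.0, 9.0)
        assert zone.method == "grey_zone"
        gray = worked_dataset.values[
            (worked_dataset.values >= zone.lower) & (worked_dataset.values < zone.upper)
        ]
        assert sorted(set(gray)) == [5.0, 6.0, 7.0, 8.0]

    def test_perfect_separation_gives_empty_zone_at_split(self):
        from grayzone.greyzone import LrTargets

        d = MarkerDataset.from_groups([1.0, 2.0, 3.0], [10.0, 11.0, 12.0])
        zone = grey_zone_bounds(empirical_roc(d), LrTargets(10.0, 0.05))
        assert zone.is_empty
        assert zone.lower == zone.upper == 10.0

    def test_overlapping_tail_collapses_flagged(self):
        from grayzone.greyzone import LrTargets

        d = MarkerDataset.from_groups(
            list(range(1, 11)), [8.0, 9.0, 10.0, 11.0, 12.0]
        )
        zone = grey_zone_bounds(empirical_roc(d), LrTargets(3.0, 2 / 19))
        assert zone.lower == zone.upper == 8.0
        assert zone.is_empty

    def test_unattainable_targets_pushed_to_extremes(self):
        from grayzone.greyzone import LrTargets

        # identical class distributions: LR+ <= 1 and LR- >= 1 everywhere,
        # so neither published target is ever reached
        vals = list(range(1, 11))
        d = MarkerDataset.from_groups(vals, vals)
        roc = empirical_roc(d)
        zone = grey_zone_bounds(roc, LrTargets(5.455, 0.191))
        assert not zone.upper_attainable and not zone.lower_attainable
        assert zone.upper == roc.thresholds[-1]  # sentinel: nobody positive
        assert zone.lower == roc.thresholds[0]   # minimum: nobody negative
        assert zone.width == pytest.approx(roc.thresholds[-1] - 1.0)

    def test_matches_bruteforce_oracle(self):
        """First-attainment limits equal a naive per-threshold LR table scan."""
        rng = np.random.default_rng(11)
        for _ in range(150):
            d = random_overlap_dataset(rng)
            bayes = pretest_from_counts(
                d.n_pos, d.n_neg,
                ppv_target=float(rng.uniform(0.3, 0.95)),
                npv_target=float(rng.uniform(0.5, 0.99)),
            )
            t = lr_targets(bayes)
            zone = grey_zone_bounds(empirical_roc(d), t)
            expect = grey_zone_oracle(
                list(d.pos_values), list(d.neg_values),
                t.lr_pos_target, t.lr_neg_target,
            )
            assert zone.lower == pytest.approx(expect["lower"])
            assert zone.upper == pytest.approx(expect["upper"])
            assert zone.lower_attainable == expect["lower_attainable"]
            assert zone.upper_attainable == expect["upper_attainable"]
            assert zone.degenerate == expect["degenerate"]

    def test_predictive_value_guarantee_on_fitting_data(self):
        """Outside-zone calls achieve the requested PPV/NPV whenever the
        corresponding limit was attainable (exact finite-sample property)."""
        rng = np.random.default_rng(7)
        checked = 0
        for _ in range(200):
            d = random_overlap_dataset(rng)
            bayes = pretest_from_counts(
                d.n_pos, d.n_neg,
                ppv_target=float(rng.uniform(0.3, 0.95)),
                npv_target=float(rng.uniform(0.5, 0.99)),
            )
            zone = grey_zone_bounds(empirical_roc(d), lr_targets(bayes))
            if zone.degenerate:
                continue
            r = zone_report(d, zone)
            if zone.upper_attainable and (r.tp + r.fp) > 0:
                assert r.tp / (r.tp + r.fp) >= bayes.ppv_target - 1e-12
                checked += 1
            if zone.lower_attainable and (r.tn + r.fn) > 0:
                assert r.tn / (r.tn + r.fn) >= bayes.npv_target - 1e-12
                checked += 1
        assert checked > 100  # the property was actually exercised

    def test_raising_targets_never_shrinks_zone(self, worked_dataset):
        roc = empirical_roc(worked_dataset)
        bayes = pretest_from_counts(worked_dataset.n_pos, worked_dataset.n_neg)
        widths = []
        for ppv, npv in [(0.3, 0.6), (0.5, 0.8), (0.6, 0.95), (0.8, 0.99)]:
            zone = grey_zone_bounds(
                roc, lr_targets(BayesSpec(bayes.pretest_prob, ppv, npv))
            )
            widths.append(zone.width)
        assert widths == sorted(widths)

    def test_isotonic_smoothing_variant(self, sii_cohort):
        """The optional monotonized scan returns a valid, documented zone."""
        roc = empirical_roc(sii_cohort)
        t = lr_targets(pretest_from_counts(sii_cohort.n_pos, sii_cohort.n_neg))
        zone = grey_zone_bounds(roc, t, smooth="isotonic")
        assert zone.lower <= zone.upper
        assert zone.lower in roc.thresholds and zone.upper in roc.thresholds
        with pytest.raises(ValueError):
            grey_zone_bounds(roc, t, smooth="loess")


class TestGrayZoneType:
    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError):
            GrayZone(lower=2.0, upper=1.0, method="grey_zone")

    def test_json_round_trip(self, tmp_path):
        import json

        zone = GrayZone(lower=1.5, upper=3.5, method="grey_zone")
        path = tmp_path / "zone.json"
        zone.to_json(path, extra={"lr_pos_target": 5.455})
        raw = json.loads(path.read_text())
        assert raw["lower"] == 1.5 and raw["upper"] == 3.5
        assert raw["lr_pos_target"] == 5.455

    def test_worked_example_from_raw_lists(self):
        # guard against fixture drift: the module-level lists stay in sync
        assert WORKED_NEG[-1] == 15.0 and WORKED_POS[0] == 5.0
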