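"""ROC analysis: AUC identity, DeLong CI, Youden cutoffs, metric scales."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from libs_tissue import (
    MetricScale,
    TissueClass,
    ValidationError,
    auc_ci_delong,
    auc_mann_whitney,
    build_metric_scale,
    classify,
    pairwise_roc_report,
    sample_features,
    youden_cutoff,
)
from libs_tissue.roc import HIGHER, LOWER


def _pair_counting_auc(pos, neg):
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestAuc:
    def test_perfect_separation(self):
        auc, direction = auc_mann_whitney([4, 5, 6], [1, 2, 3])
        assert auc == 1.0 and direction == HIGHER

    def test_identical_samples_are_chance(self):
        auc, _ = auc_mann_whitney([1, 2, 3], [3, 2, 1])
        assert auc == 0.5

    def test_enumerated_four_pairs(self):
        auc, direction = auc_mann_whitney([2, 4], [1, 3])
        assert auc == 0.75 and direction == HIGHER

    def test_lower_scores_flip_orientation(self):
        auc, direction = auc_mann_whitney([1, 2], [5, 6])
        assert auc == 1.0 and direction == LOWER

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            auc_mann_whitney([], [1.0])

    @given(
        pos=st.lists(st.integers(0, 30), min_size=1, max_size=20),
        neg=st.lists(st.integers(0, 30), min_size=1, max_size=20),
    )
    def test_matches_pair_counting_oracle(self, pos, neg):
        auc, direction = auc_mann_whitney(pos, neg)
        raw = _pair_counting_auc(pos, neg)
        expected = raw if raw >= 0.5 else 1.0 - raw
        assert auc == pytest.approx(expected, abs=1e-12)

    def test_converges_to_binormal_on_log_value(self):
        rng = np.random.default_rng(77)
        mu1, s1, mu2, s2 = 0.0, 0.6, 1.1, 0.9
        pos = rng.lognormal(mu2, s2, 5000)
        neg = rng.lognormal(mu1, s1, 5000)
        truth = sps.norm.cdf((mu2 - mu1) / np.hypot(s1, s2))
        auc, _ = auc_mann_whitney(pos, neg)
        assert auc == pytest.approx(truth, abs=0.01)


class TestDeLong:
    def test_perfect_separation_hits_upper_bound(self):
        rng = np.random.default_rng(1)
        lo, hi = auc_ci_delong(rng.uniform(10, 11, 200), rng.uniform(0, 1, 200))
        assert hi == 1.0

    def test_degenerate_variance_collapses_interval(self):
        lo, hi = auc_ci_delong([10.0, 11.0], [1.0, 2.0])
        assert (lo, hi) == (1.0, 1.0)

    def test_width_shrinks_with_sample_size(self):
        rng = np.random.default_rng(5)
        pos, neg = rng.normal(1.0, 1.0, 400), rng.normal(0.0, 1.0, 400)
        lo1, hi1 = auc_ci_delong(pos[:100], neg[:100])
        lo2, hi2 = auc_ci_delong(pos, neg)
        assert (hi2 - lo2) < (hi1 - lo1)

    def test_simulation_coverage_near_nominal(self):
        """95% CI covers the true binormal-on-log AUC 92-98% of the time."""
        rng = np.random.default_rng(13)
        mu_delta, s1, s2 = 1.0, 1.0, 1.0
        truth = sps.norm.cdf(mu_delta / np.hypot(s1, s2))
        covered = 0
        n_sim = 1000
        for _ in range(n_sim):
            pos = rng.lognormal(mu_delta, s2, 100)
            neg = rng.lognormal(0.0, s1, 100)
            lo, hi = auc_ci_delong(pos, neg)
            covered += lo <= truth <= hi
        assert 0.92 <= covered / n_sim <= 0.98


class TestYouden:
    def test_perfect_separation_gives_unit_j(self):
        r = youden_cutoff([4, 5, 6], [1, 2, 3])
        assert r.j == 1.0 and r.sensitivity == 1.0 and r.specificity == 1.0
        assert 3 < r.cutoff < 4

    def test_spec_example_with_overlapping_pairs(self):
        # AUC picks lower-is-positive here; the optimum J is 0.5.
        r = youden_cutoff([1, 3], [2, 4])
        assert r.direction == LOWER and r.j == pytest.approx(0.5)
        # Forcing the disfavoured orientation can only do worse.
        forced = youden_cutoff([1, 3], [2, 4], direction=HIGHER)
        assert forced.j == pytest.approx(0.0)

    def test_constant_samples_rejected(self):
        with pytest.raises(ValidationError):
            youden_cutoff([2.0, 2.0], [2.0, 2.0])

    def test_matches_exhaustive_scan(self):
        """Optimal J agrees with brute force over every midpoint threshold."""
        rng = np.random.default_rng(21)
        for _ in range(50):
            pos = rng.integers(0, 12, rng.integers(2, 20)).astype(float)
            neg = rng.integers(0, 12, rng.integers(2, 20)).astype(float)
            if np.all(np.concatenate([pos, neg]) == pos[0]):
                continue
            r = youden_cutoff(pos, neg)
            tp, tn = (pos, neg) if r.direction == HIGHER else (-pos, -neg)
            distinct = np.unique(np.concatenate([tp, tn]))
            best_j = max(
                np.mean(tp >= c) + np.mean(tn < c) - 1.0
                for c in (distinct[:-1] + distinct[1:]) / 2.0
            )
            assert r.j == pytest.approx(best_j, abs=1e-12)

    def test_reported_rates_recompute_at_cutoff(self):
        rng = np.random.default_rng(3)
        pos, neg = rng.normal(1, 1, 50), rng.normal(0, 1, 60)
        r = youden_cutoff(pos, neg)
        if r.direction == HIGHER:
            assert r.sensitivity == np.mean(pos >= r.cutoff)
            assert r.specificity == np.mean(neg < r.cutoff)
        else:
            assert r.sensitivity == np.mean(pos <= r.cutoff)
            assert r.specificity == np.mean(neg > r.cutoff)


@pytest.fixture(scope="module")
def report(default_run):
    return pairwise_roc_report(default_run["features"])


class TestPairwiseReport:
    def test_twelve_self_consistent_rows(self, report):
        assert len(report) == 12
        for r in report:
            lo, hi = r.ci95
            assert lo <= r.auc <= hi
            assert 0.5 <= r.auc <= 1.0
            assert 0.0 <= r.sensitivity <= 1.0 and 0.0 <= r.specificity <= 1.0

    def _auc(self, report, a, b, element):
        for r in report:
            if (r.positive_class, r.negative_class, r.element) == (a, b, element):
                return r.auc
        raise AssertionError("row not found")

    def test_calcium_beats_potassium_for_fibrosis_vs_nerve(self, report):
        ca = self._auc(report, TissueClass.FIBROSIS, TissueClass.NERVE, "Ca")
        k = self._auc(report, TissueClass.FIBROSIS, TissueClass.NERVE, "K")
        assert ca > k

    def test_potassium_beats_calcium_for_fibrosis_vs_cell_rich(self, report):
        ca = self._auc(report, TissueClass.FIBROSIS, TissueClass.CELL_RICH_TUMOR, "Ca")
        k = self._auc(report, TissueClass.FIBROSIS, TissueClass.CELL_RICH_TUMOR, "K")
        assert k > ca

    def test_missing_class_rejected(self, default_run):
        partial = [f for f in default_run["features"] if f.tissue is not TissueClass.NERVE]
        with pytest.raises(ValidationError):
            pairwise_roc_report(partial)


class TestMetricScale:
    def test_point_mass_classes_cut_between_supports(self):
        from libs_tissue import ElectrolyteFeatures

        values = {
            TissueClass.CELL_RICH_TUMOR: [1.0, 1.1],
            TissueClass.FIBROSIS: [5.0, 5.1],
            TissueClass.TUMOR_STROMA: [9.0, 9.1],
            TissueClass.NERVE: [20.0, 20.1],
        }
        feats = [
            ElectrolyteFeatures(f"{c.value}-{i}", ca_sum=v, k_sum=0.0, na_sum=0.0, tissue=c)
            for c, vals in values.items()
            for i, v in enumerate(vals)
        ]
        scale = build_metric_scale(feats, "Ca")
        assert scale.ordered_classes == (
            TissueClass.CELL_RICH_TUMOR,
            TissueClass.FIBROSIS,
            TissueClass.TUMOR_STROMA,
            TissueClass.NERVE,
        )
        assert scale.cutoffs[0] == pytest.approx((1.1 + 5.0) / 2)
        assert scale.cutoffs[1] == pytest.approx((5.1 + 9.0) / 2)
        assert scale.cutoffs[2] == pytest.approx((9.1 + 20.0) / 2)

    def test_synthetic_scales_reproduce_published_class_orders(self, default_run):
        ca = build_metric_scale(default_run["features"], "Ca")
        assert [c.value for c in ca.ordered_classes] == [
            "cell_rich_tumor", "fibrosis", "tumor_stroma", "nerve",
        ]
        k = build_metric_scale(default_run["features"], "K")
        assert [c.value for c in k.ordered_classes] == [
            "nerve", "fibrosis", "tumor_stroma", "cell_rich_tumor",
        ]
        assert ca.cutoffs[0] < ca.cutoffs[1] < ca.cutoffs[2]
        assert k.cutoffs[0] < k.cutoffs[1] < k.cutoffs[2]

    def test_non_ascending_cutoffs_rejected(self):
        with pytest.raises(ValidationError):
            MetricScale(
                element="Ca",
                ordered_classes=(
                    TissueClass.CELL_RICH_TUMOR,
                    TissueClass.FIBROSIS,
                    TissueClass.TUMOR_STROMA,
                    TissueClass.NERVE,
                ),
                cutoffs=(3.0, 2.0, 5.0),
            )


@pytest.fixture(scope="module")
def published_scales():
    ca = MetricScale(
        element="Ca",
        ordered_classes=(
            TissueClass.CELL_RICH_TUMOR,
            TissueClass.FIBROSIS,
            TissueClass.TUMOR_STROMA,
            TissueClass.NERVE,
        ),
        cutoffs=(3.414, 12.21, 53.68),
    )
    k = MetricScale(
        element="K",
        ordered_classes=(
            TissueClass.NERVE,
            TissueClass.FIBROSIS,
            TissueClass.TUMOR_STROMA,
            TissueClass.CELL_RICH_TUMOR,
        ),
        cutoffs=(2.239, 4.466, 5.549),
    )
    return ca, k


class TestClassify:
    def test_published_worked_examples(self, published_scales):
        ca, k = published_scales
        assert classify(30.04, ca) is TissueClass.TUMOR_STROMA
        assert classify(0.0, ca) is TissueClass.CELL_RICH_TUMOR
        assert classify(6.498, k) is TissueClass.CELL_RICH_TUMOR

    def test_boundary_belongs_to_upper_interval(self, published_scales):
        ca, _ = published_scales
        assert classify(3.414, ca) is TissueClass.FIBROSIS
        assert classify(53.68, ca) is TissueClass.NERVE

    def test_negative_value_rejected(self, published_scales):
        with pytest.raises(ValidationError):
            classify(-0.1, published_scales[0])

    @given(st.floats(0.0, 100.0, allow_nan=False))
    def test_monotone_in_value(self, value):
        ca = MetricScale(
            element="Ca",
            ordered_classes=(
                TissueClass.CELL_RICH_TUMOR,
                TissueClass.FIBROSIS,
                TissueClass.TUMOR_STROMA,
                TissueClass.NERVE,
            ),
            cutoffs=(3.414, 12.21, 53.68),
        )
        idx = ca.ordered_classes.index(classify(value, ca))
        idx_up = ca.ordered_classes.index(classify(value + 1.0, ca))
        assert idx_up >= idx
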