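import numpy as np
import pytest
from sklearn.metrics import normalized_mutual_info_score

from cortsim import (
    FixtureSpec,
    LabeledSamples,
    gaussian_class_samples,
    info_detection,
    info_differentiation,
    mi_stimulus_response,
    nmi,
    significance_detection,
    significance_differentiation,
    supervised_detection,
    supervised_differentiation,
)


def _two_class(delta, sd=1.0, n=500, seed=0):
    s = gaussian_class_samples(FixtureSpec(means=(0.0, delta), sds=(sd, sd),
                                           n_per_class=n, seed=seed))
    return s.values[:n], s.values[n:]


class TestNmi:
    def test_perfect_agreement(self):
        labels = [0] * 30 + [1] * 30
        assert nmi(labels, labels) == 1.0

    def test_hand_computed_contingency(self):
        """50/50 two-class truth with a 40/10 vs 10/40 confusion: MI =
        0.8 log2 1.6 + 0.2 log2 0.4 and unit entropies, NMI ~ 0.2781."""
        true = [0] * 50 + [1] * 50
        pred = [0] * 40 + [1] * 10 + [0] * 10 + [1] * 40
        assert nmi(true, pred) == pytest.approx(0.2781, abs=2e-4)

    def test_single_cluster_prediction_scores_zero(self):
        true = [0] * 50 + [1] * 50
        assert nmi(true, [0] * 100) == 0.0

    def test_symmetry_and_relabeling_invariance(self):
        rng = np.random.default_rng(1)
        a = rng.integers(0, 3, 200)
        b = rng.integers(0, 4, 200)
        assert nmi(a, b) == pytest.approx(nmi(b, a), abs=1e-12)
        remapped = np.array([10, 7, 99])[a]
        assert nmi(remapped, b) == pytest.approx(nmi(a, b), abs=1e-12)

    def test_bounded_on_random_labelings(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            a = rng.integers(0, rng.integers(1, 6), 50)
            b = rng.integers(0, rng.integers(1, 6), 50)
            v = nmi(a, b)
            assert 0.0 <= v <= 1.0

    def test_matches_reference_implementation(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            a = rng.integers(0, 4, 300)
            b = rng.integers(0, 3, 300)
            ref = normalized_mutual_info_score(a, b, average_method="geometric")
            assert nmi(a, b) == pytest.approx(ref, abs=1e-10)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            nmi([], [])
        with pytest.raises(ValueError):
            nmi([0, 1], [0])


class TestDetection:
    def test_well_separated_classes(self):
        spont, evoked = _two_class(10.0)
        assert info_detection(spont, evoked, seed=0).mean > 0.9

    def test_identical_distributions_carry_no_information(self):
        spont, evoked = _two_class(0.0)
        assert info_detection(spont, evoked, seed=0).mean < 0.05

    def test_monotone_in_class_separation(self):
        means = [info_detection(*_two_class(d, seed=7), seed=1).mean
                 for d in (0.5, 1.5, 3.0, 6.0)]
        assert np.all(np.diff(means) > -0.02)
        assert means[-1] > means[0] + 0.3

    def test_result_structure(self):
        spont, evoked = _two_class(3.0)
        res = info_detection(spont, evoked, seed=0)
        assert res.per_fold.shape == (10,)
        assert res.ci95 >= 0.0
        assert res.method == "kmeans"


class TestDifferentiation:
    def test_common_distribution_scores_zero(self):
        rng = np.random.default_rng(4)
        groups = [rng.normal(0, 1, 300) for _ in range(5)]
        assert info_differentiation(groups, seed=0).mean < 0.05

    def test_separated_intensity_ladder(self):
        rng = np.random.default_rng(5)
        groups = [rng.normal(5.0 * k, 0.5, 300) for k in range(5)]
        assert info_differentiation(groups, seed=0).mean > 0.8

    def test_needs_two_groups(self):
        with pytest.raises(ValueError):
            info_differentiation([np.zeros(10)])


class TestSupervised:
    def test_separable_oracle(self):
        spont, evoked = _two_class(10.0)
        assert supervised_detection(spont, evoked, seed=0).mean > 0.9

    def test_label_shuffle_destroys_information(self):
        rng = np.random.default_rng(6)
        spont, evoked = _two_class(6.0, seed=8)
        pooled = np.concatenate([spont, evoked])
        rng.shuffle(pooled)
        assert supervised_detection(pooled[:500], pooled[500:], seed=0).mean < 0.05

    def test_differentiation_qualitative_agreement_with_kmeans(self):
        rng = np.random.default_rng(7)
        easy = [rng.normal(4.0 * k, 0.5, 200) for k in range(5)]
        hard = [rng.normal(0.4 * k, 1.0, 200) for k in range(5)]
        km_gap = (info_differentiation(easy, seed=1).mean
                  - info_differentiation(hard, seed=1).mean)
        lg_gap = (supervised_differentiation(easy, seed=1).mean
                  - supervised_differentiation(hard, seed=1).mean)
        assert km_gap > 0.3 and lg_gap > 0.3


class TestSignificance:
    def test_null_p_values_are_uniform(self):
        """Under identical distributions the t-test p-value is U(0,1)."""
        from scipy.stats import kstest

        rng = np.random.default_rng(8)
        pvals = []
        for _ in range(400):
            a, b = rng.normal(0, 1, (2, 60))
            pvals.append(significance_detection(a, b).p_value)
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_large_separation_is_overwhelming(self):
        spont, evoked = _two_class(10.0)
        assert significance_detection(spont, evoked).p_value < 1e-6

    def test_anova_f_near_one_under_null(self):
        rng = np.random.default_rng(9)
        fs = [significance_differentiation([rng.normal(0, 1, 80) for _ in range(5)]).mean
              for _ in range(300)]
        assert np.mean(fs) == pytest.approx(1.0, abs=0.15)

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError):
            significance_detection(np.ones(20), np.ones(20))


class TestMutualInformation:
    def test_independent_responses_near_zero(self):
        rng = np.random.default_rng(10)
        groups = [rng.normal(0, 1, 500) for _ in range(5)]
        assert 0.0 <= mi_stimulus_response(groups).bits < 0.05

    def test_perfect_coding_attains_log2_k(self):
        groups = [np.full(50, 5.0 * k) for k in range(5)]
        assert mi_stimulus_response(groups).bits == pytest.approx(np.log2(5), abs=1e-9)

    def test_bounded_by_stimulus_entropy(self):
        rng = np.random.default_rng(11)
        groups = [rng.normal(3.0 * k, 0.3, 400) for k in range(4)]
        assert mi_stimulus_response(groups).bits <= np.log2(4) + 1e-9


class TestLabeledSamples:
    def test_from_arrays_and_validation(self):
        s = LabeledSamples.from_arrays(np.zeros(3), np.ones(4))
        assert s.n_classes == 2 and s.values.size == 7
        with pytest.raises(ValueError):
            LabeledSamples(np.zeros(3), np.zeros(4))
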