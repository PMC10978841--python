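import numpy as np
import pytest
from scipy.stats import norm
from sklearn.metrics import roc_auc_score

from _helpers import make_ann, make_profiles
from proxiprof import (
    RatioCutoffSelector,
    apply_cutoff,
    choose_cutoff,
    ratio_distribution,
    roc_curve,
    specificity_at,
)
from proxiprof.errors import ConfigurationError


def brute_force_auc(scores, labels):
    """Pairwise concordance with half credit for ties (independent oracle)."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    c = 0.0
    for a in pos:
        for b in neg:
            c += 1.0 if a > b else (0.5 if a == b else 0.0)
    return c / (len(pos) * len(neg))


def random_instance(rng):
    n = int(rng.integers(4, 51))
    ids = [f"P{i}" for i in range(n)]
    # coarse rounding forces plenty of ties
    ratios = np.round(np.exp2(rng.normal(1.0, 1.0, n)), 1)
    plus = rng.random(n) < 0.1
    labels = rng.random(n) < 0.5
    if labels.all():
        labels[0] = False
    if not labels.any():
        labels[0] = True
    profiles = make_profiles(
        {i: r for i, r in zip(ids, ratios)},
        only_in_plus=[i for i, p in zip(ids, plus) if p],
    )
    ann = make_ann([i for i, l in zip(ids, labels) if l])
    order = profiles["group_id"].tolist()
    scores = [
        np.inf if plus[ids.index(i)] else np.log2(ratios[ids.index(i)])
        for i in order
    ]
    lab = [labels[ids.index(i)] for i in order]
    return profiles, ann, scores, lab


class TestRatioDistribution:
    def test_hand_binned_counts(self):
        # log2 ratios {0,1,2,3}, two equal-width bins -> 2 and 2
        profiles = make_profiles(
            {"P1": 1.0, "P2": 2.0, "P3": 4.0, "P4": 8.0}
        )
        ann = make_ann(["P1", "P2"])
        hist = ratio_distribution(profiles, ann, n_bins=2)
        np.testing.assert_allclose(hist.bin_edges, [0.0, 1.5, 3.0])
        assert (hist.counts_annotated + hist.counts_unannotated).tolist() == [
            2,
            2,
        ]

    def test_single_class_counts_and_plus_sidecar(self):
        profiles = make_profiles(
            {"P1": 2.0, "P2": 4.0, "P3": 8.0, "P4": 3.0},
            only_in_plus=["P5"],
        )
        ann = make_ann(["P1", "P2", "P3", "P4", "P5"])
        hist = ratio_distribution(profiles, ann, n_bins=3)
        assert hist.counts_unannotated.sum() == 0
        assert hist.counts_annotated.sum() == 4  # P5 excluded from bins
        assert hist.n_only_in_plus == 1

    def test_no_finite_ratios_is_an_error(self):
        profiles = make_profiles({}, only_in_plus=["P1"])
        with pytest.raises(ValueError, match="histogram"):
            ratio_distribution(profiles, make_ann(["P1"]), n_bins=2)


class TestROC:
    def test_perfect_separation_gives_auc_one(self):
        profiles = make_profiles({"A1": 8.0, "A2": 9.0, "B1": 1.0, "B2": 2.0})
        assert roc_curve(profiles, make_ann(["A1", "A2"])).auc == 1.0

    def test_exchangeable_classes_give_half(self):
        profiles = make_profiles(
            {"A1": 2.0, "A2": 4.0, "B1": 2.0, "B2": 4.0}
        )
        assert roc_curve(profiles, make_ann(["A1", "A2"])).auc == pytest.approx(
            0.5
        )

    def test_curve_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(5)
        profiles, ann, _, _ = random_instance(rng)
        curve = roc_curve(profiles, ann)
        assert curve.tpr[0] == curve.fpr[0] == 0.0
        assert curve.tpr[-1] == curve.fpr[-1] == 1.0
        assert (np.diff(curve.tpr) >= 0).all()
        assert (np.diff(curve.fpr) >= 0).all()

    def test_auc_equals_pairwise_concordance_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            profiles, ann, scores, labels = random_instance(rng)
            auc = roc_curve(profiles, ann).auc
            assert auc == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-9
            )

    def test_auc_agrees_with_sklearn_cross_check(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            profiles, ann, scores, labels = random_instance(rng)
            finite = np.where(np.isinf(scores), 1e9, scores)  # rank-safe
            assert roc_curve(profiles, ann).auc == pytest.approx(
                roc_auc_score(labels, finite), abs=1e-9
            )

    def test_single_class_input_rejected(self):
        profiles = make_profiles({"P1": 2.0, "P2": 4.0})
        with pytest.raises(ValueError, match="ROC undefined"):
            roc_curve(profiles, make_ann(["P1", "P2"]))


class TestSpecificity:
    def test_direct_count(self):
        ids = [f"P{i}" for i in range(10)]
        profiles = make_profiles({i: 5.0 for i in ids})
        ann = make_ann(ids[:6])
        assert specificity_at(profiles, ann, 1.0) == pytest.approx(0.6)

    def test_all_annotated_gives_one(self):
        profiles = make_profiles({"P1": 5.0}, only_in_plus=["P2"])
        assert specificity_at(profiles, make_ann(["P1", "P2"]), 2.0) == 1.0

    def test_printed_style_list_sizes(self):
        # a 391-protein retained list with 326 annotated -> 83% specificity
        ids = [f"P{i:04d}" for i in range(391)]
        profiles = make_profiles({i: 6.0 for i in ids})
        assert specificity_at(profiles, make_ann(ids[:326]), 5.0) == (
            pytest.approx(0.834, abs=5e-4)
        )

    def test_empty_retained_set_is_an_error(self):
        profiles = make_profiles({"P1": 2.0})
        with pytest.raises(ValueError, match="specificity undefined"):
            specificity_at(profiles, make_ann(["P1"]), 100.0)


class TestChooseCutoff:
    def test_tiny_target_returns_minimum_observed_ratio(self):
        profiles = make_profiles({"P1": 2.0, "P2": 5.0, "P3": 9.0})
        ann = make_ann(["P2"])
        assert choose_cutoff(profiles, ann, 0.01) == 2.0

    def test_unreachable_target_returns_none(self):
        profiles = make_profiles({"A": 9.0, "B": 3.0})
        ann = make_ann(["B"])  # top-ranked protein unannotated
        assert choose_cutoff(profiles, ann, 1.0) is None

    def test_invalid_target_is_config_error(self):
        profiles = make_profiles({"P1": 2.0})
        for bad in (0.0, -0.2, 1.5):
            with pytest.raises(ConfigurationError):
                choose_cutoff(profiles, make_ann(["P1"]), bad)

    def test_grid_scan_oracle_on_gaussian_mixture(self):
        rng = np.random.default_rng(11)
        ids_m = [f"M{i}" for i in range(500)]
        ids_b = [f"B{i}" for i in range(500)]
        ratios = dict(
            zip(ids_m, np.exp2(rng.normal(3.0, 1.0, 500)))
        ) | dict(zip(ids_b, np.exp2(rng.normal(0.0, 1.0, 500))))
        profiles = make_profiles(ratios)
        ann = make_ann(ids_m)
        thr = choose_cutoff(profiles, ann, 0.8)
        assert specificity_at(profiles, ann, thr) >= 0.8
        # exhaustive scan: every smaller observed grid value fails
        grid = sorted(profiles["mean_ratio"].dropna().unique())
        below = [t for t in grid if t < thr]
        assert all(
            specificity_at(profiles, ann, t) < 0.8 for t in below
        )


class TestApplyCutoff:
    def test_boundary_value_is_retained(self):
        profiles = make_profiles({"P1": 4.9, "P2": 5.0, "P3": 7.2})
        result = apply_cutoff(profiles, make_ann(["P2", "P3"]), 5.0)
        assert sorted(result.retained["group_id"]) == ["P2", "P3"]

    def test_abundance_fraction_direct_sum(self):
        profiles = make_profiles(
            {"P1": 6.0, "P2": 6.0, "P3": 6.0},
            intensities={"P1": 10.0, "P2": 30.0, "P3": 60.0},
        )
        result = apply_cutoff(profiles, make_ann(["P1", "P2"]), 5.0)
        assert result.abundance_fraction == pytest.approx(0.4)
        assert result.specificity == pytest.approx(2 / 3)

    def test_all_intensity_on_annotated_gives_one(self):
        profiles = make_profiles({"P1": 6.0}, only_in_plus=["P2"])
        result = apply_cutoff(profiles, make_ann(["P1", "P2"]), 5.0)
        assert result.abundance_fraction == 1.0

    def test_submito_counts_and_matrix_coverage(self):
        profiles = make_profiles({"P1": 6.0, "P2": 6.0, "P3": 6.0, "P4": 1.0})
        ann = make_ann(
            {"P1": "matrix_star", "P2": "IMS", "P4": "matrix_star"}
        )
        result = apply_cutoff(profiles, ann, 5.0)
        assert result.submito_counts == {
            "matrix_star": 1,
            "IMS": 1,
            "MOM": 0,
            "unassigned": 0,
            "non_mito": 1,
        }
        # P4 (matrix*) fell below the cutoff: 1 of 2 matrix* covered
        assert result.matrix_coverage == pytest.approx(0.5)

    def test_retained_sets_nest_as_threshold_increases(self):
        rng = np.random.default_rng(3)
        profiles, ann, _, _ = random_instance(rng)
        previous = None
        for thr in (1.0, 2.0, 4.0, 8.0):
            try:
                retained = set(
                    apply_cutoff(profiles, ann, thr).retained["group_id"]
                )
            except ValueError:
                break
            if previous is not None:
                assert retained <= previous
            previous = retained


class TestSelectorEstimator:
    def test_fixed_threshold_mode_matches_apply_cutoff(self):
        profiles = make_profiles({"P1": 4.9, "P2": 5.0, "P3": 7.2})
        ann = make_ann(["P2", "P3"])
        sel = RatioCutoffSelector(threshold=5.0).fit(profiles, ann)
        assert sel.threshold_ == 5.0
        assert sorted(sel.transform(profiles)["group_id"]) == ["P2", "P3"]

    def test_mutually_exclusive_modes_rejected(self):
        profiles = make_profiles({"P1": 2.0, "P2": 4.0})
        with pytest.raises(ConfigurationError):
            RatioCutoffSelector(threshold=5.0, target_specificity=0.8).fit(
                profiles, make_ann(["P1"])
            )

    def test_get_params_round_trip(self):
        sel = RatioCutoffSelector(threshold=5.0)
        clone = RatioCutoffSelector(**sel.get_params())
        assert clone.get_params() == sel.get_params()


def test_empirical_auc_approaches_binormal_closed_form():
    """Two-Gaussian mixture: AUC -> Phi(dmu / sqrt(s1^2+s0^2))."""
    rng = np.random.default_rng(19)
    n = 2000
    aucs = []
    for seed in range(8):
        child = np.random.default_rng(rng.integers(2**31))
        ratios = dict(
            zip(
                [f"M{i}" for i in range(n)],
                np.exp2(child.normal(3.0, 1.0, n)),
            )
        ) | dict(
            zip(
                [f"B{i}" for i in range(n)],
                np.exp2(child.normal(0.0, 1.0, n)),
            )
        )
        profiles = make_profiles(ratios)
        ann = make_ann([f"M{i}" for i in range(n)])
        aucs.append(roc_curve(profiles, ann).auc)
    expected = norm.cdf(3.0 / np.sqrt(2.0))
    se = np.std(aucs, ddof=1) / np.sqrt(len(aucs))
    assert abs(np.mean(aucs) - expected) < 3 * se + 1e-4
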