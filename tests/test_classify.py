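import numpy as np
import pandas as pd
import pytest

from tbikit.classify import (RFConfig, metric_subset_trials, rank_rois,
                             rf_classify, threshold_classify)
from tbikit.cohort import CohortSpec, make_feature_cohort


def one_feature_cohort(d, seed, n=5):
    spec = CohortSpec(rois=("Optic Tract_Left",), metrics=("FA",),
                      effect_map={("Optic Tract_Left", "FA"): d},
                      n_sham=n, n_injured=n, seed=seed)
    return make_feature_cohort(spec)


SMALL = RFConfig(n_trees=500, seed=0, n_repeats=2)


class TestRfClassify:
    def test_separated_classes_zero_oob_error(self):
        table = one_feature_cohort(d=50.0, seed=1)
        rep = rf_classify(table, config=SMALL, compute_importance=False)
        assert rep.overall_error == 0.0
        assert rep.class_error == {"injured": 0.0, "sham": 0.0}
        assert all(v["incorrect"] == 0 for v in rep.confusion.values())

    def test_seed_determinism(self):
        table = make_feature_cohort(CohortSpec(seed=3))
        cfg = RFConfig(n_trees=300, seed=9, n_repeats=2)
        a = rf_classify(table, config=cfg)
        b = rf_classify(table, config=cfg)
        assert a.overall_error == b.overall_error
        assert a.mda.equals(b.mda)

    def test_row_label_pairing_invariance(self):
        table = make_feature_cohort(CohortSpec(seed=4))
        perm = np.random.default_rng(0).permutation(len(table))
        shuffled = table.iloc[perm].reset_index(drop=True)
        a = rf_classify(table, config=SMALL, compute_importance=False)
        b = rf_classify(shuffled, config=SMALL, compute_importance=False)
        # same rows paired with same labels -> same error structure
        assert a.confusion == b.confusion

    def test_single_class_rejected(self):
        table = one_feature_cohort(0.0, 0)
        table["group"] = "sham"
        with pytest.raises(ValueError):
            rf_classify(table, config=SMALL)

    def test_missing_values_rejected(self):
        table = one_feature_cohort(0.0, 0)
        table.iloc[0, 2] = np.nan
        with pytest.raises(ValueError):
            rf_classify(table, config=SMALL)

    def test_null_oob_accuracy_matches_reference_behaviour(self):
        """Pure-noise cohorts at n=5+5: OOB voting is pessimistic (each
        sample's own class is underrepresented in the bootstraps that
        leave it out), so mean accuracy sits well BELOW chance — the
        reference R forest shows ~0.2 under identical conditions."""
        accs = []
        for seed in range(8):
            table = make_feature_cohort(CohortSpec(seed=seed))
            rep = rf_classify(table, config=RFConfig(n_trees=500, seed=seed),
                              compute_importance=False)
            accs.append(rep.overall_accuracy)
        assert 0.0 <= np.mean(accs) < 0.45

    def test_oob_accuracy_monotone_in_effect_size(self):
        means = []
        for d in (0.0, 1.0, 2.0, 3.0):
            accs = [rf_classify(one_feature_cohort(d, seed),
                                config=RFConfig(n_trees=200, seed=seed),
                                compute_importance=False).overall_accuracy
                    for seed in range(25)]
            means.append(np.mean(accs))
        assert all(b >= a - 0.02 for a, b in zip(means, means[1:]))
        assert means[-1] > means[0] + 0.2


class TestImportance:
    def test_noise_feature_mda_near_zero(self):
        spec = CohortSpec(rois=("Optic Tract_Left", "Cortex_Left"),
                          metrics=("FA",),
                          effect_map={("Optic Tract_Left", "FA"): 4.0}, seed=5)
        cfg = RFConfig(n_trees=500, seed=1, n_repeats=20)
        rep = rf_classify(make_feature_cohort(spec), config=cfg)
        noise = rep.mda.loc["Cortex_Left_FA"]
        assert abs(noise["raw"]) <= max(2 * noise["spread"], 0.02)
        assert rep.mda.loc["Optic Tract_Left_FA", "raw"] > noise["raw"]

    def test_single_perturbed_roi_ranks_first(self):
        hits = 0
        for seed in range(10):
            spec = CohortSpec(rois=("Optic Tract_Left", "Cortex_Left",
                                    "Thalamus_Right"),
                              effect_map={("Optic Tract_Left", m): 3.0
                                          for m in ("FA", "T", "AD", "RD",
                                                    "WL", "WP")},
                              seed=seed)
            rep = rf_classify(make_feature_cohort(spec),
                              config=RFConfig(n_trees=500, seed=seed,
                                              n_repeats=3))
            hits += rank_rois(rep)["roi"].iloc[0] == "Optic Tract_Left"
        assert hits >= 9

    def test_assoc_fraction_one_keeps_argmax_only(self):
        rep = rf_classify(one_feature_cohort(3.0, 7), config=SMALL)
        ranked = rank_rois(rep, assoc_fraction=1.0)
        assert ranked["associated_metrics"].iloc[0] == ["FA"]

    def test_top_k_truncates_with_warning(self):
        rep = rf_classify(one_feature_cohort(3.0, 7), config=SMALL)
        with pytest.warns(UserWarning):
            ranked = rank_rois(rep, top_k=5)
        assert len(ranked) == 1


class TestSubsets:
    def test_full_subset_equals_full_run(self):
        table = make_feature_cohort(CohortSpec(seed=6))
        cfg = RFConfig(n_trees=300, seed=2, n_repeats=1)
        full = rf_classify(table, config=cfg, compute_importance=False)
        via_subset = metric_subset_trials(
            table, {"all": ("FA", "T", "AD", "RD", "WL", "WP")}, config=cfg,
        )["all"]
        assert via_subset.overall_error == full.overall_error
        assert via_subset.confusion == full.confusion

    def test_subset_uses_only_its_columns(self):
        from tbikit.datasets import ROI_NAMES
        table = make_feature_cohort(
            CohortSpec(effect_map={(r, "FA"): 30.0 for r in ROI_NAMES},
                       seed=7))
        cfg = RFConfig(n_trees=300, seed=3, n_repeats=1)
        trials = metric_subset_trials(table, {"FA": ("FA",), "T": ("T",)},
                                      config=cfg)
        # the separating signal lives only in FA: the T-only forest must
        # not see it
        assert trials["FA"].overall_error == 0.0
        assert trials["T"].overall_error > 0.2

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            metric_subset_trials(one_feature_cohort(0.0, 0), {"none": ()})


class TestThresholdClassify:
    def test_perfect_separation(self):
        thr, err = threshold_classify([1, 2, 3, 10, 11, 12],
                                      ["a", "a", "a", "b", "b", "b"])
        assert err == 0 and 3 < thr < 10

    def test_one_overlapping_point(self):
        thr, err = threshold_classify([1, 2, 3, 4, 10, 5, 6, 7, 8, 9],
                                      ["a"] * 5 + ["b"] * 5)
        assert err == 1

    def test_degenerate_identical_values(self):
        thr, err = threshold_classify([5.0] * 6, ["a"] * 2 + ["b"] * 4)
        assert err == 2  # min(n1, n2)

    def test_agrees_with_exhaustive_search(self, rng):
        for _ in range(40):
            n = int(rng.integers(2, 13))
            v = rng.normal(size=n)
            y = rng.choice(["a", "b"], size=n)
            if len(set(y)) < 2:
                continue
            thr, err = threshold_classify(v, y)
            # exhaustive oracle over all cut positions and orientations
            best = n + 1
            for cut in np.r_[v - 1e-9, v + 1e-9, v.min() - 1, v.max() + 1]:
                for lo in ("a", "b"):
                    e = np.sum((v <= cut) & (y != lo)) + np.sum((v > cut) & (y == lo))
                    best = min(best, int(e))
            assert err == best
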