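"""Generator contracts: determinism, planted-truth bookkeeping, calibration."""

import math

import numpy as np
import pandas as pd
import pytest

from ovmorph import survival as surv
from ovmorph import synthetic as syn

from _oracles import km_product_limit


class TestNuclearImage:
    def test_empty_request_gives_blank_noisy_background(self):
        img, truth = syn.generate_nuclear_image(
            n_nuclei=0, image_shape=(64, 64), seed=0, background_noise_sd=3.0
        )
        assert truth.nuclei == []
        assert img.shape == (64, 64)
        # noise around the background level only, no dark blobs
        assert 190 < img.mean() < 210
        assert img.min() > 150

    def test_circle_truth_area_is_analytic(self):
        _, truth = syn.generate_nuclear_image(
            n_nuclei=1, area_range=(200.0, 200.0), elongation_range=(1.0, 1.0),
            image_shape=(96, 96), seed=2,
        )
        e = truth.nuclei[0]
        assert e.a == pytest.approx(e.b)
        assert e.area == pytest.approx(math.pi * e.a**2)
        assert e.area == pytest.approx(200.0)

    def test_in_range_count_matches_brute_force_loop(self):
        _, truth = syn.generate_nuclear_image(n_nuclei=50, area_range=(50.0, 500.0), seed=7)
        n_loop = 0
        for e in truth.nuclei:  # independent loop over the truth list
            if 50.0 <= math.pi * e.a * e.b <= 500.0:
                n_loop += 1
        assert (truth.areas() >= 50).sum() + 0 == len(truth.nuclei)
        assert n_loop == len(truth.nuclei) == 50

    def test_identical_seed_reproduces_bit_identical_raster(self):
        img1, t1 = syn.generate_nuclear_image(n_nuclei=15, image_shape=(128, 128), seed=9)
        img2, t2 = syn.generate_nuclear_image(n_nuclei=15, image_shape=(128, 128), seed=9)
        assert np.array_equal(img1, img2)
        assert t1.nuclei == t2.nuclei

    def test_overdense_request_raises_placement_error(self):
        with pytest.raises(syn.PlacementError):
            syn.generate_nuclear_image(
                n_nuclei=200, area_range=(400.0, 500.0), image_shape=(96, 96),
                seed=0, max_attempts=200,
            )

    def test_centers_within_bounds_invariant(self):
        _, truth = syn.generate_nuclear_image(n_nuclei=30, seed=3)
        h, w = truth.image_shape
        for e in truth.nuclei:
            assert 0 <= e.cx < w and 0 <= e.cy < h
            assert e.a >= e.b > 0


class TestExpressionDataset:
    def test_dimensions_and_label_counts(self):
        m, labels, truth = syn.generate_expression_dataset(
            n_samples=100, n_genes=250, n_informative=10, seed=0,
            resistant_fraction=0.3,
        )
        assert m.shape == (250, 100)
        assert (labels == "resistant").sum() == 30
        assert truth.informative_gene_ids <= set(m.index)

    def test_null_fold_change_leaves_snr_centered_at_zero(self):
        mean_abs = []
        for seed in range(10):
            m, labels, _ = syn.generate_expression_dataset(
                n_samples=200, n_genes=100, n_informative=10,
                log2_fold_change=0.0, seed=seed,
            )
            sens = m.loc[:, (labels == "sensitive").values].to_numpy()
            res = m.loc[:, (labels == "resistant").values].to_numpy()
            s = (sens.mean(1) - res.mean(1)) / (sens.std(1, ddof=1) + res.std(1, ddof=1))
            mean_abs.append(np.abs(s).mean())
        assert np.mean(mean_abs) < 3 / math.sqrt(200)

    def test_planted_class_difference_matches_sample_mean_oracle(self):
        diffs = []
        for seed in range(5):
            m, labels, truth = syn.generate_expression_dataset(
                n_samples=100, n_genes=200, n_informative=20,
                log2_fold_change=1.0, noise_sd=0.5, seed=seed,
            )
            sens = m.loc[:, (labels == "sensitive").values]
            res = m.loc[:, (labels == "resistant").values]
            for g in truth.informative_gene_ids:
                diffs.append(abs(res.loc[g].mean() - sens.loc[g].mean()))
        assert abs(np.mean(diffs) - 1.0) < 0.2

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError, match="empty class"):
            syn.generate_expression_dataset(n_samples=50, n_genes=10,
                                            n_informative=5,
                                            resistant_fraction=0.0, seed=0)


class TestFeatureDataset:
    def test_planted_directions_and_shapes(self):
        m, labels, truth = syn.generate_feature_dataset(seed=4)
        assert m.shape == (130, 153)
        assert len(truth.up_features) == 5 and len(truth.down_features) == 10
        sens = m.loc[(labels == "sensitive").values]
        res = m.loc[(labels == "resistant").values]
        for f in truth.up_features:
            assert sens[f].mean() > res[f].mean()
        for f in truth.down_features:
            assert sens[f].mean() < res[f].mean()

    def test_null_features_are_block_correlated(self):
        m, _, truth = syn.generate_feature_dataset(seed=4, n_samples=400)
        planted = set(truth.up_features) | set(truth.down_features)
        nulls = [c for c in m.columns if c not in planted]
        r01 = np.corrcoef(m[nulls[0]], m[nulls[1]])[0, 1]
        assert r01 > 0.7  # same latent block


class TestSurvival:
    def test_zero_censoring_gives_all_events(self):
        labels = pd.Series(["sensitive"] * 30 + ["resistant"] * 10,
                           index=[f"S{i}" for i in range(40)])
        frame, _ = syn.generate_survival(labels, censoring_fraction=0.0, seed=0)
        assert frame["event"].all()
        assert (frame["time"] > 0).all()

    def test_censoring_fraction_calibrated(self):
        labels = pd.Series(["sensitive"] * 1500 + ["resistant"] * 500,
                           index=[f"S{i}" for i in range(2000)])
        frame, _ = syn.generate_survival(labels, hazard_ratio=2.0,
                                         censoring_fraction=0.3, seed=1)
        assert abs((~frame["event"]).mean() - 0.3) < 0.04

    def test_km_median_ratio_recovers_planted_hazard_ratio(self):
        """KM medians of the two classes should sit near the closed-form
        exponential medians, whose ratio is the planted hazard ratio 4."""
        labels = pd.Series(["sensitive"] * 500 + ["resistant"] * 500,
                           index=[f"S{i}" for i in range(1000)])
        frame, _ = syn.generate_survival(labels, hazard_ratio=4.0,
                                         baseline_median=40.0,
                                         censoring_fraction=0.1, seed=2)
        recs = {
            cls: [
                surv.SurvivalRecord(i, r["time"], bool(r["event"]), "PFS")
                for i, r in frame[labels == cls].iterrows()
            ]
            for cls in ("sensitive", "resistant")
        }
        med_s = surv.km_estimate(recs["sensitive"]).median
        med_r = surv.km_estimate(recs["resistant"]).median
        assert abs(med_s / med_r - 4.0) < 1.2  # within +-30% of 4

    def test_km_median_against_hand_product_limit(self):
        # odd n so the product-limit curve never sits exactly on 0.5
        labels = pd.Series(["sensitive"] * 201, index=[f"S{i}" for i in range(201)])
        frame, _ = syn.generate_survival(labels, censoring_fraction=0.0, seed=3,
                                         baseline_median=30.0)
        _, _, med = km_product_limit(frame["time"], frame["event"])
        recs = [surv.SurvivalRecord(i, r["time"], True, "PFS")
                for i, r in frame.iterrows()]
        assert surv.km_estimate(recs).median == pytest.approx(med)

    def test_clinical_table_schema(self):
        labels = pd.Series(["sensitive"] * 20 + ["resistant"] * 10,
                           index=[f"S{i}" for i in range(30)])
        table = syn.generate_clinical_table(labels, seed=0)
        assert list(table.columns) == [
            "response", "os_months", "os_event", "pfs_months", "pfs_event",
            "age", "stage", "grade",
        ]
        assert set(table["stage"]) <= {"II", "III", "IV"}
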