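"""AUROC, precision@k, EF@k, splits and per-target evaluation."""

import numpy as np
import pandas as pd
import pytest

import dtalink as dl
from dtalink.evaluation import RankedLabels
from dtalink.io import AssociationTable, DrugCatalog


def auroc_pairwise_oracle(scores, labels):
    """Exhaustive positive/negative pair comparison; ties count one half."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestAuroc:
    def test_perfect_separation(self):
        r = RankedLabels([0.9, 0.8, 0.2], [1, 1, 0])
        assert dl.auroc(r) == 1.0

    def test_tied_scores_count_half(self):
        r = RankedLabels([0.9, 0.5, 0.5, 0.1], [1, 0, 1, 0])
        assert dl.auroc(r) == pytest.approx(0.875)

    def test_matches_pairwise_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            n = int(rng.integers(10, 200))
            scores = np.round(rng.random(n), 2)  # rounding creates ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            r = RankedLabels(scores, labels)
            assert dl.auroc(r) == pytest.approx(
                auroc_pairwise_oracle(scores, labels), abs=1e-12
            )

    def test_random_labels_near_half(self):
        rng = np.random.default_rng(1)
        scores = rng.random(10_000)
        labels = rng.integers(0, 2, 10_000)
        assert dl.auroc(RankedLabels(scores, labels)) == pytest.approx(0.5, abs=0.02)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        scores = rng.random(300)
        labels = rng.integers(0, 2, 300)
        a = dl.auroc(RankedLabels(scores, labels))
        b = dl.auroc(RankedLabels(np.exp(5 * scores) + 3, labels))
        assert a == pytest.approx(b, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            dl.auroc(RankedLabels([0.1, 0.2], [1, 1]))


class TestPrecisionAndEf:
    def test_top_k_all_positive(self):
        r = RankedLabels([0.9, 0.8, 0.7, 0.1], [1, 1, 1, 0])
        assert dl.precision_at_k(r, 3) == 1.0

    def test_full_depth_equals_prevalence(self):
        r = RankedLabels([0.9, 0.8, 0.7, 0.1], [1, 0, 1, 0])
        assert dl.precision_at_k(r, 4) == r.prevalence

    def test_counting_oracle(self):
        rng = np.random.default_rng(3)
        scores = -np.sort(-rng.random(20))  # already ranked
        labels = rng.integers(0, 2, 20)
        r = RankedLabels(scores, labels)
        for k in range(1, 21):
            assert dl.precision_at_k(r, k) == pytest.approx(labels[:k].mean())

    def test_k_out_of_range(self):
        r = RankedLabels([0.9], [1])
        with pytest.raises(ValueError):
            dl.precision_at_k(r, 2)

    def test_ef_is_precision_over_prevalence(self):
        r = RankedLabels([0.9, 0.8] + [0.1] * 18, [1, 0] + [1, 0] * 9)
        prev = r.prevalence
        assert dl.ef_at_k(r, 2) == pytest.approx(0.5 / prev)

    def test_ef_at_full_depth_is_one(self):
        rng = np.random.default_rng(4)
        labels = rng.integers(0, 2, 50)
        labels[0] = 1  # ensure positive prevalence
        r = RankedLabels(-np.sort(-rng.random(50)), labels)
        assert dl.ef_at_k(r, len(r)) == pytest.approx(1.0)

    def test_all_positives_first(self):
        labels = [1] * 5 + [0] * 15
        r = RankedLabels(-np.sort(-np.random.default_rng(5).random(20)), labels)
        assert dl.ef_at_k(r, 5) == pytest.approx(1 / r.prevalence)


class TestRankedLabels:
    def test_na_rows_excluded_and_order_deterministic(self):
        table = pd.DataFrame(
            {
                "drug_id": ["b", "a", "c", "d"],
                "target_id": ["T"] * 4,
                "score": [0.5, 0.5, np.nan, 0.9],
                "known": [True, False, True, False],
            }
        )
        r = RankedLabels.from_candidates(table)
        assert len(r) == 3
        # 0.9 first, then the 0.5 tie broken by drug_id: a before b
        np.testing.assert_array_equal(r.labels, [0, 0, 1])


class TestMakeSplit:
    def _assoc(self, n_edges=100):
        return AssociationTable.from_pairs(
            "drug_target", [(f"d{i:03d}", f"T{i % 10}") for i in range(n_edges)]
        )

    def test_holdout_counts(self):
        train, test = dl.make_split(self._assoc(), dl.SplitSpec("holdout", 0.2, seed=7))
        assert len(test) == 20 and len(train) == 80

    def test_same_seed_reproducible(self):
        a = dl.make_split(self._assoc(), dl.SplitSpec("holdout", 0.3, seed=11))
        b = dl.make_split(self._assoc(), dl.SplitSpec("holdout", 0.3, seed=11))
        assert a[1] == b[1]

    def test_train_test_partition_input(self):
        assoc = self._assoc()
        train, test = dl.make_split(assoc, dl.SplitSpec("holdout", 0.4, seed=1))
        assert train.edge_set() | test == assoc.edge_set()
        assert not (train.edge_set() & test)

    def test_leave_class_out(self):
        assoc = self._assoc(20)
        catalog = DrugCatalog(
            drug_ids=[f"d{i:03d}" for i in range(20)],
            atc_codes={f"d{i:03d}": (["beta"] if i < 5 else ["other"]) for i in range(20)},
        )
        train, test = dl.make_split(
            assoc, dl.SplitSpec("leave_class_out", class_label="beta"), catalog
        )
        assert {d for d, _ in test} == {f"d{i:03d}" for i in range(5)}
        assert not {d for d, _ in train.edge_set()} & {f"d{i:03d}" for i in range(5)}

    def test_empty_class_errors(self):
        catalog = DrugCatalog(drug_ids=["d000"], atc_codes={"d000": ["x"]})
        with pytest.raises(ValueError, match="covers no drugs"):
            dl.make_split(
                self._assoc(10), dl.SplitSpec("leave_class_out", class_label="y"), catalog
            )

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            dl.SplitSpec("holdout", fraction=0.0)


class TestEvaluateModel:
    def test_strong_signal_auroc(self, reference_dataset):
        ds = reference_dataset
        dt5 = dl.apply_min_degree_filter(ds.dt, 5)
        train, test = dl.make_split(dt5, dl.SplitSpec("holdout", 0.2, seed=0))
        report = dl.evaluate_model(train, test, ds.sim)
        assert report.auroc > 0.95

    def test_zero_signal_auroc_near_half(self):
        cfg = dl.SyntheticConfig(
            n_drugs=120, n_targets=30, n_ades=10, p_edge_dt=0.1,
            n_causal_links=0, penetrance=0.0, background_ade_rate=0.05,
            sim_high=(2.0, 2.0), sim_low=(2.0, 2.0), seed=5,
        )
        ds = dl.generate(cfg)
        train, test = dl.make_split(ds.dt, dl.SplitSpec("holdout", 0.2, seed=0))
        report = dl.evaluate_model(train, test, ds.sim)
        assert 0.4 < report.auroc < 0.6

    def test_empty_test_errors(self, small_dataset):
        with pytest.raises(ValueError):
            dl.evaluate_model(small_dataset.dt, set(), small_dataset.sim)

    def test_training_edges_removed_from_ranking(self, tiny_sim, tiny_dt):
        train, test = dl.make_split(tiny_dt, dl.SplitSpec("holdout", 0.4, seed=2))
        report = dl.evaluate_model(train, test, tiny_sim)
        n_targets = len(train.entities)
        assert report.n_ranked <= 4 * n_targets - len(train)

    def test_leave_class_out_end_to_end(self, small_dataset):
        ds = small_dataset
        label = next(iter(ds.catalog.atc_codes.values()))[0]
        train, test = dl.make_split(
            ds.dt, dl.SplitSpec("leave_class_out", class_label=label), ds.catalog
        )
        report = dl.evaluate_model(train, test, ds.sim)
        assert 0.0 <= report.auroc <= 1.0


class TestPerTargetAuroc:
    def test_equals_groupby_oracle(self, small_dataset):
        table = dl.score_all(small_dataset.sim, small_dataset.dt)
        out = dl.per_target_auroc(table).set_index("target_id")
        for target, grp in table.groupby("target_id"):
            g = grp[grp["score"].notna()]
            labels = g["known"].astype(int)
            if labels.nunique() < 2:
                assert np.isnan(out.loc[target, "auroc"])
            else:
                expected = dl.auroc(RankedLabels(g["score"], labels))
                assert out.loc[target, "auroc"] == pytest.approx(expected)

    def test_perfect_target(self):
        table = pd.DataFrame(
            {
                "drug_id": list("abcd"),
                "target_id": ["T"] * 4,
                "score": [1.0, 1.0, 0.0, 0.0],
                "known": [True, True, False, False],
            }
        )
        out = dl.per_target_auroc(table)
        assert out.iloc[0]["auroc"] == 1.0
        assert out.iloc[0]["n_binders"] == 2

    def test_single_class_target_is_na(self):
        table = pd.DataFrame(
            {"drug_id": ["a"], "target_id": ["T"], "score": [0.5], "known": [True]}
        )
        assert np.isnan(dl.per_target_auroc(table).iloc[0]["auroc"])

    def test_binder_count_not_required_to_correlate(self, reference_dataset):
        """Individual target quality need not track binder count (checked as
        a weak-correlation bound on balanced synthetic data)."""
        from scipy.stats import spearmanr

        ds = reference_dataset
        table = dl.score_all(ds.sim, dl.apply_min_degree_filter(ds.dt, 5))
        out = dl.per_target_auroc(table).dropna()
        rho = spearmanr(out["n_binders"], out["auroc"]).statistic
        assert abs(rho) < 0.3
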