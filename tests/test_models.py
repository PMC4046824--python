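"""Family SVM training, nested cross-validation and performance measures."""

from __future__ import annotations

import numpy as np
import pytest
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from conftest import GRID4, GRID16
from pdzfam.models import (
    FamilyEncoder,
    TrainedFamilyModel,
    compute_metrics,
    cross_validate,
    eligible_for_cv,
    eligible_for_modeling,
    grid_search,
    stratified_kfold,
    train_family_model,
)
from pdzfam.negatives import UnlabeledPool
from pdzfam.records import InteractionRecord, Peptide
from pdzfam.synthetic import generate_interactions


def mann_whitney_auc(scores, labels):
    """Brute-force pair counting with half credit for ties."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == -1]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def records_from(peptides, labels, domain="D1"):
    return [
        InteractionRecord(domain, Peptide(p), l) for p, l in zip(peptides, labels)
    ]


class TestEligibility:
    @pytest.mark.parametrize(
        "n_pos,n_neg,model_ok,cv_ok",
        [(9, 50, False, False), (10, 0, True, False), (12, 15, True, True), (10, 10, True, True)],
    )
    def test_thresholds(self, n_pos, n_neg, model_ok, cv_ok):
        recs = generate_interactions(["D1"], "I", n_pos=n_pos, n_neg=n_neg, seed=0)
        assert eligible_for_modeling(recs) is model_ok
        assert eligible_for_cv(recs) is cv_ok

    def test_generated_negatives_do_not_count(self):
        recs = generate_interactions(["D1"], "I", n_pos=12, n_neg=0, seed=0)
        fake_negs = [
            InteractionRecord("D1", Peptide("AAAAA"), -1, provenance="ssl")
        ] * 15
        assert not eligible_for_cv(recs + fake_negs)


class TestStratifiedKFold:
    def test_balanced_10_10_gives_2_2_per_fold(self):
        recs = generate_interactions(["D1"], "I", n_pos=10, n_neg=10, seed=0)
        folds = stratified_kfold(recs, k=5, seed=1)
        labels = np.array([r.label for r in recs])
        for _, te in folds:
            assert (labels[te] == 1).sum() == 2 and (labels[te] == -1).sum() == 2

    def test_class_proportions_within_one_count(self):
        recs = generate_interactions(["D1"], "I", n_pos=37, n_neg=61, seed=2)
        folds = stratified_kfold(recs, k=5, seed=1)
        labels = np.array([r.label for r in recs])
        for cls in (1, -1):
            counts = [(labels[te] == cls).sum() for _, te in folds]
            assert max(counts) - min(counts) <= 1

    def test_same_seed_same_folds(self):
        recs = generate_interactions(["D1"], "I", n_pos=12, n_neg=20, seed=3)
        a = stratified_kfold(recs, k=5, seed=7)
        b = stratified_kfold(recs, k=5, seed=7)
        assert all((ta == tb).all() for (_, ta), (_, tb) in zip(a, b))

    def test_class_smaller_than_k_rejected(self):
        recs = generate_interactions(["D1"], "I", n_pos=3, n_neg=20, seed=0)
        with pytest.raises(ValueError, match="need >="):
            stratified_kfold(recs, k=5)


class TestGridSearch:
    def test_single_point_grid_returned_unchanged(self):
        recs = generate_interactions(["D1"], "I", n_pos=10, n_neg=10, seed=0)
        assert grid_search(recs, grid=((3.0, 0.25),)) == (3.0, 0.25)

    def test_tie_breaks_toward_smallest_c_then_gamma(self):
        # perfectly separable planted data: many grid points reach AUC 1.0
        recs = generate_interactions(["D1"], "I", n_pos=20, n_neg=40, seed=1)
        grid = ((8.0, 0.03125), (2.0, 0.03125), (2.0, 0.125), (8.0, 0.125))
        C, gamma = grid_search(recs, grid=grid, seed=0)
        assert (C, gamma) == (2.0, 0.03125)

    def test_matches_independent_rescoring_of_every_grid_point(self):
        """With 10% label noise the winner still equals an exhaustive,
        independently recomputed evaluation of the whole grid."""
        recs = generate_interactions(["D1"], "I", n_pos=15, n_neg=30, noise=0.1, seed=5)
        got = grid_search(recs, grid=GRID16, k=5, seed=3)

        enc = FamilyEncoder()
        X, y = enc.encode_records(recs)
        folds = list(
            StratifiedKFold(n_splits=5, shuffle=True, random_state=3).split(X, y)
        )
        scored = []
        for C, gamma in GRID16:
            aucs = []
            for tr, te in folds:
                clf = SVC(kernel="rbf", C=C, gamma=gamma).fit(X[tr], y[tr])
                aucs.append(mann_whitney_auc(clf.decision_function(X[te]), y[te]))
            scored.append((np.mean(aucs), C, gamma))
        best_auc = max(s[0] for s in scored)
        expected = min((C, g) for a, C, g in scored if abs(a - best_auc) <= 1e-12)
        assert got == expected


class TestTrainFamilyModel:
    def test_separable_toy_scored_on_correct_sides(self):
        recs = records_from(["AATAV", "AASAL", "CCCCC", "DDDDD"], [1, 1, -1, -1])
        model = train_family_model("fam", recs, (10.0, 0.1))
        scores = model.decision_score(["AATAV", "AASAL", "CCCCC", "DDDDD"])
        assert (scores[:2] > 0).all() and (scores[2:] < 0).all()

    def test_save_load_round_trip_is_bit_identical(self, tmp_path):
        recs = generate_interactions(["D1"], "I", n_pos=12, n_neg=24, seed=0)
        model = train_family_model("fam", recs, (2.0, 0.125))
        model.save(tmp_path / "fam")
        loaded = TrainedFamilyModel.load(tmp_path / "fam")
        peps = ["IETHV", "AATAV", "CCCCC"]
        assert (loaded.decision_score(peps) == model.decision_score(peps)).all()
        assert (loaded.probability(peps) == model.probability(peps)).all()
        assert loaded.manifest == model.manifest

    def test_calibration_monotone_and_bounded(self):
        recs = generate_interactions(["D1"], "I", n_pos=20, n_neg=60, seed=1)
        model = train_family_model("fam", recs, (2.0, 0.125))
        rng = np.random.default_rng(0)
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        peps = ["".join(rng.choice(aa, 5)) for _ in range(40)]
        scores = model.decision_score(peps)
        probs = model.probability(peps)
        assert ((probs >= 0) & (probs <= 1)).all()
        order = np.argsort(scores)
        assert (np.diff(probs[order]) >= -1e-12).all()

    def test_single_class_rejected(self):
        recs = records_from(["AATAV", "AASAL"], [1, 1])
        with pytest.raises(ValueError, match="both classes"):
            train_family_model("fam", recs, (1.0, 0.1))


class TestComputeMetrics:
    def test_perfect_separation(self):
        m = compute_metrics([3.0, 2.0, -1.0, -2.0], [1, 1, -1, -1])
        assert m.auc_roc == 1.0 and m.auc_pr == pytest.approx(1.0)
        assert (m.sensitivity, m.specificity, m.precision) == (1.0, 1.0, 1.0)

    def test_constant_scores_give_half_auc(self):
        m = compute_metrics([1.0] * 6, [1, 1, 1, -1, -1, -1])
        assert m.auc_roc == pytest.approx(0.5)

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            n = int(rng.integers(4, 13))
            labels = np.array([1, -1] + list(rng.choice([1, -1], size=n - 2)))
            scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
            m = compute_metrics(scores, labels)
            assert m.auc_roc == pytest.approx(mann_whitney_auc(scores, labels))

    def test_confusion_identities_and_label_inversion_swap(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=12)
        labels = np.array([1] * 6 + [-1] * 6)
        m = compute_metrics(scores, labels)
        assert m.tp + m.fp + m.tn + m.fn == 12
        assert m.sensitivity + m.fn / (m.tp + m.fn) == pytest.approx(1.0)
        inv = compute_metrics(-scores, -labels)
        # careful with threshold asymmetry: strictly-above on negated scores
        # mirrors strictly-below, so ties at 0 are the only divergence
        if not np.any(scores == 0):
            assert inv.sensitivity == pytest.approx(m.specificity)
            assert inv.specificity == pytest.approx(m.sensitivity)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            compute_metrics([1.0, 2.0], [1, 1])


class TestCrossValidate:
    def test_report_has_k_folds_and_high_auc_on_clean_family(self, class1_records):
        """Planted class-I motif (T/S at P-2, hydrophobe at P0) is recovered
        with held-out AUC-ROC >= 0.9."""
        report = cross_validate("fam", class1_records, k=5, seed=0, grid=GRID16)
        assert len(report.folds) == 5
        assert report.mean("auc_roc") >= 0.9

    def test_generated_negatives_never_reach_test_folds(self):
        # 1:1 experimental classes, so each training portion needs SSL
        # augmentation to reach the 5:1 ratio
        records = generate_interactions(["D1"], "I", n_pos=15, n_neg=15, seed=6)
        pool_rng = np.random.default_rng(8)
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        pool = UnlabeledPool(
            frozenset("".join(pool_rng.choice(aa, 5)) for _ in range(900))
        )
        report = cross_validate("fam", records, k=5, seed=0, grid=GRID4, pool=pool)
        for fold in report.folds:
            assert all(e["provenance"] == "experimental" for e in fold.test_manifest)
            train_keys = {(e["peptide"], e["provenance"]) for e in fold.train_manifest}
            test_keys = {(e["peptide"], e["provenance"]) for e in fold.test_manifest}
            assert not train_keys & test_keys
            # augmentation actually happened inside the training portion
            assert any(e["provenance"] == "ssl" for e in fold.train_manifest)

    def test_nested_selection_uses_fold_training_data_only(self, class1_records):
        report = cross_validate("fam", class1_records, k=5, seed=0, grid=GRID4)
        experimental = {
            (str(r.peptide), r.label) for r in class1_records
        }
        covered = set()
        for fold in report.folds:
            covered |= {(e["peptide"], e["label"]) for e in fold.test_manifest}
            assert (fold.C, fold.gamma) in GRID4
        assert covered == experimental

    def test_ineligible_family_rejected(self):
        recs = generate_interactions(["D1"], "I", n_pos=12, n_neg=4, seed=0)
        with pytest.raises(ValueError, match="not CV-eligible"):
            cross_validate("fam", recs)
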