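"""Fold construction, cross-validation, and tag agreement."""

import numpy as np
import pytest

from paracoder.datasets_io import TrialRecord
from paracoder.evaluation import (
    FoldPlan,
    Scheme,
    make_folds,
    run_cross_dataset,
    run_cv,
    tag_accuracy,
)
from paracoder.fixtures import SimSpec, simulate_trials
from paracoder.tagger import ErrorTag


def dummy_trials(n, n_subjects=1, targets=None):
    trials = []
    for i in range(n):
        trials.append(TrialRecord(
            subject_id=f"S{i % n_subjects:03d}", item_id=f"I{i:05d}",
            target=targets[i % len(targets)] if targets else "w",
            response="w", target_ipa="wɑ", response_ipa="wɑ"))
    return trials


def assert_partition(plan: FoldPlan, n: int):
    seen = [i for fold in plan.folds for i in fold]
    assert len(seen) == n and set(seen) == set(range(n))


class TestMakeFolds:
    def test_tenfold_sizes_on_large_study(self):
        # 22,649 trials: nine folds of 2,265 and one of 2,264
        plan = make_folds(dummy_trials(22_649), Scheme.TENFOLD, seed=0)
        sizes = sorted(len(f) for f in plan.folds)
        assert sizes == [2264] + [2265] * 9
        assert_partition(plan, 22_649)

    def test_tenfold_reproducible_and_seed_sensitive(self):
        trials = dummy_trials(100)
        a = make_folds(trials, Scheme.TENFOLD, seed=5)
        b = make_folds(trials, Scheme.TENFOLD, seed=5)
        c = make_folds(trials, Scheme.TENFOLD, seed=6)
        assert a.folds == b.folds
        assert a.folds != c.folds

    def test_tenfold_too_few_trials(self):
        with pytest.raises(ValueError):
            make_folds(dummy_trials(9), Scheme.TENFOLD, seed=0)

    def test_subject_loo_one_fold_per_subject(self):
        trials = dummy_trials(38 * 7, n_subjects=38)
        plan = make_folds(trials, Scheme.SUBJECT_LOO)
        assert plan.n_folds == 38
        assert_partition(plan, len(trials))
        for fold in plan.folds:
            assert len({trials[i].subject_id for i in fold}) == 1

    def test_item_loo_one_fold_per_target(self):
        targets = [f"word{j}" for j in range(175)]
        trials = dummy_trials(175 * 3, targets=targets)
        plan = make_folds(trials, Scheme.ITEM_LOO)
        assert plan.n_folds == 175
        assert_partition(plan, len(trials))
        for fold in plan.folds:
            assert len({trials[i].target for i in fold}) == 1

    def test_loo_units_never_straddle_folds(self, small_sim):
        _, trials, _ = small_sim
        plan = make_folds(trials, Scheme.SUBJECT_LOO)
        for k, fold in enumerate(plan.folds):
            test_subjects = {trials[i].subject_id for i in fold}
            train_subjects = {t.subject_id for i, t in enumerate(trials)
                              if i not in set(fold)}
            assert not (test_subjects & train_subjects)


class TestTagAccuracy:
    def test_identical_and_disjoint(self):
        tags = [ErrorTag.S, ErrorTag.F, ErrorTag.M]
        assert tag_accuracy(tags, tags) == 1.0
        assert tag_accuracy(tags, [ErrorTag.U] * 3) == 0.0

    def test_nine_of_ten(self):
        human = [ErrorTag.S] * 9 + [ErrorTag.F]
        predicted = [ErrorTag.S] * 10
        assert tag_accuracy(predicted, human) == 0.9

    def test_hierarchy_maps_to_semantic_by_default(self):
        assert tag_accuracy([ErrorTag.HYPERNYM], [ErrorTag.S]) == 1.0
        assert tag_accuracy([ErrorTag.HYPERNYM], [ErrorTag.S], mapping={}) == 0.0

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            tag_accuracy([ErrorTag.S], [ErrorTag.S, ErrorTag.F])


class TestRunCV:
    def test_separable_data_scores_one_everywhere(self, small_sim, onomatopoeia):
        _, trials, res = small_sim
        plan = make_folds(trials, Scheme.TENFOLD, seed=11)
        report = run_cv(trials, plan, lex=res.lexicon, kb=res.kb,
                        onomatopoeia=onomatopoeia)
        assert all(f.test_accuracy == 1.0 for f in report.folds)
        assert all(f.train_accuracy == 1.0 for f in report.folds)

    def test_summary_mean_matches_folds(self, small_sim, onomatopoeia):
        _, trials, res = small_sim
        spec = SimSpec(n_subjects=4, n_items=30, seed=31, label_noise=0.15)
        noisy, nres = simulate_trials(spec)
        plan = make_folds(noisy, Scheme.TENFOLD, seed=2)
        report = run_cv(noisy, plan, lex=nres.lexicon, kb=nres.kb,
                        onomatopoeia=onomatopoeia)
        accs = [f.test_accuracy for f in report.folds]
        assert report.summary["test_accuracy"]["mean"] == pytest.approx(np.mean(accs))
        assert (report.summary["test_accuracy"]["min"]
                <= report.summary["test_accuracy"]["mean"]
                <= report.summary["test_accuracy"]["max"])

    def test_report_serialization(self, tmp_path, small_sim, onomatopoeia):
        _, trials, res = small_sim
        plan = make_folds(trials, Scheme.SUBJECT_LOO)
        report = run_cv(trials, plan, lex=res.lexicon, kb=res.kb,
                        onomatopoeia=onomatopoeia)
        frame = report.to_frame()
        assert len(frame) == plan.n_folds
        out = tmp_path / "report.json"
        report.to_json(out)
        assert out.exists() and out.stat().st_size > 0

    def test_cross_dataset_mode(self, onomatopoeia):
        a_trials, a_res = simulate_trials(SimSpec(n_subjects=3, n_items=25, seed=41))
        b_spec = SimSpec(n_subjects=2, n_items=25, seed=41)  # same lexicon universe
        b_trials, _ = simulate_trials(b_spec, resources=a_res)
        plan = make_folds(a_trials, Scheme.TENFOLD, seed=3)
        report = run_cross_dataset(a_trials, b_trials, plan, lex=a_res.lexicon,
                                   kb=a_res.kb, onomatopoeia=onomatopoeia)
        assert len(report.folds) == 10
        assert all(f.n_test == sum(1 for _ in b_trials) for f in report.folds)
        assert all(f.test_accuracy == 1.0 for f in report.folds)
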