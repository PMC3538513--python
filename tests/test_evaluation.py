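import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chemvs.chemspace import FamilyAssignment
from chemvs.evaluation import (
    ConfusionCounts,
    confusion_stats,
    family_novelty,
    five_fold_cv,
    render_cv_table,
    screening_metrics,
    select_hyperparameters,
)
from chemvs.synth import SyntheticSpec, generate_synthetic_library

from conftest import CV_TABLES, CV_SUMMARIES


def matthews_covariance_form(tp, fn, tn, fp):
    """Independent oracle: C as the Pearson correlation between the true and
    predicted 0/1 label vectors."""
    y = np.array([1] * (tp + fn) + [0] * (tn + fp), dtype=float)
    p = np.array([1] * tp + [0] * fn + [0] * tn + [1] * fp, dtype=float)
    sy, sp_ = y.std(), p.std()
    if sy == 0 or sp_ == 0:
        return None
    return float(np.mean((y - y.mean()) * (p - p.mean())) / (sy * sp_))


class TestConfusionStats:
    def test_printed_fold_one_of_svm_study(self):
        st_ = confusion_stats(ConfusionCounts(tp=320, fn=21, tn=12651, fp=13))
        assert f"{st_.se:.2f}" == "93.84"
        assert f"{st_.sp:.2f}" == "99.90"
        assert f"{st_.q:.2f}" == "99.74"
        assert f"{st_.c:.3f}" == "0.948"

    def test_printed_fold_three_of_pnn_study(self):
        st_ = confusion_stats(ConfusionCounts(tp=330, fn=11, tn=12395, fp=269))
        assert f"{st_.c:.3f}" == "0.722"

    def test_perfect_classifier(self):
        st_ = confusion_stats(ConfusionCounts(tp=7, fn=0, tn=13, fp=0))
        assert st_.se == st_.sp == st_.q == 100.0
        assert st_.c == pytest.approx(1.0)

    def test_zero_marginal_makes_c_undefined(self):
        st_ = confusion_stats(ConfusionCounts(tp=0, fn=0, tn=5, fp=5))
        assert st_.c is None

    @given(st.tuples(*[st.integers(0, 500)] * 4))
    @settings(derandomize=True, max_examples=300)
    def test_q_is_prevalence_weighted_se_sp(self, counts):
        tp, fn, tn, fp = counts
        if tp + fn == 0 or tn + fp == 0:
            return
        st_ = confusion_stats(ConfusionCounts(tp=tp, fn=fn, tn=tn, fp=fp))
        p, n = tp + fn, tn + fp
        assert st_.q == pytest.approx((st_.se * p + st_.sp * n) / (p + n))

    @given(st.tuples(*[st.integers(0, 300)] * 4))
    @settings(derandomize=True, max_examples=1000)
    def test_matthews_agrees_with_covariance_form(self, counts):
        tp, fn, tn, fp = counts
        if tp + fn + tn + fp == 0:
            return
        st_ = confusion_stats(ConfusionCounts(tp=tp, fn=fn, tn=tn, fp=fp))
        oracle = matthews_covariance_form(tp, fn, tn, fp)
        if oracle is None:
            assert st_.c is None
        else:
            assert st_.c == pytest.approx(oracle, abs=1e-12)


class TestPrintedTables:
    """Golden-file check: all 15 printed cross-validation fold rows and their
    Average/SD/SE summaries reproduce from the printed confusion counts."""

    @pytest.mark.parametrize("study", sorted(CV_TABLES))
    def test_fold_rows(self, study):
        for tp, fn, tn, fp, se, sp, q, c in CV_TABLES[study]:
            st_ = confusion_stats(ConfusionCounts(tp=tp, fn=fn, tn=tn, fp=fp))
            assert float(f"{st_.se:.2f}") == se
            assert float(f"{st_.sp:.2f}") == sp
            assert float(f"{st_.q:.2f}") == q
            assert float(f"{st_.c:.3f}") == c

    @pytest.mark.parametrize("study", sorted(CV_TABLES))
    def test_summary_rows(self, study):
        stats = [
            confusion_stats(ConfusionCounts(tp=r[0], fn=r[1], tn=r[2], fp=r[3]))
            for r in CV_TABLES[study]
        ]
        for attr, (avg, sd, sem) in CV_SUMMARIES[study].items():
            vals = np.array([getattr(s, attr) for s in stats])
            scale = 100.0 if attr != "c" else 1.0
            assert float(f"{vals.mean():.{2 if attr != 'c' else 3}f}") == avg
            prop = vals / scale
            assert float(f"{prop.std(ddof=1):.4f}") == sd
            assert float(f"{prop.std(ddof=1) / math.sqrt(5):.4f}") == sem


class TestFiveFoldCV:
    def setup_method(self):
        self.lib = generate_synthetic_library(
            SyntheticSpec(n_active=40, n_inactive=160, n_dim=10,
                          separation=0.7, spread=0.05, seed=3)
        )

    def test_folds_partition_the_data(self):
        cv = five_fold_cv(self.lib.x, self.lib.y, "knn", seed=0)
        sizes = [c.total for c in cv.folds]
        assert sum(sizes) == len(self.lib.y)
        assert max(sizes) - min(sizes) <= 1

    def test_stratification_preserves_class_balance(self):
        cv = five_fold_cv(self.lib.x, self.lib.y, "knn", seed=0)
        pos_per_fold = [c.tp + c.fn for c in cv.folds]
        assert max(pos_per_fold) - min(pos_per_fold) <= 1

    def test_deterministic_given_seed(self):
        a = five_fold_cv(self.lib.x, self.lib.y, "svm", seed=4)
        b = five_fold_cv(self.lib.x, self.lib.y, "svm", seed=4)
        assert a.folds == b.folds

    def test_separable_data_near_perfect(self):
        cv = five_fold_cv(self.lib.x, self.lib.y, "svm", seed=1)
        s = cv.summary()
        assert s["se"]["mean"] > 95.0 and s["sp"]["mean"] > 95.0

    def test_render_has_fold_and_summary_rows(self):
        cv = five_fold_cv(self.lib.x, self.lib.y, "knn", seed=0)
        table = render_cv_table(cv)
        lines = table.splitlines()
        assert len(lines) == 2 + 5 + 3  # header+sep, 5 folds, Average/SD/SE
        assert lines[-3].startswith("| Average")

    def test_hyperparameter_grid_selection(self):
        params, c = select_hyperparameters(
            self.lib.x, self.lib.y, "knn", {"k": [1, 3]}, seed=0
        )
        assert params["k"] in (1, 3) and -1 <= c <= 1


class TestScreeningMetrics:
    def test_printed_yield_from_screen_of_recent_inhibitors(self):
        # 31 of 44 known actives recovered -> yield 70.45%
        actives = {f"a{i}" for i in range(44)}
        library = actives | {f"d{i}" for i in range(1000)}
        hits = {f"a{i}" for i in range(31)} | {f"d{i}" for i in range(10)}
        rep = screening_metrics(hits, actives, library)
        assert f"{rep.yield_pct:.2f}" == "70.45"

    def test_zero_hits(self):
        rep = screening_metrics(set(), {"a"}, {"a", "b"})
        assert rep.yield_pct == 0.0 and rep.hit_rate_pct == 0.0
        assert rep.false_hit_bound_pct is None

    def test_hits_equal_actives(self):
        rep = screening_metrics({"a", "b"}, {"a", "b"}, {"a", "b", "c"})
        assert rep.yield_pct == 100.0
        assert rep.false_hit_bound_pct == 0.0

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError):
            screening_metrics(set(), set(), set())


class TestFamilyNovelty:
    def _assignment(self):
        ids = [f"m{i}" for i in range(12)]
        fam = {i: n for n, i in enumerate(ids)}
        return FamilyAssignment(
            compound_to_family={i: n // 4 for n, i in enumerate(ids)},
            centroids=np.zeros((3, 2)),
            seed=0,
        )

    def test_printed_fraction_of_novel_hits(self):
        # 15 of 44 hits in families without training actives -> 34.1%
        fam_map = {f"h{i}": (0 if i < 29 else 1) for i in range(44)}
        fam_map["t0"] = 0
        assignment = FamilyAssignment(
            compound_to_family=fam_map, centroids=np.zeros((2, 1)), seed=0
        )
        out = family_novelty([f"h{i}" for i in range(44)], assignment, {"t0"})
        assert out["n_novel"] == 15
        assert f"{out['pct_novel']:.1f}" == "34.1"

    def test_all_hits_in_training_families(self):
        a = self._assignment()
        out = family_novelty(["m0", "m1"], a, {"m2"})
        assert out["n_novel"] == 0 and out["pct_novel"] == 0.0

    def test_empty_hit_set(self):
        out = family_novelty([], self._assignment(), {"m0"})
        assert out["n_novel"] == 0 and out["pct_novel"] == 0.0

    def test_family_positive_fractions(self):
        a = self._assignment()
        out = family_novelty(
            ["m0"], a, {"m0"}, predicted_positive_ids={"m0", "m1"}
        )
        assert out["family_positive_fraction"] == {0: 0.5}
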