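"""Validation harness: confusion statistics, 5-fold cross-validation,
screening-level metrics and compound-family novelty analysis.

Performance statistics for a binary inhibitor/non-inhibitor classifier:

    SE = TP/(TP+FN) * 100          (sensitivity)
    SP = TN/(TN+FP) * 100          (specificity)
    Q  = (TP+TN)/(TP+TN+FP+FN) * 100   (overall accuracy)
    C  = (TP*TN - FN*FP) / sqrt((TP+FN)(TP+FP)(TN+FN)(TN+FP))
                                   (Matthews correlation)

Cross-validation reports, per fold and as Average / SD / SE rows, the same
statistics; SD is the sample (ddof=1) standard deviation of the five fold
values on the proportion scale and SE is SD/sqrt(5).

Screening metrics for a virtual screen of a large library: yield
(TP/(TP+FN) over the known actives), virtual-hit rate (hits/library size)
and the false-hit-rate upper bound FP/(TP+FP), counting every hit outside
the known-active set as a false positive — in an unlabelled library some of
those may be undiscovered actives, so the true false-hit rate is at most
this bound.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Iterable

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold

from .chemspace import FamilyAssignment
from .classifiers import Engine, make_engine

__all__ = [
    "ConfusionCounts",
    "PerformanceStats",
    "CrossValidationResult",
    "ScreeningReport",
    "confusion_stats",
    "five_fold_cv",
    "screening_metrics",
    "family_novelty",
    "select_hyperparameters",
    "render_cv_table",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionCounts":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        return cls(
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
            fn=int(np.sum((y_true == 1) & (y_pred == -1))),
            tn=int(np.sum((y_true == -1) & (y_pred == -1))),
            fp=int(np.sum((y_true == -1) & (y_pred == 1))),
        )


@dataclass(frozen=True)
class PerformanceStats:
    se: float  # percent
    sp: float  # percent
    q: float   # percent
    c: float | None  # None when a marginal is zero (undefined, not 0)


def confusion_stats(counts: ConfusionCounts) -> PerformanceStats:
    """SE/SP/Q (percent) and Matthews C from a confusion table."""
    if counts.total == 0:
        raise ValueError("empty confusion table")
    pos = counts.tp + counts.fn
    neg = counts.tn + counts.fp
    pred_pos = counts.tp + counts.fp
    pred_neg = counts.tn + counts.fn
    se = 100.0 * counts.tp / pos if pos else 0.0
    sp = 100.0 * counts.tn / neg if neg else 0.0
    q = 100.0 * (counts.tp + counts.tn) / counts.total
    if min(pos, neg, pred_pos, pred_neg) == 0:
        c = None
    else:
        c = (counts.tp * counts.tn - counts.fn * counts.fp) / math.sqrt(
            float(pos) * pred_pos * pred_neg * neg
        )
    return PerformanceStats(se=se, sp=sp, q=q, c=c)


@dataclass
class CrossValidationResult:
    folds: list[ConfusionCounts]
    stats: list[PerformanceStats]
    engine: str
    params: dict[str, Any]
    seed: int

    def _series(self, attr: str) -> np.ndarray:
        vals = []
        for s in self.stats:
            v = getattr(s, attr)
            if v is None:
                raise ValueError(f"{attr} undefined in a fold")
            vals.append(v / 100.0 if attr != "c" else v)
        return np.asarray(vals)

    def summary(self) -> dict[str, dict[str, float]]:
        """Average / SD / SE rows; SD is ddof=1 on the proportion scale."""
        out = {}
        for attr in ("se", "sp", "q", "c"):
            v = self._series(attr)
            mean = float(v.mean())
            sd = float(v.std(ddof=1)) if len(v) > 1 else 0.0
            out[attr] = {
                "mean": mean * (100.0 if attr != "c" else 1.0),
                "sd": sd,
                "se": sd / math.sqrt(len(v)),
            }
        return out


def five_fold_cv(
    x: np.ndarray,
    y: np.ndarray,
    engine: str | Engine,
    params: dict[str, Any] | None = None,
    seed: int = 0,
    n_folds: int = 5,
    stratified: bool = True,
) -> CrossValidationResult:
    """Stratified random k-fold cross-validation of a screening engine.

    The data are randomly divided into ``n_folds`` groups of approximately
    equal size (class proportions preserved per fold when ``stratified``);
    each group in turn is the test set for an engine trained on the rest.
    Deterministic given the seed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    if x.shape[0] < n_folds:
        raise ValueError(f"need at least {n_folds} samples")
    name = engine if isinstance(engine, str) else engine.name
    params = dict(params or {})
    splitter_cls = StratifiedKFold if stratified else KFold
    splitter = splitter_cls(n_splits=n_folds, shuffle=True, random_state=seed)
    folds: list[ConfusionCounts] = []
    stats: list[PerformanceStats] = []
    for train_idx, test_idx in splitter.split(x, y):
        y_train = y[train_idx]
        if len(set(y_train.tolist())) < 2:
            raise ValueError(
                "a training split lost a whole class; use stratified=True or a new seed"
            )
        eng = make_engine(name, **params).fit(x[train_idx], y_train)
        counts = ConfusionCounts.from_predictions(y[test_idx], eng.predict(x[test_idx]))
        folds.append(counts)
        stats.append(confusion_stats(counts))
    return CrossValidationResult(folds=folds, stats=stats, engine=name, params=params, seed=seed)


@dataclass(frozen=True)
class ScreeningReport:
    yield_pct: float            # 100 * TP/(TP+FN) over known actives
    n_hits: int                 # virtual hits in the screened library
    hit_rate_pct: float         # 100 * hits / library size
    false_hit_bound_pct: float | None  # 100 * FP/(TP+FP); None when no hits
    n_known_active_hits: int


def screening_metrics(
    hits: Iterable[str],
    known_actives: Iterable[str],
    library_ids: Iterable[str],
) -> ScreeningReport:
    """Yield, virtual-hit rate and false-hit upper bound for a screen.

    Every hit not in the known-active set counts as a false positive, so the
    reported false-hit rate is an upper bound on the true one.
    """
    hits = set(hits)
    actives = set(known_actives)
    library = set(library_ids)
    if not library:
        raise ValueError("empty library")
    if not actives <= library:
        raise ValueError("known actives must be a subset of the library")
    tp = len(hits & actives)
    fn = len(actives - hits)
    fp = len(hits - actives)
    yield_pct = 100.0 * tp / (tp + fn) if actives else 0.0
    fh = 100.0 * fp / (tp + fp) if hits else None
    return ScreeningReport(
        yield_pct=yield_pct,
        n_hits=len(hits),
        hit_rate_pct=100.0 * len(hits) / len(library),
        false_hit_bound_pct=fh,
        n_known_active_hits=tp,
    )


def family_novelty(
    hit_ids: Iterable[str],
    assignment: FamilyAssignment,
    training_active_ids: Iterable[str],
    predicted_positive_ids: Iterable[str] | None = None,
) -> dict[str, Any]:
    """Hits falling outside the training actives' compound families.

    Returns the count and percentage of hits whose family contains no
    training active, plus — when full library predictions are supplied — the
    fraction of members predicted positive within each training-active
    family (the check that the classifier is not simply reproducing family
    membership).
    """
    fam_of = assignment.compound_to_family
    hit_ids = list(hit_ids)
    training_families = {fam_of[c] for c in training_active_ids if c in fam_of}
    missing = [h for h in hit_ids if h not in fam_of]
    if missing:
        raise ValueError(f"hits without a family assignment: {missing[:5]}")
    novel = [h for h in hit_ids if fam_of[h] not in training_families]
    pct = 100.0 * len(novel) / len(hit_ids) if hit_ids else 0.0

    family_positive_fraction: dict[int, float] = {}
    if predicted_positive_ids is not None:
        positives = set(predicted_positive_ids)
        for fam in sorted(training_families):
            members = assignment.members(fam)
            if members:
                family_positive_fraction[fam] = sum(
                    1 for m in members if m in positives
                ) / len(members)
    return {
        "n_novel": len(novel),
        "pct_novel": pct,
        "novel_hits": novel,
        "family_positive_fraction": family_positive_fraction,
    }


def select_hyperparameters(
    x: np.ndarray,
    y: np.ndarray,
    engine: str,
    grid: dict[str, list[Any]],
    seed: int = 0,
    n_folds: int = 5,
) -> tuple[dict[str, Any], float]:
    """Pick the grid point maximizing mean cross-validated Matthews C."""
    from itertools import product

    keys = sorted(grid)
    best: tuple[dict[str, Any], float] | None = None
    for combo in product(*(grid[k] for k in keys)):
        params = dict(zip(keys, combo))
        cv = five_fold_cv(x, y, engine, params, seed=seed, n_folds=n_folds)
        mean_c = cv.summary()["c"]["mean"]
        if best is None or mean_c > best[1]:
            best = (params, mean_c)
    assert best is not None
    return best


def render_cv_table(result: CrossValidationResult) -> str:
    """Markdown rendering of a cross-validation run, one row per fold plus
    Average / SD / SE rows (percentages to 2 decimals, C to 3)."""
    lines = [
        f"| fold | TP | FN | SE | TN | FP | SP | Q | C |",
        "|---|---|---|---|---|---|---|---|---|",
    ]
    for i, (cc, st) in enumerate(zip(result.folds, result.stats), 1):
        c_txt = f"{st.c:.3f}" if st.c is not None else "undefined"
        lines.append(
            f"| {i} | {cc.tp} | {cc.fn} | {st.se:.2f}% | {cc.tn} | {cc.fp} "
            f"| {st.sp:.2f}% | {st.q:.2f}% | {c_txt} |"
        )
    s = result.summary()
    lines.append(
        f"| Average | | | {s['se']['mean']:.2f}% | | | {s['sp']['mean']:.2f}% "
        f"| {s['q']['mean']:.2f}% | {s['c']['mean']:.3f} |"
    )
    for row in ("sd", "se"):
        lines.append(
            f"| {row.upper()} | | | {s['se'][row]:.4f} | | | {s['sp'][row]:.4f} "
            f"| {s['q'][row]:.4f} | {s['c'][row]:.4f} |"
        )
    return "\n".join(lines)
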