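"""Time-slice evaluation and leave-one-home-out cross-validation.

Predicted segment labels are projected back onto the 5-s grid and compared
with the ground truth slice by slice, one-vs-rest per activity (slices whose
truth is NONE or AWAY count only as negatives).  Sensitivity, specificity,
precision and F-measure are reported per activity together with their
unweighted mean, in the layout of a standard per-activity performance table.
Cross-validation pools the slice-level confusion counts over folds before
computing metrics (micro over folds, macro over activities); per-fold
metrics are also kept because pooling and averaging differ in general.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .classification import (
    ClassifierSpec,
    merge_predictions,
    predict_adl,
    predict_visitor,
    train_adl,
    train_visitor,
)
from .home import ADL_LABELS, HomeDataset
from .pipeline import PipelineConfig, prepare_homes

METRIC_NAMES = ("sensitivity", "specificity", "precision", "f_measure")


@dataclass
class ConfusionCounts:
    """One-vs-rest slice counts for a single activity."""

    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.tn + other.tn, self.fn + other.fn)


class Metrics(NamedTuple):
    sensitivity: float
    specificity: float
    precision: float
    f_measure: float


def segments_to_slices(predictions: pd.DataFrame, grid_times: np.ndarray) -> pd.DataFrame:
    """Project per-segment predictions onto the 5-s grid.

    Every slice inherits the label and visitor flag of the segment covering
    it (half-open spans); an uncovered slice is an error.
    """
    times = np.asarray(grid_times, dtype=float)
    pred = predictions.sort_values("start_s")
    starts = pred["start_s"].to_numpy(dtype=float)
    ends = pred["end_s"].to_numpy(dtype=float)
    idx = np.searchsorted(starts, times, side="right") - 1
    if len(pred) == 0 or (idx < 0).any() or (times >= ends[np.clip(idx, 0, None)]).any():
        raise ValueError("prediction segments do not cover every grid slice")
    return pd.DataFrame(
        {
            "label": pred["label"].to_numpy(dtype=object)[idx]
            if "label" in pred.columns else np.full(len(times), "", dtype=object),
            "visitor": pred["visitor"].to_numpy(dtype=int)[idx]
            if "visitor" in pred.columns else np.zeros(len(times), dtype=int),
        },
        index=pd.Index(np.asarray(grid_times), name="time_s"),
    )


def confusion(pred: np.ndarray, truth: np.ndarray, activity: str) -> ConfusionCounts:
    """One-vs-rest slice counts of ``activity``."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {truth.shape}")
    p = pred == activity
    t = truth == activity
    return ConfusionCounts(
        tp=int((p & t).sum()),
        fp=int((p & ~t).sum()),
        tn=int((~p & ~t).sum()),
        fn=int((~p & t).sum()),
    )


def metrics(c: ConfusionCounts) -> Metrics:
    """Sensitivity, specificity, precision and F-measure; 0/0 -> 0."""
    def ratio(num: int, den: int) -> float:
        return num / den if den else 0.0

    sens = ratio(c.tp, c.tp + c.fn)
    spec = ratio(c.tn, c.tn + c.fp)
    prec = ratio(c.tp, c.tp + c.fp)
    f = 2 * prec * sens / (prec + sens) if (prec + sens) else 0.0
    return Metrics(sens, spec, prec, f)


def per_activity_metrics(
    counts: dict[str, ConfusionCounts],
    activities: tuple[str, ...] = ADL_LABELS,
) -> pd.DataFrame:
    rows = {a: metrics(counts[a]) for a in activities}
    return pd.DataFrame.from_dict(rows, orient="index", columns=METRIC_NAMES)


def macro_metrics(
    counts: dict[str, ConfusionCounts],
    present_only: bool = True,
) -> Metrics:
    """Unweighted mean of per-activity metrics.

    With ``present_only`` activities that never occur in the truth
    (tp + fn = 0) are left out of the mean.
    """
    acts = [a for a, c in counts.items() if (c.tp + c.fn) > 0] if present_only \
        else list(counts)
    if not acts:
        return Metrics(0.0, 0.0, 0.0, 0.0)
    table = np.array([metrics(counts[a]) for a in acts])
    return Metrics(*table.mean(axis=0))


class MetricsReport:
    """Per-activity rows x (metric, classifier) columns, plus a Mean row."""

    def __init__(self, frame: pd.DataFrame):
        self.frame = frame

    @classmethod
    def build(cls, results: dict[str, pd.DataFrame],
              activities: tuple[str, ...] = ADL_LABELS) -> "MetricsReport":
        """``results`` maps a classifier name to its per-activity metric table."""
        blocks = {}
        for clf, table in results.items():
            missing = [a for a in activities if a not in table.index]
            if missing:
                raise ValueError(f"classifier {clf!r} missing activities {missing}")
            sub = table.loc[list(activities), list(METRIC_NAMES)].copy()
            sub.loc["Mean"] = sub.loc[list(activities)].mean(axis=0)
            blocks[clf] = sub
        frame = pd.concat(blocks, axis=1).swaplevel(axis=1)  # (metric, classifier)
        frame = frame.reindex(
            columns=pd.MultiIndex.from_product([METRIC_NAMES, list(results)])
        )
        return cls(frame)

    def render_percent(self) -> pd.DataFrame:
        """Values as percentage strings with two decimals (e.g. '66.67')."""
        return self.frame.map(lambda v: f"{100 * v:.2f}")

    def to_csv(self, path) -> None:
        self.render_percent().to_csv(path)

    def to_markdown(self) -> str:
        return self.render_percent().to_markdown()


@dataclass
class FoldResult:
    home_id: str
    counts: dict[str, ConfusionCounts]
    visitor_counts: ConfusionCounts | None = None

    def metrics_table(self) -> pd.DataFrame:
        return per_activity_metrics(self.counts, tuple(self.counts))


@dataclass
class LoocvResult:
    """Pooled and per-fold leave-one-home-out results for one classifier."""

    counts: dict[str, ConfusionCounts]
    folds: list[FoldResult]
    skipped: list[str] = field(default_factory=list)
    visitor_counts: ConfusionCounts | None = None

    @property
    def pooled_metrics(self) -> pd.DataFrame:
        return per_activity_metrics(self.counts, tuple(self.counts))

    def macro(self, present_only: bool = True) -> Metrics:
        return macro_metrics(self.counts, present_only=present_only)

    @property
    def visitor_metrics(self) -> Metrics | None:
        return metrics(self.visitor_counts) if self.visitor_counts is not None else None

    def fold_mean_metrics(self) -> pd.DataFrame:
        """Average of per-fold metric tables (differs from pooling in general)."""
        tables = [f.metrics_table() for f in self.folds]
        return sum(tables[1:], tables[0]) / len(tables)


def loocv_from_prepared(
    prepared: list[tuple[str, pd.DataFrame, pd.DataFrame]],
    spec: ClassifierSpec,
    activities: tuple[str, ...] = ADL_LABELS,
    visitor: bool = False,
    visitor_rooms: set[str] | None = None,
) -> LoocvResult:
    """Leave-one-home-out over already segmented homes."""
    if len(prepared) < 2:
        raise ValueError("leave-one-home-out needs >= 2 homes")
    pooled = {a: ConfusionCounts() for a in activities}
    pooled_vis = ConfusionCounts() if visitor else None
    folds: list[FoldResult] = []
    skipped: list[str] = []
    for h, (home_id, grid, segs) in enumerate(prepared):
        train = pd.concat(
            [s for j, (_i, _g, s) in enumerate(prepared) if j != h],
            ignore_index=True,
        )
        try:
            model = train_adl(train, spec)
        except ValueError as err:
            warnings.warn(f"skipping fold {home_id}: {err}")
            skipped.append(home_id)
            continue
        pred = predict_adl(model, segs)
        if visitor:
            try:
                vis_model = train_visitor(
                    train, ClassifierSpec("rf", n_trees=spec.n_trees,
                                          random_seed=spec.random_seed),
                    room_subset=visitor_rooms,
                )
                pred = merge_predictions(pred, predict_visitor(vis_model, segs))
            except ValueError as err:
                warnings.warn(f"fold {home_id}: visitor classifier skipped: {err}")
        slices = segments_to_slices(pred, grid.index.to_numpy())
        truth = grid["truth_label"].to_numpy(dtype=object)
        fold_counts = {a: confusion(slices["label"].to_numpy(), truth, a)
                       for a in activities}
        fold = FoldResult(home_id, fold_counts)
        for a in activities:
            pooled[a] = pooled[a] + fold_counts[a]
        if visitor and "visitor" in slices.columns:
            vc = confusion(slices["visitor"].to_numpy().astype(int),
                           grid["truth_visitor"].to_numpy().astype(int), 1)
            fold.visitor_counts = vc
            pooled_vis = pooled_vis + vc
        folds.append(fold)
    return LoocvResult(counts=pooled, folds=folds, skipped=skipped,
                       visitor_counts=pooled_vis)


def label_permutation_control(
    prepared: list[tuple[str, pd.DataFrame, pd.DataFrame]],
    spec: ClassifierSpec,
    permute_seed: int,
    test_index: int = 0,
) -> tuple[Metrics, float]:
    """Shuffle training labels and score the held-out home.

    A sanity control: with labels permuted the classifier can only learn the
    label marginals, so held-out macro metrics should collapse to chance.
    Returns the macro metrics plus the chance-level macro F implied by the
    predicted and true slice label distributions
    (F_a = 2 p_a q_a / (p_a + q_a) for each truth-present activity).
    """
    rng = np.random.default_rng(permute_seed)
    _test_id, test_grid, test_segs = prepared[test_index]
    train = pd.concat(
        [s for j, (_i, _g, s) in enumerate(prepared) if j != test_index],
        ignore_index=True,
    )
    shuffled = train.copy()
    shuffled["truth_label"] = rng.permutation(shuffled["truth_label"].to_numpy())
    model = train_adl(shuffled, spec)
    pred = predict_adl(model, test_segs)
    slices = segments_to_slices(pred, test_grid.index.to_numpy())
    truth = test_grid["truth_label"].to_numpy(dtype=object)
    pred_labels = slices["label"].to_numpy()
    counts = {a: confusion(pred_labels, truth, a) for a in ADL_LABELS}
    macro = macro_metrics(counts)

    chance_parts = []
    for a in ADL_LABELS:
        q = float((truth == a).mean())
        if q == 0:
            continue
        p = float((pred_labels == a).mean())
        chance_parts.append(2 * p * q / (p + q) if (p + q) else 0.0)
    chance = float(np.mean(chance_parts)) if chance_parts else 0.0
    return macro, chance


def leave_one_home_out(
    datasets: list[HomeDataset],
    pipeline: PipelineConfig,
    spec: ClassifierSpec,
    activities: tuple[str, ...] = ADL_LABELS,
    visitor: bool = False,
    visitor_rooms: set[str] | None = None,
) -> LoocvResult:
    """Full leave-one-home-out cross-validation from raw datasets."""
    prepared = prepare_homes(datasets, pipeline)
    return loocv_from_prepared(prepared, spec, activities=activities,
                               visitor=visitor, visitor_rooms=visitor_rooms)
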