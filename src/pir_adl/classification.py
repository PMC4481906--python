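"""ADL and visitor classification on compressed segments.

Three classifier families are supported: Gaussian naive Bayes, an RBF
support vector machine and a random forest (no pruning, sqrt(p) features
per split).  Features are the per-segment means/variances of all sensor
columns plus duration, activity degree and the categorical context (token,
previous/next token, room, weekday).  Categorical context is fed as integer
codes to the tree/NB models and one-hot encoded for the SVM, whose numeric
features are additionally standardized.

Away periods are not learned: a segment without meaningful PIR activity is
assigned the AWAY pseudo-label by rule before the classifier is consulted,
and AWAY/NONE segments are excluded from training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.compose import ColumnTransformer
from sklearn.ensemble import RandomForestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import OneHotEncoder, StandardScaler
from sklearn.svm import SVC

from .home import AWAY, GRID_STEP_S, NO_ACTIVITY, ConfigurationError
from .preprocess import room_of_column
from .room_segmentation import NO_ROOM
from .token_segmentation import compress_segments

#: Maximum activity degree at which a segment is ruled AWAY (no real motion).
AWAY_DEGREE_MAX = 0.05

#: Rooms the restricted visitor classifier watches: where a second person is
#: most detectable while the resident is busy elsewhere.
DEFAULT_VISITOR_ROOMS = frozenset({"BATHROOM", "TV_ROOM", "LIVING"})

CATEGORICAL_COLUMNS = ("token", "prev_token", "next_token", "weekday", "room")

ALGORITHMS = ("nb", "svm", "rf")


@dataclass(frozen=True)
class ClassifierSpec:
    """Algorithm choice plus the (default) hyper-parameters of its family."""

    algorithm: str
    n_trees: int = 100
    svm_kernel: str = "rbf"
    svm_c: float = 1.0
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ConfigurationError(f"unknown algorithm {self.algorithm!r}; use one of {ALGORITHMS}")
        if self.n_trees < 1:
            raise ConfigurationError("n_trees must be >= 1")


class FeatureEncoder:
    """Selects and encodes segment columns into a model feature frame."""

    def __init__(self, numeric_columns: list[str], categorical_columns: list[str]):
        self.numeric_columns = numeric_columns
        self.categorical_columns = categorical_columns
        self.room_categories: list[str] = []

    @classmethod
    def infer(
        cls,
        segments: pd.DataFrame,
        room_subset: set[str] | None = None,
        include_tokens: bool = True,
    ) -> "FeatureEncoder":
        numeric = [c for c in segments.columns if c.endswith(("_mean", "_var"))]
        if room_subset is not None:
            numeric = [
                c for c in numeric
                if room_of_column(c.rsplit("_", 1)[0]) in room_subset
            ]
        for c in ("duration_s", "activity_degree"):
            if c in segments.columns:
                numeric.append(c)
        cats = [c for c in CATEGORICAL_COLUMNS if c in segments.columns]
        if not include_tokens:
            cats = [c for c in cats if not c.endswith("token")]
        return cls(numeric, cats)

    def fit(self, segments: pd.DataFrame) -> "FeatureEncoder":
        if "room" in self.categorical_columns:
            self.room_categories = sorted(segments["room"].astype(str).unique())
        return self

    def frame(self, segments: pd.DataFrame, cats_as_str: bool) -> pd.DataFrame:
        missing = [c for c in self.numeric_columns + self.categorical_columns
                   if c not in segments.columns]
        if missing:
            raise ValueError(f"segments missing feature column(s) {missing}")
        out = segments[self.numeric_columns].astype(float).copy()
        for c in self.numeric_columns:
            if out[c].isna().any():
                raise ValueError(f"NaN values in feature column {c!r}")
        for c in self.categorical_columns:
            if c == "room":
                if cats_as_str:
                    out[c] = segments[c].astype(str)
                else:
                    # unseen rooms map to the "unknown" code -1
                    codes = {r: i for i, r in enumerate(self.room_categories)}
                    out[c] = segments[c].astype(str).map(codes).fillna(-1).astype(int)
            else:
                out[c] = segments[c].astype(str) if cats_as_str else segments[c].astype(int)
        return out


@dataclass
class FittedModel:
    """A trained classifier plus everything needed to apply it."""

    spec: ClassifierSpec
    encoder: FeatureEncoder
    estimator: object
    classes: tuple[str, ...]
    kind: str = "adl"  # or "visitor"

    @property
    def uses_string_cats(self) -> bool:
        return self.spec.algorithm == "svm"


def _make_estimator(spec: ClassifierSpec, encoder: FeatureEncoder):
    if spec.algorithm == "rf":
        return RandomForestClassifier(
            n_estimators=spec.n_trees,
            max_features="sqrt",
            random_state=spec.random_seed,
            n_jobs=1,
        )
    if spec.algorithm == "nb":
        return GaussianNB()
    pre = ColumnTransformer(
        [
            ("num", StandardScaler(), encoder.numeric_columns),
            ("cat", OneHotEncoder(handle_unknown="ignore"), encoder.categorical_columns),
        ],
        remainder="drop",
    )
    return Pipeline([("pre", pre), ("svc", SVC(kernel=spec.svm_kernel, C=spec.svm_c,
                                               random_state=spec.random_seed))])


def _fit(segments: pd.DataFrame, y: pd.Series, spec: ClassifierSpec,
         encoder: FeatureEncoder, kind: str) -> FittedModel:
    encoder.fit(segments)
    estimator = _make_estimator(spec, encoder)
    X = encoder.frame(segments, cats_as_str=spec.algorithm == "svm")
    estimator.fit(X if spec.algorithm == "svm" else X.to_numpy(dtype=float), y.astype(str))
    return FittedModel(spec=spec, encoder=encoder, estimator=estimator,
                       classes=tuple(sorted(y.astype(str).unique())), kind=kind)


def train_adl(segments: pd.DataFrame, spec: ClassifierSpec) -> FittedModel:
    """Train the ADL classifier on labelled segments.

    AWAY and NONE segments are excluded (absence is detected by rule, not
    learned).  Raises on a single-class training set or NaN features.
    """
    train = segments[~segments["truth_label"].isin((AWAY, NO_ACTIVITY))]
    labels = train["truth_label"].astype(str)
    if labels.nunique() < 2:
        raise ValueError(f"need >= 2 ADL classes to train, got {sorted(labels.unique())}")
    encoder = FeatureEncoder.infer(train)
    return _fit(train, labels, spec, encoder, kind="adl")


def predict_adl(model: FittedModel, segments: pd.DataFrame) -> pd.DataFrame:
    """Predict one label per segment.

    Segments without meaningful PIR activity (room NONE, or activity degree
    below :data:`AWAY_DEGREE_MAX` when no room column exists) are labelled
    AWAY by rule.  Returns a prediction table with segment spans.
    """
    out = pd.DataFrame({
        "start_s": segments["start_s"] if len(segments) else pd.Series(dtype=float),
        "end_s": segments["end_s"] if len(segments) else pd.Series(dtype=float),
        "label": pd.Series("", index=segments.index, dtype=object),
        "visitor": np.zeros(len(segments), dtype=np.int64),
    })
    out.index.name = "segment_id"
    if segments.empty:
        return out
    if "room" in segments.columns:
        away = segments["room"].astype(str) == NO_ROOM
    elif "activity_degree" in segments.columns:
        away = segments["activity_degree"] < AWAY_DEGREE_MAX
    else:
        away = pd.Series(False, index=segments.index)
    out.loc[away, "label"] = AWAY
    rest = segments[~away]
    if len(rest):
        X = model.encoder.frame(rest, cats_as_str=model.uses_string_cats)
        pred = model.estimator.predict(X if model.uses_string_cats
                                       else X.to_numpy(dtype=float))
        out.loc[~away, "label"] = pred
    return out


def train_visitor(
    segments: pd.DataFrame,
    spec: ClassifierSpec,
    room_subset: set[str] | None = None,
) -> FittedModel:
    """Train the parallel binary visitor classifier (random forest only).

    When ``room_subset`` is given, only sensor features of those rooms (plus
    the global duration/degree/weekday/room features) enter the model; the
    joint-room token context is never used, keeping the classifier focused
    on rooms where a second person is detectable.
    """
    if spec.algorithm != "rf":
        raise ConfigurationError("visitor detection uses the rf algorithm")
    y = segments["truth_visitor"].astype(int)
    if y.nunique() < 2:
        raise ValueError("visitor labels contain a single class; cannot train")
    encoder = FeatureEncoder.infer(segments, room_subset=room_subset, include_tokens=False)
    return _fit(segments, y.astype(str), spec, encoder, kind="visitor")


def predict_visitor(model: FittedModel, segments: pd.DataFrame) -> pd.DataFrame:
    """Predict the visitor flag per segment."""
    out = pd.DataFrame({
        "start_s": segments["start_s"] if len(segments) else pd.Series(dtype=float),
        "end_s": segments["end_s"] if len(segments) else pd.Series(dtype=float),
        "visitor": np.zeros(len(segments), dtype=np.int64),
    })
    out.index.name = "segment_id"
    if segments.empty:
        return out
    X = model.encoder.frame(segments, cats_as_str=model.uses_string_cats)
    pred = model.estimator.predict(X if model.uses_string_cats else X.to_numpy(dtype=float))
    out["visitor"] = pred.astype(int)
    return out


def merge_predictions(adl: pd.DataFrame, visitor: pd.DataFrame) -> pd.DataFrame:
    """Combine the two parallel classifiers' outputs per segment.

    The ADL label comes from the ADL classifier and the visitor flag from
    the visitor classifier; neither overrides the other.
    """
    if not adl.index.equals(visitor.index):
        raise ValueError("prediction tables cover different segment ids")
    out = adl.copy()
    out["visitor"] = visitor["visitor"].astype(int)
    return out


def slice_fixed_windows(grid: pd.DataFrame, slot_s: int = 60) -> pd.DataFrame:
    """Baseline segmentation: fixed-length time slots (default 60 s).

    The grid is cut into consecutive windows which are compressed exactly
    like inter-change-point periods; a trailing partial window is kept as a
    short final segment.
    """
    if slot_s % GRID_STEP_S != 0 or slot_s <= 0:
        raise ConfigurationError("slot_s must be a positive multiple of the 5-s grid step")
    rows = slot_s // GRID_STEP_S
    boundaries = np.arange(rows, len(grid), rows, dtype=np.int64)
    return compress_segments(grid, boundaries)
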