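"""SVM classifiers for window-level FoG detection.

Two training regimes are supported.  The *generic* model is trained
leave-one-patient-out: for each held-out subject an RBF soft-margin SVM is
fitted on all other subjects' windows, with C and γ selected from the grid
{10⁻², …, 10²} by 10-fold cross-validation maximising Sens·Spec under the
constraint that both exceed 70%.  The *personalised* model additionally
includes the half of the held-out subject's own recording containing the
first (or last) 50% of their FoG episodes, with per-pattern cost caps
C·w_t on the subject's own patterns and C·w_20 on the cohort's, where
w_t = n20/(n20 + n_half) and w_20 = n_half/(n20 + n_half) so the subject's
data carries the same total influence as the whole cohort.  Each model is
evaluated on the complementary half only; the procedure runs twice with the
halves swapped and the episode-level counts are pooled.

Features are z-scored with training-set statistics stored in the model
bundle — an implementation addition (mixed-unit features are
scale-pathological under an RBF kernel).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics.pairwise import euclidean_distances
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .evaluation import EpisodeSet
from .features import FEATURE_COLUMNS, PCABasis
from .preprocess import WINDOW_DURATION_S, WindowSeries

logger = logging.getLogger(__name__)

HYPER_GRID = tuple(10.0 ** k for k in range(-2, 3))  # {1e-2, ..., 1e2} for C and γ
CV_FOLDS = 10
MIN_SENSITIVITY = 0.70
MIN_SPECIFICITY = 0.70
LABEL_OVERLAP_MIN = 0.5


@dataclass
class LabelledDataset:
    """Window feature matrix with ±1 labels and subject/time bookkeeping.

    ``frame`` columns: ``subject``, ``session``, ``window_start_s``,
    ``f01``..``f55``, ``label`` (+1 FoG / −1 non-FoG), ``episode_id``
    (index of the overlapping ground-truth episode, −1 for non-FoG rows).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["subject", "session", "window_start_s", "label", "episode_id"]
        missing = [c for c in required + FEATURE_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"dataset frame missing columns: {missing[:5]}...")
        labels = set(self.frame["label"].unique())
        if not labels <= {1, -1}:
            raise ValueError(f"labels must be +1/-1, got {labels}")

    @property
    def X(self) -> np.ndarray:
        return self.frame[FEATURE_COLUMNS].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.frame["label"].to_numpy(dtype=int)

    @property
    def subjects(self) -> np.ndarray:
        return self.frame["subject"].to_numpy()

    def rows_for(self, subject: str) -> pd.DataFrame:
        return self.frame[self.frame["subject"] == subject]


def label_windows(
    series: WindowSeries,
    episodes: EpisodeSet,
    overlap_min: float = LABEL_OVERLAP_MIN,
) -> pd.DataFrame:
    """Map ground-truth episode intervals onto window labels.

    A window is +1 (FoG) iff at least ``overlap_min`` of its 3.2 s span is
    covered by ground-truth episode time; episode_id is the index of the
    episode with the largest overlap (−1 for non-FoG windows).
    """
    starts = np.asarray(series.start_times, dtype=float)
    out = _label_starts(starts, episodes, series.duration_s, overlap_min)
    out.insert(0, "window_start_s", starts)
    return out


def build_dataset(
    features: pd.DataFrame, episodes_by_subject: dict[str, EpisodeSet]
) -> LabelledDataset:
    """Join a feature matrix with per-subject episode ground truth."""
    parts = []
    for subject, grp in features.groupby("subject", sort=True):
        eps = episodes_by_subject[subject]
        starts = grp["window_start_s"].to_numpy(dtype=float)
        lab = _label_starts(starts, eps)
        out = grp.copy()
        out["label"] = lab["label"].to_numpy()
        out["episode_id"] = lab["episode_id"].to_numpy()
        parts.append(out)
    return LabelledDataset(pd.concat(parts, ignore_index=True))


def _label_starts(
    starts: np.ndarray,
    episodes: EpisodeSet,
    dur: float = WINDOW_DURATION_S,
    overlap_min: float = LABEL_OVERLAP_MIN,
) -> pd.DataFrame:
    labels = np.full(len(starts), -1, dtype=int)
    episode_ids = np.full(len(starts), -1, dtype=int)
    eps = list(episodes)
    for i, t in enumerate(starts):
        overlaps = [
            (min(t + dur, e) - max(t, s), j)
            for j, (s, e) in enumerate(eps)
            if min(t + dur, e) > max(t, s)
        ]
        if overlaps and sum(o for o, _ in overlaps) >= overlap_min * dur - 1e-9:
            labels[i] = 1
            episode_ids[i] = max(overlaps)[1]
    return pd.DataFrame({"label": labels, "episode_id": episode_ids})


@dataclass
class TrainedModel:
    """A fitted window classifier with everything prediction needs.

    Prediction is deterministic given the bundle: the scaler, the SVM and
    the PCA basis are all frozen at training time.
    """

    svc: SVC
    scaler: StandardScaler
    basis: PCABasis | None
    c: float
    gamma: float
    manifest: dict = field(default_factory=dict)

    def predict(self, X: np.ndarray | pd.DataFrame) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[FEATURE_COLUMNS].to_numpy(dtype=float)
        return self.svc.predict(self.scaler.transform(X)).astype(int)


BUNDLE_VERSION = 1


def save_model(model: TrainedModel, path) -> None:
    """Serialise a trained model bundle (SVM, scaler, PCA basis, manifest)."""
    import joblib

    joblib.dump({"format": "fogbench-model", "version": BUNDLE_VERSION,
                 "model": model}, path)


def load_model(path) -> TrainedModel:
    import joblib

    payload = joblib.load(path)
    if payload.get("format") != "fogbench-model":
        raise ValueError(f"{path} is not a fogbench model bundle")
    if payload.get("version") != BUNDLE_VERSION:
        raise ValueError(f"unsupported bundle version {payload.get('version')}")
    return payload["model"]


def _window_sens_spec(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float | None, float | None]:
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == -1)))
    tn = int(np.sum((y_true == -1) & (y_pred == -1)))
    fp = int(np.sum((y_true == -1) & (y_pred == 1)))
    sens = tp / (tp + fn) if tp + fn else None
    spec = tn / (tn + fp) if tn + fp else None
    return sens, spec


def select_hyperparameters(
    X: np.ndarray,
    y: np.ndarray,
    sample_weight: np.ndarray | None = None,
    grid: tuple[float, ...] = HYPER_GRID,
    folds: int = CV_FOLDS,
    seed: int = 0,
) -> tuple[float, float, bool]:
    """Grid-select (C, γ) by stratified k-fold CV on window-level metrics.

    For each of the 25 grid pairs, sensitivity and specificity are averaged
    over folds and the pair maximising their product under the 70%/70%
    constraint is returned (ties: smallest C, then smallest γ; fallback to
    the unconstrained argmax when no pair is feasible, flagged in the third
    return value).  CV metrics here are window-level: cross-validation folds
    destroy temporal contiguity, so episode-level scoring is reserved for
    the final evaluation.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == -1))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("hyperparameter selection needs both classes present")
    k = min(folds, n_pos, n_neg)
    if k < folds:
        logger.warning("reducing CV folds from %d to %d (class scarcity)", folds, k)
    if k < 2:
        raise ValueError("not enough examples per class for cross-validation")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)

    pair_scores: dict[tuple[float, float], list[tuple[float | None, float | None]]] = {
        (c, g): [] for c in grid for g in grid
    }
    for train_idx, test_idx in skf.split(X, y):
        scaler = StandardScaler().fit(X[train_idx])
        Xtr = scaler.transform(X[train_idx])
        Xte = scaler.transform(X[test_idx])
        sw = sample_weight[train_idx] if sample_weight is not None else None
        # the squared-distance matrices are shared by all 25 (C, γ) pairs,
        # so the RBF kernel is materialised once per γ instead of per fit
        d_tr = euclidean_distances(Xtr, squared=True)
        d_te = euclidean_distances(Xte, Xtr, squared=True)
        for g in grid:
            k_tr = np.exp(-g * d_tr)
            k_te = np.exp(-g * d_te)
            for c in grid:
                svc = SVC(C=c, kernel="precomputed")
                svc.fit(k_tr, y[train_idx], sample_weight=sw)
                pair_scores[(c, g)].append(
                    _window_sens_spec(y[test_idx], svc.predict(k_te))
                )

    feasible, unconstrained = [], []
    for (c, g), scores in pair_scores.items():
        sens_vals = [s for s, _ in scores if s is not None]
        spec_vals = [p for _, p in scores if p is not None]
        if not sens_vals or not spec_vals:
            continue
        sens = float(np.mean(sens_vals))
        spec = float(np.mean(spec_vals))
        item = ((sens * spec, -c, -g), c, g)
        unconstrained.append(item)
        if sens > MIN_SENSITIVITY and spec > MIN_SPECIFICITY:
            feasible.append(item)
    if not unconstrained:
        raise ValueError("no hyperparameter pair produced defined CV metrics")
    pool, constrained = (feasible, True) if feasible else (unconstrained, False)
    if not feasible:
        logger.warning(
            "no (C, gamma) pair reaches CV sensitivity and specificity > 70%%; "
            "using unconstrained argmax"
        )
    _, c, g = max(pool, key=lambda it: it[0])
    return c, g, constrained


def _fit(
    X: np.ndarray,
    y: np.ndarray,
    c: float,
    gamma: float,
    sample_weight: np.ndarray | None,
    basis: PCABasis | None,
    manifest: dict,
) -> TrainedModel:
    scaler = StandardScaler().fit(X)
    svc = SVC(C=c, gamma=gamma, kernel="rbf")
    svc.fit(scaler.transform(X), y, sample_weight=sample_weight)
    return TrainedModel(svc=svc, scaler=scaler, basis=basis, c=c, gamma=gamma,
                        manifest=manifest)


def train_generic(
    cohort: LabelledDataset,
    test_subject: str,
    basis: PCABasis | None = None,
    grid: tuple[float, ...] = HYPER_GRID,
    folds: int = CV_FOLDS,
    seed: int = 0,
) -> TrainedModel:
    """Fit the generic (user-independent) model for one held-out subject.

    The held-out subject's rows never enter hyperparameter selection,
    scaling statistics, or the final fit.
    """
    subjects = set(cohort.subjects)
    if test_subject not in subjects:
        raise ValueError(f"test subject {test_subject!r} absent from cohort")
    train_subjects = sorted(subjects - {test_subject})
    if len(train_subjects) < 2:
        raise ValueError("generic training needs at least 2 training subjects")
    mask = cohort.subjects != test_subject
    X, y = cohort.X[mask], cohort.y[mask]
    c, g, constrained = select_hyperparameters(X, y, grid=grid, folds=folds, seed=seed)
    manifest = {
        "mode": "generic",
        "test_subject": test_subject,
        "training_subjects": train_subjects,
        "C": c,
        "gamma": g,
        "cv_constrained": constrained,
        "seed": seed,
    }
    return _fit(X, y, c, g, None, basis, manifest)


def compute_personal_weights(n_20: int, n_half: int) -> tuple[float, float]:
    """Pattern weights balancing the test subject against the cohort.

    w_t = n20/(n20+n_half) applies to the test subject's own patterns and
    w_20 = n_half/(n20+n_half) to the cohort's, so the two groups carry
    equal total influence: n_half·w_t = n20·w_20.
    """
    if n_20 <= 0 or n_half <= 0:
        raise ValueError("pattern counts must be positive")
    total = n_20 + n_half
    return n_20 / total, n_half / total


@dataclass
class PersonalSplit:
    """Temporal split of one subject's data by FoG episode count.

    Half 1 holds the first ⌈E/2⌉ episodes and all windows before
    ``split_time``; half 2 the rest.  The split time is the midpoint of the
    gap between the last episode of half 1 and the first episode of half 2,
    so every window falls in exactly one half and episodes never straddle
    the boundary.
    """

    split_time: float
    episodes_first: EpisodeSet
    episodes_second: EpisodeSet

    def half_mask(self, start_times: np.ndarray, half: str) -> np.ndarray:
        starts = np.asarray(start_times, dtype=float)
        if half == "first":
            return starts < self.split_time
        if half == "second":
            return starts >= self.split_time
        raise ValueError(f"half must be 'first' or 'second', got {half!r}")

    def episodes(self, half: str) -> EpisodeSet:
        return self.episodes_first if half == "first" else self.episodes_second


def split_personal(episodes: EpisodeSet) -> PersonalSplit:
    """Split a subject's episodes chronologically into two halves."""
    eps = list(episodes)
    n = len(eps)
    if n < 2:
        raise ValueError(f"personal split needs >= 2 episodes, got {n}")
    n_first = math.ceil(n / 2)
    split_time = (eps[n_first - 1][1] + eps[n_first][0]) / 2.0
    return PersonalSplit(
        split_time=split_time,
        episodes_first=EpisodeSet(eps[:n_first]),
        episodes_second=EpisodeSet(eps[n_first:]),
    )


def train_personalized(
    cohort: LabelledDataset,
    test_subject: str,
    split: PersonalSplit,
    half: str = "first",
    basis: PCABasis | None = None,
    grid: tuple[float, ...] = HYPER_GRID,
    folds: int = CV_FOLDS,
    seed: int = 0,
    reselect_hyperparameters: bool = True,
) -> TrainedModel:
    """Fit the personalised model using one half of the test subject's data.

    Training rows are all other subjects' windows (cost cap C·w_20) plus the
    test subject's windows on the training side of the split (cost cap
    C·w_t), realised through per-sample weights which scale the box
    constraint exactly as the weighted dual requires.  Hyperparameters are
    re-selected on the weighted training set.  The complementary half is
    reserved for evaluation.
    """
    if len(split.episodes(half)) == 0:
        raise ValueError(f"{half} half contains no episodes; split invalid")
    frame = cohort.frame
    own = frame["subject"] == test_subject
    if not own.any():
        raise ValueError(f"test subject {test_subject!r} absent from cohort")
    half_mask = np.zeros(len(frame), dtype=bool)
    half_mask[own.to_numpy()] = split.half_mask(
        frame.loc[own, "window_start_s"].to_numpy(), half
    )
    train_mask = ~own.to_numpy() | half_mask
    is_own_train = half_mask[train_mask]
    n_20 = int(np.sum(~own.to_numpy()))
    n_half = int(np.sum(half_mask))
    w_t, w_20 = compute_personal_weights(n_20, n_half)
    sample_weight = np.where(is_own_train, w_t, w_20)
    X = cohort.X[train_mask]
    y = cohort.y[train_mask]
    if reselect_hyperparameters:
        c, g, constrained = select_hyperparameters(
            X, y, sample_weight=sample_weight, grid=grid, folds=folds, seed=seed
        )
    else:
        c, g, constrained = 1.0, 1.0 / X.shape[1], True
    manifest = {
        "mode": "personalized",
        "test_subject": test_subject,
        "half": half,
        "split_time": split.split_time,
        "n_20": n_20,
        "n_half": n_half,
        "w_t": w_t,
        "w_20": w_20,
        "C": c,
        "gamma": g,
        "cv_constrained": constrained,
        "seed": seed,
    }
    return _fit(X, y, c, g, sample_weight, basis, manifest)
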