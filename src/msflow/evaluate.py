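"""Fold-safe cross-validation and permutation testing.

Preprocessing choices change what a downstream classifier can see, so
they must be validated *inside* the cross-validation loop: for every
fold the transform/center/scale parameters, the SCA loadings and the
histogram grid are fitted on the training samples only and then applied
to the held-out samples.  Anything less leaks test information through
the preprocessing statistics.

The classifier is deliberately simple — per-sample feature vectors are
normalized 2-D histograms of each sample's cells in the first two SCA
components, classified by nearest group centroid (or logistic
regression).  The harness measures the effect of preprocessing, not
classifier power.

Significance is assessed by permuting group labels at the *sample*
level and re-running the entire pipeline, preprocessing fit included,
for each permutation; the p-value uses the add-one estimator
``p = (1 + #{perm acc >= observed}) / (1 + n_perm)`` so it can never be
exactly zero, alongside the raw count rendering ``<k/n``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import MultiSet
from .preprocess import (CENTER_STRATEGIES, SCALE_STRATEGIES, CenterSpec,
                         ConfigurationError, ScaleSpec, fit_preprocess)
from .sca import SCAResults, fit_sca
from .transform import TransformSpec

__all__ = [
    "CVScheme",
    "EvalResult",
    "StratificationError",
    "sample_features",
    "crossvalidate",
    "permutation_test",
    "strategy_grid",
]


class StratificationError(ValueError):
    """A CV fold is unusable (e.g. training fold without controls)."""


@dataclass(frozen=True)
class CVScheme:
    """Cross-validation layout.

    ``leave_one_out`` holds out one sample per fold; ``k_fold`` uses
    ``k`` folds (default 7) repeated ``repeats`` times (default 50) with
    reshuffling.  Stratified folding (the default) keeps group
    proportions per fold, which also guarantees control samples in every
    training fold — required by control-based strategies.
    """

    kind: str = "leave_one_out"
    k: int = 7
    repeats: int = 50
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("leave_one_out", "k_fold"):
            raise ValueError(f"unknown CV kind {self.kind!r}")
        if self.kind == "k_fold" and self.k < 2:
            raise ValueError(f"k must be >= 2, got {self.k}")
        if self.repeats < 1:
            raise ValueError(f"repeats must be >= 1, got {self.repeats}")


@dataclass
class EvalResult:
    """Cross-validated performance, optionally with a permutation null."""

    accuracy: float
    sensitivity: float
    specificity: float
    per_sample_predictions: pd.DataFrame | None = None
    permutation_accuracies: np.ndarray | None = None
    p_value: float | None = None
    n_permutations: int = 0
    n_perm_at_least: int = 0
    settings: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            "Cross-validated group discrimination",
            f"  accuracy    : {100 * self.accuracy:.1f}%",
            f"  sensitivity : {100 * self.sensitivity:.1f}%",
            f"  specificity : {100 * self.specificity:.1f}%",
        ]
        for key, val in self.settings.items():
            lines.append(f"  {key:<11} : {val}")
        if self.p_value is not None:
            lines.append(
                f"  permutation : p = {self.p_value:.4g} "
                f"(<{self.n_perm_at_least + 1}/{self.n_permutations + 1}; "
                f"{self.n_permutations} label permutations)"
            )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# per-sample histogram features
# ---------------------------------------------------------------------------

def sample_features(ms: MultiSet, model: SCAResults, bins: int = 8,
                    grid: tuple | None = None
                    ) -> tuple[np.ndarray, pd.DataFrame, tuple]:
    """Normalized 2-D score histograms, one feature vector per sample.

    Each sample's cells are projected onto the first two SCA components
    and binned on a ``bins x bins`` grid spanning the pooled score range
    of ``ms`` (or a caller-supplied ``grid``, e.g. derived from training
    data; out-of-range cells are clipped into the edge bins).  Vectors
    are normalized to sum to 1 so cell counts cancel.
    """
    if bins < 2:
        raise ValueError(f"bins must be >= 2, got {bins}")
    if model.n_components < 2:
        raise ValueError("histogram features need at least 2 SCA components")
    scores = model.project(ms)[:, :2]
    if grid is None:
        lo = scores.min(axis=0)
        hi = scores.max(axis=0)
        span = np.where(hi > lo, hi - lo, 1.0)
        grid = ((float(lo[0]), float(lo[0] + span[0])),
                (float(lo[1]), float(lo[1] + span[1])))
    (x0, x1), (y0, y1) = grid
    edges_x = np.linspace(x0, x1, bins + 1)
    edges_y = np.linspace(y0, y1, bins + 1)
    feats = np.empty((ms.n_samples, bins * bins))
    start = 0
    for i, s in enumerate(ms.samples):
        block = scores[start:start + s.n_cells]
        start += s.n_cells
        h, _, _ = np.histogram2d(
            np.clip(block[:, 0], x0, x1), np.clip(block[:, 1], y0, y1),
            bins=(edges_x, edges_y),
        )
        feats[i] = h.ravel() / s.n_cells
    info = pd.DataFrame({"sample_id": ms.sample_ids, "group_id": ms.group_ids})
    return feats, info, grid


# ---------------------------------------------------------------------------
# classifiers (per-sample feature vectors; tiny n, so kept minimal)
# ---------------------------------------------------------------------------

def _predict_nearest_centroid(f_train: np.ndarray, y_train: np.ndarray,
                              f_test: np.ndarray) -> np.ndarray:
    classes = np.unique(y_train)
    centroids = np.stack([f_train[y_train == c].mean(axis=0) for c in classes])
    d2 = ((f_test[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    return classes[np.argmin(d2, axis=1)]


def _predict_logistic(f_train: np.ndarray, y_train: np.ndarray,
                      f_test: np.ndarray) -> np.ndarray:
    from sklearn.linear_model import LogisticRegression

    clf = LogisticRegression(max_iter=1000)
    clf.fit(f_train, y_train)
    return clf.predict(f_test)


_CLASSIFIERS = {
    "nearest_centroid": _predict_nearest_centroid,
    "logistic": _predict_logistic,
}


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def _make_folds(y_binary: np.ndarray, scheme: CVScheme
                ) -> list[tuple[np.ndarray, np.ndarray, int]]:
    n = len(y_binary)
    idx = np.arange(n)
    if scheme.kind == "leave_one_out":
        return [(np.delete(idx, i), np.array([i]), 0) for i in range(n)]
    from sklearn.model_selection import KFold, StratifiedKFold

    rng = np.random.default_rng(scheme.seed)
    folds = []
    for rep in range(scheme.repeats):
        rs = int(rng.integers(2 ** 31))
        splitter_cls = StratifiedKFold if scheme.stratified else KFold
        splitter = splitter_cls(n_splits=scheme.k, shuffle=True,
                                random_state=rs)
        for train, test in splitter.split(idx, y_binary):
            folds.append((train, test, rep))
    return folds


def _binary_metrics(y_true: np.ndarray, y_pred: np.ndarray
                    ) -> tuple[float, float, float]:
    true_pos_group = y_true > 0
    pred_pos_group = y_pred > 0
    acc = float(np.mean(true_pos_group == pred_pos_group))
    pos = true_pos_group.sum()
    neg = len(y_true) - pos
    sens = float(np.sum(pred_pos_group & true_pos_group) / pos) if pos else float("nan")
    spec = float(np.sum(~pred_pos_group & ~true_pos_group) / neg) if neg else float("nan")
    return acc, sens, spec


def crossvalidate(ms: MultiSet, transform: TransformSpec | None = None,
                  center: CenterSpec | None = None,
                  scale: ScaleSpec | None = None,
                  scheme: CVScheme | None = None,
                  classifier: str = "nearest_centroid", bins: int = 8,
                  n_components: int = 2,
                  keep_predictions: bool = True) -> EvalResult:
    """Cross-validate the full pipeline (preprocessing fitted per fold).

    For each fold: fit the preprocessing model, the SCA decomposition
    and the histogram grid on training samples only; project and bin the
    held-out samples in that training space; classify.  Confusion counts
    aggregate over folds and repeats.
    """
    scheme = scheme or CVScheme()
    transform = transform or TransformSpec("none")
    center = center or CenterSpec()
    scale = scale or ScaleSpec()
    if classifier not in _CLASSIFIERS:
        raise ValueError(f"unknown classifier {classifier!r}; "
                         f"choose from {sorted(_CLASSIFIERS)}")
    predict = _CLASSIFIERS[classifier]
    groups = ms.group_ids
    y_binary = (groups > 0).astype(int)
    if y_binary.min() == y_binary.max():
        raise ValueError("cross-validation needs both control and responder "
                         "samples")
    k = min(n_components, ms.n_markers)
    folds = _make_folds(y_binary, scheme)
    needs_controls = "control_based" in (center.strategy, scale.strategy)

    rows = []
    y_true_all, y_pred_all = [], []
    for train_idx, test_idx, rep in folds:
        if needs_controls and not np.any(groups[train_idx] == 0):
            raise StratificationError(
                "a training fold contains no control samples; use "
                "stratified folding (CVScheme(stratified=True)) so every "
                "fold can fit control-based statistics"
            )
        train_ms = ms.subset(train_idx)
        test_ms = ms.subset(test_idx)
        with warnings.catch_warnings():
            # per-fold refits would repeat the advisory fit warnings
            warnings.simplefilter("ignore", UserWarning)
            model = fit_preprocess(train_ms, transform, center, scale)
        # leakage audit: the fitted statistics saw no held-out sample
        test_keys = {ms.samples[i].key for i in test_idx}
        assert test_keys.isdisjoint(model.fitted_on), "fold leakage detected"
        train_pp = model.apply(train_ms)
        sca_res = fit_sca(train_pp, k)
        f_train, _, grid = sample_features(train_pp, sca_res, bins)
        f_test, _, _ = sample_features(model.apply(test_ms), sca_res, bins,
                                       grid)
        pred = predict(f_train, y_binary[train_idx], f_test)
        y_true_all.append(y_binary[test_idx])
        y_pred_all.append(pred)
        if keep_predictions:
            for i, p in zip(test_idx, pred):
                rows.append({"repeat": rep, "sample_id": ms.samples[i].sample_id,
                             "group_id": groups[i], "true": y_binary[i],
                             "predicted": int(p)})
    y_true = np.concatenate(y_true_all)
    y_pred = np.concatenate(y_pred_all)
    acc, sens, spec = _binary_metrics(y_true, y_pred)
    return EvalResult(
        accuracy=acc, sensitivity=sens, specificity=spec,
        per_sample_predictions=pd.DataFrame(rows) if keep_predictions else None,
        settings={"transform": transform.kind, "center": center.strategy,
                  "scale": scale.strategy, "cv": scheme.kind,
                  "classifier": classifier},
    )


def permutation_test(ms: MultiSet, transform: TransformSpec | None = None,
                     center: CenterSpec | None = None,
                     scale: ScaleSpec | None = None,
                     scheme: CVScheme | None = None,
                     classifier: str = "nearest_centroid",
                     n_perm: int = 1000, seed: int = 0, bins: int = 8,
                     n_components: int = 2) -> EvalResult:
    """Permutation null for the cross-validated accuracy.

    Group labels are permuted at the sample level ``n_perm`` times and
    the full pipeline — preprocessing fit included — is re-run for every
    permutation (an honest null: nothing fitted on the true labels is
    reused).
    """
    if n_perm < 1:
        raise ValueError(f"n_perm must be >= 1, got {n_perm}")
    scheme = scheme or CVScheme()
    result = crossvalidate(ms, transform, center, scale, scheme, classifier,
                           bins, n_components)
    rng = np.random.default_rng(seed)
    perm_acc = np.empty(n_perm)
    groups = ms.group_ids
    for b in range(n_perm):
        permuted = groups[rng.permutation(len(groups))]
        res_b = crossvalidate(ms.relabel(permuted), transform, center, scale,
                              scheme, classifier, bins, n_components,
                              keep_predictions=False)
        perm_acc[b] = res_b.accuracy
    n_at_least = int(np.sum(perm_acc >= result.accuracy))
    result.permutation_accuracies = perm_acc
    result.n_permutations = n_perm
    result.n_perm_at_least = n_at_least
    result.p_value = (1 + n_at_least) / (1 + n_perm)
    return result


def strategy_grid(ms: MultiSet, scheme: CVScheme | None = None,
                  classifier: str = "nearest_centroid",
                  transform: TransformSpec | None = None,
                  estimator_center: str = "mean", estimator_scale: str = "sd",
                  ddof: int = 1, bins: int = 8,
                  n_components: int = 2) -> pd.DataFrame:
    """Cross-validated performance of every centering x scaling combination.

    Returns a 4 x 5 grid (four centerings, four scalings plus ``none``)
    as a long-format table, one row per combination.
    """
    rows = []
    for c_strategy in CENTER_STRATEGIES:
        for s_strategy in SCALE_STRATEGIES:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    res = crossvalidate(
                        ms, transform,
                        CenterSpec(c_strategy, estimator_center),
                        ScaleSpec(s_strategy, estimator_scale, ddof),
                        scheme, classifier, bins, n_components,
                        keep_predictions=False,
                    )
                    rows.append({"center": c_strategy, "scale": s_strategy,
                                 "accuracy": res.accuracy,
                                 "sensitivity": res.sensitivity,
                                 "specificity": res.specificity,
                                 "error": ""})
                except (ConfigurationError, StratificationError) as exc:
                    rows.append({"center": c_strategy, "scale": s_strategy,
                                 "accuracy": float("nan"),
                                 "sensitivity": float("nan"),
                                 "specificity": float("nan"),
                                 "error": str(exc)})
    return pd.DataFrame(rows)
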