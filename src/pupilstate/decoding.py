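"""Decoding pupil traces from fMRI: PCA features, template / linear / GRU
decoders, cross-validation and the shift and component-count sweeps."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.linear_model import ElasticNet, Lasso

from pupilstate.corrmaps import SpatialMap, concatenated_map
from pupilstate.gru import GRUConfig, GRUDecoder, fit_gru
from pupilstate.synthetic import Trial

__all__ = [
    "PCABasis",
    "ComponentSeries",
    "LinearDecoder",
    "PredictionScore",
    "CrossvalResult",
    "fit_pca",
    "project",
    "template_predict",
    "fit_linear",
    "predict",
    "pearson",
    "crossval",
    "shift_sweep",
    "component_count_sweep",
    "compare_methods",
    "DEFAULT_RIDGE_ALPHA",
]

#: published winning regularization weight for the ridge variant
DEFAULT_RIDGE_ALPHA = 19861.0


@dataclass(frozen=True)
class PCABasis:
    """Orthogonal spatial components fitted on training trials only."""

    n_components: int
    components: np.ndarray  # (n_components, n_voxels)
    mean_map: np.ndarray  # (n_voxels,)
    explained_variance_ratio: np.ndarray


@dataclass
class ComponentSeries:
    """Per-component time courses, variance-normalized per trial.

    Constant components are flagged and zeroed rather than dropped.
    """

    scores: np.ndarray  # (n_components, T)
    constant_rows: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.constant_rows is None:
            self.constant_rows = np.zeros(self.scores.shape[0], dtype=bool)

    @property
    def n_components(self) -> int:
        return int(self.scores.shape[0])


@dataclass(frozen=True)
class LinearDecoder:
    variant: str
    alpha: float
    weights: np.ndarray
    intercept: float


@dataclass(frozen=True)
class PredictionScore:
    trial_id: str
    method: str
    split: str  # {"cv", "test"}
    r: float


@dataclass
class CrossvalResult:
    cv_scores: list[PredictionScore]
    test_scores: list[PredictionScore]

    def mean_cv(self) -> float:
        return float(np.mean([s.r for s in self.cv_scores]))

    def mean_test(self) -> float:
        return float(np.mean([s.r for s in self.test_scores]))


def pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def fit_pca(training_trials: Sequence[Trial], n_components: int = 300) -> PCABasis:
    """PCA of the time-concatenated training voxel matrix.

    Component signs are fixed so that the maximum-|loading| voxel of each
    component is positive, making maps and weights reproducible.
    """
    X = np.concatenate([t.fmri.T for t in training_trials], axis=0).astype(float)
    n_frames, n_voxels = X.shape
    if n_components > min(n_frames, n_voxels):
        raise ValueError(
            f"n_components={n_components} exceeds the data rank bound "
            f"{min(n_frames, n_voxels)}"
        )
    solver = "randomized" if n_components < 0.8 * min(n_frames, n_voxels) else "full"
    pca = PCA(n_components=n_components, svd_solver=solver, random_state=0)
    pca.fit(X)
    comps = pca.components_.copy()
    flip = comps[np.arange(n_components), np.argmax(np.abs(comps), axis=1)] < 0
    comps[flip] *= -1.0
    return PCABasis(
        n_components=n_components,
        components=comps,
        mean_map=pca.mean_,
        explained_variance_ratio=pca.explained_variance_ratio_,
    )


def project(trial: Trial, basis: PCABasis) -> ComponentSeries:
    """Component scores of a trial, variance-normalized per component."""
    if trial.fmri.shape[0] != basis.mean_map.shape[0]:
        raise ValueError("trial geometry does not match the PCA basis")
    scores = basis.components @ (trial.fmri.astype(float) - basis.mean_map[:, None])
    mean = scores.mean(axis=1, keepdims=True)
    sd = scores.std(axis=1, keepdims=True)
    # relative tolerance: float accumulation leaves ~1e-18 jitter on constants
    constant = sd[:, 0] <= 1e-12 * (np.abs(mean[:, 0]) + 1.0)
    sd[constant] = 1.0
    scores = (scores - mean) / sd
    scores[constant] = 0.0
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant component score row(s)")
    return ComponentSeries(scores=scores, constant_rows=constant)


def template_predict(template: SpatialMap, trial: Trial) -> np.ndarray:
    """Spatial correlation of the template with each fMRI volume.

    One value per time point, bounded to [-1, 1]; constant volumes give 0.
    """
    if template.values.shape[0] != trial.fmri.shape[0]:
        raise ValueError("template geometry does not match the trial")
    tv = template.values - template.values.mean()
    tn = np.linalg.norm(tv)
    if tn == 0:
        raise ValueError("constant template map")
    F = trial.fmri.astype(float)
    Fc = F - F.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(Fc, axis=0)
    constant = norms == 0
    norms[constant] = 1.0
    r = (tv @ Fc) / (tn * norms)
    r[constant] = 0.0
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant fMRI volume(s): value 0")
    return np.clip(r, -1.0, 1.0)


def fit_linear(
    X: np.ndarray,
    y: np.ndarray,
    variant: str = "ridge",
    alpha: float = DEFAULT_RIDGE_ALPHA,
) -> LinearDecoder:
    """Fit a linear decoder on features X (n_components, n_frames) and trace y.

    ``ols`` and ``ridge`` use the closed-form (normal equations) solution on
    centered data; ``lasso`` and ``elastic-net`` use coordinate descent.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[1] != y.shape[0]:
        raise ValueError(f"shape mismatch: X {X.shape} vs y {y.shape}")
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    x_mean = X.mean(axis=1)
    y_mean = y.mean()
    Xc = X - x_mean[:, None]
    yc = y - y_mean
    if variant == "ols":
        G = Xc @ Xc.T
        if np.linalg.matrix_rank(G) < G.shape[0]:
            raise np.linalg.LinAlgError(
                "singular OLS system; use the ridge variant instead"
            )
        w = np.linalg.solve(G, Xc @ yc)
        alpha = 0.0
    elif variant == "ridge":
        K = X.shape[0]
        w = np.linalg.solve(Xc @ Xc.T + alpha * np.eye(K), Xc @ yc)
    elif variant in ("lasso", "elastic-net"):
        cls = Lasso if variant == "lasso" else ElasticNet
        model = cls(alpha=alpha, fit_intercept=True, max_iter=50_000)
        model.fit(X.T, y)
        w = model.coef_
    else:
        raise ValueError(f"unknown variant {variant!r}")
    intercept = float(y_mean - w @ x_mean)
    return LinearDecoder(variant=variant, alpha=float(alpha), weights=w,
                         intercept=intercept)


def predict(decoder, X: ComponentSeries | np.ndarray) -> np.ndarray:
    """Deterministic forward pass of a fitted linear or GRU decoder."""
    scores = X.scores if isinstance(X, ComponentSeries) else np.asarray(X, dtype=float)
    if isinstance(decoder, LinearDecoder):
        if scores.shape[0] != decoder.weights.shape[0]:
            raise ValueError("component count mismatch")
        return decoder.weights @ scores + decoder.intercept
    if isinstance(decoder, GRUDecoder):
        return decoder.forward(scores)
    raise TypeError(f"unknown decoder type {type(decoder)!r}")


@dataclass
class ModelSpec:
    """What to fit inside cross-validation."""

    method: str = "ridge"  # {"template", "ols", "ridge", "lasso", "elastic-net", "gru"}
    n_components: int = 300
    alpha: float = DEFAULT_RIDGE_ALPHA
    gru_config: GRUConfig | None = None
    seed: int = 0


def _fit_and_score(
    train: Sequence[Trial],
    evaluate: Sequence[Trial],
    spec: ModelSpec,
    split: str,
) -> list[PredictionScore]:
    scores: list[PredictionScore] = []
    if spec.method == "template":
        template = concatenated_map(list(train))
        for t in evaluate:
            yhat = template_predict(template, t)
            scores.append(PredictionScore(t.subject_id, "template", split,
                                          pearson(yhat, t.pupil)))
        return scores
    basis = fit_pca(train, n_components=spec.n_components)
    series = [project(t, basis) for t in train]
    X = np.concatenate([s.scores for s in series], axis=1)
    y = np.concatenate([
        (t.pupil - t.pupil.mean()) / t.pupil.std() for t in train
    ])
    if spec.method == "gru":
        cfg = spec.gru_config or GRUConfig()
        dec = fit_gru([s.scores for s in series],
                      [(t.pupil - t.pupil.mean()) / t.pupil.std() for t in train],
                      config=cfg, seed=spec.seed)
    else:
        dec = fit_linear(X, y, variant=spec.method, alpha=spec.alpha)
    for t in evaluate:
        yhat = predict(dec, project(t, basis))
        scores.append(PredictionScore(t.subject_id, spec.method, split,
                                      pearson(yhat, t.pupil)))
    return scores


def _check_disjoint(a: Sequence[Trial], b: Sequence[Trial]) -> None:
    ids_a = {t.subject_id for t in a}
    ids_b = {t.subject_id for t in b}
    leak = ids_a & ids_b
    if leak:
        raise ValueError(f"trial leakage between train and eval: {sorted(leak)}")


def crossval(
    training_trials: Sequence[Trial],
    model_spec: ModelSpec | None = None,
    n_folds: int = 4,
    test_trials: Sequence[Trial] = (),
    seed: int = 0,
) -> CrossvalResult:
    """K-fold cross-validation on the training trials plus a held-out test score.

    Every fold refits the PCA basis (and the template map, for the baseline)
    on that fold's training trials only; the final model is fitted on all
    training trials and scored on the disjoint test set.
    """
    spec = model_spec or ModelSpec()
    training_trials = list(training_trials)
    test_trials = list(test_trials)
    _check_disjoint(training_trials, test_trials)
    n = len(training_trials)
    if n_folds < 2 or n_folds > n:
        raise ValueError("n_folds must be in [2, n_trials]")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, n_folds)
    cv_scores: list[PredictionScore] = []
    for fold in folds:
        val = [training_trials[i] for i in fold]
        train = [training_trials[i] for i in order if i not in set(fold)]
        _check_disjoint(train, val)
        cv_scores.extend(_fit_and_score(train, val, spec, "cv"))
    test_scores: list[PredictionScore] = []
    if test_trials:
        test_scores = _fit_and_score(training_trials, test_trials, spec, "test")
    return CrossvalResult(cv_scores=cv_scores, test_scores=test_scores)


def _shift_trial(trial: Trial, shift: int) -> Trial:
    """Advance the pupil by ``shift`` frames relative to the fMRI.

    Positive shift pairs fmri(t) with pupil(t + shift); overhang is trimmed
    on both series.
    """
    T = trial.n_frames
    if abs(shift) > T // 4:
        raise ValueError(f"|shift| {abs(shift)} exceeds T/4 = {T // 4}")
    if shift >= 0:
        fmri = trial.fmri[:, : T - shift] if shift else trial.fmri
        pupil = trial.pupil[shift:]
    else:
        fmri = trial.fmri[:, -shift:]
        pupil = trial.pupil[: T + shift]
    return Trial(subject_id=trial.subject_id, fmri=fmri, pupil=pupil,
                 tr=trial.tr, geometry=trial.geometry,
                 meta={**trial.meta, "shift": shift})


def shift_sweep(
    training_trials: Sequence[Trial],
    shifts: Sequence[int],
    model_spec: ModelSpec | None = None,
    n_folds: int = 4,
    seed: int = 0,
) -> dict[int, float]:
    """Mean cross-validation score as a function of pupil/fMRI frame offset."""
    out: dict[int, float] = {}
    for shift in shifts:
        shifted = [_shift_trial(t, int(shift)) for t in training_trials]
        res = crossval(shifted, model_spec, n_folds=n_folds, seed=seed)
        out[int(shift)] = res.mean_cv()
    return out


def component_count_sweep(
    training_trials: Sequence[Trial],
    counts: Sequence[int],
    model_spec: ModelSpec | None = None,
    n_folds: int = 4,
    seed: int = 0,
) -> dict[int, float]:
    """Mean cross-validation score as a function of PCA component count."""
    spec = model_spec or ModelSpec()
    out: dict[int, float] = {}
    for c in counts:
        s = ModelSpec(method=spec.method, n_components=int(c), alpha=spec.alpha,
                      gru_config=spec.gru_config, seed=spec.seed)
        out[int(c)] = crossval(training_trials, s, n_folds=n_folds, seed=seed).mean_cv()
    return out


def compare_methods(scores_a: Sequence[float], scores_b: Sequence[float]
                    ) -> tuple[float, float]:
    """Two-sided paired t-test on trial-paired prediction scores."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("score sets must be paired by trial")
    if a.shape[0] < 3:
        raise ValueError("need at least 3 pairs")
    d = a - b
    if d.std(ddof=1) <= 1e-12 * max(1.0, float(np.abs(d.mean()))):
        if np.allclose(d, 0.0, atol=1e-12):
            return 0.0, 1.0
        warnings.warn("degenerate comparison: constant nonzero difference")
        return math.copysign(math.inf, float(d.mean())), 0.0
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)
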