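"""Back-projection of decoders into voxel-wise pupil-information maps,
randomization significance with FDR, per-component variance attribution and
per-cluster maps."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from pupilstate.corrmaps import SpatialMap
from pupilstate.decoding import (
    DEFAULT_RIDGE_ALPHA,
    ComponentSeries,
    LinearDecoder,
    PCABasis,
    fit_linear,
    project,
)
from pupilstate.gru import GRUDecoder
from pupilstate.synthetic import BrainGeometry, Trial

__all__ = [
    "PredictionMap",
    "ExplainedVariance",
    "integrate_linear_map",
    "integrate_gru_map",
    "empirical_p",
    "randomization_significance",
    "fdr_correct",
    "explained_variance_by_component",
    "per_cluster_maps",
]


@dataclass
class PredictionMap:
    """Signed per-voxel pupil-information weights, optionally thresholded."""

    values: np.ndarray
    geometry: BrainGeometry | None
    source: str  # {"linear_weights", "gru_gradients"}
    significance_mask: np.ndarray | None = None
    p_values: np.ndarray | None = None
    meta: dict = field(default_factory=dict)


@dataclass(frozen=True)
class ExplainedVariance:
    """Per-component pupil EV (may be <= 0 under CV) and fMRI EV ratios."""

    pupil_ev: np.ndarray
    fmri_ev_ratio: np.ndarray


def _integrate(weights: np.ndarray, basis: PCABasis) -> np.ndarray:
    if weights.shape[0] != basis.n_components:
        raise ValueError(
            f"decoder has {weights.shape[0]} weights but the basis has "
            f"{basis.n_components} components"
        )
    return (weights @ basis.components) / basis.n_components


def integrate_linear_map(
    basis: PCABasis, decoder: LinearDecoder, geometry: BrainGeometry | None = None
) -> PredictionMap:
    """Mean over components of weight-scaled component maps:
    m(v) = (1/K) sum_k w_k C_k(v)."""
    return PredictionMap(
        values=_integrate(decoder.weights, basis),
        geometry=geometry,
        source="linear_weights",
    )


def integrate_gru_map(
    basis: PCABasis,
    decoder: GRUDecoder,
    series: Sequence[ComponentSeries | np.ndarray],
    geometry: BrainGeometry | None = None,
) -> PredictionMap:
    """Integrate mean input gradients of the GRU exactly like linear weights."""
    sens = np.zeros(basis.n_components)
    for s in series:
        X = s.scores if isinstance(s, ComponentSeries) else np.asarray(s, dtype=float)
        sens += decoder.input_sensitivity(X)
    sens /= len(series)
    return PredictionMap(
        values=_integrate(sens, basis),
        geometry=geometry,
        source="gru_gradients",
        meta={"mean_sensitivity": sens},
    )


def fdr_correct(p_values: np.ndarray, q: float = 0.01,
                method: str = "bh") -> np.ndarray:
    """Benjamini-Hochberg step-up (or Benjamini-Yekutieli with method='by').

    Returns a boolean mask, True where the adjusted p-value is <= q.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("p values must lie in [0, 1]")
    m = p.shape[0]
    if method == "by":
        q = q / np.sum(1.0 / np.arange(1, m + 1))
    elif method != "bh":
        raise ValueError(f"unknown FDR method {method!r}")
    order = np.argsort(p, kind="stable")
    thresholds = q * np.arange(1, m + 1) / m
    passing = p[order] <= thresholds
    mask = np.zeros(m, dtype=bool)
    if passing.any():
        cutoff = np.max(np.flatnonzero(passing))
        mask[order[: cutoff + 1]] = True
    return mask


def empirical_p(null: np.ndarray, observed: np.ndarray) -> np.ndarray:
    """Two-sided empirical p-values with the (b+1)/(n+1) correction.

    ``null`` has shape (n_perm, n_values); ``observed`` (n_values,).
    """
    null = np.atleast_2d(np.asarray(null, dtype=float))
    observed = np.atleast_1d(np.asarray(observed, dtype=float))
    n_perm = null.shape[0]
    ge = (null >= observed).sum(axis=0)
    le = (null <= observed).sum(axis=0)
    p = 2.0 * (np.minimum(ge, le) + 1.0) / (n_perm + 1.0)
    return np.minimum(p, 1.0)


def randomization_significance(
    series_list: Sequence[ComponentSeries],
    pupil_list: Sequence[np.ndarray],
    basis: PCABasis,
    ridge_alpha: float = DEFAULT_RIDGE_ALPHA,
    n_perm: int = 1000,
    alpha: float = 0.01,
    q: float = 0.01,
    seed: int = 0,
    geometry: BrainGeometry | None = None,
) -> tuple[SpatialMap, np.ndarray]:
    """Null maps from decoders fitted on permuted trial pairings.

    Whole pupil traces are reassigned across trials ``n_perm`` times; the
    ridge decoder is refitted (on a fixed, precomputed factorization) and a
    map built for each permutation.  A voxel is deemed extreme when the
    observed value lies at or beyond the null's alpha/2 or 1 - alpha/2
    quantile; two-sided empirical p-values use the (b+1)/(n+1) estimator and
    are then FDR-corrected at level ``q``.

    Returns (p-value map, final boolean significance mask).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    n_trials = len(series_list)
    if n_trials != len(pupil_list) or n_trials < 2:
        raise ValueError("need matched series and pupil lists with >= 2 trials")
    X = np.concatenate(
        [s.scores if isinstance(s, ComponentSeries) else np.asarray(s, dtype=float)
         for s in series_list], axis=1)
    pupils = [np.asarray(p, dtype=float) for p in pupil_list]
    pupils = [(p - p.mean()) / p.std() for p in pupils]
    y = np.concatenate(pupils)
    K = X.shape[0]
    x_mean = X.mean(axis=1)
    Xc = X - x_mean[:, None]
    factor = cho_factor(Xc @ Xc.T + ridge_alpha * np.eye(K))

    def ridge_map(target: np.ndarray) -> np.ndarray:
        w = cho_solve(factor, Xc @ (target - target.mean()))
        return _integrate(w, basis)

    observed = ridge_map(y)
    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, observed.shape[0]))
    for b in range(n_perm):
        perm = rng.permutation(n_trials)
        null[b] = ridge_map(np.concatenate([pupils[i] for i in perm]))
    p = empirical_p(null, observed)
    lo = np.quantile(null, alpha / 2.0, axis=0)
    hi = np.quantile(null, 1.0 - alpha / 2.0, axis=0)
    extreme = (observed <= lo) | (observed >= hi)
    mask = extreme & fdr_correct(p, q=q)
    p_map = SpatialMap(values=p, geometry=geometry, kind="pvalue",
                       meta={"n_perm": n_perm, "alpha": alpha, "q": q})
    return p_map, mask


def explained_variance_by_component(
    X: ComponentSeries | np.ndarray,
    y: np.ndarray,
    alpha: float = DEFAULT_RIDGE_ALPHA,
    n_folds: int = 4,
    seed: int = 0,
    basis: PCABasis | None = None,
) -> ExplainedVariance:
    """Unique pupil variance attributable to each component.

    For component k: shuffle the time indices of every *other* component
    (fresh permutations per fold), fit the ridge decoder on the training
    frames and measure out-of-fold explained variance of the pupil trace.
    fMRI-side ratios are taken from the basis when provided.
    """
    scores = X.scores if isinstance(X, ComponentSeries) else np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    K, T = scores.shape
    if K < 2:
        raise ValueError("need at least 2 components")
    if y.shape[0] != T:
        raise ValueError("y length must match the series")
    rng = np.random.default_rng(seed)
    fold_edges = np.linspace(0, T, n_folds + 1).astype(int)
    ev = np.empty(K)
    var_y = y.var()
    for k in range(K):
        resid = 0.0
        for f in range(n_folds):
            lo, hi = fold_edges[f], fold_edges[f + 1]
            val = np.zeros(T, dtype=bool)
            val[lo:hi] = True
            Xs = scores.copy()
            for j in range(K):
                if j != k:
                    Xs[j] = Xs[j][rng.permutation(T)]
            dec = fit_linear(Xs[:, ~val], y[~val], variant="ridge", alpha=alpha)
            yhat = dec.weights @ Xs[:, val] + dec.intercept
            resid += float(np.sum((y[val] - yhat) ** 2))
        ev[k] = 1.0 - (resid / T) / var_y
    fmri_ev = (basis.explained_variance_ratio if basis is not None
               else np.full(K, np.nan))
    return ExplainedVariance(pupil_ev=ev, fmri_ev_ratio=fmri_ev)


def per_cluster_maps(
    trials: Sequence[Trial],
    cluster_labels: np.ndarray,
    basis: PCABasis,
    ridge_alpha: float = DEFAULT_RIDGE_ALPHA,
    n_perm: int = 1000,
    alpha: float = 0.01,
    q: float = 0.01,
    seed: int = 0,
    min_trials: int = 3,
    significance: bool = True,
) -> dict[int, PredictionMap]:
    """Refit the linear decoder per cluster (shared basis) and build its map.

    Clusters with fewer than ``min_trials`` trials are skipped with a warning.
    """
    cluster_labels = np.asarray(cluster_labels)
    if cluster_labels.shape[0] != len(trials):
        raise ValueError("one label per trial required")
    geom = trials[0].geometry
    out: dict[int, PredictionMap] = {}
    for c in np.unique(cluster_labels):
        idx = np.flatnonzero(cluster_labels == c)
        if idx.shape[0] < min_trials:
            warnings.warn(
                f"cluster {c} has only {idx.shape[0]} trial(s); skipped"
            )
            continue
        sub = [trials[i] for i in idx]
        series = [project(t, basis) for t in sub]
        Xcat = np.concatenate([s.scores for s in series], axis=1)
        ycat = np.concatenate([
            (t.pupil - t.pupil.mean()) / t.pupil.std() for t in sub
        ])
        dec = fit_linear(Xcat, ycat, variant="ridge", alpha=ridge_alpha)
        pmap = integrate_linear_map(basis, dec, geometry=geom)
        pmap.meta.update({"cluster": int(c), "n_trials": int(idx.shape[0])})
        if significance:
            p_map, mask = randomization_significance(
                series, [t.pupil for t in sub], basis,
                ridge_alpha=ridge_alpha, n_perm=n_perm, alpha=alpha, q=q,
                seed=seed + int(c), geometry=geom,
            )
            pmap.p_values = p_map.values
            pmap.significance_mask = mask
        out[int(c)] = pmap
    return out
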