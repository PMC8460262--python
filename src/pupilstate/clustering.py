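"""Brain-state clustering of per-trial correlation maps.

Neighbor-graph (UMAP) or deterministic PCA embedding, Gaussian-mixture
clustering with silhouette model selection, consensus over repeated
initializations, and the reproducibility batteries (half-split, temporal
splitting, label-match metrics).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_samples
from sklearn.mixture import GaussianMixture

from pupilstate.corrmaps import SpatialMap
from pupilstate.synthetic import Trial

__all__ = [
    "Embedding",
    "ClusterResult",
    "ConsensusResult",
    "embed_maps",
    "fit_gmm",
    "silhouette_sweep",
    "SweepResult",
    "consensus_labels",
    "align_labels",
    "label_match_ratio",
    "half_split_reproducibility",
    "split_trials_temporally",
    "cluster_consensus",
]


@dataclass(frozen=True)
class Embedding:
    points: np.ndarray  # (n_trials, D)
    D: int
    method_params: dict

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.points)):
            raise ValueError("embedding contains non-finite coordinates")


@dataclass(frozen=True)
class ClusterResult:
    labels: np.ndarray
    k: int
    mean_silhouette: float
    per_trial_silhouette: np.ndarray


@dataclass(frozen=True)
class ConsensusResult:
    final_labels: np.ndarray
    stability: np.ndarray  # per-trial fraction of runs agreeing
    n_runs: int


def _maps_matrix(maps: Sequence[SpatialMap]) -> np.ndarray:
    return np.asarray([m.values for m in maps], dtype=float)


def embed_maps(
    maps: Sequence[SpatialMap],
    D: int | None = None,
    n_neighbors: int = 7,
    min_dist: float = 0.0,
    seed: int = 0,
    method: str = "umap",
) -> Embedding:
    """Reduce per-trial maps to D coordinates.

    ``method='umap'`` is the stochastic neighbor-graph embedding used for the
    protocol; ``method='pca'`` is a deterministic fallback for tests that
    demand bit-reproducibility.  D defaults to min(72, n_trials - 2) and may
    not exceed n_trials - 2.
    """
    X = _maps_matrix(maps)
    n = X.shape[0]
    if D is None:
        D = min(72, n - 2, X.shape[1])
    if D > n - 2:
        raise ValueError(f"D={D} exceeds the n_trials - 2 = {n - 2} bound")
    if method == "pca":
        d_eff = min(D, n - 1, X.shape[1])
        pca = PCA(n_components=d_eff, svd_solver="full")
        pts = pca.fit_transform(X)
        # deterministic sign convention
        signs = np.sign(pca.components_[np.arange(d_eff),
                                        np.argmax(np.abs(pca.components_), axis=1)])
        pts = pts * signs
        if d_eff < D:
            pts = np.pad(pts, ((0, 0), (0, D - d_eff)))
        return Embedding(points=pts, D=D, method_params={
            "method": "pca", "seed": seed})
    if method == "umap":
        if n_neighbors >= n:
            raise ValueError("n_neighbors must be < n_trials")
        import umap  # deferred: heavy import

        reducer = umap.UMAP(
            n_components=D,
            n_neighbors=n_neighbors,
            min_dist=min_dist,
            random_state=seed,
            init="random" if D > 2 else "spectral",
        )
        pts = reducer.fit_transform(X)
        return Embedding(points=np.asarray(pts, dtype=float), D=D, method_params={
            "method": "umap", "n_neighbors": n_neighbors,
            "min_dist": min_dist, "seed": seed})
    raise ValueError(f"unknown embedding method {method!r}")


def fit_gmm(emb: Embedding, k: int, seed: int = 0, max_retries: int = 5) -> ClusterResult:
    """EM-fitted full-covariance Gaussian mixture with hard max-posterior labels.

    Degenerate fits (empty hard cluster or failed EM) are retried with fresh
    seeds a bounded number of times.
    """
    n = emb.points.shape[0]
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n / 2:
        raise ValueError(f"k={k} exceeds n_trials/2 = {n / 2:g}")
    last_err: Exception | None = None
    for attempt in range(max_retries + 1):
        try:
            gmm = GaussianMixture(
                n_components=k, covariance_type="full", tol=1e-3, max_iter=100,
                n_init=1, random_state=seed + 7919 * attempt,
            )
            labels = gmm.fit_predict(emb.points)
        except Exception as err:  # pragma: no cover - sklearn numerical failure
            last_err = err
            continue
        if len(np.unique(labels)) == k:
            sil = silhouette_samples(emb.points, labels, metric="euclidean")
            return ClusterResult(
                labels=labels, k=k,
                mean_silhouette=float(sil.mean()),
                per_trial_silhouette=sil,
            )
        last_err = RuntimeError("GMM produced an empty hard cluster")
    raise RuntimeError(f"GMM failed after {max_retries} retries: {last_err}")


@dataclass(frozen=True)
class SweepResult:
    k_star: int
    table: pd.DataFrame  # columns: k, mean, sd
    runs: dict  # k -> list of per-repeat label arrays


def silhouette_sweep(
    maps: Sequence[SpatialMap],
    k_range: Sequence[int] = range(3, 8),
    n_repeats: int = 100,
    seed: int = 0,
    method: str = "umap",
    n_neighbors: int = 7,
    min_dist: float = 0.0,
    D: int | None = None,
) -> SweepResult:
    """Repeated embed+cluster runs per k; k* is the argmax mean silhouette."""
    rows = []
    runs: dict[int, list[np.ndarray]] = {int(k): [] for k in k_range}
    scores: dict[int, list[float]] = {int(k): [] for k in k_range}
    for rep in range(n_repeats):
        emb = embed_maps(
            maps, D=D, n_neighbors=n_neighbors, min_dist=min_dist,
            seed=seed + rep, method=method,
        )
        for k in k_range:
            res = fit_gmm(emb, int(k), seed=seed * 100003 + rep)
            runs[int(k)].append(res.labels)
            scores[int(k)].append(res.mean_silhouette)
    for k in k_range:
        arr = np.asarray(scores[int(k)])
        sd = float(arr.std(ddof=1)) if arr.shape[0] > 1 else 0.0
        rows.append({"k": int(k), "mean": float(arr.mean()), "sd": sd,
                     "sd_defined": arr.shape[0] > 1})
    table = pd.DataFrame(rows)
    k_star = int(table.loc[table["mean"].idxmax(), "k"])
    return SweepResult(k_star=k_star, table=table, runs=runs)


def _contingency(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ka = int(a.max()) + 1
    kb = int(b.max()) + 1
    size = max(ka, kb)
    table = np.zeros((size, size), dtype=int)
    np.add.at(table, (a, b), 1)
    return table


def align_labels(reference: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Relabel ``labels`` to maximize agreement with ``reference``.

    Optimal bipartite matching (Hungarian algorithm) on the contingency table.
    """
    reference = np.asarray(reference)
    labels = np.asarray(labels)
    table = _contingency(reference, labels)
    row, col = linear_sum_assignment(-table.T)  # rows: labels' clusters
    mapping = np.empty(table.shape[0], dtype=int)
    mapping[row] = col
    return mapping[labels]


def label_match_ratio(a: np.ndarray, b: np.ndarray) -> float:
    """Fraction of trials with equal labels after optimal alignment of b onto a."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("labelings must cover the same trials")
    return float(np.mean(align_labels(a, b) == a))


def consensus_labels(runs: Sequence[np.ndarray]) -> ConsensusResult:
    """Align runs to the first and take per-trial majority votes.

    Ties are broken toward the lowest aligned label index.  ``stability`` is
    the per-trial fraction of aligned runs agreeing with the final label.
    """
    if len(runs) < 1:
        raise ValueError("need at least one run")
    ks = {len(np.unique(r)) for r in runs}
    if len(ks) != 1:
        raise ValueError(f"inconsistent cluster counts across runs: {sorted(ks)}")
    ref = np.asarray(runs[0])
    aligned = np.stack([ref] + [align_labels(ref, np.asarray(r)) for r in runs[1:]])
    n_runs, n_trials = aligned.shape
    k = int(aligned.max()) + 1
    counts = np.zeros((n_trials, k), dtype=int)
    for run in aligned:
        np.add.at(counts, (np.arange(n_trials), run), 1)
    final = counts.argmax(axis=1)  # argmax takes the lowest index on ties
    stability = counts[np.arange(n_trials), final] / n_runs
    return ConsensusResult(final_labels=final, stability=stability, n_runs=n_runs)


def cluster_consensus(
    maps: Sequence[SpatialMap],
    k: int,
    n_runs: int = 100,
    seed: int = 0,
    method: str = "umap",
    **embed_kw,
) -> ConsensusResult:
    """The full protocol for a fixed k: n_runs embed+GMM runs, then consensus."""
    runs = []
    for rep in range(n_runs):
        emb = embed_maps(maps, seed=seed + rep, method=method, **embed_kw)
        runs.append(fit_gmm(emb, k, seed=seed * 100003 + rep).labels)
    return consensus_labels(runs)


def half_split_reproducibility(
    maps: Sequence[SpatialMap],
    k: int,
    reference_labels: np.ndarray | None = None,
    n_repeats: int = 100,
    n_runs_inner: int = 10,
    seed: int = 0,
    method: str = "pca",
    **embed_kw,
) -> dict[str, np.ndarray]:
    """Cluster random halves of the cohort and compare to the full-data labels.

    Returns per-repeat aligned label match ratios and mean cluster-map
    similarities (spatial correlation of aligned cluster-mean maps).
    """
    n = len(maps)
    if n < 8:
        raise ValueError("need at least 8 trials for half splits")
    if reference_labels is None:
        reference_labels = cluster_consensus(
            maps, k, n_runs=n_runs_inner, seed=seed, method=method, **embed_kw
        ).final_labels
    reference_labels = np.asarray(reference_labels)
    X = _maps_matrix(maps)
    rng = np.random.default_rng(seed)
    ratios = np.empty(n_repeats)
    map_sims = np.empty(n_repeats)
    for rep in range(n_repeats):
        half = np.sort(rng.permutation(n)[: n // 2])
        sub = [maps[i] for i in half]
        sub_labels = cluster_consensus(
            sub, k, n_runs=n_runs_inner, seed=seed + 1000 + rep,
            method=method, **embed_kw,
        ).final_labels
        ref_half = reference_labels[half]
        aligned = align_labels(ref_half, sub_labels)
        ratios[rep] = float(np.mean(aligned == ref_half))
        sims = []
        for c in range(k):
            in_ref = reference_labels == c
            in_sub = half[aligned == c]
            if in_ref.sum() and in_sub.size:
                a = X[in_ref].mean(axis=0)
                b = X[in_sub].mean(axis=0)
                if a.std() > 0 and b.std() > 0:
                    sims.append(float(np.corrcoef(a, b)[0, 1]))
        map_sims[rep] = float(np.mean(sims)) if sims else np.nan
    return {"match_ratio": ratios, "map_similarity": map_sims}


def split_trials_temporally(trials: Sequence[Trial], segment_s: float) -> list[Trial]:
    """Cut each trial into floor(T*tr/segment_s) segments; remainder dropped."""
    if segment_s < 60:
        raise ValueError("segment_s must be >= 60 s")
    out: list[Trial] = []
    for t in trials:
        duration = t.n_frames * t.tr
        n_seg = int(duration // segment_s)
        if n_seg < 1:
            raise ValueError(
                f"segment of {segment_s}s longer than trial ({duration}s)"
            )
        frames = int(segment_s / t.tr)
        for s in range(n_seg):
            sl = slice(s * frames, (s + 1) * frames)
            out.append(Trial(
                subject_id=f"{t.subject_id}-seg{s}",
                fmri=t.fmri[:, sl],
                pupil=t.pupil[sl],
                tr=t.tr,
                geometry=t.geometry,
                meta={**t.meta, "parent": t.subject_id, "segment": s},
            ))
    return out
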