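"""Voxel-wise pupil-fMRI correlation maps, map similarity, and
spatial-autocorrelation-matched surrogate maps."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from pupilstate.synthetic import BrainGeometry, Trial

__all__ = [
    "SpatialMap",
    "voxelwise_correlation",
    "concatenated_map",
    "spatial_similarity",
    "make_surrogates",
    "variogram",
]


@dataclass
class SpatialMap:
    """One real value per in-mask voxel."""

    values: np.ndarray
    geometry: BrainGeometry
    kind: str = "correlation"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.geometry is not None and self.values.shape[0] != self.geometry.n_voxels:
            raise ValueError(
                f"map has {self.values.shape[0]} values but geometry has "
                f"{self.geometry.n_voxels} voxels"
            )
        if self.kind == "correlation" and (
            np.any(self.values < -1 - 1e-12) or np.any(self.values > 1 + 1e-12)
        ):
            raise ValueError("correlation map values must lie in [-1, 1]")


def _standardize_rows(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center/scale rows to mean 0 sd 1; constant rows become 0 (flagged)."""
    mat = np.asarray(mat, dtype=float)
    mean = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, keepdims=True)
    constant = sd[:, 0] == 0
    sd[constant] = 1.0
    out = (mat - mean) / sd
    out[constant] = 0.0
    return out, constant


def voxelwise_correlation(
    fmri: np.ndarray, pupil: np.ndarray, geometry: BrainGeometry | None = None
) -> SpatialMap:
    """Pearson r of each voxel's time course with the pupil trace.

    Constant voxels (or a constant pupil) yield r = 0 and are counted in the
    map's ``meta['n_constant']`` summary.
    """
    fmri = np.asarray(fmri, dtype=float)
    pupil = np.asarray(pupil, dtype=float)
    if fmri.ndim != 2 or pupil.ndim != 1 or fmri.shape[1] != pupil.shape[0]:
        raise ValueError(
            f"shape mismatch: fmri {fmri.shape} vs pupil {pupil.shape}"
        )
    if pupil.shape[0] < 3:
        raise ValueError("need at least 3 time points")
    z_fmri, const_vox = _standardize_rows(fmri)
    psd = pupil.std()
    n_constant = int(const_vox.sum())
    if psd == 0:
        r = np.zeros(fmri.shape[0])
        n_constant = fmri.shape[0]
        warnings.warn("constant pupil trace: correlation map set to 0")
    else:
        zp = (pupil - pupil.mean()) / psd
        r = z_fmri @ zp / pupil.shape[0]
        r = np.clip(r, -1.0, 1.0)
        if n_constant:
            warnings.warn(f"{n_constant} constant voxel(s): r set to 0")
    return SpatialMap(
        values=r, geometry=geometry, kind="correlation",
        meta={"n_constant": n_constant},
    )


def concatenated_map(trials: Sequence[Trial]) -> SpatialMap:
    """Correlation map of per-trial-standardized signals concatenated in time."""
    if not trials:
        raise ValueError("need at least one trial")
    geom = trials[0].geometry
    for t in trials:
        if t.geometry is not geom and (
            t.geometry is None or t.geometry.n_voxels != geom.n_voxels
        ):
            raise ValueError("all trials must share the same geometry")
    z_fmri = []
    z_pupil = []
    for t in trials:
        zf, _ = _standardize_rows(t.fmri)
        z_fmri.append(zf)
        z_pupil.append((t.pupil - t.pupil.mean()) / t.pupil.std())
    return voxelwise_correlation(
        np.concatenate(z_fmri, axis=1), np.concatenate(z_pupil), geometry=geom
    )


def spatial_similarity(a: SpatialMap, b: SpatialMap) -> float:
    """Pearson correlation over in-mask voxels of two maps."""
    if a.values.shape != b.values.shape:
        raise ValueError("maps must share geometry")
    if a.values.std() == 0 or b.values.std() == 0:
        raise ValueError("constant map has no defined spatial similarity")
    return float(np.corrcoef(a.values, b.values)[0, 1])


def variogram(
    values: np.ndarray,
    coords: np.ndarray,
    n_bins: int = 25,
    max_pairs: int = 50_000,
    seed: int = 0,
    pairs: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Empirical variogram (Matheron estimator) on equal-count distance bins.

    A seeded random subsample of at most ``max_pairs`` voxel pairs is used;
    pass ``pairs`` to reuse a previous sample (for comparing maps on the very
    same pair set).  Returns (bin mean distances, bin semivariances, pairs).
    """
    n = values.shape[0]
    if pairs is None:
        rng = np.random.default_rng(seed)
        i = rng.integers(0, n, size=max_pairs)
        j = rng.integers(0, n, size=max_pairs)
        keep = i != j
        pairs = (i[keep], j[keep])
    i, j = pairs
    d = np.linalg.norm(coords[i] - coords[j], axis=1)
    gamma = 0.5 * (values[i] - values[j]) ** 2
    order = np.argsort(d, kind="stable")
    d, gamma = d[order], gamma[order]
    edges = np.linspace(0, d.shape[0], n_bins + 1).astype(int)
    bin_d = np.array([d[a:b].mean() for a, b in zip(edges[:-1], edges[1:])])
    bin_g = np.array([gamma[a:b].mean() for a, b in zip(edges[:-1], edges[1:])])
    return bin_d, bin_g, pairs


def _rank_remap(candidate: np.ndarray, sorted_target: np.ndarray) -> np.ndarray:
    out = np.empty_like(sorted_target)
    out[np.argsort(candidate, kind="stable")] = sorted_target
    return out


def _masked_smooth(
    flat: np.ndarray, geom: BrainGeometry, sigma: float
) -> np.ndarray:
    if sigma <= 0:
        return flat
    vol = geom.embed(flat)
    sm = gaussian_filter(vol, sigma)
    norm = gaussian_filter(geom.mask.astype(float), sigma)
    with np.errstate(invalid="ignore", divide="ignore"):
        vol = np.where(norm > 1e-12, sm / norm, 0.0)
    return geom.extract(vol)


def make_surrogates(
    smap: SpatialMap,
    n: int = 100,
    seed: int = 0,
    variogram_tol: float = 0.20,
    similarity_bound: float = 0.8,
    n_bins: int = 25,
    max_pairs: int = 50_000,
    sigma_grid: Sequence[float] | None = None,
    max_retries: int = 10,
) -> list[SpatialMap]:
    """Surrogate maps with the original value multiset and matched variogram.

    Each surrogate is built by permuting the map values, smoothing the
    permuted field with the Gaussian width that best matches the original's
    empirical variogram, and rank-remapping back to the exact original value
    multiset.  Surrogates whose variogram deviates more than
    ``variogram_tol`` (mean relative deviation over distance bins) or that
    resemble the original (|spatial r| >= ``similarity_bound``) are rejected
    and retried.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    geom = smap.geometry
    if geom is None or geom.n_voxels < 50:
        raise ValueError("map too small for variogram matching (< 50 voxels)")
    coords = geom.coords.astype(float)
    rng = np.random.default_rng(seed)
    _, target_g, pairs = variogram(
        smap.values, coords, n_bins=n_bins, max_pairs=max_pairs,
        seed=int(rng.integers(2**31)),
    )
    sorted_vals = np.sort(smap.values)
    if sigma_grid is None:
        sigma_grid = [0.0, 0.5, 0.75, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0]

    def deviation(vals: np.ndarray) -> float:
        _, g, _ = variogram(vals, coords, n_bins=n_bins, pairs=pairs)
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.abs(g - target_g) / np.where(target_g > 0, target_g, 1.0)
        return float(rel.mean())

    out: list[SpatialMap] = []
    for _ in range(n):
        best: tuple[float, np.ndarray] | None = None
        for attempt in range(max_retries):
            perm = smap.values[rng.permutation(geom.n_voxels)]
            for sigma in sigma_grid:
                cand = _rank_remap(_masked_smooth(perm, geom, sigma), sorted_vals)
                sim = abs(float(np.corrcoef(cand, smap.values)[0, 1]))
                if sim >= similarity_bound:
                    continue
                dev = deviation(cand)
                if best is None or dev < best[0]:
                    best = (dev, cand)
            if best is not None and best[0] <= variogram_tol:
                break
        if best is None:
            raise RuntimeError("could not build a dissimilar surrogate")
        if best[0] > variogram_tol:
            warnings.warn(
                f"surrogate accepted with variogram deviation {best[0]:.3f} "
                f"after {max_retries} retries"
            )
        out.append(
            SpatialMap(values=best[1], geometry=geom, kind="surrogate",
                       meta={"variogram_deviation": float(best[0])})
        )
    return out
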