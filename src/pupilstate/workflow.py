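"""Configuration, preprocessing and the end-to-end synthetic reproduction run."""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import signal
from sklearn.metrics import adjusted_rand_score

from pupilstate import clustering, corrmaps, decoding, io, maps, synthetic
from pupilstate.gru import GRUConfig
from pupilstate.synthetic import Trial

__all__ = ["PipelineConfig", "bandpass_fmri", "run_pipeline"]

log = logging.getLogger("pupilstate")


@dataclass
class PipelineConfig:
    """Every knob of the synthetic end-to-end run, with desk-scale defaults."""

    # generator
    shape: tuple[int, int, int] = (24, 24, 12)
    mask_rule: str = "ellipsoid"
    n_components_true: int = 6
    smoothness_fwhm: float = 2.0
    n_trials_per_state: tuple[int, ...] = (8, 30, 24, 12)
    n_frames: int = 925
    tr: float = 1.0
    noise_sd_fmri: float = 1.0
    noise_sd_pupil: float = 0.2
    sin_amplitude: float = 1.0
    pupil_lag_frames: int = 0
    # preprocessing
    bandpass_low_hz: float = 0.002
    bandpass_high_hz: float = 0.15
    apply_bandpass: bool = True
    # clustering
    embed_method: str = "pca"
    k_range: tuple[int, ...] = (3, 4, 5, 6, 7)
    n_cluster_repeats: int = 20
    n_neighbors: int = 7
    min_dist: float = 0.0
    run_half_split: bool = False
    n_half_split_repeats: int = 20
    # decoding
    n_test_trials: int = 10
    n_pca_components: int = 100
    ridge_alpha: float = decoding.DEFAULT_RIDGE_ALPHA
    n_folds: int = 4
    run_gru: bool = False
    gru_hidden_size: int = 64
    gru_epochs: int = 7
    # significance
    n_perm: int = 1000
    sig_alpha: float = 0.01
    fdr_q: float = 0.01
    run_cluster_maps: bool = True
    # bookkeeping
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self) -> None:
        nyq = 0.5 / self.tr
        if not (0 < self.bandpass_low_hz < self.bandpass_high_hz < nyq):
            raise ValueError(
                f"bandpass edges must satisfy 0 < low < high < Nyquist ({nyq} Hz)"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("shape", "n_trials_per_state", "k_range"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        d = dataclasses.asdict(self)
        for key in ("shape", "n_trials_per_state", "k_range"):
            d[key] = list(d[key])
        path.write_text(yaml.safe_dump(d, sort_keys=False))
        return path


def bandpass_fmri(trial: Trial, low: float = 0.002, high: float = 0.15) -> Trial:
    """Zero-phase 4th-order Butterworth band-pass of every voxel time course."""
    fs = 1.0 / trial.tr
    nyq = fs / 2.0
    if not (0 < low < high < nyq):
        raise ValueError(f"band ({low}, {high}) Hz must lie inside (0, {nyq}) Hz")
    sos = signal.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    filtered = signal.sosfiltfilt(sos, trial.fmri.astype(float), axis=1)
    return Trial(
        subject_id=trial.subject_id,
        fmri=filtered.astype(trial.fmri.dtype),
        pupil=trial.pupil,
        tr=trial.tr,
        geometry=trial.geometry,
        meta={**trial.meta, "bandpass_hz": (low, high)},
    )


def _stage(name: str):
    log.info("stage %s", name)
    return time.time()


def run_pipeline(config: PipelineConfig) -> dict:
    """Generate -> preprocess -> correlation maps -> clustering -> decoding ->
    maps + significance -> per-cluster maps; returns the aggregated report."""
    report: dict = {"config": dataclasses.asdict(config), "stages": {}}
    rng_seed = config.seed

    t0 = _stage("generate")
    geom = synthetic.generate_geometry(config.shape, config.mask_rule, seed=rng_seed)
    atlas = synthetic.generate_component_maps(
        geom, config.n_components_true, config.smoothness_fwhm, seed=rng_seed
    )
    profiles = synthetic.default_state_profiles(config.n_components_true)
    if len(config.n_trials_per_state) > len(profiles):
        raise ValueError("at most 4 planted states are supported")
    profiles = profiles[: len(config.n_trials_per_state)]
    trials, truth = synthetic.generate_cohort(
        geom, atlas, profiles, config.n_trials_per_state,
        T=config.n_frames, tr=config.tr,
        noise_sd_fmri=config.noise_sd_fmri, noise_sd_pupil=config.noise_sd_pupil,
        seed=rng_seed, sin_amplitude=config.sin_amplitude,
        pupil_lag_frames=config.pupil_lag_frames,
    )
    report["stages"]["generate"] = {
        "n_trials": len(trials), "n_voxels": geom.n_voxels,
        "seconds": time.time() - t0,
    }

    if config.apply_bandpass:
        t0 = _stage("preprocess")
        trials = [bandpass_fmri(t, config.bandpass_low_hz, config.bandpass_high_hz)
                  for t in trials]
        report["stages"]["preprocess"] = {"seconds": time.time() - t0}

    t0 = _stage("corrmaps")
    trial_maps = [corrmaps.voxelwise_correlation(t.fmri, t.pupil, geom)
                  for t in trials]
    all_map = corrmaps.concatenated_map(trials)
    similarities = [corrmaps.spatial_similarity(all_map, m) for m in trial_maps]
    report["stages"]["corrmaps"] = {
        "similarity_to_all_trial_map": similarities,
        "seconds": time.time() - t0,
    }

    t0 = _stage("cluster")
    n_states = len(config.n_trials_per_state)
    if n_states < 2:
        report["stages"]["cluster"] = {"degenerate": True,
                                       "reason": "fewer than 2 planted states"}
        consensus = None
        labels = np.zeros(len(trials), dtype=int)
    else:
        sweep = clustering.silhouette_sweep(
            trial_maps, k_range=config.k_range,
            n_repeats=config.n_cluster_repeats, seed=rng_seed,
            method=config.embed_method, n_neighbors=config.n_neighbors,
            min_dist=config.min_dist,
        )
        consensus = clustering.consensus_labels(sweep.runs[sweep.k_star])
        labels = consensus.final_labels
        ari = adjusted_rand_score(truth.state_labels, labels)
        report["stages"]["cluster"] = {
            "k_star": sweep.k_star,
            "silhouette_table": sweep.table.to_dict(orient="records"),
            "labels": labels.tolist(),
            "stability": consensus.stability.tolist(),
            "ari_vs_truth": float(ari),
            "seconds": time.time() - t0,
        }
        if config.run_half_split:
            hs = clustering.half_split_reproducibility(
                trial_maps, k=sweep.k_star, reference_labels=labels,
                n_repeats=config.n_half_split_repeats, seed=rng_seed,
                method=config.embed_method,
            )
            report["stages"]["cluster"]["half_split_match_ratio"] = \
                hs["match_ratio"].tolist()

    t0 = _stage("decode")
    rng = np.random.default_rng(rng_seed)
    order = rng.permutation(len(trials))
    test_idx = set(order[: config.n_test_trials].tolist())
    train = [t for i, t in enumerate(trials) if i not in test_idx]
    test = [t for i, t in enumerate(trials) if i in test_idx]
    decode_report = {}
    methods = ["template", "ridge"] + (["gru"] if config.run_gru else [])
    results = {}
    for method in methods:
        spec = decoding.ModelSpec(
            method=method, n_components=config.n_pca_components,
            alpha=config.ridge_alpha, seed=rng_seed,
            gru_config=GRUConfig(hidden_size=config.gru_hidden_size,
                                 epochs=config.gru_epochs,
                                 batch_size=min(12, len(train)))
            if method == "gru" else None,
        )
        res = decoding.crossval(train, spec, n_folds=config.n_folds,
                                test_trials=test, seed=rng_seed)
        results[method] = res
        decode_report[method] = {
            "mean_cv": res.mean_cv(),
            "mean_test": res.mean_test() if test else None,
            "cv_scores": [(s.trial_id, s.r) for s in res.cv_scores],
            "test_scores": [(s.trial_id, s.r) for s in res.test_scores],
        }
    if "ridge" in results and "template" in results:
        a = sorted(results["ridge"].cv_scores, key=lambda s: s.trial_id)
        b = sorted(results["template"].cv_scores, key=lambda s: s.trial_id)
        t, p = decoding.compare_methods([s.r for s in a], [s.r for s in b])
        decode_report["ridge_vs_template"] = {"t": t, "p": p}
    decode_report["seconds"] = time.time() - t0
    report["stages"]["decode"] = decode_report

    t0 = _stage("maps")
    basis = decoding.fit_pca(train, n_components=config.n_pca_components)
    series = [decoding.project(t, basis) for t in train]
    Xcat = np.concatenate([s.scores for s in series], axis=1)
    ycat = np.concatenate([(t.pupil - t.pupil.mean()) / t.pupil.std()
                           for t in train])
    ridge = decoding.fit_linear(Xcat, ycat, variant="ridge",
                                alpha=config.ridge_alpha)
    linear_map = maps.integrate_linear_map(basis, ridge, geometry=geom)
    p_map, sig_mask = maps.randomization_significance(
        series, [t.pupil for t in train], basis,
        ridge_alpha=config.ridge_alpha, n_perm=config.n_perm,
        alpha=config.sig_alpha, q=config.fdr_q, seed=rng_seed, geometry=geom,
    )
    ev = maps.explained_variance_by_component(
        decoding.ComponentSeries(scores=Xcat), ycat,
        alpha=config.ridge_alpha, n_folds=config.n_folds, seed=rng_seed,
        basis=basis,
    )
    report["stages"]["maps"] = {
        "n_significant_voxels": int(sig_mask.sum()),
        "pupil_ev_top5": np.sort(ev.pupil_ev)[::-1][:5].tolist(),
        "fmri_ev_top5": np.sort(ev.fmri_ev_ratio)[::-1][:5].tolist(),
        "seconds": time.time() - t0,
    }

    if config.run_cluster_maps and consensus is not None:
        t0 = _stage("cluster_maps")
        train_ids = [t.meta["trial_index"] for t in train]
        cluster_maps = maps.per_cluster_maps(
            train, labels[train_ids], basis,
            ridge_alpha=config.ridge_alpha, n_perm=config.n_perm,
            alpha=config.sig_alpha, q=config.fdr_q, seed=rng_seed,
        )
        cm_report = {}
        for c, pmap in cluster_maps.items():
            entry = {"n_trials": pmap.meta["n_trials"],
                     "n_significant": int(pmap.significance_mask.sum())
                     if pmap.significance_mask is not None else None}
            # recovery metric: which planted state does this map resemble most
            sims = {int(p.state_id): float(np.corrcoef(
                pmap.values, truth.state_map(p.state_id))[0, 1])
                for p in truth.profiles}
            entry["similarity_to_state_maps"] = sims
            cm_report[int(c)] = entry
        cm_report["seconds"] = time.time() - t0
        report["stages"]["cluster_maps"] = cm_report

    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        io.save_json(report, out / "report.json")
        io.save_map_csv(all_map, out / "all_trial_correlation_map.csv")
        io.save_map_nifti(all_map, out / "all_trial_correlation_map.nii.gz")
        io.save_map_csv(linear_map_as_spatial(linear_map), out / "prediction_map.csv")
        if consensus is not None:
            io.save_labels_csv(
                [t.subject_id for t in trials], labels, consensus.stability,
                out / "cluster_labels.csv",
            )
    return report


def linear_map_as_spatial(pmap: maps.PredictionMap) -> corrmaps.SpatialMap:
    return corrmaps.SpatialMap(values=pmap.values, geometry=pmap.geometry,
                               kind="prediction")


def io_roundtrip(objects: dict, directory: str | Path) -> dict:
    """Write every supported object type and read it back (identity check)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = {}
    for name, obj in objects.items():
        if isinstance(obj, corrmaps.SpatialMap):
            path = io.save_map_csv(obj, directory / f"{name}.csv")
            out[name] = io.load_map_csv(path, geometry=obj.geometry, kind=obj.kind)
        elif isinstance(obj, Trial):
            path = io.save_trial_bundle(obj, directory / f"{name}.npz")
            out[name] = io.load_trial_bundle(path)
        elif isinstance(obj, dict):
            path = io.save_json(obj, directory / f"{name}.json")
            out[name] = io.load_json(path)
        else:
            raise TypeError(f"unsupported round-trip type {type(obj)!r}")
    return out
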